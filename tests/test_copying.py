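"""Copying-model HMM: oracle equivalence, limits, EM, aggregation."""

import numpy as np
import pytest

import paintpop as pp
from paintpop.copying import CopyParams, expected_copying, forward_backward

from helpers import enumerate_copying_loglik


def random_instance(rng, max_donors=3, max_sites=6):
    k = int(rng.integers(1, max_donors + 1))
    S = int(rng.integers(2, max_sites + 1))
    donors = rng.integers(0, 2, size=(k, S)).astype(np.int8)
    h = rng.integers(0, 2, size=S).astype(np.int8)
    regions = np.sort(rng.integers(0, rng.integers(1, 3), size=S))
    intervals = rng.uniform(1e-4, 0.5, size=S)
    params = CopyParams(
        rho=float(rng.uniform(0.05, 30)), mu=float(rng.uniform(0.001, 0.45)),
        ne_scale=float(rng.uniform(0.3, 4)),
    )
    return h, donors, intervals, regions, params


class TestForwardBackwardOracle:
    def test_loglik_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12345)
        for _ in range(60):
            h, donors, intervals, regions, params = random_instance(rng)
            fb = forward_backward(h, donors, params, intervals, regions)
            oracle = enumerate_copying_loglik(
                h, donors, intervals, regions,
                params.rho * params.ne_scale, params.mu,
            )
            assert fb.loglik == pytest.approx(oracle, rel=1e-9)
            assert np.allclose(fb.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_single_donor_posterior_is_one(self):
        h = np.array([0, 1, 1, 0], dtype=np.int8)
        donors = np.array([[0, 0, 1, 0]], dtype=np.int8)
        fb = forward_backward(h, donors, CopyParams(rho=5, mu=0.1),
                              np.full(4, 0.01), np.zeros(4, dtype=int))
        assert np.allclose(fb.posteriors, 1.0)
        occ, chunks = expected_copying(fb)
        assert occ[0] == pytest.approx(1.0)
        assert chunks[0] == pytest.approx(1.0)  # one region, one chunk

    def test_zero_switch_rate_gives_constant_posterior(self):
        rng = np.random.default_rng(7)
        donors = rng.integers(0, 2, size=(3, 5)).astype(np.int8)
        h = rng.integers(0, 2, size=5).astype(np.int8)
        params = CopyParams(rho=0.0, mu=0.1)
        fb = forward_backward(h, donors, params, np.full(5, 0.02),
                              np.zeros(5, dtype=int))
        assert np.allclose(fb.posteriors, fb.posteriors[0][None, :],
                           atol=1e-12)
        # equals the per-donor emission product, normalised
        mu = params.mu
        prod = np.array([
            np.prod(np.where(donors[d] == h, 1 - mu, mu))
            for d in range(3)
        ])
        assert np.allclose(fb.posteriors[0], prod / prod.sum(), atol=1e-12)

    def test_high_switch_uninformative_limit_chunk_count(self):
        # with mu = 0.5 and effectively independent sites, expected chunks
        # per region approach 1 + (S-1) * (k-1) / k and occupancy 1/k
        k, S = 3, 5
        donors = np.zeros((k, S), dtype=np.int8)
        h = np.zeros(S, dtype=np.int8)
        params = CopyParams(rho=1e8, mu=0.5)
        fb = forward_backward(h, donors, params, np.full(S, 0.01),
                              np.zeros(S, dtype=int))
        occ, chunks = expected_copying(fb)
        assert np.allclose(occ, 1 / k, atol=1e-9)
        expect = (1 + (S - 1) * (k - 1) / k) / k  # shared evenly by donors
        assert np.allclose(chunks, expect, atol=1e-6)

    def test_empty_donor_set_and_negative_map_rejected(self):
        h = np.zeros(3, dtype=np.int8)
        with pytest.raises(ValueError):
            forward_backward(h, np.zeros((0, 3), dtype=np.int8), CopyParams(),
                             np.zeros(3), np.zeros(3, dtype=int))
        with pytest.raises(ValueError, match="negative"):
            forward_backward(h, np.zeros((2, 3), dtype=np.int8), CopyParams(),
                             np.array([0.0, -0.1, 0.1]),
                             np.zeros(3, dtype=int))


class TestEmFit:
    def test_loglik_trace_monotone_and_rows_normalised(self, tiny_panel):
        res = pp.em_fit(tiny_panel, CopyParams(rho=200, mu=0.1,
                                               n_em_iters=25))
        trace = np.array(res.loglik_trace)
        assert len(trace) == 25
        assert np.all(np.diff(trace) >= -1e-6)
        assert np.allclose(res.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_same_individual_exclusion_is_exact(self, tiny_panel):
        res = pp.em_fit(tiny_panel, CopyParams(n_em_iters=3))
        for i in range(tiny_panel.n_individuals):
            block = res.occupancy[2 * i:2 * i + 2, 2 * i:2 * i + 2]
            assert np.all(block == 0.0)

    def test_without_exclusion_partner_haplotype_copies(self, tiny_panel):
        res = pp.em_fit(tiny_panel, CopyParams(n_em_iters=3),
                        exclude_same_individual=False)
        partner = [res.occupancy[2 * i, 2 * i + 1]
                   for i in range(tiny_panel.n_individuals)]
        assert max(partner) > 0.0
        assert np.all(np.diag(res.occupancy) == 0.0)

    def test_single_individual_with_exclusion_raises(self, tiny_panel):
        solo = tiny_panel.subset_individuals(tiny_panel.individuals[:1])
        with pytest.raises(ValueError):
            pp.em_fit(solo, CopyParams(n_em_iters=1))


class TestAggregation:
    def test_single_population_matrix_is_identity(self, tiny_panel):
        labels = {ind: "only" for ind in tiny_panel.individuals}
        res = pp.em_fit(tiny_panel, CopyParams(n_em_iters=2))
        agg = pp.aggregate_by_population(res, labels)
        assert agg.matrix.shape == (1, 1)
        assert agg.matrix.iloc[0, 0] == pytest.approx(1.0)

    def test_rows_sum_to_one(self, small_dataset):
        res = pp.em_fit(small_dataset.haplotypes, CopyParams(n_em_iters=4))
        agg = pp.aggregate_by_population(res, small_dataset.true_labels,
                                         exclude_donor_pops=("hybrid",))
        assert np.allclose(agg.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(agg.by_individual.sum(axis=1), 1.0, atol=1e-9)

    def test_unlabelled_donor_raises(self, tiny_panel):
        res = pp.em_fit(tiny_panel, CopyParams(n_em_iters=1))
        labels = {ind: "only" for ind in tiny_panel.individuals[:-1]}
        with pytest.raises(KeyError):
            pp.aggregate_by_population(res, labels)


class TestFragmentSampling:
    def test_probabilities_normalised_and_deterministic(self, tiny_panel):
        labels = {ind: ("A" if i % 2 else "B")
                  for i, ind in enumerate(tiny_panel.individuals)}
        res = pp.em_fit(tiny_panel, CopyParams(n_em_iters=4))
        a = pp.sample_fragment_assignments(res, labels, n_samples=20, seed=9)
        b = pp.sample_fragment_assignments(res, labels, n_samples=20, seed=9)
        assert a.equals(b)
        sums = a.groupby(["haplotype", "region"])["probability"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_converges_to_marginal_posterior_population_mass(self,
                                                             tiny_panel):
        labels = {ind: ("A" if i % 2 else "B")
                  for i, ind in enumerate(tiny_panel.individuals)}
        res = pp.em_fit(tiny_panel, CopyParams(n_em_iters=4))
        n = 3000
        frag = pp.sample_fragment_assignments(res, labels, n_samples=n,
                                              seed=1)
        # exact marginal: mean posterior population mass per region
        panel = res.panel
        pops = list(dict.fromkeys(labels[i] for i in panel.individuals))
        checked = 0
        for r in range(panel.n_haplotypes):
            keep = np.array([d for d in range(panel.n_haplotypes)
                             if d not in res.donor_exclusions[r]])
            fb = forward_backward(
                panel.haplotypes[r], panel.haplotypes[keep], res.params,
                panel.intervals, panel.region_ids,
            )
            pop_of = np.array([
                pops.index(labels[panel.individual_of_haplotype(d)])
                for d in keep
            ])
            hap_name = panel.haplotype_names()[r]
            for region, sl in panel.region_slices().items():
                for p, pop in enumerate(pops):
                    exact = fb.posteriors[sl][:, pop_of == p].sum(1).mean()
                    emp = frag[
                        (frag["haplotype"] == hap_name)
                        & (frag["region"] == region)
                        & (frag["population"] == pop)
                    ]["probability"].iloc[0]
                    se = np.sqrt(max(exact * (1 - exact), 1e-4) / n)
                    assert abs(emp - exact) <= 4 * se + 1e-3
                    checked += 1
            if r >= 3:
                break
        assert checked > 0

    def test_zero_samples_rejected(self, tiny_panel):
        res = pp.em_fit(tiny_panel, CopyParams(n_em_iters=1))
        labels = {ind: "A" for ind in tiny_panel.individuals}
        with pytest.raises(ValueError):
            pp.sample_fragment_assignments(res, labels, n_samples=0)


class TestNeGridSearch:
    def test_singleton_grid_returns_value(self, tiny_panel):
        best, lls = pp.ne_grid_search(tiny_panel, [2.5],
                                      CopyParams(n_em_iters=2))
        assert best == 2.5
        assert len(lls) == 1

    def test_returned_value_attains_maximum(self, tiny_panel):
        best, lls = pp.ne_grid_search(tiny_panel, [0.1, 1.0, 10.0],
                                      CopyParams(n_em_iters=3))
        assert best == lls.loc[lls["loglik"].idxmax(), "ne_scale"]

    def test_empty_grid_rejected(self, tiny_panel):
        with pytest.raises(ValueError):
            pp.ne_grid_search(tiny_panel, [])
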