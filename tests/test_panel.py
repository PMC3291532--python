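"""SNP panel selection: splits, single-SNP assignment, ranking, evaluation."""

import numpy as np
import pytest

import paintpop as pp
from paintpop.containers import GenotypeTable, make_sites
from paintpop.panel import UNASSIGNED


class TestSplitTrainTest:
    def test_half_split_with_odd_populations_rounds_up_to_training(self):
        # 52 non-hybrids in populations of 7, 13 and 32 -> train 4+7+16 = 27
        labels = {}
        for pop, n in (("A", 7), ("B", 13), ("C", 32)):
            for i in range(n):
                labels[f"{pop}{i:02d}"] = pop
        train, test = pp.split_train_test(labels, seed=5)
        assert len(train) == 27
        assert len(test) == 25
        assert set(train) | set(test) == set(labels)
        assert set(train) & set(test) == set()

    def test_hybrids_excluded_and_split_deterministic(self):
        labels = {f"s{i}": ("A" if i < 6 else "B") for i in range(12)}
        labels["h1"] = "A"
        flags = {s: False for s in labels}
        flags["h1"] = True
        a = pp.split_train_test(labels, flags, seed=3)
        b = pp.split_train_test(labels, flags, seed=3)
        assert a == b
        assert "h1" not in a[0] + a[1]

    def test_population_too_small_rejected(self):
        with pytest.raises(ValueError):
            pp.split_train_test({"x": "A", "y": "B", "z": "B"})


class TestSingleSnpAssign:
    def test_fixed_difference(self):
        assert pp.single_snp_assign(2, {"A": 1.0, "B": 0.0}) == "A"
        assert pp.single_snp_assign(0, {"A": 1.0, "B": 0.0}) == "B"

    def test_hand_computed_heterozygote_case(self):
        # P(g=1 | f) = 2 f (1-f): A -> 0.42, B -> 0.48
        assert pp.single_snp_assign(1, {"A": 0.3, "B": 0.6}) == "B"

    def test_tie_and_missing_are_unassigned(self):
        assert pp.single_snp_assign(1, {"A": 0.4, "B": 0.4}) == UNASSIGNED
        assert pp.single_snp_assign(pp.MISSING, {"A": 0.1, "B": 0.9}) == \
            UNASSIGNED


def _planted_table():
    """Six samples, two populations, with planted perfect markers.

    Sites 0 and 1 (regions r1, r2) are fixed differences; site 2 shares r1
    and is also perfect; site 3 (r3) is uninformative.
    """
    calls = np.array([
        [0, 0, 0, 1],
        [0, 0, 0, 1],
        [0, 0, 0, 1],
        [2, 2, 2, 1],
        [2, 2, 2, 1],
        [2, 2, 2, 1],
    ], dtype=np.int8)
    sites = make_sites(["r1", "r2", "r1", "r3"], [10, 10, 20, 10])
    # keep site order valid: r1 twice -> positions increasing handled below
    samples = [f"s{i}" for i in range(6)]
    labels = {s: ("A" if i < 3 else "B") for i, s in enumerate(samples)}
    return GenotypeTable(samples=samples, sites=sites, calls=calls,
                         labels=labels), labels


class TestRankAndSelect:
    def test_perfect_markers_rank_first_with_distinct_loci(self):
        table, labels = _planted_table()
        train = list(table.samples)
        panel = pp.rank_and_select(table, labels, train, 2)
        assert list(panel.table["train_accuracy"]) == [1.0, 1.0]
        assert set(panel.table["region"]) == {"r1", "r2"}
        assert panel.train_accuracy == 1.0

    def test_same_region_duplicate_skipped(self):
        table, labels = _planted_table()
        train = list(table.samples)
        panel = pp.rank_and_select(table, labels, train, 3)
        assert list(panel.table["region"]) == ["r1", "r2", "r3"]

    def test_rank_one_accuracy_dominates(self, small_dataset):
        labels = small_dataset.true_labels
        train, _ = pp.split_train_test(labels, small_dataset.hybrid_flags,
                                       seed=1)
        panel = pp.rank_and_select(small_dataset.genotypes, labels, train, 5)
        acc = panel.table["train_accuracy"].to_numpy()
        assert (acc[0] >= acc[1:]).all()

    def test_panel_larger_than_region_count_rejected(self):
        table, labels = _planted_table()
        with pytest.raises(ValueError):
            pp.rank_and_select(table, labels, list(table.samples), 4)


class TestEvaluatePanel:
    def test_fixed_difference_panel_classifies_perfectly(self):
        table, labels = _planted_table()
        train = ["s0", "s1", "s3", "s4"]
        test = ["s2", "s5"]
        panel = pp.rank_and_select(table, labels, train, 2)
        acc, report = pp.evaluate_panel(panel, table, labels, test)
        assert acc == 1.0
        assert report["correct"].all()

    def test_single_snp_panel_matches_single_snp_assign(self):
        table, labels = _planted_table()
        train = ["s0", "s1", "s3", "s4"]
        test = ["s2", "s5"]
        panel = pp.rank_and_select(table, labels, train, 1)
        acc, report = pp.evaluate_panel(panel, table, labels, test)
        j = panel.site_index[0]
        freqs = panel.training_freqs.iloc[0].to_dict()
        for _, row in report.iterrows():
            i = table.samples.index(row["sample"])
            assert row["assigned"] == pp.single_snp_assign(
                int(table.calls[i, j]), freqs
            )

    def test_hand_worked_two_snp_product(self):
        # two SNPs, two populations, three test samples; frequencies fixed
        # by a training set constructed to give f_A = (0.75, 0.25) and
        # f_B = (0.25, 0.75) before flooring (floor 1/5 keeps them)
        calls = np.array([
            [2, 1],   # train A
            [1, 0],   # train A
            [0, 1],   # train B
            [1, 2],   # train B
            [2, 0],   # test: strongly A
            [0, 2],   # test: strongly B
            [1, 1],   # test: tie -> unassigned
        ], dtype=np.int8)
        sites = make_sites(["r1", "r2"], [10, 10])
        samples = [f"s{i}" for i in range(7)]
        labels = {s: p for s, p in zip(
            samples, ["A", "A", "B", "B", "A", "B", "A"]
        )}
        table = GenotypeTable(samples=samples, sites=sites, calls=calls,
                              labels=labels)
        panel = pp.rank_and_select(table, labels, samples[:4], 2)
        fa = panel.training_freqs.to_numpy()[:, list(
            panel.training_freqs.columns).index("A")]
        fb = panel.training_freqs.to_numpy()[:, list(
            panel.training_freqs.columns).index("B")]
        assert np.allclose(sorted(fa), [0.25, 0.75])
        assert np.allclose(sorted(fb), [0.25, 0.75])
        acc, report = pp.evaluate_panel(panel, table, labels,
                                        ["s4", "s5", "s6"])
        by_sample = dict(zip(report["sample"], report["assigned"]))
        assert by_sample["s4"] == "A"
        assert by_sample["s5"] == "B"
        assert by_sample["s6"] == UNASSIGNED

    def test_leakage_guard(self):
        table, labels = _planted_table()
        train = ["s0", "s1", "s3", "s4"]
        panel = pp.rank_and_select(table, labels, train, 1)
        with pytest.raises(ValueError, match="training"):
            pp.evaluate_panel(panel, table, labels, ["s0", "s5"])


class TestFrequencyDifferentials:
    def test_fixed_difference_is_one(self):
        table, labels = _planted_table()
        out = pp.frequency_differentials(table, labels)
        assert out["max_pairwise_diff"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_three_population_case(self):
        # equal sizes, frequencies 0.1 / 0.9 / 0.5 at one site
        calls = np.concatenate([
            np.tile([0, 0, 0, 0, 1], 1),   # pop A: f = 0.1
            np.tile([2, 2, 2, 2, 1], 1),   # pop B: f = 0.9
            np.tile([1, 1, 1, 1, 1], 1),   # pop C: f = 0.5
        ]).reshape(15, 1).astype(np.int8)
        sites = make_sites(["r1"], [10])
        samples = [f"s{i}" for i in range(15)]
        labels = {s: ("A" if i < 5 else "B" if i < 10 else "C")
                  for i, s in enumerate(samples)}
        table = GenotypeTable(samples=samples, sites=sites, calls=calls,
                              labels=labels)
        out = pp.frequency_differentials(table, labels)
        assert out["max_pairwise_diff"].iloc[0] == pytest.approx(0.8)
        assert out["diff_B_vs_rest"].iloc[0] == pytest.approx(
            abs(0.9 - 0.3)
        )

    def test_label_permutation_permutes_differentials(self):
        table, labels = _planted_table()
        out = pp.frequency_differentials(table, labels)
        swapped = {s: ("B" if p == "A" else "A") for s, p in labels.items()}
        out2 = pp.frequency_differentials(table, swapped)
        assert np.allclose(
            sorted(out["max_pairwise_diff"]), sorted(out2["max_pairwise_diff"])
        )

    def test_single_population_rejected(self):
        table, labels = _planted_table()
        mono = {s: "A" for s in labels}
        with pytest.raises(ValueError):
            pp.frequency_differentials(table, mono)
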