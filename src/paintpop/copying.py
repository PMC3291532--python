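"""Li-Stephens haplotype copying model: painting, EM fitting, aggregation.

Each recipient haplotype is modelled as an imperfect mosaic of the donor
haplotypes.  The hidden state of the HMM is the donor being copied; over an
interval of ``g`` Morgans the chain stays with its donor with probability
``exp(-rho_eff * g)`` and otherwise re-chooses uniformly among all ``k``
donors (so the same donor can be re-chosen), where
``rho_eff = rho * ne_scale`` — ``rho`` is the switch-rate scale fitted by EM
and ``ne_scale`` the fixed map multiplier chosen by grid search (the
"effective population size" scaling).  Emission is ``1 - mu`` on an allele
match and ``mu`` on a mismatch.  Regions are unlinked and treated as
independent chains, each starting from the uniform donor distribution.

The forward recursion is scaled per site; the log-likelihood accumulates the
scaling constants, so underflow cannot occur regardless of panel size.  EM
updates the two global scalars only: ``rho`` from the expected number of
re-choice events per interval (a one-dimensional M-step solved numerically)
and ``mu`` from the expected mismatch copy mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import HaplotypePanel

__all__ = [
    "CopyParams",
    "FBResult",
    "CopyingResult",
    "PopulationCopyMatrix",
    "forward_backward",
    "expected_copying",
    "em_fit",
    "aggregate_by_population",
    "sample_fragment_assignments",
    "ne_grid_search",
]


@dataclass
class CopyParams:
    """Global copying-model parameters.

    ``rho`` — switch-rate scale per Morgan (EM-fitted);
    ``mu`` — per-site miscopy probability (EM-fitted);
    ``ne_scale`` — fixed multiplier applied to map distances;
    ``n_em_iters`` — number of EM iterations to run.
    """

    rho: float = 100.0
    mu: float = 0.01
    ne_scale: float = 1.0
    n_em_iters: int = 100

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if not 0.0 <= self.mu <= 0.5:
            raise ValueError("mu must lie in [0, 0.5]")
        if self.ne_scale <= 0:
            raise ValueError("ne_scale must be positive")
        if self.n_em_iters < 1:
            raise ValueError("need at least one EM iteration")


@dataclass
class FBResult:
    """Forward-backward output for one recipient haplotype.

    ``posteriors`` is sites x donors; expectation fields are the sufficient
    statistics the EM M-step consumes.  ``switches_into`` counts expected
    donor-to-donor transitions that land on each donor coming from a
    different one; together with the per-region initial posterior it yields
    expected chunk counts.
    """

    posteriors: np.ndarray
    loglik: float
    expected_jumps: np.ndarray      # per interior interval, region-concatenated
    interval_lengths: np.ndarray    # matching map distances (Morgans)
    switches_into: np.ndarray       # (k,) summed over intervals
    initial_posterior: np.ndarray   # (n_regions, k)
    mismatch_mass: float
    n_sites: int


def _fb_single_region(h: np.ndarray, donors: np.ndarray, g: np.ndarray,
                      rho_eff: float, mu: float):
    """Scaled forward-backward for one region.

    Returns (posteriors S x k, loglik, jump expectations per interval,
    switches-into per donor, initial posterior).
    """
    k, S = donors.shape
    em = np.where(donors == h[None, :], 1.0 - mu, mu)  # (k, S)
    stay = np.exp(-rho_eff * np.asarray(g, dtype=float))  # (S-1,)

    f = np.empty((S, k))
    c = np.empty(S)
    a = em[:, 0] / k
    c[0] = a.sum()
    f[0] = a / c[0]
    for j in range(1, S):
        pred = stay[j - 1] * f[j - 1] + (1.0 - stay[j - 1]) / k
        a = pred * em[:, j]
        c[j] = a.sum()
        f[j] = a / c[j]
    loglik = float(np.log(c).sum())

    b = np.empty((S, k))
    b[S - 1] = 1.0
    for j in range(S - 2, -1, -1):
        v = em[:, j + 1] * b[j + 1]
        b[j] = (stay[j] * v + (1.0 - stay[j]) * v.mean()) / c[j + 1]

    post = f * b
    post /= post.sum(axis=1, keepdims=True)

    jumps = np.empty(S - 1)
    switches_into = np.zeros(k)
    for j in range(S - 1):
        v = em[:, j + 1] * b[j + 1]
        z = c[j + 1]
        jump_mass = (1.0 - stay[j]) / k * v / z          # lands on each donor
        jumps[j] = jump_mass.sum()
        # P(x_j = d, x_{j+1} = d): stay route + jump landing back on d
        joint_diag = (stay[j] * f[j] + (1.0 - stay[j]) / k * f[j]) * v / z
        switches_into += post[j + 1] - joint_diag
    return post, loglik, jumps, switches_into, post[0].copy()


def forward_backward(recipient: np.ndarray, donors: np.ndarray,
                     params: CopyParams, intervals: np.ndarray,
                     region_ids: np.ndarray) -> FBResult:
    """Paint one recipient haplotype against a donor set.

    ``intervals[j]`` is the map distance (Morgans) from site ``j-1`` to
    ``j``; the entry at the first site of each region is ignored.  Regions
    are independent chains.
    """
    donors = np.asarray(donors)
    if donors.ndim != 2 or donors.shape[0] < 1:
        raise ValueError("need at least one donor haplotype")
    recipient = np.asarray(recipient)
    if recipient.shape != (donors.shape[1],):
        raise ValueError("recipient/donor site dimensions differ")
    intervals = np.asarray(intervals, dtype=float)
    region_ids = np.asarray(region_ids)
    rho_eff = params.rho * params.ne_scale

    k, S = donors.shape
    post = np.empty((S, k))
    loglik = 0.0
    jumps_parts, g_parts, init_parts = [], [], []
    switches_into = np.zeros(k)
    mismatch = 0.0

    start = 0
    for j in range(1, S + 1):
        if j == S or region_ids[j] != region_ids[j - 1]:
            sl = slice(start, j)
            g = intervals[start + 1:j]
            if np.any(g < 0):
                raise ValueError("negative genetic-map distance")
            p, ll, jm, sw, init = _fb_single_region(
                recipient[sl], donors[:, sl], g, rho_eff, params.mu
            )
            post[sl] = p
            loglik += ll
            jumps_parts.append(jm)
            g_parts.append(g)
            init_parts.append(init)
            switches_into += sw
            mismatch += float(
                (p * (donors[:, sl] != recipient[None, sl]).T).sum()
            )
            start = j

    return FBResult(
        posteriors=post,
        loglik=loglik,
        expected_jumps=np.concatenate(jumps_parts) if jumps_parts else np.zeros(0),
        interval_lengths=np.concatenate(g_parts) if g_parts else np.zeros(0),
        switches_into=switches_into,
        initial_posterior=np.vstack(init_parts),
        mismatch_mass=mismatch,
        n_sites=S,
    )


def expected_copying(fb: FBResult) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy fraction and expected chunk count per donor.

    Occupancy is the mean site-wise posterior; the expected number of
    maximal copied runs per donor is its initial-state posterior plus the
    expected switches into it, summed over regions.
    """
    occupancy = fb.posteriors.mean(axis=0)
    chunks = fb.initial_posterior.sum(axis=0) + fb.switches_into
    return occupancy, chunks


@dataclass
class CopyingResult:
    """Painting of every recipient haplotype in a panel.

    ``occupancy``/``chunk_counts`` are recipient-haplotype x donor-haplotype
    (full square matrices; excluded donors hold exact zeros).
    """

    occupancy: np.ndarray
    chunk_counts: np.ndarray
    loglik: float
    params: CopyParams
    panel: HaplotypePanel
    donor_exclusions: dict[int, list[int]]
    loglik_trace: list[float] = field(default_factory=list)

    def haplotype_names(self) -> list[str]:
        return self.panel.haplotype_names()

    def occupancy_frame(self) -> pd.DataFrame:
        names = self.haplotype_names()
        return pd.DataFrame(self.occupancy, index=names, columns=names)


def _donor_rows(n_hap: int, recipient_row: int,
                exclude_same_individual: bool) -> np.ndarray:
    if exclude_same_individual:
        ind = recipient_row // 2
        keep = [r for r in range(n_hap) if r // 2 != ind]
    else:
        keep = [r for r in range(n_hap) if r != recipient_row]
    return np.asarray(keep, dtype=int)


def _fb_batch(H: np.ndarray, D: np.ndarray, params: CopyParams,
              intervals: np.ndarray, region_ids: np.ndarray):
    """Forward-backward for many recipients at once.

    ``H`` is (R, S) recipients, ``D`` is (R, k, S) per-recipient donor
    alleles (all donor sets the same size, which same-individual exclusion
    guarantees).  Returns per-recipient logliks (R,), occupancy sums and
    chunk statistics (R, k), per-interval jump expectations summed over
    recipients, the matching interval lengths, and total mismatch mass —
    identical quantities to running :func:`forward_backward` per recipient.
    """
    R, k, S = D.shape
    rho_eff = params.rho * params.ne_scale
    mu = params.mu
    loglik = np.zeros(R)
    occ_sum = np.zeros((R, k))
    chunks = np.zeros((R, k))
    mismatch = np.zeros(R)
    jumps_parts: list[np.ndarray] = []
    g_parts: list[np.ndarray] = []

    start = 0
    for jend in range(1, S + 1):
        if jend < S and region_ids[jend] == region_ids[jend - 1]:
            continue
        sl = slice(start, jend)
        Sr = jend - start
        g = intervals[start + 1:jend]
        if np.any(g < 0):
            raise ValueError("negative genetic-map distance")
        stay = np.exp(-rho_eff * g)
        em = np.where(D[:, :, sl] == H[:, None, sl], 1.0 - mu, mu)  # (R,k,Sr)

        f = np.empty((Sr, R, k))
        c = np.empty((Sr, R))
        a = em[:, :, 0] / k
        c[0] = a.sum(axis=1)
        f[0] = a / c[0][:, None]
        for j in range(1, Sr):
            pred = stay[j - 1] * f[j - 1] + (1.0 - stay[j - 1]) / k
            a = pred * em[:, :, j]
            c[j] = a.sum(axis=1)
            f[j] = a / c[j][:, None]
        loglik += np.log(c).sum(axis=0)

        jm = np.zeros(Sr - 1)
        mis = D[:, :, sl] != H[:, None, sl]
        b = np.ones((R, k))
        post = f[Sr - 1] * b
        occ_sum += post
        mismatch += (post * mis[:, :, Sr - 1]).sum(axis=1)
        for j in range(Sr - 2, -1, -1):
            v = em[:, :, j + 1] * b              # (R,k)
            z = c[j + 1][:, None]
            post_next = (stay[j] * f[j] + (1.0 - stay[j]) / k) * v / z
            jump_land = (1.0 - stay[j]) / k * v / z
            jm[j] = jump_land.sum()
            # switches into donor d = post_{j+1}(d) - P(x_j = d, x_{j+1} = d)
            chunks += post_next - f[j] * (stay[j] + (1.0 - stay[j]) / k) * v / z
            b = (stay[j] * v + (1.0 - stay[j]) * v.mean(axis=1)[:, None]) / z
            post = f[j] * b
            post /= post.sum(axis=1)[:, None]
            occ_sum += post
            mismatch += (post * mis[:, :, j]).sum(axis=1)
        # initial-state posterior opens one chunk per region
        post0 = f[0] * b
        post0 /= post0.sum(axis=1)[:, None]
        chunks += post0
        jumps_parts.append(jm)
        g_parts.append(g)
        start = jend

    jumps = np.concatenate(jumps_parts) if jumps_parts else np.zeros(0)
    lengths = np.concatenate(g_parts) if g_parts else np.zeros(0)
    return loglik, occ_sum / S, chunks, jumps, lengths, float(mismatch.sum())


def _update_rho(jumps: np.ndarray, lengths: np.ndarray, n_chains: float,
                ne_scale: float) -> float:
    """M-step for rho: maximise the expected complete-data transition
    log-likelihood sum_j [(n - J_j)(-r g_j) + J_j log(1 - exp(-r g_j))]."""
    total_j = float(jumps.sum())
    if total_j <= 0 or lengths.size == 0 or lengths.sum() <= 0:
        return 1e-6
    # group equal interval lengths (maps are usually uniform per region)
    uniq, inv = np.unique(lengths, return_inverse=True)
    j_by_g = np.zeros(uniq.size)
    np.add.at(j_by_g, inv, jumps)
    n_by_g = np.bincount(inv, minlength=uniq.size).astype(float) * n_chains

    g_eff = uniq * ne_scale

    def neg_q(log_r: float) -> float:
        r = np.exp(log_r)
        s = -np.expm1(-r * g_eff)
        s = np.maximum(s, 1e-300)
        q = (-(n_by_g - j_by_g) * r * g_eff + j_by_g * np.log(s)).sum()
        return -q

    res = minimize_scalar(neg_q, bounds=(np.log(1e-6), np.log(1e8)),
                          method="bounded",
                          options={"xatol": 1e-8})
    return float(np.exp(res.x))


def em_fit(panel: HaplotypePanel, params0: CopyParams | None = None,
           exclude_same_individual: bool = True,
           donors: HaplotypePanel | None = None) -> CopyingResult:
    """Fit rho and mu by EM and paint every recipient haplotype.

    Donors for each recipient are all haplotypes of all *other* individuals
    (with ``exclude_same_individual`` the recipient's partner haplotype is
    excluded too; without it only the recipient itself is).  When a separate
    ``donors`` panel is given, recipients of ``panel`` are painted against
    the full donor panel with no exclusions.  Runs exactly
    ``params0.n_em_iters`` iterations; the log-likelihood trace (evaluated
    at the parameters entering each iteration) is recorded and is
    non-decreasing up to numerical noise.
    """
    params = replace(params0) if params0 is not None else CopyParams()
    external = donors is not None
    donor_panel = donors if external else panel
    if not external and panel.n_individuals < 2:
        raise ValueError(
            "copying needs at least two individuals when donors come from "
            "the panel itself"
        )
    n_rec = panel.n_haplotypes
    n_don = donor_panel.n_haplotypes
    intervals = panel.intervals
    region_ids = panel.region_ids

    exclusions: dict[int, list[int]] = {}
    donor_sets: list[np.ndarray] = []
    for r in range(n_rec):
        if external:
            keep = np.arange(n_don)
        else:
            keep = _donor_rows(n_don, r, exclude_same_individual)
        if keep.size == 0:
            raise ValueError(f"recipient haplotype {r} has an empty donor set")
        donor_sets.append(keep)
        exclusions[r] = sorted(set(range(n_don)) - set(keep.tolist()))

    # all donor sets share a size, so recipients batch into one array
    k = donor_sets[0].size
    assert all(ds.size == k for ds in donor_sets)
    donor_idx = np.vstack(donor_sets)
    H = panel.haplotypes
    D = donor_panel.haplotypes[donor_idx]  # (R, k, S)

    trace: list[float] = []
    for _ in range(params.n_em_iters):
        logliks, _, _, jumps, lengths, mismatch = _fb_batch(
            H, D, params, intervals, region_ids
        )
        trace.append(float(logliks.sum()))
        rho = _update_rho(jumps, lengths, n_rec, params.ne_scale)
        mu = min(max(mismatch / (n_rec * panel.n_sites), 1e-8), 0.5)
        params = replace(params, rho=rho, mu=mu)

    # final E-step at the converged parameter values
    logliks, occ, chk, _, _, _ = _fb_batch(H, D, params, intervals, region_ids)
    loglik = float(logliks.sum())

    occupancy = np.zeros((n_rec, n_don))
    chunks = np.zeros((n_rec, n_don))
    rows = np.repeat(np.arange(n_rec), k)
    occupancy[rows, donor_idx.ravel()] = occ.ravel()
    chunks[rows, donor_idx.ravel()] = chk.ravel()
    return CopyingResult(
        occupancy=occupancy,
        chunk_counts=chunks,
        loglik=loglik,
        params=params,
        panel=panel,
        donor_exclusions=exclusions,
        loglik_trace=trace,
    )


@dataclass
class PopulationCopyMatrix:
    """Population-level summary of copying proportions.

    ``matrix`` rows (recipient population) sum to one; ``by_individual``
    holds each individual's population copying vector (mean of its two
    haplotypes).
    """

    matrix: pd.DataFrame
    by_individual: pd.DataFrame


def aggregate_by_population(result: CopyingResult, labels: dict[str, str],
                            donor_labels: dict[str, str] | None = None,
                            donor_individuals: list[str] | None = None,
                            exclude_donor_pops: tuple[str, ...] = ()
                            ) -> PopulationCopyMatrix:
    """Collapse the haplotype occupancy matrix to population level.

    Each individual's two recipient haplotypes are averaged after summing
    occupancy over donors grouped by the donor's population; individual
    vectors are then averaged within each recipient population.  Donor
    populations named in ``exclude_donor_pops`` (e.g. known hybrids, which
    are not a population of origin) are dropped and rows renormalised, so
    rows still sum to one over the retained populations.
    """
    donor_inds = donor_individuals or result.panel.individuals
    dlabels = donor_labels or labels
    for ind in donor_inds:
        if ind not in dlabels:
            raise KeyError(f"donor individual {ind!r} has no population label")
    pops = list(dict.fromkeys(dlabels[i] for i in donor_inds))
    pop_of_donor_row = np.array(
        [pops.index(dlabels[donor_inds[r // 2]])
         for r in range(2 * len(donor_inds))]
    )
    n_rec_ind = result.panel.n_individuals
    by_ind = np.zeros((n_rec_ind, len(pops)))
    for i in range(n_rec_ind):
        hap_occ = result.occupancy[2 * i] + result.occupancy[2 * i + 1]
        for p in range(len(pops)):
            by_ind[i, p] = hap_occ[pop_of_donor_row == p].sum() / 2.0
    by_individual = pd.DataFrame(
        by_ind, index=result.panel.individuals, columns=pops
    )
    if exclude_donor_pops:
        keep = [p for p in pops if p not in exclude_donor_pops]
        if not keep:
            raise ValueError("every donor population excluded")
        by_individual = by_individual[keep]
        by_individual = by_individual.div(by_individual.sum(axis=1), axis=0)
        pops = keep
    rec_pops = [labels.get(ind, "unlabelled")
                for ind in result.panel.individuals]
    grouped = by_individual.groupby(pd.Series(rec_pops,
                                              index=by_individual.index))
    matrix = grouped.mean()
    matrix = matrix.loc[[p for p in pops if p in matrix.index]
                        + [p for p in matrix.index if p not in pops]]
    return PopulationCopyMatrix(matrix=matrix, by_individual=by_individual)


def sample_fragment_assignments(result: CopyingResult,
                                labels: dict[str, str],
                                n_samples: int = 100,
                                seed: int = 0,
                                donor_labels: dict[str, str] | None = None
                                ) -> pd.DataFrame:
    """Empirical per-region population-assignment probabilities.

    Draws ``n_samples`` posterior donor paths per recipient haplotype by
    backward sampling from the fitted model, maps each copied site to the
    donor's population, and averages the per-region population fractions
    over the draws.  Long-format output: haplotype, region, population,
    probability (probabilities sum to one within a fragment).
    """
    if n_samples < 1:
        raise ValueError("need at least one posterior sample")
    rng = np.random.default_rng(seed)
    panel = result.panel
    dlabels = donor_labels or labels
    donor_inds = panel.individuals
    pops = list(dict.fromkeys(dlabels[i] for i in donor_inds))
    pop_of_row = np.array(
        [pops.index(dlabels[donor_inds[r // 2]])
         for r in range(panel.n_haplotypes)]
    )
    params = result.params
    rho_eff = params.rho * params.ne_scale
    slices = panel.region_slices()
    records = []
    hap_names = panel.haplotype_names()
    for r in range(panel.n_haplotypes):
        keep = np.array(
            [d for d in range(panel.n_haplotypes)
             if d not in result.donor_exclusions[r]]
        )
        donors = panel.haplotypes[keep]
        k = keep.size
        h = panel.haplotypes[r]
        pop_of_donor = pop_of_row[keep]
        for region, sl in slices.items():
            em = np.where(donors[:, sl] == h[None, sl], 1 - params.mu,
                          params.mu)
            S = sl.stop - sl.start
            g = panel.intervals[sl.start + 1:sl.stop]
            stay = np.exp(-rho_eff * g)
            f = np.empty((S, k))
            a = em[:, 0] / k
            f[0] = a / a.sum()
            for j in range(1, S):
                pred = stay[j - 1] * f[j - 1] + (1 - stay[j - 1]) / k
                a = pred * em[:, j]
                f[j] = a / a.sum()
            # backward sampling, all draws at once
            counts = np.zeros(len(pops))
            cdf = np.cumsum(f[S - 1])
            x = np.searchsorted(cdf, rng.random(n_samples) * cdf[-1])
            np.add.at(counts, pop_of_donor[x], 1.0)
            for j in range(S - 2, -1, -1):
                fx = f[j, x]
                p_stay = stay[j] * fx / (stay[j] * fx + (1 - stay[j]) / k)
                redraw = rng.random(n_samples) >= p_stay
                m = int(redraw.sum())
                if m:
                    cdf = np.cumsum(f[j])
                    x = x.copy()
                    x[redraw] = np.searchsorted(cdf, rng.random(m) * cdf[-1])
                np.add.at(counts, pop_of_donor[x], 1.0)
            probs = counts / (n_samples * S)
            for p, pop in enumerate(pops):
                records.append((hap_names[r], region, pop, probs[p]))
    return pd.DataFrame(
        records, columns=["haplotype", "region", "population", "probability"]
    )


def ne_grid_search(panel: HaplotypePanel, grid,
                   params0: CopyParams | None = None,
                   n_em_iters: int | None = None,
                   exclude_same_individual: bool = True
                   ) -> tuple[float, pd.DataFrame]:
    """Choose the map-scaling factor maximising the fitted log-likelihood.

    Runs :func:`em_fit` for every candidate ``ne_scale`` (optionally with a
    reduced EM iteration budget) and returns the argmax plus the per-value
    log-likelihood table.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty ne_scale grid")
    base = params0 if params0 is not None else CopyParams()
    rows = []
    best_val, best_ll = None, -np.inf
    for val in grid:
        p = replace(base, ne_scale=float(val))
        if n_em_iters is not None:
            p = replace(p, n_em_iters=n_em_iters)
        res = em_fit(panel, p, exclude_same_individual=exclude_same_individual)
        rows.append((float(val), res.loglik))
        if res.loglik > best_ll:
            best_ll, best_val = res.loglik, float(val)
    return best_val, pd.DataFrame(rows, columns=["ne_scale", "loglik"])
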