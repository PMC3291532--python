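"""Synthetic structured-population generator with known ground truth.

The generator emulates the study design this package targets: a handful of
populations diverged by drift to pairwise F_ST in the 0.13-0.19 range,
genotyped at clustered SNPs in a couple of dozen unlinked genomic regions,
with first-generation (F1) hybrids, a non-recombining uniparental locus that
is occasionally discordant with genome-wide ancestry, and SNP ascertainment
in a single discovery individual.

The demographic engine is a discrete-generation Wright-Fisher model on pools
of ``2N`` haplotypes.  One ancestral pool splits sequentially (a caterpillar
topology): at the oldest split time the first population branches off, at the
next the second, and so on, with every pool drifting independently to the
present.  Recombination acts within regions at the per-interval map distance;
regions themselves are unlinked (a free recombination break between regions).
Under pure drift the expected Hudson F_ST between two populations that split
``t`` generations ago is approximately ``1 - exp(-t / 2N)``, which is what
the default split times are tuned against.

Every sampled haplotype carries a ``truth_paths`` row recording the
population whose pool generated each allele — constant for purebred samples,
and one parental population per haplotype for F1 hybrids.  For haplotypes
that are *explicit mosaics* of a donor panel (see
:func:`simulate_copying_mosaics`) the truth path records the donor population
at every site, giving a planted switch rate against which copying-model
parameter recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeTable, HaplotypePanel, make_sites

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "simulate_panel",
    "make_f1_hybrids",
    "apply_ascertainment",
    "simulate_copying_mosaics",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic structured-population scenario.

    Defaults describe a three-population scenario whose pairwise divergence
    (F_ST roughly 0.14 between the two most recently separated populations
    and roughly 0.18 from the outgroup population) matches the regime the
    pipeline is designed for.  ``pop_split_times`` are in generations before
    present, strictly decreasing, one time per split (``n_pops - 1`` of
    them); ``effective_size`` is the diploid size N of every population, so
    drift acts on pools of ``2N`` haplotypes.
    """

    n_pops: int = 3
    samples_per_pop: int = 18
    n_regions: int = 22
    snps_per_region: int = 35
    region_genetic_length: float = 0.001  # Morgans per region
    pop_split_times: tuple[int, ...] = (20, 15)
    effective_size: int = 50
    mutation_rate: float = 0.0  # per site per transmission (symmetric flip)
    n_hybrids: int = 0
    uniparental_discordance_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_pops,
            self.samples_per_pop,
            self.n_regions,
            self.snps_per_region,
            self.effective_size,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts in SimConfig must be positive")
        if self.n_pops < 2:
            raise ValueError("need at least two populations")
        if len(self.pop_split_times) != self.n_pops - 1:
            raise ValueError("need exactly n_pops - 1 split times")
        times = list(self.pop_split_times)
        if any(t < 0 for t in times) or any(
            a <= b for a, b in zip(times, times[1:])
        ):
            raise ValueError(
                "split times must be non-negative and strictly decreasing"
            )
        if not 0.0 <= self.uniparental_discordance_rate <= 1.0:
            raise ValueError("discordance rate must lie in [0, 1]")
        if self.region_genetic_length < 0:
            raise ValueError("region genetic length must be non-negative")
        if 2 * self.samples_per_pop + 2 * self.n_hybrids > 2 * self.effective_size:
            raise ValueError(
                "cannot sample more haplotypes per population than the pool"
                " holds (2N)"
            )

    def pop_names(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]


@dataclass
class SyntheticDataset:
    """A simulated panel plus every piece of generating ground truth."""

    haplotypes: HaplotypePanel
    genotypes: GenotypeTable
    true_labels: dict[str, str]
    hybrid_flags: dict[str, bool]
    uniparental_labels: dict[str, str]
    truth_paths: np.ndarray  # (n_haplotypes, n_sites) population index
    pop_names: list[str]
    config: SimConfig | None = None

    def __post_init__(self) -> None:
        expect = self.haplotypes.haplotypes[0::2] + self.haplotypes.haplotypes[1::2]
        if not np.array_equal(expect, self.genotypes.calls):
            raise ValueError("genotypes are not the site-wise sum of haplotypes")

    def non_hybrid_samples(self) -> list[str]:
        return [s for s in self.genotypes.samples if not self.hybrid_flags[s]]


def _evolve(pool: np.ndarray, generations: int, rec: np.ndarray,
            mutation_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Drift a pool of haplotypes forward ``generations`` Wright-Fisher steps.

    ``rec[j]`` is the crossover probability between columns ``j`` and
    ``j+1``; region boundaries carry probability 0.5 (unlinked).
    """
    n, n_sites = pool.shape
    for _ in range(generations):
        pa = rng.integers(0, n, size=n)
        pb = rng.integers(0, n, size=n)
        cross = rng.random((n, n_sites - 1)) < rec[None, :]
        use_b = np.zeros((n, n_sites), dtype=bool)
        use_b[:, 1:] = np.cumsum(cross, axis=1) % 2 == 1
        pool = np.where(use_b, pool[pb], pool[pa])
        if mutation_rate > 0:
            flips = rng.random(pool.shape) < mutation_rate
            pool = np.where(flips, 1 - pool, pool)
    return pool


def _recombination_probs(sites: pd.DataFrame, intervals: np.ndarray) -> np.ndarray:
    """Per-adjacent-column crossover probabilities for the WF engine."""
    regions = sites["region"].to_numpy()
    rec = np.empty(len(regions) - 1)
    same = regions[1:] == regions[:-1]
    # small map distances: Morgans ~ crossover probability (Haldane ~ identical)
    rec[same] = np.minimum(intervals[1:][same], 0.5)
    rec[~same] = 0.5
    return rec


def _ancestral_frequencies(n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """Standing variation with a drift-like (1/x) frequency spectrum."""
    lo, hi = 0.05, 0.5
    q = lo * (hi / lo) ** rng.random(n_sites)
    flip = rng.random(n_sites) < 0.5
    return np.where(flip, 1.0 - q, q)


def simulate_panel(config: SimConfig) -> SyntheticDataset:
    """Simulate a structured panel with recorded ground truth.

    Monomorphic sites (after sampling) are dropped.  When
    ``config.n_hybrids`` is positive, F1 hybrids between the first two
    populations are appended via :func:`make_f1_hybrids`.
    """
    rng = np.random.default_rng(config.seed)
    n_sites = config.n_regions * config.snps_per_region
    regions = [
        f"r{r + 1:02d}"
        for r in range(config.n_regions)
        for _ in range(config.snps_per_region)
    ]
    positions = [
        10_000 + 1_500 * j
        for _ in range(config.n_regions)
        for j in range(config.snps_per_region)
    ]
    sites = make_sites(regions, positions)
    if config.snps_per_region > 1:
        per_interval = config.region_genetic_length / (config.snps_per_region - 1)
    else:
        per_interval = 0.0
    intervals = np.full(n_sites, per_interval)
    rec = _recombination_probs(sites, intervals)

    # Found the ancestral pool from standing variation.
    two_n = 2 * config.effective_size
    q = _ancestral_frequencies(n_sites, rng)
    ancestral = (rng.random((two_n, n_sites)) < q[None, :]).astype(np.int8)

    # Caterpillar splits: pools[i] becomes population i once branched off.
    times = list(config.pop_split_times) + [0]
    pools = [ancestral]
    for i, (t_split, t_next) in enumerate(zip(times[:-1], times[1:])):
        pools.append(pools[-1].copy())  # branch off the next population
        span = t_split - t_next
        pools = [
            _evolve(p, span, rec, config.mutation_rate, rng) for p in pools
        ]
    # pools[0] drifted longest alone = first population to branch off.
    pop_names = [f"pop{i + 1}" for i in range(config.n_pops)]

    individuals: list[str] = []
    hap_rows: list[np.ndarray] = []
    truth_rows: list[np.ndarray] = []
    true_labels: dict[str, str] = {}
    hybrid_flags: dict[str, bool] = {}
    uniparental: dict[str, str] = {}
    for p, (name, pool) in enumerate(zip(pop_names, pools)):
        take = rng.choice(pool.shape[0], size=2 * config.samples_per_pop,
                          replace=False)
        for i in range(config.samples_per_pop):
            sid = f"{name}_i{i + 1:02d}"
            individuals.append(sid)
            hap_rows.append(pool[take[2 * i]])
            hap_rows.append(pool[take[2 * i + 1]])
            truth_rows.append(np.full(n_sites, p, dtype=np.int16))
            truth_rows.append(np.full(n_sites, p, dtype=np.int16))
            true_labels[sid] = name
            hybrid_flags[sid] = False
            uniparental[sid] = name

    haplotypes = np.vstack(hap_rows)
    truth = np.vstack(truth_rows)

    # Drop sites monomorphic in the sample.
    freq = haplotypes.mean(axis=0)
    keep = (freq > 0) & (freq < 1)
    if not keep.any():
        raise ValueError("simulation produced no polymorphic sites")
    keep_idx = np.flatnonzero(keep)
    panel = HaplotypePanel(
        individuals=individuals,
        sites=sites,
        haplotypes=haplotypes,
        intervals=intervals,
    ).subset_sites(keep_idx)
    truth = truth[:, keep_idx]

    # Plant uniparental discordance.
    if config.uniparental_discordance_rate > 0 and config.n_pops > 1:
        for sid in individuals:
            if rng.random() < config.uniparental_discordance_rate:
                others = [p for p in pop_names if p != true_labels[sid]]
                uniparental[sid] = others[rng.integers(len(others))]

    dataset = SyntheticDataset(
        haplotypes=panel,
        genotypes=panel.genotypes(labels=true_labels),
        true_labels=true_labels,
        hybrid_flags=hybrid_flags,
        uniparental_labels=uniparental,
        truth_paths=truth,
        pop_names=pop_names,
        config=config,
    )
    if config.n_hybrids > 0:
        dataset = make_f1_hybrids(
            dataset, pop_names[0], pop_names[1], config.n_hybrids,
            rng=rng,
        )
    return dataset


def make_f1_hybrids(dataset: SyntheticDataset, pop_a: str, pop_b: str,
                    n: int, rng: np.random.Generator | None = None,
                    seed: int | None = None) -> SyntheticDataset:
    """Append ``n`` F1 hybrids, one haplotype from each parental population.

    Each parent individual is used at most once; a parent contributes one of
    its two haplotypes, chosen at random.  The input dataset is not mutated.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n == 0:
        return dataset
    if n < 0:
        raise ValueError("n must be non-negative")
    panel = dataset.haplotypes
    parents_a = [s for s in panel.individuals if dataset.true_labels[s] == pop_a]
    parents_b = [s for s in panel.individuals if dataset.true_labels[s] == pop_b]
    if len(parents_a) < n or len(parents_b) < n:
        raise ValueError(
            f"not enough unused parents: need {n} in each of "
            f"{pop_a!r} ({len(parents_a)}) and {pop_b!r} ({len(parents_b)})"
        )
    pa = list(rng.choice(len(parents_a), size=n, replace=False))
    pb = list(rng.choice(len(parents_b), size=n, replace=False))
    pop_index = {name: i for i, name in enumerate(dataset.pop_names)}

    individuals = list(panel.individuals)
    hap = panel.haplotypes
    truth = dataset.truth_paths
    new_rows = []
    new_truth = []
    true_labels = dict(dataset.true_labels)
    hybrid_flags = dict(dataset.hybrid_flags)
    uniparental = dict(dataset.uniparental_labels)
    n_existing_hybrids = sum(dataset.hybrid_flags.values())
    n_sites = panel.n_sites
    for j in range(n):
        sid = f"hyb_{pop_a}x{pop_b}_{n_existing_hybrids + j + 1:02d}"
        ia = panel.individuals.index(parents_a[pa[j]])
        ib = panel.individuals.index(parents_b[pb[j]])
        row_a = 2 * ia + int(rng.integers(2))
        row_b = 2 * ib + int(rng.integers(2))
        new_rows.append(hap[row_a])
        new_rows.append(hap[row_b])
        new_truth.append(np.full(n_sites, pop_index[pop_a], dtype=np.int16))
        new_truth.append(np.full(n_sites, pop_index[pop_b], dtype=np.int16))
        individuals.append(sid)
        true_labels[sid] = "hybrid"
        hybrid_flags[sid] = True
        # uniparental lineage comes from one parent, chosen at random
        uniparental[sid] = (pop_a, pop_b)[int(rng.integers(2))]

    new_panel = HaplotypePanel(
        individuals=individuals,
        sites=panel.sites.copy().reset_index(drop=True),
        haplotypes=np.vstack([hap] + new_rows),
        intervals=panel.intervals.copy(),
    )
    return SyntheticDataset(
        haplotypes=new_panel,
        genotypes=new_panel.genotypes(labels=true_labels),
        true_labels=true_labels,
        hybrid_flags=hybrid_flags,
        uniparental_labels=uniparental,
        truth_paths=np.vstack([truth] + new_truth),
        pop_names=list(dataset.pop_names),
        config=dataset.config,
    )


def apply_ascertainment(dataset: SyntheticDataset,
                        discovery_sample: str) -> np.ndarray:
    """SNP "discovery" in a single genome: keep its heterozygous sites.

    Returns the sorted site-index subset; the dataset is never mutated.
    Mimics ascertainment in which nearly all discovery sequence came from a
    single individual of one population, which skews the retained minor
    allele frequency spectrum toward intermediate frequencies in that
    population.
    """
    if discovery_sample not in dataset.genotypes.samples:
        raise KeyError(f"unknown discovery sample {discovery_sample!r}")
    row = dataset.genotypes.samples.index(discovery_sample)
    het = np.flatnonzero(dataset.genotypes.calls[row] == 1)
    if het.size == 0:
        raise ValueError(
            f"discovery individual {discovery_sample!r} has no heterozygous "
            "sites; ascertainment would retain nothing"
        )
    return het


def simulate_copying_mosaics(panel: HaplotypePanel,
                             donor_pops: dict[str, str],
                             pop_names: list[str],
                             n_recipients: int,
                             switch_rate: float,
                             miscopy: float = 0.0,
                             seed: int = 0) -> tuple[HaplotypePanel, np.ndarray]:
    """Build recipient haplotypes as explicit mosaics of a donor panel.

    Recipients are generated under the haplotype copying process itself:
    within each region the donor is re-chosen after an interval of ``g``
    Morgans with probability ``1 - exp(-switch_rate * g)`` (uniformly among
    all donors), each region starts from a uniform donor, and the copied
    allele is flipped with probability ``miscopy``.  Returns a panel of
    ``n_recipients`` diploid individuals (two mosaic haplotypes each) and
    the per-site donor-population truth paths — a planted ground truth for
    switch-rate recovery and painting accuracy.
    """
    if n_recipients < 1:
        raise ValueError("need at least one recipient")
    if switch_rate < 0:
        raise ValueError("switch rate must be non-negative")
    rng = np.random.default_rng(seed)
    hap = panel.haplotypes
    n_donors, n_sites = hap.shape
    pop_index = {name: i for i, name in enumerate(pop_names)}
    donor_pop_idx = np.array(
        [pop_index[donor_pops[panel.individual_of_haplotype(r)]]
         for r in range(n_donors)]
    )
    slices = panel.region_slices()
    rows = np.empty((2 * n_recipients, n_sites), dtype=np.int8)
    truth = np.empty((2 * n_recipients, n_sites), dtype=np.int16)
    for r in range(2 * n_recipients):
        for sl in slices.values():
            g = panel.intervals[sl][1:]
            p_switch = 1.0 - np.exp(-switch_rate * g)
            donor = int(rng.integers(n_donors))
            for j in range(sl.start, sl.stop):
                if j > sl.start and rng.random() < p_switch[j - sl.start - 1]:
                    donor = int(rng.integers(n_donors))
                allele = hap[donor, j]
                if miscopy > 0 and rng.random() < miscopy:
                    allele = 1 - allele
                rows[r, j] = allele
                truth[r, j] = donor_pop_idx[donor]
    recipients = [f"mosaic_i{i + 1:02d}" for i in range(n_recipients)]
    out = HaplotypePanel(
        individuals=recipients,
        sites=panel.sites.copy().reset_index(drop=True),
        haplotypes=rows,
        intervals=panel.intervals.copy(),
    )
    return out, truth
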