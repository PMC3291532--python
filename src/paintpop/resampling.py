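"""Ascertainment-matched resampling harness for cross-dataset comparison.

Comparing population structure across datasets genotyped under different
ascertainment schemes is confounded by the SNP frequency spectrum.  The
harness removes the confound empirically: it repeatedly draws, from a large
comparison panel, the same number of individuals per population, the same
number of genomic regions, and per region a SNP set matched in count and
minor-allele-frequency histogram (bins (0,0.1], (0.1,0.2], (0.2,0.3],
(0.3,0.4], (0.4,0.5]) to a template dataset — optionally re-ascertaining
SNPs on a single held-out individual first.  Copying-model and F_ST
statistics are computed per replicate and summarised as empirical central
95% intervals, and paired exceedance counts compare named statistics across
replicates.

Per-replicate randomness derives from ``(seed, replicate_index)`` through a
`numpy` SeedSequence-style key, so any single replicate is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeTable, HaplotypePanel, MISSING
from .copying import CopyParams, aggregate_by_population, em_fit
from .structure import pairwise_fst

__all__ = [
    "MAF_BINS",
    "ResamplePlan",
    "ResampleSummary",
    "build_template",
    "match_snps_by_maf",
    "resample_replicate",
    "run_resamples",
    "exceedance_count",
]

# right-closed bins partitioning (0, 0.5]
MAF_BINS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def maf_bin_index(maf: np.ndarray) -> np.ndarray:
    """Bin index in (0,0.1], (0.1,0.2], ... (0.4,0.5]; -1 for maf == 0."""
    maf = np.asarray(maf, dtype=float)
    idx = np.searchsorted(MAF_BINS, maf, side="left") - 1
    idx[maf <= 0] = -1
    return np.clip(idx, -1, len(MAF_BINS) - 2)


@dataclass
class ResamplePlan:
    """What one replicate draws and what it must match.

    ``template`` maps each template region id to its per-bin SNP counts
    (length-5 integer array), fixing both SNP density and MAF histogram.
    """

    template: dict[str, np.ndarray]
    n_replicates: int = 100
    individuals_per_pop: int = 18
    n_regions: int = 22
    ascertain: bool = False
    em_iters: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.individuals_per_pop < 1:
            raise ValueError("replicate and individual counts must be positive")
        if len(self.template) != self.n_regions:
            raise ValueError(
                f"template has {len(self.template)} regions, plan expects "
                f"{self.n_regions}"
            )
        for region, counts in self.template.items():
            counts = np.asarray(counts)
            if counts.shape != (len(MAF_BINS) - 1,) or (counts < 0).any():
                raise ValueError(f"bad template histogram for region {region!r}")


def build_template(table: GenotypeTable) -> dict[str, np.ndarray]:
    """Per-region MAF histograms of a reference dataset (the template)."""
    present = table.calls != MISSING
    n_chrom = 2 * present.sum(axis=0)
    alt = np.where(present, table.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
    maf = np.minimum(f, 1 - f)
    bins = maf_bin_index(maf)
    regions = table.sites["region"].to_numpy()
    out: dict[str, np.ndarray] = {}
    for region in dict.fromkeys(regions):
        sel = bins[(regions == region)]
        counts = np.zeros(len(MAF_BINS) - 1, dtype=int)
        for b in sel:
            if b >= 0:
                counts[b] += 1
        out[region] = counts
    return out


def match_snps_by_maf(candidate_index: np.ndarray, candidate_maf: np.ndarray,
                      template_counts: np.ndarray,
                      rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Sample candidate sites to reproduce a template MAF histogram.

    Draws without replacement, per bin, exactly the template count.  When a
    bin holds fewer candidates than required, the shortfall is borrowed from
    the nearest non-empty bin; the number of such substitutions is returned
    alongside the (sorted) selected site indices.
    """
    candidate_index = np.asarray(candidate_index)
    candidate_maf = np.asarray(candidate_maf, dtype=float)
    template_counts = np.asarray(template_counts, dtype=int)
    if candidate_index.size == 0:
        raise ValueError("no candidate sites to match against")
    if template_counts.sum() > candidate_index.size:
        raise ValueError(
            f"template asks for {template_counts.sum()} SNPs but only "
            f"{candidate_index.size} candidates exist"
        )
    bins = maf_bin_index(candidate_maf)
    pools = [list(candidate_index[bins == b])
             for b in range(len(MAF_BINS) - 1)]
    for pool in pools:
        rng.shuffle(pool)
    chosen: list[int] = []
    borrowed = 0
    for b, want in enumerate(template_counts):
        take = min(want, len(pools[b]))
        chosen.extend(pools[b][:take])
        del pools[b][:take]
        short = want - take
        while short > 0:
            # nearest non-empty bin
            order = sorted(
                (abs(bb - b), bb) for bb in range(len(pools)) if pools[bb]
            )
            if not order:
                raise ValueError("candidate pool exhausted during matching")
            bb = order[0][1]
            chosen.append(pools[bb].pop())
            borrowed += 1
            short -= 1
    return np.sort(np.asarray(chosen)), borrowed


@dataclass
class ReplicateLog:
    index: int
    seed_key: tuple[int, int]
    individuals: list[str]
    regions: list[str]
    site_index: np.ndarray
    n_borrowed: int


def _replicate_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def resample_replicate(panel: HaplotypePanel, labels: dict[str, str],
                       plan: ResamplePlan, replicate_index: int
                       ) -> tuple[HaplotypePanel, ReplicateLog]:
    """Draw one matched replicate: individuals, regions, then SNPs.

    Deterministic given ``(plan.seed, replicate_index)``.  With
    ``plan.ascertain`` an extra individual per draw is held out, only sites
    heterozygous in it are candidates, and it is excluded from the replicate
    panel.
    """
    rng = _replicate_rng(plan.seed, replicate_index)
    pops: dict[str, list[str]] = {}
    for ind in panel.individuals:
        pops.setdefault(labels[ind], []).append(ind)
    need = plan.individuals_per_pop + (1 if plan.ascertain else 0)
    for pop, members in pops.items():
        if len(members) < need:
            raise ValueError(
                f"population {pop!r} has {len(members)} individuals, "
                f"replicate needs {need}"
            )
    chosen_inds: list[str] = []
    held_out: str | None = None
    pop_names = list(pops)
    if plan.ascertain:
        asc_pop = pop_names[int(rng.integers(len(pop_names)))]
    for pop in pop_names:
        members = list(pops[pop])
        take = list(rng.choice(len(members), size=need if
                               (plan.ascertain and pop == asc_pop)
                               else plan.individuals_per_pop, replace=False))
        picked = [members[i] for i in take]
        if plan.ascertain and pop == asc_pop:
            held_out = picked.pop()
        chosen_inds.extend(picked)

    all_regions = list(dict.fromkeys(panel.region_ids))
    if len(all_regions) < plan.n_regions:
        raise ValueError(
            f"panel has {len(all_regions)} regions, plan needs {plan.n_regions}"
        )

    sub = panel.subset_individuals(
        chosen_inds + ([held_out] if held_out else [])
    )
    geno = sub.genotypes()
    calls = geno.calls
    present = calls != MISSING
    n_chrom = 2 * present.sum(axis=0)
    alt = np.where(present, calls, 0).sum(axis=0)
    f = alt / np.maximum(n_chrom, 1)
    maf = np.minimum(f, 1 - f)
    region_of_site = sub.region_ids

    candidate_ok = maf > 0
    if held_out is not None:
        row = geno.samples.index(held_out)
        candidate_ok &= calls[row] == 1  # discovered in the held-out genome

    # pair each template region with a random panel region holding enough
    # candidates (ascertainment can empty a region entirely); most
    # demanding template regions pick first
    n_cand = {
        r: int((candidate_ok & (region_of_site == r)).sum())
        for r in all_regions
    }
    template_regions = sorted(
        plan.template, key=lambda t: -int(np.sum(plan.template[t]))
    )
    pool_regions = list(all_regions)
    assigned: dict[str, str] = {}
    for tmpl_region in template_regions:
        want = int(np.sum(plan.template[tmpl_region]))
        eligible = [r for r in pool_regions if n_cand[r] >= want]
        if not eligible:
            raise ValueError(
                f"no remaining region holds the {want} candidate SNPs that "
                f"template region {tmpl_region!r} requires"
            )
        pick = eligible[int(rng.integers(len(eligible)))]
        assigned[tmpl_region] = pick
        pool_regions.remove(pick)
    regions = [assigned[t] for t in plan.template]

    site_index_parts = []
    n_borrowed = 0
    for tmpl_region in plan.template:
        region = assigned[tmpl_region]
        cand = np.flatnonzero(candidate_ok & (region_of_site == region))
        idx, borrowed = match_snps_by_maf(
            cand, maf[cand], plan.template[tmpl_region], rng
        )
        site_index_parts.append(idx)
        n_borrowed += borrowed
    site_index = np.sort(np.concatenate(site_index_parts))

    replicate = sub.subset_individuals(chosen_inds).subset_sites(site_index)
    log = ReplicateLog(
        index=replicate_index,
        seed_key=(plan.seed, replicate_index),
        individuals=chosen_inds,
        regions=regions,
        site_index=site_index,
        n_borrowed=n_borrowed,
    )
    return replicate, log


@dataclass
class ResampleSummary:
    """Per-replicate statistics plus empirical central intervals."""

    values: pd.DataFrame        # columns: statistic, replicate, value
    intervals: pd.DataFrame     # columns: statistic, low, high
    logs: list[ReplicateLog] = field(default_factory=list)

    def replicate_values(self, statistic: str) -> np.ndarray:
        sub = self.values[self.values["statistic"] == statistic]
        return sub.sort_values("replicate")["value"].to_numpy()


def run_resamples(panel: HaplotypePanel, labels: dict[str, str],
                  plan: ResamplePlan,
                  statistics: tuple[str, ...] = ("copying", "fst"),
                  copy_params: CopyParams | None = None) -> ResampleSummary:
    """Run the full harness: replicate draws, statistics, 95% intervals.

    Statistic names in the output: ``copy/<rec>|<donor>`` for population
    copying proportions (``copy/A|A`` is within-population copying) and
    ``fst/<a>|<b>`` for pairwise F_ST.  Any replicate failure aborts with
    the replicate index.
    """
    unknown = set(statistics) - {"copying", "fst"}
    if unknown:
        raise ValueError(f"unknown statistics {sorted(unknown)}")
    records = []
    logs = []
    base = copy_params if copy_params is not None else CopyParams()
    for rep in range(plan.n_replicates):
        try:
            replicate, log = resample_replicate(panel, labels, plan, rep)
            logs.append(log)
            if "copying" in statistics:
                params = CopyParams(
                    rho=base.rho, mu=base.mu, ne_scale=base.ne_scale,
                    n_em_iters=plan.em_iters,
                )
                result = em_fit(replicate, params)
                mat = aggregate_by_population(result, labels).matrix
                for rec_pop in mat.index:
                    for don_pop in mat.columns:
                        records.append(
                            (f"copy/{rec_pop}|{don_pop}", rep,
                             float(mat.loc[rec_pop, don_pop]))
                        )
            if "fst" in statistics:
                fst = pairwise_fst(replicate.genotypes(labels=labels))
                seen = set()
                for a in fst.matrix.index:
                    for b in fst.matrix.columns:
                        if a == b or (b, a) in seen:
                            continue
                        seen.add((a, b))
                        records.append(
                            (f"fst/{a}|{b}", rep, float(fst.matrix.loc[a, b]))
                        )
        except Exception as exc:
            raise RuntimeError(f"replicate {rep} failed: {exc}") from exc
    values = pd.DataFrame(records, columns=["statistic", "replicate", "value"])
    rows = []
    for stat, sub in values.groupby("statistic", sort=False):
        v = sub["value"].to_numpy()
        lo, hi = np.quantile(v, [0.025, 0.975])  # type-7 interpolation
        rows.append((stat, float(lo), float(hi)))
    intervals = pd.DataFrame(rows, columns=["statistic", "low", "high"])
    return ResampleSummary(values=values, intervals=intervals, logs=logs)


def exceedance_count(summary: ResampleSummary, statistic_a: str,
                     statistic_b: str, direction: str = ">") -> int:
    """Count replicates where statistic_a > statistic_b (or '<'), paired."""
    a = summary.values[summary.values["statistic"] == statistic_a]
    b = summary.values[summary.values["statistic"] == statistic_b]
    a = a.set_index("replicate")["value"]
    b = b.set_index("replicate")["value"]
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError(
            f"statistics {statistic_a!r} and {statistic_b!r} cover different "
            "replicate sets"
        )
    b = b.reindex(a.index)
    if direction == ">":
        return int((a > b).sum())
    if direction == "<":
        return int((a < b).sum())
    raise ValueError("direction must be '>' or '<'")
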