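"""SNP quality control: exact Hardy-Weinberg test, filter cascade, frequencies.

The filter cascade mirrors a genotyping-assay workflow: sites flagged on
visual inspection of clustering are dropped first, then sites with more
missing calls than allowed (default: any no-call drops the site), then sites
whose genotype counts depart from Hardy-Weinberg equilibrium within any
labelled population at a configurable alpha.  A site failing several filters
is removed once but listed under every reason.

The HWE test is the exact conditional test: given the observed allele
counts, every heterozygote count of matching parity is enumerated, and the
two-sided p-value sums the probabilities of all configurations no more
probable than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeTable, MISSING

__all__ = [
    "hwe_exact_test",
    "qc_filter",
    "allele_frequencies",
    "QcReport",
]


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Enumerates every heterozygote count consistent with the observed allele
    counts and returns the summed probability of configurations whose
    conditional probability does not exceed that of the observed one.
    Symmetric in the two homozygote counts.
    """
    if n_AA < 0 or n_Aa < 0 or n_aa < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    # heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_Aa = h | n, n_A) ∝ log n! - log nAA! - log h! - log naa! + h log 2
    from scipy.special import gammaln

    n_aa_h = (rare - hets) // 2
    n_AA_h = (n - hets - n_aa_h).astype(int)
    logp = (
        hets * np.log(2.0)
        - gammaln(n_AA_h + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa_h + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = np.flatnonzero(hets == n_Aa)
    if obs.size != 1:  # pragma: no cover - guarded by count arithmetic
        raise ValueError("observed heterozygote count inconsistent with alleles")
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


@dataclass
class QcReport:
    """Tally of the filter cascade; every excluded site carries a reason."""

    n_designed: int
    n_failed_visual: int
    n_no_call: int
    n_hwe_fail: int
    n_retained: int
    reasons: dict[str, list[str]] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "designed", "failed_visual", "no_call", "hwe_fail",
                    "retained",
                ],
                "count": [
                    self.n_designed, self.n_failed_visual, self.n_no_call,
                    self.n_hwe_fail, self.n_retained,
                ],
            }
        )


def qc_filter(table: GenotypeTable, visual_fail_flags=(), max_no_call: int = 0,
              hwe_alpha: float | None = 0.001,
              labels: dict[str, str] | None = None
              ) -> tuple[GenotypeTable, QcReport]:
    """Apply the three-step site filter and report per-reason tallies.

    ``visual_fail_flags`` holds site ids (``region:pos``); ``max_no_call`` is
    the largest tolerated number of missing calls per site (0 = any no-call
    drops the site); ``hwe_alpha`` (None disables the HWE step) is applied
    within every labelled population separately.
    """
    site_ids = table.site_ids()
    id_to_idx = {s: j for j, s in enumerate(site_ids)}
    for flag in visual_fail_flags:
        if flag not in id_to_idx:
            raise KeyError(f"visual-fail flag names unknown site {flag!r}")
    labels = labels if labels is not None else table.labels
    if hwe_alpha is not None and not labels:
        raise ValueError("HWE filter requested but no population labels given")

    reasons: dict[str, list[str]] = {}

    visual = {id_to_idx[f] for f in visual_fail_flags}
    for j in visual:
        reasons.setdefault(site_ids[j], []).append("visual")

    n_missing = (table.calls == MISSING).sum(axis=0)
    no_call = set(np.flatnonzero(n_missing > max_no_call))
    for j in sorted(no_call):
        reasons.setdefault(site_ids[j], []).append("no_call")

    hwe_fail: set[int] = set()
    if hwe_alpha is not None:
        pops: dict[str, list[int]] = {}
        for i, s in enumerate(table.samples):
            if s in labels:
                pops.setdefault(labels[s], []).append(i)
        for pop, rows in pops.items():
            calls = table.calls[rows]
            for j in range(table.n_sites):
                col = calls[:, j]
                col = col[col != MISSING]
                if col.size == 0:
                    continue
                counts = [int((col == g).sum()) for g in (0, 1, 2)]
                if hwe_exact_test(*counts) < hwe_alpha:
                    hwe_fail.add(j)
        for j in sorted(hwe_fail):
            reasons.setdefault(site_ids[j], []).append("hwe")

    excluded = visual | no_call | hwe_fail
    keep = np.array([j for j in range(table.n_sites) if j not in excluded])
    filtered = (
        table.subset_sites(keep) if keep.size else
        table.subset_sites(np.array([], dtype=int))
    )
    report = QcReport(
        n_designed=table.n_sites,
        n_failed_visual=len(visual),
        n_no_call=len(no_call),
        n_hwe_fail=len(hwe_fail),
        n_retained=table.n_sites - len(excluded),
        reasons=reasons,
    )
    return filtered, report


def allele_frequencies(table: GenotypeTable, by_population: bool = False
                       ) -> pd.DataFrame:
    """Per-site alternate-allele frequency and MAF over non-missing calls.

    With ``by_population`` the frequencies are additionally computed within
    each labelled population (columns ``f_<pop>``).  Sites where every call
    is missing get NaN.
    """
    if table.n_sites == 0:
        raise ValueError("empty genotype table")

    def _freq(calls: np.ndarray) -> np.ndarray:
        present = calls != MISSING
        n_chrom = 2 * present.sum(axis=0)
        alt = np.where(present, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)

    f = _freq(table.calls)
    out = pd.DataFrame(
        {"site": table.site_ids(), "f_alt": f, "maf": np.minimum(f, 1 - f)}
    )
    if by_population:
        if not table.labels:
            raise ValueError("per-population frequencies need labels")
        for pop in dict.fromkeys(table.labels.values()):
            rows = [i for i, s in enumerate(table.samples)
                    if table.labels.get(s) == pop]
            out[f"f_{pop}"] = _freq(table.calls[rows])
    return out
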