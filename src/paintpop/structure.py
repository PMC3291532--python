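"""PCA clustering, Hudson pairwise F_ST with block jackknife, concordance.

F_ST uses the Hudson estimator on population allele frequencies with the
standard finite-sample correction, combined across sites as a ratio of
averages (sum of per-site numerators over sum of per-site denominators).
Confidence intervals come from a delete-one-block jackknife over loci
(regions), a z-interval on the ratio statistic.

PCA operates on the genotype matrix after site-mean imputation of missing
calls and mean centring (no variance scaling).  Hybrid intermediacy is
scored geometrically: a sample exactly midway between its two nearest
cluster centroids scores 1, a sample at a centroid scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm
from sklearn.decomposition import PCA

from .containers import GenotypeTable, MISSING

__all__ = [
    "PcaResult",
    "FstResult",
    "pca_cluster",
    "hudson_fst_components",
    "pairwise_fst",
    "jackknife_ci",
    "uniparental_concordance",
]


@dataclass
class PcaResult:
    """Principal-component scores, cluster assignments, hybrid scores."""

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    assignments: pd.Series
    hybrid_scores: pd.Series
    centroids: pd.DataFrame


def pca_cluster(table: GenotypeTable, n_components: int = 2,
                labels: dict[str, str] | None = None,
                distance_threshold: float | None = None) -> PcaResult:
    """Project genotypes onto the top principal components and cluster.

    Clusters come from the provided reference ``labels`` when given
    (centroid per labelled population; every sample assigned to its nearest
    centroid); otherwise from connected components of the score-space graph
    linking samples closer than ``distance_threshold`` (default: 3x the
    median nearest-neighbour distance).
    """
    if table.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    calls = table.calls.astype(float)
    calls[table.calls == MISSING] = np.nan
    site_mean = np.nanmean(calls, axis=0)
    poly = np.nanvar(calls, axis=0) > 0
    if poly.sum() < 2:
        raise ValueError("PCA needs at least two polymorphic sites")
    inds = np.where(np.isnan(calls))
    calls[inds] = site_mean[inds[1]]
    calls = calls[:, poly]
    n_components = min(n_components, min(calls.shape) - 1)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(calls - calls.mean(axis=0))
    score_df = pd.DataFrame(
        scores, index=pd.Index(table.samples, name="sample"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )

    labels = labels if labels is not None else table.labels
    if labels:
        # known hybrids are not a reference population: no centroid for them
        pops = list(dict.fromkeys(
            labels[s] for s in table.samples
            if s in labels and labels[s] != "hybrid"
        ))
        centroids = pd.DataFrame(
            [
                score_df.loc[[s for s in table.samples
                              if labels.get(s) == pop]].mean()
                for pop in pops
            ],
            index=pops,
        )
    else:
        dist = squareform(pdist(scores))
        np.fill_diagonal(dist, np.inf)
        nn = dist.min(axis=1)
        thr = distance_threshold if distance_threshold is not None \
            else 3.0 * float(np.median(nn))
        adj = (dist <= thr).astype(int)
        n_comp, comp = connected_components(adj, directed=False)
        pops = [f"cluster{c + 1}" for c in range(n_comp)]
        centroids = pd.DataFrame(
            [score_df.iloc[comp == c].mean() for c in range(n_comp)],
            index=pops,
        )

    cent = centroids.to_numpy()
    d = np.linalg.norm(scores[:, None, :] - cent[None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    assignments = pd.Series(
        [centroids.index[i] for i in nearest], index=score_df.index,
        name="assignment",
    )

    hybrid = np.zeros(len(score_df))
    if len(centroids) >= 2:
        order = np.argsort(d, axis=1)
        for i in range(len(score_df)):
            c1, c2 = cent[order[i, 0]], cent[order[i, 1]]
            gap = np.linalg.norm(c1 - c2)
            if gap == 0:
                continue
            mid = (c1 + c2) / 2.0
            hybrid[i] = max(
                0.0, 1.0 - 2.0 * np.linalg.norm(scores[i] - mid) / gap
            )
    hybrid_scores = pd.Series(hybrid, index=score_df.index, name="hybrid_score")

    return PcaResult(
        scores=score_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        assignments=assignments,
        hybrid_scores=hybrid_scores,
        centroids=centroids,
    )


def hudson_fst_components(p1, p2, n1, n2):
    """Per-site Hudson F_ST numerator and denominator.

    ``p1``/``p2`` are sample allele frequencies, ``n1``/``n2`` the numbers
    of sampled chromosomes.  numerator = (p1-p2)^2 - p1(1-p1)/(n1-1)
    - p2(1-p2)/(n2-1); denominator = p1(1-p2) + p2(1-p1).  Accepts scalars
    or arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 1) or np.any(n2 <= 1):
        raise ValueError("Hudson F_ST needs more than one chromosome per deme")
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if num.ndim == 0:
        return float(num), float(den)
    return num, den


@dataclass
class FstResult:
    """Pairwise Hudson F_ST with per-block components and jackknife CIs."""

    matrix: pd.DataFrame
    ci: dict[tuple[str, str], tuple[float, float]]
    block_components: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]

    def table(self) -> pd.DataFrame:
        rows = []
        for (a, b), (lo, hi) in self.ci.items():
            rows.append((a, b, self.matrix.loc[a, b], lo, hi))
        return pd.DataFrame(
            rows, columns=["pop_a", "pop_b", "fst", "ci_low", "ci_high"]
        )


def _pop_freqs(table: GenotypeTable, rows: list[int]):
    calls = table.calls[rows]
    present = calls != MISSING
    n_chrom = 2 * present.sum(axis=0)
    alt = np.where(present, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
    return p, n_chrom.astype(float)


def pairwise_fst(table: GenotypeTable, labels: dict[str, str] | None = None,
                 blocks: np.ndarray | None = None,
                 alpha: float = 0.05) -> FstResult:
    """Hudson F_ST for every population pair, ratio of averages over sites.

    Sites monomorphic across the pooled pair, or with fewer than two
    chromosomes called in either population, are skipped.  ``blocks``
    (default: the site's region id) defines the jackknife unit.
    """
    labels = labels if labels is not None else table.labels
    if not labels:
        raise ValueError("pairwise F_ST needs population labels")
    pops: dict[str, list[int]] = {}
    for i, s in enumerate(table.samples):
        if s in labels and labels[s] != "hybrid":
            pops.setdefault(labels[s], []).append(i)
    pops = {p: rows for p, rows in pops.items() if len(rows) >= 2}
    if len(pops) < 2:
        raise ValueError("need at least two populations with two samples each")
    if blocks is None:
        blocks = table.sites["region"].to_numpy()
    blocks = np.asarray(blocks)

    names = list(pops)
    matrix = pd.DataFrame(0.0, index=names, columns=names)
    ci: dict[tuple[str, str], tuple[float, float]] = {}
    block_components: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    freqs = {p: _pop_freqs(table, rows) for p, rows in pops.items()}
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            a, b = names[ai], names[bi]
            p1, n1 = freqs[a]
            p2, n2 = freqs[b]
            ok = (n1 >= 2) & (n2 >= 2) & ~np.isnan(p1) & ~np.isnan(p2)
            pooled = np.where(ok, (p1 * n1 + p2 * n2) / np.maximum(n1 + n2, 1),
                              np.nan)
            ok &= (pooled > 0) & (pooled < 1)  # skip monomorphic-in-both
            if not ok.any():
                raise ValueError(
                    f"no usable polymorphic sites for pair ({a}, {b})"
                )
            num, den = hudson_fst_components(p1[ok], p2[ok], n1[ok], n2[ok])
            fst = float(num.sum() / den.sum())
            site_blocks = blocks[ok]
            uniq = list(dict.fromkeys(site_blocks))
            n_b = np.array([num[site_blocks == u].sum() for u in uniq])
            d_b = np.array([den[site_blocks == u].sum() for u in uniq])
            matrix.loc[a, b] = matrix.loc[b, a] = fst
            block_components[(a, b)] = (n_b, d_b)
            if len(uniq) >= 2:
                ci[(a, b)] = jackknife_ci(n_b, d_b, alpha=alpha)
    return FstResult(matrix=matrix, ci=ci, block_components=block_components)


def jackknife_ci(block_num: np.ndarray, block_den: np.ndarray,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Delete-one-block jackknife z-interval for a ratio-of-sums statistic."""
    block_num = np.asarray(block_num, dtype=float)
    block_den = np.asarray(block_den, dtype=float)
    n_blocks = block_num.size
    if n_blocks < 2:
        raise ValueError("jackknife needs at least two blocks")
    total_n, total_d = block_num.sum(), block_den.sum()
    estimate = total_n / total_d
    loo = (total_n - block_num) / (total_d - block_den)
    se = np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum())
    z = norm.ppf(1 - alpha / 2)
    return float(estimate - z * se), float(estimate + z * se)


def uniparental_concordance(genomewide_assignments: dict[str, str],
                            uniparental_labels: dict[str, str],
                            hybrid_flags: dict[str, bool] | None = None
                            ) -> tuple[pd.DataFrame, list[str]]:
    """Cross-tabulate single-locus labels against genome-wide assignments.

    Flagged hybrids are excluded from the comparison.  Returns the
    cross-tabulation (rows: genome-wide, columns: uniparental) and the list
    of discordant non-hybrid samples.
    """
    hybrid_flags = hybrid_flags or {}
    samples = [s for s in genomewide_assignments
               if not hybrid_flags.get(s, False)]
    missing = [s for s in samples if s not in uniparental_labels]
    if missing:
        raise KeyError(f"samples lack uniparental labels: {missing}")
    gw = pd.Series({s: genomewide_assignments[s] for s in samples})
    up = pd.Series({s: uniparental_labels[s] for s in samples})
    crosstab = pd.crosstab(gw, up, rownames=["genomewide"],
                           colnames=["uniparental"])
    discordant = sorted(s for s in samples if gw[s] != up[s])
    return crosstab, discordant
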