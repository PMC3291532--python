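"""Ancestry-informative SNP panel selection and assignment evaluation.

SNPs are ranked by how well each one alone classifies training samples:
within every population the genotype probability follows Hardy-Weinberg
proportions computed from training-sample allele frequencies, a sample is
assigned to the population under which its genotype is most probable, and
the per-SNP training accuracy is the fraction of correct assignments (ties
and missing genotypes count as incorrect).  The panel is then filled
greedily down the ranking, skipping any SNP whose region (locus) is already
represented, so panel SNPs are effectively unlinked and a naive-Bayes
product over panel SNPs is a sound multi-SNP assignment rule.  Held-out
individuals never enter frequency estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeTable, MISSING

__all__ = [
    "SnpPanel",
    "split_train_test",
    "single_snp_assign",
    "rank_and_select",
    "evaluate_panel",
    "frequency_differentials",
    "centroid_assign",
]

UNASSIGNED = "unassigned"


def split_train_test(labels: dict[str, str],
                     hybrid_flags: dict[str, bool] | None = None,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Per-population random half split of the non-hybrid samples.

    Odd population sizes send the extra sample to training.  Training and
    test sets are disjoint and together cover every non-hybrid sample.
    """
    hybrid_flags = hybrid_flags or {}
    rng = np.random.default_rng(seed)
    pops: dict[str, list[str]] = {}
    for s, pop in labels.items():
        if not hybrid_flags.get(s, False):
            pops.setdefault(pop, []).append(s)
    train: list[str] = []
    test: list[str] = []
    for pop, members in pops.items():
        if len(members) < 2:
            raise ValueError(
                f"population {pop!r} has {len(members)} non-hybrid sample(s);"
                " need at least two to split"
            )
        members = list(members)
        order = rng.permutation(len(members))
        n_train = (len(members) + 1) // 2  # odd counts round up to training
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return sorted(train), sorted(test)


def single_snp_assign(genotype: int, pop_freqs: dict[str, float]) -> str:
    """Assign one genotype to the population where it is most probable.

    Genotype probabilities follow Hardy-Weinberg proportions:
    P(0) = (1-f)^2, P(1) = 2 f (1-f), P(2) = f^2.  Missing genotypes and
    exact ties return ``"unassigned"``.
    """
    if genotype == MISSING or genotype is None:
        return UNASSIGNED
    if genotype not in (0, 1, 2):
        raise ValueError(f"invalid genotype {genotype!r}")
    best_pop, best_p, tie = UNASSIGNED, -1.0, False
    for pop, f in pop_freqs.items():
        p = _hwe_prob(genotype, f)
        if p > best_p * (1 + 1e-12):
            best_pop, best_p, tie = pop, p, False
        elif abs(p - best_p) <= 1e-12 * max(p, best_p):
            tie = True
    return UNASSIGNED if tie else best_pop


def _hwe_prob(genotype: int, f: float) -> float:
    if genotype == 0:
        return (1 - f) ** 2
    if genotype == 1:
        return 2 * f * (1 - f)
    return f ** 2


def _training_freqs(table: GenotypeTable, labels: dict[str, str],
                    train_ids: list[str]) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-population alt-allele frequencies from training samples only,
    floored away from 0/1 so no genotype gets probability zero."""
    pops: dict[str, list[int]] = {}
    for s in train_ids:
        pops.setdefault(labels[s], []).append(table.samples.index(s))
    freqs = {}
    n_train = {}
    for pop, rows in pops.items():
        calls = table.calls[rows]
        present = calls != MISSING
        n_chrom = 2 * present.sum(axis=0)
        alt = np.where(present, calls, 0).sum(axis=0)
        f = alt / np.maximum(n_chrom, 1)
        floor = 1.0 / (n_chrom + 1)
        freqs[pop] = np.clip(f, floor, 1 - floor)
        n_train[pop] = len(rows)
    return pd.DataFrame(freqs, index=table.site_ids()), n_train


@dataclass
class SnpPanel:
    """Ranked distinct-locus SNP subset with classification accuracies."""

    table: pd.DataFrame              # rank, site, region, train_accuracy, max_differential
    site_index: np.ndarray           # column indices into the source table
    training_freqs: pd.DataFrame     # per-pop frequencies at panel SNPs
    train_ids: list[str]
    train_accuracy: float
    test_accuracy: float | None = None


def rank_and_select(table: GenotypeTable, labels: dict[str, str],
                    train_ids: list[str], panel_size: int,
                    distinct_locus: bool = True) -> SnpPanel:
    """Rank SNPs by single-SNP training accuracy and select a panel.

    Ties in accuracy break by larger maximum pairwise frequency
    differential, then by site order.  With ``distinct_locus`` at most one
    SNP per region enters the panel.
    """
    if panel_size < 1:
        raise ValueError("panel size must be positive")
    freqs, _ = _training_freqs(table, labels, train_ids)
    site_ids = table.site_ids()
    regions = table.sites["region"].to_numpy()
    train_rows = [table.samples.index(s) for s in train_ids]
    train_labels = [labels[s] for s in train_ids]

    pop_list = list(freqs.columns)
    fmat = freqs.to_numpy()  # sites x pops
    # accuracy of each SNP on the training samples
    acc = np.zeros(table.n_sites)
    for j in range(table.n_sites):
        pf = {pop: fmat[j, p] for p, pop in enumerate(pop_list)}
        correct = 0
        for row, want in zip(train_rows, train_labels):
            if single_snp_assign(int(table.calls[row, j]), pf) == want:
                correct += 1
        acc[j] = correct / len(train_rows)
    diffs = np.zeros(table.n_sites)
    for j in range(table.n_sites):
        diffs[j] = max(
            abs(fmat[j, a] - fmat[j, b])
            for a in range(len(pop_list)) for b in range(a + 1, len(pop_list))
        )
    order = sorted(range(table.n_sites),
                   key=lambda j: (-acc[j], -diffs[j], j))

    chosen: list[int] = []
    used_regions: set[str] = set()
    for j in order:
        if distinct_locus and regions[j] in used_regions:
            continue
        chosen.append(j)
        used_regions.add(regions[j])
        if len(chosen) == panel_size:
            break
    if len(chosen) < panel_size:
        raise ValueError(
            f"only {len(chosen)} usable region(s); cannot build a "
            f"{panel_size}-SNP distinct-locus panel"
        )

    panel_tbl = pd.DataFrame(
        {
            "rank": np.arange(1, panel_size + 1),
            "site": [site_ids[j] for j in chosen],
            "region": [regions[j] for j in chosen],
            "train_accuracy": acc[chosen],
            "max_differential": diffs[chosen],
        }
    )
    panel = SnpPanel(
        table=panel_tbl,
        site_index=np.asarray(chosen),
        training_freqs=freqs.iloc[chosen],
        train_ids=list(train_ids),
        train_accuracy=np.nan,
    )
    assign = _panel_assign(panel, table, train_ids)
    panel.train_accuracy = float(
        np.mean([assign[s] == labels[s] for s in train_ids])
    )
    return panel


def _panel_assign(panel: SnpPanel, table: GenotypeTable,
                  sample_ids: list[str]) -> dict[str, str]:
    """Naive-Bayes multi-SNP assignment: sum of log HWE genotype
    probabilities over panel SNPs, missing genotypes skipped."""
    pop_list = list(panel.training_freqs.columns)
    fmat = panel.training_freqs.to_numpy()
    out: dict[str, str] = {}
    for s in sample_ids:
        row = table.samples.index(s)
        logp = np.zeros(len(pop_list))
        informative = False
        for jj, j in enumerate(panel.site_index):
            g = int(table.calls[row, j])
            if g == MISSING:
                continue
            informative = True
            for p in range(len(pop_list)):
                logp[p] += np.log(_hwe_prob(g, fmat[jj, p]))
        if not informative:
            out[s] = UNASSIGNED
            continue
        best = logp.max()
        winners = np.flatnonzero(logp >= best - 1e-12)
        out[s] = pop_list[winners[0]] if winners.size == 1 else UNASSIGNED
    return out


def evaluate_panel(panel: SnpPanel, table: GenotypeTable,
                   labels: dict[str, str], test_ids: list[str]
                   ) -> tuple[float, pd.DataFrame]:
    """Classify held-out samples with the panel and report accuracy.

    Raises if any test sample was used for training (leakage guard).
    Returns the accuracy (unassigned counts as incorrect) and a per-sample
    report with every misassignment visible.
    """
    if len(panel.site_index) == 0:
        raise ValueError("empty panel")
    overlap = set(test_ids) & set(panel.train_ids)
    if overlap:
        raise ValueError(
            f"test samples also used in training: {sorted(overlap)}"
        )
    assign = _panel_assign(panel, table, list(test_ids))
    rows = []
    for s in test_ids:
        rows.append((s, labels[s], assign[s], assign[s] == labels[s]))
    report = pd.DataFrame(
        rows, columns=["sample", "true_population", "assigned", "correct"]
    )
    accuracy = float(report["correct"].mean())
    panel.test_accuracy = accuracy
    return accuracy, report


def frequency_differentials(table: GenotypeTable,
                            labels: dict[str, str] | None = None
                            ) -> pd.DataFrame:
    """Per-SNP max pairwise and one-vs-rest allele frequency differentials.

    One-vs-rest pools the allele counts of all other populations.
    """
    labels = labels if labels is not None else table.labels
    if not labels:
        raise ValueError("frequency differentials need labels")
    pops: dict[str, list[int]] = {}
    for i, s in enumerate(table.samples):
        if s in labels and labels[s] != "hybrid":
            pops.setdefault(labels[s], []).append(i)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    alt = {}
    chrom = {}
    for pop, rows in pops.items():
        calls = table.calls[rows]
        present = calls != MISSING
        chrom[pop] = 2 * present.sum(axis=0)
        alt[pop] = np.where(present, calls, 0).sum(axis=0)
    freqs = {pop: alt[pop] / np.maximum(chrom[pop], 1) for pop in pops}
    names = list(pops)
    out = pd.DataFrame({"site": table.site_ids(),
                        "region": table.sites["region"]})
    max_pair = np.zeros(table.n_sites)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            max_pair = np.maximum(
                max_pair, np.abs(freqs[names[a]] - freqs[names[b]])
            )
    out["max_pairwise_diff"] = max_pair
    total_alt = sum(alt.values())
    total_chrom = sum(chrom.values())
    for pop in names:
        rest_alt = total_alt - alt[pop]
        rest_chrom = total_chrom - chrom[pop]
        rest_f = rest_alt / np.maximum(rest_chrom, 1)
        out[f"diff_{pop}_vs_rest"] = np.abs(freqs[pop] - rest_f)
    return out


def centroid_assign(table: GenotypeTable, labels: dict[str, str],
                    train_ids: list[str], test_ids: list[str]
                    ) -> dict[str, str]:
    """Full-data nearest-centroid assignment (the whole-SNP-set baseline).

    Population centroids are mean genotype vectors over training samples
    (missing calls ignored sitewise); test samples go to the nearest
    centroid in Euclidean distance over their non-missing sites.
    """
    pops: dict[str, list[int]] = {}
    for s in train_ids:
        pops.setdefault(labels[s], []).append(table.samples.index(s))
    centroids = {}
    for pop, rows in pops.items():
        calls = table.calls[rows].astype(float)
        calls[table.calls[rows] == MISSING] = np.nan
        centroids[pop] = np.nanmean(calls, axis=0)
    out = {}
    for s in test_ids:
        row = table.calls[table.samples.index(s)].astype(float)
        present = row != MISSING
        best, best_d = UNASSIGNED, np.inf
        for pop, c in centroids.items():
            ok = present & ~np.isnan(c)
            d = float(((row[ok] - c[ok]) ** 2).sum())
            if d < best_d:
                best, best_d = pop, d
        out[s] = best
    return out
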