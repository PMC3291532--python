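"""Core in-memory containers shared by every pipeline stage.

Two containers cover the data the pipeline touches:

* :class:`GenotypeTable` — unphased diploid genotypes coded 0/1/2 (count of
  the alternate allele), with ``-1`` marking a missing call.
* :class:`HaplotypePanel` — phased 0/1 haplotypes, two rows per diploid
  individual, together with a per-interval genetic map in Morgans.

Site metadata live in a :class:`pandas.DataFrame` with columns
``region`` (locus/cluster identifier), ``pos`` (1-based position within the
region), ``ref`` and ``alt`` (alleles).  Positions are strictly increasing
within a region; regions are unlinked, so no genetic distance is defined
across a region boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ("region", "pos", "ref", "alt")


def make_sites(regions, positions, ref=None, alt=None) -> pd.DataFrame:
    """Assemble a site-metadata frame and validate its ordering."""
    regions = list(regions)
    positions = np.asarray(positions, dtype=int)
    n = len(regions)
    if len(positions) != n:
        raise ValueError("regions and positions must have equal length")
    ref = ["A"] * n if ref is None else list(ref)
    alt = ["G"] * n if alt is None else list(alt)
    sites = pd.DataFrame(
        {"region": regions, "pos": positions, "ref": ref, "alt": alt}
    )
    _check_sites(sites)
    return sites


def _check_sites(sites: pd.DataFrame) -> None:
    for col in SITE_COLUMNS:
        if col not in sites.columns:
            raise ValueError(f"site table lacks required column {col!r}")
    for region, sub in sites.groupby("region", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(
                f"positions not strictly increasing within region {region!r}"
            )


@dataclass
class GenotypeTable:
    """Unphased genotype matrix (samples x sites, values 0/1/2, -1 missing)."""

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be 0, 1, 2 or -1 (missing)")
        _check_sites(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_ids(self) -> list[str]:
        return [
            f"{r}:{p}" for r, p in zip(self.sites["region"], self.sites["pos"])
        ]

    def subset_sites(self, index) -> "GenotypeTable":
        index = np.asarray(index)
        return GenotypeTable(
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index].copy(),
            labels=dict(self.labels) if self.labels else None,
        )

    def subset_samples(self, sample_ids) -> "GenotypeTable":
        idx = [self.samples.index(s) for s in sample_ids]
        labels = None
        if self.labels:
            labels = {s: self.labels[s] for s in sample_ids if s in self.labels}
        return GenotypeTable(
            samples=list(sample_ids),
            sites=self.sites.reset_index(drop=True),
            calls=self.calls[idx].copy(),
            labels=labels,
        )

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            samples=list(self.samples),
            sites=self.sites.copy().reset_index(drop=True),
            calls=self.calls.copy(),
            labels=dict(self.labels) if self.labels else None,
        )


@dataclass
class HaplotypePanel:
    """Phased haplotypes, two consecutive rows per diploid individual.

    ``intervals[j]`` is the genetic distance in Morgans between site ``j-1``
    and site ``j``; its value at the first site of each region is undefined
    and ignored (regions are unlinked).
    """

    individuals: list[str]
    sites: pd.DataFrame
    haplotypes: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.haplotypes.shape != (2 * len(self.individuals), len(self.sites)):
            raise ValueError(
                "haplotype matrix must have two rows per individual and one "
                "column per site"
            )
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        if self.intervals.shape != (len(self.sites),):
            raise ValueError("intervals must have one entry per site")
        if np.any(self.intervals[self._interior_mask()] < 0):
            raise ValueError("genetic distances must be non-negative")
        _check_sites(self.sites)

    def _interior_mask(self) -> np.ndarray:
        """True at sites that have a defined distance to the previous site."""
        regions = self.sites["region"].to_numpy()
        mask = np.ones(len(regions), dtype=bool)
        mask[0] = False
        mask[1:] = regions[1:] == regions[:-1]
        return mask

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def region_ids(self) -> np.ndarray:
        return self.sites["region"].to_numpy()

    def haplotype_names(self) -> list[str]:
        return [f"{ind}.{a}" for ind in self.individuals for a in (0, 1)]

    def individual_of_haplotype(self, row: int) -> str:
        return self.individuals[row // 2]

    def region_slices(self) -> dict[str, slice]:
        """Contiguous column slice per region, in site order."""
        regions = self.region_ids
        out: dict[str, slice] = {}
        start = 0
        for j in range(1, len(regions) + 1):
            if j == len(regions) or regions[j] != regions[j - 1]:
                out[regions[start]] = slice(start, j)
                start = j
        return out

    def genotypes(self, labels: dict[str, str] | None = None) -> GenotypeTable:
        """Collapse phased haplotypes into a diploid 0/1/2 genotype table."""
        calls = self.haplotypes[0::2] + self.haplotypes[1::2]
        return GenotypeTable(
            samples=list(self.individuals),
            sites=self.sites.copy().reset_index(drop=True),
            calls=calls,
            labels=dict(labels) if labels else None,
        )

    def subset_sites(self, index) -> "HaplotypePanel":
        index = np.asarray(index)
        sub_sites = self.sites.iloc[index].reset_index(drop=True)
        # distances across removed sites are re-derived from positions is not
        # possible in general; keep per-interval distances by summing the gaps
        # between retained neighbours within a region.
        new_intervals = np.zeros(len(index), dtype=float)
        regions = self.sites["region"].to_numpy()
        cum = np.zeros(self.n_sites)
        mask = self._interior_mask()
        cum[mask] = self.intervals[mask]
        csum = np.cumsum(cum)
        for out_j in range(1, len(index)):
            a, b = index[out_j - 1], index[out_j]
            if regions[a] == regions[b]:
                new_intervals[out_j] = csum[b] - csum[a]
        return HaplotypePanel(
            individuals=list(self.individuals),
            sites=sub_sites,
            haplotypes=self.haplotypes[:, index].copy(),
            intervals=new_intervals,
        )

    def subset_individuals(self, individual_ids) -> "HaplotypePanel":
        idx = [self.individuals.index(s) for s in individual_ids]
        rows = np.array([(2 * i, 2 * i + 1) for i in idx]).reshape(-1)
        return HaplotypePanel(
            individuals=list(individual_ids),
            sites=self.sites.copy().reset_index(drop=True),
            haplotypes=self.haplotypes[rows].copy(),
            intervals=self.intervals.copy(),
        )

    def copy(self) -> "HaplotypePanel":
        return replace(
            self,
            individuals=list(self.individuals),
            sites=self.sites.copy().reset_index(drop=True),
            haplotypes=self.haplotypes.copy(),
            intervals=self.intervals.copy(),
        )
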