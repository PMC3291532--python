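"""Shared fixtures: small simulated datasets and a QC filter fixture."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import paintpop as pp
from paintpop.containers import GenotypeTable, make_sites


@pytest.fixture(scope="session")
def small_dataset() -> pp.SyntheticDataset:
    """Three populations with two planted F1 hybrids, modest size."""
    cfg = pp.SimConfig(
        samples_per_pop=8, n_regions=8, snps_per_region=12, n_hybrids=2,
        seed=2,
    )
    return pp.simulate_panel(cfg)


@pytest.fixture(scope="session")
def tiny_panel() -> pp.HaplotypePanel:
    """A very small haplotype panel for copying-model unit tests."""
    cfg = pp.SimConfig(
        samples_per_pop=4, n_regions=4, snps_per_region=8, seed=5,
    )
    return pp.simulate_panel(cfg).haplotypes


def build_qc_fixture() -> tuple[GenotypeTable, list[str]]:
    """A 768-SNP genotype table with disjoint planted QC failures.

    58 sites carry a visual-inspection flag, 14 others one missing call,
    and 5 others an extreme heterozygote excess within one population; all
    remaining sites follow Hardy-Weinberg proportions exactly.
    """
    n_pops, per_pop, n_sites = 3, 18, 768
    samples = [f"pop{p + 1}_i{i + 1:02d}" for p in range(n_pops)
               for i in range(per_pop)]
    labels = {s: s.split("_")[0] for s in samples}
    # HWE-conformant column: per population 6 ref-hom, 9 het, 3 alt-hom
    column = np.array(([0] * 6 + [1] * 9 + [2] * 3) * n_pops, dtype=np.int8)
    calls = np.tile(column[:, None], (1, n_sites))
    sites = make_sites(
        ["chr1"] * n_sites, np.arange(1, n_sites + 1) * 100
    )
    visual_idx = list(range(0, 58))
    nocall_idx = list(range(58, 72))
    hwe_idx = list(range(72, 77))
    for j in nocall_idx:
        calls[0, j] = pp.MISSING
    for j in hwe_idx:
        calls[:per_pop, j] = 1  # every pop1 individual heterozygous
    table = GenotypeTable(samples=samples, sites=sites, calls=calls,
                          labels=labels)
    flags = [table.site_ids()[j] for j in visual_idx]
    return table, flags


@pytest.fixture()
def qc_fixture() -> tuple[GenotypeTable, list[str]]:
    return build_qc_fixture()
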