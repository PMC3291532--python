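"""Readers and writers for the pipeline's on-disk formats.

All formats are plain text:

* genotypes — VCF v4.2 (biallelic SNPs, GT field, ``./.`` missing) or a TSV
  with one sample row per line and one site per column (values 0/1/2/NA);
* haplotypes — an alleles file (one row per haplotype, ``<individual>.<0|1>``
  in the first column) plus a site legend (region, position, ref, alt);
* genetic map — three columns (region, position, cumulative Morgans within
  the region);
* sample→population labels — two-column TSV;
* regions — BED (0-based half-open), one record per region.

Coordinates follow the conventions of each format: VCF/legend positions are
1-based inclusive, BED intervals 0-based half-open; the conversion happens
only here.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import GenotypeTable, HaplotypePanel, MISSING, make_sites

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_haplotypes",
    "write_haplotypes",
    "read_genetic_map",
    "write_genetic_map",
    "read_labels",
    "write_labels",
    "read_regions_bed",
    "write_regions_bed",
    "write_table",
]


# ---------------------------------------------------------------- genotypes

def read_genotypes(path, format: str = "vcf") -> GenotypeTable:
    """Read a genotype table from ``vcf`` or ``tsv``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(table: GenotypeTable, path, format: str = "vcf") -> None:
    path = Path(path)
    if format == "vcf":
        _write_vcf(table, path)
    elif format == "tsv":
        _write_genotype_tsv(table, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeTable:
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    regions, positions, ref, alt, rows = [], [], [], [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(
                f"site {rec.chrom}:{rec.pos} is not biallelic "
                f"(alts={rec.alts})"
            )
        regions.append(rec.chrom)
        positions.append(rec.pos)
        ref.append(rec.ref)
        alt.append(rec.alts[0])
        row = np.empty(len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s]["GT"]
            if gt is None or any(a is None for a in gt):
                row[i] = MISSING
            else:
                row[i] = sum(gt)
        rows.append(row)
    vf.close()
    calls = np.array(rows, dtype=np.int8).T if rows else np.zeros(
        (len(samples), 0), dtype=np.int8
    )
    return GenotypeTable(
        samples=samples,
        sites=make_sites(regions, positions, ref, alt),
        calls=calls,
    )


def _write_vcf(table: GenotypeTable, path: Path) -> None:
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for region in dict.fromkeys(table.sites["region"]):
        header.contigs.add(str(region))
    for s in table.samples:
        header.add_sample(s)
    vf = pysam.VariantFile(str(path), "w", header=header)
    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    for j, site in table.sites.iterrows():
        rec = vf.new_record(
            contig=str(site["region"]),
            start=int(site["pos"]) - 1,
            stop=int(site["pos"]),
            alleles=(str(site["ref"]), str(site["alt"])),
        )
        for i, s in enumerate(table.samples):
            rec.samples[s]["GT"] = gt_codes[int(table.calls[i, j])]
        vf.write(rec)
    vf.close()


def _read_genotype_tsv(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str,
                     keep_default_na=False)
    site_ids = list(df.columns)
    regions, positions = [], []
    for sid in site_ids:
        region, pos = sid.rsplit(":", 1)
        regions.append(region)
        positions.append(int(pos))
    calls = df.to_numpy()
    out = np.where(calls == "NA", MISSING, calls).astype(np.int8)
    return GenotypeTable(
        samples=list(df.index),
        sites=make_sites(regions, positions),
        calls=out,
    )


def _write_genotype_tsv(table: GenotypeTable, path: Path) -> None:
    df = pd.DataFrame(
        np.where(table.calls == MISSING, "NA", table.calls.astype(str)),
        index=pd.Index(table.samples, name="sample"),
        columns=table.site_ids(),
    )
    df.to_csv(path, sep="\t")


# --------------------------------------------------------------- haplotypes

def write_haplotypes(panel: HaplotypePanel, alleles_path, legend_path,
                     map_path=None) -> None:
    """Write the alleles matrix, the site legend and (optionally) the map."""
    with open(alleles_path, "w") as fh:
        fh.write("haplotype\t" + "\t".join(
            f"{r}:{p}" for r, p in zip(panel.sites["region"], panel.sites["pos"])
        ) + "\n")
        for name, row in zip(panel.haplotype_names(), panel.haplotypes):
            fh.write(name + "\t" + "\t".join(map(str, row)) + "\n")
    panel.sites.to_csv(legend_path, sep="\t", index=False)
    if map_path is not None:
        write_genetic_map(panel, map_path)


def read_haplotypes(alleles_path, legend_path, map_path=None) -> HaplotypePanel:
    legend = pd.read_csv(legend_path, sep="\t", dtype={"region": str})
    alleles = pd.read_csv(alleles_path, sep="\t", index_col=0)
    hap = alleles.to_numpy(dtype=np.int8)
    names = list(alleles.index)
    individuals: list[str] = []
    for j in range(0, len(names), 2):
        ind_a, a = names[j].rsplit(".", 1)
        ind_b, b = names[j + 1].rsplit(".", 1)
        if ind_a != ind_b or (a, b) != ("0", "1"):
            raise ValueError(
                f"haplotype rows {names[j]!r}/{names[j + 1]!r} do not form "
                "an individual's pair"
            )
        individuals.append(ind_a)
    if map_path is not None:
        intervals = _intervals_from_map(legend, read_genetic_map(map_path))
    else:
        intervals = np.zeros(len(legend))
    return HaplotypePanel(
        individuals=individuals,
        sites=legend.reset_index(drop=True),
        haplotypes=hap,
        intervals=intervals,
    )


def write_genetic_map(panel: HaplotypePanel, path) -> None:
    """Three-column map: region, 1-based position, cumulative Morgans."""
    rows = []
    for region, sl in panel.region_slices().items():
        cum = 0.0
        for j in range(sl.start, sl.stop):
            if j > sl.start:
                cum += panel.intervals[j]
            rows.append((region, int(panel.sites["pos"].iloc[j]), cum))
    pd.DataFrame(rows, columns=["region", "pos", "morgans"]).to_csv(
        path, sep="\t", index=False
    )


def read_genetic_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"region": str})
    if list(df.columns) != ["region", "pos", "morgans"]:
        raise ValueError("genetic map must have columns region, pos, morgans")
    return df


def _intervals_from_map(legend: pd.DataFrame, gmap: pd.DataFrame) -> np.ndarray:
    cum = {}
    for _, row in gmap.iterrows():
        cum[(str(row["region"]), int(row["pos"]))] = float(row["morgans"])
    intervals = np.zeros(len(legend))
    regions = legend["region"].astype(str).to_numpy()
    pos = legend["pos"].to_numpy()
    for j in range(1, len(legend)):
        if regions[j] == regions[j - 1]:
            try:
                intervals[j] = (
                    cum[(regions[j], int(pos[j]))]
                    - cum[(regions[j - 1], int(pos[j - 1]))]
                )
            except KeyError as exc:
                raise ValueError(f"genetic map lacks site {exc}") from exc
    return intervals


# ------------------------------------------------------- labels and regions

def write_labels(labels: dict[str, str], path) -> None:
    pd.DataFrame(
        {"sample": list(labels), "population": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["sample", "population"]:
        raise ValueError("labels file must have columns sample, population")
    return dict(zip(df["sample"], df["population"]))


def write_regions_bed(sites: pd.DataFrame, path) -> None:
    """One BED record per region spanning its first..last site (half-open)."""
    with open(path, "w") as fh:
        for region, sub in sites.groupby("region", sort=False):
            start = int(sub["pos"].min()) - 1  # BED is 0-based
            end = int(sub["pos"].max())
            fh.write(f"{region}\t{start}\t{end}\t{region}\n")


def read_regions_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name"], dtype={"chrom": str},
    )
    return df


# ----------------------------------------------------------- table writing

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_table(df: pd.DataFrame, path, inputs=(), comments=(), index=False) -> None:
    """Write a TSV with provenance header comments naming input hashes."""
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        for inp in inputs:
            fh.write(f"# derived-from: {Path(inp).name} sha256={_sha256(inp)}\n")
        df.to_csv(fh, sep="\t", index=index)
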