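"""Readers and writers for all on-disk interchange formats.

* genotypes: VCF v4.2 (GT field only; biallelic records; site metadata in
  the ``SRC``/``TRAIT`` INFO tags),
* depth tables: long-format TSV ``sample_id / region_id / depth`` with a
  companion per-sample totals TSV,
* panels: BED (0-based half-open, width-1 intervals for SNPs) plus a TSV
  carrying site metadata, MAF and selection status,
* reference sequences: FASTA,
* run configuration: YAML (see :mod:`gbtspanel.config`).

All TSV output is UTF-8, tab-delimited, with ``.`` for missing numeric
fields.  Internal coordinates are 1-based; only BED emission converts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .core import (
    MISSING,
    SITE_COLUMNS,
    TOTALS_COLUMNS,
    DepthMatrix,
    GenotypeMatrix,
    validate_site_frame,
)
from .errors import FormatError, UnsupportedRecordError, ValidationError

NA = "."


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path) -> GenotypeMatrix:
    """Read a biallelic VCF into a coded :class:`GenotypeMatrix`.

    Multi-allelic records are rejected (splitting them would silently
    change downstream allele frequencies).  ``./.`` and half-missing calls
    map to MISSING.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    site_rows = []
    columns = []
    try:
        for variant in vcf:
            if len(variant.ALT) != 1:
                site_id = variant.ID or f"{variant.CHROM}_{variant.POS}"
                raise UnsupportedRecordError(
                    f"multi-allelic record {site_id} at {variant.CHROM}:{variant.POS}"
                )
            ref, alt = variant.REF, variant.ALT[0]
            vclass = "SNP" if len(ref) == 1 and len(alt) == 1 else "InDel"
            src = variant.INFO.get("SRC") or "db1"
            trait = variant.INFO.get("TRAIT") is not None or src == "trait"
            site_rows.append((
                variant.ID or f"{variant.CHROM}_{variant.POS}",
                variant.CHROM, variant.POS, ref, alt, vclass,
                "trait" if trait else src, trait,
            ))
            col = np.empty(len(samples), dtype=np.int8)
            for i, gt in enumerate(variant.genotypes):
                a, b = gt[0], gt[1]
                col[i] = MISSING if (a < 0 or b < 0) else a + b
            columns.append(col)
    except UnsupportedRecordError:
        raise
    except Exception as exc:
        raise FormatError(f"malformed VCF {path}: {exc}") from exc
    sites = pd.DataFrame(site_rows, columns=list(SITE_COLUMNS))
    calls = (
        np.stack(columns, axis=1)
        if columns else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=SRC,Number=1,Type=String,Description="Source database tag">\n'
    '##INFO=<ID=TRAIT,Number=0,Type=Flag,Description="Trait-specific marker site">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write a :class:`GenotypeMatrix` as a minimal GT-only VCF v4.2 file."""
    order = np.lexsort((gm.sites["pos"].to_numpy(), gm.sites["chrom"].to_numpy()))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        chroms = gm.sites["chrom"].iloc[order].drop_duplicates()
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for j in order:
            site = gm.sites.iloc[j]
            info = f"SRC={site.source_db}"
            if site.is_trait_marker:
                info += ";TRAIT"
            gts = "\t".join(_GT_STRINGS[int(c)] for c in gm.calls[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.site_id}\t{site.ref_allele}"
                f"\t{site.alt_allele}\t.\t.\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Depth tables
# ---------------------------------------------------------------------------

def read_depth_table(depth_path, totals_path) -> DepthMatrix:
    """Read a long-format depth TSV plus a per-sample totals TSV.

    Absent (sample, region) pairs are dense zeros.  Sample order follows
    the totals file; region order follows first appearance in the depth
    file.
    """
    long = pd.read_csv(depth_path, sep="\t", dtype={"sample_id": str, "region_id": str})
    expected = ["sample_id", "region_id", "depth"]
    if list(long.columns) != expected:
        raise FormatError(f"{depth_path}: expected columns {expected}, got {list(long.columns)}")
    if (long["depth"] < 0).any():
        raise ValidationError(f"{depth_path}: negative depth value")
    totals = pd.read_csv(totals_path, sep="\t", dtype={"sample_id": str})
    if list(totals.columns) != ["sample_id", *TOTALS_COLUMNS]:
        raise FormatError(f"{totals_path}: unexpected columns {list(totals.columns)}")
    totals = totals.set_index("sample_id")
    samples = list(totals.index)
    regions = list(dict.fromkeys(long["region_id"]))
    unknown = set(long["sample_id"]) - set(samples)
    if unknown:
        raise ValidationError(f"depth rows for samples absent from totals: {sorted(unknown)[:3]}")
    depth = np.zeros((len(samples), len(regions)), dtype=np.int64)
    s_idx = {s: i for i, s in enumerate(samples)}
    r_idx = {r: j for j, r in enumerate(regions)}
    depth[
        long["sample_id"].map(s_idx).to_numpy(),
        long["region_id"].map(r_idx).to_numpy(),
    ] = long["depth"].to_numpy()
    return DepthMatrix(samples=samples, regions=regions, depth=depth, totals=totals)


def write_depth_table(dm: DepthMatrix, depth_path, totals_path) -> None:
    """Write the long-format depth TSV (zero cells omitted) and totals TSV."""
    s_grid, r_grid = np.nonzero(dm.depth)
    long = pd.DataFrame({
        "sample_id": np.array(dm.samples, dtype=object)[s_grid],
        "region_id": np.array(dm.regions, dtype=object)[r_grid],
        "depth": dm.depth[s_grid, r_grid],
    })
    long.to_csv(depth_path, sep="\t", index=False)
    dm.totals.rename_axis("sample_id").reset_index().to_csv(
        totals_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

PANEL_TSV_COLUMNS = [*SITE_COLUMNS, "maf", "status"]


def write_panel(panel_table: pd.DataFrame, bed_path, tsv_path) -> None:
    """Write a panel as BED + TSV, sorted by (chrom, pos).

    ``panel_table`` must carry the canonical site columns plus ``maf``
    (NaN allowed, written as ``.``) and ``status``.
    """
    if len(panel_table) == 0:
        raise ValidationError("cannot write an empty panel")
    validate_site_frame(panel_table)
    for col in ("maf", "status"):
        if col not in panel_table.columns:
            raise ValidationError(f"panel table missing column {col!r}")
    ordered = panel_table.sort_values(["chrom", "pos"], kind="mergesort")
    with open(bed_path, "w", encoding="utf-8") as fh:
        for r in ordered.itertuples(index=False):
            # 1-based inclusive position -> 0-based half-open interval
            end = r.pos + max(len(r.ref_allele) - 1, 0)
            fh.write(f"{r.chrom}\t{r.pos - 1}\t{end}\t{r.site_id}\n")
    out = ordered[PANEL_TSV_COLUMNS].copy()
    out.to_csv(tsv_path, sep="\t", index=False, na_rep=NA)


def read_panel(tsv_path) -> pd.DataFrame:
    """Read a panel TSV back into the canonical table (inverse of write_panel)."""
    df = pd.read_csv(
        tsv_path, sep="\t", na_values=[NA], keep_default_na=False,
        dtype={"site_id": str, "chrom": str, "status": str},
    )
    if list(df.columns) != PANEL_TSV_COLUMNS:
        raise FormatError(f"{tsv_path}: unexpected panel columns {list(df.columns)}")
    df["is_trait_marker"] = df["is_trait_marker"].map(
        {"True": True, "False": False, True: True, False: False}
    ).astype(bool)
    validate_site_frame(df)
    return df


# ---------------------------------------------------------------------------
# FASTA reference
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Load a reference FASTA as {sequence name: uppercase sequence}."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise FormatError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Generic TSV report helper
# ---------------------------------------------------------------------------

def write_report(df: pd.DataFrame, path) -> None:
    """Write a report table as UTF-8 TSV with '.' for missing values."""
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
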