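"""Per-site diversity statistics and marker-set summary tables.

Statistics follow the field's standard definitions: minor allele
frequency (MAF), polymorphism information content

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2,

observed allele number Ao (alleles with p > 0), effective allele number
Ae = 1 / sum_i p_i^2, observed heterozygosity Ho (fraction of non-missing
calls that are heterozygous) and Nei's expected heterozygosity
He = 1 - sum_i p_i^2.  Allele frequencies are always computed over
non-missing calls only.  PIC values are labelled low (<= 0.10), medium
(0.10, 0.25], high (0.25, 0.40] and very high (0.40, 0.50].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .errors import ValidationError

PIC_CATEGORIES = ("low", "medium", "high", "very_high")


@dataclass
class AlleleFrequencySpectrum:
    site_id: str
    alleles: list[str]
    freqs: np.ndarray
    n_called: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.freqs) != len(self.alleles):
            raise ValidationError(f"{self.site_id}: alleles/freqs length mismatch")
        if self.n_called < 1:
            raise ValidationError(f"{self.site_id}: n_called must be >= 1")
        if (self.freqs < 0).any() or (self.freqs > 1).any():
            raise ValidationError(f"{self.site_id}: frequencies must be in [0, 1]")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValidationError(f"{self.site_id}: frequencies must sum to 1")


@dataclass
class DiversityRecord:
    site_id: str
    maf: float
    pic: float
    ao: int
    ae: float
    ho: float
    he: float
    pic_category: str


def pic(freqs) -> float:
    """Polymorphism information content of an allele-frequency vector."""
    p = freqs.freqs if isinstance(freqs, AlleleFrequencySpectrum) else np.asarray(freqs, dtype=float)
    sq = p ** 2
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    cross = float(sq.sum() ** 2 - (sq ** 2).sum())
    return float(1.0 - sq.sum() - cross)


def pic_category(value: float) -> str:
    if value < 0 or value > 0.5:
        raise ValidationError(f"PIC must lie in [0, 0.5], got {value}")
    if value <= 0.10:
        return "low"
    if value <= 0.25:
        return "medium"
    if value <= 0.40:
        return "high"
    return "very_high"


def spectrum(gm: GenotypeMatrix, site_id: str) -> AlleleFrequencySpectrum:
    """Allele-frequency spectrum at one site over non-missing calls."""
    col = gm.site_column(site_id)
    called = col[col >= 0]
    if called.size == 0:
        raise ValidationError(f"{site_id}: no non-missing calls")
    meta = gm.sites.set_index("site_id").loc[site_id]
    n_alt = int(called.sum())
    n_total = 2 * called.size
    freqs = np.array([(n_total - n_alt) / n_total, n_alt / n_total])
    return AlleleFrequencySpectrum(
        site_id=site_id,
        alleles=[meta.ref_allele, meta.alt_allele],
        freqs=freqs,
        n_called=int(called.size),
    )


def diversity_record(gm: GenotypeMatrix, site_id: str) -> DiversityRecord | None:
    """All six diversity statistics for one site; None when nothing is called."""
    col = gm.site_column(site_id)
    called = col[col >= 0]
    if called.size == 0:
        return None
    spec = spectrum(gm, site_id)
    p = spec.freqs
    sum_sq = float((p ** 2).sum())
    he = 1.0 - sum_sq
    ho = float((called == 1).mean())
    ao = int((p > 0).sum())
    ae = 1.0 / sum_sq
    maf = float(p.min()) if ao > 1 else 0.0
    pic_val = pic(p)
    return DiversityRecord(
        site_id=site_id, maf=maf, pic=pic_val, ao=ao, ae=ae, ho=ho, he=he,
        pic_category=pic_category(pic_val),
    )


def diversity_table(gm: GenotypeMatrix) -> pd.DataFrame:
    """Diversity records for every site with at least one call (vectorized)."""
    called = gm.calls >= 0
    n_called = called.sum(axis=0)
    ok = n_called > 0
    n_alt = np.where(called, gm.calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(ok, n_alt / (2.0 * n_called), np.nan)
    p_ref = 1.0 - p_alt
    sum_sq = p_ref ** 2 + p_alt ** 2
    he = 1.0 - sum_sq
    ho = np.where(ok, (gm.calls == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
    ao = np.where(ok, (p_ref > 0).astype(int) + (p_alt > 0).astype(int), 0)
    ae = 1.0 / sum_sq
    maf = np.minimum(p_alt, p_ref)
    cross = sum_sq ** 2 - (p_ref ** 4 + p_alt ** 4)
    pic_vals = 1.0 - sum_sq - cross
    df = pd.DataFrame({
        "site_id": gm.sites["site_id"].to_numpy(),
        "maf": maf, "pic": pic_vals, "ao": ao, "ae": ae, "ho": ho, "he": he,
    })
    df = df.loc[ok].reset_index(drop=True)
    df["pic_category"] = [pic_category(v) for v in df["pic"]]
    return df


STAT_COLUMNS = ("maf", "pic", "ao", "ae", "ho", "he")


def summarize_marker_set(records: pd.DataFrame, grouping: str | None = None) -> pd.DataFrame:
    """Mean and population SD (divisor N) of each statistic across sites.

    With ``grouping`` a column name, one Average/SD pair per group; groups
    with fewer than 2 records are omitted with a warning.  Report-layer
    rounding to 2 decimals.
    """
    import warnings

    def _rows(name, grp):
        out = []
        mean = grp[list(STAT_COLUMNS)].mean()
        sd = grp[list(STAT_COLUMNS)].std(ddof=0)
        out.append({"group": name, "row": "Average", "n_sites": len(grp),
                    **{c: round(float(mean[c]), 2) for c in STAT_COLUMNS}})
        out.append({"group": name, "row": "SD", "n_sites": len(grp),
                    **{c: round(float(sd[c]), 2) for c in STAT_COLUMNS}})
        return out

    rows = []
    if grouping is None:
        rows += _rows("all", records)
    else:
        for name, grp in records.groupby(grouping, sort=False):
            if len(grp) < 2:
                warnings.warn(f"group {name!r} has < 2 records; omitted", stacklevel=2)
                continue
            rows += _rows(name, grp)
    return pd.DataFrame(rows)


def database_attribution(sites_with_maf: pd.DataFrame) -> pd.DataFrame:
    """Per-source-database site counts by MAF class, with a total row.

    Input: a site table with ``source_db`` and ``maf`` columns.  Trait
    sites are excluded; unknown tags raise.  The proportion column is
    (MAF > 0.05 count) / (all sites) in percent, 2 decimals.
    """
    for col in ("source_db", "maf"):
        if col not in sites_with_maf.columns:
            raise ValidationError(f"attribution input missing column {col!r}")
    df = sites_with_maf.loc[sites_with_maf["source_db"] != "trait"]
    known = {"db1", "db2", "db3", "db4"}
    unknown = set(df["source_db"]) - known
    if unknown:
        raise ValidationError(f"unknown source database tags: {sorted(unknown)}")
    rows = []
    for db in sorted(known):
        grp = df.loc[df["source_db"] == db]
        if len(grp) == 0:
            continue
        n_all = len(grp)
        n_gt = int((grp["maf"] > 0.05).sum())
        rows.append({
            "source_db": db, "all_sites": n_all, "maf_le_005": n_all - n_gt,
            "maf_gt_005": n_gt, "proportion_pct": round(100.0 * n_gt / n_all, 2),
        })
    n_all = sum(r["all_sites"] for r in rows)
    n_gt = sum(r["maf_gt_005"] for r in rows)
    rows.append({
        "source_db": "total", "all_sites": n_all, "maf_le_005": n_all - n_gt,
        "maf_gt_005": n_gt,
        "proportion_pct": round(100.0 * n_gt / n_all, 2) if n_all else float("nan"),
    })
    return pd.DataFrame(rows)
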