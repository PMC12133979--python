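"""Core in-memory containers shared by every pipeline stage.

Genotypes are stored as a dense coded matrix (samples x sites) with

    0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
    MISSING (-1) = no call,

which is the natural encoding for biallelic diploid data and keeps every
downstream statistic a vectorized numpy expression.  Positions are 1-based
throughout the library; the BED writer converts to 0-based half-open on
output only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Coded genotype value for a missing diploid call.
MISSING: int = -1

DNA_ALPHABET = frozenset("ACGT")

SOURCE_DBS = ("db1", "db2", "db3", "db4", "trait")
VARIANT_CLASSES = ("SNP", "InDel")

#: Column order of the canonical site table.
SITE_COLUMNS = (
    "site_id",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "variant_class",
    "source_db",
    "is_trait_marker",
)


@dataclass(frozen=True)
class CandidateSite:
    """One SNP/InDel locus flowing through selection and optimization."""

    site_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: str = "SNP"
    source_db: str = "db1"
    is_trait_marker: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.site_id}: pos must be >= 1, got {self.pos}")
        for name in ("ref_allele", "alt_allele"):
            allele = getattr(self, name)
            if not allele or set(allele) - DNA_ALPHABET:
                raise ValidationError(f"{self.site_id}: bad {name} {allele!r}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"{self.site_id}: unknown variant_class {self.variant_class!r}")
        if self.variant_class == "SNP" and (len(self.ref_allele) != 1 or len(self.alt_allele) != 1):
            raise ValidationError(f"{self.site_id}: SNP alleles must have length 1")
        if self.source_db not in SOURCE_DBS:
            raise ValidationError(f"{self.site_id}: unknown source_db {self.source_db!r}")
        if (self.source_db == "trait") != self.is_trait_marker:
            raise ValidationError(
                f"{self.site_id}: source_db == 'trait' must coincide with is_trait_marker"
            )


def sites_to_frame(sites) -> pd.DataFrame:
    """Build the canonical site table from an iterable of :class:`CandidateSite`."""
    rows = [
        (s.site_id, s.chrom, s.pos, s.ref_allele, s.alt_allele,
         s.variant_class, s.source_db, s.is_trait_marker)
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=list(SITE_COLUMNS))
    validate_site_frame(df)
    return df


def frame_to_sites(df: pd.DataFrame) -> list[CandidateSite]:
    return [
        CandidateSite(
            site_id=str(r.site_id), chrom=str(r.chrom), pos=int(r.pos),
            ref_allele=str(r.ref_allele), alt_allele=str(r.alt_allele),
            variant_class=str(r.variant_class), source_db=str(r.source_db),
            is_trait_marker=bool(r.is_trait_marker),
        )
        for r in df.itertuples(index=False)
    ]


def validate_site_frame(df: pd.DataFrame) -> None:
    missing_cols = set(SITE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"site table missing columns: {sorted(missing_cols)}")
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
        raise ValidationError(f"duplicate site_id {dup!r} in site table")
    if (df["pos"] < 1).any():
        raise ValidationError("site positions must be 1-based (>= 1)")


@dataclass
class GenotypeMatrix:
    """Samples x sites coded diploid calls with explicit missingness.

    ``calls[i, j]`` is the coded genotype of sample *i* at site *j*; the
    site metadata lives in :attr:`sites` (canonical site-table columns),
    aligned with the columns of :attr:`calls`.
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        validate_site_frame(self.sites)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValidationError("coded genotypes must be in {-1, 0, 1, 2}")
        self._site_index = {sid: j for j, sid in enumerate(self.sites["site_id"])}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_column(self, site_id: str) -> np.ndarray:
        """Coded genotype column for one site (length ``n_samples``)."""
        try:
            j = self._site_index[site_id]
        except KeyError:
            raise ValidationError(f"site {site_id!r} absent from genotype matrix") from None
        return self.calls[:, j]

    def subset_sites(self, site_ids) -> "GenotypeMatrix":
        idx = [self._site_index[s] for s in site_ids]
        return GenotypeMatrix(
            samples=self.samples,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
        )


TOTALS_COLUMNS = ("total_reads", "on_target_reads", "duplicate_reads")


@dataclass
class DepthMatrix:
    """Samples x target-regions read depths plus per-sample read totals.

    ``totals`` is indexed by sample id with columns ``total_reads``,
    ``on_target_reads``, ``duplicate_reads``.
    """

    samples: list[str]
    regions: list[str]
    depth: np.ndarray
    totals: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.regions = list(self.regions)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.shape != (len(self.samples), len(self.regions)):
            raise ValidationError(
                f"depth shape {self.depth.shape} does not match "
                f"{len(self.samples)} samples x {len(self.regions)} regions"
            )
        if (self.depth < 0).any():
            raise ValidationError("read depths must be non-negative")
        if list(self.totals.index) != self.samples:
            raise ValidationError("totals index must equal the sample list, in order")
        for col in TOTALS_COLUMNS:
            if col not in self.totals.columns:
                raise ValidationError(f"totals table missing column {col!r}")
            if (self.totals[col] < 0).any():
                raise ValidationError(f"{col} must be non-negative")
        t = self.totals
        if (t["on_target_reads"] > t["total_reads"]).any():
            raise ValidationError("on_target_reads exceeds total_reads for some sample")
        if (t["duplicate_reads"] > t["total_reads"]).any():
            raise ValidationError("duplicate_reads exceeds total_reads for some sample")
        row_sums = self.depth.sum(axis=1)
        if (row_sums > t["on_target_reads"].to_numpy()).any():
            raise ValidationError("per-region depths sum past on_target_reads for some sample")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_regions(self) -> int:
        return len(self.regions)
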