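"""Capture-sequencing QC metrics and nominal-depth downsampling.

Uniformity_X for one sample is the fraction of target regions whose read
depth reaches X% of that sample's own mean region depth; panel-level
values are the unweighted mean over samples.  The on-target (capture
efficiency) rate is on_target_reads / total_reads; the effective data
rate additionally removes the duplicate share apportioned to on-target
reads.  Detection rate is the fraction of (sample, site) pairs with a
non-missing genotype call, split by variant class.  The 40X "simulated
depth" operation is an independent binomial thinning of every depth cell
with probability nominal_depth / cohort mean depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DepthMatrix, GenotypeMatrix
from .errors import ParameterError, ValidationError

UNIFORMITY_THRESHOLDS = (0.10, 0.20, 0.50)


@dataclass
class CaptureQCReport:
    """Per-sample metrics plus their cohort (unweighted mean) summary."""

    per_sample: pd.DataFrame
    cohort: pd.Series

    def as_percent_table(self) -> pd.DataFrame:
        """Cohort row formatted in percent with 2 decimals (report layer)."""
        out = (self.cohort.drop("mean_region_depth") * 100).round(2).to_frame().T
        out.insert(0, "mean_region_depth", round(self.cohort["mean_region_depth"], 2))
        return out


@dataclass
class DetectionReport:
    snp_detection_rate: float | None
    indel_detection_rate: float | None
    overall_detection_rate: float | None


def uniformity(dm: DepthMatrix, thresholds=UNIFORMITY_THRESHOLDS) -> pd.DataFrame:
    """Per-sample uniformity at each threshold (columns ``uniformity_10`` ...).

    A sample with an all-zero depth row has no defined mean; its
    uniformity is reported as 0 with a warning.
    """
    if dm.n_samples == 0 or dm.n_regions == 0:
        raise ValidationError("need at least one sample and one region")
    mean_depth = dm.depth.mean(axis=1)
    zero_rows = mean_depth == 0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} sample(s) with all-zero depth; uniformity set to 0",
            stacklevel=2,
        )
    out = {}
    for t in thresholds:
        cutoff = t * mean_depth[:, None]
        frac = (dm.depth >= cutoff).mean(axis=1)
        frac[zero_rows] = 0.0
        out[f"uniformity_{int(round(t * 100))}"] = frac
    return pd.DataFrame(out, index=pd.Index(dm.samples, name="sample_id"))


def on_target_rate(dm: DepthMatrix) -> pd.DataFrame:
    """Per-sample on-target, effective-data and duplication rates.

    Samples with zero total reads get NaN (undefined, reported missing).
    Duplicate reads are apportioned to the on-target share by the sample's
    overall duplication rate.
    """
    t = dm.totals
    total = t["total_reads"].to_numpy(dtype=float)
    on = t["on_target_reads"].to_numpy(dtype=float)
    dup = t["duplicate_reads"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(total > 0, on / total, np.nan)
        dup_rate = np.where(total > 0, dup / total, np.nan)
        effective = np.where(total > 0, (on - dup_rate * on) / total, np.nan)
    return pd.DataFrame(
        {
            "on_target_rate": rate,
            "effective_data_rate": effective,
            "duplication_rate": dup_rate,
        },
        index=pd.Index(dm.samples, name="sample_id"),
    )


def capture_report(dm: DepthMatrix) -> CaptureQCReport:
    """Full per-sample QC table plus the cohort mean row."""
    per_sample = uniformity(dm).join(on_target_rate(dm))
    per_sample["mean_region_depth"] = dm.depth.mean(axis=1)
    return CaptureQCReport(per_sample=per_sample, cohort=per_sample.mean())


def detection_rate(gm: GenotypeMatrix) -> DetectionReport:
    """Non-missing call rate, split by variant class.

    An empty class reports None (missing), never 0.
    """
    called = gm.calls >= 0
    is_snp = gm.sites["variant_class"].eq("SNP").to_numpy()

    def _rate(mask: np.ndarray) -> float | None:
        if mask.sum() == 0 or gm.n_samples == 0:
            return None
        return float(called[:, mask].mean())

    overall = float(called.mean()) if gm.n_sites and gm.n_samples else None
    return DetectionReport(
        snp_detection_rate=_rate(is_snp),
        indel_detection_rate=_rate(~is_snp),
        overall_detection_rate=overall,
    )


def downsample_depth(dm: DepthMatrix, nominal_depth: float = 40, seed: int = 0) -> DepthMatrix:
    """Binomially thin every depth cell toward a nominal cohort mean depth.

    Each cell is thinned with probability p = nominal_depth / cohort mean
    region depth (capped at 1), so the expected new cohort mean is
    min(nominal_depth, old mean).  Totals are thinned consistently: the
    on-target surplus (reads not assigned to regions), the off-target
    reads and the duplicates are each thinned at the same p, preserving
    all totals invariants.  Zero cells stay zero and no cell increases.
    """
    if nominal_depth <= 0:
        raise ParameterError("nominal_depth must be positive")
    cohort_mean = dm.depth.mean()
    if cohort_mean <= 0:
        raise ValidationError("cohort mean region depth must be positive")
    p = min(1.0, nominal_depth / cohort_mean)
    if p == 1.0:
        return dm
    rng = np.random.default_rng(seed)
    new_depth = rng.binomial(dm.depth, p)
    row_sums = dm.depth.sum(axis=1)
    on = dm.totals["on_target_reads"].to_numpy()
    total = dm.totals["total_reads"].to_numpy()
    dup = dm.totals["duplicate_reads"].to_numpy()
    new_row_sums = new_depth.sum(axis=1)
    surplus = rng.binomial(on - row_sums, p)
    new_on = new_row_sums + surplus
    new_off = rng.binomial(total - on, p)
    new_total = new_on + new_off
    new_dup = np.minimum(rng.binomial(dup, p), new_total)
    totals = pd.DataFrame(
        {
            "total_reads": new_total,
            "on_target_reads": new_on,
            "duplicate_reads": new_dup,
        },
        index=dm.totals.index,
    )
    return DepthMatrix(
        samples=dm.samples, regions=dm.regions, depth=new_depth, totals=totals
    )


@dataclass(frozen=True)
class PerSampleCost:
    """Per-sample assay cost components (RMB) for the GBTS workflow."""

    dna_extraction: float = 1.5
    library_prep: float = 3.5
    hybridization_capture: float = 40.0
    sequencing: float = 5.4

    @property
    def total(self) -> float:
        return self.dna_extraction + self.library_prep + self.hybridization_capture + self.sequencing
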