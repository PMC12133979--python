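"""Background-SNP selection at simulated 40X depth.

Per site, three QC statistics are computed across samples:

* ``missing_rate`` — fraction of samples with a missing genotype call,
* ``site_uniformity`` — fraction of samples whose depth at the site
  reaches 25% of the cohort mean region depth,
* ``target_rate`` — fraction of samples with at least one on-target read
  at the site (after downsampling to the nominal 40X).

A background site is retained (a high-confidence SNP) iff, with strict
inequalities, missing_rate < 0.1 and site_uniformity > 0.25 and
target_rate > 0.5.  Trait-specific sites bypass the filter entirely.
Discarded sites carry the list of criteria they failed; sites with no
calls at all have undefined MAF and are discarded with reason
``no_calls``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .core import DepthMatrix, GenotypeMatrix
from .errors import ValidationError


def compute_maf_all(gm: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per site over non-missing calls (NaN if none)."""
    called = gm.calls >= 0
    n_called = called.sum(axis=0)
    alt_alleles = np.where(called, gm.calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(n_called > 0, alt_alleles / (2.0 * n_called), np.nan)
    return np.where(np.isnan(p_alt), np.nan, np.minimum(p_alt, 1.0 - p_alt))


def compute_maf(gm: GenotypeMatrix, site_id: str) -> float:
    """MAF at one site (raises if the site is absent; NaN if nothing called)."""
    col = gm.site_column(site_id)
    called = col >= 0
    if called.sum() == 0:
        return float("nan")
    p_alt = col[called].sum() / (2.0 * called.sum())
    return float(min(p_alt, 1.0 - p_alt))


def compute_site_qc(
    gm: GenotypeMatrix,
    depths_40x: DepthMatrix,
    uniformity_threshold: float = 0.25,
) -> pd.DataFrame:
    """Per-site QC table from genotypes and 40X-downsampled depths.

    Region ids of ``depths_40x`` must map 1:1 onto the genotype matrix's
    site ids (same order).
    """
    if depths_40x.regions != list(gm.sites["site_id"]):
        raise ValidationError("depth regions must match genotype sites 1:1, in order")
    if depths_40x.samples != gm.samples:
        raise ValidationError("depth samples must match genotype samples, in order")
    n = gm.n_samples
    missing_rate = (gm.calls < 0).sum(axis=0) / n
    cohort_mean = depths_40x.depth.mean()
    depth_cutoff = uniformity_threshold * cohort_mean
    site_uniformity = (depths_40x.depth >= depth_cutoff).sum(axis=0) / n
    target_rate = (depths_40x.depth >= 1).sum(axis=0) / n
    return pd.DataFrame({
        "site_id": gm.sites["site_id"].to_numpy(),
        "missing_rate": missing_rate,
        "site_uniformity": site_uniformity,
        "target_rate": target_rate,
        "maf": compute_maf_all(gm),
    })


def select_background(
    site_qc: pd.DataFrame,
    config: RunConfig | None = None,
    sites: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition background candidates into (selected, discarded).

    Strict inequalities, exactly as published: a site with
    missing_rate == 0.1 is discarded.  If ``sites`` (the canonical site
    table) is given, trait-specific sites are removed from the candidate
    set before filtering — the selection criteria do not apply to them.
    The discarded table carries a ``failed`` column listing the violated
    criteria (comma-separated).
    """
    config = config or RunConfig()
    qc = site_qc.copy()
    if sites is not None:
        trait_ids = set(sites.loc[sites["is_trait_marker"], "site_id"])
        qc = qc[~qc["site_id"].isin(trait_ids)].reset_index(drop=True)

    failed_lists = []
    for row in qc.itertuples(index=False):
        failed = []
        if np.isnan(row.maf):
            failed.append("no_calls")
        if not row.missing_rate < config.missing_rate_max:
            failed.append("missing_rate")
        if not row.site_uniformity > config.site_uniformity_min:
            failed.append("uniformity")
        if not row.target_rate > config.target_rate_min:
            failed.append("target_rate")
        failed_lists.append(",".join(failed))
    qc = qc.assign(failed=failed_lists)
    keep = qc["failed"] == ""
    selected = qc.loc[keep].drop(columns="failed").reset_index(drop=True)
    discarded = qc.loc[~keep].reset_index(drop=True)
    return selected, discarded
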