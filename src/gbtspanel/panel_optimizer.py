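"""Five-criterion panel optimization and gap/MAF reporting.

After the first selection pass, discarded SNPs with MAF > 0.05 form a
reinsertion pool (criterion 1).  A two-phase greedy then repairs the
panel under a reinsertion budget of strictly less than 1% of the selected
background (criterion 3):

* Phase A (gap repair): while any chromosome's mean adjacent-marker gap
  exceeds 0.3 Mbp (criterion 2), reinsert the pool site that maximally
  reduces that chromosome's mean gap (ties: larger MAF, then smaller
  position).  Because the mean gap telescopes to span/(k-1), any interior
  site yields the same maximal reduction, so the MAF tie-break does real
  work.
* Phase B (MAF shares): while the MAF > 0.05 share of the background is
  below 60% (criterion 4) or the top MAF class (MAF > 0.4) is below 20%
  of the total panel (criterion 5), reinsert the highest-MAF pool site
  (ties: smaller chromosome, then position).

Unmet criteria are reported, never silently forced — the published
criteria are not jointly satisfiable on every input, and infeasibility is
a legitimate, audited outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ParameterError, ValidationError

MAF_BIN_LABELS = (
    "[0,0.05]", "(0.05,0.1]", "(0.1,0.2]", "(0.2,0.3]", "(0.3,0.4]", "(0.4,0.5]",
)
_MAF_BIN_EDGES = np.array([0.05, 0.1, 0.2, 0.3, 0.4, 0.5])

#: MAF strictly above this value puts a site in the top threshold class.
TOP_BIN_MIN_MAF = 0.4


# ---------------------------------------------------------------------------
# Gap statistics
# ---------------------------------------------------------------------------

@dataclass
class GapReport:
    """Per-chromosome adjacent-marker gap statistics, in bp."""

    per_chrom: pd.DataFrame  # chrom, length_bp, n_sites, min_gap, max_gap, mean_gap

    def genome_average(self) -> pd.Series:
        """Unweighted mean over chromosomes; undefined rows are excluded."""
        cols = ["length_bp", "min_gap", "max_gap", "mean_gap"]
        return self.per_chrom[cols].mean()

    def as_mbp_table(self) -> pd.DataFrame:
        """Report-layer table: lengths/gaps in Mbp (2 decimals), min gap in
        bp, plus a genome-average row."""
        out = pd.DataFrame({
            "chromosome": self.per_chrom["chrom"],
            "length_mbp": (self.per_chrom["length_bp"] / 1e6).round(2),
            "min_gap_bp": self.per_chrom["min_gap"],
            "max_gap_mbp": (self.per_chrom["max_gap"] / 1e6).round(2),
            "mean_gap_mbp": (self.per_chrom["mean_gap"] / 1e6).round(2),
        })
        avg = genome_average_row(out.drop(columns="chromosome"))
        avg["chromosome"] = "Average"
        return pd.concat([out, pd.DataFrame([avg])], ignore_index=True)


def genome_average_row(per_chrom_values: pd.DataFrame) -> dict:
    """Unweighted mean of per-chromosome report values, 2 decimals.

    Operates on the report-layer (already rounded) columns, matching how
    the published summary row is derived from its printed table.
    """
    return {col: round(float(per_chrom_values[col].mean()), 2)
            for col in per_chrom_values.columns}


def gap_stats(sites: pd.DataFrame, chrom_lengths_bp: dict[str, float] | None = None) -> GapReport:
    """Adjacent-gap statistics per chromosome.

    ``sites`` must be sorted by (chrom, pos); chromosomes with fewer than
    two sites report undefined (NaN) gaps and are excluded from the
    genome average.
    """
    for col in ("chrom", "pos"):
        if col not in sites.columns:
            raise ValidationError(f"site table missing column {col!r}")
    sorted_check = sites.sort_values(["chrom", "pos"], kind="mergesort")
    if not (sorted_check["chrom"].to_numpy() == sites["chrom"].to_numpy()).all() or not (
        sorted_check["pos"].to_numpy() == sites["pos"].to_numpy()
    ).all():
        raise ValidationError("sites must be sorted by (chrom, pos)")
    rows = []
    for chrom, grp in sites.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        length = (chrom_lengths_bp or {}).get(chrom, np.nan)
        if len(pos) < 2:
            rows.append((chrom, length, len(pos), np.nan, np.nan, np.nan))
            continue
        gaps = np.diff(pos)
        rows.append((chrom, length, len(pos),
                     float(gaps.min()), float(gaps.max()), float(gaps.mean())))
    per_chrom = pd.DataFrame(
        rows, columns=["chrom", "length_bp", "n_sites", "min_gap", "max_gap", "mean_gap"]
    )
    return GapReport(per_chrom=per_chrom)


# ---------------------------------------------------------------------------
# MAF binning
# ---------------------------------------------------------------------------

def bin_maf(maf_values) -> pd.Series:
    """Counts per MAF threshold class.

    Classes: [0,0.05], (0.05,0.1], (0.1,0.2], (0.2,0.3], (0.3,0.4],
    (0.4,0.5] — the 0.05 boundary belongs to the lowest class.
    """
    maf = np.asarray(maf_values, dtype=float)
    if maf.size and (np.isnan(maf).any() or maf.min() < 0 or maf.max() > 0.5):
        raise ValidationError("MAF values must lie in [0, 0.5]")
    idx = np.searchsorted(_MAF_BIN_EDGES, maf, side="left")
    counts = np.bincount(idx, minlength=len(MAF_BIN_LABELS))
    return pd.Series(counts, index=list(MAF_BIN_LABELS), name="count")


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

@dataclass
class PanelDefinition:
    """The optimized panel: site table with status flags plus audit trail."""

    sites: pd.DataFrame          # canonical columns + maf + status
    report: dict                 # constraint report (criteria flags, shares, gaps)
    audit: pd.DataFrame          # one row per reinsertion step

    @property
    def accounting(self) -> dict:
        status = self.sites["status"]
        n_background = int(status.isin(("selected", "reinserted")).sum())
        n_trait = int((status == "trait").sum())
        return {
            "n_background": n_background,
            "n_trait": n_trait,
            "total": n_background + n_trait,
        }


def reinsertion_budget(n_selected: int, frac: float) -> int:
    """Largest reinsertion count strictly below ``frac`` of the selected set."""
    raw = frac * n_selected
    budget = int(np.floor(raw))
    if budget == raw:  # exact integer: floor would equal, not undercut, the cap
        budget = max(0, budget - 1)
    return budget


def _shares(background_maf: np.ndarray, panel_maf: np.ndarray) -> tuple[float, float]:
    """(MAF>0.05 share of background, top-class share of total panel)."""
    maf05 = float((background_maf > 0.05).sum() / len(background_maf))
    top = float((panel_maf > TOP_BIN_MIN_MAF).sum() / len(panel_maf))
    return maf05, top


def optimize(
    selected: pd.DataFrame,
    discarded: pd.DataFrame,
    trait_sites: pd.DataFrame,
    config: RunConfig | None = None,
    chrom_lengths_bp: dict[str, float] | None = None,
) -> PanelDefinition:
    """Run the two-phase greedy reinsertion and emit the final panel.

    ``selected`` and ``discarded`` must carry site_id/chrom/pos/maf;
    ``trait_sites`` the same (its maf may be NaN).  Nothing in the input
    is mutated.
    """
    config = config or RunConfig()
    if len(selected) == 0:
        raise ParameterError("nothing to optimize: the selected set is empty")
    for name, df in (("selected", selected), ("discarded", discarded)):
        for col in ("site_id", "chrom", "pos", "maf"):
            if col not in df.columns:
                raise ValidationError(f"{name} table missing column {col!r}")

    budget = reinsertion_budget(len(selected), config.reinsertion_budget_frac)
    pool = discarded.loc[discarded["maf"] > 0.05].copy()  # criterion 1
    pool_used = np.zeros(len(pool), dtype=bool)
    pool_chrom = pool["chrom"].to_numpy()
    pool_pos = pool["pos"].to_numpy(dtype=np.int64)
    pool_maf = pool["maf"].to_numpy(dtype=float)

    # per-chromosome span bookkeeping (mean gap telescopes to span/(k-1))
    stats: dict[str, list] = {}
    for chrom, grp in selected.groupby("chrom"):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        stats[chrom] = [int(pos.min()), int(pos.max()), len(pos)]

    def mean_gap(chrom: str) -> float:
        first, last, k = stats[chrom]
        return (last - first) / (k - 1) if k >= 2 else float("nan")

    audit_rows: list[dict] = []
    reinserted_idx: list[int] = []

    def record(phase: str, i: int, chrom: str, before: float, after: float) -> None:
        audit_rows.append({
            "step": len(audit_rows) + 1, "phase": phase,
            "site_id": pool["site_id"].iloc[i], "chrom": chrom,
            "maf": float(pool_maf[i]),
            "metric_before": before, "metric_after": after,
        })

    # ---- Phase A: gap repair -------------------------------------------
    stuck: set[str] = set()
    while len(reinserted_idx) < budget:
        offenders = {
            c: g for c in stats
            if (g := mean_gap(c)) == g and g > config.max_mean_gap_bp and c not in stuck
        }
        if not offenders:
            break
        target = max(offenders, key=offenders.get)
        current = offenders[target]
        first, last, k = stats[target]
        cand = np.flatnonzero(~pool_used & (pool_chrom == target))
        if cand.size == 0:
            stuck.add(target)
            continue
        new_span = np.maximum(last, pool_pos[cand]) - np.minimum(first, pool_pos[cand])
        new_mean = new_span / k  # k+1 sites -> k gaps
        reducing = new_mean < current
        if not reducing.any():
            stuck.add(target)
            continue
        cand, new_mean = cand[reducing], new_mean[reducing]
        # best reduction; ties -> larger maf, then smaller position
        order = np.lexsort((pool_pos[cand], -pool_maf[cand], new_mean))
        best = cand[order[0]]
        record("gap_repair", best, target, current, float(new_mean[order[0]]))
        pool_used[best] = True
        reinserted_idx.append(best)
        stats[target] = [
            min(first, int(pool_pos[best])), max(last, int(pool_pos[best])), k + 1,
        ]

    # ---- Phase B: MAF shares -------------------------------------------
    sel_maf = selected["maf"].to_numpy(dtype=float)
    trait_maf = (
        trait_sites["maf"].to_numpy(dtype=float)
        if len(trait_sites) and "maf" in trait_sites.columns
        else np.empty(0)
    )

    def current_shares() -> tuple[float, float]:
        re_maf = pool_maf[reinserted_idx] if reinserted_idx else np.empty(0)
        background = np.concatenate([sel_maf, re_maf])
        panel = np.concatenate([background, trait_maf[~np.isnan(trait_maf)]])
        # trait sites without a defined MAF still count in the panel size
        n_panel = len(background) + len(trait_maf)
        maf05 = float((background > 0.05).sum() / len(background))
        top = float((panel > TOP_BIN_MIN_MAF).sum() / n_panel)
        return maf05, top

    while len(reinserted_idx) < budget:
        maf05, top = current_shares()
        need_maf05 = maf05 < config.maf05_share_min
        need_top = top < config.top_bin_share_min
        if not (need_maf05 or need_top):
            break
        avail = np.flatnonzero(~pool_used)
        if avail.size == 0:
            break
        order = np.lexsort((pool_pos[avail], pool_chrom[avail], -pool_maf[avail]))
        best = avail[order[0]]
        if not need_maf05 and need_top and pool_maf[best] <= TOP_BIN_MIN_MAF:
            break  # no remaining site can raise the top-class share
        record("maf_shares", best, str(pool_chrom[best]), maf05, top)
        pool_used[best] = True
        reinserted_idx.append(best)

    # ---- Assemble panel and constraint report --------------------------
    carry = [c for c in ("site_id", "chrom", "pos", "ref_allele", "alt_allele",
                         "variant_class", "source_db", "is_trait_marker", "maf")
             if c in selected.columns]
    parts = [selected[carry].assign(status="selected")]
    if reinserted_idx:
        parts.append(pool.iloc[reinserted_idx][
            [c for c in carry if c in pool.columns]
        ].assign(status="reinserted"))
    if len(trait_sites):
        parts.append(trait_sites[
            [c for c in carry if c in trait_sites.columns]
        ].assign(status="trait"))
    panel = (
        pd.concat(parts, ignore_index=True)
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )

    gaps = gap_stats(panel[["chrom", "pos"]], chrom_lengths_bp)
    defined = gaps.per_chrom["mean_gap"].dropna()
    maf05, top = current_shares()
    n_reinserted = len(reinserted_idx)
    report = {
        "reinserted_count": n_reinserted,
        "budget": budget,
        "maf05_share": maf05,
        "top_bin_share": top,
        "max_chrom_mean_gap_bp": float(defined.max()) if len(defined) else float("nan"),
        "criteria": {
            "gap": bool((defined <= config.max_mean_gap_bp).all()),
            "budget": n_reinserted < config.reinsertion_budget_frac * len(selected),
            "maf05_share": maf05 >= config.maf05_share_min,
            "top_bin_share": top >= config.top_bin_share_min,
        },
    }
    audit = pd.DataFrame(
        audit_rows,
        columns=["step", "phase", "site_id", "chrom", "maf", "metric_before", "metric_after"],
    )
    return PanelDefinition(sites=panel, report=report, audit=audit)
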