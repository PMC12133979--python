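import numpy as np
import pandas as pd
import pytest

from gbtspanel.config import RunConfig
from gbtspanel.errors import ParameterError, ValidationError
from gbtspanel.panel_optimizer import (
    MAF_BIN_LABELS,
    PanelDefinition,
    bin_maf,
    gap_stats,
    genome_average_row,
    optimize,
    reinsertion_budget,
)
from gbtspanel.synthio import simulate_optimizer_fixture


def sites_on(chrom, positions, prefix="s", maf=0.3):
    return pd.DataFrame({
        "site_id": [f"{prefix}{chrom}_{i}" for i in range(len(positions))],
        "chrom": chrom,
        "pos": positions,
        "maf": maf,
    })


class TestGapStats:
    def test_hand_arithmetic(self):
        report = gap_stats(sites_on("c1", [100, 200, 400]))
        row = report.per_chrom.iloc[0]
        assert (row["min_gap"], row["max_gap"], row["mean_gap"]) == (100, 200, 150)

    def test_duplicate_position_gives_zero_min_gap(self):
        report = gap_stats(sites_on("c1", [100, 100, 300]))
        assert report.per_chrom["min_gap"].iloc[0] == 0

    def test_single_site_chromosome_excluded_from_average(self):
        sites = pd.concat([sites_on("c1", [100, 200]), sites_on("c2", [50])],
                          ignore_index=True)
        report = gap_stats(sites)
        assert np.isnan(report.per_chrom.set_index("chrom").loc["c2", "mean_gap"])
        assert report.genome_average()["mean_gap"] == 100

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValidationError):
            gap_stats(sites_on("c1", [400, 100]))

    def test_agrees_with_naive_pairwise_recomputation(self, rng):
        frames = []
        for c in range(4):
            pos = np.sort(rng.integers(1, 10_000, size=rng.integers(2, 50)))
            frames.append(sites_on(f"c{c}", pos, prefix=f"p{c}"))
        sites = pd.concat(frames, ignore_index=True)
        report = gap_stats(sites).per_chrom.set_index("chrom")
        for c, grp in sites.groupby("chrom"):
            gaps = [b - a for a, b in zip(grp["pos"], grp["pos"][1:])]
            assert report.loc[c, "mean_gap"] == pytest.approx(sum(gaps) / len(gaps))
            assert report.loc[c, "min_gap"] == min(gaps)
            assert report.loc[c, "max_gap"] == max(gaps)


class TestGenomeAverageRow:
    def test_unweighted_mean_rounded(self):
        table = pd.DataFrame({"length_mbp": [10.0, 20.0, 31.0], "mean_gap_mbp": [0.1, 0.2, 0.3]})
        row = genome_average_row(table)
        assert row == {"length_mbp": 20.33, "mean_gap_mbp": 0.2}


class TestBinMAF:
    def test_boundary_belongs_to_lowest_class(self):
        counts = bin_maf([0.05])
        assert counts["[0,0.05]"] == 1

    def test_top_class(self):
        assert bin_maf([0.41])["(0.4,0.5]"] == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bin_maf([0.6])

    def test_counts_match_comparison_chain_recount(self, rng):
        maf = rng.uniform(0, 0.5, size=500)
        maf[:20] = [0.05, 0.1, 0.2, 0.3, 0.4, 0.5] * 3 + [0.0, 0.05]
        counts = bin_maf(maf)
        edges = [(0.0, 0.05), (0.05, 0.1), (0.1, 0.2), (0.2, 0.3), (0.3, 0.4), (0.4, 0.5)]
        for (lo, hi), label in zip(edges, MAF_BIN_LABELS):
            if label == "[0,0.05]":
                expected = sum(1 for v in maf if 0 <= v <= 0.05)
            else:
                expected = sum(1 for v in maf if lo < v <= hi)
            assert counts[label] == expected
        assert counts.sum() == len(maf)


class TestReinsertionBudget:
    def test_strictly_below_one_percent(self):
        assert reinsertion_budget(11174, 0.01) == 111
        assert reinsertion_budget(2000, 0.01) == 19  # exact integer undercut
        assert reinsertion_budget(50, 0.01) == 0


class TestOptimize:
    def _feasible_inputs(self):
        # one chromosome, gaps well under the ceiling, shares already met
        positions = list(range(1000, 1000 + 200 * 50, 200))
        selected = sites_on("c1", positions)
        maf = np.full(len(selected), 0.2)
        maf[: len(maf) // 4] = 0.45  # 25% in the top class
        maf[-len(maf) // 10:] = 0.01
        selected["maf"] = maf
        trait = sites_on("c1", [1500, 2500], prefix="t", maf=0.45)
        empty_pool = selected.iloc[:0]
        return selected, empty_pool, trait

    def test_fixed_point_when_criteria_met_and_pool_empty(self):
        selected, pool, trait = self._feasible_inputs()
        cfg = RunConfig(max_mean_gap_bp=300.0)
        panel = optimize(selected, pool, trait, cfg)
        assert panel.report["reinserted_count"] == 0
        assert all(panel.report["criteria"].values())
        assert set(panel.sites.loc[panel.sites["status"] == "selected", "site_id"]) == set(
            selected["site_id"]
        )

    def test_single_step_gap_repair(self):
        # mean gap 0.5 Mbp; one pool site inside the largest gap
        selected = sites_on("c1", [1_000_000, 1_500_000, 2_000_000], maf=0.3)
        pool = sites_on("c1", [1_700_000], prefix="pool", maf=0.2)
        trait = selected.iloc[:0]
        cfg = RunConfig(max_mean_gap_bp=450_000.0, reinsertion_budget_frac=0.5)
        panel = optimize(selected, pool, trait, cfg)
        assert panel.report["reinserted_count"] == 1
        step = panel.audit.iloc[0]
        assert step["site_id"] == "poolc1_0"
        assert step["metric_after"] < step["metric_before"]

    def test_budget_zero_reports_unmet_criteria(self):
        selected = sites_on("c1", [1_000_000, 2_000_000], maf=0.01)  # all monomorphic-ish
        pool = sites_on("c1", [1_500_000], prefix="pool", maf=0.45)
        cfg = RunConfig(max_mean_gap_bp=300_000.0, reinsertion_budget_frac=0.0)
        panel = optimize(selected, pool, selected.iloc[:0], cfg)
        assert panel.report["reinserted_count"] == 0
        crit = panel.report["criteria"]
        assert not crit["gap"] and not crit["maf05_share"] and not crit["top_bin_share"]

    def test_empty_selected_set_rejected(self):
        selected, pool, trait = self._feasible_inputs()
        with pytest.raises(ParameterError):
            optimize(selected.iloc[:0], pool, trait)

    def test_deterministic_on_fixture(self):
        sel, disc, trait, cfg = simulate_optimizer_fixture(seed=4)
        a = optimize(sel, disc, trait, cfg)
        b = optimize(sel, disc, trait, cfg)
        pd.testing.assert_frame_equal(a.sites, b.sites)
        pd.testing.assert_frame_equal(a.audit, b.audit)

    def test_phase_b_raises_maf_share_monotonically(self):
        # 55% of background above 0.05: phase B must insert high-MAF sites
        selected = sites_on("c1", list(range(1000, 21000, 1000)), maf=0.2)
        selected.loc[selected.index[:9], "maf"] = 0.01  # 11/20 = 55% > 0.05
        pool = sites_on("c1", list(range(1500, 9500, 1000)), prefix="pool", maf=0.45)
        cfg = RunConfig(max_mean_gap_bp=10_000.0, reinsertion_budget_frac=0.26)
        panel = optimize(selected, pool, selected.iloc[:0], cfg)
        steps = panel.audit[panel.audit["phase"] == "maf_shares"]
        assert len(steps) > 0
        shares = steps["metric_before"].to_numpy()
        assert (np.diff(shares) >= 0).all()
        assert panel.report["criteria"]["maf05_share"]

    def test_reinserted_sites_all_polymorphic(self):
        sel, disc, trait, cfg = simulate_optimizer_fixture(seed=8)
        panel = optimize(sel, disc, trait, cfg)
        re = panel.sites.loc[panel.sites["status"] == "reinserted", "maf"]
        assert (re > 0.05).all()


def test_panel_definition_accounting():
    sites = pd.DataFrame({
        "site_id": [f"x{i}" for i in range(5)],
        "chrom": "c1", "pos": range(1, 6),
        "status": ["selected", "selected", "reinserted", "trait", "trait"],
    })
    acct = PanelDefinition(sites=sites, report={}, audit=pd.DataFrame()).accounting
    assert acct == {"n_background": 3, "n_trait": 2, "total": 5}
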