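import numpy as np
import pandas as pd
import pytest

from gbtspanel.core import MISSING
from gbtspanel.errors import ValidationError
from gbtspanel.popstats import (
    database_attribution,
    diversity_record,
    diversity_table,
    pic,
    pic_category,
    summarize_marker_set,
)
from gbtspanel.synthio import SimSpec, simulate_genotypes, simulate_sites

from conftest import make_gm


def pic_double_loop(freqs):
    """Independent brute-force evaluation over all i < j allele pairs."""
    total = 1.0 - sum(p * p for p in freqs)
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            total -= 2 * freqs[i] ** 2 * freqs[j] ** 2
    return total


class TestPIC:
    def test_monomorphic_site_is_zero(self):
        assert pic([1.0]) == 0.0

    def test_balanced_biallelic(self):
        assert pic([0.5, 0.5]) == pytest.approx(0.375, abs=0)

    def test_balanced_triallelic(self):
        val = pic([1 / 3, 1 / 3, 1 / 3])
        assert val == pytest.approx(1 - 1 / 3 - 6 / 81, abs=1e-12)
        assert val == pytest.approx(pic_double_loop([1 / 3] * 3), abs=1e-12)

    def test_agrees_with_double_loop_on_random_spectra(self, rng):
        for _ in range(300):
            k = rng.integers(1, 7)
            f = rng.dirichlet(np.ones(k))
            assert pic(f) == pytest.approx(pic_double_loop(f), abs=1e-12)


class TestPICCategories:
    @pytest.mark.parametrize("value,expected", [
        (0.0, "low"), (0.10, "low"), (0.15, "medium"), (0.25, "medium"),
        (0.27, "high"), (0.40, "high"), (0.41, "very_high"), (0.5, "very_high"),
    ])
    def test_printed_ranges_with_gap_values(self, value, expected):
        assert pic_category(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            pic_category(0.6)


class TestDiversityRecord:
    def test_all_heterozygous(self):
        gm = make_gm([[1, 1, 1, 1]])
        rec = diversity_record(gm, "s0")
        assert rec.ho == 1.0 and rec.he == 0.5 and rec.ao == 2 and rec.ae == 2.0

    def test_all_homozygous_ref(self):
        gm = make_gm([[0, 0, 0]])
        rec = diversity_record(gm, "s0")
        assert (rec.ho, rec.he, rec.ao, rec.ae, rec.pic) == (0, 0, 1, 1, 0)
        assert rec.pic_category == "low"

    def test_hand_arithmetic_from_counts(self):
        # AA, AB, BB, BB: p_ref = 3/8
        gm = make_gm([[0, 1, 2, 2]])
        rec = diversity_record(gm, "s0")
        assert rec.he == pytest.approx(30 / 64)
        assert rec.ho == pytest.approx(0.25)
        assert rec.ae == pytest.approx(64 / 34)
        assert rec.maf == pytest.approx(3 / 8)

    def test_no_calls_reported_missing(self):
        gm = make_gm([[MISSING, MISSING]])
        assert diversity_record(gm, "s0") is None

    def test_table_matches_per_site_records(self, rng):
        calls = rng.integers(-1, 3, size=(40, 15))
        gm = make_gm(calls.T.tolist())
        table = diversity_table(gm).set_index("site_id")
        for sid in table.index:
            rec = diversity_record(gm, sid)
            for stat in ("maf", "pic", "ao", "ae", "ho", "he"):
                assert table.loc[sid, stat] == pytest.approx(getattr(rec, stat))
            assert table.loc[sid, "pic_category"] == rec.pic_category

    def test_he_complements_sum_of_squares(self, rng):
        calls = rng.integers(0, 3, size=(25, 10))
        gm = make_gm(calls.T.tolist())
        table = diversity_table(gm)
        p = table["maf"]
        np.testing.assert_allclose(table["he"], 1 - (p**2 + (1 - p) ** 2))


class TestSummaries:
    def test_identical_records_have_zero_sd(self):
        records = pd.DataFrame(
            {c: [0.2] * 5 for c in ("maf", "pic", "ao", "ae", "ho", "he")}
        )
        out = summarize_marker_set(records)
        assert (out.loc[out["row"] == "SD", ["maf", "he"]] == 0).all().all()

    def test_two_record_mean(self):
        records = pd.DataFrame(
            {c: [0.1, 0.3] for c in ("maf", "pic", "ao", "ae", "ho", "he")}
        )
        out = summarize_marker_set(records)
        assert out.loc[out["row"] == "Average", "maf"].iloc[0] == pytest.approx(0.2)

    def test_simulated_he_matches_beta_moment(self):
        """Mean He over Beta(2,2) sites within 3 SE of the closed-form
        E[2p(1-p)] = 2ab / ((a+b)(a+b+1)) = 0.4."""
        spec = SimSpec(
            db_counts={"db1": 1000, "db2": 0, "db3": 0, "db4": 0},
            db_beta={"db1": (2.0, 2.0)}, n_samples=400, seed=11,
        )
        sites = simulate_sites(spec)
        gm = simulate_genotypes(sites, spec.n_samples, 0.0, seed=13)
        he = diversity_table(gm)["he"]
        se = he.std(ddof=1) / np.sqrt(len(he))
        assert abs(he.mean() - 0.4) < 3 * se


def attribution_input_from_counts(counts):
    """Site table realizing given per-db (all, maf<=0.05) count pairs."""
    rows = []
    for db, (n_all, n_le) in counts.items():
        rows += [{"source_db": db, "maf": 0.01}] * n_le
        rows += [{"source_db": db, "maf": 0.30}] * (n_all - n_le)
    return pd.DataFrame(rows)


class TestDatabaseAttribution:
    def test_published_count_pairs_reproduce_proportions(self):
        table = database_attribution(attribution_input_from_counts({
            "db1": (8362, 2632), "db2": (563, 261),
            "db3": (795, 79), "db4": (1454, 1434),
        })).set_index("source_db")
        assert table.loc["db1", "proportion_pct"] == 68.52
        assert table.loc["db2", "proportion_pct"] == 53.64
        assert table.loc["db3", "proportion_pct"] == 90.06
        assert table.loc["db4", "proportion_pct"] == 1.38
        assert table.loc["total", "proportion_pct"] == 60.57
        assert table.loc["total", "all_sites"] == 11174

    def test_monomorphic_database_scores_zero(self):
        table = database_attribution(attribution_input_from_counts({"db1": (50, 50)}))
        assert table.set_index("source_db").loc["db1", "proportion_pct"] == 0.0

    def test_counts_match_group_and_count_oracle(self, rng):
        df = pd.DataFrame({
            "source_db": rng.choice(["db1", "db2", "db3", "db4", "trait"], 400),
            "maf": rng.uniform(0, 0.5, 400),
        })
        table = database_attribution(df).set_index("source_db")
        for db in ("db1", "db2", "db3", "db4"):
            grp = df[df["source_db"] == db]
            assert table.loc[db, "all_sites"] == len(grp)
            assert table.loc[db, "maf_gt_005"] == (grp["maf"] > 0.05).sum()
        assert "trait" not in table.index

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValidationError):
            database_attribution(pd.DataFrame({"source_db": ["db9"], "maf": [0.1]}))
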