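import numpy as np
import pandas as pd
import pytest

from gbtspanel import formats
from gbtspanel.config import RunConfig
from gbtspanel.core import MISSING, GenotypeMatrix
from gbtspanel.errors import FormatError, UnsupportedRecordError, ValidationError

from conftest import make_dm, make_gm, make_sites


class TestGenotypesVCF:
    def test_identity_case_no_missing(self, tmp_path):
        gm = make_gm([[0, 1], [2, 0], [1, 1]])  # 3 sites x 2 samples
        path = tmp_path / "g.vcf"
        formats.write_genotypes(gm, path)
        back = formats.read_genotypes(path)
        assert back.n_samples == 2 and back.n_sites == 3
        assert (back.calls >= 0).all()

    def test_missing_gt_maps_to_missing_code(self, tmp_path):
        gm = make_gm([[MISSING, 1]])
        path = tmp_path / "g.vcf"
        formats.write_genotypes(gm, path)
        back = formats.read_genotypes(path)
        assert back.calls[0, 0] == MISSING and back.calls[1, 0] == 1

    def test_round_trip_randomized(self, tmp_path, rng):
        n_samples, n_sites = 7, 40
        calls = rng.integers(-1, 3, size=(n_samples, n_sites)).astype(np.int8)
        sites = make_sites(n_sites)
        sites.loc[5, "source_db"] = "db3"
        sites.loc[7, ["source_db", "is_trait_marker"]] = ["trait", True]
        gm = GenotypeMatrix(
            samples=[f"S{i}" for i in range(n_samples)], sites=sites, calls=calls
        )
        path = tmp_path / "g.vcf"
        formats.write_genotypes(gm, path)
        back = formats.read_genotypes(path)
        assert back.samples == gm.samples
        pd.testing.assert_frame_equal(
            back.sites.sort_values("site_id").reset_index(drop=True),
            gm.sites.sort_values("site_id").reset_index(drop=True),
            check_dtype=False,
        )
        order = [back.sites["site_id"].tolist().index(s) for s in gm.sites["site_id"]]
        np.testing.assert_array_equal(back.calls[:, order], gm.calls)

    def test_multiallelic_record_rejected(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\n"
            "chr1\t100\tsiteX\tA\tG,T\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(UnsupportedRecordError, match="siteX"):
            formats.read_genotypes(path)

    def test_malformed_vcf_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("this is not a vcf\n")
        with pytest.raises(FormatError):
            formats.read_genotypes(path)


class TestDepthTables:
    def test_valid_table(self, tmp_path):
        dm = make_dm([[10, 10], [10, 10]])
        formats.write_depth_table(dm, tmp_path / "d.tsv", tmp_path / "t.tsv")
        back = formats.read_depth_table(tmp_path / "d.tsv", tmp_path / "t.tsv")
        np.testing.assert_array_equal(back.depth, dm.depth)

    def test_on_target_exceeding_total_rejected(self):
        with pytest.raises(ValidationError, match="on_target"):
            make_dm([[5, 5]], total=[8], on_target=[10])

    def test_negative_depth_rejected(self, tmp_path):
        (tmp_path / "d.tsv").write_text("sample_id\tregion_id\tdepth\nS0\tr0\t-3\n")
        (tmp_path / "t.tsv").write_text(
            "sample_id\ttotal_reads\ton_target_reads\tduplicate_reads\nS0\t10\t5\t0\n"
        )
        with pytest.raises(ValidationError, match="negative"):
            formats.read_depth_table(tmp_path / "d.tsv", tmp_path / "t.tsv")

    def test_round_trip_with_zero_cells(self, tmp_path, rng):
        depth = rng.integers(0, 30, size=(5, 12))
        depth[rng.random(depth.shape) < 0.4] = 0
        dm = make_dm(depth, on_target=depth.sum(axis=1) + 7,
                     total=depth.sum(axis=1) + 20, duplicate=np.full(5, 2))
        formats.write_depth_table(dm, tmp_path / "d.tsv", tmp_path / "t.tsv")
        back = formats.read_depth_table(tmp_path / "d.tsv", tmp_path / "t.tsv")
        assert back.samples == dm.samples
        # region order may drop all-zero regions from the long format; compare present ones
        idx = [dm.regions.index(r) for r in back.regions]
        np.testing.assert_array_equal(back.depth, dm.depth[:, idx])
        pd.testing.assert_frame_equal(back.totals, dm.totals)


class TestPanelIO:
    def _panel(self):
        sites = make_sites(3)
        sites["pos"] = [100, 50, 200]
        sites["maf"] = [0.25, np.nan, 0.4]
        sites["status"] = ["selected", "reinserted", "trait"]
        sites.loc[2, ["source_db", "is_trait_marker"]] = ["trait", True]
        return sites

    def test_bed_is_zero_based_half_open(self, tmp_path):
        panel = self._panel()
        formats.write_panel(panel, tmp_path / "p.bed", tmp_path / "p.tsv")
        lines = (tmp_path / "p.bed").read_text().splitlines()
        starts = [int(l.split("\t")[1]) for l in lines]
        ends = [int(l.split("\t")[2]) for l in lines]
        assert starts == [49, 99, 199]  # sorted by pos, 1-based 50/100/200
        assert ends == [50, 100, 200]

    def test_output_sorted_by_chrom_then_pos(self, tmp_path):
        panel = self._panel()
        panel.loc[0, "chrom"] = "SL2.40ch02"
        formats.write_panel(panel, tmp_path / "p.bed", tmp_path / "p.tsv")
        back = pd.read_csv(tmp_path / "p.tsv", sep="\t")
        assert back["chrom"].is_monotonic_increasing
        assert back.groupby("chrom")["pos"].apply(lambda s: s.is_monotonic_increasing).all()

    def test_round_trip_preserves_fields(self, tmp_path):
        panel = self._panel()
        formats.write_panel(panel, tmp_path / "p.bed", tmp_path / "p.tsv")
        back = formats.read_panel(tmp_path / "p.tsv")
        expected = panel.sort_values(["chrom", "pos"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(back, expected[back.columns])

    def test_empty_panel_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            formats.write_panel(self._panel().iloc[:0], tmp_path / "p.bed", tmp_path / "p.tsv")


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(missing_rate_max=0.2, max_mean_gap_bp=5000.0, seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert RunConfig.from_yaml(tmp_path / "c.yaml") == cfg

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            RunConfig(missing_rate_max=1.5)

    def test_unknown_key_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("no_such_option: 1\n")
        with pytest.raises(ValidationError):
            RunConfig.from_yaml(tmp_path / "c.yaml")
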