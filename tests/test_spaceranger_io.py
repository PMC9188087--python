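"""Space Ranger dialect readers/writers and round-trip fidelity."""

import gzip
import os

import numpy as np
import pandas as pd
import pytest

from visiumview import fixtures, spaceranger_io as srio
from visiumview.annotation import AnnotationTable


class TestRoundTrip:
    def test_counts_match_generator_truth(self, sample, truth):
        assert (sample.counts.counts != truth.counts.counts).nnz == 0
        assert sample.counts.gene_ids == truth.counts.gene_ids
        assert sample.counts.gene_symbols == truth.counts.gene_symbols
        assert sample.counts.barcodes == truth.counts.barcodes

    def test_positions_match_truth(self, sample, truth):
        assert list(sample.spots.barcode) == list(truth.spots.barcode)
        np.testing.assert_array_equal(sample.spots.array_row,
                                      truth.spots.array_row)
        np.testing.assert_array_equal(sample.spots.array_col,
                                      truth.spots.array_col)
        np.testing.assert_allclose(sample.spots.pxl_row_fullres,
                                   truth.spots.pxl_row_fullres, rtol=1e-9)
        np.testing.assert_allclose(sample.spots.pxl_col_fullres,
                                   truth.spots.pxl_col_fullres, rtol=1e-9)

    def test_scalefactors_and_image_match_truth(self, sample, truth):
        assert sample.scalefactors == truth.scalefactors
        np.testing.assert_array_equal(sample.images["lowres"].pixels,
                                      truth.image.pixels)

    def test_clusters_and_projection_match_truth(self, sample, truth):
        labels = sample.spot_covariates["graphclust"]
        np.testing.assert_array_equal(
            labels.astype(int), truth.layer_of_spot)
        np.testing.assert_allclose(sample.reduced_dims["umap"], truth.umap,
                                   rtol=1e-9)

    def test_plain_and_gz_matrices_parse_identically(self, sim_cfg, tmp_path):
        d_gz, d_plain = tmp_path / "gz", tmp_path / "plain"
        fixtures.write_spaceranger_dir(sim_cfg, str(d_gz), gz=True)
        fixtures.write_spaceranger_dir(sim_cfg, str(d_plain), gz=False)
        a = srio.load_sample(str(d_gz), "a")
        b = srio.load_sample(str(d_plain), "b")
        assert (a.counts.counts != b.counts.counts).nnz == 0
        assert a.counts.gene_ids == b.counts.gene_ids


class TestPositionsDialects:
    ROW = "AAACAACGAA-1,1,0,16,1000,2000\n"
    HEADER = ("barcode,in_tissue,array_row,array_col,"
              "pxl_row_in_fullres,pxl_col_in_fullres\n")

    def test_headerless_row_parses(self, tmp_path):
        p = tmp_path / "tissue_positions_list.csv"
        p.write_text(self.ROW)
        spots = srio.read_tissue_positions(str(p))
        assert spots.barcode[0] == "AAACAACGAA-1"
        assert spots.in_tissue[0]
        assert spots.array_row[0] == 0 and spots.array_col[0] == 16
        assert spots.pxl_row_fullres[0] == 1000
        assert spots.pxl_col_fullres[0] == 2000

    def test_v2_header_gives_identical_table(self, tmp_path):
        p1 = tmp_path / "tissue_positions_list.csv"
        p1.write_text(self.ROW)
        p2 = tmp_path / "tissue_positions.csv"
        p2.write_text(self.HEADER + self.ROW)
        a, b = (srio.read_tissue_positions(str(p)) for p in (p1, p2))
        assert list(a.barcode) == list(b.barcode)
        np.testing.assert_array_equal(a.pxl_row_fullres, b.pxl_row_fullres)

    def test_dialect_equivalence_on_generated_data(self, sim_cfg, tmp_path):
        d1, d2 = tmp_path / "v1", tmp_path / "v2"
        fixtures.write_spaceranger_dir(sim_cfg, str(d1),
                                       positions_dialect="v1")
        fixtures.write_spaceranger_dir(sim_cfg, str(d2),
                                       positions_dialect="v2")
        a = srio.load_sample(str(d1), "a")
        b = srio.load_sample(str(d2), "b")
        assert list(a.spots.barcode) == list(b.spots.barcode)
        np.testing.assert_array_equal(a.spots.pxl_col_fullres,
                                      b.spots.pxl_col_fullres)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "tissue_positions_list.csv"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            srio.read_tissue_positions(str(p))

    def test_wrong_column_count_errors(self, tmp_path):
        p = tmp_path / "tissue_positions_list.csv"
        p.write_text("a,1,0,16,1000\n")
        with pytest.raises(ValueError, match="6 columns"):
            srio.read_tissue_positions(str(p))

    def test_non_numeric_coordinate_names_row(self, tmp_path):
        p = tmp_path / "tissue_positions_list.csv"
        p.write_text("a,1,0,0,10,20\nb,1,1,1,oops,20\n")
        with pytest.raises(ValueError, match="row 1"):
            srio.read_tissue_positions(str(p))


class TestScaleFactors:
    def test_fields_mapped(self, tmp_path):
        p = tmp_path / "scalefactors_json.json"
        p.write_text('{"spot_diameter_fullres":130.0,'
                     '"tissue_hires_scalef":0.17,'
                     '"tissue_lowres_scalef":0.05}')
        sf = srio.read_scalefactors(str(p))
        assert sf.spot_diameter_fullres == 130.0
        assert sf.fiducial_diameter_fullres is None
        assert sf.tissue_hires_scalef == 0.17
        assert sf.tissue_lowres_scalef == 0.05

    def test_missing_required_key_named(self, tmp_path):
        p = tmp_path / "sf.json"
        p.write_text('{"spot_diameter_fullres":130.0,'
                     '"tissue_hires_scalef":0.17}')
        with pytest.raises(ValueError, match="tissue_lowres_scalef"):
            srio.read_scalefactors(str(p))

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "sf.json"
        p.write_text('{"spot_diameter_fullres":130.0,'
                     '"tissue_hires_scalef":-0.17,'
                     '"tissue_lowres_scalef":0.05}')
        with pytest.raises(ValueError, match="tissue_hires_scalef"):
            srio.read_scalefactors(str(p))

    def test_unknown_keys_ignored(self, tmp_path):
        p = tmp_path / "sf.json"
        p.write_text('{"spot_diameter_fullres":130.0,'
                     '"tissue_hires_scalef":0.17,'
                     '"tissue_lowres_scalef":0.05,"regist_target_img":9}')
        assert srio.read_scalefactors(str(p)).spot_diameter_fullres == 130.0


class TestCountsErrors:
    def test_feature_count_mismatch_states_both(self, sim_dir, tmp_path):
        src, _ = sim_dir
        import shutil
        dst = tmp_path / "broken"
        shutil.copytree(src, dst)
        fpath = dst / "filtered_feature_bc_matrix" / "features.tsv.gz"
        with gzip.open(fpath, "rt") as fh:
            lines = fh.readlines()
        with gzip.open(fpath, "wt") as fh:
            fh.writelines(lines[:-1])
        with pytest.raises(ValueError, match=r"declares 120.*119"):
            srio.read_counts(srio.SpaceRangerDir.detect(str(dst)))

    def test_empty_matrix_valid(self, tmp_path):
        d = tmp_path / "m"
        d.mkdir()
        (d / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n2 3 0\n")
        (d / "features.tsv").write_text("g1\tG1\tGene Expression\n"
                                        "g2\tG2\tGene Expression\n")
        (d / "barcodes.tsv").write_text("b1\nb2\nb3\n")
        sr = srio.SpaceRangerDir(root_path=str(tmp_path), matrix_dir=str(d),
                                 positions_path="", scalefactors_path="",
                                 spatial_dir="", analysis_dir=None)
        cm = srio.read_counts(sr)
        assert cm.counts.shape == (2, 3) and cm.counts.nnz == 0

    def test_malformed_mtx_names_file(self, tmp_path):
        d = tmp_path / "m"
        d.mkdir()
        (d / "matrix.mtx").write_text("not a matrix\n")
        (d / "features.tsv").write_text("g1\tG1\n")
        (d / "barcodes.tsv").write_text("b1\n")
        sr = srio.SpaceRangerDir(root_path=str(tmp_path), matrix_dir=str(d),
                                 positions_path="", scalefactors_path="",
                                 spatial_dir="", analysis_dir=None)
        with pytest.raises(ValueError, match="matrix.mtx"):
            srio.read_counts(sr)


class TestAnalysisReaders:
    def test_clusters_round_trip(self, sim_dir):
        path, truth = sim_dir
        sr = srio.SpaceRangerDir.detect(path)
        clusters = srio.read_analysis_clusters(sr)
        assert set(clusters) == {"graphclust"}
        assert sorted(set(clusters["graphclust"].values())) == [1, 2, 3]

    def test_missing_analysis_dir_is_empty_mapping(self, tmp_path, sim_cfg):
        d = tmp_path / "noanalysis"
        fixtures.write_spaceranger_dir(sim_cfg, str(d))
        import shutil
        shutil.rmtree(d / "analysis")
        sr = srio.SpaceRangerDir.detect(str(d))
        assert srio.read_analysis_clusters(sr) == {}
        assert srio.read_analysis_projections(sr) == {}

    def test_unknown_barcode_dropped_with_warning(self, sim_dir, tmp_path,
                                                  caplog):
        import logging
        import shutil
        src, truth = sim_dir
        dst = tmp_path / "extra"
        shutil.copytree(src, dst)
        cpath = dst / "analysis" / "clustering" / "graphclust" / "clusters.csv"
        with open(cpath, "a") as fh:
            fh.write("NOT-A-BARCODE-1,2\n")
        sr = srio.SpaceRangerDir.detect(str(dst))
        with caplog.at_level(logging.WARNING):
            clusters = srio.read_analysis_clusters(sr, truth.counts.barcodes)
        assert "NOT-A-BARCODE-1" not in clusters["graphclust"]
        assert "dropping 1" in caplog.text

    def test_umap_projection_shape(self, sim_dir):
        path, truth = sim_dir
        sr = srio.SpaceRangerDir.detect(path)
        proj = srio.read_analysis_projections(sr)
        assert proj["umap"].shape == (len(truth.spots), 2)


class TestLoadSampleContracts:
    def test_missing_scalefactors_errors(self, sim_cfg, tmp_path):
        d = tmp_path / "nosf"
        fixtures.write_spaceranger_dir(sim_cfg, str(d))
        os.remove(d / "spatial" / "scalefactors_json.json")
        with pytest.raises(FileNotFoundError, match="scalefactors"):
            srio.load_sample(str(d), "x")

    def test_error_prefixed_with_sample_id(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="mysample"):
            srio.load_sample(str(tmp_path), "mysample")

    def test_missing_image_tolerated(self, sim_cfg, tmp_path):
        d = tmp_path / "noimg"
        fixtures.write_spaceranger_dir(sim_cfg, str(d))
        os.remove(d / "spatial" / "tissue_lowres_image.png")
        s = srio.load_sample(str(d), "x")
        assert s.images == {}


class TestResultAndAnnotationCsv:
    def test_results_csv_row_count(self, tmp_path):
        df = pd.DataFrame({"a": [1, 2, 3], "b": ["x", "y", "z"]})
        p = tmp_path / "r.csv"
        srio.write_results_csv(df, str(p))
        assert len(p.read_text().splitlines()) == 4

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            srio.write_results_csv(pd.DataFrame({"a": []}),
                                   str(tmp_path / "r.csv"))

    def test_annotation_round_trip_with_commas(self, tmp_path):
        tab = AnnotationTable(pd.DataFrame({
            "sample_id": ["s1", "s1", "s2"],
            "barcode": ["b1", "b2", "b1"],
            "label": ["layer 1, deep", "WM", "L6"]}))
        p = tmp_path / "ann.csv"
        srio.write_annotations(tab, str(p))
        assert '"layer 1, deep"' in p.read_text()
        assert srio.read_annotations(str(p)) == tab

    def test_annotation_csv_line_count(self, tmp_path):
        tab = AnnotationTable(pd.DataFrame({
            "sample_id": ["s"] * 3, "barcode": ["a", "b", "c"],
            "label": ["x"] * 3}))
        p = tmp_path / "ann.csv"
        srio.write_annotations(tab, str(p))
        assert len(p.read_text().splitlines()) == 4


class TestBundle:
    def test_bundle_round_trip(self, sample, tmp_path):
        bundle = tmp_path / "bundle"
        srio.save_sample_to_bundle(sample, str(bundle))
        loaded = srio.load_bundle(str(bundle))
        assert len(loaded) == 1
        s2 = loaded[0]
        assert (s2.counts.counts != sample.counts.counts).nnz == 0
        assert set(s2.spot_covariates) == set(sample.spot_covariates)
        np.testing.assert_array_equal(
            s2.spot_covariates["graphclust"].astype(str),
            sample.spot_covariates["graphclust"].astype(str))
        np.testing.assert_allclose(s2.reduced_dims["umap"],
                                   sample.reduced_dims["umap"], rtol=1e-9)
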