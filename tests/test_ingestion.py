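"""Measurement-table dialect, GeoJSON annotations, detector."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

import epidermap as em
from epidermap.datatypes import ParameterError, TissueParams
from epidermap.qupath_io import write_qupath_measurements


@pytest.fixture(scope="module")
def written(tmp_path_factory, sparse_dataset):
    path = tmp_path_factory.mktemp("io") / "measurements.csv"
    write_qupath_measurements(sparse_dataset.nuclei, path)
    return path, sparse_dataset.nuclei


class TestMeasurementTable:
    def test_round_trip_field_equality(self, written):
        path, original = written
        back = em.read_qupath_measurements(path)
        for col in ("centroid_x", "centroid_y", "area", "perimeter", "circularity",
                    "brdu_mean", "ki67_mean", "dapi_sd"):
            np.testing.assert_allclose(back[col], original[col], rtol=1e-9)
        assert back["true_archetype"].tolist() == original["true_archetype"].tolist()
        assert back["true_brdu_pos"].tolist() == original["true_brdu_pos"].tolist()

    def test_qupath_headers_map_to_canonical_names(self, written):
        path, _ = written
        raw = pd.read_csv(path)
        assert "Nucleus: Area µm^2" in raw.columns
        assert "BrdU: Nucleus: Mean" in raw.columns
        back = em.read_qupath_measurements(path)
        assert "area" in back.columns and "brdu_mean" in back.columns

    def test_bad_numeric_cell_drops_row(self, tmp_path, caplog):
        df = pd.DataFrame(
            {
                "Centroid X µm": [1.0, 2.0, 3.0],
                "Centroid Y µm": [1.0, 1.0, 1.0],
                "Nucleus: Area µm^2": ["30.0", "oops", "50.0"],
                "Nucleus: Circularity": [0.9, 0.9, 0.9],
            }
        )
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        with caplog.at_level("WARNING"):
            table = em.read_qupath_measurements(path)
        assert len(table) == 2
        assert "1 row" in caplog.text

    def test_missing_required_column_is_named(self, tmp_path):
        path = tmp_path / "t.csv"
        pd.DataFrame({"Centroid X µm": [1.0], "Centroid Y µm": [2.0]}).to_csv(path, index=False)
        with pytest.raises(ParameterError, match="area"):
            em.read_qupath_measurements(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("\n")
        with pytest.raises((ParameterError, pd.errors.EmptyDataError)):
            em.read_qupath_measurements(path)

    def test_comma_decimal_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "Centroid X µm,Centroid Y µm,Nucleus: Area µm^2,Nucleus: Circularity\n"
            '"1,5","2,0","30,5","0,9"\n'
        )
        with pytest.raises(ParameterError, match="comma"):
            em.read_qupath_measurements(path)

    def test_mm_units_converted(self, tmp_path):
        path = tmp_path / "t.csv"
        pd.DataFrame(
            {
                "Centroid X mm": [0.001],
                "Centroid Y mm": [0.002],
                "Nucleus: Area µm^2": [30.0],
                "Nucleus: Circularity": [0.9],
            }
        ).to_csv(path, index=False)
        table = em.read_qupath_measurements(
            path, column_map={"Centroid X mm": "centroid_x", "Centroid Y mm": "centroid_y"}
        )
        assert table.loc[0, "centroid_x"] == pytest.approx(1.0)


class TestAnnotations:
    def test_geojson_round_trip(self, tmp_path, sparse_dataset):
        path = tmp_path / "ann.geojson"
        em.write_annotations_geojson(sparse_dataset.annotations, path)
        back = em.read_annotations_geojson(path)
        orig = sparse_dataset.annotations
        assert back.basement_membrane[0].equals_exact(orig.basement_membrane[0], 1e-9)
        assert back.epidermal_surface[0].equals_exact(orig.epidermal_surface[0], 1e-9)
        assert len(back.hair_follicles) == len(orig.hair_follicles)

    def test_missing_follicles_is_valid(self, tmp_path):
        params = TissueParams(section_length=500, hf_positions=())
        ann = em.generate_tissue_geometry(params)
        path = tmp_path / "ann.geojson"
        em.write_annotations_geojson(ann, path)
        back = em.read_annotations_geojson(path)
        assert back.hair_follicles == []

    def test_missing_border_rejected(self, tmp_path):
        path = tmp_path / "bad.geojson"
        path.write_text(
            '{"type": "FeatureCollection", "features": [{"type": "Feature",'
            '"geometry": {"type": "LineString", "coordinates": [[0,0],[1,0]]},'
            '"properties": {"classification": {"name": "BasementMembrane"}}}]}'
        )
        with pytest.raises(ParameterError, match="EpidermalSurface"):
            em.read_annotations_geojson(path)


class TestOmeTiff:
    def test_round_trip_image_and_metadata(self, tmp_path, rng):
        from epidermap.qupath_io import read_ome_tiff, write_ome_tiff

        img = rng.normal(10, 2, size=(3, 32, 48)).astype(np.float32)
        path = tmp_path / "sec.ome.tif"
        write_ome_tiff(img, path, ("dapi", "brdu", "ki67"), pixel_size=0.5)
        back, meta = read_ome_tiff(path)
        np.testing.assert_array_equal(back, img)
        assert meta["pixel_size"] == pytest.approx(0.5)
        assert meta["channel_names"] == ["dapi", "brdu", "ki67"]


class TestDetector:
    def test_blank_image_detects_nothing(self, rng):
        img = rng.normal(0, 0.5, size=(3, 64, 64)).astype(np.float32)
        img -= img.min()  # noise only, no structure above Otsu of noise
        labels, table = em.detect_nuclei_simple(np.zeros((3, 64, 64)), pixel_size=0.5)
        assert len(table) == 0 and labels.max() == 0

    def test_single_disk_features(self):
        """Rasterized disk r=4 µm: area ~16π µm², circularity >= 0.85."""
        from skimage.draw import disk

        px = 0.5
        img = np.zeros((3, 80, 80), dtype=np.float32)
        rr, cc = disk((40, 40), 4.0 / px)
        img[0, rr, cc] = 100.0
        _, table = em.detect_nuclei_simple(img, pixel_size=px)
        assert len(table) == 1
        assert table.loc[0, "area"] == pytest.approx(16 * np.pi, rel=0.15)
        assert table.loc[0, "circularity"] >= 0.85

    def test_elongated_ellipse_low_circularity(self):
        from skimage.draw import ellipse

        img = np.zeros((1, 120, 120), dtype=np.float32)
        rr, cc = ellipse(60, 60, 40, 10)
        img[0, rr, cc] = 100.0
        _, table = em.detect_nuclei_simple(
            img, pixel_size=1.0, channel_names=("dapi",), min_peak_distance=60
        )
        assert len(table) == 1
        assert table.loc[0, "circularity"] <= 0.8

    def test_recovers_rendered_nuclei(self, sparse_dataset):
        """>=45/50 detections matched to ground truth within 2 µm."""
        img, mask = em.render_section_image(sparse_dataset)
        _, table = em.detect_nuclei_simple(img, pixel_size=0.5)
        truth = sparse_dataset.nuclei
        offset = np.array(
            [truth.centroid_x.min() - 20.0, truth.centroid_y.min() - 20.0]
        )
        tree = cKDTree(table[["centroid_x", "centroid_y"]].to_numpy() + offset)
        d, _ = tree.query(truth[["centroid_x", "centroid_y"]].to_numpy())
        matched = (d < 2.0).sum()
        assert matched >= 45
        # recall and precision both >= 0.9 on the default-noise render
        assert matched / len(truth) >= 0.9
        assert matched / len(table) >= 0.9

    def test_wrong_dimensionality_rejected(self):
        with pytest.raises(ParameterError):
            em.detect_nuclei_simple(np.zeros((10, 10)), pixel_size=0.5)
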