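"""Per-object feature extraction: intensity, morphometry, gradient, FSD,
Haralick, and composite nuclei features."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

import _oracles
from histokit.features import (
    GRADIENT_COLUMNS,
    HARALICK_COLUMNS,
    INTENSITY_COLUMNS,
    MORPHOMETRY_COLUMNS,
    compute_fsd_features,
    compute_gradient_features,
    compute_haralick_features,
    compute_intensity_features,
    compute_morphometry_features,
    compute_nuclei_features,
    cytoplasm_rings,
)
from histokit.synth import synth_label_texture


def binary_disk(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= radius**2


def random_regions(rng, shape=(32, 32), n=4):
    """A label image of n rectangular regions plus a random raster."""
    labels = np.zeros(shape, dtype=int)
    for i in range(n):
        r = rng.integers(0, shape[0] - 8)
        c = rng.integers(0, shape[1] - 8)
        labels[r : r + rng.integers(3, 8), c : c + rng.integers(3, 8)] = i + 1
    raster = rng.uniform(0, 255, size=shape)
    return labels, raster


class TestIntensity:
    def test_constant_region(self):
        labels, raster = synth_label_texture("constant", size=(8, 8), low=40, high=40)
        row = compute_intensity_features(labels, raster).loc[1]
        assert row["Intensity.Min"] == row["Intensity.Max"] == 40.0
        assert row["Intensity.Std"] == 0.0
        assert row["Intensity.HistEntropy"] == 0.0
        assert row["Intensity.HistEnergy"] == 1.0
        assert row["Intensity.Skewness"] == 0.0
        assert row["Intensity.Kurtosis"] == 0.0

    def test_two_point_distribution(self):
        labels, raster = synth_label_texture("checkerboard", size=(8, 8),
                                             low=0.0, high=1.0)
        row = compute_intensity_features(labels, raster).loc[1]
        assert row["Intensity.Mean"] == 0.5
        assert row["Intensity.HistEntropy"] == 1.0
        assert row["Intensity.HistEnergy"] == 0.5

    def test_matches_formula_oracle(self, rng):
        for _ in range(5):
            labels, raster = random_regions(rng)
            table = compute_intensity_features(labels, raster)
            for idx in np.unique(labels[labels > 0]):
                want = _oracles.intensity_stats(raster[labels == idx])
                for col in INTENSITY_COLUMNS:
                    assert abs(table.loc[idx, col] - want[col]) <= 1e-9, col

    def test_no_cross_object_leakage(self, rng):
        labels, raster = random_regions(rng)
        table = compute_intensity_features(labels, raster)
        for idx in np.unique(labels[labels > 0]):
            solo = compute_intensity_features((labels == idx).astype(int), raster)
            assert np.allclose(table.loc[idx].values, solo.loc[1].values)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_intensity_features(np.ones((4, 4), int), np.ones((5, 5)))


class TestMorphometry:
    def test_disk_analytics(self):
        labels = binary_disk((64, 64), (32, 32), 20).astype(int)
        row = compute_morphometry_features(labels).loc[1]
        assert abs(row["Shape.Area"] - np.pi * 400) <= 0.02 * np.pi * 400
        assert abs(row["Shape.Circularity"] - 1.0) <= 0.10
        assert row["Shape.Eccentricity"] < 0.1
        assert abs(row["Shape.EquivalentDiameter"] - 40.0) < 1.0

    def test_square_extent_solidity(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[4:14, 6:16] = 1
        row = compute_morphometry_features(labels).loc[1]
        assert row["Shape.Extent"] == 1.0
        assert row["Shape.Solidity"] == 1.0
        assert row["Shape.Area"] == 100.0

    def test_hu_rotation_invariance(self, rng):
        blob = np.zeros((40, 40), dtype=int)
        blob[10:28, 14:25] = 1
        blob[12:20, 25:30] = 1
        rot = np.rot90(blob)
        a = compute_morphometry_features(blob).loc[1]
        b = compute_morphometry_features(rot).loc[1]
        for i in range(1, 8):
            col = f"Shape.HuMoments{i}"
            denom = max(abs(a[col]), abs(b[col]), 1e-300)
            assert abs(a[col] - b[col]) / denom <= 1e-6

    def test_single_pixel_conventions(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[2, 2] = 1
        row = compute_morphometry_features(labels).loc[1]
        assert row["Shape.Area"] == 1.0
        assert row["Shape.Perimeter"] == 0.0
        assert row["Shape.Circularity"] == 1.0

    def test_weighted_hu_present_only_with_intensity(self, rng):
        labels, raster = random_regions(rng, n=2)
        without = compute_morphometry_features(labels)
        with_int = compute_morphometry_features(labels, raster)
        assert "Shape.WeightedHuMoments1" not in without.columns
        assert "Shape.WeightedHuMoments1" in with_int.columns
        assert list(without.columns) == MORPHOMETRY_COLUMNS


class TestGradient:
    def test_constant_region_all_zero(self):
        labels, raster = synth_label_texture("constant", size=(8, 8))
        row = compute_gradient_features(labels, raster).loc[1]
        assert (row == 0.0).all()

    def test_ramp_slope(self):
        s = 2.5
        labels = np.ones((16, 32), dtype=int)
        raster = s * np.arange(32)[None, :].repeat(16, axis=0).astype(float)
        row = compute_gradient_features(labels, raster).loc[1]
        assert abs(row["Gradient.Mag.Mean"] - s) <= 0.02 * s

    def test_matches_formula_oracle(self, rng):
        for _ in range(5):
            labels, raster = random_regions(rng)
            gy, gx = np.gradient(raster)
            mag = np.hypot(gy, gx)
            table = compute_gradient_features(labels, raster)
            for idx in np.unique(labels[labels > 0]):
                v = mag[labels == idx]
                if not (v > 0).any():
                    continue
                want = _oracles.intensity_stats(v)
                pairs = [
                    ("Gradient.Mag.Mean", "Intensity.Mean"),
                    ("Gradient.Mag.Std", "Intensity.Std"),
                    ("Gradient.Mag.Skewness", "Intensity.Skewness"),
                    ("Gradient.Mag.Kurtosis", "Intensity.Kurtosis"),
                    ("Gradient.Mag.HistEntropy", "Intensity.HistEntropy"),
                    ("Gradient.Mag.HistEnergy", "Intensity.HistEnergy"),
                ]
                for got_col, want_col in pairs:
                    assert abs(table.loc[idx, got_col] - want[want_col]) <= 1e-9


class TestFSD:
    def test_circle_energy_in_lowest_bin(self):
        labels = binary_disk((64, 64), (32, 32), 20).astype(int)
        row = compute_fsd_features(labels).loc[1]
        assert row["FSD.Bin1"] >= 0.95
        assert row["FSD.Degenerate"] == 0.0

    def test_rotation_invariance(self):
        blob = np.zeros((48, 48), dtype=int)
        blob[10:30, 15:35] = 1
        blob[8:10, 20:28] = 1
        a = compute_fsd_features(blob).loc[1]
        b = compute_fsd_features(np.rot90(blob).copy()).loc[1]
        for i in range(1, 7):
            # rotation moves the trace start point, which shifts the
            # arc-length resampling grid by a fraction of a pixel
            assert abs(a[f"FSD.Bin{i}"] - b[f"FSD.Bin{i}"]) <= 1e-5

    def test_star_more_complex_than_circle(self):
        # 5-pointed star vs. circle of comparable area
        h = w = 96
        rr, cc = np.mgrid[0:h, 0:w].astype(float)
        ang = np.arctan2(rr - 48, cc - 48)
        rad = np.hypot(rr - 48, cc - 48)
        star_r = 18 + 12 * np.cos(5 * ang)
        star = (rad <= star_r).astype(int)
        circle = binary_disk((h, w), (48, 48), 24).astype(int)
        s = compute_fsd_features(star).loc[1]
        c = compute_fsd_features(circle).loc[1]
        assert s["FSD.Bin4"] + s["FSD.Bin5"] + s["FSD.Bin6"] > (
            c["FSD.Bin4"] + c["FSD.Bin5"] + c["FSD.Bin6"]
        )

    def test_bin_energies_sum_to_one(self, rng):
        labels = binary_disk((40, 40), (20, 20), 12).astype(int)
        row = compute_fsd_features(labels).loc[1]
        total = sum(row[f"FSD.Bin{i}"] for i in range(1, 7))
        assert abs(total - 1.0) <= 1e-9

    def test_degenerate_object_flagged(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[3, 3] = 1
        row = compute_fsd_features(labels).loc[1]
        assert row["FSD.Degenerate"] == 1.0
        assert row["FSD.Bin1"] == 0.0

    def test_k_validation(self):
        with pytest.raises(ValueError):
            compute_fsd_features(np.ones((8, 8), int), K=4)


class TestHaralick:
    def test_constant_region(self):
        labels, raster = synth_label_texture("constant", size=(8, 8))
        row = compute_haralick_features(labels, raster).loc[1]
        assert row["Haralick.ASM"] == 1.0
        assert row["Haralick.Contrast"] == 0.0
        assert row["Haralick.Entropy"] == 0.0
        assert row["Haralick.Degenerate"] == 0.0

    def test_checkerboard_hand_computed(self):
        labels, raster = synth_label_texture("checkerboard", size=(8, 8),
                                             low=0.0, high=255.0)
        row = compute_haralick_features(labels, raster, levels=2,
                                        offsets=[(0, 1)]).loc[1]
        # horizontally adjacent pixels always differ -> contrast 1,
        # perfect anti-correlation
        assert row["Haralick.Contrast"] == 1.0
        assert row["Haralick.Correlation"] == -1.0

    def test_matches_formula_oracle(self, rng):
        offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]
        levels = 8
        for _ in range(5):
            labels = np.zeros((12, 12), dtype=int)
            labels[2:10, 1:9] = 1
            raster = rng.uniform(0, 255, size=(12, 12))
            table = compute_haralick_features(labels, raster, levels=levels)
            sub = labels == 1
            q = np.zeros(labels.shape, dtype=int)
            q[sub] = _oracles.quantize_minmax(raster[sub], levels)
            per_offset = []
            for off in offsets:
                glcm = _oracles.glcm_counts(sub, q, levels, off)
                if glcm.sum() > 0:
                    per_offset.append(_oracles.haralick_13(glcm / glcm.sum()))
            for col in HARALICK_COLUMNS:
                want = np.mean([f[col] for f in per_offset])
                assert abs(table.loc[1, col] - want) <= 1e-9, col

    def test_degenerate_tiny_object(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[3, 3] = 1
        row = compute_haralick_features(labels, np.random.default_rng(0)
                                        .uniform(size=(8, 8))).loc[1]
        assert row["Haralick.Degenerate"] == 1.0

    def test_levels_validation(self):
        with pytest.raises(ValueError):
            compute_haralick_features(np.ones((4, 4), int), np.ones((4, 4)),
                                      levels=1)


class TestNucleiComposite:
    def test_column_count_and_composition(self, rng):
        labels = binary_disk((48, 48), (16, 16), 8).astype(int)
        labels[binary_disk((48, 48), (34, 34), 7)] = 2
        density = ndi.gaussian_filter(rng.uniform(0, 1, (48, 48)), 1.0)
        table = compute_nuclei_features(labels, density)
        n_morph = len(MORPHOMETRY_COLUMNS) + 7  # weighted Hu present
        n_expected = n_morph + 7 + len(INTENSITY_COLUMNS) + len(GRADIENT_COLUMNS) \
            + len(HARALICK_COLUMNS) + 1
        assert table.shape == (2, n_expected)
        alone = compute_intensity_features(labels, density)
        for col in INTENSITY_COLUMNS:
            assert np.allclose(table[f"Nucleus.{col}"], alone[col])

    def test_cytoplasm_rings_disjoint(self):
        labels = np.zeros((32, 32), dtype=int)
        labels[binary_disk((32, 32), (15, 10), 5)] = 1
        labels[binary_disk((32, 32), (15, 22), 5)] = 2
        rings = cytoplasm_rings(labels, 6)
        assert ((rings > 0) & (labels > 0)).sum() == 0
        # rings of adjacent nuclei never overlap (each pixel has one owner)
        assert set(np.unique(rings)) <= {0, 1, 2}

    def test_cytoplasm_columns_present(self, rng):
        labels = binary_disk((32, 32), (16, 16), 6).astype(int)
        density = rng.uniform(0, 1, (32, 32))
        table = compute_nuclei_features(labels, density, cytoplasm_density=density)
        assert "Cytoplasm.Intensity.Mean" in table.columns
        assert not table.isna().any().any()


class TestGraphFeatures:
    def test_unit_square_mst(self):
        from histokit.features import compute_global_cell_graph_features

        pts = [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)]
        out = compute_global_cell_graph_features(pts)
        assert out["Graph.MSTTotalLength"] == 3.0

    def test_unit_square_delaunay_mean(self):
        from histokit.features import compute_global_cell_graph_features

        pts = [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)]
        out = compute_global_cell_graph_features(pts)
        assert abs(out["Graph.DelaunayEdgeLength.Mean"] - (4 + np.sqrt(2)) / 5) <= 1e-9

    def test_mst_matches_prim(self, rng):
        from histokit.features import mst_total_length

        pts = rng.uniform(0, 100, size=(50, 2))
        assert abs(mst_total_length(pts) - _oracles.prim_mst_length(pts)) <= 1e-9

    def test_too_few_or_collinear_points_rejected(self):
        from histokit.features import compute_global_cell_graph_features

        with pytest.raises(ValueError):
            compute_global_cell_graph_features([(0, 0), (1, 1), (2, 2)])
        with pytest.raises(ValueError):
            compute_global_cell_graph_features([(0, 0), (1, 1), (2, 2), (3, 3)])

    def test_metrics_in_range(self, rng):
        from histokit.features import compute_global_cell_graph_features

        pts = rng.uniform(0, 50, size=(30, 2))
        out = compute_global_cell_graph_features(pts)
        for key, val in out.items():
            assert np.isfinite(val), key
            if key.endswith("Disorder") or key.endswith("MinMaxRatio"):
                assert 0.0 <= val <= 1.0, key


class TestDeterminism:
    def test_tables_bit_identical(self, rng):
        labels, raster = random_regions(rng)
        a = compute_nuclei_features(labels, raster)
        b = compute_nuclei_features(labels, raster)
        pd.testing.assert_frame_equal(a, b)
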