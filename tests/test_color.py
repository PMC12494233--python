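"""Color module: spaces, density transforms, deconvolution, estimation,
normalization, and augmentation."""

import numpy as np
import pytest

from histokit.color import (
    AugmentParams,
    DEFAULT_HE_MATRIX,
    ReinhardStats,
    StainMatrix,
    aggregate_reinhard_stats,
    angular_distance_deg,
    apply_stain_affine,
    color_convolution,
    color_deconvolution,
    complement_stain_matrix,
    convert_color_space,
    deconvolution_normalize,
    estimate_stains_macenko,
    estimate_stains_snmf,
    hsi_to_rgb,
    intensity_density_transform,
    match_stain_columns,
    od_to_rgb,
    perturb_stain_concentration,
    reinhard_normalize,
    reinhard_stats,
    rgb_to_hsi,
    rgb_to_lab,
    rgb_to_od,
    rgb_to_sda,
    sda_to_rgb,
    snmf_objective,
)
from histokit.color.macenko import CollinearStainsWarning
from histokit.synth import synth_stain_field


def random_rgb(rng, shape=(20, 50, 3), lo=1.0, hi=255.0):
    return rng.uniform(lo, hi, size=shape)


# ---------------------------------------------------------------------------
# color spaces
# ---------------------------------------------------------------------------

class TestSpaces:
    def test_gray_pixel_has_zero_saturation(self):
        im = np.full((1, 1, 3), 100.0)
        hsi = rgb_to_hsi(im)
        assert hsi[0, 0, 1] == 0.0
        assert hsi[0, 0, 2] == 100.0

    def test_pure_red_has_hue_zero(self):
        im = np.array([[[255.0, 0.0, 0.0]]])
        assert rgb_to_hsi(im)[0, 0, 0] == 0.0

    def test_hsi_round_trip(self, rng):
        im = random_rgb(rng)
        back = hsi_to_rgb(rgb_to_hsi(im))
        assert np.max(np.abs(back - im)) < 0.5

    def test_cielab_round_trip(self, rng):
        im = random_rgb(rng, lo=0.0)
        back = convert_color_space(convert_color_space(im, "cielab"), "cielab",
                                   inverse=True)
        assert np.max(np.abs(back - im)) < 0.5

    def test_log_opponent_round_trip(self, rng):
        im = random_rgb(rng)
        back = convert_color_space(convert_color_space(im, "log_opponent"),
                                   "log_opponent", inverse=True)
        assert np.max(np.abs(back - im)) < 0.5

    def test_nonfinite_rejected(self):
        im = np.full((2, 2, 3), np.nan)
        with pytest.raises(ValueError):
            rgb_to_hsi(im)
        with pytest.raises(ValueError):
            rgb_to_lab(im)

    def test_unknown_space_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown color space"):
            convert_color_space(random_rgb(rng), "xyz")

    def test_hue_periodicity(self):
        # hue +1 full turn reconstructs the same color
        hsi = np.array([[[0.3, 0.4, 120.0]]])
        shifted = hsi.copy()
        shifted[0, 0, 0] += 1.0
        assert np.allclose(hsi_to_rgb(hsi), hsi_to_rgb(shifted))


# ---------------------------------------------------------------------------
# density transforms
# ---------------------------------------------------------------------------

class TestDensity:
    def test_background_maps_to_zero(self):
        assert rgb_to_od(np.full((1, 1, 3), 255.0))[0, 0, 0] == 0.0

    def test_tenfold_attenuation_is_od_one(self):
        od = rgb_to_od(np.full((1, 1, 3), 25.5))
        assert np.allclose(od, 1.0)

    def test_od_round_trip(self, rng):
        od = rng.uniform(0.0, 2.0, size=(10, 10, 3))
        back = rgb_to_od(od_to_rgb(od))
        assert np.max(np.abs(back - od)) < 1e-6

    def test_rgb_od_rgb_round_trip(self, rng):
        im = random_rgb(rng)
        assert np.max(np.abs(od_to_rgb(rgb_to_od(im)) - im)) < 0.5

    def test_sda_range_and_round_trip(self, rng):
        im = random_rgb(rng)
        sda = rgb_to_sda(im)
        assert sda.min() >= 0.0 and sda.max() <= 255.0 + 1e-9
        assert np.max(np.abs(sda_to_rgb(sda) - im)) < 0.5

    def test_zero_intensity_clamped_not_error(self):
        od = rgb_to_od(np.zeros((1, 1, 3)))
        assert np.isfinite(od).all()
        assert np.allclose(od, np.log10(255.0))

    def test_monotone_decreasing(self):
        vals = np.linspace(1, 255, 100).reshape(-1, 1, 1).repeat(3, axis=2)
        od = rgb_to_od(vals)
        assert (np.diff(od[:, 0, 0]) < 0).all()

    def test_dispatcher(self, rng):
        im = random_rgb(rng, shape=(4, 4, 3))
        for space in ("optical_density", "stain_darkness"):
            d = intensity_density_transform(im, space)
            back = intensity_density_transform(d, space, inverse=True)
            assert np.max(np.abs(back - im)) < 0.5
        with pytest.raises(ValueError):
            intensity_density_transform(im, "nope")


# ---------------------------------------------------------------------------
# stain matrices, deconvolution
# ---------------------------------------------------------------------------

class TestDeconvolution:
    def test_identity_unmixing(self, rng):
        im = random_rgb(rng, shape=(8, 8, 3))
        conc = color_deconvolution(im, np.eye(3))
        assert np.allclose(conc, np.maximum(rgb_to_od(im), 0.0))

    def test_convolve_deconvolve_round_trip(self, rng):
        conc = rng.uniform(0.0, 1.0, size=(16, 16, 2))
        w = DEFAULT_HE_MATRIX
        rec = color_deconvolution(color_convolution(conc, w), w.complemented())
        assert np.max(np.abs(rec[..., :2] - conc)) < 1e-4
        assert np.max(np.abs(rec[..., 2])) < 1e-4

    def test_pure_stain_isolated(self):
        conc = np.zeros((8, 8, 2))
        conc[..., 0] = 0.7
        rgb = color_convolution(conc, DEFAULT_HE_MATRIX)
        rec = color_deconvolution(rgb, DEFAULT_HE_MATRIX)
        assert np.max(rec[..., 1:]) < 1e-3 * rec[..., 0].mean()

    def test_zero_concentration_gives_background(self):
        rgb = color_convolution(np.zeros((4, 4, 2)), DEFAULT_HE_MATRIX)
        assert np.allclose(rgb, 255.0)

    def test_beer_lambert_closed_form(self):
        w = DEFAULT_HE_MATRIX.matrix[:, 0]
        conc = np.zeros((1, 1, 2))
        conc[0, 0, 0] = 1.0
        rgb = color_convolution(conc, DEFAULT_HE_MATRIX)
        assert np.allclose(rgb[0, 0], 255.0 * 10.0 ** (-w))

    def test_singular_matrix_names_columns(self):
        v = np.array([0.6, 0.7, 0.3])
        bad = np.column_stack([v, v, np.zeros(3)])
        with pytest.raises(ValueError, match="collinear"):
            color_deconvolution(np.full((2, 2, 3), 128.0), bad)

    def test_complement_of_e1_e2_is_e3(self):
        w = complement_stain_matrix(np.column_stack([np.eye(3)[:, 0], np.eye(3)[:, 1]]))
        assert np.allclose(w.matrix[:, 2], [0, 0, 1])

    def test_complement_orthogonality(self):
        w = DEFAULT_HE_MATRIX.complemented().matrix
        assert abs(w[:, 2] @ w[:, 0]) < 1e-9
        assert abs(w[:, 2] @ w[:, 1]) < 1e-9

    def test_complement_matches_gram_schmidt(self):
        w = DEFAULT_HE_MATRIX.complemented().matrix
        a, b = w[:, 0], w[:, 1]
        # independent orthogonalization: Gram-Schmidt then a vector
        # orthogonal to the plane via another GS step on a random vector
        u1 = a / np.linalg.norm(a)
        u2 = b - (b @ u1) * u1
        u2 /= np.linalg.norm(u2)
        rng = np.random.default_rng(0)
        v = rng.normal(size=3)
        u3 = v - (v @ u1) * u1 - (v @ u2) * u2
        u3 /= np.linalg.norm(u3)
        assert min(np.linalg.norm(w[:, 2] - u3), np.linalg.norm(w[:, 2] + u3)) < 1e-9

    def test_columns_unit_norm(self):
        norms = np.linalg.norm(DEFAULT_HE_MATRIX.complemented().matrix, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_stain_matrix_json_round_trip(self):
        w = DEFAULT_HE_MATRIX
        w2 = StainMatrix.from_json(w.to_json())
        assert np.allclose(w.matrix, w2.matrix)
        assert w.names == w2.names

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            StainMatrix(np.ones((2, 2)))


# ---------------------------------------------------------------------------
# stain estimation
# ---------------------------------------------------------------------------

class TestMacenko:
    def test_noise_free_recovery(self):
        rgb, _ = synth_stain_field(seed=3)
        est = estimate_stains_macenko(rgb)
        _, angles = match_stain_columns(est.matrix[:, :2], DEFAULT_HE_MATRIX)
        assert angles.max() < 1.0

    def test_noisy_recovery(self):
        rgb, _ = synth_stain_field(noise_sd=2.0, seed=5)
        est = estimate_stains_macenko(rgb)
        _, angles = match_stain_columns(est.matrix[:, :2], DEFAULT_HE_MATRIX)
        assert angles.max() < 5.0

    def test_hematoxylin_ordering_convention(self):
        rgb, _ = synth_stain_field(seed=3)
        est = estimate_stains_macenko(rgb)
        assert est.matrix[1, 0] >= est.matrix[1, 1]
        assert est.names[0] == "hematoxylin"

    def test_single_stain_rejected(self):
        conc = np.zeros((40, 40, 2))
        conc[..., 0] = np.random.default_rng(0).uniform(0.3, 1.0, (40, 40))
        rgb = color_convolution(conc, DEFAULT_HE_MATRIX)
        with pytest.raises(ValueError):
            estimate_stains_macenko(rgb)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError, match="pixels"):
            estimate_stains_macenko(np.full((10, 10, 3), 254.0))

    def test_narrow_spread_warns(self):
        # two nearly identical stains: spread above the error floor but
        # below the warning threshold
        v1 = np.array([0.65, 0.70, 0.29])
        v2 = v1 + np.array([0.0, 0.03, 0.0])
        w = StainMatrix(np.column_stack([v1, v2]))
        rng = np.random.default_rng(0)
        conc = np.zeros((60, 60, 2))
        conc[:, :30, 0] = rng.uniform(0.4, 1.0, (60, 30))
        conc[:, 30:, 1] = rng.uniform(0.4, 1.0, (60, 30))
        rgb = color_convolution(conc, w)
        with pytest.warns(CollinearStainsWarning):
            estimate_stains_macenko(rgb)


class TestSNMF:
    def test_noise_free_recovery(self):
        rgb, _ = synth_stain_field(seed=7)
        with np.errstate(all="ignore"):
            est = estimate_stains_snmf(rgb)
        _, angles = match_stain_columns(est.matrix[:, :2], DEFAULT_HE_MATRIX)
        assert angles.max() < 2.0

    def test_objective_non_increasing(self):
        rgb, _ = synth_stain_field(seed=7, size=(48, 48))
        _, trace = estimate_stains_snmf(rgb, return_objective=True)
        assert (np.diff(trace) <= 1e-9 * np.abs(trace[:-1]) + 1e-12).all()

    def test_sparsity_zero_fits_no_worse(self):
        from scipy.optimize import nnls

        rgb, _ = synth_stain_field(seed=7, size=(48, 48))
        od = rgb_to_od(rgb).reshape(-1, 3)
        keep = np.linalg.norm(od, axis=1) >= 0.15
        v = od[keep].T

        def recon_error(w):
            cols = w.matrix[:, :2]
            h = np.column_stack([nnls(cols, v[:, i])[0] for i in range(v.shape[1])])
            return snmf_objective(v, cols, h, 0.0)

        plain = estimate_stains_snmf(rgb, sparsity=0.0)
        sparse = estimate_stains_snmf(rgb, sparsity=0.1)
        assert recon_error(plain) <= recon_error(sparse) + 1e-6

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            estimate_stains_snmf(np.full((5, 5, 3), 254.0))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestReinhard:
    def test_identity_normalization(self, rng):
        im = random_rgb(rng, shape=(16, 16, 3), lo=20.0, hi=240.0)
        out = reinhard_normalize(im, reinhard_stats(im))
        assert np.max(np.abs(out - im)) < 0.5

    def test_output_stats_match_target(self, rng):
        im = random_rgb(rng, shape=(32, 32, 3), lo=20.0, hi=240.0)
        # target stats taken from a second in-gamut image, so the
        # normalized result does not clip
        target = reinhard_stats(random_rgb(rng, shape=(32, 32, 3),
                                           lo=60.0, hi=200.0))
        out = reinhard_normalize(im, target)
        got = reinhard_stats(out)
        assert np.max(np.abs(got.mu - target.mu)) < 0.01
        assert np.max(np.abs(got.sigma - target.sigma)) < 0.01

    def test_constant_image_maps_to_target_mean(self):
        im = np.full((8, 8, 3), 120.0)
        target = reinhard_stats(np.full((4, 4, 3), 60.0))
        out = reinhard_normalize(im, target)
        assert np.max(np.abs(out - 60.0)) < 0.5

    def test_pooled_stats_equal_concatenated(self, rng):
        tiles = [random_rgb(rng, shape=(h, w, 3), lo=10.0)
                 for h, w in [(8, 8), (8, 16), (4, 4), (12, 8)]]
        pooled = aggregate_reinhard_stats([reinhard_stats(t) for t in tiles])
        allpix = np.concatenate([t.reshape(-1, 3) for t in tiles]).reshape(1, -1, 3)
        direct = reinhard_stats(allpix)
        assert np.max(np.abs(pooled.mu - direct.mu)) < 1e-9
        assert np.max(np.abs(pooled.sigma - direct.sigma)) < 1e-9
        assert pooled.pixel_count == direct.pixel_count

    def test_pooled_mean_of_equal_parts(self):
        a = ReinhardStats([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], 10)
        b = ReinhardStats([2.0, 2.0, 2.0], [1.0, 1.0, 1.0], 10)
        assert np.allclose(aggregate_reinhard_stats([a, b]).mu, 1.0)

    def test_single_part_unchanged(self):
        a = ReinhardStats([0.1, 0.2, 0.3], [1.0, 2.0, 3.0], 7)
        assert aggregate_reinhard_stats([a]) is a

    def test_empty_aggregate_rejected(self):
        with pytest.raises(ValueError):
            aggregate_reinhard_stats([])

    def test_slide_level_stats_remove_seams(self, rng):
        # identical pixels in two tiles map identically under pooled
        # stats but not under per-tile stats
        base = random_rgb(rng, shape=(16, 16, 3), lo=20.0, hi=240.0)
        extra = random_rgb(rng, shape=(16, 16, 3), lo=20.0, hi=240.0)
        tile_a = base
        tile_b = np.concatenate([base[:8], extra[:8]], axis=0)
        target = ReinhardStats([0.3, 0.0, 0.0], [0.2, 0.05, 0.05], 1)
        pooled = aggregate_reinhard_stats(
            [reinhard_stats(tile_a), reinhard_stats(tile_b)]
        )
        out_a = reinhard_normalize(tile_a, target, source=pooled)
        out_b = reinhard_normalize(tile_b, target, source=pooled)
        assert np.array_equal(out_a[:8], out_b[:8])
        per_a = reinhard_normalize(tile_a, target)
        per_b = reinhard_normalize(tile_b, target)
        assert not np.allclose(per_a[:8], per_b[:8])

    def test_json_round_trip(self):
        a = ReinhardStats([0.1, 0.2, 0.3], [1.0, 2.0, 3.0], 7)
        b = ReinhardStats.from_json(a.to_json())
        assert np.allclose(a.mu, b.mu) and np.allclose(a.sigma, b.sigma)
        assert a.pixel_count == b.pixel_count


class TestDeconvolutionNormalize:
    def test_same_basis_is_identity(self):
        rgb, _ = synth_stain_field(seed=11)
        w = DEFAULT_HE_MATRIX
        out = deconvolution_normalize(rgb, w, source_w=w)
        assert np.max(np.abs(out - rgb)) < 0.5

    def test_closed_loop_recovers_target(self):
        source = StainMatrix(
            np.column_stack([[0.55, 0.76, 0.35], [0.15, 0.90, 0.25]])
        )
        rgb, _ = synth_stain_field(stain_matrix=source, seed=11)
        out = deconvolution_normalize(rgb, DEFAULT_HE_MATRIX)
        est = estimate_stains_macenko(out)
        _, angles = match_stain_columns(est.matrix[:, :2], DEFAULT_HE_MATRIX)
        assert angles.max() < 2.0

    def test_background_pixels_unchanged(self):
        rgb, _ = synth_stain_field(seed=11)
        rgb = rgb.copy()
        rgb[:4, :4] = 255.0  # clean background corner
        out = deconvolution_normalize(rgb, DEFAULT_HE_MATRIX,
                                      source_w=DEFAULT_HE_MATRIX)
        assert np.array_equal(out[:4, :4], rgb[:4, :4])


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

class TestAugment:
    def test_zero_sigmas_identity(self):
        rgb, _ = synth_stain_field(seed=2)
        out = perturb_stain_concentration(rgb, DEFAULT_HE_MATRIX,
                                          AugmentParams(0.0, 0.0, seed=9))
        assert np.max(np.abs(out - rgb)) < 0.5

    def test_seed_determinism(self):
        rgb, _ = synth_stain_field(seed=2)
        p = AugmentParams(0.3, 0.3, seed=4)
        a = perturb_stain_concentration(rgb, DEFAULT_HE_MATRIX, p)
        b = perturb_stain_concentration(rgb, DEFAULT_HE_MATRIX, p)
        assert np.array_equal(a, b)

    def test_injected_affine_matches_deconvolved_output(self):
        rgb, conc = synth_stain_field(seed=2)
        alpha, beta = np.array([1.1, 0.9]), np.array([5.0, -3.0])
        out = apply_stain_affine(rgb, DEFAULT_HE_MATRIX,
                                 np.append(alpha, 1.0), np.append(beta, 0.0))
        sda_scale = 255.0 / np.log10(255.0)
        got = color_deconvolution(out, DEFAULT_HE_MATRIX) * sda_scale
        want = np.maximum(
            color_deconvolution(rgb, DEFAULT_HE_MATRIX) * sda_scale
            * np.append(alpha, 1.0) + np.append(beta, 0.0), 0.0,
        )
        # compare where nothing clipped at the RGB stage
        ok = (out > 0.5).all(axis=-1) & (out < 254.5).all(axis=-1)
        assert np.max(np.abs((got - want)[ok])) < 1e-3 * sda_scale

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            AugmentParams(-0.1, 0.0)


class TestStainComparison:
    def test_angular_distance_sign_blind(self):
        u = np.array([1.0, 0.0, 0.0])
        assert angular_distance_deg(u, -u) == 0.0
        assert abs(angular_distance_deg(u, [0, 1, 0]) - 90.0) < 1e-12

    def test_hungarian_matching_handles_swaps(self):
        w = DEFAULT_HE_MATRIX.matrix
        swapped = w[:, [1, 0]]
        pairs, angles = match_stain_columns(swapped, w)
        assert set(pairs) == {(0, 1), (1, 0)}
        assert angles.max() < 1e-9
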