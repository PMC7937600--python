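"""Feature-family unit tests: first order, run length, fractal, morphology, extraction."""

import numpy as np
import pytest

from ibrad.features import (
    FeatureConfig,
    box_counting_fd,
    extract_all,
    first_order_features,
    fractal_features,
    glrl_matrix,
    glrlm_features,
    morphological_features,
    quantize,
    realised_feature_count,
    shape_metrics,
)
from ibrad.imaging import ROIMask, ScanImage


def brute_force_runs(levels, mask, directions):
    """Independent exhaustive run scanner used as the GLRLM oracle."""
    levels = np.atleast_3d(levels.reshape((1,) + levels.shape) if levels.ndim == 2 else levels)
    mask = mask.reshape(levels.shape)
    runs = []
    n_sl, n_r, n_c = levels.shape
    for k in range(n_sl):
        for dr, dc in directions:
            # line start points: cells whose predecessor along (dr,dc) is outside
            for r0 in range(n_r):
                for c0 in range(n_c):
                    pr, pc = r0 - dr, c0 - dc
                    if 0 <= pr < n_r and 0 <= pc < n_c:
                        continue
                    r, c = r0, c0
                    current, length = None, 0
                    while 0 <= r < n_r and 0 <= c < n_c:
                        val = levels[k, r, c] if mask[k, r, c] else None
                        if val is not None and val == current:
                            length += 1
                        else:
                            if current is not None:
                                runs.append((current, length))
                            current, length = val, 1 if val is not None else 0
                        r, c = r + dr, c + dc
                    if current is not None:
                        runs.append((current, length))
    return runs


class TestFirstOrder:
    def test_energy_is_sum_of_squares(self):
        assert first_order_features(np.array([1.0, 2.0, 2.0]))["energy"] == 9.0

    def test_symmetric_sample_has_zero_skewness(self):
        assert first_order_features(np.array([1.0, 2.0, 3.0]))["skewness"] == pytest.approx(0.0)

    def test_moments_match_independent_accumulation(self, rng):
        v = rng.standard_normal(200)
        out = first_order_features(v)
        mean = sum(v) / len(v)
        var = sum((x - mean) ** 2 for x in v) / len(v)
        skew = (sum((x - mean) ** 3 for x in v) / len(v)) / var**1.5
        assert out["variance"] == pytest.approx(var, abs=1e-10)
        assert abs(out["variance"] - 1.0) < 0.25
        assert out["skewness"] == pytest.approx(skew, abs=1e-10)

    def test_constant_sample_has_missing_skewness_not_zero(self):
        out = first_order_features(np.array([5.0, 5.0, 5.0]))
        assert np.isnan(out["skewness"])
        assert out["uniformity"] == 1.0 and out["entropy"] == 0.0


class TestQuantize:
    def test_two_point_range(self):
        np.testing.assert_array_equal(quantize(np.array([0.0, 1.0]), 2), [1, 2])

    def test_upper_half_open_bin_boundary(self):
        np.testing.assert_array_equal(quantize(np.array([0.0, 0.5, 1.0]), 2), [1, 2, 2])

    def test_affine_invariance_of_level_map(self, rng):
        v = rng.normal(size=100)
        np.testing.assert_array_equal(quantize(v, 16), quantize(3.0 * v + 10.0, 16))

    def test_constant_input_maps_to_level_one(self):
        np.testing.assert_array_equal(quantize(np.full(5, 2.0), 8), np.ones(5, dtype=int))


class TestGLRLM:
    def test_single_row_two_runs(self):
        levels = np.array([[1, 1, 2, 2]])
        m = glrl_matrix(levels, np.ones_like(levels, bool), directions=((0, 1),))
        assert m.total_runs == 2
        assert m.counts[0, 1] == 1  # level 1, length 2
        assert m.counts[1, 1] == 1  # level 2, length 2

    def test_alternating_row_four_unit_runs(self):
        levels = np.array([[1, 2, 1, 2]])
        m = glrl_matrix(levels, np.ones_like(levels, bool), directions=((0, 1),))
        assert m.total_runs == 4
        assert m.counts[:, 0].sum() == 4

    def test_mask_breaks_runs(self):
        levels = np.array([[1, 1, 1, 1]])
        mask = np.array([[True, True, False, True]])
        m = glrl_matrix(levels, mask, directions=((0, 1),))
        assert m.counts[0, 1] == 1 and m.counts[0, 0] == 1

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(1, 3, size=(8, 8))
        mask = rng.random((8, 8)) > 0.25
        mask[0, 0] = True
        directions = ((0, 1), (1, 0), (1, 1), (1, -1))
        m = glrl_matrix(levels, mask, directions=directions, n_levels=2)
        oracle = brute_force_runs(levels, mask, directions)
        assert m.total_runs == len(oracle)
        for g in (1, 2):
            for r in range(1, m.counts.shape[1] + 1):
                want = sum(1 for og, orun in oracle if og == g and orun == r)
                assert m.counts[g - 1, r - 1] == want

    def test_glnu_rlnu_hand_arithmetic(self):
        # runs {(1,len2)x1, (2,len2)x1}
        m = glrl_matrix(np.array([[1, 1, 2, 2]]), np.ones((1, 4), bool), directions=((0, 1),))
        f = glrlm_features(m)
        assert f["glnu"] == pytest.approx(1.0)
        assert f["rlnu"] == pytest.approx(2.0)
        # [1,2,1,2]: 4 unit runs, 2 per level
        m2 = glrl_matrix(np.array([[1, 2, 1, 2]]), np.ones((1, 4), bool), directions=((0, 1),))
        f2 = glrlm_features(m2)
        assert f2["glnu"] == pytest.approx(2.0)
        assert f2["rlnu"] == pytest.approx(4.0)

    def test_single_run_unity(self):
        m = glrl_matrix(np.array([[3, 3, 3]]), np.ones((1, 3), bool), directions=((0, 1),))
        f = glrlm_features(m)
        assert f["glnu"] == 1.0 and f["rlnu"] == 1.0 and f["run_pct"] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_feature_bounds(self, seed):
        rng = np.random.default_rng(100 + seed)
        levels = rng.integers(1, 6, size=(2, 10, 10))
        mask = rng.random((2, 10, 10)) > 0.3
        mask[0, 0, 0] = True
        f = glrlm_features(glrl_matrix(levels, mask))
        n = glrl_matrix(levels, mask).total_runs
        assert 1.0 <= f["glnu"] <= n and 1.0 <= f["rlnu"] <= n
        assert 0.0 < f["run_pct"] <= 1.0


def sierpinski_carpet(level):
    m = np.ones((1, 1), dtype=bool)
    cell = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool)
    for _ in range(level):
        m = np.kron(cell, m)
    return m


class TestBoxCounting:
    def test_filled_square_is_plane_like(self):
        assert box_counting_fd(np.ones((64, 64), bool)) == pytest.approx(2.0, abs=0.1)

    def test_line_is_curve_like(self):
        line = np.zeros((64, 64), bool)
        line[30, :] = True
        assert box_counting_fd(line) == pytest.approx(1.0, abs=0.1)

    def test_sierpinski_carpet_dimension(self):
        fd = box_counting_fd(sierpinski_carpet(4))
        assert fd == pytest.approx(np.log(8) / np.log(3), abs=0.1)

    def test_square_above_its_boundary(self):
        square = np.ones((32, 32), bool)
        boundary = np.zeros((32, 32), bool)
        boundary[0, :] = boundary[-1, :] = boundary[:, 0] = boundary[:, -1] = True
        assert box_counting_fd(square) > box_counting_fd(boundary)

    def test_too_few_sizes_is_missing(self):
        assert np.isnan(box_counting_fd(np.ones((2, 2), bool)))


class TestFractalAggregation:
    def test_identical_slices_collapse_aggregates(self):
        sl = np.zeros((20, 20), bool)
        sl[5:15, 5:15] = True
        cluster = np.stack([sl, sl, sl])
        f = fractal_features(cluster)
        assert f["max_fd"] == f["median_fd"] == f["mean_fd"]

    def test_small_slices_skipped(self):
        sl_big = np.zeros((20, 20), bool)
        sl_big[2:18, 2:18] = True
        sl_tiny = np.zeros((20, 20), bool)
        sl_tiny[0, :5] = True  # below min_pixels
        f = fractal_features(np.stack([sl_big, sl_tiny]), min_pixels=10)
        assert f["max_fd"] == pytest.approx(box_counting_fd(sl_big))

    def test_no_eligible_slice_is_all_missing(self):
        cluster = np.zeros((2, 10, 10), bool)
        cluster[0, 0, 0] = True
        f = fractal_features(cluster)
        assert all(np.isnan(v) for v in f.values())


class TestMorphology:
    def test_digital_ball_is_nearly_spherical(self):
        r = 20
        zz, rr, cc = np.ogrid[-24:25, -24:25, -24:25]
        ball = zz**2 + rr**2 + cc**2 <= r**2
        f = morphological_features(ball, (1.0, 1.0, 1.0))
        assert f["asphericity"] < 0.1
        assert f["compactness"] == pytest.approx(1.0, abs=0.15)

    def test_cube_closed_form_through_formula_layer(self):
        a = 10.0
        f = shape_metrics(volume_mm3=a**3, surface_mm2=6 * a**2)
        assert f["compactness"] == pytest.approx(np.pi / 6, abs=1e-12)
        assert f["asphericity"] == pytest.approx((6 / np.pi) ** (1 / 3) - 1, abs=1e-12)

    def test_spacing_scale_invariance_of_shape_features(self):
        zz, rr, cc = np.ogrid[-10:11, -10:11, -10:11]
        ball = zz**2 + rr**2 + cc**2 <= 64
        f1 = morphological_features(ball, (1.0, 1.0, 1.0))
        f2 = morphological_features(ball, (2.0, 2.0, 2.0))
        # marching-cubes vertices are float32, so scale equivariance holds to ~1e-5
        assert f2["volume_ml"] == pytest.approx(8 * f1["volume_ml"], rel=1e-9)
        assert f2["surface_mm2"] == pytest.approx(4 * f1["surface_mm2"], rel=1e-5)
        assert f2["compactness"] == pytest.approx(f1["compactness"], rel=1e-5)
        assert f2["asphericity"] == pytest.approx(f1["asphericity"], rel=1e-5)


class TestExtractAll:
    def test_schema_complete_and_deterministic(self, small_pair):
        img, mask = small_pair
        cfg = FeatureConfig(ib_step_pct=50)
        out1 = extract_all(img, mask, cfg)
        out2 = extract_all(img, mask, cfg)
        assert len(out1) == realised_feature_count(cfg)
        assert out1.keys() == out2.keys()
        for k in out1:
            assert (np.isnan(out1[k]) and np.isnan(out2[k])) or out1[k] == out2[k]

    def test_step_50_produces_exactly_three_bands(self, small_pair):
        img, mask = small_pair
        out = extract_all(img, mask, FeatureConfig(ib_step_pct=50))
        bands = {k.rsplit(".", 1)[1] for k in out if ".ib_" in k}
        assert bands == {"ib_0_50", "ib_0_100", "ib_50_100"}

    def test_ib_features_invariant_under_gain_and_offset(self, small_pair):
        img, mask = small_pair
        img2 = ScanImage(1.8 * img.voxels + 300.0, img.spacing, img.patient_id, img.cohort)
        cfg = FeatureConfig(ib_step_pct=25)
        out1 = extract_all(img, mask, cfg)
        out2 = extract_all(img2, mask, cfg)
        for key in out1:
            if ".ib_" not in key:
                continue
            a, b = out1[key], out2[key]
            if np.isnan(a) or np.isnan(b):
                assert np.isnan(a) and np.isnan(b)
            else:
                assert a == pytest.approx(b, abs=1e-8), key
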