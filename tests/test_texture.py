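import numpy as np
import pytest
from conftest import level_grid_of, make_sample, random_voi

import _oracles
from adrenomics import (
    DegenerateError,
    ParameterError,
    PhantomSpec,
    TextureConfig,
    compute_glcm,
    compute_rlm,
    extract_features,
    first_order_features,
    generate_phantom,
    glcm_features,
    quantize,
    rlm_features,
)
from adrenomics.texture import (
    FEATURE_NAMES,
    FIRST_ORDER_NAMES,
    GLCM_NAMES,
    OFFSETS_2D,
    OFFSETS_3D,
    RLM_NAMES,
)


class TestQuantize:
    def test_endpoints_map_to_extreme_levels(self):
        q = quantize(make_sample([0.0, 10.0]), ng=2)
        np.testing.assert_array_equal(q.levels, [1, 2])

    def test_constant_voi_all_level_one(self):
        q = quantize(make_sample([7.0] * 5), ng=32)
        np.testing.assert_array_equal(q.levels, [1] * 5)

    def test_one_value_per_bin(self):
        q = quantize(make_sample(np.arange(32.0)), ng=32)
        np.testing.assert_array_equal(q.levels, np.arange(1, 33))

    def test_ng_below_two_rejected(self):
        with pytest.raises(ParameterError):
            quantize(make_sample([1.0, 2.0]), ng=1)

    def test_shift_invariance(self, rng):
        values = rng.normal(size=50)
        a = quantize(make_sample(values), ng=8).levels
        b = quantize(make_sample(values + 123.4), ng=8).levels
        np.testing.assert_array_equal(a, b)


class TestFirstOrder:
    def test_constant_voi_degenerate_histogram(self):
        f = first_order_features(make_sample([12.0] * 10))
        assert f["histogram_sd"] == 0.0
        assert f["histogram_entropy"] == 0.0
        assert f["histogram_skewness"] == 0.0
        assert f["histogram_kurtosis"] == 0.0

    def test_uniform_histogram_entropy_is_log2_ng(self):
        # 32 values, one per bin -> maximal entropy log2(32) = 5 bits
        f = first_order_features(make_sample(np.arange(32.0)), ng=32)
        assert f["histogram_entropy"] == pytest.approx(5.0)

    def test_mean(self):
        assert first_order_features(make_sample([10.0, 20.0, 30.0]))["histogram_mean"] == pytest.approx(20.0)

    def test_moment_definitions(self, rng):
        v = rng.normal(size=200)
        f = first_order_features(make_sample(v))
        m2 = ((v - v.mean()) ** 2).mean()
        assert f["histogram_sd"] == pytest.approx(v.std(ddof=1))
        assert f["histogram_skewness"] == pytest.approx(((v - v.mean()) ** 3).mean() / m2**1.5)
        # kurtosis is the raw m4/m2^2, no excess-3 subtraction
        assert f["histogram_kurtosis"] == pytest.approx(((v - v.mean()) ** 4).mean() / m2**2)


class TestGLCM:
    def test_hand_enumerated_two_row_example(self):
        # 2x2x1 grid, levels [[1,1],[2,2]]; single in-plane direction (0,1,0)
        sample = make_sample([0, 0, 10, 10], coords=[[0, 0, 0], [0, 1, 0], [1, 0, 0], [1, 1, 0]])
        q = quantize(sample, ng=2)
        m = compute_glcm(q, (2, 2, 1), offsets=((0, 1, 0),))
        assert m.n_pairs == 4
        np.testing.assert_allclose(m.p, [[0.5, 0.0], [0.0, 0.5]])
        f = glcm_features(m)
        assert f["glcm_entropy"] == pytest.approx(1.0)
        assert f["glcm_autocorrelation"] == pytest.approx(2.5)
        assert f["glcm_homogeneity_idm"] == pytest.approx(1.0)
        assert f["glcm_maximum_probability"] == pytest.approx(0.5)

    def test_constant_voi_point_mass(self):
        q = quantize(make_sample([5.0] * 8, shape=(2, 2, 2)), ng=4)
        m = compute_glcm(q, (2, 2, 2))
        assert m.p[0, 0] == pytest.approx(1.0)
        assert m.p.sum() == pytest.approx(1.0)
        f = glcm_features(m)
        assert f["glcm_entropy"] == 0.0
        assert f["glcm_maximum_probability"] == 1.0
        assert f["glcm_homogeneity_idm"] == 1.0
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_energy"] == 1.0
        assert f["glcm_correlation"] == 0.0  # zero-variance fallback

    def test_normalization_symmetry_and_marginals(self, rng):
        for _ in range(10):
            q, shape = random_voi(rng)
            try:
                m = compute_glcm(q, shape)
            except DegenerateError:
                continue
            assert m.p.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(m.p, m.p.T, atol=1e-12)
            assert m.p_sum.sum() == pytest.approx(1.0, abs=1e-9)
            assert m.p_diff.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_voxel_voi_degenerate(self):
        q = quantize(make_sample([3.0], coords=[[0, 0, 0]]), ng=2)
        with pytest.raises(DegenerateError):
            compute_glcm(q, (1, 1, 1))

    def test_agrees_with_skimage_on_2d_slice(self, rng):
        """Cross-check pair counting against scikit-image's 2-D graycomatrix."""
        from skimage.feature import graycomatrix

        img = rng.integers(0, 4, size=(6, 5))
        sample = make_sample(img.ravel(), coords=np.argwhere(np.ones((6, 5, 1), bool)))
        q = quantize(sample, ng=4)
        # horizontal offset (0,1,0) == skimage angle 0 on the (i,j) image
        m = compute_glcm(q, (6, 5, 1), offsets=((0, 1, 0),))
        sk = graycomatrix(img.astype(np.uint8), [1], [0], levels=4, symmetric=True, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(m.p, sk, atol=1e-12)


class TestRLM:
    def test_hand_enumerated_row(self):
        # row [1,1,2,2,2] along j: runs (1,2) and (2,3)
        sample = make_sample([0, 0, 9, 9, 9], coords=[[0, j, 0] for j in range(5)])
        q = quantize(sample, ng=2)
        m = compute_rlm(q, (1, 5, 1), offsets=((0, 1, 0),))
        assert m.n_runs == 2
        assert m.r[0, 1] == 1 and m.r[1, 2] == 1
        f = rlm_features(m)
        assert f["rlm_sre"] == pytest.approx((1 / 4 + 1 / 9) / 2)
        assert f["rlm_lre"] == pytest.approx(6.5)
        assert f["rlm_rp"] == pytest.approx(0.4)
        assert f["rlm_gln"] == pytest.approx(1.0)
        assert f["rlm_lgre"] == pytest.approx(0.625)
        assert f["rlm_hgre"] == pytest.approx(2.5)

    def test_constant_row_single_run_closed_forms(self):
        n = 7
        sample = make_sample([4.0] * n, coords=[[0, j, 0] for j in range(n)])
        q = quantize(sample, ng=2)
        m = compute_rlm(q, (1, n, 1), offsets=((0, 1, 0),))
        assert m.n_runs == 1 and m.r[0, n - 1] == 1
        f = rlm_features(m)
        assert f["rlm_sre"] == pytest.approx(1 / n**2)
        assert f["rlm_lre"] == pytest.approx(n**2)
        assert f["rlm_rp"] == pytest.approx(1 / n)

    def test_alternating_row_all_unit_runs(self):
        sample = make_sample([0, 9, 0, 9], coords=[[0, j, 0] for j in range(4)])
        q = quantize(sample, ng=2)
        m = compute_rlm(q, (1, 4, 1), offsets=((0, 1, 0),))
        assert m.n_runs == 4
        assert m.r[:, 0].sum() == 4  # all runs have length 1

    def test_run_accounting_per_direction(self, rng):
        """Per direction, run lengths must account for every in-VOI voxel."""
        q, shape = random_voi(rng)
        grid = level_grid_of(q, shape)
        n_in = int((grid > 0).sum())
        lengths = np.arange(1, max(shape) + 1)
        for off in OFFSETS_3D:
            m = compute_rlm(q, shape, offsets=(off,))
            assert int((m.r * lengths[None, :]).sum()) == n_in


class TestOracleEquivalence:
    """Vectorized GLCM/RLM vs independent brute-force enumerators."""

    @pytest.mark.parametrize("mode,offsets", [("3d", OFFSETS_3D), ("2d", OFFSETS_2D)])
    def test_features_match_brute_force(self, rng, mode, offsets):
        for _ in range(10):
            q, shape = random_voi(rng)
            grid = level_grid_of(q, shape)
            try:
                m = compute_glcm(q, shape, mode=mode)
            except DegenerateError:
                continue
            p_ref, n_ref = _oracles.brute_glcm(grid, offsets)
            assert m.n_pairs == n_ref
            ref = _oracles.brute_glcm_features(p_ref)
            got = glcm_features(m)
            for name in GLCM_NAMES:
                assert got[name] == pytest.approx(ref[name], abs=1e-9), name

            rm = compute_rlm(q, shape, mode=mode)
            runs_ref, nr_ref, nv_ref = _oracles.brute_rlm(grid, offsets)
            assert rm.n_runs == nr_ref
            assert rm.n_voxels_traversed == nv_ref
            ref_r = _oracles.brute_rlm_features(runs_ref, nr_ref, nv_ref)
            got_r = rlm_features(rm)
            for name in RLM_NAMES:
                assert got_r[name] == pytest.approx(ref_r[name], abs=1e-9), name


class TestExtractFeatures:
    def test_exactly_32_named_features(self):
        vols, mask = generate_phantom(PhantomSpec.for_class("adenoma", seed=0, shape=(12, 12, 6)))
        fv = extract_features(vols["unenhanced"], mask)
        assert len(fv.features) == 32
        assert tuple(fv.features) == FEATURE_NAMES
        assert len(FIRST_ORDER_NAMES) == 5 and len(GLCM_NAMES) == 16 and len(RLM_NAMES) == 11
        assert all(np.isfinite(v) for v in fv.features.values())

    def test_determinism(self):
        vols, mask = generate_phantom(PhantomSpec.for_class("carcinoma", seed=5, shape=(12, 12, 6)))
        a = extract_features(vols["venous"], mask)
        b = extract_features(vols["venous"], mask)
        assert a.features == b.features

    def test_constant_phantom_degenerate_values(self):
        from adrenomics import CTVolume, VOIMask

        vol = CTVolume(values=np.full((4, 4, 2), 25.0), spacing=(1, 1, 1))
        mask = VOIMask(mask=np.ones((4, 4, 2), bool), spacing=(1, 1, 1))
        fv = extract_features(vol, mask)
        assert fv.features["histogram_entropy"] == 0.0
        assert fv.features["glcm_entropy"] == 0.0
        assert fv.features["glcm_homogeneity_idm"] == 1.0
        assert fv.features["glcm_energy"] == 1.0

    def test_intensity_shift_changes_only_first_order_mean(self):
        from adrenomics import CTVolume

        vols, mask = generate_phantom(PhantomSpec.for_class("adenoma", seed=2, shape=(12, 12, 6)))
        vol = vols["unenhanced"]
        shifted = CTVolume(values=vol.values + 100.0, spacing=vol.spacing, phase=vol.phase)
        a = extract_features(vol, mask).features
        b = extract_features(shifted, mask).features
        assert b["histogram_mean"] == pytest.approx(a["histogram_mean"] + 100.0)
        for name in FEATURE_NAMES:
            if name != "histogram_mean":
                assert b[name] == pytest.approx(a[name], abs=1e-9), name

    def test_config_validation(self):
        with pytest.raises(ParameterError):
            TextureConfig(ng=1)
        with pytest.raises(ParameterError):
            TextureConfig(mode="4d")
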