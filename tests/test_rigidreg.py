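import numpy as np
import pytest
from scipy import ndimage

from conftest import make_sphere_mask
from oracles import ncc_oracle

from cbctreg.rigidreg import (
    DegenerateIntensityError,
    InsufficientOverlapError,
    RegConfig,
    ncc,
    propagate_contour,
    register_bony,
    register_contours,
    register_rigid,
)
from cbctreg.transform import RigidTransform
from cbctreg.volgrid import BinaryMask, ImageVolume, Modality


def textured_volume(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0), seed=0, sigma=1.5):
    rng = np.random.default_rng(seed)
    v = ndimage.gaussian_filter(rng.normal(0, 100, shape), sigma)
    return ImageVolume(v, spacing, (0.0, 0.0, 0.0))


FAST = RegConfig(levels=2, shrink_factors=(2, 1), smoothing_sigmas=(2.0, 0.0))


class TestNCC:
    def test_identical_volumes_give_one(self):
        v = textured_volume()
        assert ncc(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_invariance_to_positive_linear_map(self):
        """The reason NCC suits an uncalibrated CBCT: gain/offset cancel."""
        v = textured_volume(seed=1)
        w = ImageVolume(3.2 * v.voxels + 40.0, v.spacing, v.origin)
        assert ncc(v, w) == pytest.approx(1.0, abs=1e-12)

    def test_negated_volume_gives_minus_one(self):
        v = textured_volume(seed=2)
        w = ImageVolume(-v.voxels, v.spacing, v.origin)
        assert ncc(v, w) == pytest.approx(-1.0, abs=1e-12)

    def test_masked_value_matches_brute_force_oracle(self):
        fixed = textured_volume(shape=(14, 12, 10), seed=3)
        moving = textured_volume(shape=(14, 12, 10), seed=4)
        t = RigidTransform(rotations=(0.05, -0.03, 0.08), translations=(0.7, -1.1, 0.4),
                           center=(6.5, 5.5, 4.5))
        rng = np.random.default_rng(5)
        fmask = BinaryMask((rng.random((14, 12, 10)) > 0.4).astype(np.uint8), fixed.spacing, fixed.origin)
        mmask = BinaryMask((rng.random((14, 12, 10)) > 0.2).astype(np.uint8), moving.spacing, moving.origin)
        got = ncc(fixed, moving, t, fixed_mask=fmask, moving_mask=mmask)
        expected, n = ncc_oracle(fixed, moving, t, fmask, mmask)
        assert n >= 100
        assert got == pytest.approx(expected, abs=1e-10)

    def test_symmetry_under_swap_with_inverse(self):
        a = textured_volume(seed=6, sigma=2.5)
        b = textured_volume(seed=7, sigma=2.5)
        t = RigidTransform(translations=(1.0, -0.5, 0.5))
        assert ncc(a, b, t) == pytest.approx(ncc(b, a, t.inverse()), abs=2e-2)

    def test_insufficient_overlap_raises(self):
        v = textured_volume(shape=(8, 8, 8))
        mask = BinaryMask(np.zeros((8, 8, 8), dtype=np.uint8), v.spacing, v.origin)
        mask.voxels[0, 0, 0] = 1
        with pytest.raises(InsufficientOverlapError):
            ncc(v, v, fixed_mask=mask)

    def test_degenerate_intensities_raise(self):
        v = ImageVolume(np.full((8, 8, 8), 5.0), (1, 1, 1), (0, 0, 0))
        w = textured_volume(shape=(8, 8, 8), seed=8)
        with pytest.raises(DegenerateIntensityError):
            ncc(w, v)


class TestRegisterRigid:
    def test_recovers_known_translation(self):
        fixed = textured_volume(shape=(40, 40, 40), seed=9, sigma=2.0)
        t_true = RigidTransform(translations=(2.0, 0.0, 0.0))
        from cbctreg.volgrid import resample

        moving = fixed
        fixed_shifted = resample(fixed, t_true, fixed.grid, interp="linear", fill=0.0)
        res = register_rigid(fixed_shifted, moving, cfg=FAST)
        got = res.transform.with_center((0, 0, 0))
        np.testing.assert_allclose(got.translations, (2.0, 0.0, 0.0), atol=0.5)

    def test_start_at_optimum_converges_immediately(self):
        v = textured_volume(shape=(32, 32, 32), seed=10, sigma=2.0)
        res = register_rigid(v, v, cfg=FAST)
        assert res.stop_reason in ("gradient_tolerance", "step_tolerance")
        assert res.final_metric >= 0.999
        assert res.converged

    def test_max_iter_one_reports_no_convergence(self):
        v = textured_volume(shape=(32, 32, 32), seed=11)
        cfg = RegConfig(levels=1, shrink_factors=(1,), smoothing_sigmas=(0.0,), max_iter=1)
        res = register_rigid(v, v, RigidTransform(translations=(3.0, 0, 0)), cfg)
        assert res.stop_reason == "max_iterations"
        assert not res.converged

    def test_deterministic(self):
        fixed = textured_volume(shape=(24, 24, 24), seed=12, sigma=2.0)
        moving = textured_volume(shape=(24, 24, 24), seed=13, sigma=2.0)
        r1 = register_rigid(fixed, moving, cfg=FAST)
        r2 = register_rigid(fixed, moving, cfg=FAST)
        assert r1.transform == r2.transform
        assert r1.final_metric == r2.final_metric
        assert r1.iterations == r2.iterations

    def test_metric_never_below_initialization(self):
        fixed = textured_volume(shape=(24, 24, 24), seed=14, sigma=2.0)
        moving = textured_volume(shape=(24, 24, 24), seed=15, sigma=2.0)
        init = RigidTransform(translations=(1.0, -1.0, 0.5))
        res = register_rigid(fixed, moving, init, FAST)
        assert res.final_metric >= res.initial_metric - 1e-12

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RegConfig(relaxation=1.5)
        with pytest.raises(ValueError):
            RegConfig(min_step=0.9, step_size=0.5)
        with pytest.raises(ValueError):
            RegConfig(levels=2)  # mismatched pyramid tuples


class TestBonyStrategy:
    def test_no_bone_gives_degenerate_error(self):
        soft_ct = ImageVolume(np.full((24, 24, 24), 30.0), (1, 1, 1), (0, 0, 0), Modality.CT)
        soft_cb = ImageVolume(np.full((24, 24, 24), 7.0), (1, 1, 1), (0, 0, 0), Modality.CBCT)
        with pytest.raises(DegenerateIntensityError):
            register_bony(soft_ct, soft_cb, FAST)


class TestContourRegistration:
    def test_identical_masks_recover_identity(self):
        m = make_sphere_mask(shape=(32, 32, 32), radius=8.0)
        res = register_contours(m, m, FAST)
        got = res.transform.with_center((0, 0, 0))
        assert np.linalg.norm(got.translations) < 0.3
        prop = propagate_contour(m, res.transform, m.grid)
        from cbctreg.evalmetrics import dice

        assert dice(prop, m) == pytest.approx(1.0, abs=0.01)

    def test_translated_mask_recovered(self):
        m = make_sphere_mask(shape=(40, 40, 40), radius=8.0, center=(16.5, 19.5, 19.5))
        shifted = make_sphere_mask(shape=(40, 40, 40), radius=8.0, center=(22.5, 19.5, 19.5))
        # registration maps fixed (shifted) points into moving (m) space
        res = register_contours(m, shifted, FAST)
        prop = propagate_contour(m, res.transform, shifted.grid)
        from cbctreg.evalmetrics import dice

        assert dice(prop, shifted) >= 0.95

    def test_different_shapes_align_centroids(self):
        sphere = make_sphere_mask(shape=(40, 40, 40), radius=8.0)
        g = np.indices((40, 40, 40)).transpose(1, 2, 3, 0).astype(float)
        c = np.array([19.5, 19.5, 19.5])
        d = (g - c) / np.array([10.0, 7.0, 8.0])
        ell = BinaryMask((np.sum(d * d, axis=-1) <= 1).astype(np.uint8), (1, 1, 1), (0, 0, 0))
        res = register_contours(sphere, ell, FAST)
        got = res.transform.with_center(tuple(c))
        assert np.linalg.norm(got.translations) <= 1.0


class TestPropagation:
    def test_identity_same_grid_identical(self):
        m = make_sphere_mask()
        out = propagate_contour(m, RigidTransform(), m.grid)
        np.testing.assert_array_equal(out.voxels, m.voxels)

    def test_translation_moves_centroid(self):
        m = make_sphere_mask(shape=(32, 32, 32), radius=6.0)
        t = RigidTransform(translations=(-4.0, 2.0, 0.0))  # pull-back: contour moves by -t
        out = propagate_contour(m, t, m.grid)
        delta = out.centroid() - m.centroid()
        np.testing.assert_allclose(delta, (4.0, -2.0, 0.0), atol=0.5)
        assert set(np.unique(out.voxels)) <= {0, 1}
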