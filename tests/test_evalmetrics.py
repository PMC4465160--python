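import numpy as np
import pytest

from conftest import make_sphere_mask
from oracles import bld_oracle

from cbctreg.evalmetrics import (
    MethodEval,
    PairEvaluation,
    bd,
    bld_per_point,
    dice,
    dice_interval_upper,
    dice_noreg,
    is_failure,
    success_rate_percent,
    summarize,
)
from cbctreg.volgrid import BinaryMask


def mask_from(voxels, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.asarray(voxels, dtype=np.uint8), spacing, (0.0, 0.0, 0.0))


class TestDice:
    def test_identical_and_disjoint(self):
        m = make_sphere_mask()
        assert dice(m, m) == 1.0
        vox = np.zeros_like(m.voxels)
        vox[0, 0, 0] = 1
        other = mask_from(vox, m.spacing)
        other = BinaryMask(vox, m.spacing, m.origin)
        assert dice(m, other) == 0.0

    def test_partial_overlap_forced_value(self):
        a = np.zeros((4, 4, 4)); a[0, 0, 0] = a[0, 0, 1] = 1
        b = np.zeros((4, 4, 4)); b[0, 0, 0] = 1
        assert dice(mask_from(a), mask_from(b)) == pytest.approx(2 / 3)

    def test_symmetry_and_nested(self):
        rng = np.random.default_rng(1)
        a = mask_from(rng.random((6, 6, 6)) > 0.5)
        b = mask_from(rng.random((6, 6, 6)) > 0.5)
        assert dice(a, b) == dice(b, a)
        inner = make_sphere_mask(radius=4.0)
        outer = make_sphere_mask(radius=7.0)
        expected = 2 * inner.count() / (inner.count() + outer.count())
        assert dice(inner, outer) == pytest.approx(expected)

    def test_errors(self):
        a = mask_from(np.ones((4, 4, 4)))
        b = BinaryMask(np.ones((4, 4, 4), dtype=np.uint8), (2.0, 1.0, 1.0), (0, 0, 0))
        with pytest.raises(ValueError, match="grid"):
            dice(a, b)
        empty = mask_from(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="undefined"):
            dice(empty, empty)


class TestBLD:
    def test_identical_point_sets_are_zero(self):
        pts = np.random.default_rng(2).uniform(0, 10, (30, 3))
        np.testing.assert_allclose(bld_per_point(pts, pts), 0.0, atol=1e-12)

    def test_single_points(self):
        out = bld_per_point(np.array([[0.0, 0, 0]]), np.array([[3.0, 0, 0]]))
        np.testing.assert_allclose(out, [3.0])

    @pytest.mark.parametrize("n_ref,n_tgt,seed", [(50, 70, 3), (200, 150, 4), (10, 200, 5)])
    def test_matches_quadratic_oracle(self, n_ref, n_tgt, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(0, 20, (n_ref, 3))
        tgt = rng.uniform(0, 20, (n_tgt, 3))
        # same distances and associations; float summation order may differ
        # in the last ulp
        np.testing.assert_allclose(bld_per_point(ref, tgt), bld_oracle(ref, tgt),
                                   rtol=1e-12, atol=1e-12)

    def test_tie_cases_match_oracle(self):
        # integer grids force exact distance ties; both must pick the lowest index
        ref = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        tgt = np.array([[1.0, 0, 0], [3.0, 0, 0], [1.0, 2, 0], [3.0, 2, 0]])
        np.testing.assert_array_equal(bld_per_point(ref, tgt), bld_oracle(ref, tgt))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bld_per_point(np.empty((0, 3)), np.array([[0.0, 0, 0]]))


class TestBD:
    def test_identical_masks_zero(self):
        m = make_sphere_mask()
        assert bd(m, m) == 0.0

    def test_single_voxels_three_mm_apart(self):
        a = np.zeros((8, 8, 8)); a[1, 1, 1] = 1
        b = np.zeros((8, 8, 8)); b[4, 1, 1] = 1
        assert bd(mask_from(a), mask_from(b)) == pytest.approx(3.0)

    def test_bd_at_least_mean_forward_distance(self):
        from cbctreg.volgrid import extract_surface_points

        a = make_sphere_mask(radius=6.0)
        b = make_sphere_mask(radius=8.0)
        ref = extract_surface_points(a)
        tgt = extract_surface_points(b)
        fwd = np.array([np.min(np.linalg.norm(tgt - p, axis=1)) for p in ref])
        assert bd(a, b) >= fwd.mean() - 1e-12

    def test_asymmetric_in_general(self):
        a = np.zeros((10, 10, 4)); a[1, 1, 1] = 1
        b = np.zeros((10, 10, 4)); b[1, 1, 1] = 1; b[8, 8, 1] = 1
        assert bd(mask_from(a), mask_from(b)) != bd(mask_from(b), mask_from(a))


class TestFailureRule:
    def test_clinical_threshold_examples(self):
        assert is_failure(0.69, 0.731)       # 0.69 < 0.95 * 0.731
        assert not is_failure(0.70, 0.731)

    def test_boundary_is_success(self):
        assert not is_failure(0.95 * 0.8, 0.8)

    def test_cap_variant(self):
        # with a 0.95 cap, a high no-registration Dice cannot raise the bar above it
        assert not is_failure(0.96, 0.999, cap=0.95)
        assert is_failure(0.94, 0.999, cap=0.95)


class TestDiceNoReg:
    def test_equals_direct_dice_on_common_grid(self, coarse_moving_pair):
        from cbctreg.transform import RigidTransform
        from cbctreg.volgrid import resample

        ct_ctv = coarse_moving_pair.ct_structs["ctv"]
        manual = coarse_moving_pair.cbct_structs_truth["ctv"]
        moved = resample(ct_ctv, RigidTransform(), manual.grid, interp="nearest")
        assert dice_noreg(ct_ctv, manual) == dice(moved, manual)

    def test_zero_motion_high_overlap(self, coarse_clean_pair):
        d = dice_noreg(coarse_clean_pair.ct_structs["ctv"],
                       coarse_clean_pair.cbct_structs_truth["ctv"])
        assert d >= 0.95

    def test_large_shift_lowers_overlap(self):
        import dataclasses

        from cbctreg.phantom import PhantomSpec, generate_pair

        base = PhantomSpec(ct_shape=(80, 80, 30), ct_spacing=(2, 2, 6),
                           cbct_shape=(80, 80, 56), cbct_spacing=(2, 2, 3))
        still = generate_pair(dataclasses.replace(base, seed=1))
        moved = generate_pair(dataclasses.replace(base, prostate_offset=(10.0, 0, 0), seed=1))
        d0 = dice_noreg(still.ct_structs["ctv"], still.cbct_structs_truth["ctv"])
        d1 = dice_noreg(moved.ct_structs["ctv"], moved.cbct_structs_truth["ctv"])
        assert d1 < d0


class TestSummarize:
    def _evals(self, values):
        out = []
        for i, (d, b, failed) in enumerate(values):
            ev = PairEvaluation(pair_id=f"p{i}", dice_noreg=0.8)
            ev.methods["m"] = MethodEval(d, b, failed)
            out.append(ev)
        return out

    def test_single_pair_warns_and_reports_zero_sd(self):
        with pytest.warns(UserWarning, match="SD undefined"):
            s = summarize(self._evals([(0.9, 1.0, False)]), "m")
        assert s.dice_median == 0.9 and s.dice_sd == 0.0 and s.n_pairs == 1

    def test_constant_values(self):
        s = summarize(self._evals([(0.8, 2.0, False)] * 3), "m")
        assert s.dice_median == pytest.approx(0.8) and s.dice_sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(6)
        vals = [(float(d), float(b), bool(f)) for d, b, f in
                zip(rng.uniform(0.5, 1.0, 9), rng.uniform(0.5, 4.0, 9), rng.random(9) > 0.7)]
        s = summarize(self._evals(vals), "m")
        ds = [v[0] for v in vals]
        bs = [v[1] for v in vals]
        assert s.dice_median == pytest.approx(np.median(ds))
        assert s.dice_sd == pytest.approx(np.std(ds, ddof=1))
        assert s.bd_median_mm == pytest.approx(np.median(bs))
        assert s.bd_sd_mm == pytest.approx(np.std(bs, ddof=1))
        assert s.n_failed == sum(v[2] for v in vals)

    def test_errors_excluded(self):
        evals = self._evals([(0.9, 1.0, False), (0.7, 2.0, True)])
        evals[1].methods["m"].error = "boom"
        with pytest.warns(UserWarning):
            s = summarize(evals, "m")
        assert s.n_pairs == 1 and s.n_failed == 0


class TestHeadlineArithmetic:
    def test_success_rates_from_failure_counts(self):
        assert success_rate_percent(3, 115) == 97
        assert success_rate_percent(6, 115) == 95
        assert success_rate_percent(1, 115) == 99

    def test_interval_upper_bound(self):
        assert dice_interval_upper(0.858, 0.035) == 0.95

    def test_validation(self):
        with pytest.raises(ValueError):
            success_rate_percent(5, 0)
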