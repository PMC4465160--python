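"""Masked rigid registration: NCC metric, relaxed gradient descent, pyramid.

The similarity metric is mean-subtracted normalized cross-correlation
restricted to the intersection of a fixed-image mask and a moving-image
mask; moving values are trilinearly interpolated.  The optimizer is a
deterministic gradient descent in a scaled 6-parameter space (rotations are
scaled so 1 rad weighs like ``rotation_scale`` mm): the step length starts
at ``step_size`` and shrinks by ``relaxation`` each time the gradient
reverses direction, and the parameters move one normalized-gradient step
per iteration.  Three resolution levels (shrink 4/2/1 with Gaussian
pre-smoothing 4/2/0 mm) run coarse to fine, each seeding the next.

Convention used throughout: fixed = CBCT, moving = CT, so the recovered
transform maps CBCT physical points into CT space and planning contours are
propagated onto the CBCT grid by pull-back resampling::

    CBCT grid point q --t--> CT point t(q) --lookup--> CT contour value

Everything is deterministic: identical inputs and configuration produce a
bit-identical result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from cbctreg._kernels import ncc_sums
from cbctreg.transform import RigidTransform
from cbctreg.volgrid import BinaryMask, Grid, ImageVolume, Modality, resample

__all__ = [
    "RegConfig",
    "RegistrationResult",
    "InsufficientOverlapError",
    "DegenerateIntensityError",
    "ncc",
    "register_rigid",
    "register_global",
    "register_bony",
    "register_local",
    "register_contours",
    "propagate_contour",
]

#: minimum number of metric samples; guards tiny-mask degeneracy
MIN_SAMPLES = 100


class InsufficientOverlapError(RuntimeError):
    pass


class DegenerateIntensityError(RuntimeError):
    pass


@dataclass(frozen=True)
class RegConfig:
    """Optimizer and pyramid parameters for the rigid registration engine."""

    step_size: float = 0.5
    relaxation: float = 0.7
    min_step: float = 0.1
    grad_tol: float = 1e-5
    max_iter: int = 500
    levels: int = 3
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (4.0, 2.0, 0.0)  # mm
    rotation_scale: float = 50.0  # mm per radian in the scaled parameter space
    grad_delta: float = 0.1  # central-difference perturbation, scaled units

    def __post_init__(self):
        if not (0.0 < self.relaxation < 1.0):
            raise ValueError("relaxation must be in (0, 1)")
        if self.min_step >= self.step_size:
            raise ValueError("min_step must be smaller than step_size")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.shrink_factors) != self.levels or len(self.smoothing_sigmas) != self.levels:
            raise ValueError("shrink_factors and smoothing_sigmas must have `levels` entries")


@dataclass
class RegistrationResult:
    """Recovered transform plus convergence diagnostics."""

    transform: RigidTransform
    final_metric: float
    iterations: tuple[int, ...]
    stop_reason: str  # step_tolerance | gradient_tolerance | max_iterations
    converged: bool
    initial_metric: float = float("nan")
    levels_skipped: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# metric


def _sample_arrays(fixed: ImageVolume, fixed_mask: BinaryMask | None):
    if fixed_mask is None:
        idx = np.indices(fixed.voxels.shape).reshape(3, -1).T
        vals = fixed.voxels.reshape(-1).astype(np.float64)
    else:
        idx = np.argwhere(fixed_mask.voxels > 0)
        vals = fixed.voxels[fixed_mask.voxels > 0].astype(np.float64)
    pts = fixed.grid.points(idx)
    return np.ascontiguousarray(vals), np.ascontiguousarray(pts, dtype=np.float64)


def _ncc_from_sums(n, sf, sm, sff, smm, sfm) -> float:
    if n < MIN_SAMPLES:
        raise InsufficientOverlapError(
            f"insufficient mask overlap: {n} samples (< {MIN_SAMPLES})"
        )
    var_f = sff - sf * sf / n
    var_m = smm - sm * sm / n
    scale = max(sff, smm, 1.0)
    if var_f <= 1e-12 * scale or var_m <= 1e-12 * scale:
        raise DegenerateIntensityError("degenerate intensities: zero variance in a channel")
    cov = sfm - sf * sm / n
    val = cov / np.sqrt(var_f * var_m)
    return float(np.clip(val, -1.0, 1.0))


def _eval_ncc(fixed_vals, fixed_pts, t: RigidTransform, moving_arr, mov_origin,
              mov_spacing, moving_mask_arr):
    sums = ncc_sums(
        fixed_vals, fixed_pts, t.matrix, t.offset,
        moving_arr, mov_origin, mov_spacing, moving_mask_arr,
    )
    return _ncc_from_sums(*sums), sums[0]


def ncc(
    fixed: ImageVolume,
    moving: ImageVolume,
    t: RigidTransform = RigidTransform(),
    fixed_mask: BinaryMask | None = None,
    moving_mask: BinaryMask | None = None,
) -> float:
    """Masked mean-subtracted NCC of ``moving`` mapped onto ``fixed`` by ``t``.

    Samples are the fixed-grid voxels where the fixed mask is 1, whose
    mapped point lies inside the moving support, and where the moving mask
    (nearest-neighbor lookup) is 1.  Raises on fewer than 100 samples or a
    zero-variance channel.
    """
    params = np.concatenate([t.rotations, t.translations, t.center])
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite transform parameters")
    fixed_vals, fixed_pts = _sample_arrays(fixed, fixed_mask)
    mov_arr = np.ascontiguousarray(moving.voxels, dtype=np.float64)
    mmask = (
        np.ones(moving.voxels.shape, dtype=np.uint8)
        if moving_mask is None
        else np.ascontiguousarray(moving_mask.voxels, dtype=np.uint8)
    )
    val, _ = _eval_ncc(
        fixed_vals, fixed_pts, t, mov_arr,
        np.asarray(moving.origin, dtype=np.float64),
        np.asarray(moving.spacing, dtype=np.float64), mmask,
    )
    return val


# ---------------------------------------------------------------------------
# pyramid


def _smooth_shrink(vol: ImageVolume, factor: int, sigma_mm: float) -> ImageVolume:
    arr = vol.voxels.astype(np.float64)
    if sigma_mm > 0:
        sig_vox = sigma_mm / np.asarray(vol.spacing)
        arr = ndimage.gaussian_filter(arr, sigma=sig_vox, mode="nearest")
    if factor > 1:
        arr = arr[::factor, ::factor, ::factor]
        spacing = tuple(s * factor for s in vol.spacing)
    else:
        spacing = vol.spacing
    return ImageVolume(np.ascontiguousarray(arr), spacing, vol.origin, vol.modality)


def _shrink_mask(mask: BinaryMask | None, factor: int) -> BinaryMask | None:
    if mask is None or factor == 1:
        return mask
    return BinaryMask(
        np.ascontiguousarray(mask.voxels[::factor, ::factor, ::factor]),
        tuple(s * factor for s in mask.spacing),
        mask.origin,
    )


# ---------------------------------------------------------------------------
# optimizer


def _params_from_transform(t: RigidTransform, center, scale: float) -> np.ndarray:
    tc = t.with_center(center)
    return np.array(
        [tc.rotations[0] * scale, tc.rotations[1] * scale, tc.rotations[2] * scale,
         tc.translations[0], tc.translations[1], tc.translations[2]]
    )


def _transform_from_params(p: np.ndarray, center, scale: float) -> RigidTransform:
    return RigidTransform(
        (p[0] / scale, p[1] / scale, p[2] / scale),
        (p[3], p[4], p[5]),
        tuple(center),
    )


def _optimize_level(objective, p0: np.ndarray, cfg: RegConfig):
    """Relaxed gradient descent on the scaled parameters.

    ``objective(p)`` returns the NCC (to be maximized).  Returns the best
    parameters seen, the iteration count and the stop reason.
    """
    p = p0.copy()
    lam = cfg.step_size
    prev_g = None
    best_p = p.copy()
    best_f = objective(p)
    iters = 0
    stop = "max_iterations"
    for _ in range(cfg.max_iter):
        iters += 1
        g = np.empty(6)
        for d in range(6):
            pp = p.copy()
            pp[d] += cfg.grad_delta
            fp = objective(pp)
            pp[d] -= 2 * cfg.grad_delta
            fm = objective(pp)
            g[d] = -(fp - fm) / (2 * cfg.grad_delta)  # gradient of -NCC
        if not np.all(np.isfinite(g)):
            raise RuntimeError("non-finite metric gradient during optimization")
        gnorm = float(np.linalg.norm(g))
        if gnorm < cfg.grad_tol:
            stop = "gradient_tolerance"
            break
        if prev_g is not None and float(np.dot(g, prev_g)) < 0.0:
            lam *= cfg.relaxation
        if lam < cfg.min_step:
            stop = "step_tolerance"
            break
        p = p - lam * g / gnorm
        prev_g = g
        f = objective(p)
        if not np.isfinite(f):
            raise RuntimeError("non-finite metric value during optimization")
        if f > best_f:
            best_f = f
            best_p = p.copy()
    return best_p, best_f, iters, stop


def register_rigid(
    fixed: ImageVolume,
    moving: ImageVolume,
    init: RigidTransform | None = None,
    cfg: RegConfig = RegConfig(),
    fixed_mask: BinaryMask | None = None,
    moving_mask: BinaryMask | None = None,
    center=None,
) -> RegistrationResult:
    """Multi-resolution masked rigid registration of ``moving`` onto ``fixed``.

    The returned transform maps fixed-grid physical points into moving
    space.  ``center`` is the rotation center (defaults to the fixed-grid
    physical center).  Coarse levels whose masks yield fewer than 100
    samples are skipped; the finest level must be valid.
    """
    if center is None:
        center = tuple(fixed.grid.center)
    if init is None:
        init = RigidTransform(center=center)
    scale = cfg.rotation_scale

    t_cur = init
    iterations: list[int] = []
    skipped: list[int] = []
    stop = "max_iterations"
    final_metric = float("nan")
    initial_metric = float("nan")
    n_levels = cfg.levels
    for li, (factor, sigma) in enumerate(zip(cfg.shrink_factors, cfg.smoothing_sigmas)):
        finest = li == n_levels - 1
        fx = _smooth_shrink(fixed, factor, sigma)
        mv = _smooth_shrink(moving, factor, sigma)
        fmask = _shrink_mask(fixed_mask, factor)
        mov_arr = np.ascontiguousarray(mv.voxels, dtype=np.float64)
        mov_origin = np.asarray(mv.origin, dtype=np.float64)
        mov_spacing = np.asarray(mv.spacing, dtype=np.float64)
        mmask_l = _shrink_mask(moving_mask, factor)
        mmask_arr = (
            np.ones(mov_arr.shape, dtype=np.uint8)
            if mmask_l is None
            else np.ascontiguousarray(mmask_l.voxels, dtype=np.uint8)
        )
        fixed_vals, fixed_pts = _sample_arrays(fx, fmask)

        def objective(p, _fv=fixed_vals, _fp=fixed_pts, _ma=mov_arr,
                      _mo=mov_origin, _ms=mov_spacing, _mm=mmask_arr):
            t = _transform_from_params(p, center, scale)
            val, _ = _eval_ncc(_fv, _fp, t, _ma, _mo, _ms, _mm)
            return val

        p0 = _params_from_transform(t_cur, center, scale)
        try:
            f0 = objective(p0)
        except InsufficientOverlapError:
            if finest:
                raise
            skipped.append(li)
            continue
        if finest:
            initial_metric = objective(_params_from_transform(init, center, scale))
            # never let a coarse level leave us worse than the caller's init
            if initial_metric > f0:
                p0 = _params_from_transform(init, center, scale)
        p_best, f_best, iters, stop = _optimize_level(objective, p0, cfg)
        t_cur = _transform_from_params(p_best, center, scale)
        iterations.append(iters)
        if finest:
            final_metric = f_best

    return RegistrationResult(
        transform=t_cur,
        final_metric=final_metric,
        iterations=tuple(iterations),
        stop_reason=stop,
        converged=stop != "max_iterations",
        initial_metric=initial_metric,
        levels_skipped=tuple(skipped),
    )


# ---------------------------------------------------------------------------
# registration strategies


def _body_masks(ct, cbct, thresholds):
    from cbctreg.preprocess import ThresholdConfig, compute_body_mask

    cfg = thresholds if thresholds is not None else ThresholdConfig()
    return compute_body_mask(ct, cfg), compute_body_mask(cbct, cfg)


def register_global(
    ct: ImageVolume,
    cbct: ImageVolume,
    cfg: RegConfig = RegConfig(),
    filter_gas: bool = False,
    thresholds=None,
    body_ct: BinaryMask | None = None,
    body_cbct: BinaryMask | None = None,
) -> RegistrationResult:
    """Whole-image registration restricted to the patient body masks.

    With ``filter_gas`` the rectal-gas filter (clamp below the modality gas
    threshold) is applied to both images before registration.
    """
    from cbctreg.preprocess import ThresholdConfig, replace_gas

    th = thresholds if thresholds is not None else ThresholdConfig()
    if body_ct is None or body_cbct is None:
        body_ct, body_cbct = _body_masks(ct, cbct, th)
    if filter_gas:
        ct = replace_gas(ct, th)
        cbct = replace_gas(cbct, th)
    return register_rigid(cbct, ct, None, cfg, fixed_mask=body_cbct, moving_mask=body_ct)


def register_bony(
    ct: ImageVolume,
    cbct: ImageVolume,
    cfg: RegConfig = RegConfig(),
    thresholds=None,
    body_ct: BinaryMask | None = None,
    body_cbct: BinaryMask | None = None,
) -> RegistrationResult:
    """Registration of the bone-thresholded images (never gas-filtered).

    Body masks are computed on the *unthresholded* images; the bone clamp
    flattens all soft tissue (and gas) to a constant so the pelvic bones are
    the only metric signal.
    """
    from cbctreg.preprocess import ThresholdConfig, threshold_bone

    th = thresholds if thresholds is not None else ThresholdConfig()
    if body_ct is None or body_cbct is None:
        body_ct, body_cbct = _body_masks(ct, cbct, th)
    ct_b = threshold_bone(ct, th)
    cbct_b = threshold_bone(cbct, th)
    return register_rigid(cbct_b, ct_b, None, cfg, fixed_mask=body_cbct, moving_mask=body_ct)


def register_local(
    ct: ImageVolume,
    cbct: ImageVolume,
    ctv_mask: BinaryMask,
    margin_mm: float,
    bony_result: RegistrationResult,
    cfg: RegConfig = RegConfig(),
    filter_gas: bool = False,
    thresholds=None,
    body_cbct: BinaryMask | None = None,
) -> RegistrationResult:
    """Local soft-tissue refinement inside the margin-expanded CTV.

    The CT-side (moving) mask is the CTV expanded by ``margin_mm``; the
    CBCT-side mask stays the body mask.  The bony transform initializes the
    optimizer and the rotation center is the CTV centroid.
    """
    from cbctreg.preprocess import ThresholdConfig, compute_body_mask, expand_margin, replace_gas

    th = thresholds if thresholds is not None else ThresholdConfig()
    if body_cbct is None:
        body_cbct = compute_body_mask(cbct, th)
    if filter_gas:
        ct = replace_gas(ct, th)
        cbct = replace_gas(cbct, th)
    roi = expand_margin(ctv_mask, margin_mm)
    center = tuple(ctv_mask.centroid())
    return register_rigid(
        cbct, ct, bony_result.transform, cfg,
        fixed_mask=body_cbct, moving_mask=roi, center=center,
    )


def register_contours(
    ct_mask: BinaryMask,
    cbct_mask: BinaryMask,
    cfg: RegConfig = RegConfig(),
) -> RegistrationResult:
    """Rigid registration of two binary masks (the per-pair Dice upper bound).

    Masks are Gaussian-smoothed by one voxel so the metric has gradients,
    then registered with full-volume masks.
    """
    def as_image(m: BinaryMask) -> ImageVolume:
        arr = ndimage.gaussian_filter(m.voxels.astype(np.float64), sigma=1.0)
        return ImageVolume(arr, m.spacing, m.origin, Modality.CT)

    fixed = as_image(cbct_mask)
    moving = as_image(ct_mask)
    center = tuple(cbct_mask.centroid())
    return register_rigid(fixed, moving, None, cfg, center=center)


def propagate_contour(ct_mask: BinaryMask, t: RigidTransform, cbct_grid: Grid) -> BinaryMask:
    """Propagate a CT contour onto the CBCT grid through ``t`` (CBCT→CT map)."""
    return resample(ct_mask, t, cbct_grid, interp="nearest", fill=0)
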