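"""Registration quality metrics: Dice, bidirectional local distance, failure rule.

The Dice coefficient between volumes A and B is ``2 |A∩B| / (|A| + |B|)``
by voxel counts on a shared grid.  The bidirectional local distance (BLD)
is a per-reference-point surface distance: the forward nearest distance to
the target surface, maximized with the distances of all target points whose
nearest reference point is that point.  BD is the mean BLD over the
reference (ground-truth) contour — note BD is asymmetric in its arguments.

A registration counts as *failed* when its Dice falls below 95% of the
Dice obtained without registration (isocenter alignment only); an optional
absolute cap at 0.95 reflects the delineation-uncertainty ceiling measured
by manual-contour registration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from cbctreg.volgrid import BinaryMask, extract_surface_points

__all__ = [
    "PairEvaluation",
    "MethodSummary",
    "dice",
    "bld_per_point",
    "bd",
    "is_failure",
    "dice_noreg",
    "summarize",
    "success_rate_percent",
    "dice_interval_upper",
]


@dataclass
class MethodEval:
    """Per-method scores for one CT/CBCT pair."""

    dice_after: float
    bd_mm: float
    failed: bool
    error: str | None = None


@dataclass
class PairEvaluation:
    """All scores for one CT/CBCT pair."""

    pair_id: str
    dice_noreg: float
    methods: dict[str, MethodEval] = field(default_factory=dict)
    F: float = float("nan")
    predicted_failure: bool = False
    #: per-method RegistrationResult objects (intermediate transforms persisted)
    registrations: dict = field(default_factory=dict)


@dataclass
class MethodSummary:
    """Median/SD summary of one registration method over a cohort."""

    method: str
    dice_median: float
    dice_sd: float
    bd_median_mm: float
    bd_sd_mm: float
    n_failed: int
    n_pairs: int


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|) of two masks on an identical grid."""
    if a.grid != b.grid:
        raise ValueError("dice requires masks on an identical grid")
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        raise ValueError("undefined Dice: both masks empty")
    inter = int(np.sum((a.voxels > 0) & (b.voxels > 0)))
    return 2.0 * inter / (na + nb)


def bld_per_point(ref_pts: np.ndarray, tgt_pts: np.ndarray) -> np.ndarray:
    """Bidirectional local distance at each reference point (mm).

    Forward: d(a) = min_b ||a - b||.  Backward: each target point b is
    associated with its nearest reference point (ties broken toward the
    lowest reference index), and BLD(a) = max(d(a), max ||b - a|| over the
    b associated with a); the backward term is absent when no target point
    maps to a.
    """
    ref = np.asarray(ref_pts, dtype=float)
    tgt = np.asarray(tgt_pts, dtype=float)
    if ref.ndim != 2 or len(ref) == 0 or tgt.ndim != 2 or len(tgt) == 0:
        raise ValueError("point lists must be nonempty (N, 3) arrays")
    # chunked brute force: deterministic lowest-index tie-breaking (argmin
    # takes the first occurrence), exact distances, flat memory
    out = np.empty(len(ref))
    for lo in range(0, len(ref), 512):
        d2 = np.sum((ref[lo:lo + 512, None, :] - tgt[None, :, :]) ** 2, axis=2)
        out[lo:lo + 512] = np.sqrt(d2.min(axis=1))
    back_d = np.empty(len(tgt))
    back_idx = np.empty(len(tgt), dtype=np.intp)
    for lo in range(0, len(tgt), 512):
        d2 = np.sum((tgt[lo:lo + 512, None, :] - ref[None, :, :]) ** 2, axis=2)
        back_idx[lo:lo + 512] = d2.argmin(axis=1)
        back_d[lo:lo + 512] = np.sqrt(d2[np.arange(len(d2)), back_idx[lo:lo + 512]])
    np.maximum.at(out, back_idx, back_d)
    return out


def bd(ref_mask: BinaryMask, tgt_mask: BinaryMask) -> float:
    """Mean BLD (mm) over the reference surface; reference = ground truth."""
    ref_pts = extract_surface_points(ref_mask)
    tgt_pts = extract_surface_points(tgt_mask)
    return float(np.mean(bld_per_point(ref_pts, tgt_pts)))


def is_failure(dice_after: float, dice_no_reg: float, cap: float | None = None) -> bool:
    """Failure iff dice_after < 0.95 * dice_noreg (strict).

    With ``cap`` (e.g. 0.95), the alternate reading fails a registration
    when its Dice is below ``min(0.95 * dice_noreg, cap)``.
    """
    thresh = 0.95 * dice_no_reg
    if cap is not None:
        thresh = min(thresh, cap)
    return bool(dice_after < thresh)


def dice_noreg(ct_ctv: BinaryMask, cbct_ctv_manual: BinaryMask) -> float:
    """Dice with no registration: the CT CTV resampled identically onto the CBCT grid."""
    from cbctreg.transform import RigidTransform
    from cbctreg.volgrid import resample

    on_cbct = resample(ct_ctv, RigidTransform(), cbct_ctv_manual.grid, interp="nearest")
    return dice(on_cbct, cbct_ctv_manual)


def summarize(evals: list[PairEvaluation], method: str) -> MethodSummary:
    """Median and sample SD (n-1) of a method's Dice and BD over a cohort."""
    ds, bds, failed = [], [], 0
    for ev in evals:
        me = ev.methods.get(method)
        if me is None or me.error is not None:
            continue
        ds.append(me.dice_after)
        bds.append(me.bd_mm)
        failed += int(me.failed)
    if not ds:
        raise ValueError(f"no successful evaluations for method '{method}'")
    if len(ds) == 1:
        warnings.warn(f"method '{method}': single pair, SD undefined; reporting 0")
        sd_d = sd_b = 0.0
    else:
        sd_d = float(np.std(ds, ddof=1))
        sd_b = float(np.std(bds, ddof=1))
    return MethodSummary(
        method=method,
        dice_median=float(np.median(ds)),
        dice_sd=sd_d,
        bd_median_mm=float(np.median(bds)),
        bd_sd_mm=sd_b,
        n_failed=failed,
        n_pairs=len(ds),
    )


def success_rate_percent(n_failed: int, n_pairs: int) -> float:
    """Success rate as the nearest whole percent, e.g. 6 failures of 115 -> 95."""
    if n_pairs <= 0 or n_failed < 0 or n_failed > n_pairs:
        raise ValueError("need 0 <= n_failed <= n_pairs, n_pairs > 0")
    return float(round(100.0 * (n_pairs - n_failed) / n_pairs))


def dice_interval_upper(mean: float, sd: float, z: float = 2.58) -> float:
    """Upper bound of the mean ± z·SD interval (z = 2.58 covers ~99% under normality)."""
    return round(mean + z * sd, 2)
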