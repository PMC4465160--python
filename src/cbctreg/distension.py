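"""Rectal-distension scoring and registration-failure prediction.

Rectal filling change between planning CT and treatment CBCT is quantified
without any CBCT contour, from mean intensities only::

    F = | (Ī_CBCT,r − Ī_CBCT,p) − (Ī_CT,r − Ī_CT,p) |

where the ``r`` means are taken over R_partial — the part of the CT rectum
inside the margin-expanded CTV registration mask — and the ``p`` means over
the prostate.  CBCT means are sampled (linear interpolation) at the same
CT-grid masked points pushed through the bony alignment, so the CT contours
are the only contours needed.  Subtracting the prostate means cancels any
constant intensity shift between CBCT acquisitions; a multiplicative gain
is *not* cancelled (known limitation of the score).

A pair is predicted to fail its local registration when F exceeds a cutoff
(default 104.4 au, the midpoint of the all-successful bound F1 = 61.2 and
the all-failed bound F2 = 147.6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cbctreg.preprocess import expand_margin
from cbctreg.transform import RigidTransform
from cbctreg.volgrid import BinaryMask, ImageVolume

__all__ = [
    "DistensionResult",
    "compute_rpartial",
    "compute_F",
    "predict_failure",
    "sensitivity_specificity",
    "sort_pairs_by_F",
    "default_cutoff",
    "F1_ALL_SUCCESS",
    "F2_ALL_FAIL",
]

#: F at or below which no local registration failed / above which all did
F1_ALL_SUCCESS = 61.2
F2_ALL_FAIL = 147.6


def default_cutoff(f1: float = F1_ALL_SUCCESS, f2: float = F2_ALL_FAIL) -> float:
    """Midpoint cutoff between the all-success and all-failure F bounds."""
    return (f1 + f2) / 2.0


@dataclass
class DistensionResult:
    """The F score with its constituent means and the failure prediction."""

    F: float
    mean_ct_rectum: float
    mean_ct_prostate: float
    mean_cbct_rectum: float
    mean_cbct_prostate: float
    n_voxels_rpartial: int
    predicted_failure: bool
    cutoff: float


def compute_rpartial(rectum_ct: BinaryMask, ctv_ct: BinaryMask, margin_mm: float = 8.0) -> BinaryMask:
    """R_partial: the CT rectum inside the margin-expanded CTV."""
    if rectum_ct.grid != ctv_ct.grid:
        raise ValueError("rectum and CTV masks must share one grid")
    roi = expand_margin(ctv_ct, margin_mm)
    inter = (roi.voxels > 0) & (rectum_ct.voxels > 0)
    if not inter.any():
        warnings.warn("R_partial is empty; F will be undefined for this pair")
    return BinaryMask(inter.astype(np.uint8), rectum_ct.spacing, rectum_ct.origin)


def _mean_pullback(cbct: ImageVolume, mask: BinaryMask, ct_to_cbct: RigidTransform) -> float:
    """Mean CBCT intensity at the masked CT-grid points mapped into CBCT space."""
    idx = np.argwhere(mask.voxels > 0)
    pts = mask.grid.points(idx)
    q = ct_to_cbct.apply(pts)
    ci = cbct.grid.continuous_index(q)
    vals = ndimage.map_coordinates(
        cbct.voxels.astype(np.float64), ci.T, order=1, mode="constant",
        cval=cbct.fill_value, prefilter=False,
    )
    return float(np.mean(vals))


def compute_F(
    ct: ImageVolume,
    cbct: ImageVolume,
    bony_ct_to_cbct: RigidTransform,
    prostate_ct: BinaryMask,
    rpartial: BinaryMask,
    cutoff: float | None = None,
) -> DistensionResult:
    """Compute F from the CT/CBCT pair, the bony alignment and the CT masks.

    ``bony_ct_to_cbct`` maps CT physical points into CBCT space (the inverse
    of the registration engine's recovered CBCT→CT transform).  F is always
    computed on *unfiltered* images: gas replacement would erase the signal.
    """
    if rpartial.count() == 0:
        raise ValueError("F undefined for this pair: empty R_partial")
    if cutoff is None:
        cutoff = default_cutoff()
    mean_ct_r = float(ct.voxels[rpartial.voxels > 0].mean())
    mean_ct_p = float(ct.voxels[prostate_ct.voxels > 0].mean())
    mean_cb_r = _mean_pullback(cbct, rpartial, bony_ct_to_cbct)
    mean_cb_p = _mean_pullback(cbct, prostate_ct, bony_ct_to_cbct)
    F = abs((mean_cb_r - mean_cb_p) - (mean_ct_r - mean_ct_p))
    return DistensionResult(
        F=F,
        mean_ct_rectum=mean_ct_r,
        mean_ct_prostate=mean_ct_p,
        mean_cbct_rectum=mean_cb_r,
        mean_cbct_prostate=mean_cb_p,
        n_voxels_rpartial=rpartial.count(),
        predicted_failure=predict_failure(F, cutoff),
        cutoff=cutoff,
    )


def predict_failure(F: float, cutoff: float | None = None) -> bool:
    """Predict local-registration failure iff F strictly exceeds the cutoff."""
    if cutoff is None:
        cutoff = default_cutoff()
    return bool(F > cutoff)


def sensitivity_specificity(predicted, actual) -> tuple[float | None, float | None]:
    """Sensitivity/specificity of failure prediction (positive = failure).

    A component that is undefined (no actual positives, or no actual
    negatives) is returned as ``None`` rather than 0.
    """
    pred = np.asarray(predicted, dtype=bool)
    act = np.asarray(actual, dtype=bool)
    if pred.shape != act.shape:
        raise ValueError("predicted and actual must have equal length")
    tp = int(np.sum(pred & act))
    fn = int(np.sum(~pred & act))
    tn = int(np.sum(~pred & ~act))
    fp = int(np.sum(pred & ~act))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return sens, spec


def sort_pairs_by_F(evals) -> list:
    """Pairs sorted by ascending F (ties broken by pair id); deterministic.

    Accepts any sequence of objects with ``F`` and ``pair_id`` attributes
    (e.g. :class:`cbctreg.evalmetrics.PairEvaluation`).
    """
    return sorted(evals, key=lambda e: (e.F, str(e.pair_id)))
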