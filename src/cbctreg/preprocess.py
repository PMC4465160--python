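"""Pre-processing for CT/CBCT registration.

Five steps precede registration: (1) offset the planning CT so its
isocenter coincides with the treatment (LINAC) isocenter, (2) mask the
patient body on both images, (3) clamp everything below the bone threshold
(bony registration only), (4) replace rectal gas by a tissue-equivalent
value (global and local registration only), (5) expand the CT CTV by a
physical margin to build the local registration mask.

Bone "thresholding" is realized as a clamp-from-below at the threshold:
soft tissue flattens to a constant, so bone edges carry the only NCC
signal.  Margin expansion uses a Euclidean distance transform in physical
mm (anisotropy-aware), not voxel-count dilation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cbctreg.volgrid import BinaryMask, ImageVolume, Modality, StructureSet

__all__ = [
    "ThresholdConfig",
    "apply_isocenter_offset",
    "compute_body_mask",
    "threshold_bone",
    "replace_gas",
    "expand_margin",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Modality-specific intensity thresholds.

    Bone: 150 HU (CT) / -140 au (CBCT); gas: -150 HU / -500 au.  Body
    thresholds sit between tissue and air and are configurable.
    """

    bone_ct: float = 150.0
    bone_cbct: float = -140.0
    gas_ct: float = -150.0
    gas_cbct: float = -500.0
    body_ct: float = -300.0
    body_cbct: float = -400.0

    def __post_init__(self):
        if self.gas_ct >= self.bone_ct or self.gas_cbct >= self.bone_cbct:
            raise ValueError("gas threshold must be below bone threshold per modality")

    def bone(self, modality: Modality) -> float:
        return self.bone_ct if Modality(modality) is Modality.CT else self.bone_cbct

    def gas(self, modality: Modality) -> float:
        return self.gas_ct if Modality(modality) is Modality.CT else self.gas_cbct

    def body(self, modality: Modality) -> float:
        return self.body_ct if Modality(modality) is Modality.CT else self.body_cbct


def apply_isocenter_offset(
    ct: ImageVolume,
    ct_structs: StructureSet | None,
    ct_isocenter,
    linac_isocenter=(0.0, 0.0, 0.0),
):
    """Shift the CT (and its structures) so the plan isocenter lands on the LINAC isocenter.

    Only the origin moves, by ``linac_isocenter - ct_isocenter``; voxels are
    untouched.  Returns ``(ct, structs)`` copies.
    """
    iso = np.asarray(ct_isocenter, dtype=float)
    linac = np.asarray(linac_isocenter, dtype=float)
    if not (np.all(np.isfinite(iso)) and np.all(np.isfinite(linac))):
        raise ValueError("isocenter coordinates must be finite")
    delta = linac - iso
    out = ImageVolume(ct.voxels, ct.spacing, tuple(np.asarray(ct.origin) + delta), ct.modality)
    out_structs = ct_structs.shifted(delta) if ct_structs is not None else None
    return out, out_structs


def compute_body_mask(v: ImageVolume, cfg: ThresholdConfig = ThresholdConfig()) -> BinaryMask:
    """Patient-body mask: threshold, largest 6-connected component, closing, slice-wise fill.

    Excludes exterior air and any table-like structure below the body
    threshold.  Raises when nothing exceeds the threshold.
    """
    fg = v.voxels >= cfg.body(v.modality)
    if not fg.any():
        raise ValueError("no body found: no voxel above the body threshold")
    labels, nlab = ndimage.label(fg, structure=ndimage.generate_binary_structure(3, 1))
    if nlab > 1:
        counts = np.bincount(labels.reshape(-1))
        counts[0] = 0
        fg = labels == int(np.argmax(counts))
    ball = _ball_structure(3, v.spacing)
    pad = tuple((h, h) for h in (np.asarray(ball.shape) // 2))
    padded = np.pad(fg, pad, mode="edge")  # avoid border erosion at volume faces
    closed = ndimage.binary_closing(padded, structure=ball)
    fg = closed[tuple(slice(p[0], s + p[0]) for p, s in zip(pad, fg.shape))]
    # hole fill per axial (constant-z) slice
    filled = np.empty_like(fg)
    for k in range(fg.shape[2]):
        filled[:, :, k] = ndimage.binary_fill_holes(fg[:, :, k])
    return BinaryMask(filled.astype(np.uint8), v.spacing, v.origin)


def _ball_structure(radius_vox: float, spacing) -> np.ndarray:
    """Ellipsoidal structuring element ~ a ball of ``radius_vox`` in-plane voxels (mm-aware)."""
    sp = np.asarray(spacing, dtype=float)
    r_mm = radius_vox * float(min(sp[:2]))
    half = np.maximum(np.floor(r_mm / sp).astype(int), 0)
    grids = np.meshgrid(*(np.arange(-h, h + 1) for h in half), indexing="ij")
    d2 = sum((g * s) ** 2 for g, s in zip(grids, sp))
    return d2 <= r_mm ** 2 + 1e-9


def threshold_bone(v: ImageVolume, cfg: ThresholdConfig = ThresholdConfig()) -> ImageVolume:
    """Clamp-from-below at the modality bone threshold (idempotent, monotone)."""
    level = cfg.bone(v.modality)
    return ImageVolume(np.maximum(v.voxels, level), v.spacing, v.origin, v.modality)


def replace_gas(v: ImageVolume, cfg: ThresholdConfig = ThresholdConfig()) -> ImageVolume:
    """Replace gas by a tissue-equivalent value: clamp below the gas threshold.

    Applies to global and local registration inputs only — never to the
    bony registration (the bone clamp already removes gas contrast) and
    never to the images used for the distension statistic F (it would erase
    the very signal F measures).
    """
    level = cfg.gas(v.modality)
    return ImageVolume(np.maximum(v.voxels, level), v.spacing, v.origin, v.modality)


def expand_margin(m: BinaryMask, margin_mm: float) -> BinaryMask:
    """Expand a mask by a physical margin (mm): a voxel joins the mask iff
    its center is within Euclidean distance ``margin_mm`` of some input
    voxel center, measured in mm on the (possibly anisotropic) grid.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    if margin_mm == 0 or m.count() == 0:
        return m.copy()
    dist = ndimage.distance_transform_edt(m.voxels == 0, sampling=m.spacing)
    out = (m.voxels > 0) | (dist <= margin_mm + 1e-9)
    return BinaryMask(out.astype(np.uint8), m.spacing, m.origin)
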