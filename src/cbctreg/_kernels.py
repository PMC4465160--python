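"""Numba inner loops for the masked NCC metric.

One sequential pass over the fixed-image sample points: each point is mapped
through the rigid matrix, trilinearly interpolated in the moving image, and
accumulated into the five NCC sums.  Single-threaded and free of temporaries,
so evaluation is deterministic and memory-flat even at full scan resolution.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ncc_sums"]


@njit(cache=True)
def ncc_sums(
    fixed_vals,      # (N,) float64 fixed-image values at the sample points
    fixed_pts,       # (N, 3) float64 physical coordinates of the sample points
    R,               # (3, 3) rigid rotation matrix
    offset,          # (3,) offset: mapped point = R p + offset
    moving,          # (nx, ny, nz) float64 moving image
    mov_origin,      # (3,)
    mov_spacing,     # (3,)
    moving_mask,     # (nx, ny, nz) uint8; all-ones array when unmasked
):
    """Return (n, sf, sm, sff, smm, sfm) over admissible samples.

    A sample is admissible when its mapped point lies strictly inside the
    moving support (all 8 trilinear corners valid) and the moving mask is 1
    at the nearest voxel.  Sums are mean-free later, in float64.
    """
    nx, ny, nz = moving.shape
    n = 0
    sf = 0.0
    sm = 0.0
    sff = 0.0
    smm = 0.0
    sfm = 0.0
    for s in range(fixed_pts.shape[0]):
        px = fixed_pts[s, 0]
        py = fixed_pts[s, 1]
        pz = fixed_pts[s, 2]
        qx = R[0, 0] * px + R[0, 1] * py + R[0, 2] * pz + offset[0]
        qy = R[1, 0] * px + R[1, 1] * py + R[1, 2] * pz + offset[1]
        qz = R[2, 0] * px + R[2, 1] * py + R[2, 2] * pz + offset[2]
        cx = (qx - mov_origin[0]) / mov_spacing[0]
        cy = (qy - mov_origin[1]) / mov_spacing[1]
        cz = (qz - mov_origin[2]) / mov_spacing[2]
        if cx < 0.0 or cx > nx - 1 or cy < 0.0 or cy > ny - 1 or cz < 0.0 or cz > nz - 1:
            continue
        # nearest voxel for the moving-side mask (half-up, matches the oracle)
        mi = int(np.floor(cx + 0.5))
        mj = int(np.floor(cy + 0.5))
        mk = int(np.floor(cz + 0.5))
        if moving_mask[mi, mj, mk] == 0:
            continue
        i0 = int(np.floor(cx))
        j0 = int(np.floor(cy))
        k0 = int(np.floor(cz))
        if i0 == nx - 1:
            i0 -= 1
        if j0 == ny - 1:
            j0 -= 1
        if k0 == nz - 1:
            k0 -= 1
        fx = cx - i0
        fy = cy - j0
        fz = cz - k0
        c000 = moving[i0, j0, k0]
        c100 = moving[i0 + 1, j0, k0]
        c010 = moving[i0, j0 + 1, k0]
        c110 = moving[i0 + 1, j0 + 1, k0]
        c001 = moving[i0, j0, k0 + 1]
        c101 = moving[i0 + 1, j0, k0 + 1]
        c011 = moving[i0, j0 + 1, k0 + 1]
        c111 = moving[i0 + 1, j0 + 1, k0 + 1]
        c00 = c000 * (1 - fx) + c100 * fx
        c10 = c010 * (1 - fx) + c110 * fx
        c01 = c001 * (1 - fx) + c101 * fx
        c11 = c011 * (1 - fx) + c111 * fx
        c0 = c00 * (1 - fy) + c10 * fy
        c1 = c01 * (1 - fy) + c11 * fy
        m = c0 * (1 - fz) + c1 * fz
        f = fixed_vals[s]
        n += 1
        sf += f
        sm += m
        sff += f * f
        smm += m * m
        sfm += f * m
    return n, sf, sm, sff, smm, sfm
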