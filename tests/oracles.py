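"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition with plain
loops/enumeration, staying independent of the library code paths they
check.
"""

from __future__ import annotations

import numpy as np


def ncc_oracle(fixed, moving, t, fixed_mask=None, moving_mask=None):
    """Loop-based masked NCC following the sample-admission rule verbatim."""
    fshape = fixed.voxels.shape
    forigin = np.asarray(fixed.origin)
    fspacing = np.asarray(fixed.spacing)
    morigin = np.asarray(moving.origin)
    mspacing = np.asarray(moving.spacing)
    mov = moving.voxels
    nx, ny, nz = mov.shape
    R = t.matrix
    o = t.offset
    fs, ms = [], []
    for i in range(fshape[0]):
        for j in range(fshape[1]):
            for k in range(fshape[2]):
                if fixed_mask is not None and fixed_mask.voxels[i, j, k] == 0:
                    continue
                p = forigin + np.array([i, j, k]) * fspacing
                q = R @ p + o
                c = (q - morigin) / mspacing
                if np.any(c < 0) or c[0] > nx - 1 or c[1] > ny - 1 or c[2] > nz - 1:
                    continue
                mi = tuple(int(np.floor(cc + 0.5)) for cc in c)
                if moving_mask is not None and moving_mask.voxels[mi] == 0:
                    continue
                i0, j0, k0 = (min(int(np.floor(cc)), n - 2) for cc, n in zip(c, (nx, ny, nz)))
                fx, fy, fz = c - (i0, j0, k0)
                val = 0.0
                for di, wx in ((0, 1 - fx), (1, fx)):
                    for dj, wy in ((0, 1 - fy), (1, fy)):
                        for dk, wz in ((0, 1 - fz), (1, fz)):
                            val += wx * wy * wz * mov[i0 + di, j0 + dj, k0 + dk]
                fs.append(fixed.voxels[i, j, k])
                ms.append(val)
    f = np.asarray(fs) - np.mean(fs)
    m = np.asarray(ms) - np.mean(ms)
    return float(np.sum(f * m) / np.sqrt(np.sum(f * f) * np.sum(m * m))), len(fs)


def bld_oracle(ref_pts, tgt_pts):
    """O(n^2) bidirectional local distance, ties to the lowest index."""
    ref = np.asarray(ref_pts, dtype=float)
    tgt = np.asarray(tgt_pts, dtype=float)
    out = np.empty(len(ref))
    for a in range(len(ref)):
        out[a] = min(np.linalg.norm(ref[a] - b) for b in tgt)
    for b in range(len(tgt)):
        dists = [np.linalg.norm(tgt[b] - r) for r in ref]
        a = int(np.argmin(dists))
        out[a] = max(out[a], dists[a])
    return out


def expand_oracle(mask_voxels, spacing, margin):
    """All-pairs voxel-center distance check for margin expansion."""
    spacing = np.asarray(spacing, dtype=float)
    src = np.argwhere(np.asarray(mask_voxels) > 0) * spacing
    out = np.zeros_like(np.asarray(mask_voxels), dtype=np.uint8)
    for idx in np.ndindex(out.shape):
        p = np.asarray(idx) * spacing
        d = np.sqrt(np.sum((src - p) ** 2, axis=1)).min()
        if d <= margin + 1e-9:
            out[idx] = 1
    return out


def surface_oracle(mask_voxels):
    """Brute-force 6-connected surface voxels (out of bounds counts as 0)."""
    v = np.asarray(mask_voxels)
    pts = []
    for idx in np.argwhere(v > 0):
        i, j, k = idx
        on_surface = False
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            n = idx + d
            if np.any(n < 0) or np.any(n >= v.shape) or v[tuple(n)] == 0:
                on_surface = True
        if on_surface:
            pts.append((i, j, k))
    return sorted(pts)
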