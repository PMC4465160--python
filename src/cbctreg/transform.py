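"""6-DOF rigid transforms in physical (mm) space.

A transform maps a point p to ``R (p - c) + c + t`` where ``R = Rz Ry Rx``
(fixed composition order, angles in radians), ``c`` is the rotation center
and ``t`` the translation, all in mm.  Composition and inversion stay
within the type: the composed map is reduced back to Euler angles about a
chosen center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform"]


def _rot_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _euler_from_matrix(R: np.ndarray) -> tuple[float, float, float]:
    """Invert ``R = Rz(rz) Ry(ry) Rx(rx)``; gimbal-lock safe for |ry| = 90 deg."""
    sy = -R[2, 0]
    sy = float(np.clip(sy, -1.0, 1.0))
    ry = float(np.arcsin(sy))
    if abs(sy) < 1.0 - 1e-12:
        rx = float(np.arctan2(R[2, 1], R[2, 2]))
        rz = float(np.arctan2(R[1, 0], R[0, 0]))
    else:  # degenerate: rx and rz couple; fold everything into rx
        rx = float(np.arctan2(-R[1, 2], R[1, 1]))
        rz = 0.0
    return rx, ry, rz


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map p -> R (p - center) + center + translations, R = Rz·Ry·Rx."""

    rotations: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "rotations", tuple(float(r) for r in self.rotations))
        object.__setattr__(self, "translations", tuple(float(t) for t in self.translations))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    # -- matrix form -------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        return _rot_matrix(*self.rotations)

    @property
    def offset(self) -> np.ndarray:
        """o such that the map is p -> R p + o."""
        c = np.asarray(self.center)
        return c - self.matrix @ c + np.asarray(self.translations)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to points of shape (3,) or (N, 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.matrix.T + self.offset

    # -- algebra -----------------------------------------------------------
    @classmethod
    def from_matrix(cls, R: np.ndarray, offset: np.ndarray,
                    center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        rx, ry, rz = _euler_from_matrix(np.asarray(R, dtype=float))
        c = np.asarray(center, dtype=float)
        t = np.asarray(offset, dtype=float) - c + np.asarray(R) @ c
        return cls((rx, ry, rz), tuple(t), tuple(c))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: the map q -> self(other(q)), centered at self.center."""
        R = self.matrix @ other.matrix
        o = self.matrix @ other.offset + self.offset
        return RigidTransform.from_matrix(R, o, self.center)

    def inverse(self) -> "RigidTransform":
        R = self.matrix.T
        o = -R @ self.offset
        return RigidTransform.from_matrix(R, o, self.center)

    def with_center(self, center) -> "RigidTransform":
        """Same physical map re-expressed about a different rotation center."""
        return RigidTransform.from_matrix(self.matrix, self.offset, center)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def translation(cls, t) -> "RigidTransform":
        return cls(translations=tuple(float(x) for x in t))

    # -- plain-text serialization ("rx ry rz tx ty tz" / "cx cy cz") -------
    def to_text(self) -> str:
        r, t, c = self.rotations, self.translations, self.center
        line1 = " ".join(f"{x:.17g}" for x in (*r, *t))
        line2 = " ".join(f"{x:.17g}" for x in c)
        return line1 + "\n" + line2 + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RigidTransform":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        if len(lines) < 2:
            raise ValueError("transform text must have two lines: parameters and center")
        p = [float(x) for x in lines[0].split()]
        c = [float(x) for x in lines[1].split()]
        if len(p) != 6 or len(c) != 3:
            raise ValueError("transform text must be 'rx ry rz tx ty tz' then 'cx cy cz'")
        return cls(tuple(p[:3]), tuple(p[3:]), tuple(c))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path: str) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_text(fh.read())
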