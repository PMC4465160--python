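"""Constructive pelvis phantom: paired planning-CT / treatment-CBCT volumes.

The phantom emulates the acquisition conditions of prostate IGRT: an
anisotropic planning CT (default 160x160x60 voxels at 1x1x3 mm), a
higher-resolution treatment CBCT (160x160x168 at 1x1x1 mm), an
*uncalibrated* linear CBCT intensity map ``I_cbct = a * I_ct + b + noise``,
a rigid whole-anatomy setup error between the scans, an independent
prostate displacement relative to the bones, and variable rectal
distension/gas in the peri-prostatic rectum.

Geometry is constructive solid (ellipsoids, an elliptic body cylinder, a
rectal tube, a sacral block), rasterized at voxel centers with a fixed
precedence (gas > bone > prostate > bladder > rectum > tissue > exterior),
so organ masks are pairwise disjoint by construction.  Ground-truth CBCT
masks are rasterized analytically on the CBCT grid — never resampled from
the CT masks — and the true transforms are carried alongside the images.

Anatomy lives in the machine frame (LINAC isocenter at the origin).  The
stored CT is displaced by ``ct_isocenter`` so that the isocenter-offset
pre-processing step has real work to do; the CBCT is generated directly in
the machine frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from cbctreg.transform import RigidTransform
from cbctreg.volgrid import BinaryMask, Grid, ImageVolume, Modality, StructureSet

__all__ = [
    "PhantomSpec", "PhantomPair", "generate_pair", "make_cohort",
    "recovery_cohort", "stress_cohort",
]


def _centered_grid(shape, spacing) -> Grid:
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    return Grid(shape, spacing, origin)


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one CT/CBCT phantom pair.

    Distances in mm, intensities in HU on the CT side.  ``distension_factor``
    scales the CBCT rectum radius (>= 1); ``gas_fraction`` is the fraction of
    the peri-prostatic CBCT rectal lumen cross-section filled with gas.
    """

    # grids
    ct_shape: tuple[int, int, int] = (160, 160, 60)
    ct_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    cbct_shape: tuple[int, int, int] = (160, 160, 168)
    cbct_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # anatomy (machine frame, mm); +y posterior, +z superior
    body_semi_axes: tuple[float, float] = (72.0, 64.0)
    iliac_centers: tuple[tuple[float, float, float], ...] = ((-48.0, 0.0, 5.0), (48.0, 0.0, 5.0))
    iliac_semi_axes: tuple[float, float, float] = (14.0, 25.0, 40.0)
    sacrum_box: tuple[tuple[float, float], ...] = ((-22.0, 22.0), (48.0, 58.0), (-40.0, 40.0))
    prostate_center: tuple[float, float, float] = (0.0, 5.0, 0.0)
    prostate_semi_axes: tuple[float, float, float] = (20.0, 17.0, 18.0)
    bladder_center: tuple[float, float, float] = (0.0, -25.0, 28.0)
    bladder_semi_axes: tuple[float, float, float] = (24.0, 20.0, 20.0)
    rectum_radius: float = 12.0
    rectum_z_range: tuple[float, float] = (-70.0, 70.0)
    # motion / filling
    distension_factor: float = 1.0
    gas_fraction: float = 0.0
    gas_fraction_ct: float = 0.0
    #: axial offset (mm) of the CT gas pocket relative to the peri-prostatic
    #: window; a nonzero value emulates gas that moved between the scans and
    #: gives the unfiltered registration a false alignment target
    gas_z_offset_ct: float = 0.0
    setup_transform: RigidTransform = field(default_factory=RigidTransform)
    prostate_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ct_isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # intensities (HU)
    tissue_hu: float = 30.0
    prostate_hu: float = 40.0
    bladder_hu: float = 10.0
    bone_hu: float = 700.0
    gas_hu: float = -1000.0
    air_hu: float = -1000.0
    #: solid/fluid rectal content surrounding a gas core (present only when
    #: that side has gas, i.e. when the empty-rectum protocol is violated);
    #: sits between the gas and tissue ranges and above the gas thresholds,
    #: so the replace-gas filter removes the core but not the content
    content_hu: float = -120.0
    #: soft-tissue texture: a smooth random field fixed to the anatomy and
    #: therefore identical (up to the linear map) on CT and CBCT — the
    #: cross-modality structure that drives soft-tissue NCC in real scans.
    #: Amplitude is clipped at ±3 sigma so tissue never crosses the bone or
    #: gas thresholds.  Organ interiors (prostate, bladder, rectum) are more
    #: homogeneous than the surrounding fat/muscle and carry only
    #: ``organ_texture_scale`` of the amplitude.
    texture_sigma_hu: float = 20.0
    texture_corr_mm: float = 8.0
    organ_texture_scale: float = 0.3
    # CBCT intensity model.  The offset is chosen so the linear map is
    # consistent with the institution-style CBCT thresholds: 150 HU (CT
    # bone level) maps to -140 au, i.e. b = -140 - 150 a.  Soft tissue then
    # sits near -250 au, which is what makes the -500 au gas clamp a
    # *tissue-equivalent* replacement and lets the -140 au bone clamp
    # actually isolate bone on the CBCT.
    cbct_gain: float = 0.9
    cbct_offset: float = -275.0
    #: optional reconstruction floor (au): CBCT output clipped from below
    cbct_floor: float | None = None
    noise_sigma: float = 5.0
    streaks: bool = False
    # misc
    blur_sigma_vox: float = 0.0  # optional partial-volume emulation
    seed: int = 0

    def __post_init__(self):
        if self.distension_factor < 1.0:
            raise ValueError("distension_factor must be >= 1")
        for g in (self.gas_fraction, self.gas_fraction_ct):
            if not (0.0 <= g <= 1.0):
                raise ValueError("gas fractions must lie in [0, 1]")

    @property
    def ct_grid(self) -> Grid:
        g = _centered_grid(self.ct_shape, self.ct_spacing)
        return Grid(g.shape, g.spacing, tuple(np.asarray(g.origin) + np.asarray(self.ct_isocenter)))

    @property
    def cbct_grid(self) -> Grid:
        return _centered_grid(self.cbct_shape, self.cbct_spacing)

    def coarse(self) -> "PhantomSpec":
        """A reduced-resolution variant for cohort-scale runs (same anatomy)."""
        return replace(
            self,
            ct_shape=(108, 108, 44), ct_spacing=(1.5, 1.5, 3.0),
            cbct_shape=(108, 108, 84), cbct_spacing=(1.5, 1.5, 1.5),
        )


@dataclass
class PhantomPair:
    """One generated CT/CBCT pair with ground truth."""

    ct: ImageVolume
    ct_structs: StructureSet
    cbct: ImageVolume
    cbct_structs_truth: StructureSet
    truth_setup: RigidTransform      # anatomy map CT(machine) -> CBCT
    truth_prostate: RigidTransform   # setup composed with the prostate offset
    spec: PhantomSpec
    pair_id: str = "pair-0"

    @property
    def expected_bony_registration(self) -> RigidTransform:
        """The transform a perfect bony registration recovers (CBCT -> CT)."""
        return self.truth_setup.inverse()

    @property
    def expected_prostate_registration(self) -> RigidTransform:
        """The transform a perfect prostate-local registration recovers."""
        return self.truth_prostate.inverse()


# ---------------------------------------------------------------------------
# shape evaluation


def _ellipsoid(pts, center, semi):
    d = (pts - np.asarray(center)) / np.asarray(semi)
    return np.einsum("ij,ij->i", d, d) <= 1.0


def _shapes_at(pts: np.ndarray, spec: PhantomSpec, cbct_side: bool) -> dict[str, np.ndarray]:
    """Evaluate the anatomy at machine-frame points, with precedence applied."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    bx, by = spec.body_semi_axes
    body = (x / bx) ** 2 + (y / by) ** 2 <= 1.0

    bone = np.zeros(len(pts), dtype=bool)
    for c in spec.iliac_centers:
        bone |= _ellipsoid(pts, c, spec.iliac_semi_axes)
    (x0, x1), (y0, y1), (z0, z1) = spec.sacrum_box
    bone |= (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1) & (z >= z0) & (z <= z1)
    bone &= body

    shift = np.asarray(spec.prostate_offset) if cbct_side else np.zeros(3)
    prostate = _ellipsoid(pts - shift, spec.prostate_center, spec.prostate_semi_axes)
    prostate &= body & ~bone

    bladder = _ellipsoid(pts, spec.bladder_center, spec.bladder_semi_axes)
    bladder &= body & ~bone & ~prostate

    r = spec.rectum_radius * (spec.distension_factor if cbct_side else 1.0)
    yr = spec.prostate_center[1] + spec.prostate_semi_axes[1] + spec.rectum_radius
    rad2 = x ** 2 + (y - yr) ** 2
    zlo, zhi = spec.rectum_z_range
    rectum = (rad2 <= r ** 2) & (z >= zlo) & (z <= zhi)
    rectum &= body & ~bone & ~prostate & ~bladder

    g = spec.gas_fraction if cbct_side else spec.gas_fraction_ct
    gas = np.zeros(len(pts), dtype=bool)
    content = np.zeros(len(pts), dtype=bool)
    if g > 0:
        zc = spec.prostate_center[2] + (0.0 if cbct_side else spec.gas_z_offset_ct)
        peri = np.abs(z - zc) <= spec.prostate_semi_axes[2] + 4.0
        gas_r = np.sqrt(g) * (r - 1.5)
        content_r = min(gas_r + 3.0, r - 0.5)
        gas = rectum & peri & (rad2 <= gas_r ** 2)
        content = rectum & peri & (rad2 <= content_r ** 2) & ~gas

    return {
        "body": body, "bone": bone, "ctv": prostate, "bladder": bladder,
        "rectum": rectum, "gas": gas, "content": content,
    }


class _TextureField:
    """Smooth zero-mean random field on a coarse anatomy-frame lattice.

    Evaluated by trilinear interpolation at arbitrary physical points, so CT
    and CBCT sample the *same* tissue structure wherever the anatomy maps.
    Values are clipped at ±3 sigma.
    """

    EXTENT = 100.0  # mm half-extent of the lattice cube

    def __init__(self, sigma_hu: float, corr_mm: float, seed: int):
        self.sigma = float(sigma_hu)
        n = max(int(np.ceil(2 * self.EXTENT / max(corr_mm, 1.0))) + 1, 4)
        rng = np.random.default_rng(seed)
        # white noise on the lattice + trilinear interpolation: correlation
        # length ~ one lattice cell (corr_mm), no long-range regional bias
        lattice = rng.normal(0.0, 1.0, size=(n, n, n))
        self.lattice = np.clip(lattice * self.sigma, -3 * self.sigma, 3 * self.sigma)
        self.spacing = 2 * self.EXTENT / (n - 1)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        if self.sigma == 0.0:
            return np.zeros(len(pts))
        ci = (np.asarray(pts) + self.EXTENT) / self.spacing
        return ndimage.map_coordinates(
            self.lattice, ci.T, order=1, mode="nearest", prefilter=False
        )


def _prostate_follow_weight(pts: np.ndarray, spec: PhantomSpec,
                            falloff_mm: float = 15.0) -> np.ndarray:
    """How much of the prostate displacement each point inherits (1 -> 0).

    The falloff is wide enough that tissue within the largest useful local
    registration margin (~8 mm from the gland surface) moves essentially
    with the gland — the coherent-neighborhood assumption behind using a
    margin-expanded target mask in the first place.
    """
    if not any(spec.prostate_offset):
        return np.zeros(len(pts))
    d = (pts - np.asarray(spec.prostate_center)) / np.asarray(spec.prostate_semi_axes)
    rho = np.sqrt(np.einsum("ij,ij->i", d, d))
    mean_semi = float(np.mean(spec.prostate_semi_axes))
    dist_mm = np.maximum(rho - 1.0, 0.0) * mean_semi
    return np.exp(-0.5 * (dist_mm / falloff_mm) ** 2)


def _intensity_from_shapes(
    sh: dict[str, np.ndarray], spec: PhantomSpec,
    pts: np.ndarray | None = None, texture: "_TextureField | None" = None,
) -> np.ndarray:
    vals = np.full(len(sh["body"]), spec.air_hu, dtype=np.float64)
    vals[sh["body"]] = spec.tissue_hu
    vals[sh["bladder"]] = spec.bladder_hu
    vals[sh["ctv"]] = spec.prostate_hu
    if texture is not None and pts is not None and texture.sigma > 0:
        soft = sh["body"] & ~sh["bone"] & ~sh["gas"] & ~sh["content"]
        organs = sh["ctv"] | sh["bladder"] | sh["rectum"]
        tex = np.zeros(len(vals))
        tex[soft] = texture(pts[soft])
        tex[soft & organs] *= spec.organ_texture_scale
        vals += tex
    vals[sh["content"]] = spec.content_hu
    vals[sh["bone"]] = spec.bone_hu
    vals[sh["gas"]] = spec.gas_hu
    return vals


def _validate_anatomy(spec: PhantomSpec) -> None:
    """Reject organs leaving the body or grossly overlapping specifications."""
    grid = _centered_grid(spec.ct_shape, spec.ct_spacing)
    pts = grid.all_points()
    x, y = pts[:, 0], pts[:, 1]
    bx, by = spec.body_semi_axes
    body = (x / bx) ** 2 + (y / by) ** 2 <= 1.0

    raw = {}
    raw["prostate"] = _ellipsoid(pts, spec.prostate_center, spec.prostate_semi_axes)
    raw["bladder"] = _ellipsoid(pts, spec.bladder_center, spec.bladder_semi_axes)
    yr = spec.prostate_center[1] + spec.prostate_semi_axes[1] + spec.rectum_radius
    rad2 = x ** 2 + (y - yr) ** 2
    zlo, zhi = spec.rectum_z_range
    raw["rectum"] = (rad2 <= spec.rectum_radius ** 2) & (pts[:, 2] >= zlo) & (pts[:, 2] <= zhi)
    bone = np.zeros(len(pts), dtype=bool)
    for c in spec.iliac_centers:
        bone |= _ellipsoid(pts, c, spec.iliac_semi_axes)
    (x0, x1), (y0, y1), (z0, z1) = spec.sacrum_box
    bone |= ((x >= x0) & (x <= x1) & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
             & (pts[:, 2] >= z0) & (pts[:, 2] <= z1))
    raw["bone"] = bone

    for name, m in raw.items():
        if np.any(m & ~body):
            raise ValueError(f"organ '{name}' extends outside the body")
    names = list(raw)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = int(np.sum(raw[a] & raw[b]))
            smaller = min(int(raw[a].sum()), int(raw[b].sum()))
            if smaller > 0 and inter > 0.05 * smaller:
                raise ValueError(f"overlapping organ specification: '{a}' vs '{b}'")


# ---------------------------------------------------------------------------
# generation


def _masks_to_structs(sh: dict[str, np.ndarray], grid: Grid) -> StructureSet:
    def mk(name):
        return BinaryMask(sh[name].reshape(grid.shape).astype(np.uint8), grid.spacing, grid.origin)

    return StructureSet({n: mk(n) for n in ("ctv", "rectum", "bladder", "body")})


def _add_streaks(arr: np.ndarray, gas: np.ndarray, rng: np.random.Generator) -> None:
    """Straight ±150 au lines through gas-pocket centers in axial planes."""
    labels, nlab = ndimage.label(gas.astype(np.uint8))
    for lab in range(1, nlab + 1):
        ci, cj, ck = (int(round(c)) for c in ndimage.center_of_mass(labels == lab))
        for _ in range(4):
            theta = rng.uniform(0, np.pi)
            amp = 150.0 * rng.choice((-1.0, 1.0))
            n = max(arr.shape[0], arr.shape[1])
            ts = np.arange(-n, n)
            ii = np.round(ci + ts * np.cos(theta)).astype(int)
            jj = np.round(cj + ts * np.sin(theta)).astype(int)
            ok = (ii >= 0) & (ii < arr.shape[0]) & (jj >= 0) & (jj < arr.shape[1])
            arr[ii[ok], jj[ok], ck] += amp


def generate_pair(spec: PhantomSpec, pair_id: str = "pair-0") -> PhantomPair:
    """Generate one CT/CBCT pair with ground-truth structures and transforms.

    Deterministic: the same spec (including its seed) yields bit-identical
    volumes.
    """
    _validate_anatomy(spec)
    rng = np.random.default_rng(spec.seed)
    texture = _TextureField(spec.texture_sigma_hu, spec.texture_corr_mm, spec.seed)

    # --- planning CT, machine frame then displaced by ct_isocenter
    ct_machine_grid = _centered_grid(spec.ct_shape, spec.ct_spacing)
    pts_ct = ct_machine_grid.all_points()
    sh_ct = _shapes_at(pts_ct, spec, cbct_side=False)
    ct_vals = _intensity_from_shapes(sh_ct, spec, pts_ct, texture).reshape(ct_machine_grid.shape)
    if spec.blur_sigma_vox > 0:
        ct_vals = ndimage.gaussian_filter(ct_vals, spec.blur_sigma_vox)
    ct_grid = spec.ct_grid
    ct = ImageVolume(ct_vals, ct_grid.spacing, ct_grid.origin, Modality.CT)
    ct_structs = StructureSet(
        {
            n: BinaryMask(m.voxels, m.spacing, ct_grid.origin)
            for n, m in _masks_to_structs(sh_ct, ct_machine_grid).items()
        }
    )

    # --- treatment CBCT, machine frame; anatomy moved by the setup transform
    cbct_grid = spec.cbct_grid
    q = cbct_grid.all_points()
    p = spec.setup_transform.inverse().apply(q)
    sh_cb = _shapes_at(p, spec, cbct_side=True)
    # texture is evaluated at the anatomy-frame points p: it moves with the
    # anatomy, exactly like real tissue structure.  The prostate offset is
    # carried by a smooth displacement field: weight 1 inside the gland,
    # Gaussian falloff (~10 mm) outside, so peri-prostatic tissue moves with
    # the gland while distant tissue stays with the bones.
    p_tex = p - np.outer(_prostate_follow_weight(p, spec), np.asarray(spec.prostate_offset))
    p_tex[sh_cb["ctv"]] = p[sh_cb["ctv"]] - np.asarray(spec.prostate_offset)
    ideal = _intensity_from_shapes(sh_cb, spec, p_tex, texture).reshape(cbct_grid.shape)
    if spec.blur_sigma_vox > 0:
        ideal = ndimage.gaussian_filter(ideal, spec.blur_sigma_vox)
    cbct_vals = spec.cbct_gain * ideal + spec.cbct_offset
    if spec.streaks:
        _add_streaks(cbct_vals, sh_cb["gas"].reshape(cbct_grid.shape), rng)
    if spec.noise_sigma > 0:
        cbct_vals = cbct_vals + rng.normal(0.0, spec.noise_sigma, size=cbct_vals.shape)
    if spec.cbct_floor is not None:
        cbct_vals = np.maximum(cbct_vals, spec.cbct_floor)
    cbct = ImageVolume(cbct_vals, cbct_grid.spacing, cbct_grid.origin, Modality.CBCT)
    cbct_structs = _masks_to_structs(sh_cb, cbct_grid)

    truth_setup = spec.setup_transform
    truth_prostate = truth_setup.compose(RigidTransform.translation(spec.prostate_offset))
    return PhantomPair(
        ct=ct, ct_structs=ct_structs, cbct=cbct, cbct_structs_truth=cbct_structs,
        truth_setup=truth_setup, truth_prostate=truth_prostate, spec=spec, pair_id=pair_id,
    )


# ---------------------------------------------------------------------------
# cohorts


def make_cohort(
    n_pairs: int,
    distension_grid: list[tuple[float, float]],
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    max_setup_translation: float = 8.0,
    max_setup_rotation_deg: float = 3.0,
    max_prostate_offset: float = 6.0,
    push_per_gas: float = 5.0,
    push_per_distension: float = 3.0,
    offset_jitter: float = 1.5,
    gas_ct_ratio: float = 0.0,
    gas_z_offset_ct: float = 0.0,
) -> list[PhantomPair]:
    """Generate a cohort spanning a (distension_factor, gas_fraction) grid.

    Setup errors are drawn uniformly within ±``max_setup_translation`` mm and
    ±``max_setup_rotation_deg`` degrees per axis.  The prostate offset has a
    random component plus an anterior push of ``push_per_gas * gas_fraction +
    push_per_distension * (distension_factor - 1)`` mm (the physiological
    coupling that makes high-gas pairs both displaced and high-F), capped at
    ``max_prostate_offset`` mm.  ``gas_ct_ratio`` puts gas on the planning CT
    too (fraction = ratio × the pair's CBCT gas fraction) displaced axially
    by ``gas_z_offset_ct`` mm — gas that moved between the scans, the
    misleading signal behind real registration failures.  Deterministic
    given ``seed``; pairs cycle through the grid.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not distension_grid:
        raise ValueError("empty distension grid")
    base = base_spec if base_spec is not None else PhantomSpec()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_pairs)]
    rng = np.random.default_rng(ss.generate_state(1)[0] % (2 ** 31))

    pairs = []
    for i in range(n_pairs):
        dist, gas = distension_grid[i % len(distension_grid)]
        trans = rng.uniform(-max_setup_translation, max_setup_translation, 3)
        rots = np.deg2rad(rng.uniform(-max_setup_rotation_deg, max_setup_rotation_deg, 3))
        setup = RigidTransform(tuple(rots), tuple(trans), (0.0, 0.0, 0.0))
        push = push_per_gas * gas + push_per_distension * (dist - 1.0)
        offset = np.array([0.0, -push, 0.0]) + rng.uniform(-offset_jitter, offset_jitter, 3)
        norm = float(np.linalg.norm(offset))
        if norm > max_prostate_offset:
            offset *= max_prostate_offset / norm
        spec = replace(
            base,
            distension_factor=float(dist),
            gas_fraction=float(gas),
            gas_fraction_ct=float(np.clip(gas_ct_ratio * gas, 0.0, 1.0)),
            gas_z_offset_ct=float(gas_z_offset_ct),
            setup_transform=setup,
            prostate_offset=tuple(offset),
            seed=child_seeds[i],
        )
        pairs.append(generate_pair(spec, pair_id=f"pair-{i}"))
    return pairs


def recovery_cohort(
    n_pairs: int = 20,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[PhantomPair]:
    """Clean (gas-free) pairs for transform-recovery studies.

    Setup errors up to ±8 mm / ±3° per axis with independent prostate
    offsets up to 6 mm: the bony registration should recover the setup
    regardless of the offset, and the local registration the prostate
    displacement on top of it.
    """
    return make_cohort(
        n_pairs, [(1.0, 0.0)], seed=seed, base_spec=base_spec,
        max_setup_translation=8.0, max_setup_rotation_deg=3.0,
        max_prostate_offset=6.0, push_per_gas=0.0, push_per_distension=0.0,
        offset_jitter=3.5,
    )


def stress_cohort(
    n_pairs: int = 20,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    gas_levels: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.85),
) -> list[PhantomPair]:
    """A failure-prone graded-gas cohort.

    Conditions chosen so that high-gas pairs can genuinely *fail* the local
    registration (end up worse than no registration at all): setup errors
    calibrated so the no-registration Dice sits near the clinical ~0.73
    median, small prostate offsets, and rectal gas cores (embedded in solid
    content) on both scans whose mismatch grows with gas and distension —
    the unmatched dark gas next to the prostate drags the unfiltered
    metric, while the gas filter clamps the cores into the content range
    and restores the soft-tissue signal.  Distension grows with gas as
    1 + g/2; the CT pocket holds 80% of the CBCT gas fraction.
    """
    grid = [(1.0 + g / 2.0, g) for g in gas_levels]
    return make_cohort(
        n_pairs, grid, seed=seed, base_spec=base_spec,
        max_setup_translation=5.0, max_setup_rotation_deg=2.0,
        max_prostate_offset=2.0, push_per_gas=0.0, push_per_distension=0.0,
        gas_ct_ratio=0.8, gas_z_offset_ct=0.0,
    )
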