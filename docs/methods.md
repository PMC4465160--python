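# Methods

This note documents the models and numerical choices behind `cbctreg`: the
registration engine, the evaluation metrics, the rectal-distension score,
and — in most detail — the synthetic pelvis phantom, because the phantom
*is* the study population here and every quantitative claim the test suite
makes is conditional on it.

## Geometry conventions

All coordinates are physical millimetres.  Grids are axis-aligned (no
direction cosines — a deliberate restriction; the phantom and the pelvic
scans it emulates need none), voxel indices are 0-based, and a voxel's
position is its center: `x(i,j,k) = origin + (i,j,k)·spacing`.  A rigid
transform maps `p ↦ R(p−c) + c + t` with `R = Rz·Ry·Rx` (fixed order,
radians) about center `c`.  Composition and inversion are closed in this
parameterization (Euler angles are re-extracted from the composed matrix;
the gimbal-locked case `|ry| = 90°` folds the coupled rotation into rx —
irrelevant in practice at setup-error magnitudes).

Registration convention: **fixed = CBCT, moving = CT**.  The recovered
transform maps CBCT physical points into CT space, so planning contours are
propagated onto the CBCT grid by pull-back: the CBCT voxel at q receives
the CT mask value at t(q), nearest-neighbor interpolated (which preserves
binarity).  Images are resampled with linear interpolation, masks with
nearest-neighbor; points outside a volume's support take the modality air
value (−1000 HU for CT, −500 au for CBCT) or 0 for masks.

## The metric

Masked mean-subtracted NCC.  The sample set is: fixed-grid voxels where the
fixed mask is 1, whose mapped point lies inside the moving support (all
eight trilinear corners valid), and where the moving mask is 1 at the
nearest voxel.  Fewer than 100 samples is an error ("insufficient mask
overlap") — this guards the 1-mm-margin masks at coarse pyramid levels,
which are skipped and resolved at the next finer level.  Zero variance in
either channel ("degenerate intensities") is an error rather than a
spurious 0 or 1 — it is how a bony registration with no bone announces
itself.  The inner loop is a single sequential numba pass accumulating the
five sums in float64, so the value is deterministic and matches a direct
two-pass evaluation to ~1e-12.

## The optimizer

Deterministic gradient descent in a scaled parameter space: rotations are
multiplied by 50 mm/rad so one scaled unit ≈ 1 mm of motion at 50 mm from
the rotation center (about the prostate-to-bone distance).  The gradient is
estimated by central finite differences with perturbation 0.1 scaled units.
Each iteration moves one normalized-gradient step of length λ; λ starts at
0.5 and is multiplied by 0.7 whenever the gradient reverses direction
(negative dot product with the previous gradient); iteration stops when
λ < 0.1, when the scaled-gradient norm falls below 1e-5, or after 500
iterations.  The best-seen iterate is returned, and at the finest level the
caller's initialization is re-evaluated and kept if better — so the final
metric can never fall below the metric at the initialization (asserted in
the tests).  Three pyramid levels shrink by (4, 2, 1) after Gaussian
smoothing of (4, 2, 0) mm; masks are subsampled without smoothing.  The
rotation center is the fixed-grid center for global/bony registration and
the CTV centroid for the local refinement (this choice decouples rotation
from translation where it matters most).

Strategy specifics: *bony* registers the bone-clamped images (soft tissue
flattens to the threshold constant, leaving bone edges as the only signal)
inside body masks computed on the unclamped images, and is never
gas-filtered.  *Local* uses the margin-expanded CTV as the moving-side
mask, the CBCT body mask on the fixed side, and the bony result as
initialization.  *Contour registration* (the per-pair Dice ceiling)
Gaussian-smooths the two binary masks by one voxel to create gradients and
registers them with full-volume masks.

## Evaluation

Dice by voxel counting on a shared grid.  Surface distance: BLD per
reference surface point (forward nearest distance, maximized with the
distances of target points whose nearest reference point it is, ties to the
lowest index), averaged into BD over the ground-truth contour; surfaces are
the centers of 6-connected boundary voxels, so BD is resolution-dependent
(computed between voxelized surfaces, not meshes).  The BLD implementation
is chunked brute force rather than a k-d tree so that tie-breaking is
exactly reproducible; an O(n²) oracle asserts equality in the tests.
Summaries report the median and the sample (n−1) SD.  A registration
*fails* when its Dice falls below 95% of the no-registration Dice (strict
inequality; the no-registration Dice is computed after the isocenter offset
only).  An optional absolute cap at 0.95 — the manual-contour registration
ceiling mean 0.858 + 2.58·0.035 ≈ 0.95 — reflects the alternate reading of
the failure rule and is exposed as a flag, not the default.

## The distension score F

`F = |(Ī_CBCT,r − Ī_CBCT,p) − (Ī_CT,r − Ī_CT,p)|` with the `r` means over
R_partial (CT rectum ∩ CTV expanded by the F margin, default 8 mm) and the
`p` means over the CT prostate mask.  CBCT means are obtained by sampling
the CBCT with linear interpolation at the masked CT-grid points mapped
through the bony alignment (pull-back), avoiding any mask resampling; the
two routes agree to interpolation tolerance, verified against a direct
voxel-mean oracle.  F is always computed on **unfiltered** images — the gas
filter would erase the signal F exists to measure.  Subtracting the
prostate means cancels any constant CBCT intensity shift exactly (asserted
numerically); a multiplicative gain is *not* cancelled — on constant
images F(a) = |a·Δ_CBCT − Δ_CT| — a documented limitation inherited from
the score's definition.  The default cutoff is 104.4 au, the midpoint of
the all-success bound F1 = 61.2 and the all-failure bound F2 = 147.6;
prediction is strict (`F > cutoff`).

## The phantom

Constructive solid geometry rasterized at voxel centers, with fixed
precedence gas > bone > prostate > bladder > rectum > tissue > exterior, so
organ masks are pairwise disjoint by construction.  The body is an elliptic
cylinder (72 × 64 mm semi-axes); bones are two iliac ellipsoids plus a
sacral block; the prostate (20/17/18 mm semi-axes, 40 HU) abuts the rectum
(radius 12 mm tube, posterior); the bladder (10 HU) sits superior-anterior.
CT: 160×160×60 at 1×1×3 mm; CBCT: 160×160×168 at 1×1×1 mm (the reduced
`coarse()` grids, 108×108×44 at 1.5×1.5×3 and 108×108×84 at 1.5 mm, are
used for cohort-scale runs; the documented problem sizes below say which).
Ground-truth CBCT masks are rasterized analytically on the CBCT grid from
the transformed shapes — never resampled CT masks — and agree with
pulled-back CT masks at Dice ≥ 0.95 (discretization-limited).

**Intensity model.**  CT tissue 30 HU, prostate 40, bladder 10, bone 700,
gas −1000, exterior −1000.  The CBCT is `a·I + b + ε`, ε ~ N(0, σ²),
evaluated on the anatomy moved by the setup transform.  The gain is
a = 0.9; the offset is **b = −140 − 150·a = −275 au**, derived from the
bone-threshold correspondence (150 HU on CT ↔ −140 au on CBCT).  This
calibration is what makes the published threshold semantics hold inside the
phantom: CBCT soft tissue sits near −250 au, so the −140 au bone clamp
actually isolates bone, and the −500 au gas clamp is a genuinely
tissue-range ("tissue-equivalent") replacement.  Noise is σ = 5 au by
default: the phantom's organs are perfectly homogeneous, so σ is chosen to
keep the prostate-boundary contrast-to-noise on CBCT comparable to clinical
scans rather than to match raw CBCT noise magnitudes.

**Soft-tissue texture.**  Real CT and CBCT share anatomical structure; a
phantom without it gives the NCC almost no true soft-tissue signal, and the
local registration is then dominated by mask-boundary artifacts (the metric
can "improve" by pushing mismatched voxels out of the mask intersection).
The phantom therefore carries a smooth random field fixed to the anatomy
(white noise on an 8-mm lattice, trilinearly interpolated, σ = 20 HU,
clipped at ±3σ so tissue never crosses the bone or gas thresholds), sampled
identically by both scans wherever the anatomy maps.  Organ interiors are
more homogeneous than fat/muscle and carry 30% of the amplitude.  The
prostate's displacement is carried into the surrounding texture by a
Gaussian falloff field (weight 1 inside the gland, 15-mm falloff outside),
so tissue within the local registration margin moves essentially with the
gland — the coherent-neighborhood assumption on which margin-based local
registration rests.

**Rectal filling.**  `distension_factor ≥ 1` scales the CBCT rectum radius.
Gas occupies a coaxial core (`radius = √g · (r − 1.5 mm)`) of the
peri-prostatic lumen; when a side has gas the core is wrapped in 3 mm of
solid *content* at −120 HU — dark, but above the gas thresholds.  The
empty-rectum protocol case (no gas, no distension) renders the rectum as
plain tissue, within 15 HU of the prostate mean.  This content model is
what gives the replace-gas filter its clinically observed effect: the
filter clamps the gas core into the content range (CT −1000 → −150; CBCT
−1175 → −500 vs. content at −383), removing the dominant misleading
contrast while leaving the unfilterable soft content in place.  An optional
axial offset of the CT gas pocket models gas that moved between the scans,
and optional ±150 au streak lines through gas-pocket centers model
reconstruction artifacts (both off by default).

**Cohorts.**  `make_cohort` draws setup errors uniformly within ±8 mm and
±3° per axis (defaults) and prostate offsets as an anterior push
proportional to gas and distension plus jitter, capped at 6 mm.
`recovery_cohort` (20 clean pairs, full resolution) exercises transform
recovery.  `stress_cohort` is the failure-prone configuration: setup errors
±5 mm / ±2° — calibrated so the no-registration Dice median (~0.75) sits
near the clinically reported 0.73 — small (≤2 mm) prostate offsets, gas
graded over 0–0.85 with the CT pocket holding 80% of the CBCT fraction,
and distension 1 + g/2.  Under these conditions the unfiltered 8-mm local
registration genuinely fails (ends below 95% of the no-registration Dice)
on the highest-gas pairs, the filtered arm does not, and the failing pairs
carry the largest F values — the qualitative pattern of the clinical
cohort, reproduced mechanistically rather than numerically.

**What the phantom does not model** — and hence what passing tests do not
show about real data: CBCT scatter, cupping and beam-hardening; cone-beam
reconstruction geometry; deformable organ motion (the prostate moves as a
rigid body, per the standard first-order assumption); seminal vesicles;
inter-observer contour variability (ground truth is exact here, so absolute
Dice values run higher than clinical ones and the manual-contour ceiling is
not reproduced); and realistic CBCT noise texture.  Failure *counts* on
phantom cohorts are qualitative analogues of the clinical tables, not
estimates of them.

## Problem sizes and determinism

The test suite and the acceptance script use: 20 full-resolution pairs for
transform recovery (bony within 1 mm / 0.5°, local prostate error within
1 mm at offsets ≤ 6 mm); a 20-pair reduced-grid stress cohort for the
filter-effect and failure-prediction checks; 11 reduced-grid pairs for the
F-versus-gas trend (Spearman ρ > 0.9; F saturates above g ≈ 0.7 as
R_partial fills with gas, which bounds ρ below 1); and a 2-pair cohort run
twice for byte-level determinism of the CSV reports.  Every random draw
descends from a single seed through `numpy` SeedSequence spawning; there is
no other source of randomness (the optimizer is deterministic), so
identical inputs and configuration give bit-identical results.

## Known limitations

- NCC with a moving-side region mask can still prefer transforms that push
  mismatched structures across the mask boundary (sample-set change); the
  100-sample floor bounds, but does not remove, this effect.  It is the
  mechanism behind the phantom's local-registration failures — plausibly
  also a mechanism in the clinical failures — and the reason the bony
  fallback and the F gate exist.
- BD is computed between voxel surfaces; its absolute values shrink with
  grid refinement and should only be compared within one resolution.
- F mixes CT and CBCT intensity units by subtraction; it is invariant to a
  CBCT offset but not to a gain change.
- The Euler-angle parameterization is adequate for setup-scale rotations
  (≤ a few degrees) but would need care near gimbal lock.
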