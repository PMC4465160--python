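# cbctreg

Automatic CT-to-CBCT setup correction for prostate radiotherapy, with
rectal-distension scoring — exercised end to end on a synthetic pelvis
phantom with known ground truth.

## The problem

Before each treatment fraction of prostate radiotherapy, the daily
cone-beam CT (CBCT) must be aligned to the planning CT so the target is
irradiated where it actually is.  The prostate moves relative to the pelvic
bones — mostly pushed by rectal filling — so a bone-based alignment alone
leaves a residual target error, while a soft-tissue alignment can be misled
by the very thing that moved the gland: gas and stool in the rectum.

`cbctreg` implements the automatic correction pipeline and its quality
assurance:

- **Rigid registration engine** — 6-DOF transforms, a masked
  mean-subtracted normalized cross-correlation (NCC) metric
  `NCC = Σ(f−f̄)(m−m̄) / √(Σ(f−f̄)² Σ(m−m̄)²)` computed over the
  intersection of the two image masks (invariant to the CBCT's uncalibrated
  linear intensity scale), a deterministic relaxed gradient-descent
  optimizer (step 0.5, relaxation 0.7 on gradient reversal, step tolerance
  0.1, gradient tolerance 1e-5, ≤500 iterations) and a 3-level
  multi-resolution pyramid.
- **Three strategies** — *global* (body masks), *bony* (images clamped
  below the bone threshold: 150 HU on CT, −140 au on CBCT), and *local*
  soft-tissue refinement of the bony result inside the clinical target
  volume (CTV) expanded by a 1–20 mm margin.
- **Pre-processing** — plan-isocenter offset, body masking, bone clamping,
  replace-gas-by-tissue filtering (clamp below −150 HU / −500 au), and
  anisotropy-aware margin expansion in physical mm.
- **Evaluation** — Dice coefficient `2|A∩B|/(|A|+|B|)` between propagated
  and reference contours, the bidirectional local distance (BLD) averaged
  into a surface distance BD, and the failure rule *Dice_after < 0.95 ·
  Dice_without-registration*.
- **Rectal-distension score** —
  `F = |(Ī_CBCT,r − Ī_CBCT,p) − (Ī_CT,r − Ī_CT,p)|`, mean intensities in
  the peri-prostatic rectum portion (R_partial = rectum ∩ expanded CTV) and
  in the prostate, after bony alignment; needs **only the planning-CT
  contours**.  `F > 104.4` au (midpoint of the published all-success /
  all-failure bounds 61.2 and 147.6) predicts local-registration failure,
  usable as a pre-treatment QA gate.
- **Pelvis phantom** — paired CT (1×1×3 mm) / CBCT (1 mm) volumes with
  constructive anatomy, shared soft-tissue texture, an uncalibrated linear
  CBCT intensity map, rigid setup error, independent prostate displacement,
  and graded rectal distension/gas with known ground-truth transforms and
  contours, so every claim above is testable without patient data.

## Worked example

```python
import dataclasses
from cbctreg import (PhantomSpec, generate_pair, register_bony, register_local,
                     propagate_contour, dice, dice_noreg)
from cbctreg.distension import compute_rpartial, compute_F
from cbctreg.transform import RigidTransform

spec = dataclasses.replace(
    PhantomSpec().coarse(),                       # reduced grid for speed
    setup_transform=RigidTransform(translations=(4.0, -3.0, 2.0)),
    prostate_offset=(0.0, -4.0, 0.0),             # gland pushed anteriorly
    gas_fraction=0.5, gas_fraction_ct=0.4, distension_factor=1.25,
    seed=42,
)
pair = generate_pair(spec)

bony = register_bony(pair.ct, pair.cbct)
local = register_local(pair.ct, pair.cbct, pair.ct_structs["ctv"], 8.0, bony)

manual = pair.cbct_structs_truth["ctv"]
d0 = dice_noreg(pair.ct_structs["ctv"], manual)
db = dice(propagate_contour(pair.ct_structs["ctv"], bony.transform, pair.cbct.grid), manual)
dl = dice(propagate_contour(pair.ct_structs["ctv"], local.transform, pair.cbct.grid), manual)

rpartial = compute_rpartial(pair.ct_structs["rectum"], pair.ct_structs["ctv"], 8.0)
dist = compute_F(pair.ct, pair.cbct, bony.transform.inverse(),
                 pair.ct_structs["ctv"], rpartial)

print(f"Dice without registration: {d0:.3f}")
print(f"Dice after bony RR:        {db:.3f}")
print(f"Dice after 8-mm local RR:  {dl:.3f}")
print(f"rectal distension F = {dist.F:.1f} au "
      f"(cutoff {dist.cutoff:.1f}, predicted failure: {dist.predicted_failure})")
```

prints

```
Dice without registration: 0.654
Dice after bony RR:        0.822
Dice after 8-mm local RR:  0.943
rectal distension F = 332.0 au (cutoff 104.4, predicted failure: True)
```

The setup error alone leaves a 0.654 overlap; aligning the bones fixes the
couch error but not the 4 mm gland displacement (0.822); the 8-mm local
refinement recovers the gland (0.943).  The large F value correctly flags
this as a high-distension pair — the regime in which unfiltered local
registrations are at risk (here the registration still succeeded; the gate
is deliberately conservative).

A command-line interface mirrors the library: `cbctreg simulate`,
`cbctreg preprocess …`, `cbctreg register {global,bony,local,contours}`,
`cbctreg distension` (exit code usable as a QA gate) and `cbctreg run` for
a full phantom-cohort study writing per-pair and summary CSVs.

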