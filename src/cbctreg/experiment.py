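"""Orchestration of the full setup-correction study on a cohort of pairs.

For every CT/CBCT pair and every configured method (global, bony, local
with a margin), the pipeline runs isocenter offset → registration →
contour propagation → Dice / BD / failure evaluation, plus the
rectal-distension score F with its failure prediction.  Summaries (median,
SD, failure count per method) and an F-sorted per-pair report are emitted
as CSV.  Everything is deterministic under a fixed seed and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cbctreg import distension as dist_mod
from cbctreg import evalmetrics as em
from cbctreg import rigidreg as rr
from cbctreg.phantom import PhantomPair
from cbctreg.preprocess import ThresholdConfig, apply_isocenter_offset, compute_body_mask
from cbctreg.volgrid import BinaryMask, ImageVolume, StructureSet

__all__ = ["ExperimentConfig", "run_pair", "run_experiment", "ALLOWED_MARGINS"]

ALLOWED_MARGINS = (1.0, 3.0, 5.0, 8.0, 10.0, 12.0, 15.0, 20.0)


def _parse_method(name: str) -> tuple[str, float | None]:
    if name in ("global", "bony"):
        return name, None
    if name.startswith("local-"):
        margin = float(name.split("-", 1)[1])
        if margin not in ALLOWED_MARGINS:
            raise ValueError(f"local margin {margin} mm not in {ALLOWED_MARGINS}")
        return "local", margin
    raise ValueError(f"unknown method '{name}' (use global, bony or local-<margin>)")


@dataclass(frozen=True)
class ExperimentConfig:
    """Methods, arms and parameters for one experiment run."""

    methods: tuple[str, ...] = ("global", "bony", "local-8")
    filter_gas_arms: tuple[bool, ...] = (False,)
    reg: rr.RegConfig = field(default_factory=rr.RegConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    f_margin: float = 8.0
    f_cutoff: float | None = None  # None -> distension.default_cutoff()
    f_method: str = "local-8"      # method whose failures F is meant to predict
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.methods:
            raise ValueError("at least one method is required")
        for m in self.methods:
            _parse_method(m)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pair(
    ct: ImageVolume,
    ct_structs: StructureSet,
    cbct: ImageVolume,
    cbct_manual_ctv: BinaryMask | None,
    cfg: ExperimentConfig = ExperimentConfig(),
    filter_gas: bool = False,
    ct_isocenter=(0.0, 0.0, 0.0),
    bony_result: rr.RegistrationResult | None = None,
    pair_id: str = "pair-0",
) -> em.PairEvaluation:
    """Run every configured method on one pair and evaluate it.

    A stage error in one method is recorded in its cell; the other methods
    continue.  ``bony_result`` may be supplied to share the (never
    gas-filtered) bony registration across filtering arms.
    """
    ct, ct_structs = apply_isocenter_offset(ct, ct_structs, ct_isocenter)
    body_ct = compute_body_mask(ct, cfg.thresholds)
    body_cbct = compute_body_mask(cbct, cfg.thresholds)

    d_noreg = float("nan")
    if cbct_manual_ctv is not None:
        d_noreg = em.dice_noreg(ct_structs["ctv"], cbct_manual_ctv)

    ev = em.PairEvaluation(pair_id=pair_id, dice_noreg=d_noreg)

    needs_bony = bony_result is None and (
        "bony" in cfg.methods or any(m.startswith("local-") for m in cfg.methods)
    )
    bony_error: str | None = None
    if needs_bony:
        try:
            bony_result = rr.register_bony(
                ct, cbct, cfg.reg, cfg.thresholds, body_ct=body_ct, body_cbct=body_cbct
            )
        except Exception as exc:
            bony_error = f"{type(exc).__name__}: {exc}"
    if bony_result is not None and bony_error is None:
        ev.registrations["bony"] = bony_result

    results: dict[str, rr.RegistrationResult | None] = {}
    errors: dict[str, str | None] = {}
    for name in cfg.methods:
        kind, margin = _parse_method(name)
        try:
            if kind == "global":
                res = rr.register_global(
                    ct, cbct, cfg.reg, filter_gas, cfg.thresholds,
                    body_ct=body_ct, body_cbct=body_cbct,
                )
            elif kind == "bony":
                if bony_error is not None:
                    raise RuntimeError(bony_error)
                res = bony_result
            else:
                if bony_error is not None:
                    raise RuntimeError(f"bony initialization failed: {bony_error}")
                res = rr.register_local(
                    ct, cbct, ct_structs["ctv"], margin, bony_result, cfg.reg,
                    filter_gas, cfg.thresholds, body_cbct=body_cbct,
                )
            results[name], errors[name] = res, None
            ev.registrations[name] = res
        except Exception as exc:
            results[name], errors[name] = None, f"{type(exc).__name__}: {exc}"

    for name in cfg.methods:
        if errors[name] is not None:
            ev.methods[name] = em.MethodEval(float("nan"), float("nan"), False, errors[name])
            continue
        if cbct_manual_ctv is None:
            ev.methods[name] = em.MethodEval(float("nan"), float("nan"), False, "no manual CTV")
            continue
        res = results[name]
        prop = rr.propagate_contour(ct_structs["ctv"], res.transform, cbct_manual_ctv.grid)
        d_after = em.dice(prop, cbct_manual_ctv)
        bd_mm = em.bd(cbct_manual_ctv, prop)
        ev.methods[name] = em.MethodEval(d_after, bd_mm, em.is_failure(d_after, d_noreg))

    # rectal-distension score on the unfiltered images, from CT contours only
    if bony_result is not None and bony_error is None:
        try:
            rpart = dist_mod.compute_rpartial(ct_structs["rectum"], ct_structs["ctv"], cfg.f_margin)
            dres = dist_mod.compute_F(
                ct, cbct, bony_result.transform.inverse(), ct_structs["ctv"], rpart,
                cutoff=cfg.f_cutoff,
            )
            ev.F = dres.F
            ev.predicted_failure = dres.predicted_failure
        except ValueError:
            pass  # empty R_partial: F stays NaN
    return ev


def run_experiment(cohort: list[PhantomPair], cfg: ExperimentConfig = ExperimentConfig()):
    """Run all methods and arms over a phantom cohort.

    Returns ``(per_pair, summary, f_report)`` DataFrames and, when
    ``cfg.output_dir`` is set, writes ``per_pair.csv``, ``summary.csv``,
    ``f_report.csv`` and a manifest with the configuration hash.  Phantom
    truth CBCT masks stand in for manual CBCT contours.
    """
    if not cohort:
        raise ValueError("empty cohort")

    rows = []
    evals_by_arm: dict[bool, list[em.PairEvaluation]] = {a: [] for a in cfg.filter_gas_arms}
    for pair in cohort:
        bony_shared: rr.RegistrationResult | None = None
        for arm in cfg.filter_gas_arms:
            ev = run_pair(
                pair.ct, pair.ct_structs, pair.cbct,
                pair.cbct_structs_truth["ctv"], cfg, filter_gas=arm,
                ct_isocenter=pair.spec.ct_isocenter,
                bony_result=bony_shared, pair_id=pair.pair_id,
            )
            if bony_shared is None:
                bony_shared = ev.registrations.get("bony")
            evals_by_arm[arm].append(ev)
            for name, me in ev.methods.items():
                rows.append(
                    dict(
                        pair_id=pair.pair_id, filter_gas=arm, method=name,
                        dice_noreg=ev.dice_noreg, dice_after=me.dice_after,
                        bd_mm=me.bd_mm, failed=me.failed,
                        error=me.error if me.error is not None else "",
                        F=ev.F, predicted_failure=ev.predicted_failure,
                    )
                )
    per_pair = pd.DataFrame(rows)

    srows = []
    for arm in cfg.filter_gas_arms:
        for name in cfg.methods:
            s = em.summarize(evals_by_arm[arm], name)
            srows.append(
                dict(
                    filter_gas=arm, method=name,
                    dice_median=round(s.dice_median, 3), dice_sd=round(s.dice_sd, 3),
                    bd_median_mm=round(s.bd_median_mm, 2), bd_sd_mm=round(s.bd_sd_mm, 2),
                    n_failed=s.n_failed, n_pairs=s.n_pairs,
                )
            )
    summary = pd.DataFrame(srows)

    # F-sorted report for the designated method, first arm
    arm0 = cfg.filter_gas_arms[0]
    f_rows = []
    for ev in dist_mod.sort_pairs_by_F(evals_by_arm[arm0]):
        me = ev.methods.get(cfg.f_method)
        f_rows.append(
            dict(
                pair_id=ev.pair_id, F=ev.F,
                failed=me.failed if me is not None else "",
                predicted_failure=ev.predicted_failure,
            )
        )
    f_report = pd.DataFrame(f_rows)

    if cfg.output_dir:
        os.makedirs(cfg.output_dir, exist_ok=True)
        kw = dict(index=False, float_format="%.10g", lineterminator="\n")
        per_pair.to_csv(os.path.join(cfg.output_dir, "per_pair.csv"), **kw)
        summary.to_csv(os.path.join(cfg.output_dir, "summary.csv"), **kw)
        f_report.to_csv(os.path.join(cfg.output_dir, "f_report.csv"), **kw)
        manifest = dict(
            config=dataclasses.asdict(cfg), config_hash=cfg.config_hash(),
            n_pairs=len(cohort), pair_ids=[p.pair_id for p in cohort],
        )
        with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return per_pair, summary, f_report
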