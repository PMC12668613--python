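"""End-to-end analysis pipeline: simulate -> fit -> equipoise -> cohorts ->
incentives -> evaluate, with a YAML config, on-disk stage artifacts and a
run manifest of content digests for reproducibility checks.

Every stage reads only on-disk artifacts of earlier stages, so any
figure-equivalent table can be regenerated without hidden state, and two
runs with the same config and seed produce digest-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohorts as coh
from . import equipoise as eq
from . import metrics as met
from . import registry as reg
from . import survival as surv
from .errors import ConfigurationError, XenoeqError
from .incentives import ModelSet, ScenarioParams, incentivized_fractions

log = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "equipoise", "cohorts", "incentives",
          "evaluate")

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "xenoeq_run",
    "generator": {"n_patients": 10_000, "n_centers": 20, "n_donors": 3_000},
    "model": {"backend": "cox", "horizon": 25.0},
    "assumptions": {"n_grid": [0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0],
                    "q": 75.0, "relist_level": "cohort"},
    "scenarios": {"priority_multiplier": 5.0,
                  "which": ["base", "inactive_accrual",
                            "living_donor_priority", "highest_priority"],
                  "cohort_ids": [1, 2, 3, 4]},
    "metrics": {"min_correct": 15,
                "censor_policy": "exclude_censored_before_tau"},
}

_ALLOWED = {
    "": {"seed", "output_dir", "generator", "model", "assumptions",
         "scenarios", "metrics"},
    "model": {"backend", "horizon"},
    "assumptions": {"n_grid", "q", "relist_level"},
    "scenarios": {"priority_multiplier", "which", "cohort_ids"},
    "metrics": {"min_correct", "censor_policy"},
}


class MissingArtifactError(XenoeqError):
    """An upstream stage's output is absent."""


def load_config(path=None, seed=None, output_dir=None) -> dict:
    """Load and validate a pipeline config, merged over the defaults.

    Unknown keys are rejected with the offending field path.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError("config root must be a mapping")
        for key, val in user.items():
            if key not in _ALLOWED[""]:
                raise ConfigurationError(f"unknown config key '{key}'")
            if isinstance(val, dict) and key != "generator":
                for sub in val:
                    if sub not in _ALLOWED[key]:
                        raise ConfigurationError(
                            f"unknown config key '{key}.{sub}'")
                cfg[key].update(val)
            else:
                cfg[key] = val
    if seed is not None:
        cfg["seed"] = int(seed)
    if output_dir is not None:
        cfg["output_dir"] = str(output_dir)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    a = cfg["assumptions"]
    if "n_grid" not in a or not a["n_grid"]:
        raise ConfigurationError("missing required field 'assumptions.n_grid'")
    try:
        eq.XenoAssumptions(n_grid=tuple(a["n_grid"]), q=a.get("q", 75.0))
    except XenoeqError as e:
        raise ConfigurationError(f"assumptions.n_grid: {e}") from e
    if cfg["model"]["backend"] not in ("cox",):
        raise ConfigurationError(
            "model.backend: the pipeline runs the cox backend "
            "(rsf/km are available through the library API)")
    for s in cfg["scenarios"]["which"]:
        if s not in ("base", "inactive_accrual", "living_donor_priority",
                     "highest_priority"):
            raise ConfigurationError(f"scenarios.which: unknown scenario '{s}'")
    try:
        reg.GeneratorConfig(seed=int(cfg["seed"]), **cfg["generator"])
    except (TypeError, ConfigurationError) as e:
        raise ConfigurationError(f"generator: {e}") from e


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _update_manifest(out: Path, cfg: dict, stage: str, artifacts) -> None:
    mpath = out / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {
        "config_hash": _config_hash(cfg), "seed": cfg["seed"],
        "software_version": _version(), "stages": {}}
    manifest["stages"][stage] = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "digests": {p.name: _digest(p) for p in artifacts},
    }
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _version() -> str:
    from . import __version__
    return __version__


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def _need(path: Path, what: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing upstream artifact for {what}: {path}")
    return path


def _load_models(out: Path) -> ModelSet:
    blob = json.loads(_need(out / "models.json", "models").read_text())
    return ModelSet(**{t: surv.FittedSurvivalModel.from_dict(d)
                       for t, d in blob.items()})


def _active(patients: pd.DataFrame) -> pd.DataFrame:
    return patients[patients["active"]].reset_index(drop=True)


# --------------------------------------------------------------------------
# stages

def stage_simulate(cfg: dict, out: Path):
    gcfg = reg.GeneratorConfig(seed=int(cfg["seed"]), **cfg["generator"])
    bundle = reg.generate_registry(gcfg)
    reg.write_registry(bundle, out / "registry")
    return [out / "registry" / f for f in
            ("patients.csv", "donors.csv", "offers.csv", "config.json")]


def stage_fit(cfg: dict, out: Path):
    bundle = reg.read_registry(_need(out / "registry", "fit"))
    patients = _active(bundle.patients)
    horizon = float(cfg["model"]["horizon"])
    blob = {}
    for target in surv.TARGETS:
        model = surv.fit_model(patients, target, backend="cox",
                               horizon=horizon, seed=int(cfg["seed"]))
        blob[target] = model.to_dict()
    (out / "models.json").write_text(
        json.dumps(blob, indent=2, sort_keys=True))
    return [out / "models.json"]


def _assumptions(cfg) -> eq.XenoAssumptions:
    a = cfg["assumptions"]
    return eq.XenoAssumptions(n_grid=tuple(a["n_grid"]), q=a["q"])


def stage_equipoise(cfg: dict, out: Path):
    bundle = reg.read_registry(_need(out / "registry", "equipoise"))
    models = _load_models(out)
    patients = _active(bundle.patients)
    assumptions = _assumptions(cfg)
    relist = eq.estimate_relist_probability(
        patients, level=cfg["assumptions"]["relist_level"],
        patients=patients)
    results = eq.identify_viable(patients, models, assumptions,
                                 relist=relist, donors=bundle.donors)
    table = eq.sensitivity_table(results,
                                 expected_grid=assumptions.n_grid)
    return [_write_csv(results, out / "equipoise_results.csv"),
            _write_csv(table, out / "sensitivity.csv")]


def stage_cohorts(cfg: dict, out: Path):
    bundle = reg.read_registry(_need(out / "registry", "cohorts"))
    patients = _active(bundle.patients)
    agg = coh.aggressiveness(bundle.offers,
                             center_ids=range(bundle.ground_truth.n_centers))
    assignments = coh.assign_cohorts_frame(patients, coh.tertile_map(agg))
    artifacts = [_write_csv(agg, out / "aggressiveness.csv"),
                 _write_csv(assignments, out / "cohort_assignments.csv")]

    res_path = out / "equipoise_results.csv"
    if res_path.exists():
        results = pd.read_csv(res_path)
        table = eq.sensitivity_table(results, assignments=assignments)
        artifacts.append(_write_csv(table, out / "cohort_sensitivity.csv"))

    rows = []
    for cdef in coh.DEFAULT_COHORTS:
        members = patients.merge(
            assignments[assignments["cohort_id"] == cdef.cohort_id],
            on="patient_id")
        if len(members) == 0:
            log.info("cohort %d is empty; skipped", cdef.cohort_id)
            continue
        report = coh.cohort_report(members)
        for kind in ("survival", "time_to_transplant"):
            band = report[kind]
            if band.suppressed:
                log.info("cohort %d %s curve suppressed (%d events)",
                         cdef.cohort_id, kind, band.n_events)
                continue
            y = (band.curve.probabilities if kind == "survival"
                 else band.curve.cumulative_probability)
            for t, v, lo, hi in zip(band.curve.times, y, band.lower,
                                    band.upper):
                rows.append({"cohort_id": cdef.cohort_id, "kind": kind,
                             "time": t, "value": v, "lower": lo,
                             "upper": hi, "size": report["size"]})
    curves = pd.DataFrame(rows, columns=["cohort_id", "kind", "time",
                                         "value", "lower", "upper", "size"])
    artifacts.append(_write_csv(curves, out / "cohort_curves.csv"))
    return artifacts


def stage_incentives(cfg: dict, out: Path):
    bundle = reg.read_registry(_need(out / "registry", "incentives"))
    models = _load_models(out)
    patients = _active(bundle.patients)
    assignments = pd.read_csv(
        _need(out / "cohort_assignments.csv", "incentives"))
    cohort_ids = list(cfg["scenarios"]["cohort_ids"])
    sub = assignments[assignments["cohort_id"].isin(cohort_ids)]
    pats = patients[patients["patient_id"].isin(sub["patient_id"])] \
        .reset_index(drop=True)
    if len(pats) == 0:
        raise XenoeqError("no patients in the requested incentive cohorts")
    relist = eq.estimate_relist_probability(patients, level="cohort")
    scen = [ScenarioParams(scenario=s,
                           q=float(cfg["assumptions"]["q"]),
                           priority_multiplier=float(
                               cfg["scenarios"]["priority_multiplier"]),
                           horizon=float(cfg["model"]["horizon"]))
            for s in cfg["scenarios"]["which"]]
    report = incentivized_fractions(pats, sub, scen, _assumptions(cfg),
                                    models, bundle.donors,
                                    relist.probability)
    for r in report[report["suppressed"]].itertuples():
        log.info("incentive row suppressed: cohort %d scenario %s n=%g",
                 r.cohort_id, r.scenario, r.n)
    return [_write_csv(report, out / "incentive_report.csv")]


def stage_evaluate(cfg: dict, out: Path):
    bundle = reg.read_registry(_need(out / "registry", "evaluate"))
    results = pd.read_csv(_need(out / "equipoise_results.csv", "evaluate"))
    patients = _active(bundle.patients)
    le = results.drop_duplicates("patient_id").set_index(
        "patient_id")["le_status_quo"]
    outcomes = patients[["patient_id", "outcome_type", "outcome_time"]]
    rows = []
    for tau in _assumptions(cfg).n_grid:
        mcfg = met.MetricsConfig(tau=float(tau),
                                 min_correct=int(cfg["metrics"]["min_correct"]))
        rep = met.evaluate(le, outcomes, mcfg)
        if rep.suppressed:
            log.info("metrics at tau=%g suppressed (n_correct=%d)", tau,
                     rep.n_correct)
        if rep.hit_rate is None or rep.capture_rate is None:
            log.info("metrics at tau=%g has an undefined rate", tau)
        rows.append(rep.to_dict())
    df = pd.DataFrame(rows)
    return [_write_csv(df, out / "metrics.csv")]


_STAGE_FNS = {"simulate": stage_simulate, "fit": stage_fit,
              "equipoise": stage_equipoise, "cohorts": stage_cohorts,
              "incentives": stage_incentives, "evaluate": stage_evaluate}


def run(stage: str, config=None, seed=None, output_dir=None) -> list:
    """Run one stage or ``all``; returns the artifact paths written.

    ``config`` may be a path to a YAML file or an already-validated dict.
    """
    if stage != "all" and stage not in STAGES:
        raise ConfigurationError(
            f"unknown stage '{stage}'; expected one of {STAGES + ('all',)}")
    cfg = config if isinstance(config, dict) else \
        load_config(config, seed=seed, output_dir=output_dir)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = STAGES if stage == "all" else (stage,)
    written = []
    for st in stages:
        log.info("running stage %s", st)
        artifacts = _STAGE_FNS[st](cfg, out)
        _update_manifest(out, cfg, st, artifacts)
        written.extend(artifacts)
    return written


def output_digests(output_dir) -> dict:
    """Stable name -> sha256 digest map of a run's artifacts (manifest and
    its timestamps excluded)."""
    out = Path(output_dir)
    files = sorted(p for p in out.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    return {str(p.relative_to(out)): _digest(p) for p in files}
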