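"""Survival model fitting and per-patient curve prediction.

Three right-censored targets are supported on a registry's patient table:

* ``waitlist_death`` — time from listing to death-or-delisting, with
  transplant and administrative censoring treated as censoring events;
* ``time_to_transplant`` — time from listing to transplant, with death
  treated as censoring (a competing-risks cumulative-incidence variant is
  available via :func:`cumulative_incidence`);
* ``post_transplant_death`` — time from transplant to death among
  recipients, including the matched donor's quality as a covariate.

Backends: Cox proportional hazards (lifelines, Efron ties), random survival
forest (scikit-survival) and Kaplan-Meier.  Every fitted model predicts a
valid :class:`~xenoeq.curves.SurvivalCurve` on a monthly grid up to the
horizon; beyond the last observed event time the curve is carried forward at
its last value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from . import registry as reg
from .curves import (MONTH, CurveWithBand, IncidenceCurve, SurvivalCurve,
                     time_grid)
from .errors import (EstimationError, MissingCovariateError,
                     UnsupportedBackendError, XenoeqError)

log = logging.getLogger(__name__)

TARGETS = ("waitlist_death", "time_to_transplant", "post_transplant_death")
BACKENDS = ("cox", "rsf", "km")

DEFAULT_COVARIATES = {
    "waitlist_death": ["diabetes", "age_c", "albumin_c", "sdi_c"],
    "time_to_transplant": ["blood_B", "blood_AB", "blood_O", "cpra_frac",
                           "previous_transplant", "age_c", "diabetes"],
    "post_transplant_death": ["age_c", "diabetes", "donor_quality"],
}

MIN_EVENTS_WARN = 50
SUPPRESSION_EVENTS = 15


def _target_frame(records: pd.DataFrame, target: str):
    """(duration, event, raw-records) arrays for a fitting target."""
    if target == "waitlist_death":
        return (records["outcome_time"].to_numpy(float),
                (records["outcome_type"] == "death_or_delisting").to_numpy(),
                records)
    if target == "time_to_transplant":
        return (records["outcome_time"].to_numpy(float),
                (records["outcome_type"] == "transplant").to_numpy(),
                records)
    if target == "post_transplant_death":
        sub = records[records["outcome_type"] == "transplant"]
        return (sub["post_tx_time"].to_numpy(float),
                sub["post_tx_event"].to_numpy(bool), sub)
    raise XenoeqError(f"unknown target {target!r}; expected one of {TARGETS}")


def _design(records: pd.DataFrame, covariates) -> pd.DataFrame:
    try:
        X = reg.design_matrix(records)
    except KeyError as e:
        raise MissingCovariateError(f"patient records lack field {e}") from e
    missing = [c for c in covariates if c not in X.columns]
    if missing:
        raise MissingCovariateError(
            f"missing covariate '{missing[0]}' for prediction")
    return X[list(covariates)].astype(float)


def _step_interp(grid, times, values, left=1.0):
    """Right-continuous step interpolation of a step function onto ``grid``."""
    idx = np.searchsorted(times, grid, side="right") - 1
    out = np.where(idx >= 0, np.asarray(values)[np.maximum(idx, 0)], left)
    return out


@dataclass
class FittedSurvivalModel:
    """A fitted survival model with a deterministic curve-prediction path.

    Cox and KM models are reduced at fit time to arrays (coefficients,
    covariate means, baseline survival on the monthly grid), so prediction
    is a vectorized power transform and serialization is plain JSON.  RSF
    models keep the fitted forest (with its recorded seed) in memory.
    """

    backend: str
    target: str
    covariates: list
    horizon: float
    time_step: float = MONTH
    seed: int | None = None
    coefs: dict = field(default_factory=dict)       # cox
    means: dict = field(default_factory=dict)       # cox centering
    coef_se: dict = field(default_factory=dict)     # cox
    baseline_survival: np.ndarray | None = None     # cox / km, on the grid
    n_events: int = 0
    dropped_covariates: list = field(default_factory=list)
    _rsf: object = None

    @property
    def grid(self) -> np.ndarray:
        return time_grid(self.horizon, self.time_step)

    # -- prediction ---------------------------------------------------------

    def predict_matrix(self, records: pd.DataFrame) -> np.ndarray:
        """Survival probabilities, shape (n_patients, n_grid_times)."""
        grid = self.grid
        if self.backend == "km":
            return np.tile(self.baseline_survival, (len(records), 1))
        X = _design(records, self.covariates)
        if self.backend == "cox":
            lp = self.linear_predictor(X)
            s0 = np.clip(self.baseline_survival, 1e-300, 1.0)
            S = s0[None, :] ** np.exp(lp)[:, None]
            S[:, 0] = 1.0
            return S
        if self.backend == "rsf":
            fns = self._rsf.predict_survival_function(
                X.to_numpy(), return_array=True)
            S = np.empty((len(records), len(grid)))
            for i, row in enumerate(fns):
                S[i] = _step_interp(grid, self._rsf.unique_times_, row)
            S[:, 0] = 1.0
            return np.minimum.accumulate(np.clip(S, 0.0, 1.0), axis=1)
        raise UnsupportedBackendError(self.backend)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        """Centred Cox linear predictor beta . (x - mean)."""
        if self.backend != "cox":
            raise UnsupportedBackendError(
                "linear_predictor is only defined for the cox backend")
        lp = np.zeros(len(X))
        for c in self.covariates:
            lp += self.coefs[c] * (X[c].to_numpy(float) - self.means[c])
        return lp

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        if self.backend == "rsf":
            raise UnsupportedBackendError(
                "rsf models are not JSON-serializable; refit from the "
                "registry with the recorded seed instead")
        return {
            "format_version": 1,
            "backend": self.backend, "target": self.target,
            "covariates": list(self.covariates), "horizon": self.horizon,
            "time_step": self.time_step, "seed": self.seed,
            "coefs": self.coefs, "means": self.means, "coef_se": self.coef_se,
            "baseline_survival": [round(float(v), 12)
                                  for v in self.baseline_survival],
            "n_events": int(self.n_events),
            "dropped_covariates": list(self.dropped_covariates),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedSurvivalModel":
        d = dict(d)
        d.pop("format_version", None)
        d["baseline_survival"] = np.asarray(d["baseline_survival"], float)
        return cls(**d)


def fit_model(records: pd.DataFrame, target: str, backend: str = "cox",
              covariates=None, horizon: float = 25.0,
              time_step: float = MONTH, seed: int = 0,
              n_estimators: int = 100,
              min_samples_leaf: int = 15) -> FittedSurvivalModel:
    """Fit a survival model for one of the registry targets.

    Zero-variance covariates are dropped with a logged warning (they carry
    no information and break the Cox fit).  Raises
    :class:`EstimationError` when the target has no uncensored events.
    """
    if backend not in BACKENDS:
        raise UnsupportedBackendError(backend)
    duration, event, raw = _target_frame(records, target)
    n_events = int(event.sum())
    if n_events == 0:
        raise EstimationError(f"no uncensored events for target {target!r}")
    if n_events < MIN_EVENTS_WARN:
        log.warning("target %s has only %d events; estimates may be unstable",
                    target, n_events)

    model = FittedSurvivalModel(
        backend=backend, target=target, covariates=[], horizon=horizon,
        time_step=time_step, seed=seed, n_events=n_events)
    grid = model.grid

    if backend == "km":
        km = KaplanMeierFitter()
        km.fit(duration, event)
        sf = km.survival_function_.iloc[:, 0]
        model.baseline_survival = _step_interp(grid, sf.index.to_numpy(),
                                               sf.to_numpy())
        return model

    covariates = list(covariates or DEFAULT_COVARIATES[target])
    X = _design(raw, covariates)
    dropped = [c for c in covariates if X[c].std() == 0.0]
    if dropped:
        log.warning("dropping constant covariate(s) %s from %s fit",
                    dropped, target)
        covariates = [c for c in covariates if c not in dropped]
        X = X[covariates]
    model.covariates = covariates
    model.dropped_covariates = dropped

    if backend == "cox":
        df = X.copy()
        df["_T"] = duration
        df["_E"] = event.astype(int)
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_T", event_col="_E")
        model.coefs = {c: float(cph.params_[c]) for c in covariates}
        model.coef_se = {c: float(cph.standard_errors_[c])
                         for c in covariates}
        model.means = {c: float(cph._norm_mean[c]) for c in covariates}
        bs = cph.baseline_survival_.iloc[:, 0]
        model.baseline_survival = _step_interp(grid, bs.index.to_numpy(),
                                               bs.to_numpy())
        return model

    # rsf
    from sksurv.ensemble import RandomSurvivalForest
    y = np.empty(len(X), dtype=[("event", bool), ("time", float)])
    y["event"] = event
    y["time"] = duration
    rsf = RandomSurvivalForest(
        n_estimators=n_estimators, min_samples_leaf=min_samples_leaf,
        random_state=seed, n_jobs=1)
    rsf.fit(X.to_numpy(), y)
    model._rsf = rsf
    return model


def predict_curve(model: FittedSurvivalModel, patient) -> SurvivalCurve:
    """Predict one patient's survival curve on the monthly grid."""
    records = patient if isinstance(patient, pd.DataFrame) \
        else pd.DataFrame([patient])
    S = model.predict_matrix(records)
    return SurvivalCurve(model.grid,
                         np.minimum.accumulate(np.clip(S[0], 0.0, 1.0)))


@dataclass(frozen=True)
class VariableImportanceTable:
    """Per-variable importance scores with dense ranks (1 = most important)."""

    backend: str
    entries: dict  # variable -> (score, rank)

    def top(self, k: int) -> list:
        order = sorted(self.entries, key=lambda v: self.entries[v][1])
        return order[:k]


def variable_importance(model: FittedSurvivalModel, records: pd.DataFrame,
                        seed: int = 0,
                        n_repeats: int = 10) -> VariableImportanceTable:
    """Rank the model's covariates by importance.

    Cox: absolute standardized coefficient |beta_j| * sd(x_j) on the given
    records.  RSF: permutation importance of Harrell's concordance on
    held-out records, averaged over ``n_repeats`` seeded permutations.
    """
    if model.backend == "km":
        raise UnsupportedBackendError(
            "the km backend has no covariates to rank")
    X = _design(records, model.covariates)
    if model.backend == "cox":
        scores = {c: abs(model.coefs[c]) * float(X[c].std())
                  for c in model.covariates}
    else:
        from sklearn.inspection import permutation_importance
        duration, event, raw = _target_frame(records, model.target)
        X = _design(raw, model.covariates)
        y = np.empty(len(X), dtype=[("event", bool), ("time", float)])
        y["event"], y["time"] = event, duration
        res = permutation_importance(model._rsf, X.to_numpy(), y,
                                     n_repeats=n_repeats, random_state=seed)
        scores = {c: float(res.importances_mean[i])
                  for i, c in enumerate(model.covariates)}
    order = sorted(scores, key=lambda v: (-scores[v], v))
    entries = {v: (scores[v], i + 1) for i, v in enumerate(order)}
    return VariableImportanceTable(backend=model.backend, entries=entries)


def top_k_union(table_a: VariableImportanceTable,
                table_b: VariableImportanceTable, k: int) -> set:
    """Union of the k best-ranked variables of two importance tables."""
    if set(table_a.entries) != set(table_b.entries):
        raise XenoeqError("importance tables rank different variable sets")
    if k > len(table_a.entries):
        raise XenoeqError(f"k={k} exceeds the {len(table_a.entries)} variables")
    return set(table_a.top(k)) | set(table_b.top(k))


def km_with_band(records: pd.DataFrame, target: str,
                 kind: str = "survival",
                 min_events: int = SUPPRESSION_EVENTS) -> CurveWithBand:
    """Kaplan-Meier curve with Greenwood log-log 95% bands, or one-minus-KM
    of the transplant event as a cumulative-incidence curve.

    Strata with fewer than ``min_events`` events return a suppressed result
    (flag set, no curve), mirroring small-cell reporting rules.
    """
    duration, event, _ = _target_frame(records, target)
    n_events = int(event.sum())
    if n_events < min_events:
        return CurveWithBand(curve=None, suppressed=True, n_events=n_events)
    horizon = float(np.ceil(duration.max() * 12) / 12) if len(duration) else 1.0
    grid = time_grid(max(horizon, MONTH))
    km = KaplanMeierFitter()
    km.fit(duration, event)
    sf = km.survival_function_.iloc[:, 0]
    ci = km.confidence_interval_  # exponential Greenwood (log-log) bounds
    s = _step_interp(grid, sf.index.to_numpy(), sf.to_numpy())
    lo = _step_interp(grid, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
    hi = _step_interp(grid, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
    s = np.minimum.accumulate(np.clip(s, 0, 1))
    lo, hi = np.clip(lo, 0, 1), np.clip(hi, 0, 1)
    lo, hi = np.minimum(lo, s), np.maximum(hi, s)
    if kind == "survival":
        return CurveWithBand(curve=SurvivalCurve(grid, s), lower=lo, upper=hi,
                             n_events=n_events)
    if kind == "incidence":
        inc = IncidenceCurve(grid, 1.0 - s)
        return CurveWithBand(curve=inc, lower=1.0 - hi, upper=1.0 - lo,
                             n_events=n_events)
    raise XenoeqError(f"unknown curve kind {kind!r}")


def cumulative_incidence(records: pd.DataFrame,
                         event_type: str = "transplant") -> IncidenceCurve:
    """Aalen-Johansen cumulative incidence treating the other outcome as a
    competing risk (sensitivity variant to the censoring convention)."""
    from lifelines import AalenJohansenFitter
    codes = {"censored": 0, "death_or_delisting": 1, "transplant": 2}
    ev = records["outcome_type"].map(codes).to_numpy()
    t = records["outcome_time"].to_numpy(float)
    ajf = AalenJohansenFitter(calculate_variance=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ajf.fit(t, ev, event_of_interest=codes[event_type])
    ci = ajf.cumulative_density_.iloc[:, 0]
    horizon = float(np.ceil(t.max() * 12) / 12)
    grid = time_grid(max(horizon, MONTH))
    vals = _step_interp(grid, ci.index.to_numpy(), ci.to_numpy(), left=0.0)
    return IncidenceCurve(grid, np.maximum.accumulate(np.clip(vals, 0, 1)))
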