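"""Seeded synthetic kidney-waitlist registry generator.

Real waitlist analyses of this kind run on restricted-access national
registries (candidate files, dialysis histories, center offer logs).  This
module generates registries with the same statistical skeleton and *known*
ground-truth parameters, so that every downstream stage — survival model
fitting, equipoise comparison, center aggressiveness, incentive
counterfactuals — can be tested against the truth.

The generative model:

* Covariates per waitlist registration: age at listing (mixture over the
  18-49 / 50-64 / 65+ bands used in national reporting), diabetes, blood
  type, previous transplant, CPRA (zero-inflated, with a mass at >= 99.5 so
  highly sensitized cohorts are populated), BMI, serum albumin, a social
  deprivation index, and a small set of comorbidity flags.
* Competing risks on the waitlist: independent latent times for
  death-or-delisting and for transplant, each from a Weibull
  proportional-hazards model with configurable baseline rate, shape and
  log-hazard-ratios on design-matrix columns; an independent exponential
  censoring time; everything administratively truncated at the horizon.
  The observed outcome is the earliest of the four.
* Post-transplant survival from a third Weibull PH model that includes the
  matched donor's quality score; follow-up is truncated at the horizon
  (measured from listing).
* Relisting after graft failure: a Bernoulli graft-failure indicator among
  transplant recipients, then a logistic model on the same design columns
  for whether the patient relists.
* A center offer log: marginal (low-quality-donor) and standard offers
  arrive per patient-year; whether an offer is *seen* depends on the
  center's opt-in screen propensity, and acceptance on the center's
  acceptance propensity.  Acceptance implies seen.

Randomness is split into independent per-table streams spawned from the one
seed, so enlarging the donor pool does not perturb the patient table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

#: Design-matrix columns that hazard/logit coefficient maps may reference.
DESIGN_COLUMNS = (
    "diabetes",
    "age_c",        # (age_at_listing - 55) / 10
    "albumin_c",    # (albumin - 4.0) / 0.5
    "sdi_c",        # (sdi - 50) / 25
    "bmi_c",        # (bmi - 28) / 5
    "previous_transplant",
    "cpra_frac",    # cpra / 100
    "blood_B",
    "blood_AB",
    "blood_O",      # reference category: A
    "donor_quality",
)

#: Reserved keys in hazard-coefficient maps (not design columns).
_HAZARD_RESERVED = ("baseline", "shape")

PATIENT_COLUMNS = [
    "patient_id", "center_id", "age_at_listing", "diabetes", "blood_type",
    "previous_transplant", "cpra", "bmi", "albumin", "sdi",
    "comorb_copd", "comorb_pvd", "comorb_smoker",
    "waiting_time_elapsed", "active", "outcome_type", "outcome_time",
    "donor_id", "donor_quality", "post_tx_time", "post_tx_event",
    "graft_failure", "relisted",
]
DONOR_COLUMNS = ["donor_id", "blood_type", "quality"]
OFFER_COLUMNS = [
    "offer_id", "center_id", "patient_id", "donor_id",
    "marginal", "seen", "accepted",
]

OUTCOME_TYPES = ("death_or_delisting", "transplant", "censored")


@dataclass
class OfferParams:
    """Knobs of the synthetic center offer log."""

    marginal_offer_rate: float = 0.6      # marginal offers per patient-year
    standard_offer_rate: float = 0.4      # non-marginal offers per patient-year
    acceptance_propensity: tuple = ()     # per center, in [0,1]
    screen_propensity: tuple = ()         # per center opt-in screen, in [0,1]
    marginal_quality_threshold: float = 0.35


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of a synthetic registry.

    Hazard coefficient maps take design-column names (see
    :data:`DESIGN_COLUMNS`) to log-hazard-ratios, plus the reserved keys
    ``baseline`` (per-year baseline rate) and ``shape`` (Weibull shape;
    1 = exponential).  ``relist_logit_coefs`` takes design columns to
    log-odds plus an ``intercept`` key.
    """

    n_patients: int = 10_000
    n_centers: int = 20
    n_donors: int = 3_000
    seed: int = 0
    death_hazard_coefs: dict = field(default_factory=lambda: {
        "baseline": 0.11, "shape": 1.1,
        "diabetes": 0.50, "age_c": 0.35, "albumin_c": -0.30, "sdi_c": 0.15,
    })
    transplant_hazard_coefs: dict = field(default_factory=lambda: {
        "baseline": 0.085, "shape": 1.4,
        "blood_B": -0.50, "blood_O": -0.40, "blood_AB": 0.30,
        "cpra_frac": -1.20, "previous_transplant": -0.30,
        "age_c": -0.15, "diabetes": -0.20,
    })
    post_tx_hazard_coefs: dict = field(default_factory=lambda: {
        "baseline": 0.075, "shape": 1.0,
        "age_c": 0.35, "diabetes": 0.40, "donor_quality": -1.00,
    })
    relist_logit_coefs: dict = field(default_factory=lambda: {
        "intercept": 0.5, "age_c": -0.40, "diabetes": -0.30,
    })
    graft_failure_prob: float = 0.35
    censor_rate: float = 0.02
    horizon_years: float = 25.0
    time_step: float = 1.0 / 12.0
    inactive_prob: float = 0.10
    offer_params: OfferParams = field(default_factory=OfferParams)

    def __post_init__(self):
        if isinstance(self.offer_params, dict):
            self.offer_params = OfferParams(**self.offer_params)
        self.validate()

    def validate(self) -> None:
        for name in ("n_patients", "n_centers", "n_donors"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("censor_rate", "graft_failure_prob", "inactive_prob"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for label in ("death", "transplant", "post_tx"):
            coefs = getattr(self, f"{label}_hazard_coefs")
            if coefs.get("baseline", 0.0) < 0:
                raise ConfigurationError(f"{label} baseline hazard must be >= 0")
            if coefs.get("shape", 1.0) <= 0:
                raise ConfigurationError(f"{label} Weibull shape must be > 0")
            unknown = set(coefs) - set(DESIGN_COLUMNS) - set(_HAZARD_RESERVED)
            if unknown:
                raise ConfigurationError(
                    f"unknown design column(s) in {label}_hazard_coefs: {sorted(unknown)}"
                )
        n = round(self.horizon_years / self.time_step)
        if n <= 0 or abs(n * self.time_step - self.horizon_years) > 1e-9:
            raise ConfigurationError("time_step must evenly divide horizon_years")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["offer_params"]["acceptance_propensity"] = list(
            d["offer_params"]["acceptance_propensity"])
        d["offer_params"]["screen_propensity"] = list(
            d["offer_params"]["screen_propensity"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        op = dict(d.pop("offer_params", {}))
        for key in ("acceptance_propensity", "screen_propensity"):
            if key in op:
                op[key] = tuple(op[key])
        return cls(offer_params=OfferParams(**op), **d)


@dataclass
class RegistryBundle:
    """Patients, donors and offers plus the ground truth that produced them."""

    patients: pd.DataFrame
    donors: pd.DataFrame
    offers: pd.DataFrame
    ground_truth: GeneratorConfig


def design_matrix(patients: pd.DataFrame) -> pd.DataFrame:
    """Model-ready covariate columns from raw patient records.

    Continuous covariates are centred/scaled so coefficients are
    per-standardized-unit log-hazard-ratios; blood type is dummy-coded with
    A as the reference.  ``donor_quality`` is passed through when present.
    """
    X = pd.DataFrame(index=patients.index)
    X["diabetes"] = patients["diabetes"].astype(float)
    X["age_c"] = (patients["age_at_listing"] - 55.0) / 10.0
    X["albumin_c"] = (patients["albumin"] - 4.0) / 0.5
    X["sdi_c"] = (patients["sdi"] - 50.0) / 25.0
    X["bmi_c"] = (patients["bmi"] - 28.0) / 5.0
    X["previous_transplant"] = patients["previous_transplant"].astype(float)
    X["cpra_frac"] = patients["cpra"] / 100.0
    bt = patients["blood_type"]
    X["blood_B"] = (bt == "B").astype(float)
    X["blood_AB"] = (bt == "AB").astype(float)
    X["blood_O"] = (bt == "O").astype(float)
    if "donor_quality" in patients.columns:
        X["donor_quality"] = patients["donor_quality"].astype(float)
    return X


def linear_predictor(X: pd.DataFrame, coefs: dict) -> np.ndarray:
    """Sum of coef * design column over the non-reserved keys of ``coefs``."""
    lp = np.zeros(len(X))
    for name, beta in coefs.items():
        if name in _HAZARD_RESERVED or name == "intercept":
            continue
        lp += beta * X[name].to_numpy()
    return lp


def _weibull_ph_times(rng, coefs: dict, X: pd.DataFrame) -> np.ndarray:
    """Latent event times under a Weibull proportional-hazards model.

    Cumulative hazard H(t) = baseline * t^shape * exp(lp); inversion of
    S(t) = exp(-H(t)) at a uniform draw gives the time.  A zero baseline
    yields +inf (the event never happens).
    """
    rate = float(coefs.get("baseline", 0.0))
    shape = float(coefs.get("shape", 1.0))
    n = len(X)
    if rate == 0.0:
        return np.full(n, np.inf)
    lp = linear_predictor(X, coefs)
    u = rng.uniform(size=n)
    return (-np.log(u) / (rate * np.exp(lp))) ** (1.0 / shape)


def _sample_covariates(rng, cfg: GeneratorConfig) -> pd.DataFrame:
    n = cfg.n_patients
    band = rng.choice(3, size=n, p=[0.35, 0.45, 0.20])
    age = np.where(
        band == 0, rng.uniform(18, 50, size=n),
        np.where(band == 1, rng.uniform(50, 65, size=n),
                 rng.uniform(65, 80, size=n)),
    )
    cpra_kind = rng.choice(3, size=n, p=[0.65, 0.30, 0.05])
    cpra = np.where(
        cpra_kind == 0, 0.0,
        np.where(cpra_kind == 1, rng.uniform(1, 99, size=n),
                 rng.uniform(99.5, 100.0, size=n)),
    )
    return pd.DataFrame({
        "patient_id": np.arange(n),
        "center_id": rng.integers(0, cfg.n_centers, size=n),
        "age_at_listing": np.round(age, 6),
        "diabetes": rng.uniform(size=n) < 0.45,
        "blood_type": rng.choice(["O", "A", "B", "AB"], size=n,
                                 p=[0.48, 0.34, 0.14, 0.04]),
        "previous_transplant": rng.uniform(size=n) < 0.12,
        "cpra": np.round(cpra, 6),
        "bmi": np.round(np.clip(rng.normal(28, 5, size=n), 15, 50), 6),
        "albumin": np.round(np.clip(rng.normal(3.9, 0.5, size=n), 1.5, 5.5), 6),
        "sdi": np.round(rng.uniform(0, 100, size=n), 6),
        "comorb_copd": rng.uniform(size=n) < 0.10,
        "comorb_pvd": rng.uniform(size=n) < 0.15,
        "comorb_smoker": rng.uniform(size=n) < 0.12,
    })


def _generate_donors(rng, cfg: GeneratorConfig) -> pd.DataFrame:
    n = cfg.n_donors
    return pd.DataFrame({
        "donor_id": np.arange(n),
        "blood_type": rng.choice(["O", "A", "B", "AB"], size=n,
                                 p=[0.48, 0.34, 0.14, 0.04]),
        "quality": np.round(rng.beta(3.0, 2.0, size=n), 6),
    })


def _generate_offers(rng, cfg: GeneratorConfig, patients: pd.DataFrame,
                     donors: pd.DataFrame) -> pd.DataFrame:
    op = cfg.offer_params
    accept = np.asarray(op.acceptance_propensity, dtype=float)
    screen = np.asarray(op.screen_propensity, dtype=float)
    marginal_donors = donors.index[
        donors["quality"] < op.marginal_quality_threshold].to_numpy()
    standard_donors = donors.index[
        donors["quality"] >= op.marginal_quality_threshold].to_numpy()

    exposure = np.minimum(patients["outcome_time"].to_numpy(),
                          cfg.horizon_years)
    rows = []
    for marginal, rate, pool in (
        (True, op.marginal_offer_rate, marginal_donors),
        (False, op.standard_offer_rate, standard_donors),
    ):
        if rate <= 0 or len(pool) == 0:
            continue
        counts = rng.poisson(rate * exposure)
        pid = np.repeat(patients["patient_id"].to_numpy(), counts)
        cid = np.repeat(patients["center_id"].to_numpy(), counts)
        m = len(pid)
        did = donors["donor_id"].to_numpy()[rng.choice(pool, size=m)]
        seen = rng.uniform(size=m) < screen[cid]
        accepted = seen & (rng.uniform(size=m) < accept[cid])
        rows.append(pd.DataFrame({
            "center_id": cid, "patient_id": pid, "donor_id": did,
            "marginal": np.full(m, marginal), "seen": seen,
            "accepted": accepted,
        }))
    offers = (pd.concat(rows, ignore_index=True) if rows
              else pd.DataFrame(columns=OFFER_COLUMNS[1:]))
    offers.insert(0, "offer_id", np.arange(len(offers)))
    return offers


def generate_registry(config: GeneratorConfig) -> RegistryBundle:
    """Generate a full synthetic registry bundle.

    The same config (including seed) reproduces the bundle bit for bit.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_p, rng_d, rng_o = (np.random.default_rng(s) for s in ss.spawn(3))

    cfg = config
    if len(cfg.offer_params.acceptance_propensity) != cfg.n_centers:
        # Center propensities are part of the ground truth; draw them once
        # from the patient stream's seed sequence sibling when unspecified.
        rng_c = np.random.default_rng(np.random.SeedSequence(cfg.seed + 777_001))
        cfg = dataclasses.replace(cfg, offer_params=dataclasses.replace(
            cfg.offer_params,
            acceptance_propensity=tuple(
                np.round(rng_c.beta(2.0, 2.0, size=cfg.n_centers), 6)),
            screen_propensity=tuple(
                np.round(rng_c.beta(5.0, 2.0, size=cfg.n_centers), 6)),
        ))

    donors = _generate_donors(rng_d, cfg)
    patients = _sample_covariates(rng_p, cfg)
    X = design_matrix(patients)

    t_death = _weibull_ph_times(rng_p, cfg.death_hazard_coefs, X)
    t_tx = _weibull_ph_times(rng_p, cfg.transplant_hazard_coefs, X)
    if cfg.censor_rate > 0:
        t_cens = rng_p.exponential(1.0 / cfg.censor_rate, size=len(X))
    else:
        t_cens = np.full(len(X), np.inf)

    horizon = cfg.horizon_years
    t_obs = np.minimum.reduce([t_death, t_tx, t_cens,
                               np.full(len(X), horizon)])
    outcome = np.where(
        t_obs == t_death, "death_or_delisting",
        np.where(t_obs == t_tx, "transplant", "censored"),
    )
    patients["waiting_time_elapsed"] = np.round(
        rng_p.uniform(size=len(X)) * t_obs, 6)
    patients["active"] = rng_p.uniform(size=len(X)) >= cfg.inactive_prob
    patients["outcome_type"] = outcome
    patients["outcome_time"] = np.round(np.maximum(t_obs, 1e-6), 6)

    # Post-transplant follow-up for recipients: match a random donor, draw a
    # post-transplant death time from the PH model with the donor's quality,
    # truncate follow-up at the horizon measured from listing.
    tx = outcome == "transplant"
    n_tx = int(tx.sum())
    donor_id = np.full(len(X), -1)
    donor_quality = np.full(len(X), np.nan)
    post_time = np.full(len(X), np.nan)
    post_event = np.zeros(len(X), dtype=bool)
    graft_failure = np.zeros(len(X), dtype=bool)
    relisted = np.zeros(len(X), dtype=bool)
    if n_tx:
        matched = rng_p.integers(0, cfg.n_donors, size=n_tx)
        donor_id[tx] = donors["donor_id"].to_numpy()[matched]
        donor_quality[tx] = donors["quality"].to_numpy()[matched]
        Xp = X.loc[tx].copy()
        Xp["donor_quality"] = donor_quality[tx]
        t_post = _weibull_ph_times(rng_p, cfg.post_tx_hazard_coefs, Xp)
        follow = horizon - t_obs[tx]
        post_event[tx] = t_post <= follow
        post_time[tx] = np.round(np.maximum(np.minimum(t_post, follow), 1e-6), 6)
        graft_failure[tx] = rng_p.uniform(size=n_tx) < cfg.graft_failure_prob
        logit = (cfg.relist_logit_coefs.get("intercept", 0.0)
                 + linear_predictor(X.loc[tx], cfg.relist_logit_coefs))
        p_relist = 1.0 / (1.0 + np.exp(-logit))
        relisted[tx] = graft_failure[tx] & (rng_p.uniform(size=n_tx) < p_relist)
    patients["donor_id"] = donor_id
    patients["donor_quality"] = np.round(donor_quality, 6)
    patients["post_tx_time"] = post_time
    patients["post_tx_event"] = post_event
    patients["graft_failure"] = graft_failure
    patients["relisted"] = relisted
    patients = patients[PATIENT_COLUMNS]

    offers = _generate_offers(rng_o, cfg, patients, donors)
    return RegistryBundle(patients=patients, donors=donors, offers=offers,
                          ground_truth=cfg)


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The package's default study conditions with a caller-chosen seed."""
    return GeneratorConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# On-disk round trip: one CSV per table plus a JSON ground-truth sidecar.
# Booleans are serialized as 0/1 and times as decimal years (6 digits).

_BOOL_COLS = {
    "patients": ["diabetes", "previous_transplant", "comorb_copd",
                 "comorb_pvd", "comorb_smoker", "active", "post_tx_event",
                 "graft_failure", "relisted"],
    "donors": [],
    "offers": ["marginal", "seen", "accepted"],
}
_REQUIRED = {"patients": PATIENT_COLUMNS, "donors": DONOR_COLUMNS,
             "offers": OFFER_COLUMNS}


def write_registry(bundle: RegistryBundle, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in ("patients", "donors", "offers"):
        df = getattr(bundle, name).copy()
        for col in _BOOL_COLS[name]:
            df[col] = df[col].astype(int)
        df.to_csv(path / f"{name}.csv", index=False, float_format="%.6f")
    with open(path / "config.json", "w") as fh:
        json.dump(bundle.ground_truth.to_dict(), fh, indent=2, sort_keys=True)


def read_registry(path) -> RegistryBundle:
    path = Path(path)
    tables = {}
    for name in ("patients", "donors", "offers"):
        f = path / f"{name}.csv"
        if not f.exists():
            raise FormatError(f"missing registry table: {f}")
        df = pd.read_csv(f)
        missing = [c for c in _REQUIRED[name] if c not in df.columns]
        if missing:
            raise FormatError(
                f"{name}.csv is missing required column '{missing[0]}'")
        for col in _BOOL_COLS[name]:
            df[col] = df[col].astype(bool)
        tables[name] = df[_REQUIRED[name]]
    cfg_path = path / "config.json"
    if not cfg_path.exists():
        raise FormatError(f"missing ground-truth sidecar: {cfg_path}")
    with open(cfg_path) as fh:
        cfg = GeneratorConfig.from_dict(json.load(fh))
    return RegistryBundle(ground_truth=cfg, **tables)
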