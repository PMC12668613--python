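import numpy as np
import pandas as pd
import pytest

import xenoeq as xq
from xenoeq.incentives import ModelSet


@pytest.fixture(scope="session")
def bundle():
    """A mid-sized default-condition registry shared across tests."""
    return xq.generate_registry(xq.default_config(seed=7, n_patients=2500))


@pytest.fixture(scope="session")
def active(bundle):
    return bundle.patients[bundle.patients["active"]].reset_index(drop=True)


@pytest.fixture(scope="session")
def models(active):
    """Cox models for all three targets, fitted on the shared bundle."""
    return ModelSet(
        waitlist_death=xq.fit_model(active, "waitlist_death"),
        time_to_transplant=xq.fit_model(active, "time_to_transplant"),
        post_transplant_death=xq.fit_model(active, "post_transplant_death"),
    )


@pytest.fixture(scope="session")
def death_model(models):
    return models.waitlist_death


def make_patient(**overrides):
    """One synthetic patient row with sensible defaults."""
    row = {
        "patient_id": 0, "center_id": 0, "age_at_listing": 55.0,
        "diabetes": True, "blood_type": "O", "previous_transplant": False,
        "cpra": 0.0, "bmi": 28.0, "albumin": 4.0, "sdi": 50.0,
        "comorb_copd": False, "comorb_pvd": False, "comorb_smoker": False,
        "waiting_time_elapsed": 0.0, "active": True,
        "outcome_type": "censored", "outcome_time": 10.0,
        "donor_id": -1, "donor_quality": np.nan,
        "post_tx_time": np.nan, "post_tx_event": False,
        "graft_failure": False, "relisted": False,
    }
    row.update(overrides)
    return pd.Series(row)


def patient_frame(rows):
    return pd.DataFrame([make_patient(patient_id=i, **r)
                         for i, r in enumerate(rows)])
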