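import numpy as np
import pandas as pd
import pytest

from syntharm.fixture import CohortConfig, simulate_cohort
from syntharm.trial_data import FeatureSchema, TrialDataset


@pytest.fixture
def tiny_schema():
    return [
        FeatureSchema(name="gender", ftype="binary", categories=("F", "M")),
        FeatureSchema(name="stage", ftype="categorical", categories=("I", "II", "III")),
        FeatureSchema(name="age", ftype="continuous"),
        FeatureSchema(name="arm", ftype="binary", categories=("ctrl", "act"), role="arm"),
        FeatureSchema(name="time", ftype="continuous", role="survival_time"),
        FeatureSchema(name="event", ftype="binary", categories=(0, 1), role="event_indicator"),
    ]


@pytest.fixture
def tiny_dataset(tiny_schema):
    df = pd.DataFrame(
        {
            "gender": ["F", "M", "F"],
            "stage": ["I", "III", "II"],
            "age": [55.0, 63.0, 71.0],
            "arm": ["ctrl", "act", "ctrl"],
            "time": [12.0, 5.5, 30.0],
            "event": [1, 0, 1],
        }
    )
    return TrialDataset(schema=tiny_schema, df=df)


@pytest.fixture(scope="session")
def small_cohort():
    """200-patient cohort shared by metric-level tests."""
    cfg = CohortConfig(n_control=120, n_active=80, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    from syntharm.fixture import default_nscls_config

    cfg = default_nscls_config()
    cfg.seed = 42
    return simulate_cohort(cfg)


def make_survival_dataset(times, events, extra=None):
    """Minimal valid TrialDataset around explicit survival times/events."""
    n = len(times)
    schema = [
        FeatureSchema(name="x", ftype="binary", categories=(0, 1)),
        FeatureSchema(name="arm", ftype="binary", categories=("a", "b"), role="arm"),
        FeatureSchema(name="time", ftype="continuous", role="survival_time"),
        FeatureSchema(name="event", ftype="binary", categories=(0, 1), role="event_indicator"),
    ]
    df = pd.DataFrame(
        {
            "x": (extra if extra is not None else np.zeros(n, dtype=int)),
            "arm": ["a"] * n,
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
        }
    )
    return TrialDataset(schema=schema, df=df)
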