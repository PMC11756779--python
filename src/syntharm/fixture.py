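"""Simulated two-arm oncology cohort used throughout tests and benchmarks.

The simulator produces a structural stand-in for an advanced-NSCLC registry
extract: two treatment arms, mostly balanced binary covariates, continuous
age, and right-censored overall survival from a Weibull proportional-hazards
model with uniform accrual and administrative censoring.  It is never a
claim about any real registry's distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .trial_data import FeatureSchema, TrialDataset, validate_schema

CONTROL_LABEL = "chemo"
ACTIVE_LABEL = "pembro"


@dataclass
class CohortConfig:
    n_control: int = 397
    n_active: int = 248
    n_binary: int = 8
    n_categorical: int = 1
    n_categories: int = 3  # levels per non-binary categorical covariate
    include_age: bool = True
    age_range: tuple[float, float] = (40.0, 90.0)
    age_mean: float = 68.0
    age_sd: float = 9.0
    log_hazard_ratio: float = float(np.log(0.6))  # active-arm benefit
    weibull_shape: float = 1.2
    weibull_scale: float = 14.0  # months
    covariate_effect_scale: float = 0.2  # |log-HR| cap for covariate effects
    accrual_months: float = 57.0
    followup_extra_months: float = 3.0
    binary_balance_jitter: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_control, self.n_active) < 1:
            raise ArgumentError("arm sizes must be >= 1")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ArgumentError("Weibull parameters must be positive")
        if self.n_binary < 0 or self.n_categorical < 0:
            raise ArgumentError("covariate counts must be non-negative")
        if self.accrual_months <= 0:
            raise ArgumentError("accrual window must be positive")
        if self.followup_extra_months < 0:
            raise ArgumentError("follow-up cutoff cannot precede accrual end")
        if self.age_range[0] >= self.age_range[1]:
            raise ArgumentError("age_range must be increasing")

    @property
    def binary_share(self) -> float:
        total = self.n_binary + self.n_categorical + (1 if self.include_age else 0)
        return self.n_binary / total if total else 0.0


def default_nscls_config() -> CohortConfig:
    """Defaults mirroring the reference cohort: 397 control + 248 active
    (645 total), >= 75% binary covariates, active-arm benefit."""
    cfg = CohortConfig()
    cfg.validate()
    assert cfg.n_control + cfg.n_active == 645
    assert cfg.binary_share >= 0.75
    assert cfg.log_hazard_ratio < 0
    return cfg


def cohort_schema(c: CohortConfig) -> list[FeatureSchema]:
    schema: list[FeatureSchema] = []
    for i in range(c.n_binary):
        schema.append(FeatureSchema(name=f"bin_{i}", ftype="binary", categories=(0, 1)))
    for i in range(c.n_categorical):
        cats = tuple(f"c{j}" for j in range(c.n_categories))
        schema.append(FeatureSchema(name=f"cat_{i}", ftype="categorical", categories=cats))
    if c.include_age:
        schema.append(FeatureSchema(name="age", ftype="continuous"))
    schema.append(FeatureSchema(name="arm", ftype="binary",
                                categories=(CONTROL_LABEL, ACTIVE_LABEL), role="arm"))
    schema.append(FeatureSchema(name="survival_months", ftype="continuous", role="survival_time"))
    schema.append(FeatureSchema(name="event", ftype="binary", categories=(0, 1),
                                role="event_indicator"))
    validate_schema(schema)
    return schema


def simulate_cohort(c: CohortConfig) -> TrialDataset:
    """Draw one cohort: covariates, Weibull PH event times, accrual +
    administrative censoring.  Reproducible under ``c.seed``."""
    c.validate()
    rng = np.random.default_rng(c.seed)
    n = c.n_control + c.n_active
    arm = np.array([CONTROL_LABEL] * c.n_control + [ACTIVE_LABEL] * c.n_active, dtype=object)

    cols: dict[str, np.ndarray] = {}
    lp = np.where(arm == ACTIVE_LABEL, c.log_hazard_ratio, 0.0).astype(float)
    effect_rng = np.random.default_rng(c.seed + 10_000)  # effects fixed per config seed
    for i in range(c.n_binary):
        p = 0.5 + rng.uniform(-c.binary_balance_jitter, c.binary_balance_jitter)
        x = rng.binomial(1, p, size=n)
        beta = effect_rng.uniform(-c.covariate_effect_scale, c.covariate_effect_scale)
        lp += beta * x
        cols[f"bin_{i}"] = x
    for i in range(c.n_categorical):
        levels = [f"c{j}" for j in range(c.n_categories)]
        x = rng.integers(0, c.n_categories, size=n)
        betas = effect_rng.uniform(-c.covariate_effect_scale, c.covariate_effect_scale,
                                   size=c.n_categories)
        lp += betas[x]
        cols[f"cat_{i}"] = np.array([levels[j] for j in x], dtype=object)
    if c.include_age:
        lo, hi = c.age_range
        age = np.clip(rng.normal(c.age_mean, c.age_sd, size=n), lo, hi)
        z = (age - c.age_mean) / max(c.age_sd, 1e-9)
        lp += effect_rng.uniform(0.0, c.covariate_effect_scale) * z
        cols["age"] = age

    # Weibull PH: S(t | x) = exp(-(t/scale)^shape * e^lp)
    u = rng.uniform(size=n)
    t_event = c.weibull_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / c.weibull_shape)
    entry = rng.uniform(0.0, c.accrual_months, size=n)
    cutoff = c.accrual_months + c.followup_extra_months
    t_censor = cutoff - entry
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    df = pd.DataFrame(cols)
    df["arm"] = arm
    df["survival_months"] = time
    df["event"] = event
    return TrialDataset(schema=cohort_schema(c), df=df)
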