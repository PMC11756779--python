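"""Survival-based utility distances between original and synthetic arms.

Four distances, all oriented lower-is-better:

* ``cox_beta_distance`` — Euclidean norm of the difference between Cox
  log-hazard-ratio vectors fitted on each dataset.
* ``median_survival_distance`` — |KM median difference|.
* ``survival_curve_distance`` — integral of |S_orig - S_synth| over the
  shared follow-up window, computed exactly on the merged step grid.
* ``predicted_survival_distance`` — mean absolute gap between
  patient-specific survival curves predicted by a flexible parametric
  (spline-baseline proportional-hazards) model fitted on each dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as LLConvergenceError

from .errors import ArgumentError, ConvergenceError, UndefinedMedianError
from .trial_data import TrialDataset


@dataclass
class SurvivalCurve:
    """Right-continuous step function S(t) with S(0) = 1."""

    times: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.censor_times = np.asarray(self.censor_times, dtype=float)
        if self.times.shape != self.survival.shape:
            raise ArgumentError("times and survival must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ArgumentError("times must be ascending")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ArgumentError("survival must be non-increasing")

    def at(self, t) -> np.ndarray:
        """Evaluate the step function (S = 1 before the first time point)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out

    @property
    def max_time(self) -> float:
        candidates = [self.times.max() if self.times.size else 0.0]
        if self.censor_times.size:
            candidates.append(self.censor_times.max())
        return float(max(candidates))

    def median(self) -> float:
        below = self.survival <= 0.5
        if not below.any():
            raise UndefinedMedianError("survival curve never reaches 0.5")
        return float(self.times[np.argmax(below)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


@dataclass
class CoxFit:
    coefficients: pd.Series
    converged: bool


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimate; censored subjects leave the risk set after
    their time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ArgumentError("times and events must have equal length")
    if (times < 0).any():
        raise ArgumentError("times must be non-negative")
    km = KaplanMeierFitter()
    km.fit(times, events)
    sf = km.survival_function_
    return SurvivalCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        censor_times=np.sort(times[events == 0]),
    )


def _cox_frame(d: TrialDataset, covariates: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "T": d.df[d.survival_time_col].to_numpy(dtype=float),
            "E": d.df[d.event_col].to_numpy(dtype=int),
        }
    )
    for name in covariates:
        f = d.feature(name)
        if f.is_categorical:
            codes = {c: i for i, c in enumerate(f.categories)}
            df[name] = d.df[name].map(codes).astype(float)
        else:
            df[name] = d.df[name].to_numpy(dtype=float)
    return df


def fit_cox(d: TrialDataset, covariates: list[str], **cox_kwargs) -> CoxFit:
    """Cox partial-likelihood fit with Efron tie handling (lifelines)."""
    if not covariates:
        raise ArgumentError("need at least one covariate")
    df = _cox_frame(d, covariates)
    if df["E"].sum() == 0:
        raise ConvergenceError("no events: partial likelihood undefined")
    cf = CoxPHFitter(**cox_kwargs)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cf.fit(df, duration_col="T", event_col="E")
    except (LLConvergenceError, Exception) as exc:  # lifelines raises several types
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc
    coefs = cf.params_.loc[covariates]
    if not np.isfinite(coefs.to_numpy()).all():
        raise ConvergenceError("non-finite coefficients")
    return CoxFit(coefficients=coefs, converged=True)


def cox_beta_distance(
    original: TrialDataset, synthetic: TrialDataset, covariates: list[str]
) -> float:
    """Euclidean norm of the difference between the two log-HR vectors."""
    b1 = fit_cox(original, covariates).coefficients.to_numpy()
    b2 = fit_cox(synthetic, covariates).coefficients.to_numpy()
    return float(np.linalg.norm(b1 - b2))


def km_curve(d: TrialDataset) -> SurvivalCurve:
    return km_estimate(
        d.df[d.survival_time_col].to_numpy(dtype=float),
        d.df[d.event_col].to_numpy(dtype=int),
    )


def median_survival_distance(original: TrialDataset, synthetic: TrialDataset) -> float:
    """|KM median difference|; raises UndefinedMedianError when a curve never
    crosses 0.5 (never a silent number)."""
    return abs(km_curve(original).median() - km_curve(synthetic).median())


def survival_curve_distance(original: TrialDataset, synthetic: TrialDataset) -> float:
    """Exact integral of the absolute KM-curve gap on the merged step grid."""
    if original.n_patients == 0 or synthetic.n_patients == 0:
        raise ArgumentError("empty dataset")
    c1, c2 = km_curve(original), km_curve(synthetic)
    return curve_area_between(c1, c2)


def curve_area_between(c1: SurvivalCurve, c2: SurvivalCurve) -> float:
    T = min(c1.max_time, c2.max_time)
    grid = np.unique(np.concatenate(([0.0], c1.times, c2.times, [T])))
    grid = grid[grid <= T]
    area = 0.0
    for lo, hi in zip(grid[:-1], grid[1:]):
        gap = abs(float(c1.at(lo)[0]) - float(c2.at(lo)[0]))  # step value on [lo, hi)
        area += gap * (hi - lo)
    return float(area)


def default_time_grid(d: TrialDataset, n_points: int = 24) -> np.ndarray:
    t = d.df[d.survival_time_col].to_numpy(dtype=float)
    upper = float(np.quantile(t, 0.95))
    return np.linspace(max(upper * 1e-3, 1e-6), upper, n_points)


def _fit_flexible_model(d: TrialDataset, covariates: list[str]) -> CoxPHFitter:
    df = _cox_frame(d, covariates)
    if df["E"].sum() == 0:
        raise ConvergenceError("no events: cannot fit parametric survival model")
    df.loc[df["T"] <= 0, "T"] = df.loc[df["T"] > 0, "T"].min() * 0.5 if (df["T"] > 0).any() else 1e-6
    cf = CoxPHFitter(baseline_estimation_method="spline", n_baseline_knots=2)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cf.fit(df, duration_col="T", event_col="E")
    except Exception as exc:
        raise ConvergenceError(f"flexible parametric fit failed: {exc}") from exc
    return cf


def predicted_survival_distance(
    original: TrialDataset,
    synthetic: TrialDataset,
    covariates: list[str],
    grid: np.ndarray | None = None,
) -> float:
    """Mean (over original patients) of the mean absolute gap between the
    per-patient survival curves predicted by models fitted on each dataset;
    bounded in [0, 1]."""
    if grid is None:
        grid = default_time_grid(original)
    m1 = _fit_flexible_model(original, covariates)
    m2 = _fit_flexible_model(synthetic, covariates)
    X = _cox_frame(original, covariates)
    s1 = m1.predict_survival_function(X, times=grid).to_numpy()
    s2 = m2.predict_survival_function(X, times=grid).to_numpy()
    return float(np.mean(np.abs(s1 - s2)))
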