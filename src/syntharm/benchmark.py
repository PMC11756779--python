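"""End-to-end benchmark: fit -> (generalize) -> synthesize -> reverse ->
evaluate -> rank, plus the hybrid-arm use case.

Per generator and run, the control arm's training split is synthesized and
scored with the resemblance, utility and privacy measures; run-level values
are averaged into a :class:`~syntharm.ranking.MetricMatrix` and aggregated
into rank scores.  Failures are recorded per (generator, run) and excluded
from averaging with a warning, never imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import generators as gen
from .errors import ArgumentError, ConvergenceError, UndefinedMedianError
from .generalization import (
    BinSpec,
    GeneralizationMap,
    PrivacyBudget,
    fit_generalization_map,
    generalize_dataset,
    reverse_generalize,
)
from .privacy import default_cap_columns, privacy_report
from .ranking import Measure, MetricMatrix, RankReport, aggregate_ranks
from .resemblance import classifier_agreement, univariate_report
from .trial_data import TrialDataset, split_holdout
from .utility import (
    SurvivalCurve,
    cox_beta_distance,
    fit_cox,
    km_curve,
    median_survival_distance,
    predicted_survival_distance,
    survival_curve_distance,
)

log = logging.getLogger("syntharm.benchmark")

MEASURES = [
    Measure("mean_ks", "resemblance", "lower_better"),
    Measure("mean_js", "resemblance", "lower_better"),
    Measure("linear_agreement", "resemblance", "lower_better"),
    Measure("rf_agreement", "resemblance", "lower_better"),
    Measure("cox_beta", "utility", "lower_better"),
    Measure("median_survival", "utility", "lower_better"),
    Measure("survival_curve", "utility", "lower_better"),
    Measure("predicted_survival", "utility", "lower_better"),
    Measure("cap", "privacy", "higher_better"),
    Measure("detection", "privacy", "higher_better"),
    Measure("dcr", "privacy", "higher_better"),
    Measure("nndr", "privacy", "higher_better"),
]


@dataclass
class BenchmarkConfig:
    generator_specs: list[gen.GeneratorSpec]
    n_runs: int = 10
    holdout_fraction: float = 0.2
    generalize: bool = True
    generalization_features: list[str] | None = None
    n_bins: int = 10
    generalization_epsilon: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_runs < 1:
            raise ArgumentError("n_runs must be >= 1")
        if not self.generator_specs:
            raise ArgumentError("need at least one generator spec")
        if not 0 < self.holdout_fraction < 1:
            raise ArgumentError("holdout_fraction must be in (0, 1)")


@dataclass
class BenchmarkResult:
    matrix: MetricMatrix
    ranks: RankReport
    run_records: pd.DataFrame  # generator, run, measure, value (tidy)
    failures: list[dict] = field(default_factory=list)
    manifest: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# No-generalization path for all-categorical generators: each distinct value
# of a continuous feature becomes its own category (cardinality preserved)
# and is decoded back by value after sampling.


def exact_categorize(d: TrialDataset, features: list[str]) -> TrialDataset:
    from .trial_data import FeatureSchema

    df = d.df.copy()
    schema = []
    for f in d.schema:
        if f.name in features:
            vals = np.unique(df[f.name].to_numpy(dtype=float))
            labels = tuple(repr(float(v)) for v in vals)
            df[f.name] = [repr(float(v)) for v in df[f.name]]
            schema.append(FeatureSchema(name=f.name, ftype="categorical",
                                        categories=labels, role=f.role))
        else:
            schema.append(f)
    return TrialDataset(schema=schema, df=df)


def exact_decode(d: TrialDataset, features: list[str]) -> TrialDataset:
    from .trial_data import FeatureSchema

    df = d.df.copy()
    schema = []
    for f in d.schema:
        if f.name in features:
            df[f.name] = df[f.name].map(float)
            schema.append(FeatureSchema(name=f.name, ftype="continuous", role=f.role))
        else:
            schema.append(f)
    return TrialDataset(schema=schema, df=df)


# ---------------------------------------------------------------------------


def _needs_categorical(spec: gen.GeneratorSpec) -> bool:
    return spec.kind == "privbayes"


def synthesize_control(
    spec: gen.GeneratorSpec,
    train: TrialDataset,
    cfg: BenchmarkConfig,
    seed: int,
) -> TrialDataset:
    """Fit one generator on the (optionally generalized) training data and
    return a reversed, schema-valid synthetic dataset of the same size."""
    cont = [f.name for f in train.schema if f.ftype == "continuous"]
    features = cfg.generalization_features or cont
    if cfg.generalize and features:
        gmap = fit_generalization_map(
            train, features=features, n_bins=cfg.n_bins,
            budget=PrivacyBudget(cfg.generalization_epsilon), seed=seed,
        )
        fit_input = generalize_dataset(train, gmap)
        fitted = gen.fit(spec, fit_input, seed)
        synth_binned = gen.sample(fitted, train.n_patients, seed + 1)
        return reverse_generalize(synth_binned, gmap, seed + 2)
    if _needs_categorical(spec) and cont:
        fit_input = exact_categorize(train, cont)
        fitted = gen.fit(spec, fit_input, seed)
        synth_cat = gen.sample(fitted, train.n_patients, seed + 1)
        return exact_decode(synth_cat, cont)
    fitted = gen.fit(spec, train, seed)
    return gen.sample(fitted, train.n_patients, seed + 1)


def score_synthetic(
    train: TrialDataset,
    holdout: TrialDataset,
    synthetic: TrialDataset,
    seed: int,
) -> dict[str, float]:
    """All twelve benchmark measures for one synthetic dataset."""
    uni = univariate_report(train, synthetic)
    agree = classifier_agreement(train, synthetic, holdout, seed)
    covs = [f.name for f in train.schema if f.role == "covariate" and f.is_categorical]
    covs = covs[: min(3, len(covs))] or [train.covariate_cols[0]]
    priv = privacy_report(train, holdout, synthetic, seed=seed)
    return {
        "mean_ks": uni.mean_ks,
        "mean_js": uni.mean_js,
        "linear_agreement": agree.agreement("linear"),
        "rf_agreement": agree.agreement("rf"),
        "cox_beta": cox_beta_distance(train, synthetic, covs),
        "median_survival": median_survival_distance(train, synthetic),
        "survival_curve": survival_curve_distance(train, synthetic),
        "predicted_survival": predicted_survival_distance(train, synthetic, covs),
        "cap": priv.cap_score,
        "detection": priv.detection_score,
        "dcr": priv.dcr,
        "nndr": priv.nndr,
    }


def run_benchmark(d: TrialDataset, cfg: BenchmarkConfig) -> BenchmarkResult:
    """Full benchmark on the control arm of *d*."""
    cfg.validate()
    control_label = d.feature(d.arm_col).categories[0]
    control = d.arm_subset(control_label)
    holdout, train = split_holdout(control, cfg.holdout_fraction, cfg.seed)
    records: list[dict] = []
    failures: list[dict] = []
    manifest: list[dict] = []
    for spec in cfg.generator_specs:
        for run in range(cfg.n_runs):
            run_seed = cfg.seed + 1000 * run + 17
            try:
                synthetic = synthesize_control(spec, train, cfg, run_seed)
                scores = score_synthetic(train, holdout, synthetic, run_seed)
            except (ArgumentError, ConvergenceError, UndefinedMedianError) as exc:
                warnings.warn(f"{spec.name} run {run} failed: {exc}")
                failures.append({"generator": spec.name, "run": run, "error": str(exc)})
                continue
            manifest.append({"generator": spec.name, "run": run, "seed": run_seed,
                             "generalize": cfg.generalize})
            for name, value in scores.items():
                records.append({"generator": spec.name, "run": run,
                                "measure": name, "value": value})
    run_df = pd.DataFrame(records)
    if run_df.empty:
        raise ConvergenceError("every benchmark run failed")
    means = run_df.pivot_table(index="generator", columns="measure", values="value",
                               aggfunc="mean")
    names = [s.name for s in cfg.generator_specs if s.name in means.index]
    matrix = MetricMatrix(generators=names, measures=list(MEASURES),
                          values=means.loc[names, [m.name for m in MEASURES]])
    ranks = aggregate_ranks(matrix)
    return BenchmarkResult(matrix=matrix, ranks=ranks, run_records=run_df,
                           failures=failures, manifest=manifest)


# ---------------------------------------------------------------------------
# Hybrid-arm use case


@dataclass
class HybridResult:
    curves: list[SurvivalCurve]
    mean_curve: SurvivalCurve
    hr_original: np.ndarray
    hr_hybrid: np.ndarray


def build_hybrid(synthetic_control: TrialDataset, original_active: TrialDataset) -> TrialDataset:
    """Synthetic control arm + original active arm, original control excluded."""
    s_names = [f.name for f in synthetic_control.schema]
    a_names = [f.name for f in original_active.schema]
    if s_names != a_names:
        raise ArgumentError("hybrid inputs must share a schema")
    df = pd.concat([synthetic_control.df, original_active.df], ignore_index=True)
    return TrialDataset(schema=list(original_active.schema), df=df)


def bootstrap_hazard_ratios(d: TrialDataset, B: int, seed: int) -> np.ndarray:
    """B case-resampled Cox refits with the arm indicator as sole covariate;
    returns hazard ratios (exponentiated coefficients)."""
    if B < 1:
        raise ArgumentError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = d.n_patients
    out = np.empty(B)
    for b in range(B):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            boot = d.with_df(d.df.iloc[idx])
            if boot.df[d.event_col].astype(int).sum() == 0:
                continue
            try:
                fit = fit_cox(boot, [d.arm_col])
            except ConvergenceError:
                continue
            out[b] = float(np.exp(fit.coefficients.iloc[0]))
            break
        else:
            raise ConvergenceError(f"bootstrap replicate {b} failed after 10 attempts")
    return out


def mean_km_curve(curves: list[SurvivalCurve]) -> SurvivalCurve:
    """Pointwise mean of step curves on their merged time grid."""
    grid = np.unique(np.concatenate([c.times for c in curves]))
    values = np.mean([c.at(grid) for c in curves], axis=0)
    return SurvivalCurve(times=grid, survival=values, censor_times=np.array([]))


def hybrid_analysis(
    d: TrialDataset,
    spec: gen.GeneratorSpec,
    cfg: BenchmarkConfig,
    B: int = 500,
    n_runs: int | None = None,
) -> HybridResult:
    """KM curves per synthetic-control run plus bootstrap HR distributions
    for the original and hybrid datasets."""
    control_label, active_label = d.feature(d.arm_col).categories
    control = d.arm_subset(control_label)
    active = d.arm_subset(active_label)
    runs = n_runs if n_runs is not None else cfg.n_runs
    curves, hybrids = [], []
    for run in range(runs):
        run_seed = cfg.seed + 1000 * run + 29
        synth_control = synthesize_control(spec, control, cfg, run_seed)
        curves.append(km_curve(synth_control))
        hybrids.append(build_hybrid(synth_control, active))
    hr_original = bootstrap_hazard_ratios(d, B, cfg.seed + 7)
    hr_hybrid = bootstrap_hazard_ratios(hybrids[0], B, cfg.seed + 7)
    return HybridResult(curves=curves, mean_curve=mean_km_curve(curves),
                        hr_original=hr_original, hr_hybrid=hr_hybrid)
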