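"""Statistical resemblance between synthetic and original tables.

Univariate: Kolmogorov-Smirnov statistic for continuous features and
Jensen-Shannon distance (base-2, square-root convention, range [0, 1]) for
categorical features.  Multivariate proxy: classifiers trained on original
vs synthetic data, compared by accuracy on a shared hold-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import ks_2samp
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .errors import ArgumentError
from .trial_data import TrialDataset


@dataclass
class ResemblanceReport:
    ks_per_feature: dict[str, float] = field(default_factory=dict)
    js_per_feature: dict[str, float] = field(default_factory=dict)
    accuracy: dict[str, float] = field(default_factory=dict)  # e.g. "linear_original"

    @property
    def mean_ks(self) -> float:
        return float(np.mean(list(self.ks_per_feature.values()))) if self.ks_per_feature else 0.0

    @property
    def mean_js(self) -> float:
        return float(np.mean(list(self.js_per_feature.values()))) if self.js_per_feature else 0.0

    def agreement(self, family: str) -> float:
        return abs(self.accuracy[f"{family}_original"] - self.accuracy[f"{family}_synthetic"])


def ks_statistic(a, b) -> float:
    """Sup-distance between the empirical CDFs of two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ArgumentError("ks_statistic requires non-empty samples")
    return float(ks_2samp(a, b).statistic)


def js_distance(p, q) -> float:
    """Square root of the base-2 Jensen-Shannon divergence of two pmfs."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ArgumentError("probability vectors must share support length")
    for v in (p, q):
        if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
            raise ArgumentError("inputs must be probability vectors summing to 1")
    return float(min(jensenshannon(p, q, base=2), 1.0))


def category_frequencies(values, categories) -> np.ndarray:
    counts = pd.Series(values).value_counts()
    freq = np.array([counts.get(c, 0) for c in categories], dtype=float)
    total = freq.sum()
    if total == 0:
        raise ArgumentError("empty column")
    return freq / total


def univariate_report(original: TrialDataset, synthetic: TrialDataset) -> ResemblanceReport:
    """KS per continuous feature, JS distance per categorical feature."""
    rep = ResemblanceReport()
    for f in original.schema:
        if f.is_categorical:
            p = category_frequencies(original.df[f.name], f.categories)
            q = category_frequencies(synthetic.df[f.name], f.categories)
            rep.js_per_feature[f.name] = js_distance(p, q)
        else:
            rep.ks_per_feature[f.name] = ks_statistic(original.df[f.name], synthetic.df[f.name])
    return rep


def _design_matrix(d: TrialDataset, covariates: list[str]) -> np.ndarray:
    cols = []
    for name in covariates:
        f = d.feature(name)
        if f.is_categorical:
            codes = {c: i for i, c in enumerate(f.categories)}
            cols.append(d.df[name].map(codes).to_numpy(dtype=float))
        else:
            cols.append(d.df[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def classifier_agreement(
    original: TrialDataset,
    synthetic: TrialDataset,
    holdout: TrialDataset,
    seed: int,
) -> ResemblanceReport:
    """Train {logistic, random forest} on original and on synthetic data and
    score both on the hold-out; target = event indicator, covariates exclude
    survival time (it would leak the label)."""
    covs = [
        f.name
        for f in original.schema
        if f.role in ("covariate", "arm") and f.name != original.survival_time_col
    ]
    target = original.event_col
    rep = ResemblanceReport()
    X_hold = _design_matrix(holdout, covs)
    y_hold = holdout.df[target].to_numpy(dtype=int)
    for label, train in (("original", original), ("synthetic", synthetic)):
        y = train.df[target].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise ArgumentError(f"single-class target in {label} training data")
        X = _design_matrix(train, covs)
        models = {
            "linear": LogisticRegression(max_iter=2000),
            "rf": RandomForestClassifier(n_estimators=200, random_state=seed),
        }
        for family, model in models.items():
            model.fit(X, y)
            rep.accuracy[f"{family}_{label}"] = float(np.mean(model.predict(X_hold) == y_hold))
    return rep
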