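"""Re-identification risk measures with a hold-out baseline.

Distances between mixed-type records use a Gower-style mean of per-feature
distances: range-normalized absolute difference for continuous features and
0/1 mismatch for categorical ones, so every record distance lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold

from .errors import ArgumentError
from .trial_data import FeatureSchema, TrialDataset


@dataclass
class PrivacyReport:
    cap_score: float
    detection_score: float
    dcr: float
    nndr: float
    holdout_dcr: float
    holdout_nndr: float

    @property
    def memorization_flag(self) -> bool:
        """True when synthetic records sit closer to training data than an
        untouched hold-out does (dcr < holdout_dcr)."""
        return self.dcr < self.holdout_dcr


# ---------------------------------------------------------------------------
# Mixed-type distances


def _ranges(schema: list[FeatureSchema], reference: pd.DataFrame) -> dict[str, float]:
    out = {}
    for f in schema:
        if not f.is_categorical:
            lo, hi = float(reference[f.name].min()), float(reference[f.name].max())
            out[f.name] = max(hi - lo, 1e-12)
    return out


def mixed_distance(a, b, schema: list[FeatureSchema], ranges: dict[str, float] | None = None) -> float:
    """Gower-style distance between two records (mappings name -> value)."""
    if ranges is None:
        ranges = {}
    parts = []
    for f in schema:
        if f.name not in a or f.name not in b:
            raise ArgumentError(f"record missing feature {f.name!r}")
        if f.is_categorical:
            parts.append(0.0 if a[f.name] == b[f.name] else 1.0)
        else:
            r = ranges.get(f.name, 1.0)
            parts.append(min(abs(float(a[f.name]) - float(b[f.name])) / r, 1.0))
    return float(np.mean(parts))


def _distance_matrix(query: TrialDataset, reference: TrialDataset) -> np.ndarray:
    """All-pairs Gower distances, query rows x reference rows.  Ranges for
    continuous normalization come from the reference (training) data."""
    schema = reference.schema
    ranges = _ranges(schema, reference.df)
    n_q, n_r, p = query.n_patients, reference.n_patients, len(schema)
    total = np.zeros((n_q, n_r))
    for f in schema:
        qv = query.df[f.name].to_numpy()
        rv = reference.df[f.name].to_numpy()
        if f.is_categorical:
            total += (qv[:, None] != rv[None, :]).astype(float)
        else:
            d = np.abs(qv[:, None].astype(float) - rv[None, :].astype(float)) / ranges[f.name]
            total += np.minimum(d, 1.0)
    return total / p


def dcr(original_train: TrialDataset, synthetic: TrialDataset) -> float:
    """Median over synthetic records of the distance to the closest original
    training record."""
    if original_train.n_patients == 0 or synthetic.n_patients == 0:
        raise ArgumentError("empty dataset")
    dm = _distance_matrix(synthetic, original_train)
    return float(np.median(dm.min(axis=1)))


def nndr(original_train: TrialDataset, synthetic: TrialDataset) -> float:
    """Median over synthetic records of (1st nearest distance / 5th nearest
    distance) against the training data; a zero 5th distance gives ratio 1."""
    if original_train.n_patients < 5:
        raise ArgumentError("nndr needs at least 5 original records")
    if synthetic.n_patients == 0:
        raise ArgumentError("empty synthetic dataset")
    dm = np.sort(_distance_matrix(synthetic, original_train), axis=1)
    d1, d5 = dm[:, 0], dm[:, 4]
    ratios = np.where(d5 > 0, d1 / np.where(d5 > 0, d5, 1.0), 1.0)
    return float(np.median(ratios))


# ---------------------------------------------------------------------------
# Attribution and detection


def default_cap_columns(d: TrialDataset) -> tuple[list[str], str]:
    """Keys = 3 categorical covariates of highest cardinality, target = the
    next categorical covariate."""
    cats = [f for f in d.schema if f.is_categorical and f.role == "covariate"]
    if len(cats) < 2:
        raise ArgumentError("need at least two categorical covariates for CAP")
    ranked = sorted(cats, key=lambda f: (-len(f.categories), f.name))
    keys = [f.name for f in ranked[:3]] if len(ranked) > 3 else [f.name for f in ranked[:-1]]
    target = next(f.name for f in ranked if f.name not in keys)
    return keys, target


def cap_categorical(
    original: TrialDataset, synthetic: TrialDataset, key_features: list[str], target_feature: str
) -> float:
    """Safety-oriented Correct Attribution Probability.

    The attacker holds each original record's key attributes and predicts
    its target as the majority target among synthetic records matching on
    all keys; unmatched records count as attacker failures.  Returns
    1 - P(correct attribution): high = safe.
    """
    if target_feature in key_features:
        raise ArgumentError("target cannot be among the keys")
    for name in [*key_features, target_feature]:
        if not original.feature(name).is_categorical:
            raise ArgumentError(f"CAP requires categorical columns, {name!r} is continuous")
    maj = (
        synthetic.df.groupby(key_features)[target_feature]
        .agg(lambda s: s.value_counts().idxmax())
        .to_dict()
    )
    correct = 0
    for _, row in original.df.iterrows():
        key = tuple(row[k] for k in key_features)
        if len(key_features) == 1:
            key = key[0]
        pred = maj.get(key)
        if pred is not None and pred == row[target_feature]:
            correct += 1
    return 1.0 - correct / original.n_patients


def detection_score(original: TrialDataset, synthetic: TrialDataset, seed: int) -> float:
    """Mean AUROC of a boosted-tree classifier separating original from
    synthetic records under stratified 5-fold CV.  Higher = records more
    distinguishable = lower memorization risk."""
    if original.n_patients < 10 or synthetic.n_patients < 10:
        raise ArgumentError("need at least 10 records per class for 5-fold CV")
    X_parts = []
    for d in (original, synthetic):
        cols = {}
        for f in d.schema:
            if f.is_categorical:
                codes = {c: i for i, c in enumerate(f.categories)}
                cols[f.name] = d.df[f.name].map(codes).to_numpy(dtype=float)
            else:
                cols[f.name] = d.df[f.name].to_numpy(dtype=float)
        X_parts.append(pd.DataFrame(cols).to_numpy())
    X = np.vstack(X_parts)
    y = np.concatenate([np.ones(original.n_patients), np.zeros(synthetic.n_patients)])
    # identical feature vectors are indistinguishable by construction: keep
    # them in one fold so duplicate memorization cannot invert the AUROC
    _, groups = np.unique(X, axis=0, return_inverse=True)
    skf = StratifiedGroupKFold(n_splits=5, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y, groups):
        clf = HistGradientBoostingClassifier(random_state=seed)
        clf.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], clf.predict_proba(X[te])[:, 1]))
    return float(np.mean(aucs))


def privacy_report(
    original_train: TrialDataset,
    holdout: TrialDataset,
    synthetic: TrialDataset,
    keys: list[str] | None = None,
    target: str | None = None,
    seed: int = 0,
) -> PrivacyReport:
    """All four scores plus the hold-out DCR/NNDR baselines (hold-out
    substituted for the synthetic set on the same distance metric)."""
    if keys is None or target is None:
        auto_keys, auto_target = default_cap_columns(original_train)
        keys = keys or auto_keys
        target = target or auto_target
    return PrivacyReport(
        cap_score=cap_categorical(original_train, synthetic, keys, target),
        detection_score=detection_score(original_train, synthetic, seed),
        dcr=dcr(original_train, synthetic),
        nndr=nndr(original_train, synthetic),
        holdout_dcr=dcr(original_train, holdout),
        holdout_nndr=nndr(original_train, holdout),
    )
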