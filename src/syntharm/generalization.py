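"""Reversible data generalization with differentially private reversal.

Continuous, high-cardinality features are binned (quantile or explicit
edges) before synthesis, which turns them into ordered categorical columns
a generator can model.  After synthesis the binning is reversed: each bin
label is replaced by a draw from a truncated normal distribution over the
bin's support, whose mean and standard deviation were estimated from the
original per-bin values under the Laplace mechanism.

Bins partition patients into disjoint groups, so the per-feature privacy
spend equals the per-bin spend (parallel composition); spends across
features add up (sequential composition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .errors import ArgumentError, DataValidationError
from .trial_data import FeatureSchema, TrialDataset

SD_FLOOR_FRACTION = 1e-3  # sd floor as a fraction of bin width


@dataclass(frozen=True)
class BinSpec:
    """Ordered bin edges for one feature; bins are [b_n, b_{n+1}) with the
    top bin closed so the maximum is representable."""

    feature: str
    edges: tuple
    strategy: str = "explicit"

    def __post_init__(self):
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        if len(edges) < 2:
            raise ArgumentError(f"{self.feature!r}: need at least 2 edges")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ArgumentError(f"{self.feature!r}: edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def labels(self) -> list[str]:
        e = self.edges
        out = [f"[{e[i]:g},{e[i + 1]:g})" for i in range(self.n_bins - 1)]
        out.append(f"[{e[-2]:g},{e[-1]:g}]")
        return out

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Map values to integer bin indices; out-of-range raises."""
        v = np.asarray(values, dtype=float)
        lo, hi = self.edges[0], self.edges[-1]
        bad = (v < lo) | (v > hi)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DataValidationError(
                f"value {v[row]} of feature {self.feature!r} (row {row}) "
                f"outside [{lo}, {hi}]"
            )
        idx = np.searchsorted(self.edges, v, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)  # v == b_N folds into top bin


@dataclass
class BinParams:
    """Truncated-normal parameters for one bin."""

    mean: float
    sd: float
    support: tuple[float, float]
    empty_flag: bool = False

    def __post_init__(self):
        lo, hi = self.support
        if not lo < hi:
            raise ArgumentError("bin support must have positive width")
        if not (lo <= self.mean <= hi):
            raise ArgumentError("bin mean must lie inside its support")
        if self.sd < 0:
            raise ArgumentError("bin sd must be non-negative")


@dataclass(frozen=True)
class PrivacyBudget:
    """Per-feature epsilon with its split between mean and sd estimation."""

    epsilon: float
    split: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ArgumentError("epsilon must be positive")
        if len(self.split) != 2 or abs(sum(self.split) - 1.0) > 1e-9 or min(self.split) <= 0:
            raise ArgumentError("split must be two positive proportions summing to 1")


@dataclass
class GeneralizationMap:
    """Reversible-transform state: bin edges and DP bin parameters per feature."""

    bin_specs: dict[str, BinSpec] = field(default_factory=dict)
    bin_params: dict[str, list[BinParams]] = field(default_factory=dict)
    epsilon_per_feature: dict[str, float] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)

    @property
    def epsilon_spent(self) -> float:
        # sequential composition across features; parallel across bins
        return float(sum(self.epsilon_per_feature.values()))

    def validate(self) -> None:
        for name, spec in self.bin_specs.items():
            params = self.bin_params.get(name)
            if params is None or len(params) != spec.n_bins:
                raise ArgumentError(f"feature {name!r} lacks a full BinParams set")

    def to_dict(self) -> dict:
        return {
            "features": {
                name: {
                    "edges": list(spec.edges),
                    "strategy": spec.strategy,
                    "epsilon": self.epsilon_per_feature.get(name),
                    "seed": self.seeds.get(name),
                    "bins": [
                        {
                            "mean": p.mean,
                            "sd": p.sd,
                            "support": list(p.support),
                            "empty": p.empty_flag,
                        }
                        for p in self.bin_params[name]
                    ],
                }
                for name, spec in self.bin_specs.items()
            },
            "epsilon_spent": self.epsilon_spent,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, doc: dict) -> "GeneralizationMap":
        m = cls()
        for name, entry in doc["features"].items():
            m.bin_specs[name] = BinSpec(name, tuple(entry["edges"]), entry.get("strategy", "explicit"))
            m.bin_params[name] = [
                BinParams(b["mean"], b["sd"], tuple(b["support"]), b["empty"])
                for b in entry["bins"]
            ]
            if entry.get("epsilon") is not None:
                m.epsilon_per_feature[name] = entry["epsilon"]
            if entry.get("seed") is not None:
                m.seeds[name] = entry["seed"]
        m.validate()
        return m


# ---------------------------------------------------------------------------
# Operations


def fit_quantile_bins(values, n_bins: int, feature: str = "feature") -> BinSpec:
    """Edges at the 0, 1/N, ..., 1 empirical quantiles; duplicate edges are
    collapsed (reducing the bin count) with a warning."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ArgumentError("cannot fit bins to an empty vector")
    if n_bins < 1:
        raise ArgumentError("n_bins must be >= 1")
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.quantile(v, qs)
    uniq = np.unique(edges)
    if uniq.size < 2:
        # all values identical: widen to a degenerate-but-valid single bin
        uniq = np.array([uniq[0], uniq[0] + max(abs(uniq[0]) * 1e-9, 1e-9)])
        warnings.warn(f"{feature!r}: constant values, using a single degenerate bin")
    elif uniq.size < edges.size:
        warnings.warn(
            f"{feature!r}: duplicate quantile edges collapsed "
            f"({n_bins} -> {uniq.size - 1} bins)"
        )
    return BinSpec(feature=feature, edges=tuple(uniq), strategy="quantile")


def generalize(d: TrialDataset, specs: list[BinSpec]) -> TrialDataset:
    """Replace each spec'd continuous feature by its ordered bin label."""
    df = d.df.copy()
    schema = []
    by_name = {s.feature: s for s in specs}
    for f in d.schema:
        spec = by_name.pop(f.name, None)
        if spec is None:
            schema.append(f)
            continue
        if f.ftype != "continuous":
            raise ArgumentError(f"cannot generalize non-continuous feature {f.name!r}")
        labels = spec.labels()
        idx = spec.assign(df[f.name].to_numpy())
        df[f.name] = [labels[i] for i in idx]
        schema.append(
            FeatureSchema(name=f.name, ftype="categorical", categories=tuple(labels), role=f.role)
        )
    if by_name:
        raise ArgumentError(f"spec features not in dataset: {sorted(by_name)}")
    return TrialDataset(schema=schema, df=df)


def laplace_noise(value: float, sensitivity: float, epsilon: float, seed=None) -> float:
    """value + Laplace(0, sensitivity / epsilon) noise.

    *seed* may be an int or a ``numpy.random.Generator``.
    """
    if sensitivity <= 0:
        raise ArgumentError("sensitivity must be positive")
    if epsilon <= 0:
        raise ArgumentError("epsilon must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return float(value + rng.laplace(0.0, sensitivity / epsilon))


def estimate_bin_params_dp(values_in_bin, support, budget: PrivacyBudget, seed=None) -> BinParams:
    """DP estimate of a bin's truncated-normal mean and sd.

    Sensitivity of the mean of m points on a width-w interval is w/m; the
    same bound is used for the sd.  The budget is split between the two
    statistics.  Empty bins get uniform-fallback parameters and an empty
    flag (no privacy spend: there is nothing to protect).
    """
    lo, hi = float(support[0]), float(support[1])
    if not np.isfinite(lo) or not np.isfinite(hi) or not lo < hi:
        raise ArgumentError("support must be a bounded interval of positive width")
    w = hi - lo
    sd_floor = w * SD_FLOOR_FRACTION
    v = np.asarray(values_in_bin, dtype=float)
    if v.size == 0:
        # uniform over the bin: mean at midpoint, sd = w / sqrt(12)
        return BinParams(mean=(lo + hi) / 2, sd=w / np.sqrt(12.0), support=(lo, hi), empty_flag=True)
    if v.min() < lo or v.max() > hi:
        raise ArgumentError("values must lie inside the bin support")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = v.size
    sens = w / m
    eps_mean = budget.epsilon * budget.split[0]
    eps_sd = budget.epsilon * budget.split[1]
    mean = laplace_noise(float(v.mean()), sens, eps_mean, rng)
    sd = laplace_noise(float(v.std(ddof=0)), sens, eps_sd, rng)
    mean = float(np.clip(mean, lo, hi))
    sd = float(np.clip(sd, sd_floor, w))
    return BinParams(mean=mean, sd=sd, support=(lo, hi))


def fit_generalization_map(
    d: TrialDataset,
    features: list[str] | None = None,
    n_bins: int = 10,
    budget: PrivacyBudget = PrivacyBudget(10.0),
    seed: int = 0,
) -> GeneralizationMap:
    """Fit quantile bins and DP bin parameters for the selected features.

    Defaults to all continuous features (continuous covariates plus survival
    time), mirroring generalization of 'age' and 'survival time'.
    """
    if features is None:
        features = [f.name for f in d.schema if f.ftype == "continuous"]
    m = GeneralizationMap()
    rng = np.random.default_rng(seed)
    for i, name in enumerate(features):
        if d.feature(name).ftype != "continuous":
            raise ArgumentError(f"feature {name!r} is not continuous")
        vals = d.df[name].to_numpy(dtype=float)
        spec = fit_quantile_bins(vals, n_bins, feature=name)
        idx = spec.assign(vals)
        params = []
        feat_seed = int(rng.integers(0, 2**31 - 1))
        feat_rng = np.random.default_rng(feat_seed)
        for b in range(spec.n_bins):
            lo, hi = spec.edges[b], spec.edges[b + 1]
            params.append(
                estimate_bin_params_dp(vals[idx == b], (lo, hi), budget, feat_rng)
            )
        m.bin_specs[name] = spec
        m.bin_params[name] = params
        m.epsilon_per_feature[name] = budget.epsilon  # parallel composition over bins
        m.seeds[name] = feat_seed
    m.validate()
    return m


def generalize_dataset(d: TrialDataset, m: GeneralizationMap) -> TrialDataset:
    """Apply the map's bin specs to a dataset."""
    return generalize(d, list(m.bin_specs.values()))


def reverse_generalize(d_binned: TrialDataset, m: GeneralizationMap, seed: int) -> TrialDataset:
    """Restore generalized features to continuous values.

    Each bin label becomes a draw from the truncated normal with the map's
    parameters; every sample lies inside its bin's support.  Columns whose
    original role was survival_time are additionally clamped non-negative
    and get their role back.
    """
    rng = np.random.default_rng(seed)
    df = d_binned.df.copy()
    schema = []
    for f in d_binned.schema:
        if f.name not in m.bin_specs:
            schema.append(f)
            continue
        spec = m.bin_specs[f.name]
        params = m.bin_params[f.name]
        labels = spec.labels()
        label_to_bin = {lab: i for i, lab in enumerate(labels)}
        col = df[f.name]
        unknown = ~col.isin(label_to_bin)
        if unknown.any():
            bad = col[unknown].iloc[0]
            raise DataValidationError(f"bin label {bad!r} of feature {f.name!r} absent from map")
        idx = col.map(label_to_bin).to_numpy()
        out = np.empty(len(col), dtype=float)
        for b in np.unique(idx):
            p = params[b]
            lo, hi = p.support
            sd = max(p.sd, 1e-12)
            a, bb = (lo - p.mean) / sd, (hi - p.mean) / sd
            n_b = int((idx == b).sum())
            out[idx == b] = truncnorm.rvs(a, bb, loc=p.mean, scale=sd, size=n_b, random_state=rng)
        if f.role == "survival_time":
            out = np.maximum(out, 0.0)
        df[f.name] = out
        schema.append(FeatureSchema(name=f.name, ftype="continuous", role=f.role))
    return TrialDataset(schema=schema, df=df)
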