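"""Synthetic data generators behind a common fit/sample contract.

Natively implemented kinds:

``dummy``
    Replicates the training data (upper quality bound).  At sample sizes
    other than the training size it resamples rows with replacement.
``uniform``
    Uniform sampling of marginals (lower quality bound): categoricals
    uniform over observed categories, continuous uniform over the observed
    range.
``independent``
    Independent sampling from each feature's empirical marginal.
``privbayes``
    Differentially private Bayesian network: greedy structure search with
    the exponential mechanism (mutual-information quality) plus
    Laplace-noised conditional tables, then ancestral sampling.  Requires
    an all-categorical dataset (generalize continuous features first).
``external``
    A plugin resolved from an entry-point string ``"module:attribute"``
    whose value is a callable returning an object with
    ``fit(dataset, seed)`` and ``sample(n, seed)`` methods.  Samples pass
    through the same schema validator as native generators.
"""

from __future__ import annotations

import importlib
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .trial_data import FeatureSchema, TrialDataset

KINDS = ("dummy", "uniform", "independent", "privbayes", "external")


@dataclass(frozen=True)
class GeneratorSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)
    name: str | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ArgumentError(f"unknown generator kind {self.kind!r}")
        eps = self.hyperparameters.get("epsilon")
        if eps is not None and eps <= 0:
            raise ArgumentError("epsilon must be positive")
        if self.hyperparameters.get("max_parents", 0) < 0:
            raise ArgumentError("max_parents must be >= 0")
        if self.name is None:
            object.__setattr__(self, "name", self.kind)


@dataclass
class FittedGenerator:
    spec: GeneratorSpec
    schema: list[FeatureSchema]
    state: object
    fit_seed: int
    epsilon_spent: float = 0.0


# ---------------------------------------------------------------------------
# PrivBayes internals


@dataclass
class BayesNetModel:
    """Node order, parent sets (|parents| <= k) and conditional tables.

    Tables map a parent-value tuple to a probability vector over the node's
    categories; construction order is topological by design.
    """

    order: list[str]
    parents: dict[str, tuple[str, ...]]
    categories: dict[str, tuple]
    tables: dict[str, dict[tuple, np.ndarray]] = field(default_factory=dict)
    epsilon_structure: float = 0.0
    epsilon_params: float = 0.0

    @property
    def epsilon_total(self) -> float:
        # sequential composition of the two stages
        return self.epsilon_structure + self.epsilon_params

    def validate_structure(self) -> None:
        seen: set[str] = set()
        for node in self.order:
            if not set(self.parents[node]) <= seen:
                raise ArgumentError(f"parent set of {node!r} is not topologically earlier")
            seen.add(node)


def mutual_information(x, y) -> float:
    """Empirical mutual information (bits) between two discrete vectors."""
    tab = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy(dtype=float)
    n = tab.sum()
    pxy = tab / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log2(pxy / (px @ py))
    return float(np.nansum(terms))


def _mi_sensitivity(n: int) -> float:
    # standard upper bound on the sensitivity of empirical MI under one
    # record change (general, non-binary case)
    if n < 2:
        return 1.0
    return (2.0 / n) * np.log2((n + 1) / 2.0) + ((n - 1.0) / n) * np.log2((n + 1.0) / (n - 1.0))


def exponential_mechanism(scores, epsilon: float, sensitivity: float, rng) -> int:
    """Index drawn with probability proportional to exp(eps * q / (2 * dq))."""
    q = np.asarray(scores, dtype=float)
    logits = epsilon * q / (2.0 * max(sensitivity, 1e-300))
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    return int(rng.choice(len(q), p=p))


def _joint_key(df: pd.DataFrame, cols: tuple[str, ...]) -> pd.Series:
    if not cols:
        return pd.Series(np.zeros(len(df), dtype=int))
    sub = df[list(cols)].astype(str)
    key = sub.iloc[:, 0]
    for c in sub.columns[1:]:
        key = key + "\x1f" + sub[c]
    return key


def fit_privbayes_structure(
    d: TrialDataset,
    k: int,
    epsilon_structure: float,
    seed: int,
    order: list[str] | None = None,
) -> BayesNetModel:
    """Greedy DP structure search.

    Nodes are taken in a seeded random order (or the supplied *order*); the
    parent set of each node is picked among all subsets of earlier nodes of
    size <= k by the exponential mechanism with mutual-information quality.
    k = 0 forces the independent-marginals structure.
    """
    _require_all_categorical(d)
    if k < 0:
        raise ArgumentError("k must be >= 0")
    if epsilon_structure <= 0:
        raise ArgumentError("epsilon_structure must be positive")
    rng = np.random.default_rng(seed)
    names = [f.name for f in d.schema]
    if order is None:
        order = [names[i] for i in rng.permutation(len(names))]
    elif sorted(order) != sorted(names):
        raise ArgumentError("order must be a permutation of the feature names")
    n = d.n_patients
    sens = _mi_sensitivity(n)
    eps_step = epsilon_structure / max(len(order) - 1, 1)
    parents: dict[str, tuple[str, ...]] = {order[0]: ()}
    for i, node in enumerate(order[1:], start=1):
        prev = order[:i]
        candidates: list[tuple[str, ...]] = [()]
        for size in range(1, min(k, len(prev)) + 1):
            candidates.extend(itertools.combinations(prev, size))
        if k == 0 or len(candidates) == 1:
            parents[node] = ()
            continue
        scores = [
            mutual_information(d.df[node], _joint_key(d.df, cand)) if cand else 0.0
            for cand in candidates
        ]
        choice = exponential_mechanism(scores, eps_step, sens, rng)
        parents[node] = candidates[choice]
    cats = {f.name: tuple(f.categories) for f in d.schema}
    model = BayesNetModel(order=order, parents=parents, categories=cats,
                          epsilon_structure=epsilon_structure)
    model.validate_structure()
    return model


def fit_privbayes_conditionals(
    d: TrialDataset, model: BayesNetModel, epsilon_params: float, seed: int
) -> BayesNetModel:
    """Laplace-noised conditional tables (sensitivity 1 per table, budget
    split evenly across the per-node tables); negatives clipped, rows
    renormalized, all-zero rows fall back to uniform."""
    _require_all_categorical(d)
    if epsilon_params <= 0:
        raise ArgumentError("epsilon_params must be positive")
    rng = np.random.default_rng(seed)
    eps_table = epsilon_params / len(model.order)
    scale = 1.0 / eps_table
    for node in model.order:
        cats = list(model.categories[node])
        pcols = model.parents[node]
        pcats = [list(model.categories[p]) for p in pcols]
        table: dict[tuple, np.ndarray] = {}
        counts = (
            d.df.groupby(list(pcols) + [node]).size().to_dict()
            if pcols
            else d.df.groupby(node).size().to_dict()
        )
        for combo in itertools.product(*pcats) if pcols else [()]:
            row = np.zeros(len(cats))
            for j, c in enumerate(cats):
                key = (*combo, c) if pcols else c
                row[j] = float(counts.get(key, 0))
            row = row + rng.laplace(0.0, scale, size=len(cats))
            row = np.clip(row, 0.0, None)
            total = row.sum()
            table[combo] = row / total if total > 0 else np.full(len(cats), 1.0 / len(cats))
        model.tables[node] = table
    model.epsilon_params = epsilon_params
    return model


def sample_bayesnet(model: BayesNetModel, n: int, seed: int,
                    schema: list[FeatureSchema] | None = None) -> pd.DataFrame | TrialDataset:
    """Ancestral sampling in construction (topological) order."""
    if n < 1:
        raise ArgumentError("n must be >= 1")
    for node in model.order:
        if node not in model.tables:
            raise ArgumentError(f"conditional table missing for node {node!r}")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for node in model.order:
        cats = list(model.categories[node])
        pcols = model.parents[node]
        out = np.empty(n, dtype=object)
        if not pcols:
            p = model.tables[node][()]
            idx = rng.choice(len(cats), size=n, p=p)
            out[:] = [cats[i] for i in idx]
        else:
            parent_vals = np.array(list(zip(*(cols[p] for p in pcols))), dtype=object)
            keys = [tuple(row) for row in parent_vals]
            uniq: dict[tuple, list[int]] = {}
            for i, kk in enumerate(keys):
                uniq.setdefault(kk, []).append(i)
            for kk, rows in uniq.items():
                p = model.tables[node].get(kk)
                if p is None:
                    p = np.full(len(cats), 1.0 / len(cats))
                idx = rng.choice(len(cats), size=len(rows), p=p)
                for r, j in zip(rows, idx):
                    out[r] = cats[j]
        cols[node] = out
    df = pd.DataFrame({name: cols[name] for name in model.order})
    if schema is not None:
        df = df[[f.name for f in schema]]
        return TrialDataset(schema=list(schema), df=df)
    return df


def _require_all_categorical(d: TrialDataset) -> None:
    bad = [f.name for f in d.schema if not f.is_categorical]
    if bad:
        raise ArgumentError(
            f"privbayes requires all-categorical features; continuous columns {bad} "
            "must be generalized first"
        )


# ---------------------------------------------------------------------------
# fit / sample front-end


def fit(spec: GeneratorSpec, d: TrialDataset, seed: int) -> FittedGenerator:
    """Fit *spec* to *d*; deterministic under (spec, d, seed)."""
    if spec.kind == "dummy":
        state = d.copy()
        eps = 0.0
    elif spec.kind == "uniform":
        state = {
            f.name: tuple(f.categories)
            if f.is_categorical
            else (float(d.df[f.name].min()), float(d.df[f.name].max()))
            for f in d.schema
        }
        eps = 0.0
    elif spec.kind == "independent":
        state = {f.name: d.df[f.name].to_numpy() for f in d.schema}
        eps = 0.0
    elif spec.kind == "privbayes":
        hp = spec.hyperparameters
        epsilon = float(hp.get("epsilon", 10.0))
        k = int(hp.get("max_parents", 2))
        split = float(hp.get("structure_share", 0.5))
        if not 0 < split < 1:
            raise ArgumentError("structure_share must be in (0, 1)")
        eps_s, eps_p = epsilon * split, epsilon * (1 - split)
        model = fit_privbayes_structure(d, k, eps_s, seed)
        model = fit_privbayes_conditionals(d, model, eps_p, seed + 1)
        assert abs(model.epsilon_total - epsilon) < 1e-9
        state = model
        eps = epsilon
    elif spec.kind == "external":
        ref = spec.hyperparameters.get("entry_point")
        if not ref:
            raise ArgumentError("external generator needs an 'entry_point' hyperparameter")
        mod_name, _, attr = ref.partition(":")
        factory = getattr(importlib.import_module(mod_name), attr)
        plugin = factory(**{k: v for k, v in spec.hyperparameters.items() if k != "entry_point"})
        plugin.fit(d, seed)
        state = plugin
        eps = float(spec.hyperparameters.get("epsilon", 0.0) or 0.0)
    else:  # pragma: no cover - guarded by GeneratorSpec
        raise ArgumentError(f"unknown kind {spec.kind!r}")
    return FittedGenerator(spec=spec, schema=list(d.schema), state=state,
                           fit_seed=seed, epsilon_spent=eps)


def sample(g: FittedGenerator, n: int, seed: int) -> TrialDataset:
    """Draw n rows; output always validates against the training schema."""
    if n < 1:
        raise ArgumentError("n must be >= 1")
    rng = np.random.default_rng(seed)
    kind = g.spec.kind
    if kind == "dummy":
        train: TrialDataset = g.state
        if n == train.n_patients:
            df = train.df.copy()
        else:
            idx = rng.integers(0, train.n_patients, size=n)
            df = train.df.iloc[idx].reset_index(drop=True)
        return TrialDataset(schema=list(g.schema), df=df)
    if kind == "uniform":
        cols = {}
        for f in g.schema:
            support = g.state[f.name]
            if f.is_categorical:
                idx = rng.integers(0, len(support), size=n)
                cols[f.name] = [support[i] for i in idx]
            else:
                lo, hi = support
                draws = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)
                if f.role == "survival_time":
                    draws = np.maximum(draws, 0.0)
                cols[f.name] = draws
        return TrialDataset(schema=list(g.schema), df=pd.DataFrame(cols))
    if kind == "independent":
        cols = {
            name: values[rng.integers(0, len(values), size=n)]
            for name, values in g.state.items()
        }
        return TrialDataset(schema=list(g.schema), df=pd.DataFrame(cols))
    if kind == "privbayes":
        return sample_bayesnet(g.state, n, seed, schema=g.schema)
    if kind == "external":
        out = g.state.sample(n, seed)
        df = out.df if isinstance(out, TrialDataset) else pd.DataFrame(out)
        return TrialDataset(schema=list(g.schema), df=df)
    raise ArgumentError(f"unknown kind {kind!r}")  # pragma: no cover
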