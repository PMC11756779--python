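"""Typed patient tables for small two-arm survival datasets.

A :class:`TrialDataset` wraps a :class:`pandas.DataFrame` together with a
list of :class:`FeatureSchema` entries describing each column's type
(binary / categorical / continuous) and role (covariate, survival time,
event indicator, arm).  All downstream stages (generalization, generators,
metrics) consume and produce validated ``TrialDataset`` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ArgumentError, DataValidationError, SchemaError

FTYPES = ("binary", "categorical", "continuous")
ROLES = ("covariate", "survival_time", "event_indicator", "arm")


@dataclass(frozen=True)
class FeatureSchema:
    """Declared type and role of one column.

    ``categories`` is required for binary/categorical features and must be
    ``None`` for continuous ones.  Binary features are stored exactly like
    categorical features with two categories; "binary" is an annotation.
    """

    name: str
    ftype: str
    categories: tuple | None = None
    role: str = "covariate"

    def __post_init__(self):
        if self.ftype not in FTYPES:
            raise SchemaError(f"unknown ftype {self.ftype!r} for {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if self.ftype == "continuous":
            if self.categories is not None:
                raise SchemaError(f"{self.name!r}: continuous feature cannot list categories")
        else:
            if not self.categories:
                raise SchemaError(f"{self.name!r}: {self.ftype} feature requires categories")
            object.__setattr__(self, "categories", tuple(self.categories))
            if len(set(self.categories)) != len(self.categories):
                raise SchemaError(f"{self.name!r}: duplicate categories")
            if self.ftype == "binary" and len(self.categories) != 2:
                raise SchemaError(f"{self.name!r}: binary feature needs exactly 2 categories")

    @property
    def is_categorical(self) -> bool:
        return self.ftype in ("binary", "categorical")


def validate_schema(schema: Sequence[FeatureSchema]) -> None:
    """Check the cross-column invariants of a schema list."""
    names = [f.name for f in schema]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate feature names in schema")
    for role, required in (("survival_time", 1), ("event_indicator", 1), ("arm", 1)):
        cnt = sum(1 for f in schema if f.role == role)
        if cnt != required:
            raise SchemaError(f"schema needs exactly {required} {role} column, found {cnt}")
    ev = next(f for f in schema if f.role == "event_indicator")
    if not ev.is_categorical or set(ev.categories) != {0, 1}:
        raise SchemaError("event_indicator must be binary with categories {0, 1}")
    arm = next(f for f in schema if f.role == "arm")
    if not arm.is_categorical or len(arm.categories) != 2:
        raise SchemaError("arm must have exactly two categories")
    # survival_time is continuous in canonical datasets; it may temporarily be
    # categorical while generalized (binned) pre/post synthesis.


@dataclass
class TrialDataset:
    """A validated patient table plus its schema."""

    schema: list[FeatureSchema]
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        validate_schema(self.schema)
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # -- schema accessors -------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.df)

    def feature(self, name: str) -> FeatureSchema:
        for f in self.schema:
            if f.name == name:
                return f
        raise KeyError(name)

    def _role_col(self, role: str) -> str:
        return next(f.name for f in self.schema if f.role == role)

    @property
    def survival_time_col(self) -> str:
        return self._role_col("survival_time")

    @property
    def event_col(self) -> str:
        return self._role_col("event_indicator")

    @property
    def arm_col(self) -> str:
        return self._role_col("arm")

    @property
    def covariate_cols(self) -> list[str]:
        return [f.name for f in self.schema if f.role == "covariate"]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        cols = [f.name for f in self.schema]
        missing = set(cols) - set(self.df.columns)
        if missing:
            raise DataValidationError(f"columns absent from table: {sorted(missing)}")
        unknown = set(self.df.columns) - set(cols)
        if unknown:
            raise DataValidationError(f"unknown columns: {sorted(unknown)}")
        self.df = self.df[cols]
        for f in self.schema:
            col = self.df[f.name]
            na = col.isna()
            if na.any():
                raise DataValidationError(
                    f"missing value in column {f.name!r}, row {int(np.flatnonzero(na)[0])}"
                )
            if f.is_categorical:
                allowed = set(f.categories)
                bad = ~col.isin(allowed)
                if bad.any():
                    row = int(np.flatnonzero(bad)[0])
                    raise DataValidationError(
                        f"value {col.iloc[row]!r} in column {f.name!r} (row {row}) "
                        f"not among categories {list(f.categories)}"
                    )
            else:
                vals = pd.to_numeric(col, errors="coerce")
                if vals.isna().any():
                    row = int(np.flatnonzero(vals.isna())[0])
                    raise DataValidationError(
                        f"non-numeric value in continuous column {f.name!r}, row {row}"
                    )
                self.df[f.name] = vals.astype(float)
        st_feature = self.feature(self.survival_time_col)
        if st_feature.ftype == "continuous":
            st = self.df[self.survival_time_col]
            neg = st < 0
            if neg.any():
                row = int(np.flatnonzero(neg)[0])
                raise DataValidationError(f"negative survival time in row {row}")

    # -- convenience ------------------------------------------------------
    def with_df(self, df: pd.DataFrame) -> "TrialDataset":
        return TrialDataset(schema=list(self.schema), df=df)

    def arm_subset(self, arm_label) -> "TrialDataset":
        return self.with_df(self.df[self.df[self.arm_col] == arm_label])

    def copy(self) -> "TrialDataset":
        return TrialDataset(schema=list(self.schema), df=self.df.copy())


# ---------------------------------------------------------------------------
# I/O


def _coerce_cell(value, feature: FeatureSchema):
    """Map a raw CSV string to the matching schema category (by string equality)."""
    for cat in feature.categories:
        if str(cat) == str(value):
            return cat
    return value  # left as-is; validate() reports it with row/column context


def read_trial_table(path, schema: Sequence[FeatureSchema]) -> TrialDataset:
    """Read a comma-delimited, headered table and validate it against *schema*."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    expected = [f.name for f in schema]
    unknown = set(raw.columns) - set(expected)
    if unknown:
        raise DataValidationError(f"unknown column(s) in {path}: {sorted(unknown)}")
    absent = set(expected) - set(raw.columns)
    if absent:
        raise DataValidationError(f"column(s) missing from {path}: {sorted(absent)}")
    df = pd.DataFrame(index=raw.index)
    for f in schema:
        if f.is_categorical:
            df[f.name] = raw[f.name].map(lambda v, f=f: _coerce_cell(v, f) if pd.notna(v) else v)
        else:
            df[f.name] = pd.to_numeric(raw[f.name], errors="coerce").where(raw[f.name].notna())
    return TrialDataset(schema=list(schema), df=df)


def write_trial_table(d: TrialDataset, path) -> None:
    """Write the value table as UTF-8 CSV with a header row (roundtrip-safe)."""
    d.df.to_csv(path, index=False)


def split_holdout(d: TrialDataset, fraction: float, seed: int) -> tuple[TrialDataset, TrialDataset]:
    """Partition rows into (holdout, rest) with |holdout| = round(fraction * n).

    Disjoint, exhaustive and reproducible under *seed*.
    """
    if not 0 < fraction < 1:
        raise ArgumentError(f"fraction must be in (0, 1), got {fraction}")
    if d.n_patients < 2:
        raise ArgumentError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    n = d.n_patients
    k = int(round(fraction * n))
    perm = rng.permutation(n)
    hold_idx, rest_idx = np.sort(perm[:k]), np.sort(perm[k:])
    return d.with_df(d.df.iloc[hold_idx]), d.with_df(d.df.iloc[rest_idx])


# ---------------------------------------------------------------------------
# Schema (de)serialization for config documents


def schema_to_dict(schema: Sequence[FeatureSchema]) -> list[dict]:
    out = []
    for f in schema:
        entry = {"name": f.name, "ftype": f.ftype, "role": f.role}
        if f.categories is not None:
            entry["categories"] = list(f.categories)
        out.append(entry)
    return out


def schema_from_dict(entries: Iterable[dict]) -> list[FeatureSchema]:
    schema = [
        FeatureSchema(
            name=e["name"],
            ftype=e["ftype"],
            categories=tuple(e["categories"]) if e.get("categories") is not None else None,
            role=e.get("role", "covariate"),
        )
        for e in entries
    ]
    validate_schema(schema)
    return schema


def write_schema(schema: Sequence[FeatureSchema], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schema_to_dict(schema), fh, sort_keys=False)


def read_schema(path) -> list[FeatureSchema]:
    with open(path) as fh:
        return schema_from_dict(yaml.safe_load(fh))
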