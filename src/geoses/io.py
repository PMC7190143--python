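"""Unit-level table I/O and weighted tabulation.

Census-style sources arrive as per-record counts (events, denominators)
with expansion weights that restore population representativity.  This
module turns those records into the per-unit *processed* variables the
index consumes: weighted percentages for count variables and weighted
means for value variables (e.g. income), then reads/writes them as plain
CSV.

Missing data are a hard error: the index's loadings would silently change
under imputation, so rows with missing in-scope values are rejected with
the offending unit ids named.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateInputError, SchemaError

VALID_KINDS = ("percentage", "mean", "ice")

#: column ranges enforced per variable kind
_KIND_BOUNDS = {"percentage": (0.0, 100.0), "ice": (-1.0, 1.0)}


@dataclass(frozen=True)
class VariableMeta:
    """Kind and dimension membership of one processed variable."""

    kind: str
    dimension: str

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise SchemaError(
                f"unknown variable kind {self.kind!r}; expected one of {VALID_KINDS}"
            )


@dataclass
class VariableTable:
    """Rectangular units x variables matrix with per-unit weights.

    The common currency of the pipeline: ``values`` is indexed by unit id,
    one column per processed variable; ``weights`` are the per-unit
    expansion weights; ``meta`` maps each column to its
    :class:`VariableMeta`.
    """

    values: pd.DataFrame
    weights: pd.Series
    meta: Mapping[str, VariableMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.weights = pd.Series(self.weights)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise SchemaError(f"duplicated unit_id(s): {dupes}")
        if idx.isna().any():
            raise SchemaError("missing unit_id in table index")
        if not self.weights.index.equals(idx):
            self.weights = self.weights.reindex(idx)
        if self.weights.isna().any() or (self.weights <= 0).any():
            bad = self.weights.index[~(self.weights > 0)].tolist()
            raise DataError(f"non-positive or missing weight for unit(s): {bad}")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise DataError(f"missing values for unit(s): {bad}")
        for var, m in self.meta.items():
            if var not in self.values.columns:
                raise SchemaError(f"metadata names unknown column {var!r}")
            bounds = _KIND_BOUNDS.get(m.kind)
            if bounds is not None:
                col = self.values[var].to_numpy(float)
                lo, hi = bounds
                if (col < lo - 1e-9).any() or (col > hi + 1e-9).any():
                    raise DataError(
                        f"column {var!r} of kind {m.kind!r} outside [{lo}, {hi}]"
                    )

    # -- conveniences -----------------------------------------------------
    @property
    def unit_ids(self) -> pd.Index:
        return self.values.index

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_units(self) -> int:
        return len(self.values)

    def subset(self, variables: list[str]) -> "VariableTable":
        """Column subset preserving unit order, weights and metadata."""
        missing = [v for v in variables if v not in self.values.columns]
        if missing:
            raise SchemaError(f"unknown variable(s): {missing}")
        meta = {v: self.meta[v] for v in variables if v in self.meta}
        return VariableTable(self.values[variables].copy(), self.weights.copy(), meta)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# weighted tabulation ("second step": records -> per-unit processed values)
# ---------------------------------------------------------------------------

def _as_series(x, name):
    s = pd.Series(x, name=name)
    return s.reset_index(drop=True)


def weighted_percentage(counts, totals, weights=None, by=None) -> pd.Series:
    """Expansion-weighted percentage per unit, on the 0-100 scale.

    With sub-records grouped by ``by``, each unit gets
    ``100 * sum(w * count) / sum(w * total)``; with one record per unit
    (``by=None``) this reduces to ``100 * count / total``.
    """
    unit_index = counts.index if isinstance(counts, pd.Series) else None
    counts = _as_series(counts, "count").astype(float)
    totals = _as_series(totals, "total").astype(float)
    if weights is None:
        weights = pd.Series(1.0, index=counts.index)
    else:
        weights = _as_series(weights, "weight").astype(float)
    if (counts < 0).any() or (totals < 0).any():
        raise DataError("counts and totals must be nonnegative")
    if (counts > totals).any():
        raise DataError("count exceeds total in at least one record")
    if (weights <= 0).any():
        raise DataError("weights must be positive")
    num = weights * counts
    den = weights * totals
    if by is None:
        if (den == 0).any():
            raise DataError("zero denominator with by=None")
        out = 100.0 * num / den
        out.name = None
        if unit_index is not None:
            out.index = unit_index
        return out
    by = _as_series(by, "unit")
    num_g = num.groupby(by, sort=False).sum()
    den_g = den.groupby(by, sort=False).sum()
    if (den_g == 0).any():
        bad = den_g.index[den_g == 0].tolist()
        raise DataError(f"zero pooled denominator for unit(s): {bad}")
    out = 100.0 * num_g / den_g
    out.index.name = None
    return out


def weighted_mean(values, weights=None, by=None) -> float | pd.Series:
    """Expansion-weighted mean ``sum(w*x)/sum(w)``, optionally per unit."""
    values = _as_series(values, "value").astype(float)
    if weights is None:
        weights = pd.Series(1.0, index=values.index)
    else:
        weights = _as_series(weights, "weight").astype(float)
    if (weights < 0).any():
        raise DataError("weights must be nonnegative")
    if by is None:
        sw = weights.sum()
        if sw == 0:
            raise DegenerateInputError("all weights zero")
        return float((weights * values).sum() / sw)
    by = _as_series(by, "unit")
    sw = weights.groupby(by, sort=False).sum()
    if (sw == 0).any():
        bad = sw.index[sw == 0].tolist()
        raise DegenerateInputError(f"all-zero weights for unit(s): {bad}")
    out = (weights * values).groupby(by, sort=False).sum() / sw
    out.index.name = None
    return out


# ---------------------------------------------------------------------------
# CSV reader / writers
# ---------------------------------------------------------------------------

def _read_csv(path, dialect: str) -> pd.DataFrame:
    if dialect == "standard":
        return pd.read_csv(path)
    if dialect == "br":
        # Brazilian sources: semicolon separator, comma decimal
        return pd.read_csv(path, sep=";", decimal=",")
    raise SchemaError(f"unknown CSV dialect {dialect!r}")


def read_variable_table(
    path,
    meta: Mapping[str, VariableMeta],
    dialect: str = "standard",
    unit_col: str = "unit_id",
    weight_col: str = "weight",
) -> VariableTable:
    """Read a per-unit variable CSV (one row per unit) into a validated table."""
    df = _read_csv(path, dialect)
    required = {unit_col, weight_col}
    if not required.issubset(df.columns):
        raise SchemaError(f"CSV must contain columns {sorted(required)}")
    unknown = [c for c in df.columns if c not in required and c not in meta]
    if unknown:
        raise SchemaError(f"unknown column(s) not in metadata: {unknown}")
    missing = [v for v in meta if v not in df.columns]
    if missing:
        raise SchemaError(f"metadata variable(s) absent from CSV: {missing}")
    for col in list(meta) + [weight_col]:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.loc[coerced.isna() & df[col].notna(), unit_col].tolist()
            if bad:
                raise DataError(f"non-numeric value in {col!r} for unit(s): {bad}")
            df[col] = coerced
    values = df.set_index(unit_col)[list(meta)]
    weights = df.set_index(unit_col)[weight_col]
    return VariableTable(values, weights, dict(meta))


def write_variable_table(path, table: VariableTable) -> None:
    df = table.values.copy()
    df.insert(0, "weight", table.weights)
    df.index.name = "unit_id"
    df.to_csv(path, float_format="%.17g")


def write_scores(path, result) -> None:
    """Write a fitted index result: unit_id, score, raw score, and the
    original-unit values of each dimension's representative variable.

    Column order is stable: unit_id, geoses, geoses_raw, then one
    ``<dimension>:<variable>`` column per active dimension in registry order.
    """
    df = pd.DataFrame({"geoses": result.scores, "geoses_raw": result.raw_scores})
    for dim, rep in result.dimension_representative.items():
        df[f"{dim}:{rep.variable}"] = rep.values
    df.index.name = "unit_id"
    try:
        df.to_csv(path, float_format="%.17g")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise DataError(f"cannot write scores to {path}: {exc}") from exc


def read_scores(path) -> pd.DataFrame:
    """Read back a scores CSV written by :func:`write_scores`."""
    df = pd.read_csv(path).set_index("unit_id")
    if "geoses" not in df.columns:
        raise SchemaError("scores CSV lacks a 'geoses' column")
    return df
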