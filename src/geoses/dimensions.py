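"""Seven-dimension registry and the Index of Concentration at the Extremes.

The index groups its input variables into seven themed dimensions of
socioeconomic context — education, mobility, poverty, wealth, income,
segregation and material deprivation / access to services.  Residential
segregation is measured with the Index of Concentration at the Extremes
(ICE): for an area, the number of people in the privileged extreme
(above the 80th percentile of the reference distribution) minus the
number in the deprived extreme (below the 20th percentile), divided by
the total reference population of the area.  ICE ranges from -1 (area
entirely in the deprived extreme) to +1 (entirely privileged); 0 means
the area is not dominated by either extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, RegistryError
from .io import VariableMeta, VariableTable

#: canonical dimension names, in registry order
DIMENSIONS = (
    "education",
    "mobility",
    "poverty",
    "wealth",
    "income",
    "segregation",
    "deprivation",
)


@dataclass
class DimensionRegistry:
    """Ordered partition of variables into dimensions, with polarity and kind.

    ``polarity`` records whether a variable rises (+1) or falls (-1) with
    socioeconomic advantage; it is metadata for orientation and reporting,
    never applied as a sign flip of the data itself.
    """

    dimensions: dict[str, list[str]]
    polarity: dict[str, int]
    kind: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for dim, variables in self.dimensions.items():
            if not variables:
                raise RegistryError(f"dimension {dim!r} has no variables")
            for v in variables:
                if v in seen:
                    raise RegistryError(
                        f"variable {v!r} assigned to both {seen[v]!r} and {dim!r}"
                    )
                seen[v] = dim
        for v in seen:
            p = self.polarity.get(v)
            if p not in (+1, -1):
                raise RegistryError(f"variable {v!r} needs polarity +1 or -1")
            self.kind.setdefault(v, "percentage")

    # -- views ------------------------------------------------------------
    @property
    def variables(self) -> list[str]:
        """All variables in registry (dimension, then within-dimension) order."""
        return [v for vs in self.dimensions.values() for v in vs]

    def dimension_of(self, variable: str) -> str:
        for dim, vs in self.dimensions.items():
            if variable in vs:
                return dim
        raise RegistryError(f"variable {variable!r} not in registry")

    def variable_meta(self) -> dict[str, VariableMeta]:
        return {
            v: VariableMeta(kind=self.kind[v], dimension=dim)
            for dim, vs in self.dimensions.items()
            for v in vs
        }

    # -- serialisation: {dimension: {variable: {kind, polarity}}} ----------
    @classmethod
    def from_dict(cls, data: Mapping) -> "DimensionRegistry":
        dims: dict[str, list[str]] = {}
        pol: dict[str, int] = {}
        kind: dict[str, str] = {}
        for dim, variables in data.items():
            dims[dim] = list(variables)
            for v, spec in variables.items():
                pol[v] = int(spec.get("polarity", 1))
                kind[v] = spec.get("kind", "percentage")
        return cls(dims, pol, kind)

    @classmethod
    def from_yaml(cls, path) -> "DimensionRegistry":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            dim: {v: {"kind": self.kind[v], "polarity": self.polarity[v]} for v in vs}
            for dim, vs in self.dimensions.items()
        }

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# ICE
# ---------------------------------------------------------------------------

@dataclass
class ExtremeCounts:
    """Per-unit counts in the extreme groups of a reference population."""

    privileged: pd.Series
    deprived: pd.Series
    total: pd.Series

    def __post_init__(self) -> None:
        self.privileged = pd.Series(self.privileged).astype(float)
        self.deprived = pd.Series(self.deprived).astype(float)
        self.total = pd.Series(self.total).astype(float)
        for name, s in (
            ("privileged", self.privileged),
            ("deprived", self.deprived),
            ("total", self.total),
        ):
            if (s < 0).any():
                raise DataError(f"negative {name} count")
        if ((self.privileged + self.deprived) > self.total + 1e-9).any():
            raise DataError("privileged + deprived exceeds total for some unit")


def compute_ice(x: ExtremeCounts) -> pd.Series:
    """ICE_i = (privileged_i - deprived_i) / total_i, in [-1, 1].

    Units with ``total == 0`` have no reference population and no defined
    ICE; they raise rather than being silently set to zero.
    """
    zero = x.total == 0
    if zero.any():
        raise DataError(f"ICE undefined (total=0) for unit(s): {x.total.index[zero].tolist()}")
    ice = (x.privileged - x.deprived) / x.total
    return ice.clip(-1.0, 1.0)


def extreme_thresholds(values, weights=None) -> tuple[float, float]:
    """Weighted 20th/80th percentiles of the pooled reference population.

    The pinned definition is the Weibull plotting position (the classic
    "type 6" sample percentile): observation ``k`` of ``n`` sits at
    probability ``k/(n+1)`` and quantiles are linear interpolations
    between adjacent order statistics, clamped at the extremes.  Under
    general weights the position of an observation is its cumulative
    weight share rescaled by ``n/(n+1)``, which reduces to ``k/(n+1)``
    for unit weights and is invariant to positive rescaling of weights.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("empty reference population")
    if weights is None:
        w = np.ones_like(v)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != v.shape:
            raise DataError("values and weights must have equal length")
        if (w < 0).any():
            raise DataError("negative weights")
    keep = w > 0
    v, w = v[keep], w[keep]
    if v.size < 5:
        raise DataError("need at least 5 observations with positive weight")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    n = v.size
    pos = np.cumsum(w) / w.sum() * (n / (n + 1.0))
    p20 = float(np.interp(0.20, pos, v))
    p80 = float(np.interp(0.80, pos, v))
    return p20, p80


def ice_from_values(values, weights, unit_of) -> pd.Series:
    """End-to-end ICE from person-level values: pooled thresholds, then
    per-unit extreme counts (weighted persons below p20 / above p80)."""
    p20, p80 = extreme_thresholds(values, weights)
    v = np.asarray(values, dtype=float)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    unit = pd.Series(unit_of)
    df = pd.DataFrame({"unit": unit.to_numpy(), "w": w})
    df["depr"] = np.where(v < p20, w, 0.0)
    df["priv"] = np.where(v > p80, w, 0.0)
    g = df.groupby("unit", sort=False).sum()
    return compute_ice(ExtremeCounts(g["priv"], g["depr"], g["w"]))


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------

def partition_by_dimension(
    table: VariableTable, registry: DimensionRegistry
) -> dict[str, VariableTable]:
    """Split a table's columns into per-dimension sub-tables.

    Columns are disjoint across the output and union to the input;
    unit order is preserved.  Dimensions with no columns in the table are
    omitted (a dimension may be inactive in a given analysis).
    """
    known = set(registry.variables)
    unknown = [c for c in table.variables if c not in known]
    if unknown:
        raise RegistryError(f"table column(s) not in registry: {unknown}")
    out: dict[str, VariableTable] = {}
    for dim, variables in registry.dimensions.items():
        cols = [v for v in variables if v in table.values.columns]
        if cols:
            out[dim] = table.subset(cols)
    return out
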