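"""Content and construct validation of a fitted index.

Content validation asks whether the retained items form an internally
consistent scale (Cronbach's alpha); construct validation compares the
index and its dimension representatives against an external benchmark
index through a Pearson correlation matrix; and the interpretation layer
decomposes the index by reporting, per dimension, the variable most
correlated with the final scores in its original units, so a value like
"45.78% without schooling" can be compared across areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dimensions import DimensionRegistry, partition_by_dimension
from .errors import DegenerateInputError
from .io import VariableTable


@dataclass
class ValidationReport:
    cronbach_alpha: float
    correlations: pd.DataFrame
    dimension_representative: dict[str, object] = field(default_factory=dict)


def cronbach_alpha(
    table: VariableTable,
    items: list[str] | None = None,
    polarity: dict[str, int] | None = None,
) -> float:
    """Internal-consistency alpha of an item set.

    alpha = k/(k-1) * (1 - sum(var_j) / var(total)), computed on
    z-scored items whose signs are aligned by polarity so every item
    points toward advantage; mixed-direction items would otherwise
    spuriously deflate alpha.  With z-scored items var_j = 1, so
    alpha = k/(k-1) * (1 - k / var(sum of items)).
    """
    items = items or table.variables
    if len(items) < 2:
        raise DegenerateInputError("alpha needs >= 2 items")
    X = table.values[items].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if (sd <= 0).any():
        bad = [items[j] for j in np.flatnonzero(sd <= 0)]
        raise DegenerateInputError(f"zero-variance item(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    if polarity:
        signs = np.array([polarity.get(v, 1) for v in items], dtype=float)
        Z = Z * signs
    k = len(items)
    total_var = Z.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DegenerateInputError("zero total variance across items")
    return float(k / (k - 1) * (1.0 - k / total_var))


def correlation_matrix(columns: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of named per-unit vectors.

    Symmetric with unit diagonal; constant columns are a named error
    rather than NaN rows.
    """
    df = pd.DataFrame(columns)
    if len(df) < 3:
        raise DegenerateInputError("need >= 3 units for correlations")
    sd = df.std(ddof=1)
    bad = sd.index[~(sd > 0)].tolist()
    if bad:
        raise DegenerateInputError(f"constant column(s): {bad}")
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def dimension_contribution(
    result,
    table: VariableTable,
    registry: DimensionRegistry,
) -> dict[str, object]:
    """Per dimension, the variable most |correlated| with the final scores.

    The representative is reported with its original-unit values (the
    pre-shift processed table), so dimension contributions stay readable
    as percentages, mean incomes, or ICE values.  Empty dimensions are
    skipped.  Ties break by registry order.
    """
    from .pipeline import Representative  # local: avoid import cycle

    scores = result.scores
    out: dict[str, Representative] = {}
    for dim, sub in partition_by_dimension(table, registry).items():
        best: tuple[float, str] | None = None
        for v in sub.variables:
            col = sub.values[v]
            if col.std(ddof=1) <= 0:
                continue
            r = float(np.corrcoef(col.to_numpy(float), scores.to_numpy(float))[0, 1])
            if best is None or abs(r) > abs(best[0]) + 1e-12:
                best = (r, v)
        if best is not None:
            r, v = best
            out[dim] = Representative(variable=v, correlation=r, values=table.values[v])
    return out


def validation_report(
    result,
    table: VariableTable,
    registry: DimensionRegistry,
    external: pd.DataFrame | pd.Series | None = None,
    alpha_items: str = "retained",
) -> ValidationReport:
    """Assemble alpha + correlation matrix + dimension decomposition.

    ``alpha_items`` selects the item set: ``"retained"`` (the variables
    the index actually uses, default) or ``"all"`` (pre-pruning set).
    ``external`` supplies benchmark column(s) (e.g. a human-development
    index) aligned on unit id.
    """
    items = result.retained_variables if alpha_items == "retained" else table.variables
    alpha = cronbach_alpha(table, items=items, polarity=registry.polarity)

    reps = dimension_contribution(result, table, registry)
    cols = {"geoses": result.scores}
    for dim, rep in reps.items():
        cols[f"{dim}:{rep.variable}"] = rep.values
    frame = pd.DataFrame(cols)
    if external is not None:
        ext = pd.DataFrame(external)
        frame = frame.join(ext, how="inner")
    corr = correlation_matrix(frame)
    return ValidationReport(
        cronbach_alpha=alpha, correlations=corr, dimension_representative=reps
    )
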