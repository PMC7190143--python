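"""The staged-PCA index pipeline.

The composite index is the first principal component of a pruned set of
census variables, computed on the *correlation* matrix throughout, then
min-max standardized to [-1, 1]:

0. Preprocessing: add a constant (default 10) to every value.  Under
   correlation-matrix PCA this shift is inert — it exists to keep the
   covariance computation away from poorly conditioned raw scales and is
   verified to leave final scores unchanged.
1. Within each dimension, run a PCA; keep the smallest number of
   components whose cumulative explained variance reaches the threshold
   (default 75%), and select the variable with the largest absolute
   loading on each kept component.
2. Pool all selected variables and take the first principal component.
3. Prune variables whose absolute first-component loading falls below
   the mean absolute loading; re-fit the PCA once on the remainder.
   Its first component defines the index.
4. Score each unit by projecting its z-scored values on the final
   loadings.
5. Standardize scores linearly so the minimum unit maps to -1 and the
   maximum to +1.

PCA signs are intrinsically arbitrary; an explicit orientation step
fixes them so that a reference variable (by default an income-type,
advantage-positive variable) loads positively, making higher scores mean
better socioeconomic context.

Everything here is deterministic: eigendecomposition of an explicitly
formed correlation matrix, no iterative solver, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dimensions import DimensionRegistry, partition_by_dimension
from .errors import (
    ConfigurationError,
    DataError,
    DegenerateInputError,
    PipelineError,
)
from .io import VariableTable

PRUNE_RULES = ("below_mean_abs", "below_mean_signed")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the index pipeline.

    shift_constant
        Added to every value before analysis; inert under correlation
        PCA (kept for fidelity to the published procedure).
    variance_threshold
        Cumulative explained-variance target of the per-dimension
        selection step, in (0, 1].
    prune_rule
        ``below_mean_abs`` removes variables with |loading| below the
        mean of |loadings| (default); ``below_mean_signed`` compares
        signed loadings to their signed mean (alternative reading).
    orientation_reference
        Variable whose loading is forced positive, or ``"auto"``.
    iterate_prune
        Repeat the prune/re-fit cycle until no variable falls below the
        mean (off by default: the procedure is a single pass).
    """

    shift_constant: float = 10.0
    variance_threshold: float = 0.75
    prune_rule: str = "below_mean_abs"
    orientation_reference: str = "auto"
    iterate_prune: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ConfigurationError("variance_threshold must be in (0, 1]")
        if self.prune_rule not in PRUNE_RULES:
            raise ConfigurationError(f"prune_rule must be one of {PRUNE_RULES}")


@dataclass
class PCAResult:
    """Correlation-matrix PCA: loadings, explained variance, z-scaling."""

    variables: list[str]
    loadings: np.ndarray  # variables x components, orthonormal columns
    explained_ratio: np.ndarray
    center: np.ndarray
    scale: np.ndarray

    def first_component(self) -> pd.Series:
        return pd.Series(self.loadings[:, 0], index=self.variables)

    def flipped(self) -> "PCAResult":
        return PCAResult(
            list(self.variables),
            self.loadings * np.array([-1.0] + [1.0] * (self.loadings.shape[1] - 1)),
            self.explained_ratio.copy(),
            self.center.copy(),
            self.scale.copy(),
        )


@dataclass
class Representative:
    """A dimension's most score-correlated variable, in original units."""

    variable: str
    correlation: float
    values: pd.Series


@dataclass
class GeoSESResult:
    """Fitted index: final variables, loadings, raw and [-1,1] scores."""

    retained_variables: list[str]
    loadings: pd.Series
    raw_scores: pd.Series
    scores: pd.Series
    step1_selection: dict[str, list[str]]
    dimension_representative: dict[str, Representative] = field(default_factory=dict)
    final_pca: PCAResult | None = None
    log: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def preprocess_shift(table: VariableTable, c: float) -> VariableTable:
    """Add a constant to every value; metadata and weights unchanged.

    The shifted table intentionally drops kind-range validation metadata
    (a percentage plus 10 is no longer in [0, 100]); the shift is an
    internal numerical step, not a new processed table.
    """
    shifted = table.values + float(c)
    return VariableTable(shifted, table.weights.copy(), {})


def _correlation_matrix(X: np.ndarray, variables: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    bad = [variables[j] for j in np.flatnonzero(scale <= 0)]
    if bad:
        raise DegenerateInputError(f"zero-variance column(s): {bad}")
    Z = (X - center) / scale
    R = (Z.T @ Z) / (X.shape[0] - 1)
    # exact symmetry and unit diagonal: float summation order must not
    # leak into downstream tie-breaks
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return R, center, scale


def _fix_column_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic provisional signs: largest-|entry| coordinate positive."""
    out = vecs.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        k = int(np.argmax(np.abs(col)))
        if col[k] < 0:
            out[:, j] = -col
    return out


def pca_correlation(table: VariableTable) -> PCAResult:
    """Eigendecomposition of the correlation matrix of the table's columns.

    Components are ordered by explained variance (descending); each
    eigenvector's sign is fixed deterministically (final orientation of
    the first component is a separate, explicit step).
    """
    X = table.matrix()
    n, p = X.shape
    if p < 2:
        raise DegenerateInputError("PCA needs at least 2 variables")
    if n < 3:
        raise DegenerateInputError("PCA needs at least 3 units")
    R, center, scale = _correlation_matrix(X, table.variables)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = _fix_column_signs(eigvec[:, order])
    return PCAResult(
        variables=table.variables,
        loadings=eigvec,
        explained_ratio=eigval / eigval.sum(),
        center=center,
        scale=scale,
    )


def step1_select(dim_table: VariableTable, threshold: float) -> list[str]:
    """Per-dimension selection: top |loading| variable of each of the
    components needed to reach the explained-variance threshold.

    Single-variable dimensions pass through unchanged.  A variable that
    tops two components is selected once; ties go to the earlier column.
    """
    variables = dim_table.variables
    if len(variables) == 0:
        raise DegenerateInputError("empty dimension table")
    if len(variables) == 1:
        return list(variables)
    pca = pca_correlation(dim_table)
    cum = np.cumsum(pca.explained_ratio)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, len(variables))
    selected: list[str] = []
    for j in range(k):
        col = np.abs(pca.loadings[:, j])
        # loadings within 1e-9 of the top count as tied (a two-variable
        # block has an analytically symmetric eigenvector, so float noise
        # must not decide); ties go to the earlier registry position
        winner = variables[int(np.flatnonzero(col >= col.max() - 1e-9)[0])]
        if winner not in selected:
            selected.append(winner)
    return selected


def step2_overall(table: VariableTable) -> PCAResult:
    """First principal component over the pooled step-1 selections."""
    if len(table.variables) < 2:
        raise PipelineError(
            "overall PCA needs >= 2 selected variables; "
            f"got {table.variables}"
        )
    return pca_correlation(table)


def step3_prune(
    pc: PCAResult,
    table: VariableTable,
    rule: str = "below_mean_abs",
    iterate: bool = False,
) -> tuple[list[str], PCAResult, list[str]]:
    """Remove low-contribution variables and re-fit.

    Variables whose first-component loading falls below the mean (of
    absolute loadings under the default rule) are eliminated and the PCA
    re-run on the remainder; the refit's first component defines the
    index.  If nothing falls below the mean the refit is skipped.

    Returns (retained variables, final PCA, pruned variables).
    """
    if rule not in PRUNE_RULES:
        raise ConfigurationError(f"unknown prune rule {rule!r}")
    current = pc
    pruned_all: list[str] = []
    while True:
        lo = current.loadings[:, 0]
        crit = np.abs(lo) if rule == "below_mean_abs" else lo
        # margin keeps float noise (row order, shift constant) from
        # flipping boundary cases
        below = crit < crit.mean() - 1e-9
        if not below.any():
            return list(current.variables), current, pruned_all
        keep = [v for v, b in zip(current.variables, below) if not b]
        pruned_all += [v for v, b in zip(current.variables, below) if b]
        if len(keep) < 2:
            raise PipelineError(
                f"pruning would leave {len(keep)} variable(s) ({keep}); "
                "review the variance threshold or input variables"
            )
        current = pca_correlation(table.subset(keep))
        if not iterate:
            return list(current.variables), current, pruned_all


def orient(
    pc: PCAResult,
    reference: str = "auto",
    registry: DimensionRegistry | None = None,
) -> tuple[PCAResult, str, bool]:
    """Fix the first component's sign so the reference variable loads > 0.

    ``"auto"`` picks, among the component's variables, the first
    advantage-positive (polarity +1) income-dimension variable in
    registry order, else the first polarity +1 variable, else the first
    variable.  Returns (oriented PCA, reference used, whether flipped).
    """
    if reference == "auto":
        if registry is None:
            reference = pc.variables[0]
        else:
            income = [
                v
                for v in registry.dimensions.get("income", [])
                if v in pc.variables and registry.polarity.get(v) == 1
            ]
            positive = [
                v
                for v in registry.variables
                if v in pc.variables and registry.polarity.get(v) == 1
            ]
            reference = (income or positive or [pc.variables[0]])[0]
    if reference not in pc.variables:
        raise ConfigurationError(
            f"orientation reference {reference!r} not among {pc.variables}"
        )
    j = pc.variables.index(reference)
    if pc.loadings[j, 0] < 0:
        return pc.flipped(), reference, True
    return pc, reference, False


def compute_scores(table: VariableTable, core: PCAResult) -> pd.Series:
    """Raw score: projection of z-scored retained variables on the final
    first-component loadings, using the final PCA's centers and scales."""
    missing = [v for v in core.variables if v not in table.values.columns]
    if missing:
        raise DataError(f"table lacks retained variable(s): {missing}")
    X = table.values[core.variables].to_numpy(float)
    Z = (X - core.center) / core.scale
    return pd.Series(Z @ core.loadings[:, 0], index=table.unit_ids)


def standardize(raw: pd.Series) -> pd.Series:
    """Affine map of raw scores onto [-1, 1]: min -> -1, max -> +1."""
    raw = pd.Series(raw)
    lo, hi = float(raw.min()), float(raw.max())
    if not hi > lo:
        raise DegenerateInputError("all raw scores equal; scores undefined")
    return 2.0 * (raw - lo) / (hi - lo) - 1.0


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def run_pipeline(
    table: VariableTable,
    registry: DimensionRegistry,
    config: PipelineConfig | None = None,
) -> GeoSESResult:
    """Execute shift -> per-dimension selection -> overall PCA -> prune ->
    orient -> score -> standardize, logging every decision."""
    from .evaluation import dimension_contribution  # local: avoid cycle

    config = config or PipelineConfig()
    log: list[str] = []

    shifted = preprocess_shift(table, config.shift_constant)
    shifted.meta = {}  # ranges no longer meaningful post-shift

    step1: dict[str, list[str]] = {}
    for dim, sub in partition_by_dimension(shifted, registry).items():
        sel = step1_select(sub, config.variance_threshold)
        step1[dim] = sel
        log.append(f"step1 {dim}: {len(sub.variables)} var(s) -> selected {sel}")

    pooled = [v for sel in step1.values() for v in sel]
    # keep registry order for determinism of downstream tie-breaks
    pooled = [v for v in registry.variables if v in pooled]
    overall = step2_overall(shifted.subset(pooled))
    log.append(f"step2: overall PCA on {pooled}")

    retained, final_pca, pruned = step3_prune(
        overall, shifted, rule=config.prune_rule, iterate=config.iterate_prune
    )
    if pruned:
        log.append(f"step3: pruned {pruned}; retained {retained}")
    else:
        log.append("step3: nothing below mean loading; refit skipped")

    final_pca, ref, flipped = orient(
        final_pca, config.orientation_reference, registry
    )
    log.append(f"orient: reference {ref!r}, flipped={flipped}")

    raw = compute_scores(shifted, final_pca)
    scores = standardize(raw)

    result = GeoSESResult(
        retained_variables=list(final_pca.variables),
        loadings=final_pca.first_component(),
        raw_scores=raw,
        scores=scores,
        step1_selection=step1,
        final_pca=final_pca,
        log=log,
    )
    result.dimension_representative = dimension_contribution(result, table, registry)
    return result
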