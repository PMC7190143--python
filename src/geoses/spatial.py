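"""Applicability layer: standardized risks, regression, spatial diagnostics.

To check that an area-level socioeconomic index actually explains a
health outcome, the workflow is: (1) indirectly standardize stratified
event counts (by e.g. sex and age band) into per-area relative risks,
(2) regress risk on the index with OLS, and (3) test the residuals for
leftover spatial structure with Moran's I under Queen-contiguity
weights, using a seeded permutation null.  Residual spatial dependence
(p < 0.05 by convention) signals that a spatially varying model — e.g.
geographically weighted regression, run in external GIS tooling — is
warranted; that step is deliberately outside this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError, DegenerateInputError, WeightsError


# ---------------------------------------------------------------------------
# spatial weights
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeights:
    """Symmetric binary contiguity structure over the analysis units."""

    neighbors: dict[object, set]

    def __post_init__(self) -> None:
        for i, ns in self.neighbors.items():
            self.neighbors[i] = set(ns)
        for i, ns in self.neighbors.items():
            if i in ns:
                raise WeightsError(f"unit {i!r} is its own neighbor")
            if not ns:
                raise WeightsError(f"island unit {i!r} has no neighbors")
            for j in ns:
                if j not in self.neighbors:
                    raise WeightsError(f"neighbor {j!r} of {i!r} is not a unit")
                if i not in self.neighbors[j]:
                    raise WeightsError(f"asymmetric pair ({i!r}, {j!r})")

    @property
    def ids(self) -> list:
        return list(self.neighbors)

    @property
    def n(self) -> int:
        return len(self.neighbors)

    def matrix(self, ids=None, row_standardized: bool = False) -> np.ndarray:
        ids = list(ids) if ids is not None else self.ids
        pos = {u: k for k, u in enumerate(ids)}
        W = np.zeros((len(ids), len(ids)))
        for i, ns in self.neighbors.items():
            if i not in pos:
                continue
            for j in ns:
                if j in pos:
                    W[pos[i], pos[j]] = 1.0
        if row_standardized:
            rs = W.sum(axis=1, keepdims=True)
            if (rs == 0).any():
                raise WeightsError("row-standardizing weights with an empty row")
            W = W / rs
        return W


def queen_lattice(n_rows: int, n_cols: int, ids=None) -> SpatialWeights:
    """Queen contiguity on a rectangular grid (8 neighbors interior,
    5 on an edge, 3 in a corner), the synthetic stand-in for polygon
    contiguity."""
    if n_rows * n_cols < 2:
        raise WeightsError("lattice needs at least 2 cells")
    if ids is None:
        ids = list(range(n_rows * n_cols))
    if len(ids) != n_rows * n_cols:
        raise WeightsError("ids length must equal n_rows * n_cols")
    grid = np.array(ids, dtype=object).reshape(n_rows, n_cols)
    nbrs: dict[object, set] = {i: set() for i in ids}
    for r in range(n_rows):
        for c in range(n_cols):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < n_rows and 0 <= cc < n_cols:
                        nbrs[grid[r, c]].add(grid[rr, cc])
    return SpatialWeights(nbrs)


def rook_lattice(n_rows: int, n_cols: int, ids=None) -> SpatialWeights:
    """Rook (edge-sharing only) contiguity on a rectangular grid."""
    if ids is None:
        ids = list(range(n_rows * n_cols))
    grid = np.array(ids, dtype=object).reshape(n_rows, n_cols)
    nbrs: dict[object, set] = {i: set() for i in ids}
    for r in range(n_rows):
        for c in range(n_cols):
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    nbrs[grid[r, c]].add(grid[rr, cc])
    return SpatialWeights(nbrs)


def read_gal(path) -> SpatialWeights:
    """Read a GAL neighbor file (GeoDa exchange dialect).

    First line: unit count (optionally preceded by a '0' flag and
    followed by dataset/key fields, all ignored except the count); then
    per unit a header line ``id n_neighbors`` and a line of neighbor ids.
    """
    with open(path, "r", encoding="utf-8") as fh:
        tokens_lines = [ln.split() for ln in fh if ln.strip()]
    if not tokens_lines:
        raise DataError("empty GAL file")
    header = tokens_lines[0]
    # GeoDa writes "0 n shapefile key"; plain files write just "n"
    n = int(header[1]) if len(header) >= 2 and header[0] == "0" else int(header[0])
    flat = [t for line in tokens_lines[1:] for t in line]
    nbrs: dict[object, set] = {}
    k = 0
    for _ in range(n):
        if k + 1 >= len(flat) + 1:
            raise DataError("truncated GAL file")
        uid, cnt = flat[k], int(flat[k + 1])
        k += 2
        if k + cnt > len(flat):
            raise DataError(f"truncated neighbor list for unit {uid!r}")
        nbrs[uid] = set(flat[k : k + cnt])
        k += cnt
    if len(nbrs) != n:
        raise DataError("GAL header count does not match record count")
    unknown = {j for ns in nbrs.values() for j in ns if j not in nbrs}
    if unknown:
        raise DataError(f"GAL references unknown id(s): {sorted(unknown)}")
    try:
        return SpatialWeights(nbrs)
    except WeightsError as exc:
        raise DataError(f"invalid GAL structure: {exc}") from exc


def write_gal(path, w: SpatialWeights) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{w.n}\n")
        for i in w.ids:
            ns = sorted(w.neighbors[i], key=str)
            fh.write(f"{i} {len(ns)}\n")
            fh.write(" ".join(str(j) for j in ns) + "\n")


# ---------------------------------------------------------------------------
# indirect standardization
# ---------------------------------------------------------------------------

@dataclass
class OutcomeTable:
    """Per-unit observed/expected events and relative risks."""

    observed: pd.Series
    expected: pd.Series
    relative_risk: pd.Series
    reference_rates: pd.Series


def indirect_standardize(
    outcome: pd.DataFrame,
    reference: pd.Series | str = "internal",
    min_expected_warn: float = 5.0,
) -> OutcomeTable:
    """Indirect standardization of stratified counts into relative risks.

    ``outcome`` is tidy: columns unit_id, stratum, population, events.
    Expected events per unit apply per-stratum reference rates to the
    unit's stratum populations: ``expected_i = sum_s rate_s * pop_is``;
    the relative risk is ``observed_i / expected_i``.  The ``"internal"``
    reference pools rates from the data itself
    (``rate_s = sum_i events_is / sum_i pop_is``), which makes total
    expected equal total observed exactly.

    Risks built on few expected events are unstable; units below
    ``min_expected_warn`` expected events trigger a warning rather than
    any smoothing.
    """
    required = {"unit_id", "stratum", "population", "events"}
    if not required.issubset(outcome.columns):
        raise DataError(f"outcome table needs columns {sorted(required)}")
    df = outcome.copy()
    if (df["population"] < 0).any():
        raise DataError("negative populations")
    if (df["events"] < 0).any():
        raise DataError("negative event counts")
    if ((df["population"] == 0) & (df["events"] > 0)).any():
        raise DataError("events observed in a stratum with zero population")

    if isinstance(reference, str):
        if reference != "internal":
            raise DataError(f"unknown reference {reference!r}")
        g = df.groupby("stratum", sort=False)
        pop = g["population"].sum()
        if (pop == 0).any():
            rates = (g["events"].sum() / pop).fillna(0.0)
        else:
            rates = g["events"].sum() / pop
    else:
        rates = pd.Series(reference, dtype=float)
        missing = set(df["stratum"]) - set(rates.index)
        if missing:
            raise DataError(f"reference rates missing strata: {sorted(missing)}")

    df["_rate"] = df["stratum"].map(rates)
    df["_exp"] = df["_rate"] * df["population"]
    per_unit = df.groupby("unit_id", sort=False)
    observed = per_unit["events"].sum().astype(float)
    expected = per_unit["_exp"].sum()
    bad = expected.index[(expected == 0) & (observed > 0)].tolist()
    if bad:
        raise DataError(f"zero expected with observed events for unit(s): {bad}")
    low = expected.index[(expected > 0) & (expected < min_expected_warn)].tolist()
    if low:
        warnings.warn(
            f"{len(low)} unit(s) have expected events < {min_expected_warn}; "
            "their relative risks are unstable",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rr = observed / expected
    return OutcomeTable(observed, expected, rr, rates.astype(float))


# ---------------------------------------------------------------------------
# regression + Moran's I
# ---------------------------------------------------------------------------

@dataclass
class OLSResult:
    intercept: float
    slope: float
    slope_se: float
    residuals: pd.Series
    adj_r_squared: float
    aic: float


def ols_fit(y, x) -> OLSResult:
    """Simple linear regression of outcome on the index (Gaussian AIC);
    residuals are returned for the spatial diagnostics."""
    y = pd.Series(y).astype(float)
    x = pd.Series(x).astype(float)
    if len(y) != len(x):
        raise DataError("y and x must align")
    if len(y) < 3:
        raise DegenerateInputError("OLS needs >= 3 units")
    if x.std(ddof=1) <= 0:
        raise DegenerateInputError("constant regressor: design is singular")
    X = sm.add_constant(x.to_numpy())
    fit = sm.OLS(y.to_numpy(), X).fit()
    return OLSResult(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        residuals=pd.Series(fit.resid, index=y.index),
        adj_r_squared=float(fit.rsquared_adj),
        aic=float(fit.aic),
    )


def morans_i(
    values,
    w: SpatialWeights,
    n_permutations: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
    return_null: bool = False,
):
    """Global Moran's I with a permutation p-value.

    I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2), with z the
    deviations from the mean and S0 the total weight.  The null
    distribution comes from random relabelings of the values over the
    units (seed-reproducible); the one-sided "greater" p-value is
    (1 + #{I_perm >= I}) / (1 + n_permutations).  With
    ``return_null=True`` the permutation draws are returned as a third
    element (their mean approaches the exact null expectation
    ``-1/(n-1)``).
    """
    values = pd.Series(values)
    if len(values) < 4:
        raise DegenerateInputError("Moran's I needs >= 4 units")
    ids = list(values.index)
    if set(ids) != set(w.neighbors):
        raise WeightsError("weights ids do not match value ids")
    z = values.to_numpy(float)
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise DegenerateInputError("constant values: Moran's I undefined")
    W = w.matrix(ids=ids)
    s0 = W.sum()
    n = len(z)

    def stat(zv: np.ndarray) -> float:
        return float(n / s0 * (zv @ W @ zv) / (zv @ zv))

    I = stat(z)
    if n_permutations <= 0:
        return (I, float("nan"), np.array([])) if return_null else (I, float("nan"))
    if alternative not in ("greater", "less", "two-sided"):
        raise DataError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(seed)
    null = np.array([stat(rng.permutation(z)) for _ in range(n_permutations)])
    if alternative == "greater":
        count = int((null >= I - 1e-15).sum())
    elif alternative == "less":
        count = int((null <= I + 1e-15).sum())
    else:
        count = int((np.abs(null) >= abs(I) - 1e-15).sum())
    p = (1.0 + count) / (1.0 + n_permutations)
    if return_null:
        return I, p, null
    return I, p


def spatial_diagnostics(
    scores,
    outcome: pd.DataFrame,
    weights: SpatialWeights,
    n_permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """Full applicability check: standardize outcome, regress relative
    risk on the index, and test residuals for spatial autocorrelation."""
    std = indirect_standardize(outcome)
    scores = pd.Series(scores)
    rr = std.relative_risk.reindex(scores.index)
    if rr.isna().any():
        raise DataError("outcome lacks units present in scores")
    fit = ols_fit(rr, scores)
    resid_std = (fit.residuals - fit.residuals.mean()) / fit.residuals.std(ddof=1)
    I, p = morans_i(resid_std, weights, n_permutations=n_permutations, seed=seed)
    return {
        "relative_risk": rr,
        "ols": fit,
        "morans_i": I,
        "morans_p": p,
        "residual_spatial_dependence": bool(p < 0.05),
    }
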