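"""Group-level metabolic covariance networks.

A group's network is built across subjects: each ROI's mean-uptake column is
residualized on the nuisance covariates (age, sex) with an intercept, and the
partial correlation between two ROIs is the Pearson correlation of their
residuals.  The resulting symmetric matrix is binarized by a sparsity
threshold — keep the top ``s`` fraction of the R(R−1)/2 node pairs by signed
correlation — over a sweep of sparsities (default 6–40% in 1% steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .roi_io import RoiSignalTable

__all__ = [
    "PartialCorrelationMatrix",
    "BinaryNetworkStack",
    "partial_correlation",
    "binarize_at_sparsity",
    "sparsity_sweep",
    "default_sparsity_grid",
]


@dataclass
class PartialCorrelationMatrix:
    """Covariate-adjusted ROI×ROI association matrix for one group."""

    values: np.ndarray
    roi_names: list[str]
    group_label: str = ""
    n_subjects: int = 0
    covariates_removed: list[str] = field(default_factory=list)
    undefined_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"matrix must be square, got shape {v.shape}")
        if not np.array_equal(v, v.T, equal_nan=True):
            raise ValueError("matrix must be exactly symmetric")
        finite = np.isfinite(v)
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("diagonal must be 1")
        off = v[finite & ~np.eye(len(v), dtype=bool)]
        if off.size and np.max(np.abs(off)) > 1 + 1e-12:
            raise ValueError("off-diagonal entries must lie in [-1, 1]")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def _residualize(signals: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of each signal column on [1, design] by least squares."""
    n = signals.shape[0]
    X = np.column_stack([np.ones(n), design])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design matrix")
    beta, *_ = np.linalg.lstsq(X, signals, rcond=None)
    return signals - X @ beta


def partial_correlation(
    table: RoiSignalTable,
    covariates: Sequence[str] = ("age", "sex"),
    group_label: str | None = None,
) -> PartialCorrelationMatrix:
    """Pairwise partial correlation between ROIs, controlling the covariates.

    Each ROI column is residualized on the covariates (plus intercept), then
    the Pearson correlation of the residuals is taken.  With no covariates
    this reduces to the plain Pearson correlation matrix.

    A zero-variance residual leaves the affected entries undefined (NaN) and
    the pairs are recorded in ``undefined_pairs``.
    """
    covariates = list(covariates)
    if table.n_subjects <= len(covariates) + 2:
        raise ValueError(
            f"need more than {len(covariates) + 2} subjects for "
            f"{len(covariates)} covariates, got {table.n_subjects}"
        )
    resid = _residualize(table.signals, table.covariate_matrix(covariates))
    sd = resid.std(axis=0, ddof=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (resid - resid.mean(axis=0)) / np.where(degenerate, np.nan, sd)
        corr = (z.T @ z) / table.n_subjects
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    undefined: list[tuple[int, int]] = []
    if degenerate.any():
        bad = np.flatnonzero(degenerate)
        for i in bad:
            for j in range(table.n_rois):
                if i != j:
                    undefined.append((int(min(i, j)), int(max(i, j))))
        undefined = sorted(set(undefined))
    return PartialCorrelationMatrix(
        values=corr,
        roi_names=list(table.roi_names),
        group_label=group_label if group_label is not None else _infer_group(table),
        n_subjects=table.n_subjects,
        covariates_removed=covariates,
        undefined_pairs=undefined,
    )


def _infer_group(table: RoiSignalTable) -> str:
    groups = table.data["group"].unique()
    return str(groups[0]) if len(groups) == 1 else ""


def _ranked_pairs(values: np.ndarray, absolute: bool) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pair indices ranked by correlation, strongest first.

    Ties broken by lexicographic (i, j) pair order for determinism.
    """
    r = values.shape[0]
    iu, ju = np.triu_indices(r, k=1)
    vals = values[iu, ju]
    if absolute:
        vals = np.abs(vals)
    vals = np.where(np.isnan(vals), -np.inf, vals)  # undefined pairs rank last
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


def binarize_at_sparsity(
    matrix: PartialCorrelationMatrix | np.ndarray,
    sparsity: float,
    absolute: bool = False,
) -> np.ndarray:
    """Binarize an association matrix keeping the top ``sparsity`` fraction of pairs.

    Exactly ``round(sparsity × P)`` unordered pairs become edges, where
    P = R(R−1)/2, ranked by signed value (largest first) or by magnitude when
    ``absolute`` is set.  Round-half-to-even is used at the .5 boundary.
    """
    values = matrix.values if isinstance(matrix, PartialCorrelationMatrix) else np.asarray(matrix)
    if not 0 < sparsity < 1:
        raise ValueError(f"sparsity must be in (0, 1), got {sparsity}")
    r = values.shape[0]
    n_pairs = r * (r - 1) // 2
    n_edges = int(np.round(sparsity * n_pairs))
    if n_edges == 0:
        raise ValueError(f"sparsity {sparsity} yields zero edges on {r} nodes")
    iu, ju = _ranked_pairs(values, absolute)
    adj = np.zeros((r, r), dtype=np.int8)
    sel_i, sel_j = iu[:n_edges], ju[:n_edges]
    adj[sel_i, sel_j] = 1
    adj[sel_j, sel_i] = 1
    return adj


def default_sparsity_grid(
    lo: float = 0.06, hi: float = 0.40, step: float = 0.01
) -> np.ndarray:
    """The standard sparsity sweep: 6%..40% inclusive in 1% steps (35 levels)."""
    n = int(round((hi - lo) / step)) + 1
    return np.round(np.linspace(lo, hi, n), 10)


@dataclass
class BinaryNetworkStack:
    """Binarized adjacency matrices indexed by sparsity, nested by construction."""

    sparsities: np.ndarray
    adjacency: dict[float, np.ndarray]
    group_label: str = ""

    def __getitem__(self, sparsity: float) -> np.ndarray:
        return self.adjacency[float(sparsity)]

    def __iter__(self):
        return iter(self.sparsities)

    def __len__(self) -> int:
        return len(self.sparsities)


def sparsity_sweep(
    matrix: PartialCorrelationMatrix | np.ndarray,
    grid: Sequence[float] | None = None,
    absolute: bool = False,
) -> BinaryNetworkStack:
    """Binarize across a sparsity grid; edge sets are nested as sparsity grows.

    Nestedness follows from a single deterministic ranking of pairs shared by
    all levels.
    """
    if grid is None:
        grid = default_sparsity_grid()
    grid = np.asarray(sorted(float(s) for s in grid))
    if np.any(grid < 0.06 - 1e-12) or np.any(grid > 0.40 + 1e-12):
        raise ValueError("sparsity grid must lie within [0.06, 0.40]")
    if len(np.unique(grid)) != len(grid):
        raise ValueError("sparsity grid must be strictly increasing")
    values = matrix.values if isinstance(matrix, PartialCorrelationMatrix) else np.asarray(matrix)
    r = values.shape[0]
    n_pairs = r * (r - 1) // 2
    iu, ju = _ranked_pairs(values, absolute)
    adjacency: dict[float, np.ndarray] = {}
    for s in grid:
        n_edges = int(np.round(s * n_pairs))
        if n_edges == 0:
            raise ValueError(f"sparsity {s} yields zero edges on {r} nodes")
        adj = np.zeros((r, r), dtype=np.int8)
        adj[iu[:n_edges], ju[:n_edges]] = 1
        adj[ju[:n_edges], iu[:n_edges]] = 1
        adjacency[float(s)] = adj
    label = matrix.group_label if isinstance(matrix, PartialCorrelationMatrix) else ""
    return BinaryNetworkStack(sparsities=grid, adjacency=adjacency, group_label=label)
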