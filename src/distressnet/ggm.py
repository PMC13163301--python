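"""Gaussian graphical model estimation with EBIC-selected graphical lasso.

The network's edges are regularized partial correlations
``omega_ij = -kappa_ij / sqrt(kappa_ii * kappa_jj)`` from a sparse precision
matrix ``kappa`` estimated by the graphical lasso over a logarithmic penalty
grid; the extended Bayesian information criterion

    EBIC = -2 logL + E log n + 4 E gamma log p

(E = number of nonzero upper-triangle precision entries) selects the penalty.
Larger ``gamma`` favors sparser graphs; 0.5 is the default throughout.
The penalized estimate itself is used for the likelihood (no post-selection
refit), matching common practice for this selector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glasso import glasso_path
from .preprocess import CorrelationResult, correlation_matrix, nonparanormal_transform

__all__ = [
    "PartialCorrelationNetwork",
    "ebic",
    "gaussian_loglik",
    "partial_correlations",
    "fit_ebicglasso",
    "network_from_data",
    "residual_network",
    "extended_network",
]


@dataclass
class PartialCorrelationNetwork:
    node_ids: tuple
    weights: np.ndarray
    gamma: float
    lambda_selected: float
    lambda_grid: np.ndarray
    sample_size: int
    input_correlation: str = "pearson"
    node_classes: dict = field(default_factory=dict)  # node -> symptom|external
    correlation_repaired: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.shape[0] != w.shape[1] or w.shape[0] != len(self.node_ids):
            raise ValueError("weight matrix shape does not match node_ids")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) != 0.0:
            raise ValueError("diagonal must be zero")
        if np.abs(w).max(initial=0.0) > 1.0 + 1e-9:
            raise ValueError("partial correlations must satisfy |omega| <= 1")
        self.weights = w

    @property
    def p(self) -> int:
        return len(self.node_ids)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_ids, columns=self.node_ids)

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0.0:
                    rows.append((self.node_ids[i], self.node_ids[j], w))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])


def ebic(log_likelihood: float, n_edges: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC; reduces to BIC at gamma = 0."""
    if n_edges < 0:
        raise ValueError("edge count cannot be negative")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    return (
        -2.0 * log_likelihood
        + n_edges * np.log(n)
        + 4.0 * n_edges * gamma * np.log(p)
    )


def gaussian_loglik(precision: np.ndarray, corr: np.ndarray, n: int) -> float:
    """Profile Gaussian log-likelihood (n/2)(log det K - tr(S K)),
    dropping the constant term."""
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        raise ValueError("precision estimate is not positive definite")
    return 0.5 * n * (logdet - float(np.sum(precision * corr)))


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """omega_ij = -kappa_ij / sqrt(kappa_ii kappa_jj); zero diagonal."""
    d = np.diag(precision)
    if (d <= 0).any():
        raise ValueError("precision diagonal must be positive")
    s = np.sqrt(d)
    omega = -precision / np.outer(s, s)
    np.fill_diagonal(omega, 0.0)
    return 0.5 * (omega + omega.T)


def fit_ebicglasso(
    corr: np.ndarray | CorrelationResult | pd.DataFrame,
    n: int,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    node_ids=None,
    input_correlation: str | None = None,
) -> PartialCorrelationNetwork:
    """Graphical lasso over a log-spaced penalty grid, EBIC-selected.

    The grid runs from lambda_max (the smallest penalty giving an empty
    graph, i.e. the largest absolute off-diagonal correlation) down to
    ``lambda_min_ratio * lambda_max``.  Ties in EBIC resolve to the sparser
    (larger-penalty) model.
    """
    repaired = False
    if isinstance(corr, CorrelationResult):
        node_ids = node_ids or corr.columns
        input_correlation = input_correlation or corr.method
        repaired = corr.repaired
        corr = corr.matrix
    elif isinstance(corr, pd.DataFrame):
        node_ids = node_ids or tuple(corr.columns)
        corr = corr.to_numpy()
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if node_ids is None:
        node_ids = tuple(f"X{i+1}" for i in range(p))
    eigs = np.linalg.eigvalsh(corr)
    if eigs[0] <= 0:
        raise ValueError(
            f"input correlation matrix is not positive definite "
            f"(min eigenvalue {eigs[0]:.3g})"
        )

    off = np.abs(corr - np.diag(np.diag(corr)))
    lam_max = float(off.max())
    if lam_max == 0.0:  # exact independence: the empty graph, any penalty
        grid = np.array([1.0])
        weights = np.zeros((p, p))
        return PartialCorrelationNetwork(
            tuple(node_ids), weights, gamma, 1.0, grid, n,
            input_correlation or "pearson", correlation_repaired=repaired,
        )
    grid = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)
    precisions, flags = glasso_path(corr, grid)
    if not flags.all():
        bad = grid[~flags][0]
        raise RuntimeError(f"graphical lasso failed to converge at penalty {bad:.5g}")

    best_idx, best_val = 0, np.inf
    iu = np.triu_indices(p, k=1)
    for idx in range(len(grid)):
        K = precisions[idx]
        E = int(np.count_nonzero(K[iu]))
        val = ebic(gaussian_loglik(K, corr, n), E, n, p, gamma)
        if val < best_val:  # strict: ties keep the sparser earlier model
            best_idx, best_val = idx, val
    K = precisions[best_idx]
    omega = partial_correlations(K)
    return PartialCorrelationNetwork(
        node_ids=tuple(node_ids),
        weights=omega,
        gamma=gamma,
        lambda_selected=float(grid[best_idx]),
        lambda_grid=grid,
        sample_size=n,
        input_correlation=input_correlation or "pearson",
        correlation_repaired=repaired,
    )


def network_from_data(
    data: pd.DataFrame,
    gamma: float = 0.5,
    method: str = "npn-pearson",
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    node_classes: dict | None = None,
) -> PartialCorrelationNetwork:
    """Full estimation path from a participants x variables table.

    ``method``: 'spearman' or 'pearson' (correlation on the raw columns) or
    'npn-pearson' (nonparanormal transform, then Pearson; the default for
    network estimation of ordinal/skewed data).
    """
    df = pd.DataFrame(data).astype(float)
    if method == "npn-pearson":
        cr = correlation_matrix(nonparanormal_transform(df), method="pearson")
        tag = "npn-pearson"
    elif method in ("spearman", "pearson"):
        cr = correlation_matrix(df, method=method)
        tag = method
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    net = fit_ebicglasso(
        cr, n=len(df), gamma=gamma, n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio, input_correlation=tag,
    )
    if node_classes:
        net.node_classes = dict(node_classes)
    return net


def _dummy_code(covariates: pd.DataFrame) -> np.ndarray:
    """Reference-coded design matrix (first category dropped per covariate)."""
    parts = [np.ones((len(covariates), 1))]
    names = ["intercept"]
    for col in covariates.columns:
        levels = np.sort(covariates[col].unique())
        for lev in levels[1:]:
            parts.append((covariates[col].to_numpy() == lev)[:, None].astype(float))
            names.append(f"{col}={lev}")
    design = np.hstack(parts)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"collinear covariate design ({design.shape[1]} columns, rank {rank}); "
            f"columns: {names}"
        )
    return design


def residual_network(
    items: pd.DataFrame,
    covariates: pd.DataFrame,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> PartialCorrelationNetwork:
    """Symptom network net of covariates.

    Each symptom is regressed on the dummy-coded covariates by least squares;
    the residuals receive a nonparanormal transform and the network is
    re-estimated with the EBIC graphical lasso.  A symptom fully determined
    by covariates leaves a (near-)constant residual column, which the
    nonparanormal step rejects explicitly.
    """
    items = pd.DataFrame(items).astype(float)
    if items.isna().any().any() or covariates.isna().any().any():
        raise ValueError("missing entries; impute before residualization")
    design = _dummy_code(covariates)
    Y = items.to_numpy()
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = pd.DataFrame(Y - design @ coef, index=items.index, columns=items.columns)
    cr = correlation_matrix(nonparanormal_transform(resid), method="pearson")
    return fit_ebicglasso(
        cr, n=len(items), gamma=gamma, n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio, input_correlation="residual-npn-pearson",
    )


def extended_network(
    items: pd.DataFrame,
    external: pd.DataFrame,
    gamma: float = 0.5,
    method: str = "npn-pearson",
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> PartialCorrelationNetwork:
    """Joint network over symptom items and external variables (coded
    covariates, psychosocial totals, or QoL domains)."""
    items = pd.DataFrame(items).astype(float)
    external = pd.DataFrame(external).astype(float)
    dup = set(items.columns) & set(external.columns)
    if dup:
        raise ValueError(f"duplicated column names: {sorted(dup)}")
    joint = pd.concat([items, external], axis=1)
    classes = {c: "symptom" for c in items.columns}
    classes.update({c: "external" for c in external.columns})
    return network_from_data(
        joint, gamma=gamma, method=method, n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio, node_classes=classes,
    )
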