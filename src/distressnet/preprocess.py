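"""Shared data preparation: train/validation split, chained PMM imputation,
nonparanormal transformation, and positive-definite correlation input."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplitAssignment",
    "split_train_validation",
    "impute_pmm",
    "nonparanormal_transform",
    "CorrelationResult",
    "correlation_matrix",
    "positive_rate",
]


@dataclass(frozen=True)
class SplitAssignment:
    training_ids: tuple
    validation_ids: tuple
    seed: int
    proportion: float

    def __post_init__(self) -> None:
        overlap = set(self.training_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"overlapping ids: {sorted(overlap)[:5]}")

    def to_dict(self) -> dict:
        return {
            "training_ids": list(self.training_ids),
            "validation_ids": list(self.validation_ids),
            "seed": self.seed,
            "proportion": self.proportion,
        }


def split_train_validation(participant_ids, proportion: float, seed: int) -> SplitAssignment:
    """Uniform random partition with |training| = floor(n * proportion)."""
    ids = list(participant_ids)
    if hasattr(participant_ids, "n_participants"):  # CohortDataset convenience
        ids = list(participant_ids.items.values.index)
    n = len(ids)
    if not 0 < proportion < 1:
        raise ValueError("proportion must be in (0, 1)")
    if n < 4:
        raise ValueError("need at least 4 participants to split")
    n_train = int(np.floor(n * proportion))
    if n_train == 0 or n_train == n:
        raise ValueError(f"degenerate split: {n_train}/{n - n_train}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = tuple(ids[i] for i in sorted(perm[:n_train]))
    valid = tuple(ids[i] for i in sorted(perm[n_train:]))
    return SplitAssignment(train, valid, seed=seed, proportion=proportion)


def impute_pmm(
    data: pd.DataFrame,
    n_iterations: int = 10,
    n_donors: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-chain predictive-mean-matching imputation.

    Columns are cycled in fixed (left-to-right) order; each missing cell is
    filled by fitting a least-squares linear predictor on the currently
    completed other columns, finding the ``n_donors`` observed cases with the
    closest predictions, and copying one donor's observed value at random.
    Imputed values therefore always come from a column's observed support.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(data)
    work = data.astype(float).copy()
    missing = work.isna()
    if not missing.any().any():
        return work
    for col in work.columns:
        n_obs = int((~missing[col]).sum())
        if n_obs == 0:
            raise ValueError(f"column {col!r} is fully missing")
        if n_obs < n_donors:
            raise ValueError(
                f"column {col!r} has {n_obs} observed values; "
                f"needs >= n_donors = {n_donors}"
            )
    rng = np.random.default_rng(seed)
    # initialize missing entries at column means of the observed values
    for col in work.columns:
        work.loc[missing[col], col] = work[col].mean()

    X = work.to_numpy()
    miss = missing.to_numpy()
    n, p = X.shape
    for _ in range(n_iterations):
        for j in range(p):
            mrows = np.nonzero(miss[:, j])[0]
            if mrows.size == 0:
                continue
            orows = np.nonzero(~miss[:, j])[0]
            others = [k for k in range(p) if k != j]
            design = np.column_stack([np.ones(n), X[:, others]])
            coef, *_ = np.linalg.lstsq(design[orows], X[orows, j], rcond=None)
            pred = design @ coef
            for r in mrows:
                dist = np.abs(pred[orows] - pred[r])
                donor_pool = orows[np.argsort(dist, kind="stable")[:n_donors]]
                donor = donor_pool[rng.integers(len(donor_pool))]
                X[r, j] = X[donor, j]
    return pd.DataFrame(X, index=data.index, columns=data.columns)


def nonparanormal_transform(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Rank-based mapping of each column to standard-normal quantiles.

    Ties-averaged ranks are scaled by 1/(n+1) and Winsorized at the
    truncation level delta_n = 1 / (4 n^{1/4} sqrt(pi log n)) before applying
    the normal quantile function, bounding the influence of extreme ranks.
    Rank order within each column is preserved.
    """
    df = pd.DataFrame(matrix).astype(float)
    n = len(df)
    if n < 2:
        raise ValueError("need at least 2 rows")
    delta = 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))
    out = {}
    for col in df.columns:
        x = df[col].to_numpy()
        if not np.isfinite(x).all():
            raise ValueError(f"column {col!r} has missing values")
        if np.unique(x).size < 2:
            raise ValueError(f"column {col!r} is constant")
        u = stats.rankdata(x, method="average") / (n + 1.0)
        u = np.clip(u, delta, 1.0 - delta)
        out[col] = stats.norm.ppf(u)
    return pd.DataFrame(out, index=df.index)


@dataclass(frozen=True)
class CorrelationResult:
    matrix: np.ndarray
    columns: tuple
    method: str
    repaired: bool
    max_abs_change: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.columns, columns=self.columns)


def correlation_matrix(
    matrix: pd.DataFrame | np.ndarray,
    method: str = "spearman",
    min_eigenvalue: float = 1e-6,
) -> CorrelationResult:
    """Correlation matrix guaranteed positive definite.

    If the smallest eigenvalue falls below ``min_eigenvalue`` the matrix is
    repaired by clipping eigenvalues and re-standardizing the diagonal; the
    maximum absolute off-diagonal perturbation is recorded.
    """
    df = pd.DataFrame(matrix).astype(float)
    if len(df) < 3:
        raise ValueError("need at least 3 participants")
    if df.isna().any().any():
        raise ValueError("missing entries; impute before correlation")
    if method == "spearman":
        raw = df.corr(method="spearman").to_numpy()
    elif method == "pearson":
        raw = df.corr(method="pearson").to_numpy()
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.isnan(raw).any():
        const = [c for c in df.columns if df[c].nunique() < 2]
        raise ValueError(f"constant column(s): {const}")
    raw = 0.5 * (raw + raw.T)
    np.fill_diagonal(raw, 1.0)

    eigval, eigvec = np.linalg.eigh(raw)
    repaired = bool(eigval[0] < min_eigenvalue)
    fixed = raw
    if repaired:
        clipped = np.clip(eigval, min_eigenvalue, None)
        fixed = (eigvec * clipped) @ eigvec.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        fixed = 0.5 * (fixed + fixed.T)
        np.fill_diagonal(fixed, 1.0)
    max_change = float(np.max(np.abs(fixed - raw))) if repaired else 0.0
    return CorrelationResult(
        matrix=fixed,
        columns=tuple(df.columns),
        method=method,
        repaired=repaired,
        max_abs_change=max_change,
    )


def positive_rate(item, threshold: int = 2) -> float:
    """Fraction of responses at or above the positive-response cutoff."""
    arr = np.asarray(item, dtype=float)
    if arr.size == 0:
        raise ValueError("empty item vector")
    if not np.isfinite(arr).all():
        raise ValueError("item vector contains missing values")
    return float((arr >= threshold).mean())
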