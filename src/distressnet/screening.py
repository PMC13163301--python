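"""Three-track parallel node screening with freezing and validation.

Candidate items (negative-mood dimensions only) must clear a strict >50%
positive-response prevalence filter, then pass through three tracks run on
the training set only:

  A. Spearman correlation with a core distress indicator (|rho| >= 0.30 and
     positive-response rate >= 0.50);
  B. 10-fold cross-validated L1-penalized linear regression on continuous
     distress, keeping items with nonzero coefficients at the
     minimum-CV-error penalty;
  C. repeated cross-validated L1-penalized logistic regression on
     median-dichotomized distress, keeping items selected in >= 60% of
     repetitions.

Track selections combine by weighted vote (1/2/2, retained at vote >= 3),
redundant pairs (Spearman > 0.80) are pruned in favor of the item more
correlated with the core indicator, and the surviving node set is frozen
before any validation data are touched.

The core distress indicator is the leave-one-out total of the negative-mood
items (total minus the candidate item), avoiding item-total inflation for
the per-item track; the regression tracks use the plain negative-item total
(items necessarily contribute to it, which makes those tracks behave as
redundancy filters rather than pure association filters — see the package
methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .datatypes import NEGATIVE_DIMENSIONS, ItemResponseMatrix
from .preprocess import positive_rate

__all__ = [
    "ScreeningConfig",
    "ScreeningResult",
    "prevalence_filter",
    "leave_one_out_totals",
    "track_spearman",
    "track_cv_lasso",
    "track_repeated_logistic",
    "combine_tracks",
    "redundancy_prune",
    "validate_nodes",
    "screen_nodes",
]


@dataclass(frozen=True)
class ScreeningConfig:
    positive_threshold: int = 2
    min_prevalence: float = 0.50     # strict > for candidacy
    rho_min: float = 0.30
    rate_min: float = 0.50
    folds: int = 10
    reps: int = 100
    select_frac: float = 0.60
    weights: tuple[int, int, int] = (1, 2, 2)
    vote_min: int = 3
    rho_max: float = 0.80
    loo_core: bool = True
    seed: int = 0


@dataclass
class ScreeningResult:
    candidates: list
    track_a: set
    track_b: set
    track_c: set
    track_c_frequencies: dict
    votes: dict
    frozen_nodes: list
    pruned_pairs: list
    config: ScreeningConfig
    auc_validation: float | None = None
    auc_full: float | None = None
    consistency: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "candidates": list(self.candidates),
            "track_a": sorted(self.track_a),
            "track_b": sorted(self.track_b),
            "track_c": sorted(self.track_c),
            "track_c_frequencies": {k: float(v) for k, v in self.track_c_frequencies.items()},
            "votes": {k: int(v) for k, v in self.votes.items()},
            "frozen_nodes": list(self.frozen_nodes),
            "pruned_pairs": [
                {"kept": a, "dropped": b, "rho": float(r)} for a, b, r in self.pruned_pairs
            ],
            "auc_validation": self.auc_validation,
            "auc_full": self.auc_full,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
            },
        }


def prevalence_filter(
    items: ItemResponseMatrix,
    threshold: int = 2,
    min_rate: float = 0.50,
) -> list[str]:
    """Negative-mood items with positive-response rate strictly above
    ``min_rate``; vigor items are never candidates."""
    negative = items.items_in_dimensions(NEGATIVE_DIMENSIONS)
    rates = {c: positive_rate(items.values[c], threshold) for c in negative}
    kept = [c for c in negative if rates[c] > min_rate]
    if not kept:
        raise ValueError(f"no item passed the prevalence filter; rates: {rates}")
    return kept


def leave_one_out_totals(items_df: pd.DataFrame) -> pd.DataFrame:
    """Per-item core indicator: total of all columns minus the item itself."""
    total = items_df.sum(axis=1)
    return items_df.rsub(total, axis=0)


def track_spearman(
    items_df: pd.DataFrame,
    core_indicator: pd.DataFrame | pd.Series,
    rho_min: float = 0.30,
    rate_min: float = 0.50,
    threshold: int = 2,
) -> set[str]:
    """Items with |Spearman rho| >= rho_min against the core indicator AND
    positive-response rate >= rate_min.

    ``core_indicator`` may be a Series (one shared indicator) or a DataFrame
    with one leave-one-out column per item.
    """
    selected = set()
    for col in items_df.columns:
        core = (
            core_indicator[col]
            if isinstance(core_indicator, pd.DataFrame)
            else core_indicator
        )
        if np.unique(core).size < 2:
            raise ValueError(f"constant core indicator for item {col!r}")
        rho = stats.spearmanr(items_df[col], core).statistic
        rate = positive_rate(items_df[col], threshold)
        if abs(rho) >= rho_min and rate >= rate_min:
            selected.add(col)
    return selected


def track_cv_lasso(
    items_df: pd.DataFrame,
    outcome,
    folds: int = 10,
    seed: int = 0,
) -> set[str]:
    """Cross-validated lasso on a continuous outcome; items with nonzero
    coefficients at the minimum-CV-error penalty."""
    y = np.asarray(outcome, dtype=float)
    n = len(items_df)
    if folds > n:
        raise ValueError(f"folds ({folds}) exceed sample size ({n})")
    if np.std(y) == 0:
        return set()
    X = items_df.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(alphas=100, eps=1e-3, cv=cv, max_iter=50_000)
    model.fit(X, y)
    return {c for c, coef in zip(items_df.columns, model.coef_) if coef != 0.0}


def track_repeated_logistic(
    items_df: pd.DataFrame,
    outcome,
    reps: int = 100,
    folds: int = 10,
    select_frac: float = 0.60,
    seed: int = 0,
) -> tuple[set[str], dict[str, float]]:
    """Repeated CV L1 logistic regression on a binary outcome
    (stability-selection style).

    Each repetition draws a random half of the participants, runs stratified
    CV over a log C grid inside the subsample, picks the strongest penalty
    whose mean accuracy is within one standard error of the best (the
    one-standard-error rule curbs the over-selection of prediction-optimal
    penalties), and refits the subsample at that penalty.  An item's
    frequency is the fraction of repetitions with a nonzero coefficient;
    retained iff frequency >= select_frac.
    """
    y = np.asarray(outcome)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"outcome must have exactly 2 classes, got {len(classes)}")
    X = items_df.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    c_grid = np.logspace(-4, 4, 10)
    counts = np.zeros(X.shape[1])
    rng = np.random.default_rng(seed)
    n = len(y)
    n_sub = max(folds + 1, n // 2)
    for rep in range(reps):
        idx = rng.permutation(n)[:n_sub]
        Xr, yr = X[idx], y[idx]
        if len(np.unique(yr)) < 2:  # resample a degenerate subsample
            idx = rng.permutation(n)[:n_sub]
            Xr, yr = X[idx], y[idx]
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        splits = list(cv.split(Xr, yr))
        acc = np.zeros((len(c_grid), len(splits)))
        for ci, c_val in enumerate(c_grid):
            for k, (tr, te) in enumerate(splits):
                model = LogisticRegression(
                    l1_ratio=1, C=c_val, solver="liblinear", max_iter=2000,
                    random_state=0
                )
                model.fit(Xr[tr], yr[tr])
                acc[ci, k] = float(np.mean(model.predict(Xr[te]) == yr[te]))
        mean = acc.mean(axis=1)
        se = acc.std(axis=1, ddof=1) / np.sqrt(acc.shape[1])
        best = int(np.argmax(mean))
        # strongest penalty (smallest C) within one SE of the best
        best = int(np.nonzero(mean >= mean[best] - se[best])[0][0])
        model = LogisticRegression(
            l1_ratio=1, C=c_grid[best], solver="liblinear", max_iter=2000,
            random_state=0
        )
        model.fit(Xr, yr)
        counts += (model.coef_.ravel() != 0.0).astype(float)
    freqs = {c: counts[k] / reps for k, c in enumerate(items_df.columns)}
    selected = {c for c, f in freqs.items() if f >= select_frac}
    return selected, freqs


def combine_tracks(
    track_a: set,
    track_b: set,
    track_c: set,
    weights: tuple[int, int, int] = (1, 2, 2),
    vote_min: int = 3,
    candidates=None,
) -> tuple[set, dict]:
    """Weighted vote across tracks; retained iff vote >= vote_min."""
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    pool = set(candidates) if candidates is not None else track_a | track_b | track_c
    votes = {
        item: weights[0] * (item in track_a)
        + weights[1] * (item in track_b)
        + weights[2] * (item in track_c)
        for item in pool
    }
    retained = {item for item, v in votes.items() if v >= vote_min}
    return retained, votes


def redundancy_prune(
    items_df: pd.DataFrame,
    retained: set,
    core_indicator: pd.DataFrame | pd.Series,
    rho_max: float = 0.80,
) -> tuple[list, list]:
    """Iteratively resolve item pairs with |Spearman| > rho_max.

    Of each offending pair (worst first), the item with the weaker absolute
    correlation to the core indicator is dropped; ties break toward keeping
    the higher-variance item, then by column order.  Returns the surviving
    items in original column order and the (kept, dropped, rho) log.
    """
    if not retained:
        raise ValueError("retained set is empty")
    order = [c for c in items_df.columns if c in retained]
    pruned_pairs = []
    current = list(order)
    while True:
        if len(current) < 2:
            break
        sub = items_df[current]
        if len(current) == 2:
            r = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1]).statistic
            rho = np.array([[1.0, r], [r, 1.0]])
        else:
            rho = stats.spearmanr(sub).statistic
        np.fill_diagonal(rho, 0.0)
        absrho = np.abs(rho)
        i, j = np.unravel_index(np.argmax(absrho), absrho.shape)
        if absrho[i, j] <= rho_max:
            break
        a, b = current[i], current[j]

        def core_corr(item: str) -> float:
            core = (
                core_indicator[item]
                if isinstance(core_indicator, pd.DataFrame)
                else core_indicator
            )
            return abs(stats.spearmanr(items_df[item], core).statistic)

        ca, cb = core_corr(a), core_corr(b)
        if ca != cb:
            keep, drop = (a, b) if ca > cb else (b, a)
        else:
            va, vb = items_df[a].var(), items_df[b].var()
            if va != vb:
                keep, drop = (a, b) if va > vb else (b, a)
            else:
                keep, drop = (a, b) if order.index(a) < order.index(b) else (b, a)
        pruned_pairs.append((keep, drop, float(rho[i, j])))
        current.remove(drop)
    return current, pruned_pairs


def _distress_outcome(items: ItemResponseMatrix) -> pd.Series:
    negative = items.items_in_dimensions(NEGATIVE_DIMENSIONS)
    return items.values[negative].sum(axis=1)


def _dichotomize(values: pd.Series) -> np.ndarray:
    med = float(np.median(values))
    return (values > med).astype(int).to_numpy()


def validate_nodes(
    frozen_nodes,
    validation_items: ItemResponseMatrix,
    threshold: int = 2,
) -> tuple[float, pd.DataFrame]:
    """Discrimination of the frozen-node sum score for median-dichotomized
    total distress in held-out data, plus per-node descriptives.

    Returns (AUC, consistency table with one row per frozen node).
    """
    frozen_nodes = list(frozen_nodes)
    vals = validation_items.values
    score = vals[frozen_nodes].sum(axis=1)
    outcome = _dichotomize(_distress_outcome(validation_items))
    if len(np.unique(outcome)) < 2:
        raise ValueError("validation outcome has a single class")
    auc = float(roc_auc_score(outcome, score))
    table = pd.DataFrame(
        {
            "node": frozen_nodes,
            "mean": [float(vals[c].mean()) for c in frozen_nodes],
            "positive_rate": [
                positive_rate(vals[c], threshold) for c in frozen_nodes
            ],
        }
    ).set_index("node")
    return auc, table


def screen_nodes(
    training_items: ItemResponseMatrix,
    config: ScreeningConfig | None = None,
) -> ScreeningResult:
    """Run the full three-track screen on TRAINING data only.

    Validation data never enter this function; evaluate the frozen set
    afterwards with :func:`validate_nodes`.
    """
    cfg = config or ScreeningConfig()
    candidates = prevalence_filter(
        training_items, cfg.positive_threshold, cfg.min_prevalence
    )
    cand_df = training_items.values[candidates]
    if cand_df.isna().any().any():
        raise ValueError("training items contain missing entries (impute first)")

    negative_total = _distress_outcome(training_items)
    core: pd.DataFrame | pd.Series
    if cfg.loo_core:
        # leave-one-out against the full negative-item total
        core = pd.DataFrame(
            {c: negative_total - training_items.values[c] for c in candidates}
        )
    else:
        core = negative_total

    a = track_spearman(cand_df, core, cfg.rho_min, cfg.rate_min, cfg.positive_threshold)
    b = track_cv_lasso(cand_df, negative_total, cfg.folds, cfg.seed)
    c, freqs = track_repeated_logistic(
        cand_df,
        _dichotomize(negative_total),
        cfg.reps,
        cfg.folds,
        cfg.select_frac,
        cfg.seed + 10_000,
    )
    retained, votes = combine_tracks(
        a, b, c, cfg.weights, cfg.vote_min, candidates=candidates
    )
    if retained:
        frozen, pruned = redundancy_prune(cand_df, retained, core, cfg.rho_max)
    else:
        frozen, pruned = [], []
    return ScreeningResult(
        candidates=candidates,
        track_a=a,
        track_b=b,
        track_c=c,
        track_c_frequencies=freqs,
        votes=votes,
        frozen_nodes=frozen,
        pruned_pairs=pruned,
        config=cfg,
    )
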