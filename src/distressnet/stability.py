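"""Bootstrap accuracy and stability of the estimated network.

Two resampling schemes: a nonparametric bootstrap (resample participants
with replacement, refit the full estimation pipeline, percentile confidence
intervals per edge) and a case-dropping bootstrap for centrality, summarized
by the correlation-stability (CS) coefficient — the largest proportion of
cases that can be dropped while at least 95% of subsample-to-full centrality
correlations stay at or above 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ggm import network_from_data
from .netstats import expected_influence, strength

__all__ = [
    "EdgeBootstrapResult",
    "CaseDropResult",
    "bootstrap_edges",
    "case_dropping",
    "cs_coefficient",
    "DEFAULT_DROP_GRID",
]

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))


@dataclass
class EdgeBootstrapResult:
    node_ids: tuple
    observed: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_boot: int

    def as_frame(self) -> pd.DataFrame:
        rows = []
        p = len(self.node_ids)
        for i in range(p):
            for j in range(i + 1, p):
                rows.append(
                    (
                        self.node_ids[i], self.node_ids[j],
                        self.observed[i, j], self.mean[i, j],
                        self.lower[i, j], self.upper[i, j],
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["node_a", "node_b", "observed", "boot_mean", "lower", "upper"],
        )


@dataclass
class CaseDropResult:
    drop_proportions: tuple
    correlations: dict  # proportion -> np.ndarray of per-resample correlations
    metric: str
    cor_threshold: float = 0.7
    prob_threshold: float = 0.95

    def summary(self) -> pd.DataFrame:
        rows = []
        for prop in self.drop_proportions:
            cors = self.correlations[prop]
            rows.append(
                (
                    prop,
                    float(np.mean(cors)),
                    float(np.mean(cors >= self.cor_threshold)),
                )
            )
        return pd.DataFrame(
            rows, columns=["drop_proportion", "mean_correlation", "prop_above_threshold"]
        )


def bootstrap_edges(
    data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    gamma: float = 0.5,
    method: str = "npn-pearson",
    n_lambda: int = 100,
    ci: float = 0.95,
) -> EdgeBootstrapResult:
    """Percentile bootstrap confidence intervals for every edge weight."""
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    df = pd.DataFrame(data).astype(float)
    n = len(df)
    full = network_from_data(df, gamma=gamma, method=method, n_lambda=n_lambda)
    rng = np.random.default_rng(seed)
    p = full.p
    boots = np.zeros((B, p, p))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        net = network_from_data(
            df.iloc[idx], gamma=gamma, method=method, n_lambda=n_lambda
        )
        boots[b] = net.weights
    alpha = (1.0 - ci) / 2.0
    return EdgeBootstrapResult(
        node_ids=full.node_ids,
        observed=full.weights,
        mean=boots.mean(axis=0),
        lower=np.quantile(boots, alpha, axis=0),
        upper=np.quantile(boots, 1.0 - alpha, axis=0),
        n_boot=B,
    )


def case_dropping(
    data: pd.DataFrame,
    proportions=DEFAULT_DROP_GRID,
    B: int = 1000,
    metric: str = "strength",
    seed: int = 0,
    gamma: float = 0.5,
    method: str = "npn-pearson",
    n_lambda: int = 100,
) -> CaseDropResult:
    """Case-dropping bootstrap of centrality.

    For each drop proportion, draws B subsamples without replacement, refits
    the network, and records the Pearson correlation between subsample and
    full-sample centrality vectors.
    """
    props = tuple(float(x) for x in proportions)
    if any(x >= 1.0 or x < 0.0 for x in props):
        raise ValueError("drop proportions must lie in [0, 1)")
    df = pd.DataFrame(data).astype(float)
    n, p = df.shape
    if min((1.0 - x) for x in props) * n < p + 5:
        raise ValueError(
            "smallest retained subsample would be below p + 5 participants"
        )
    metric_fn = {"strength": strength, "ei": expected_influence}.get(metric)
    if metric_fn is None:
        raise ValueError("metric must be 'strength' or 'ei'")
    full = network_from_data(df, gamma=gamma, method=method, n_lambda=n_lambda)
    full_cent = metric_fn(full)
    rng = np.random.default_rng(seed)
    correlations = {}
    for prop in props:
        keep = n - int(round(prop * n))
        cors = np.zeros(B)
        for b in range(B):
            idx = rng.permutation(n)[:keep]
            net = network_from_data(
                df.iloc[idx], gamma=gamma, method=method, n_lambda=n_lambda
            )
            cent = metric_fn(net)
            if np.std(cent) == 0 or np.std(full_cent) == 0:
                cors[b] = 0.0
            else:
                cors[b] = float(np.corrcoef(cent, full_cent)[0, 1])
        correlations[prop] = cors
    return CaseDropResult(drop_proportions=props, correlations=correlations, metric=metric)


def cs_coefficient(result: CaseDropResult) -> float:
    """Largest drop proportion with >= 95% of correlations >= 0.7 (or 0)."""
    if not result.drop_proportions:
        raise ValueError("empty drop-proportion grid")
    cs = 0.0
    for prop in sorted(result.drop_proportions):
        cors = result.correlations[prop]
        if np.mean(cors >= result.cor_threshold) >= result.prob_threshold:
            cs = prop
    return cs
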