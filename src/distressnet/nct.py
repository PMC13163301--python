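"""Permutation-based network comparison across median-split subgroups.

Two invariance statistics: M, the maximum absolute edge-weight difference
between the two group networks (network structure), and S, the absolute
difference in global strength.  The null distribution comes from shuffling
group labels and refitting the full estimation pipeline for both groups at
each permutation; p-values use the add-one correction
``(1 + #{perm >= observed}) / (1 + n_perm)`` and so are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ggm import PartialCorrelationNetwork, network_from_data
from .netstats import global_strength

__all__ = ["NCTResult", "median_split", "nct_statistics", "nct_permutation"]


@dataclass
class NCTResult:
    m_stat: float
    p_m: float
    gs_low: float
    gs_high: float
    s_stat: float
    p_s: float
    n_perm: int
    group_sizes: tuple

    def as_row(self, variable: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": variable,
                    "M": self.m_stat,
                    "p_M": self.p_m,
                    "GS_low": self.gs_low,
                    "GS_high": self.gs_high,
                    "S": self.s_stat,
                    "p_S": self.p_s,
                }
            ]
        )


def median_split(values) -> np.ndarray:
    """Dichotomize at the median; ties go to the low group.

    Returns an array of 'low'/'high' labels.
    """
    arr = np.asarray(values, dtype=float)
    if np.unique(arr).size < 2:
        raise ValueError("cannot median-split a constant vector")
    med = np.median(arr)
    labels = np.where(arr <= med, "low", "high")
    if (labels == "high").sum() == 0:
        # heavy ties at the median can empty the high group; split strictly
        # above the largest value <= median instead
        raise ValueError("median split produced an empty high group")
    return labels


def nct_statistics(
    net_a: PartialCorrelationNetwork, net_b: PartialCorrelationNetwork
) -> tuple[float, float, float, float]:
    """(M, S, GS_a, GS_b) for two networks over the same node set."""
    if tuple(net_a.node_ids) != tuple(net_b.node_ids):
        raise ValueError("networks have different node sets/orderings")
    iu = np.triu_indices(net_a.p, k=1)
    m = float(np.max(np.abs(net_a.weights[iu] - net_b.weights[iu])))
    gs_a = global_strength(net_a)
    gs_b = global_strength(net_b)
    return m, abs(gs_a - gs_b), gs_a, gs_b


def nct_permutation(
    data: pd.DataFrame,
    group_labels,
    n_perm: int = 1000,
    gamma: float = 0.5,
    seed: int = 0,
    method: str = "npn-pearson",
    n_lambda: int = 100,
) -> NCTResult:
    """Permutation test of network-structure (M) and global-strength (S)
    invariance between two groups.

    Every permutation refits the complete pipeline (correlation input and
    EBIC penalty selection) for both shuffled groups.
    """
    df = pd.DataFrame(data).astype(float)
    labels = np.asarray(group_labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    low, high = levels[0], levels[1]
    if "low" in levels and "high" in levels:
        low, high = "low", "high"
    n_low = int((labels == low).sum())
    n_high = int((labels == high).sum())
    p = df.shape[1]
    if min(n_low, n_high) < p + 5:
        raise ValueError(
            f"degenerate group: sizes ({n_low}, {n_high}) with p = {p} nodes"
        )

    def fit_pair(lab):
        net_a = network_from_data(
            df.loc[lab == low], gamma=gamma, method=method, n_lambda=n_lambda
        )
        net_b = network_from_data(
            df.loc[lab == high], gamma=gamma, method=method, n_lambda=n_lambda
        )
        return net_a, net_b

    net_low, net_high = fit_pair(labels)
    m_obs, s_obs, gs_low, gs_high = nct_statistics(net_low, net_high)

    rng = np.random.default_rng(seed)
    m_ge, s_ge = 0, 0
    for _ in range(n_perm):
        perm = labels[rng.permutation(len(labels))]
        na, nb = fit_pair(perm)
        m_p, s_p, _, _ = nct_statistics(na, nb)
        if m_p >= m_obs:
            m_ge += 1
        if s_p >= s_obs:
            s_ge += 1
    return NCTResult(
        m_stat=m_obs,
        p_m=(1 + m_ge) / (1 + n_perm),
        gs_low=gs_low,
        gs_high=gs_high,
        s_stat=s_obs,
        p_s=(1 + s_ge) / (1 + n_perm),
        n_perm=n_perm,
        group_sizes=(n_low, n_high),
    )
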