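"""Node- and network-level descriptive statistics.

Strength is the sum of absolute incident edge weights; expected influence
(EI) the signed sum, so the two coincide exactly on all-positive networks.
Centrality plots conventionally show z-standardized values, computed here
with the population standard deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ggm import PartialCorrelationNetwork

__all__ = [
    "strength",
    "expected_influence",
    "z_standardize",
    "global_strength",
    "count_edges",
    "centrality_table",
]


def strength(network: PartialCorrelationNetwork) -> np.ndarray:
    return np.abs(network.weights).sum(axis=1)


def expected_influence(network: PartialCorrelationNetwork) -> np.ndarray:
    return network.weights.sum(axis=1)


def z_standardize(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = arr.std(ddof=0)
    if sd == 0:
        raise ValueError("zero spread; z-scores undefined")
    return (arr - arr.mean()) / sd


def global_strength(network: PartialCorrelationNetwork) -> float:
    """Sum of absolute edge weights over unique node pairs."""
    iu = np.triu_indices(network.p, k=1)
    return float(np.abs(network.weights[iu]).sum())


def count_edges(network: PartialCorrelationNetwork) -> tuple[int, int]:
    """(nonzero edge count, possible edge count p(p-1)/2).

    Nonzero means exactly nonzero: the sparse solver returns exact zeros for
    absent edges, so no epsilon is applied.
    """
    p = network.p
    iu = np.triu_indices(p, k=1)
    return int(np.count_nonzero(network.weights[iu])), p * (p - 1) // 2


def centrality_table(network: PartialCorrelationNetwork) -> pd.DataFrame:
    """Raw and z-standardized strength and expected influence per node."""
    s = strength(network)
    e = expected_influence(network)
    table = pd.DataFrame(
        {"strength_raw": s, "ei_raw": e}, index=list(network.node_ids)
    )
    for raw, z in (("strength_raw", "strength_z"), ("ei_raw", "ei_z")):
        vals = table[raw].to_numpy()
        if np.unique(vals).size >= 2:
            table[z] = z_standardize(vals)
        else:
            table[z] = 0.0
    return table
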