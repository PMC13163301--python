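"""Simulation benchmarks exercising the pipeline against known truth.

Each benchmark generates data from the synthetic model, runs the estimation
machinery, and reports operating characteristics (edge-recovery rates, null
selection behavior, permutation-test size, screening recall).  They are used
by the validation suite and the reproduction script; sizes are arguments so
callers can trade precision for runtime.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import TrueNetworkSpec
from .ggm import network_from_data
from .nct import nct_permutation
from .screening import ScreeningConfig, screen_nodes
from .synthetic import (
    equiprobable_cutpoints,
    make_screening_benchmark,
    make_true_network,
    sample_latent_gaussian,
    sample_ordinal_responses,
)

__all__ = [
    "frozen_node_network_spec",
    "edge_recovery",
    "null_selection",
    "nct_type_one_error",
    "screening_recovery",
]


def frozen_node_network_spec(seed: int = 0) -> TrueNetworkSpec:
    """16-node five-block ground truth in the frozen-node layout
    (3 tension, 4 depression, 1 anger, 5 fatigue, 3 confusion items)."""
    labels = ("TA",) * 3 + ("DD",) * 4 + ("AH",) + ("FI",) * 5 + ("CB",) * 3
    return TrueNetworkSpec(
        n_nodes=16,
        block_assignment=labels,
        within_block_weight_range=(0.15, 0.25),
        cross_block_edges=(
            (2, 11, 0.20), (1, 14, 0.15), (6, 1, 0.15),
            (8, 1, 0.18), (8, 10, 0.15), (15, 11, 0.12), (13, 2, 0.12),
        ),
        seed=seed,
    )


def edge_recovery(
    n_seeds: int = 50,
    n: int = 415,
    gamma: float = 0.5,
    seed: int = 0,
) -> dict:
    """Mean edge-support sensitivity/specificity of the EBIC graphical lasso
    against a sparse 16-node latent truth."""
    omega = make_true_network(frozen_node_network_spec())
    iu = np.triu_indices(omega.shape[0], 1)
    truth = omega[iu] != 0
    sens, spec = [], []
    for k in range(n_seeds):
        X = sample_latent_gaussian(omega, n, seed=seed + k)
        net = network_from_data(X, gamma=gamma)
        est = net.weights[iu] != 0
        sens.append(float((est & truth).sum() / truth.sum()))
        spec.append(float((~est & ~truth).sum() / (~truth).sum()))
    return {
        "sensitivity": float(np.mean(sens)),
        "specificity": float(np.mean(spec)),
        "n_seeds": n_seeds,
        "n": n,
    }


def null_selection(
    n_seeds: int = 50,
    n: int = 415,
    p: int = 16,
    gamma: float = 0.5,
    seed: int = 0,
) -> dict:
    """Fraction of independent-data replicates on which the selected network
    is exactly empty."""
    empties = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        X = pd.DataFrame(rng.standard_normal((n, p)))
        net = network_from_data(X, gamma=gamma)
        empties += int(np.count_nonzero(net.weights) == 0)
    return {"empty_fraction": empties / n_seeds, "n_seeds": n_seeds, "n": n, "p": p}


def nct_type_one_error(
    n_replicates: int = 200,
    n_perm: int = 200,
    n_per_group: int = 150,
    alpha: float = 0.05,
    seed: int = 0,
    n_lambda: int = 30,
) -> dict:
    """Rejection rates of the permutation comparison when both groups come
    from one generating network (8 ordinal nodes, two blocks)."""
    spec = TrueNetworkSpec(
        8, ("TA",) * 4 + ("FI",) * 4, (0.15, 0.25),
        ((1, 5, 0.2), (2, 6, 0.15)), seed=3,
    )
    omega = make_true_network(spec)
    cuts = equiprobable_cutpoints()
    labels = np.array(["low"] * n_per_group + ["high"] * n_per_group)
    rej_m = rej_s = 0
    for rep in range(n_replicates):
        items = sample_ordinal_responses(omega, 2 * n_per_group, cuts, seed=seed + rep)
        res = nct_permutation(
            items.values, labels, n_perm=n_perm, gamma=0.5,
            seed=seed + 100_000 + rep, n_lambda=n_lambda,
        )
        rej_m += int(res.p_m <= alpha)
        rej_s += int(res.p_s <= alpha)
    return {
        "rejection_rate_m": rej_m / n_replicates,
        "rejection_rate_s": rej_s / n_replicates,
        "n_replicates": n_replicates,
        "n_perm": n_perm,
        "n_per_group": n_per_group,
    }


def screening_recovery(
    n_seeds: int = 20,
    n: int = 290,
    reps: int = 25,
    seed: int = 0,
) -> dict:
    """Fraction of seeds on which the three-track screen retains at least 14
    of the 16 planted-signal items (screening thresholds at their defaults:
    |rho| >= 0.30, rate >= 0.50, >= 60% of repetitions, weights 1/2/2,
    prune at rho > 0.80)."""
    successes = 0
    retained_counts = []
    for k in range(n_seeds):
        items, signal, _ = make_screening_benchmark(n, seed=seed + k)
        result = screen_nodes(items, ScreeningConfig(reps=reps, seed=seed + k))
        n_retained = sum(1 for s in signal if s in result.frozen_nodes)
        retained_counts.append(n_retained)
        successes += int(n_retained >= 14)
    return {
        "success_fraction": successes / n_seeds,
        "mean_signal_retained": float(np.mean(retained_counts)),
        "n_seeds": n_seeds,
        "n": n,
        "reps": reps,
    }
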