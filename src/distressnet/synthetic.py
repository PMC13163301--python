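"""Synthetic cohort generator with known ground-truth network structure.

Ordinal mood-item responses are generated from a latent Gaussian copula: a
sparse partial-correlation matrix on the latent scale (the ground truth the
estimation pipeline should recover) implies a latent correlation matrix;
multivariate-normal draws are thresholded into the 0-4 response categories by
per-item cutpoints.  Psychosocial totals and quality-of-life domain scores are
linear-plus-noise functions of per-dimension latent factors, with the
generating loadings retained in the dataset metadata for recovery tests.

Ordinal thresholding attenuates observed correlations relative to the latent
truth, so recovery checks compare against the latent structure with stated
tolerances rather than expecting exact agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
import pandas as pd

from .datatypes import (
    NEGATIVE_DIMENSIONS,
    CohortDataset,
    ItemResponseMatrix,
    TrueNetworkSpec,
)

__all__ = [
    "make_true_network",
    "latent_correlation",
    "equiprobable_cutpoints",
    "calibrate_cutpoints",
    "sample_ordinal_responses",
    "CohortConfig",
    "sample_cohort",
    "inject_missingness",
    "default_network_spec",
    "make_screening_benchmark",
]

_MIN_EIGENVALUE = 1e-3
# Diagonal inflation shrinks every requested weight by 1/(1+c); beyond this
# bound the generated network no longer resembles the request.
_MAX_INFLATION = 1.0


def make_true_network(spec: TrueNetworkSpec) -> np.ndarray:
    """Build the ground-truth partial-correlation matrix for ``spec``.

    Every within-block node pair receives a weight drawn uniformly from
    ``spec.within_block_weight_range`` (seeded), plus the explicit cross-block
    edges.  If the implied precision matrix (unit diagonal, off-diagonal
    ``-weight``) is not positive definite, the diagonal is inflated uniformly
    and the weights re-standardized, which shrinks all weights by a common
    factor; inflation beyond a fixed bound raises, naming the worst block.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_nodes
    omega = np.zeros((p, p))
    lo, hi = spec.within_block_weight_range
    for _, members in spec.blocks.items():
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                w = rng.uniform(lo, hi)
                i, j = members[a_idx], members[b_idx]
                omega[i, j] = omega[j, i] = w
    for i, j, w in spec.cross_block_edges:
        omega[i, j] = omega[j, i] = w

    precision = np.eye(p) - omega
    np.fill_diagonal(precision, 1.0)
    min_eig = float(np.linalg.eigvalsh(precision)[0])
    if min_eig < _MIN_EIGENVALUE:
        c = _MIN_EIGENVALUE - min_eig
        if c > _MAX_INFLATION:
            raise ValueError(
                "requested weights cannot be made positive definite within "
                f"the inflation bound (needed +{c:.3f} on the diagonal); "
                f"worst block: {_worst_block(spec, omega)!r}"
            )
        precision = precision + c * np.eye(p)
        d = np.sqrt(np.diag(precision))
        omega = -precision / np.outer(d, d)
        np.fill_diagonal(omega, 0.0)
    omega = 0.5 * (omega + omega.T)
    return omega


def _ensure_pd(omega: np.ndarray) -> np.ndarray:
    """Uniform diagonal inflation + re-standardization of the implied
    precision, shrinking all weights by a common factor if needed."""
    p = omega.shape[0]
    precision = np.eye(p) - omega
    np.fill_diagonal(precision, 1.0)
    min_eig = float(np.linalg.eigvalsh(precision)[0])
    if min_eig >= _MIN_EIGENVALUE:
        return omega
    c = _MIN_EIGENVALUE - min_eig
    precision = precision + c * np.eye(p)
    d = np.sqrt(np.diag(precision))
    out = -precision / np.outer(d, d)
    np.fill_diagonal(out, 0.0)
    return 0.5 * (out + out.T)


def _worst_block(spec: TrueNetworkSpec, omega: np.ndarray) -> str:
    worst, worst_eig = "", np.inf
    for label, members in spec.blocks.items():
        if len(members) < 2:
            continue
        sub = np.eye(len(members)) - omega[np.ix_(members, members)]
        np.fill_diagonal(sub, 1.0)
        e = float(np.linalg.eigvalsh(sub)[0])
        if e < worst_eig:
            worst, worst_eig = label, e
    return worst or "cross-block edges"


def latent_correlation(omega: np.ndarray) -> np.ndarray:
    """Latent Gaussian correlation matrix implied by partial correlations."""
    p = omega.shape[0]
    precision = np.eye(p) - omega
    np.fill_diagonal(precision, 1.0)
    eigs = np.linalg.eigvalsh(precision)
    if eigs[0] <= 0:
        raise ValueError(
            f"partial-correlation matrix implies a non-PD precision "
            f"(min eigenvalue {eigs[0]:.4g})"
        )
    cov = np.linalg.inv(precision)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def sample_latent_gaussian(
    true_net: np.ndarray,
    n: int,
    seed: int,
    item_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Continuous draws from the latent layer of the copula (no
    thresholding); used for recovery checks against the latent truth."""
    corr = latent_correlation(true_net)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    latent = rng.standard_normal((n, corr.shape[0])) @ chol.T
    if item_ids is None:
        item_ids = [f"X{i+1}" for i in range(corr.shape[0])]
    return pd.DataFrame(latent, columns=list(item_ids))


def equiprobable_cutpoints() -> np.ndarray:
    """Latent thresholds giving five equally likely response categories."""
    return stats.norm.ppf([0.2, 0.4, 0.6, 0.8])


def calibrate_cutpoints(
    target_mean: float,
    target_positive_rate: float,
    threshold: int = 2,
) -> np.ndarray:
    """Solve item cutpoints matching a target mean and positive rate.

    Cutpoints come from a graded-response family ``c_k = (k - 0.5 - mu)/sigma``
    for ``k = 1..4``: a location/scale shift of equally spaced thresholds.
    ``P(score >= threshold)`` pins one threshold; ``sigma`` is then solved so
    that the implied mean ``sum_k P(score >= k)`` matches ``target_mean``.
    """
    if not 0 < target_positive_rate < 1:
        raise ValueError("target positive rate must be in (0, 1)")
    if not 0 < target_mean < 4:
        raise ValueError("target mean must be in (0, 4)")
    z_rate = stats.norm.ppf(1.0 - target_positive_rate)

    def mean_given_sigma(sigma: float) -> float:
        mu = threshold - 0.5 - sigma * z_rate
        ks = np.arange(1, 5)
        return float(np.sum(1.0 - stats.norm.cdf((ks - 0.5 - mu) / sigma)))

    sigmas = np.geomspace(0.05, 20.0, 400)
    means = np.array([mean_given_sigma(s) for s in sigmas])
    diffs = means - target_mean
    sign_change = np.nonzero(np.diff(np.sign(diffs)) != 0)[0]
    if len(sign_change) == 0:
        raise ValueError(
            f"mean {target_mean} is unreachable at positive rate "
            f"{target_positive_rate} (threshold {threshold}): attainable "
            f"range [{means.min():.3f}, {means.max():.3f}]"
        )
    k = sign_change[0]
    sigma = optimize.brentq(
        lambda s: mean_given_sigma(s) - target_mean, sigmas[k], sigmas[k + 1]
    )
    mu = threshold - 0.5 - sigma * z_rate
    return (np.arange(1, 5) - 0.5 - mu) / sigma


def sample_ordinal_responses(
    true_net: np.ndarray,
    n: int,
    cutpoints: np.ndarray | Mapping[str, np.ndarray],
    seed: int,
    item_ids: Sequence[str] | None = None,
    dimension_labels: Mapping[str, str] | None = None,
) -> ItemResponseMatrix:
    """Draw n participants from the latent copula and threshold to 0-4.

    ``cutpoints`` is either a (p, 4) array (rows strictly increasing) or a
    mapping item id -> 4 thresholds.  Deterministic given ``seed``.
    """
    p = true_net.shape[0]
    if item_ids is None:
        item_ids = [f"X{i+1}" for i in range(p)]
    item_ids = list(item_ids)
    if dimension_labels is None:
        dimension_labels = {iid: "TA" for iid in item_ids}
    if isinstance(cutpoints, Mapping):
        cuts = np.vstack([np.asarray(cutpoints[iid], float) for iid in item_ids])
    else:
        cuts = np.asarray(cutpoints, float)
        if cuts.ndim == 1:
            cuts = np.tile(cuts, (p, 1))
    if cuts.shape != (p, 4):
        raise ValueError(f"cutpoints must have shape ({p}, 4), got {cuts.shape}")
    if not (np.diff(cuts, axis=1) > 0).all():
        raise ValueError("cutpoints must be strictly increasing per item")

    corr = latent_correlation(true_net)  # raises on non-PD input
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    latent = rng.standard_normal((n, p)) @ chol.T
    scores = np.zeros((n, p))
    for j in range(p):
        scores[:, j] = np.searchsorted(cuts[j], latent[:, j], side="left")
    values = pd.DataFrame(scores, columns=item_ids)
    values.index = [f"P{i+1:04d}" for i in range(n)]
    return ItemResponseMatrix(values, dict(dimension_labels))


# ---------------------------------------------------------------------------
# Default study-scale cohort
# ---------------------------------------------------------------------------

# Marginal calibration targets for the sixteen high-prevalence negative mood
# items (training-set means and positive-response proportions at the >=2
# cutoff).  Remaining negative items default to sub-50% prevalence, vigor
# items to moderate endorsement.
DEFAULT_ITEM_CALIBRATION: dict[str, tuple[float, float]] = {
    "TA2": (2.82, 0.948),
    "TA3": (2.43, 0.903),
    "TA4": (2.41, 0.938),
    "DD1": (2.37, 0.903),
    "DD2": (2.29, 0.903),
    "DD3": (2.28, 0.783),
    "DD4": (2.29, 0.917),
    "AH2": (1.91, 0.659),
    "FI1": (2.93, 0.945),
    "FI2": (3.01, 0.990),
    "FI3": (2.98, 0.955),
    "FI4": (2.47, 0.821),
    "FI5": (2.49, 0.948),
    "CB1": (2.10, 0.766),
    "CB2": (2.39, 0.862),
    "CB3": (2.28, 0.869),
}
_LOW_PREVALENCE_CALIBRATION = (1.35, 0.42)
_VIGOR_CALIBRATION = (2.0, 0.60)

# Coded covariate margins (category probabilities in the coded order).
DEFAULT_COVARIATE_MARGINS: dict[str, tuple[float, ...]] = {
    "D1": (0.193, 0.306, 0.289, 0.212),          # age group
    "D2": (0.012, 0.875, 0.019, 0.094),          # marital status
    "D3": (0.829, 0.171),                        # type of menopause
    "D4": (0.029, 0.822, 0.132, 0.017),          # parity
    "D5": (0.400, 0.386, 0.116, 0.098),          # educational level
    "D6": (0.253, 0.501, 0.212, 0.034),          # employment status
    "D7": (0.053, 0.747, 0.200),                 # monthly income level
    "D8": (0.774, 0.195, 0.031),                 # primary caregiver
    "D9": (0.477, 0.492, 0.031),                 # medical insurance
    "D10": (0.50, 0.35, 0.15),                   # surgical approach
    "D11": (0.330, 0.335, 0.263, 0.072),         # tumor stage
    "D12": (0.40, 0.30, 0.20, 0.10),             # treatment modality
}

# External-variable loadings onto per-dimension latent factors, plus the
# marginal location/scale/range used to place totals on each instrument's
# scale.  Self-perceived burden loads on fatigue; neuroticism on
# tension/depression; psychological capital protects against depression;
# negative illness perception tracks tension; financial toxicity is scored so
# LOWER totals mean more toxicity, hence the negative fatigue loading.
DEFAULT_PSYCHOSOCIAL_SPEC: dict[str, dict] = {
    "SPBS": {"loadings": {"FI": 0.55}, "loc": 30.0, "scale": 7.0, "range": (10, 50)},
    "BFI_N": {"loadings": {"TA": 0.40, "DD": 0.25}, "loc": 24.0, "scale": 6.0, "range": (8, 40)},
    "PPQTS": {"loadings": {"DD": -0.45}, "loc": 88.0, "scale": 14.0, "range": (26, 130)},
    "IPQR": {"loadings": {"TA": 0.40}, "loc": 44.0, "scale": 11.0, "range": (0, 80)},
    "COST_PROM": {"loadings": {"FI": -0.35}, "loc": 22.0, "scale": 7.0, "range": (0, 44)},
}

# QoL domains: E1-E5 functional (higher = better, so negative loadings on
# distress factors), E6-E12 symptoms (higher = worse).
DEFAULT_QOL_SPEC: dict[str, dict] = {
    "E1": {"loadings": {"FI": -0.45}, "loc": 70.0, "scale": 15.0},
    "E2": {"loadings": {"FI": -0.40}, "loc": 68.0, "scale": 16.0},
    "E3": {"loadings": {"DD": -0.45, "TA": -0.20}, "loc": 65.0, "scale": 16.0},
    "E4": {"loadings": {"CB": -0.40}, "loc": 72.0, "scale": 15.0},
    "E5": {"loadings": {"DD": -0.30}, "loc": 70.0, "scale": 16.0},
    "E6": {"loadings": {"FI": 0.30}, "loc": 35.0, "scale": 18.0},
    "E7": {"loadings": {"FI": 0.55}, "loc": 45.0, "scale": 18.0},
    "E8": {"loadings": {"FI": 0.35}, "loc": 25.0, "scale": 16.0},
    "E9": {"loadings": {"FI": 0.25, "DD": 0.15}, "loc": 30.0, "scale": 17.0},
    "E10": {"loadings": {"FI": 0.15}, "loc": 22.0, "scale": 15.0},
    "E11": {"loadings": {"TA": 0.20}, "loc": 20.0, "scale": 14.0},
    "E12": {"loadings": {"FI": 0.15}, "loc": 18.0, "scale": 13.0},
}


def default_network_spec(seed: int = 0) -> TrueNetworkSpec:
    """30-item six-dimension ground truth: within-dimension cliques plus a
    few cross-dimension couplings (fatigue-anxiety, fatigue-confusion,
    depression-anxiety) and negative vigor links."""
    labels = tuple(
        f"{dim}" for dim in ("TA", "DD", "AH", "FI", "CB", "V") for _ in range(5)
    )
    # item index layout: TA 0-4, DD 5-9, AH 10-14, FI 15-19, CB 20-24, V 25-29
    cross = (
        (3, 18, 0.15),   # TA4 - FI4
        (1, 21, 0.12),   # TA2 - CB2
        (8, 1, 0.10),    # DD4 - TA2
        (16, 6, 0.10),   # FI2 - DD2
        (11, 1, 0.10),   # AH2 - TA2
        (22, 18, 0.10),  # CB3 - FI4
        (26, 16, -0.08),  # V2 - FI2
        (27, 7, -0.07),  # V3 - DD3
    )
    # five-item cliques stay well-conditioned only for modest partial
    # correlations (row sums below 1); the implied marginal correlations
    # then sit in the 0.2-0.4 range typical of mood inventories
    return TrueNetworkSpec(
        n_nodes=30,
        block_assignment=labels,
        within_block_weight_range=(0.12, 0.18),
        cross_block_edges=cross,
        seed=seed,
    )


def _default_item_ids() -> list[str]:
    return [f"{d}{k}" for d in ("TA", "DD", "AH", "FI", "CB", "V") for k in range(1, 6)]


def default_cutpoints(item_ids: Sequence[str], dimension_labels: Mapping[str, str],
                      positive_threshold: int = 2) -> dict[str, np.ndarray]:
    cuts = {}
    for iid in item_ids:
        if iid in DEFAULT_ITEM_CALIBRATION:
            m, r = DEFAULT_ITEM_CALIBRATION[iid]
        elif dimension_labels[iid] == "V":
            m, r = _VIGOR_CALIBRATION
        else:
            m, r = _LOW_PREVALENCE_CALIBRATION
        cuts[iid] = calibrate_cutpoints(m, r, threshold=positive_threshold)
    return cuts


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.  Defaults emulate the study
    conditions: n = 415 participants, 30 ordinal items over six dimensions,
    twelve coded covariates, five psychosocial totals, twelve QoL domains."""

    n: int = 415
    spec: TrueNetworkSpec = field(default_factory=default_network_spec)
    item_ids: tuple[str, ...] = field(default_factory=lambda: tuple(_default_item_ids()))
    cutpoints: Mapping[str, np.ndarray] | None = None
    psychosocial_spec: Mapping[str, dict] = field(
        default_factory=lambda: dict(DEFAULT_PSYCHOSOCIAL_SPEC)
    )
    qol_spec: Mapping[str, dict] = field(default_factory=lambda: dict(DEFAULT_QOL_SPEC))
    covariate_margins: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MARGINS)
    )
    external_noise_sd: float = 0.8
    seed: int = 0


def sample_cohort(config: CohortConfig | None = None, **overrides) -> CohortDataset:
    """Generate a full synthetic cohort.

    Psychosocial totals and QoL domains are built as
    ``loc + scale * (sum_d loading_d * factor_d + noise)`` where ``factor_d``
    is the mean of dimension d's latent Gaussians, then clipped to the
    instrument range; generating loadings are stored in ``metadata`` for
    recovery tests.  Covariates are independent categorical draws matching
    the configured margins.
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    if config.n < 2:
        raise ValueError("cohort size must be at least 2")
    for name, spec_ in config.psychosocial_spec.items():
        for dim, coef in spec_["loadings"].items():
            if not np.isfinite(coef):
                raise ValueError(f"non-finite loading for {name} on {dim}")

    rng = np.random.default_rng(config.seed)
    omega = make_true_network(config.spec)
    dim_labels = {
        iid: config.spec.block_assignment[k] for k, iid in enumerate(config.item_ids)
    }
    cuts = config.cutpoints or default_cutpoints(config.item_ids, dim_labels)

    corr = latent_correlation(omega)
    chol = np.linalg.cholesky(corr)
    latent = rng.standard_normal((config.n, len(config.item_ids))) @ chol.T
    cut_arr = np.vstack([np.asarray(cuts[iid], float) for iid in config.item_ids])
    scores = np.zeros_like(latent)
    for j in range(latent.shape[1]):
        scores[:, j] = np.searchsorted(cut_arr[j], latent[:, j], side="left")
    index = [f"P{i+1:04d}" for i in range(config.n)]
    items = ItemResponseMatrix(
        pd.DataFrame(scores, columns=list(config.item_ids), index=index), dim_labels
    )

    # per-dimension latent factors
    factors = {}
    for dim in set(config.spec.block_assignment):
        cols = [k for k, lab in enumerate(config.spec.block_assignment) if lab == dim]
        factors[dim] = latent[:, cols].mean(axis=1)

    def build_external(spec_map: Mapping[str, dict], clip_range=None) -> pd.DataFrame:
        out = {}
        for name, s in spec_map.items():
            signal = np.zeros(config.n)
            for dim, coef in s["loadings"].items():
                signal += coef * factors[dim]
            signal += config.external_noise_sd * rng.standard_normal(config.n)
            vals = s["loc"] + s["scale"] * signal
            lo, hi = s.get("range", clip_range)
            out[name] = np.clip(vals, lo, hi)
        return pd.DataFrame(out, index=index)

    psychosocial = build_external(config.psychosocial_spec)
    qol = build_external(config.qol_spec, clip_range=(0.0, 100.0))

    covariates = pd.DataFrame(
        {
            name: rng.choice(len(probs), size=config.n, p=np.asarray(probs) / np.sum(probs))
            for name, probs in config.covariate_margins.items()
        },
        index=index,
    )

    metadata = {
        "seed": config.seed,
        "cutpoints": {k: np.asarray(v).tolist() for k, v in cuts.items()},
        "psychosocial_loadings": {
            k: dict(v["loadings"]) for k, v in config.psychosocial_spec.items()
        },
        "qol_loadings": {k: dict(v["loadings"]) for k, v in config.qol_spec.items()},
        "true_partial_correlations": omega.tolist(),
    }
    return CohortDataset(
        items=items,
        covariates=covariates,
        psychosocial=psychosocial,
        qol=qol,
        truth=config.spec,
        metadata=metadata,
    )


def inject_missingness(data: CohortDataset, rate: float, seed: int) -> CohortDataset:
    """Set item entries missing completely at random at the given rate.

    Only the mood items are masked (external tables stay complete); the mask
    is recorded under ``metadata['missing_mask']``.
    """
    if not 0 <= rate < 0.5:
        raise ValueError(f"missingness rate must be in [0, 0.5), got {rate}")
    out = CohortDataset(
        items=data.items.copy(),
        covariates=data.covariates.copy(),
        psychosocial=data.psychosocial.copy(),
        qol=data.qol.copy(),
        truth=data.truth,
        metadata=dict(data.metadata),
    )
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    vals = out.items.values.to_numpy()
    mask = rng.random(vals.shape) < rate
    vals[mask] = np.nan
    out.items.values.iloc[:, :] = vals
    out.metadata["missing_mask"] = mask.tolist()
    out.metadata["missing_seed"] = seed
    return out


# ---------------------------------------------------------------------------
# Screening benchmark: planted signal vs weakly linked items
# ---------------------------------------------------------------------------

def make_screening_benchmark(
    n: int, seed: int, n_weak: int = 7
) -> tuple[ItemResponseMatrix, list[str], list[str]]:
    """Cohort of 16 planted-signal and ``n_weak`` weakly linked ordinal items.

    The sixteen signal items form five dimension blocks with moderate
    within-block partial correlations plus hub couplings (mirroring the
    frozen-node layout TA x3, DD x4, AH x1, FI x5, CB x3); each weak item has
    a single faint edge (0.06) to one signal node.  All items are calibrated
    to >50% positive-response prevalence so the weak items survive the
    prevalence filter and must be removed by the association tracks.

    Returns (items, signal_ids, weak_ids).
    """
    signal_ids = [
        "TA2", "TA3", "TA4",
        "DD1", "DD2", "DD3", "DD4",
        "AH2",
        "FI1", "FI2", "FI3", "FI4", "FI5",
        "CB1", "CB2", "CB3",
    ]
    blocks = {
        "TA": [0, 1, 2],
        "DD": [3, 4, 5, 6],
        "AH": [7],
        "FI": [8, 9, 10, 11, 12],
        "CB": [13, 14, 15],
    }
    p = 16 + n_weak
    rng = np.random.default_rng(seed + 90_001)
    omega = np.zeros((p, p))
    for members in blocks.values():
        # keep each clique's row sum of partial correlations below 1 so the
        # block stays comfortably positive definite before hub edges
        scale = max(1, len(members) - 1)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                w = rng.uniform(0.60, 0.80) / scale
                i, j = members[a], members[b]
                omega[i, j] = omega[j, i] = w
    # hub couplings keep every block (and the single anger item) tied to the
    # shared distress core
    for i, j, w in [
        (2, 11, 0.25),   # TA4 - FI4
        (1, 14, 0.20),   # TA2 - CB2
        (6, 1, 0.18),    # DD4 - TA2
        (9, 4, 0.18),    # FI2 - DD2
        (7, 1, 0.22),    # AH2 - TA2
        (7, 10, 0.20),   # AH2 - FI3
        (15, 11, 0.16),  # CB3 - FI4
        (13, 2, 0.14),   # CB1 - TA4
    ]:
        omega[i, j] = omega[j, i] = w
    weak_ids = [f"W{k+1}" for k in range(n_weak)]
    anchors = rng.integers(0, 16, size=n_weak)
    for k, anchor in enumerate(anchors):
        omega[16 + k, anchor] = omega[anchor, 16 + k] = 0.06
    omega = _ensure_pd(omega)

    item_ids = signal_ids + weak_ids
    dims = {}
    for iid in signal_ids:
        dims[iid] = iid[:2]
    weak_dims = ["TA", "DD", "AH", "FI", "CB", "TA", "DD"]
    for k, iid in enumerate(weak_ids):
        dims[iid] = weak_dims[k % len(weak_dims)]

    cuts = {}
    for iid in signal_ids:
        m, r = DEFAULT_ITEM_CALIBRATION[iid]
        cuts[iid] = calibrate_cutpoints(m, r)
    for iid in weak_ids:
        cuts[iid] = calibrate_cutpoints(2.1, 0.70)

    items = sample_ordinal_responses(
        omega, n, cuts, seed=seed, item_ids=item_ids, dimension_labels=dims
    )
    return items, signal_ids, weak_ids
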