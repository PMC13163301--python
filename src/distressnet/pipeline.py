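"""End-to-end orchestration: synthesize (optional) -> impute -> split ->
screen/freeze -> validate -> primary network + centrality + stability ->
extended and residual networks -> permutation comparisons, with every stage's
outputs and seeds written to an output directory."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import CohortDataset, ItemResponseMatrix
from .ggm import PartialCorrelationNetwork, extended_network, network_from_data, residual_network
from .nct import median_split, nct_permutation
from .netstats import centrality_table, count_edges, global_strength
from .preprocess import impute_pmm, split_train_validation
from .screening import ScreeningConfig, screen_nodes, validate_nodes
from .stability import bootstrap_edges, case_dropping, cs_coefficient
from .synthetic import CohortConfig, inject_missingness, sample_cohort

__all__ = ["PipelineConfig", "run_pipeline", "export_network"]

# Settings the source procedure leaves unstated; echoed in the manifest so
# downstream users can audit them.
_ASSUMED_DEFAULTS = (
    "positive_threshold", "vote_min", "reps", "correlation_method",
    "split_proportion", "loo_core",
)


@dataclass
class PipelineConfig:
    output_dir: str = "distressnet_run"
    input_dir: str | None = None          # read a cohort instead of simulating
    n: int = 415
    missing_rate: float = 0.05
    split_proportion: float = 0.70
    positive_threshold: int = 2
    rho_min: float = 0.30
    rate_min: float = 0.50
    select_frac: float = 0.60
    weights: tuple[int, int, int] = (1, 2, 2)
    vote_min: int = 3
    rho_max: float = 0.80
    reps: int = 100
    folds: int = 10
    gamma: float = 0.50
    correlation_method: str = "npn-pearson"
    n_lambda: int = 100
    b_boot: int = 1000
    b_case: int = 1000
    n_perm: int = 1000
    seed_simulate: int | None = 1
    seed_missing: int | None = 2
    seed_impute: int | None = 3
    seed_split: int | None = 4
    seed_screening: int | None = 5
    seed_bootstrap: int | None = 6
    seed_permutation: int | None = 7

    def validate(self) -> None:
        for name in (
            "seed_simulate", "seed_missing", "seed_impute", "seed_split",
            "seed_screening", "seed_bootstrap", "seed_permutation",
        ):
            if getattr(self, name) is None:
                raise ValueError(f"config is missing a seed: {name}")
        if not 0 < self.split_proportion < 1:
            raise ValueError("split_proportion must be in (0, 1)")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        for name, lo, hi in (
            ("rho_min", 0, 1), ("rate_min", 0, 1), ("select_frac", 0, 1),
            ("rho_max", 0, 1), ("gamma", 0, 10),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


def export_network(
    network: PartialCorrelationNetwork, path: str | Path, format: str = "matrix"
) -> Path:
    """Write a network as a square weight-matrix CSV or long edge list."""
    path = Path(path)
    if format == "matrix":
        network.as_frame().to_csv(path, float_format="%.17g")
    elif format == "edgelist":
        network.edge_list().to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _network_meta(net: PartialCorrelationNetwork) -> dict:
    nz, possible = count_edges(net)
    return {
        "gamma": net.gamma,
        "lambda_selected": net.lambda_selected,
        "sample_size": net.sample_size,
        "input_correlation": net.input_correlation,
        "correlation_repaired": net.correlation_repaired,
        "n_nodes": net.p,
        "nonzero_edges": nz,
        "possible_edges": possible,
        "global_strength": global_strength(net),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns a result bundle and writes every
    stage's outputs under ``config.output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "assumed_defaults": list(_ASSUMED_DEFAULTS),
        "stages": {},
    }
    bundle: dict = {}

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            manifest["stages"][name] = {
                "elapsed_s": round(time.perf_counter() - t0, 3), **info,
            }
        return done

    # --- data -------------------------------------------------------------
    done = stage("data")
    if config.input_dir:
        cohort = CohortDataset.from_directory(config.input_dir)
    else:
        cohort = sample_cohort(CohortConfig(n=config.n, seed=config.seed_simulate))
        if config.missing_rate > 0:
            cohort = inject_missingness(
                cohort, config.missing_rate, config.seed_missing
            )
        cohort.to_directory(out / "cohort")
    done(n=cohort.n_participants, n_items=len(cohort.items.item_ids))

    done = stage("impute")
    completed = impute_pmm(cohort.items.values, seed=config.seed_impute)
    completed = completed.round().clip(0, 4)
    items = ItemResponseMatrix(completed, dict(cohort.items.dimension_labels))
    done(imputed_cells=int(cohort.items.values.isna().sum().sum()))

    # --- split + screening -------------------------------------------------
    done = stage("split")
    split = split_train_validation(
        items.values.index, config.split_proportion, config.seed_split
    )
    (out / "split.json").write_text(json.dumps(split.to_dict(), indent=2))
    done(n_train=len(split.training_ids), n_validation=len(split.validation_ids))

    done = stage("screening")
    train_items = ItemResponseMatrix(
        items.values.loc[list(split.training_ids)], dict(items.dimension_labels)
    )
    valid_items = ItemResponseMatrix(
        items.values.loc[list(split.validation_ids)], dict(items.dimension_labels)
    )
    scr_cfg = ScreeningConfig(
        positive_threshold=config.positive_threshold,
        rho_min=config.rho_min,
        rate_min=config.rate_min,
        folds=config.folds,
        reps=config.reps,
        select_frac=config.select_frac,
        weights=config.weights,
        vote_min=config.vote_min,
        rho_max=config.rho_max,
        seed=config.seed_screening,
    )
    screening = screen_nodes(train_items, scr_cfg)
    frozen = screening.frozen_nodes
    if len(frozen) < 3:
        raise RuntimeError(
            f"screening stage retained only {len(frozen)} nodes; "
            "network estimation needs at least 3"
        )
    auc_val, table_val = validate_nodes(frozen, valid_items, config.positive_threshold)
    auc_full, _ = validate_nodes(frozen, items, config.positive_threshold)
    _, table_train = validate_nodes(frozen, train_items, config.positive_threshold)
    screening.auc_validation = auc_val
    screening.auc_full = auc_full
    consistency = table_train.join(table_val, lsuffix="_training", rsuffix="_validation")
    screening.consistency = consistency
    (out / "screening.json").write_text(json.dumps(screening.to_dict(), indent=2))
    consistency.to_csv(out / "consistency.csv")
    bundle["screening"] = screening
    done(n_frozen=len(frozen), auc_validation=auc_val, auc_full=auc_full)

    # --- primary network ---------------------------------------------------
    done = stage("primary_network")
    frozen_df = items.values[frozen]
    primary = network_from_data(
        frozen_df, gamma=config.gamma, method=config.correlation_method,
        n_lambda=config.n_lambda,
    )
    export_network(primary, out / "network_primary.csv")
    export_network(primary, out / "network_primary_edges.csv", format="edgelist")
    centrality_table(primary).to_csv(out / "centrality_primary.csv")
    bundle["primary"] = primary
    done(**_network_meta(primary))

    # --- stability ---------------------------------------------------------
    done = stage("stability")
    boot = bootstrap_edges(
        frozen_df, B=config.b_boot, seed=config.seed_bootstrap,
        gamma=config.gamma, method=config.correlation_method,
        n_lambda=config.n_lambda,
    )
    boot.as_frame().to_csv(out / "bootstrap_edges.csv", index=False)
    drop = case_dropping(
        frozen_df, B=config.b_case, seed=config.seed_bootstrap + 1,
        gamma=config.gamma, method=config.correlation_method,
        n_lambda=config.n_lambda,
    )
    cs = cs_coefficient(drop)
    drop.summary().to_csv(out / "case_dropping.csv", index=False)
    (out / "stability.json").write_text(json.dumps(
        {"cs_coefficient": cs, "metric": drop.metric,
         "cor_threshold": drop.cor_threshold, "prob_threshold": drop.prob_threshold},
        indent=2))
    bundle["cs_coefficient"] = cs
    done(cs_coefficient=cs)

    # --- extended + residual networks --------------------------------------
    done = stage("extended_networks")
    nets = {}
    for label, external in (
        ("demographic", cohort.covariates),
        ("psychosocial", cohort.psychosocial),
        ("qol", cohort.qol),
    ):
        net = extended_network(
            frozen_df, external, gamma=config.gamma,
            method=config.correlation_method, n_lambda=config.n_lambda,
        )
        export_network(net, out / f"network_extended_{label}.csv")
        centrality_table(net).to_csv(out / f"centrality_extended_{label}.csv")
        nets[label] = net
    resid = residual_network(
        frozen_df, cohort.covariates, gamma=config.gamma, n_lambda=config.n_lambda
    )
    export_network(resid, out / "network_residual.csv")
    nets["residual"] = resid
    bundle["networks"] = nets
    done(**{k: _network_meta(v)["nonzero_edges"] for k, v in nets.items()})

    # --- network comparison -------------------------------------------------
    done = stage("nct")
    rows = []
    for k, var in enumerate(cohort.psychosocial.columns):
        labels = median_split(cohort.psychosocial[var])
        res = nct_permutation(
            frozen_df, labels, n_perm=config.n_perm, gamma=config.gamma,
            seed=config.seed_permutation + k, method=config.correlation_method,
            n_lambda=config.n_lambda,
        )
        rows.append(res.as_row(var))
        bundle.setdefault("nct", {})[var] = res
    nct_table = pd.concat(rows, ignore_index=True)
    nct_table.to_csv(out / "nct.csv", index=False)
    done(n_variables=len(rows))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
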