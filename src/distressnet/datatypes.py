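"""Core data containers shared across the pipeline.

The raw unit of analysis is a participants x items matrix of ordinal mood
ratings (0-4 Likert), each item tagged with one of six mood dimensions:
tension/anxiety (TA), depression/dejection (DD), anger/hostility (AH),
fatigue/inertia (FI), confusion/bewilderment (CB), and vigor (V).  A cohort
bundles the item matrix with coded demographic/clinical covariates,
psychosocial scale totals, and quality-of-life domain scores, all sharing one
participant ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MOOD_DIMENSIONS = ("TA", "DD", "AH", "FI", "CB", "V")
NEGATIVE_DIMENSIONS = ("TA", "DD", "AH", "FI", "CB")

RESPONSE_MIN = 0
RESPONSE_MAX = 4


@dataclass(frozen=True)
class TrueNetworkSpec:
    """Ground-truth sparse partial-correlation structure for simulation.

    Within each dimension block every node pair is connected with a weight
    drawn uniformly from ``within_block_weight_range``; additional explicit
    cross-block edges are given as ``(i, j, weight)`` triples.  The implied
    precision matrix must be positive definite (enforced, with bounded
    diagonal inflation, by :func:`distressnet.synthetic.make_true_network`).
    """

    n_nodes: int
    block_assignment: tuple[str, ...]
    within_block_weight_range: tuple[float, float] = (0.2, 0.35)
    cross_block_edges: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if len(self.block_assignment) != self.n_nodes:
            raise ValueError(
                f"block_assignment has {len(self.block_assignment)} labels "
                f"for {self.n_nodes} nodes"
            )
        unknown = set(self.block_assignment) - set(MOOD_DIMENSIONS)
        if unknown:
            raise ValueError(f"unknown dimension labels: {sorted(unknown)}")
        lo, hi = self.within_block_weight_range
        if not (-1 < lo <= hi < 1):
            raise ValueError("within-block weights must lie in (-1, 1)")
        for i, j, w in self.cross_block_edges:
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes) or i == j:
                raise ValueError(f"invalid cross-block edge ({i}, {j})")
            if not abs(w) < 1:
                raise ValueError(f"edge weight |{w}| must be < 1")

    @property
    def blocks(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for idx, lab in enumerate(self.block_assignment):
            out.setdefault(lab, []).append(idx)
        return out


@dataclass
class ItemResponseMatrix:
    """Participants x ordinal items, with per-item mood-dimension labels.

    ``values`` is a float DataFrame (NaN marks missing); every non-missing
    entry must lie in {0, 1, 2, 3, 4}.
    """

    values: pd.DataFrame
    dimension_labels: dict[str, str]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        for col in self.values.columns:
            if col not in self.dimension_labels:
                raise ValueError(f"item {col!r} has no dimension label")
        arr = self.values.to_numpy()
        finite = arr[np.isfinite(arr)]
        if finite.size and (
            (finite < RESPONSE_MIN).any()
            or (finite > RESPONSE_MAX).any()
            or (finite != np.round(finite)).any()
        ):
            raise ValueError(
                f"item responses must be integers in "
                f"[{RESPONSE_MIN}, {RESPONSE_MAX}]"
            )

    @property
    def item_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def participant_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_participants(self) -> int:
        return len(self.values)

    def items_in_dimensions(self, dims: Sequence[str]) -> list[str]:
        dims = set(dims)
        return [c for c in self.values.columns if self.dimension_labels[c] in dims]

    def copy(self) -> "ItemResponseMatrix":
        return ItemResponseMatrix(self.values.copy(), dict(self.dimension_labels))


@dataclass
class CohortDataset:
    """One simulated or observed cohort: items + external variables.

    All component tables share the participant index.  ``truth`` carries the
    generating network spec when the cohort is synthetic; ``metadata`` holds
    seeds, cutpoints, external-variable loadings, and the missingness mask so
    recovery tests can compare estimates against the generating process.
    """

    items: ItemResponseMatrix
    covariates: pd.DataFrame
    psychosocial: pd.DataFrame
    qol: pd.DataFrame
    truth: TrueNetworkSpec | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.items.values.index
        for name, tab in (
            ("covariates", self.covariates),
            ("psychosocial", self.psychosocial),
            ("qol", self.qol),
        ):
            if len(tab) != len(idx) or not (tab.index == idx).all():
                raise ValueError(f"{name} index does not match items index")
        if len(self.qol.columns):
            q = self.qol.to_numpy(dtype=float)
            q = q[np.isfinite(q)]
            if q.size and ((q < 0).any() or (q > 100).any()):
                raise ValueError("QoL domain scores must lie in [0, 100]")

    @property
    def n_participants(self) -> int:
        return self.items.n_participants

    def subset(self, participant_ids: Sequence) -> "CohortDataset":
        ids = list(participant_ids)
        return CohortDataset(
            items=ItemResponseMatrix(
                self.items.values.loc[ids], dict(self.items.dimension_labels)
            ),
            covariates=self.covariates.loc[ids],
            psychosocial=self.psychosocial.loc[ids],
            qol=self.qol.loc[ids],
            truth=self.truth,
            metadata=self.metadata,
        )

    def to_directory(self, path: str | Path) -> None:
        """Write the cohort as plain CSV tables plus a JSON metadata file."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.items.values.to_csv(path / "items.csv")
        self.covariates.to_csv(path / "covariates.csv")
        self.psychosocial.to_csv(path / "psychosocial.csv")
        self.qol.to_csv(path / "qol.csv")
        meta = {
            "dimension_labels": self.items.dimension_labels,
            "metadata": _jsonable(self.metadata),
        }
        if self.truth is not None:
            meta["truth"] = {
                "n_nodes": self.truth.n_nodes,
                "block_assignment": list(self.truth.block_assignment),
                "within_block_weight_range": list(
                    self.truth.within_block_weight_range
                ),
                "cross_block_edges": [list(e) for e in self.truth.cross_block_edges],
                "seed": self.truth.seed,
            }
        (path / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_directory(cls, path: str | Path) -> "CohortDataset":
        path = Path(path)
        meta = json.loads((path / "metadata.json").read_text())
        items = ItemResponseMatrix(
            pd.read_csv(path / "items.csv", index_col=0),
            dict(meta["dimension_labels"]),
        )
        truth = None
        if "truth" in meta:
            t = meta["truth"]
            truth = TrueNetworkSpec(
                n_nodes=t["n_nodes"],
                block_assignment=tuple(t["block_assignment"]),
                within_block_weight_range=tuple(t["within_block_weight_range"]),
                cross_block_edges=tuple(
                    (int(i), int(j), float(w)) for i, j, w in t["cross_block_edges"]
                ),
                seed=t["seed"],
            )
        return cls(
            items=items,
            covariates=pd.read_csv(path / "covariates.csv", index_col=0),
            psychosocial=pd.read_csv(path / "psychosocial.csv", index_col=0),
            qol=pd.read_csv(path / "qol.csv", index_col=0),
            truth=truth,
            metadata=meta.get("metadata", {}),
        )


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
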