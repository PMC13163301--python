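"""Scoring rules for the measurement battery.

Covers the 30-item mood inventory (six dimensions scored 0-4), the
illness-perception questionnaire (IPQR, eight scored 0-10 items, three
reverse-coded), the neuroticism subscale (BFI-N, eight 1-5 items, three
reverse-coded), positive psychological capital (PPQ, 26 1-5 items, five
reverse-coded), financial toxicity (COST-PROM, eleven 0-4 items, seven
reverse-coded; lower totals = worse toxicity), self-perceived burden (SPBS,
ten 1-5 items with none/mild/moderate/severe bands), and the EORTC QLQ-C30
0-100 linear domain transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ItemResponseMatrix, NEGATIVE_DIMENSIONS

__all__ = [
    "ScaleDefinition",
    "INSTRUMENTS",
    "reverse_code",
    "score_total",
    "categorize_spbs",
    "score_qlq_domain",
    "cronbach_alpha",
    "score_bpoms",
]


@dataclass(frozen=True)
class ScaleDefinition:
    name: str
    item_count: int
    response_min: int
    response_max: int
    reverse_items: tuple[int, ...] = ()  # 1-based, as printed on the form
    category_cuts: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.response_min >= self.response_max:
            raise ValueError(f"{self.name}: response_min must be < response_max")
        bad = [i for i in self.reverse_items if not 1 <= i <= self.item_count]
        if bad:
            raise ValueError(f"{self.name}: reverse items {bad} out of 1..{self.item_count}")


INSTRUMENTS: dict[str, ScaleDefinition] = {
    "IPQR": ScaleDefinition("IPQR", item_count=8, response_min=0, response_max=10,
                            reverse_items=(3, 4, 7)),
    "BFI_N": ScaleDefinition("BFI_N", item_count=8, response_min=1, response_max=5,
                             reverse_items=(2, 5, 7)),
    "PPQTS": ScaleDefinition("PPQTS", item_count=26, response_min=1, response_max=5,
                             reverse_items=(8, 10, 12, 14, 25)),
    "COST_PROM": ScaleDefinition("COST_PROM", item_count=11, response_min=0,
                                 response_max=4,
                                 reverse_items=(2, 3, 4, 5, 8, 9, 10)),
    "SPBS": ScaleDefinition("SPBS", item_count=10, response_min=1, response_max=5,
                            category_cuts=(("none", 20.0), ("mild", 30.0),
                                           ("moderate", 40.0), ("severe", np.inf))),
}


def reverse_code(value, response_min: int, response_max: int):
    """Reflect a score about the response-range midpoint."""
    arr = np.asarray(value, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and ((finite < response_min).any() or (finite > response_max).any()):
        bad = finite[(finite < response_min) | (finite > response_max)][0]
        raise ValueError(
            f"value {bad} outside response range [{response_min}, {response_max}]"
        )
    out = response_min + response_max - arr
    if np.isscalar(value) or np.ndim(value) == 0:
        return float(out)
    return out


def score_total(items, definition: ScaleDefinition) -> float:
    """Sum the item vector after reverse-coding the listed items."""
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 1 or arr.size != definition.item_count:
        raise ValueError(
            f"{definition.name}: expected {definition.item_count} items, got {arr.size}"
        )
    if not np.isfinite(arr).all():
        missing = np.nonzero(~np.isfinite(arr))[0]
        raise ValueError(
            f"{definition.name}: missing responses at item(s) "
            f"{[int(i) + 1 for i in missing]} (impute before scoring)"
        )
    arr = arr.copy()
    for idx in definition.reverse_items:
        arr[idx - 1] = reverse_code(
            arr[idx - 1], definition.response_min, definition.response_max
        )
    return float(arr.sum())


def categorize_spbs(total: float) -> str:
    """Band a self-perceived-burden total: none (<20), mild (20-29),
    moderate (30-39), severe (>=40)."""
    spbs = INSTRUMENTS["SPBS"]
    lo = spbs.item_count * spbs.response_min
    hi = spbs.item_count * spbs.response_max
    if not lo <= total <= hi:
        raise ValueError(f"SPBS total {total} outside instrument range [{lo}, {hi}]")
    for label, upper in spbs.category_cuts:
        if total < upper:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def score_qlq_domain(items, domain_kind: str, item_range: int = 4) -> float:
    """EORTC QLQ-C30 linear transform of a domain to the 0-100 scale.

    RS is the item mean; functional domains score (1 - (RS-1)/range) * 100 so
    the best functioning maps to 100, symptom and global domains
    ((RS-1)/range) * 100 so the worst burden maps to 100; range is
    item_range - 1 (3 for the 4-point items, 6 for the two 7-point items).
    """
    if domain_kind not in ("functional", "symptom", "global"):
        raise ValueError(f"unknown domain kind {domain_kind!r}")
    arr = np.asarray(items, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("missing item responses in QLQ domain")
    if ((arr < 1) | (arr > item_range)).any():
        raise ValueError(
            f"item responses outside the declared 1..{item_range} range "
            "(mixed-range domain?)"
        )
    rs = float(arr.mean())
    rng = item_range - 1
    if domain_kind == "functional":
        return (1.0 - (rs - 1.0) / rng) * 100.0
    return ((rs - 1.0) / rng) * 100.0


def cronbach_alpha(items) -> float:
    """Internal consistency alpha = k/(k-1) * (1 - sum(var_i)/var_total).

    Variances use the population (n) denominator throughout; the estimate is
    invariant to that choice since the denominator cancels.
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2 or arr.shape[0] < 3:
        raise ValueError("alpha needs >= 3 participants and >= 2 items")
    if not np.isfinite(arr).all():
        raise ValueError("alpha requires complete data")
    k = arr.shape[1]
    item_vars = arr.var(axis=0, ddof=0)
    total_var = arr.sum(axis=1).var(ddof=0)
    if total_var == 0:
        raise ValueError("total-score variance is zero")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def score_bpoms(
    items: ItemResponseMatrix, subtract_vigor: bool = True
) -> pd.DataFrame:
    """Per-dimension sums and a total distress score per participant.

    The default total follows the total-mood-disturbance convention: sum of
    the five negative dimensions minus the vigor sum; ``subtract_vigor=False``
    gives the plain negative-dimension sum.  Higher totals mean greater
    distress under both conventions.
    """
    vals = items.values
    if vals.isna().any().any():
        raise ValueError("mood items contain missing entries (impute first)")
    dims = sorted(set(items.dimension_labels.values()))
    out = {}
    for dim in dims:
        cols = items.items_in_dimensions([dim])
        out[dim] = vals[cols].sum(axis=1)
    table = pd.DataFrame(out, index=vals.index)
    negative = [d for d in NEGATIVE_DIMENSIONS if d in table.columns]
    total = table[negative].sum(axis=1)
    if subtract_vigor and "V" in table.columns:
        total = total - table["V"]
    table["total_distress"] = total
    return table
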