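"""Item-level intake coding: eating-occasion construction and serving vectors.

An eating occasion (EO) is any set of foods or drinks consumed simultaneously
that together contribute at least 210 kJ.  Items are merged into occasions by
single-linkage clustering of their reported start times within a configurable
window (default 0 minutes, i.e. identical reported times), then occasions
below the energy threshold are discarded.

Servings are quantified per six outcomes: the five core food groups
(vegetables, fruits, grains, meats and alternatives, dairy and alternatives),
whose per-item serving equivalences are supplied with the data, and
discretionary foods, quantified as 600 kJ per serving.  Modelled outcomes are
``ln(servings + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MIN_EO_ENERGY_KJ = 210.0
DISCRETIONARY_SERVING_KJ = 600.0

CORE_GROUPS = ("vegetables", "fruits", "grains", "meat_alt", "dairy_alt")
OUTCOME_GROUPS = CORE_GROUPS + ("discretionary",)

__all__ = [
    "MIN_EO_ENERGY_KJ",
    "DISCRETIONARY_SERVING_KJ",
    "CORE_GROUPS",
    "OUTCOME_GROUPS",
    "FoodItem",
    "EatingOccasion",
    "group_items_into_eos",
    "compute_servings",
    "log_transform",
    "back_transform",
    "items_from_frame",
    "eos_to_frame",
]


@dataclass(frozen=True)
class FoodItem:
    """One reported food or beverage item."""

    participant_id: str
    day_index: int
    timestamp: float  # minutes since midnight
    energy_kj: float
    group: str | None = None  # one of CORE_GROUPS, or None
    discretionary: bool = False
    servings_per_unit: float = 0.0  # pre-resolved ADG serving equivalence

    def __post_init__(self) -> None:
        if self.energy_kj < 0:
            raise ValueError(f"energy_kj must be >= 0, got {self.energy_kj}")
        if self.group is not None and self.group not in CORE_GROUPS:
            raise ValueError(f"group must be one of {CORE_GROUPS} or None")
        if self.discretionary and self.group is not None:
            raise ValueError("a discretionary item cannot carry a core food group")
        if self.servings_per_unit < 0:
            raise ValueError("servings_per_unit must be >= 0")


@dataclass(frozen=True)
class EatingOccasion:
    """A timestamped eating event: its items, total energy and serving vector."""

    participant_id: str
    day_index: int
    start_time: float
    items: tuple[FoodItem, ...]
    total_energy_kj: float
    servings: dict[str, float] = field(default_factory=dict)
    context: object | None = None

    def __post_init__(self) -> None:
        if self.total_energy_kj < MIN_EO_ENERGY_KJ:
            raise ValueError(
                f"an EO requires >= {MIN_EO_ENERGY_KJ} kJ, got {self.total_energy_kj}"
            )
        total = sum(i.energy_kj for i in self.items)
        if abs(total - self.total_energy_kj) > 1e-6:
            raise ValueError("total_energy_kj must equal the sum of item energies")


def group_items_into_eos(
    items: Iterable[FoodItem],
    simultaneity_window: float = 0.0,
    min_energy_kj: float = MIN_EO_ENERGY_KJ,
) -> list[EatingOccasion]:
    """Merge items into eating occasions and drop sub-threshold clusters.

    Within each (participant, day), items whose start times chain together
    with gaps <= ``simultaneity_window`` minutes form one occasion
    (single-linkage in time).  Clusters totalling less than ``min_energy_kj``
    are discarded entirely.  Every retained item belongs to exactly one EO.
    """
    if simultaneity_window < 0:
        raise ValueError("simultaneity_window must be >= 0")
    by_day: dict[tuple[str, int], list[FoodItem]] = {}
    for it in items:
        by_day.setdefault((it.participant_id, it.day_index), []).append(it)

    eos: list[EatingOccasion] = []
    for (pid, day), group in sorted(by_day.items()):
        group.sort(key=lambda i: i.timestamp)
        cluster: list[FoodItem] = []
        for it in group:
            if cluster and it.timestamp - cluster[-1].timestamp > simultaneity_window:
                eos.extend(_finish_cluster(pid, day, cluster, min_energy_kj))
                cluster = []
            cluster.append(it)
        eos.extend(_finish_cluster(pid, day, cluster, min_energy_kj))
    return eos


def _finish_cluster(pid: str, day: int, cluster: list[FoodItem],
                    min_energy_kj: float) -> list[EatingOccasion]:
    if not cluster:
        return []
    total = sum(i.energy_kj for i in cluster)
    if total < min_energy_kj:
        return []
    eo = EatingOccasion(
        participant_id=pid, day_index=day, start_time=cluster[0].timestamp,
        items=tuple(cluster), total_energy_kj=total,
    )
    return [compute_servings(eo)]


def compute_servings(eo: EatingOccasion) -> EatingOccasion:
    """Attach the six-element serving vector to an occasion.

    Discretionary servings are total discretionary energy / 600 kJ; each core
    group's servings are the sum of its items' pre-resolved equivalences.
    Unclassified items (no group, not discretionary) are an error.
    """
    unclassified = [i for i in eo.items if i.group is None and not i.discretionary]
    if unclassified:
        raise ValueError(
            "unclassified items (neither discretionary nor a core group): "
            + ", ".join(f"{i.participant_id}@{i.timestamp:g}min {i.energy_kj:g}kJ"
                        for i in unclassified)
        )
    servings = {g: 0.0 for g in OUTCOME_GROUPS}
    for it in eo.items:
        if it.discretionary:
            servings["discretionary"] += it.energy_kj / DISCRETIONARY_SERVING_KJ
        else:
            servings[it.group] += it.servings_per_unit
    return EatingOccasion(
        participant_id=eo.participant_id, day_index=eo.day_index,
        start_time=eo.start_time, items=eo.items,
        total_energy_kj=eo.total_energy_kj, servings=servings, context=eo.context,
    )


def log_transform(servings):
    """Modelled outcome scale: ``ln(servings + 1)`` (0 maps to 0)."""
    arr = np.asarray(servings, dtype=float)
    if np.any(arr < 0):
        raise ValueError("servings must be non-negative")
    out = np.log1p(arr)
    return float(out) if np.isscalar(servings) else out


def back_transform(values):
    """Inverse transform ``exp(y) - 1``, clipped below at 0 servings."""
    out = np.clip(np.expm1(np.asarray(values, dtype=float)), 0.0, None)
    return float(out) if np.isscalar(values) else out


def items_from_frame(frame: pd.DataFrame) -> list[FoodItem]:
    """Read items from a table with the FoodItem column schema."""
    items = []
    for rec in frame.to_dict("records"):
        group = rec.get("group")
        if isinstance(group, float) and np.isnan(group):
            group = None
        items.append(FoodItem(
            participant_id=str(rec["participant_id"]),
            day_index=int(rec["day_index"]),
            timestamp=float(rec["timestamp"]),
            energy_kj=float(rec["energy_kj"]),
            group=group,
            discretionary=bool(rec.get("discretionary", False)),
            servings_per_unit=float(rec.get("servings_per_unit", 0.0) or 0.0),
        ))
    return items


def eos_to_frame(eos: Sequence[EatingOccasion]) -> pd.DataFrame:
    """One row per EO: keys, energy, servings and log-servings per group."""
    rows = []
    for k, eo in enumerate(eos, start=1):
        rec = {
            "participant_id": eo.participant_id,
            "day_index": eo.day_index,
            "eo_id": f"{eo.participant_id}-d{eo.day_index}-t{eo.start_time:g}",
            "start_time": eo.start_time,
            "total_energy_kj": eo.total_energy_kj,
        }
        for g in OUTCOME_GROUPS:
            s = eo.servings.get(g, 0.0)
            rec[f"servings_{g}"] = s
            rec[f"log_servings_{g}"] = log_transform(s)
        rows.append(rec)
    return pd.DataFrame(rows)
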