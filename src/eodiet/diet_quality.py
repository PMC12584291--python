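"""Daily Dietary Guideline Index (DGI) scoring.

The DGI measures adherence to the 2013 Australian Dietary Guidelines through
12 food-based components, each scored 0-10, totalling 0-120 (higher = better
diet quality).  Scoring here is fully configuration-driven: each component
maps a daily intake quantity to a score, by default proportionally between a
zero-score cut-off and a full-score target, in either direction:

* ``healthy_max`` — more is better up to the target (e.g. vegetable servings);
* ``limit_max`` — full score at or below the target, zero at or beyond the
  cut-off (e.g. discretionary servings).

The default 12-component set is a reconstruction in the spirit of the
DGI-2013 adaptation for 24-hour-recall data; cut-offs are editable without
code change and should be treated as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "DGIComponentConfig",
    "DGIScore",
    "default_dgi_components",
    "load_components",
    "components_to_document",
    "score_component",
    "score_day",
    "daily_totals_from_servings",
    "full_score_day",
]

N_COMPONENTS = 12
MAX_COMPONENT_SCORE = 10.0


@dataclass(frozen=True)
class DGIComponentConfig:
    """One DGI component: a bounded piecewise-linear (or step) scoring rule."""

    component_id: int
    description: str
    quantity: str  # key into the daily-totals mapping
    direction: str  # "healthy_max" | "limit_max"
    zero_cutoff: float  # intake at (or beyond) which the score is 0
    full_target: float  # intake at (or beyond, direction-wise) which score is 10
    mode: str = "proportional"  # "proportional" | "step"

    def __post_init__(self) -> None:
        if not 1 <= self.component_id <= N_COMPONENTS:
            raise ValueError("component_id must be in 1..12")
        if self.direction not in ("healthy_max", "limit_max"):
            raise ValueError("direction must be 'healthy_max' or 'limit_max'")
        if self.mode not in ("proportional", "step"):
            raise ValueError("mode must be 'proportional' or 'step'")
        if self.direction == "healthy_max" and not self.full_target > self.zero_cutoff:
            raise ValueError("healthy_max requires full_target > zero_cutoff")
        if self.direction == "limit_max" and not self.full_target < self.zero_cutoff:
            raise ValueError("limit_max requires full_target < zero_cutoff")


@dataclass(frozen=True)
class DGIScore:
    """Daily DGI result: 12 component scores in [0, 10] and their total."""

    participant_id: str
    day_index: int
    component_scores: tuple[float, ...]
    total: float

    def __post_init__(self) -> None:
        if len(self.component_scores) != N_COMPONENTS:
            raise ValueError("exactly 12 component scores required")
        if any(not 0 <= s <= MAX_COMPONENT_SCORE for s in self.component_scores):
            raise ValueError("component scores must lie in [0, 10]")
        if abs(self.total - sum(self.component_scores)) > 1e-9:
            raise ValueError("total must equal the sum of component scores")


def default_dgi_components() -> list[DGIComponentConfig]:
    """A 12-component reconstruction of the adapted DGI-2013 (see module docs)."""
    C = DGIComponentConfig
    return [
        C(1, "Food variety (distinct core food groups eaten)", "variety_score",
          "healthy_max", 0.0, 10.0),
        C(2, "Vegetables and legumes (servings/day)", "vegetables", "healthy_max", 0.0, 5.0),
        C(3, "Fruit (servings/day)", "fruits", "healthy_max", 0.0, 2.0),
        C(4, "Grain foods (servings/day)", "grains", "healthy_max", 0.0, 6.0),
        C(5, "Wholegrain share of grain intake", "wholegrain_proportion",
          "healthy_max", 0.0, 0.5),
        C(6, "Lean meats and alternatives (servings/day)", "meat_alt",
          "healthy_max", 0.0, 2.5),
        C(7, "Dairy and alternatives (servings/day)", "dairy_alt", "healthy_max", 0.0, 2.5),
        C(8, "Reduced-fat share of dairy intake", "reduced_fat_dairy_proportion",
          "healthy_max", 0.0, 0.5),
        C(9, "Water share of total beverages", "water_proportion", "healthy_max", 0.0, 1.0),
        C(10, "Discretionary foods (servings/day, limit)", "discretionary",
          "limit_max", 6.0, 2.0),
        C(11, "Alcohol (standard drinks/day, limit)", "alcohol_drinks",
          "limit_max", 4.0, 2.0),
        C(12, "Added-sugar beverages (servings/day, limit)", "sugary_drinks",
          "limit_max", 2.0, 0.0),
    ]


def load_components(path) -> list[DGIComponentConfig]:
    """Read a 12-component scoring configuration from a YAML/JSON document.

    The document is a list of mappings with the :class:`DGIComponentConfig`
    field names, so cut-offs can be edited without code change.
    """
    import pathlib

    import yaml

    doc = yaml.safe_load(pathlib.Path(path).read_text())
    return [DGIComponentConfig(**entry) for entry in doc]


def components_to_document(components: Sequence[DGIComponentConfig]) -> list[dict]:
    """Serialisable form of a component set (inverse of :func:`load_components`)."""
    import dataclasses

    return [dataclasses.asdict(c) for c in components]


def score_component(component: DGIComponentConfig, value: float) -> float:
    """Score one component; clamps to [0, 10] for any non-negative intake."""
    lo, hi = component.zero_cutoff, component.full_target
    if component.direction == "healthy_max":
        meets = value >= hi
        frac = (value - lo) / (hi - lo)
    else:
        meets = value <= hi
        frac = (lo - value) / (lo - hi)
    if component.mode == "step":
        return MAX_COMPONENT_SCORE if meets else 0.0
    return float(min(max(frac, 0.0), 1.0) * MAX_COMPONENT_SCORE)


def score_day(
    daily_totals: Mapping[str, float],
    config: Sequence[DGIComponentConfig] | None = None,
    participant_id: str = "",
    day_index: int = 0,
) -> DGIScore:
    """Score one participant-day against the 12 DGI components."""
    components = list(config) if config is not None else default_dgi_components()
    if len(components) != N_COMPONENTS:
        raise ValueError(f"DGI requires exactly {N_COMPONENTS} components, got {len(components)}")
    scores = []
    for comp in components:
        if comp.quantity not in daily_totals:
            raise KeyError(
                f"component {comp.component_id} ({comp.description!r}) requires "
                f"missing quantity {comp.quantity!r}"
            )
        scores.append(score_component(comp, float(daily_totals[comp.quantity])))
    return DGIScore(participant_id=participant_id, day_index=day_index,
                    component_scores=tuple(scores), total=float(sum(scores)))


# Auxiliary quantities that item-level serving data alone cannot determine
# (beverage composition, wholegrain share, ...).  Defaults are neutral
# mid-adherence values; real analyses should supply observed values.
_DEFAULT_AUX = {
    "wholegrain_proportion": 0.25,
    "reduced_fat_dairy_proportion": 0.25,
    "water_proportion": 0.7,
    "alcohol_drinks": 0.5,
    "sugary_drinks": 0.5,
}


def daily_totals_from_servings(day_rows, aux: Mapping[str, float] | None = None) -> dict:
    """Build the daily-totals mapping from a participant-day's EO serving rows.

    ``day_rows`` is a DataFrame (or mapping of columns) holding the day's EOs
    with ``servings_<group>`` columns; group servings are summed over EOs and a
    simple variety score counts core groups eaten (2 points each).
    """
    totals = {}
    for g in ("vegetables", "fruits", "grains", "meat_alt", "dairy_alt", "discretionary"):
        totals[g] = float(day_rows[f"servings_{g}"].sum())
    core = ("vegetables", "fruits", "grains", "meat_alt", "dairy_alt")
    totals["variety_score"] = 2.0 * sum(totals[g] > 0 for g in core)
    totals.update(_DEFAULT_AUX)
    if aux:
        totals.update(aux)
    return totals


def full_score_day() -> dict[str, float]:
    """A synthetic daily-totals mapping meeting every default component's target."""
    totals = {}
    for comp in default_dgi_components():
        totals[comp.quantity] = comp.full_target
    return totals
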