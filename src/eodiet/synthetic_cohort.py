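"""Synthetic EMA cohort generator.

Generates young-adult cohorts (person-level contextual factors) and per-day
eating-occasion (EO) records with the statistical structure the downstream
models assume: per-EO food-group servings that are zero-inflated and
right-skewed, with occurrence and amount each driven by known, configurable
covariate effects.  The known data-generating parameters (:class:`TruthParams`)
serve as ground truth for model-recovery tests.

The hurdle-style generative process, per EO and food group ``g``::

    occurrence ~ Bernoulli( logistic(b0_g + sum_j beta_gj * x_j) )
    z | occurrence ~ Normal(m0_g + sum_j gamma_gj * x_j, sd_g) truncated to z > 0
    servings = min(exp(z) - 1, cap)        # so ln(servings + 1) = z

Numeric covariates enter the linear predictors rescaled to [-1, 1] over their
declared instrument range; categorical covariates enter as 0/1 indicators named
``"column=level"``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

__all__ = [
    "PersonContext",
    "EOContext",
    "GroupTruth",
    "TruthParams",
    "CohortConfig",
    "ConfigError",
    "FOOD_GROUPS",
    "SCORE_RANGES",
    "CATEGORY_LEVELS",
    "generate_cohort",
    "cohort_to_frame",
    "generate_occasions",
    "inject_missingness",
    "default_truth",
    "write_run_outputs",
]

FOOD_GROUPS = ("vegetables", "fruits", "grains", "meat_alt", "dairy_alt", "discretionary")

#: closed instrument ranges for every numeric person-level score
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "age": (18, 30),
    "meal_prep_score": (12, 84),
    "food_shopping_score": (0, 21),
    "self_efficacy": (17, 85),
    "cooking_confidence": (0, 21),
    "time_scarcity": (4, 16),
    "food_choice_barriers": (0, 11),
    "family_support": (3, 15),
    "friend_support": (3, 15),
    "food_nearness": (16, 63),
    "food_availability": (0, 12),
}

CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "country_of_birth": ("Australia", "other"),
    "income_band": ("<120", "120-499", "500-999", ">=1000"),
    "education": ("low", "mid", "high"),
    "smoking": ("never", "past", "current"),
    "living_situation": ("family", "alone", "partner", "share"),
    "seifa": ("low", "medium", "high"),
}

EO_CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "presence": ("alone", "friends", "other_people"),
    "activity": ("nothing", "visiting", "screen", "other"),
    "location": ("home", "outside_home", "transit", "other"),
    "purchase_place": ("supermarket", "convenience", "restaurant", "other"),
    "eo_type": ("breakfast", "lunch", "dinner", "snack"),
}


class ConfigError(ValueError):
    """Raised when a generator configuration value is invalid."""


@dataclass(frozen=True)
class PersonContext:
    """One participant's intrapersonal / socio- and physical-environmental factors."""

    participant_id: str
    age: float
    sex: str
    country_of_birth: str
    income_band: str
    education: str
    smoking: str
    pa_guideline_met: int
    meal_prep_score: int
    food_shopping_score: int
    self_efficacy: int
    cooking_confidence: int
    time_scarcity: int
    food_choice_barriers: int
    family_support: int
    friend_support: int
    living_situation: str
    food_nearness: int
    food_availability: int
    seifa: str

    def __post_init__(self) -> None:
        for name, (lo, hi) in SCORE_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v!r} outside declared range [{lo}, {hi}]")
        for name, levels in CATEGORY_LEVELS.items():
            v = getattr(self, name)
            if v not in levels:
                raise ValueError(f"{name}={v!r} not one of {levels}")
        if self.pa_guideline_met not in (0, 1):
            raise ValueError("pa_guideline_met must be 0 or 1")


@dataclass(frozen=True)
class EOContext:
    """Momentary (EO-level) context of a single eating event."""

    presence: str
    activity: str
    location: str
    purchase_place: str
    homemade: int
    eo_type: str
    start_time: float  # hours since midnight, in [0, 24)

    def __post_init__(self) -> None:
        for name, levels in EO_CATEGORY_LEVELS.items():
            v = getattr(self, name)
            if v not in levels:
                raise ValueError(f"{name}={v!r} not one of {levels}")
        if self.homemade not in (0, 1):
            raise ValueError("homemade must be 0 or 1")
        if not 0 <= self.start_time < 24:
            raise ValueError("start_time must lie in [0, 24)")


@dataclass(frozen=True)
class GroupTruth:
    """Ground-truth hurdle parameters for a single food group."""

    occurrence_intercept: float
    occurrence_effects: Mapping[str, float] = field(default_factory=dict)
    amount_intercept: float = 0.6
    amount_effects: Mapping[str, float] = field(default_factory=dict)
    amount_sd: float = 0.45

    def __post_init__(self) -> None:
        if self.amount_sd <= 0:
            raise ValueError("amount_sd must be > 0")


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameterisation of the EO data-generating process."""

    groups: Mapping[str, GroupTruth]
    eos_per_day_rate: float = 17.03 / 4  # mean EOs per recording day
    days_per_participant: int = 4
    serving_cap: float = 6.0

    def __post_init__(self) -> None:
        if self.eos_per_day_rate <= 0:
            raise ValueError("eos_per_day_rate must be > 0")
        if self.days_per_participant not in (3, 4):
            raise ValueError("days_per_participant must be 3 or 4")
        known = set(SCORE_RANGES) | {"pa_guideline_met", "homemade", "start_time"}
        for g, gt in self.groups.items():
            for feat in list(gt.occurrence_effects) + list(gt.amount_effects):
                base = feat.split("=", 1)[0]
                if base not in known and base not in CATEGORY_LEVELS and base not in EO_CATEGORY_LEVELS:
                    raise ValueError(f"unknown effect feature {feat!r} for group {g!r}")


# Marginal distributions for the default cohort: categorical proportions and
# (mean, sd) for truncated-normal scores.  Instruments whose published summary
# mean falls outside the declared instrument range (food shopping, food
# availability) get in-range defaults; see docs/methods.md.
_DEFAULT_PROPS: dict[str, tuple[float, ...]] = {
    "sex": (0.7333, 0.2667),
    "country_of_birth": (0.7511, 0.2489),
    "income_band": (0.2124, 0.3629, 0.2029, 0.2219),
    "education": (0.2844, 0.1274, 0.5881),
    "smoking": (0.8044, 0.1052, 0.0904),
    "living_situation": (0.3644, 0.1126, 0.2578, 0.2652),
    "seifa": (0.1387, 0.2526, 0.6034),
}
_DEFAULT_SCORES: dict[str, tuple[float, float]] = {
    "age": (24.24, 3.3),
    "meal_prep_score": (63.22, 9.7),
    "food_shopping_score": (15.0, 4.0),
    "self_efficacy": (54.41, 13.5),
    "cooking_confidence": (15.34, 4.0),
    "time_scarcity": (7.11, 2.6),
    "food_choice_barriers": (2.07, 1.5),
    "family_support": (9.49, 2.7),
    "friend_support": (6.91, 2.7),
    "food_nearness": (44.36, 10.3),
    "food_availability": (9.5, 2.2),
}
_DEFAULT_PA_MET = 0.6326


@dataclass(frozen=True)
class CohortConfig:
    """Marginal distributions of the person-level factors.

    ``proportions`` maps each categorical factor to per-level probabilities (in
    the order of :data:`CATEGORY_LEVELS`); ``score_moments`` maps each numeric
    score to (mean, sd) of a range-truncated normal.
    """

    proportions: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(_DEFAULT_PROPS)
    )
    score_moments: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SCORES)
    )
    pa_met_prop: float = _DEFAULT_PA_MET

    def validated(self) -> "CohortConfig":
        for name, p in self.proportions.items():
            if name not in CATEGORY_LEVELS:
                raise ConfigError(f"unknown categorical factor {name!r}")
            if len(p) != len(CATEGORY_LEVELS[name]):
                raise ConfigError(
                    f"{name!r}: {len(p)} proportions for {len(CATEGORY_LEVELS[name])} levels"
                )
            if any(x < 0 for x in p) or sum(p) <= 0:
                raise ConfigError(f"{name!r}: proportions must be non-negative, not all zero")
        for name, (mean, sd) in self.score_moments.items():
            if name not in SCORE_RANGES:
                raise ConfigError(f"unknown numeric score {name!r}")
            lo, hi = SCORE_RANGES[name]
            if not lo <= mean <= hi:
                raise ConfigError(f"{name!r}: mean {mean} outside declared range [{lo}, {hi}]")
            if sd <= 0:
                raise ConfigError(f"{name!r}: sd must be > 0")
        if not 0 <= self.pa_met_prop <= 1:
            raise ConfigError("pa_met_prop: must be a probability")
        return self


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    n_participants: int,
    seed: int,
    config: CohortConfig | None = None,
) -> list[PersonContext]:
    """Draw ``n_participants`` independent :class:`PersonContext` records.

    Deterministic given ``seed``; marginals follow ``config`` (defaults emulate
    a young-adult cohort aged 18-30, ~73% female).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    cfg = (config or CohortConfig()).validated()
    rng = np.random.default_rng(seed)

    cats: dict[str, np.ndarray] = {}
    for name, levels in CATEGORY_LEVELS.items():
        p = np.asarray(cfg.proportions[name], dtype=float)
        cats[name] = rng.choice(len(levels), size=n_participants, p=p / p.sum())
    pa = (rng.random(n_participants) < cfg.pa_met_prop).astype(int)

    scores: dict[str, np.ndarray] = {}
    for name, (mean, sd) in cfg.score_moments.items():
        lo, hi = SCORE_RANGES[name]
        draw = _trunc_normal(rng, mean, sd, lo, hi, n_participants)
        if name != "age":  # instrument scores are integer-valued
            draw = np.clip(np.rint(draw), lo, hi)
        scores[name] = draw

    width = max(4, len(str(n_participants)))
    cohort = []
    for i in range(n_participants):
        cohort.append(PersonContext(
            participant_id=f"P{i + 1:0{width}d}",
            age=float(scores["age"][i]),
            sex=CATEGORY_LEVELS["sex"][cats["sex"][i]],
            country_of_birth=CATEGORY_LEVELS["country_of_birth"][cats["country_of_birth"][i]],
            income_band=CATEGORY_LEVELS["income_band"][cats["income_band"][i]],
            education=CATEGORY_LEVELS["education"][cats["education"][i]],
            smoking=CATEGORY_LEVELS["smoking"][cats["smoking"][i]],
            pa_guideline_met=int(pa[i]),
            meal_prep_score=int(scores["meal_prep_score"][i]),
            food_shopping_score=int(scores["food_shopping_score"][i]),
            self_efficacy=int(scores["self_efficacy"][i]),
            cooking_confidence=int(scores["cooking_confidence"][i]),
            time_scarcity=int(scores["time_scarcity"][i]),
            food_choice_barriers=int(scores["food_choice_barriers"][i]),
            family_support=int(scores["family_support"][i]),
            friend_support=int(scores["friend_support"][i]),
            living_situation=CATEGORY_LEVELS["living_situation"][cats["living_situation"][i]],
            food_nearness=int(scores["food_nearness"][i]),
            food_availability=int(scores["food_availability"][i]),
            seifa=CATEGORY_LEVELS["seifa"][cats["seifa"][i]],
        ))
    return cohort


def cohort_to_frame(cohort: Sequence[PersonContext]) -> pd.DataFrame:
    """Tabulate a cohort, one row per participant."""
    return pd.DataFrame([dataclasses.asdict(p) for p in cohort])


def covariate_value(feature: str, row: Mapping[str, object]) -> float:
    """Value of a (possibly indicator-named) covariate on the effect scale.

    Numeric scores are rescaled to [-1, 1] over their declared range;
    ``"column=level"`` names are 0/1 indicators; binary fields pass through.
    """
    if "=" in feature:
        col, level = feature.split("=", 1)
        return 1.0 if str(row[col]) == level else 0.0
    if feature in SCORE_RANGES:
        lo, hi = SCORE_RANGES[feature]
        return (2.0 * (float(row[feature]) - lo) / (hi - lo)) - 1.0
    if feature == "start_time":
        return (float(row[feature]) - 12.0) / 12.0
    return float(row[feature])  # binary 0/1 fields


def _linear_predictor(effects: Mapping[str, float], intercept: float,
                      row: Mapping[str, object]) -> float:
    return intercept + sum(b * covariate_value(f, row) for f, b in effects.items())


def default_truth() -> TruthParams:
    """Default ground truth: realistic zero fractions and a few known drivers."""
    g = {
        "vegetables": GroupTruth(-0.6, {"cooking_confidence": 1.0, "eo_type=dinner": 1.5},
                                 0.55, {"meal_prep_score": 0.4}, 0.45),
        "fruits": GroupTruth(-1.5, {"self_efficacy": 0.8, "food_availability": 0.6},
                             0.45, {"food_availability": 0.3}, 0.40),
        "grains": GroupTruth(0.4, {"activity=screen": 0.5, "homemade": 0.5},
                             0.65, {"food_choice_barriers": -0.3}, 0.45),
        "meat_alt": GroupTruth(-0.3, {"eo_type=dinner": 1.2, "cooking_confidence": 0.5},
                               0.55, {"purchase_place=restaurant": 0.4}, 0.45),
        "dairy_alt": GroupTruth(-0.3, {"eo_type=breakfast": 1.0},
                                0.40, {"education=high": 0.2}, 0.40),
        "discretionary": GroupTruth(0.2, {"location=outside_home": 0.8, "time_scarcity": 0.6},
                                    0.70, {"location=outside_home": 0.4,
                                           "time_scarcity": 0.3}, 0.50),
    }
    return TruthParams(groups=g)


# EO-context sampling probabilities (by EO type where the context plausibly
# depends on it only through start time, kept marginal otherwise)
_EO_PROBS = {
    "presence": (0.55, 0.20, 0.25),
    "activity": (0.30, 0.15, 0.40, 0.15),
    "location": (0.60, 0.25, 0.08, 0.07),
    "purchase_place": (0.55, 0.12, 0.25, 0.08),
    "eo_type": (0.22, 0.25, 0.25, 0.28),
}
_EO_TYPE_HOURS = {"breakfast": (7.5, 1.0), "lunch": (12.5, 1.0),
                  "dinner": (18.5, 1.2), "snack": (15.0, 3.0)}
_HOMEMADE_PROP = 0.55


def _zero_truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson counts whose (truncated) mean equals ``mean``."""
    if mean <= 1:
        return np.ones(size, dtype=int)
    lam = brentq(lambda l: l / (1.0 - np.exp(-l)) - mean, 1e-9, 10 * mean)
    out = rng.poisson(lam, size=size)
    while (mask := out == 0).any():  # rejection of zeros; P(0) is small
        out[mask] = rng.poisson(lam, size=int(mask.sum()))
    return out


def _positive_normal(rng: np.random.Generator, mu: float, sd: float) -> float:
    """Normal(mu, sd) truncated to (0, inf); rejection with inverse-CDF fallback."""
    for _ in range(64):
        z = rng.normal(mu, sd)
        if z > 0:
            return z
    a = (0.0 - mu) / sd
    return float(truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng))


def _draw_eo_context(rng: np.random.Generator) -> EOContext:
    draws = {
        name: EO_CATEGORY_LEVELS[name][rng.choice(len(p), p=np.asarray(p) / np.sum(p))]
        for name, p in _EO_PROBS.items()
    }
    mu, sd = _EO_TYPE_HOURS[draws["eo_type"]]
    start = float(np.clip(rng.normal(mu, sd), 0.0, 23.99))
    return EOContext(
        presence=draws["presence"], activity=draws["activity"],
        location=draws["location"], purchase_place=draws["purchase_place"],
        homemade=int(rng.random() < _HOMEMADE_PROP),
        eo_type=draws["eo_type"], start_time=start,
    )


def generate_occasions(
    cohort: Sequence[PersonContext],
    truth: TruthParams,
    seed: int,
) -> pd.DataFrame:
    """Simulate eating occasions for a cohort under known hurdle ground truth.

    Returns one row per EO with participant keys, EO-level context and a
    ``servings_<group>`` column per food group.  Per participant-day the EO
    count is zero-truncated Poisson with mean ``truth.eos_per_day_rate``; per
    EO and group, occurrence is Bernoulli-logistic in the covariates and the
    positive amount is a shifted log-normal capped at ``truth.serving_cap``.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(seed)
    rows = []
    for person in cohort:
        prow = dataclasses.asdict(person)
        n_days = truth.days_per_participant
        counts = _zero_truncated_poisson(rng, truth.eos_per_day_rate, n_days)
        for day in range(1, n_days + 1):
            for j in range(int(counts[day - 1])):
                ctx = _draw_eo_context(rng)
                row = dict(prow)
                row.update(dataclasses.asdict(ctx))
                rec = {
                    "participant_id": person.participant_id,
                    "day_index": day,
                    "eo_id": f"{person.participant_id}-d{day}-e{j + 1}",
                    **dataclasses.asdict(ctx),
                }
                for gname, gt in truth.groups.items():
                    eta = _linear_predictor(gt.occurrence_effects, gt.occurrence_intercept, row)
                    p_occ = 1.0 / (1.0 + np.exp(-eta))
                    if rng.random() < p_occ:
                        mu = _linear_predictor(gt.amount_effects, gt.amount_intercept, row)
                        z = _positive_normal(rng, mu, gt.amount_sd)
                        servings = min(float(np.expm1(z)), truth.serving_cap)
                    else:
                        servings = 0.0
                    rec[f"servings_{gname}"] = servings
                rows.append(rec)
    return pd.DataFrame(rows)


def true_occurrence_probability(person: PersonContext, ctx: EOContext,
                                gt: GroupTruth) -> float:
    """Closed-form P(occurrence) for one EO under the ground truth (oracle)."""
    row = {**dataclasses.asdict(person), **dataclasses.asdict(ctx)}
    eta = _linear_predictor(gt.occurrence_effects, gt.occurrence_intercept, row)
    return float(1.0 / (1.0 + np.exp(-eta)))


def inject_missingness(
    feature_table: pd.DataFrame,
    rate: float,
    seed: int,
    columns: Sequence[str] | None = None,
    protected: Sequence[str] = (),
) -> pd.DataFrame:
    """Blank cells completely at random at the given per-column rate.

    Outcome (``servings_*``) columns, key columns and anything in ``protected``
    are never made missing.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    never = {"participant_id", "day_index", "eo_id", *protected}
    never |= {c for c in feature_table.columns if c.startswith("servings_")}
    cols = [c for c in (columns if columns is not None else feature_table.columns)
            if c not in never]
    out = feature_table.copy()
    if rate == 0 or not cols:
        return out
    rng = np.random.default_rng(seed)
    for c in cols:
        mask = rng.random(len(out)) < rate
        if mask.any():
            col = out[c]
            if col.dtype.kind in "iub":  # int/bool cannot hold NaN
                out[c] = col.astype(float)
            out.loc[mask, c] = np.nan
    return out


def write_run_outputs(out_dir: str | Path, cohort: Sequence[PersonContext],
                      occasions: pd.DataFrame, truth: TruthParams,
                      seed: int) -> dict[str, str]:
    """Write cohort/EO CSVs, the ground truth JSON and a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cframe = cohort_to_frame(cohort)
    cframe.to_csv(out / "cohort.csv", index=False)
    merged = occasions.merge(cframe, on="participant_id", how="left")
    merged.to_csv(out / "occasions.csv", index=False)
    truth_dict = dataclasses.asdict(truth)
    truth_dict["groups"] = {g: dataclasses.asdict(t) for g, t in truth.groups.items()}
    (out / "truth.json").write_text(json.dumps(truth_dict, indent=2, default=dict))
    manifest = {"seed": seed, "n_participants": len(cohort), "n_occasions": len(occasions)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"cohort": str(out / "cohort.csv"), "occasions": str(out / "occasions.csv"),
            "truth": str(out / "truth.json"), "manifest": str(out / "manifest.json")}
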