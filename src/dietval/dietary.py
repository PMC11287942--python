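"""Aggregation of 24 h dietary-recall records into daily and per-participant intakes.

A recall day is a list of consumed items (food code, grams).  Linking the
items with a per-100 g food-composition table gives the day's energy and
nutrient totals; a food-group map gives grams per food group.  Days are
screened against energy-plausibility thresholds, and per-participant means
over the available recall days (2-3 in a study-conformant dataset) form
the unit of all downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    EPCT_NUTRIENTS,
    FOOD_GROUPS,
    METHODS,
    NUTRIENT_COLUMNS,
    EnergyFactors,
    PlausibilityConfig,
)

logger = logging.getLogger(__name__)

#: grams/day columns of a daily-intake record, in composition-table order
GRAM_FIELDS = NUTRIENT_COLUMNS
EPCT_FIELDS = tuple(f"{n}_epct" for n in EPCT_NUTRIENTS)
DENSITY_FIELDS = ("fibre_g_per_mj", "wholegrain_g_per_10mj")
GROUP_FIELDS = tuple(f"fg_{g}" for g in FOOD_GROUPS)

#: every numeric field of a DailyIntake, in output order
DAILY_FIELDS = ("energy_kj",) + GRAM_FIELDS + EPCT_FIELDS + DENSITY_FIELDS + GROUP_FIELDS


class UnknownFoodCodeError(KeyError):
    """A consumed item references a food code absent from the composition table."""


@dataclass(frozen=True)
class ConsumedItem:
    food_code: str
    amount_g: float

    def __post_init__(self):
        if not self.amount_g >= 0:
            raise ValueError(f"amount_g must be >= 0, got {self.amount_g}")


@dataclass(frozen=True)
class RecallDay:
    participant_id: str
    method: str
    day_index: int
    is_weekend: bool
    items: tuple[ConsumedItem, ...]

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.day_index not in (1, 2, 3):
            raise ValueError(f"day_index must be in {{1,2,3}}, got {self.day_index}")


@dataclass(frozen=True)
class DailyIntake:
    """One participant-day of aggregated intake.

    ``values`` is a Series over :data:`DAILY_FIELDS`: energy (kJ/day),
    nutrient grams/day, E% shares, fibre g/MJ, wholegrain g/10 MJ and
    grams/day per food group (groups absent from the day are 0).
    """

    participant_id: str
    method: str
    day_index: int
    values: pd.Series
    plausibility_flag: str  # 'ok' | 'low' | 'high'


@dataclass(frozen=True)
class ParticipantIntake:
    """Field-wise mean of a participant's daily intakes for one method."""

    participant_id: str
    method: str
    n_days: int
    values: pd.Series  # DAILY_FIELDS plus red_processed_meat_weekly_g


def check_composition_table(fct: pd.DataFrame, factors: EnergyFactors | None = None,
                            rel_tol: float = 0.25) -> pd.DataFrame:
    """Validate (and gently repair) a per-100 g food-composition table.

    Negative values raise; missing nutrient values become 0 with a logged
    warning; rows whose stated energy disagrees with the macronutrient sum
    by more than ``rel_tol`` (relative) are warned about, never rejected
    (composition databases legitimately include non-macronutrient energy).
    """
    factors = factors or EnergyFactors()
    fct = fct.copy()
    required = ["energy_kj"] + list(NUTRIENT_COLUMNS)
    missing_cols = [c for c in required if c not in fct.columns]
    if missing_cols:
        raise ValueError(f"composition table missing columns: {missing_cols}")
    n_missing = int(fct[required].isna().sum().sum())
    if n_missing:
        logger.warning("composition table: %d missing nutrient values treated as 0", n_missing)
        fct[required] = fct[required].fillna(0.0)
    if (fct[required] < 0).any().any():
        bad = fct.index[(fct[required] < 0).any(axis=1)].tolist()
        raise ValueError(f"negative nutrient values for food codes {bad}")
    macro_kj = (
        fct["protein_g"] * factors.protein
        + fct["fat_g"] * factors.fat
        + fct["carbohydrate_g"] * factors.carbohydrate
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(macro_kj - fct["energy_kj"]) / fct["energy_kj"].replace(0, np.nan)
    inconsistent = fct.index[rel > rel_tol].tolist()
    if inconsistent:
        logger.warning(
            "composition table: energy inconsistent with macronutrients (> %.0f%%) "
            "for %d food codes: %s", 100 * rel_tol, len(inconsistent), inconsistent[:10],
        )
    return fct


def energy_percent(nutrient_g: float, factor_kj_per_g: float, energy_kj: float) -> float:
    """Share of daily energy supplied by a nutrient, in percent.

    Returns NaN (missing) when the day's energy is zero rather than dividing.
    """
    if energy_kj == 0:
        return float("nan")
    return 100.0 * nutrient_g * factor_kj_per_g / energy_kj


def plausibility_flag(energy_kj: float, cfg: PlausibilityConfig | None = None) -> str:
    """Screen a day's energy: 'high' above 3500 kcal, 'low' below 800 kcal.

    Both bounds are strict, so a day at exactly 3500 kcal is 'ok'.
    """
    cfg = cfg or PlausibilityConfig()
    if energy_kj < 0:
        raise ValueError(f"energy must be >= 0, got {energy_kj}")
    if energy_kj > cfg.high_kj:
        return "high"
    if energy_kj < cfg.low_kj:
        return "low"
    return "ok"


def aggregate_day(
    day: RecallDay,
    fct: pd.DataFrame,
    fgm: pd.DataFrame,
    factors: EnergyFactors | None = None,
    plaus: PlausibilityConfig | None = None,
) -> DailyIntake:
    """Aggregate one recall day against a composition table and food-group map.

    ``fct`` is indexed by food_code with per-100 g columns ``energy_kj`` and
    :data:`~dietval.config.NUTRIENT_COLUMNS`; ``fgm`` has columns
    (food_code, group), one row per membership (a food may carry several
    groups).  An unknown food code is a hard error naming the code; an empty
    day is valid and aggregates to all-zero intake flagged 'low'.
    """
    factors = factors or EnergyFactors()
    acc = dict.fromkeys(DAILY_FIELDS, 0.0)

    group_of: dict[str, list[str]] = {}
    for code, grp in zip(fgm["food_code"], fgm["group"]):
        group_of.setdefault(str(code), []).append(grp)
    comp_rows = {str(code): row for code, row in
                 zip(fct.index, fct[["energy_kj", *NUTRIENT_COLUMNS]].to_numpy())}

    for item in day.items:
        code = str(item.food_code)
        if code not in comp_rows:
            raise UnknownFoodCodeError(
                f"food code {code!r} (participant {day.participant_id}, "
                f"day {day.day_index}) not found in composition table"
            )
        row = comp_rows[code]
        scale = item.amount_g / 100.0
        acc["energy_kj"] += scale * row[0]
        for k, col in enumerate(NUTRIENT_COLUMNS, start=1):
            acc[col] += scale * row[k]
        for grp in group_of.get(code, ()):
            acc[f"fg_{grp}"] += item.amount_g
    values = pd.Series(acc, index=list(DAILY_FIELDS))

    energy = values["energy_kj"]
    for nutrient in EPCT_NUTRIENTS:
        values[f"{nutrient}_epct"] = energy_percent(
            values[f"{nutrient}_g"], factors.for_nutrient(nutrient), energy
        )
    if energy > 0:
        values["fibre_g_per_mj"] = values["fibre_g"] / (energy / 1000.0)
        values["wholegrain_g_per_10mj"] = values["wholegrain_g"] / (energy / 10000.0)
    else:
        values["fibre_g_per_mj"] = float("nan")
        values["wholegrain_g_per_10mj"] = float("nan")

    flag = plausibility_flag(energy, plaus)
    if flag != "ok":
        logger.info(
            "flagged day: participant=%s method=%s day=%d energy=%.0f kJ flag=%s",
            day.participant_id, day.method, day.day_index, energy, flag,
        )
    return DailyIntake(day.participant_id, day.method, day.day_index, values, flag)


def participant_mean(days: list[DailyIntake], exclude_flagged: bool = False) -> ParticipantIntake:
    """Arithmetic mean of daily intakes; flagged days are retained by default.

    Red + processed meat is additionally expressed per week as
    7 x (mean daily red meat + mean daily processed meat).
    """
    if exclude_flagged:
        days = [d for d in days if d.plausibility_flag == "ok"]
    if not days:
        raise ValueError("participant_mean requires at least one (retained) day")
    ids = {d.participant_id for d in days}
    methods = {d.method for d in days}
    if len(ids) > 1 or len(methods) > 1:
        raise ValueError(f"days mix participants {ids} or methods {methods}")
    mat = pd.concat([d.values for d in days], axis=1)
    mean = mat.mean(axis=1)
    mean["red_processed_meat_weekly_g"] = 7.0 * (mean["fg_red_meat"] + mean["fg_processed_meat"])
    return ParticipantIntake(days[0].participant_id, days[0].method, len(days), mean)


def recall_days_from_frame(recalls: pd.DataFrame) -> list[RecallDay]:
    """Group a tidy item-level recall table into RecallDay records.

    Expected columns: participant_id, method, day_index, is_weekend,
    food_code, amount_g (one row per consumed item).
    """
    days: list[RecallDay] = []
    keys = ["participant_id", "method", "day_index"]
    for (pid, method, day_idx), sub in recalls.groupby(keys, sort=True):
        items = tuple(
            ConsumedItem(str(c), float(a)) for c, a in zip(sub["food_code"], sub["amount_g"])
        )
        weekend = bool(sub["is_weekend"].iloc[0])
        days.append(RecallDay(str(pid), str(method), int(day_idx), weekend, items))
    return days


def aggregate_cohort(
    recalls: pd.DataFrame,
    fct: pd.DataFrame,
    fgm: pd.DataFrame,
    factors: EnergyFactors | None = None,
    plaus: PlausibilityConfig | None = None,
    exclude_flagged: bool = False,
) -> pd.DataFrame:
    """Aggregate an item-level recall table to per-participant means.

    Returns a tidy frame with one row per (participant, method) holding
    every daily field, the weekly meat total, n_days and the count of
    flagged days.
    """
    fct = check_composition_table(fct, factors)
    rows = []
    daily = [aggregate_day(d, fct, fgm, factors, plaus) for d in recall_days_from_frame(recalls)]
    frame = pd.DataFrame({"pid": [d.participant_id for d in daily],
                          "method": [d.method for d in daily]})
    for (pid, method), idx in frame.groupby(["pid", "method"]).groups.items():
        sub = [daily[i] for i in idx]
        pm = participant_mean(sub, exclude_flagged=exclude_flagged)
        row = pm.values.copy()
        row["participant_id"] = pid
        row["method"] = method
        row["n_days"] = pm.n_days
        row["n_flagged"] = sum(d.plausibility_flag != "ok" for d in sub)
        rows.append(row)
    out = pd.DataFrame(rows)
    lead = ["participant_id", "method", "n_days", "n_flagged"]
    return out[lead + [c for c in out.columns if c not in lead]]


def cohort_summary(intakes: pd.DataFrame, by: str = "method") -> pd.DataFrame:
    """Sample mean and SD (n-1 denominator) of every numeric variable per method."""
    if intakes["participant_id"].nunique() < 2:
        raise ValueError("cohort_summary requires at least 2 participants")
    numeric = intakes.select_dtypes("number").drop(columns=["n_days", "n_flagged"],
                                                   errors="ignore")
    grouped = numeric.groupby(intakes[by])
    mean = grouped.mean().T.add_suffix("_mean")
    sd = grouped.std(ddof=1).T.add_suffix("_sd")
    out = pd.concat([mean, sd], axis=1).sort_index(axis=1)
    out.index.name = "variable"
    return out
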