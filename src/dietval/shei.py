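"""Swedish Healthy Eating Index (SHEI) scoring.

Nine diet components — fruit & vegetables (g/day), wholegrain (g/10 MJ),
fibre (g/MJ), PUFA (E%), MUFA (E%), SFA (E%), fish & shellfish (g/day),
red + processed meat (g/week) and added sugar (E%) — are each scored 0-1
against food-based dietary-guideline reference values and summed to a
total of 0-9.  Higher totals mean better adherence.

All scoring is piecewise linear: components scored ``higher_better`` ramp
from 0 at/below the lower reference to 1 at/above the upper reference;
``lower_better`` is the mirror image; ``range_better`` components (the
unsaturated-fat shares, which have both a floor and a ceiling in the
guidelines) score 1 inside the reference band and ramp to 0 at configurable
outer bounds.  The reference values ship as a default configuration and are
deliberately *all* configuration, not code: published index revisions can
be dropped in as a YAML file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

COMPONENTS = (
    "fruit_veg",
    "wholegrain",
    "fibre",
    "pufa",
    "mufa",
    "sfa",
    "fish_shellfish",
    "red_processed_meat",
    "added_sugar",
)

#: ParticipantIntake field backing each component, at the unit the index uses
COMPONENT_FIELDS = {
    "fruit_veg": "fg_fruit_veg",                   # g/day
    "wholegrain": "wholegrain_g_per_10mj",         # g/10 MJ
    "fibre": "fibre_g_per_mj",                     # g/MJ
    "pufa": "pufa_epct",                           # E%
    "mufa": "mufa_epct",                           # E%
    "sfa": "sfa_epct",                             # E%
    "fish_shellfish": "fg_fish_shellfish",         # g/day
    "red_processed_meat": "red_processed_meat_weekly_g",  # g/week
    "added_sugar": "sucrose_epct",                 # E% (configurable column)
}


@dataclass(frozen=True)
class SHEIComponentConfig:
    name: str
    unit: str           # 'g/day' | 'g/10 MJ' | 'g/MJ' | 'E%' | 'g/week'
    direction: str      # 'higher_better' | 'lower_better' | 'range_better'
    lower_ref: float
    upper_ref: float
    outer_lower: float | None = None  # range_better only: score 0 at/below
    outer_upper: float | None = None  # range_better only: score 0 at/above
    field: str | None = None          # override of the backing intake field

    def __post_init__(self):
        if not self.lower_ref < self.upper_ref:
            raise ValueError(f"{self.name}: lower_ref must be < upper_ref")
        if self.direction == "range_better":
            if self.outer_lower is None or self.outer_upper is None:
                raise ValueError(f"{self.name}: range_better needs outer bounds")
            if not (self.outer_lower < self.lower_ref and self.outer_upper > self.upper_ref):
                raise ValueError(f"{self.name}: outer bounds must bracket the reference band")
        elif self.direction not in ("higher_better", "lower_better"):
            raise ValueError(f"{self.name}: unknown direction {self.direction!r}")


def default_config() -> list[SHEIComponentConfig]:
    """Default reference values for the nine components.

    These are working defaults chosen to match the guideline targets the
    index encodes (e.g. 500 g/day fruit & vegetables, at most 500 g/week
    red and processed meat, at most 10 E% added sugar and saturated fat);
    the published index's exact cut-offs can replace them via YAML without
    code changes.  The meat component scores combined red + processed meat
    per week; added sugar is backed by the sucrose E% column by default.
    """
    return [
        SHEIComponentConfig("fruit_veg", "g/day", "higher_better", 0.0, 500.0),
        SHEIComponentConfig("wholegrain", "g/10 MJ", "higher_better", 0.0, 75.0),
        SHEIComponentConfig("fibre", "g/MJ", "higher_better", 2.0, 3.0),
        SHEIComponentConfig("pufa", "E%", "range_better", 5.0, 10.0,
                            outer_lower=2.5, outer_upper=12.5),
        SHEIComponentConfig("mufa", "E%", "range_better", 10.0, 20.0,
                            outer_lower=5.0, outer_upper=25.0),
        SHEIComponentConfig("sfa", "E%", "lower_better", 10.0, 17.0),
        SHEIComponentConfig("fish_shellfish", "g/day", "higher_better", 0.0, 35.0),
        SHEIComponentConfig("red_processed_meat", "g/week", "lower_better", 500.0, 700.0),
        SHEIComponentConfig("added_sugar", "E%", "lower_better", 10.0, 20.0),
    ]


def load_config(path: str | Path) -> list[SHEIComponentConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [SHEIComponentConfig(**block) for block in raw]


def save_config(cfgs: list[SHEIComponentConfig], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([asdict(c) for c in cfgs], fh, sort_keys=False)


def _ramp(value: float, at_zero: float, at_one: float) -> float:
    """Linear ramp worth 0 at ``at_zero`` and 1 at ``at_one``, clipped to [0,1]."""
    t = (value - at_zero) / (at_one - at_zero)
    return min(1.0, max(0.0, t))


def component_score(value: float, cfg: SHEIComponentConfig) -> float:
    """Score one component value on [0, 1]; NaN input yields NaN (missing)."""
    if math.isnan(value):
        return float("nan")
    if value < 0:
        raise ValueError(f"{cfg.name}: component value must be >= 0, got {value}")
    if cfg.unit == "E%" and value >= 100:
        raise ValueError(f"{cfg.name}: E% value must be < 100, got {value}")
    if cfg.direction == "higher_better":
        return _ramp(value, cfg.lower_ref, cfg.upper_ref)
    if cfg.direction == "lower_better":
        return _ramp(value, cfg.upper_ref, cfg.lower_ref)
    # range_better: full score inside the band, ramps to 0 at the outer bounds
    if value < cfg.lower_ref:
        return _ramp(value, cfg.outer_lower, cfg.lower_ref)
    if value > cfg.upper_ref:
        return _ramp(value, cfg.outer_upper, cfg.upper_ref)
    return 1.0


@dataclass(frozen=True)
class SHEIScore:
    participant_id: str
    method: str
    components: dict[str, float]
    total: float


def shei_total(
    intake: pd.Series,
    cfgs: list[SHEIComponentConfig] | None = None,
    participant_id: str = "",
    method: str = "",
    missing_policy: str = "propagate",
) -> SHEIScore:
    """Total SHEI score (0-9) from a participant-mean intake record.

    ``intake`` is a Series carrying the fields named in
    :data:`COMPONENT_FIELDS` (a ``ParticipantIntake.values``).  A missing
    component makes the total missing under the default policy; with
    ``missing_policy='rescale'`` the total is rescaled to the 0-9 range
    from the components that are present.
    """
    cfgs = cfgs if cfgs is not None else default_config()
    if len(cfgs) != len(COMPONENTS) or {c.name for c in cfgs} != set(COMPONENTS):
        raise ValueError("expected exactly the nine SHEI component configs")
    scores: dict[str, float] = {}
    for cfg in cfgs:
        field = cfg.field or COMPONENT_FIELDS[cfg.name]
        scores[cfg.name] = component_score(float(intake[field]), cfg)
    vals = list(scores.values())
    n_missing = sum(math.isnan(v) for v in vals)
    if n_missing == 0:
        total = float(sum(vals))
    elif missing_policy == "rescale" and n_missing < len(vals):
        present = [v for v in vals if not math.isnan(v)]
        total = float(sum(present) * len(vals) / len(present))
    else:
        total = float("nan")
    return SHEIScore(participant_id, method, scores, total)


def score_cohort(
    intakes: pd.DataFrame,
    cfgs: list[SHEIComponentConfig] | None = None,
    missing_policy: str = "propagate",
) -> pd.DataFrame:
    """Score every (participant, method) row of an aggregated-intake table."""
    rows = []
    for _, row in intakes.iterrows():
        s = shei_total(row, cfgs, str(row["participant_id"]), str(row["method"]),
                       missing_policy)
        rows.append({"participant_id": s.participant_id, "method": s.method,
                     **{f"shei_{k}": v for k, v in s.components.items()},
                     "shei_total": s.total})
    return pd.DataFrame(rows)
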