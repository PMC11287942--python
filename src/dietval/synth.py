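"""Synthetic validation-study cohorts with known ground truth.

Generates the complete input bundle of a dietary validation study — three
24 h recall days per participant for two self-report methods (a web tool
and telephone interviews covering the same days), a food-composition table,
a food-group map, and doubly-labelled-water dose and urine-enrichment
records for a sub-sample — so that every pipeline stage can be exercised
and checked against stored ground truth without access to any real data.

The energy model: each participant has a true total energy expenditure
TEE ~ Normal(mean, SD); habitual energy intake equals
``TEE x (1 + bias_mean) + bias_slope x (TEE - mean_TEE)``, so the expected
cohort mean difference between intake and TEE is exactly
``bias_mean x mean_TEE`` while ``bias_slope`` induces a proportional bias
(differences growing with level) of the kind seen when low consumers
under-report and high consumers over-report.  True daily intake varies
around habitual intake with a day-to-day CV, both methods observe the
*same* true days (recall days are matched), and each method's report
multiplies the true day by ``(1 + e_method)`` with the two methods' errors
jointly normal at a configurable correlation — the "shared errors of
self-report" that inflate between-method agreement.

Food-group grams are drawn per participant from either a zero-truncated
Gaussian (ubiquitous groups) or a zero-inflated lognormal (episodically
consumed groups), then decomposed into synthetic food codes; macronutrient
staple foods are solved per day so that the aggregated recall reproduces
the reported energy and the configured macronutrient E% split exactly.

Isotope data follow two-exponential washout: dilution spaces derive from
body weight and a body-water fraction, the deuterium elimination rate is
drawn directly, and the oxygen-18 rate is solved from the participant's
TEE through the same CO2-production model the analysis chain uses, giving
an exact noise-free round trip.

Randomness comes from a single ``numpy.random.default_rng`` (PCG64) seeded
generator: equal seeds give byte-identical output files on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FOOD_GROUPS, EnergyFactors, DLWConstants
from . import dlw as dlw_mod

# --------------------------------------------------------------------------
# food universe: per-100 g (protein, fat, carbohydrate, sucrose, fibre,
# wholegrain, pufa, mufa, sfa); energy is derived as 17 p + 37 f + 17 c
# --------------------------------------------------------------------------

_Z = dict.fromkeys(
    ("protein_g", "fat_g", "carbohydrate_g", "sucrose_g", "fibre_g",
     "wholegrain_g", "pufa_g", "mufa_g", "sfa_g"), 0.0)


def _food(**kw):
    row = dict(_Z)
    row.update(kw)
    return row


GROUP_FOODS: dict[str, dict[str, dict]] = {
    "fruit_veg": {
        "FV01": _food(protein_g=0.5, fat_g=0.2, carbohydrate_g=12, sucrose_g=2.5, fibre_g=2.0),
        "FV02": _food(protein_g=1.0, fat_g=0.2, carbohydrate_g=8, sucrose_g=2.0, fibre_g=2.5),
        "FV03": _food(protein_g=2.0, fat_g=0.4, carbohydrate_g=3, sucrose_g=0.5, fibre_g=2.0),
    },
    "fish_shellfish": {
        "FS01": _food(protein_g=18, fat_g=1.0, pufa_g=0.3, mufa_g=0.3, sfa_g=0.2),
        "FS02": _food(protein_g=20, fat_g=11, pufa_g=3.0, mufa_g=4.5, sfa_g=2.5),
        "FS03": _food(protein_g=16, fat_g=1.5, pufa_g=0.5, mufa_g=0.3, sfa_g=0.3),
    },
    "nuts_seeds": {
        "NS01": _food(protein_g=20, fat_g=50, carbohydrate_g=12, sucrose_g=2, fibre_g=8,
                      pufa_g=18, mufa_g=24, sfa_g=6),
        "NS02": _food(protein_g=25, fat_g=45, carbohydrate_g=10, sucrose_g=1, fibre_g=9,
                      pufa_g=20, mufa_g=18, sfa_g=5),
    },
    "red_meat": {
        "RM01": _food(protein_g=21, fat_g=8, pufa_g=0.4, mufa_g=3.5, sfa_g=3.5),
        "RM02": _food(protein_g=20, fat_g=12, pufa_g=1.2, mufa_g=5.0, sfa_g=4.5),
    },
    "processed_meat": {
        "PM01": _food(protein_g=13, fat_g=22, carbohydrate_g=3, pufa_g=2.0, mufa_g=10, sfa_g=8.5),
        "PM02": _food(protein_g=18, fat_g=6, pufa_g=0.7, mufa_g=2.8, sfa_g=2.2),
    },
    "sweet_savoury_treats": {
        "ST01": _food(protein_g=6, fat_g=30, carbohydrate_g=55, sucrose_g=40,
                      pufa_g=1.0, mufa_g=9.5, sfa_g=18),
        "ST02": _food(protein_g=7, fat_g=15, carbohydrate_g=55, sucrose_g=14, fibre_g=2,
                      wholegrain_g=5, pufa_g=1.8, mufa_g=5.5, sfa_g=7),
        "ST03": _food(protein_g=6, fat_g=32, carbohydrate_g=50, sucrose_g=1, fibre_g=4,
                      pufa_g=7.5, mufa_g=20, sfa_g=3.5),
    },
    "ssb": {"SB01": _food(carbohydrate_g=10.5, sucrose_g=10.5)},
    "asb": {"AB01": _food()},
    "fruit_juice": {"FJ01": _food(carbohydrate_g=10, sucrose_g=3.5, fibre_g=0.2)},
}

#: staple foods used to top the day up to its reported energy and E% targets
STAPLES = {
    "SP01": _food(protein_g=25, fat_g=3, pufa_g=0.4, mufa_g=1.2, sfa_g=1.2),   # protein
    "SF01": _food(fat_g=80, pufa_g=11, mufa_g=33, sfa_g=36),                   # fat
    "SC01": _food(protein_g=7, fat_g=2, carbohydrate_g=70, fibre_g=7,
                  wholegrain_g=18, pufa_g=0.9, mufa_g=0.7, sfa_g=0.4),         # carbohydrate
    "SS01": _food(carbohydrate_g=100, sucrose_g=100),                          # added sugar
}


def build_composition() -> pd.DataFrame:
    """Food-composition table (per 100 g) of the synthetic food universe."""
    factors = EnergyFactors()
    rows = {}
    for foods in (*GROUP_FOODS.values(), STAPLES):
        for code, comp in foods.items():
            energy = (comp["protein_g"] * factors.protein
                      + comp["fat_g"] * factors.fat
                      + comp["carbohydrate_g"] * factors.carbohydrate)
            rows[code] = {"energy_kj": energy, **comp}
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "food_code"
    return out


def build_foodgroup_map() -> pd.DataFrame:
    rows = [
        {"food_code": code, "group": group}
        for group, foods in GROUP_FOODS.items()
        for code in sorted(foods)
    ]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FoodGroupSpec:
    """Target distribution of one food group's participant-mean intake (g/day)."""

    family: str            # 'truncnorm' | 'lognorm' | 'zi_lognorm'
    mean: float
    sd: float
    p_zero: float = 0.0    # zi_lognorm: probability of a non-consumer

    def __post_init__(self):
        if self.family not in ("truncnorm", "lognorm", "zi_lognorm"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.sd < 0 or self.mean < 0 or not 0 <= self.p_zero < 1:
            raise ValueError("invalid food-group spec")


def default_food_groups() -> dict[str, FoodGroupSpec]:
    """Per-group calibration: means/SDs of the study population.

    Episodically consumed groups (fish, nuts, sugar- and artificially
    sweetened beverages, juice) get a zero-inflated lognormal, consistent
    with SDs exceeding means; fruit & vegetables a zero-truncated Gaussian.
    """
    return {
        "fruit_veg": FoodGroupSpec("truncnorm", 426.0, 149.0),
        "fish_shellfish": FoodGroupSpec("zi_lognorm", 33.8, 47.2, p_zero=0.25),
        "nuts_seeds": FoodGroupSpec("zi_lognorm", 9.0, 11.0, p_zero=0.20),
        "red_meat": FoodGroupSpec("lognorm", 39.0, 44.0),
        "processed_meat": FoodGroupSpec("lognorm", 28.0, 33.0),
        "sweet_savoury_treats": FoodGroupSpec("lognorm", 70.0, 46.0),
        "ssb": FoodGroupSpec("zi_lognorm", 107.0, 177.0, p_zero=0.35),
        "asb": FoodGroupSpec("zi_lognorm", 78.0, 159.0, p_zero=0.45),
        "fruit_juice": FoodGroupSpec("zi_lognorm", 95.0, 108.0, p_zero=0.30),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults are pinned to the cohort this generator emulates: TEE
    10252 (SD 1197) kJ/day, body weight 67.1 (SD 7.6) kg, a -2.3% mean
    intake bias relative to TEE, n = 52 recall participants of whom 24
    have isotope data.
    """

    n_participants: int = 52
    n_dlw: int = 24
    tee_mean_kj: float = 10252.0
    tee_sd_kj: float = 1197.0
    weight_mean_kg: float = 67.1
    weight_sd_kg: float = 7.6
    bias_mean: float = -237.0 / 10252.0   # fractional intake bias vs TEE
    bias_slope: float = 0.10              # extra intake per kJ of TEE deviation
    day_cv: float = 0.23                  # day-to-day CV of true energy intake
    method_error_sd: float = 0.18         # per-day reporting error SD, both methods
    shared_error_corr: float = 0.3        # web/telephone error correlation
    group_day_cv: float = 0.5             # day-to-day CV of food-group grams
    epct_targets: dict = field(default_factory=lambda: {
        "protein": 15.0, "fat": 41.0, "carbohydrate": 44.0, "sucrose": 9.0})
    food_groups: dict = field(default_factory=default_food_groups)
    n_days: int = 3
    # isotope sub-model
    body_water_fraction: float = 0.55     # total body water as fraction of weight
    dsr_mean: float = 1.035               # 2H/18O dilution-space ratio
    dsr_sd: float = 0.010
    kd_mean: float = 0.09                 # deuterium elimination rate, per day
    kd_sd: float = 0.008
    dose_enr_2h: float = 998000.0         # dose-water excess enrichment, ppm
    dose_enr_18o: float = 250000.0
    baseline_2h: float = 150.0            # background abundance, ppm
    baseline_18o: float = 2000.0
    enrichment_noise_cv: float = 0.01     # multiplicative measurement noise
    urine_days: tuple = (1.0, 5.0, 8.0, 12.0, 15.0)
    baseline_days: tuple = (-2.0, -1.0)

    def __post_init__(self):
        if self.n_participants < 1 or not 0 <= self.n_dlw <= self.n_participants:
            raise ValueError("need 1 <= n_dlw <= n_participants")
        for name in ("tee_sd_kj", "weight_sd_kg", "day_cv", "method_error_sd",
                     "group_day_cv", "dsr_sd", "kd_sd", "enrichment_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1 <= self.shared_error_corr <= 1:
            raise ValueError("shared_error_corr must be in [-1, 1]")
        total = sum(self.epct_targets[k] for k in ("protein", "fat", "carbohydrate"))
        if not 0 < total <= 100:
            raise ValueError("macronutrient E% targets must sum into (0, 100]")
        if self.epct_targets["sucrose"] > self.epct_targets["carbohydrate"]:
            raise ValueError("sucrose E% cannot exceed carbohydrate E%")
        for g, spec in self.food_groups.items():
            if g not in FOOD_GROUPS:
                raise ValueError(f"unknown food group {g!r}")
            if not isinstance(spec, FoodGroupSpec):
                raise TypeError("food_groups values must be FoodGroupSpec")


@dataclass
class CohortData:
    recalls: pd.DataFrame
    composition: pd.DataFrame
    foodgroups: pd.DataFrame
    doses: pd.DataFrame
    urines: pd.DataFrame
    groundtruth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("recalls", "composition", "foodgroups", "doses", "urines",
                     "groundtruth"):
            df = getattr(self, name)
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=(name == "composition"))
            paths[name] = path
        return paths


# --------------------------------------------------------------------------
# random draws
# --------------------------------------------------------------------------


def _lognorm_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _draw_group_means(rng: np.random.Generator, spec: FoodGroupSpec, n: int) -> np.ndarray:
    if spec.mean == 0:
        return np.zeros(n)
    if spec.family == "truncnorm":
        return np.clip(rng.normal(spec.mean, spec.sd, n), 0.0, None)
    if spec.family == "lognorm":
        mu, sig = _lognorm_params(spec.mean, max(spec.sd, 1e-9))
        return rng.lognormal(mu, sig, n)
    # zero-inflated lognormal, moment-matched so the marginal keeps mean/sd
    q = 1.0 - spec.p_zero
    m_l = spec.mean / q
    v_l = (spec.sd**2 + spec.mean**2) / q - m_l**2
    sd_l = np.sqrt(v_l) if v_l > 0 else 0.1 * m_l
    mu, sig = _lognorm_params(m_l, sd_l)
    vals = rng.lognormal(mu, sig, n)
    vals[rng.random(n) < spec.p_zero] = 0.0
    return vals


def _day_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative mean-one lognormal day-to-day factor."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    mu, sig = _lognorm_params(1.0, cv)
    return rng.lognormal(mu, sig, size)


def _method_errors(rng: np.random.Generator, sd: float, corr: float, size=None) -> np.ndarray:
    """Jointly normal reporting errors; last axis is (web, telephone)."""
    if sd == 0:
        shape = (2,) if size is None else tuple(np.atleast_1d(size)) + (2,)
        return np.zeros(shape)
    cov = np.array([[sd**2, corr * sd**2], [corr * sd**2, sd**2]])
    return rng.multivariate_normal(np.zeros(2), cov, size=size)


# --------------------------------------------------------------------------
# energy sub-model (shared by the full generator and calibration checks)
# --------------------------------------------------------------------------


def simulate_energy(cfg: GeneratorConfig, rng: np.random.Generator,
                    n: int | None = None) -> dict[str, np.ndarray]:
    """Draw TEE, habitual and per-day true/reported energies.

    Returns arrays: ``tee`` (n,), ``habitual`` (n,), ``true_day`` (n, days),
    ``web`` and ``telephone`` (n, days) reported energies in kJ.
    """
    n = n or cfg.n_participants
    tee = np.clip(rng.normal(cfg.tee_mean_kj, cfg.tee_sd_kj, n), 4000.0, None)
    habitual = tee * (1.0 + cfg.bias_mean) + cfg.bias_slope * (tee - cfg.tee_mean_kj)
    day = _day_factor(rng, cfg.day_cv, (n, cfg.n_days))
    true_day = np.clip(habitual[:, None] * day, 500.0, None)
    err = _method_errors(rng, cfg.method_error_sd, cfg.shared_error_corr,
                         (n, cfg.n_days))
    web = np.clip(true_day * (1.0 + err[..., 0]), 300.0, None)
    tel = np.clip(true_day * (1.0 + err[..., 1]), 300.0, None)
    return {"tee": tee, "habitual": habitual, "true_day": true_day,
            "web": web, "telephone": tel}


# --------------------------------------------------------------------------
# the generator proper
# --------------------------------------------------------------------------


def _solve_staples(energy_kj: float, group_items: list[tuple[str, float]],
                   comp: pd.DataFrame, targets: dict) -> list[tuple[str, float]]:
    """Staple amounts (g) so the day hits its energy and E% targets.

    Solved in closed form in the order sugar -> carbohydrate -> protein ->
    fat staple (each staple introduces at most the nutrients already
    solved); amounts are floored at zero when group foods alone exceed a
    target, which shifts that day's E% slightly.
    """
    f = EnergyFactors()
    need = {
        "protein": targets["protein"] / 100.0 * energy_kj / f.protein,
        "fat": targets["fat"] / 100.0 * energy_kj / f.fat,
        "carbohydrate": targets["carbohydrate"] / 100.0 * energy_kj / f.carbohydrate,
        "sucrose": targets["sucrose"] / 100.0 * energy_kj / f.carbohydrate,
    }
    have = dict.fromkeys(need, 0.0)
    for code, grams in group_items:
        row = comp.loc[code]
        for k, col in (("protein", "protein_g"), ("fat", "fat_g"),
                       ("carbohydrate", "carbohydrate_g"), ("sucrose", "sucrose_g")):
            have[k] += grams / 100.0 * float(row[col])
    sp, sf, sc, ss = STAPLES["SP01"], STAPLES["SF01"], STAPLES["SC01"], STAPLES["SS01"]
    a_ss = max(0.0, (need["sucrose"] - have["sucrose"]) / (ss["sucrose_g"] / 100.0))
    a_sc = max(0.0, (need["carbohydrate"] - have["carbohydrate"]
                     - a_ss * ss["carbohydrate_g"] / 100.0) / (sc["carbohydrate_g"] / 100.0))
    a_sp = max(0.0, (need["protein"] - have["protein"]
                     - a_sc * sc["protein_g"] / 100.0) / (sp["protein_g"] / 100.0))
    a_sf = max(0.0, (need["fat"] - have["fat"] - a_sp * sp["fat_g"] / 100.0
                     - a_sc * sc["fat_g"] / 100.0) / (sf["fat_g"] / 100.0))
    out = [("SS01", a_ss), ("SC01", a_sc), ("SP01", a_sp), ("SF01", a_sf)]
    return [(c, a) for c, a in out if a > 1e-9]


def generate_cohort(cfg: GeneratorConfig | None = None, seed: int = 0) -> CohortData:
    """Generate a full synthetic study bundle with ground-truth sidecar."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    comp = build_composition()
    fgm = build_foodgroup_map()
    constants = DLWConstants()
    n = cfg.n_participants
    pids = [f"P{i + 1:03d}" for i in range(n)]

    energy = simulate_energy(cfg, rng)
    weight = np.clip(rng.normal(cfg.weight_mean_kg, cfg.weight_sd_kg, n), 40.0, None)

    group_means = {g: _draw_group_means(rng, spec, n)
                   for g, spec in cfg.food_groups.items()}
    # fixed per-participant split of each group over its food codes
    group_splits: dict[str, dict[str, np.ndarray]] = {}
    for g in cfg.food_groups:
        codes = sorted(GROUP_FOODS[g])
        group_splits[g] = {
            pid: rng.dirichlet(np.full(len(codes), 2.0)) if len(codes) > 1
            else np.ones(1)
            for pid in pids
        }

    recall_rows = []
    reported = {"web_recall": energy["web"], "telephone_recall": energy["telephone"]}
    for i, pid in enumerate(pids):
        for j in range(cfg.n_days):
            day_idx = j + 1
            weekend = day_idx == cfg.n_days
            # true group grams for this day, shared by both methods, with one
            # correlated (web, telephone) reporting-error pair per group
            day_grams, group_err = {}, {}
            for g in cfg.food_groups:
                base = group_means[g][i]
                day_grams[g] = base * _day_factor(rng, cfg.group_day_cv) if base > 0 else 0.0
                group_err[g] = _method_errors(rng, cfg.method_error_sd,
                                              cfg.shared_error_corr)
            for mcol, method in enumerate(("web_recall", "telephone_recall")):
                items: list[tuple[str, float]] = []
                for g in cfg.food_groups:
                    grams = day_grams[g]
                    if grams <= 0:
                        continue
                    rep = max(0.0, grams * (1.0 + group_err[g][mcol]))
                    codes = sorted(GROUP_FOODS[g])
                    for code, w in zip(codes, group_splits[g][pid]):
                        if rep * w > 1e-9:
                            items.append((code, rep * w))
                e_day = reported[method][i, j]
                items += _solve_staples(e_day, items, comp, cfg.epct_targets)
                for code, grams in items:
                    recall_rows.append({
                        "participant_id": pid, "method": method, "day_index": day_idx,
                        "is_weekend": weekend, "food_code": code,
                        "amount_g": round(grams, 6),
                    })
    recalls = pd.DataFrame(recall_rows)

    # isotope sub-sample -------------------------------------------------
    dose_rows, urine_rows = [], []
    kd_true = np.full(n, np.nan)
    ko_true = np.full(n, np.nan)
    nd_true = np.full(n, np.nan)
    no_true = np.full(n, np.nan)
    eeq = dlw_mod.energy_equivalent(constants.food_quotient, constants)
    for i in range(cfg.n_dlw):
        pid = pids[i]
        n_o = weight[i] * cfg.body_water_fraction * 1000.0 / constants.mw_2h2o
        dsr = rng.normal(cfg.dsr_mean, cfg.dsr_sd)
        n_d = dsr * n_o
        k_d = max(0.04, rng.normal(cfg.kd_mean, cfg.kd_sd))
        rco2_mol = energy["tee"][i] / eeq / constants.molar_volume_l
        n_pool = 0.5 * (n_d / constants.frac_2h + n_o / constants.frac_18o)
        diff = rco2_mol / (constants.rco2_coefficient * n_pool)
        k_o = (diff + constants.frac_2h * k_d) / constants.frac_18o
        kd_true[i], ko_true[i], nd_true[i], no_true[i] = k_d, k_o, n_d, n_o
        dose_2h = constants.dose_2h2o_g_per_kg * weight[i]
        dose_18o = constants.dose_h218o_g_per_kg * weight[i]
        e0_d = (dose_2h / constants.mw_2h2o) * cfg.dose_enr_2h / n_d
        e0_o = (dose_18o / constants.mw_h218o) * cfg.dose_enr_18o / n_o
        dose_rows.append({
            "participant_id": pid, "weight_kg": round(weight[i], 6),
            "dose_2h2o_g": round(dose_2h, 6), "dose_h218o_g": round(dose_18o, 6),
            "dose_enr_2h": cfg.dose_enr_2h, "dose_enr_18o": cfg.dose_enr_18o,
            "dosing_time": "2019-11-01T08:00:00",
        })
        for t in cfg.baseline_days:
            urine_rows.append({
                "participant_id": pid, "time_days": t,
                "enr_2h": cfg.baseline_2h, "enr_18o": cfg.baseline_18o,
                "is_baseline": True,
            })
        for t in cfg.urine_days:
            noise = rng.normal(0.0, cfg.enrichment_noise_cv, 2) if cfg.enrichment_noise_cv else np.zeros(2)
            urine_rows.append({
                "participant_id": pid, "time_days": t,
                "enr_2h": cfg.baseline_2h + e0_d * np.exp(-k_d * t) * (1 + noise[0]),
                "enr_18o": cfg.baseline_18o + e0_o * np.exp(-k_o * t) * (1 + noise[1]),
                "is_baseline": False,
            })
    doses = pd.DataFrame(dose_rows, columns=[
        "participant_id", "weight_kg", "dose_2h2o_g", "dose_h218o_g",
        "dose_enr_2h", "dose_enr_18o", "dosing_time"])
    urines = pd.DataFrame(urine_rows, columns=[
        "participant_id", "time_days", "enr_2h", "enr_18o", "is_baseline"])

    gt = pd.DataFrame({
        "participant_id": pids,
        "weight_kg": weight,
        "tee_kj": energy["tee"],
        "habitual_intake_kj": energy["habitual"],
        **{f"fg_{g}_true_mean": group_means.get(g, np.zeros(n)) for g in FOOD_GROUPS},
        "k_d_true": kd_true, "k_o_true": ko_true,
        "n_d_true_mol": nd_true, "n_o_true_mol": no_true,
    })
    return CohortData(recalls, comp, fgm, doses, urines, gt)


# --------------------------------------------------------------------------
# calibration check
# --------------------------------------------------------------------------


def calibration_check(cfg: GeneratorConfig | None = None, replicates: int = 200,
                      seed: int = 0, n: int | None = None) -> pd.DataFrame:
    """Monte-Carlo behaviour of the energy model under a configuration.

    For each replicate cohort of ``n`` participants (default: the isotope
    sub-sample size) computes, for 3-day mean web-reported intake vs TEE:
    the mean difference, 2 SD limits of agreement, the difference-on-average
    regression slope, and Pearson r; plus the web-vs-telephone intake
    correlation.  Used to confirm that the configured bias is recovered and
    that a positive ``bias_slope`` induces a positive proportional-bias
    slope.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    n = n or cfg.n_dlw
    from .compare import PairedSeries, bland_altman  # local import to avoid cycle

    rows = []
    for rep in range(replicates):
        sim = simulate_energy(cfg, rng, n)
        ei_web = sim["web"].mean(axis=1)
        ei_tel = sim["telephone"].mean(axis=1)
        ba = bland_altman(PairedSeries("energy", "kJ/day", ei_web, sim["tee"]),
                          reference="series_b")
        r_tee = float(np.corrcoef(ei_web, sim["tee"])[0, 1])
        r_methods = float(np.corrcoef(ei_web, ei_tel)[0, 1])
        rows.append({"replicate": rep, "mean_diff": ba.mean_diff,
                     "loa_half_width": ba.loa_half_width, "ba_slope": ba.slope,
                     "r_ei_tee": r_tee, "r_web_tel": r_methods})
    return pd.DataFrame(rows)
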