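"""Total energy expenditure from doubly labelled water (DLW).

A participant drinks a weighed dose of water labelled with deuterium and
oxygen-18 (0.08 g 2H2O and 0.15 g H218O per kg body weight by default) and
collects urine over two weeks (nominally days 1, 5, 8, 12 and 15 post-dose,
plus two pre-dose baselines).  Both isotopes wash out of body water
mono-exponentially; 18O leaves by water *and* CO2, deuterium by water only,
so the difference of the elimination rates measures CO2 production:

1. baseline-corrected log-linear regression of urine enrichment on time
   gives the elimination rates ``k_d`` and ``k_O`` (per day) and the
   zero-time intercepts (slope-intercept / multipoint protocol);
2. dilution spaces ``N = dose_moles x dose_enrichment / intercept`` give
   the apparent body-water pools of each isotope (their ratio, ~1.035, is
   a quality-control quantity);
3. the two-pool CO2-production equation combines pools and rates with
   isotope-fractionation corrections (see
   :class:`~dietval.config.DLWConstants` for the exact form);
4. CO2 production times the Weir energy equivalent of CO2 at the diet's
   food quotient (default 0.86) gives TEE in kJ/day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import DLWConstants

ISOTOPES = ("2H", "18O")


@dataclass(frozen=True)
class EliminationFit:
    isotope: str
    k: float                 # elimination rate, per day
    zero_time_excess: float  # back-extrapolated excess enrichment at t=0
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class DLWResult:
    participant_id: str
    k_d: float
    k_O: float
    N_d_mol: float
    N_O_mol: float
    dilution_space_ratio: float
    rco2_mol_day: float
    rco2_l_day: float
    food_quotient: float
    energy_equiv_kj_per_l: float
    tee_kj_day: float
    dsr_qc_ok: bool
    r_squared_2h: float
    r_squared_18o: float


def fit_elimination(times_days, excess, isotope: str) -> EliminationFit:
    """Least-squares fit of ln(excess enrichment) on time since dose.

    ``excess`` must already be baseline-corrected (enrichment above the
    mean of the pre-dose samples) and strictly positive.  Returns
    ``k = -slope`` and the exponentiated intercept.
    """
    t = np.asarray(times_days, dtype=float)
    e = np.asarray(excess, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and excess must be 1-d arrays of equal length")
    if t.size < 2:
        raise ValueError(f"{isotope}: need >= 2 post-dose samples, got {t.size}")
    bad = np.nonzero(e <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{isotope}: non-positive excess enrichment at t={t[bad].tolist()} days; "
            "check baseline subtraction"
        )
    res = stats.linregress(t, np.log(e))
    r2 = float(res.rvalue**2) if t.size > 2 else 1.0
    return EliminationFit(isotope, -float(res.slope), float(np.exp(res.intercept)),
                          r2, int(t.size))


def dilution_space(dose_g: float, dose_enrichment: float, fit: EliminationFit,
                   constants: DLWConstants | None = None) -> float:
    """Isotope dilution space in mol of body water.

    ``N = (dose_g / MW) x dose_enrichment / zero_time_excess`` with the
    molar mass of the labelled water (18.02 for 2H2O as water equivalent,
    20.02 for H218O).  Dose and sample enrichments must share one unit —
    the unit cancels here but only if it is the same on both sides.
    """
    constants = constants or DLWConstants()
    if fit.zero_time_excess <= 0:
        raise ValueError(f"{fit.isotope}: zero-time excess must be > 0")
    if dose_g <= 0 or dose_enrichment <= 0:
        raise ValueError("dose mass and dose enrichment must be > 0")
    mw = constants.mw_2h2o if fit.isotope == "2H" else constants.mw_h218o
    return (dose_g / mw) * dose_enrichment / fit.zero_time_excess


def co2_production(n_d_mol: float, n_o_mol: float, k_d: float, k_o: float,
                   constants: DLWConstants | None = None) -> tuple[float, float]:
    """CO2 production (mol/day, L/day) from the two-pool equation.

    The fractionation-weighted rate difference ``f18O*kO - f2H*kd`` must be
    non-negative (oxygen turns over faster than hydrogen in any physiological
    record); exact cancellation yields zero production.
    """
    c = constants or DLWConstants()
    n_pool = 0.5 * (n_d_mol / c.frac_2h + n_o_mol / c.frac_18o)
    diff = c.frac_18o * k_o - c.frac_2h * k_d
    if diff < 0:
        raise ValueError(
            f"non-physiological rates: f18O*kO - f2H*kd = {diff:.6g} < 0 "
            f"(kO={k_o:.6g}, kd={k_d:.6g})"
        )
    rco2_mol = c.rco2_coefficient * n_pool * diff
    return rco2_mol, rco2_mol * c.molar_volume_l


def energy_equivalent(food_quotient: float,
                      constants: DLWConstants | None = None) -> float:
    """Weir energy equivalent of CO2, kJ per litre, at a given food quotient."""
    c = constants or DLWConstants()
    if not 0.7 <= food_quotient <= 1.0:
        raise ValueError(f"food quotient {food_quotient} outside [0.7, 1.0]")
    kcal_per_l = c.weir_a / food_quotient + c.weir_b
    return kcal_per_l * c.kcal_to_kj


def tee(rco2_l_day: float, energy_equiv_kj_per_l: float) -> float:
    """Total energy expenditure, kJ/day."""
    return rco2_l_day * energy_equiv_kj_per_l


def process_participant(dose: pd.Series, urines: pd.DataFrame,
                        constants: DLWConstants | None = None) -> DLWResult:
    """Full DLW chain for one participant.

    ``dose`` carries weight_kg, dose_2h2o_g, dose_h218o_g, dose_enr_2h,
    dose_enr_18o; ``urines`` has columns time_days, enr_2h, enr_18o,
    is_baseline.  Baseline = mean of the pre-dose samples, subtracted from
    the post-dose enrichments before the log-linear fits.
    """
    c = constants or DLWConstants()
    base = urines[urines["is_baseline"].astype(bool)]
    post = urines[~urines["is_baseline"].astype(bool)].sort_values("time_days")
    if len(base) < 1:
        raise ValueError("no baseline urine samples")
    fits = {}
    for iso, col in (("2H", "enr_2h"), ("18O", "enr_18o")):
        excess = post[col].to_numpy(float) - float(base[col].mean())
        fits[iso] = fit_elimination(post["time_days"].to_numpy(float), excess, iso)
    n_d = dilution_space(float(dose["dose_2h2o_g"]), float(dose["dose_enr_2h"]),
                         fits["2H"], c)
    n_o = dilution_space(float(dose["dose_h218o_g"]), float(dose["dose_enr_18o"]),
                         fits["18O"], c)
    dsr = n_d / n_o
    rco2_mol, rco2_l = co2_production(n_d, n_o, fits["2H"].k, fits["18O"].k, c)
    eeq = energy_equivalent(c.food_quotient, c)
    return DLWResult(
        participant_id=str(dose["participant_id"]),
        k_d=fits["2H"].k,
        k_O=fits["18O"].k,
        N_d_mol=n_d,
        N_O_mol=n_o,
        dilution_space_ratio=dsr,
        rco2_mol_day=rco2_mol,
        rco2_l_day=rco2_l,
        food_quotient=c.food_quotient,
        energy_equiv_kj_per_l=eeq,
        tee_kj_day=tee(rco2_l, eeq),
        dsr_qc_ok=bool(c.dsr_qc_low <= dsr <= c.dsr_qc_high),
        r_squared_2h=fits["2H"].r_squared,
        r_squared_18o=fits["18O"].r_squared,
    )


def process_cohort(doses: pd.DataFrame, urines: pd.DataFrame,
                   constants: DLWConstants | None = None) -> pd.DataFrame:
    """DLW results for every participant in a dose table."""
    rows = []
    for _, dose in doses.iterrows():
        sub = urines[urines["participant_id"] == dose["participant_id"]]
        res = process_participant(dose, sub, constants)
        rows.append(vars(res))
    return pd.DataFrame(rows)
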