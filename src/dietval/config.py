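"""Shared constants and configuration objects.

Every physical/physiological constant used anywhere in the package lives
here so that alternative laboratory conventions (energy conversion factors,
isotope fractionation coefficients, Weir constants) can be swapped without
touching computation code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: kcal -> kJ conversion (thermochemical calorie convention used by food tables)
KCAL_TO_KJ = 4.184

#: nutrients tracked per 100 g in the food-composition table (grams)
NUTRIENT_COLUMNS = (
    "protein_g",
    "fat_g",
    "carbohydrate_g",
    "sucrose_g",
    "fibre_g",
    "wholegrain_g",
    "pufa_g",
    "mufa_g",
    "sfa_g",
)

#: the nine food groups tracked for diet-quality scoring
FOOD_GROUPS = (
    "fruit_veg",
    "fish_shellfish",
    "nuts_seeds",
    "red_meat",
    "processed_meat",
    "sweet_savoury_treats",
    "ssb",
    "asb",
    "fruit_juice",
)

#: valid assessment-method labels
METHODS = ("web_recall", "telephone_recall")


@dataclass(frozen=True)
class EnergyFactors:
    """Metabolisable-energy conversion factors in kJ per gram.

    Applied when expressing a nutrient as a percentage of total energy
    (E%).  Fibre is not assigned energy under this convention.
    """

    protein: float = 17.0
    carbohydrate: float = 17.0
    fat: float = 37.0

    def for_nutrient(self, nutrient: str) -> float:
        """kJ/g factor for an E%-eligible nutrient name (e.g. ``'sucrose'``)."""
        if nutrient in ("protein",):
            return self.protein
        if nutrient in ("carbohydrate", "sucrose"):
            return self.carbohydrate
        if nutrient in ("fat", "pufa", "mufa", "sfa"):
            return self.fat
        raise KeyError(f"no energy factor defined for nutrient {nutrient!r}")


#: nutrients for which an E% is reported, with the factor family they use
EPCT_NUTRIENTS = ("protein", "fat", "carbohydrate", "sucrose", "pufa", "mufa", "sfa")


@dataclass(frozen=True)
class PlausibilityConfig:
    """Daily-energy screening thresholds.

    Thresholds are stored in kcal (the convention of the screening rule)
    and compared after converting the day's kJ total; both comparisons are
    strict ("exceeded" / "less than").
    """

    low_kcal: float = 800.0
    high_kcal: float = 3500.0
    kcal_to_kj: float = KCAL_TO_KJ

    @property
    def low_kj(self) -> float:
        return self.low_kcal * self.kcal_to_kj

    @property
    def high_kj(self) -> float:
        return self.high_kcal * self.kcal_to_kj


@dataclass(frozen=True)
class DLWConstants:
    """Constants of the doubly-labelled-water calculation chain.

    The CO2-production equation is the two-pool formulation

        rCO2 = (N / pool_divisor) * (f18O*kO - f2H*kd)
               - frac_coeff * (frac_water_fraction * N * (f18O*kO - f2H*kd))

    with N the fractionation-normalised mean body-water pool,
    N = (N_d/f2H + N_O/f18O) / 2.  The energy equivalent of CO2 follows
    the Weir expression (weir_a / FQ + weir_b) kcal per litre CO2.
    """

    mw_2h2o: float = 18.02   # g/mol, labelled water treated as water equivalent
    mw_h218o: float = 20.02  # g/mol
    pool_divisor: float = 2.078
    frac_2h: float = 1.041   # deuterium dilution-space fractionation multiplier
    frac_18o: float = 1.007  # oxygen-18 dilution-space fractionation multiplier
    frac_water_fraction: float = 1.05  # fraction of water loss subject to fractionation
    frac_coeff: float = 0.0246
    molar_volume_l: float = 22.4  # L CO2 per mol at STP
    weir_a: float = 3.941    # kcal/L O2 term of the Weir expression
    weir_b: float = 1.106    # kcal/L CO2 term
    kcal_to_kj: float = KCAL_TO_KJ
    food_quotient: float = 0.86
    dose_2h2o_g_per_kg: float = 0.08
    dose_h218o_g_per_kg: float = 0.15
    dsr_qc_low: float = 1.00   # QC band for the 2H/18O dilution-space ratio
    dsr_qc_high: float = 1.07
    wilcoxon_exact_max_n: int = 25

    @property
    def rco2_coefficient(self) -> float:
        """Net multiplier c in rCO2 = c * N * (f18O*kO - f2H*kd)."""
        return 1.0 / self.pool_divisor - self.frac_coeff * self.frac_water_fraction


def load_yaml_config(path: str | Path, cls):
    """Instantiate a frozen config dataclass from a YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return cls(**raw)


def dump_yaml_config(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
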