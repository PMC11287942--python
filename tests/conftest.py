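import numpy as np
import pandas as pd
import pytest

from dietval import dietary, synth


@pytest.fixture(scope="session")
def simple_fct() -> pd.DataFrame:
    """Tiny per-100 g composition table with hand-checkable numbers."""
    rows = {
        # code: energy, protein, fat, carb, sucrose, fibre, wholegrain, pufa, mufa, sfa
        "A": [500.0, 2.0, 2.0, 20.0, 5.0, 1.0, 0.0, 0.2, 0.5, 0.8],
        "B": [1000.0, 10.0, 5.0, 30.0, 2.0, 3.0, 10.0, 1.0, 1.5, 1.8],
        "C": [2000.0, 5.0, 40.0, 10.0, 1.0, 0.0, 0.0, 5.0, 15.0, 18.0],
    }
    fct = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["energy_kj", *dietary.NUTRIENT_COLUMNS])
    fct.index.name = "food_code"
    return fct


@pytest.fixture(scope="session")
def simple_fgm() -> pd.DataFrame:
    return pd.DataFrame({
        "food_code": ["A", "B", "C", "C"],
        "group": ["fruit_veg", "fish_shellfish", "red_meat", "sweet_savoury_treats"],
    })


@pytest.fixture(scope="session")
def default_cohort() -> synth.CohortData:
    """One default-configuration synthetic cohort shared across tests."""
    return synth.generate_cohort(synth.GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def default_intakes(default_cohort) -> pd.DataFrame:
    return dietary.aggregate_cohort(default_cohort.recalls, default_cohort.composition,
                                    default_cohort.foodgroups)


def make_day(items, pid="p1", method="web_recall", day_index=1):
    return dietary.RecallDay(
        pid, method, day_index, False,
        tuple(dietary.ConsumedItem(c, a) for c, a in items),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
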