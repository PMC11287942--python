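#!/usr/bin/env python
"""Aggregate recall days to participant-mean intakes.

Links every consumed item with the food-composition table, screens daily
energy against the 800/3500 kcal plausibility bounds, and averages the
2-3 recall days per participant and method.  Writes the participant-level
intakes and the per-method cohort summary (mean, SD) under results/.
"""

from pathlib import Path

import pandas as pd

from dietval.dietary import aggregate_cohort, cohort_summary

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    recalls = pd.read_csv(COHORT / "recalls.csv")
    comp = pd.read_csv(COHORT / "composition.csv").set_index("food_code")
    fgm = pd.read_csv(COHORT / "foodgroups.csv")

    intakes = aggregate_cohort(recalls, comp, fgm)
    RESULTS.mkdir(exist_ok=True)
    intakes.to_csv(COHORT / "participant_intakes.csv", index=False)

    summary = cohort_summary(intakes)
    summary.round(2).to_csv(RESULTS / "cohort_summary.csv")

    n_flagged = int(intakes.n_flagged.sum())
    web = intakes[intakes.method == "web_recall"]
    print(f"aggregated {len(intakes)} participant-method records "
          f"({n_flagged} flagged days retained)")
    print(f"  web energy intake: {web.energy_kj.mean():.0f} "
          f"(SD {web.energy_kj.std(ddof=1):.0f}) kJ/day")
    print(f"  wrote {RESULTS / 'cohort_summary.csv'}")


if __name__ == "__main__":
    main()
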