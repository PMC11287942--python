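#!/usr/bin/env python
"""Score adherence to food-based dietary guidelines (SHEI, 0-9).

Scores each participant-method record on the nine-component index and
summarises component and total scores per method under results/.
"""

from pathlib import Path

import pandas as pd

from dietval.shei import score_cohort

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    intakes = pd.read_csv(COHORT / "participant_intakes.csv")
    scores = score_cohort(intakes)
    scores.to_csv(COHORT / "shei_scores.csv", index=False)

    summary = scores.drop(columns="participant_id").groupby("method").agg(["mean", "std"])
    summary.columns = [f"{a}_{b}" for a, b in summary.columns]
    RESULTS.mkdir(exist_ok=True)
    summary.round(3).T.to_csv(RESULTS / "shei_summary.csv")

    for method, sub in scores.groupby("method"):
        print(f"  {method}: total SHEI {sub.shei_total.mean():.2f} "
              f"(SD {sub.shei_total.std(ddof=1):.2f})")
    print(f"  wrote {RESULTS / 'shei_summary.csv'}")


if __name__ == "__main__":
    main()
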