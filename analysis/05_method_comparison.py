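#!/usr/bin/env python
"""Method comparison: web recalls vs telephone recalls, and intake vs TEE.

Builds the validation tables — per-variable means, paired location tests,
correlations and Bland-Altman agreement — for the two self-report methods,
and the energy-intake-vs-TEE agreement analysis on the isotope sub-sample.
Writes summary tables and Bland-Altman plot coordinates under results/.
"""

from pathlib import Path

import pandas as pd

from dietval.compare import PairedSeries, bland_altman, summarize_validation
from dietval.pipeline import DEFAULT_COMPARISON_VARIABLES

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    intakes = pd.read_csv(COHORT / "participant_intakes.csv")
    scores = pd.read_csv(COHORT / "shei_scores.csv")
    merged = intakes.merge(scores, on=["participant_id", "method"])
    web = merged[merged.method == "web_recall"]
    tel = merged[merged.method == "telephone_recall"]

    variables = DEFAULT_COMPARISON_VARIABLES + ["shei_total"]
    table, plots = summarize_validation(web, tel, variables,
                                        label_a="web", label_b="telephone")
    RESULTS.mkdir(exist_ok=True)
    table.round(4).to_csv(RESULTS / "comparison_summary.csv", index=False)
    plots["energy_kj"].round(2).to_csv(RESULTS / "blandaltman_energy.csv", index=False)

    row = table.set_index("variable").loc["energy_kj"]
    print("web vs telephone energy intake:")
    print(f"  mean diff {row.mean_diff:+.0f} kJ/day, LoA half-width "
          f"{row.loa_half_width:.0f} kJ, r = {row.r:.3f} ({row.correlation})")

    # energy intake (web) vs TEE on the isotope sub-sample
    dlw_res = pd.read_csv(COHORT / "dlw_results.csv").set_index("participant_id")
    ei = web.set_index("participant_id").energy_kj
    common = ei.index.intersection(dlw_res.index)
    series = PairedSeries("energy_vs_tee", "kJ/day", ei.loc[common].to_numpy(),
                          dlw_res.tee_kj_day.loc[common].to_numpy())
    ba = bland_altman(series, reference="series_b")
    pd.DataFrame([vars(ba)]).round(4).to_csv(RESULTS / "energy_vs_tee.csv", index=False)
    print(f"energy intake vs TEE (n={ba.n}):")
    print(f"  mean diff {ba.mean_diff:+.0f} kJ/day ({ba.mean_diff_pct:+.1f}% of TEE), "
          f"LoA half-width {ba.loa_half_width:.0f} kJ")
    print(f"  difference-on-average slope {ba.slope:+.2f} (r = {ba.r:.3f}, p = {ba.p:.3f})")
    print(f"  wrote {RESULTS / 'comparison_summary.csv'}")


if __name__ == "__main__":
    main()
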