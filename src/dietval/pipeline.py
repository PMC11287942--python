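"""End-to-end orchestration: inputs -> intakes -> scores -> DLW -> comparisons."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import compare, dietary, dlw, shei, validate
from .config import EnergyFactors, PlausibilityConfig, DLWConstants

logger = logging.getLogger(__name__)

#: variables compared between the two recall methods by default
DEFAULT_COMPARISON_VARIABLES = [
    "energy_kj", "protein_epct", "fat_epct", "carbohydrate_epct", "sucrose_epct",
    "fg_fruit_veg", "fg_fish_shellfish", "fg_nuts_seeds", "fg_red_meat",
    "fg_processed_meat", "fg_sweet_savoury_treats", "fg_ssb", "fg_asb",
    "fg_fruit_juice", "wholegrain_g_per_10mj", "fibre_g_per_mj",
    "red_processed_meat_weekly_g",
]


@dataclass
class RunConfig:
    recalls: Path
    composition: Path
    foodgroups: Path
    outdir: Path
    doses: Path | None = None
    urines: Path | None = None
    shei_config: Path | None = None
    variables: list[str] = field(default_factory=lambda: list(DEFAULT_COMPARISON_VARIABLES))
    exclude_flagged: bool = False

    def __post_init__(self):
        for name in ("recalls", "composition", "foodgroups"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        self.outdir = Path(self.outdir)
        for name in ("doses", "urines", "shei_config"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run validation, aggregation, scoring, DLW and comparisons; write CSVs.

    Returns the mapping of artifact name to written path.  Raises
    ``ValueError`` on validation errors (findings are still written); any
    partially written outputs are removed on failure.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    findings = validate.validate_inputs(cfg.recalls, cfg.composition, cfg.foodgroups,
                                        cfg.doses, cfg.urines)
    findings_path = cfg.outdir / "validation_findings.json"
    validate.findings_to_json(findings, findings_path)
    artifacts["findings"] = findings_path
    if validate.has_errors(findings):
        raise ValueError(f"input validation failed; see {findings_path}")

    try:
        recalls = pd.read_csv(cfg.recalls)
        comp = pd.read_csv(cfg.composition).set_index("food_code")
        comp.index = comp.index.astype(str)
        fgm = pd.read_csv(cfg.foodgroups)
        intakes = dietary.aggregate_cohort(recalls, comp, fgm,
                                           exclude_flagged=cfg.exclude_flagged)
        path = cfg.outdir / "participant_intakes.csv"
        intakes.to_csv(path, index=False)
        artifacts["intakes"] = path

        summary = dietary.cohort_summary(intakes)
        path = cfg.outdir / "cohort_summary.csv"
        summary.to_csv(path)
        artifacts["cohort_summary"] = path

        shei_cfg = shei.load_config(cfg.shei_config) if cfg.shei_config else None
        scores = shei.score_cohort(intakes, shei_cfg)
        path = cfg.outdir / "shei_scores.csv"
        scores.to_csv(path, index=False)
        artifacts["shei_scores"] = path

        merged = intakes.merge(scores, on=["participant_id", "method"])
        web = merged[merged["method"] == "web_recall"]
        tel = merged[merged["method"] == "telephone_recall"]
        variables = [v for v in cfg.variables + ["shei_total"] if v in merged.columns]
        if len(web) >= 3 and len(tel) >= 3:
            table, plots = compare.summarize_validation(
                web, tel, variables, label_a="web", label_b="telephone")
            path = cfg.outdir / "comparison_summary.csv"
            table.to_csv(path, index=False)
            artifacts["comparison_summary"] = path
            for var, plot in plots.items():
                p = cfg.outdir / f"blandaltman_{var}.csv"
                plot.to_csv(p, index=False)
                artifacts[f"blandaltman_{var}"] = p

        if cfg.doses is not None and cfg.urines is not None:
            doses = pd.read_csv(cfg.doses)
            urines = pd.read_csv(cfg.urines)
            results = dlw.process_cohort(doses, urines)
            path = cfg.outdir / "dlw_results.csv"
            results.to_csv(path, index=False)
            artifacts["dlw_results"] = path
            # energy intake (web) vs TEE on the isotope sub-sample
            ei = web.set_index("participant_id")["energy_kj"]
            tee = results.set_index("participant_id")["tee_kj_day"]
            common = ei.index.intersection(tee.index)
            if len(common) >= 3:
                series = compare.PairedSeries("energy_vs_tee", "kJ/day",
                                              ei.loc[common].to_numpy(),
                                              tee.loc[common].to_numpy())
                ba = compare.bland_altman(series, reference="series_b")
                path = cfg.outdir / "energy_vs_tee.csv"
                pd.DataFrame([vars(ba)]).to_csv(path, index=False)
                artifacts["energy_vs_tee"] = path
        else:
            logger.info("isotope files absent: DLW stage skipped")
    except Exception:
        for p in artifacts.values():
            if p != findings_path and p.exists():
                p.unlink()
        raise
    return artifacts
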