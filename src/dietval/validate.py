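"""Schema validation of input CSV bundles.

Every finding carries a severity ('error' blocks the run, 'warning' does
not), a location (file, row, column where determinable) and a message.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .config import FOOD_GROUPS, METHODS, NUTRIENT_COLUMNS


@dataclass(frozen=True)
class Finding:
    severity: str  # 'error' | 'warning'
    file: str
    message: str
    row: int | None = None
    column: str | None = None


RECALL_COLUMNS = ("participant_id", "method", "day_index", "is_weekend",
                  "food_code", "amount_g")
DOSE_COLUMNS = ("participant_id", "weight_kg", "dose_2h2o_g", "dose_h218o_g",
                "dose_enr_2h", "dose_enr_18o")
URINE_COLUMNS = ("participant_id", "time_days", "enr_2h", "enr_18o", "is_baseline")


def _read(path: Path, findings: list[Finding]) -> pd.DataFrame | None:
    try:
        return pd.read_csv(path)
    except Exception as exc:  # unreadable file is itself a finding
        findings.append(Finding("error", str(path), f"unreadable: {exc}"))
        return None


def _require_columns(df: pd.DataFrame, cols, path: Path, findings: list[Finding]) -> bool:
    missing = [c for c in cols if c not in df.columns]
    for c in missing:
        findings.append(Finding("error", str(path), f"missing column {c!r}", column=c))
    return not missing


def validate_inputs(
    recalls_path: str | Path,
    composition_path: str | Path,
    foodgroups_path: str | Path,
    doses_path: str | Path | None = None,
    urines_path: str | Path | None = None,
) -> list[Finding]:
    """Validate a study input bundle; isotope files are optional."""
    findings: list[Finding] = []

    comp = _read(Path(composition_path), findings)
    known_codes: set[str] = set()
    if comp is not None:
        path = Path(composition_path)
        if "food_code" in comp.columns:
            comp = comp.set_index("food_code")
        known_codes = set(comp.index.astype(str))
        if _require_columns(comp, ("energy_kj",) + NUTRIENT_COLUMNS, path, findings):
            for col in ("energy_kj",) + NUTRIENT_COLUMNS:
                bad = comp.index[comp[col] < 0]
                for code in bad:
                    findings.append(Finding("error", str(path),
                                            f"negative {col} for food {code!r}", column=col))
                n_na = int(comp[col].isna().sum())
                if n_na:
                    findings.append(Finding("warning", str(path),
                                            f"{n_na} missing values in {col} (treated as 0)",
                                            column=col))

    fgm = _read(Path(foodgroups_path), findings)
    if fgm is not None and _require_columns(fgm, ("food_code", "group"),
                                            Path(foodgroups_path), findings):
        for i, grp in fgm["group"].items():
            if grp not in FOOD_GROUPS:
                findings.append(Finding("error", str(foodgroups_path),
                                        f"unknown food group {grp!r}", row=int(i),
                                        column="group"))

    recalls = _read(Path(recalls_path), findings)
    if recalls is not None and _require_columns(recalls, RECALL_COLUMNS,
                                                Path(recalls_path), findings):
        p = str(recalls_path)
        for i, row in recalls.iterrows():
            if row["method"] not in METHODS:
                findings.append(Finding("error", p, f"invalid method {row['method']!r}",
                                        row=int(i), column="method"))
            if row["day_index"] not in (1, 2, 3):
                findings.append(Finding("error", p,
                                        f"day_index {row['day_index']!r} outside 1-3",
                                        row=int(i), column="day_index"))
            if not row["amount_g"] >= 0:
                findings.append(Finding("error", p, f"negative amount_g {row['amount_g']!r}",
                                        row=int(i), column="amount_g"))
            if known_codes and str(row["food_code"]) not in known_codes:
                findings.append(Finding("error", p,
                                        f"food code {row['food_code']!r} not in "
                                        "composition table", row=int(i), column="food_code"))

    if doses_path is not None:
        doses = _read(Path(doses_path), findings)
        if doses is not None and _require_columns(doses, DOSE_COLUMNS, Path(doses_path),
                                                  findings):
            for i, row in doses.iterrows():
                for col in ("dose_2h2o_g", "dose_h218o_g", "dose_enr_2h", "dose_enr_18o"):
                    if not row[col] > 0:
                        findings.append(Finding("error", str(doses_path),
                                                f"{col} must be > 0", row=int(i), column=col))
    if urines_path is not None:
        urines = _read(Path(urines_path), findings)
        if urines is not None:
            _require_columns(urines, URINE_COLUMNS, Path(urines_path), findings)

    return findings


def findings_to_json(findings: list[Finding], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(f) for f in findings], fh, indent=2)


def has_errors(findings: list[Finding]) -> bool:
    return any(f.severity == "error" for f in findings)
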