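"""File-format validation and configuration loading.

CSV dialect is fixed: UTF-8, header row, '.' decimal separator; times in hours
relative to dosing (pre-dose negative), intervals in ms, concentrations in
nmol/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

ECG_REQUIRED_COLUMNS = (
    "subject_id",
    "period",
    "treatment",
    "time_h",
    "replicate",
    "qt_ms",
    "rr_ms",
)
PK_REQUIRED_COLUMNS = ("subject_id", "period", "treatment", "time_h", "conc_nmol_l")


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {"ok": self.ok, "errors": self.errors, "warnings": self.warnings}


def _read(table) -> pd.DataFrame:
    if isinstance(table, (str, Path)):
        return pd.read_csv(table)
    return table


def validate_inputs(ecg, pk=None) -> ValidationReport:
    """Schema and sanity checks on ECG (and optionally PK) tables.

    Hard errors: missing columns, nonpositive intervals, QT >= RR, replicate
    outside 1-3, negative concentrations, non-monotone PK times within a
    profile.  Warnings: incomplete triplicates.
    """
    report = ValidationReport()
    ecg = _read(ecg)
    missing = [c for c in ECG_REQUIRED_COLUMNS if c not in ecg.columns]
    if missing:
        report.errors.append(f"ecg: missing columns {missing}")
        return report
    for col in ("qt_ms", "rr_ms"):
        bad = ecg.index[ecg[col] <= 0].tolist()
        if bad:
            report.errors.append(f"ecg: nonpositive {col} at rows {bad[:10]}")
    bad = ecg.index[ecg["qt_ms"] >= ecg["rr_ms"]].tolist()
    if bad:
        report.errors.append(f"ecg: QT >= RR at rows {bad[:10]}")
    bad = ecg.index[~ecg["replicate"].isin([1, 2, 3])].tolist()
    if bad:
        report.errors.append(f"ecg: replicate outside 1-3 at rows {bad[:10]}")
    rep_counts = ecg.groupby(["subject_id", "period", "time_h"])["replicate"].nunique()
    incomplete = rep_counts[rep_counts < 3]
    if len(incomplete):
        report.warnings.append(
            f"ecg: {len(incomplete)} timepoints with fewer than 3 replicates"
        )
    if pk is not None:
        pk = _read(pk)
        missing = [c for c in PK_REQUIRED_COLUMNS if c not in pk.columns]
        if missing:
            report.errors.append(f"pk: missing columns {missing}")
            return report
        if (pk["conc_nmol_l"] < 0).any():
            report.errors.append("pk: negative concentrations")
        for key, sub in pk.groupby(["subject_id", "period"]):
            if sub["time_h"].duplicated().any() or not sub["time_h"].is_monotonic_increasing:
                if not sub.sort_values("time_h")["time_h"].is_unique:
                    report.errors.append(f"pk: duplicated times in profile {key}")
    return report


def load_yaml_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
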