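"""Tabular and image file contracts.

All tabular interchange is plain CSV with fixed, versioned column schemas
so every stage can be re-run or replaced independently:

* filament table:  cell_id, stage, length_um, width_um, theta_deg, x_um, y_um
* manifest:        cell_id, replicate, condition, recovery_min, detached,
                   annexin_sd, planted_class (optional)
* metrics table:   cell_id, stage, n, R, nu_rad, F_um2, L_um, defined
* alterations:     cell_id, replicate, condition, recovery_min, delta_F,
                   delta_L, delta_nu, delta_T, apoptotic, assigned_class,
                   excluded_reason

Images are single- or multi-page TIFF read via tifffile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

SCHEMA_VERSION = "1"

FILAMENT_COLUMNS = ["cell_id", "stage", "length_um", "width_um", "theta_deg", "x_um", "y_um"]
MANIFEST_COLUMNS = ["cell_id", "replicate", "condition", "recovery_min",
                    "detached", "annexin_sd"]
ALTERATION_COLUMNS = ["cell_id", "replicate", "condition", "recovery_min",
                      "delta_F", "delta_L", "delta_nu", "delta_T",
                      "apoptotic", "assigned_class", "excluded_reason"]


@dataclass
class Violation:
    path: str
    row: int | None
    field: str
    message: str
    fatal: bool = True

    def __str__(self) -> str:
        loc = f"{self.path}"
        if self.row is not None:
            loc += f":row {self.row}"
        return f"{'FATAL' if self.fatal else 'WARN'} {loc} [{self.field}]: {self.message}"


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(v.fatal for v in self.violations)

    def add(self, *args, **kwargs) -> None:
        self.violations.append(Violation(*args, **kwargs))

    def __str__(self) -> str:
        if not self.violations:
            return "all inputs valid"
        return "\n".join(str(v) for v in self.violations)


def read_filament_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_tiff(path) -> np.ndarray:
    """Read a single- or multi-page TIFF as a 2D image or 3D stack."""
    return tifffile.imread(path)


def write_tiff(path, image: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image)
    return path


def validate_filament_csv(path, report: ValidationReport | None = None) -> ValidationReport:
    """Schema and range checks for a filament table CSV."""
    report = report if report is not None else ValidationReport()
    p = str(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:   # unreadable file is a single fatal violation
        report.add(p, None, "file", f"cannot read CSV: {exc}")
        return report
    for col in FILAMENT_COLUMNS:
        if col not in df.columns:
            report.add(p, None, col, "missing required column")
    if not report.ok:
        return report
    for idx, row in df.iterrows():
        if not row["length_um"] > 0:
            report.add(p, int(idx), "length_um", f"must be > 0, got {row['length_um']}")
        if not row["width_um"] > 0:
            report.add(p, int(idx), "width_um", f"must be > 0, got {row['width_um']}")
        if not (0 <= row["theta_deg"] < 180):
            report.add(p, int(idx), "theta_deg", f"must lie in [0, 180), got {row['theta_deg']}")
    return report


def validate_manifest_csv(path, report: ValidationReport | None = None) -> ValidationReport:
    report = report if report is not None else ValidationReport()
    p = str(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        report.add(p, None, "file", f"cannot read CSV: {exc}")
        return report
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            report.add(p, None, col, "missing required column")
    if not report.ok:
        return report
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        report.add(p, None, "cell_id", f"duplicate cell_id {dup!r}")
    for idx, row in df.iterrows():
        sd = row["annexin_sd"]
        if pd.notna(sd) and sd < 0:
            report.add(p, int(idx), "annexin_sd", f"must be >= 0, got {sd}")
    return report


def validate_tiff(path, report: ValidationReport | None = None) -> ValidationReport:
    report = report if report is not None else ValidationReport()
    try:
        arr = tifffile.imread(path)
        if arr.ndim not in (2, 3):
            report.add(str(path), None, "image", f"expected 2D/3D, got ndim={arr.ndim}")
    except Exception as exc:
        report.add(str(path), None, "file", f"cannot read TIFF: {exc}")
    return report


def validate_inputs(filament_csvs=(), manifest_csvs=(), tiffs=()) -> ValidationReport:
    """Validate a set of input files; violations carry row/field coordinates."""
    report = ValidationReport()
    for f in filament_csvs:
        validate_filament_csv(f, report)
    for m in manifest_csvs:
        validate_manifest_csv(m, report)
    for t in tiffs:
        validate_tiff(t, report)
    return report
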