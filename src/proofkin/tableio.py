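"""Cell-table and fit-report readers/writers.

The single-cell table schema mirrors the deposited study data: one row per
cell with its day/dataset identifiers, the applied light intensity, the
enforced binding half-life, receptor occupancy and the signaling readout.
Tables round-trip through CSV (UTF-8, header row) and can be ingested from
XLSX spreadsheets with a column mapping absorbing foreign headers.  Fit
reports are JSON with a provenance block (input hash, config, seed, version,
timestamp) sufficient to regenerate them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .proofreading import ProofreadingFit

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "CellTableResult",
    "FitReport",
    "read_cell_table",
    "write_cell_table",
    "write_fit_report",
    "read_fit_report",
    "table_hash",
]

REQUIRED_COLUMNS = (
    "day_id",
    "dataset_id",
    "cell_id",
    "light_intensity",
    "half_life_s",
    "occupancy_au",
    "dag_au",
    "adhesion_antibody",
)
OPTIONAL_COLUMNS = ("reporter",)

_NUMERIC = ("light_intensity", "half_life_s", "occupancy_au", "dag_au")


@dataclass(frozen=True)
class CellTableResult:
    """A validated cell table plus the rows rejected during validation."""

    table: pd.DataFrame
    rejected: pd.DataFrame  # offending rows with a 'rejection_reason' column

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_cell_table(
    path: str | Path, column_mapping: dict[str, str] | None = None, sheet: int | str = 0
) -> CellTableResult:
    """Read and validate a cell table from CSV or XLSX.

    ``column_mapping`` renames source headers to schema names before
    validation.  A missing required column raises; rows violating row-level
    invariants (missing values, non-positive half-life) are rejected and
    returned with reasons rather than silently dropped.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    else:
        df = pd.read_csv(path)
    if column_mapping:
        df = df.rename(columns=column_mapping)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table missing required columns: {missing}")

    df = df[[c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]].copy()
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    reasons = pd.Series("", index=df.index)
    na_mask = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    reasons[na_mask] = "missing value in required column"
    bad_tau = df["half_life_s"].notna() & (df["half_life_s"] <= 0)
    reasons[bad_tau] = "non-positive half_life_s"
    bad = reasons != ""

    rejected = df.loc[bad].copy()
    rejected["rejection_reason"] = reasons[bad]
    good = df.loc[~bad].reset_index(drop=True)
    good["adhesion_antibody"] = good["adhesion_antibody"].astype(bool)
    return CellTableResult(table=good, rejected=rejected)


def write_cell_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a cell table as UTF-8 CSV with a header row."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def table_hash(table: pd.DataFrame) -> str:
    """SHA-256 of the canonical CSV serialization of a table."""
    payload = table.to_csv(index=False, float_format="%.17g").encode("utf-8")
    return hashlib.sha256(payload).hexdigest()


@dataclass(frozen=True)
class FitReport:
    """Per-group proofreading fits plus full provenance."""

    fits: dict[str, ProofreadingFit]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fits": {group: fit.to_dict() for group, fit in self.fits.items()},
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitReport":
        return cls(
            fits={g: ProofreadingFit.from_dict(f) for g, f in d["fits"].items()},
            provenance=d.get("provenance", {}),
        )


def write_fit_report(
    fits: dict[str, ProofreadingFit],
    path: str | Path,
    input_table: pd.DataFrame | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> FitReport:
    """Serialize proofreading fits to JSON with a provenance block.

    The provenance records a hash of the input table, the run configuration,
    the seed, the software version and a UTC timestamp; reading the file back
    reproduces every numeric field at full precision.
    """
    if not fits:
        raise ValueError("no fits to write")
    report = FitReport(
        fits=fits,
        provenance={
            "input_hash": table_hash(input_table) if input_table is not None else None,
            "config": config or {},
            "seed": seed,
            "software_version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    )
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))
    return report


def read_fit_report(path: str | Path) -> FitReport:
    return FitReport.from_dict(json.loads(Path(path).read_text()))
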