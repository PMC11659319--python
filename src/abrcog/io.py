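"""File formats: canonical cohort CSV, epoch matrices, source-data workbook.

The cohort CSV (columns and units in :mod:`abrcog.schema`) is the single
interchange format between pipeline stages. Epoch matrices travel as
delimited numeric text with a JSON sidecar (sampling rate, onset, seed,
artifact mask). The deposited per-participant workbook for reproduction
runs is mapped onto the canonical schema through an explicit, user-editable
YAML column map — unmapped required columns are an error, never a guess.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .abr import EpochSet
from .schema import (
    COHORT_COLUMN_ORDER,
    COHORT_SCHEMA,
    InputError,
    MappingError,
)


@dataclass
class ValidationIssue:
    row: int | None  # 0-based data row, None for table-level issues
    column: str
    message: str
    severity: str  # "error" | "warning"

    def __str__(self) -> str:
        where = f"row {self.row}, column '{self.column}'" if self.row is not None else f"column '{self.column}'"
        return f"[{self.severity}] {where}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]


def validate_cohort(table: pd.DataFrame) -> ValidationReport:
    """Schema validation: mandatory columns, parsability, unit ranges."""
    report = ValidationReport()
    for name, spec in COHORT_SCHEMA.items():
        if spec.required and name not in table.columns:
            report.issues.append(ValidationIssue(None, name, "mandatory column missing", "error"))
    for name, spec in COHORT_SCHEMA.items():
        if name not in table.columns or not spec.numeric:
            continue
        raw = table[name]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        for idx in np.flatnonzero(bad.to_numpy()):
            report.issues.append(
                ValidationIssue(int(idx), name, f"unparsable value {raw.iloc[idx]!r}", "error")
            )
        if spec.hard_range is not None:
            lo, hi = spec.hard_range
            out = (numeric < lo) | (numeric > hi)
            for idx in np.flatnonzero(out.to_numpy()):
                report.issues.append(
                    ValidationIssue(
                        int(idx), name,
                        f"value {numeric.iloc[idx]} outside allowed range [{lo}, {hi}] {spec.unit}",
                        "error",
                    )
                )
        if spec.warn_range is not None:
            lo, hi = spec.warn_range
            out = (numeric < lo) | (numeric > hi)
            for idx in np.flatnonzero(out.to_numpy()):
                report.issues.append(
                    ValidationIssue(
                        int(idx), name,
                        f"value {numeric.iloc[idx]} outside plausible range [{lo}, {hi}] {spec.unit}",
                        "warning",
                    )
                )
    return report


def read_cohort(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Numeric columns are typed, unknown columns preserved. The validation
    report is attached as ``df.attrs["validation"]``; warnings are emitted
    via :mod:`warnings`, and errors raise :class:`InputError` when
    ``strict`` (the default).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"cohort file not found: {path}")
    table = pd.read_csv(path, dtype=str)
    report = validate_cohort(table)
    if strict and report.errors:
        details = "; ".join(str(i) for i in report.errors[:10])
        raise InputError(f"cohort validation failed ({len(report.errors)} errors): {details}")
    for issue in report.warnings:
        warnings.warn(f"cohort validation: {issue}", stacklevel=2)
    for name, spec in COHORT_SCHEMA.items():
        if name in table.columns and spec.numeric:
            table[name] = pd.to_numeric(table[name], errors="coerce")
    table.attrs["validation"] = report
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    """Write the canonical cohort CSV (schema columns first, stable order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ordered = [c for c in COHORT_COLUMN_ORDER if c in table.columns]
    ordered += [c for c in table.columns if c not in ordered]
    table[ordered].to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# epoch matrices
# ---------------------------------------------------------------------------


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Epochs as a TSV matrix plus a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, epochs.data, delimiter="\t", fmt="%.6g")
    meta = {
        "sampling_rate": epochs.sampling_rate,
        "onset_time": epochs.onset_time,
        "accepted_mask": epochs.accepted_mask.astype(int).tolist(),
        "seed": epochs.meta.get("seed"),
    }
    if "artifact_mask" in epochs.meta:
        meta["artifact_mask"] = np.asarray(epochs.meta["artifact_mask"]).astype(int).tolist()
    Path(f"{path}.meta.json").write_text(json.dumps(meta))
    return path


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    if not path.exists():
        raise InputError(f"epoch matrix not found: {path}")
    meta_path = Path(f"{path}.meta.json")
    if not meta_path.exists():
        raise InputError(f"epoch sidecar metadata not found: {meta_path}")
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = json.loads(meta_path.read_text())
    extra = {"seed": meta.get("seed")}
    if "artifact_mask" in meta:
        extra["artifact_mask"] = np.asarray(meta["artifact_mask"], dtype=bool)
    return EpochSet(
        data=data,
        sampling_rate=float(meta["sampling_rate"]),
        onset_time=float(meta.get("onset_time", 0.0)),
        accepted_mask=np.asarray(meta["accepted_mask"], dtype=bool)
        if "accepted_mask" in meta
        else None,
        meta=extra,
    )


# ---------------------------------------------------------------------------
# deposited source data (reproduction runs)
# ---------------------------------------------------------------------------

#: canonical columns that a reproduction run cannot do without
REQUIRED_SOURCE_COLUMNS = (
    "age",
    "pta",
    "wave_v_latency",
    "wave_v_amplitude",
)


def default_column_map() -> dict:
    """Editable template mapping the workbook onto the canonical schema.

    ``sheet`` names the worksheet; ``columns`` maps canonical -> source
    header. Identity mapping by default; edit to match the actual workbook.
    """
    return {
        "sheet": 0,
        "columns": {name: name for name in COHORT_COLUMN_ORDER},
    }


def export_column_map(path: str | Path, column_map: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(column_map or default_column_map(), sort_keys=False))
    return path


def load_column_map(path: str | Path) -> dict:
    mapping = yaml.safe_load(Path(path).read_text())
    if not isinstance(mapping, dict) or "columns" not in mapping:
        raise MappingError(f"column map {path} must be a mapping with a 'columns' section")
    return mapping


def load_source_data(path: str | Path, column_map: dict | str | Path | None = None) -> pd.DataFrame:
    """Load the deposited per-participant workbook for a reproduction run.

    Maps the workbook's sheet/columns onto the canonical cohort schema via
    the column map. Required canonical columns that the map does not cover,
    or that the workbook lacks, raise :class:`MappingError` — nothing is
    guessed silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"reproduction input not found: {path} — place the deposited per-participant "
            "workbook there (the pipeline runs on synthetic data without it)"
        )
    if column_map is None:
        mapping = default_column_map()
    elif isinstance(column_map, (str, Path)):
        mapping = load_column_map(column_map)
    else:
        mapping = column_map

    raw = pd.read_excel(path, sheet_name=mapping.get("sheet", 0), engine="openpyxl")
    columns: dict[str, str] = mapping["columns"]

    unmapped = [c for c in REQUIRED_SOURCE_COLUMNS if c not in columns]
    if unmapped:
        raise MappingError(f"column map does not cover required canonical columns: {unmapped}")
    absent = [src for canon, src in columns.items()
              if canon in REQUIRED_SOURCE_COLUMNS and src not in raw.columns]
    if absent:
        raise MappingError(
            f"workbook sheet lacks mapped source columns {absent}; "
            f"available: {list(raw.columns)} — edit the column map"
        )

    out = pd.DataFrame(index=raw.index)
    for canon, src in columns.items():
        if src in raw.columns:
            out[canon] = raw[src]
    if "participant_id" not in out.columns:
        out.insert(0, "participant_id", [f"P{i + 1:03d}" for i in range(len(out))])
    for name, spec in COHORT_SCHEMA.items():
        if name in out.columns and spec.numeric:
            out[name] = pd.to_numeric(out[name], errors="coerce")
    return out
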