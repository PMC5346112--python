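"""Readers, writers and run configuration.

The interchange format is a tidy UTF-8 CSV with "." decimals and header

    survey_id,participant_id,manufacturer_code,analyte,sample_id,
    concentration_ku_l,allergen_class

where an empty field means "not reported".  Malformed rows are collected
into an error report with line numbers, never silently dropped.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .panel_model import ClassScale, DEFAULT_CLASS_SCALE, DeviceProfile, RESULT_COLUMNS

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_results",
    "write_results",
    "read_device_profiles",
    "write_device_profiles",
    "load_config",
]

PathLike = Union[str, Path]

DEVICE_COLUMNS = ["manufacturer_code", "top_calibration", "top_class"]


class SchemaError(ValueError):
    """The file does not match the documented column contract."""


@dataclass(frozen=True)
class RunConfig:
    """Evaluation thresholds; defaults are the scheme's published values."""

    min_collective_size: int = 4
    pass_band: float = 0.25
    quality_mark_pct: float = 20.0
    outlier_concentration_margin: float = 0.20
    outlier_class_margin: float = 0.5
    divergence_min_gap: float = 2.0
    class_boundaries: tuple[float, ...] = DEFAULT_CLASS_SCALE.boundaries
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_collective_size",
            "pass_band",
            "quality_mark_pct",
            "outlier_concentration_margin",
            "outlier_class_margin",
            "divergence_min_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def class_scale(self) -> ClassScale:
        return ClassScale(tuple(self.class_boundaries))


def load_config(path: Optional[PathLike]) -> RunConfig:
    """Load a YAML key-value config; missing file/keys fall back to defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
    if "class_boundaries" in raw:
        raw["class_boundaries"] = tuple(float(b) for b in raw["class_boundaries"])
    return RunConfig(**raw)


def read_results(path: PathLike) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a participant-result CSV; returns (results, error report).

    Malformed fields and row-level invariant violations land in the error
    report with their 1-based file line number and a reason.  A row with
    one unreadable numeric field keeps its other (valid) value; rows
    violating an invariant (negative concentration, neither value present)
    are removed from the results table.

    Raises
    ------
    SchemaError
        If required columns are missing.
    """
    df = pd.read_csv(
        path,
        dtype={
            "survey_id": str,
            "participant_id": str,
            "manufacturer_code": str,
            "analyte": str,
            "sample_id": str,
        },
    )
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s) in {path}: {sorted(missing)}")
    df = df[list(RESULT_COLUMNS) + [c for c in df.columns if c not in RESULT_COLUMNS]]

    errors = []
    bad_index = []
    for col in ("concentration_ku_l", "allergen_class"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        malformed = coerced.isna() & df[col].notna()
        for idx in df.index[malformed]:
            errors.append(
                {"line": int(idx) + 2, "column": col,
                 "reason": f"not a number: {df.at[idx, col]!r}"}
            )
        df[col] = coerced

    neg = df["concentration_ku_l"] < 0
    for idx in df.index[neg.fillna(False)]:
        errors.append(
            {"line": int(idx) + 2, "column": "concentration_ku_l",
             "reason": f"negative concentration: {df.at[idx, 'concentration_ku_l']}"}
        )
        bad_index.append(idx)
    both_absent = df["concentration_ku_l"].isna() & df["allergen_class"].isna()
    for idx in df.index[both_absent]:
        errors.append(
            {"line": int(idx) + 2, "column": "concentration_ku_l,allergen_class",
             "reason": "neither concentration nor class reported"}
        )
        bad_index.append(idx)

    report = pd.DataFrame(errors, columns=["line", "column", "reason"])
    clean = df.drop(index=sorted(set(bad_index))).reset_index(drop=True)
    return clean, report


def write_results(results: pd.DataFrame, path: PathLike) -> None:
    """Write a result table in the canonical column order, "." decimals."""
    out = results[RESULT_COLUMNS]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_device_profiles(path: PathLike) -> dict[str, DeviceProfile]:
    """Read a device CSV (manufacturer_code, top_calibration, top_class)."""
    df = pd.read_csv(path, dtype={"manufacturer_code": str})
    missing = set(DEVICE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s) in {path}: {sorted(missing)}")
    return {
        str(r.manufacturer_code): DeviceProfile(
            str(r.manufacturer_code), float(r.top_calibration), float(r.top_class)
        )
        for r in df.itertuples()
    }


def write_device_profiles(profiles: dict[str, DeviceProfile], path: PathLike) -> None:
    rows = [
        {
            "manufacturer_code": p.manufacturer_code,
            "top_calibration": p.top_calibration,
            "top_class": p.top_class,
        }
        for p in profiles.values()
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=DEVICE_COLUMNS).to_csv(path, index=False)
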