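"""CSV round-tripping, configuration serialisation, and run manifests.

Schemas (header order is fixed):

* ``subjects.csv``: id, sex, age, height_cm, mass_kg, chest_cm,
  waist_narrow_cm, waist_navel_cm, hips_cm, biceps_cm, thigh_cm,
  desired_mass_kg (optional; derived from the normal-BMI midpoint when blank)
* ``exams.csv``: subject_id, exam_index, day, measured_mass_kg; prediction
  output appends expected_mass_kg, phase_before, phase_after, deviation,
  flags (semicolon-joined)

All files use UTF-8, a decimal point, and a mandatory header row.  Mass
fields round-trip losslessly to 6 decimal places.  Each run writes a JSON
manifest capturing the full configuration, the seed, and a SHA-256 hash of
the configuration, so a run can be reproduced byte-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd

from .anthropometry import CIRCUMFERENCE_SITES, Subject
from .errors import InvalidInputError

__all__ = [
    "SUBJECT_COLUMNS",
    "EXAM_COLUMNS",
    "EXAM_OUTPUT_COLUMNS",
    "subjects_to_frame",
    "frame_to_subjects",
    "read_subjects",
    "write_subjects",
    "read_exams",
    "write_exams",
    "config_to_dict",
    "config_hash",
    "write_manifest",
    "read_manifest",
]

SUBJECT_COLUMNS = [
    "id", "sex", "age", "height_cm", "mass_kg",
    "chest_cm", "waist_narrow_cm", "waist_navel_cm",
    "hips_cm", "biceps_cm", "thigh_cm", "desired_mass_kg",
]

EXAM_COLUMNS = ["subject_id", "exam_index", "day", "measured_mass_kg"]

EXAM_OUTPUT_COLUMNS = EXAM_COLUMNS + [
    "expected_mass_kg", "phase_before", "phase_after", "deviation", "flags",
]

#: Mass fields are written with this many decimals (lossless round-trip).
_FLOAT_FMT = "%.6f"


def subjects_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    """Tabulate subjects in the subjects.csv schema."""
    rows = []
    for s in subjects:
        row: dict[str, Any] = {
            "id": s.id,
            "sex": s.sex,
            "age": s.age,
            "height_cm": s.height_cm,
            "mass_kg": s.initial_mass_kg,
            "desired_mass_kg": s.desired_mass_kg,
        }
        for site in CIRCUMFERENCE_SITES:
            row[f"{site}_cm"] = s.circumferences_cm.get(site)
        rows.append(row)
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)


def frame_to_subjects(frame: pd.DataFrame) -> list[Subject]:
    """Build Subject objects from a subjects.csv-schema frame.

    Blank ``desired_mass_kg`` cells are derived from the normal-BMI band.
    """
    missing = [c for c in SUBJECT_COLUMNS[:5] if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"subjects table is missing columns: {missing}")
    subjects = []
    for _, row in frame.iterrows():
        circ = {}
        for site in CIRCUMFERENCE_SITES:
            col = f"{site}_cm"
            if col in frame.columns and pd.notna(row[col]):
                circ[site] = float(row[col])
        wd = row.get("desired_mass_kg")
        subjects.append(
            Subject(
                id=str(row["id"]),
                sex=str(row["sex"]),
                age=int(row["age"]),
                height_cm=float(row["height_cm"]),
                initial_mass_kg=float(row["mass_kg"]),
                desired_mass_kg=float(wd) if pd.notna(wd) else None,
                circumferences_cm=circ,
            )
        )
    return subjects


def write_subjects(subjects: list[Subject], path: str | Path) -> None:
    subjects_to_frame(subjects).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_subjects(path: str | Path) -> list[Subject]:
    return frame_to_subjects(pd.read_csv(path))


def write_exams(frame: pd.DataFrame, path: str | Path,
                columns: list[str] | None = None) -> None:
    """Write examination records, defaulting to the columns present."""
    if columns is not None:
        missing = [c for c in columns if c not in frame.columns]
        if missing:
            raise InvalidInputError(f"exam table is missing columns: {missing}")
        frame = frame[columns]
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_exams(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in EXAM_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing exam columns {missing}")
    return frame


def config_to_dict(config: Any) -> Any:
    """Recursively serialise (nested) dataclass configurations to plain JSON types."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        return {f.name: config_to_dict(getattr(config, f.name))
                for f in dataclasses.fields(config)}
    if isinstance(config, dict):
        return {k: config_to_dict(v) for k, v in config.items()}
    if isinstance(config, (list, tuple)):
        return [config_to_dict(v) for v in config]
    if isinstance(config, frozenset):
        return sorted(config)
    return config


def config_hash(config: Any) -> str:
    """SHA-256 of the canonical JSON serialisation of a configuration."""
    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_manifest(path: str | Path, **configs: Any) -> dict:
    """Write a JSON run manifest with each config and its hash."""
    body = {name: config_to_dict(cfg) for name, cfg in configs.items()}
    manifest = {
        "configs": body,
        "config_hash": hashlib.sha256(
            json.dumps(body, sort_keys=True).encode()
        ).hexdigest(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
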