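"""Landmark JSON and tidy rating-table I/O.

Landmark files are JSON with one object per case::

    {
      "case_id": "S01-T0",
      "arches": [
        {"arch": "upper",
         "teeth": [{"fdi": 11, "landmarks": [{"name": "incisal_edge",
                                              "xyz_mm": [0.0, 43.0, -2.5]}]}],
         "flags": {"13": ["impacted"]}},
        {"arch": "lower", ...}
      ]
    }

The reader validates against this schema and reports *every* violation it
finds, not just the first.  Rating tables are CSV with the canonical columns
``subject,timepoint,method,rater,session,trait,value`` in any order.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .agreement import RATING_COLUMNS
from .geometry import ArchLandmarks, CASE_FLAGS, Landmark, LANDMARK_NAMES, VALID_FDI


def write_landmarks(path, upper: ArchLandmarks, lower: ArchLandmarks, case_id: str) -> None:
    """Serialise an arch pair to the landmark JSON schema (full precision)."""
    doc = {"case_id": case_id, "arches": []}
    for arch in (upper, lower):
        teeth = {}
        for lm in arch.landmarks:
            teeth.setdefault(lm.tooth_id, []).append(
                {"name": lm.name, "xyz_mm": [float(c) for c in lm.position]}
            )
        doc["arches"].append(
            {
                "arch": arch.arch,
                "teeth": [
                    {"fdi": fdi, "landmarks": lms} for fdi, lms in sorted(teeth.items())
                ],
                "flags": {str(fdi): sorted(fl) for fdi, fl in sorted(arch.case_flags.items())},
            }
        )
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def _parse_arch(obj, where: str, errors: list[str]) -> ArchLandmarks | None:
    arch = obj.get("arch")
    if arch not in ("upper", "lower"):
        errors.append(f"{where}: arch must be 'upper'/'lower', got {arch!r}")
        return None
    landmarks: list[Landmark] = []
    present: set[int] = set()
    seen: set[tuple[int, str]] = set()
    for i, tooth in enumerate(obj.get("teeth", [])):
        fdi = tooth.get("fdi")
        twhere = f"{where}.teeth[{i}]"
        if not isinstance(fdi, int) or fdi not in VALID_FDI:
            errors.append(f"{twhere}: invalid FDI code {fdi!r}")
            continue
        present.add(fdi)
        for j, lm in enumerate(tooth.get("landmarks", [])):
            name = lm.get("name")
            xyz = lm.get("xyz_mm")
            lwhere = f"{twhere}.landmarks[{j}]"
            if name not in LANDMARK_NAMES:
                errors.append(f"{lwhere}: unknown landmark name {name!r}")
                continue
            if (fdi, name) in seen:
                errors.append(f"{lwhere}: duplicate landmark ({fdi}, {name})")
                continue
            if not (isinstance(xyz, list) and len(xyz) == 3):
                errors.append(f"{lwhere}: xyz_mm must be a 3-element list, got {xyz!r}")
                continue
            seen.add((fdi, name))
            landmarks.append(Landmark(fdi, name, xyz))
    flags = {}
    for key, fl in (obj.get("flags") or {}).items():
        try:
            fdi = int(key)
        except (TypeError, ValueError):
            errors.append(f"{where}.flags: non-integer tooth key {key!r}")
            continue
        bad = set(fl) - CASE_FLAGS
        if bad:
            errors.append(f"{where}.flags[{key}]: unknown flags {sorted(bad)}")
            continue
        flags[fdi] = set(fl)
        present.add(fdi)
    if errors:
        return None
    return ArchLandmarks(arch, landmarks, present, flags)


def read_landmarks(path) -> tuple[ArchLandmarks, ArchLandmarks, str]:
    """Load and validate a landmark file; returns (upper, lower, case_id)."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError([f"{path}: not valid JSON ({exc})"]) from exc
    errors: list[str] = []
    arches = doc.get("arches")
    if not isinstance(arches, list) or len(arches) != 2:
        raise SchemaError([f"{path}: 'arches' must list exactly the upper and lower arch"])
    parsed = {}
    for i, obj in enumerate(arches):
        arch = _parse_arch(obj, f"{path}:arches[{i}]", errors)
        if arch is not None:
            parsed[arch.arch] = arch
    if errors:
        raise SchemaError(errors)
    if set(parsed) != {"upper", "lower"}:
        raise SchemaError([f"{path}: need one upper and one lower arch, got {sorted(parsed)}"])
    return parsed["upper"], parsed["lower"], str(doc.get("case_id", Path(path).stem))


def write_ratings(path, records: pd.DataFrame) -> None:
    """Write the tidy rating table with stable canonical column order."""
    records[list(RATING_COLUMNS)].to_csv(path, index=False)


def read_ratings(path) -> pd.DataFrame:
    """Read a rating CSV; columns may appear in any order."""
    df = pd.read_csv(path)
    missing = set(RATING_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError([f"{path}: rating table missing columns {sorted(missing)}"])
    return df[list(RATING_COLUMNS)]
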