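"""Landmark table readers/writers (CSV and JSON dialects).

CSV dialect: header ``name,x_mm,y_mm,z_mm,present``, one row per landmark,
positions in world millimetres.  Landmarks absent from the file are marked
not-present.  The JSON dialect is
``{"subject_id": ..., "landmarks": {name: {"position_mm": [x, y, z],
"present": bool}, ...}}``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .landmarks import LANDMARK_INDEX, N_LANDMARKS, ALL_LANDMARKS, LandmarkSet

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(text: str, path: Path, line: int) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"{path}:{line}: malformed 'present' value {text!r}")


def read_landmarks(path: str | Path, subject_id: str | None = None) -> LandmarkSet:
    """Read a landmark table (.csv or .json) into a :class:`LandmarkSet`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_json(path, subject_id)
    return _read_csv(path, subject_id)


def _read_csv(path: Path, subject_id: str | None) -> LandmarkSet:
    coords = np.full((N_LANDMARKS, 3), np.nan)
    present = np.zeros(N_LANDMARKS, dtype=bool)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty landmark file") from None
        expected = ["name", "x_mm", "y_mm", "z_mm", "present"]
        if [h.strip() for h in header] != expected:
            raise ValueError(
                f"{path}:1: expected header {','.join(expected)}, got {','.join(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
            name = row[0].strip()
            if name not in LANDMARK_INDEX:
                raise ValueError(f"{path}:{lineno}: unknown landmark name {name!r}")
            if not _parse_bool(row[4], path, lineno):
                continue
            try:
                pos = [float(c) for c in row[1:4]]
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed coordinates {row[1:4]!r}"
                ) from None
            i = LANDMARK_INDEX[name]
            coords[i] = pos
            present[i] = True
    return LandmarkSet(subject_id or path.stem, coords, present)


def _read_json(path: Path, subject_id: str | None) -> LandmarkSet:
    with open(path) as fh:
        payload = json.load(fh)
    coords = np.full((N_LANDMARKS, 3), np.nan)
    present = np.zeros(N_LANDMARKS, dtype=bool)
    for name, entry in payload.get("landmarks", {}).items():
        if name not in LANDMARK_INDEX:
            raise ValueError(f"{path}: unknown landmark name {name!r}")
        if not entry.get("present", True):
            continue
        i = LANDMARK_INDEX[name]
        coords[i] = np.asarray(entry["position_mm"], dtype=float)
        present[i] = True
    sid = subject_id or payload.get("subject_id") or path.stem
    return LandmarkSet(sid, coords, present)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    """Write a landmark table; format chosen by suffix (.csv or .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "subject_id": landmarks.subject_id,
            "landmarks": {
                name: {
                    "position_mm": [float(c) for c in landmarks.coords[i]],
                    "present": True,
                }
                for i, name in enumerate(ALL_LANDMARKS)
                if landmarks.present[i]
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x_mm", "y_mm", "z_mm", "present"])
        for i, name in enumerate(ALL_LANDMARKS):
            if landmarks.present[i]:
                x, y, z = landmarks.coords[i]
                writer.writerow([name, repr(float(x)), repr(float(y)), repr(float(z)), "true"])
            else:
                writer.writerow([name, "", "", "", "false"])


def read_cohort_dir(directory: str | Path) -> list[LandmarkSet]:
    """Read every landmark file (*.csv, *.json) in a directory, sorted."""
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in {".csv", ".json"} and p.name != "manifest.json"
    )
    if not files:
        raise FileNotFoundError(f"no landmark files found in {directory}")
    return [read_landmarks(p) for p in files]
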