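"""Plain-text readers/writers for head points, fiducials, sensors, layouts.

Formats
-------
* Head points: whitespace- or comma-delimited text with three numeric
  columns (x y z, mm); an optional single header line is skipped.
* Fiducials: JSON object ``{"NAS": [x,y,z], ...}`` or a labelled TSV with
  rows ``label<TAB>x<TAB>y<TAB>z``.
* Sensors: TSV/CSV with columns label, x, y, z (header optional).
* Layouts: FieldTrip-style ``.lay`` text (``index x y width height label``)
  or JSON carrying eccentricity/angle/xy per channel plus outline metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .mesh import FIDUCIAL_LABELS
from .projection import Layout2D, SensorLocation2D


def _split(line: str) -> list[str]:
    line = line.strip()
    if "," in line:
        return [tok.strip() for tok in line.split(",") if tok.strip()]
    return line.split()


def read_head_points(path) -> np.ndarray:
    """Three numeric columns; an optional non-numeric header line is skipped."""
    rows = []
    for ln, raw in enumerate(Path(path).read_text().splitlines()):
        toks = _split(raw)
        if not toks or raw.lstrip().startswith("#"):
            continue
        try:
            vals = [float(t) for t in toks]
        except ValueError:
            if ln == 0 or not rows:
                continue  # header
            raise InputError(f"{path}: non-numeric row {ln + 1}: {raw!r}")
        if len(vals) < 3:
            raise InputError(f"{path}: row {ln + 1} has fewer than 3 columns")
        rows.append(vals[:3])
    if not rows:
        raise InputError(f"{path}: no numeric point rows found")
    return np.asarray(rows, dtype=float)


def write_head_points(path, points: np.ndarray) -> None:
    points = np.asarray(points, dtype=float)
    lines = ["x\ty\tz"]
    lines += [f"{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}" for p in points]
    Path(path).write_text("\n".join(lines) + "\n")


def read_fiducials(path) -> dict[str, np.ndarray]:
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        raw = json.loads(text)
        out = {}
        for k, v in raw.items():
            if k not in FIDUCIAL_LABELS:
                raise InputError(f"{path}: unknown fiducial label {k!r}")
            out[k] = np.asarray(v, dtype=float).reshape(3)
        return out
    out = {}
    for ln, raw_line in enumerate(text.splitlines()):
        toks = _split(raw_line)
        if not toks:
            continue
        if len(toks) != 4:
            raise InputError(f"{path}: fiducial row {ln + 1} must be 'label x y z'")
        label = toks[0]
        if label not in FIDUCIAL_LABELS:
            raise InputError(f"{path}: unknown fiducial label {label!r}")
        out[label] = np.asarray([float(t) for t in toks[1:]], dtype=float)
    if not out:
        raise InputError(f"{path}: no fiducials found")
    return out


def write_fiducials(path, fiducials: dict) -> None:
    payload = {k: [float(x) for x in np.asarray(v).reshape(3)] for k, v in fiducials.items()}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_sensors(path) -> pd.DataFrame:
    rows = []
    for ln, raw in enumerate(Path(path).read_text().splitlines()):
        toks = _split(raw)
        if not toks or raw.lstrip().startswith("#"):
            continue
        if len(toks) < 4:
            raise InputError(f"{path}: sensor row {ln + 1} needs 'label x y z'")
        try:
            xyz = [float(t) for t in toks[1:4]]
        except ValueError:
            if not rows:
                continue  # header line
            raise InputError(f"{path}: non-numeric coordinates on row {ln + 1}")
        rows.append({"label": toks[0], "x": xyz[0], "y": xyz[1], "z": xyz[2]})
    if not rows:
        raise InputError(f"{path}: no sensor rows found")
    return pd.DataFrame(rows)


def write_sensors(path, sensors: pd.DataFrame) -> None:
    lines = ["label\tx\ty\tz"]
    for row in sensors.itertuples(index=False):
        lines.append(f"{row.label}\t{row.x:.6f}\t{row.y:.6f}\t{row.z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_lay(path, layout: Layout2D, width: float = 0.08, height: float = 0.08) -> None:
    """FieldTrip-style .lay: ``index x y width height label``, 6 decimals, LF."""
    lines = []
    for i, (label, ch) in enumerate(layout.channels.items(), start=1):
        lines.append(
            f"{i} {ch.xy[0]:.6f} {ch.xy[1]:.6f} {width:.6f} {height:.6f} {label}"
        )
    Path(path).write_text("\n".join(lines) + "\n", newline="\n")


def read_lay(path) -> Layout2D:
    channels = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines()):
        toks = raw.split()
        if not toks:
            continue
        if len(toks) < 6:
            raise InputError(f"{path}: .lay row {ln + 1} needs 6 fields")
        x, y = float(toks[1]), float(toks[2])
        label = " ".join(toks[5:])
        ecc = float(np.hypot(x, y))
        ang = float(np.mod(np.rad2deg(np.arctan2(y, x)), 360.0))
        channels[label] = SensorLocation2D(
            label=label, eccentricity=ecc, angle=ang, xy=np.array([x, y])
        )
    if not channels:
        raise InputError(f"{path}: empty layout file")
    return Layout2D(channels=channels)


def write_layout_json(path, layout: Layout2D) -> None:
    payload = {
        "outline": layout.outline,
        "channels": {
            label: {
                "eccentricity": ch.eccentricity,
                "angle": ch.angle,
                "x": float(ch.xy[0]),
                "y": float(ch.xy[1]),
            }
            for label, ch in layout.channels.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", newline="\n")


def read_layout_json(path) -> Layout2D:
    raw = json.loads(Path(path).read_text())
    channels = {}
    for label, ch in raw["channels"].items():
        channels[label] = SensorLocation2D(
            label=label,
            eccentricity=float(ch["eccentricity"]),
            angle=float(ch["angle"]),
            xy=np.array([float(ch["x"]), float(ch["y"])]),
        )
    return Layout2D(channels=channels, outline=raw.get("outline", {}))


def read_values(path) -> pd.Series:
    """Per-channel scalar values: CSV/TSV rows ``label,value``."""
    out = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines()):
        toks = _split(raw)
        if not toks:
            continue
        if len(toks) < 2:
            raise InputError(f"{path}: value row {ln + 1} needs 'label value'")
        try:
            out[toks[0]] = float(toks[1])
        except ValueError:
            if not out:
                continue
            raise InputError(f"{path}: non-numeric value on row {ln + 1}")
    if not out:
        raise InputError(f"{path}: no values found")
    return pd.Series(out, name="value")
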