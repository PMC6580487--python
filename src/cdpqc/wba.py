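"""Whole-body autoradiography calibration: linear standard curve and the
raw-signal -> decays-per-minute (dpm) transform."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class StandardCurve:
    slope: float        # dpm per raw-signal unit
    intercept: float    # dpm
    r_squared: float
    n_standards: int


@dataclass(frozen=True)
class TissueMeasurement:
    tissue: str
    raw_signal: float
    dpm: float | None = None
    flags: tuple[str, ...] = ()


def fit_standard_curve(standards: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of known dpm on raw signal.

    ``standards`` are (raw_signal, known_dpm) pairs; at least two with
    non-identical raw signals are required.
    """
    if len(standards) < 2:
        raise ValueError(f"need >= 2 standards, got {len(standards)}")
    raw = np.asarray([s[0] for s in standards], dtype=float)
    dpm = np.asarray([s[1] for s in standards], dtype=float)
    if np.ptp(raw) == 0:
        raise ValueError("standards have zero variance in raw_signal")
    fit = stats.linregress(raw, dpm)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_standards=len(standards),
    )


def to_dpm(
    measurements: Sequence[TissueMeasurement], curve: StandardCurve
) -> list[TissueMeasurement]:
    """Transform raw tissue signals through the standard curve.

    dpm = slope * raw + intercept; a negative prediction is clamped to 0
    and flagged ``below_curve`` (radioactivity cannot be negative).
    """
    out: list[TissueMeasurement] = []
    for m in measurements:
        dpm = curve.slope * m.raw_signal + curve.intercept
        flags = m.flags
        if dpm < 0:
            dpm = 0.0
            flags = flags + ("below_curve",)
        out.append(TissueMeasurement(tissue=m.tissue, raw_signal=m.raw_signal,
                                     dpm=dpm, flags=flags))
    return out


def read_standards(path: str | Path) -> list[tuple[float, float]]:
    """CSV with columns raw_signal,known_dpm (id column optional)."""
    path = Path(path)
    standards: list[tuple[float, float]] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"raw_signal", "known_dpm"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns raw_signal,known_dpm")
        for row in reader:
            standards.append((float(row["raw_signal"]), float(row["known_dpm"])))
    return standards


def read_tissues(path: str | Path) -> list[TissueMeasurement]:
    """CSV with columns tissue,raw_signal."""
    path = Path(path)
    out: list[TissueMeasurement] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"tissue", "raw_signal"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns tissue,raw_signal")
        for row in reader:
            out.append(TissueMeasurement(tissue=row["tissue"],
                                         raw_signal=float(row["raw_signal"])))
    return out


def write_tissues(measurements: Sequence[TissueMeasurement], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tissue", "raw_signal", "dpm", "flags"])
        for m in measurements:
            writer.writerow([m.tissue, m.raw_signal,
                             "" if m.dpm is None else m.dpm, ";".join(m.flags)])


__all__ = [
    "StandardCurve",
    "TissueMeasurement",
    "fit_standard_curve",
    "to_dpm",
    "read_standards",
    "read_tissues",
    "write_tissues",
]
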