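"""Chromatogram trace data types, delimited-text I/O, and batch layout.

A trace is a retention-time-ordered series of (RT, absorbance) points with a
sample identity and a treatment label. Batches are ordered injection lists in
which a blank run is interleaved ahead of groups of intact/reduced sample
pairs; each pair is normalized against the most recent preceding blank.
"""

from __future__ import annotations

import csv
import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np


class Treatment(str, enum.Enum):
    BLANK = "blank"
    INTACT = "intact"
    REDUCED = "reduced"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TraceError(ValueError):
    """Invalid trace data or trace file."""


class FilenameParseError(ValueError):
    """Filename does not match the configured naming convention."""


class LayoutError(ValueError):
    """Batch run list violates the pairing/blank preconditions."""


@dataclass(frozen=True)
class Trace:
    """A UV-absorbance chromatogram trace.

    Parameters
    ----------
    sample_id : str
        Identifier of the injected sample (or blank).
    treatment : Treatment
        One of blank / intact / reduced.
    rt : numpy.ndarray
        Retention times in minutes, strictly increasing, length >= 2.
    absorbance : numpy.ndarray
        Absorbance values (mAU assumed), same length as ``rt``.
    """

    sample_id: str
    treatment: Treatment
    rt: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        rt = np.asarray(self.rt, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "absorbance", ab)
        if rt.ndim != 1 or ab.ndim != 1:
            raise TraceError("rt and absorbance must be one-dimensional")
        if rt.size < 2:
            raise TraceError("trace needs at least 2 points")
        if rt.size != ab.size:
            raise TraceError(
                f"rt ({rt.size}) and absorbance ({ab.size}) lengths differ"
            )
        if not (np.all(np.isfinite(rt)) and np.all(np.isfinite(ab))):
            raise TraceError("trace contains non-finite values")
        if not np.all(np.diff(rt) > 0):
            raise TraceError("retention times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.rt.size)

    @property
    def rt_step(self) -> float:
        """Median grid step, in minutes."""
        return float(np.median(np.diff(self.rt)))


DIALECT_DELIMITERS = {"simple_csv": ",", "tsv": "\t"}


def read_trace(
    path: str | Path,
    dialect: str = "simple_csv",
    sample_id: str | None = None,
    treatment: Treatment | str | None = None,
) -> Trace:
    """Read a two-column (RT, absorbance) delimited text file.

    An optional single header line is tolerated. When ``sample_id`` or
    ``treatment`` are omitted they are recovered from the filename via
    :func:`parse_trace_filename`; a blank treatment is assumed if the
    filename does not match either.
    """
    path = Path(path)
    if dialect not in DIALECT_DELIMITERS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    delim = DIALECT_DELIMITERS[dialect]

    rts: list[float] = []
    abs_: list[float] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise TraceError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            try:
                rt = float(row[0])
                ab = float(row[1])
            except ValueError:
                if lineno == 1:  # optional header line
                    continue
                raise TraceError(f"{path}:{lineno}: non-numeric row {row!r}") from None
            if not (math.isfinite(rt) and math.isfinite(ab)):
                raise TraceError(f"{path}:{lineno}: non-finite value")
            rts.append(rt)
            abs_.append(ab)

    if len(rts) < 2:
        raise TraceError(f"{path}: fewer than 2 data points")

    if sample_id is None or treatment is None:
        try:
            sid, trt = parse_trace_filename(path.name)
        except FilenameParseError:
            sid, trt = path.stem, Treatment.BLANK
        sample_id = sample_id if sample_id is not None else sid
        treatment = treatment if treatment is not None else trt
    return Trace(
        sample_id=sample_id,
        treatment=Treatment(treatment),
        rt=np.array(rts),
        absorbance=np.array(abs_),
    )


def write_trace(trace: Trace, path: str | Path, dialect: str = "simple_csv") -> None:
    """Serialize a trace back to two-column delimited text (full precision)."""
    if dialect not in DIALECT_DELIMITERS:
        raise ValueError(f"unknown dialect {dialect!r}")
    delim = DIALECT_DELIMITERS[dialect]
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        for rt, ab in zip(trace.rt, trace.absorbance):
            writer.writerow([repr(float(rt)), repr(float(ab))])


# Default naming convention: <sampleid>_<TOKEN>.<ext>, TOKEN in
# {INTACT, DTT, BLANK} (case-insensitive).
DEFAULT_FILENAME_PATTERN = (
    r"^(?P<sample_id>.+)_(?P<treatment>INTACT|DTT|BLANK)\.[^.]+$"
)
_TREATMENT_TOKENS = {
    "INTACT": Treatment.INTACT,
    "DTT": Treatment.REDUCED,
    "BLANK": Treatment.BLANK,
}


def parse_trace_filename(
    name: str, pattern: str = DEFAULT_FILENAME_PATTERN
) -> tuple[str, Treatment]:
    """Extract (sample_id, treatment) from a chromatogram filename.

    ``pattern`` is a regex with named groups ``sample_id`` and ``treatment``;
    the treatment token is matched case-insensitively. A non-matching name
    raises :class:`FilenameParseError` (never a silent skip).
    """
    m = re.match(pattern, name, flags=re.IGNORECASE)
    if m is None:
        raise FilenameParseError(f"filename {name!r} does not match the naming convention")
    token = m.group("treatment").upper()
    treatment = _TREATMENT_TOKENS.get(token)
    if treatment is None:
        try:
            treatment = Treatment(token.lower())
        except ValueError:
            raise FilenameParseError(
                f"unknown treatment token {token!r} in filename {name!r}"
            ) from None
    return m.group("sample_id"), treatment


@dataclass(frozen=True)
class RunRecord:
    run_index: int
    sample_id: str
    treatment: Treatment
    path: Path | None = None


@dataclass(frozen=True)
class PairAssignment:
    intact: RunRecord
    reduced: RunRecord
    blank: RunRecord


@dataclass(frozen=True)
class BatchLayout:
    """Injection-ordered run list with blank assignments per sample pair."""

    runs: tuple[RunRecord, ...]
    pair_assignments: Mapping[str, PairAssignment] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.pair_assignments)


def build_batch_layout(runs: Sequence[RunRecord]) -> BatchLayout:
    """Pair up intact/reduced runs and assign each pair its preceding blank.

    The assigned blank is the most recent blank whose run index strictly
    precedes the *earlier* member of the pair; the blank may not fall between
    the pair's two injections.
    """
    runs = tuple(sorted(runs, key=lambda r: r.run_index))
    seen_indices = [r.run_index for r in runs]
    if len(set(seen_indices)) != len(seen_indices):
        raise LayoutError("duplicate run_index in run list")

    by_sample: dict[str, dict[Treatment, RunRecord]] = {}
    blanks: list[RunRecord] = []
    for run in runs:
        if run.treatment is Treatment.BLANK:
            blanks.append(run)
            continue
        slot = by_sample.setdefault(run.sample_id, {})
        if run.treatment in slot:
            raise LayoutError(
                f"sample {run.sample_id!r} has duplicate {run.treatment.value} runs"
            )
        slot[run.treatment] = run

    assignments: dict[str, PairAssignment] = {}
    for sample_id, slot in by_sample.items():
        missing = {Treatment.INTACT, Treatment.REDUCED} - set(slot)
        if missing:
            raise LayoutError(
                f"sample {sample_id!r} missing treatment(s): "
                + ", ".join(sorted(t.value for t in missing))
            )
        intact, reduced = slot[Treatment.INTACT], slot[Treatment.REDUCED]
        first_idx = min(intact.run_index, reduced.run_index)
        preceding = [b for b in blanks if b.run_index < first_idx]
        if not preceding:
            raise LayoutError(f"sample {sample_id!r} has no preceding blank run")
        blank = max(preceding, key=lambda b: b.run_index)
        assignments[sample_id] = PairAssignment(intact=intact, reduced=reduced, blank=blank)

    ordered = dict(
        sorted(
            assignments.items(),
            key=lambda kv: min(kv[1].intact.run_index, kv[1].reduced.run_index),
        )
    )
    return BatchLayout(runs=runs, pair_assignments=ordered)


def read_manifest(path: str | Path, dialect: str = "simple_csv") -> list[RunRecord]:
    """Read a batch manifest CSV (run_index,sample_id,treatment,path)."""
    path = Path(path)
    delim = DIALECT_DELIMITERS.get(dialect, ",")
    records: list[RunRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        required = {"run_index", "sample_id", "treatment"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise LayoutError(
                f"manifest {path} must have columns run_index,sample_id,treatment[,path]"
            )
        for row in reader:
            trace_path = row.get("path") or None
            records.append(
                RunRecord(
                    run_index=int(row["run_index"]),
                    sample_id=row["sample_id"],
                    treatment=Treatment(row["treatment"].strip().lower()),
                    path=Path(trace_path) if trace_path else None,
                )
            )
    return records


def write_manifest(runs: Iterable[RunRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["run_index", "sample_id", "treatment", "path"])
        for run in runs:
            writer.writerow(
                [run.run_index, run.sample_id, run.treatment.value,
                 "" if run.path is None else str(run.path)]
            )
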