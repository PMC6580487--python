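"""Four-category quality classification of intact/reduced trace pairs.

Category semantics (counts include shoulder peaks):

* ``Complex``  — either trace shows more peaks than the -Classification bound.
* ``Perfect``  — one peak per trace and the reduced apex is shifted beyond
  the overlap tolerance (disulfides formed, fully reduced by DTT).
* ``PerfectPartial`` — one intact peak, two reduced peaks of which exactly
  one overlaps the intact apex (partial reduction).
* ``Simple``   — everything else, with diagnostic flags for the notable
  residual cases (no shift, empty peak lists).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .peaks import Peak, PeakParams, find_all_peaks
from .preprocess import estimate_noise, subtract_blank
from .trace_model import BatchLayout, Trace


class Category(str, enum.Enum):
    PERFECT = "Perfect"
    PERFECT_PARTIAL = "PerfectPartial"
    SIMPLE = "Simple"
    COMPLEX = "Complex"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ClassifyParams:
    """overlap_tol: max apex-RT distance (min) for two peaks to overlap;
    simple_max_peaks: the -Classification peak-count bound for Simple."""

    overlap_tol: float = 0.1
    simple_max_peaks: int = 2

    def __post_init__(self) -> None:
        if not self.overlap_tol > 0:
            raise ValueError("overlap_tol must be > 0")
        if self.simple_max_peaks < 2:
            raise ValueError("simple_max_peaks must be >= 2")


@dataclass(frozen=True)
class PairClassification:
    sample_id: str
    category: Category
    n_peaks_intact: int
    n_peaks_reduced: int
    shift_detected: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class PairError:
    """Per-sample failure record; the batch run continues past it."""

    sample_id: str
    message: str


@dataclass(frozen=True)
class BatchResult:
    classifications: list[PairClassification] = field(default_factory=list)
    errors: list[PairError] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def classify_pair(
    intact_peaks: Sequence[Peak],
    reduced_peaks: Sequence[Peak],
    params: ClassifyParams,
    sample_id: str = "",
) -> PairClassification:
    """Apply the decision rule to one intact/reduced peak-list pair.

    The rule is total: every pair of finite peak lists maps to exactly one
    category. Precedence is Complex, Perfect, PerfectPartial, then Simple
    as the residual class.
    """
    n_i, n_r = len(intact_peaks), len(reduced_peaks)
    flags: list[str] = []
    shift_detected = False

    if max(n_i, n_r) > params.simple_max_peaks:
        category = Category.COMPLEX
    elif n_i == 1 and n_r == 1:
        shift = abs(reduced_peaks[0].apex_rt - intact_peaks[0].apex_rt)
        if shift > params.overlap_tol:
            category = Category.PERFECT
            shift_detected = True
        else:
            category = Category.SIMPLE
            flags.append("no_reduction_shift")
    elif n_i == 1 and n_r == 2:
        overlaps = [
            p for p in reduced_peaks
            if abs(p.apex_rt - intact_peaks[0].apex_rt) <= params.overlap_tol
        ]
        if len(overlaps) == 1:
            category = Category.PERFECT_PARTIAL
            shifted = [p for p in reduced_peaks if p is not overlaps[0]]
            shift_detected = any(
                abs(p.apex_rt - intact_peaks[0].apex_rt) > params.overlap_tol
                for p in shifted
            )
        else:
            category = Category.SIMPLE
    else:
        category = Category.SIMPLE

    if category is Category.SIMPLE and (n_i == 0 or n_r == 0):
        flags.append("no_peaks")
    return PairClassification(
        sample_id=sample_id,
        category=category,
        n_peaks_intact=n_i,
        n_peaks_reduced=n_r,
        shift_detected=shift_detected,
        flags=tuple(flags),
    )


TraceStore = Mapping[int, Trace] | Callable[[int], Trace]


def _resolve(traces: TraceStore, run_index: int) -> Trace:
    if callable(traces):
        return traces(run_index)
    return traces[run_index]


def classify_batch(
    layout: BatchLayout,
    traces: TraceStore,
    peak_params: PeakParams,
    classify_params: ClassifyParams,
) -> BatchResult:
    """Classify every sample pair in a batch layout.

    For each pair: subtract its assigned blank from both members, estimate
    noise on each normalized trace (peak-free flanks), detect peaks plus
    shoulders, classify. A trace that cannot be loaded produces a
    :class:`PairError` record and the batch continues. Deterministic for
    fixed inputs and parameters.
    """
    result = BatchResult()
    window = (peak_params.min_rt, peak_params.max_rt)
    for sample_id, pair in layout.pair_assignments.items():
        try:
            blank = _resolve(traces, pair.blank.run_index)
            peak_lists = {}
            for member in (pair.intact, pair.reduced):
                sample = _resolve(traces, member.run_index)
                normalized = subtract_blank(sample, blank)
                sigma = estimate_noise(normalized, region="auto", peak_window=window)
                peak_lists[member.treatment] = find_all_peaks(
                    normalized, peak_params, sigma
                )
        except Exception as exc:  # per-sample isolation is the contract
            result.errors.append(PairError(sample_id=sample_id, message=str(exc)))
            continue
        result.classifications.append(
            classify_pair(
                peak_lists[pair.intact.treatment],
                peak_lists[pair.reduced.treatment],
                classify_params,
                sample_id=sample_id,
            )
        )
    return result


def write_report(result: BatchResult, path: str | Path) -> None:
    """Batch report CSV: one row per classified sample."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "category", "n_peaks_intact", "n_peaks_reduced",
             "shift_detected", "flags"]
        )
        for c in result.classifications:
            writer.writerow(
                [c.sample_id, c.category.value, c.n_peaks_intact,
                 c.n_peaks_reduced, c.shift_detected, ";".join(c.flags)]
            )


__all__ = [
    "Category",
    "ClassifyParams",
    "PairClassification",
    "PairError",
    "BatchResult",
    "classify_pair",
    "classify_batch",
    "write_report",
]
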