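"""SNR-gated peak detection with shoulder-peak flagging.

Detection is moving-average smoothing followed by a discrete local-maximum
search gated on prominence and apex height, both expressed as multiples of
the baseline noise sigma. Partially resolved secondary maxima whose
separating valley stays high relative to the adjacent apexes are retained
and flagged as shoulders; they count toward the peak total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .trace_model import Trace

# Relative prominence floor replacing the SNR gate on noise-free input.
_EPS_FRAC = 1e-9


@dataclass(frozen=True)
class Peak:
    """One detected elution peak."""

    apex_rt: float
    apex_height: float
    left_rt: float
    right_rt: float
    is_shoulder: bool = False

    def __post_init__(self) -> None:
        if not (self.left_rt <= self.apex_rt <= self.right_rt):
            raise ValueError("peak boundaries must bracket the apex")
        if not self.apex_height > 0:
            raise ValueError("apex_height must be positive")


@dataclass(frozen=True)
class PeakParams:
    """Detection parameters.

    sn : signal-to-noise threshold (the -SN parameter).
    min_rt, max_rt : peak-search window in minutes (-MinRTForPeak /
        -MaxRTForPeak).
    smooth_window : moving-average width in points, odd.
    shoulder_valley_frac : a secondary maximum is a shoulder when the valley
        separating it from its neighbour stays at or above this fraction of
        the smaller adjacent apex height.
    """

    sn: float = 10.0
    min_rt: float = 5.0
    max_rt: float = 12.0
    smooth_window: int = 5
    shoulder_valley_frac: float = 0.7

    def __post_init__(self) -> None:
        if not self.sn > 0:
            raise ValueError("sn must be > 0")
        if not self.min_rt < self.max_rt:
            raise ValueError("min_rt must be < max_rt")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if not 0 < self.shoulder_valley_frac <= 1:
            raise ValueError("shoulder_valley_frac must be in (0, 1]")


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    kernel = np.ones(window) / window
    # reflect-pad so the peak apex is not pulled toward the edges
    pad = window // 2
    padded = np.pad(values, pad, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


@dataclass(frozen=True)
class _Candidate:
    index: int          # apex index on the unsmoothed grid
    height: float       # unsmoothed apex height
    smooth_height: float
    prominence: float
    left_base: int
    right_base: int


def _find_candidates(trace: Trace, params: PeakParams) -> tuple[list[_Candidate], np.ndarray]:
    """All local maxima of the smoothed trace inside the RT window."""
    y = trace.absorbance
    ys = _smooth(y, params.smooth_window)
    max_height = float(np.max(ys)) if ys.size else 0.0
    floor = max(_EPS_FRAC * max(max_height, 1.0), np.finfo(float).tiny)
    idx, props = find_peaks(ys, prominence=floor, plateau_size=(1, None))
    candidates: list[_Candidate] = []
    for k, i in enumerate(idx):
        # plateau maxima: report the midpoint
        le, re_ = int(props["left_edges"][k]), int(props["right_edges"][k])
        apex = (le + re_) // 2
        lb, rb = int(props["left_bases"][k]), int(props["right_bases"][k])
        # apex refined to the unsmoothed maximum within the smoothed support
        # (kept at the plateau midpoint when the raw values tie)
        lo = max(lb, apex - params.smooth_window)
        hi = min(rb, apex + params.smooth_window) + 1
        refined = lo + int(np.argmax(y[lo:hi]))
        if y[refined] > y[apex]:
            apex = refined
        rt = trace.rt[apex]
        if not (params.min_rt <= rt <= params.max_rt):
            continue
        candidates.append(
            _Candidate(
                index=apex,
                height=float(y[apex]),
                smooth_height=float(ys[apex]),
                prominence=float(props["prominences"][k]),
                left_base=lb,
                right_base=rb,
            )
        )
    # adjacent smoothed maxima can refine to one raw apex; keep the most prominent
    by_index: dict[int, _Candidate] = {}
    for c in candidates:
        prev = by_index.get(c.index)
        if prev is None or c.prominence > prev.prominence:
            by_index[c.index] = c
    return sorted(by_index.values(), key=lambda c: c.index), ys


def _check_window(trace: Trace, params: PeakParams) -> None:
    if params.max_rt < trace.rt[0] or params.min_rt > trace.rt[-1]:
        raise ValueError(
            f"RT window [{params.min_rt:g}, {params.max_rt:g}] lies outside the "
            f"trace domain [{trace.rt[0]:g}, {trace.rt[-1]:g}]"
        )


def _gates(trace: Trace, params: PeakParams, sigma: float) -> tuple[float, float]:
    """(height gate, resolved-peak prominence gate)."""
    if sigma > 0:
        g = params.sn * sigma
        return g, g
    max_height = float(np.max(np.abs(trace.absorbance)))
    g = _EPS_FRAC * max(max_height, 1.0)
    return g, g


def _to_peak(trace: Trace, cand: _Candidate, is_shoulder: bool = False) -> Peak:
    return Peak(
        apex_rt=float(trace.rt[cand.index]),
        apex_height=cand.height,
        left_rt=float(trace.rt[cand.left_base]),
        right_rt=float(trace.rt[cand.right_base]),
        is_shoulder=is_shoulder,
    )


def detect_peaks(trace: Trace, params: PeakParams, sigma: float) -> list[Peak]:
    """Detect fully resolved peaks above the SNR gate inside [min_rt, max_rt].

    A local maximum is a resolved peak when both its apex height and its
    prominence reach ``sn * sigma`` (an epsilon-scale floor when sigma is 0).
    Shoulders are added separately by :func:`detect_shoulders`.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    _check_window(trace, params)
    height_gate, prom_gate = _gates(trace, params, sigma)
    candidates, _ = _find_candidates(trace, params)
    return [
        _to_peak(trace, c)
        for c in candidates
        if c.height >= height_gate and c.prominence >= prom_gate
    ]


def detect_shoulders(
    trace: Trace, peaks: list[Peak], params: PeakParams, sigma: float
) -> list[Peak]:
    """Augment a resolved-peak list with shoulder peaks.

    A candidate maximum counts as a shoulder when the valley separating it
    from its taller neighbour never descends below
    ``shoulder_valley_frac x min(adjacent apex heights)``; a valley deeper
    than that marks both features as resolved. Shoulder candidates must
    still clear the apex-height gate plus a reduced prominence gate of
    ``sn * sigma / sqrt(smooth_window)`` (noise bumps riding on a peak flank
    have tiny smoothed prominence and are rejected by it).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    _check_window(trace, params)
    height_gate, prom_gate = _gates(trace, params, sigma)
    shoulder_prom_gate = prom_gate / np.sqrt(params.smooth_window)
    candidates, ys = _find_candidates(trace, params)

    resolved_rts = {round(p.apex_rt, 9) for p in peaks if not p.is_shoulder}
    kept: list[tuple[_Candidate, bool]] = []  # (candidate, resolved?)
    for c in candidates:
        rt = round(float(trace.rt[c.index]), 9)
        if rt in resolved_rts:
            kept.append((c, True))
        elif c.height >= height_gate and c.prominence >= shoulder_prom_gate:
            kept.append((c, False))

    out: list[Peak] = []
    n = len(kept)
    for i, (c, resolved) in enumerate(kept):
        # valley rule against adjacent maxima; the lower of a high-valley
        # pair is the shoulder, regardless of its prominence
        is_shoulder = False
        for j in (i - 1, i + 1):
            if not (0 <= j < n):
                continue
            other, _ = kept[j]
            lo, hi = sorted((c.index, other.index))
            valley = float(np.min(ys[lo : hi + 1]))
            taller = (other.smooth_height, -other.index) > (c.smooth_height, -c.index)
            if taller and valley >= params.shoulder_valley_frac * min(
                c.smooth_height, other.smooth_height
            ):
                is_shoulder = True
                break
        if resolved or is_shoulder:
            out.append(_to_peak(trace, c, is_shoulder=is_shoulder))
    out.sort(key=lambda p: p.apex_rt)
    return out


def find_all_peaks(trace: Trace, params: PeakParams, sigma: float) -> list[Peak]:
    """Resolved peaks plus shoulders, ordered by apex RT."""
    resolved = detect_peaks(trace, params, sigma)
    return detect_shoulders(trace, resolved, params, sigma)


def peaks_to_rows(
    peaks: list[Peak], sample_id: str = "", treatment: str = ""
) -> list[dict]:
    """Serializable CSV rows for a peak list."""
    return [
        {
            "sample_id": sample_id,
            "treatment": treatment,
            "apex_rt": p.apex_rt,
            "apex_height": p.apex_height,
            "left_rt": p.left_rt,
            "right_rt": p.right_rt,
            "is_shoulder": p.is_shoulder,
        }
        for p in peaks
    ]


__all__ = [
    "Peak",
    "PeakParams",
    "detect_peaks",
    "detect_shoulders",
    "find_all_peaks",
    "peaks_to_rows",
]
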