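"""Blank-subtraction normalization and baseline-noise estimation.

Sample traces are normalized by subtracting the preceding blank run,
linearly interpolated onto the sample's RT grid. The noise scale feeding the
signal-to-noise peak gate is a robust (MAD-based) statistic of the
normalized trace restricted to peak-free flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace_model import Trace, TraceError, Treatment

# Blank may fall short of the sample RT domain by this many sample grid
# steps at each end; beyond that the domains are considered incompatible.
EDGE_TOLERANCE_STEPS = 2

MAD_TO_SIGMA = 1.4826  # consistency factor for Gaussian noise


@dataclass(frozen=True)
class NormalizedTrace(Trace):
    """A blank-subtracted sample trace; RT grid equals the source sample's."""

    blank_id: str = ""


def subtract_blank(sample: Trace, blank: Trace) -> NormalizedTrace:
    """Subtract the blank trace, interpolated onto the sample RT grid.

    The blank's RT domain must cover the sample's within an edge tolerance
    of ``EDGE_TOLERANCE_STEPS`` sample grid steps per side; inside that
    tolerance the blank is extrapolated flat (nearest value held).
    """
    step = sample.rt_step
    tol = EDGE_TOLERANCE_STEPS * step
    if blank.rt[0] > sample.rt[0] + tol or blank.rt[-1] < sample.rt[-1] - tol:
        raise TraceError(
            "blank RT domain "
            f"[{blank.rt[0]:g}, {blank.rt[-1]:g}] does not cover sample domain "
            f"[{sample.rt[0]:g}, {sample.rt[-1]:g}] within {tol:g} min edge tolerance"
        )
    # np.interp holds endpoint values outside the blank domain (flat).
    blank_on_grid = np.interp(sample.rt, blank.rt, blank.absorbance)
    return NormalizedTrace(
        sample_id=sample.sample_id,
        treatment=sample.treatment,
        rt=sample.rt.copy(),
        absorbance=sample.absorbance - blank_on_grid,
        blank_id=blank.sample_id,
    )


def _diff_quartile_sigma(values: np.ndarray) -> float:
    """Fallback noise scale: lower quartile of |first differences| / sqrt(2)."""
    diffs = np.abs(np.diff(values))
    if diffs.size == 0:
        return 0.0
    return float(np.percentile(diffs, 25) / np.sqrt(2.0))


def estimate_noise(
    trace: Trace,
    region: tuple[float, float] | str = "auto",
    peak_window: tuple[float, float] | None = None,
) -> float:
    """Robust noise sigma of a (normalized) trace.

    Parameters
    ----------
    trace : Trace
        Typically a :class:`NormalizedTrace`.
    region : (float, float) or "auto"
        Explicit RT interval known to be peak-free, or ``"auto"`` to use the
        flanks outside ``peak_window`` (the [min_rt, max_rt] peak-search
        window). An explicit region must contain at least 10 points.
    peak_window : (float, float), optional
        Required when ``region == "auto"``; the interval excluded from the
        noise region.

    Returns
    -------
    float
        sigma = 1.4826 x median absolute deviation of the selected points.
        If the auto region has fewer than 10 points, falls back to the lower
        quartile of |first differences| / sqrt(2) over the whole trace.
    """
    values = trace.absorbance
    if region == "auto":
        if peak_window is None:
            mask = np.ones(trace.rt.size, dtype=bool)
        else:
            lo, hi = peak_window
            mask = (trace.rt < lo) | (trace.rt > hi)
        selected = values[mask]
        if selected.size < 10:
            return _diff_quartile_sigma(values)
    else:
        lo, hi = region
        mask = (trace.rt >= lo) & (trace.rt <= hi)
        selected = values[mask]
        if selected.size == 0:
            raise ValueError(f"noise region [{lo:g}, {hi:g}] is outside the trace domain")
        if selected.size < 10:
            raise ValueError(
                f"noise region [{lo:g}, {hi:g}] contains only {selected.size} points (need >= 10)"
            )
    mad = np.median(np.abs(selected - np.median(selected)))
    return float(MAD_TO_SIGMA * mad)


__all__ = [
    "NormalizedTrace",
    "subtract_blank",
    "estimate_noise",
    "EDGE_TOLERANCE_STEPS",
    "MAD_TO_SIGMA",
    "Treatment",
]
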