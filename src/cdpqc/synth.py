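"""Synthetic chromatogram and batch generation.

Produces labeled fixtures with the statistical structure the classifier
assumes: Gaussian elution peaks on a retention-time grid with linear
baseline drift and additive Gaussian noise, sample pairs laid out in
injection order with a blank run interleaved ahead of every three pairs,
and per-class pair geometries constructed to satisfy the classification
decision rule by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .classify import Category, ClassifyParams
from .trace_model import (
    BatchLayout,
    RunRecord,
    Trace,
    Treatment,
    build_batch_layout,
    write_manifest,
    write_trace,
)

PAIRS_PER_BLANK = 3  # one blank run ahead of every three sample pairs


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian elution component."""

    apex_rt: float
    height: float
    width_sd: float

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError("height must be > 0")
        if not self.width_sd > 0:
            raise ValueError("width_sd must be > 0")


def simulate_trace(
    peaks: list[PeakSpec],
    rt_grid: tuple[float, float, float] = (0.0, 15.0, 0.01),
    noise_sd: float = 0.0,
    drift: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    sample_id: str = "synthetic",
    treatment: Treatment = Treatment.INTACT,
) -> Trace:
    """Simulate one trace: sum of Gaussians + linear drift + Gaussian noise.

    ``drift`` is (slope, intercept) in absorbance units per minute /
    absorbance units. Reproducible for a fixed seed.
    """
    start, stop, step = rt_grid
    if step <= 0:
        raise ValueError("rt grid step must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rt = np.arange(start, stop + step / 2, step)
    if rt.size < 2:
        raise ValueError("empty rt grid")
    values = drift[0] * rt + drift[1]
    for p in peaks:
        values = values + p.height * np.exp(-((rt - p.apex_rt) ** 2) / (2 * p.width_sd**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=rt.size)
    return Trace(sample_id=sample_id, treatment=treatment, rt=rt, absorbance=values)


@dataclass(frozen=True)
class GeneratorParams:
    """Geometry and noise knobs for labeled batch generation.

    Defaults are sized against the default detection/classification
    parameters: peaks are placed inside the [5, 12] min search window,
    reduction shifts exceed 2 x overlap_tol, and overlap jitter stays under
    overlap_tol / 2, so labels hold by construction at zero noise.
    """

    rt_grid: tuple[float, float, float] = (0.0, 15.0, 0.01)
    peak_region: tuple[float, float] = (6.0, 11.0)
    width_sd: float = 0.1
    height_range: tuple[float, float] = (80.0, 120.0)
    shift_range: tuple[float, float] = (0.5, 1.0)
    overlap_jitter: float = 0.04
    min_separation: float = 1.2
    drift: tuple[float, float] = (0.05, 1.0)
    noise_sd: float = 0.0
    simple_max_peaks: int = 2

    def __post_init__(self) -> None:
        cls = ClassifyParams(simple_max_peaks=self.simple_max_peaks)
        lo, hi = self.shift_range
        if not lo > 2 * cls.overlap_tol:
            raise ValueError("shift_range must exceed 2 x overlap_tol")
        if not self.overlap_jitter < cls.overlap_tol / 2:
            raise ValueError("overlap_jitter must stay below overlap_tol / 2")


@dataclass(frozen=True)
class SyntheticBatch:
    layout: BatchLayout
    traces: Mapping[int, Trace]
    true_labels: Mapping[str, Category]
    seed: int
    peak_specs: Mapping[int, tuple[PeakSpec, ...]] = field(default_factory=dict)


def _pair_geometry(
    category: Category, rng: np.random.Generator, params: GeneratorParams
) -> tuple[list[PeakSpec], list[PeakSpec]]:
    """Intact and reduced peak specs realizing one category label."""
    lo, hi = params.peak_region
    sd = params.width_sd
    h = lambda: float(rng.uniform(*params.height_range))
    shift = lambda: float(rng.uniform(*params.shift_range))
    sep = params.min_separation

    if category is Category.PERFECT:
        r = float(rng.uniform(lo + hi, 2 * hi) / 2)  # upper half: room to shift left
        return [PeakSpec(r, h(), sd)], [PeakSpec(r - shift(), h(), sd)]
    if category is Category.PERFECT_PARTIAL:
        r = float(rng.uniform((lo + hi) / 2, hi))
        jitter = float(rng.uniform(-params.overlap_jitter, params.overlap_jitter))
        return (
            [PeakSpec(r, h(), sd)],
            [PeakSpec(r + jitter, h(), sd), PeakSpec(r - shift(), h(), sd)],
        )
    if category is Category.SIMPLE:
        # one trace carries exactly simple_max_peaks well-separated peaks
        n = params.simple_max_peaks
        first = float(rng.uniform(lo, hi - (n - 1) * sep))
        intact = [PeakSpec(first + k * sep, h(), sd) for k in range(n)]
        reduced = [PeakSpec(first - shift() + 0.4, h(), sd)]
        return intact, reduced
    if category is Category.COMPLEX:
        n = params.simple_max_peaks + 1
        first = float(rng.uniform(lo, hi - (n - 1) * sep))
        intact = [PeakSpec(float(rng.uniform(lo, hi)), h(), sd)]
        reduced = [PeakSpec(first + k * sep, h(), sd) for k in range(n)]
        return intact, reduced
    raise ValueError(f"unknown category {category!r}")  # pragma: no cover


def simulate_batch(
    class_counts: Mapping[Category | str, int],
    params: GeneratorParams = GeneratorParams(),
    seed: int = 0,
) -> SyntheticBatch:
    """Generate an injection-ordered labeled batch.

    A blank run is emitted ahead of every :data:`PAIRS_PER_BLANK` sample
    pairs. Each pair's intact/reduced geometry is drawn to satisfy its
    label under the default decision rule; labels are recorded as ground
    truth. Fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    order: list[Category] = []
    for cat, count in class_counts.items():
        cat = Category(cat)
        if count < 0:
            raise ValueError("class counts must be >= 0")
        order.extend([cat] * count)

    runs: list[RunRecord] = []
    traces: dict[int, Trace] = {}
    labels: dict[str, Category] = {}
    specs: dict[int, tuple[PeakSpec, ...]] = {}
    run_index = 0
    n_blanks = 0

    def add_run(sample_id: str, treatment: Treatment, peak_specs: list[PeakSpec]) -> None:
        nonlocal run_index
        run_index += 1
        trace = simulate_trace(
            peak_specs,
            rt_grid=params.rt_grid,
            noise_sd=params.noise_sd,
            drift=params.drift,
            seed=int(rng.integers(0, 2**31)),
            sample_id=sample_id,
            treatment=treatment,
        )
        runs.append(RunRecord(run_index=run_index, sample_id=sample_id, treatment=treatment))
        traces[run_index] = trace
        specs[run_index] = tuple(peak_specs)

    for i, category in enumerate(order):
        if i % PAIRS_PER_BLANK == 0:
            n_blanks += 1
            add_run(f"BLK{n_blanks:03d}", Treatment.BLANK, [])
        sample_id = f"SYN{i + 1:04d}"
        intact_specs, reduced_specs = _pair_geometry(category, rng, params)
        add_run(sample_id, Treatment.INTACT, intact_specs)
        add_run(sample_id, Treatment.REDUCED, reduced_specs)
        labels[sample_id] = category

    layout = (
        build_batch_layout(runs)
        if order
        else BatchLayout(runs=tuple(runs), pair_assignments={})
    )
    return SyntheticBatch(
        layout=layout, traces=traces, true_labels=labels, seed=seed, peak_specs=specs
    )


def write_batch(batch: SyntheticBatch, directory: str | Path) -> Path:
    """Write a batch as trace CSVs + manifest.csv + labels.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    token = {Treatment.INTACT: "INTACT", Treatment.REDUCED: "DTT", Treatment.BLANK: "BLANK"}
    runs_with_paths: list[RunRecord] = []
    for run in batch.layout.runs:
        name = f"{run.sample_id}_{token[run.treatment]}.csv"
        write_trace(batch.traces[run.run_index], directory / name)
        # manifest paths are relative to the batch directory (portable tree)
        runs_with_paths.append(
            RunRecord(run_index=run.run_index, sample_id=run.sample_id,
                      treatment=run.treatment, path=Path(name))
        )
    manifest = directory / "manifest.csv"
    write_manifest(runs_with_paths, manifest)
    with (directory / "labels.csv").open("w", newline="") as fh:
        fh.write("sample_id,category\n")
        for sample_id, cat in batch.true_labels.items():
            fh.write(f"{sample_id},{cat.value}\n")
    return manifest


__all__ = [
    "PeakSpec",
    "GeneratorParams",
    "SyntheticBatch",
    "simulate_trace",
    "simulate_batch",
    "write_batch",
    "PAIRS_PER_BLANK",
]
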