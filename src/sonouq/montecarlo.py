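"""Monte Carlo propagation of tissue-property uncertainty.

Evaluates a field-valued model (the full acoustic simulation, or a fitted
surrogate for "PCE Monte Carlo") at every row of a sample set and
accumulates the per-voxel sample mean and standard deviation (unbiased,
n-1 denominator), plus a running-statistics trace at a probe voxel
(default: the focal voxel) used for convergence plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import SonoUQError
from .tissuedb import SampleSet

__all__ = ["UQField", "ConvergenceTrace", "run_mc", "convergence_gap"]

#: Sentinel returned by convergence_gap when the final std is zero.
UNDEFINED_GAP = float("nan")


@dataclass
class UQField:
    """Per-voxel mean and std of intensity (W/cm^2) with provenance."""

    mean: np.ndarray
    std: np.ndarray
    n_samples: int
    source: str  # "mc-simulation" | "pce-resampled" | "pce-analytic"
    seed: int | None

    def __post_init__(self) -> None:
        if self.mean.shape != self.std.shape:
            raise ValueError("mean/std shape mismatch")
        if np.any(self.std < -1e-12):
            raise ValueError("std must be non-negative")


@dataclass
class ConvergenceTrace:
    """Running mean/std of the probe voxel after k = 1..n samples."""

    probe_index: tuple[int, ...]
    values: np.ndarray
    running_mean: np.ndarray
    running_std: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


class ModelEvaluationError(SonoUQError):
    def __init__(self, row: int, cause: Exception):
        super().__init__(f"model failed on sample row {row}: {cause!r}")
        self.row = row


def _running_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Welford recurrence: exact zeros for constant inputs, stable otherwise
    n = values.shape[0]
    mean = np.zeros(n)
    std = np.zeros(n)
    m, m2 = 0.0, 0.0
    for k, x in enumerate(values, start=1):
        delta = x - m
        m += delta / k
        m2 += delta * (x - m)
        mean[k - 1] = m
        if k > 1:
            std[k - 1] = math.sqrt(max(m2, 0.0) / (k - 1))
    return mean, std


def run_mc(
    model: Callable[[int, SampleSet], np.ndarray],
    samples: SampleSet,
    probe_index: tuple[int, ...] | None = None,
    source: str = "mc-simulation",
) -> tuple[UQField, ConvergenceTrace]:
    """Propagate a sample set through a field-valued model.

    ``model(k, samples)`` must return the intensity field (W/cm^2) for
    sample row k; identical sample sets yield identical statistics whatever
    the model (simulation or surrogate), which is what makes matched-input
    comparisons meaningful. A failing row aborts with its index — rows are
    never silently skipped.
    """
    if samples.n_samples < 1:
        raise ValueError("empty sample set")
    mean = None
    m2 = None
    probe_vals = np.zeros(samples.n_samples)
    shape: tuple[int, ...] | None = None
    for k in range(samples.n_samples):
        try:
            field = np.asarray(model(k, samples), dtype=float)
        except Exception as exc:  # noqa: BLE001 - report the failing row
            raise ModelEvaluationError(k, exc) from exc
        if mean is None:
            shape = field.shape
            if probe_index is None:
                probe_index = (0,) * field.ndim
            mean = np.zeros(shape)
            m2 = np.zeros(shape)
        elif field.shape != shape:
            raise ModelEvaluationError(
                k, ValueError(f"field shape changed: {field.shape} vs {shape}")
            )
        # Welford update: per-voxel mean/variance without catastrophic
        # cancellation, exactly zero variance for identical fields
        delta = field - mean
        mean += delta / (k + 1)
        m2 += delta * (field - mean)
        probe_vals[k] = field[tuple(probe_index)]

    n = samples.n_samples
    var = m2 / (n - 1) if n > 1 else np.zeros_like(mean)
    rmean, rstd = _running_stats(probe_vals)
    uq = UQField(mean, np.sqrt(np.maximum(var, 0.0)), n, source, samples.seed)
    trace = ConvergenceTrace(tuple(probe_index), probe_vals, rmean, rstd)
    return uq, trace


def convergence_gap(trace: ConvergenceTrace, k: int) -> float:
    """Relative change of the running std between k samples and all n.

    Returns |std_k - std_n| / std_n, or NaN (flagged sentinel) when the
    final std is zero (constant model).
    """
    if not 1 <= k <= trace.n_samples:
        raise ValueError(f"k must be in [1, {trace.n_samples}]")
    std_n = trace.running_std[-1]
    if std_n == 0:
        return UNDEFINED_GAP
    return float(abs(trace.running_std[k - 1] - std_n) / std_n)
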