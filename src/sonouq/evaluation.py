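"""Accuracy metrics for surrogate-vs-simulation comparison.

All metrics are restricted to an evaluation mask: the voxels whose
reference (nominal-property) intensity exceeds a threshold, by default
1 W/cm^2 = 2% of the 50 W/cm^2 free-water calibration peak, since most of
the domain is untouched by the beam. The headline metrics are the
root mean squared percentage error

    RMSPE = sqrt( (1/n) sum_i ((y_i - yhat_i) / y_i)^2 ) * 100

with y the Monte Carlo (simulation) value and yhat the surrogate value,
and the pass/fail success rate: the fraction of masked voxels whose
relative difference |sim - pred|/sim stays below 3%, averaged over a set
of validation simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .acoustics import IntensityField
from .errors import EvaluationError
from .montecarlo import UQField

__all__ = [
    "MetricsReport",
    "threshold_mask",
    "rmspe",
    "success_rate",
    "compare_uq",
    "DEFAULT_THRESHOLD_W_CM2",
    "DEFAULT_TOLERANCE",
]

DEFAULT_THRESHOLD_W_CM2 = 1.0  # 2% of the 50 W/cm^2 free-water peak
DEFAULT_TOLERANCE = 0.03


@dataclass
class MetricsReport:
    """Summary of surrogate accuracy over the evaluation mask."""

    rmspe_mean_pct: float | None = None
    rmspe_std_pct: float | None = None
    max_abs_err_mean_w_cm2: float | None = None
    max_abs_err_std_w_cm2: float | None = None
    success_rate_pct: float | None = None
    per_simulation_success_pct: list[float] = field(default_factory=list)
    mask_voxel_count: int = 0
    threshold_w_cm2: float = DEFAULT_THRESHOLD_W_CM2
    tolerance: float = DEFAULT_TOLERANCE

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def threshold_mask(
    reference: IntensityField | np.ndarray,
    threshold_w_cm2: float = DEFAULT_THRESHOLD_W_CM2,
) -> np.ndarray:
    """Boolean mask of voxels with reference intensity strictly above the
    threshold; raises if no voxel qualifies."""
    if threshold_w_cm2 <= 0:
        raise EvaluationError("threshold must be positive")
    arr = reference.intensity if isinstance(reference, IntensityField) else reference
    mask = arr > threshold_w_cm2
    if not mask.any():
        raise EvaluationError(
            f"no voxels exceed {threshold_w_cm2} W/cm^2; nothing to evaluate"
        )
    return mask


def rmspe(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean squared percentage error (%) with y as the reference."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise EvaluationError("rmspe inputs must have equal length")
    if np.any(y == 0):
        raise EvaluationError("reference contains zeros; apply the threshold mask")
    return float(np.sqrt(np.mean(((y - y_hat) / y) ** 2)) * 100.0)


def success_rate(
    validation_sims: Sequence[IntensityField | np.ndarray],
    surrogate_preds: Sequence[np.ndarray],
    mask: np.ndarray,
    tolerance: float = DEFAULT_TOLERANCE,
) -> MetricsReport:
    """Pass/fail accuracy over matched validation pairs.

    For each (simulation, prediction) pair — same uncertain inputs — the
    per-simulation rate is the fraction of masked voxels with relative
    difference |sim - pred| / sim strictly below ``tolerance``; the overall
    success rate is the mean over simulations, in percent.
    """
    if len(validation_sims) != len(surrogate_preds):
        raise EvaluationError("validation pairs are mismatched in length")
    if len(validation_sims) == 0:
        raise EvaluationError("no validation pairs")
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise EvaluationError("empty evaluation mask")
    per_sim: list[float] = []
    for sim, pred in zip(validation_sims, surrogate_preds):
        s = (sim.intensity if isinstance(sim, IntensityField) else sim)[mask]
        p = np.asarray(pred)
        p = (p.reshape(mask.shape)[mask] if p.shape == mask.shape else p)
        if p.shape != s.shape:
            raise EvaluationError("prediction does not match mask")
        if np.any(s == 0):
            raise EvaluationError("simulated intensity is zero on the mask")
        per_sim.append(float(np.mean(np.abs(s - p) / s < tolerance) * 100.0))
    return MetricsReport(
        success_rate_pct=float(np.mean(per_sim)),
        per_simulation_success_pct=per_sim,
        mask_voxel_count=n_mask,
        tolerance=tolerance,
    )


def compare_uq(
    mc: UQField,
    pce: UQField,
    mask: np.ndarray,
    threshold_w_cm2: float = DEFAULT_THRESHOLD_W_CM2,
) -> MetricsReport:
    """RMSPE and max-absolute-error of mean and std fields on the mask.

    The Monte Carlo field is the reference of the (asymmetric) RMSPE; the
    max-absolute errors are symmetric in argument order.
    """
    if mc.mean.shape != pce.mean.shape or mc.mean.shape != mask.shape:
        raise EvaluationError("UQ fields and mask must share a grid")
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise EvaluationError("empty evaluation mask")
    mc_mean, pce_mean = mc.mean[mask], pce.mean[mask]
    mc_std, pce_std = mc.std[mask], pce.std[mask]
    report = MetricsReport(
        rmspe_mean_pct=rmspe(mc_mean, pce_mean),
        max_abs_err_mean_w_cm2=float(np.max(np.abs(mc_mean - pce_mean))),
        max_abs_err_std_w_cm2=float(np.max(np.abs(mc_std - pce_std))),
        mask_voxel_count=n_mask,
        threshold_w_cm2=threshold_w_cm2,
    )
    if np.all(mc_std > 0):
        report.rmspe_std_pct = rmspe(mc_std, pce_std)
    elif np.all(mc_std == 0) and np.all(pce_std == 0):
        report.rmspe_std_pct = 0.0  # degenerate zero-uncertainty comparison
    else:
        report.rmspe_std_pct = None
    return report
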