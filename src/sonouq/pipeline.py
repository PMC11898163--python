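"""End-to-end workflows: Monte Carlo benchmark, PCE surrogate UQ, and the
matched-input comparison between them.

The ``compare`` mode reproduces the full study design on a phantom:
calibrate the source in free water, simulate the nominal phantom to fix the
evaluation mask, fit a second-order cross-term-free PCE from a small
training set, benchmark it against simulation Monte Carlo with matched
inputs, and score the surrogate on fresh validation simulations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .acoustics import (
    CalibrationResult,
    IntensityField,
    SimulationConfig,
    TransducerSpec,
    assign_properties,
    calibrate_source,
    focal_metrics,
    intensity_from_pressure,
    simulate_pressure,
    water_materials,
)
from .errors import ConfigurationError
from .evaluation import (
    DEFAULT_THRESHOLD_W_CM2,
    DEFAULT_TOLERANCE,
    MetricsReport,
    compare_uq,
    success_rate,
    threshold_mask,
)
from .montecarlo import ConvergenceTrace, UQField, run_mc
from .pce import PCESurrogate, build_basis, evaluate_pce, fit_pce
from .phantom import LabelVolume, default_desk_phantom
from .tissuedb import (
    SampleSet,
    TissueTable,
    child_seed,
    default_tissue_table,
    draw_samples,
    resolve_preset,
)

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "free_water_characterization",
    "REFERENCE_GRID_SHAPE",
    "REFERENCE_SPACING_MM",
]

#: The reference free-water domain: 71 x 71 x 96.5 mm at 0.5 mm
#: (one-twelfth of the 250 kHz wavelength in water).
REFERENCE_GRID_SHAPE: tuple[int, int, int] = (142, 142, 193)
REFERENCE_SPACING_MM: float = 0.5

#: Apex standoff from the grid face along the beam axis (mm).
APEX_DEPTH_MM = 2.0


@dataclass
class RunConfig:
    """Study configuration; paths may replace generated defaults."""

    phantom_path: str | None = None  # None -> default desk phantom
    tissue_table_path: str | None = None  # None -> built-in table
    uncertainty_preset: str = "speed8"
    n_pce_samples: int = 20
    n_mc_samples: int = 100
    n_validation_sims: int = 50
    pce_order: int = 2
    master_seed: int = 0
    target_isppa_w_cm2: float = 50.0
    threshold_w_cm2: float = DEFAULT_THRESHOLD_W_CM2
    tolerance: float = DEFAULT_TOLERANCE
    n_periods: int = 50
    points_per_wavelength: int = 6  # desk-scale: 1 mm at 250 kHz in water
    out_dir: str | None = None
    overwrite: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in ("out_dir", "overwrite")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    metrics: MetricsReport
    calibration: CalibrationResult
    nominal: IntensityField
    mask: np.ndarray
    mc_field: UQField | None = None
    mc_trace: ConvergenceTrace | None = None
    pce_field: UQField | None = None
    pce_trace: ConvergenceTrace | None = None
    surrogate: PCESurrogate | None = None
    validation_probe_sim: np.ndarray | None = None
    validation_probe_pred: np.ndarray | None = None
    seed: int = 0
    config_digest: str = ""


def _load_table(config: RunConfig) -> TissueTable:
    if config.tissue_table_path is None:
        return default_tissue_table()
    p = str(config.tissue_table_path)
    if p.endswith((".yml", ".yaml")):
        return TissueTable.from_yaml(p)
    return TissueTable.from_csv(p)


def _load_phantom(config: RunConfig, table: TissueTable) -> LabelVolume:
    if config.phantom_path is None:
        return default_desk_phantom(table)
    from . import io as _io

    p = str(config.phantom_path)
    if p.endswith((".h5", ".hdf5")):
        return _io.load_label_volume_h5(p)
    return _io.load_label_volume_nifti(p)


def default_transducer_for(vol: LabelVolume) -> TransducerSpec:
    """CTX-250 on the beam axis through the phantom's transverse center."""
    nx, ny = vol.shape[0], vol.shape[1]
    return TransducerSpec(
        face_center_mm=(
            nx * vol.spacing_mm / 2.0,
            ny * vol.spacing_mm / 2.0,
            APEX_DEPTH_MM,
        )
    )


def _probe_voxel(
    vol: LabelVolume, transducer: TransducerSpec
) -> tuple[int, ...]:
    # geometric focus voxel: rated focal depth along the beam axis
    pos = np.asarray(transducer.face_center_mm) + (
        transducer.rated_focal_depth_mm * np.asarray(transducer.axis)
    )
    idx = np.clip(
        (pos / vol.spacing_mm).astype(int), 0, np.array(vol.shape) - 1
    )
    return tuple(int(i) for i in idx)


def run_pipeline(
    config: RunConfig,
    mode: str = "compare",
    *,
    table: TissueTable | None = None,
    phantom: LabelVolume | None = None,
    transducer: TransducerSpec | None = None,
) -> PipelineResult:
    """Execute the requested workflow.

    mode "mc": simulation Monte Carlo only; "pce": train + fit + surrogate
    resampling with matched inputs; "compare": both, plus RMSPE/max-error
    comparison and the validation success rate. ``table``/``phantom``/
    ``transducer`` override the config-derived defaults (in-memory use).
    """
    if mode not in ("mc", "pce", "compare"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    table = table if table is not None else _load_table(config)
    vol = phantom if phantom is not None else _load_phantom(config, table)
    transducer = (
        transducer if transducer is not None else default_transducer_for(vol)
    )
    sim = SimulationConfig(
        n_periods=config.n_periods,
        points_per_wavelength=config.points_per_wavelength,
        c_ref_m_s=table.max_speed_bound,
    )

    cal = calibrate_source(
        transducer, sim, vol.shape, vol.spacing_mm,
        config.target_isppa_w_cm2, table,
    )
    sim = replace(sim, source_amplitude_pa=cal.scale)

    nominal_mats = assign_properties(vol, table)
    nominal = intensity_from_pressure(
        simulate_pressure(nominal_mats, transducer, sim), nominal_mats
    )
    mask = threshold_mask(nominal, config.threshold_w_cm2)
    probe = _probe_voxel(vol, transducer)

    def sim_model(k: int, samples: SampleSet) -> np.ndarray:
        mats = assign_properties(vol, table, samples.row_overrides(k))
        p = simulate_pressure(mats, transducer, sim)
        return intensity_from_pressure(p, mats, provenance=f"sample-{k}").intensity

    index = resolve_preset(config.uncertainty_preset)
    result = PipelineResult(
        metrics=MetricsReport(
            threshold_w_cm2=config.threshold_w_cm2, tolerance=config.tolerance,
            mask_voxel_count=int(mask.sum()),
        ),
        calibration=cal,
        nominal=nominal,
        mask=mask,
        seed=config.master_seed,
        config_digest=config.digest(),
    )

    surrogate = None
    if mode in ("pce", "compare"):
        train = draw_samples(
            table, index, config.n_pce_samples,
            child_seed(config.master_seed, "train"),
        )
        responses = np.stack(
            [sim_model(k, train) for k in range(train.n_samples)]
        )
        basis = build_basis(len(index), config.pce_order, cross_terms=False)
        surrogate = fit_pce(train, responses, basis)
        result.surrogate = surrogate

    if mode in ("mc", "compare"):
        mc_samples = draw_samples(
            table, index, config.n_mc_samples, child_seed(config.master_seed, "mc")
        )
        result.mc_field, result.mc_trace = run_mc(
            sim_model, mc_samples, probe, source="mc-simulation"
        )

    if mode in ("pce", "compare"):
        # surrogate resampling with inputs matched to the MC rows
        resample = (
            mc_samples
            if mode == "compare"
            else draw_samples(
                table, index, config.n_mc_samples,
                child_seed(config.master_seed, "mc"),
            )
        )

        def pce_model(k: int, samples: SampleSet) -> np.ndarray:
            flat = evaluate_pce(surrogate, samples.standardized[k])
            return flat.reshape(surrogate.grid_shape)

        result.pce_field, result.pce_trace = run_mc(
            pce_model, resample, probe, source="pce-resampled"
        )

    if mode == "compare":
        cmp_report = compare_uq(
            result.mc_field, result.pce_field, mask, config.threshold_w_cm2
        )
        val = draw_samples(
            table, index, config.n_validation_sims,
            child_seed(config.master_seed, "validate"),
        )
        sims = []
        preds = []
        for k in range(val.n_samples):
            sims.append(sim_model(k, val))
            preds.append(
                evaluate_pce(surrogate, val.standardized[k]).reshape(
                    surrogate.grid_shape
                )
            )
        sr = success_rate(sims, preds, mask, config.tolerance)
        result.validation_probe_sim = np.array([s[probe] for s in sims])
        result.validation_probe_pred = np.array([p[probe] for p in preds])
        result.metrics = MetricsReport(
            rmspe_mean_pct=cmp_report.rmspe_mean_pct,
            rmspe_std_pct=cmp_report.rmspe_std_pct,
            max_abs_err_mean_w_cm2=cmp_report.max_abs_err_mean_w_cm2,
            max_abs_err_std_w_cm2=cmp_report.max_abs_err_std_w_cm2,
            success_rate_pct=sr.success_rate_pct,
            per_simulation_success_pct=sr.per_simulation_success_pct,
            mask_voxel_count=int(mask.sum()),
            threshold_w_cm2=config.threshold_w_cm2,
            tolerance=config.tolerance,
        )
    elif mode == "mc":
        result.metrics.mask_voxel_count = int(mask.sum())

    if config.out_dir is not None:
        _persist(config, mode, result)
    return result


def _persist(config: RunConfig, mode: str, result: PipelineResult) -> None:
    from . import io as _io

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "provenance.json"
    if marker.exists() and not config.overwrite:
        existing = json.loads(marker.read_text())
        if existing.get("config_digest") == result.config_digest:
            raise ConfigurationError(
                f"{out} already holds results for this config digest; "
                "pass overwrite=True to replace them"
            )
    result.metrics.to_json(out / "metrics.json")
    _io.save_intensity_h5(result.nominal, out / "nominal_intensity.h5")
    if result.mc_field is not None:
        _io.save_uq_field(result.mc_field, out / "uq_mc.h5")
        _io.save_trace_csv(result.mc_trace, out / "trace_mc.csv")
    if result.pce_field is not None:
        _io.save_uq_field(result.pce_field, out / "uq_pce.h5")
        _io.save_trace_csv(result.pce_trace, out / "trace_pce.csv")
    if result.surrogate is not None:
        _io.save_surrogate(result.surrogate, out / "surrogate.h5")
    marker.write_text(
        json.dumps(
            {"config_digest": result.config_digest, "seed": result.seed,
             "mode": mode},
            indent=2,
        )
    )


def free_water_characterization(
    grid_shape: Sequence[int] = REFERENCE_GRID_SHAPE,
    spacing_mm: float = REFERENCE_SPACING_MM,
    n_periods: int = 50,
    target_isppa_w_cm2: float = 50.0,
    points_per_wavelength: int = 12,
    transducer: TransducerSpec | None = None,
):
    """Calibrated free-water focal field of the CTX-250 and its metrics.

    Returns (FocalMetrics, IntensityField, CalibrationResult) on the
    reference 0.5 mm grid by default.
    """
    nx, ny, _ = grid_shape
    if transducer is None:
        transducer = TransducerSpec(
            face_center_mm=(
                nx * spacing_mm / 2.0, ny * spacing_mm / 2.0, APEX_DEPTH_MM
            )
        )
    sim = SimulationConfig(
        n_periods=n_periods, points_per_wavelength=points_per_wavelength
    )
    cal = calibrate_source(
        transducer, sim, tuple(grid_shape), spacing_mm, target_isppa_w_cm2
    )
    intensity = cal.calibrated_intensity()
    return focal_metrics(intensity, transducer), intensity, cal
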