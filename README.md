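# sonouq

Uncertainty quantification for transcranial low-intensity focused
ultrasound (LIFUS) intensity fields.

Computational planning of LIFUS neuromodulation rests on simulated acoustic
intensity maps, but the tissue acoustic properties those simulations need —
density and speed of sound of skin, skull, CSF, gray/white matter and the
target structure — are only known to within sizeable population spreads
(the skull speed of sound alone carries a ~12% standard deviation). This
package quantifies how those property uncertainties propagate into the
predicted intensity field, and does it two ways so they can be compared:

- **Monte Carlo**: draw property samples, run the full wave simulation for
  each, accumulate per-voxel mean and standard deviation of intensity.
- **PCE surrogate**: fit a per-voxel polynomial chaos expansion from a
  handful of simulations, then resample the cheap surrogate instead.

The surrogate is a cross-term-free second-order expansion in orthonormal
Hermite polynomials of the standardized inputs ξ,

    Y(ξ) = Σₙ cₙ Ψₙ(ξ),    M = u·n + 1 terms   (17 for u = 8 inputs),

fitted per voxel by least squares from black-box simulation samples
(minimum-norm in the under-determined regime). Orthonormality gives
closed-form moments (mean c₀, variance Σₙ≥₁ cₙ²); matched-input surrogate
resampling is used for like-for-like benchmarks against Monte Carlo.

The forward model is an FDTD solver for the lossy linear acoustic pressure
wave equation with heterogeneous density, speed and attenuation
(Γ = 2αc damping, so plane waves decay as exp(−αx)), driven by a
CTX-250-class focused bowl (64 mm radius of curvature, 64 mm aperture,
250 kHz, four annular elements with electronic focal-depth compensation).
Accuracy is scored on the voxels above 1 W/cm² (2% of the 50 W/cm²
free-water calibration peak) with standard voxelwise metrics: voxelwise
RMSPE, maximum absolute error, and the 3% relative-difference pass/fail
success rate over validation simulations.

Everything runs on synthetic multi-tissue head phantoms (curved,
segmentation-rough layers with an embedded amygdala-analog target) so the
whole pipeline is testable without any external data.

## Worked example

```python
from sonouq import RunConfig, run_pipeline

result = run_pipeline(RunConfig(master_seed=1), mode="compare")
m = result.metrics
print(f"mask voxels:   {m.mask_voxel_count}")
print(f"RMSPE(mean):   {m.rmspe_mean_pct:.2f} %")
print(f"RMSPE(std):    {m.rmspe_std_pct:.2f} %")
print(f"max |d mean|:  {m.max_abs_err_mean_w_cm2:.3f} W/cm^2")
print(f"max |d std|:   {m.max_abs_err_std_w_cm2:.3f} W/cm^2")
print(f"success rate:  {m.success_rate_pct:.1f} %")
```

This builds the default desk-scale head phantom (72×72×90 voxels at 1 mm),
calibrates the source to a 50 W/cm² free-water peak, runs a 20-sample
training set for the 17-term surrogate (speed of sound of the 8 non-water
tissues uncertain), benchmarks it against a 100-sample simulation Monte
Carlo with matched inputs, and scores 50 validation simulations — about
170 wave simulations, ~12 minutes on one CPU. It prints:

```
mask voxels:   38080
RMSPE(mean):   1.11 %
RMSPE(std):    29.30 %
max |d mean|:  0.323 W/cm^2
max |d std|:   0.638 W/cm^2
success rate:  45.9 %
```

(The nominal in-head peak is about 21 W/cm^2, i.e. the skull and soft
tissue remove roughly 60% of the 50 W/cm^2 free-water focal intensity.)

The mean intensity field of the 20-sample surrogate agrees with Monte
Carlo to about 1% RMSPE (max error ~0.3 W/cm², under 1% of the free-water
peak). The standard-deviation field and the per-voxel 3% pass rate are
markedly worse on this phantom: most of the evaluation mask lies in the
water/skin region between transducer and skull, where the steady-state
intensity oscillates with the sampled layer speeds (coherent interference
between outgoing and layer-echo waves) and is not representable by a
20-point quadratic fit; see `docs/methods.md` for the analysis.

Free-water characterization of the transducer on the 0.5 mm reference
grid:

```python
from sonouq import free_water_characterization
metrics, intensity, cal = free_water_characterization()
print(metrics.axial_distance_mm)      # 61.3 mm peak distance from the bowl apex
print(metrics.axial_extent_mm)        # 37.5 mm -3 dB focal length
print(metrics.transverse_extents_mm)  # 6.05 mm focal width
print(intensity.peak)                 # 50.0 W/cm^2 after calibration
```

The device model phases its four annular elements so the continuum
radiating-cap design peaks at the rated 64 mm focal distance; at the
reference resolution the discrete solver realizes that design a few
millimetres short (the focal position converges with grid refinement, and
`TransducerSpec(dispersion_compensation=True)` realizes the continuum
design exactly — that setting is used when verifying the solver against
the radiating-cap integral oracle).

A thin CLI mirrors the stages: `sonouq phantom`, `sonouq calibrate`,
`sonouq simulate`, `sonouq sample`, `sonouq pipeline`, `sonouq evaluate`.

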