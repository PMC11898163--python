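# Methods

`sonouq` quantifies how uncertainty in tissue acoustic properties propagates
into the predicted acoustic intensity field of low-intensity focused
ultrasound (LIFUS) neuromodulation. It chains four stages: a lossy acoustic
wave solver on a segmented voxel phantom, a polynomial-chaos-expansion (PCE)
surrogate fitted from a handful of simulations, Monte Carlo propagation
(by direct simulation and by surrogate resampling), and voxelwise accuracy
metrics comparing the two routes.

## Acoustic model

The solver integrates the damped linear acoustic pressure wave equation on
a regular voxel grid with heterogeneous density `rho(x)` (kg/m^3), speed of
sound `c(x)` (m/s) and amplitude attenuation `alpha(x)` (Np/m):

    rho div( (1/rho) grad p ) - (1/c^2) p_tt - (Gamma/c^2) p_t = 0,
    Gamma = 2 alpha c .

The first-order damping coefficient `Gamma = 2 alpha c` is chosen so that a
continuous-wave plane wave decays spatially as `exp(-alpha x)` — the
physically meaningful contract for a Np/m attenuation coefficient, enforced
by a decay-slope test against the skin value (5.29 Np/m). For soft tissue
and bone at 250 kHz, `alpha c / Omega <= 0.025`, so the dispersion
correction of this damping form is negligible.

Discretisation: explicit second-order leapfrog in time and central
differences in space on a collocated grid, with the heterogeneous-density
term evaluated through face buoyancies `0.5 (1/rho_i + 1/rho_nb)`. The
damping term is integrated semi-implicitly (centered `p_t`), which stays
stable for arbitrarily strong damping; the CFL number defaults to 0.45
(stability bound `1/sqrt(3) ~ 0.577` in 3D). The time step divides the
excitation period exactly so that steady-state extraction windows cover an
integer number of periods. Within a sampling study, the time step is fixed
from the property table's truncation bound `max(c_mean + 4 c_std)` rather
than per-sample maxima, so the simulated response is a smooth function of
the sampled properties (no discrete steps-per-period jumps between
samples).

Boundaries: an absorbing sponge — a quadratic damping ramp rising to
`2 Omega` over 1.25 wavelengths — attached *outside* the stated physical
domain: the grid is padded by the sponge thickness (edge-replicated
materials) and cropped after stepping, so the sponge never overlaps the
transducer aperture or the region of interest. Measured plane-wave
reflection ripple is ~1% (contract: < 2%).

Excitation and extraction: continuous-wave drive for 50 periods with a
2-period cosine-taper onset. Source voxels are driven either as a
transparent (additive) monopole layer — the default, matching the
radiating-cap integral idealization — or as hard (Dirichlet) voxels. The
steady-state amplitude is `sqrt(2) x RMS` of the final 2 periods per voxel
(exact for a pure sinusoid). Time-averaged intensity is
`I = p_amp^2 / (2 rho c)`, reported in W/cm^2.

## Transducer model

The applicator is a CTX-250-class focused bowl: 64 mm radius of curvature,
64 mm aperture, 250 kHz, four annular elements of equal area. The cap is
rasterized onto the grid as the voxels within half a voxel of the spherical
surface inside the aperture cone, each carrying its element's amplitude and
phase.

Element phasing deserves a note. A uniform in-phase bowl of this geometry
*cannot* place its intensity peak at the 64 mm curvature center: the exact
radiating-cap (O'Neil-type) integral puts the free-field peak at 57.1 mm
with a 32.2 mm −3 dB extent — the classic low-Fresnel-number focal shift.
Annular arrays exist precisely to compensate this shift electronically.
The default model therefore drives the four rings with conjugate phases
aimed at the axial point (found by bisection on the cap integral) that
places the continuum on-axis intensity peak at the device's rated focal
distance, i.e. the 64 mm curvature radius. Explicit per-element
phases/amplitudes can be supplied instead.

Two further modelling choices shape the source. First, an
impedance-matched absorbing backing occupies the shell behind the cap
(quadratic absorption ramp, 6 mm, as in physically backed transducers),
so backward radiation of the transparent source and echoes returning from
tissue are absorbed rather than re-injected. A bare hard-source cap was
rejected: it re-reflects tissue echoes and builds a multi-pass cavity
between transducer and skull whose interference is strongly non-smooth in
the sampled tissue speeds. Second, the device drives its *rated*
(continuum-design) phases on any grid, exactly as a physical device would
— the solver's numerical dispersion is then part of the simulated
physics, as it is in any FDTD study. Because the leapfrog scheme's
numerical wavenumber exceeds `omega/c` anisotropically (about +1% along
grid axes at 12 points per wavelength), the realized focal peak sits a
few millimetres short of the continuum prediction at the reference
resolution (61.3 mm instead of 64.1 mm from the apex), converging as the
grid is refined. For solver *verification*, `TransducerSpec` offers
`dispersion_compensation=True`: each voxel's drive phase is advanced by
`(k_num(direction) - k) x distance-to-aim` with `k_num` from the scheme's
exact dispersion relation, making the discrete run realize the continuum
design (peak 64.2 mm at 12 points per wavelength, 63.3 mm at 6 — i.e.
resolution-consistent) so that the on-axis profile can be compared
directly against the radiating-cap integral oracle; they agree to ~2.5%
of the peak. The compensated source is deliberately not the study
default: retuning drive phases per grid is something no physical device
does.

Calibration: one unit-amplitude free-water run; by linearity the source
scale is `sqrt(target / unit_peak)` with target 50 W/cm^2. The scale is
reused unchanged for all heterogeneous runs. (With the additive source the
uncalibrated amplitude depends on rasterization density, so absolute field
scales are only meaningful after calibration — which every study performs.)

Focal metrics: the peak voxel is refined by 3-point parabolic interpolation
per axis; −3 dB intensity extents are the contiguous half-maximum intervals
of the grid-line profiles through the peak, with linear interpolation at
the crossings. A peak on the domain boundary sets a warning flag.

## Tissue properties and uncertainty model

The built-in table holds nine tissues (amygdala, cerebellum, CSF, gray
matter, skull, skin, ventricles, water, white matter) with density and
speed-of-sound mean ± std and fixed attenuation; CSF and ventricles are
identical and water carries no attenuation and no uncertainty. Uncertain
properties are independent Gaussians truncated at ±4 sigma (violations
redrawn) — a <0.01% distortion that guarantees physical (positive) values.
Two presets mirror the study designs: `speed8` (speed of sound of the 8
non-water tissues, u = 8) and `speed+density16` (u = 16). Attenuation
cannot be made uncertain. A single master seed spawns deterministic
per-stage child seeds (training / MC / validation).

## Surrogate

The intensity at each voxel is expanded in products of probabilists'
Hermite polynomials of the standardized inputs `xi` (sigma units),
orthonormal under the standard normal weight. Because the inputs are
independent, cross terms are omitted by default: the second-order basis is
the constant plus each input at degrees 1 and 2, `M = u n + 1` terms
(17 for u = 8; 33 for u = 16); the full tensor truncation
`M = (u+n)!/(u! n!)` is available for comparison. Coefficients are fitted
per voxel by ordinary least squares on the standardized training inputs;
with fewer samples than terms (the deliberately under-determined 5- and
10-sample regimes) the minimum-norm solution is used. Negative surrogate
predictions of the non-negative intensity are clamped to zero with a
diagnostic counter.

Two moment routes are exposed: analytic (mean `c_0`, variance
`sum_{n>=1} c_n^2`, exact for the orthonormal basis) and matched-input
resampling, in which the surrogate is evaluated at exactly the Monte Carlo
sample rows. Resampling is the default for benchmark comparisons because it
makes the sampling error common-mode between the two routes; the analytic
route is cross-checked against resampling in tests.

## Monte Carlo propagation

`run_mc` evaluates any field-valued model (full simulation or surrogate) at
every sample row and accumulates per-voxel mean and unbiased (n−1) std via
Welford's recurrence — numerically stable, and exactly zero variance for
identical fields, which keeps the zero-uncertainty degenerate cases exact.
A convergence trace records running mean/std at a probe voxel (default:
the geometric focus). Rows are never silently skipped; a failing model run
aborts with its row index.

## Accuracy metrics

All metrics are restricted to the voxels whose *nominal-property* intensity
exceeds 1 W/cm^2 (2% of the 50 W/cm^2 free-water calibration peak); the
nominal field is used because it is deterministic and sample-independent.
Reported quantities: RMSPE
`sqrt(mean(((y - yhat)/y)^2)) x 100` with the simulation route as reference
`y`; maximum absolute differences of the mean and std fields (W/cm^2); and
the pass/fail success rate — the fraction of masked voxels whose relative
difference `|sim - pred|/sim` is strictly below 3%, averaged over a set of
validation simulations with matched inputs. Thresholds use strict
inequalities (mask: `> 1 W/cm^2`; pass: `< 3%`).

## Synthetic phantoms and the scaled-down benchmark

Head anatomy is emulated by deterministic synthetic phantoms: planar tissue
slabs stacked along the beam axis, concentric-shell (curved) geometries,
and an embedded ellipsoidal target (an amygdala analog). Voxel centers sit
at `(index + 0.5) x spacing` with the propagation axis last.

The default desk-scale phantom is 72 x 72 x 90 voxels at 1 mm — wide
enough to contain the 64 mm aperture — and models the temporal-window
placement used for amygdala sonication: a spherically curved head analog
(90 mm outer radius) with, on axis, a 12 mm water coupling gap, 3 mm
skin, 3 mm squamous temporal bone, 3 mm CSF, 4 mm gray matter and white
matter inside, plus the 8 mm-radius amygdala sphere 62 mm deep. Every
inter-tissue boundary carries a fixed, seeded, per-column displacement of
up to one voxel, emulating the voxel-scale irregularity of MRI-segmented
anatomy. These geometric choices matter for the surrogate premise:
perfectly flat or perfectly smooth layers act as idealized coherent
thickness resonators whose per-voxel intensity oscillates in the sampled
layer speeds (a skull-speed sweep on a flat-slab variant shows
interference nulls sweeping through voxels — not representable by any
second-order polynomial), whereas curvature, thin temporal bone and
segmentation-scale roughness decohere the layer echoes, restoring the
largely quadratic response the surrogate design presumes.

The benchmark study runs at this desk scale: 1 mm spacing (6 points per
wavelength in water at 250 kHz; the 0.5 mm, 12-point resolution is used for
the free-water focal characterization), 50-period runs, a 20-sample
training set for the 17-term u = 8 surrogate, a 100-sample simulation Monte
Carlo benchmark (the focal-voxel statistics converge well before 100
samples), matched-input surrogate resampling, and 50 validation
simulations — about 170 wave simulations in total, chosen to complete in
minutes on one CPU.

What the phantom does *not* emulate: skull curvature and thickness
variation across the beam, internal skull porosity, tissue interfaces
oblique to the grid, and realistic amygdala geometry. Flat interfaces
produce somewhat stronger standing-wave structure between transducer and
skull than curved anatomy would. Passing benchmarks here therefore
demonstrate the correctness and convergence of the machinery (solver,
surrogate, statistics, metrics) under realistic property variation, not
clinical-geometry accuracy.

## Numerical choices and edge cases

- Grid spacing is validated against `c_min / (f x points_per_wavelength)`
  (10% slack); the CFL bound is checked before stepping.
- `basis_size`/`build_basis` enforce `u >= 1, n >= 0`; order-0 bases are a
  single constant.
- Rank-deficient over-determined fits (duplicated samples) warn and return
  the minimum-norm solution.
- An empty evaluation mask, a zero reference voxel inside RMSPE, or
  mismatched validation pairs raise errors rather than degrade silently.
- `convergence_gap` returns a NaN sentinel when the final running std is
  zero (constant model).
- Fields are stepped in float32 (memory-bandwidth bound kernel) with
  float64 accumulation for RMS extraction and statistics; the linearity
  contract holds to ~1e-6 relative.

## What the benchmark does and does not achieve

On the default phantom the 20-sample surrogate reproduces the Monte Carlo
*mean* intensity field to about 1% RMSPE with a maximum error well under
1% of the free-water peak. Its *standard-deviation* field and the 3%
per-voxel pass rate are markedly worse. The error concentrates in the
water/skin region between transducer and skull (about a third of the
evaluation mask), where the steady state is an interference pattern of the
outgoing wave with layer echoes: at the tabulated skull and skin speed
spreads (12% and 5.7% sigma), the per-voxel continuous-wave intensity
there traverses an appreciable fraction of an interference cycle across
the sampled range and is not representable by any 17-term quadratic.
Curvature, thin temporal bone and boundary roughness progressively
decohere these echoes (each step was verified by speed-sweep residual
measurements), but a deterministic analytic phantom at 1 mm resolution
does not reach the decoherence of real segmented anatomy, for which this
class of surrogate is reported to reach >90% pass rates. The machinery —
solver contracts, fitting, matched-input statistics, metrics — is
verified independently of this geometric gap.

## Known limitations

- Shear waves in bone, nonlinear propagation, frequency-dependent
  attenuation and thermal effects are out of scope.
- The hard-source cap reflects incident waves; in strongly reverberant
  geometries a soft-source model would differ in the standing-wave detail.
- The annular-element phasing model assumes the device compensates the
  focal shift to its rated focal distance; devices configured for other
  focal depths should be described with explicit `element_phases`.
- At 6 points per wavelength the desk-scale solver carries a few percent of
  numerical dispersion; this is common-mode between the Monte Carlo and
  surrogate routes being compared.
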