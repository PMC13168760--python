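# Methods

This note documents the models, conventions, and design choices behind
`pillarforce`, and what its synthetic benchmarks do and do not demonstrate
about real recordings.

## Beam mechanics

Pillars are modeled as linearly elastic Euler–Bernoulli cantilevers with an
elliptical cross-section, clamped at the base, point-loaded at height *h*
(the tissue attaches near the pillar free end, so the default load height
is the full pillar height). The relations I = πab³/4, k = 3EI/h³, F = kδ
are exact within that model; a numerically integrated bending ODE
(`tip_deflection_numeric`) is kept alongside as an independent oracle and
agrees with the closed form to better than 0.1%.

Linear elasticity is a deliberate simplification of the nearly
incompressible hyperelastic behavior of soft 3-D-printed resins: all
quantities the package reports are linear in the load, and nonlinear and
large-rotation effects only matter beyond the small-deflection regime. Any
predicted deflection exceeding 10% of pillar height is therefore flagged
with a warning rather than silently reported.

Two spring constants coexist by design. The formula value at the standard
geometry (a = 300 μm, b = 200 μm, h = 4 mm, E = 2.414 MPa) is
k ≈ 0.213 μN/μm; bench calibration of a printed pillar can yield a
different value (e.g. 0.249 μN/μm), plausibly reflecting a lower effective
attachment height or print deviations. The package never silently
substitutes one for the other: the formula is the default, a calibrated
override is accepted everywhere a stiffness is consumed, and the CLI
refuses to compute forces without an explicit choice.

The design-space sweep varies pillar height (3.0–5.0 mm) and the
bending-direction semi-axis b (150–300 μm) at a fixed 1.5:1 elliptical
aspect ratio, so the standard pillar (300, 200) μm is a grid point. The
sweep values are interpreted as semi-axes, not full thicknesses, precisely
so that the chosen design lies inside the swept range.

Units: user-facing lengths in μm, moduli in MPa, forces in μN, stiffness in
μN/μm (numerically equal to N/m). Conversions to SI happen once, inside the
beam module.

## Orientation analysis

The angular convention is: 0° along the horizontal interpillar axis,
counterclockwise positive, angles folded into [−90°, +90°) (fiber
orientation is axial — θ and θ+180° are the same fiber). The histogram uses
36 half-open 5° bins with centers −87.5° … +87.5°; the idealized OI limits
(exactly 0 and 1) are realized by evaluating the statistic on point
distributions, which the `OrientationDistribution` container supports
directly. The discrete-uniform OI is 0.6368 at 5° bins and converges to
2/π as the bins shrink.

`orientation_index` requires weights that already sum to one (tolerance
1e-9) and raises otherwise — silent renormalization would mask upstream
bugs. OI of any valid distribution lies in [0, 1] because cos θ ≥ 0 on the
domain.

The histogram estimator tiles the image with half-overlapping windows
(default 64 px), Hann-windows and mean-subtracts each tile, and accumulates
2-D FFT power into angular sectors after rotating spectral angles by 90°
(a fiber's energy lies perpendicular to its wave vector). The DC core
(radius ≤ 2/tile) and near-Nyquist rim (radius ≥ 0.45 cycles/px) are
excluded. A constant image carries no directional signal and returns a
flagged uniform distribution with a warning. This estimator reproduces the
behavior of Fourier-spectrum directionality analysis but is not a
bit-for-bit reimplementation of any particular plugin; its validation is
statistical (modal-angle recovery within one bin at SNR ≥ 5, isotropic OI
within 0.05 of 2/π averaged over seeds, monotonicity in the concentration
of the generating distribution).

Multiple regions of interest per construct can be emulated by analyzing
deterministic tiles or seeded random crops; per-region OI and
pooled-histogram OI are both legitimate summaries and both are available
(the package does not hard-code one pooling rule).

## Pillar tracking

Detection is deterministic: global Otsu threshold, connected components,
area filter (default ≥ 20 px), intensity-weighted centroid per blob,
blobs ordered left to right. Exactly the expected number of blobs must
survive the filter; anything else raises an error naming the frame, rather
than guessing. Coordinates are 0-based pixel centers; distances are
center-to-center and calibrated by the pixel size.

Frame 0 is the zero-deflection reference. Per-pillar deflection is the
signed displacement along the interpillar axis, positive toward the
opposite pillar (contraction positive), so a symmetric contraction gives
equal positive deflections on both pillars. Identity across frames is kept
by nearest-neighbor assignment; a step larger than half the current
interpillar distance aborts with a tracking error since it likely means an
identity swap. Pre-tension present before the recording started is
unrecoverable from video by construction — forces derived from such traces
underestimate total force when evoked deflection is small relative to
pre-deflection, which is why metrics are also reported baseline-subtracted.

Compaction is measured as distance(t₀) − distance(t₁) per analysis window,
positive for shortening, with linear interpolation between samples.

## Contractility

Force per pillar is F = kδ per frame; the two-pillar total is the sum
(a 76 μN total corresponds to 38 μN per pillar), and the default analysis
channel is the per-pillar mean.

Baseline is the median of the 2 s preceding each stimulation epoch (falling
back to the epoch's 5th percentile when the recording starts mid-epoch).
Twitch amplitude is the mean of per-period peak heights above baseline;
peaks are local maxima with prominence ≥ 3× the trace noise scale
(MAD of first differences, rescaled) and separation ≥ half a stimulation
period — deterministic and documented rather than hand-tuned per trace. A
trace with no resolvable peaks yields zero amplitude with a warning.
Tetanic force is the mean of the last half of the tetanic epoch above
baseline (the first half is the fusion transient); plateau ripple is
reported alongside, and epochs shorter than twice the twitch relaxation
time trigger an unreliable-plateau warning.

The simulation kernel is a peak-normalized double exponential
A·(e^(−t/τ_d) − e^(−t/τ_r)) summed linearly over pulse times, plus optional
Gaussian noise, deterministic given a seed. Linear summation is a
deliberate simplification of excitation–contraction coupling: it reproduces
twitch trains, fusion, and a monotone force–frequency relation, but has no
saturation, so its high-frequency plateau grows linearly with rate and the
fusion ratio is larger than physiological values. Benchmarks that render
videos from this model therefore use short decay times (τ_d ≈ 0.1 s) to
keep plateau deflections inside the frame and the small-deflection regime.

Dose–response summaries report per-dose mean ± SD, n, ratio to vehicle, and
a monotonic-trend flag from the sign of the Spearman correlation between
dose and group mean (vehicle entering at dose 0). Effect sizes are pooled-SD
Cohen's d and two-group η² = SS_between/SS_total; zero pooled variance is
an error, not a zero.

## Electric field

The analytic estimate is the parallel-plate field E = V/d. The 2-D solver
discretizes Laplace's equation on a uniform grid (5-point stencil),
imposes Dirichlet potentials on the electrode columns, homogeneous Neumann
(mirror) conditions on walls and insulator boundaries, and solves the
sparse system directly; the discrete residual must fall below 10⁻⁶ of the
applied potential. Field magnitude uses central differences where both
neighbors conduct and one-sided differences at boundaries. The 2-D
cross-section stands in for the full 3-D chamber — adequate for shallow
observation wells — and insulators are perfect (zero normal flux), the
limiting case of a thin high-resistance coating. Validation: the empty
domain reproduces V/d within 0.5%, an insulating cylindrical inclusion
matches the classical analytic perturbation φ = −E₀(r + R²/r)cos θ away
from the staircase boundary, the solution is linear in voltage, flux
through closed interior contours vanishes, and mesh refinement changes
interior values by < 0.2%.

## Synthetic data

The generator emulates the study conditions of a two-pillar platform:
2.6 mm initial pillar spacing (260 px at the default 10 μm/px), elliptical
pillar tips elongated across the interpillar axis (semi-axes 300 × 200 μm),
bright pillars on a dim textured background, Gaussian pixel noise, and an
every-other-day imaging cadence for compaction series (8 frames spanning
two weeks). Compaction moves both pillars symmetrically inward following a
piecewise-linear profile; contraction adds a per-pillar inward waveform.
Every artifact carries a `GroundTruth` sidecar and is bitwise reproducible
from its seed.

Fiber textures are sums of anti-aliased line segments whose angles follow a
double-angle von Mises distribution (the standard axial construction), with
noise added to a requested SNR (signal SD / noise SD). Drug scenarios
program only the *direction* and rough magnitude of dose effects
(decreasing for the glucocorticoid ladder at 0.01/0.1/1.0 mM, increasing
for the androgen ladder at 0.01/0.1/1.0 μM, 5% between-tissue CV); the
multipliers are free parameters chosen once, not measurements. The
spacer/no-spacer scenario programs zero compaction for the spacer-held
(fixed-length) condition.

What passing these benchmarks shows: the pipeline recovers programmed
displacements, angles, and forces without systematic bias at realistic
noise levels, and propagates effect directions through to the summary
statistics. What it does not show: robustness to real-microscopy
confounders the generator omits — debris and focus drift, uneven
illumination, tissue occluding the pillars, out-of-plane motion, or
staining variability. Real deployments should verify detection masks on a
few frames before trusting batch output.

## Benchmark problem sizes

The compaction benchmark uses 10 tissues × 8 frames (≈ 400 × 130 px); the
video contractility benchmark uses 5 seeds × 450 frames at 30 Hz. These
sizes make the cohort means stable at the programmed tissue-to-tissue
spread while keeping the full suite fast on a laptop. The cohort-mean
recovery bound is 2 SEM of the programmed spread (SD 147.6 μm, n = 10
→ 2 SEM ≈ 93 μm); the tracking itself is accurate to a few μm, so nearly
all of the spread in the recovered mean is the programmed sampling
variation of the draws, not measurement error.

## Known limitations

- The beam model ignores shear deformation (Timoshenko corrections ~ (b/h)²
  ≈ 0.3% here), base compliance, and the stiffening disk at the pillar tip.
- The orientation estimator's angular resolution is set by the 5° bins and
  the tile size; textures with period ≳ tile size leak into the DC cutoff.
- Detection assumes bright pillars on a darker background and exactly two
  survive the area filter; occlusion by dense tissue will raise detection
  errors rather than degrade silently.
- The kernel model's linearity overstates fusion; absolute simulated
  tetanic forces are not physiological predictions.
- The field solver is 2-D and purely ohmic: no electrode polarization,
  electrochemistry, or 3-D well geometry.
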