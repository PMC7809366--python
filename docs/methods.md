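# Methods

This note records the models behind `holomass`, the defaults and why
they were chosen, the estimators and their numerical details, and what
the synthetic benchmarks do and do not establish about real data.

## 1. The signal model

A single cell's dry-mass trace over one cell-cycle interphase is

    m(t) = m0 + g·t + s(t) + b(t) + ε(t),     t = 0, 5, …, T(j) minutes

* `m0 + g·t` — linear growth; by default cells double their birth mass
  (~300 pg) over their cycle, so `g = m0/T(j)`.
* `s(t)` — the ultradian rhythm: a train of symmetric raised-cosine
  pulses, amplitude 100 pg, period 250 min (0.004 min⁻¹), full width
  60 min, i.e. **30 min full width at half maximum**. The width
  parameter denotes the raised cosine's support; its FWHM is half that.
  This parameterization reproduces both the reported spike width of the
  reconstructed waveform (~30 min) and the decaying harmonic comb of the
  cohort spectrum; a pulse with 30 min support (15 min FWHM) would make
  harmonics 1–8 nearly equal in amplitude, which contradicts the
  observed spectra and biases peak identification toward high
  harmonics. A triangular pulse and a negative pulse sign are available;
  cohort statistics use absolute amplitudes and cannot distinguish mass
  rise from drop — that ambiguity is intrinsic, and is why the waveform
  reconstruction returns a sign pair.
* `b(t)` — "biological" 1/f noise: spectrally shaped white Gaussian
  noise with power ∝ 1/f² (amplitude ∝ 1/f), ensemble-normalized to
  100 pg rms per trace and anchored to zero at birth so mass is
  continuous through divisions. Ensemble (not per-realization)
  normalization matters for red spectra: a single random slow component
  dominates each realization's variance, and rescaling by it would
  randomly rescale the rhythm band. The exponent follows the observed
  1/f amplitude background; the rms is a calibration choice (no value
  is published): 100 pg makes the rhythm undetectable in single cells
  and in ~30-cell cohorts but clearly detected at a few hundred cells,
  with the detection threshold crossed around a hundred cells —
  mirroring the reported emergence of the peak.
* `ε(t)` — white measurement noise, 35 pg (the stated precision of the
  lens-free dry-mass measurement).

Cohorts draw interphase durations from a lognormal (median 1200 min,
σ_log 0.25, truncated to [2 periods, observation length]) and uniform
pulse phase offsets (asynchronous culture). Each cell consumes an
independent, deterministically spawned substream of the master seed, so
cohorts are bitwise reproducible.

## 2. Optics

**Forward model.** A cell is a phase object: `A₀ = exp(i 2π OPD/λ)`,
λ = 647 nm. Phantoms are radially symmetric cosine domes (or soft-edged
discs) whose integrated OPD equals `mass · α` exactly, so the phantom's
ground-truth mass is recoverable by integration to better than 1 %.
Propagation to the sensor at Z = 1.5 mm uses the paraxial (Fresnel)
transfer function `H(f) = exp(−iπλZ|f|²)` applied in Fourier space with
periodic boundaries — unitary by construction, kernel of −Z the
conjugate of +Z. Pixel pitch defaults to 1.67 µm.

**Inverse problem.** Only `I_Z = |A_Z|²` is recorded. The retrieval
finds the sensor phase φ_Z minimizing the smoothed isotropic total
variation of the back-propagated field

    ε(φ_Z) = Σ √( ε₀ + |∂_x A₀|² + |∂_y A₀|² ),
    A₀ = (√I_Z · e^{iφ_Z}) * h_{−Z},   ε₀ = 10⁻⁴,

with forward differences and periodic wrap. The squared gradient moduli
make the criterion differentiable everywhere, which is the stated
purpose of ε₀ (with absolute values instead of squares no ε would make
it differentiable); the squared form also retains 0.65–0.8 of the
integrated cell phase on phantoms, consistent with the instrument-
calibration report of a ~0.65 signal reduction, whereas the
absolute-value form crushes half the signal. The data term is hard:
any φ_Z reproduces the measured intensity exactly.

**Optimizer.** Nonlinear conjugate gradients: analytic gradient
`∇ε = Im( conj(B) · P_{+Z}(V) )` with `V` the discrete divergence of the
normalized field gradients (validated against central finite differences
to 10⁻⁴ relative); Hestenes–Stiefel conjugation clamped at β ≥ 0 with a
descent-direction restart; step from a second-order expansion of the
criterion along the direction (curvature by symmetric differencing at a
~0.05 rad step), safeguarded by backtracking; fixed stop after 15
iterations. The criterion is non-increasing across iterations.

On a compact rounded-cell phantom (disc radius 8 µm, peak OPD 0.05 µm)
the 15-iteration retrieval halves the object-plane phase RMSE relative
to plain back-propagation of √I. The improvement is largest for compact
objects, whose twin image dominates the error budget; for large spread
cells the RMSE still drops but by less, and the dominant residual is
the sparsity-induced phase attenuation. Downstream mass conversion
divides by the 0.65 retention factor when the input came through the
retrieval; the factor is configurable and can be re-measured on
phantoms.

**Unwrapping.** Reconstructed phases beyond +π wrap to negative values;
every 4-connected strictly negative region is set to +π. On
reconstructions whose background ripples straddle zero the literal rule
would promote half the field, so the pipeline only promotes regions
dipping below −π/2 (`min_depth` parameter; the literal rule remains the
default of the function). Setting wrapped regions to the constant +π
caps their content, so quantitative mass work keeps peak phases below π
(peak OPD ≤ ~0.3 µm at 647 nm).

## 3. Detection, segmentation, tracking, divisions

Detection is scale-normalized Laplacian-of-Gaussian at σ = D/(2√2) for
the configured blob diameter D = 15 px, with responses normalized so an
ideal Gaussian blob of unit (radian) height scores 1.0, an absolute
quality threshold of 0.7, and sub-pixel quadratic refinement.
Segmentation grows 4-connected regions above a single phase threshold
from each seed; seeds sharing a component are split on the watershed of
the inverted phase. Linking solves an optimal assignment per frame pair
(squared displacement, 15 px cutoff, with no-link alternatives), then
closes gaps (≤ 15 px, ≤ 5 frames, ties by distance then gap) and
discards tracks with < 10 spots.

A division is declared when a track's mass drops ≥ 30 % within two
frames while a new track is born nearby. The implementation robustifies
this rule, necessarily at the detector's resolution: before/after
levels are 3-sample medians; the birth window is widened by one frame
on each side; the association radius is `gap_close + blob_radius`
(cells closer than a blob diameter are unresolvable, so a daughter's
first own detection appears up to a blob radius beyond her physical
appearance point); a transient elevation over the track's own growth
trend (two cells crossing, then separating) is rejected; repeated
triggers of one event are merged and the division frame is placed at
the sharpest single-frame drop. The 30 % threshold separates halving
(45–55 % drop) from noise and remains configurable.

The scene generator that exercises this chain renders cells as domes
whose radius tracks mass at fixed peak OPD (0.5 µm for the
ideal-phase tracking benchmark; 0.3 µm in the imaging pipeline, below
the wrap point); freshly divided cells start rounded (0.9 µm peak,
mass conserved) and re-spread over ~30 min; cells move as random
walkers (1.2 px/frame) with soft contact exclusion, since adherent
cells do not interpenetrate; daughters appear 13 px from the mother and
the siblings push apart. Mother and in-place continuation are one
physical trajectory — the tracker correctly follows the cell through
division — so purity/completeness are scored against merged
trajectories, and division recall counts events whose daughter lives
long enough to form a track at all (≥ min_spots frames before the
record ends). On the default scene the linker reaches purity ≈ 1.0 and
completeness ≈ 0.93–1.0, and division recall/precision ≈ 0.94/0.97
pooled over eight scene seeds.

## 4. Cohort spectral statistics

Per cell: linear detrend by least squares; apodization with
`sin(π(t−t₀)/T(j))` (zero at both ends); DFT amplitudes on the grid
`k/(T(j)·M)`, M = 25, evaluated by zero-padding to `M·(N−1)` points;
absolute amplitudes normalized by the window sum, making a unit
cosine's peak trace-length-invariant. Cohort: amplitudes accumulated in
bins of width `n_f/(T_max·M)` (n_f = 1 default), recording per-bin
mean, SD, count and **mean squared amplitude**.

**Background.** The mean amplitude in the 0.001–0.02 min⁻¹ band is fit
by iterative log-log least squares with 3-SD peak masking; a log-log
quadratic is used for subtraction (the windowed red noise bends away
from a pure power law near the low-frequency edge, and the misfit of a
straight line creates spurious edge excess), while the reported
background coefficient/exponent come from the best pure power law.

**Fundamental identification.** Bins are scored by standardized excess
`z = (mean − background)/(SD/√count)`, smoothed over ~M/2 bins (the
per-cell grids oversample the spectral resolution M-fold). The
fundamental is the maximizer of a harmonic-comb score (z stacked over
four harmonics, 1/√m weights) with an integer subharmonic walk-down
(factors 2 and 3) — matching the identification of the first sharp
peak together with its higher harmonics, and necessary because against
a 1/f background the single most significant bin is often a harmonic.
f₀ is refined by per-harmonic centroids (higher harmonics localize the
fundamental m-fold better); the refined estimate is unbiased to well
under one bin across replicate cohorts. A peak is "detected" when its
smoothed z exceeds 3 and its first harmonic shows positive excess —
the harmonic confirmation keeps the family-wise false-alarm rate of the
~1000-bin search far below the 5 % that a bare 3σ rule would give.

**Amplitude estimation.** The mean absolute amplitude of signal plus
incoherent noise is biased (Rice distribution), so harmonic amplitudes
for the reconstruction are recovered from the mean *squared* amplitude:
`a_m = √(mean_sq − background_sq)` at the local peak near m·f₀, which
is exactly unbiased (E|s+n|² − E|n|² = a²). The mean-amplitude AF of
the fundamental bin is still reported. For dose–response comparisons
(`fundamental_amplitude`, `compare_conditions`) the frequency is known
from the control, and the amplitude is read at that fixed frequency
against a local sideband background (flanks at 1–3 resolution widths,
local power-law fit) — this keeps the readout linear in the injected
amplitude down to 25 pg (R² > 0.99) and lets a fully suppressed
condition report ≈ 0.

**Reconstruction.** `s(t) = ± Σ_{m≤6} a_m cos(2π m f₀ t)`. Averaged
absolute amplitudes carry no phase, so harmonics are cosine-aligned and
exactly two sign solutions exist. Spike metrics: inter-spike interval
from the mean spacing of above-half-maximum groups; FWHM at
(max+min)/2 of the spike nearest the record midpoint; amplitude as
peak-to-trough. With six harmonics the ideal noiseless chain returns
102 pg / 31 min for the injected 100 pg / 30 min FWHM pulse; at default
noise, 300-cell cohorts give ≈ 95–105 pg, 31–35 min and 4.14–4.17 h
across seeds.

## 5. Problem sizes and runtime

The statistical claims are tested at desk scale: 300-cell cohorts
(≈ 240 samples per trace), 100 seeded replicates for the negative
controls, ten replicates for amplitude recovery, a 600-trace pool for
the cohort-size scan, 256×256 optics scenes and a 288×288, 180-frame
tracking scene with five founder cells. The full test suite runs in
about two minutes on one CPU; the acceptance script in seconds.

## 6. What the synthetic benchmarks do not show

The generator emulates the statistical structure the analysis assumes —
it cannot validate that structure against reality. In particular:
pulses are strictly periodic within a cell (no period drift or phase
diffusion), noise is Gaussian and stationary with a single spectral
exponent, phantom cells are radially symmetric phase objects without
absorption or internal structure, illumination is monochromatic and
fully coherent, motility is a random walk with contact exclusion rather
than measured cell behaviour, and the division morphology (rounding,
13 px daughter offset, separation drift) is stylized. Passing tests
therefore demonstrates that the pipeline recovers what it is designed
to recover under its own assumptions, with correctly calibrated
statistics — not that real cells behave this way. The retrieval loss
factor is fixed at 0.65 by default; on real instruments it should be
re-measured against a quantitative reference. The unwrap heuristic caps
wrapped regions at +π and is quantitative only for cells below the
wrap point.
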