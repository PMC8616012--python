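# Methods

## Polarization formalism and conventions

Stokes vectors are `[I, Q, U, V]ᵀ` with `I ≥ 0`; `Q`, `U`, `V` are the
residual intensities of 0° linear, 45° linear and right-handed circular
polarization.  `V > 0` means right-handed.  Orientation angles are measured
counter-clockwise from horizontal and are **degrees** at every public
interface.  The ideal linear retarder follows the sign convention in which a
quarter-wave plate with horizontal fast axis maps `[1, 0, 1, 0]` (45°
linear) to `[1, 0, 0, −1]` (left-handed circular).  The circular-analyzer
chain used by the instrument — a 135° quarter-wave plate followed by a 90°
polarizer — then has first-row response ∝ `[1, 0, 0, −1]`: it passes
left-handed circular light, which is what its channel name `L` denotes.
This is one of the two self-consistent handedness conventions; choosing the
other flips the sign of every `v`, with no effect on classification.

Inverted Stokes vectors from noisy voltages may fall outside the physical
cone (`Q² + U² + V² > I²`, i.e. DOP > 1).  They are **retained and flagged**,
never clipped: clipping would bias the distribution of `q, u, v, DOP` used
downstream.

## Analyzer forward model and calibration

The division-of-amplitude analyzer's instrument matrix is built row-by-row:
row *k* is the first row of the Mueller product of channel *k*'s elements,
scaled by the channel's splitter fraction, detector gain, and a pre-split
factor.  With unit gains and equal splits the rows are proportional to
`[1,0,0,−1]`, `[1,1,0,0]`, `[1,−1,0,0]`, `[1,0,1,0]`, each carrying the
polarizer's factor ½.

Design choices:

* **Splitter assignment.** The instrument's splitter stock (two 30:70, one
  50:50) is arranged 30 / 21 / 24.5 / 24.5 — the most nearly equal four-way
  split those parts allow.  The assignment only affects conditioning (the
  calibrated inversion absorbs any fixed throughput), so it is configurable.
* **Pre-split factor.** The 50:50 splitter that diverts light to the
  fluorescence arm is modeled as a configurable scalar (`pre_split`,
  default 1): in a calibrated instrument it is indistinguishable from an
  overall gain.
* **Noise model.** Additive zero-mean Gaussian noise per channel, SD
  configurable.  No instrument-specific noise spectrum is assumed.

Calibration solves `min_A Σ‖A·Sᵢ − Iᵢ‖²` over probe pairs (known Stokes
state, measured voltages); the solution is exact when the system is exactly
determined.  The default probe set is the six canonical fully polarized
states (H, V, ±45°, RCP, LCP), a standard well-conditioned choice.  Probe
sets are validated for ≥4 states and rank 4; a rank-deficient set is refused
with the unspanned Stokes direction named.  Reconstruction errors in
`q, u, v` are reported both worst-case and RMS, as **percentages of full
scale 2** (each component spans [−1, 1]); the full-scale denominator is
stated explicitly because percentage error is otherwise ambiguous.

## Pulse pipeline

* **Baseline**: rolling median (window defaulting to ~1/8 of the trace,
  odd), with noise SD = 1.4826 × MAD of the residual.  The median ignores
  sparse transits, so pulses do not inflate their own baseline.
* **Trigger**: the *sum* of the four scattering channels — a
  polarization-independent total-intensity proxy — must exceed
  baseline + k·noise_sd (default k = 5) for ≥ `min_width` samples (default
  8); runs closer than `min_separation` are merged.  SNR is defined as
  (peak − baseline)/noise_sd of the summed channels.
* **Integrals** are baseline-subtracted sums × sample interval
  (volt·seconds), over half-open index windows; the fluorescence integral
  `Fm` is taken over the *same* window as the scattering pulse, which is the
  instrument's simultaneity premise.
* **Rejection floor**: records whose recovered `I` falls below
  k·noise_sd·min_width·dt are counted and dropped rather than raised —
  dividing by a near-zero `I` would blow up every ratio feature.
* The default sampling rate (200 kHz) puts ≥20 samples across the 0.1 ms
  transit time.

## Fluorescence physics chain

The volumetric yield is the five-factor product
`F' = PAR · [chl a] · a̅* · Qa*(λem) · φF` in μmol photons m⁻³ s⁻¹.  The
μmol-photons → watts conversion (`N_A·h·c/λ` per mole, default emission
685 nm) is isolated in one routine so the unit bookkeeping is testable on
its own.  Collected power is total power × Ω/4π (0.014 sr → 0.11%), and
voltage is power × radiant sensitivity (default 5 V/nW) × an explicit DAQ
gain (default 1) — the gain is a per-instrument property with no principled
default, so it is a parameter rather than a constant.

Occupancy is concentration × volume (10⁵ mL⁻¹ × 0.01 μL = 1), with the
Poisson coincidence probability `P(≥2) = 1 − e^{−λ}(1+λ)` reported
alongside.  The exposure check multiplies beam power × dwell time × a
geometric interception factor (cell cross-section over focal-spot area,
capped at 1): only intercepted light deposits energy on the cell, and for a
micron-scale cell in a ~10 μm spot this factor is ≪1, which is why
sub-microjoule exposures are consistent with a 300 mW beam.  The default
damage threshold is 816.43 μJ (photosystem-II growth inhibition).

## Instrument simulator

Per-particle scattering Mueller matrices are drawn from a **parametric
family**: depolarizer · linear retarder · linear diattenuator, with
per-particle Gaussian jitter on the class parameters.  Each factor is a
physical Mueller matrix, so the product maps the physical Stokes cone into
itself by construction.  This family is *not* a Mie/T-matrix computation —
no per-class 120°-backscatter Mueller matrices are published for the target
particles — and every preset parameter is a constructed synthetic value.
The presets therefore reproduce the *qualitative* structure of the three
benchmark experiments, never measured values:

* `ps10-family`: three non-fluorescent microsphere classes distinguishable
  by polarization, plus a fluorescent twin with optics identical to one of
  them (separable only through `F`).
* `algae4`: four algae-like classes; two share one optical family
  (polarization overlap) and differ in fluorescence, with the highest-`F`
  class also having the widest spread, and class-mean `F` ordered
  P.G. > M.A. > D.S. > P.T.
* `submicron`: three low-amplitude classes (a bare submicron bead and two
  ~1 μm cyanobacteria analogues) separable with two LDA coordinates plus `F`.

Transits arrive as a Poisson process; each contributes a Gaussian temporal
profile (SD = transit_time/4) with a lognormal per-class amplitude — the
transit of a particle through a Gaussian focal volume at random impact
parameter.  Overlapping arrivals are rendered additively and counted, which
matches the single-occupancy operating assumption (they are rare at valid
concentrations, not impossible).  Every generator takes a mandatory seed and
is exactly reproducible.

What the simulator does **not** emulate: Mie-resonance structure, detector
impulse response, drift and 1/f noise, hydrodynamics of stirring, spectral
shape of the fluorescence.  Passing tests therefore demonstrate the
correctness of the measurement-and-classification chain, not instrument-level
performance on real water samples.

## Classification

LDA uses the Fisher criterion (scikit-learn, eigen solver) with optional
shrinkage for singular within-class scatter; projections are deterministic
given input order.  The classifier is an RBF-kernel SVM with a 5-fold
cross-validated grid search over C ∈ {1, 10, 100} and γ ∈ {scale, 0.1, 1},
evaluated on a stratified 70/30 held-out split with a fixed seed; features
are z-scored with training-split statistics only, since `I` and `F` live on
different scales from `q, u, v`.  Kernel and grid are package defaults (the
benchmark comparisons are directional, not tuned); both are configurable.

## Problem sizes and numerical choices

Benchmarks default to 300–500 particles per class (feature mode) or ~1 s of
200 kHz traces; the detection benchmark pools 100 seeded 0.05 s runs
(~500 events).  These sizes give the acceptance quantities sampling noise
well below their decision margins.  Tolerances: physicality and DOP checks
at 1e−9 relative; noiseless round trips asserted at <1e−9; Monte-Carlo
means at 4 standard errors.  Degenerate inputs (empty traces, I ≤ 0,
rank-deficient probe sets, singular scatter matrices) raise named errors
rather than propagating NaNs, except the per-pulse low-intensity rejection,
which is counted instead of raised.

## Known limitations

* The parametric scattering family spans diattenuation/retardance/
  depolarization but not full 16-parameter Mueller structure; classes are
  defined in that reduced space.
* Calibration is plain least squares; eigenvalue-calibration and
  self-calibration schemes are out of scope.
* The pipeline is offline (whole traces in memory); no streaming mode.
* Multi-particle coincidences are flagged but not deconvolved.
* Fluorescence is a single broadband integral; spectral resolution is out
  of scope.
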