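# Methods

This note documents the models, estimators and numerical choices behind the
package, the parameters that matter, and what the synthetic-data tests do and
do not demonstrate about real recordings.

## Problem setting

Linear-array ("laminar") probes record local field potentials (LFP) and
multi-unit spiking simultaneously across cortical depth. Assigning contacts
to cortical layers usually relies on current-source-density (CSD) analysis of
stimulus-evoked responses, which requires a triggering event and a clean
evoked sink/source pattern. The laminar-phase-coupling (LPC) method instead
uses the structure of ongoing activity: multi-unit spikes everywhere in the
column prefer the trough (±π) of the LFP measured on superficial and input
contacts, but the peak (0 rad) of the LFP measured on deep contacts. The
depth at which this preferred angle flips by ~π marks the boundary between
the input (granular) and deep (infragranular) layers. Because no stimulus is
needed, the boundary can be re-estimated on short epochs to track probe
drift.

## Generalized phase

Instantaneous phase is taken from the analytic signal `x + iH[x]` of the LFP
after a wideband 5–50 Hz fourth-order Butterworth filter applied
forward-and-reverse (zero phase). The high-pass edge removes slow
fluctuations that offset the analytic representation by a complex constant
and corrupt the arctangent phase; the 50 Hz low-pass keeps spike-waveform
energy out of the field. A wideband signal is not narrowband-analytic:
high-frequency intrusions ride on the dominant cycle and appear as epochs of
*negative* instantaneous frequency. These are detected from the
finite-difference phase derivative (computed by complex-plane
multiplication, `angle(X[n+1]·conj(X[n]))`); each maximal run of `N_c`
negative-frequency samples, together with the following `2·N_c` samples, is
replaced by shape-preserving piecewise-cubic (pchip) interpolation of the
unwrapped phase, anchored on valid samples at both ends.

Numerical choices:

* Detection and re-interpolation iterate (up to 4 passes) because
  interpolation near a gap edge can create a small new violation. Residual
  violations after the final pass are removed by a running-maximum
  projection of the unwrapped phase — a monotone repair that can introduce
  zero-frequency but never negative-frequency samples. After correction no
  interior sample has negative instantaneous frequency.
* pchip is local (each interval depends only on adjacent slopes), so the
  interpolator is built on a small set of anchor samples around each gap;
  this reproduces the full-series interpolant inside the gaps at a fraction
  of the cost.
* Filtering and the Hilbert transform run in single precision; the resulting
  phase error (~1e-5 rad) is orders of magnitude below the 0.05 rad
  tolerance used for phase accuracy. Edge transients are suppressed by 1 s
  reflect-padding before the forward-reverse filter.
* Filters are applied per run in the wrapped domain and re-wrapped to
  (−π, π] on output.

## Spike–LFP coupling and the LPC matrix

The spike-phase index (SPI) of a spike train against a phase series is the
mean resultant length of the phases sampled at spike times (nearest LFP
sample; at 1 kHz the sample period is ≪ one cycle of the 5–50 Hz band, so
interpolation would not change anything material). SPI ranges from 0
(uniform spike-phase distribution) to 1 (perfect locking); for von Mises
phase preference with concentration κ the population SPI is I₁(κ)/I₀(κ).

The LPC matrix evaluates every spike channel against every LFP channel's
generalized phase. Rows (spike channels) with fewer than `min_spikes = 300`
spikes are flagged invalid — preferred angles stabilize with a few hundred
spikes — but are still populated.

## Boundary detection

Column `c` of the angle matrix is summarized by the SPI-weighted circular
mean `phi(c)` over valid rows (weighting by SPI de-emphasizes cells whose
angle is poorly determined; an unweighted option is kept). For every cut
`k` between channels, let `d(k)` be the absolute circular distance between
the circular means of `phi` above and below the cut, and `R_above`,
`R_below` the corresponding mean resultant lengths. The detector maximizes

    score(k) = R_above(k) · R_below(k) · d(k)

The coherence factors are essential, not cosmetic: with an antipodal
profile, a side that mixes exact-π and exact-0 angles still has a circular
mean of exactly ±π (the unit vectors are collinear), so the bare distance
`d(k)` plateaus at π for *every* cut past the true flip and the argmax would
be decided by noise. The resultant lengths decay as the mixture grows, so
the product peaks uniquely at the flip. Ties resolve to the shallowest cut.

`boundary_channel` is the deepest channel on the superficial side (0-based).
The reported `reversal_strength` is `d(k*)/π ∈ [0, 1]`, and the estimate is
valid when `d(k*) ≥ min_strength` (default π/2, halfway between the
antipodal and degenerate cases). Both the score and the strength depend only
on angular differences, so the estimate is invariant to any global rotation
of the phase map, to a global LFP gain (phase is amplitude-free), and — in
expectation — to spike thinning that respects `min_spikes`.

Drift tracking applies the same detector to sequential windows (default
3-minute epochs); epochs with too few spikes yield an invalid estimate
rather than being dropped. Grand averaging re-indexes sessions to
boundary-relative depth and combines SPI arithmetically and angles by the
circular mean, with per-cell coverage counts.

## CSD analysis

The evoked response is the baseline-subtracted mean over stimulus-locked
epochs; events whose window leaves the record are dropped with a warning.
The CSD is the negated discrete second spatial difference
`−(V_{i−1} − 2V_i + V_{i+1})/h²` on interior channels, with conductivity
folded into the scale (σ = 1, units µV/mm²) since only the relative spatial
pattern matters here; sinks are negative. No edge extrapolation (Vaknin
padding) is applied — boundary finding never needs the outermost contacts.
Bicubic 4× depth upsampling is available for display; detection always runs
on the raw map. The input layer is the *earliest* sink: channels whose
windowed CSD minimum reaches `threshold_frac = 0.5` of the global minimum
form contiguous candidate regions, each dated by its first threshold
crossing, and the earliest region's top/bottom channels and onset are
returned. The bottom of this sink is the CSD reference for the input/deep
boundary.

## Laminar power and rate profiles

Band power per channel is the Welch PSD (1 s Hann segments, 50 % overlap)
averaged inside a low (8–30 Hz) and a high (65–100 Hz) band, normalized by
the across-channel, both-band mean, then z-scored across channels
(population SD), making the profile gain-invariant. The power crossover is
the first shallow→deep sign change of `high_z − low_z` from positive to
non-positive, linearly interpolated between the bracketing contacts; the
expected laminar pattern is superficial high-band dominance and deep
low-band dominance, so the first such crossing is the meaningful one.
Firing-rate profiles are spike counts per second normalized to the
all-channel mean rate.

## Circular statistics

Implemented directly from the standard closed forms: weighted mean
resultant; Watson–Williams F with the `1 + 3/(8κ̂)` small-concentration
correction (κ̂ from the pooled within-group resultant via Fisher's
approximation), with a warning attached when any group's mean resultant
length falls below 0.45; Jammalamadaka–SenGupta circular–circular
correlation with the large-sample normal p; Mardia circular–linear
correlation with the χ²(2) p. Degenerate inputs (antipodal means, zero
angular variance, constant covariates) return explicit undefined flags
rather than arbitrary values. The tests cross-check the correlations
against `pingouin` and the Watson–Williams p against a 10,000-shuffle
permutation null.

## Synthetic laminar recordings

The generator produces ground-truth sessions for every estimator:

* **Shared drive.** Unit-variance Gaussian noise band-limited to 5–50 Hz.
  Channel `i` receives `±drive`: +1 at or above the configured boundary
  channel, −1 below — the hard sign flip is the simplest expression of the
  dipole picture of the input/deep transition (a smooth-transition width
  parameter exists, default 0).
* **Spikes.** Inhomogeneous Poisson by thinning, rate
  `r · exp(κ·cos(φ_s − π))/I₀(κ)` where `φ_s` is the generalized phase of
  the drive, so all spikes prefer the trough of superficial-sign LFP and
  the peak of deep-sign LFP. The I₀ normalization keeps the mean rate
  κ-independent, decoupling the rate and coupling ground truths. Layer
  parameters default to κ = 0.35/0.25/0.15 and r = 2/6/5 Hz for
  superficial/input/deep — chosen to reproduce the qualitative laminar
  ordering (coupling strength decreasing with depth, superficial rates
  lowest) without targeting any real-data values; the input layer spans the
  5 channels ending at the boundary.
* **Background.** Per-channel 1/f-amplitude noise at half the drive SD
  (`noise_sd = 0.5`) — a realistic noise floor for cortical LFP.
* **Spectral gradient.** Independent 65–100 Hz noise on channels at/above
  the boundary and 8–30 Hz noise below it (amplitude 0.5 of the drive SD),
  so the high/low band-power z-profiles cross at the boundary, emulating
  the laminar power inversion.
* **Drift.** An optional schedule re-labels the flip depth over time.
* **Evoked trials.** A depth profile whose discrete second difference is a
  sink exactly on the configured channels and sources on the flanks (the
  injected second difference sums to zero — current conservation), scaled to
  unit LFP peak, with a Gaussian time course whose half-maximum rise sits
  exactly at the configured onset latency. Trial noise is white in time but
  spatially correlated across contacts (Gaussian kernel, SD 3 contacts =
  300 µm): ongoing LFP is coherent over several hundred micrometres, and
  spatially white noise would inject unrealistically large spatial curvature
  directly into the CSD.

One seed fixes all randomness; identical configurations reproduce sessions
bit-for-bit.

**What the generator does not emulate.** Biophysical forward models
(compartmental neurons, realistic volume conduction), task structure and eye
movements, non-stationary rates, spike-waveform leakage into the LFP,
common-reference artifacts, and real across-session heterogeneity of
coupling strength. Passing the synthetic checks therefore demonstrates the
estimators' correctness and robustness under the stated generative
assumptions — an antipodal phase flip observed through noise — not their
performance on any particular real dataset.

## Study-scale checks and problem sizes

The end-to-end suite uses a 20-session ensemble (32 channels, 100 µm
spacing, 600 s at 1 kHz, boundaries spread over channels 10–22, default
generator parameters) and verifies: boundary recovery within ±1 contact in
≥ 18/20 sessions; agreement of the power crossover with the LPC boundary
within ±1 contact in ≥ 18/20; and invariance of the estimate to a global
LFP gain, a global phase-map rotation, and 50 % spike thinning in ≥ 18/20.
Dedicated constructions check SPI against an independent Bessel-series
oracle (3 SE at n = 5000), generalized-phase accuracy on single tones
(< 0.05 rad RMS) and two-tone mixtures (zero interior negative-frequency
samples), exact and noisy CSD sink recovery, Watson–Williams agreement with
a 10,000-shuffle permutation null (±0.03 over 20 scenarios), and exact
recovery of a +2-channel mid-session drift. `scripts/acceptance.py`
recomputes all of these from scratch for any seed.

## Known limitations

* The detector localizes only the input/deep transition; the
  superficial/input boundary is not resolved by the phase flip.
* With very weak coupling (κ well below ~0.1) or spike counts below
  `min_spikes`, column angles are too noisy for a reliable flip estimate;
  the validity flag, not the boundary value, is the guard.
* The Watson–Williams p-value inherits the usual F-approximation error when
  group concentrations are low (the R < 0.45 warning).
* CSD units are relative (σ = 1); absolute current densities are out of
  scope.
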