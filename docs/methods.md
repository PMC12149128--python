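# Methods

## Signal model and the enhancement operation

Abdominal-surface EHG mixes two physiological bands: a slow wave
(0.01–0.1 Hz) of comparatively large amplitude and a fast wave (0.34–1 Hz)
that carries the conventional contraction signature but is weak and
noise-prone. Both are active during contractions. The enhancement treats
the slow wave as a contraction-synchronous gain:

    en(t_i) = RMS_slow(t_i) · f(t_i)

with the RMS envelope computed over a centred sliding window of
n = 50 samples at 5 Hz (10 s). Window bounds are inclusive,
`[i − ⌊n/2⌋, i + ⌊n/2⌋]`, truncated at the series edges, and the mean
inside the square root is always taken over the number of samples actually
present — so a constant input yields a constant envelope up to the edges
and partial windows are unbiased rather than zero-padded. An interior
window therefore holds n + 1 = 51 samples; every downstream statistic is
either scale-invariant or threshold-swept, so this choice of window
cardinality affects no result, only the exact energy values.

The 10 s window follows from the physiology: contractions last 30–90 s, so
windows above ~30 s oversmooth (the pipeline config warns in that case),
while much shorter windows track local structure such as spike artifacts.
With the slow band's upper edge at 0.1 Hz, 10 s spans one period of the
fastest slow-wave component. The enhanced signal's units are mV² (a
voltage times an RMS); no renormalisation is applied.

## Preprocessing

Band-splitting uses 4th-order Butterworth bandpass filters applied
forward–backward (`sosfiltfilt`) in second-order sections. Zero-phase
filtering is chosen so that contraction timing is not shifted relative to
the TOCO reference mask; the price is a doubled effective attenuation
order. Second-order sections keep the 0.01 Hz edge numerically stable at a
2048 Hz native rate (normalised cutoff ~1e-5). Filtering happens at the
native rate; both bands are then downsampled to 5 Hz with polyphase
rational resampling (ratio reduced to lowest terms, e.g. 5/2048). The
anti-aliasing FIR uses a Kaiser window with β = 14 and line-extrapolation
padding: passband ripple is then below 1e-6, which a constant-signal test
checks directly. The first/last 30 s of a filtered recording are flagged in
metadata as potential edge transients; downstream operations use the full
series, since no principled trimming rule exists for 20-min recordings with
contractions possibly near the ends.

Channel screening keeps a channel iff its maximum absolute fast-wave
amplitude lies in the closed interval [0.01, 0.3] mV — below it the
electrode has effectively lost signal, above it the trace is dominated by
artifacts. The maximum is taken after trimming three time constants of the
band's low edge (≈1.4 s for the fast wave) at each end so filter
transients cannot trip the screen. Screening is applied after
downsampling, at 5 Hz.

## Quality metrics

Each channel is scanned with the same centred 10 s window; each window
contributes one energy value `e = Σ i(t_j)²`. The energy histogram has a
baseline-noise mode and a contraction mode, and three statistics quantify
their separation: skewness and kurtosis as *population* standardised
moments (divisor N, kurtosis not excess — a Gaussian gives 3), and
PAER = 20·log₁₀(max e / mean e) in dB. N is the number of windows
(energy samples), i.e. the statistics describe the energy distribution
over all subsequences of the channel.

Spike artifacts inflate all three metrics, so energies above the empirical
0.95 quantile (linear-interpolation definition) are *discarded* before
computing them. Discarding, rather than clipping, bounds artifact
influence on PAER's maximum as well as on the moments. The quantile rule
applies to the metric computation only, not to detection: the threshold
grid is meant to span the energies the detector will actually see,
artifacts included.

## Detection and ROC evaluation

A sample is predicted "contraction" when its windowed energy strictly
exceeds a threshold (ties count as baseline). Thresholds sweep the z-score
grid μ + k·0.05σ, k = −60..60 (121 thresholds spanning μ ± 3σ), with μ and
σ (sample std) computed on the full untrimmed energy series. Predictions
are scored per sample at 5 Hz against the reference binary mask; windows
were considered as a scoring unit but per-sample counting is deterministic
and needs no extra convention. The ROC curve is anchored at (0,0) and
(1,1) and integrated by the trapezoid rule — implemented in integer
TP/FP counts so the AUC is exact (a perfectly separating channel scores
exactly 1.0). The operating threshold maximises Youden's J = TPR − FPR;
ties resolve to the lower threshold (higher sensitivity).

The package also exposes the threshold-free Mann–Whitney rank AUC of the
same energies. On random instances the 121-point grid AUC stays within
0.02 of it (grid-resolution bound, asserted in tests); the grid version is
the primary statistic because it reflects the thresholds the detector can
actually use.

## Spatial analysis

Channels with AUC ≥ 0.8 against the TOCO mask are "high-consistency". For
the signaling distance their electrode positions are projected along the
anterior–posterior axis (y := 0), the 2-D convex hull of the projected
(x, z) points is taken, and d is the mean Euclidean distance from the hull
*vertices* to the vertex centroid. Three conventions needed fixing where
the construction is ambiguous:

- the projection reading is the default; measuring the same hull vertices
  in full 3-D coordinates is available via `projected=False`;
- the centroid averages hull vertices only, not all set members and not
  the polygon-area centroid;
- collinear boundary electrodes are not vertices (strict hull, as computed
  by Qhull); vertices are listed counterclockwise from the lexicographically
  smallest projected point.

Degenerate sets degrade gracefully: one electrode gives d = 0; two
electrodes, or a fully collinear set, reduce to the segment extremes and
d = half the segment length — the same mean-distance formula applied to
the two extreme points. The growth ratios r_c and r_d compare
high-consistency channel count and signaling distance between the
fast-wave and enhanced arms; they are exact ratios, rounded to two
decimals only in report tables.

## Statistics

Arms are summarised as median and IQR (linear-interpolation quantiles)
because paired differences of the channel metrics are not normal. The
paired comparison is the two-sided Wilcoxon signed-rank test with zero
differences dropped and tied ranks averaged: exact null distribution up to
25 non-zero differences, normal approximation with continuity correction
above. Significance is declared at α = 0.05 and no multiple-testing
correction is applied (three metrics are reported as a family of
descriptive comparisons, matching standard practice for this analysis).

Note that a paired test across five subjects (n = 5) cannot reach
p < 0.05 two-sided — the exact floor is 2/2⁵ = 0.0625. The package
therefore reports exact p-values at whatever n it is given and leaves the
interpretation to the analyst; subject-level claims of significance at
n = 5 require a one-sided reading or channel-level pooling.

## Synthetic data: what it emulates and what it does not

The generator builds a 20-min recording (default) with a contraction
schedule drawn as: first onset uniform in [30, 120] s, inter-onset gaps
uniform in [120, 300] s, durations uniform in [30, 90] s. Since the
minimum gap exceeds the maximum duration, contractions never overlap; a
configuration violating that is rejected. Each contraction multiplies
band-limited slow and fast bursts (white noise filtered through the *same*
Butterworth designs as the analysis, normalised to unit RMS and scaled by
`slow_amp` > `fast_amp`) by a raised-cosine on/off envelope with 5 s ramps
and by exp(−distance/λ) attenuation from an origin electrode on a
half-cylindrical abdomen layout (radius 150 mm, anterior surface,
y = anterior→posterior). White Gaussian measurement noise is added
everywhere; optional spike artifacts are Poisson-placed transients of
width one 5-Hz sample and amplitude 10× `fast_amp`. All randomness flows
from the single config seed.

`SimConfig` defaults mirror a clinical recording (2048 Hz native rate,
1200 s). The named presets used by the test suites run at a 64 Hz carrier
instead: both analysis bands sit below 1 Hz, so after the 5 Hz downsample
the result is spectrally equivalent while simulation stays fast. Preset
amplitudes place the fast-wave detector where each regime requires —
`low_snr` (fast amplitude near the in-band noise floor; median fast-wave
grid AUC ≈ 0.6–0.8, calibrated once and pinned by seed), `high_snr` (both
arms ≥ 0.9) and `spiky` (exercises quantile trimming).

The generator reproduces the *spectral and timing* structure that the
enhancement exploits, plus distance-dependent attenuation. It does not
model myometrial electrophysiology (no action-potential propagation or
conduction velocity), electrode-skin impedance variation, maternal
ECG/respiration crosstalk, power-line interference, or non-stationary
motion artifacts. Passing suites therefore demonstrate that the pipeline
behaves as designed under the stated signal model — larger, noise-robust
slow waves co-occurring with weak fast waves — not that clinical
recordings will show effects of the same magnitude.

## Numerical and interface choices

- Sliding sums use cumulative sums (O(N)); tiny negative values from
  cancellation are clamped to zero before the square root.
- Half-open `[start, end)` mask intervals are rasterised by flooring the
  start and ceiling the end index, so quantisation never shortens a
  contraction; overlapping intervals merge with a warning.
- Growth-ratio and metric errors (zero denominator, zero variance,
  all-zero energies, single-class masks) raise informative `ValueError`s
  rather than returning NaN.
- On-disk formats are diff-able text: a delimited CSV dialect for
  recordings (`# fs=<Hz> band=<tag>` header, channel-id row, samples in
  rows), CSV for layouts/intervals/tables, YAML for pipeline config. EDF
  reading is available through `mne` when installed; there is no EDF
  writer.
- The pipeline is a pure function of (inputs, config, seed); the manifest
  records a config hash and per-stage log lines, and repeated runs are
  byte-identical.

## Known limitations

- Per-sample ROC scoring ignores event-level structure: a detector that
  fragments one long contraction into many short detections scores the
  same as one that finds it whole.
- The quality screen uses only the fast-wave amplitude range; flat-lined
  or railed slow-wave channels pass it.
- The signaling distance is Euclidean in electrode coordinates, not a
  geodesic over the body surface, and the projection convention makes it a
  2-D quantity by default.
- Exact Wilcoxon p-values are limited to n ≤ 25 non-zero differences;
  beyond that the normal approximation is used.
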