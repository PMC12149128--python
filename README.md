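# ehgkit

Slow-wave envelope enhancement of electrohysterography (EHG) signals, with
the full evaluation chain for contraction detection and spatial signaling
analysis.

## The problem

EHG records the electrical activity of the uterus from surface electrodes
on the abdomen. Contraction monitoring conventionally uses the *fast wave*
(0.34–1 Hz band), but that component is weak and easily swamped by motion
artifacts and measurement noise in a labor-and-delivery room, which degrades
energy-based contraction detection. The *slow wave* (0.01–0.1 Hz) is much
larger in amplitude and far more robust to the same noise, and it is active
during the same contractions.

`ehgkit` implements an enhancement that uses the slow wave as a time-varying
weight on the fast wave. With `s(t_i)` and `f(t_i)` the band-filtered slow
and fast signals (both downsampled to 5 Hz),

```
en(t_i) = RMS_slow(t_i) · f(t_i)
```

where `RMS_slow` is the sliding-window root-mean-square envelope of the slow
wave (window n = 50 samples = 10 s, centred, edge-truncated with the mean
taken over the samples actually present). During contractions the envelope
is high and baseline noise between contractions is suppressed, raising the
contrast between contraction bursts and background.

Around this operation the package provides, for multi-channel recordings:

- **preprocess** — 4th-order Butterworth band-splitting (zero-phase, SOS),
  polyphase downsampling to 5 Hz, and amplitude-based channel-quality
  screening (keep max |fast| within [0.01, 0.3] mV);
- **metrics** — sliding-window energies `e = Σ i(t_j)²`, 0.95-quantile
  spike trimming, and three separability metrics: skewness, kurtosis
  (population moments) and PAER = 10·log₁₀(max(e)²/mean(e)²) dB;
- **detect** — energy-threshold detection swept over a 121-point z-score
  grid (μ ± 3σ, step 0.05σ), per-sample ROC/AUC against a
  tocodynamometer (TOCO) binary mask, optimal threshold by Youden's J;
- **spatial** — high-consistency channels (AUC ≥ 0.8), convex-hull
  signaling distance (mean hull-vertex-to-centroid distance after
  projecting out the anterior–posterior axis), and the growth ratios
  `r_c = (ch_E − ch_f)/ch_f`, `r_d = (d_E − d_f)/d_f`;
- **stats** — median/IQR summaries and paired two-sided Wilcoxon
  signed-rank tests (exact null up to n = 25);
- **synthetic** — a seeded generator of multi-channel recordings with known
  contraction ground truth, distance-dependent attenuation from a
  contraction origin, and optional spike artifacts, so every stage is
  testable without clinical data.

It is aimed at researchers working on uterine electrophysiology and
biomedical signal processing who need a reproducible reference
implementation of the envelope-enhancement method and its evaluation stack.

## Worked example

Simulate a low-SNR 12-channel labor recording and run the whole chain:

```bash
cat > demo.yaml <<EOF
seed: 7
preset: low_snr
n_channels: 12
EOF
ehgkit run --config demo.yaml --out-dir demo_out
```

prints

```
input: simulated preset 'low_snr', 12 channels, 6 contractions
preprocess: kept 12/12 channels at 5.0 Hz
enhance: window 50 samples (10.0 s)
mask: 32.9% positive samples
metrics: skewness/kurtosis/PAER per channel per band
detect: median AUC fast=0.638 enhanced=0.947
spatial: consistency sets, hulls, growth ratios
stats: paired Wilcoxon fast vs enhanced
```

The median detector AUC rises from 0.638 (fast wave alone) to 0.947 after
enhancement: on low-SNR channels the energy detector misses contractions
that the slow-wave weighting recovers. `demo_out/stats.csv` holds the
paired comparison —

```
  metric  median_fast  median_enhanced  p_value
skewness     0.356224         2.123864 0.000488
kurtosis     2.500837         6.942170 0.000488
    paer     5.317399        17.562416 0.000488
```

— all three separability metrics increase on every channel (with 12
channels the two-sided exact Wilcoxon floor is 2/2¹² ≈ 0.000488), and
`demo_out/spatial.csv` shows the high-consistency region growing from 2 to
11 channels (`r_c = 4.5`) with the signaling distance rising from 41 mm to
177 mm. The same stages are available individually (`ehgkit simulate`,
`preprocess`, `enhance`, `metrics`, `detect`, `spatial`, `stats`) and as
library functions.

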