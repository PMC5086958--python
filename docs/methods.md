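# Methods

This note documents the models, statistical procedures and numerical
choices behind `tmseeg`, and what the synthetic validation does and
does not establish about real recordings.

## Synthetic TMS-EEG model

A simulated trial for one block (subject × TBS condition × phase ×
stimulated area) is

    x(c, t) = Σⱼ aⱼ fⱼ s τⱼ(c) g(t; λⱼ, wⱼ)              (TEP components)
            + Σₘ bₘ fₘ s ρₘ(c) e(t; dₘ) cos(2π f̃ₘ t + φₘ)  (induced oscillations)
            + noise(c, t)

* **TEP components.** Six Gaussian-envelope deflections named by their
  polarity and latency — P30 (30 ms), N45 (45), P60 (60), N100 (100),
  P180 (180), N280 (280 ms) — each with a phenomenological scalp
  topography τ: a Gaussian spatial kernel on the 2-D projected montage,
  centered on a named electrode. M1 templates center the early
  positivity and the P180 on C3 (kernel SD 0.30 / 0.32 head radii),
  the N45 contralaterally on C4, and the N100 on Cz (0.42); the
  noise-free sum peaks at ≈ ±4 µV. PPC templates are parietal and
  ~30 % smaller. Component envelopes are deliberately broad for the
  late components (N100 SD 45 ms, P180 SD 60 ms): briefer envelopes
  would carry broadband spectral energy into the α band, which would
  confound evoked-amplitude changes with oscillatory-power changes in
  the TRSP (real late TEP components are slow waves, not impulses).
* **Induced oscillations.** Exponentially decaying sinusoids with a
  uniformly random phase per trial (so they average out of the evoked
  response but survive in trial-averaged wavelet power) and small
  per-trial frequency jitter. M1: 11 Hz (amplitude 5.5 µV, decay time
  constant 150 ms) and 18 Hz (4.5 µV, 100 ms), centered on C3 — the
  high-α / low-β "natural frequency" of sensorimotor cortex. PPC: 6
  and 14 Hz. Phase randomness is part of the noise model
  (`phase_jitter`), so the zero-noise limit is fully deterministic.
* **Noise.** Per channel: white sensor noise (SD 1.5 µV), 1/f
  background (SD 3.5 µV) that is *spatially correlated* across
  electrodes (rows of a Gaussian mixing kernel, radius 0.5 head radii,
  per-channel SD preserved) — background cortical activity is coherent
  over centimeters, and the LMFP, which measures deviation from the
  local mean, cancels exactly this common mode — 50 Hz line noise with
  random phase per epoch, Poisson blink transients (3/min, 90 µV,
  frontally projected, dominant on the EOG channels when present), and
  a deterministic residual pulse artifact, 50 µV decaying with a 3 ms
  time constant over 0–10 ms, for the interpolation stage to remove.
  These SDs describe the 1–80 Hz band-limited content at the 1000 Hz
  simulation rate; equipment-level recordings at 5 kHz with a 1 kHz
  antialiasing band carry correspondingly larger broadband SDs.
* **Between-subject variability.** Each subject multiplies every
  component/oscillation amplitude by an independent lognormal factor
  (σ = 0.1), drawn once per subject and shared across that subject's
  blocks, which is what makes the pre/post contrast a paired design.
* **TBS-like modulation** applies to *post* blocks only: a gain on TEP
  components whose latency falls in 100–200 ms, restricted to the
  affected channels (default: FCz, FC1, Cz, C3, CP1, CP5), and
  per-band gains on oscillation amplitude. Defaults mirror the
  direction structure of interest: cTBS gain 1.3 with α × 0.7, iTBS
  gain 0.7 with β × 1.3, sham the identity. The gains are free
  parameters of the generator, not empirical estimates.

**Calibration.** Single-trial noise levels and subject variance are
not identifiable from group statistics alone, so they were fixed once
by the requirement that the default study design (10 subjects per
group, 80 trials per block) has high power for the default effect
sizes while null simulations stay at nominal false-positive rates:
at these defaults the P180-window cluster, the LMFP run, and the TRSP
post-hoc pattern are each recovered in ≳ 90 % of simulated studies,
and null (unit-gain) simulations show ≈ 0–5 % positives. These are
*assumptions*: passing tests show that the analysis chain detects the
statistical structure it targets at realistic sample sizes, not that
real TMS-EEG data have this signal-to-noise ratio.

**Fast path.** `simulate_evoked_dataset` draws each block's trial mean
directly: Gaussian noise at SD/√n (exact), the random-phase
oscillation residual from its central-limit distribution (two
quadratures, each N(0, 1/(2n))). Line noise, blinks and the pulse
artifact — targets of preprocessing, absent from clean data — are
omitted. A test verifies the fast path's residual scale against the
trial-level reference. Simulation studies (type-I, power) use this
path; the TRSP study needs single trials and simulates them on the
ROI channels at 500 Hz.

What the generator does **not** emulate: latency jitter of components,
dipolar (signed) topographies, non-stationary noise, electrode drift
or bridging, inter-areal propagation delays, and any biophysics —
topographies are phenomenological kernels, not forward-model fields.

## Statistics

* **Cluster test.** Element threshold: |t| > t₉₇.₅ of the t(n−1)
  distribution per tail (the printed p < 0.025 rule). Linking: montage
  neighbors at the same timepoint, same electrode at consecutive
  timepoints; a component qualifies only if two member electrodes are
  graph neighbors at some common timepoint (so a single electrode,
  however long suprathreshold, never forms a cluster). The null is the
  per-permutation maximum |mass| pooled over all six windows and both
  polarities — one family-wise control across the whole TEP analysis.
  Degenerate zero-variance elements get t = 0 and are counted in the
  result rather than raising, since flat synthetic channels would
  otherwise poison the map. Monte Carlo p-values use the add-one
  correction and a relative tolerance of 1e-9 when counting ties so
  the identity permutation is never lost to roundoff.
* **LMFP test order.** Pointwise sign-flip permutation p-values →
  Benjamini–Hochberg across timepoints (q = 0.05, configurable or
  disabled) → threshold p < 0.025 → runs of ≥ 10 consecutive rejected
  points. With min_run = 1, FDR off and exhaustive flips this reduces
  to the pointwise exact sign-flip test (asserted in a test). The run
  criterion counts *timepoints*, so its temporal extent depends on the
  analysis sampling rate (10 points = 10 ms at 1 kHz); `min_run` is
  configurable. Note that at 3000 permutations the smallest achievable
  pointwise p is ~3×10⁻⁴ (or 1/(2ⁿ+1) under exhaustive flips), which
  bounds how sparse a significant region can be and still survive
  BH FDR — permutation counts much below 3000 make the combined
  procedure extremely conservative.
* **rm-ANOVA.** Classical sums-of-squares decomposition for fully
  crossed within-subject designs (any number of factors; the error
  term for an effect is its interaction with subjects), computed by
  inclusion–exclusion over cell totals. Greenhouse–Geisser ε and
  Mauchly's W come from the covariance of subject scores projected on
  the effect's orthonormal contrast (Kronecker product across factors);
  Mauchly's p uses the chi-square approximation with the second-order
  term, matching ezANOVA/pingouin. GG-corrected degrees of freedom are
  applied only when Mauchly's p < 0.05 and the effect has more than
  1 df. Partial η² = SS_effect / (SS_effect + SS_error). Huynh–Feldt
  is not implemented. Both the three-way (TBS × Time × Frequency) and
  the post−pre two-way (TBS × Frequency) parameterizations are
  provided; for a balanced design their interaction F values coincide,
  which the example output reproduces. Bonferroni post-hocs multiply by
  the number of comparisons actually made.
* **Permutation scheme.** Paired condition swaps = sign flips of
  per-subject differences; exhaustive enumeration of all 2ⁿ
  assignments replaces sampling whenever 2ⁿ ≤ n_perm, making small-n
  p-values exact.

## Time–frequency decomposition

Morlet wavelets come from mne (`mne.time_frequency.morlet`,
zero-mean, σ_t = cycles/(2πf)); the transform is a batched
FFT "same" convolution over all trials and channels per frequency,
asserted numerically identical to `mne.time_frequency.tfr_array_morlet`
in the test suite. The frequency grid is *linear*, 4–50 Hz in 23 steps
(≈ 2.09 Hz spacing); the printed integer band edges (θ 4–6, α 7–13,
β 14–30, γ 31–50 Hz) are applied to bin centers as [low, high+ε), so
bins strictly inside the 6–7 Hz gap belong to no band. TRSP values are
raw power differences in µV² (subtractive baseline), not dB.

Samples closer to an epoch edge than a wavelet's effective
half-support, cycles/(2f) seconds, are flagged invalid; baseline and
analysis windows must avoid them. At 3.5 cycles the 4 Hz half-support
is 0.44 s, so with −1 s epochs the earliest valid baseline start is
−0.5625 s; the default baseline is [−0.55, −0.15) s.

## Preprocessing choices

Stage order is fixed (interpolate → average reference → band-pass →
notch → ICA → epoch → reject) and the driver refuses a reordering
without an explicit override. The cubic artifact interpolation fits a
least-squares cubic to 5 ms flanks ([−6, −1] and [+10, +15] ms; at
least 4 samples per side) rather than a 4-point spline — exact for
cubic inputs, robust to noisy flanks. Butterworth order 3 applied
forward–backward (zero phase, effective order 6); notch is a
second-order IIR, quality 30, zero phase. ICA: PCA whitening to the
data rank (average-referenced data lose one dimension), extended
INFOMAX (mne's implementation) with a fixed seed, and automated
component rejection replacing visual inspection: |r| ≥ 0.7 with an
EOG channel (ocular), ≥ 60 % of spectral power above 60 Hz (muscle),
or RMS in the 0–30 ms post-pulse windows ≥ 3× overall RMS (residual
TMS artifact); all scores are logged per component. Channels labeled
EOG* are excluded from the average reference, trial rejection and all
statistics but feed the ocular criterion. Trial rejection flags (never
deletes) trials with scalp peak-to-peak > 200 µV.

## Known limitations and deliberate scope

* The montage ships the study's printed 31-channel list; the parietal
  ROI named in the source protocol includes electrodes (P5/P6) absent
  from that list, so the default PPC ROI is {P3, P7}, overridable in
  the config.
* Analyses assume a complete paired design; missing cells are an
  error, not imputed.
* Simulation studies in the tests and the acceptance script run at
  reduced replicate counts (12–40 datasets per rate) with binomial
  margins computed at the count actually used; the default sampling
  rate is 1000 Hz (simulation) and 500 Hz (time–frequency studies),
  chosen as desk-scale working points and configurable up to 5 kHz.
* No source localization, no TFCE, no cluster-size statistic, no
  between-group (unpaired) cluster test, no Huynh–Feldt, no dB-scaled
  TRSP, no EDF/CNT readers, and no plotting — result tables are
  written as TSV for external plotting tools.
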