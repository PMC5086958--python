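# tmseeg

Analysis pipeline for TMS-EEG experiments: TMS-evoked potential (TEP)
statistics with spatiotemporal cluster-based permutation tests, local
mean field power (LMFP) contrasts, Morlet-wavelet TMS-related spectral
perturbation (TRSP) with repeated-measures ANOVA, the preprocessing
chain that feeds them, and a synthetic multi-subject TMS-EEG generator
with known ground truth for validating every stage.

It is written for researchers who record EEG time-locked to single TMS
pulses (here: over primary motor cortex M1 and posterior parietal
cortex PPC) and want to test how an intervention — continuous or
intermittent theta-burst stimulation (cTBS / iTBS) of the cerebellum,
applied between a *pre* and a *post* block — changes evoked and
induced cortical activity.

## The analyses

**TEP cluster statistics.** Per-subject evoked responses (trial means)
are compared pre vs post with elementwise dependent t-tests inside six
component windows of interest (P30 10–35 ms, N45 35–55, P60 55–70,
N100 70–130, P180 130–250, N280 250–360 ms). Suprathreshold elements
(per-tail p < 0.025) of one polarity are linked across neighboring
electrodes (Delaunay adjacency) and consecutive timepoints; a cluster
needs at least two co-active neighboring electrodes. Cluster mass
(summed t) is referred to a Monte Carlo null of the per-permutation
maximum |mass| over all windows and both polarities, built from 3000
subject-level condition swaps (sign flips of paired differences, with
exhaustive enumeration when 2^n is smaller), with the add-one
correction so p ≥ 1/(1+n_perm).

**LMFP.** For an ROI of K electrodes (M1: C3, CP1, CP5; PPC: P3, P7),

    LMFP(t) = sqrt( (1/K) Σᵢ (Vᵢ(t) − V̄(t))² )

the root-mean-square deviation of ROI voltages from their instantaneous
mean — a reference-free index of local activation, computed from
−100 to +500 ms. Pre/post subject traces are compared pointwise
(paired t, sign-flip permutation p, Benjamini–Hochberg FDR across
timepoints at q = 0.05, threshold p < 0.025), and only runs of at
least 10 consecutive significant timepoints are reported.

**TRSP.** Single trials are decomposed with complex Morlet wavelets
(23 linearly spaced frequencies, 4–50 Hz, 3.5 cycles), and
TRSP(f,t) = (1/n) Σₖ |Fₖ(f,t)|², the trial-averaged power, is
baseline-normalized by subtracting the mean pre-stimulus power
spectrum. Band averages (θ 4–6, α 7–13, β 14–30, γ 31–50 Hz) over the
ROI and 10–300 ms feed a within-subject TBS × Time × Frequency ANOVA
with Mauchly's sphericity test, Greenhouse–Geisser correction when
Mauchly's p < 0.05, partial η², and Bonferroni post-hocs.

**Preprocessing.** Cubic interpolation of the residual TMS artifact
(−1 to +10 ms), average re-reference, 1–80 Hz zero-phase Butterworth
band-pass, 50 Hz notch, INFOMAX ICA with automated ocular / muscle /
residual-artifact component rejection, epoching −1 to +1 s, and
amplitude-based trial flagging.

**Synthetic generator.** Multi-subject datasets with a stereotyped TEP
component sequence, area-specific induced oscillations (M1: 11 and
18 Hz; PPC: 6 and 14 Hz), spatially correlated 1/f background plus
sensor noise, line noise, blinks, a decaying pulse artifact, lognormal
between-subject amplitude variability, and an injectable TBS-like
modulation (default: cTBS ×1.3 / iTBS ×0.7 on components in
100–200 ms over the M1 electrodes, with α ×0.7 under cTBS and β ×1.3
under iTBS on the induced oscillations). See `docs/methods.md` for the
model and its calibration.

## Worked example

Run the full chain on a simulated study (10 subjects, cTBS and iTBS,
both areas, 80 trials per block at 500 Hz; ~2 minutes):

```python
from tmseeg.config import PipelineConfig
from tmseeg.pipeline import run_pipeline

config = PipelineConfig({
    "seed": 5,
    "simulation": {"n_real": 10, "n_sham": 0, "sampling_rate": 500.0},
    "tep": {"n_perm": 1000},
})
run_pipeline(config, "results_demo")
```

`results_demo/tep_clusters.tsv` then contains (significant rows,
p < 0.025):

```
area condition contrast     toi  polarity t_start_ms t_end_ms channels               mass      monte_carlo_p
M1   cTBS      post_vs_pre  P180 positive 130.0      248.0    C3,CP1,CP5,Cz,...      1179.7     0.000999
M1   cTBS      post_vs_pre  N100 negative 70.0       128.0    C3,CP1,Cz,FC1,FCz      -896.4     0.000999
M1   iTBS      post_vs_pre  P180 negative 130.0      248.0    C3,CP1,CP5,Cz,FC1,FCz  -1193.4    0.000999
...
```

cTBS produces a positive late cluster over the stimulated-hemisphere
electrodes (the injected 1.3 gain on P180 raises voltage there after
the intervention) and a negative N100-window cluster (the same gain
makes the negative N100 more negative); iTBS mirrors both. The
`lmfp_runs.tsv` table localizes the change in time:

```
area condition    contrast            start_ms end_ms direction
M1   cTBS         post_vs_pre         52.0     234.0  post>pre
M1   iTBS         post_vs_pre         62.0     244.0  post<pre
M1   cTBS_vs_iTBS post_pre_difference 48.0     246.0  cond1>cond2
```

and `trsp_anova.tsv` / `trsp_posthoc.tsv` report the oscillatory
effect, e.g. for M1 the TBS × Time × Frequency interaction
F(1.16, 10.45) = 46.35, p = 0.000026, partial η² = 0.837
(Greenhouse–Geisser corrected; Mauchly p < 0.05), with post-hocs
showing the α decrease under cTBS (pre−post = +22.7 µV², Bonferroni
p = 0.0067) and the β increase under iTBS (pre−post = −13.2 µV²,
p = 0.00003). Occasional short significant runs outside the modulated
window (e.g. a pre-stimulus LMFP run) are the false discoveries the
q = 0.05 FDR level permits.

The same steps are available from the shell:

```bash
tmseeg simulate --seed 5 --n-subjects 10 --out sim/
tmseeg report --seed 5 --out results_demo/
```

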