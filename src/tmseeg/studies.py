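"""Simulation studies: type-I error and effect-recovery rates.

These helpers run one simulated study dataset through a single analysis
stage and report the qualitative outcome (cluster found / significant
run found / post-hoc pattern found). Aggregating the outcomes over many
seeds gives empirical false-positive rates on null (unit-gain) data and
recovery rates under the default theta-burst-like modulation. The
statistics-level studies use the evoked fast path of the generator and
the study-scale design (10 subjects, 80 trials per block); the
time-frequency study simulates trials on the ROI channels at 500 Hz to
keep the wavelet transforms tractable.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .cluster import cluster_permutation_test
from .lmfp import M1_ROI, ROIDefinition, compute_lmfp, lmfp_condition_test
from .montage import Montage, build_neighbor_graph, default_montage
from .simulate import (ModulationSpec, NoiseModel, SimulationConfig,
                       default_modulation, simulate_dataset,
                       simulate_evoked_dataset)
from .trsp import WaveletParams, band_roi_average, baseline_normalize, morlet_power, trsp_anova

__all__ = [
    "M1_ROI_CHANNELS",
    "null_modulations",
    "effect_modulations",
    "single_area_design",
    "tep_cluster_outcome",
    "lmfp_outcome",
    "trsp_outcome",
    "roi_montage",
]

M1_ROI_CHANNELS = ("C3", "CP1", "CP5")


def null_modulations(roi_only: bool = False) -> dict[str, ModulationSpec]:
    """Unit-gain (no-effect) modulations for both TBS labels."""
    channels = M1_ROI_CHANNELS if roi_only else \
        tuple(default_modulation("cTBS").affected_channels)
    return {
        "cTBS": ModulationSpec("cTBS", gain=1.0, affected_channels=channels),
        "iTBS": ModulationSpec("iTBS", gain=1.0, affected_channels=channels),
        "sham": ModulationSpec("sham"),
    }


def effect_modulations(roi_only: bool = False) -> dict[str, ModulationSpec]:
    """The default cTBS/iTBS modulations (optionally ROI channels only)."""
    roi = M1_ROI_CHANNELS if roi_only else None
    return {c: default_modulation(c, roi) for c in ("cTBS", "iTBS", "sham")}


def single_area_design(n_subjects: int, area: str = "M1",
                       conditions: tuple[str, ...] = ("cTBS", "iTBS"),
                       ) -> pd.DataFrame:
    """A reduced design table: one area, pre/post, the given conditions."""
    rows = []
    for i in range(n_subjects):
        sid = f"R{i + 1:02d}"
        for cond in conditions:
            for phase in ("pre", "post"):
                rows.append((sid, "real" if cond != "sham" else "sham", cond,
                             phase, area, f"{sid}_{cond}_{phase}_{area}"))
    return pd.DataFrame(rows, columns=["subject_id", "group", "condition",
                                       "phase", "area", "block_id"])


def roi_montage(channels: tuple[str, ...] = M1_ROI_CHANNELS) -> Montage:
    """Montage restricted to a channel subset (for ROI-only simulation)."""
    full = default_montage()
    idx = [full.index(c) for c in channels]
    return Montage(list(channels), full.positions_2d[idx],
                   None if full.positions_3d is None else full.positions_3d[idx])


def _evoked_stacks(seed: int, n_subjects: int, condition: str,
                   modulations: Mapping[str, ModulationSpec],
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    design = single_area_design(n_subjects, conditions=(condition,))
    config = SimulationConfig(n_subjects=n_subjects, seed=seed)
    evokeds = simulate_evoked_dataset(design, config, modulations)
    subjects = list(dict.fromkeys(design["subject_id"]))
    pre = np.stack([evokeds[(s, condition, "pre", "M1")] for s in subjects])
    post = np.stack([evokeds[(s, condition, "post", "M1")] for s in subjects])
    return config.times, pre, post, config.montage.channel_labels


def tep_cluster_outcome(
    seed: int,
    condition: str = "cTBS",
    modulations: Mapping[str, ModulationSpec] | None = None,
    n_subjects: int = 10,
    n_perm: int = 500,
    alpha: float = 0.025,
) -> dict:
    """Cluster test of post vs pre for one simulated dataset.

    Returns the significant clusters plus convenience flags: whether any
    cluster is significant at ``alpha`` per tail, and whether a
    P180-window cluster of the expected polarity touches the M1 ROI.
    """
    modulations = modulations or effect_modulations()
    times, pre, post, labels = _evoked_stacks(seed, n_subjects, condition, modulations)
    graph = build_neighbor_graph(default_montage())
    result = cluster_permutation_test(post, pre, times, graph, labels,
                                      n_perm=n_perm, seed=seed)
    significant = result.significant(alpha)
    expected_polarity = "positive" if condition == "cTBS" else "negative"
    hit = any(c.toi == "P180" and c.polarity == expected_polarity
              and set(M1_ROI_CHANNELS) & set(c.channels) for c in significant)
    return {"n_significant": len(significant), "any_significant": bool(significant),
            "p180_roi_hit": hit,
            "clusters": [(c.toi, c.polarity, c.monte_carlo_p, c.channels)
                         for c in significant]}


def lmfp_outcome(
    seed: int,
    condition: str = "cTBS",
    modulations: Mapping[str, ModulationSpec] | None = None,
    n_subjects: int = 10,
    n_perm: int = 3000,
    roi: ROIDefinition = M1_ROI,
    effect_window: tuple[float, float] = (0.10, 0.20),
) -> dict:
    """LMFP post-vs-pre run detection for one simulated dataset."""
    modulations = modulations or effect_modulations()
    times, pre, post, labels = _evoked_stacks(seed, n_subjects, condition, modulations)
    pre_tr = np.stack([compute_lmfp(e, labels, roi, times).values for e in pre])
    post_tr = np.stack([compute_lmfp(e, labels, roi, times).values for e in post])
    trace_times = compute_lmfp(pre[0], labels, roi, times).times
    runs = lmfp_condition_test(pre_tr, post_tr, trace_times, n_perm=n_perm, seed=seed)
    expected = "post>pre" if condition == "cTBS" else "post<pre"
    hit = any(a < effect_window[1] and b >= effect_window[0] and d == expected
              for a, b, d in runs.intervals)
    return {"intervals": runs.intervals, "any_run": bool(runs.intervals),
            "window_hit": hit}


def trsp_outcome(
    seed: int,
    modulations: Mapping[str, ModulationSpec] | None = None,
    n_subjects: int = 10,
    trials_per_block: int = 80,
    sampling_rate: float = 500.0,
    alpha: float = 0.05,
) -> dict:
    """Band-power ANOVA outcome for one simulated two-condition dataset.

    Simulates cTBS and iTBS pre/post blocks on the M1 ROI channels,
    computes baseline-normalized TRSP band averages per block, runs the
    TBS x Time x Frequency ANOVA, and reports whether the three-way
    interaction is significant and whether the post-hoc pattern (alpha
    decrease under cTBS, beta increase under iTBS) is present.
    """
    modulations = modulations or effect_modulations(roi_only=True)
    montage = roi_montage()
    noise = NoiseModel(line_amplitude=0.0, blink_rate=0.0, artifact_amplitude=0.0)
    config = SimulationConfig(
        n_subjects=n_subjects, trials_per_block=trials_per_block,
        sampling_rate=sampling_rate, noise_model=noise, seed=seed,
        montage=montage)
    design = single_area_design(n_subjects)
    dataset = simulate_dataset(design, config, modulations)
    params = WaveletParams()
    rows = []
    for (subject, cond, phase, _area), epochs in dataset.items():
        tfr = baseline_normalize(morlet_power(epochs, params))
        for band, value in band_roi_average(tfr, montage.channel_labels).items():
            rows.append({"subject": subject, "condition": cond, "phase": phase,
                         "band": band, "value": value})
    table = pd.DataFrame(rows)
    res = trsp_anova(table)
    interaction = res.effects["condition x phase x band"]
    ph = res.posthoc
    def cell(cond, band):
        row = ph[(ph["tbs"] == cond) & (ph["band"] == band)]
        return row.iloc[0]
    a = cell("cTBS", "alpha")
    b = cell("iTBS", "beta")
    # post vs pre comparison: level_a is post or pre depending on table order
    def signed_change(row):
        sign = 1.0 if row["level_a"] == "post" else -1.0
        return sign * row["mean_diff"], row["p_bonferroni"]
    a_change, a_p = signed_change(a)
    b_change, b_p = signed_change(b)
    pattern = (a_change < 0 and a_p < alpha) and (b_change > 0 and b_p < alpha)
    return {
        "interaction_p": interaction.p,
        "interaction_significant": interaction.p < alpha,
        "alpha_ctbs_change": a_change, "alpha_ctbs_p": a_p,
        "beta_itbs_change": b_change, "beta_itbs_p": b_p,
        "pattern_recovered": bool(pattern),
        "table": table,
        "anova": res,
    }
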