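"""End-to-end pipeline driver.

Runs simulate -> preprocess -> TEP cluster statistics -> LMFP -> TRSP
for a :class:`~tmseeg.config.PipelineConfig`, writing tab-separated
result tables and a machine-readable JSON run report (all seeds and
package versions included). A failure in any stage aborts with the
stage name and cause; the whole run is a pure function of
(config, seed), so repeated runs produce byte-identical outputs.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import TOISet, cluster_permutation_test
from .config import PipelineConfig
from .containers import EpochedEEG
from .lmfp import ROIDefinition, compute_lmfp, lmfp_condition_test, lmfp_difference_contrast
from .montage import build_neighbor_graph, default_montage
from .preprocess import (bandpass_filter, interpolate_tms_artifact, notch_filter,
                         reject_epochs, rereference_average, run_ica_cleanup)
from .simulate import (ModulationSpec, NoiseModel, SimulationConfig, StudyDesign,
                       simulate_dataset)
from .trsp import WaveletParams, band_roi_average, baseline_normalize, morlet_power, trsp_anova, trsp_difference_anova

__all__ = ["run_pipeline", "PipelineError", "preprocess_epochs", "modulations_from_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def modulations_from_config(config: PipelineConfig) -> dict[str, ModulationSpec]:
    sim = config["simulation"]
    channels = tuple(sim["affected_channels"])
    out = {"sham": ModulationSpec("sham")}
    for cond in ("cTBS", "iTBS"):
        spec = sim["modulation"][cond]
        out[cond] = ModulationSpec(
            cond, tuple(spec["window"]), float(spec["gain"]), channels,
            {k: float(v) for k, v in spec.get("band_gain", {}).items()})
    return out


def preprocess_epochs(epochs: EpochedEEG, config: PipelineConfig,
                      seed: int) -> EpochedEEG:
    """Apply the preprocessing chain to already-epoched data."""
    pp = config["preprocess"]
    out = interpolate_tms_artifact(epochs, tuple(pp["interpolation_window"]))
    out = rereference_average(out)
    out = bandpass_filter(out, *pp["band"])
    out = notch_filter(out, pp["notch"])
    if pp["run_ica"]:
        out, _ = run_ica_cleanup(out, seed=seed)
    out = reject_epochs(out, pp["rejection_threshold"])
    return out


def _stack(evokeds: dict, subjects: list[str], cond: str, phase: str,
           area: str) -> np.ndarray:
    return np.stack([evokeds[(s, cond, phase, area)] for s in subjects])


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Execute the full analysis chain and write results.

    Returns the report dict; writes ``report.json``,
    ``tep_clusters.tsv``, ``lmfp_runs.tsv``, ``trsp_bands.tsv``,
    ``trsp_anova.tsv`` and ``trsp_posthoc.tsv`` under the output
    directory.
    """
    out_dir = Path(output_dir if output_dir is not None else config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    report: dict = {
        "versions": _versions(),
        "seed": seed,
        "config": config.tree,
        "stages": [],
    }

    # ---- simulate -------------------------------------------------------
    try:
        sim = config["simulation"]
        sim_config = SimulationConfig(
            n_subjects=sim["n_real"],
            trials_per_block=sim["trials_per_block"],
            sampling_rate=sim["sampling_rate"],
            epoch_window=tuple(sim["epoch_window"]),
            between_subject_sd=sim["between_subject_sd"],
            seed=seed,
        )
        design = StudyDesign.default(n_real=sim["n_real"], n_sham=sim["n_sham"])
        dataset = simulate_dataset(design, sim_config,
                                   modulations=modulations_from_config(config))
        report["stages"].append({"stage": "simulate", "n_blocks": len(dataset)})
    except Exception as err:  # noqa: BLE001
        raise PipelineError("simulate", err) from err

    # ---- preprocess -----------------------------------------------------
    try:
        rejected = {}
        for key in list(dataset):
            dataset[key] = preprocess_epochs(dataset[key], config, seed)
            rejected["/".join(key)] = int(dataset[key].rejection_mask.sum())
        report["stages"].append({"stage": "preprocess", "n_rejected": rejected})
    except Exception as err:  # noqa: BLE001
        raise PipelineError("preprocess", err) from err

    montage = default_montage()
    graph = build_neighbor_graph(montage)
    labels = montage.channel_labels
    times = dataset[next(iter(dataset))].times
    real = [s for s in design.subjects if s.startswith("R")][: sim["n_real"]]
    sham = [s for s in design.subjects if s.startswith("S")]
    evokeds = {key: ep.evoked() for key, ep in dataset.items()}

    contrasts = []  # (area, condition, label, stack_a, stack_b, subjects)
    for area in ("M1", "PPC"):
        for cond in ("cTBS", "iTBS"):
            contrasts.append((area, cond, "post_vs_pre",
                              _stack(evokeds, real, cond, "post", area),
                              _stack(evokeds, real, cond, "pre", area)))
        contrasts.append((area, "baseline", "pre_cTBS_vs_pre_iTBS",
                          _stack(evokeds, real, "cTBS", "pre", area),
                          _stack(evokeds, real, "iTBS", "pre", area)))
    if sham:
        contrasts.append(("M1", "sham", "post_vs_pre",
                          _stack(evokeds, sham, "sham", "post", "M1"),
                          _stack(evokeds, sham, "sham", "pre", "M1")))

    # ---- TEP cluster statistics ----------------------------------------
    try:
        tep_cfg = config["tep"]
        toi_set = TOISet(tuple((name, tuple(win)) for name, win in tep_cfg["tois"]))
        rows = []
        for area, cond, label, post, pre in contrasts:
            result = cluster_permutation_test(
                post, pre, times, graph, labels, toi_set,
                threshold_p=tep_cfg["threshold_p"], n_perm=tep_cfg["n_perm"],
                seed=seed)
            for c in result.clusters:
                rows.append({
                    "area": area, "condition": cond, "contrast": label,
                    "toi": c.toi, "polarity": c.polarity,
                    "t_start_ms": round(c.time_range[0] * 1000, 3),
                    "t_end_ms": round(c.time_range[1] * 1000, 3),
                    "channels": ",".join(c.channels),
                    "mass": c.mass, "monte_carlo_p": c.monte_carlo_p,
                })
        tep_table = pd.DataFrame(
            rows, columns=["area", "condition", "contrast", "toi", "polarity",
                           "t_start_ms", "t_end_ms", "channels", "mass",
                           "monte_carlo_p"])
        tep_table.to_csv(out_dir / "tep_clusters.tsv", sep="\t", index=False)
        report["stages"].append({"stage": "tep", "n_clusters": len(rows)})
        report["tep_significant"] = tep_table[
            tep_table["monte_carlo_p"] < 2 * tep_cfg["threshold_p"]
        ].to_dict("records") if len(rows) else []
    except Exception as err:  # noqa: BLE001
        raise PipelineError("tep", err) from err

    # ---- LMFP -----------------------------------------------------------
    try:
        lm = config["lmfp"]
        window = tuple(lm["window"])
        rows = []
        roi_defs = {name: ROIDefinition(name, tuple(chs))
                    for name, chs in lm["rois"].items()}

        def subject_traces(subjects, cond, phase, area, roi):
            return np.stack([
                compute_lmfp(evokeds[(s, cond, phase, area)], labels, roi,
                             times, window).values
                for s in subjects])

        lm_kw = dict(n_perm=lm["n_perm"], alpha=lm["alpha"], fdr_q=lm["fdr_q"],
                     min_run=lm["min_run"], seed=seed, p_source=lm["p_source"])
        lmfp_times = compute_lmfp(evokeds[next(iter(evokeds))], labels,
                                  roi_defs["M1"], times, window).times
        cond_sets = [("M1", "cTBS", real), ("M1", "iTBS", real),
                     ("PPC", "cTBS", real), ("PPC", "iTBS", real)]
        if sham:
            cond_sets.append(("M1", "sham", sham))
        diffs = {}
        for area, cond, subjects in cond_sets:
            roi = roi_defs[area]
            pre = subject_traces(subjects, cond, "pre", area, roi)
            post = subject_traces(subjects, cond, "post", area, roi)
            diffs[(area, cond)] = post - pre
            runs = lmfp_condition_test(pre, post, lmfp_times, **lm_kw)
            for start, end, direction in runs.intervals:
                rows.append({"area": area, "condition": cond,
                             "contrast": "post_vs_pre",
                             "start_ms": round(start * 1000, 3),
                             "end_ms": round(end * 1000, 3),
                             "direction": direction})
        for area in ("M1", "PPC"):
            runs = lmfp_difference_contrast(
                diffs[(area, "cTBS")], diffs[(area, "iTBS")], lmfp_times, **lm_kw)
            for start, end, direction in runs.intervals:
                rows.append({"area": area, "condition": "cTBS_vs_iTBS",
                             "contrast": "post_pre_difference",
                             "start_ms": round(start * 1000, 3),
                             "end_ms": round(end * 1000, 3),
                             "direction": direction})
        lm_table = pd.DataFrame(rows, columns=["area", "condition", "contrast",
                                               "start_ms", "end_ms", "direction"])
        lm_table.to_csv(out_dir / "lmfp_runs.tsv", sep="\t", index=False)
        report["stages"].append({"stage": "lmfp", "n_runs": len(rows)})
        report["lmfp_runs"] = rows
    except Exception as err:  # noqa: BLE001
        raise PipelineError("lmfp", err) from err

    # ---- TRSP -----------------------------------------------------------
    try:
        tr = config["trsp"]
        params = WaveletParams(tr["f_min"], tr["f_max"], tr["n_steps"],
                               tr["cycles"], tr["spacing"])
        bands = {k: tuple(v) for k, v in tr["bands"].items()}
        band_rows = []
        for (subject, cond, phase, area), ep in dataset.items():
            roi_channels = list(lm["rois"][area])
            tfr = morlet_power(ep, params, picks=roi_channels)
            tfr = baseline_normalize(tfr, tuple(tr["baseline"]))
            values = band_roi_average(tfr, roi_channels, tuple(tr["window"]), bands)
            for band, value in values.items():
                band_rows.append({"subject": subject, "condition": cond,
                                  "phase": phase, "area": area, "band": band,
                                  "value": value})
        band_table = pd.DataFrame(band_rows)
        band_table.to_csv(out_dir / "trsp_bands.tsv", sep="\t", index=False)
        anova_rows, posthoc_frames = [], []
        for area in ("M1", "PPC"):
            sub = band_table[(band_table["area"] == area)
                             & band_table["condition"].isin(["cTBS", "iTBS"])]
            if sub.empty:
                continue
            res = trsp_anova(sub)
            t = res.table()
            t.insert(0, "area", area)
            t.insert(1, "analysis", "tbs_time_band")
            anova_rows.append(t)
            ph = res.posthoc.copy()
            ph.insert(0, "area", area)
            ph.insert(1, "analysis", "tbs_time_band")
            posthoc_frames.append(ph)
            res_d = trsp_difference_anova(sub)
            t = res_d.table()
            t.insert(0, "area", area)
            t.insert(1, "analysis", "post_pre_difference")
            anova_rows.append(t)
            ph = res_d.posthoc.copy()
            ph.insert(0, "area", area)
            ph.insert(1, "analysis", "post_pre_difference")
            posthoc_frames.append(ph)
        anova_table = pd.concat(anova_rows, ignore_index=True)
        anova_table.to_csv(out_dir / "trsp_anova.tsv", sep="\t", index=False)
        posthoc_table = pd.concat(posthoc_frames, ignore_index=True)
        posthoc_table.to_csv(out_dir / "trsp_posthoc.tsv", sep="\t", index=False)
        report["stages"].append({"stage": "trsp", "n_band_rows": len(band_rows)})
        report["trsp_anova"] = json.loads(anova_table.to_json(orient="records"))
    except Exception as err:  # noqa: BLE001
        raise PipelineError("trsp", err) from err

    (out_dir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2, default=str) + "\n",
        encoding="utf-8")
    return report


def _versions() -> dict[str, str]:
    import mne
    import scipy

    return {"tmseeg": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "mne": mne.__version__}
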