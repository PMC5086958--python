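"""TMS-related spectral perturbation (TRSP) analysis.

Single trials are decomposed with complex Morlet wavelets (23 linearly
spaced frequencies from 4 to 50 Hz, 3.5 cycles at every frequency); the
TRSP is the trial-averaged power TRSP(f, t) = (1/n) sum_k |F_k(f, t)|^2
and is baseline-normalized by *subtracting* the mean pre-stimulus power
spectrum per channel and frequency (values stay in μV², may be negative
after normalization). Band x ROI averages over a post-stimulus analysis
window feed a repeated-measures ANOVA with factors TBS protocol,
frequency band, and time (pre, post), with Mauchly/Greenhouse–Geisser
handling and Bonferroni post-hocs.

Samples closer to an epoch edge than a wavelet's effective half-support
(cycles / (2 f) seconds) are flagged invalid and are refused in
baseline and analysis windows.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from mne.time_frequency import morlet as morlet_wavelets
from scipy.fft import fft, ifft, next_fast_len

from .containers import EpochedEEG
from .stats import AnovaResult, bonferroni_posthoc, rm_anova

__all__ = [
    "BANDS",
    "WaveletParams",
    "TimeFrequencyRepresentation",
    "morlet_power",
    "baseline_normalize",
    "band_bins",
    "band_roi_average",
    "trsp_anova",
    "trsp_difference_anova",
]

#: analysis bands, Hz, closed integer edges as printed; the 6-7 Hz gap
#: between theta and alpha is deliberate — bins strictly inside it
#: belong to neither band
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 6.0),
    "alpha": (7.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (31.0, 50.0),
}

DEFAULT_ANALYSIS_WINDOW = (0.010, 0.300)
DEFAULT_BASELINE_WINDOW = (-0.55, -0.15)


@dataclass(frozen=True)
class WaveletParams:
    """Morlet decomposition grid: 23 frequencies in [4, 50] Hz, 3.5 cycles."""

    f_min: float = 4.0
    f_max: float = 50.0
    n_steps: int = 23
    cycles: float = 3.5
    spacing: str = "linear"  # or "log"

    def __post_init__(self) -> None:
        if not (self.f_min >= 4.0 - 1e-9 and self.f_max <= 50.0 + 1e-9):
            raise ValueError("frequency range must stay within [4, 50] Hz")
        if self.n_steps < 2 or self.cycles <= 0:
            raise ValueError("invalid wavelet grid")

    @property
    def frequencies(self) -> np.ndarray:
        if self.spacing == "linear":
            return np.linspace(self.f_min, self.f_max, self.n_steps)
        if self.spacing == "log":
            return np.geomspace(self.f_min, self.f_max, self.n_steps)
        raise ValueError(f"unknown spacing {self.spacing!r}")

    def half_support(self, freq: float) -> float:
        """Effective wavelet half-support in seconds at ``freq``."""
        return self.cycles / (2.0 * freq)


@dataclass
class TimeFrequencyRepresentation:
    """Channels x frequencies x timepoints trial-averaged power (μV²)."""

    power: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    channel_labels: list[str]
    valid_mask: np.ndarray  # (n_freqs, n_times): outside edge half-support
    normalized: bool = False
    baseline_window: tuple[float, float] | None = None

    def time_indices(self, window: tuple[float, float]) -> np.ndarray:
        eps = 0.5 * float(np.median(np.diff(self.times)))
        return np.nonzero((self.times >= window[0] - eps)
                          & (self.times < window[1] - eps))[0]


def _trial_mean_power(data: np.ndarray, sfreq: float, freqs: np.ndarray,
                      cycles: float) -> np.ndarray:
    """Trial-mean Morlet power via batched FFT convolution.

    The wavelet bank comes from mne (zero-mean complex Morlets,
    sigma_t = cycles / (2 pi f)); the "same"-mode convolution is done
    for all trials x channels at once per frequency, which is much
    faster than per-trial transforms and numerically identical.
    """
    n_trials, n_ch, n_times = data.shape
    ws = morlet_wavelets(sfreq, freqs, n_cycles=cycles, zero_mean=True)
    longest = max(len(w) for w in ws)
    if longest > n_times:
        raise ValueError(
            f"epoch of {n_times / sfreq:.3f} s shorter than the "
            f"{freqs.min():.1f} Hz wavelet support ({longest / sfreq:.3f} s)")
    nfft = next_fast_len(n_times + longest - 1)
    flat = data.reshape(n_trials * n_ch, n_times)
    spectra = fft(flat, nfft, axis=-1)
    out = np.empty((n_ch, len(freqs), n_times))
    for i, w in enumerate(ws):
        wf = fft(w, nfft)
        full = ifft(spectra * wf[None, :], axis=-1)
        start = (len(w) - 1) // 2  # center the "same" segment
        seg = full[:, start:start + n_times]
        power = (seg.real ** 2 + seg.imag ** 2).reshape(n_trials, n_ch, n_times)
        out[:, i, :] = power.mean(axis=0)
    return out


def morlet_power(
    epochs: EpochedEEG,
    params: WaveletParams | None = None,
    picks: Sequence[str] | None = None,
) -> TimeFrequencyRepresentation:
    """Trial-averaged Morlet wavelet power of the unmasked trials.

    Averaging over trials happens on raw per-trial power, before any
    normalization, so induced (non-phase-locked) activity is retained.
    """
    params = params or WaveletParams()
    freqs = params.frequencies
    keep = ~epochs.rejection_mask
    if not keep.any():
        raise ValueError("all trials are masked")
    if picks is None:
        picks = list(epochs.channel_labels)
    idx = epochs.channel_indices(picks)
    data = epochs.data[keep][:, idx, :]
    epoch_len = epochs.n_samples / epochs.sfreq
    if epoch_len < 2.0 * params.half_support(freqs.min()):
        raise ValueError(
            f"epoch of {epoch_len:.3f} s shorter than the "
            f"{freqs.min():.1f} Hz wavelet support")
    power = _trial_mean_power(data, epochs.sfreq, freqs, params.cycles)
    times = epochs.times
    half = params.cycles / (2.0 * freqs)
    valid = ((times[None, :] - times[0] >= half[:, None])
             & (times[-1] - times[None, :] >= half[:, None]))
    return TimeFrequencyRepresentation(power, freqs, times, list(picks), valid)


def baseline_normalize(
    tfr: TimeFrequencyRepresentation,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
) -> TimeFrequencyRepresentation:
    """Subtract the mean baseline power spectrum per channel x frequency.

    The baseline window must be strictly pre-stimulus and clear of the
    edge-invalid samples of every frequency. After normalization the
    mean of the normalized values over the baseline window is exactly
    zero for each channel and frequency.
    """
    if tfr.normalized:
        raise ValueError("TFR is already baseline-normalized")
    lo, hi = baseline_window
    if hi > 0:
        raise ValueError("baseline window must end before the TMS pulse")
    idx = tfr.time_indices(baseline_window)
    if idx.size == 0:
        raise ValueError("baseline window contains no samples")
    if not tfr.valid_mask[:, idx].all():
        raise ValueError("baseline window overlaps edge-invalid samples")
    baseline = tfr.power[:, :, idx].mean(axis=2, keepdims=True)
    return TimeFrequencyRepresentation(
        tfr.power - baseline, tfr.frequencies, tfr.times,
        list(tfr.channel_labels), tfr.valid_mask,
        normalized=True, baseline_window=(lo, hi))


def band_bins(frequencies: np.ndarray, band: tuple[float, float],
              eps: float = 1e-9) -> np.ndarray:
    """Indices of frequency bins whose center lies in [low, high + eps)."""
    lo, hi = band
    return np.nonzero((frequencies >= lo - eps) & (frequencies < hi + eps))[0]


def band_roi_average(
    tfr: TimeFrequencyRepresentation,
    roi_channels: Sequence[str],
    window: tuple[float, float] = DEFAULT_ANALYSIS_WINDOW,
    bands: Mapping[str, tuple[float, float]] = BANDS,
) -> dict[str, float]:
    """Mean normalized TRSP over ROI channels x band bins x window times."""
    if not tfr.normalized:
        raise ValueError("band averages are defined on baseline-normalized TRSP")
    missing = [c for c in roi_channels if c not in tfr.channel_labels]
    if missing:
        raise KeyError(f"ROI channels missing from TFR: {missing}")
    lut = {c: i for i, c in enumerate(tfr.channel_labels)}
    ch_idx = [lut[c] for c in roi_channels]
    t_idx = tfr.time_indices(window)
    if t_idx.size == 0:
        raise ValueError("analysis window contains no samples")
    out = {}
    for name, edges in bands.items():
        f_idx = band_bins(tfr.frequencies, edges)
        if f_idx.size == 0:
            raise ValueError(f"band {name} has no frequency bins on this grid")
        if not tfr.valid_mask[np.ix_(f_idx, t_idx)].all():
            raise ValueError(f"analysis window overlaps edge-invalid samples for {name}")
        out[name] = float(tfr.power[np.ix_(ch_idx, f_idx, t_idx)].mean())
    return out


BAND_ORDER = ("theta", "alpha", "beta", "gamma")


def trsp_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    tbs: str = "condition",
    time: str = "phase",
    band: str = "band",
    posthoc: bool = True,
) -> AnovaResult:
    """TBS x Time x Frequency repeated-measures ANOVA on band power.

    ``table`` holds one row per subject x TBS condition x phase x band
    (already ROI- and window-averaged). Post-hocs compare post vs pre
    within each (TBS, band) cell, Bonferroni-corrected by the number of
    comparisons made.
    """
    res = rm_anova(table, dv=dv, subject=subject, within=[tbs, time, band])
    if posthoc:
        frames = []
        cells = [(c, b) for c in dict.fromkeys(table[tbs])
                 for b in dict.fromkeys(table[band])]
        for cond, bd in cells:
            ph = bonferroni_posthoc(table, dv=dv, subject=subject, factor=time,
                                    within_levels_of={tbs: cond, band: bd})
            ph.insert(0, "band", bd)
            ph.insert(0, "tbs", cond)
            frames.append(ph)
        post = pd.concat(frames, ignore_index=True)
        # correct over all cells compared, not per cell
        post["p_bonferroni"] = np.minimum(1.0, post["p_uncorrected"] * len(post))
        res.posthoc = post
    return res


def trsp_difference_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    tbs: str = "condition",
    time: str = "phase",
    band: str = "band",
    posthoc: bool = True,
) -> AnovaResult:
    """TBS x Frequency ANOVA on post - pre band-power differences."""
    wide = table.pivot_table(index=[subject, tbs, band], columns=time,
                             values=dv, aggfunc="mean")
    if not {"pre", "post"} <= set(wide.columns):
        raise ValueError("table must contain pre and post phases")
    diff = (wide["post"] - wide["pre"]).rename(dv).reset_index()
    res = rm_anova(diff, dv=dv, subject=subject, within=[tbs, band])
    if posthoc:
        frames = []
        for bd in dict.fromkeys(diff[band]):
            ph = bonferroni_posthoc(diff, dv=dv, subject=subject, factor=tbs,
                                    within_levels_of={band: bd})
            ph.insert(0, "band", bd)
            frames.append(ph)
        post = pd.concat(frames, ignore_index=True)
        post["p_bonferroni"] = np.minimum(1.0, post["p_uncorrected"] * len(post))
        res.posthoc = post
    return res
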