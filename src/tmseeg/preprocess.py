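"""Preprocessing of raw TMS-EEG recordings into clean epochs.

Canonical stage order (enforced by the pipeline driver):

1. cubic interpolation of the TMS pulse artifact (−1 to +10 ms),
2. average re-reference,
3. 1–80 Hz Butterworth band-pass (zero phase, forward–backward),
4. 50 Hz notch,
5. INFOMAX ICA with automated artifact-component rejection,
6. epoching −1 to +1 s around each pulse,
7. amplitude-based trial rejection (flagging, never deletion).

The cubic fit uses least-squares over [−6, −1] ms and [+10, +15] ms
flanking segments rather than a 4-point spline, which is robust to
noisy flank samples. Channels whose label starts with "EOG" are carried
along but excluded from the average reference, the rejection criterion
and all downstream statistics; they feed the ICA ocular criterion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig

from mne.preprocessing import infomax

from .containers import ContinuousEEG, EpochedEEG

__all__ = [
    "STAGE_ORDER",
    "interpolate_tms_artifact",
    "rereference_average",
    "bandpass_filter",
    "notch_filter",
    "ICACriteria",
    "ICAResult",
    "run_ica_cleanup",
    "epoch",
    "reject_epochs",
    "decimate_epochs",
    "preprocess_continuous",
]

STAGE_ORDER = ("interpolate", "rereference", "bandpass", "notch", "ica",
               "epoch", "reject")


def _scalp_indices(labels: list[str]) -> np.ndarray:
    return np.array([i for i, c in enumerate(labels) if not c.upper().startswith("EOG")])


# ---------------------------------------------------------------------------
# TMS artifact interpolation


def _cubic_replace(data: np.ndarray, win: slice, flank_idx: np.ndarray) -> None:
    """In place: replace ``data[:, win]`` by a least-squares cubic fitted
    to the flank samples. Vectorized over channels."""
    x0 = flank_idx.mean()
    scale = max(flank_idx.max() - flank_idx.min(), 1.0)
    xf = (flank_idx - x0) / scale
    V = np.vander(xf, 4)  # (n_flank, 4)
    coef, *_ = np.linalg.lstsq(V, data[:, flank_idx].T, rcond=None)
    xw = (np.arange(win.start, win.stop) - x0) / scale
    data[:, win] = (np.vander(xw, 4) @ coef).T


def interpolate_tms_artifact(
    signal: ContinuousEEG | EpochedEEG,
    window: tuple[float, float] = (-0.001, 0.010),
    flank: float = 0.005,
) -> ContinuousEEG | EpochedEEG:
    """Replace the residual TMS pulse artifact by a cubic polynomial.

    ``window`` is relative to each TMS pulse (continuous input: every
    event labeled "TMS"; epoched input: t = 0). The cubic is fitted by
    least squares to ``flank``-second segments immediately before and
    after the window; samples outside the window are bit-unchanged.
    """
    out = signal.copy()
    sfreq = out.sfreq
    # at least 4 flank samples per side or the cubic is underdetermined
    n_flank = max(4, int(round(flank * sfreq)))

    def windows_for(n_samples: int, pulse_sample: float):
        i0 = int(round(pulse_sample + window[0] * sfreq))
        i1 = int(round(pulse_sample + window[1] * sfreq))
        lo = i0 - n_flank
        hi = i1 + n_flank
        if lo < 0 or hi > n_samples:
            raise ValueError("interpolation window (with flanks) exceeds record bounds")
        flank_idx = np.concatenate([np.arange(lo, i0), np.arange(i1, hi)])
        return slice(i0, i1), flank_idx

    if isinstance(out, ContinuousEEG):
        pulses = [s for s, label in out.events if label == "TMS"]
        for s in pulses:
            win, fl = windows_for(out.n_samples, s)
            _cubic_replace(out.data, win, fl)
        out.log("interpolate", window=list(window), flank=flank, n_pulses=len(pulses))
    else:
        pulse_sample = -out.tmin * sfreq
        win, fl = windows_for(out.n_samples, pulse_sample)
        for k in range(out.n_trials):
            _cubic_replace(out.data[k], win, fl)
        out.log("interpolate", window=list(window), flank=flank)
    return out


# ---------------------------------------------------------------------------
# reference and filters


def rereference_average(signal: ContinuousEEG | EpochedEEG) -> ContinuousEEG | EpochedEEG:
    """Subtract the instantaneous mean of the scalp channels (idempotent)."""
    out = signal.copy()
    scalp = _scalp_indices(out.channel_labels)
    if scalp.size < 2:
        raise ValueError("average reference needs at least 2 scalp channels")
    if isinstance(out, ContinuousEEG):
        out.data[scalp] -= out.data[scalp].mean(axis=0, keepdims=True)
    else:
        out.data[:, scalp, :] -= out.data[:, scalp, :].mean(axis=1, keepdims=True)
    out.log("rereference", scheme="average", n_channels=int(scalp.size))
    return out


def _apply_sos(out, sos) -> None:
    if isinstance(out, ContinuousEEG):
        out.data = sig.sosfiltfilt(sos, out.data, axis=-1)
    else:
        out.data = sig.sosfiltfilt(sos, out.data, axis=-1)


def bandpass_filter(
    signal: ContinuousEEG | EpochedEEG,
    low: float = 1.0,
    high: float = 80.0,
    order: int = 3,
) -> ContinuousEEG | EpochedEEG:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    ``order`` is the one-pass order; the forward–backward application
    doubles the effective order and cancels the phase response.
    """
    nyq = signal.sfreq / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band edges ({low}, {high}) invalid for {signal.sfreq} Hz")
    out = signal.copy()
    sos = sig.butter(order, [low, high], btype="bandpass", fs=out.sfreq, output="sos")
    _apply_sos(out, sos)
    out.log("bandpass", low=low, high=high, order=order, zero_phase=True)
    return out


def notch_filter(
    signal: ContinuousEEG | EpochedEEG,
    freq: float = 50.0,
    quality: float = 30.0,
) -> ContinuousEEG | EpochedEEG:
    """Zero-phase second-order IIR notch at the line frequency."""
    nyq = signal.sfreq / 2.0
    if not 0 < freq < nyq:
        raise ValueError(f"notch frequency {freq} invalid for {signal.sfreq} Hz")
    out = signal.copy()
    b, a = sig.iirnotch(freq, quality, fs=out.sfreq)
    out.data = sig.filtfilt(b, a, out.data, axis=-1)
    out.log("notch", freq=freq, quality=quality, zero_phase=True)
    return out


# ---------------------------------------------------------------------------
# ICA cleanup


@dataclass(frozen=True)
class ICACriteria:
    """Automated component-rejection thresholds (None disables a criterion).

    ``eog_correlation``: |Pearson r| with any EOG channel at or above
    which a component is ocular. ``muscle_hf_fraction``: fraction of
    spectral power above 60 Hz at or above which it is muscle.
    ``tms_concentration``: ratio of RMS inside [0, 30] ms post-pulse
    windows to overall RMS at or above which it is residual TMS
    artifact.
    """

    eog_correlation: float | None = 0.7
    muscle_hf_fraction: float | None = 0.6
    tms_concentration: float | None = 3.0

    @classmethod
    def disabled(cls) -> "ICACriteria":
        return cls(None, None, None)


@dataclass
class ICAResult:
    mixing: np.ndarray  # (n_channels, n_components)
    unmixing: np.ndarray  # (n_components, n_channels)
    classification: list[dict]  # per component: status + criterion scores
    seed: int | None
    n_iter_extended: bool = False

    @property
    def rejected(self) -> list[int]:
        return [c["component"] for c in self.classification if c["status"] == "rejected"]


def _component_scores(sources, sfreq, eog, pulse_samples, n_samples_per_trial=None):
    """Criterion scores per ICA component."""
    n_comp = sources.shape[0]
    scores = []
    freqs, psd = sig.welch(sources, fs=sfreq, nperseg=min(1024, sources.shape[1]))
    hf = psd[:, freqs > 60.0].sum(axis=1) / np.maximum(psd.sum(axis=1), 1e-30)
    for c in range(n_comp):
        s = sources[c]
        eog_r = 0.0
        for e in eog:
            denom = s.std() * e.std()
            if denom > 0:
                eog_r = max(eog_r, abs(float(np.dot(s - s.mean(), e - e.mean())
                                              / (denom * s.size))))
        conc = 0.0
        if pulse_samples is not None and len(pulse_samples):
            early = []
            n_early = int(round(0.030 * sfreq))
            for p in pulse_samples:
                p = int(p)
                if 0 <= p and p + n_early <= sources.shape[1]:
                    early.append(s[p:p + n_early])
            if early:
                early = np.concatenate(early)
                overall = np.sqrt(np.mean(s ** 2))
                conc = float(np.sqrt(np.mean(early ** 2)) / max(overall, 1e-30))
        scores.append({"component": c, "eog_correlation": float(eog_r),
                       "hf_power_fraction": float(hf[c]),
                       "tms_concentration": conc})
    return scores


def run_ica_cleanup(
    signal: ContinuousEEG | EpochedEEG,
    criteria: ICACriteria | None = None,
    seed: int | None = 0,
    max_iter: int = 500,
) -> tuple[ContinuousEEG | EpochedEEG, ICAResult]:
    """INFOMAX ICA decomposition with automated artifact rejection.

    Scalp channels are PCA-whitened to the data rank (average-referenced
    data lose one dimension), unmixed by extended-infomax, and each
    component is scored against the ocular, muscle and residual-TMS
    criteria; rejected components are zeroed before back-projection.
    Fully reproducible for a fixed seed. EOG channels pass through
    untouched.
    """
    criteria = criteria if criteria is not None else ICACriteria()
    out = signal.copy()
    scalp = _scalp_indices(out.channel_labels)
    eog_idx = [i for i in range(len(out.channel_labels)) if i not in scalp]
    if isinstance(out, ContinuousEEG):
        X = out.data[scalp]
        eog = [out.data[i] for i in eog_idx]
        pulses = np.array([s for s, lab in out.events if lab == "TMS"], dtype=float)
        n_obs = X.shape[1]
    else:
        X = out.data[:, scalp, :].transpose(1, 0, 2).reshape(scalp.size, -1)
        eog = [out.data[:, i, :].reshape(-1) for i in eog_idx]
        pulse_in_trial = -out.tmin * out.sfreq
        pulses = pulse_in_trial + out.n_samples * np.arange(out.n_trials)
        n_obs = X.shape[1]
    n_ch = X.shape[0]
    if n_obs < n_ch ** 2:
        raise ValueError(
            f"{n_obs} samples insufficient for ICA on {n_ch} channels "
            f"(need >= channels^2 = {n_ch ** 2})")

    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    cov = np.cov(Xc)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = evals[0] * 1e-10
    rank = int(np.sum(evals > tol))
    evals, evecs = evals[:rank], evecs[:, :rank]
    whitener = (evecs / np.sqrt(evals)).T  # (rank, n_ch)
    Z = whitener @ Xc
    W = infomax(Z.T, extended=True, max_iter=max_iter, random_state=seed)
    unmixing = W @ whitener  # (rank, n_ch)
    mixing = np.linalg.pinv(unmixing)  # (n_ch, rank)
    sources = unmixing @ Xc

    scores = _component_scores(sources, out.sfreq, eog, pulses)
    for entry in scores:
        reasons = []
        if (criteria.eog_correlation is not None
                and entry["eog_correlation"] >= criteria.eog_correlation):
            reasons.append("eog")
        if (criteria.muscle_hf_fraction is not None
                and entry["hf_power_fraction"] >= criteria.muscle_hf_fraction):
            reasons.append("muscle")
        if (criteria.tms_concentration is not None
                and entry["tms_concentration"] >= criteria.tms_concentration):
            reasons.append("tms_artifact")
        entry["status"] = "rejected" if reasons else "kept"
        entry["reasons"] = reasons
    result = ICAResult(mixing, unmixing, scores, seed)

    keep = np.array([e["status"] == "kept" for e in scores])
    cleaned = mixing[:, keep] @ sources[keep] + mean
    if isinstance(out, ContinuousEEG):
        out.data[scalp] = cleaned
    else:
        out.data[:, scalp, :] = cleaned.reshape(
            scalp.size, out.n_trials, out.n_samples).transpose(1, 0, 2)
    out.log("ica", n_components=int(rank), rejected=result.rejected, seed=seed,
            criteria=vars(criteria) if not isinstance(criteria, dict) else criteria)
    return out, result


# ---------------------------------------------------------------------------
# epoching and rejection


def epoch(
    continuous: ContinuousEEG,
    markers: list[int] | None = None,
    window: tuple[float, float] = (-1.0, 1.0),
) -> EpochedEEG:
    """Segment a continuous recording into pulse-locked epochs."""
    if markers is None:
        markers = [s for s, lab in continuous.events if lab == "TMS"]
    if not markers:
        raise ValueError("no TMS markers to epoch around")
    sfreq = continuous.sfreq
    n_pre = int(round(-window[0] * sfreq))
    n_post = int(round(window[1] * sfreq))
    n_len = n_pre + n_post
    trials = []
    for m in markers:
        lo = m - n_pre
        hi = m + n_post
        if lo < 0 or hi > continuous.n_samples:
            raise ValueError(f"marker at sample {m} too close to the record edge")
        trials.append(continuous.data[:, lo:hi])
    epochs = EpochedEEG(np.stack(trials), sfreq, -n_pre / sfreq,
                        list(continuous.channel_labels),
                        provenance=[dict(p) for p in continuous.provenance])
    epochs.log("epoch", window=list(window), n_trials=len(markers), n_samples=n_len)
    return epochs


def reject_epochs(
    epochs: EpochedEEG,
    amplitude_threshold: float = 200.0,
) -> EpochedEEG:
    """Flag trials whose scalp peak-to-peak exceeds the threshold (μV).

    Trials are masked, never deleted; the rejected fraction is logged.
    An infinite threshold masks nothing.
    """
    out = epochs.copy()
    scalp = _scalp_indices(out.channel_labels)
    ptp = out.data[:, scalp, :].max(axis=2) - out.data[:, scalp, :].min(axis=2)
    mask = (ptp > amplitude_threshold).any(axis=1)
    out.rejection_mask = out.rejection_mask | mask
    out.log("reject", threshold=float(amplitude_threshold),
            n_rejected=int(mask.sum()),
            fraction=float(mask.mean()))
    return out


def decimate_epochs(epochs: EpochedEEG, factor: int) -> EpochedEEG:
    """Anti-aliased decimation (zero-phase FIR) to sfreq / factor."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return epochs.copy()
    data = sig.decimate(epochs.data, factor, ftype="fir", axis=-1, zero_phase=True)
    out = EpochedEEG(data, epochs.sfreq / factor, epochs.tmin,
                     list(epochs.channel_labels), epochs.rejection_mask.copy(),
                     [dict(p) for p in epochs.provenance])
    out.log("decimate", factor=factor, sfreq=out.sfreq)
    return out


def preprocess_continuous(
    raw: ContinuousEEG,
    interpolation_window: tuple[float, float] = (-0.001, 0.010),
    band: tuple[float, float] = (1.0, 80.0),
    notch: float = 50.0,
    ica_criteria: ICACriteria | None = None,
    epoch_window: tuple[float, float] = (-1.0, 1.0),
    rejection_threshold: float = 200.0,
    decimate: int = 1,
    seed: int | None = 0,
    stage_order: tuple[str, ...] | None = None,
    allow_reorder: bool = False,
    run_ica: bool = True,
) -> tuple[EpochedEEG, ICAResult | None]:
    """Run the full preprocessing chain in the canonical stage order.

    A non-canonical ``stage_order`` is refused unless ``allow_reorder``
    is set; every stage appends a provenance record so the final
    epochs' log reconstructs all parameters.
    """
    order = tuple(stage_order) if stage_order is not None else STAGE_ORDER
    expected = tuple(s for s in STAGE_ORDER if s != "ica" or run_ica)
    if tuple(s for s in order if s != "ica" or run_ica) != expected and not allow_reorder:
        raise ValueError(
            f"stage order {order} deviates from the canonical {STAGE_ORDER}; "
            "pass allow_reorder=True to override")
    stages = {
        "interpolate": lambda x: interpolate_tms_artifact(x, interpolation_window),
        "rereference": rereference_average,
        "bandpass": lambda x: bandpass_filter(x, *band),
        "notch": lambda x: notch_filter(x, notch),
        "epoch": lambda x: epoch(x, window=epoch_window),
        "reject": lambda x: reject_epochs(x, rejection_threshold),
    }
    current: ContinuousEEG | EpochedEEG = raw
    ica_result: ICAResult | None = None
    for name in order:
        if name == "ica":
            if run_ica:
                current, ica_result = run_ica_cleanup(current, ica_criteria, seed=seed)
            continue
        current = stages[name](current)
    if decimate > 1:
        current = decimate_epochs(current, decimate)
    return current, ica_result
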