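"""In-memory containers for continuous and epoched TMS-EEG recordings.

Voltages are microvolts throughout. Epoched data are time-locked to the
TMS pulse at t = 0; analysis windows are half-open ``[start, end)`` in
seconds. Channel order is montage order and is preserved by every
operation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ContinuousEEG", "EpochedEEG"]


def _as_labels(labels: Sequence[str]) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise ValueError("channel labels must be unique")
    return labels


@dataclass
class ContinuousEEG:
    """A continuous multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    sfreq : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per row of ``data``.
    events : list of (int, str)
        Marker events as ``(sample_index, label)`` pairs. TMS pulses use
        the label ``"TMS"``.
    provenance : list of dict
        Ordered processing-stage records.
    """

    data: np.ndarray
    sfreq: float
    channel_labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        self.channel_labels = _as_labels(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if not self.sfreq > 0:
            raise ValueError("sampling rate must be positive")
        n = self.data.shape[1]
        for idx, _ in self.events:
            if not 0 <= idx < n:
                raise ValueError(f"event sample {idx} outside record of {n} samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def log(self, stage: str, **params) -> None:
        self.provenance.append({"stage": stage, **params})

    def copy(self) -> "ContinuousEEG":
        return ContinuousEEG(
            self.data.copy(), self.sfreq, list(self.channel_labels),
            [tuple(e) for e in self.events], [dict(p) for p in self.provenance],
        )


@dataclass
class EpochedEEG:
    """Epochs time-locked to the TMS pulse.

    ``data`` has shape (n_trials, n_channels, n_samples); ``tmin`` is the
    time of the first sample relative to the pulse. ``rejection_mask`` is
    True for trials flagged as artifactual; flagged trials are retained in
    the array and excluded from averages.
    """

    data: np.ndarray
    sfreq: float
    tmin: float
    channel_labels: list[str]
    rejection_mask: np.ndarray | None = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        self.channel_labels = _as_labels(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("one label per channel required")
        if not self.sfreq > 0:
            raise ValueError("sampling rate must be positive")
        if self.rejection_mask is None:
            self.rejection_mask = np.zeros(self.data.shape[0], dtype=bool)
        self.rejection_mask = np.asarray(self.rejection_mask, dtype=bool)
        if self.rejection_mask.shape != (self.data.shape[0],):
            raise ValueError("rejection mask must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds, uniform step 1/sfreq, t = 0 at the pulse."""
        return self.tmin + np.arange(self.n_samples) / self.sfreq

    def time_slice(self, window: tuple[float, float]) -> slice:
        """Sample slice for the half-open window ``[start, end)`` seconds."""
        start, end = window
        if end <= start:
            raise ValueError("window end must exceed start")
        t = self.times
        eps = 0.5 / self.sfreq
        if start < t[0] - eps or end > t[-1] + 1.0 / self.sfreq + eps:
            raise ValueError(
                f"window [{start}, {end}) outside epoch [{t[0]}, {t[-1] + 1 / self.sfreq})"
            )
        i0 = int(np.searchsorted(t, start - eps))
        i1 = int(np.searchsorted(t, end - eps))
        return slice(i0, i1)

    def channel_indices(self, labels: Sequence[str]) -> np.ndarray:
        missing = [c for c in labels if c not in self.channel_labels]
        if missing:
            raise KeyError(f"channels not in epochs: {missing}")
        lut = {c: i for i, c in enumerate(self.channel_labels)}
        return np.array([lut[c] for c in labels], dtype=int)

    def evoked(self) -> np.ndarray:
        """Mean over unmasked trials (channels x samples).

        Raises if every trial is masked.
        """
        keep = ~self.rejection_mask
        if not keep.any():
            raise ValueError("all trials are masked; no evoked can be computed")
        return self.data[keep].mean(axis=0)

    def log(self, stage: str, **params) -> None:
        self.provenance.append({"stage": stage, **params})

    def copy(self) -> "EpochedEEG":
        return EpochedEEG(
            self.data.copy(), self.sfreq, self.tmin, list(self.channel_labels),
            self.rejection_mask.copy(), [dict(p) for p in self.provenance],
        )
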