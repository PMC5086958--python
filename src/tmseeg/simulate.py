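"""Synthetic multi-subject TMS-EEG generator with known ground truth.

The generator emulates the statistical structure a TMS-EEG study design
assumes: a stereotyped TMS-evoked potential (TEP) sequence (P30, N45,
P60, N100, P180, N280) with phenomenological Gaussian scalp
topographies, area-specific induced oscillations (M1: high-alpha /
low-beta; PPC: theta / alpha), realistic noise (white + 1/f + 50 Hz
line + blink transients + a decaying residual TMS artifact), lognormal
between-subject amplitude variability, and an injectable theta-burst
(TBS)-like modulation: a multiplicative gain on late TEP components in
a time window plus per-band gains on oscillation amplitude.

Every simulated quantity is a pure function of the study design, the
configuration, and the seed. Two paths are provided:

* :func:`simulate_dataset` — trial-level epochs (the reference path);
* :func:`simulate_evoked_dataset` — draws each block's *trial mean*
  directly, with noise scaled by 1/sqrt(n_trials) (exact for the
  Gaussian noise components, central-limit for the random-phase
  oscillation residual). Orders of magnitude faster; intended for
  statistics-level simulation studies on cleaned data, so line noise,
  blinks and the residual TMS artifact (preprocessing targets) are not
  included in this path.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import EpochedEEG
from .montage import Montage, default_montage

__all__ = [
    "ComponentSpec",
    "OscillationSpec",
    "ModulationSpec",
    "NoiseModel",
    "SimulationConfig",
    "StudyDesign",
    "gaussian_topography",
    "default_templates",
    "default_modulation",
    "apply_modulation",
    "render_components",
    "render_oscillation",
    "simulate_block",
    "simulate_dataset",
    "simulate_evoked_dataset",
]

COMPONENT_NAMES = ("P30", "N45", "P60", "N100", "P180", "N280")

from .trsp import BANDS as BAND_EDGES  # noqa: E402  (single source for band edges)


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class ComponentSpec:
    """One TEP component: a Gaussian temporal envelope times a topography.

    ``topography`` holds one weight in [-1, 1] per montage channel; the
    evoked contribution is ``amplitude * topography[:, None] *
    exp(-(t - latency)^2 / (2 width^2))`` microvolts.
    """

    name: str
    latency: float  # s, in (0, 0.5]
    width: float  # s, Gaussian SD
    amplitude: float  # signed, μV
    topography: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in COMPONENT_NAMES:
            raise ValueError(f"unknown component name {self.name!r}")
        if not 0 < self.latency <= 0.5:
            raise ValueError("latency must lie in (0, 0.5] s")
        if not self.width > 0:
            raise ValueError("width must be positive")
        object.__setattr__(self, "topography", np.asarray(self.topography, dtype=float))
        if self.topography.ndim != 1:
            raise ValueError("topography must be a per-channel vector")
        if np.abs(self.topography).max() > 1 + 1e-12:
            raise ValueError("topography weights must lie in [-1, 1]")


@dataclass(frozen=True)
class OscillationSpec:
    """An induced oscillation: exponentially decaying sinusoid after onset."""

    center_frequency: float  # Hz, in [4, 50]
    bandwidth: float  # Hz, per-trial frequency jitter FWHM-like scale
    onset: float  # s
    decay_constant: float  # s
    amplitude: float  # μV
    topography: np.ndarray

    def __post_init__(self) -> None:
        if not 4.0 <= self.center_frequency <= 50.0:
            raise ValueError("center_frequency must lie in [4, 50] Hz")
        if not self.decay_constant > 0:
            raise ValueError("decay_constant must be positive")
        object.__setattr__(self, "topography", np.asarray(self.topography, dtype=float))
        if self.topography.ndim != 1:
            raise ValueError("topography must be a per-channel vector")

    @property
    def band(self) -> str:
        for name, (lo, hi) in BAND_EDGES.items():
            if lo <= self.center_frequency <= hi:
                return name
        raise ValueError(f"{self.center_frequency} Hz falls between bands")


@dataclass(frozen=True)
class ModulationSpec:
    """TBS-like modulation of the templates.

    ``gain`` multiplies TEP component amplitude on ``affected_channels``
    for components whose latency lies in ``window``; ``band_gain`` maps
    band name -> multiplicative factor on oscillation amplitude on the
    same channels. ``sham`` must be the identity.
    """

    condition: str  # cTBS | iTBS | sham
    window: tuple[float, float] = (0.10, 0.20)
    gain: float = 1.0
    affected_channels: tuple[str, ...] = ()
    band_gain: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in ("cTBS", "iTBS", "sham"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.gain > 0:
            raise ValueError("gain must be positive")
        if any(not g > 0 for g in self.band_gain.values()):
            raise ValueError("band gains must be positive")
        if self.condition == "sham":
            if self.gain != 1.0 or any(g != 1.0 for g in self.band_gain.values()):
                raise ValueError("sham modulation must have unit gains")
        elif not self.affected_channels:
            raise ValueError("non-sham modulation needs affected channels")


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise parameters (μV unless noted).

    ``phase_jitter`` is the half-width of the uniform per-trial phase of
    induced oscillations (pi = fully random phase, 0 = phase-locked);
    it is part of the noise model so the zero-noise limit is fully
    deterministic.

    The pink (1/f) component models background cortical activity and is
    spatially correlated across electrodes (Gaussian kernel of
    ``pink_spatial_radius`` head radii, per-channel SD preserved); the
    white component models sensor/amplifier noise and is independent
    per channel.
    """

    white_sd: float = 1.5
    pink_sd: float = 3.5
    pink_exponent: float = 1.0
    pink_spatial_radius: float = 0.5
    line_frequency: float = 50.0
    line_amplitude: float = 2.0
    blink_rate: float = 3.0  # events / minute
    blink_amplitude: float = 90.0
    artifact_amplitude: float = 50.0  # residual TMS artifact peak
    artifact_decay: float = 0.003  # s
    phase_jitter: float = float(np.pi)

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(white_sd=0.0, pink_sd=0.0, line_amplitude=0.0, blink_rate=0.0,
                   blink_amplitude=0.0, artifact_amplitude=0.0, phase_jitter=0.0)


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 10
    trials_per_block: int = 80
    sampling_rate: float = 1000.0
    epoch_window: tuple[float, float] = (-1.0, 1.0)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    between_subject_sd: float = 0.1  # lognormal sigma on template amplitudes
    seed: int = 0
    montage: Montage | None = None
    include_eog: bool = False

    def __post_init__(self) -> None:
        if self.trials_per_block <= 0:
            raise ValueError("trials_per_block must be positive")
        if not (self.epoch_window[0] < 0 < self.epoch_window[1]):
            raise ValueError("epoch window must span t = 0")
        if self.montage is None:
            object.__setattr__(self, "montage", default_montage())

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.epoch_window[1] - self.epoch_window[0]) * self.sampling_rate))
        return self.epoch_window[0] + np.arange(n) / self.sampling_rate

    @property
    def channel_labels(self) -> list[str]:
        labels = list(self.montage.channel_labels)
        if self.include_eog:
            labels += ["EOG1", "EOG2"]
        return labels


@dataclass
class StudyDesign:
    """Study design table: one row per recorded block.

    Columns: subject_id, group (real | sham), condition, phase
    (pre | post), area (M1 | PPC), block_id. Real-group subjects have
    pre and post blocks for both TBS conditions and both areas; the
    sham group is stimulated over M1 only.
    """

    table: pd.DataFrame

    REQUIRED = ("subject_id", "group", "condition", "phase", "area", "block_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns {missing}")
        self.validate()

    def validate(self) -> None:
        t = self.table
        bad = set(t["condition"]) - {"cTBS", "iTBS", "sham"}
        if bad:
            raise ValueError(f"unknown conditions {bad}")
        if set(t["phase"]) - {"pre", "post"}:
            raise ValueError("phase must be pre or post")
        if set(t["area"]) - {"M1", "PPC"}:
            raise ValueError("area must be M1 or PPC")
        for subj, sub in t.groupby("subject_id"):
            group = sub["group"].iloc[0]
            if (sub["group"] != group).any():
                raise ValueError(f"subject {subj} assigned to multiple groups")
            have = {(r.condition, r.phase, r.area) for r in sub.itertuples()}
            if group == "real":
                need = {
                    (c, p, a)
                    for c in ("cTBS", "iTBS") for p in ("pre", "post") for a in ("M1", "PPC")
                }
                if not need <= have:
                    raise ValueError(f"real subject {subj} lacks blocks {need - have}")
            elif group == "sham":
                need = {("sham", p, "M1") for p in ("pre", "post")}
                if not need <= have:
                    raise ValueError(f"sham subject {subj} lacks blocks {need - have}")
                if any(a == "PPC" for (_, _, a) in have):
                    raise ValueError(f"sham subject {subj} has PPC blocks")
            else:
                raise ValueError(f"unknown group {group!r}")

    @classmethod
    def default(cls, n_real: int = 10, n_sham: int = 10) -> "StudyDesign":
        rows = []
        for i in range(n_real):
            sid = f"R{i + 1:02d}"
            for cond in ("cTBS", "iTBS"):
                for phase in ("pre", "post"):
                    for area in ("M1", "PPC"):
                        rows.append((sid, "real", cond, phase, area,
                                     f"{sid}_{cond}_{phase}_{area}"))
        for i in range(n_sham):
            sid = f"S{i + 1:02d}"
            for phase in ("pre", "post"):
                rows.append((sid, "sham", "sham", phase, "M1",
                             f"{sid}_sham_{phase}_M1"))
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.table["subject_id"]))


# ---------------------------------------------------------------------------
# templates


def gaussian_topography(montage: Montage, center: str | tuple[float, float],
                        radius: float) -> np.ndarray:
    """Gaussian spatial kernel on the 2-D montage, peak weight 1.

    ``center`` is an electrode label or a 2-D position; ``radius`` is the
    kernel SD in head radii.
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    if isinstance(center, str):
        if center in montage.channel_labels:
            c = montage.positions_2d[montage.index(center)]
        else:
            # kernel centers may name electrodes outside a channel subset
            full = default_montage()
            if center not in full.channel_labels:
                raise KeyError(f"unknown electrode {center!r}")
            c = full.positions_2d[full.index(center)]
    else:
        c = np.asarray(center, dtype=float)
    d2 = np.sum((montage.positions_2d - c) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * radius ** 2))


def default_templates(area: str, montage: Montage | None = None,
                      ) -> tuple[list[ComponentSpec], list[OscillationSpec]]:
    """Default TEP component and oscillation templates for a stimulated area.

    M1 templates place the early positivity and the late P180 over the
    hand-knob electrodes (C3/CP1/CP5), the N45 over the contralateral
    hemisphere, and the N100 bilaterally over central electrodes; peak
    absolute summed amplitude is ~4 μV. M1 induced oscillations sit at
    11 and 18 Hz (high-alpha / low-beta), PPC at 6 and 14 Hz
    (theta / alpha); PPC evoked responses are smaller than M1's.
    """
    montage = montage or default_montage()
    g = lambda center, radius: gaussian_topography(montage, center, radius)  # noqa: E731
    if area == "M1":
        components = [
            ComponentSpec("P30", 0.030, 0.008, 3.2, g("C3", 0.30)),
            ComponentSpec("N45", 0.045, 0.010, -2.2, g("C4", 0.40)),
            ComponentSpec("P60", 0.060, 0.010, 2.0, g("FCz", 0.40)),
            ComponentSpec("N100", 0.100, 0.045, -4.0, g("Cz", 0.42)),
            ComponentSpec("P180", 0.180, 0.060, 4.2, g("C3", 0.32)),
            ComponentSpec("N280", 0.280, 0.050, -1.8, g("FCz", 0.50)),
        ]
        oscillations = [
            OscillationSpec(11.0, 2.0, 0.0, 0.15, 5.5, g("C3", 0.35)),
            OscillationSpec(18.0, 2.0, 0.0, 0.10, 4.5, g("C3", 0.35)),
        ]
    elif area == "PPC":
        components = [
            ComponentSpec("P30", 0.030, 0.008, 2.4, g("P3", 0.30)),
            ComponentSpec("N45", 0.045, 0.010, -1.6, g("P4", 0.40)),
            ComponentSpec("P60", 0.060, 0.010, 1.4, g("Pz", 0.40)),
            ComponentSpec("N100", 0.100, 0.045, -2.8, g("CP1", 0.42)),
            ComponentSpec("P180", 0.180, 0.060, 3.0, g("P3", 0.32)),
            ComponentSpec("N280", 0.280, 0.050, -1.4, g("Pz", 0.50)),
        ]
        oscillations = [
            OscillationSpec(14.0, 2.0, 0.0, 0.10, 3.5, g("P3", 0.35)),
            OscillationSpec(6.0, 1.5, 0.0, 0.12, 3.5, g("P3", 0.40)),
        ]
    else:
        raise ValueError(f"unknown area {area!r}; expected 'M1' or 'PPC'")
    return components, oscillations


def default_modulation(condition: str, roi_channels: Iterable[str] | None = None,
                       ) -> ModulationSpec:
    """Default TBS-like modulation: opposite-sign late-window gains.

    cTBS boosts TEP components in [0.10, 0.20) s by 1.3 and damps alpha
    oscillation amplitude by 0.7; iTBS does the reverse (gain 0.7, beta
    amplitude x 1.3); sham is the identity. Affected channels default to
    the electrodes surrounding the M1 hand knob.
    """
    channels = tuple(roi_channels) if roi_channels is not None else (
        "FCz", "FC1", "Cz", "C3", "CP1", "CP5")
    if condition == "cTBS":
        return ModulationSpec("cTBS", (0.10, 0.20), 1.3, channels, {"alpha": 0.7})
    if condition == "iTBS":
        return ModulationSpec("iTBS", (0.10, 0.20), 0.7, channels, {"beta": 1.3})
    if condition == "sham":
        return ModulationSpec("sham", (0.10, 0.20), 1.0, ())
    raise ValueError(f"unknown condition {condition!r}")


def apply_modulation(
    components: list[ComponentSpec],
    oscillations: list[OscillationSpec],
    modulation: ModulationSpec,
    channel_labels: list[str],
) -> tuple[list[ComponentSpec], list[OscillationSpec]]:
    """Apply a TBS-like modulation to template lists.

    Only components whose latency lies in the modulation window and only
    the affected channels change; sham returns the inputs unchanged.
    """
    if modulation.condition == "sham":
        return list(components), list(oscillations)
    idx = [channel_labels.index(c) for c in modulation.affected_channels
           if c in channel_labels]
    missing = [c for c in modulation.affected_channels if c not in channel_labels]
    if missing:
        raise ValueError(f"affected channels not in montage: {missing}")
    sel = np.zeros(len(channel_labels), dtype=bool)
    sel[idx] = True
    lo, hi = modulation.window
    out_c = []
    for comp in components:
        if lo <= comp.latency < hi and modulation.gain != 1.0:
            topo = comp.topography.copy()
            topo[sel] *= modulation.gain
            # keep the topography in [-1, 1]: fold any excess into amplitude
            peak = np.abs(topo).max()
            if peak > 1.0:
                out_c.append(replace(comp, topography=topo / peak,
                                     amplitude=comp.amplitude * peak))
            else:
                out_c.append(replace(comp, topography=topo))
        else:
            out_c.append(comp)
    out_o = []
    for osc in oscillations:
        gain = modulation.band_gain.get(osc.band, 1.0)
        if gain != 1.0:
            topo = osc.topography.copy()
            topo[sel] *= gain
            peak = np.abs(topo).max()
            if peak > 1.0:
                out_o.append(replace(osc, topography=topo / peak,
                                     amplitude=osc.amplitude * peak))
            else:
                out_o.append(replace(osc, topography=topo))
        else:
            out_o.append(osc)
    return out_c, out_o


# ---------------------------------------------------------------------------
# rendering


def render_components(components: list[ComponentSpec], times: np.ndarray,
                      amplitude_factors: Mapping[str, float] | None = None,
                      ) -> np.ndarray:
    """Noise-free evoked response (channels x samples) of the TEP templates."""
    n_ch = len(components[0].topography) if components else 0
    out = np.zeros((n_ch, len(times)))
    for comp in components:
        factor = 1.0 if amplitude_factors is None else amplitude_factors.get(comp.name, 1.0)
        env = np.exp(-((times - comp.latency) ** 2) / (2.0 * comp.width ** 2))
        out += comp.amplitude * factor * comp.topography[:, None] * env[None, :]
    return out


def render_oscillation(osc: OscillationSpec, times: np.ndarray, phase: float = 0.0,
                       frequency: float | None = None, amplitude_factor: float = 1.0,
                       ) -> np.ndarray:
    """One oscillation burst (channels x samples) at a given trial phase."""
    f = osc.center_frequency if frequency is None else frequency
    rel = times - osc.onset
    env = np.where(rel >= 0, np.exp(-np.maximum(rel, 0) / osc.decay_constant), 0.0)
    wave = env * np.cos(2 * np.pi * f * rel + phase)
    return osc.amplitude * amplitude_factor * osc.topography[:, None] * wave[None, :]


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                sfreq: float, exponent: float, sd: float) -> np.ndarray:
    """1/f^alpha Gaussian noise, unit-free shaping normalized to SD ``sd``."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(shaped ** 2))
    return shaped * (sd / rms) if rms > 0 else shaped


def _spatial_mixer(config: SimulationConfig, radius: float) -> np.ndarray | None:
    """Row-normalized Gaussian mixing matrix imposing spatial correlation.

    Unit-variance independent inputs keep unit variance per channel but
    gain distance-dependent correlation. EOG rows are identity.
    """
    if radius <= 0:
        return None
    pos = config.montage.positions_2d
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=2)
    k = np.exp(-d2 / (2.0 * radius ** 2))
    k /= np.linalg.norm(k, axis=1, keepdims=True)
    n = len(config.channel_labels)
    if n > k.shape[0]:  # EOG channels: uncorrelated
        full = np.eye(n)
        full[: k.shape[0], : k.shape[0]] = k
        return full
    return k


def _blink_waveform(times: np.ndarray, t0: float, width: float = 0.08) -> np.ndarray:
    return np.exp(-((times - t0) ** 2) / (2.0 * width ** 2))


def _blink_topography(config: SimulationConfig) -> np.ndarray:
    """Frontally weighted blink projection, strong on the EOG channels."""
    montage = config.montage
    front = np.array([0.0, 0.95])
    d2 = np.sum((montage.positions_2d - front) ** 2, axis=1)
    topo = np.exp(-d2 / (2.0 * 0.35 ** 2))
    if config.include_eog:
        topo = np.concatenate([topo, [2.0, 2.0]])
    return topo


def _artifact_topography(config: SimulationConfig) -> np.ndarray:
    topo = gaussian_topography(config.montage, "Cz", 0.8)
    if config.include_eog:
        topo = np.concatenate([topo, [0.2, 0.2]])
    return topo


def _pad_topo(topo: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Extend a montage topography with zeros for the EOG channels."""
    if config.include_eog:
        return np.concatenate([topo, [0.0, 0.0]])
    return topo


def _subject_factors(seed: int, subject_index: int, sd: float,
                     components: list[ComponentSpec], n_osc: int,
                     ) -> tuple[dict[str, float], np.ndarray]:
    """Lognormal per-subject amplitude factors, stable across blocks."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, subject_index, 7717]))
    comp_f = {c.name: float(np.exp(rng.normal(0.0, sd))) for c in components}
    osc_f = np.exp(rng.normal(0.0, sd, size=n_osc))
    return comp_f, osc_f


_COND_INDEX = {"cTBS": 0, "iTBS": 1, "sham": 2}
_PHASE_INDEX = {"pre": 0, "post": 1}
_AREA_INDEX = {"M1": 0, "PPC": 1}


def _block_rng(config: SimulationConfig, subject_index: int, condition: str,
               phase: str, area: str, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence([config.seed, subject_index, _COND_INDEX[condition],
                                 _PHASE_INDEX[phase], _AREA_INDEX[area], stream])
    return np.random.default_rng(ss)


def simulate_block(
    components: list[ComponentSpec],
    oscillations: list[OscillationSpec],
    config: SimulationConfig,
    rng: np.random.Generator,
    comp_factors: Mapping[str, float] | None = None,
    osc_factors: np.ndarray | None = None,
) -> EpochedEEG:
    """Simulate one block of trials for one (subject, condition, phase, area).

    Trial = subject-scaled TEP template (phase-locked) + induced
    oscillations with per-trial random phase and frequency jitter +
    white + pink noise + 50 Hz line with per-trial phase + Poisson blink
    transients + a deterministic residual TMS artifact on [0, 10] ms.
    """
    nm = config.noise_model
    times = config.times
    n_t, n_s = config.trials_per_block, len(times)
    labels = config.channel_labels
    n_ch = len(labels)
    for spec in list(components) + list(oscillations):
        if len(spec.topography) != config.montage.n_channels:
            raise ValueError("template topography does not match montage channel count")

    evoked = render_components(components, times, comp_factors)
    evoked = np.vstack([evoked, np.zeros((n_ch - evoked.shape[0], n_s))]) \
        if evoked.shape[0] < n_ch else evoked
    data = np.broadcast_to(evoked, (n_t, n_ch, n_s)).copy()

    osc_factors = np.ones(len(oscillations)) if osc_factors is None else osc_factors
    for osc, factor in zip(oscillations, osc_factors):
        phases = rng.uniform(-nm.phase_jitter, nm.phase_jitter, size=n_t) \
            if nm.phase_jitter > 0 else np.zeros(n_t)
        freqs = osc.center_frequency + (
            rng.normal(0.0, osc.bandwidth / 4.0, size=n_t) if osc.bandwidth > 0
            and nm.phase_jitter > 0 else np.zeros(n_t))
        topo = _pad_topo(osc.topography, config)
        rel = times - osc.onset
        env = np.where(rel >= 0, np.exp(-np.maximum(rel, 0) / osc.decay_constant), 0.0)
        waves = env[None, :] * np.cos(2 * np.pi * freqs[:, None] * rel[None, :]
                                      + phases[:, None])
        data += osc.amplitude * factor * topo[None, :, None] * waves[:, None, :]

    if nm.white_sd > 0:
        data += rng.normal(0.0, nm.white_sd, size=(n_t, n_ch, n_s))
    if nm.pink_sd > 0:
        pink = _pink_noise(rng, (n_t, n_ch), n_s, config.sampling_rate,
                           nm.pink_exponent, nm.pink_sd)
        mixer = _spatial_mixer(config, nm.pink_spatial_radius)
        data += pink if mixer is None else np.einsum("ij,tjs->tis", mixer, pink)
    if nm.line_amplitude > 0:
        line_phase = rng.uniform(0, 2 * np.pi, size=n_t)
        data += nm.line_amplitude * np.sin(
            2 * np.pi * nm.line_frequency * times[None, None, :] + line_phase[:, None, None])
    if nm.blink_rate > 0 and nm.blink_amplitude > 0:
        epoch_len = times[-1] - times[0]
        topo = _blink_topography(config)
        counts = rng.poisson(nm.blink_rate * epoch_len / 60.0, size=n_t)
        for k in np.nonzero(counts)[0]:
            for t0 in rng.uniform(times[0], times[-1], size=counts[k]):
                data[k] += nm.blink_amplitude * topo[:, None] * _blink_waveform(times, t0)[None, :]
    if nm.artifact_amplitude > 0:
        topo = _artifact_topography(config)
        mask = (times >= 0) & (times < 0.010)
        art = np.zeros(n_s)
        art[mask] = nm.artifact_amplitude * np.exp(-times[mask] / nm.artifact_decay)
        data += topo[:, None] * art[None, :]

    epochs = EpochedEEG(data, config.sampling_rate, float(times[0]), labels)
    epochs.log("simulate_block", n_trials=n_t, seed=int(config.seed))
    return epochs


def _design_table(design) -> pd.DataFrame:
    """Accept a StudyDesign or a bare design table (no completeness checks)."""
    table = design.table if isinstance(design, StudyDesign) else design
    missing = [c for c in StudyDesign.REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"design table missing columns {missing}")
    return table


def _prepare_templates(design, config: SimulationConfig,
                       modulations: Mapping[str, ModulationSpec] | None):
    if modulations is None:
        modulations = {c: default_modulation(c) for c in ("cTBS", "iTBS", "sham")}
    templates = {area: default_templates(area, config.montage) for area in ("M1", "PPC")}
    modulated = {}
    for area, (comps, oscs) in templates.items():
        for cond, mod in modulations.items():
            modulated[(area, cond)] = apply_modulation(
                comps, oscs, mod, config.montage.channel_labels)
    return templates, modulated


def simulate_dataset(
    design: StudyDesign | pd.DataFrame,
    config: SimulationConfig,
    modulations: Mapping[str, ModulationSpec] | None = None,
) -> dict[tuple[str, str, str, str], EpochedEEG]:
    """Simulate trial-level epochs for every block of a study design.

    Returns a dict keyed by ``(subject_id, condition, phase, area)``.
    The modulation for a condition is applied to ``post`` blocks only;
    subject amplitude factors are shared between a subject's blocks so
    the pre/post contrast is a paired design.
    """
    table = _design_table(design)
    templates, modulated = _prepare_templates(design, config, modulations)
    subjects = list(dict.fromkeys(table["subject_id"]))
    out: dict[tuple[str, str, str, str], EpochedEEG] = {}
    for row in table.itertuples():
        s_idx = subjects.index(row.subject_id)
        comps, oscs = templates[row.area]
        if row.phase == "post":
            comps, oscs = modulated[(row.area, row.condition)]
        comp_f, osc_f = _subject_factors(config.seed, s_idx, config.between_subject_sd,
                                         comps, len(oscs))
        rng = _block_rng(config, s_idx, row.condition, row.phase, row.area, stream=11)
        out[(row.subject_id, row.condition, row.phase, row.area)] = simulate_block(
            comps, oscs, config, rng, comp_f, osc_f)
    return out


def simulate_evoked_dataset(
    design: StudyDesign | pd.DataFrame,
    config: SimulationConfig,
    modulations: Mapping[str, ModulationSpec] | None = None,
) -> dict[tuple[str, str, str, str], np.ndarray]:
    """Fast path: draw each block's trial-mean evoked directly.

    The Gaussian noise components enter at SD/sqrt(n_trials) (exact);
    random-phase oscillations leave a residual drawn from the
    central-limit distribution of a mean of n unit phasors (two
    quadratures, each N(0, 1/(2 n_trials))). Line noise, blinks and the
    TMS artifact are preprocessing targets and are omitted here; arrays
    are montage channels only (no EOG).
    """
    table = _design_table(design)
    templates, modulated = _prepare_templates(design, config, modulations)
    subjects = list(dict.fromkeys(table["subject_id"]))
    times = config.times
    n_s = len(times)
    n_ch = config.montage.n_channels
    n_t = config.trials_per_block
    nm = config.noise_model
    out: dict[tuple[str, str, str, str], np.ndarray] = {}
    for row in table.itertuples():
        s_idx = subjects.index(row.subject_id)
        comps, oscs = templates[row.area]
        if row.phase == "post":
            comps, oscs = modulated[(row.area, row.condition)]
        comp_f, osc_f = _subject_factors(config.seed, s_idx, config.between_subject_sd,
                                         comps, len(oscs))
        rng = _block_rng(config, s_idx, row.condition, row.phase, row.area, stream=23)
        evoked = render_components(comps, times, comp_f)
        for osc, factor in zip(oscs, osc_f):
            if nm.phase_jitter > 0:
                a, b = rng.normal(0.0, np.sqrt(1.0 / (2 * n_t)), size=2)
                rel = times - osc.onset
                env = np.where(rel >= 0, np.exp(-np.maximum(rel, 0) / osc.decay_constant), 0.0)
                carrier = a * np.cos(2 * np.pi * osc.center_frequency * rel) \
                    + b * np.sin(2 * np.pi * osc.center_frequency * rel)
                evoked += osc.amplitude * factor * osc.topography[:, None] * (env * carrier)[None, :]
            else:
                evoked += render_oscillation(osc, times, 0.0, amplitude_factor=factor)
        if nm.white_sd > 0:
            evoked += rng.normal(0.0, nm.white_sd / np.sqrt(n_t), size=(n_ch, n_s))
        if nm.pink_sd > 0:
            pink = _pink_noise(rng, (n_ch,), n_s, config.sampling_rate,
                               nm.pink_exponent, nm.pink_sd / np.sqrt(n_t))
            mixer = _spatial_mixer(config, nm.pink_spatial_radius)
            evoked += pink if mixer is None else mixer[:n_ch, :n_ch] @ pink
        out[(row.subject_id, row.condition, row.phase, row.area)] = evoked
    return out
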