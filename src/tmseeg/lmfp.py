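"""Local mean field power (LMFP) analysis.

LMFP(t) = sqrt( (1/K) * sum_i (V_i(t) - V_mean(t))^2 ) over the K
channels of a region of interest (ROI), where V_mean is the
instantaneous mean of the ROI channels — the root-mean-square deviation
of the local voltages from their common mode, a reference-free index of
local activation. Condition contrasts are tested pointwise with paired
t-tests, a subject sign-flip permutation null, FDR correction across
timepoints, and a minimum-consecutive-points run criterion.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .stats import fdr_bh, sign_flip_matrix, t_values_1samp

__all__ = [
    "ROIDefinition",
    "M1_ROI",
    "PPC_ROI",
    "LMFPTrace",
    "SignificantRuns",
    "compute_lmfp",
    "lmfp_condition_test",
    "lmfp_difference_contrast",
    "boolean_runs",
]


@dataclass(frozen=True)
class ROIDefinition:
    """A named electrode subset; LMFP needs at least two channels."""

    name: str
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.channel_labels) < 2:
            raise ValueError("LMFP of a single channel is identically zero; "
                             "ROI needs >= 2 channels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channels in ROI")


#: electrodes closest to the stimulated areas
M1_ROI = ROIDefinition("M1", ("C3", "CP1", "CP5"))
#: the montage has no P5; P7 is the nearest shipped parietal neighbor of P3
PPC_ROI = ROIDefinition("PPC", ("P3", "P7"))


@dataclass
class LMFPTrace:
    values: np.ndarray  # μV, >= 0
    times: np.ndarray  # s
    roi: ROIDefinition | None = None


def compute_lmfp(
    evoked: np.ndarray,
    channel_labels: Sequence[str],
    roi: ROIDefinition,
    times: np.ndarray,
    window: tuple[float, float] = (-0.1, 0.5),
) -> LMFPTrace:
    """LMFP of an evoked response over an ROI within a time window.

    ``evoked`` is (n_channels, n_samples) in μV on the ``times`` axis;
    the returned trace covers the half-open ``window``. Invariant to a
    common offset added to all ROI channels.
    """
    evoked = np.asarray(evoked, float)
    times = np.asarray(times, float)
    missing = [c for c in roi.channel_labels if c not in channel_labels]
    if missing:
        raise KeyError(f"ROI channels missing from data: {missing}")
    lut = {c: i for i, c in enumerate(channel_labels)}
    idx = [lut[c] for c in roi.channel_labels]
    eps = 0.5 * float(np.median(np.diff(times)))
    if window[0] < times[0] - eps or window[1] > times[-1] + 2 * eps + eps:
        raise ValueError("window outside the epoch")
    i0 = int(np.searchsorted(times, window[0] - eps))
    i1 = int(np.searchsorted(times, window[1] - eps))
    v = evoked[idx, i0:i1]
    dev = v - v.mean(axis=0, keepdims=True)
    values = np.sqrt(np.mean(dev ** 2, axis=0))
    return LMFPTrace(values, times[i0:i1], roi)


def boolean_runs(mask: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_run, as (start, stop) slices."""
    mask = np.asarray(mask, bool)
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    padded = np.concatenate([[False], mask, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    stops = np.nonzero(~padded[1:] & padded[:-1])[0]
    return [(int(a), int(b)) for a, b in zip(starts, stops) if b - a >= min_run]


@dataclass
class SignificantRuns:
    """Intervals of >= min_run consecutive significant timepoints."""

    intervals: list[tuple[float, float, str]]  # (start s, end s, "post>pre"/"post<pre")
    pointwise_p: np.ndarray
    rejected: np.ndarray
    times: np.ndarray
    params: dict = field(default_factory=dict)

    def overlapping(self, window: tuple[float, float]) -> list[tuple[float, float, str]]:
        lo, hi = window
        return [iv for iv in self.intervals if iv[0] < hi and iv[1] >= lo]


def _pointwise_test(
    diffs: np.ndarray,
    times: np.ndarray,
    n_perm: int,
    alpha: float,
    fdr_q: float | None,
    min_run: int,
    seed: int | None,
    p_source: str,
    direction_labels: tuple[str, str] = ("post>pre", "post<pre"),
) -> SignificantRuns:
    n_subj, n_time = diffs.shape
    t_obs = t_values_1samp(diffs, axis=0)
    if p_source == "parametric":
        p = 2.0 * sps.t.sf(np.abs(t_obs), n_subj - 1)
        scheme = "parametric"
        n_used = 0
    elif p_source == "permutation":
        rng = np.random.default_rng(seed)
        signs, scheme = sign_flip_matrix(n_subj, n_perm, rng)
        n_used = signs.shape[0]
        mean = signs @ diffs / n_subj
        meansq = (diffs ** 2).mean(axis=0)
        var = (meansq[None, :] - mean ** 2) * (n_subj / (n_subj - 1.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = mean / (np.sqrt(var) / np.sqrt(n_subj))
        t_perm[~np.isfinite(t_perm)] = 0.0
        # tolerance so exact ties (e.g. the identity flip) are counted
        tol = 1e-9 * (1.0 + np.abs(t_obs))
        exceed = (np.abs(t_perm) >= (np.abs(t_obs) - tol)[None, :]).sum(axis=0)
        p = (1.0 + exceed) / (1.0 + n_used)
    else:
        raise ValueError("p_source must be 'permutation' or 'parametric'")
    rejected = (p < alpha) if fdr_q is None else fdr_bh(p, fdr_q) & (p < alpha)
    intervals = []
    for a, b in boolean_runs(rejected, min_run):
        sign = np.sign(diffs.mean(axis=0)[a:b].mean())
        direction = direction_labels[0] if sign >= 0 else direction_labels[1]
        intervals.append((float(times[a]), float(times[b - 1]), direction))
    return SignificantRuns(
        intervals, p, rejected, times,
        params={"n_perm": n_used, "scheme": scheme, "alpha": alpha,
                "fdr_q": fdr_q, "min_run": min_run, "seed": seed,
                "p_source": p_source})


def lmfp_condition_test(
    traces_pre: np.ndarray,
    traces_post: np.ndarray,
    times: np.ndarray,
    n_perm: int = 3000,
    alpha: float = 0.025,
    fdr_q: float | None = 0.05,
    min_run: int = 10,
    seed: int | None = 0,
    p_source: str = "permutation",
) -> SignificantRuns:
    """Test post vs pre subject LMFP traces pointwise.

    ``traces_pre``/``traces_post`` are (n_subjects, n_timepoints) paired
    stacks on a common time axis. Pointwise paired t-tests get
    permutation p-values from subject sign flips (exhaustive for small
    n), are FDR-corrected across timepoints (Benjamini–Hochberg, q =
    ``fdr_q``; ``None`` disables the correction) at threshold
    ``alpha``, and only runs of at least ``min_run`` consecutive
    rejected timepoints are reported.
    """
    pre = np.asarray(traces_pre, float)
    post = np.asarray(traces_post, float)
    if pre.shape != post.shape or pre.ndim != 2:
        raise ValueError("paired (n_subjects, n_timepoints) stacks required")
    times = np.asarray(times, float)
    if times.size != pre.shape[1]:
        raise ValueError("mismatched time axes")
    return _pointwise_test(post - pre, times, n_perm, alpha, fdr_q, min_run,
                           seed, p_source)


def lmfp_difference_contrast(
    diffs_condition1: np.ndarray,
    diffs_condition2: np.ndarray,
    times: np.ndarray,
    n_perm: int = 3000,
    alpha: float = 0.025,
    fdr_q: float | None = 0.05,
    min_run: int = 10,
    seed: int | None = 0,
    p_source: str = "permutation",
) -> SignificantRuns:
    """Compare two conditions' post-pre LMFP changes per subject.

    Same machinery as :func:`lmfp_condition_test` applied to the paired
    difference of per-subject (post - pre) traces.
    """
    d1 = np.asarray(diffs_condition1, float)
    d2 = np.asarray(diffs_condition2, float)
    if d1.shape != d2.shape or d1.ndim != 2:
        raise ValueError("paired (n_subjects, n_timepoints) stacks required")
    times = np.asarray(times, float)
    if times.size != d1.shape[1]:
        raise ValueError("mismatched time axes")
    return _pointwise_test(d1 - d2, times, n_perm, alpha, fdr_q, min_run, seed,
                           p_source, direction_labels=("cond1>cond2", "cond1<cond2"))
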