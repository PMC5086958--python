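"""Spatiotemporal cluster-based permutation statistics for TEP waveforms.

Paired (pre vs post, or condition vs condition) evoked responses are
compared with elementwise dependent t-tests inside component time
windows of interest (TOIs). Suprathreshold (electrode, timepoint)
elements of one polarity are linked when the electrodes are montage
neighbors at the same timepoint or the same electrode at consecutive
timepoints; a connected component qualifies as a cluster only if at
least two member electrodes are graph neighbors co-active at some
timepoint. Cluster mass is the sum of member t-values. Significance is
a Monte Carlo estimate against the permutation null of the maximum
absolute cluster mass over both polarities and all TOIs, under
subject-level condition swaps (sign flips of the paired differences),
with the add-one correction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components

from .containers import EpochedEEG
from .montage import NeighborGraph
from .stats import sign_flip_matrix, t_values_1samp

__all__ = [
    "TOISet",
    "DEFAULT_TOIS",
    "Cluster",
    "ClusterTestResult",
    "subject_evoked",
    "t_map",
    "find_clusters",
    "cluster_permutation_test",
]

#: component time windows of interest, half-open seconds
DEFAULT_TOIS = (
    ("P30", (0.010, 0.035)),
    ("N45", (0.035, 0.055)),
    ("P60", (0.055, 0.070)),
    ("N100", (0.070, 0.130)),
    ("P180", (0.130, 0.250)),
    ("N280", (0.250, 0.360)),
)


@dataclass(frozen=True)
class TOISet:
    """Ordered, non-overlapping component windows of interest."""

    windows: tuple[tuple[str, tuple[float, float]], ...] = DEFAULT_TOIS

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for name, (start, end) in self.windows:
            if end <= start:
                raise ValueError(f"TOI {name} has empty window")
            if start < prev_end:
                raise ValueError(f"TOI {name} overlaps the previous window")
            prev_end = end

    def names(self) -> list[str]:
        return [name for name, _ in self.windows]


@dataclass
class Cluster:
    """One spatiotemporal cluster of suprathreshold elements."""

    toi: str
    polarity: str  # "positive" | "negative"
    members: list[tuple[str, int]]  # (channel label, global sample index)
    mass: float
    monte_carlo_p: float
    time_range: tuple[float, float]  # seconds, inclusive member extremes
    channels: tuple[str, ...]


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    params: dict = field(default_factory=dict)
    n_degenerate: int = 0  # zero-variance elements mapped to t = 0

    def per_toi(self) -> dict[str, list[Cluster]]:
        out: dict[str, list[Cluster]] = {}
        for c in self.clusters:
            out.setdefault(c.toi, []).append(c)
        return out

    def significant(self, alpha: float = 0.025) -> list[Cluster]:
        return [c for c in self.clusters if c.monte_carlo_p < alpha]


def subject_evoked(epochs: EpochedEEG) -> np.ndarray:
    """Per-subject evoked response: mean over unmasked trials."""
    return epochs.evoked()


def t_map(condition_a: np.ndarray, condition_b: np.ndarray) -> np.ndarray:
    """Elementwise paired t map over subjects (axis 0).

    Inputs are stacked per-subject evokeds (n_subjects, n_channels,
    n_timepoints) in paired order. Degenerate zero-variance elements map
    to t = 0 so flat channels cannot form clusters.
    """
    a = np.asarray(condition_a, dtype=float)
    b = np.asarray(condition_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired conditions must have identical shapes")
    return t_values_1samp(a - b, axis=0)


def _components(mask: np.ndarray, edge_pairs: np.ndarray,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Connected components of one polarity's suprathreshold mask.

    Returns (labels_per_node, node_flat_indices, has_spatial_edge_per_component).
    Spatial links: graph-neighbor electrodes at the same timepoint;
    temporal links: same electrode at consecutive timepoints.
    """
    n_ch, n_t = mask.shape
    nodes = np.flatnonzero(mask.ravel())
    if nodes.size == 0:
        return np.empty(0, int), nodes, np.empty(0, bool)
    pos = -np.ones(n_ch * n_t, dtype=int)
    pos[nodes] = np.arange(nodes.size)

    rows, cols = [], []
    # temporal adjacency
    both = mask[:, :-1] & mask[:, 1:]
    ch_i, t_i = np.nonzero(both)
    if ch_i.size:
        a = ch_i * n_t + t_i
        rows.append(pos[a])
        cols.append(pos[a + 1])
    # spatial adjacency
    n_spatial = 0
    spatial_rows = []
    if edge_pairs.size:
        ea, eb = edge_pairs[:, 0], edge_pairs[:, 1]
        both = mask[ea, :] & mask[eb, :]  # (n_edges, n_t)
        e_i, t_i = np.nonzero(both)
        if e_i.size:
            a = ea[e_i] * n_t + t_i
            b = eb[e_i] * n_t + t_i
            rows.append(pos[a])
            cols.append(pos[b])
            spatial_rows.append(pos[a])
            n_spatial = e_i.size
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        adj = sparse.coo_matrix(
            (np.ones(r.size, dtype=np.int8), (r, c)), shape=(nodes.size, nodes.size))
        n_comp, labels = connected_components(adj, directed=False)
    else:
        n_comp = nodes.size
        labels = np.arange(nodes.size)
    has_spatial = np.zeros(n_comp, dtype=bool)
    if n_spatial:
        has_spatial[labels[np.concatenate(spatial_rows)]] = True
    return labels, nodes, has_spatial


def _cluster_masses(t_values: np.ndarray, t_crit: float, edge_pairs: np.ndarray,
                    ) -> tuple[list[tuple[np.ndarray, float, str]], float]:
    """All qualifying clusters of both polarities and the max |mass|.

    Returns ([(node_flat_indices, mass, polarity), ...], max_abs_mass).
    """
    out: list[tuple[np.ndarray, float, str]] = []
    max_mass = 0.0
    for polarity, mask in (("positive", t_values > t_crit),
                           ("negative", t_values < -t_crit)):
        labels, nodes, has_spatial = _components(mask, edge_pairs)
        if nodes.size == 0:
            continue
        tv = t_values.ravel()[nodes]
        for comp in np.nonzero(has_spatial)[0]:
            members = nodes[labels == comp]
            mass = float(tv[labels == comp].sum())
            out.append((members, mass, polarity))
            max_mass = max(max_mass, abs(mass))
    return out, max_mass


def find_clusters(
    t_values: np.ndarray,
    threshold_p: float,
    df: int,
    neighbor_graph: NeighborGraph,
    channel_labels: list[str],
) -> list[tuple[np.ndarray, float, str]]:
    """Qualifying clusters of a t map at a per-tail threshold.

    ``threshold_p`` is the one-tailed element threshold (the printed
    p < 0.025 rule); elements with t beyond ``t_{df}`` quantiles form
    candidate members. Returns ``(flat member indices, mass, polarity)``
    tuples; components without a same-timepoint pair of neighboring
    member electrodes are discarded.
    """
    if not 0 < threshold_p < 0.5:
        raise ValueError("threshold_p must lie in (0, 0.5)")
    if set(channel_labels) - set(neighbor_graph.channel_labels):
        raise ValueError("neighbor graph does not cover all channels")
    t_crit = float(sps.t.isf(threshold_p, df))
    edge_pairs = neighbor_graph.edge_index_pairs(channel_labels)
    clusters, _ = _cluster_masses(np.asarray(t_values, float), t_crit, edge_pairs)
    return clusters


def cluster_permutation_test(
    condition_a: np.ndarray,
    condition_b: np.ndarray,
    times: np.ndarray,
    neighbor_graph: NeighborGraph,
    channel_labels: list[str],
    toi_set: TOISet | None = None,
    threshold_p: float = 0.025,
    n_perm: int = 3000,
    seed: int | None = 0,
) -> ClusterTestResult:
    """TOI-windowed spatiotemporal cluster permutation test.

    ``condition_a`` and ``condition_b`` are paired per-subject evoked
    stacks (n_subjects, n_channels, n_timepoints) on the common ``times``
    axis. The permutation scheme swaps condition labels per subject
    (sign flips of the paired differences); with few subjects the
    scheme switches to exhaustive enumeration of all 2^n flips. One
    shared null of the per-permutation maximum absolute cluster mass
    spans all TOIs and both polarities.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable Monte Carlo p-values")
    toi_set = toi_set or TOISet()
    a = np.asarray(condition_a, float)
    b = np.asarray(condition_b, float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("conditions must be (n_subjects, n_channels, n_times) pairs")
    if a.shape[1] != len(channel_labels):
        raise ValueError("channel label count mismatch")
    times = np.asarray(times, float)
    if times.size != a.shape[2]:
        raise ValueError("times axis mismatch")
    diffs = a - b
    n_subj = diffs.shape[0]
    df = n_subj - 1
    t_crit = float(sps.t.isf(threshold_p, df))
    edge_pairs = neighbor_graph.edge_index_pairs(channel_labels)
    if set(channel_labels) - set(neighbor_graph.channel_labels):
        raise ValueError("neighbor graph does not cover all channels")

    eps = 0.5 * float(np.median(np.diff(times)))  # half a sample step
    toi_slices = {}
    for name, (start, end) in toi_set.windows:
        i0 = int(np.searchsorted(times, start - eps))
        i1 = int(np.searchsorted(times, end - eps))
        if i1 <= i0:
            raise ValueError(f"TOI {name} contains no timepoints")
        toi_slices[name] = slice(i0, i1)

    # observed clusters and degenerate-element count
    n_degenerate = 0
    observed: list[tuple[str, np.ndarray, float, str, slice]] = []
    toi_diffs = {}
    for name, sl in toi_slices.items():
        d = diffs[:, :, sl]
        toi_diffs[name] = (d, (d ** 2).mean(axis=0))
        t_obs = t_values_1samp(d, axis=0)
        n_degenerate += int(np.sum(d.std(axis=0) == 0))
        found, _ = _cluster_masses(t_obs, t_crit, edge_pairs)
        for members, mass, polarity in found:
            observed.append((name, members, mass, polarity, sl))

    rng = np.random.default_rng(seed)
    signs, scheme = sign_flip_matrix(n_subj, n_perm, rng)
    n_used = signs.shape[0]
    null = np.zeros(n_used)
    sqrt_n = np.sqrt(n_subj)
    corr = n_subj / (n_subj - 1.0)
    for i, s in enumerate(signs):
        max_mass = 0.0
        for name, (d, meansq) in toi_diffs.items():
            mean = np.einsum("s,sct->ct", s, d) / n_subj
            var = (meansq - mean ** 2) * corr
            with np.errstate(divide="ignore", invalid="ignore"):
                t_perm = mean / (np.sqrt(var) / sqrt_n)
            t_perm[~np.isfinite(t_perm)] = 0.0
            _, m = _cluster_masses(t_perm, t_crit, edge_pairs)
            max_mass = max(max_mass, m)
        null[i] = max_mass

    clusters = []
    n_t_by_toi = {name: toi_slices[name].stop - toi_slices[name].start
                  for name in toi_slices}
    for name, members, mass, polarity, sl in observed:
        tol = 1e-9 * (1.0 + abs(mass))  # count exact ties despite roundoff
        p = float((1.0 + np.sum(null >= abs(mass) - tol)) / (1.0 + n_used))
        n_t = n_t_by_toi[name]
        ch_idx = members // n_t
        t_idx = members % n_t + sl.start
        labels = [(channel_labels[c], int(t)) for c, t in zip(ch_idx, t_idx)]
        clusters.append(Cluster(
            toi=name, polarity=polarity, members=labels, mass=mass,
            monte_carlo_p=p,
            time_range=(float(times[t_idx.min()]), float(times[t_idx.max()])),
            channels=tuple(sorted({channel_labels[c] for c in ch_idx})),
        ))
    clusters.sort(key=lambda c: c.monte_carlo_p)
    return ClusterTestResult(
        clusters=clusters,
        params={"threshold_p": threshold_p, "n_perm": n_used, "scheme": scheme,
                "seed": seed, "neighbor_rule": neighbor_graph.construction_rule,
                "tois": list(toi_set.windows)},
        n_degenerate=n_degenerate,
    )
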