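"""Electrode montage and neighbor-graph construction.

The package ships a frozen 31-channel 10-20 montage (TMS-compatible
EasyCap layout: Fp1 ... Iz) with 2-D azimuthal-equidistant projected
positions on a unit head radius. Cluster statistics depend on the
adjacency relation, so the default neighbor graph — Delaunay
triangulation of the 2-D positions with edges longer than 0.6 head
radii pruned — is deterministic for the shipped fixture.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "Montage",
    "NeighborGraph",
    "default_montage",
    "build_neighbor_graph",
    "EASYCAP_31_CHANNELS",
]

#: the 31 scalp channels of the TMS-compatible EasyCap layout, in cap order
EASYCAP_31_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FCz",
    "FC2", "FC6", "TP9", "T7", "C3", "Cz", "C4", "T8", "TP10", "CP5",
    "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8", "O1", "O2", "Iz",
]


@dataclass
class Montage:
    """Electrode labels with 2-D projected (and optional 3-D) positions."""

    channel_labels: list[str]
    positions_2d: np.ndarray  # (n, 2), unit head radius
    positions_3d: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("montage labels must be unique")
        self.positions_2d = np.asarray(self.positions_2d, dtype=float)
        if self.positions_2d.shape != (len(self.channel_labels), 2):
            raise ValueError("positions_2d must be (n_channels, 2)")
        if not np.all(np.isfinite(self.positions_2d)):
            raise ValueError("positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def index(self, label: str) -> int:
        return self.channel_labels.index(label)


@dataclass
class NeighborGraph:
    """Symmetric electrode adjacency used for cluster formation."""

    channel_labels: list[str]
    adjacency: dict[str, set[str]]
    construction_rule: str = "unspecified"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch in self.channel_labels:
            self.adjacency.setdefault(ch, set())
        for a, nbrs in self.adjacency.items():
            if a in nbrs:
                raise ValueError(f"self-edge at {a}")
            for b in nbrs:
                if a not in self.adjacency.get(b, set()):
                    raise ValueError(f"asymmetric edge {a}-{b}")

    def neighbors(self, label: str) -> set[str]:
        return set(self.adjacency[label])

    def edge_index_pairs(self, labels: list[str] | None = None) -> np.ndarray:
        """Edges as (m, 2) integer index pairs into ``labels`` (a < b)."""
        labels = labels if labels is not None else self.channel_labels
        lut = {c: i for i, c in enumerate(labels)}
        pairs = sorted(
            {
                (min(lut[a], lut[b]), max(lut[a], lut[b]))
                for a, nbrs in self.adjacency.items() if a in lut
                for b in nbrs if b in lut
            }
        )
        return np.array(pairs, dtype=int).reshape(-1, 2)

    def is_connected(self) -> bool:
        if not self.channel_labels:
            return True
        seen = {self.channel_labels[0]}
        stack = [self.channel_labels[0]]
        while stack:
            for b in self.adjacency[stack.pop()]:
                if b not in seen:
                    seen.add(b)
                    stack.append(b)
        return len(seen) == len(self.channel_labels)


def default_montage() -> Montage:
    """Load the shipped 31-channel fixture montage."""
    text = resources.files("tmseeg.data").joinpath("montage_easycap31.tsv").read_text()
    lines = [ln for ln in text.strip().splitlines()[1:] if ln]
    labels, p2, p3 = [], [], []
    for ln in lines:
        parts = ln.split("\t")
        labels.append(parts[0])
        p2.append([float(parts[1]), float(parts[2])])
        p3.append([float(parts[4]), float(parts[5]), float(parts[3])])
    return Montage(labels, np.array(p2), np.array(p3))


def build_neighbor_graph(
    montage: Montage,
    rule: str = "delaunay",
    parameter: float = 0.6,
) -> NeighborGraph:
    """Construct the electrode adjacency relation.

    Parameters
    ----------
    rule : {"delaunay", "distance"}
        ``delaunay`` triangulates the 2-D positions and keeps edges no
        longer than ``parameter`` head radii (default 0.6). ``distance``
        connects every pair within ``parameter`` head radii.
    """
    xy = montage.positions_2d
    labels = montage.channel_labels
    adjacency: dict[str, set[str]] = {c: set() for c in labels}
    if rule == "delaunay":
        if len(labels) < 3:
            raise ValueError("delaunay rule needs at least 3 channels")
        try:
            tri = Delaunay(xy)
        except QhullError as err:
            raise ValueError(f"degenerate electrode positions for delaunay: {err}") from err
        for simplex in tri.simplices:
            for a, b in itertools.combinations(simplex, 2):
                if np.linalg.norm(xy[a] - xy[b]) <= parameter:
                    adjacency[labels[a]].add(labels[b])
                    adjacency[labels[b]].add(labels[a])
    elif rule == "distance":
        if not parameter > 0:
            raise ValueError("distance rule needs a positive radius")
        for a, b in itertools.combinations(range(len(labels)), 2):
            if np.linalg.norm(xy[a] - xy[b]) <= parameter:
                adjacency[labels[a]].add(labels[b])
                adjacency[labels[b]].add(labels[a])
    else:
        raise ValueError(f"unknown neighbor rule {rule!r}")
    return NeighborGraph(list(labels), adjacency, rule, {"parameter": parameter})
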