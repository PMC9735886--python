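"""Electrode channel graph construction.

The scalp montage is modelled as an undirected graph: vertices are EEG
channels, edges connect spatially close electrodes, and the binary adjacency
matrix drives the masked attention of the spatial branch.  Edges come from a
k-nearest-neighbour rule on the 3D electrode positions, symmetrized so that
the graph is undirected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .exceptions import ParameterError, ValidationError

__all__ = [
    "Montage",
    "ChannelGraph",
    "build_knn_adjacency",
    "neighbors",
    "default_montage",
    "load_montage",
    "save_edge_list",
    "plot_channel_graph",
]


@dataclass(frozen=True)
class Montage:
    """A named set of electrodes with unit-sphere scalp coordinates.

    Parameters
    ----------
    channel_names
        Unique channel labels, e.g. ``["F3", "F4", ...]``.
    coordinates
        Array of shape ``(n_channels, 3)`` with finite 3D positions
        (dimensionless, nominally on the unit sphere).
    """

    channel_names: tuple[str, ...]
    coordinates: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError(
                f"coordinates must be (n, 3), got shape {coords.shape}"
            )
        if len(names) != coords.shape[0]:
            raise ValidationError(
                f"{len(names)} names but {coords.shape[0]} coordinate rows"
            )
        if len(names) < 2:
            raise ValidationError("a montage needs at least 2 channels")
        if len(set(names)) != len(names):
            raise ValidationError("channel names must be unique")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


@dataclass(frozen=True)
class ChannelGraph:
    """Undirected electrode graph: montage + binary adjacency.

    Invariants enforced at construction: the adjacency is symmetric with a
    zero diagonal, entries are 0/1, and every node has at least one
    neighbour.
    """

    montage: Montage
    adjacency: np.ndarray = field(repr=False)
    k: int

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = self.montage.n_channels
        if a.shape != (n, n):
            raise ValidationError(f"adjacency must be ({n}, {n}), got {a.shape}")
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency diagonal must be zero (no self-loops)")
        if not np.all(np.isin(a, (0, 1))):
            raise ValidationError("adjacency entries must be 0 or 1")
        if np.any(a.sum(axis=1) == 0):
            raise ValidationError("every node must have at least one neighbor")
        object.__setattr__(self, "adjacency", a.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return self.montage.n_channels

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def build_knn_adjacency(montage: Montage, k: int) -> ChannelGraph:
    """Connect each electrode to its ``k`` nearest neighbours.

    Distances are Euclidean in the montage's 3D coordinates.  The directed
    k-NN relation is symmetrized by OR: an undirected edge {i, j} exists if i
    selects j or j selects i.  Distance ties are broken toward the lower
    channel index, which makes the construction fully deterministic.

    Parameters
    ----------
    montage
        Electrode set; coordinates must be pairwise distinct.
    k
        Neighbours per node, ``1 <= k <= n - 1``.
    """
    n = montage.n_channels
    if not 1 <= k <= n - 1:
        raise ParameterError(f"k must be in [1, {n - 1}], got {k}")
    coords = montage.coordinates
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    off_diag = ~np.eye(n, dtype=bool)
    if np.any(dist[off_diag] == 0.0):
        raise ValidationError("montage has duplicate coordinates")

    adjacency = np.zeros((n, n), dtype=np.int8)
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        # lexsort: primary key distance, secondary key channel index
        order = np.lexsort((others, dist[i, others]))
        for j in others[order[:k]]:
            adjacency[i, j] = 1
            adjacency[j, i] = 1
    return ChannelGraph(montage=montage, adjacency=adjacency, k=k)


def neighbors(graph: ChannelGraph, node_index: int) -> list[int]:
    """Return the ascending indices adjacent to ``node_index``.

    The node itself is never included (the graph has no self-loops).
    """
    n = graph.n_nodes
    if not 0 <= node_index < n:
        raise ParameterError(f"node_index must be in [0, {n}), got {node_index}")
    return np.flatnonzero(graph.adjacency[node_index]).tolist()


def default_montage() -> Montage:
    """The packaged 6-channel montage (F3, F4, C3, C4, O1, O2).

    Positions are the idealized 10-20 system locations on the unit sphere
    (x toward the right ear, y toward the nasion, z up).
    """
    ref = resources.files("mganet.data").joinpath("montage_6ch.json")
    with ref.open("r") as fh:
        return _montage_from_dict(json.load(fh))


def load_montage(path: str | Path) -> Montage:
    """Load a montage from a JSON file with a ``channels`` list."""
    with open(path) as fh:
        return _montage_from_dict(json.load(fh))


def _montage_from_dict(payload: dict) -> Montage:
    try:
        channels = payload["channels"]
        names = tuple(ch["name"] for ch in channels)
        coords = np.array([ch["xyz"] for ch in channels], dtype=float)
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed montage JSON: {exc}") from exc
    return Montage(channel_names=names, coordinates=coords)


def save_edge_list(graph: ChannelGraph, path: str | Path) -> None:
    """Write the undirected edge list as tab-separated ``i<TAB>j``, i < j."""
    with open(path, "w") as fh:
        for i in range(graph.n_nodes):
            for j in range(i + 1, graph.n_nodes):
                if graph.adjacency[i, j]:
                    fh.write(f"{i}\t{j}\n")


def plot_channel_graph(graph: ChannelGraph, path: str | Path) -> None:
    """Save a 2D top-down plot of the electrode graph (x-y projection)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = graph.montage.coordinates
    fig, ax = plt.subplots(figsize=(4, 4))
    for i in range(graph.n_nodes):
        for j in range(i + 1, graph.n_nodes):
            if graph.adjacency[i, j]:
                ax.plot(coords[[i, j], 0], coords[[i, j], 1], "-", color="0.6", lw=1)
    ax.scatter(coords[:, 0], coords[:, 1], s=80, zorder=3)
    for name, (x, y, _z) in zip(graph.montage.channel_names, coords):
        ax.annotate(name, (x, y), textcoords="offset points", xytext=(4, 4))
    ax.set_aspect("equal")
    ax.set_xlabel("x (right)")
    ax.set_ylabel("y (anterior)")
    ax.set_title(f"channel graph (k={graph.k})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
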