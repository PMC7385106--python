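"""Temporal-network data model, file I/O and synthetic generators.

A temporal network is represented as a sequence of ``L`` static snapshot
graphs on a shared node set of size ``N``.  Snapshot ``t`` (1-based in the
file formats, 0-based in the API) aggregates every contact that occurred in
the half-open time window ``[t_min + (t-1)*delta, t_min + t*delta)``; the
final window is closed so the last event is not lost.  Edges are undirected
and unweighted, self-loops are dropped, and duplicate contacts within one
window collapse to a single edge.

Synthetic temporal scale-free networks are built by drawing each snapshot
independently from a Barabasi-Albert preferential-attachment model on the
same ``n`` node labels: the generator starts from ``m`` isolated seed nodes
and attaches each of the remaining ``n - m`` nodes with ``m`` edges, so each
snapshot carries exactly ``m * (n - m)`` edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger("tns")

Edge = tuple[int, int]


def _canon(u: int, v: int) -> Edge:
    return (u, v) if u < v else (v, u)


@dataclass
class TemporalNetwork:
    """``N`` nodes observed over ``L`` undirected snapshot edge sets.

    Parameters
    ----------
    n_nodes:
        Number of nodes ``N``; node indices are contiguous ``0..N-1``.
    snapshots:
        Ordered list of edge sets, one per snapshot; each edge is a
        canonical ``(u, v)`` pair with ``u < v``.
    interval:
        Snapshot width ``delta`` in the original time units, or ``None``
        for synthetic networks with no physical clock.
    node_labels:
        Optional external labels, index-aligned with internal node ids.
    """

    n_nodes: int
    snapshots: list[set[Edge]]
    interval: float | None = None
    node_labels: list[Hashable] | None = None
    _neighbors: list[list[list[int]]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.n_nodes <= 0:
            raise ValueError("n_nodes must be positive")
        if not self.snapshots:
            raise ValueError("a temporal network needs at least one snapshot")
        clean: list[set[Edge]] = []
        for t, edges in enumerate(self.snapshots):
            snap: set[Edge] = set()
            for u, v in edges:
                if u == v:
                    logger.debug("dropping self-loop (%d,%d) in snapshot %d", u, v, t)
                    continue
                if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                    raise ValueError(
                        f"edge ({u},{v}) in snapshot {t} outside node range "
                        f"[0,{self.n_nodes})"
                    )
                snap.add(_canon(u, v))
            clean.append(snap)
        self.snapshots = clean
        if self.node_labels is not None and len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length must equal n_nodes")

    # -- basic quantities -------------------------------------------------

    @property
    def n_snapshots(self) -> int:
        """Number of snapshots ``L``."""
        return len(self.snapshots)

    @property
    def n_events(self) -> int:
        """Total edge count ``E = sum_t |E_t|``."""
        return sum(len(s) for s in self.snapshots)

    @property
    def horizon(self) -> float | None:
        """Observation length ``T = L * delta`` (``None`` without a clock)."""
        if self.interval is None:
            return None
        return self.n_snapshots * self.interval

    # -- cached views -----------------------------------------------------

    def neighbors(self, t: int) -> list[list[int]]:
        """Sorted adjacency lists of snapshot ``t`` (0-based)."""
        if self._neighbors is None:
            self._neighbors = []
            for edges in self.snapshots:
                adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
                for u, v in sorted(edges):
                    adj[u].append(v)
                    adj[v].append(u)
                self._neighbors.append([sorted(a) for a in adj])
        return self._neighbors[t]

    def adjacency(self, t: int) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix of snapshot ``t``."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        for u, v in self.snapshots[t]:
            a[u, v] = a[v, u] = 1.0
        return a

    def degree_matrix(self) -> np.ndarray:
        """``L x N`` matrix of per-snapshot degrees."""
        d = np.zeros((self.n_snapshots, self.n_nodes))
        for t, edges in enumerate(self.snapshots):
            for u, v in edges:
                d[t, u] += 1
                d[t, v] += 1
        return d

    def relabel(self, perm: Sequence[int]) -> "TemporalNetwork":
        """Return a copy with node ``v`` renamed ``perm[v]``."""
        if sorted(perm) != list(range(self.n_nodes)):
            raise ValueError("perm must be a permutation of 0..N-1")
        snaps = [
            {_canon(perm[u], perm[v]) for u, v in edges} for edges in self.snapshots
        ]
        return TemporalNetwork(self.n_nodes, snaps, interval=self.interval)


@dataclass
class AggregatedView:
    """Union of all snapshots with per-pair snapshot multiplicities.

    ``multiplicity[(u, v)]`` counts the snapshots containing the pair
    (always in ``[1, L]``); ``temporal_degree[v]`` is the sum of ``v``'s
    snapshot degrees, i.e. the sum of multiplicities over incident pairs.
    """

    multiplicity: dict[Edge, int]
    temporal_degree: np.ndarray
    neighbors: list[list[int]]


def aggregate(net: TemporalNetwork) -> AggregatedView:
    """Collapse the snapshot sequence into an :class:`AggregatedView`."""
    mult: dict[Edge, int] = {}
    for edges in net.snapshots:
        for e in edges:
            mult[e] = mult.get(e, 0) + 1
    tdeg = np.zeros(net.n_nodes)
    adj: list[list[int]] = [[] for _ in range(net.n_nodes)]
    for (u, v), c in mult.items():
        tdeg[u] += c
        tdeg[v] += c
        adj[u].append(v)
        adj[v].append(u)
    return AggregatedView(mult, tdeg, [sorted(a) for a in adj])


# -- event-stream binning -------------------------------------------------


def bin_edge_stream(
    events: Iterable[tuple[Hashable, Hashable, float]],
    n_snapshots: int,
    t_min: float,
    t_max: float,
) -> TemporalNetwork:
    """Bin a timestamped edge stream into ``L`` equal-width snapshots.

    An event with timestamp ``tau`` lands in snapshot
    ``1 + floor((tau - t_min) / delta)`` with ``delta = (t_max - t_min)/L``;
    ``tau == t_max`` is clamped into the final snapshot.  Node labels may be
    arbitrary hashables and are mapped to contiguous indices (sorted when
    the labels are orderable, else first-appearance order).
    """
    events = list(events)
    if not events:
        raise ValueError("empty event stream")
    if n_snapshots < 1:
        raise ValueError("need at least one snapshot")
    if not t_min < t_max:
        raise ValueError("t_min must be strictly below t_max")
    labels: list[Hashable] = []
    seen: set[Hashable] = set()
    for u, v, _ in events:
        for x in (u, v):
            if x not in seen:
                seen.add(x)
                labels.append(x)
    try:
        labels = sorted(labels)
    except TypeError:
        pass
    index = {lab: i for i, lab in enumerate(labels)}
    delta = (t_max - t_min) / n_snapshots
    snaps: list[set[Edge]] = [set() for _ in range(n_snapshots)]
    for u, v, tau in events:
        if not (t_min <= tau <= t_max):
            raise ValueError(
                f"event ({u!r}, {v!r}, {tau}) outside time range [{t_min}, {t_max}]"
            )
        if u == v:
            logger.debug("dropping self-loop event (%r, %r, %s)", u, v, tau)
            continue
        t = min(int((tau - t_min) / delta), n_snapshots - 1)
        snaps[t].add(_canon(index[u], index[v]))
    return TemporalNetwork(len(labels), snaps, interval=delta, node_labels=labels)


# -- synthetic generator --------------------------------------------------


def generate_temporal_ba(
    n: int, m: int, n_snapshots: int, seed: int
) -> TemporalNetwork:
    """Temporal scale-free network: ``L`` independent BA snapshots.

    Each snapshot is a Barabasi-Albert graph on the same ``n`` labels with
    attachment parameter ``m`` (``m*(n-m)`` edges per snapshot).  Snapshot
    seeds are spawned from ``seed`` so generation is bit-reproducible.
    """
    if m < 1 or n <= m:
        raise ValueError("need n > m >= 1 for preferential attachment")
    if n_snapshots < 1:
        raise ValueError("need at least one snapshot")
    sub = np.random.SeedSequence(seed).generate_state(n_snapshots)
    snaps = []
    for t in range(n_snapshots):
        g = nx.barabasi_albert_graph(n, m, seed=int(sub[t]))
        snaps.append({_canon(u, v) for u, v in g.edges()})
    return TemporalNetwork(n, snaps)


# -- file formats ----------------------------------------------------------


def read_event_stream(path) -> list[tuple[int, int, float]]:
    """Read a KONECT-style TSV event stream: ``u v t`` per line.

    Lines starting with ``#`` or ``%`` are comments; columns beyond the
    third are ignored.
    """
    events: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line[0] in "#%":
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 'u v t', got {line!r}")
            try:
                u, v, tau = parts[0], parts[1], float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad timestamp in {line!r}") from exc
            events.append((int(u) if u.isdigit() else u, int(v) if v.isdigit() else v, tau))
    return events


def write_snapshots(net: TemporalNetwork, path) -> None:
    """Write the per-snapshot edge lists: header ``N L`` then ``t u v`` lines."""
    with open(path, "w") as fh:
        fh.write(f"{net.n_nodes} {net.n_snapshots}\n")
        for t, edges in enumerate(net.snapshots, start=1):
            for u, v in sorted(edges):
                fh.write(f"{t} {u} {v}\n")


def read_snapshots(path) -> TemporalNetwork:
    """Read a snapshot file written by :func:`write_snapshots`.

    Snapshot indices may appear in any order; they are 1-based in the file.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}:1: expected header 'N L'")
        n, n_snapshots = int(header[0]), int(header[1])
        snaps: list[set[Edge]] = [set() for _ in range(n_snapshots)]
        for lineno, line in enumerate(fh, 2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 't u v', got {line!r}")
            t, u, v = (int(p) for p in parts)
            if not 1 <= t <= n_snapshots:
                raise ValueError(f"{path}:{lineno}: snapshot index {t} outside [1,{n_snapshots}]")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"{path}:{lineno}: node index outside [0,{n})")
            snaps[t - 1].add(_canon(u, v))
    return TemporalNetwork(n, snaps)
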