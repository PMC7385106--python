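"""Time-respecting shortest paths on the time-ordered graph.

A temporal (time-respecting) path starting at snapshot offset ``t`` is a
sequence of node occupancies, one per snapshot ``t+1, t+2, ...``: at each
snapshot the walker either waits where it is or traverses a single edge of
that snapshot.  "Shortest" means *foremost* — minimal arrival snapshot —
and the temporal distance ``Delta_{t,T}(v, u)`` is the number of snapshots
elapsed until ``u`` is first occupied.  Two trajectories are distinct paths
whenever their occupancy sequences differ, even if only in where they wait;
this is exactly path counting in the time-ordered DAG.  Trajectories stop
on first reaching the destination.

These primitives power the temporal closeness and betweenness centralities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .temporal_graph import TemporalNetwork


@dataclass
class ArrivalTable:
    """Foremost-arrival data for one (source, start-offset) pair.

    ``distance[u]`` is ``Delta_{t,T}(source, u)`` in snapshots (``inf`` if
    unreachable, 0 at the source itself).  ``sigma[d]`` counts foremost
    trajectories to ``d``; ``sigma_avoiding[d, v]`` counts those that never
    occupy ``v`` — so ``sigma[d] - sigma_avoiding[d, v]`` is the number of
    foremost paths with ``v`` in their interior.
    """

    source: int
    start: int
    distance: np.ndarray
    sigma: np.ndarray | None = None
    sigma_avoiding: np.ndarray | None = None

    def through(self, d: int, v: int) -> float:
        if self.sigma is None or self.sigma_avoiding is None:
            raise ValueError("path counts were not computed for this table")
        return float(self.sigma[d] - self.sigma_avoiding[d, v])


def earliest_arrival(net: TemporalNetwork, source: int, start: int = 0) -> np.ndarray:
    """Foremost-arrival distances from ``source`` starting at offset ``start``.

    ``start`` is 0-based: the walker departs at the boundary before snapshot
    ``start + 1`` and may use snapshots ``start+1 .. L``.  Returns an array
    of ``Delta`` values with ``inf`` for unreachable nodes.
    """
    n, L = net.n_nodes, net.n_snapshots
    if not 0 <= source < n:
        raise ValueError(f"source {source} outside [0,{n})")
    if not 0 <= start < L:
        raise ValueError(f"start offset {start} outside [0,{L})")
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    reached = {source}
    for t in range(start, L):
        adj = net.neighbors(t)
        new: set[int] = set()
        for u in reached:
            for w in adj[u]:
                if w not in reached:
                    new.add(w)
        if new:
            for w in new:
                dist[w] = t + 1 - start
            reached |= new
        if len(reached) == n:
            break
    return dist


def _arrival_and_counts(net: TemporalNetwork, source: int, start: int) -> ArrivalTable:
    """Foremost arrivals plus path counts to every destination at once.

    The count recursion over the time-ordered DAG is the matrix update
    ``w <- (I + A_t) w`` (wait or traverse one snapshot-``t`` edge).  For
    interior counts, the same update runs on a matrix ``W`` whose column
    ``v`` is the count vector of trajectories forbidden to occupy ``v``
    (enforced by zeroing ``W[v, v]`` after every step).  Counts are read
    off at each destination's foremost arrival snapshot.
    """
    n, L = net.n_nodes, net.n_snapshots
    ways = np.zeros(n)
    ways[source] = 1.0
    W = np.zeros((n, n))
    W[source, :] = 1.0
    arrival = np.full(n, np.inf)
    arrival[source] = 0.0
    sigma = np.zeros(n)
    sigma_av = np.zeros((n, n))
    pending = n - 1
    for t in range(start, L):
        if pending == 0 or not ways.any():
            break
        a = net.adjacency(t)
        ways = ways + a @ ways
        W = W + a @ W
        np.fill_diagonal(W, 0.0)
        newly = (ways > 0) & np.isinf(arrival)
        if newly.any():
            idx = np.flatnonzero(newly)
            arrival[idx] = t + 1 - start
            sigma[idx] = ways[idx]
            sigma_av[idx, :] = W[idx, :]
            pending -= len(idx)
    return ArrivalTable(source, start, arrival, sigma, sigma_av)


def count_shortest_paths(
    net: TemporalNetwork, s: int, d: int, start: int = 0
) -> tuple[float, dict[int, float]]:
    """Count foremost temporal paths ``s -> d`` and their interior visits.

    Returns ``(sigma, through)`` where ``sigma`` is the number of foremost
    trajectories and ``through[v]`` (for each ``v`` not in ``{s, d}``) the
    number of those occupying ``v`` at some snapshot.  ``sigma == 0`` when
    ``d`` is unreachable from ``s`` within the horizon.
    """
    if s == d:
        raise ValueError("source and destination must differ")
    table = _arrival_and_counts(net, s, start)
    sigma = float(table.sigma[d])
    through = {
        v: (table.through(d, v) if sigma > 0 else 0.0)
        for v in range(net.n_nodes)
        if v not in (s, d)
    }
    return sigma, through
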