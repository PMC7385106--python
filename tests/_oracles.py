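"""Brute-force reference implementations used only by the tests.

Everything here enumerates explicitly — full occupancy-sequence
enumeration for temporal paths, boolean front propagation for the
deterministic epidemic limit — and is kept independent of the package's
dynamic-programming and simulation code paths.
"""

from __future__ import annotations

import numpy as np

from tns import TemporalNetwork


def _nbrs(net: TemporalNetwork, t: int) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {v: [] for v in range(net.n_nodes)}
    for u, v in net.snapshots[t]:
        adj[u].append(v)
        adj[v].append(u)
    return adj


def all_trajectories(net: TemporalNetwork, s: int, start: int) -> list[tuple[int, ...]]:
    """Every occupancy sequence from ``s`` over snapshots ``start+1 .. L``.

    A sequence lists the occupied node at offsets 0 (the start) through
    ``L - start``; at each snapshot the walker waits or crosses one edge.
    """
    seqs = [(s,)]
    for t in range(start, net.n_snapshots):
        adj = _nbrs(net, t)
        seqs = [seq + (p,) for seq in seqs for p in [seq[-1]] + adj[seq[-1]]]
    return seqs


def earliest_arrival_oracle(net: TemporalNetwork, s: int, start: int) -> np.ndarray:
    dist = np.full(net.n_nodes, np.inf)
    dist[s] = 0.0
    for seq in all_trajectories(net, s, start):
        for step, node in enumerate(seq):
            dist[node] = min(dist[node], step)
    return dist


def shortest_path_counts_oracle(
    net: TemporalNetwork, s: int, d: int, start: int
) -> tuple[int, dict[int, int]]:
    """Foremost-path count and per-node interior counts by enumeration.

    Trajectories are truncated at their first visit to ``d``; distinct
    truncated sequences arriving at the minimal offset are the foremost
    paths.
    """
    arrivals: dict[tuple[int, ...], int] = {}
    for seq in all_trajectories(net, s, start):
        if d not in seq:
            continue
        hit = seq.index(d)
        arrivals[seq[: hit + 1]] = hit
    if not arrivals:
        return 0, {v: 0 for v in range(net.n_nodes) if v not in (s, d)}
    best = min(arrivals.values())
    foremost = [seq for seq, hit in arrivals.items() if hit == best]
    through = {
        v: sum(1 for seq in foremost if v in seq)
        for v in range(net.n_nodes)
        if v not in (s, d)
    }
    return len(foremost), through


def tc_oracle(net: TemporalNetwork) -> np.ndarray:
    scores = np.zeros(net.n_nodes)
    for start in range(net.n_snapshots):
        for v in range(net.n_nodes):
            dist = earliest_arrival_oracle(net, v, start)
            for u in range(net.n_nodes):
                if u != v and np.isfinite(dist[u]):
                    scores[v] += 1.0 / dist[u]
    return scores


def tb_oracle(net: TemporalNetwork) -> np.ndarray:
    n = net.n_nodes
    scores = np.zeros(n)
    for start in range(net.n_snapshots):
        for s in range(n):
            for d in range(n):
                if d == s:
                    continue
                sigma, through = shortest_path_counts_oracle(net, s, d, start)
                if sigma == 0:
                    continue
                for v, cnt in through.items():
                    scores[v] += cnt / sigma
    return scores


def front_reachable_count(net: TemporalNetwork, s: int) -> int:
    """Deterministic epidemic limit: nodes reached by a front that advances
    exactly one hop per snapshot (hop ``i`` must use an edge of snapshot
    ``i``), seeded at ``s`` before snapshot 1."""
    reached = np.zeros(net.n_nodes, dtype=bool)
    reached[s] = True
    active = reached.copy()
    for t in range(net.n_snapshots):
        a = net.adjacency(t).astype(bool)
        new = (a @ active) & ~reached
        reached |= new
        active = new
    return int(reached.sum())
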