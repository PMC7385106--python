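"""Discrete-time SIR spreading over temporal-network snapshots.

The simulator follows the convention standard for snapshot-based contact
networks: during snapshot ``t`` every infectious node attempts, once and
independently with probability ``beta``, to infect each of its currently
susceptible neighbours in ``G_t``; nodes infected during ``t`` become
infectious at snapshot ``t+1``; and every node that was infectious during
``t`` recovers with probability ``mu`` at the end of ``t``.  The epidemic
is seeded by a single node, infectious from snapshot 1.  With ``mu = 1``
(the default throughout) every node is infectious for exactly one snapshot,
so at ``beta = 1`` the dynamics reduce to a deterministic front that
advances one hop per snapshot along consecutively timed edges.

The *infected scale* ``N_v(L)`` of a seed ``v`` — the ever-infected count
``|I ∪ R|`` after snapshot ``L`` — is the ground-truth spreading influence
used both as the regression label for MLI and as the evaluation reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .score import ScoreVector
from .temporal_graph import TemporalNetwork


@dataclass
class SIRParams:
    """Per-snapshot SIR rates and Monte-Carlo settings.

    ``beta`` is the per-contact infection probability, ``mu`` the
    per-snapshot recovery probability (1 by convention), ``runs`` the
    number of Monte-Carlo realizations averaged per seed node.
    """

    beta: float
    mu: float = 1.0
    runs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0,1]")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0,1]")
        if self.runs < 1:
            raise ValueError("runs must be at least 1")


@dataclass
class SpreadResult:
    """Monte-Carlo infected scales for one seed node."""

    source: int
    scales: list[int] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.scales))

    @property
    def std_error(self) -> float:
        if len(self.scales) < 2:
            return float("nan")
        return float(np.std(self.scales, ddof=1) / np.sqrt(len(self.scales)))


def sir_single_run(
    net: TemporalNetwork,
    source: int,
    beta: float,
    mu: float,
    rng: np.random.Generator,
) -> int:
    """One SIR realization; returns the ever-infected count ``N_v(L)``.

    Iteration order (sorted infectious nodes, sorted neighbour lists) is
    fixed so a given generator state always produces the same outcome.
    """
    n = net.n_nodes
    if not 0 <= source < n:
        raise ValueError(f"source {source} outside [0,{n})")
    susceptible = np.ones(n, dtype=bool)
    susceptible[source] = False
    infectious = [source]
    ever = 1
    for t in range(net.n_snapshots):
        if not infectious:
            break
        adj = net.neighbors(t)
        newly: list[int] = []
        if beta > 0.0:
            for i in infectious:
                for u in adj[i]:
                    if susceptible[u] and rng.random() < beta:
                        susceptible[u] = False
                        newly.append(u)
        ever += len(newly)
        if mu >= 1.0:
            infectious = newly
        elif mu <= 0.0:
            infectious = infectious + newly
        else:
            infectious = [i for i in infectious if rng.random() >= mu] + newly
        infectious.sort()
    return ever


def mean_infected_scale(
    net: TemporalNetwork, source: int, params: SIRParams
) -> SpreadResult:
    """Average ``N_v(L)`` over ``params.runs`` seeded realizations.

    Each (seed, source) pair owns an independent random substream, so the
    result does not depend on which other nodes were simulated before it.
    """
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, source)))
    result = SpreadResult(source)
    for _ in range(params.runs):
        result.scales.append(
            sir_single_run(net, source, params.beta, params.mu, rng)
        )
    return result


def label_vector(
    net: TemporalNetwork, params: SIRParams, normalize: bool = True
) -> ScoreVector:
    """Mean infected scale of every node, as an influence score vector.

    With ``normalize=True`` scales are divided by ``N`` so labels live in
    ``[1/N, 1]`` regardless of network size; rankings are unaffected.
    """
    means = np.array(
        [mean_infected_scale(net, v, params).mean for v in range(net.n_nodes)]
    )
    if normalize:
        means = means / net.n_nodes
    return ScoreVector(
        "sir",
        means,
        params={
            "beta": params.beta,
            "mu": params.mu,
            "runs": params.runs,
            "seed": params.seed,
            "normalized": normalize,
        },
    )
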