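import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tns import TemporalNetwork

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy4() -> TemporalNetwork:
    """Four-node chain whose edges appear one per snapshot: 0-1, 1-2, 2-3."""
    return TemporalNetwork(4, [{(0, 1)}, {(1, 2)}, {(2, 3)}])


def random_network(rng: np.random.Generator, n_max: int = 5, l_max: int = 3,
                   p: float | None = None) -> TemporalNetwork:
    """Small Erdos-Renyi-per-snapshot temporal network for oracle sweeps."""
    n = int(rng.integers(2, n_max + 1))
    L = int(rng.integers(1, l_max + 1))
    p = float(rng.uniform(0.2, 0.7)) if p is None else p
    snaps = []
    for _ in range(L):
        edges = {
            (u, v)
            for u in range(n)
            for v in range(u + 1, n)
            if rng.random() < p
        }
        snaps.append(edges)
    return TemporalNetwork(n, snaps)
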