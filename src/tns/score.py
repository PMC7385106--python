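"""Per-node score vectors shared by the simulators, centralities and MLI."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd


@dataclass
class ScoreVector:
    """One real-valued score per node, tagged with the producing method.

    ``params`` records whatever parameters the method depended on
    (e.g. ``beta``/``mu`` for the dynamics-sensitive centrality or the
    SIR ground truth).
    """

    method: str
    values: np.ndarray
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("scores must be a flat per-node vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def ranking(self) -> np.ndarray:
        """Node order by descending score; ties broken by ascending index."""
        return rank_nodes(self.values)

    def top_fraction(self, fraction: float) -> set[int]:
        """Top ``ceil(fraction * N)`` nodes under :meth:`ranking`."""
        k = int(np.ceil(fraction * len(self.values)))
        return set(self.ranking()[:k].tolist())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"node": np.arange(len(self.values)), "score": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, method: str = "file") -> "ScoreVector":
        df = pd.read_csv(path)
        df = df.sort_values("node")
        if not np.array_equal(df["node"].to_numpy(), np.arange(len(df))):
            raise ValueError(f"{path}: node column must cover 0..N-1")
        return cls(method, df["score"].to_numpy())


def rank_nodes(values: np.ndarray) -> np.ndarray:
    """Descending-score node order with ascending-index tie break."""
    values = np.asarray(values, dtype=float)
    return np.lexsort((np.arange(len(values)), -values))
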