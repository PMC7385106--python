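"""MLI: machine-learning index for critical nodes in temporal networks.

Each node is embedded as a small ``D x D`` feature matrix built from its
temporal neighbourhood, a convolutional network is trained to regress the
SIR infected scale from that matrix, and nodes are ranked by the trained
network's score.

Neighbourhood selection.  The ``D`` slots of a node ``v`` hold ``v`` itself
followed by up to ``D - 1`` companions chosen breadth-first on the
aggregated union graph: 1-hop neighbours before 2-hop neighbours, and
within a hop layer nodes with larger temporal degree first (ascending node
index breaks remaining ties).  Missing slots are padding.

Feature matrix.  Snapshot ``t`` (1-based, out of ``L``) carries the decay
weight ``w_t = alpha ** (t - 1)``: the first snapshot has weight 1 and
later snapshots fade geometrically.  The decay points *forward* in time
because the epidemic is seeded at snapshot 1 — with recovery rate 1 the
outbreak is decided almost entirely by the earliest snapshots, so those
are the ones the embedding must preserve.  Off-diagonal entry ``(i, j)``
is the decay-weighted number of snapshots containing the edge
``(s_i, s_j)``; diagonal entry ``(i, i)`` is the decay-weighted degree of
``s_i``.  Rows and columns of padded slots are zero.  At ``alpha = 1`` the
matrix degenerates to the plain aggregated adjacency patch with temporal
degrees on the diagonal.  Feature stacks are max-normalized per network so
that networks of different density share the input scale.

Regressor.  Two 5x5 same-padding convolutions (1→16 and 16→32 channels),
each followed by ReLU and 2x2 max-pooling, then a fully connected
``32·(D/4)² → 1`` head; squared-error loss, Adam optimizer.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._cnn import Adam, Conv2dSame, Flatten, Linear, MaxPool2, ReLU, Sequential, mse_loss
from .score import ScoreVector, rank_nodes
from .spreading import SIRParams, label_vector
from .temporal_graph import AggregatedView, TemporalNetwork, aggregate

PAD = -1  # marker for an absent neighbourhood slot

DEFAULT_D = 8
DEFAULT_ALPHA = 0.2
DEFAULT_BETA_T = 0.1


@dataclass
class RegressorSpec:
    """Architecture of the convolutional regressor.

    ``d`` must be divisible by 4 because two rounds of 2x2 pooling reduce
    the ``d x d`` input to ``d/4 x d/4`` before the fully connected head,
    whose input width is therefore ``channels2 * (d/4)**2``.
    """

    d: int = DEFAULT_D
    channels1: int = 16
    channels2: int = 32
    kernel: int = 5

    def __post_init__(self) -> None:
        if self.d < 4 or self.d % 4 != 0:
            raise ValueError(f"D={self.d} must be a positive multiple of 4")

    @property
    def fc_in(self) -> int:
        return self.channels2 * (self.d // 4) ** 2


@dataclass
class TrainingConfig:
    """Label generation and optimization settings for MLI training."""

    beta_t: float = DEFAULT_BETA_T
    mu_t: float = 1.0
    label_runs: int = 100
    lr: float = 1e-3
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta_t <= 1.0:
            raise ValueError("beta_t must lie in [0,1]")


# -- neighbourhood embedding ----------------------------------------------


def select_neighborhood(
    net: TemporalNetwork, v: int, d: int, agg: AggregatedView | None = None
) -> list[int]:
    """Slots ``[v, s_2, ..., s_D]`` (``PAD`` where no candidate exists)."""
    if d < 1:
        raise ValueError("D must be at least 1")
    if not 0 <= v < net.n_nodes:
        raise ValueError(f"node {v} outside [0,{net.n_nodes})")
    if agg is None:
        agg = aggregate(net)
    slots = [v]
    visited = {v}
    layer = [v]
    while len(slots) < d and layer:
        nxt = {u for w in layer for u in agg.neighbors[w] if u not in visited}
        layer = sorted(nxt, key=lambda u: (-agg.temporal_degree[u], u))
        visited |= nxt
        slots.extend(layer[: d - len(slots)])
    slots.extend([PAD] * (d - len(slots)))
    return slots


def feature_matrix(
    net: TemporalNetwork,
    v: int,
    d: int = DEFAULT_D,
    alpha: float = DEFAULT_ALPHA,
    agg: AggregatedView | None = None,
    slots: list[int] | None = None,
) -> np.ndarray:
    """Decay-weighted ``d x d`` neighbourhood matrix of node ``v``."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0,1]")
    if slots is None:
        slots = select_neighborhood(net, v, d, agg)
    L = net.n_snapshots
    weights = alpha ** np.arange(L)  # w_t = alpha**(t-1), t = 1..L
    deg = net.degree_matrix()
    mat = np.zeros((d, d))
    for i, si in enumerate(slots):
        if si == PAD:
            continue
        mat[i, i] = float(weights @ deg[:, si])
        for j in range(i + 1, d):
            sj = slots[j]
            if sj == PAD:
                continue
            e = (si, sj) if si < sj else (sj, si)
            w = sum(weights[t] for t in range(L) if e in net.snapshots[t])
            mat[i, j] = mat[j, i] = w
    return mat


def feature_tensor(
    net: TemporalNetwork,
    d: int = DEFAULT_D,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
) -> np.ndarray:
    """Stack of all nodes' feature matrices, shape ``(N, 1, d, d)``.

    With ``normalize=True`` the whole stack is divided by its maximum
    entry (when positive), the per-network input scaling used for both
    training and scoring.
    """
    agg = aggregate(net)
    feats = np.stack(
        [feature_matrix(net, v, d, alpha, agg) for v in range(net.n_nodes)]
    )[:, None, :, :]
    if normalize:
        peak = feats.max()
        if peak > 0:
            feats = feats / peak
    return feats


# -- the regressor ---------------------------------------------------------


class MLIRegressor:
    """Conv-conv-FC regressor mapping a feature matrix to a scalar score."""

    def __init__(self, spec: RegressorSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0)))
        self.net = Sequential(
            [
                Conv2dSame(1, spec.channels1, spec.kernel, rng),
                ReLU(),
                MaxPool2(),
                Conv2dSame(spec.channels1, spec.channels2, spec.kernel, rng),
                ReLU(),
                MaxPool2(),
                Flatten(),
                Linear(spec.fc_in, 1, rng),
            ]
        )
        self.trained = False
        # affine label transform fitted during training; predictions are
        # mapped back to label units (ranking is unaffected either way)
        self.y_loc = 0.0
        self.y_scale = 1.0

    def predict(self, feats: np.ndarray) -> np.ndarray:
        """Scalar score per feature matrix; ``feats`` is ``(B, 1, d, d)``."""
        feats = np.asarray(feats, dtype=float)
        if feats.ndim == 3:
            feats = feats[:, None, :, :]
        if feats.shape[1:] != (1, self.spec.d, self.spec.d):
            raise ValueError(
                f"feature shape {feats.shape[1:]} does not match D={self.spec.d}"
            )
        return self.net.forward(feats).ravel() * self.y_scale + self.y_loc


def build_regressor(spec: RegressorSpec | None = None, seed: int = 0) -> MLIRegressor:
    """Freshly initialized (untrained) regressor with seeded weights."""
    return MLIRegressor(spec or RegressorSpec(), seed)


def train(
    model: MLIRegressor,
    features: np.ndarray,
    labels: ScoreVector | np.ndarray,
    cfg: TrainingConfig | None = None,
) -> tuple[MLIRegressor, list[float]]:
    """Fit the regressor by mini-batch Adam on squared error.

    Targets are standardized internally (zero mean, unit variance) so the
    optimization scale does not depend on network size or infection rate;
    :meth:`MLIRegressor.predict` maps scores back to label units.  The
    reported loss history is on the standardized scale.  Returns the model
    (modified in place) and the per-epoch mean batch loss; aborts with a
    diagnostic if the loss goes non-finite.
    """
    cfg = cfg or TrainingConfig()
    y = labels.values if isinstance(labels, ScoreVector) else np.asarray(labels, float)
    x = np.asarray(features, dtype=float)
    if x.ndim == 3:
        x = x[:, None, :, :]
    if len(x) != len(y):
        raise ValueError("one label per feature matrix required")
    model.y_loc = float(y.mean())
    model.y_scale = float(y.std()) or 1.0  # constant labels: fit the offset only
    y = (y - model.y_loc) / model.y_scale
    opt = Adam(model.net.params, lr=cfg.lr)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x5F)))
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(x))
        losses = []
        for lo in range(0, len(x), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            pred = model.net.forward(x[idx]).ravel()
            loss, dpred = mse_loss(pred, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss!r}; "
                    "lower the learning rate or check the labels"
                )
            model.net.backward(dpred[:, None])
            opt.step(model.net.grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    model.trained = True
    model.config = cfg
    return model, history


def score_nodes(
    model: MLIRegressor,
    net: TemporalNetwork,
    d: int = DEFAULT_D,
    alpha: float = DEFAULT_ALPHA,
) -> ScoreVector:
    """Score every node of ``net`` with a trained regressor."""
    if d != model.spec.d:
        raise ValueError(f"model was built for D={model.spec.d}, got D={d}")
    feats = feature_tensor(net, d, alpha)
    return ScoreVector("mli", model.predict(feats), params={"d": d, "alpha": alpha})


def rank(scores: ScoreVector) -> np.ndarray:
    """Node order by descending score, ties by ascending node index."""
    return rank_nodes(scores.values)


def fit_mli(
    train_net: TemporalNetwork,
    cfg: TrainingConfig | None = None,
    spec: RegressorSpec | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[MLIRegressor, list[float]]:
    """End-to-end training: SIR labels at ``beta_t`` + feature embedding + fit."""
    cfg = cfg or TrainingConfig()
    spec = spec or RegressorSpec()
    labels = label_vector(
        train_net,
        SIRParams(cfg.beta_t, cfg.mu_t, runs=cfg.label_runs, seed=cfg.seed),
    )
    feats = feature_tensor(train_net, spec.d, alpha)
    model = build_regressor(spec, seed=cfg.seed)
    return train(model, feats, labels, cfg)


# -- persistence -----------------------------------------------------------


def save_model(model: MLIRegressor, path) -> None:
    """Serialize spec, training config and weights into one ``.npz`` file."""
    meta = {
        "spec": asdict(model.spec),
        "config": asdict(model.config) if getattr(model, "config", None) else None,
        "seed": model.seed,
        "trained": model.trained,
        "y_loc": model.y_loc,
        "y_scale": model.y_scale,
    }
    weights = model.net.get_weights()
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **{f"w{i}": w for i, w in enumerate(weights)},
    )


def load_model(path) -> MLIRegressor:
    """Load a model saved by :func:`save_model`; refuses a spec mismatch."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        spec = RegressorSpec(**meta["spec"])
        model = MLIRegressor(spec, seed=meta.get("seed", 0))
        weights = [data[f"w{i}"] for i in range(len(model.net.params))]
        model.net.set_weights(weights)
    model.trained = bool(meta.get("trained", True))
    model.y_loc = float(meta.get("y_loc", 0.0))
    model.y_scale = float(meta.get("y_scale", 1.0))
    if meta.get("config"):
        model.config = TrainingConfig(**meta["config"])
    return model
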