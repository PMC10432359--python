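"""Surrogate performance predictor over encoded architecture DAGs.

A two-layer GIN-style network adapted to directed graphs: each node
aggregates the summed representations of its in-neighbors, applies a
trainable weight matrix, adds a self-loop term ``B_l h_v`` and passes the
result through a PReLU with a learnable scalar slope,

    h_v^(l) = PReLU(W_l * sum_{u in N_in(v)} h_u^(l-1) + B_l * h_v^(l-1)).

Node representations after the last layer are mean-averaged into a
graph-level vector, followed by two fully connected layers producing a
single scalar: the predicted validation RMSE of the encoded architecture.

Training minimizes the batch smooth-L1 loss: a squared term 0.5 e^2/beta
when the absolute elementwise error is below beta, the absolute term
|e| - 0.5 beta otherwise, averaged over the batch; this damps the influence
of outlier architectures on the gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from . import nn
from .codec import ArchitectureGraph, EvaluatedArchitecture, encode
from .space import SearchSpace

__all__ = [
    "SurrogateConfig", "SurrogateModel", "RankReport",
    "elementwise_loss", "batch_loss", "forward", "fit", "predict_pool",
    "rank_report",
]


@dataclass
class SurrogateConfig:
    """Training hyperparameters for the surrogate.

    Defaults: Adam with learning rate 1e-5 and L2 regularization 5e-4,
    500 epochs, smooth-L1 threshold beta=1, random 80/20 train/test split.
    Hidden width and batch size are free choices (64 and 32).
    """

    num_gnn_layers: int = 2
    hidden_width: int = 64
    beta: float = 1.0
    learning_rate: float = 1e-5
    weight_decay: float = 5e-4
    epochs: int = 500
    batch_size: int = 32
    split_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Loss closed forms


def elementwise_loss(pred: float, truth: float, beta: float = 1.0) -> float:
    """Smooth-L1 elementwise loss of error e = truth - pred."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    e = truth - pred
    if abs(e) < beta:
        return 0.5 * e * e / beta
    return abs(e) - 0.5 * beta


def batch_loss(preds: Sequence[float], truths: Sequence[float],
               beta: float = 1.0) -> float:
    """Mean of the elementwise smooth-L1 losses over a batch."""
    if len(preds) != len(truths):
        raise ValueError("preds and truths must have equal length")
    if len(preds) == 0:
        raise ValueError("empty batch")
    return float(
        np.mean([elementwise_loss(p, t, beta) for p, t in zip(preds, truths)])
    )


# ---------------------------------------------------------------------------
# Model


class SurrogateModel:
    """Parameters of the directed-GIN predictor.

    The network is trained on standardized labels (``label_offset`` and
    ``label_scale`` hold the training-label mean and standard deviation); raw
    RMSE labels live on a ~1e-2 scale, far below the smooth-L1 threshold and
    the L2 regularization strength, so optimizing on the standardized scale
    is what makes the stated hyperparameters well conditioned. Predictions
    are mapped back to the raw scale.
    """

    def __init__(self, feature_dim: int, hidden_width: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        q, h = feature_dim, hidden_width
        self.feature_dim = q
        self.hidden_width = h
        self.W = [nn.glorot(rng, q, h), nn.glorot(rng, h, h)]
        self.B = [nn.glorot(rng, q, h), nn.glorot(rng, h, h)]
        self.slopes = [nn.parameter([0.25]), nn.parameter([0.25])]
        h2 = max(h // 2, 1)
        self.F1 = nn.glorot(rng, h, h2)
        self.b1 = nn.parameter(np.zeros(h2))
        # small output layer so initial predictions sit at the label mean
        self.F2 = nn.glorot(rng, h2, 1, scale=0.1)
        self.b2 = nn.parameter(np.zeros(1))
        self.label_offset = 0.0
        self.label_scale = 1.0

    def parameters(self) -> list[nn.Tensor]:
        return [*self.W, *self.B, *self.slopes, self.F1, self.b1, self.F2, self.b2]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(
            path,
            meta=np.array([self.feature_dim, self.hidden_width,
                           self.label_offset, self.label_scale]),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SurrogateModel":
        with np.load(path) as f:
            q, h, offset, scale = f["meta"]
            model = cls(int(q), int(h))
            for i, p in enumerate(model.parameters()):
                p.data = f[f"p{i}"]
            model.label_offset = float(offset)
            model.label_scale = float(scale)
        return model


def _batch_graphs(graphs: Sequence[ArchitectureGraph]):
    """Disjoint-union batch: stacked features, offset edge indices, and a
    node -> graph index vector."""
    feats, srcs, dsts, gids = [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        n = g.num_nodes
        feats.append(g.features)
        for s, d in g.edges:
            srcs.append(s + offset)
            dsts.append(d + offset)
        gids.extend([gi] * n)
        offset += n
    x = np.vstack(feats) if feats else np.zeros((0, 0))
    return (x, np.array(srcs, dtype=np.int64), np.array(dsts, dtype=np.int64),
            np.array(gids, dtype=np.int64), len(graphs))


def _forward_batch(model: SurrogateModel, batch) -> nn.Tensor:
    x, src, dst, gids, n_graphs = batch
    n_nodes = x.shape[0]
    h = nn.Tensor(x)
    for layer in range(2):
        if len(src):
            msgs = nn.gather_rows(h, src)
            agg = nn.segment_sum(msgs, dst, n_nodes)
        else:
            agg = h * 0.0
        pre = (agg @ model.W[layer]) + (h @ model.B[layer])
        h = pre.prelu(model.slopes[layer])
    pooled = nn.segment_mean(h, gids, n_graphs)
    z = ((pooled @ model.F1) + model.b1).relu()
    out = (z @ model.F2) + model.b2
    return out.reshape(-1)


def _to_raw(model: SurrogateModel, standardized: np.ndarray) -> np.ndarray:
    return standardized * model.label_scale + model.label_offset


def forward(model: SurrogateModel, graph: ArchitectureGraph) -> float:
    """Predicted validation RMSE for one encoded architecture."""
    if graph.features.shape[1] != model.feature_dim:
        raise ValueError(
            f"graph feature dim {graph.features.shape[1]} != model "
            f"feature dim {model.feature_dim}"
        )
    return float(_to_raw(model, _forward_batch(model, _batch_graphs([graph])).data)[0])


def predict_pool(model: SurrogateModel, graphs: Sequence[ArchitectureGraph],
                 batch_size: int = 512) -> np.ndarray:
    """Order-preserving batched predictions for a pool of encodings."""
    preds = []
    for i in range(0, len(graphs), batch_size):
        chunk = graphs[i: i + batch_size]
        if chunk and chunk[0].features.shape[1] != model.feature_dim:
            raise ValueError("graph feature dimension does not match model")
        preds.append(_to_raw(model, _forward_batch(model, _batch_graphs(chunk)).data))
    return np.concatenate(preds) if preds else np.zeros(0)


# ---------------------------------------------------------------------------
# Training


@dataclass
class FitHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None

    def to_rows(self) -> list[tuple[int, float, float]]:
        return list(zip(self.epochs, self.train_loss, self.test_loss))


def fit(
    pairs: Sequence[EvaluatedArchitecture],
    space: SearchSpace,
    config: SurrogateConfig | None = None,
) -> tuple[SurrogateModel, FitHistory]:
    """Train the surrogate on (architecture, validation-RMSE) pairs.

    Pairs are encoded as DAGs, split 80/20 into train/test by the config
    seed, and the model is trained with the batch smooth-L1 objective.
    Returns the model and the per-epoch loss history (train and held-out).
    """
    if config is None:
        config = SurrogateConfig()
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    if len(pairs) < 10:
        import warnings

        warnings.warn(
            f"only {len(pairs)} training pairs; the surrogate is intended "
            "for >= 10", stacklevel=2,
        )
    labels = np.array([p.performance for p in pairs], dtype=np.float64)
    if np.allclose(labels, labels[0]):
        import warnings

        warnings.warn("all performance labels identical; surrogate will be flat")

    graphs = [encode(p.descriptor, space) for p in pairs]
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(pairs))
    n_train = max(1, int(round(config.split_fraction * len(pairs))))
    train_idx, test_idx = perm[:n_train], perm[n_train:]

    model = SurrogateModel(
        feature_dim=graphs[0].features.shape[1],
        hidden_width=config.hidden_width,
        seed=config.seed,
    )
    model.label_offset = float(labels[train_idx].mean())
    scale = float(labels[train_idx].std())
    model.label_scale = scale if scale > 1e-12 else 1.0

    train_graphs = [graphs[i] for i in train_idx]
    test_graphs = [graphs[i] for i in test_idx]
    # optimize on the standardized label scale (see SurrogateModel docstring)
    y_train = (labels[train_idx] - model.label_offset) / model.label_scale
    y_test = (labels[test_idx] - model.label_offset) / model.label_scale
    test_batch = _batch_graphs(test_graphs) if len(test_graphs) else None

    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    history = FitHistory(train_indices=train_idx, test_indices=test_idx)

    n = len(train_graphs)
    bs = min(config.batch_size, n)
    # pre-batch fixed mini-batches once per epoch ordering draw
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, bs):
            idx = order[start: start + bs]
            batch = _batch_graphs([train_graphs[i] for i in idx])
            preds = _forward_batch(model, batch)
            loss = nn.smooth_l1(preds, y_train[idx], beta=config.beta)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(epoch_losses)))
        if test_batch is not None and len(y_test):
            test_preds = _forward_batch(model, test_batch).data
            history.test_loss.append(
                batch_loss(test_preds.tolist(), y_test.tolist(), config.beta)
            )
        else:
            history.test_loss.append(math.nan)
    return model, history


# ---------------------------------------------------------------------------
# Ranking metrics


@dataclass
class RankReport:
    rmse: float
    pearson: float
    kendall_tau: float
    degenerate: bool = False  # zero-variance input: correlations undefined

    def to_json(self) -> dict:
        return {
            "rmse": self.rmse,
            "pearson": self.pearson,
            "kendall_tau": self.kendall_tau,
            "degenerate": self.degenerate,
        }


def rank_report(truths: Sequence[float], preds: Sequence[float]) -> RankReport:
    """RMSE, Pearson r and Kendall tau between measured and predicted
    performance (tau-b tie handling)."""
    t = np.asarray(truths, dtype=np.float64)
    p = np.asarray(preds, dtype=np.float64)
    if t.shape != p.shape or t.size < 2:
        raise ValueError("need two equal-length sequences of length >= 2")
    rmse = float(np.sqrt(np.mean((t - p) ** 2)))
    if np.allclose(t, t[0]) or np.allclose(p, p[0]):
        return RankReport(rmse=rmse, pearson=math.nan, kendall_tau=math.nan,
                          degenerate=True)
    pearson = float(stats.pearsonr(t, p).statistic)
    tau = float(stats.kendalltau(t, p).statistic)
    return RankReport(rmse=rmse, pearson=pearson, kendall_tau=tau)
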