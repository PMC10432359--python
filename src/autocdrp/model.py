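"""Candidate drug-response models: data containers, splits, and the
descriptor-configurable two-branch regressor.

A candidate model has a drug branch (two graph-convolution layers over the
molecular graph, configured by the per-layer choices of an
:class:`~autocdrp.space.ArchitectureDescriptor`, followed by a graph pooling)
and a cell branch (a fixed two-layer fully connected encoder over the binary
cell-line feature vector). The two embeddings are concatenated and passed
through two fully connected layers with a logistic output, regressing the
min-max normalized ln(IC50) of a (drug, cell line) pair. Training
hyperparameters (optimizer, learning rate, weight regulation) come from the
descriptor's global choices; the model is trained with MSE on the normalized
targets and its validation RMSE is the ground-truth label used to train the
surrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from . import nn
from .space import ArchitectureDescriptor

logger = logging.getLogger(__name__)

__all__ = [
    "DrugGraph", "CellLineProfile", "ResponseRecord", "ResponseDataset",
    "SplitSpec", "ResponseNormalizer", "normalize_responses", "split",
    "build_model", "train_eval", "pair_accounting", "CDRPModel",
    "ATOM_SYMBOLS", "DRUG_FEATURE_DIM", "CELL_FEATURE_DIM",
]

# 78-D atom featurization: symbol one-hot (44) + degree one-hot (11)
# + total-H one-hot (11) + implicit-valence one-hot (11) + aromaticity (1).
ATOM_SYMBOLS = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "Unknown",
)
_DEGREE_SLOTS = 11
_HS_SLOTS = 11
_VALENCE_SLOTS = 11
DRUG_FEATURE_DIM = len(ATOM_SYMBOLS) + _DEGREE_SLOTS + _HS_SLOTS + _VALENCE_SLOTS + 1
assert DRUG_FEATURE_DIM == 78
CELL_FEATURE_DIM = 735


@dataclass
class DrugGraph:
    """Molecular graph: atoms are nodes with 78-D features, bonds are
    symmetric directed edge pairs."""

    drug_id: str
    node_features: np.ndarray  # (n_atoms, 78)
    edges: list  # [(i, j)] containing both directions of every bond

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        if self.node_features.ndim != 2 or self.node_features.shape[1] != DRUG_FEATURE_DIM:
            raise ValueError(
                f"drug {self.drug_id!r}: node features must be "
                f"(n_atoms, {DRUG_FEATURE_DIM})"
            )
        edge_set = {(int(i), int(j)) for i, j in self.edges}
        for i, j in edge_set:
            if i == j:
                raise ValueError(f"drug {self.drug_id!r}: self-bond at atom {i}")
            if (j, i) not in edge_set:
                raise ValueError(f"drug {self.drug_id!r}: edge ({i},{j}) not symmetric")
        self.edges = sorted(edge_set)

    @property
    def num_atoms(self) -> int:
        return self.node_features.shape[0]


@dataclass
class CellLineProfile:
    cell_id: str
    features: np.ndarray  # binary vector

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if not np.isin(self.features, (0.0, 1.0)).all():
            raise ValueError(f"cell {self.cell_id!r}: features must be binary")


@dataclass
class ResponseRecord:
    drug_id: str
    cell_id: str
    ln_ic50: float
    y: Optional[float] = None  # normalized target in (0, 1)


@dataclass
class ResponseDataset:
    """Observed entries of the c x d drug-response matrix plus the drug and
    cell-line feature objects they reference."""

    drugs: list
    cells: list
    records: list

    def __post_init__(self) -> None:
        drug_ids = {d.drug_id for d in self.drugs}
        cell_ids = {c.cell_id for c in self.cells}
        if len(drug_ids) != len(self.drugs):
            raise ValueError("duplicate drug ids")
        if len(cell_ids) != len(self.cells):
            raise ValueError("duplicate cell ids")
        seen = set()
        for r in self.records:
            if r.drug_id not in drug_ids:
                raise ValueError(f"record references unknown drug {r.drug_id!r}")
            if r.cell_id not in cell_ids:
                raise ValueError(f"record references unknown cell {r.cell_id!r}")
            key = (r.drug_id, r.cell_id)
            if key in seen:
                raise ValueError(f"duplicate (drug, cell) pair {key}")
            seen.add(key)

    @property
    def drug_index(self) -> dict:
        return {d.drug_id: i for i, d in enumerate(self.drugs)}

    @property
    def cell_index(self) -> dict:
        return {c.cell_id: i for i, c in enumerate(self.cells)}


@dataclass
class SplitSpec:
    mode: Literal["mixed", "blind_drug", "blind_cell"] = "mixed"
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions) or abs(sum(self.fractions) - 1) > 1e-9:
            raise ValueError("fractions must be positive and sum to 1")
        if self.mode not in ("mixed", "blind_drug", "blind_cell"):
            raise ValueError(f"unknown split mode {self.mode!r}")


# ---------------------------------------------------------------------------
# Target normalization


@dataclass
class ResponseNormalizer:
    """Min-max map of ln(IC50) onto (0, 1), fitted on the training portion
    and clipped to [eps, 1-eps] so the logistic output can reach all targets."""

    vmin: float
    vmax: float
    eps: float = 1e-6

    @classmethod
    def fit(cls, values: Sequence[float], eps: float = 1e-6) -> "ResponseNormalizer":
        v = np.asarray(values, dtype=np.float64)
        if v.size < 2 or np.isclose(v.min(), v.max()):
            raise ValueError("need at least two distinct ln_ic50 values")
        return cls(vmin=float(v.min()), vmax=float(v.max()), eps=eps)

    def transform(self, value: float) -> float:
        y = (value - self.vmin) / (self.vmax - self.vmin)
        return float(np.clip(y, self.eps, 1.0 - self.eps))

    def inverse(self, y: float) -> float:
        return self.vmin + y * (self.vmax - self.vmin)


def normalize_responses(
    records: Sequence[ResponseRecord],
    train_records: Sequence[ResponseRecord] | None = None,
    eps: float = 1e-6,
) -> tuple[list[ResponseRecord], ResponseNormalizer]:
    """Attach normalized targets y to records; the min-max parameters are
    fitted on ``train_records`` (default: all records) and returned for
    inverse mapping."""
    fit_on = train_records if train_records is not None else records
    norm = ResponseNormalizer.fit([r.ln_ic50 for r in fit_on], eps=eps)
    out = [
        ResponseRecord(r.drug_id, r.cell_id, r.ln_ic50, norm.transform(r.ln_ic50))
        for r in records
    ]
    return out, norm


# ---------------------------------------------------------------------------
# Splitting


def _partition_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    return n_train, n_val, n_test


def split(
    dataset: ResponseDataset, spec: SplitSpec
) -> tuple[list[ResponseRecord], list[ResponseRecord], list[ResponseRecord]]:
    """Partition records into train/val/test.

    ``mixed`` shuffles interaction pairs; ``blind_drug``/``blind_cell``
    partition the drug (cell) ids instead, so no drug (cell) appears in two
    partitions — the cold-start setting.
    """
    if not dataset.records:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "mixed":
        order = rng.permutation(len(dataset.records))
        n_train, n_val, n_test = _partition_sizes(len(order), spec.fractions)
        recs = [dataset.records[i] for i in order]
        return (recs[:n_train], recs[n_train:n_train + n_val],
                recs[n_train + n_val:])

    key = "drug_id" if spec.mode == "blind_drug" else "cell_id"
    ids = sorted({getattr(r, key) for r in dataset.records})
    if len(ids) < 3:
        raise ValueError(f"{spec.mode} split needs >= 3 distinct {key}s")
    order = rng.permutation(len(ids))
    n_train, n_val, n_test = _partition_sizes(len(ids), spec.fractions)
    n_train, n_val, n_test = max(1, n_train), max(1, n_val), max(1, n_test)
    shuffled = [ids[i] for i in order]
    train_ids = set(shuffled[:len(ids) - n_val - n_test])
    val_ids = set(shuffled[len(ids) - n_val - n_test: len(ids) - n_test])
    test_ids = set(shuffled[len(ids) - n_test:])
    buckets: dict[str, list[ResponseRecord]] = {"train": [], "val": [], "test": []}
    for r in dataset.records:
        rid = getattr(r, key)
        if rid in train_ids:
            buckets["train"].append(r)
        elif rid in val_ids:
            buckets["val"].append(r)
        else:
            buckets["test"].append(r)
    return buckets["train"], buckets["val"], buckets["test"]


# ---------------------------------------------------------------------------
# Accounting


def pair_accounting(n_drugs: int, n_cells: int, n_observed: int) -> dict:
    """Total drug x cell interaction pairs and the percentage missing
    (rounded to one decimal)."""
    total = n_drugs * n_cells
    if n_observed > total:
        raise ValueError("observed pairs exceed drug x cell total")
    missing_pct = round(100.0 * (total - n_observed) / total, 1) if total else 0.0
    return {"total_pairs": total, "missing_pct": missing_pct}


# ---------------------------------------------------------------------------
# Model construction


def _batch_drugs(drugs: Sequence[DrugGraph]):
    feats, srcs, dsts, gids = [], [], [], []
    offset = 0
    for gi, d in enumerate(drugs):
        feats.append(d.node_features)
        for s, t in d.edges:
            srcs.append(s + offset)
            dsts.append(t + offset)
        gids.extend([gi] * d.num_atoms)
        offset += d.num_atoms
    return (np.vstack(feats), np.array(srcs, dtype=np.int64),
            np.array(dsts, dtype=np.int64), np.array(gids, dtype=np.int64),
            len(drugs))


def _gcn_norm(src, dst, n_nodes):
    """Symmetric normalization coefficients with self-loops (computed once
    per drug batch)."""
    src_sl = np.concatenate([src, np.arange(n_nodes)])
    dst_sl = np.concatenate([dst, np.arange(n_nodes)])
    deg = np.bincount(dst_sl, minlength=n_nodes).astype(np.float64)
    w = 1.0 / np.sqrt(deg[src_sl] * deg[dst_sl])
    return src_sl, dst_sl, w.reshape(-1, 1)


class _ConvHead:
    """One head of a graph convolution layer (parameters only)."""

    KNOWN = ("GCNConv", "GENConv", "GINConv", "SGConv", "Linear")

    def __init__(self, conv: str, in_dim: int, out_dim: int, rng):
        if conv not in self.KNOWN:
            raise ValueError(f"unknown convolution option {conv!r}")
        self.conv = conv
        if conv == "GENConv":
            self.W1 = nn.glorot(rng, in_dim, out_dim)
            self.b1 = nn.parameter(np.zeros(out_dim))
            self.W2 = nn.glorot(rng, out_dim, out_dim)
            self.b2 = nn.parameter(np.zeros(out_dim))
        else:
            self.W = nn.glorot(rng, in_dim, out_dim)
            self.b = nn.parameter(np.zeros(out_dim))

    def parameters(self):
        if self.conv == "GENConv":
            return [self.W1, self.b1, self.W2, self.b2]
        return [self.W, self.b]

    def forward(self, h, batch, aggregation: str):
        x, src, dst, gids, _ = batch
        n_nodes = h.shape[0]

        def neighbor_agg(t):
            if len(src) == 0:
                return t * 0.0
            msgs = nn.gather_rows(t, src)
            if aggregation == "add":
                return nn.segment_sum(msgs, dst, n_nodes)
            if aggregation == "mean":
                return nn.segment_mean(msgs, dst, n_nodes)
            return nn.segment_max(msgs, dst, n_nodes)

        if self.conv == "Linear":
            return (h @ self.W) + self.b
        if self.conv == "GINConv":
            return ((h + neighbor_agg(h)) @ self.W) + self.b
        if self.conv == "GENConv":
            agg = neighbor_agg(h.relu() + 1e-7)
            z = ((h + agg) @ self.W1) + self.b1
            return (z.relu() @ self.W2) + self.b2
        # GCNConv / SGConv: fixed symmetrically-normalized sum propagation
        src_sl, dst_sl, w = _gcn_norm(src, dst, n_nodes)
        wt = nn.Tensor(w)

        def propagate(t):
            msgs = nn.gather_rows(t, src_sl) * wt
            return nn.segment_sum(msgs, dst_sl, n_nodes)

        hops = 2 if self.conv == "SGConv" else 1
        out = h
        for _ in range(hops):
            out = propagate(out)
        return (out @ self.W) + self.b


class _ConvLayer:
    """A full searched convolution layer: multi-head convolution, activation,
    normalizer and dropout."""

    _INERT_AGG = {"GCNConv", "SGConv", "Linear"}

    def __init__(self, descriptor: ArchitectureDescriptor, layer: int,
                 in_dim: int, rng):
        self.conv = descriptor.choice("convolution", layer)
        self.aggregation = descriptor.choice("aggregation", layer)
        self.activation = descriptor.choice("activation", layer)
        self.normalizer = descriptor.choice("normalizer", layer)
        if self.aggregation not in ("add", "mean", "max"):
            raise ValueError(f"unknown aggregation option {self.aggregation!r}")
        if self.activation not in ("Softplus", "Linear", "relu", "PReLU", "Sigmoid"):
            raise ValueError(f"unknown activation option {self.activation!r}")
        if self.normalizer not in ("BatchNorm", "GraphNorm", "none"):
            raise ValueError(f"unknown normalizer option {self.normalizer!r}")
        self.out_dim = int(descriptor.choice("hidden", layer))
        self.heads = [
            _ConvHead(self.conv, in_dim, self.out_dim, rng)
            for _ in range(int(descriptor.choice("multi-head", layer)))
        ]
        drop = descriptor.choice("dropout", layer)
        self.dropout = 0.0 if drop == "False" else float(drop)
        if self.conv in self._INERT_AGG and self.aggregation != "add":
            logger.info(
                "aggregation %r is inert for convolution %r (fixed reduction)",
                self.aggregation, self.conv,
            )
        if self.activation == "PReLU":
            self.prelu_slope = nn.parameter([0.25])
        if self.normalizer in ("BatchNorm", "GraphNorm"):
            self.gamma = nn.parameter(np.ones(self.out_dim))
            self.beta = nn.parameter(np.zeros(self.out_dim))

    def parameters(self):
        params = [p for head in self.heads for p in head.parameters()]
        if self.activation == "PReLU":
            params.append(self.prelu_slope)
        if self.normalizer in ("BatchNorm", "GraphNorm"):
            params += [self.gamma, self.beta]
        return params

    def forward(self, h, batch, training: bool, rng):
        outs = [head.forward(h, batch, self.aggregation) for head in self.heads]
        acc = outs[0]
        for o in outs[1:]:
            acc = acc + o
        h = acc * (1.0 / len(outs))
        if self.activation == "Softplus":
            h = h.softplus()
        elif self.activation == "relu":
            h = h.relu()
        elif self.activation == "PReLU":
            h = h.prelu(self.prelu_slope)
        elif self.activation == "Sigmoid":
            h = h.sigmoid()
        # "Linear": identity
        if self.normalizer == "BatchNorm":
            m = h.mean(axis=0, keepdims=True)
            d = h - m
            v = (d * d).mean(axis=0, keepdims=True)
            h = d / (v + 1e-5).sqrt() * self.gamma + self.beta
        elif self.normalizer == "GraphNorm":
            _, _, _, gids, n_graphs = batch
            m = nn.segment_mean(h, gids, n_graphs)
            d = h - nn.gather_rows(m, gids)
            v = nn.segment_mean(d * d, gids, n_graphs)
            h = d / (nn.gather_rows(v, gids) + 1e-5).sqrt() * self.gamma + self.beta
        if training and self.dropout > 0:
            mask = (rng.uniform(size=h.shape) >= self.dropout) / (1 - self.dropout)
            h = h * nn.Tensor(mask)
        return h


class CDRPModel:
    """The instantiated two-branch regressor for one architecture."""

    CELL_WIDTHS = (256, 128)
    HEAD_WIDTH = 128

    def __init__(self, descriptor: ArchitectureDescriptor,
                 drug_feature_dim: int = DRUG_FEATURE_DIM,
                 cell_feature_dim: int = CELL_FEATURE_DIM, seed: int = 0,
                 num_layers: int = 2):
        rng = np.random.default_rng(seed)
        self.descriptor = descriptor
        self.seed = seed
        self.layers = []
        in_dim = drug_feature_dim
        for layer in range(1, num_layers + 1):
            cl = _ConvLayer(descriptor, layer, in_dim, rng)
            self.layers.append(cl)
            in_dim = cl.out_dim
        self.pooling = descriptor.choice("pooling")
        if self.pooling not in ("global_add_pool", "global_max_pool"):
            raise ValueError(f"unknown pooling option {self.pooling!r}")
        w1, w2 = self.CELL_WIDTHS
        self.C1 = nn.glorot(rng, cell_feature_dim, w1)
        self.c1 = nn.parameter(np.zeros(w1))
        self.C2 = nn.glorot(rng, w1, w2)
        self.c2 = nn.parameter(np.zeros(w2))
        joint = in_dim + w2
        self.H1 = nn.glorot(rng, joint, self.HEAD_WIDTH)
        self.h1 = nn.parameter(np.zeros(self.HEAD_WIDTH))
        self.H2 = nn.glorot(rng, self.HEAD_WIDTH, 1)
        self.h2 = nn.parameter(np.zeros(1))
        # training hyperparameters from the descriptor's global choices
        self.learning_rate = float(descriptor.choice("learning-rate"))
        self.weight_decay = float(descriptor.choice("weight-regulation"))
        self.optimizer_name = descriptor.choice("optimizer")
        self._dropout_rng = np.random.default_rng(seed + 1)

    def parameters(self):
        params = [p for layer in self.layers for p in layer.parameters()]
        params += [self.C1, self.c1, self.C2, self.c2,
                   self.H1, self.h1, self.H2, self.h2]
        return params

    def make_optimizer(self):
        cls = nn.Adam if self.optimizer_name == "Adam" else nn.SGD
        return cls(self.parameters(), lr=self.learning_rate,
                   weight_decay=self.weight_decay)

    def drug_embeddings(self, drug_batch, training: bool = False):
        h = nn.Tensor(drug_batch[0])
        for layer in self.layers:
            h = layer.forward(h, drug_batch, training, self._dropout_rng)
        gids, n_graphs = drug_batch[3], drug_batch[4]
        if self.pooling == "global_add_pool":
            return nn.segment_sum(h, gids, n_graphs)
        return nn.segment_max(h, gids, n_graphs)

    def cell_embeddings(self, cell_features: np.ndarray):
        z = ((nn.Tensor(cell_features) @ self.C1) + self.c1).relu()
        return ((z @ self.C2) + self.c2).relu()

    def forward(self, drug_batch, cell_features: np.ndarray,
                drug_idx: np.ndarray, cell_idx: np.ndarray,
                training: bool = False):
        """Predicted normalized response for each (drug_idx, cell_idx) pair;
        output lies in (0, 1)."""
        demb = self.drug_embeddings(drug_batch, training)
        cemb = self.cell_embeddings(cell_features)
        pairs = nn.concat(
            [nn.gather_rows(demb, drug_idx), nn.gather_rows(cemb, cell_idx)],
            axis=1,
        )
        z = ((pairs @ self.H1) + self.h1).relu()
        out = ((z @ self.H2) + self.h2).sigmoid()
        return out.reshape(-1)


def build_model(descriptor: ArchitectureDescriptor,
                drug_feature_dim: int = DRUG_FEATURE_DIM,
                cell_feature_dim: int = CELL_FEATURE_DIM,
                seed: int = 0) -> CDRPModel:
    """Instantiate a trainable candidate model from a descriptor."""
    return CDRPModel(descriptor, drug_feature_dim, cell_feature_dim, seed=seed)


# ---------------------------------------------------------------------------
# Training / evaluation


def _metrics(preds: np.ndarray, ys: np.ndarray) -> tuple[float, float]:
    rmse = float(np.sqrt(np.mean((preds - ys) ** 2)))
    if np.allclose(ys, ys[0]) or np.allclose(preds, preds[0]):
        return rmse, float("nan")
    pcc = float(np.corrcoef(preds, ys)[0, 1])
    return rmse, pcc


def train_eval(
    model: CDRPModel,
    dataset: ResponseDataset,
    splits: tuple[list[ResponseRecord], list[ResponseRecord], list[ResponseRecord]],
    epochs: int = 200,
    seed: int = 0,
    batch_size: int = 128,
) -> dict:
    """Train the candidate with MSE on normalized targets and report RMSE and
    Pearson correlation on the validation and test partitions.

    ``val_rmse`` is the ground-truth performance label for the surrogate.
    With ``epochs=0`` the untrained model is evaluated (no error).
    """
    train_recs, val_recs, test_recs = splits
    if epochs > 0 and not train_recs:
        raise ValueError("empty train partition")
    norm = ResponseNormalizer.fit([r.ln_ic50 for r in (train_recs or dataset.records)])
    drug_ix = dataset.drug_index
    cell_ix = dataset.cell_index
    drug_batch = _batch_drugs(dataset.drugs)
    cell_feats = np.vstack([c.features for c in dataset.cells])

    def arrays(recs):
        di = np.array([drug_ix[r.drug_id] for r in recs], dtype=np.int64)
        ci = np.array([cell_ix[r.cell_id] for r in recs], dtype=np.int64)
        y = np.array([norm.transform(r.ln_ic50) for r in recs])
        return di, ci, y

    tr = arrays(train_recs) if train_recs else None
    va = arrays(val_recs) if val_recs else None
    te = arrays(test_recs) if test_recs else None

    rng = np.random.default_rng(seed)
    opt = model.make_optimizer()
    for _epoch in range(epochs):
        order = rng.permutation(len(train_recs))
        for start in range(0, len(order), batch_size):
            idx = order[start: start + batch_size]
            preds = model.forward(drug_batch, cell_feats, tr[0][idx], tr[1][idx],
                                  training=True)
            err = preds - nn.Tensor(tr[2][idx])
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()

    out: dict = {}
    for name, part in (("val", va), ("test", te)):
        if part is None or len(part[2]) == 0:
            out[f"{name}_rmse"] = float("nan")
            out[f"{name}_pcc"] = float("nan")
            continue
        preds = model.forward(drug_batch, cell_feats, part[0], part[1],
                              training=False).data
        rmse, pcc = _metrics(preds, part[2])
        out[f"{name}_rmse"] = rmse
        out[f"{name}_pcc"] = pcc
    return out
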