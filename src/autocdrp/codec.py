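"""Encode architectures as directed acyclic graphs (and back).

Every chosen option becomes a node; nodes carry a one-hot feature over the
space's global option vocabulary (length q), so the encoding of any two
architectures of the same space differs only in the feature rows, never in
the topology. Edges follow the data-processing flow through the network plus
sub-module relations (a hyperparameter node points at the component it
parameterizes), making the graph a DAG whose unique sink is the training
criterion (for the default space).

The graph label slot carries the architecture's measured validation RMSE
when the graph is used as a surrogate training example.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .space import ArchitectureDescriptor, SearchSpace, validate

__all__ = ["ArchNode", "ArchitectureGraph", "EvaluatedArchitecture",
           "encode", "decode", "adjacency"]


@dataclass(frozen=True)
class ArchNode:
    id: int
    component: str
    layer: Optional[int]  # 1-based for per-layer components, None for global
    option_index: int  # index into the space's option vocabulary [0, q)


@dataclass
class ArchitectureGraph:
    """A DAG encoding of one architecture: nodes, directed edges, one-hot
    node features (num_nodes x q) and an optional performance label."""

    nodes: list[ArchNode]
    edges: list[tuple[int, int]]
    features: np.ndarray
    label: Optional[float] = None

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    def to_json(self) -> dict:
        return {
            "nodes": [
                {"id": n.id, "component": n.component, "layer": n.layer,
                 "option_index": n.option_index}
                for n in self.nodes
            ],
            "edges": [list(e) for e in self.edges],
            "label": self.label,
        }

    @classmethod
    def from_json(cls, obj: dict, q: int) -> "ArchitectureGraph":
        nodes = [
            ArchNode(d["id"], d["component"], d["layer"], d["option_index"])
            for d in obj["nodes"]
        ]
        feats = np.zeros((len(nodes), q))
        for n in nodes:
            feats[n.id, n.option_index] = 1.0
        return cls(nodes=nodes, edges=[tuple(e) for e in obj["edges"]],
                   features=feats, label=obj.get("label"))


@dataclass
class EvaluatedArchitecture:
    """An (architecture, measured performance) training pair for the
    surrogate; performance is a validation RMSE on normalized targets."""

    descriptor: ArchitectureDescriptor
    performance: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.performance < 0:
            raise ValueError("performance (RMSE) must be non-negative")


# Edge scheme for the default 12-component space. Within each layer the
# sub-module choices point at the convolution, the data flows
# convolution -> activation -> normalizer -> dropout, layers are chained
# through dropout, and training hyperparameters converge on the optimizer and
# the loss criterion (the unique sink).
_DEFAULT_COMPONENTS = {
    "aggregation", "convolution", "dropout", "activation", "normalizer",
    "hidden", "multi-head", "learning-rate", "weight-regulation", "optimizer",
    "loss-criterion", "pooling",
}


def _node_key(component: str, layer: Optional[int]) -> tuple:
    return (component, layer)


def _default_edges(num_layers: int) -> list[tuple[tuple, tuple]]:
    edges = []
    for layer in range(1, num_layers + 1):
        conv = ("convolution", layer)
        edges += [
            (("aggregation", layer), conv),
            (("hidden", layer), conv),
            (("multi-head", layer), conv),
            (conv, ("activation", layer)),
            (("activation", layer), ("normalizer", layer)),
            (("normalizer", layer), ("dropout", layer)),
        ]
        if layer < num_layers:
            edges.append((("dropout", layer), ("convolution", layer + 1)))
    edges += [
        (("dropout", num_layers), ("pooling", None)),
        (("learning-rate", None), ("optimizer", None)),
        (("weight-regulation", None), ("optimizer", None)),
        (("pooling", None), ("loss-criterion", None)),
        (("optimizer", None), ("loss-criterion", None)),
    ]
    return edges


def _generic_edges(space: SearchSpace) -> list[tuple[tuple, tuple]]:
    """Fallback scheme for non-default spaces: chain the per-layer components
    in space order within each layer, chain layers, then chain globals."""
    edges = []
    pl = [c.name for c in space.per_layer_components]
    gl = [c.name for c in space.global_components]
    for layer in range(1, space.num_layers + 1):
        for a, b in zip(pl, pl[1:]):
            edges.append(((a, layer), (b, layer)))
        if layer < space.num_layers and pl:
            edges.append(((pl[-1], layer), (pl[0], layer + 1)))
    chain: list[tuple] = []
    if pl:
        chain.append((pl[-1], space.num_layers))
    chain += [(g, None) for g in gl]
    for a, b in zip(chain, chain[1:]):
        edges.append((a, b))
    return edges


def encode(descriptor: ArchitectureDescriptor, space: SearchSpace) -> ArchitectureGraph:
    """Encode a descriptor as an ArchitectureGraph (one-hot features over the
    q-option vocabulary; topology fixed by the space)."""
    problems = validate(descriptor, space)
    if problems:
        raise ValueError("invalid descriptor: " + "; ".join(problems))

    vocab = space.option_vocabulary()
    vocab_index = {co: i for i, co in enumerate(vocab)}

    nodes: list[ArchNode] = []
    key_to_id: dict[tuple, int] = {}
    for layer in range(1, space.num_layers + 1):
        for c in space.per_layer_components:
            opt = descriptor.per_layer_choices[c.name][layer - 1]
            nid = len(nodes)
            nodes.append(ArchNode(nid, c.name, layer, vocab_index[(c.name, opt)]))
            key_to_id[_node_key(c.name, layer)] = nid
    for c in space.global_components:
        opt = descriptor.global_choices[c.name]
        nid = len(nodes)
        nodes.append(ArchNode(nid, c.name, None, vocab_index[(c.name, opt)]))
        key_to_id[_node_key(c.name, None)] = nid

    comp_names = {c.name for c in space.components}
    if comp_names == _DEFAULT_COMPONENTS:
        raw_edges = _default_edges(space.num_layers)
    else:
        raw_edges = _generic_edges(space)
    edges = [(key_to_id[a], key_to_id[b]) for a, b in raw_edges]

    g = nx.DiGraph()
    g.add_nodes_from(range(len(nodes)))
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise AssertionError("encoding produced a cyclic graph")

    features = np.zeros((len(nodes), len(vocab)))
    for n in nodes:
        features[n.id, n.option_index] = 1.0
    return ArchitectureGraph(nodes=nodes, edges=edges, features=features)


def decode(graph: ArchitectureGraph, space: SearchSpace) -> ArchitectureDescriptor:
    """Recover the descriptor from an encoded graph; inverse of :func:`encode`."""
    vocab = space.option_vocabulary()
    q = len(vocab)
    if graph.features.shape != (len(graph.nodes), q):
        raise ValueError(
            f"feature matrix shape {graph.features.shape} does not match "
            f"({len(graph.nodes)}, {q})"
        )
    row_sums = graph.features.sum(axis=1)
    if not np.allclose(row_sums, 1.0) or not np.allclose(graph.features.max(axis=1), 1.0):
        raise ValueError("feature rows must be exact one-hot vectors")

    per_layer: dict[str, list[Optional[str]]] = {
        c.name: [None] * space.num_layers for c in space.per_layer_components
    }
    global_: dict[str, Optional[str]] = {c.name: None for c in space.global_components}
    for node in graph.nodes:
        opt_idx = int(np.argmax(graph.features[node.id]))
        comp_name, opt = vocab[opt_idx]
        if comp_name != node.component:
            raise ValueError(
                f"node {node.id}: feature row points at component "
                f"{comp_name!r} but node is for {node.component!r}"
            )
        if node.layer is not None:
            if not (1 <= node.layer <= space.num_layers):
                raise ValueError(f"node {node.id}: bad layer {node.layer}")
            if per_layer[comp_name][node.layer - 1] is not None:
                raise ValueError(f"duplicate node for {comp_name!r} layer {node.layer}")
            per_layer[comp_name][node.layer - 1] = opt
        else:
            if global_[comp_name] is not None:
                raise ValueError(f"duplicate node for global {comp_name!r}")
            global_[comp_name] = opt

    for name, layers in per_layer.items():
        if any(v is None for v in layers):
            raise ValueError(f"missing node(s) for per-layer component {name!r}")
    for name, v in global_.items():
        if v is None:
            raise ValueError(f"missing node for global component {name!r}")

    return ArchitectureDescriptor(
        {k: tuple(v) for k, v in per_layer.items()}, global_
    )


def adjacency(graph: ArchitectureGraph) -> np.ndarray:
    """Dense 0/1 adjacency matrix: A[i, j] = 1 iff edge i -> j exists."""
    n = graph.num_nodes
    a = np.zeros((n, n), dtype=int)
    for i, j in graph.edges:
        a[i, j] = 1
    return a
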