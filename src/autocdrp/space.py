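"""Architecture search-space definition, counting, validation and sampling.

A search space is an ordered list of design components, each with a finite
option list and a scope: ``per_layer`` components (aggregation, convolution,
dropout, ...) are chosen independently for every GNN layer, while ``global``
components (learning rate, optimizer, ...) are chosen once per architecture.
A concrete assignment of options is an :class:`ArchitectureDescriptor` — the
unit that is sampled, encoded as a DAG, and evaluated.

The sampler implements controlled stratified random sampling: every option of
every component is fixed in turn and a minimum number ``m`` of architectures
containing it is drawn, so each option is guaranteed a floor of coverage in
the evaluated set.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

__all__ = [
    "ComponentDef",
    "SearchSpace",
    "ArchitectureDescriptor",
    "SamplingPlan",
    "default_space",
    "total_size",
    "count_options",
    "lower_limit",
    "stratified_sample",
    "random_descriptor",
    "validate",
    "enumerate_space",
]

Scope = Literal["per_layer", "global"]


@dataclass(frozen=True)
class ComponentDef:
    """One design component: a name, its option labels, and its scope."""

    name: str
    options: tuple[str, ...]
    scope: Scope = "per_layer"

    def __post_init__(self) -> None:
        if not self.options:
            raise ValueError(f"component {self.name!r} has no options")
        if len(set(self.options)) != len(self.options):
            raise ValueError(f"component {self.name!r} has duplicate options")
        if self.scope not in ("per_layer", "global"):
            raise ValueError(f"component {self.name!r}: bad scope {self.scope!r}")
        object.__setattr__(self, "options", tuple(str(o) for o in self.options))


@dataclass(frozen=True)
class SearchSpace:
    """An ordered set of components plus the (fixed) number of GNN layers."""

    components: tuple[ComponentDef, ...]
    num_layers: int = 2

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("search space needs at least one component")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def per_layer_components(self) -> tuple[ComponentDef, ...]:
        return tuple(c for c in self.components if c.scope == "per_layer")

    @property
    def global_components(self) -> tuple[ComponentDef, ...]:
        return tuple(c for c in self.components if c.scope == "global")

    def component(self, name: str) -> ComponentDef:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def option_vocabulary(self) -> list[tuple[str, str]]:
        """Global option vocabulary: (component, option) in space order.

        The index of an entry in this list is the option's one-hot index in
        the DAG encoding; its length is ``q``.
        """
        return [(c.name, o) for c in self.components for o in c.options]

    def to_json(self) -> dict:
        return {
            "components": [
                {"name": c.name, "options": list(c.options), "scope": c.scope}
                for c in self.components
            ],
            "num_layers": self.num_layers,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "SearchSpace":
        comps = tuple(
            ComponentDef(d["name"], tuple(d["options"]), d.get("scope", "per_layer"))
            for d in obj["components"]
        )
        return cls(comps, int(obj.get("num_layers", 2)))


@dataclass(frozen=True)
class ArchitectureDescriptor:
    """A single architecture: one option per global component, and one option
    per layer for every per-layer component."""

    per_layer_choices: dict  # component name -> tuple of num_layers labels
    global_choices: dict  # component name -> label

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "per_layer_choices",
            {k: tuple(v) for k, v in self.per_layer_choices.items()},
        )
        object.__setattr__(self, "global_choices", dict(self.global_choices))

    def choice(self, component: str, layer: int | None = None) -> str:
        if component in self.global_choices:
            return self.global_choices[component]
        if layer is None:
            raise ValueError(f"{component!r} is per-layer; a layer index is required")
        return self.per_layer_choices[component][layer - 1]

    def contains(self, component: str, option: str) -> bool:
        """True if ``option`` is chosen for ``component`` in any layer (or
        globally)."""
        if component in self.global_choices:
            return self.global_choices[component] == option
        return option in self.per_layer_choices.get(component, ())

    def to_json(self) -> dict:
        out: dict = {k: list(v) for k, v in self.per_layer_choices.items()}
        out.update(self.global_choices)
        return out

    @classmethod
    def from_json(cls, obj: dict, space: SearchSpace) -> "ArchitectureDescriptor":
        per_layer = {}
        global_ = {}
        for c in space.components:
            if c.name not in obj:
                raise ValueError(f"descriptor JSON missing component {c.name!r}")
            v = obj[c.name]
            if c.scope == "per_layer":
                per_layer[c.name] = tuple(v)
            else:
                global_[c.name] = v
        return cls(per_layer, global_)

    def canonical(self) -> str:
        """Stable serialization used for hashing, dedup and tie-breaking."""
        return json.dumps(self.to_json(), sort_keys=True, separators=(",", ":"))

    def __hash__(self) -> int:  # frozen dataclass with dict fields
        return hash(self.canonical())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArchitectureDescriptor):
            return NotImplemented
        return self.canonical() == other.canonical()


@dataclass(frozen=True)
class SamplingPlan:
    """Bookkeeping for one stratified draw: budget n, option count q, the
    per-option floor m = ceil(n/q), and the seed."""

    n: int
    q: int
    seed: int
    m: int = field(init=False)

    def __post_init__(self) -> None:
        if self.n < 1 or self.q < 1:
            raise ValueError("n and q must be positive")
        object.__setattr__(self, "m", lower_limit(self.n, self.q))


# ---------------------------------------------------------------------------
# The 12-component default space


def default_space() -> SearchSpace:
    """The default two-layer search space: seven per-layer architecture
    components and five global training hyperparameters (42 options)."""
    return SearchSpace(
        components=(
            ComponentDef("aggregation", ("add", "mean", "max"), "per_layer"),
            ComponentDef(
                "convolution",
                ("GCNConv", "GENConv", "GINConv", "SGConv", "Linear"),
                "per_layer",
            ),
            ComponentDef("dropout", ("False", "0.2", "0.4", "0.6"), "per_layer"),
            ComponentDef(
                "activation",
                ("Softplus", "Linear", "relu", "PReLU", "Sigmoid"),
                "per_layer",
            ),
            ComponentDef("normalizer", ("BatchNorm", "GraphNorm", "none"), "per_layer"),
            ComponentDef("hidden", ("16", "64", "128", "256"), "per_layer"),
            ComponentDef("multi-head", ("1", "2", "4", "6", "8"), "per_layer"),
            ComponentDef("learning-rate", ("1e-2", "1e-3", "1e-4", "5e-4"), "global"),
            ComponentDef("weight-regulation", ("1e-3", "1e-4", "5e-4"), "global"),
            ComponentDef("optimizer", ("Adam", "SGD"), "global"),
            ComponentDef("loss-criterion", ("CrossEntropyLoss", "NllLoss"), "global"),
            ComponentDef("pooling", ("global_add_pool", "global_max_pool"), "global"),
        ),
        num_layers=2,
    )


# ---------------------------------------------------------------------------
# Counting


def total_size(space: SearchSpace) -> int:
    """Number of distinct architectures in the space (exact integer)."""
    size = 1
    for c in space.per_layer_components:
        size *= len(c.options) ** space.num_layers
    for c in space.global_components:
        size *= len(c.options)
    return size


def count_options(space: SearchSpace) -> int:
    """q: total number of options, each counted once (not per layer)."""
    return sum(len(c.options) for c in space.components)


def lower_limit(n: int, q: int) -> int:
    """Per-option floor m = ceil(n/q) of sampled architectures that must
    contain each option."""
    if n < 1 or q < 1:
        raise ValueError("n and q must be positive")
    return max(1, math.ceil(n / q))


# ---------------------------------------------------------------------------
# Sampling


def random_descriptor(
    space: SearchSpace, seed: int | None = None, rng: np.random.Generator | None = None
) -> ArchitectureDescriptor:
    """Draw one descriptor with every choice uniform and independent."""
    if rng is None:
        rng = np.random.default_rng(seed)
    per_layer = {
        c.name: tuple(
            c.options[rng.integers(len(c.options))] for _ in range(space.num_layers)
        )
        for c in space.per_layer_components
    }
    global_ = {
        c.name: c.options[rng.integers(len(c.options))]
        for c in space.global_components
    }
    return ArchitectureDescriptor(per_layer, global_)


def _descriptor_with_fixed(
    space: SearchSpace,
    component: ComponentDef,
    option: str,
    rng: np.random.Generator,
) -> ArchitectureDescriptor:
    """Uniform descriptor constrained to contain ``option`` for ``component``;
    for per-layer components the pinned layer is drawn uniformly."""
    d = random_descriptor(space, rng=rng)
    if component.scope == "global":
        g = dict(d.global_choices)
        g[component.name] = option
        return ArchitectureDescriptor(d.per_layer_choices, g)
    layer = int(rng.integers(space.num_layers))
    choices = list(d.per_layer_choices[component.name])
    choices[layer] = option
    pl = dict(d.per_layer_choices)
    pl[component.name] = tuple(choices)
    return ArchitectureDescriptor(pl, d.global_choices)


def stratified_sample(
    space: SearchSpace, n: int, seed: int = 0
) -> list[ArchitectureDescriptor]:
    """Controlled stratified random sample of architectures.

    Every option of every component is fixed in turn, and m = ceil(n/q)
    architectures containing it are drawn (the pinned layer of a per-layer
    option is uniform). Within a stratum, draws that collide with an already
    sampled descriptor are retried a bounded number of times; any remaining
    duplicates are dropped, so the result has at most q*m distinct
    descriptors and every option is contained in at least m of them whenever
    the space is large enough to allow it.
    """
    q = count_options(space)
    if n < q:
        raise ValueError(f"budget n={n} below option count q={q}: cannot cover")
    plan = SamplingPlan(n=n, q=q, seed=seed)
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[ArchitectureDescriptor] = []
    for comp in space.components:
        for opt in comp.options:
            for _ in range(plan.m):
                d = _descriptor_with_fixed(space, comp, opt, rng)
                for _attempt in range(100):
                    if d.canonical() not in seen:
                        break
                    d = _descriptor_with_fixed(space, comp, opt, rng)
                key = d.canonical()
                if key not in seen:
                    seen.add(key)
                    out.append(d)
    return out


def uniform_sample(
    space: SearchSpace, n: int, seed: int = 0
) -> list[ArchitectureDescriptor]:
    """n independent uniform draws, deduplicated (order-preserving)."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[ArchitectureDescriptor] = []
    for _ in range(n):
        d = random_descriptor(space, rng=rng)
        if d.canonical() not in seen:
            seen.add(d.canonical())
            out.append(d)
    return out


# ---------------------------------------------------------------------------
# Validation and enumeration


def validate(descriptor: ArchitectureDescriptor, space: SearchSpace) -> list[str]:
    """Check a descriptor against a space; returns a list of violations
    (empty means OK)."""
    violations: list[str] = []
    for c in space.per_layer_components:
        choices = descriptor.per_layer_choices.get(c.name)
        if choices is None:
            violations.append(f"missing per-layer component {c.name!r}")
            continue
        if len(choices) != space.num_layers:
            violations.append(
                f"{c.name!r}: expected {space.num_layers} layer choices, "
                f"got {len(choices)}"
            )
        for layer, opt in enumerate(choices, start=1):
            if opt not in c.options:
                violations.append(
                    f"{c.name!r} layer {layer}: unknown option {opt!r}"
                )
    for c in space.global_components:
        opt = descriptor.global_choices.get(c.name)
        if opt is None:
            violations.append(f"missing global component {c.name!r}")
        elif opt not in c.options:
            violations.append(f"{c.name!r}: unknown option {opt!r}")
    extra = set(descriptor.per_layer_choices) - {
        c.name for c in space.per_layer_components
    }
    extra |= set(descriptor.global_choices) - {c.name for c in space.global_components}
    for name in sorted(extra):
        violations.append(f"unknown component {name!r}")
    return violations


def enumerate_space(space: SearchSpace) -> Iterator[ArchitectureDescriptor]:
    """Yield every architecture in the space (use only on small spaces)."""
    pl_comps = space.per_layer_components
    g_comps = space.global_components
    pl_axes = [
        list(itertools.product(c.options, repeat=space.num_layers)) for c in pl_comps
    ]
    g_axes = [c.options for c in g_comps]
    for pl_combo in itertools.product(*pl_axes):
        per_layer = {c.name: v for c, v in zip(pl_comps, pl_combo)}
        for g_combo in itertools.product(*g_axes):
            global_ = {c.name: v for c, v in zip(g_comps, g_combo)}
            yield ArchitectureDescriptor(per_layer, global_)
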