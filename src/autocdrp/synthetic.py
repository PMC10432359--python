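"""Synthetic fitness landscapes and drug-response datasets.

Everything needed to exercise the search framework at desk scale with no
downloads: a deterministic architecture -> pseudo-RMSE oracle standing in
for full candidate training, and small response datasets with planted
drug-graph and cell-vector signal.

The oracle emulates the statistical shape of measured validation RMSEs:
values near a base level (default 0.08, matching the scale of normalized-
target RMSEs in drug-response work) perturbed by additive per-option
effects, a sparse set of pairwise option interactions (so the landscape is
not purely additive and a linear probe cannot trivially solve it), and
optional seeded noise. It is a pure function of (descriptor, oracle state).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
import numpy as np

from .codec import EvaluatedArchitecture
from .model import (
    ATOM_SYMBOLS,
    CELL_FEATURE_DIM,
    DRUG_FEATURE_DIM,
    CellLineProfile,
    DrugGraph,
    ResponseDataset,
    ResponseRecord,
)
from .space import ArchitectureDescriptor, SearchSpace, count_options, stratified_sample

__all__ = [
    "FitnessOracle", "SyntheticDatasetSpec", "oracle_fitness",
    "make_dataset", "make_arch_perf_pairs",
]


@dataclass
class FitnessOracle:
    """Deterministic pseudo-RMSE landscape over a search space."""

    space: SearchSpace
    option_weights: np.ndarray  # (q,) additive effect per option
    interactions: dict  # {(i, j): weight} over option-vocabulary indices
    base: float = 0.08
    noise_sd: float = 0.0
    seed: int = 0
    _vocab_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        vocab = self.space.option_vocabulary()
        if len(self.option_weights) != len(vocab):
            raise ValueError("option_weights length must equal q")
        self._vocab_index = {co: i for i, co in enumerate(vocab)}

    @classmethod
    def create(
        cls,
        space: SearchSpace,
        seed: int = 0,
        noise_sd: float = 0.0,
        weight_sd: float = 0.005,
        interaction_sd: float = 0.01,
        n_interactions: int = 10,
        base: float = 0.08,
    ) -> "FitnessOracle":
        """Draw a random landscape: per-option weights ~ N(0, weight_sd) and
        ``n_interactions`` cross-component option pairs with weights
        ~ N(0, interaction_sd)."""
        rng = np.random.default_rng(seed)
        q = count_options(space)
        weights = rng.normal(0.0, weight_sd, size=q)
        vocab = space.option_vocabulary()
        interactions: dict = {}
        tries = 0
        while len(interactions) < n_interactions and tries < 1000:
            tries += 1
            i, j = sorted(rng.choice(q, size=2, replace=False).tolist())
            if vocab[i][0] == vocab[j][0]:  # same component: never co-active
                continue
            interactions[(i, j)] = float(rng.normal(0.0, interaction_sd))
        return cls(space=space, option_weights=weights, interactions=interactions,
                   base=base, noise_sd=noise_sd, seed=seed)

    def active_indices(self, descriptor: ArchitectureDescriptor) -> list[int]:
        """Vocabulary indices of the descriptor's options, with per-layer
        multiplicity (an option picked in both layers counts twice)."""
        idx = []
        for c in self.space.per_layer_components:
            for opt in descriptor.per_layer_choices[c.name]:
                idx.append(self._vocab_index[(c.name, opt)])
        for c in self.space.global_components:
            idx.append(self._vocab_index[(c.name, descriptor.global_choices[c.name])])
        return idx


def oracle_fitness(descriptor: ArchitectureDescriptor, oracle: FitnessOracle) -> float:
    """Pseudo validation RMSE of a descriptor under the oracle landscape:
    base + sum of active option weights + active interaction weights
    + seeded per-descriptor noise, clamped at >= 0."""
    active = oracle.active_indices(descriptor)
    value = oracle.base + float(oracle.option_weights[active].sum())
    present = set(active)
    for (i, j), w in oracle.interactions.items():
        if i in present and j in present:
            value += w
    if oracle.noise_sd > 0:
        h = zlib.crc32(descriptor.canonical().encode()) ^ (oracle.seed & 0xFFFFFFFF)
        noise_rng = np.random.default_rng(h)
        value += float(noise_rng.normal(0.0, oracle.noise_sd))
    return max(value, 0.0)


# ---------------------------------------------------------------------------
# Synthetic response datasets


@dataclass
class SyntheticDatasetSpec:
    """Shape and signal parameters for a generated response dataset.

    Defaults emulate the processed-data shapes of public drug-sensitivity
    panels at reduced size: molecular-like drug graphs with 78-D structured
    atom features, 735-D binary cell profiles, and a dense-to-sparse
    observed fraction of the drug x cell response matrix.
    """

    n_drugs: int = 24
    n_cells: int = 100
    atoms_range: tuple[int, int] = (8, 30)
    cell_dim: int = CELL_FEATURE_DIM
    density: float = 1.0
    drug_effect: float = 2.0
    cell_effect: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.cell_dim < 1:
            raise ValueError("cell_dim must be >= 1")
        if round(self.density * self.n_drugs * self.n_cells) < 1:
            raise ValueError("density yields zero observed records")


def _random_molecular_graph(rng: np.random.Generator, n_atoms: int,
                            drug_id: str) -> DrugGraph:
    """Random connected molecular-like graph: a random tree plus a few extra
    edges, degree capped at 4, with valid 78-D one-hot-structured features."""
    edges: set[tuple[int, int]] = set()
    deg = np.zeros(n_atoms, dtype=int)
    for v in range(1, n_atoms):
        candidates = [u for u in range(v) if deg[u] < 4]
        u = int(rng.choice(candidates)) if candidates else int(rng.integers(v))
        edges.add((u, v))
        deg[u] += 1
        deg[v] += 1
    n_extra = int(rng.integers(0, max(1, n_atoms // 6) + 1))
    for _ in range(n_extra):
        u, v = sorted(rng.choice(n_atoms, size=2, replace=False).tolist())
        if (u, v) in edges or deg[u] >= 4 or deg[v] >= 4:
            continue
        edges.add((u, v))
        deg[u] += 1
        deg[v] += 1

    # common organic subset of the symbol vocabulary
    organic = [ATOM_SYMBOLS.index(s) for s in ("C", "C", "C", "N", "O", "S", "F", "Cl")]
    feats = np.zeros((n_atoms, DRUG_FEATURE_DIM))
    for a in range(n_atoms):
        feats[a, organic[int(rng.integers(len(organic)))]] = 1.0
        feats[a, 44 + min(int(deg[a]), 10)] = 1.0  # degree block
        feats[a, 55 + int(rng.integers(0, 4))] = 1.0  # total-H block
        feats[a, 66 + min(int(deg[a]) + 1, 10)] = 1.0  # valence block
        feats[a, 77] = float(rng.random() < 0.3)  # aromaticity flag
    sym_edges = [(u, v) for u, v in edges] + [(v, u) for u, v in edges]
    return DrugGraph(drug_id=drug_id, node_features=feats, edges=sym_edges)


def _planted_response(spec: SyntheticDatasetSpec, drug: DrugGraph,
                      cell: CellLineProfile, w_drug: np.ndarray,
                      w_cell: np.ndarray) -> float:
    s_drug = float(drug.node_features.mean(axis=0) @ w_drug)
    s_cell = float(cell.features[: len(w_cell)] @ w_cell)
    return spec.drug_effect * s_drug + spec.cell_effect * s_cell


def make_dataset(spec: SyntheticDatasetSpec) -> ResponseDataset:
    """Generate a ResponseDataset with planted linear signal.

    ln(IC50) of a pair is a linear function of the drug's mean atom-feature
    vector and a 20-column subset of the cell profile, plus N(0, noise_sd)
    noise. Exactly round(density * n_drugs * n_cells) pairs are observed.
    """
    rng = np.random.default_rng(spec.seed)
    drugs = [
        _random_molecular_graph(
            rng, int(rng.integers(spec.atoms_range[0], spec.atoms_range[1] + 1)),
            f"D{i:03d}",
        )
        for i in range(spec.n_drugs)
    ]
    cells = [
        CellLineProfile(f"C{i:04d}", (rng.random(spec.cell_dim) < 0.5).astype(float))
        for i in range(spec.n_cells)
    ]
    w_drug = rng.normal(0.0, 1.0, size=DRUG_FEATURE_DIM)
    w_cell = rng.normal(0.0, 0.3, size=min(20, spec.cell_dim))

    n_obs = int(round(spec.density * spec.n_drugs * spec.n_cells))
    all_pairs = [(d, c) for d in range(spec.n_drugs) for c in range(spec.n_cells)]
    chosen = rng.choice(len(all_pairs), size=n_obs, replace=False)
    records = []
    for k in sorted(chosen.tolist()):
        di, ci = all_pairs[k]
        value = _planted_response(spec, drugs[di], cells[ci], w_drug, w_cell)
        if spec.noise_sd > 0:
            value += float(rng.normal(0.0, spec.noise_sd))
        records.append(ResponseRecord(drugs[di].drug_id, cells[ci].cell_id, value))
    return ResponseDataset(drugs=drugs, cells=cells, records=records)


def planted_weights(spec: SyntheticDatasetSpec) -> tuple[np.ndarray, np.ndarray]:
    """The exact planted coefficient vectors for a spec (for zero-noise
    recomputation checks). Must mirror the draws in :func:`make_dataset`."""
    rng = np.random.default_rng(spec.seed)
    for i in range(spec.n_drugs):
        n_atoms = int(rng.integers(spec.atoms_range[0], spec.atoms_range[1] + 1))
        _random_molecular_graph(rng, n_atoms, f"D{i:03d}")
    for i in range(spec.n_cells):
        (rng.random(spec.cell_dim) < 0.5).astype(float)
    w_drug = rng.normal(0.0, 1.0, size=DRUG_FEATURE_DIM)
    w_cell = rng.normal(0.0, 0.3, size=min(20, spec.cell_dim))
    return w_drug, w_cell


# ---------------------------------------------------------------------------
# Architecture-performance pairs


def make_arch_perf_pairs(
    space: SearchSpace,
    n: int,
    oracle: FitnessOracle,
    seed: int = 0,
) -> list[EvaluatedArchitecture]:
    """Stratified-sample n architectures and label each with its oracle
    pseudo-RMSE — a synthetic surrogate training set."""
    descriptors = stratified_sample(space, n, seed=seed)
    return [
        EvaluatedArchitecture(
            descriptor=d,
            performance=oracle_fitness(d, oracle),
            metadata={"seed": seed, "source": "oracle"},
        )
        for d in descriptors
    ]
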