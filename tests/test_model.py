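"""Candidate CDRP models: normalization, splits, builder, training."""

import numpy as np
import pytest

from autocdrp.model import (
    CellLineProfile,
    DrugGraph,
    ResponseDataset,
    ResponseNormalizer,
    ResponseRecord,
    SplitSpec,
    build_model,
    normalize_responses,
    pair_accounting,
    split,
    train_eval,
    DRUG_FEATURE_DIM,
)
from autocdrp.model import _batch_drugs
from autocdrp.space import ArchitectureDescriptor, random_descriptor
from autocdrp.synthetic import SyntheticDatasetSpec, make_dataset


class TestNormalize:
    def test_midpoint(self):
        recs = [ResponseRecord("d", "c1", 0.0), ResponseRecord("d", "c2", 10.0),
                ResponseRecord("d", "c3", 5.0)]
        out, _ = normalize_responses(recs)
        assert out[2].y == pytest.approx(0.5)

    def test_boundary_clip(self):
        recs = [ResponseRecord("d", "c1", 0.0), ResponseRecord("d", "c2", 10.0)]
        out, norm = normalize_responses(recs)
        assert out[0].y == pytest.approx(norm.eps)
        assert out[1].y == pytest.approx(1 - norm.eps)

    def test_inverse_roundtrip_interior(self):
        norm = ResponseNormalizer.fit([-3.0, 7.0])
        for x in np.linspace(-2.9, 6.9, 7):
            assert norm.inverse(norm.transform(x)) == pytest.approx(x, abs=1e-9)

    def test_monotone_interior(self):
        norm = ResponseNormalizer.fit([0.0, 1.0])
        xs = np.linspace(0.01, 0.99, 50)
        ys = [norm.transform(x) for x in xs]
        assert all(a < b for a, b in zip(ys, ys[1:]))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            ResponseNormalizer.fit([2.0, 2.0, 2.0])


class TestSplit:
    def test_mixed_exact_fractions(self, tiny_dataset):
        tr, va, te = split(tiny_dataset, SplitSpec(mode="mixed", seed=0))
        assert (len(tr), len(va), len(te)) == (240, 30, 30)
        ids = {(r.drug_id, r.cell_id) for r in tr + va + te}
        assert len(ids) == 300

    def test_blind_drug_disjoint_many_seeds(self, tiny_dataset):
        for seed in range(50):
            tr, va, te = split(tiny_dataset, SplitSpec(mode="blind_drug", seed=seed))
            sets = [{r.drug_id for r in part} for part in (tr, va, te)]
            assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) \
                and not (sets[1] & sets[2])

    def test_blind_cell_disjoint(self, tiny_dataset):
        for seed in range(10):
            tr, va, te = split(tiny_dataset, SplitSpec(mode="blind_cell", seed=seed))
            sets = [{r.cell_id for r in part} for part in (tr, va, te)]
            assert not (sets[0] & sets[1]) and not (sets[1] & sets[2]) \
                and not (sets[0] & sets[2])

    def test_determinism(self, tiny_dataset):
        s = SplitSpec(mode="mixed", seed=3)
        a = split(tiny_dataset, s)
        b = split(tiny_dataset, s)
        assert all(
            [(r.drug_id, r.cell_id) for r in pa] == [(r.drug_id, r.cell_id) for r in pb]
            for pa, pb in zip(a, b)
        )

    def test_blind_needs_three_entities(self):
        ds = make_dataset(SyntheticDatasetSpec(n_drugs=2, n_cells=5, seed=0))
        with pytest.raises(ValueError):
            split(ds, SplitSpec(mode="blind_drug"))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.5, 0.5))


class TestPairAccounting:
    @pytest.mark.parametrize(
        "nd,nc,obs,total,miss",
        [
            (223, 948, 172114, 211404, 18.6),
            (24, 436, 10464, 10464, 0.0),
            (1, 1, 1, 1, 0.0),
        ],
    )
    def test_worked_examples(self, nd, nc, obs, total, miss):
        out = pair_accounting(nd, nc, obs)
        assert out["total_pairs"] == total
        assert out["missing_pct"] == miss

    def test_overcount_rejected(self):
        with pytest.raises(ValueError):
            pair_accounting(2, 2, 5)


class TestDataTypes:
    def test_drug_graph_dimension_enforced(self):
        with pytest.raises(ValueError):
            DrugGraph("d", np.zeros((3, 10)), [])

    def test_asymmetric_edges_rejected(self):
        with pytest.raises(ValueError):
            DrugGraph("d", np.zeros((3, DRUG_FEATURE_DIM)), [(0, 1)])

    def test_self_bond_rejected(self):
        with pytest.raises(ValueError):
            DrugGraph("d", np.zeros((3, DRUG_FEATURE_DIM)), [(1, 1)])

    def test_nonbinary_cell_rejected(self):
        with pytest.raises(ValueError):
            CellLineProfile("c", np.array([0.0, 0.5]))

    def test_duplicate_pair_rejected(self, tiny_dataset):
        recs = tiny_dataset.records[:1] * 2
        with pytest.raises(ValueError):
            ResponseDataset(tiny_dataset.drugs, tiny_dataset.cells, recs)


def _descriptor(space, **overrides):
    d = random_descriptor(space, 0)
    pl = dict(d.per_layer_choices)
    g = dict(d.global_choices)
    for k, v in overrides.items():
        if k in pl:
            pl[k] = v
        else:
            g[k] = v
    return ArchitectureDescriptor(pl, g)


class TestBuildModel:
    def test_output_in_unit_interval(self, space, tiny_dataset):
        rng = np.random.default_rng(2)
        batch = _batch_drugs(tiny_dataset.drugs)
        cells = np.vstack([c.features for c in tiny_dataset.cells])
        for _ in range(5):
            d = random_descriptor(space, rng=rng)
            m = build_model(d, seed=0)
            preds = m.forward(batch, cells, np.array([0, 1]), np.array([0, 1])).data
            assert ((preds > 0) & (preds < 1)).all()

    def test_same_seed_same_init(self, space):
        d = random_descriptor(space, 4)
        m1, m2 = build_model(d, seed=9), build_model(d, seed=9)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(p1.data, p2.data)

    def test_linear_convolution_ignores_edges(self, space, tiny_dataset):
        d = _descriptor(space, convolution=("Linear", "Linear"),
                        dropout=("False", "False"), normalizer=("none", "none"))
        m = build_model(d, seed=1)
        cells = np.vstack([c.features for c in tiny_dataset.cells])
        batch = _batch_drugs(tiny_dataset.drugs)
        # strip all edges: per-node transform must be unchanged
        drugs_no_edges = [DrugGraph(dr.drug_id, dr.node_features, [])
                          for dr in tiny_dataset.drugs]
        batch2 = _batch_drugs(drugs_no_edges)
        idx = np.arange(5)
        p1 = m.forward(batch, cells, idx, idx).data
        p2 = m.forward(batch2, cells, idx, idx).data
        assert np.allclose(p1, p2)

    def test_atom_permutation_invariance_edge_aware(self, space, tiny_dataset):
        cells = np.vstack([c.features for c in tiny_dataset.cells])
        rng = np.random.default_rng(6)
        for conv in ("GCNConv", "GINConv", "SGConv", "GENConv"):
            d = _descriptor(space, convolution=(conv, conv),
                            dropout=("False", "False"))
            m = build_model(d, seed=3)
            drug = tiny_dataset.drugs[0]
            idx0 = np.array([0])
            base = m.forward(_batch_drugs([drug]), cells, idx0, idx0).data
            for _ in range(5):
                perm = rng.permutation(drug.num_atoms)
                inv = np.argsort(perm)
                permuted = DrugGraph(
                    drug.drug_id,
                    drug.node_features[inv],
                    [(int(perm[i]), int(perm[j])) for i, j in drug.edges],
                )
                out = m.forward(_batch_drugs([permuted]), cells, idx0, idx0).data
                assert np.allclose(out, base, atol=1e-10), conv

    def test_unknown_option_rejected(self, space):
        d = _descriptor(space, convolution=("GATConv", "GCNConv"))
        with pytest.raises((KeyError, ValueError)):
            build_model(d, seed=0)

    def test_multihead_one_is_single_branch(self, space):
        d = _descriptor(space, **{"multi-head": ("1", "1")})
        m = build_model(d, seed=0)
        assert all(len(layer.heads) == 1 for layer in m.layers)


class TestTrainEval:
    def test_beats_mean_baseline_on_planted_signal(self, space, tiny_dataset):
        splits = split(tiny_dataset, SplitSpec(mode="mixed", seed=4))
        d = _descriptor(
            space,
            convolution=("GCNConv", "GCNConv"), dropout=("False", "False"),
            normalizer=("none", "none"), activation=("relu", "relu"),
            hidden=("64", "64"), **{
                "multi-head": ("1", "1"), "learning-rate": "1e-3",
                "weight-regulation": "1e-4", "optimizer": "Adam",
            },
        )
        m = build_model(d, seed=1)
        metrics = train_eval(m, tiny_dataset, splits, epochs=30, seed=1)
        norm = ResponseNormalizer.fit([r.ln_ic50 for r in splits[0]])
        ytr = np.array([norm.transform(r.ln_ic50) for r in splits[0]])
        yva = np.array([norm.transform(r.ln_ic50) for r in splits[1]])
        baseline = float(np.sqrt(np.mean((yva - ytr.mean()) ** 2)))
        assert metrics["val_rmse"] < baseline
        assert metrics["val_pcc"] > 0

    def test_epochs_zero_evaluates_untrained(self, space, tiny_dataset):
        splits = split(tiny_dataset, SplitSpec(mode="mixed", seed=4))
        m = build_model(random_descriptor(space, 5), seed=0)
        metrics = train_eval(m, tiny_dataset, splits, epochs=0, seed=0)
        assert np.isfinite(metrics["val_rmse"])

    def test_reproducible_metrics(self, space, tiny_dataset):
        splits = split(tiny_dataset, SplitSpec(mode="mixed", seed=4))
        d = random_descriptor(space, 8)
        m1 = build_model(d, seed=2)
        m2 = build_model(d, seed=2)
        r1 = train_eval(m1, tiny_dataset, splits, epochs=3, seed=2)
        r2 = train_eval(m2, tiny_dataset, splits, epochs=3, seed=2)
        assert r1["val_rmse"] == pytest.approx(r2["val_rmse"], abs=1e-6)

    def test_random_sweep_val_rmse_finite(self, space, tiny_dataset):
        splits = split(tiny_dataset, SplitSpec(mode="mixed", seed=4))
        rng = np.random.default_rng(10)
        for _ in range(20):
            d = random_descriptor(space, rng=rng)
            m = build_model(d, seed=0)
            metrics = train_eval(m, tiny_dataset, splits, epochs=1, seed=0)
            assert np.isfinite(metrics["val_rmse"]) and metrics["val_rmse"] >= 0
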