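"""Splitting hygiene, loss arithmetic, training loop, and metrics."""

import numpy as np
import pytest

from redoxsolv.chemgraph import featurize
from redoxsolv.mpnn import ModelConfig, RedoxMPNN
from redoxsolv.nn import Tensor
from redoxsolv.solventdb import SolventSpec
from redoxsolv.synthetic import SYNTHETIC_SOLVENTS, SyntheticTruth, gen_dataset
from redoxsolv.training import (
    Metrics,
    TrainConfig,
    build_sd_records,
    combined_loss,
    evaluate,
    loso_protocol,
    split_molecules,
    train,
)


class TestSplitMolecules:
    def test_exact_80_10_10_on_100_ids(self):
        ids = [f"m{i}" for i in range(100)]
        split = split_molecules(ids, (0.8, 0.1, 0.1), seed=7)
        counts = {p: sum(1 for v in split.values() if v == p)
                  for p in ("train", "val", "test")}
        assert counts == {"train": 80, "val": 10, "test": 10}

    def test_deterministic_and_disjoint(self):
        ids = [f"m{i}" for i in range(57)]
        a = split_molecules(ids, seed=3)
        b = split_molecules(ids, seed=3)
        assert a == b
        assert set(a) == set(ids)  # exhaustive, single assignment per id

    def test_sizes_within_one_of_exact_fractions(self):
        for n in (10, 23, 101, 250):
            ids = [str(i) for i in range(n)]
            split = split_molecules(ids, (0.8, 0.1, 0.1), seed=0)
            for part, frac in zip(("train", "val", "test"), (0.8, 0.1, 0.1)):
                count = sum(1 for v in split.values() if v == part)
                assert abs(count - n * frac) <= 1

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            split_molecules(["a", "b", "c"])


class TestCombinedLoss:
    def test_perfect_predictions_give_zero(self):
        preds = {"y": Tensor(np.array([[1.0], [2.0]]))}
        loss = combined_loss(preds, {"y": np.array([[1.0], [2.0]])})
        assert float(loss.data) == 0.0

    def test_hand_mae_single_dimension(self):
        preds = {"y": Tensor(np.array([[0.0], [1.0]]))}
        loss = combined_loss(preds, {"y": np.array([[1.0], [1.0]])})
        assert float(loss.data) == pytest.approx(0.5)

    def test_dimensions_sum(self):
        preds = {"y": Tensor(np.array([[0.0, 0.0], [1.0, 1.0]]))}
        t = np.array([[1.0, 1.0], [1.0, 1.0]])  # MAE 0.5 per column
        assert float(combined_loss(preds, {"y": t}).data) == pytest.approx(1.0)

    def test_fully_masked_records_do_not_change_loss(self):
        preds = {"y": Tensor(np.array([[0.0], [1.0], [99.0]]))}
        t = np.array([[1.0], [1.0], [123.0]])
        mask = np.array([[1.0], [1.0], [0.0]])
        loss = combined_loss(preds, {"y": t}, {"y": mask})
        assert float(loss.data) == pytest.approx(0.5)

    def test_no_unmasked_targets_is_error(self):
        preds = {"y": Tensor(np.zeros((2, 1)))}
        with pytest.raises(ValueError, match="unmasked"):
            combined_loss(preds, {"y": np.ones((2, 1))}, {"y": np.zeros((2, 1))})


def _tiny_dataset(n=14, seed=5, solvents=None):
    solvents = solvents or {k: v for k, v in SYNTHETIC_SOLVENTS.items() if k != "SYN6"}
    truth = SyntheticTruth(noise_sd=0.02, seed=seed)
    ds, _ = gen_dataset(n, solvents=solvents, truth=truth, max_heavy=6)
    return ds


def _tiny_model(seed=0, variant="SD"):
    return RedoxMPNN(ModelConfig(variant=variant, node_dim=8, edge_dim=8,
                                 graph_dim=16, n_attention_heads=2,
                                 head_hidden=8, solvent_dim=4, seed=seed))


class TestTrain:
    def test_zero_epochs_returns_initial_params_empty_history(self):
        ds = _tiny_dataset()
        model = _tiny_model()
        split = split_molecules([m.id for m in ds.molecules], seed=0)
        before = [p.data.copy() for p in model.parameters()]
        model, history = train(model, ds, split, TrainConfig(epochs=0, seed=0))
        assert history == []
        for p, b in zip(model.parameters(), before):
            assert np.array_equal(p.data, b)

    def test_same_seed_identical_loss_history(self):
        ds = _tiny_dataset()
        split = split_molecules([m.id for m in ds.molecules], seed=0)
        cfg = TrainConfig(epochs=2, batch_size=8, learning_rate=1e-3, seed=9)
        _, h1 = train(_tiny_model(seed=4), ds, split, cfg)
        _, h2 = train(_tiny_model(seed=4), ds, split, cfg)
        assert h1 == h2

    def test_one_step_reduces_loss_on_single_example(self):
        """Gradient-flow smoke test: a step of AdamW on one example helps."""
        ds = _tiny_dataset(n=12)
        mol = ds.molecules[0]
        recs = build_sd_records([mol], ds.solvents, "minmax")
        model = _tiny_model(seed=1)
        from redoxsolv.training import _sd_batch_loss
        from redoxsolv.nn import AdamW
        idx = [0]
        before = float(_sd_batch_loss(model, recs, idx).data)
        opt = AdamW(model.parameters(), lr=1e-2, weight_decay=0.0)
        for _ in range(3):
            loss = _sd_batch_loss(model, recs, idx)
            opt.zero_grad()
            loss.backward()
            opt.step()
        after = float(_sd_batch_loss(model, recs, idx).data)
        assert after <= before

    def test_vs_variant_trains(self):
        ds = _tiny_dataset()
        split = split_molecules([m.id for m in ds.molecules], seed=0)
        model, history = train(_tiny_model(variant="VS"), ds, split,
                               TrainConfig(epochs=2, batch_size=8, seed=0))
        assert len(history) == 2
        assert model.forward_vs("CC").reduction_potential.shape == (5,)


class TestEvaluate:
    def _dataset_with(self, preds_to_targets):
        # molecules with fixed targets; evaluation is against these
        from redoxsolv.training import MoleculeData, RedoxDataset
        solvents = {"ACN": SYNTHETIC_SOLVENTS["ACN"]}
        mols = [MoleculeData(id=f"m{i}", graph=featurize("C" * (i + 1)), ea=None,
                             potentials={"ACN": t})
                for i, t in enumerate(preds_to_targets)]
        return RedoxDataset(molecules=mols, solvents=solvents)

    def test_perfect_predictor_metrics(self, monkeypatch):
        ds = self._dataset_with([1.0, 2.0, 3.0])
        model = _tiny_model()
        targets = iter([])

        def fake_forward(graphs, desc, feature_noise=None):
            vals = np.array([[ds.molecules[i].potentials["ACN"]]
                             for i in range(len(graphs))])
            return {"e_red": Tensor(vals), "ea": Tensor(vals),
                    "solvent": Tensor(np.zeros_like(vals))}

        monkeypatch.setattr(model, "forward_batch", fake_forward)
        m = evaluate(model, ds)
        assert m.mae == 0.0 and m.r2 == pytest.approx(1.0)

    def test_mean_value_predictor_has_zero_r2(self, monkeypatch):
        ds = self._dataset_with([1.0, 2.0, 3.0])
        model = _tiny_model()

        def fake_forward(graphs, desc, feature_noise=None):
            vals = np.full((len(graphs), 1), 2.0)
            return {"e_red": Tensor(vals), "ea": Tensor(vals),
                    "solvent": Tensor(np.zeros_like(vals))}

        monkeypatch.setattr(model, "forward_batch", fake_forward)
        m = evaluate(model, ds)
        assert m.r2 == pytest.approx(0.0)

    def test_hand_mae(self, monkeypatch):
        ds = self._dataset_with([2.0, 2.0])
        model = _tiny_model()

        def fake_forward(graphs, desc, feature_noise=None):
            vals = np.array([[1.0], [2.0]])[: len(graphs)]
            return {"e_red": Tensor(vals), "ea": Tensor(vals),
                    "solvent": Tensor(np.zeros_like(vals))}

        monkeypatch.setattr(model, "forward_batch", fake_forward)
        m = evaluate(model, ds)
        assert m.mae == pytest.approx(0.5)

    def test_constant_targets_report_undefined_r2(self, monkeypatch):
        ds = self._dataset_with([2.0, 2.0])
        model = _tiny_model()

        def fake_forward(graphs, desc, feature_noise=None):
            vals = np.zeros((len(graphs), 1))
            return {"e_red": Tensor(vals), "ea": Tensor(vals),
                    "solvent": Tensor(vals)}

        monkeypatch.setattr(model, "forward_batch", fake_forward)
        m = evaluate(model, ds)
        assert m.r2 is None
        assert m.per_solvent["ACN"]["r2"] is None


class TestLoso:
    def test_withheld_solvent_absent_from_training_records(self):
        ds = _tiny_dataset(solvents=dict(SYNTHETIC_SOLVENTS))
        recs = build_sd_records(ds.molecules, ds.solvents, "minmax",
                                exclude_solvent="THF")
        assert all(r[4] != "THF" for r in recs)
        # and nothing else was dropped
        assert len(recs) == len(ds.molecules) * (len(ds.solvents) - 1)

    def test_absent_solvent_is_error(self):
        ds = _tiny_dataset()
        with pytest.raises(KeyError, match="XYZ"):
            loso_protocol(ds, "XYZ", TrainConfig(epochs=1))

    def test_each_withheld_solvent_yields_metrics(self):
        # structural check on tiny data: one Metrics record per withheld solvent
        ds = _tiny_dataset(n=12)
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0)
        mc = ModelConfig(variant="SD", node_dim=8, edge_dim=8, graph_dim=16,
                         n_attention_heads=2, head_hidden=8, solvent_dim=4, seed=0)
        out = {s: loso_protocol(ds, s, cfg, mc) for s in list(ds.solvents)[:2]}
        assert all(isinstance(m, Metrics) and m.n > 0 for m in out.values())
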