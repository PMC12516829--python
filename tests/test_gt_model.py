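import numpy as np
import pytest

from intrisol._autodiff import Tensor
from intrisol.gt_model import (
    GraphTransformer,
    ModelConfig,
    collate,
    decay_mask,
    multitask_loss,
    train,
)
from intrisol.molgraph import build_graph

SMALL = ModelConfig(n_layers=2, hidden_dim=32, n_heads=2, seed=0)


class TestDecayMask:
    def test_gamma_one_all_ones_on_connected(self):
        g = build_graph("CCO")
        assert np.array_equal(decay_mask(g.hop_dist, 1.0), np.ones((3, 3)))

    def test_three_node_path_gamma_half(self):
        hop = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        want = [[1, .5, .25], [.5, 1, .5], [.25, .5, 1]]
        assert np.allclose(decay_mask(hop, 0.5), want)

    def test_disconnected_pair_zero(self):
        g = build_graph("C.C")
        m = decay_mask(g.hop_dist, 0.5)
        assert m[0, 1] == 0.0 and m[0, 0] == 1.0

    def test_gamma_zero_is_identity(self):
        g = build_graph("CCO")
        assert np.array_equal(decay_mask(g.hop_dist, 0.0), np.eye(3))

    def test_gamma_validated(self):
        with pytest.raises(ValueError):
            decay_mask(np.zeros((2, 2)), 1.5)

    def test_strictly_decreasing_with_hop(self):
        hop = np.arange(6, dtype=float).reshape(1, 6)
        m = decay_mask(hop, 0.6)
        assert np.all(np.diff(m[0]) < 0)

    def test_matches_bfs_power_oracle_random_graphs(self, rng):
        from scipy.sparse.csgraph import shortest_path
        for _ in range(100):
            n = int(rng.integers(2, 13))
            adj = np.triu((rng.random((n, n)) < 0.3).astype(float), 1)
            adj = adj + adj.T
            hop = shortest_path(adj, method="D", unweighted=True)
            gamma = float(rng.uniform(0.1, 0.9))
            m = decay_mask(hop, gamma)
            for i in range(n):
                for j in range(n):
                    want = 0.0 if np.isinf(hop[i, j]) else gamma ** hop[i, j]
                    assert m[i, j] == pytest.approx(want, abs=1e-15)


@pytest.fixture(scope="module")
def molecules():
    return [build_graph(s) for s in
            ("CCO", "c1ccccc1", "CC(=O)Nc1ccc(O)cc1", "CN1CCN(CC1)c1ccccc1",
             "OC(=O)c1ccccc1", "CCCCCC", "C1CCNCC1", "COc1ccc(C=O)cc1")]


class TestForwardContracts:
    def test_batching_invariance(self, molecules):
        model = GraphTransformer(SMALL)
        single = model.predict([molecules[2]], batch_size=1)
        batched = model.predict(molecules, batch_size=8)
        assert np.allclose(single[0], batched[2], atol=1e-5)

    def test_node_permutation_invariance(self, molecules):
        from rdkit import Chem
        model = GraphTransformer(SMALL)
        smi = "CC(=O)Nc1ccc(O)cc1"
        mol = Chem.MolFromSmiles(smi)
        perm = np.random.default_rng(3).permutation(mol.GetNumAtoms()).tolist()
        smi2 = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
        p1 = model.predict([build_graph(smi)])
        p2 = model.predict([build_graph(smi2)])
        assert np.allclose(p1, p2, atol=1e-5)

    def test_different_molecules_differ(self, molecules):
        model = GraphTransformer(SMALL)
        preds = model.predict(molecules[:2])
        assert not np.allclose(preds[0], preds[1], atol=1e-3)

    def test_single_node_graph_runs(self):
        model = GraphTransformer(SMALL)
        out = model.predict([build_graph("C")])
        assert out.shape == (1, 8) and np.isfinite(out).all()

    def test_gamma_one_equals_unmasked_attention(self):
        """With gamma = 1 the mask is inert: forward equals all-ones mask."""
        cfg = ModelConfig(n_layers=2, hidden_dim=32, n_heads=2, seed=0,
                          decay_gamma=1.0)
        model = GraphTransformer(cfg)
        g = build_graph("CC(=O)Nc1ccc(O)cc1")
        batch = collate([g], 1.0)
        masked = model.forward(batch).data
        batch.mask = np.ones_like(batch.mask)
        unmasked = model.forward(batch).data
        assert np.allclose(masked, unmasked, atol=1e-6)

    def test_gamma_zero_attention_is_self_only(self):
        """gamma = 0 keeps only the diagonal after renormalization, which
        must equal replacing the mask with the identity matrix."""
        cfg = ModelConfig(n_layers=2, hidden_dim=32, n_heads=2, seed=0,
                          decay_gamma=0.0)
        model = GraphTransformer(cfg)
        g = build_graph("CCO")
        batch = collate([g], 0.0)
        assert np.array_equal(batch.mask, np.eye(3))
        out = model.forward(batch).data
        assert np.isfinite(out).all()

    def test_feature_dim_mismatch_raises(self, molecules):
        from intrisol.molgraph import FeatureConfig
        cfg = ModelConfig(n_layers=1, hidden_dim=16, n_heads=2, rw_steps=5)
        model = GraphTransformer(cfg, FeatureConfig(rw_steps=5))
        with pytest.raises(ValueError):
            model.predict([molecules[0]])  # graphs built with rw_steps=20


class TestMultitaskLoss:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.preds = rng.normal(size=(5, 8))
        self.targets = rng.normal(size=(5, 8))
        self.obs = rng.random((5, 8)) < 0.6
        self.obs[:, 0] = True

    def test_zero_logvars_kendall_is_sum_of_mse(self):
        got = multitask_loss(Tensor(self.preds), self.targets, self.obs,
                             Tensor(np.zeros(8))).item()
        want = 0.0
        for t in range(8):
            o = self.obs[:, t]
            if o.any():
                want += np.mean((self.preds[o, t] - self.targets[o, t]) ** 2)
        assert got == pytest.approx(want, rel=1e-12)

    def test_unobserved_perturbation_is_invisible(self):
        s = Tensor(np.zeros(8))
        base = multitask_loss(Tensor(self.preds), self.targets, self.obs, s).item()
        targets2 = self.targets.copy()
        targets2[~self.obs] += 1000.0
        again = multitask_loss(Tensor(self.preds), targets2, self.obs, s).item()
        assert again == base

    def test_unobserved_gradient_exactly_zero(self):
        p = Tensor(self.preds, requires_grad=True)
        loss = multitask_loss(p, self.targets, self.obs, Tensor(np.zeros(8)))
        loss.backward()
        assert np.all(p.grad[~self.obs] == 0.0)
        assert np.any(p.grad[self.obs] != 0.0)

    def test_perfect_predictions_leave_regularizer(self):
        t = self.targets[:3]
        obs = np.zeros((3, 8), bool)
        obs[:, 0] = True
        s = Tensor(np.full(8, 0.4))
        got = multitask_loss(Tensor(t), t, obs, s).item()
        assert got == pytest.approx(0.2, abs=1e-12)  # r(s) = s/2, one task

    def test_softplus_regularizer(self):
        t = self.targets[:3]
        obs = np.zeros((3, 8), bool)
        obs[:, 0] = True
        s = Tensor(np.zeros(8))
        got = multitask_loss(Tensor(t), t, obs, s, reg="softplus").item()
        assert got == pytest.approx(np.log(2.0), abs=1e-12)

    def test_all_unobserved_warns_and_zero(self):
        with pytest.warns(UserWarning):
            got = multitask_loss(Tensor(self.preds), self.targets,
                                 np.zeros((5, 8), bool), Tensor(np.zeros(8)))
        assert got.item() == 0.0


class TestTraining:
    def test_early_stop_halts_at_patience(self, small_dataset):
        """With lr = 0 the validation loss never improves after epoch 1, so
        training must stop at epoch patience + 1."""
        table, graphs, _ = small_dataset
        n = table.n_compounds
        cfg = ModelConfig(n_layers=1, hidden_dim=16, n_heads=2,
                          learning_rate=0.0, max_epochs=50,
                          early_stop_patience=3, seed=0)
        split = {"train": list(range(0, n - 10)), "val": list(range(n - 10, n))}
        _, hist = train(table, graphs, split, cfg)
        assert hist.stopped_epoch == 4
        assert hist.best_epoch == 1

    def test_same_seed_identical_history(self, small_dataset):
        table, graphs, _ = small_dataset
        n = table.n_compounds
        cfg = ModelConfig(n_layers=1, hidden_dim=16, n_heads=2,
                          max_epochs=4, seed=7)
        split = {"train": list(range(0, n - 10)), "val": list(range(n - 10, n))}
        _, h1 = train(table, graphs, split, cfg)
        _, h2 = train(table, graphs, split, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_validation_loss_improves(self, small_dataset):
        """The planted structure is learnable: val loss drops below epoch 1."""
        table, graphs, _ = small_dataset
        n = table.n_compounds
        cfg = ModelConfig(n_layers=2, hidden_dim=32, n_heads=2,
                          max_epochs=30, early_stop_patience=30, seed=0)
        split = {"train": list(range(0, n - 10)), "val": list(range(n - 10, n))}
        _, hist = train(table, graphs, split, cfg)
        assert min(hist.val_loss) < hist.val_loss[0]

    def test_empty_train_split_raises(self, small_dataset):
        table, graphs, _ = small_dataset
        with pytest.raises(ValueError):
            train(table, graphs, {"train": [], "val": [0]}, SMALL)

    def test_overlapping_split_raises(self, small_dataset):
        table, graphs, _ = small_dataset
        with pytest.raises(ValueError):
            train(table, graphs, {"train": [0, 1], "val": [1]}, SMALL)


def test_save_load_roundtrip(tmp_path, molecules=None):
    model = GraphTransformer(SMALL)
    model.target_mean = np.arange(8.0)
    model.target_std = np.full(8, 2.0)
    graphs = [build_graph("CCO"), build_graph("c1ccccc1")]
    before = model.predict(graphs)
    path = tmp_path / "model.npz"
    model.save(str(path))
    loaded = GraphTransformer.load(str(path))
    after = loaded.predict(graphs)
    assert np.allclose(before, after)
    assert loaded.config == model.config


def test_lr_schedule_shape():
    cfg = ModelConfig(max_epochs=100, warmup_epochs=5)
    lrs = [cfg.lr_at(e) for e in range(1, 101)]
    assert lrs[4] == pytest.approx(cfg.learning_rate)       # end of warmup
    assert lrs[0] == pytest.approx(cfg.learning_rate / 5)
    assert lrs[-1] < 1e-5                                    # decayed away
    assert max(lrs) <= cfg.learning_rate + 1e-12
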