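"""Normalization, masked loss, schedules, transfer modes, repeat selection."""

import numpy as np
import pytest

from gsnet._autodiff import Tensor
from gsnet.graphs import build_residue_graph
from gsnet.model import GNNModel, ModelConfig
from gsnet.synthetic import SynthSpec, generate_dataset, generate_structure
from gsnet.training import (
    Example,
    NormStats,
    TrainConfig,
    TrainResult,
    evaluate,
    fit_normalization,
    masked_mse,
    normalize_examples,
    select_best,
    top_k_summary,
    train,
)

TINY = dict(variant="GSnet", head_spec="global1", node_dim=12, n_layers=2, n_heads=2,
            edge_in_dim=300, head_hidden_dim=32)


def tiny_model(seed=0, head="global1", dtype="float32"):
    cfg = ModelConfig(**{**TINY, "head_spec": head, "dtype": dtype})
    return GNNModel(cfg, seed=seed)


def rg_examples(n, seed, n_res=(8, 14)):
    data = generate_dataset(n, seed=seed, n_residue_range=n_res, include_hydrogens=False)
    return [Example(graph=build_residue_graph(s), y=[t.Rg]) for s, t in data]


class TestNormalization:
    def test_train_stats_give_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        ex = [Example(graph=None, y=rng.normal(5, 3, 6), mask=rng.random(6) > 0.3) for _ in range(40)]
        stats = fit_normalization(ex)
        normed = normalize_examples(ex, stats)
        Y = np.stack([e.y for e in normed])
        M = np.stack([e.mask for e in normed])
        for j in range(6):
            col = Y[M[:, j], j]
            assert col.mean() == pytest.approx(0.0, abs=1e-12)
            assert col.std() == pytest.approx(1.0, abs=1e-12)

    def test_invert_apply_identity(self):
        stats = NormStats(mean=np.array([3.0, -1.0]), sd=np.array([2.0, 0.5]))
        x = np.array([10.0, 0.25])
        np.testing.assert_allclose(stats.invert(stats.apply(x)), x, atol=1e-12)

    def test_validation_uses_training_stats(self):
        rng = np.random.default_rng(1)
        train_ex = [Example(graph=None, y=rng.normal(0, 1, 2)) for _ in range(20)]
        val_ex = [Example(graph=None, y=rng.normal(4, 1, 2)) for _ in range(20)]
        stats = fit_normalization(train_ex)
        val_normed = np.stack([e.y for e in normalize_examples(val_ex, stats)])
        assert abs(val_normed.mean()) > 1.0  # shifted set stays shifted

    def test_zero_variance_rejected(self):
        ex = [Example(graph=None, y=[1.0, 2.0]) for _ in range(5)]
        with pytest.raises(ValueError, match="variance"):
            fit_normalization(ex)

    def test_too_few_masked_in_rejected(self):
        ex = [Example(graph=None, y=[1.0], mask=[False]) for _ in range(5)]
        with pytest.raises(ValueError):
            fit_normalization(ex)


class TestMaskedMSE:
    def test_perfect_prediction_zero(self):
        pred = Tensor(np.array([[1.0, 2.0]]))
        assert masked_mse(pred, np.array([[1.0, 2.0]]), np.ones((1, 2), bool)).data == 0.0

    def test_hand_arithmetic(self):
        pred = Tensor(np.array([[1.0, 2.0]]))
        loss = masked_mse(pred, np.array([[0.0, 2.0]]), np.ones((1, 2), bool))
        assert loss.data == pytest.approx(0.5)  # ((1)² + 0) / 2

    def test_denominator_counts_masked_in_only(self):
        pred = Tensor(np.array([[1.0, 2.0, 3.0]]))
        loss = masked_mse(pred, np.array([[0.0, 0.0, 3.0]]), np.array([[True, False, True]]))
        assert loss.data == pytest.approx(0.5)  # (1 + 0)/2, the masked middle ignored

    def test_fully_masked_batch_warns_zero(self, caplog):
        pred = Tensor(np.array([[1.0]]))
        with caplog.at_level("WARNING"):
            loss = masked_mse(pred, np.array([[9.0]]), np.array([[False]]))
        assert loss.data == 0.0
        assert "masked" in caplog.text

    def test_masked_entry_has_exactly_zero_gradient(self):
        w = Tensor(np.array([[2.0], [1.0]]), requires_grad=True)  # (2 targets) from 1 feature
        x = Tensor(np.array([[3.0]]))
        pred = (w @ x).reshape(1, 2)
        mask = np.array([[True, False]])
        loss = masked_mse(pred, np.array([[0.0, -100.0]]), mask)
        loss.backward()
        assert w.grad[1, 0] == 0.0  # exact zero, not small
        assert w.grad[0, 0] != 0.0


class TestTrainingLoop:
    def test_lr_switch_at_epoch_51_without_moment_reset(self):
        ex = rg_examples(4, seed=2)
        stats = fit_normalization(ex)
        ex = normalize_examples(ex, stats)
        cfg = TrainConfig(fixed_epochs=52, lr_switch_epoch=50, seed=0, batch_size=4)
        res = train(tiny_model(), ex, ex[:2], cfg)
        assert res.history.loc[res.history.epoch == 50, "lr"].item() == pytest.approx(1e-4)
        assert res.history.loc[res.history.epoch == 51, "lr"].item() == pytest.approx(1e-5)

    def test_tiny_overfit(self):
        ex = rg_examples(5, seed=3)
        stats = fit_normalization(ex)
        ex = normalize_examples(ex, stats)
        cfg = TrainConfig(fixed_epochs=150, lr_initial=3e-3, lr_switch_epoch=10**6, seed=1, batch_size=5)
        model = tiny_model(seed=1)
        first_loss = evaluate(model, ex)
        res = train(model, ex, [], cfg)
        assert res.history.train_loss.iloc[-1] < 0.01 * first_loss

    def test_reproducible_at_fixed_seed(self):
        ex = rg_examples(4, seed=4)
        stats = fit_normalization(ex)
        ex = normalize_examples(ex, stats)
        cfg = TrainConfig(fixed_epochs=5, seed=7, batch_size=2)
        h1 = train(tiny_model(seed=2), ex, ex[:2], cfg).history
        h2 = train(tiny_model(seed=2), ex, ex[:2], cfg).history
        np.testing.assert_array_equal(h1.train_loss.values, h2.train_loss.values)

    def test_early_stopping_on_patience(self):
        ex = rg_examples(4, seed=5)
        stats = fit_normalization(ex)
        ex = normalize_examples(ex, stats)
        # a fully-masked validation set pins the validation loss at 0, so no
        # epoch after the first can strictly improve it
        val = [Example(graph=e.graph, y=e.y, mask=np.zeros_like(e.mask)) for e in ex[:2]]
        cfg = TrainConfig(max_epochs=400, patience=3, seed=0, batch_size=4)
        res = train(tiny_model(), ex, val, cfg)
        assert len(res.history) == 1 + 3


class TestTransferModes:
    def test_frozen_keeps_gnn_bit_identical(self):
        ex = rg_examples(5, seed=6)
        stats = fit_normalization(ex)
        ex = normalize_examples(ex, stats)
        model = tiny_model(seed=3)
        gnn_before = {k: v.copy() for k, v in model.state_dict().items() if not k.startswith("head.")}
        head_before = {k: v.copy() for k, v in model.state_dict().items() if k.startswith("head.")}
        train(model, ex, [], TrainConfig(fixed_epochs=8, seed=0, batch_size=5), mode="transfer_frozen")
        after = model.state_dict()
        for k, v in gnn_before.items():
            np.testing.assert_array_equal(after[k], v)
        assert any(not np.array_equal(after[k], v) for k, v in head_before.items())

    def test_finetune_changes_gnn_parameters(self):
        ex = rg_examples(5, seed=6)
        stats = fit_normalization(ex)
        ex = normalize_examples(ex, stats)
        model = tiny_model(seed=3)
        gnn_before = {k: v.copy() for k, v in model.state_dict().items() if not k.startswith("head.")}
        train(model, ex, [], TrainConfig(fixed_epochs=8, seed=0, batch_size=5), mode="transfer_finetune")
        after = model.state_dict()
        assert any(not np.array_equal(after[k], v) for k, v in gnn_before.items())

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            train(tiny_model(), [], [], TrainConfig(), mode="bogus")


class TestSelection:
    def _results(self, losses):
        import pandas as pd

        return [TrainResult(model=None, history=pd.DataFrame(), best_val_loss=x, best_epoch=1) for x in losses]

    def test_argmin(self):
        assert select_best(self._results([0.5, 0.3, 0.9])) == 1

    def test_tie_breaks_to_lowest_index(self):
        assert select_best(self._results([0.3, 0.3])) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])

    def test_top_k_mean_sem(self):
        test_vals = [1.0, 2.0, 3.0, 4.0]
        val_rmse = [0.4, 0.1, 0.3, 0.2]  # top-2 by validation: indices 1, 3
        out = top_k_summary(test_vals, val_rmse, k=2)
        assert out["indices"] == [1, 3]
        assert out["mean"] == pytest.approx(3.0)
        assert out["sem"] == pytest.approx(np.std([2.0, 4.0], ddof=1) / np.sqrt(2))


def test_train_config_from_yaml(tmp_path):
    f = tmp_path / "cfg.yaml"
    f.write_text("lr_initial: 0.001\nbatch_size: 16\nfixed_epochs: 3\n")
    cfg = TrainConfig.from_yaml(f)
    assert cfg.lr_initial == 0.001 and cfg.batch_size == 16 and cfg.fixed_epochs == 3
    f.write_text("not_a_field: 1\n")
    with pytest.raises(ValueError, match="unknown config keys"):
        TrainConfig.from_yaml(f)


def test_pka_head_dropout_train_vs_eval(helix20):
    cfg = ModelConfig(variant="GSnet", head_spec="pka_gsnet", node_dim=12, n_layers=1,
                      n_heads=1, edge_in_dim=300, head_hidden_dim=32, dropout=0.2)
    model = GNNModel(cfg, seed=0)
    g = build_residue_graph(helix20)
    model.train(True)
    rng = np.random.default_rng(5)
    stoch = {model.forward(g, 3, rng).data.item() for _ in range(4)}
    assert len(stoch) > 1
    model.eval()
    det = {model.forward(g, 3).data.item() for _ in range(4)}
    assert len(det) == 1
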