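"""Network architecture: activations, encoders, attention layers, readouts, heads."""

import time

import numpy as np
import pytest

from conftest import random_rotation
from gsnet._autodiff import Tensor
from gsnet.graphs import build_atom_graph, build_residue_graph
from gsnet.model import GNNModel, ModelConfig, load_checkpoint, save_checkpoint
from gsnet.synthetic import SynthSpec, assign_charges, generate_structure


def _f64(cfg_kwargs):
    return ModelConfig(dtype="float64", **cfg_kwargs)


class TestSSP:
    def test_zero_at_origin(self):
        assert Tensor(np.array(0.0)).ssp().data == pytest.approx(0.0)

    def test_linear_asymptote(self):
        assert Tensor(np.array(50.0)).ssp().data == pytest.approx(50.0 - np.log(2), abs=1e-9)

    def test_strictly_increasing(self):
        x = np.linspace(-20, 20, 201)
        y = Tensor(x).ssp().data
        assert (np.diff(y) > 0).all()


class TestEncoders:
    def test_gsnet_width_150(self, helix20):
        model = GNNModel(ModelConfig.gsnet("global6"), seed=0)
        g = build_residue_graph(helix20)
        assert model.encode_nodes(g).shape == (20, 150)

    def test_alcnet_width_75(self, helix20):
        model = GNNModel(ModelConfig.alcnet(), seed=0)
        g = build_atom_graph(helix20, 4)
        assert model.encode_nodes(g).shape == (g.n_nodes, 75)

    def test_identical_inputs_identical_embeddings(self, helix20):
        # the encoder is a pure function of per-node inputs: copying one
        # node's raw features onto another yields identical embeddings
        model = GNNModel(ModelConfig.gsnet("global6"), seed=1)
        g = build_residue_graph(helix20)
        g.aa_index[5] = g.aa_index[3]
        g.dihedral_feats[5] = g.dihedral_feats[3]
        g.com_dist[5] = g.com_dist[3]
        H = model.encode_nodes(g).data
        np.testing.assert_array_equal(H[3], H[5])


class TestEdgeTransform:
    def test_zero_params_give_zero(self):
        cfg = _f64(dict(variant="GSnet", head_spec="global6", node_dim=8, n_layers=1, n_heads=2, edge_in_dim=10))
        model = GNNModel(cfg, seed=0)
        layer = model.layers[0]
        layer.edge_lin.weight.data[:] = 0.0
        layer.edge_lin.bias.data[:] = 0.0
        e = layer.edge_lin(Tensor(np.random.default_rng(0).standard_normal((4, 10)))).ssp()
        np.testing.assert_array_equal(e.data, 0.0)

    def test_per_head_width_totals_node_dim(self):
        cfg = ModelConfig.gsnet("global6")
        model = GNNModel(cfg, seed=0)
        layer = model.layers[0]
        assert layer.edge_lin.weight.shape == (300, 150)
        assert layer.d_head * layer.n_heads == cfg.node_dim

    def test_matches_dense_algebra_oracle(self, rng):
        cfg = _f64(dict(variant="GSnet", head_spec="global6", node_dim=6, n_layers=1, n_heads=1, edge_in_dim=12))
        model = GNNModel(cfg, seed=3)
        layer = model.layers[0]
        e_in = rng.standard_normal((5, 12))
        out = layer.edge_lin(Tensor(e_in)).ssp().data
        W, b = layer.edge_lin.weight.data, layer.edge_lin.bias.data
        expected = np.log1p(np.exp(e_in @ W + b)) - np.log(2)
        np.testing.assert_allclose(out, expected, rtol=1e-9)


def brute_force_layer(layer, H, edge_index, edge_feats):
    """Independent dense re-implementation enumerating each node's in-neighbours."""
    n, d = H.shape
    heads, dh = layer.n_heads, layer.d_head
    We, be = layer.edge_lin.weight.data, layer.edge_lin.bias.data
    e = (np.logaddexp(0, edge_feats @ We + be) - np.log(2)).reshape(-1, heads, dh)
    Wq, bq = layer.q.weight.data, layer.q.bias.data
    Wk, bk = layer.k.weight.data, layer.k.bias.data
    Wv, bv = layer.v.weight.data, layer.v.bias.data
    q = (H @ Wq + bq).reshape(n, heads, dh)
    k = (H @ Wk + bk).reshape(n, heads, dh)
    v = (H @ Wv + bv).reshape(n, heads, dh)
    h_hat = np.zeros((n, heads, dh))
    src, dst = edge_index
    for i in range(n):
        nbr = [idx for idx in range(len(dst)) if dst[idx] == i]
        if not nbr:
            continue
        for c in range(heads):
            logits = np.array([q[i, c] @ (k[src[idx], c] + e[idx, c]) for idx in nbr]) / np.sqrt(dh)
            alpha = np.exp(logits - logits.max())
            alpha /= alpha.sum()
            h_hat[i, c] = sum(a * (v[src[idx], c] + e[idx, c]) for a, idx in zip(alpha, nbr))
    h_hat = h_hat.reshape(n, d)
    if layer.root is not None:
        h_hat = h_hat + H @ layer.root.weight.data + layer.root.bias.data
    x = H + h_hat
    mu = x.mean(axis=1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
    normed = (x - mu) / np.sqrt(var + 1e-5)
    return normed * layer.norm.scale.data + layer.norm.offset.data


class TestMessagePassing:
    @pytest.fixture()
    def small_layer(self):
        cfg = _f64(dict(variant="GSnet", head_spec="global6", node_dim=6, n_layers=1, n_heads=2, edge_in_dim=9))
        return GNNModel(cfg, seed=5).layers[0]

    def test_attention_sums_to_one_per_receiver(self, small_layer, rng):
        # 3-node path graph: 0-1, 1-2 (both orientations)
        edge_index = np.array([[0, 1, 1, 2], [1, 0, 2, 1]])
        H = Tensor(rng.standard_normal((3, 6)))
        ef = Tensor(rng.standard_normal((4, 9)))
        alpha = small_layer.attention_weights(H, edge_index, ef)
        dst = edge_index[1]
        for i in range(3):
            if (dst == i).any():
                np.testing.assert_allclose(alpha[dst == i].sum(axis=0), 1.0, rtol=1e-12)

    def test_zeroed_messages_reduce_to_layernorm(self, small_layer, rng):
        for lin in (small_layer.v, small_layer.root, small_layer.edge_lin):
            lin.weight.data[:] = 0.0
            lin.bias.data[:] = 0.0
        edge_index = np.array([[0, 1, 1, 2], [1, 0, 2, 1]])
        H = rng.standard_normal((3, 6))
        out = small_layer(Tensor(H), edge_index, Tensor(rng.standard_normal((4, 9))))
        # Ĥ = 0 (after ssp(0)=0 edge features and zero value/root maps)
        expected = brute_force_layer(small_layer, H, edge_index, rng.standard_normal((4, 9)) * 0)
        mu = H.mean(axis=1, keepdims=True)
        var = ((H - mu) ** 2).mean(axis=1, keepdims=True)
        ln = (H - mu) / np.sqrt(var + 1e-5) * small_layer.norm.scale.data + small_layer.norm.offset.data
        np.testing.assert_allclose(out.data, ln, rtol=1e-9)
        np.testing.assert_allclose(out.data, expected, rtol=1e-9)

    def test_matches_bruteforce_attention_oracle(self, small_layer, rng):
        edge_index = np.array([[0, 1, 1, 2], [1, 0, 2, 1]])
        H = rng.standard_normal((3, 6))
        ef = rng.standard_normal((4, 9))
        out = small_layer(Tensor(H), edge_index, Tensor(ef)).data
        np.testing.assert_allclose(out, brute_force_layer(small_layer, H, edge_index, ef), rtol=1e-9)


class TestReadout:
    def _model(self, head, variant="GSnet", node_dim=6):
        cfg = _f64(dict(variant=variant, head_spec=head, node_dim=node_dim, n_layers=1,
                        n_heads=1, edge_in_dim=9))
        return GNNModel(cfg, seed=0)

    def test_identical_embeddings_mean_equals_row(self, helix20):
        model = self._model("pka_gsnet")
        g = build_residue_graph(helix20)
        H = Tensor(np.tile(np.arange(6.0), (g.n_nodes, 1)))
        feats = model.readout(H, g, i=4).data
        np.testing.assert_allclose(feats, np.tile(np.arange(6.0), 7), rtol=1e-12)

    def test_tiny_protein_radius_means_collapse_to_global(self, tmp_path):
        from gsnet.structure import parse_structure

        p = tmp_path / "tiny.pdb"
        p.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       3.000   0.000   0.000  1.00  0.00           C\n"
        )
        s = parse_structure(p)
        g = build_residue_graph(s)
        model = self._model("pka_gsnet")
        H = Tensor(np.random.default_rng(0).standard_normal((2, 6)))
        feats = model.readout(H, g, i=0).data
        mu = H.data.mean(axis=0)
        for blk in range(2, 7):  # all five radius means equal the global mean
            np.testing.assert_allclose(feats[6 * blk : 6 * (blk + 1)], mu, rtol=1e-12)

    def test_radius_mean_matches_subset_oracle(self, helix20, rng):
        model = self._model("pka_gsnet")
        g = build_residue_graph(helix20)
        H = rng.standard_normal((g.n_nodes, 6))
        i = 9
        feats = model.readout(Tensor(H), g, i=i).data
        d = np.linalg.norm(g.coords - g.coords[i], axis=1)
        mu_8 = H[d <= 8.0].mean(axis=0)
        np.testing.assert_allclose(feats[6 * 3 : 6 * 4], mu_8, rtol=1e-12)  # block order: mu, h_i, mu_6, mu_8, ...
        assert (d <= 6.0)[i]  # self-inclusion makes every V_r non-empty

    def test_alcnet_concat_blocks(self, helix20):
        cfg = _f64(dict(variant="aLCnet", head_spec="pka_alcnet", node_dim=6, n_layers=1, n_heads=1, edge_in_dim=9))
        model = GNNModel(cfg, seed=0)
        g = build_atom_graph(helix20, 4)
        H = np.random.default_rng(1).standard_normal((g.n_nodes, 6))
        feats = model.readout(Tensor(H), g).data
        assert feats.shape == (18,)
        np.testing.assert_allclose(feats[:6], H.mean(axis=0), rtol=1e-12)
        np.testing.assert_allclose(feats[6:12], H[g.ca_node], rtol=1e-12)
        np.testing.assert_allclose(feats[12:], H[g.residue_node_set].mean(axis=0), rtol=1e-12)

    def test_residue_index_required(self, helix20):
        model = self._model("residue1")
        g = build_residue_graph(helix20)
        with pytest.raises(ValueError):
            model.readout(Tensor(np.zeros((20, 6))), g)


class TestHeads:
    def test_feature_and_head_dimensions(self):
        assert ModelConfig.gsnet("pka_gsnet").head_in_dim == 1050
        assert ModelConfig.alcnet("pka_alcnet").head_in_dim == 225
        assert ModelConfig.gsnet("global6").head_in_dim == 150
        assert ModelConfig.gsnet("global6").head_out_dim == 6

    def test_layer_counts(self):
        global_head = GNNModel(ModelConfig.gsnet("global6"), seed=0).head
        assert global_head.n_linear == 4 and global_head.n_activation == 3 and global_head.n_dropout == 0
        pka_head = GNNModel(ModelConfig.gsnet("pka_gsnet"), seed=0).head
        assert pka_head.n_linear == 6 and pka_head.n_activation == 5 and pka_head.n_dropout == 6
        assert all(d.p == 0.2 for d in pka_head.dropouts)

    def test_eval_mode_deterministic_train_mode_stochastic(self, helix20):
        model = GNNModel(ModelConfig.gsnet("pka_gsnet"), seed=0)
        g = build_residue_graph(helix20)
        p1, p2 = model.predict(g, 4), model.predict(g, 4)
        np.testing.assert_array_equal(p1, p2)
        model.train(True)
        rng = np.random.default_rng(0)
        t1 = model.forward(g, 4, rng).data
        t2 = model.forward(g, 4, rng).data
        assert not np.allclose(t1, t2)


class TestEndToEnd:
    def test_rigid_motion_invariance(self, helix20, rng):
        model = GNNModel(ModelConfig.gsnet("global6"), seed=0)
        g0 = build_residue_graph(helix20)
        base = model.predict(g0)
        moved = helix20.transformed(rotation=random_rotation(rng), translation=rng.standard_normal(3) * 30)
        np.testing.assert_allclose(model.predict(build_residue_graph(moved)), base, atol=1e-4)

    def test_node_order_permutation_invariance(self, helix20, rng):
        from gsnet.graphs import ResidueGraph

        model = GNNModel(ModelConfig.gsnet("global6", dtype="float64"), seed=0)
        g = build_residue_graph(helix20)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        g_perm = ResidueGraph(
            aa_index=g.aa_index[perm],
            dihedral_feats=g.dihedral_feats[perm],
            com_dist=g.com_dist[perm],
            coords=g.coords[perm],
            edge_index=inv[g.edge_index],
            edge_dist=g.edge_dist,
            edge_feats=g.edge_feats,
            spec=g.spec,
        )
        np.testing.assert_allclose(model.predict(g_perm), model.predict(g), atol=1e-9)
        # per-node embeddings are equivariant
        H = model.embed(g).data
        Hp = model.embed(g_perm).data
        np.testing.assert_allclose(Hp, H[perm], atol=1e-9)

    def test_checkpoint_roundtrip_bit_identical(self, tmp_path, helix20):
        model = GNNModel(ModelConfig.gsnet("global6"), seed=0)
        g = build_residue_graph(helix20)
        base = model.predict(g)
        f = tmp_path / "ckpt.npz"
        save_checkpoint(model, f, extra={"note": "test"})
        loaded, extra = load_checkpoint(f)
        assert extra["note"] == "test"
        np.testing.assert_array_equal(loaded.predict(g), base)

    def test_checkpoint_refuses_mismatched_config(self, tmp_path):
        model = GNNModel(ModelConfig.gsnet("global6"), seed=0)
        f = tmp_path / "ckpt.npz"
        save_checkpoint(model, f)
        with pytest.raises(ValueError, match="config"):
            load_checkpoint(f, config=ModelConfig.gsnet("global1"))

    def test_full_gsnet_under_one_second_for_50_residues(self):
        s = generate_structure(SynthSpec(n_residues=50, conformation="coil", jitter_sd=0.3, seed=8))
        model = GNNModel(ModelConfig.gsnet("global6"), seed=0)
        g = build_residue_graph(s)
        model.predict(g)  # warm-up
        t0 = time.perf_counter()
        model.predict(g)
        assert time.perf_counter() - t0 < 1.0
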