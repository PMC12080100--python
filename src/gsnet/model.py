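"""The networks: node encoders, transformer message-passing layers, readouts
and output MLP heads.

Two variants share one implementation:

* **GSnet** — residue graph, 150-d nodes, 6 layers, 1 attention head;
  global (6- or 1-target), per-residue and pKa heads.
* **aLCnet** — local atom graph, 75-d nodes, 3 layers, 3 attention heads,
  charge-aware encoder; pKa head.

Message passing follows the transformer-convolution form: per head *c*,
attention logits ⟨W_q h_i, W_k h_j + e_c,ij⟩/√d_head over in-neighbours j,
messages α_ij (W_v h_j + e_c,ij), plus a learned root transform of h_i;
the layer output is LayerNorm(H + Ĥ). Edge features enter through a
per-layer shifted-softplus linear transform of the smeared distances.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat, gather_rows, segment_softmax, segment_sum
from .graphs import AtomGraph, ResidueGraph
from .nn import MLP, Adam, Dropout, Embedding, LayerNorm, Linear, Module, ssp

__all__ = ["ModelConfig", "GNNModel", "HEAD_SPECS", "save_checkpoint", "load_checkpoint"]

HEAD_SPECS = ("global6", "global1", "residue1", "pka_gsnet", "pka_alcnet")
POOL_RADII = (6.0, 8.0, 10.0, 12.0, 15.0)  # Å, for the pKa readout
N_AA_EMBED = 21  # 20 standard residues + generic


@dataclass
class ModelConfig:
    variant: str  # "GSnet" | "aLCnet"
    head_spec: str
    node_dim: int = 150
    n_layers: int = 6
    n_heads: int = 1
    edge_in_dim: int = 300
    aa_embed_dim: int = 64
    atom_embed_dim: int = 64
    encoder_hidden_dim: int = 64
    head_hidden_dim: int = 1024
    dropout: float = 0.0
    root_term: bool = True
    dtype: str = "float32"

    def __post_init__(self):
        if self.variant not in ("GSnet", "aLCnet"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.head_spec not in HEAD_SPECS:
            raise ValueError(f"unknown head_spec {self.head_spec!r}")
        if self.node_dim % self.n_heads != 0:
            raise ValueError("node_dim must be divisible by n_heads")
        if self.head_spec == "pka_gsnet" and self.variant != "GSnet":
            raise ValueError("pka_gsnet head requires the GSnet variant")
        if self.head_spec == "pka_alcnet" and self.variant != "aLCnet":
            raise ValueError("pka_alcnet head requires the aLCnet variant")

    @classmethod
    def gsnet(cls, head_spec: str = "global6", **kw) -> "ModelConfig":
        return cls(variant="GSnet", head_spec=head_spec, node_dim=150, n_layers=6, n_heads=1,
                   dropout=0.2 if head_spec.startswith("pka") else 0.0, **kw)

    @classmethod
    def alcnet(cls, head_spec: str = "pka_alcnet", **kw) -> "ModelConfig":
        return cls(variant="aLCnet", head_spec=head_spec, node_dim=75, n_layers=3, n_heads=3,
                   dropout=0.2 if head_spec.startswith("pka") else 0.0, **kw)

    @property
    def head_in_dim(self) -> int:
        return {"pka_gsnet": 7 * self.node_dim, "pka_alcnet": 3 * self.node_dim}.get(self.head_spec, self.node_dim)

    @property
    def head_out_dim(self) -> int:
        return 6 if self.head_spec == "global6" else 1

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


class _MessagePassingLayer(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d, h = cfg.node_dim, cfg.n_heads
        self.d_head = d // h
        self.n_heads = h
        dt = cfg.np_dtype
        self.edge_lin = self.add_child("edge_lin", Linear(cfg.edge_in_dim, d, rng, dtype=dt))
        self.q = self.add_child("q", Linear(d, d, rng, dtype=dt))
        self.k = self.add_child("k", Linear(d, d, rng, dtype=dt))
        self.v = self.add_child("v", Linear(d, d, rng, dtype=dt))
        self.root = self.add_child("root", Linear(d, d, rng, dtype=dt)) if cfg.root_term else None
        self.norm = self.add_child("norm", LayerNorm(d, dtype=dt))

    def __call__(self, H: Tensor, edge_index: np.ndarray, edge_feats: Tensor) -> Tensor:
        n, d = H.shape
        src, dst = edge_index
        e = ssp(self.edge_lin(edge_feats)).reshape(-1, self.n_heads, self.d_head)
        q = self.q(H).reshape(n, self.n_heads, self.d_head)
        k = self.k(H).reshape(n, self.n_heads, self.d_head)
        v = self.v(H).reshape(n, self.n_heads, self.d_head)
        k_src = gather_rows(k, src) + e
        v_src = gather_rows(v, src) + e
        q_dst = gather_rows(q, dst)
        logits = (q_dst * k_src).sum(axis=-1) * (1.0 / np.sqrt(self.d_head))  # (E, heads)
        alpha = segment_softmax(logits, dst, n)
        msg = alpha.reshape(-1, self.n_heads, 1) * v_src
        h_hat = segment_sum(msg, dst, n).reshape(n, d)
        if self.root is not None:
            h_hat = h_hat + self.root(H)
        return self.norm(H + h_hat)

    def attention_weights(self, H: Tensor, edge_index: np.ndarray, edge_feats: Tensor) -> np.ndarray:
        """Attention coefficients α_ij (E, heads) — diagnostics only."""
        n = H.shape[0]
        src, dst = edge_index
        e = ssp(self.edge_lin(edge_feats)).reshape(-1, self.n_heads, self.d_head)
        q = self.q(H).reshape(n, self.n_heads, self.d_head)
        k = self.k(H).reshape(n, self.n_heads, self.d_head)
        logits = (gather_rows(q, dst) * (gather_rows(k, src) + e)).sum(axis=-1) * (1.0 / np.sqrt(self.d_head))
        return segment_softmax(logits, dst, n).data


class GNNModel(Module):
    """One network (encoder + message passing + readout + head)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        dt = config.np_dtype
        hid = config.encoder_hidden_dim
        self.aa_embed = self.add_child("aa_embed", Embedding(N_AA_EMBED, config.aa_embed_dim, rng, dtype=dt))
        if config.variant == "GSnet":
            self.dihedral_mlp = self.add_child("dihedral_mlp", MLP([15, hid, hid], rng, dtype=dt))
            self.com_mlp = self.add_child("com_mlp", MLP([1, hid, hid], rng, dtype=dt))
            concat_dim = config.aa_embed_dim + 2 * hid
        else:
            self.atom_embed = self.add_child("atom_embed", Embedding(len("CHNOS"), config.atom_embed_dim, rng, dtype=dt))
            self.charge_mlp = self.add_child("charge_mlp", MLP([1, hid, hid], rng, dtype=dt))
            concat_dim = config.aa_embed_dim + config.atom_embed_dim + hid
        self.reducer = self.add_child("reducer", MLP([concat_dim, 2 * config.node_dim, config.node_dim], rng, dtype=dt))
        self.layers = [
            self.add_child(f"layer{l}", _MessagePassingLayer(config, rng)) for l in range(config.n_layers)
        ]
        hd = config.head_hidden_dim
        if config.head_spec.startswith("pka"):
            dims = [config.head_in_dim] + [hd] * 5 + [1]  # 6 linear, 5 SSP, 6 dropout
            self.head = self.add_child("head", MLP(dims, rng, dropout=config.dropout, dtype=dt))
        else:
            dims = [config.head_in_dim] + [hd] * 3 + [config.head_out_dim]  # 4 linear, 3 SSP
            self.head = self.add_child("head", MLP(dims, rng, dtype=dt))

    # -- parameter groups ------------------------------------------------------
    def gnn_modules(self) -> dict[str, Module]:
        out = {k: v for k, v in self._children.items() if k != "head"}
        return out

    def gnn_parameters(self) -> list[Tensor]:
        out = []
        for m in self.gnn_modules().values():
            out.extend(m.parameters())
        return out

    def head_parameters(self) -> list[Tensor]:
        return self.head.parameters()

    # -- forward ---------------------------------------------------------------
    def encode_nodes(self, graph: ResidueGraph | AtomGraph) -> Tensor:
        dt = self.config.np_dtype
        if self.config.variant == "GSnet":
            if not isinstance(graph, ResidueGraph):
                raise TypeError("GSnet expects a ResidueGraph")
            blocks = [
                self.aa_embed(graph.aa_index),
                self.dihedral_mlp(Tensor(graph.dihedral_feats.astype(dt))),
                self.com_mlp(Tensor(graph.com_dist.reshape(-1, 1).astype(dt))),
            ]
        else:
            if not isinstance(graph, AtomGraph):
                raise TypeError("aLCnet expects an AtomGraph")
            blocks = [
                self.aa_embed(graph.aa_index),
                self.atom_embed(graph.atom_type_index),
                self.charge_mlp(Tensor(graph.charge.reshape(-1, 1).astype(dt))),
            ]
        return self.reducer(concat(blocks, axis=1))

    def embed(self, graph: ResidueGraph | AtomGraph) -> Tensor:
        """Node embeddings after all message-passing layers (n, node_dim)."""
        H = self.encode_nodes(graph)
        edge_feats = Tensor(graph.edge_feats.astype(self.config.np_dtype))
        for layer in self.layers:
            H = layer(H, graph.edge_index, edge_feats)
        return H

    def readout(self, H: Tensor, graph: ResidueGraph | AtomGraph, i: int | None = None) -> Tensor:
        """Head-specific feature vector.

        * global heads — element-wise mean μ over all nodes;
        * residue1 — the node embedding h_i;
        * pka_gsnet — [μ, h_i, μ_6, μ_8, μ_10, μ_12, μ_15] (7·node_dim);
        * pka_alcnet — [μ, h_Cα, μ_residue] (3·node_dim).
        """
        spec = self.config.head_spec
        if spec in ("global6", "global1"):
            return H.mean(axis=0)
        if i is None and spec != "pka_alcnet":
            raise ValueError(f"head_spec {spec!r} requires a residue index")
        if spec == "residue1":
            return gather_rows(H, np.array([i])).reshape(-1)
        if spec == "pka_gsnet":
            mu = H.mean(axis=0)
            h_i = gather_rows(H, np.array([i])).reshape(-1)
            dist = np.linalg.norm(graph.coords - graph.coords[i], axis=1)
            parts = [mu, h_i]
            for r in POOL_RADII:
                idx = np.where(dist <= r)[0]  # always contains i (distance 0)
                parts.append(gather_rows(H, idx).mean(axis=0))
            return concat(parts, axis=0)
        if spec == "pka_alcnet":
            if not isinstance(graph, AtomGraph):
                raise TypeError("pka_alcnet readout requires an AtomGraph")
            mu = H.mean(axis=0)
            h_ca = gather_rows(H, np.array([graph.ca_node])).reshape(-1)
            mu_aa = gather_rows(H, graph.residue_node_set).mean(axis=0)
            return concat([mu, h_ca, mu_aa], axis=0)
        raise ValueError(spec)

    def forward(self, graph: ResidueGraph | AtomGraph, i: int | None = None,
                rng: np.random.Generator | None = None) -> Tensor:
        """Full prediction: graph → embeddings → readout → head MLP output."""
        H = self.embed(graph)
        feats = self.readout(H, graph, i)
        return self.head(feats.reshape(1, -1), rng).reshape(-1)

    __call__ = forward

    def predict(self, graph, i: int | None = None) -> np.ndarray:
        """Deterministic (eval-mode) prediction as a numpy array."""
        was_training = self.training
        self.eval()
        out = self.forward(graph, i).data.copy()
        self.train(was_training)
        return out


# -- checkpoints ---------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(model: GNNModel, path: str | Path, extra: dict | None = None) -> None:
    """Single-file checkpoint: config echo + all parameter arrays, versioned."""
    meta = {"version": _CHECKPOINT_VERSION, "config": asdict(model.config), "extra": extra or {}}
    np.savez(path, _meta=json.dumps(meta), **model.state_dict())


def load_checkpoint(path: str | Path, config: ModelConfig | None = None) -> tuple[GNNModel, dict]:
    """Rebuild a model from a checkpoint.

    If ``config`` is given it must match the checkpoint's config echo exactly
    (the load refuses to proceed otherwise).
    """
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["_meta"]))
        if meta["version"] != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        stored = ModelConfig(**meta["config"])
        if config is not None and asdict(config) != asdict(stored):
            raise ValueError("checkpoint config does not match the requested config")
        model = GNNModel(stored, seed=0)
        model.load_state_dict({k: data[k] for k in data.files if k != "_meta"})
        return model, meta.get("extra", {})
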