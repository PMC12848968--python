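"""Message-passing network with Set Transformer readout for redox prediction.

Architecture: atom and bond features are projected into latent node and edge
states; six iterations of residual message passing follow, where each
directed edge computes a message from (source state, target state, edge
state) through a learned MLP, messages are sum-aggregated on the receiving
node and added to its state, and edge states are updated residually from
the messages on them.  The final node and edge states jointly form a set
that is pooled by multihead attention against learned seed queries (the
Set Transformer's PMA block), giving a permutation-invariant graph vector.

Two output variants:

* ``VS`` — an MLP head emits a fixed-order vector of potentials, one per
  training solvent, alongside the electron-affinity head.
* ``SD`` — one linear head sees the graph vector only (the solvent-
  independent electron-affinity component) and a second head sees the graph
  vector concatenated with the projected solvent descriptor (the solvent-
  dependent component); the reduction potential is their sum.  Because the
  solvent enters only as the (epsilon, n) descriptor pair, the SD variant
  can predict in solvents never seen in training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np

from redoxsolv import nn
from redoxsolv.chemgraph import MolGraph, featurize, to_directed, DEFAULT_VOCABULARY
from redoxsolv.nn import Tensor, concat, gather_rows, segment_sum, segment_softmax
from redoxsolv.solventdb import SolventSpec, TRAINING_SOLVENTS, descriptor_vector

__all__ = ["ModelConfig", "Prediction", "RedoxMPNN", "BatchedGraphs"]


@dataclass
class ModelConfig:
    """Hyperparameters; defaults are the shipped configuration."""

    variant: str = "SD"
    n_message_iterations: int = 6
    node_dim: int = 128
    edge_dim: int = 128
    graph_dim: int = 256
    n_attention_heads: int = 4
    n_solvents: int = 5
    solvent_dim: int = 16
    head_hidden: int = 64
    pool_edges: bool = True
    # "cardinality" multiplies the attention-pooled vector by the element
    # count, making the readout extensive (energy-like targets); "none"
    # keeps the plain convex attention average
    pool_scale: str = "cardinality"
    descriptor_scheme: str = "minmax"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("SD", "VS"):
            raise ValueError(f"variant must be 'SD' or 'VS', got {self.variant!r}")
        if self.n_message_iterations < 1:
            raise ValueError("n_message_iterations must be >= 1")
        if min(self.node_dim, self.edge_dim, self.graph_dim, self.head_hidden) <= 0:
            raise ValueError("latent dimensions must be positive")
        if self.graph_dim % self.n_attention_heads != 0:
            raise ValueError("n_attention_heads must divide graph_dim")


@dataclass
class Prediction:
    """Split prediction: solvent-independent + solvent-dependent = potential."""

    ea_component: float
    reduction_potential: float | np.ndarray
    solvent_component: float | None = None
    variant: str = "SD"


class BatchedGraphs:
    """Concatenated node/edge arrays for a batch of molecular graphs."""

    def __init__(self, graphs: Sequence[MolGraph]):
        if not graphs:
            raise ValueError("empty batch")
        self.n_graphs = len(graphs)
        nf, ef, src, dst, eidx, ngid, egid = [], [], [], [], [], [], []
        n_off = e_off = 0
        for gi, g in enumerate(graphs):
            nf.append(g.node_features())
            ef.append(g.edge_features())
            s, d, k = to_directed(g)
            src.append(s + n_off)
            dst.append(d + n_off)
            eidx.append(k + e_off)
            ngid += [gi] * g.n_heavy
            egid += [gi] * len(g.edges)
            n_off += g.n_heavy
            e_off += len(g.edges)
        self.node_features = np.concatenate(nf, axis=0)
        self.edge_features = (np.concatenate(ef, axis=0) if e_off
                              else np.zeros((0, graphs[0].edge_features().shape[1])))
        self.src = np.concatenate(src) if src else np.zeros(0, dtype=np.int64)
        self.dst = np.concatenate(dst) if dst else np.zeros(0, dtype=np.int64)
        self.edge_index = np.concatenate(eidx) if eidx else np.zeros(0, dtype=np.int64)
        self.node_graph = np.asarray(ngid, dtype=np.int64)
        self.edge_graph = np.asarray(egid, dtype=np.int64)
        self.n_nodes = n_off
        self.n_edges = e_off


class RedoxMPNN:
    """The predictor model; construct fresh or load from a checkpoint."""

    def __init__(self, config: ModelConfig | None = None,
                 vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY):
        self.config = config or ModelConfig()
        self.vocabulary = tuple(vocabulary)
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        n_node_feat = len(self.vocabulary) + 7
        n_edge_feat = 6
        self.node_proj = nn.Linear(n_node_feat, cfg.node_dim, rng)
        self.edge_proj = nn.Linear(n_edge_feat, cfg.edge_dim, rng)
        # message function shared across iterations (weight tying)
        self.msg_mlp = nn.MLP(
            [2 * cfg.node_dim + cfg.edge_dim, cfg.node_dim, cfg.node_dim], rng)
        self.edge_update = nn.Linear(cfg.node_dim, cfg.edge_dim, rng)

        # PMA pooling: project node and edge states into a common element
        # space, attend with learned per-head queries
        d_el = cfg.graph_dim
        dh = cfg.graph_dim // cfg.n_attention_heads
        self.node_to_el = nn.Linear(cfg.node_dim, d_el, rng)
        self.edge_to_el = nn.Linear(cfg.edge_dim, d_el, rng)
        self.attn_k = [nn.Linear(d_el, dh, rng) for _ in range(cfg.n_attention_heads)]
        self.attn_v = [nn.Linear(d_el, dh, rng) for _ in range(cfg.n_attention_heads)]
        bound = 1.0 / np.sqrt(dh)
        self.attn_q = [nn.Parameter(rng.uniform(-bound, bound, size=(dh, 1)))
                       for _ in range(cfg.n_attention_heads)]
        self.pool_out = nn.Linear(cfg.graph_dim, cfg.graph_dim, rng)

        self.ea_head = nn.MLP([cfg.graph_dim, cfg.head_hidden, 1], rng)
        if cfg.variant == "SD":
            self.solvent_proj = nn.Linear(2, cfg.solvent_dim, rng)
            self.solv_head = nn.MLP(
                [cfg.graph_dim + cfg.solvent_dim, cfg.head_hidden, 1], rng)
        else:
            self.vs_head = nn.MLP([cfg.graph_dim, cfg.head_hidden, cfg.n_solvents], rng)

        # output normalization (set from training targets by the trainer):
        # raw head outputs are affinely mapped so that at initialization the
        # model predicts the training-set means
        self.out_scale: float = 1.0
        self.ea_center: float = 0.0
        self.solv_center: float = 0.0
        self.pot_center: np.ndarray = np.zeros(cfg.n_solvents)

    def set_output_normalization(self, scale: float, ea_center: float,
                                 solv_center: float = 0.0,
                                 pot_center: np.ndarray | None = None) -> None:
        self.out_scale = float(scale) if scale > 0 else 1.0
        self.ea_center = float(ea_center)
        self.solv_center = float(solv_center)
        if pot_center is not None:
            self.pot_center = np.asarray(pot_center, dtype=np.float64)

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[nn.Parameter]:
        params = (self.node_proj.parameters() + self.edge_proj.parameters()
                  + self.msg_mlp.parameters() + self.edge_update.parameters()
                  + self.node_to_el.parameters() + self.edge_to_el.parameters()
                  + self.pool_out.parameters() + self.ea_head.parameters())
        for k, v, q in zip(self.attn_k, self.attn_v, self.attn_q):
            params += k.parameters() + v.parameters() + [q]
        if self.config.variant == "SD":
            params += self.solvent_proj.parameters() + self.solv_head.parameters()
        else:
            params += self.vs_head.parameters()
        return params

    # -- forward ------------------------------------------------------------

    def message_pass(self, batch: BatchedGraphs, h: Tensor, e: Tensor) -> tuple[Tensor, Tensor]:
        """One residual message-passing iteration; shapes preserved."""
        if batch.n_edges == 0:
            return h, e
        # RMS-normalize the message inputs so the residual stream can grow
        # without saturating the message MLP
        hn, en = nn.rms_norm(h), nn.rms_norm(e)
        m = self.msg_mlp(concat([gather_rows(hn, batch.src),
                                 gather_rows(hn, batch.dst),
                                 gather_rows(en, batch.edge_index)], axis=1))
        h = h + segment_sum(m, batch.dst, batch.n_nodes)
        e = e + self.edge_update(segment_sum(m, batch.edge_index, batch.n_edges))
        return h, e

    def readout(self, batch: BatchedGraphs, h: Tensor, e: Tensor) -> Tensor:
        """PMA attention pooling of the joint node+edge element set."""
        hn = nn.rms_norm(h)
        if self.config.pool_edges and batch.n_edges > 0:
            elements = concat([self.node_to_el(hn), self.edge_to_el(nn.rms_norm(e))], axis=0)
            el_graph = np.concatenate([batch.node_graph, batch.edge_graph])
        else:
            elements = self.node_to_el(hn)
            el_graph = batch.node_graph
        if elements.shape[0] == 0:
            raise ValueError("readout over an empty element set")
        elements = elements.tanh()
        dh = self.config.graph_dim // self.config.n_attention_heads
        pooled = []
        for k, v, q in zip(self.attn_k, self.attn_v, self.attn_q):
            scores = (k(elements) @ q) * (1.0 / np.sqrt(dh))
            alpha = segment_softmax(scores, el_graph, batch.n_graphs)
            pooled.append(segment_sum(alpha * v(elements), el_graph, batch.n_graphs))
        out = concat(pooled, axis=1)
        if self.config.pool_scale == "cardinality":
            counts = np.bincount(el_graph, minlength=batch.n_graphs).astype(np.float64)
            out = out * Tensor(counts[:, None])
        return self.pool_out(out)

    def encode(self, batch: BatchedGraphs) -> Tensor:
        """Graph vectors (n_graphs, graph_dim) after full message passing."""
        h = self.node_proj(Tensor(batch.node_features))
        e = self.edge_proj(Tensor(batch.edge_features))
        for _ in range(self.config.n_message_iterations):
            h, e = self.message_pass(batch, h, e)
        return self.readout(batch, h, e)

    def forward_batch(self, graphs: Sequence[MolGraph],
                      solvent_descriptors: np.ndarray | None = None,
                      feature_noise: tuple[np.random.Generator, float] | None = None,
                      ) -> dict[str, Tensor]:
        """Differentiable batched forward; returns output tensors by name.

        For the SD variant ``solvent_descriptors`` is an (n_graphs, 2) array,
        one descriptor row per record (repeat the graph to query several
        solvents).  ``feature_noise`` (rng, sd) jitters input features — a
        train-time augmentation, never used at inference.
        """
        batch = BatchedGraphs(graphs)
        if feature_noise is not None:
            rng, sd = feature_noise
            batch.node_features = batch.node_features + rng.normal(
                0.0, sd, batch.node_features.shape)
            if batch.n_edges:
                batch.edge_features = batch.edge_features + rng.normal(
                    0.0, sd, batch.edge_features.shape)
        z = self.encode(batch)
        ea = self.ea_head(z) * self.out_scale + self.ea_center
        if self.config.variant == "VS":
            pots = self.vs_head(z) * self.out_scale + Tensor(self.pot_center)
            return {"ea": ea, "potentials": pots}
        if solvent_descriptors is None:
            raise ValueError("SD variant requires solvent descriptors")
        sd = np.atleast_2d(np.asarray(solvent_descriptors, dtype=np.float64))
        if sd.shape != (len(graphs), 2):
            raise ValueError(f"expected ({len(graphs)}, 2) descriptors, got {sd.shape}")
        s = self.solvent_proj(Tensor(sd)).tanh()
        solv = self.solv_head(concat([z, s], axis=1)) * self.out_scale + self.solv_center
        return {"ea": ea, "solvent": solv, "e_red": ea + solv}

    # -- convenience single-molecule API ------------------------------------

    def _as_graph(self, mol: MolGraph | str) -> MolGraph:
        return mol if isinstance(mol, MolGraph) else featurize(mol, self.vocabulary)

    def forward_sd(self, mol: MolGraph | str, solvent: SolventSpec) -> Prediction:
        """Predict in one solvent; potential = EA head + solvent head, exactly."""
        if self.config.variant != "SD":
            raise ValueError("forward_sd requires an SD-variant model")
        g = self._as_graph(mol)
        d = descriptor_vector(solvent, self.config.descriptor_scheme)
        out = self.forward_batch([g], d[None, :])
        ea = float(out["ea"].data[0, 0])
        sv = float(out["solvent"].data[0, 0])
        return Prediction(ea_component=ea, solvent_component=sv,
                          reduction_potential=ea + sv, variant="SD")

    def forward_vs(self, mol: MolGraph | str) -> Prediction:
        """Predict the fixed-order five-solvent potential vector plus EA."""
        if self.config.variant != "VS":
            raise ValueError("forward_vs requires a VS-variant model")
        out = self.forward_batch([self._as_graph(mol)])
        return Prediction(ea_component=float(out["ea"].data[0, 0]),
                          reduction_potential=out["potentials"].data[0].copy(),
                          variant="VS")

    def predict_solvents(self, mol: MolGraph | str,
                         solvents: Sequence[SolventSpec]) -> np.ndarray:
        """SD model queried across several solvents -> potential vector."""
        g = self._as_graph(mol)
        d = np.stack([descriptor_vector(s, self.config.descriptor_scheme)
                      for s in solvents])
        out = self.forward_batch([g] * len(solvents), d)
        return out["e_red"].data[:, 0].copy()

    # -- checkpointing ------------------------------------------------------

    def save(self, directory: str | Path, metadata: dict | None = None) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        cfg["vocabulary"] = list(self.vocabulary)
        (d / "config.json").write_text(json.dumps(cfg, indent=2))
        np.savez(d / "weights.npz",
                 **{f"p{i}": p.data for i, p in enumerate(self.parameters())})
        (d / "normalization.json").write_text(json.dumps({
            "out_scale": self.out_scale, "ea_center": self.ea_center,
            "solv_center": self.solv_center,
            "pot_center": self.pot_center.tolist()}, indent=2))
        (d / "meta.json").write_text(json.dumps(metadata or {}, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "RedoxMPNN":
        d = Path(directory)
        cfg = json.loads((d / "config.json").read_text())
        vocab = tuple(cfg.pop("vocabulary", DEFAULT_VOCABULARY))
        model = cls(ModelConfig(**cfg), vocabulary=vocab)
        with np.load(d / "weights.npz") as z:
            params = model.parameters()
            if len(z.files) != len(params):
                raise ValueError("checkpoint incompatible with model configuration")
            for i, p in enumerate(params):
                stored = z[f"p{i}"]
                if stored.shape != p.data.shape:
                    raise ValueError("checkpoint incompatible with model configuration")
                p.data = stored.astype(np.float64)
        norm_path = d / "normalization.json"
        if norm_path.exists():
            norm = json.loads(norm_path.read_text())
            model.set_output_normalization(
                norm["out_scale"], norm["ea_center"], norm["solv_center"],
                np.asarray(norm["pot_center"]))
        return model


def training_solvent_specs() -> list[SolventSpec]:
    from redoxsolv.solventdb import get_solvent
    return [get_solvent(n) for n in TRAINING_SOLVENTS]
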