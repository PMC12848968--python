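"""Training loop, molecule-level splitting, metrics, and LOSO evaluation.

Splitting operates on molecule identity: all records belonging to one
molecule — its potentials in every solvent and its electron affinity —
land in the same partition, so no structural information leaks across
train/validation/test.  The leave-one-solvent-out (LOSO) protocol trains a
solvent-descriptor (SD) model with every record of one solvent withheld and
evaluates only in that solvent, probing zero-shot generalization to unseen
solvents.

The loss is the sum over output dimensions of the per-dimension mean
absolute error: for the VS variant the five solvent columns plus the EA,
for the SD variant the per-record potential plus the auxiliary EA.
Optimization is AdamW (lr 1e-4, weight decay 1e-5 by default); the returned
model carries the best-validation-epoch weights, not the final ones.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from redoxsolv.chemgraph import MolGraph
from redoxsolv.mpnn import ModelConfig, RedoxMPNN
from redoxsolv.nn import AdamW, Tensor
from redoxsolv.solventdb import SolventSpec, descriptor_vector

__all__ = [
    "TrainConfig", "MoleculeData", "RedoxDataset", "SplitAssignment", "Metrics",
    "split_molecules", "combined_loss", "train", "evaluate", "loso_protocol",
    "build_sd_records",
]


@dataclass
class TrainConfig:
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    seed: int = 0
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    clip_norm: float | None = None  # global gradient-norm clip; off by default
    lr_decay: str = "none"          # "none" (constant) or "cosine" to 1/10 lr
    swa_fraction: float = 0.0       # average weights over the final fraction of
                                    # epochs; kept only if it beats the best
                                    # single epoch on validation loss
    feature_noise: float = 0.0      # train-time Gaussian jitter on input features

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {self.ratios}")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass
class MoleculeData:
    """One molecule with its targets: optional EA and per-solvent potentials (eV)."""

    id: str
    graph: MolGraph
    ea: float | None = None
    potentials: dict[str, float] = field(default_factory=dict)


@dataclass
class RedoxDataset:
    """Molecules plus the solvent registry slice they were measured in."""

    molecules: list[MoleculeData]
    solvents: dict[str, SolventSpec]

    @property
    def solvent_names(self) -> list[str]:
        return list(self.solvents)

    def subset(self, ids: set[str]) -> list[MoleculeData]:
        return [m for m in self.molecules if m.id in ids]


SplitAssignment = dict[str, str]  # molecule id -> "train" | "val" | "test"


def desk_scale_model_config(seed: int = 0, variant: str = "SD") -> ModelConfig:
    """Reduced-size model for CPU-scale studies on synthetic data."""
    return ModelConfig(variant=variant, node_dim=32, edge_dim=32, graph_dim=64,
                       n_attention_heads=2, head_hidden=32, solvent_dim=8, seed=seed)


def desk_scale_train_config(seed: int = 0, epochs: int = 60) -> TrainConfig:
    """Training recipe for the desk-scale synthetic studies.

    Shorter and more aggressive than the full-data defaults: higher learning
    rate with cosine decay, gradient clipping, and weight averaging over the
    final quarter of epochs.
    """
    return TrainConfig(epochs=epochs, batch_size=32, learning_rate=3e-3,
                       weight_decay=3e-4, seed=seed, clip_norm=5.0,
                       lr_decay="cosine", swa_fraction=0.25)


def split_molecules(ids: list[str],
                    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                    seed: int = 0) -> SplitAssignment:
    """Deterministic molecule-level train/val/test partition.

    Partition sizes are the exact fractional counts rounded by largest
    remainder, so 100 ids at 80/10/10 give (80, 10, 10).
    """
    if len(ids) < 10:
        raise ValueError(f"need at least 10 molecule ids to split, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate molecule ids")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(ids)
    exact = [n * r for r in ratios]
    counts = [int(math.floor(x)) for x in exact]
    rem = n - sum(counts)
    order = sorted(range(3), key=lambda i: exact[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    rng = np.random.default_rng(seed)
    shuffled = list(ids)
    rng.shuffle(shuffled)
    parts = ("train", "val", "test")
    out: SplitAssignment = {}
    k = 0
    for part, c in zip(parts, counts):
        for mid in shuffled[k:k + c]:
            out[mid] = part
        k += c
    return out


def combined_loss(predictions: dict[str, Tensor],
                  targets: dict[str, np.ndarray],
                  masks: dict[str, np.ndarray] | None = None) -> Tensor:
    """Sum over output dimensions of masked per-dimension MAE.

    ``predictions[k]`` is an (n, d_k) tensor; matching targets are (n, d_k)
    arrays, with optional 0/1 masks for missing entries.  Each of the d_k
    columns contributes its own MAE term to the sum.
    """
    masks = masks or {}
    total: Tensor | None = None
    any_dim = False
    for key, pred in predictions.items():
        if key not in targets:
            continue
        t = np.atleast_2d(np.asarray(targets[key], dtype=np.float64))
        m = masks.get(key)
        m = np.ones_like(t) if m is None else np.atleast_2d(np.asarray(m, dtype=np.float64))
        col = ((pred - Tensor(t)).abs() * Tensor(m)).sum(axis=0)  # (d_k,)
        for j in range(t.shape[1]):
            n_obs = m[:, j].sum()
            if n_obs == 0:
                continue
            any_dim = True
            # per-column extraction via a one-hot selector
            sel = np.zeros(t.shape[1]); sel[j] = 1.0
            mae_j = (col * Tensor(sel)).sum() / float(n_obs)
            total = mae_j if total is None else total + mae_j
    if not any_dim:
        raise ValueError("no unmasked targets in batch")
    return total


# -- record expansion -------------------------------------------------------

def build_sd_records(molecules: list[MoleculeData],
                     solvents: dict[str, SolventSpec],
                     scheme: str,
                     exclude_solvent: str | None = None,
                     ) -> list[tuple[MolGraph, np.ndarray, float, float | None, str]]:
    """Expand molecules into (graph, descriptor, e_red, ea, solvent) records.

    One record per (molecule, solvent) pair with an observed potential;
    records in ``exclude_solvent`` are dropped entirely (the LOSO guard).
    """
    records = []
    for m in molecules:
        for sname, pot in m.potentials.items():
            if sname == exclude_solvent:
                continue
            if sname not in solvents:
                raise KeyError(f"solvent {sname!r} absent from dataset registry")
            d = descriptor_vector(solvents[sname], scheme)
            records.append((m.graph, d, pot, m.ea, sname))
    return records


def _sd_batch_loss(model: RedoxMPNN, records, idx, feature_noise=None) -> Tensor:
    graphs = [records[i][0] for i in idx]
    desc = np.stack([records[i][1] for i in idx])
    e_red = np.array([[records[i][2]] for i in idx])
    ea = np.array([[records[i][3] if records[i][3] is not None else 0.0] for i in idx])
    ea_mask = np.array([[0.0 if records[i][3] is None else 1.0] for i in idx])
    out = model.forward_batch(graphs, desc, feature_noise=feature_noise)
    return combined_loss(
        {"e_red": out["e_red"], "ea": out["ea"]},
        {"e_red": e_red, "ea": ea},
        {"ea": ea_mask},
    )


def _vs_batch_loss(model: RedoxMPNN, molecules: list[MoleculeData],
                   solvent_order: list[str], idx) -> Tensor:
    mols = [molecules[i] for i in idx]
    graphs = [m.graph for m in mols]
    t = np.zeros((len(mols), len(solvent_order)))
    mask = np.zeros_like(t)
    for r, m in enumerate(mols):
        for c, sname in enumerate(solvent_order):
            if sname in m.potentials:
                t[r, c] = m.potentials[sname]
                mask[r, c] = 1.0
    ea = np.array([[m.ea if m.ea is not None else 0.0] for m in mols])
    ea_mask = np.array([[0.0 if m.ea is None else 1.0] for m in mols])
    out = model.forward_batch(graphs)
    return combined_loss(
        {"potentials": out["potentials"], "ea": out["ea"]},
        {"potentials": t, "ea": ea},
        {"potentials": mask, "ea": ea_mask},
    )


def train(model: RedoxMPNN, dataset: RedoxDataset, split: SplitAssignment,
          cfg: TrainConfig, exclude_solvent: str | None = None,
          ) -> tuple[RedoxMPNN, list[dict[str, float]]]:
    """Train in place; returns the best-validation model and loss history.

    ``exclude_solvent`` removes every record of that solvent from both the
    training and validation streams (LOSO).  History is one dict per epoch
    with keys ``train_loss`` and ``val_loss``.
    """
    variant = model.config.variant
    train_mols = [m for m in dataset.molecules if split.get(m.id) == "train"]
    val_mols = [m for m in dataset.molecules if split.get(m.id) == "val"]
    if not train_mols or not val_mols:
        raise ValueError("train and val partitions must both be non-empty")

    aug_rng = np.random.default_rng((cfg.seed, 1))
    noise = ((aug_rng, cfg.feature_noise) if cfg.feature_noise > 0 else None)
    if variant == "SD":
        scheme = model.config.descriptor_scheme
        train_items = build_sd_records(train_mols, dataset.solvents, scheme, exclude_solvent)
        val_items = build_sd_records(val_mols, dataset.solvents, scheme, exclude_solvent)
        batch_loss = lambda idx: _sd_batch_loss(model, train_items, idx, feature_noise=noise)
        val_loss_fn = lambda: _eval_loss(
            lambda idx: _sd_batch_loss(model, val_items, idx), len(val_items), cfg.batch_size)
    else:
        order = dataset.solvent_names
        train_items = train_mols
        batch_loss = lambda idx: _vs_batch_loss(model, train_mols, order, idx)
        val_loss_fn = lambda: _eval_loss(
            lambda idx: _vs_batch_loss(model, val_mols, order, idx), len(val_mols), cfg.batch_size)

    # set output normalization from training targets: at initialization the
    # model then predicts the training means, which conditions optimization
    if variant == "SD":
        e_red = np.array([r[2] for r in train_items])
        eas = np.array([r[3] for r in train_items if r[3] is not None])
        ea_c = float(eas.mean()) if len(eas) else float(e_red.mean())
        model.set_output_normalization(float(e_red.std()), ea_c,
                                       float(e_red.mean()) - ea_c)
    else:
        order = dataset.solvent_names
        pc = np.zeros(len(order))
        allv = []
        for c, sname in enumerate(order):
            vals = [m.potentials[sname] for m in train_mols if sname in m.potentials]
            pc[c] = np.mean(vals) if vals else 0.0
            allv += vals
        eas = np.array([m.ea for m in train_mols if m.ea is not None])
        ea_c = float(eas.mean()) if len(eas) else float(np.mean(allv))
        model.set_output_normalization(float(np.std(allv)) if allv else 1.0,
                                       ea_c, pot_center=pc)

    history: list[dict[str, float]] = []
    if cfg.epochs == 0:
        return model, history

    opt = AdamW(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    swa_state: list[np.ndarray] | None = None
    swa_n = 0
    n_items = len(train_items)

    for epoch in range(cfg.epochs):
        if cfg.lr_decay == "cosine":
            frac = epoch / max(cfg.epochs - 1, 1)
            opt.lr = cfg.learning_rate * (0.1 + 0.9 * 0.5 * (1 + math.cos(math.pi * frac)))
        perm = rng.permutation(n_items)
        epoch_loss = 0.0
        n_batches = 0
        for k in range(0, n_items, cfg.batch_size):
            idx = perm[k:k + cfg.batch_size]
            loss = batch_loss(idx)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            if cfg.clip_norm is not None:
                _clip_grad_norm(model.parameters(), cfg.clip_norm)
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val = val_loss_fn()
        history.append({"train_loss": epoch_loss / max(n_batches, 1), "val_loss": val})
        if val < best_val:
            best_val = val
            best_state = [p.data.copy() for p in model.parameters()]
        if cfg.swa_fraction > 0 and epoch >= cfg.epochs * (1.0 - cfg.swa_fraction):
            if swa_state is None:
                swa_state = [p.data.copy() for p in model.parameters()]
                swa_n = 1
            else:
                swa_n += 1
                for acc, p in zip(swa_state, model.parameters()):
                    acc += (p.data - acc) / swa_n

    if swa_state is not None:
        for p, w in zip(model.parameters(), swa_state):
            p.data = w.copy()
        swa_val = val_loss_fn()
        if swa_val < best_val:
            best_state = swa_state
    if best_state is not None:
        for p, w in zip(model.parameters(), best_state):
            p.data = w
    return model, history


def _clip_grad_norm(params, max_norm: float) -> None:
    total = math.sqrt(sum(float((p.grad ** 2).sum())
                          for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def _eval_loss(batch_loss_fn, n_items: int, batch_size: int) -> float:
    total = 0.0
    count = 0
    for k in range(0, n_items, batch_size):
        idx = np.arange(k, min(k + batch_size, n_items))
        total += float(batch_loss_fn(idx).data)
        count += 1
    return total / max(count, 1)


@dataclass
class Metrics:
    """MAE/R2 over a partition, with the per-solvent breakdown.

    ``r2`` is the unweighted mean of the per-solvent coefficients of
    determination (R2 = 1 - SS_res/SS_tot); ``r2_pooled`` treats all records
    as one set.  R2 is None where targets are constant (SS_tot = 0).
    """

    mae: float
    r2: float | None
    n: int
    per_solvent: dict[str, dict[str, float | None]]
    r2_pooled: float | None = None


def _r2(pred: np.ndarray, true: np.ndarray) -> float | None:
    ss_tot = float(((true - true.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return None
    ss_res = float(((true - pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def evaluate(model: RedoxMPNN, dataset: RedoxDataset, ids: set[str] | None = None,
             solvents: list[str] | None = None, batch_size: int = 64) -> Metrics:
    """Per-solvent MAE and R2 on the given molecule ids (default: all)."""
    mols = dataset.molecules if ids is None else dataset.subset(ids)
    if not mols:
        raise ValueError("empty evaluation partition")
    solvent_names = solvents or dataset.solvent_names

    preds: dict[str, list[float]] = {s: [] for s in solvent_names}
    trues: dict[str, list[float]] = {s: [] for s in solvent_names}

    if model.config.variant == "SD":
        records = build_sd_records(mols, dataset.solvents, model.config.descriptor_scheme)
        records = [r for r in records if r[4] in solvent_names]
        for k in range(0, len(records), batch_size):
            chunk = records[k:k + batch_size]
            out = model.forward_batch([r[0] for r in chunk],
                                      np.stack([r[1] for r in chunk]))
            for (g, d, pot, ea, sname), p in zip(chunk, out["e_red"].data[:, 0]):
                preds[sname].append(float(p))
                trues[sname].append(pot)
    else:
        order = dataset.solvent_names
        for k in range(0, len(mols), batch_size):
            chunk = mols[k:k + batch_size]
            out = model.forward_batch([m.graph for m in chunk])
            for m, row in zip(chunk, out["potentials"].data):
                for c, sname in enumerate(order):
                    if sname in solvent_names and sname in m.potentials:
                        preds[sname].append(float(row[c]))
                        trues[sname].append(m.potentials[sname])

    per_solvent: dict[str, dict[str, float | None]] = {}
    all_p: list[float] = []
    all_t: list[float] = []
    r2s: list[float] = []
    for sname in solvent_names:
        p = np.asarray(preds[sname]); t = np.asarray(trues[sname])
        if len(p) == 0:
            continue
        r2 = _r2(p, t)
        per_solvent[sname] = {"mae": float(np.abs(p - t).mean()), "r2": r2, "n": len(p)}
        if r2 is not None:
            r2s.append(r2)
        all_p += list(p); all_t += list(t)
    if not all_p:
        raise ValueError("no evaluable records in partition")
    ap, at = np.asarray(all_p), np.asarray(all_t)
    return Metrics(
        mae=float(np.abs(ap - at).mean()),
        r2=float(np.mean(r2s)) if r2s else None,
        n=len(ap),
        per_solvent=per_solvent,
        r2_pooled=_r2(ap, at),
    )


def loso_protocol(dataset: RedoxDataset, withheld_solvent: str, cfg: TrainConfig,
                  model_config: ModelConfig | None = None,
                  split: SplitAssignment | None = None) -> Metrics:
    """Leave-one-solvent-out: train without one solvent, evaluate only in it.

    Every record of ``withheld_solvent`` is removed from the training and
    validation streams; the returned metrics cover only withheld-solvent
    records of test-partition molecules.
    """
    if withheld_solvent not in dataset.solvents:
        raise KeyError(f"withheld solvent {withheld_solvent!r} absent from dataset")
    if len(dataset.solvents) < 2:
        raise ValueError("LOSO requires at least two solvents")
    mc = model_config or ModelConfig(variant="SD", seed=cfg.seed)
    if mc.variant != "SD":
        raise ValueError("LOSO requires the solvent-descriptor (SD) variant")
    model = RedoxMPNN(mc)
    ids = [m.id for m in dataset.molecules]
    split = split or split_molecules(ids, cfg.ratios, cfg.seed)
    model, _ = train(model, dataset, split, cfg, exclude_solvent=withheld_solvent)
    test_ids = {i for i, part in split.items() if part == "test"}
    return evaluate(model, dataset, test_ids, solvents=[withheld_solvent])
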