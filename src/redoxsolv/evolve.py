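"""Evolutionary inverse design of molecules with targeted reduction potentials.

A mutation-only (mu+lambda) elitist loop over molecular graphs: each
generation mutates the current population (adding/removing atoms, changing
bond orders, substituting atom types, moving terminal groups), keeps only
chemically valid, constraint-satisfying and synthetically accessible
offspring, scores them with an ensemble of predictors through a windowed
sigmoid objective, and selects the top scorers.  A candidate is *accepted*
only when every ensemble member predicts a potential inside the target
window — the ensemble acts as an implicit uncertainty filter.

The window objective is f(x) = sigma(k(x - lo)) - sigma(k(x - hi)) with
logistic sigma and steepness k: ~1 deep inside [lo, hi], ~0 far outside,
0.5 at the edges.  The default k = 50/V keeps the score at ~1 at the
midpoint of even a 0.25 V window, the narrowest application preset.
"""

from __future__ import annotations

import math
import os
import sys
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem

from redoxsolv.chemgraph import MolGraph, featurize
from redoxsolv.solventdb import SolventSpec

__all__ = [
    "TargetWindow", "EvolutionConfig", "Candidate", "Rejection", "ObjectiveResult",
    "window_score", "sa_gate", "mutate", "ensemble_objective", "evolve_loop",
    "APPLICATION_WINDOWS", "MUTATION_ACTIONS",
]

_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "S": 2, "Cl": 1, "Br": 1}

MUTATION_ACTIONS = ("add_atom", "remove_atom", "change_bond",
                    "substitute_atom", "move_group")

#: Experimentally motivated target windows (volts, vs the named reference).
#: Conversion to the absolute scale goes through solventdb electrode offsets.
APPLICATION_WINDOWS = {
    "PEDOT": {"lo": -0.90, "hi": -0.19, "reference": "Fc", "solvent": "ACN"},
    "PPT": {"lo": -2.24, "hi": -1.99, "reference": "Fc", "solvent": "ACN"},
    "LI_ION_ADDITIVE": {"lo": 2.5, "hi": 3.5, "reference": "Li", "solvent": "DMSO"},
    "RFB_ANOLYTE": {"lo": -0.4, "hi": 0.2, "reference": "SHE", "solvent": "H2O"},
}


@dataclass(frozen=True)
class TargetWindow:
    """Absolute-potential interval [lo, hi] with sigmoid steepness (1/V)."""

    lo: float
    hi: float
    steepness: float = 50.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi


@dataclass
class EvolutionConfig:
    max_heavy_atoms: int = 15
    allowed_elements: frozenset[str] = frozenset({"C", "N", "O", "F", "S", "Cl", "Br"})
    sa_threshold: float = 4.5
    population_size: int = 20
    max_generations: int = 50
    n_children: int = 2              # mutation attempts per parent per generation
    time_limit: float | None = None  # seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_heavy_atoms < 1:
            raise ValueError("max_heavy_atoms must be >= 1")
        if not self.allowed_elements:
            raise ValueError("allowed_elements must be non-empty")


@dataclass
class Candidate:
    smiles: str
    ensemble_predictions: list[float]
    score: float
    sa_score: float
    generation: int
    parent: str | None = None


@dataclass(frozen=True)
class Rejection:
    reason: str


@dataclass
class ObjectiveResult:
    score: float
    accept: bool
    predictions: list[float] = field(default_factory=list)
    reason: str | None = None


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def window_score(x: float, w: TargetWindow) -> float:
    """Sigmoid/(1 - sigmoid) combination: ~1 in the window, ~0 outside."""
    if not math.isfinite(x):
        raise ValueError("potential must be finite")
    k = w.steepness
    return _sigmoid(k * (x - w.lo)) - _sigmoid(k * (x - w.hi))


# -- synthetic accessibility ------------------------------------------------

_sascorer = None


def _load_sascorer():
    """RDKit-contributed fragment-contribution SA score implementation."""
    global _sascorer
    if _sascorer is None:
        from rdkit.Chem import RDConfig
        sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
        import sascorer
        _sascorer = sascorer
    return _sascorer


def sa_gate(mol: MolGraph | str, threshold: float = 4.5) -> tuple[bool, float]:
    """Synthetic-accessibility gate: pass iff SA score <= threshold.

    The score runs from ~1 (easy to make) to ~10 (hard), combining fragment
    contributions with a complexity penalty; deterministic per canonical
    SMILES.
    """
    smiles = mol.smiles if isinstance(mol, MolGraph) else mol
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        return False, float("inf")
    score = float(_load_sascorer().calculateScore(m))
    return score <= threshold, score


# -- mutations ---------------------------------------------------------------

def _free_valence(mol: Chem.Mol, idx: int) -> int:
    a = mol.GetAtomWithIdx(idx)
    cap = _VALENCE.get(a.GetSymbol(), 0)
    used = int(sum(b.GetBondTypeAsDouble() for b in a.GetBonds()))
    return cap - used


def _finalize(rw: Chem.RWMol, cfg: EvolutionConfig) -> MolGraph | Rejection:
    try:
        m = rw.GetMol()
        Chem.SanitizeMol(m)
        smi = Chem.MolToSmiles(m)
    except Exception as exc:
        return Rejection(f"invalid chemistry: {exc}")
    if "." in smi:
        return Rejection("disconnected product")
    g = featurize(smi)
    if g.n_heavy > cfg.max_heavy_atoms:
        return Rejection(f"size: {g.n_heavy} > {cfg.max_heavy_atoms} heavy atoms")
    bad = {g.vocabulary[a.element_index] for a in g.nodes} - set(cfg.allowed_elements)
    if bad:
        return Rejection(f"element(s) outside allowed set: {sorted(bad)}")
    return g


def mutate(g: MolGraph, action: str, cfg: EvolutionConfig,
           rng: np.random.Generator | None = None) -> MolGraph | Rejection:
    """Apply one graph-edit action; rejection is a return value, not an error."""
    if action not in MUTATION_ACTIONS:
        raise ValueError(f"unknown action {action!r}; choose from {MUTATION_ACTIONS}")
    rng = rng or np.random.default_rng()
    mol = Chem.MolFromSmiles(g.smiles)
    if mol is None:
        return Rejection("parent SMILES failed to parse")
    Chem.Kekulize(mol, clearAromaticFlags=True)  # edit on the kekulized graph
    rw = Chem.RWMol(mol)
    elements = sorted(cfg.allowed_elements)

    if action == "add_atom":
        if rw.GetNumAtoms() >= cfg.max_heavy_atoms:
            return Rejection(f"size: adding an atom exceeds {cfg.max_heavy_atoms} heavy atoms")
        anchors = [i for i in range(rw.GetNumAtoms()) if _free_valence(rw, i) >= 1]
        if not anchors:
            return Rejection("no atom with free valence")
        a = int(anchors[rng.integers(len(anchors))])
        el = str(elements[rng.integers(len(elements))])
        j = rw.AddAtom(Chem.Atom(el))
        rw.AddBond(a, j, Chem.BondType.SINGLE)

    elif action == "remove_atom":
        if rw.GetNumAtoms() <= 1:
            return Rejection("removal would empty the graph")
        terminals = [a.GetIdx() for a in rw.GetAtoms() if a.GetDegree() == 1]
        if not terminals:
            return Rejection("no removable terminal atom")
        rw.RemoveAtom(int(terminals[rng.integers(len(terminals))]))

    elif action == "change_bond":
        if rw.GetNumBonds() == 0:
            return Rejection("no bonds to change")
        b = rw.GetBondWithIdx(int(rng.integers(rw.GetNumBonds())))
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if b.GetBondType() == Chem.BondType.SINGLE:
            if _free_valence(rw, i) >= 1 and _free_valence(rw, j) >= 1:
                b.SetBondType(Chem.BondType.DOUBLE)
            else:
                return Rejection("no valence capacity for bond-order increase")
        else:
            b.SetBondType(Chem.BondType.SINGLE)

    elif action == "substitute_atom":
        a = rw.GetAtomWithIdx(int(rng.integers(rw.GetNumAtoms())))
        used = int(sum(b.GetBondTypeAsDouble() for b in a.GetBonds()))
        options = [e for e in elements
                   if e != a.GetSymbol() and _VALENCE[e] >= used]
        if not options:
            return Rejection("no element fits the current bonding")
        a.SetAtomicNum(Chem.Atom(str(options[rng.integers(len(options))])).GetAtomicNum())

    elif action == "move_group":
        terminals = [a.GetIdx() for a in rw.GetAtoms()
                     if a.GetDegree() == 1 and rw.GetNumAtoms() > 2]
        if not terminals:
            return Rejection("no terminal group to move")
        t = int(terminals[rng.integers(len(terminals))])
        old_anchor = rw.GetAtomWithIdx(t).GetNeighbors()[0].GetIdx()
        targets = [i for i in range(rw.GetNumAtoms())
                   if i not in (t, old_anchor) and _free_valence(rw, i) >= 1]
        if not targets:
            return Rejection("no reattachment site with free valence")
        new_anchor = int(targets[rng.integers(len(targets))])
        rw.RemoveBond(t, old_anchor)
        rw.AddBond(t, new_anchor, Chem.BondType.SINGLE)

    return _finalize(rw, cfg)


# -- objective ---------------------------------------------------------------

def ensemble_objective(mol: MolGraph | str, models: Sequence, solvent: SolventSpec,
                       window: TargetWindow) -> ObjectiveResult:
    """Mean window score over ensemble members; accept iff all in-window.

    ``models`` are SD-variant predictors sharing the featurization; a member
    failing on the molecule yields accept=False with the failure reason.
    """
    if not models:
        raise ValueError("ensemble must contain at least one model")
    g = mol if isinstance(mol, MolGraph) else featurize(mol)
    preds: list[float] = []
    for m in models:
        try:
            preds.append(float(m.forward_sd(g, solvent).reduction_potential))
        except Exception as exc:
            return ObjectiveResult(score=0.0, accept=False, predictions=preds,
                                   reason=f"model failure: {exc}")
    score = float(np.mean([window_score(p, window) for p in preds]))
    accept = all(window.contains(p) for p in preds)
    return ObjectiveResult(score=score, accept=accept, predictions=preds)


def evolve_loop(seeds: Sequence[str], cfg: EvolutionConfig,
                objective: Callable[[MolGraph], ObjectiveResult],
                ) -> tuple[list[Candidate], list[dict]]:
    """(mu+lambda) elitist evolution from seed molecules.

    Returns accepted candidates (all ensemble members in-window), ranked by
    score then SA score and de-duplicated by canonical SMILES, plus
    per-generation statistics.  Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    population: dict[str, Candidate] = {}
    accepted: dict[str, Candidate] = {}
    t0 = time.monotonic()

    def consider(g: MolGraph, generation: int, parent: str | None) -> None:
        if g.smiles in population:
            return
        ok, sa = sa_gate(g, cfg.sa_threshold)
        if not ok:
            return
        res = objective(g)
        cand = Candidate(smiles=g.smiles, ensemble_predictions=list(res.predictions),
                         score=res.score, sa_score=sa, generation=generation,
                         parent=parent)
        population[g.smiles] = cand
        if res.accept:
            accepted.setdefault(g.smiles, cand)

    n_valid_seeds = 0
    for smi in seeds:
        try:
            g = featurize(smi)
        except Exception:
            continue
        check = _finalize(Chem.RWMol(Chem.MolFromSmiles(g.smiles)), cfg)
        if isinstance(check, Rejection):
            continue
        consider(g, generation=0, parent=None)
        n_valid_seeds += 1
    if n_valid_seeds == 0:
        raise ValueError("no valid, constraint-satisfying seed molecules")

    history: list[dict] = []
    for gen in range(1, cfg.max_generations + 1):
        if cfg.time_limit is not None and time.monotonic() - t0 > cfg.time_limit:
            break
        parents = sorted(population.values(),
                         key=lambda c: (-c.score, c.sa_score, c.smiles))
        parents = parents[:cfg.population_size]
        population = {c.smiles: c for c in parents}
        for parent in parents:
            pg = featurize(parent.smiles)
            for _ in range(cfg.n_children):
                action = MUTATION_ACTIONS[rng.integers(len(MUTATION_ACTIONS))]
                child = mutate(pg, action, cfg, rng)
                if isinstance(child, Rejection):
                    continue
                consider(child, generation=gen, parent=parent.smiles)
        history.append({
            "generation": gen,
            "population": len(population),
            "accepted": len(accepted),
            "best_score": max((c.score for c in population.values()), default=0.0),
        })
        if cfg.time_limit is not None and time.monotonic() - t0 > cfg.time_limit:
            break

    ranked = sorted(accepted.values(), key=lambda c: (-c.score, c.sa_score, c.smiles))
    return ranked, history
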