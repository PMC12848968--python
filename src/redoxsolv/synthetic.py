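"""Synthetic molecules, ground-truth potentials and curation fixtures.

Everything the toolkit needs for end-to-end exercise without quantum
chemistry or downloads: random valid molecules, a solvent-dependent
ground-truth potential surface with known parameters, and curation records
engineered to trip each stability filter.

The ground truth mimics the physics the solvent-descriptor model must
learn: a solvent-independent electron-affinity term linear in molecular
count features, plus a Born-like reaction-field term in (1 - 1/epsilon)
and a smaller electronic-polarizability term in (n^2 - 1)/(n^2 + 2), both
scaled by a molecule-dependent charge-localization factor.  Because the
solvent enters only through smooth functions of (epsilon, n), zero-shot
generalization to an unseen solvent is genuinely learnable from the two
descriptors.  Noise is homoscedastic Gaussian; the error structure of real
DFT data is not emulated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from redoxsolv.chemgraph import DEFAULT_VOCABULARY, MolGraph, featurize
from redoxsolv.curation import SpeciesRecord
from redoxsolv.solventdb import SolventSpec
from redoxsolv.training import MoleculeData, RedoxDataset

__all__ = [
    "SyntheticTruth", "count_features", "gen_molecules", "synth_potential",
    "gen_dataset", "gen_curation_fixtures", "SYNTHETIC_SOLVENTS",
]

RDLogger.DisableLog("rdApp.*")

_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "S": 2, "Cl": 1, "Br": 1}

#: Five synthetic training solvents plus a sixth for leave-one-out tests;
#: (epsilon, n) values span the realistic polar-solvent range.
SYNTHETIC_SOLVENTS: dict[str, SolventSpec] = {
    "ACN": SolventSpec("ACN", 35.9, 1.344),
    "H2O": SolventSpec("H2O", 78.4, 1.333),
    "THF": SolventSpec("THF", 7.4, 1.407),
    "DMSO": SolventSpec("DMSO", 46.8, 1.479),
    "DMF": SolventSpec("DMF", 36.7, 1.430),
    "SYN6": SolventSpec("SYN6", 20.5, 1.386),
}


@dataclass
class SyntheticTruth:
    """Known parameters of the synthetic potential surface.

    ``ea_weights`` has one coefficient per count feature (eV per unit);
    ``solv_weight`` scales the Born-like (1 - 1/epsilon) term and
    ``n_weight`` the refractive-index term.
    """

    ea_weights: np.ndarray = field(default_factory=lambda: np.array(
        # per-element counts (H C N O F S Cl Br), then bonds, aromatic atoms
        [0.0, 0.06, 0.18, 0.25, 0.32, 0.14, 0.20, 0.28, 0.04, 0.05]))
    ea_intercept: float = 0.5
    solv_weight: float = 2.0
    n_weight: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.ea_weights = np.asarray(self.ea_weights, dtype=np.float64)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def count_features(g: MolGraph) -> np.ndarray:
    """Element counts over the vocabulary, bond count, aromatic-atom count."""
    counts = np.zeros(len(g.vocabulary) + 2)
    for a in g.nodes:
        counts[a.element_index] += 1
        if a.aromatic:
            counts[-1] += 1
    counts[-2] = len(g.edges)
    return counts


def _charge_localization(g: MolGraph) -> float:
    """Molecule-dependent scaling of the reaction-field terms, in (0, 1]."""
    carbon = g.vocabulary.index("C") if "C" in g.vocabulary else -1
    n_hetero = sum(1 for a in g.nodes
                   if a.element_index != carbon and g.vocabulary[a.element_index] != "H")
    return (1.0 + n_hetero) / (1.0 + g.n_heavy)


def synth_potential(g: MolGraph, s: SolventSpec, t: SyntheticTruth) -> tuple[float, float]:
    """Ground-truth (EA, E_red) in eV for one molecule in one solvent.

    Deterministic: the noise draw is seeded from the truth seed and the
    (canonical SMILES, solvent name) pair, so repeated calls agree exactly.
    """
    f = count_features(g)
    if len(f) != len(t.ea_weights):
        raise ValueError("ea_weights length does not match count features")
    ea = t.ea_intercept + float(t.ea_weights @ f)
    q = _charge_localization(g)
    born = t.solv_weight * q * (1.0 - 1.0 / s.epsilon)
    n2 = s.refractive_index ** 2
    pol = t.n_weight * q * (n2 - 1.0) / (n2 + 2.0)
    e_red = ea + born + pol
    if t.noise_sd > 0:
        tag = zlib.crc32(f"{g.smiles}|{s.name}".encode()) & 0x7FFFFFFF
        rng = np.random.default_rng((t.seed, tag))
        e_red += float(rng.normal(0.0, t.noise_sd))
    return ea, e_red


def gen_molecules(n: int, max_heavy: int = 12,
                  elements: tuple[str, ...] = ("C", "N", "O", "F", "S", "Cl", "Br"),
                  seed: int = 0) -> list[str]:
    """Generate ``n`` unique, valid, single-fragment SMILES.

    Molecules are grown as random trees with occasional ring closures and
    double bonds, respecting element valences; results are deduplicated by
    canonical SMILES and deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    bad = [e for e in elements if e not in _VALENCE]
    if bad:
        raise ValueError(f"unsupported element(s) for generation: {bad}")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    max_attempts = 400 * n
    # element frequencies roughly matching organic redox compounds:
    # carbon-dominated skeletons with sparse heteroatoms and rare halogens
    _FREQ = {"C": 0.70, "N": 0.09, "O": 0.12, "F": 0.03, "S": 0.04,
             "Cl": 0.015, "Br": 0.005}
    weights = np.array([_FREQ.get(e, 0.05) for e in elements])
    weights /= weights.sum()
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not generate {n} unique molecules within {max_attempts} attempts")
        size = int(rng.integers(1, max_heavy + 1))
        smi = _grow_molecule(size, elements, weights, rng)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        out.append(smi)
    return out


def _grow_molecule(size, elements, weights, rng) -> str | None:
    mol = Chem.RWMol()
    free: list[int] = []  # remaining valence per atom index
    first = str(rng.choice(elements, p=weights))
    mol.AddAtom(Chem.Atom(first))
    free.append(_VALENCE[first])
    for _ in range(size - 1):
        anchors = [i for i, v in enumerate(free) if v >= 1]
        if not anchors:
            break
        a = int(anchors[rng.integers(len(anchors))])
        el = str(rng.choice(elements, p=weights))
        j = mol.AddAtom(Chem.Atom(el))
        free.append(_VALENCE[el])
        double = (free[a] >= 2 and free[j] >= 2 and rng.random() < 0.15)
        order = Chem.BondType.DOUBLE if double else Chem.BondType.SINGLE
        mol.AddBond(a, j, order)
        dec = 2 if double else 1
        free[a] -= dec
        free[j] -= dec
    # optional ring closure between non-bonded atoms with free valence
    if mol.GetNumAtoms() >= 5 and rng.random() < 0.5:
        cands = [i for i, v in enumerate(free) if v >= 1]
        rng.shuffle(cands)
        for a in cands:
            for b in cands:
                if b > a and mol.GetBondBetweenAtoms(a, b) is None:
                    path = Chem.GetShortestPath(mol, a, b)
                    if len(path) >= 3:  # ring size >= 3
                        mol.AddBond(a, b, Chem.BondType.SINGLE)
                        free[a] -= 1
                        free[b] -= 1
                        break
            else:
                continue
            break
    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        smi = Chem.MolToSmiles(m)
    except Exception:
        return None
    if "." in smi:
        return None
    return smi


def gen_dataset(n_mol: int, solvents: dict[str, SolventSpec] | None = None,
                truth: SyntheticTruth | None = None, max_heavy: int = 12,
                seed: int | None = None) -> tuple[RedoxDataset, SyntheticTruth]:
    """Full synthetic training table: EA plus per-solvent potentials.

    Returns the in-memory dataset alongside the truth object so parameter-
    recovery checks can compare against exact ground truth.
    """
    truth = truth or SyntheticTruth()
    if seed is not None:
        truth.seed = seed
    if solvents is None:
        solvents = {k: v for k, v in SYNTHETIC_SOLVENTS.items() if k != "SYN6"}
    if len(solvents) < 2:
        raise ValueError("need at least two solvents")
    smiles = gen_molecules(n_mol, max_heavy=max_heavy, seed=truth.seed)
    molecules = []
    for i, smi in enumerate(smiles):
        g = featurize(smi)
        pots = {}
        ea = None
        for name, spec in solvents.items():
            ea, e_red = synth_potential(g, spec, truth)
            pots[name] = e_red
        molecules.append(MoleculeData(id=f"mol{i:05d}", graph=g, ea=ea, potentials=pots))
    return RedoxDataset(molecules=molecules, solvents=dict(solvents)), truth


def write_dataset_csv(dataset: RedoxDataset, path: str | Path) -> None:
    """Write the (id, smiles, ea, per-solvent) table consumed by training."""
    names = dataset.solvent_names
    lines = ["id,smiles,ea," + ",".join(names)]
    for m in dataset.molecules:
        pots = ",".join(f"{m.potentials.get(s, float('nan')):.6f}" for s in names)
        lines.append(f"{m.id},{m.graph.smiles},{m.ea:.6f},{pots}")
    Path(path).write_text("\n".join(lines) + "\n")


def gen_curation_fixtures(seed: int = 0) -> tuple[list[SpeciesRecord], dict[str, str | None]]:
    """Ten curation records: six clean, four tripping one filter each.

    Returns the records plus the expected outcome per molecule id
    (``None`` for kept, otherwise the removal tag).
    """
    rng = np.random.default_rng(seed)

    def pair(stretch: float) -> tuple[np.ndarray, np.ndarray]:
        parent = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.2, 0.0]])
        reduced = parent.copy()
        reduced[1, 0] = 1.0 * (1.0 + stretch)
        return parent, reduced

    def clean(mid: str) -> SpeciesRecord:
        p, r = pair(float(rng.uniform(0.0, 0.15)))
        return SpeciesRecord(
            molecule_id=mid, parent_geometry=p, reduced_geometry=r,
            elements=["C", "C", "O"], bonds=[(0, 1), (1, 2)],
            frequencies=[float(rng.uniform(50, 3000)) for _ in range(4)],
            s_squared=float(rng.uniform(0.75, 0.79)), multiplicity=2,
            bulk_electrostatic=float(rng.uniform(-3.5, -0.3)))

    records: list[SpeciesRecord] = []
    expected: dict[str, str | None] = {}

    for i in range(3):
        rec = clean(f"clean{i}")
        records.append(rec)
        expected[rec.molecule_id] = None

    p, r = pair(0.50)
    rec = clean("bond_breaker")
    rec.parent_geometry, rec.reduced_geometry = p, r
    records.append(rec)
    expected[rec.molecule_id] = "bond_change"

    rec = clean("spin_contaminated")
    rec.s_squared = 0.86  # doublet: 0.86/0.75 - 1 = 14.7% deviation
    records.append(rec)
    expected[rec.molecule_id] = "spin_contamination"

    for i in range(2):
        rec = clean(f"clean{3 + i}")
        records.append(rec)
        expected[rec.molecule_id] = None

    rec = clean("saddle_point")
    rec.frequencies = [-25.0, 120.0, 900.0]
    records.append(rec)
    expected[rec.molecule_id] = "imaginary_frequency"

    rec = clean("electrostatic_outlier")
    rec.bulk_electrostatic = -5.0
    records.append(rec)
    expected[rec.molecule_id] = "electrostatic_range"

    rec = clean("clean5")
    records.append(rec)
    expected[rec.molecule_id] = None

    return records, expected
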