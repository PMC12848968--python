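"""SMILES to featurized molecular graph conversion.

Molecules are heavy-atom graphs (hydrogens implicit).  Each atom carries a
categorical element index plus topological and tabulated-property features:
number of heavy-atom neighbors, ring membership, aromaticity, atomic mass,
van der Waals radius, covalent radius and valence.  Mass and radii are
min-max scaled over the element vocabulary with constants frozen below.
Bonds carry a bond-type category (single/double/triple/aromatic),
conjugation and ring membership.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

__all__ = [
    "DEFAULT_VOCABULARY",
    "AtomNode",
    "BondEdge",
    "MolGraph",
    "featurize",
    "read_molecule_table",
    "to_directed",
    "SmilesParseError",
    "VocabularyError",
]

log = logging.getLogger(__name__)

#: Default element vocabulary: the generated-molecule element set plus H.
DEFAULT_VOCABULARY: tuple[str, ...] = ("H", "C", "N", "O", "F", "S", "Cl", "Br")

# Atomic masses (u), Bondi van der Waals radii and Pyykko covalent radii (A),
# frozen so the min-max scaling never drifts with library versions.
_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
         "S": 32.06, "Cl": 35.45, "Br": 79.904, "P": 30.974, "I": 126.904}
_VDW = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
        "S": 1.80, "Cl": 1.75, "Br": 1.85, "P": 1.80, "I": 1.98}
_COV = {"H": 0.32, "C": 0.75, "N": 0.71, "O": 0.63, "F": 0.64,
        "S": 1.03, "Cl": 0.99, "Br": 1.14, "P": 1.11, "I": 1.33}

_BOND_TYPES = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}
N_BOND_TYPES = 4


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class VocabularyError(ValueError):
    """Raised when a molecule contains an element outside the vocabulary."""


@dataclass(frozen=True)
class AtomNode:
    element_index: int
    n_heavy_neighbors: int
    in_ring: bool
    aromatic: bool
    mass_scaled: float
    vdw_radius_scaled: float
    covalent_radius_scaled: float
    valence: int


@dataclass(frozen=True)
class BondEdge:
    endpoints: tuple[int, int]
    bond_type: int
    conjugated: bool
    in_ring: bool


@dataclass
class MolGraph:
    """Featurized heavy-atom molecular graph with SMILES provenance.

    Edges are stored undirected once each; :func:`to_directed` expands them
    to both directions for message passing.
    """

    smiles: str
    nodes: list[AtomNode]
    edges: list[BondEdge]
    vocabulary: tuple[str, ...] = field(default=DEFAULT_VOCABULARY)

    @property
    def n_heavy(self) -> int:
        return len(self.nodes)

    def node_features(self) -> np.ndarray:
        """(n_nodes, n_vocab + 6) float array: one-hot element then numerics."""
        nv = len(self.vocabulary)
        out = np.zeros((len(self.nodes), nv + 6), dtype=np.float64)
        for i, a in enumerate(self.nodes):
            out[i, a.element_index] = 1.0
            out[i, nv:] = (
                a.n_heavy_neighbors / 4.0,
                float(a.in_ring),
                float(a.aromatic),
                a.mass_scaled,
                a.vdw_radius_scaled,
                a.covalent_radius_scaled,
            )
        # valence folded in as an extra scaled column appended below
        val = np.array([a.valence / 6.0 for a in self.nodes])[:, None]
        return np.concatenate([out, val], axis=1)

    def edge_features(self) -> np.ndarray:
        """(n_edges, 6) float array: one-hot bond type, conjugated, in_ring."""
        out = np.zeros((len(self.edges), N_BOND_TYPES + 2), dtype=np.float64)
        for i, b in enumerate(self.edges):
            out[i, b.bond_type] = 1.0
            out[i, N_BOND_TYPES] = float(b.conjugated)
            out[i, N_BOND_TYPES + 1] = float(b.in_ring)
        return out


def _scaled(table: dict[str, float], sym: str, vocab: tuple[str, ...]) -> float:
    vals = [table[s] for s in vocab]
    lo, hi = min(vals), max(vals)
    return (table[sym] - lo) / (hi - lo) if hi > lo else 0.0


def featurize(smiles: str, vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY) -> MolGraph:
    """Parse a SMILES string and extract the atom/bond feature graph.

    Raises :class:`SmilesParseError` for unparsable input,
    :class:`VocabularyError` for out-of-vocabulary elements, and
    ``ValueError`` for multi-fragment (salt) input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValueError(f"multi-fragment SMILES rejected: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)

    for t in (_MASS, _VDW, _COV):
        missing = [s for s in vocabulary if s not in t]
        if missing:
            raise VocabularyError(f"no tabulated properties for element(s) {missing}")

    index = {s: i for i, s in enumerate(vocabulary)}
    nodes: list[AtomNode] = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in index:
            raise VocabularyError(
                f"element {sym!r} in {smiles!r} outside vocabulary {vocabulary}"
            )
        nodes.append(AtomNode(
            element_index=index[sym],
            n_heavy_neighbors=sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1),
            in_ring=atom.IsInRing(),
            aromatic=atom.GetIsAromatic(),
            mass_scaled=_scaled(_MASS, sym, vocabulary),
            vdw_radius_scaled=_scaled(_VDW, sym, vocabulary),
            covalent_radius_scaled=_scaled(_COV, sym, vocabulary),
            valence=atom.GetTotalValence(),
        ))

    edges: list[BondEdge] = []
    for bond in mol.GetBonds():
        bt = _BOND_TYPES.get(bond.GetBondType())
        if bt is None:
            raise ValueError(f"unsupported bond type {bond.GetBondType()} in {smiles!r}")
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append(BondEdge(
            endpoints=(i, j),
            bond_type=bt,
            conjugated=bond.GetIsConjugated(),
            in_ring=bond.IsInRing(),
        ))

    return MolGraph(smiles=canonical, nodes=nodes, edges=edges, vocabulary=tuple(vocabulary))


def to_directed(g: MolGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand undirected edges to both directions.

    Returns ``(src, dst, edge_index)`` integer arrays of length 2*n_edges;
    the two directions of one chemical bond share one ``edge_index`` into
    ``g.edge_features()``.
    """
    src, dst, eidx = [], [], []
    for k, b in enumerate(g.edges):
        i, j = b.endpoints
        src += [i, j]
        dst += [j, i]
        eidx += [k, k]
    return (np.asarray(src, dtype=np.int64),
            np.asarray(dst, dtype=np.int64),
            np.asarray(eidx, dtype=np.int64))


def read_molecule_table(path: str | Path) -> list[tuple[str, str, dict[str, float]]]:
    """Read an (id, smiles, targets...) CSV table.

    Rows whose SMILES fail to parse are skipped with a logged count.  Target
    columns are every column other than ``id`` and ``smiles``; empty cells
    become missing targets (absent keys).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a CSV header")
        cols = [c.strip() for c in reader.fieldnames]
        if "id" not in cols or "smiles" not in cols:
            raise ValueError(f"{path}: header must name 'id' and 'smiles', got {cols}")
        target_cols = [c for c in cols if c not in ("id", "smiles")]
        records: list[tuple[str, str, dict[str, float]]] = []
        n_skipped = 0
        for row in reader:
            smi = row["smiles"].strip()
            if Chem.MolFromSmiles(smi) is None:
                n_skipped += 1
                continue
            targets = {c: float(row[c]) for c in target_cols
                       if row.get(c) not in (None, "", "NA", "nan")}
            records.append((row["id"].strip(), smi, targets))
    if n_skipped:
        log.warning("%s: skipped %d row(s) with unparsable SMILES", path, n_skipped)
    return records
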