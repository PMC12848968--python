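"""Stability and sanity filters for DFT-derived redox records.

A candidate (parent, reduced) species pair survives curation only if:

* no bond stretches or contracts by more than 40% upon one-electron
  reduction (larger changes indicate rearrangement or decomposition);
* open-shell species show <S^2> within 10% of the single-reference value
  S(S+1) (larger deviations indicate spin contamination);
* neither species has an imaginary (negative) vibrational frequency;
* the bulk electrostatic contribution of the reaction-field treatment lies
  inside the keep-range [-4.0, -0.1] eV (values outside flag numerical
  trouble; boundary values are kept).

Each removed record carries the tag of the first failing rule, in the fixed
order bond_change, spin_contamination, imaginary_frequency,
electrostatic_range; because the rules are independent predicates, the
kept-set does not depend on the order in which filters are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeciesRecord", "FilterThresholds", "FilterResult",
    "max_bond_change", "s_squared_deviation", "apply_filters",
    "read_xyz", "write_xyz",
]


@dataclass
class SpeciesRecord:
    """Curation inputs for one molecule: geometries, frequencies, spin data."""

    molecule_id: str
    parent_geometry: np.ndarray | None = None   # (n_atoms, 3), Angstrom
    reduced_geometry: np.ndarray | None = None
    elements: list[str] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)
    frequencies: list[float] | None = None      # cm^-1, both species pooled
    s_squared: float | None = None              # reduced (open-shell) species
    multiplicity: int = 2
    bulk_electrostatic: float | None = None     # eV


@dataclass(frozen=True)
class FilterThresholds:
    max_bond_change: float = 0.40
    max_spin_deviation: float = 0.10
    frequency_floor: float = 0.0                 # any mode below this is imaginary
    electrostatic_keep: tuple[float, float] = (-4.0, -0.1)


@dataclass
class FilterResult:
    kept: list[SpeciesRecord]
    removed: list[tuple[SpeciesRecord, str]]


def max_bond_change(parent_geometry: np.ndarray, reduced_geometry: np.ndarray,
                    bonds: list[tuple[int, int]]) -> float:
    """Largest relative bond-length change between parent and reduced geometries.

    Bond connectivity comes from the parent; a bond broken on reduction thus
    registers as a large change, which is the intended behavior.
    """
    p = np.asarray(parent_geometry, dtype=float)
    r = np.asarray(reduced_geometry, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"geometry atom counts differ: {p.shape} vs {r.shape}")
    if not bonds:
        return 0.0
    worst = 0.0
    for i, j in bonds:
        d_p = float(np.linalg.norm(p[i] - p[j]))
        d_r = float(np.linalg.norm(r[i] - r[j]))
        if d_p <= 0:
            raise ValueError(f"degenerate parent bond {i}-{j}")
        worst = max(worst, abs(d_r - d_p) / d_p)
    return worst


def s_squared_deviation(s_squared: float, multiplicity: int) -> float:
    """Relative deviation of <S^2> from the single-reference value S(S+1).

    For a doublet (multiplicity 2) the ideal value is 0.75; the returned
    fraction is s_squared/ideal - 1.  Closed-shell species (multiplicity 1)
    with non-zero <S^2> are inconsistent inputs.
    """
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    if multiplicity == 1:
        if s_squared != 0.0:
            raise ValueError(
                f"closed-shell species with non-zero <S^2> = {s_squared}: inconsistent record")
        return 0.0
    s = (multiplicity - 1) / 2.0
    ideal = s * (s + 1.0)
    return s_squared / ideal - 1.0


def _check_record(rec: SpeciesRecord, th: FilterThresholds) -> str | None:
    """First failing rule tag, or None if the record passes all filters."""
    if rec.parent_geometry is not None or rec.reduced_geometry is not None or rec.bonds:
        if rec.parent_geometry is None or rec.reduced_geometry is None:
            raise ValueError(f"{rec.molecule_id}: bond-change filter needs both geometries")
        if max_bond_change(rec.parent_geometry, rec.reduced_geometry, rec.bonds) \
                > th.max_bond_change:
            return "bond_change"
    if rec.s_squared is not None:
        if s_squared_deviation(rec.s_squared, rec.multiplicity) > th.max_spin_deviation:
            return "spin_contamination"
    if rec.frequencies is not None:
        if any(f < th.frequency_floor for f in rec.frequencies):
            return "imaginary_frequency"
    if rec.bulk_electrostatic is not None:
        lo, hi = th.electrostatic_keep
        v = rec.bulk_electrostatic
        if not math.isfinite(v):
            raise ValueError(f"{rec.molecule_id}: non-finite electrostatic contribution")
        if not (lo <= v <= hi):
            return "electrostatic_range"
    return None


def apply_filters(records: list[SpeciesRecord],
                  thresholds: FilterThresholds | None = None) -> FilterResult:
    """Partition records into kept and removed-with-reason, order preserved."""
    th = thresholds or FilterThresholds()
    kept: list[SpeciesRecord] = []
    removed: list[tuple[SpeciesRecord, str]] = []
    for rec in records:
        tag = _check_record(rec, th)
        if tag is None:
            kept.append(rec)
        else:
            removed.append((rec, tag))
    return FilterResult(kept=kept, removed=removed)


def read_xyz(text: str) -> tuple[list[str], np.ndarray]:
    """Parse a single-frame XYZ block into element symbols and coordinates."""
    lines = text.strip().splitlines()
    n = int(lines[0].split()[0])
    elements, coords = [], []
    for line in lines[2:2 + n]:
        parts = line.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return elements, np.asarray(coords)


def write_xyz(elements: list[str], coords: np.ndarray, comment: str = "") -> str:
    rows = [str(len(elements)), comment]
    for el, (x, y, z) in zip(elements, np.asarray(coords)):
        rows.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
    return "\n".join(rows) + "\n"
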