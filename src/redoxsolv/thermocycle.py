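"""Reduction-potential arithmetic from thermodynamic-cycle components.

The solution-phase reduction free energy of a one-electron reduction
A(solv) + e-(g) -> A-(solv) is assembled from four cycle legs — gas-phase
Gibbs free energies of the parent and reduced species and their solvation
free energies — plus the free energy of the gas-phase electron.  The
reduction potential follows as

    E_red(solv) = -dG_red(solv) / F - E_REF

with F Faraday's constant and E_REF the absolute potential of the chosen
reference electrode (SHE: -4.48 V, Fermi-Dirac electron convention).

All energies are J/mol internally; conversions to eV-per-particle divide by
Faraday's constant (1 eV per particle == 96485.3383 J/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "FARADAY",
    "E_REF_SHE",
    "G_ELECTRON",
    "PhysicalConstants",
    "ThermoComponents",
    "delta_g_reduction",
    "reduction_potential",
    "electron_affinity",
    "ev_to_joules_per_mol",
    "joules_per_mol_to_ev",
]

#: Faraday constant, C/mol (equivalently J/(mol*V) and J/mol per eV).
FARADAY = 96485.3383

#: Absolute potential of the standard hydrogen electrode in acetonitrile,
#: volts, under Fermi-Dirac statistics for the electron.
E_REF_SHE = -4.48

#: Gibbs free energy of the gas-phase electron, J/mol, electron convention
#: (Fermi-Dirac statistics): -3.632 kJ/mol.
G_ELECTRON = -3632.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable constants of the cycle; override only via explicit construction."""

    faraday: float = FARADAY
    e_ref_she: float = E_REF_SHE


@dataclass
class ThermoComponents:
    """Free-energy legs of the reduction thermodynamic cycle, J/mol.

    ``g_electron`` defaults to the Fermi-Dirac electron-convention value.
    """

    g_gas_parent: float
    g_gas_reduced: float
    dg_solv_parent: float
    dg_solv_reduced: float
    g_electron: float = field(default=G_ELECTRON)

    def __post_init__(self) -> None:
        for name in ("g_gas_parent", "g_gas_reduced", "dg_solv_parent",
                     "dg_solv_reduced", "g_electron"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite thermodynamic component {name!r}: {v}")


def delta_g_reduction(c: ThermoComponents) -> float:
    """Gibbs free energy of reduction in solution, J/mol.

    dG_red(solv) = [G_gas(A-) + dG_solv(A-)] - [G_gas(A) + dG_solv(A)] - G(e-).

    The electron is a reactant of A + e- -> A-, so its free energy is
    subtracted; with the (negative) electron-convention value this makes
    dG_red more positive by 3632 J/mol.
    """
    return (
        (c.g_gas_reduced + c.dg_solv_reduced)
        - (c.g_gas_parent + c.dg_solv_parent)
        - c.g_electron
    )


def reduction_potential(
    dg_red: float,
    e_ref: float = E_REF_SHE,
    constants: PhysicalConstants | None = None,
) -> float:
    """Reduction potential, volts, vs the reference at absolute potential ``e_ref``.

    E_red = -dG_red / F - E_REF.  With dG_red = 0 and the SHE reference the
    result is +4.48 V: the absolute potential of the electron at rest relative
    to SHE.
    """
    if not math.isfinite(dg_red):
        raise ValueError(f"non-finite reduction free energy: {dg_red}")
    k = constants or PhysicalConstants()
    return -dg_red / k.faraday - e_ref


def electron_affinity(g_gas_parent: float, g_gas_reduced: float) -> float:
    """Adiabatic electron affinity, eV per particle, from gas-phase free energies.

    EA = G_gas(parent) - G_gas(reduced), converted from J/mol; positive when
    the reduced species is lower in free energy.
    """
    if not (math.isfinite(g_gas_parent) and math.isfinite(g_gas_reduced)):
        raise ValueError("non-finite gas-phase free energy")
    return joules_per_mol_to_ev(g_gas_parent - g_gas_reduced)


def ev_to_joules_per_mol(x: float) -> float:
    return x * FARADAY


def joules_per_mol_to_ev(x: float) -> float:
    return x / FARADAY
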