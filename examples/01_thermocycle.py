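"""Reduction potentials from thermodynamic-cycle components.

Assembles the reduction free energy of a one-electron reduction from its
cycle legs (gas-phase free energies of parent and reduced species plus
their solvation free energies, J/mol) and converts it to a potential
against the standard hydrogen electrode.
"""

from redoxsolv import (ThermoComponents, delta_g_reduction, electron_affinity,
                       reduction_potential)

# a hypothetical quinone-like species: the reduced form is lower in free
# energy (favourable electron attachment) and better solvated (an anion)
components = ThermoComponents(
    g_gas_parent=-1.8e8,          # J/mol
    g_gas_reduced=-1.8e8 - 1.0e5, # gas-phase reduction releases 1.0e5 J/mol
    dg_solv_parent=-3.0e4,
    dg_solv_reduced=-1.2e5,       # the anion is much better solvated
)

dg = delta_g_reduction(components)
e_red = reduction_potential(dg)   # SHE reference, E_REF = -4.48 V
ea = electron_affinity(components.g_gas_parent, components.g_gas_reduced)

print(f"dG_red(solv) = {dg:.1f} J/mol")
print(f"E_red        = {e_red:.3f} V (E_red = -dG_red/F - E_REF)")
print(f"EA           = {ea:.3f} eV")
print()
print("The potential is -dG_red/F minus the reference potential; a more")
print("negative reduction free energy means a more positive potential.")
print("The EA is the gas-phase part of the cycle expressed per particle.")
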