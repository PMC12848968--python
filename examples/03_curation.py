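"""Stability filtering of candidate redox records.

Runs the four curation rules (bond-length change on reduction, spin
contamination, imaginary frequencies, reaction-field electrostatic range)
over an engineered fixture whose outcomes are known.
"""

from redoxsolv import apply_filters
from redoxsolv.synthetic import gen_curation_fixtures

records, expected = gen_curation_fixtures(seed=0)
result = apply_filters(records)

print(f"input records: {len(records)}")
print(f"kept:          {len(result.kept)}")
print("removed:")
for rec, tag in result.removed:
    print(f"  {rec.molecule_id:<22} -> {tag}")

print()
print("Each removed record carries the first failing rule among bond_change")
print("(>40% bond-length change), spin_contamination (<S^2> >10% off S(S+1)),")
print("imaginary_frequency (any negative mode) and electrostatic_range")
print("(outside the keep-interval [-4.0, -0.1] eV).")
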