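"""SMILES to featurized molecular graph.

Shows the heavy-atom graph the predictor consumes: per-atom categorical and
scaled numeric features, per-bond categories, and the directed edge
expansion used during message passing.
"""

from redoxsolv import featurize, to_directed

g = featurize("CC(=O)c1ccccc1")  # acetophenone
print(f"canonical SMILES: {g.smiles}")
print(f"heavy atoms: {g.n_heavy}, bonds: {len(g.edges)}")

src, dst, eidx = to_directed(g)
print(f"directed message-passing edges: {len(src)} (= 2 x bonds)")

print("\nfirst three atoms (element idx, heavy neighbors, ring, aromatic, valence):")
for a in g.nodes[:3]:
    print(f"  {g.vocabulary[a.element_index]:>2}  neighbors={a.n_heavy_neighbors} "
          f"ring={a.in_ring} aromatic={a.aromatic} valence={a.valence}")

print("\nnode feature matrix shape:", g.node_features().shape)
print("Each row one-hot encodes the element and appends scaled mass, radii,")
print("degree and valence; these are the inputs projected into latent space.")
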