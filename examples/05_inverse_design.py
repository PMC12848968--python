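"""Evolutionary inverse design against a target potential window.

Trains a small ensemble of three solvent-descriptor models on synthetic
data, then evolves molecules from simple seeds toward a 0.5 V window.  A
candidate is accepted only when every ensemble member predicts inside the
window — the ensemble doubles as an implicit uncertainty filter.
Runs in a couple of minutes on one CPU.
"""

from redoxsolv import RedoxMPNN, split_molecules, train
from redoxsolv.evolve import EvolutionConfig, TargetWindow, ensemble_objective, evolve_loop
from redoxsolv.solventdb import get_solvent
from redoxsolv.synthetic import gen_dataset
from redoxsolv.training import desk_scale_model_config, desk_scale_train_config

dataset, truth = gen_dataset(300, seed=0)
ids = [m.id for m in dataset.molecules]

models = []
for k in range(3):  # distinct splits and seeds, as in deep-ensemble screening
    mc = desk_scale_model_config(seed=k)
    tc = desk_scale_train_config(seed=k, epochs=25)
    split = split_molecules(ids, tc.ratios, seed=k)
    model, _ = train(RedoxMPNN(mc), dataset, split, tc)
    models.append(model)

solvent = get_solvent("ACN")
window = TargetWindow(2.3, 2.8)  # absolute volts
objective = lambda g: ensemble_objective(g, models, solvent, window)

cfg = EvolutionConfig(max_heavy_atoms=10, population_size=15,
                      max_generations=25, n_children=3, seed=0)
ranked, history = evolve_loop(["CC", "CCO", "c1ccccc1"], cfg, objective)

print(f"generations: {len(history)}, accepted candidates: {len(ranked)}")
for c in ranked[:5]:
    preds = ", ".join(f"{p:.2f}" for p in c.ensemble_predictions)
    print(f"  {c.smiles:<18} score {c.score:.3f}  SA {c.sa_score:.2f}  preds [{preds}] V")

print()
print("Every listed molecule is valid, within size/element constraints, below")
print("the synthetic-accessibility threshold, and predicted inside the window")
print("by all three ensemble members.")
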