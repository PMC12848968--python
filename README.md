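# redoxsolv

Multi-solvent prediction of one-electron reduction potentials for organic
molecules, with the surrounding machinery a redox-screening workflow needs:
thermodynamic-cycle arithmetic, data-set curation filters, leave-one-solvent-out
evaluation, a synthetic ground-truth generator, and evolutionary inverse design.

## Who this is for

Computational chemists and ML practitioners screening redox-active organics
(battery electrolytes and additives, flow-battery anolytes, redox-matched
polymer partners) who need potentials in *several* solvents — including
solvents absent from the training data — without running a DFT campaign per
molecule and solvent.

## The model

The reduction potential in solvent *s* follows from the reduction Gibbs free
energy via

```
E_red(solv) = -ΔG_red(solv)/F - E_REF
```

with `F = 96485.3383 C mol⁻¹` and `E_REF = -4.48 V` for the standard hydrogen
electrode (Fermi–Dirac electron convention; the gas-phase electron carries
`G(e⁻) = -3.632 kJ mol⁻¹`). `ΔG_red` decomposes over a thermodynamic cycle into
gas-phase reduction plus the solvation free-energy difference of the parent and
reduced species.

The learned predictor mirrors this physics. A message-passing neural network
operates on the heavy-atom molecular graph (atom features: element, heavy-atom
degree, ring membership, aromaticity, scaled mass and radii, valence; bond
features: bond type, conjugation, ring membership). Six residual
message-passing iterations update node and edge states jointly; the final
states form a set pooled by multihead attention against learned seed queries
(a Set Transformer readout), rescaled by set cardinality so energy-like
(extensive) targets are representable. Two output variants:

* **GNN-VS** — a head emits a fixed vector of potentials, one per training
  solvent, plus the electron affinity (EA);
* **GNN-SD** — one head sees the molecule only (the solvent-independent EA
  term); a second sees the molecule together with the solvent descriptor
  (ε, n) — static dielectric constant and refractive index — and predicts the
  solvent-dependent term. Their sum is the potential, and because the solvent
  enters only through (ε, n), the model extrapolates to unseen solvents.

Training minimizes the summed per-output-dimension mean absolute error with
AdamW; splits are at molecule level, so every record of a molecule shares one
partition and nothing leaks across train/validation/test. The
leave-one-solvent-out (LOSO) protocol withholds every record of one solvent
from training and evaluates only in that solvent.

For inverse design, an ensemble of SD models scores candidate molecules
through a windowed sigmoid objective
`f(x) = σ(k(x-lo)) - σ(k(x-hi))` (≈1 inside the target window `[lo, hi]`,
≈0 outside); an evolutionary loop mutates molecular graphs (add/remove atoms,
change bonds, substitute atoms, move groups) under size, element, and
synthetic-accessibility constraints, and accepts a candidate only when *all*
ensemble members predict inside the window.

## Worked example

`examples/04_train_synthetic.py` trains the SD variant on 400 synthetic
molecules with exact ground-truth potentials in five solvents (Gaussian noise
0.05 eV), then leaves a sixth synthetic solvent out entirely:

```
validation loss: 0.584 -> 0.067
held-out molecules: MAE 0.040 eV, R^2 0.989
unseen solvent (LOSO): MAE 0.056 eV
```

The noise floor of the synthetic truth is ≈0.04 eV MAE, so the held-out error
means the model recovered the underlying potential surface, and the barely
higher LOSO error shows the (ε, n) descriptors suffice to predict in a solvent
never seen during training. The other examples cover cycle arithmetic
(`01_thermocycle.py`), featurization (`02_featurize.py`), curation
(`03_curation.py`) and inverse design (`05_inverse_design.py`); each prints
the numbers it computes with a note on what they mean.

A thin CLI wraps the same library calls, e.g.:

```bash
redoxsolv potential --dg 0 --ref SHE     # -> 4.48
redoxsolv solvents
redoxsolv synth --n 200 --seed 1 --out data/
```

## Layout

```
src/redoxsolv/
  thermocycle.py   cycle arithmetic and physical constants
  solventdb.py     solvent (ε, n) registry, reference electrodes
  chemgraph.py     SMILES featurization, molecule tables
  nn.py            autodiff engine, layers, AdamW
  mpnn.py          message passing + attention readout, VS/SD variants
  training.py      splits, loss, training loop, metrics, LOSO
  curation.py      stability filters
  synthetic.py     molecule generator, ground-truth surface, fixtures
  evolve.py        window objective, mutations, evolutionary loop
  cli.py           thin command-line interface
```
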