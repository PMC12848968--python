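# Methods

## Thermodynamic cycle and constants

The solution-phase reduction free energy of A(solv) + e⁻(g) → A⁻(solv) is
assembled as

    ΔG_red(solv) = [G_gas(A⁻) + ΔG_solv(A⁻)] − [G_gas(A) + ΔG_solv(A)] − G(e⁻)

with the electron treated as a reactant under the electron convention
(Fermi–Dirac statistics), G(e⁻) = −3632 J mol⁻¹. The sign of the electron
term is the one place this arithmetic admits ambiguity; it is fixed by a
dedicated test (an electron-only cycle yields ΔG_red = +3632 J mol⁻¹).
The potential follows as E_red = −ΔG_red/F − E_REF with
F = 96485.3383 C mol⁻¹ and E_REF(SHE) = −4.48 V. All energies are J mol⁻¹
internally; eV-per-particle conversions divide by F. The electron affinity is
computed from free energies by default (a flag for electronic-energy-only EA
exists because stored tables differ in what they record).

Reference-electrode conversion is affine: absolute = relative + offset. The
SHE offset (+4.48 V) follows from the cycle; ferrocene (+0.40 V vs SHE in
acetonitrile) and Li/Li⁺ (−3.04 V vs SHE) ship as documented literature
defaults that users should override when their convention differs — they are
configuration inputs, not measurements made here.

## Solvent representation

A solvent is exactly the pair (ε, n): static dielectric constant and
refractive index at 25 °C. The registry carries standard literature values
(water 78.4/1.333, acetonitrile 35.9/1.344, THF 7.4/1.407, DMSO 46.8/1.479,
DMF 36.7/1.430), all replaceable at runtime. The default model input is each
of (ε, n) min–max scaled over fixed bounds (ε: 1–100, n: 1–1.8) so that
adding a solvent never changes the transform; an Onsager-style option
((ε−1)/(ε+2), (n²−1)/(n²+2)) is available. Both transforms are strictly
increasing in each argument and vanish in the vacuum limit. Temperature
dependence is out of scope — everything is 25 °C.

## Featurization

Molecules are heavy-atom graphs (hydrogens implicit — the "number of heavy
atom neighbors" feature only makes sense on a heavy-atom graph). The element
vocabulary defaults to {H, C, N, O, F, S, Cl, Br}; unknown elements raise
errors rather than falling into an "other" bucket, keeping failures loud.
Atomic mass, van der Waals radius and covalent radius are min–max scaled over
the vocabulary with constants frozen in code (so library upgrades cannot
silently shift features). Multi-fragment SMILES are rejected; the intended
inputs are single molecules. Stereochemistry and 3-D conformers are not
featurized.

## Architecture

Node and edge features are linearly projected into latent states (defaults:
node 128, edge 128). Each of six message-passing iterations computes, per
directed edge, a message from the RMS-normalized (source state, target state,
edge state) through a two-layer tanh MLP shared across iterations; messages
are sum-aggregated on the receiving node (sum is injective on multisets,
unlike mean) and added residually; edge states are updated residually from
the messages on them. The RMS normalization applies only to the *inputs* of
the message function: the residual stream itself is left free to grow, which
is what lets states accumulate count information, while the normalization
prevents the tanh layers from saturating as they otherwise do within a few
iterations.

The readout pools the joint set of node and edge states (each projected into
a common element space; pooling nodes only is a config flag) by multihead
attention against learned seed queries — one pooling seed, four heads by
default, graph vector 256. The attention-pooled vector is multiplied by the
element count of the set (`pool_scale="cardinality"`). This rescaling is
deliberate: a softmax-attention pool is a convex combination of value
vectors and therefore cannot represent extensive, energy-like quantities
(doubling a molecule could never double the output). On the synthetic truth
below, the plain convex pool plateaued at several times the noise floor while
memorizing the training set; the cardinality rescaling — attention choosing
*what* to pool, the multiplicity restoring *how much* — reaches the noise
floor. The plain pool remains available (`pool_scale="none"`).

Heads: the EA head is a two-layer MLP on the graph vector alone; the SD
solvent head sees the graph vector concatenated with the projected (ε, n)
descriptor; their raw outputs are affinely rescaled by training-target
mean/std (stored in the checkpoint) so an untrained model predicts the
training means — this output normalization removes the slow
"learn-the-offset" phase. The reduction potential is the exact sum of the two
head outputs. The VS variant replaces the solvent head with a five-output
head in fixed solvent order (ACN, H₂O, THF, DMSO, DMF). The EA output is
always trained as an auxiliary target since EA labels accompany the data.

Weight initialization is fan-in uniform from a recorded seed; the whole model
is deterministic given (config, seed).

## Training

The loss sums per-output-dimension mean absolute errors (each of the five VS
columns, the per-record SD potential, and the EA term), with missing targets
masked out. The optimizer is AdamW (defaults: lr 1e-4, weight decay 1e-5,
batch 32, 60 epochs); the checkpoint returned is the best-validation epoch,
not the last. Splits are by molecule id with largest-remainder rounding
(100 ids at 80/10/10 give exactly 80/10/10); all of a molecule's records
share its partition. LOSO removes every record of the withheld solvent from
the training *and* validation streams and evaluates only withheld-solvent
records of test molecules. R² is reported both as the unweighted mean of
per-solvent values (headline) and pooled; constant-target partitions report
R² as undefined rather than a number.

Three optional training refinements are config-exposed and off by default
(the defaults keep the plain recipe: constant learning rate, no clipping):
cosine learning-rate decay to a tenth of the initial rate, global
gradient-norm clipping, and weight averaging over the final fraction of
epochs (kept only if it beats the best single epoch on validation loss).
Desk-scale runs enable all three; see below.

## Synthetic ground truth

The generator grows random organic-like molecules (element draw frequencies
C 0.70, O 0.12, N 0.09, S 0.04, F 0.03, Cl 0.015, Br 0.005; random trees with
occasional double bonds and ring closures, valences respected, deduplicated
by canonical SMILES). The potential surface is

    EA(m)        = c₀ + w · counts(m)
    E(m, s)      = EA(m) + A·q(m)·(1 − 1/ε) + B·q(m)·(n²−1)/(n²+2) + noise

with counts(m) the per-element/bond/aromatic-atom counts, q(m) a normalized
heteroatom fraction in (0, 1], A = 2.0 eV, B = 0.5 eV, and homoscedastic
Gaussian noise (default sd 0.05 eV) drawn deterministically per
(molecule, solvent) pair from the truth seed. The solvent enters only through
smooth Born/Onsager-type functions of (ε, n), so zero-shot solvent
generalization is genuinely learnable from the two descriptors — the premise
the SD variant is built on. What the generator does *not* emulate: the ring
statistics, radical fraction, or error structure of real DFT data sets;
passing these tests shows the machinery learns the intended functional
dependence, not that real-data accuracy follows.

Six synthetic solvents are defined; five train, the sixth (ε 20.5, n 1.386 —
interior to the training range) serves the LOSO probe.

## Desk-scale study conditions

The synthetic recovery runs (tests and the acceptance script) use 400
molecules × 5 solvents, noise 0.05 eV, a reduced model (node/edge 32, graph
64, 2 heads), and a shorter, more aggressive recipe (60 epochs, lr 3e-3 with
cosine decay, weight decay 3e-4, clip 5, weight averaging over the final
quarter). These sizes keep a full study to a few CPU-minutes while the
conclusions — held-out MAE at the noise floor (≈0.04 eV against a 0.10 eV
bound), LOSO barely higher (≈0.06 eV against 0.20 eV) — are stable across
seeds tried during development.

## Curation

Four independent predicate filters with configurable thresholds: maximum
relative bond-length change on reduction (> 0.40 removes; bonds from parent
connectivity, so a bond broken on reduction registers as a large change,
which is intended), spin contamination (⟨S²⟩/S(S+1) − 1 > 0.10 removes),
imaginary frequencies (any mode below 0 cm⁻¹ removes), and the
reaction-field bulk electrostatic keep-range ([−4.0, −0.1] eV closed —
boundary values are kept). Removed records carry the first failing tag in
that fixed order; since the rules are independent, the kept-set is
order-invariant. Missing fields for a requested filter raise per-record
errors rather than passing silently. Wave-function stability checking itself
is a quantum-chemistry step and out of scope; its boolean result can ride
along as an input column.

## Inverse design

The window objective is f(x) = σ(k(x−lo)) − σ(k(x−hi)) with steepness
k = 50 V⁻¹ by default — chosen so the narrowest application preset (the
0.25 V polyphenylthiophene window) still scores > 0.99 at its midpoint.
Selection is (μ+λ) elitist with mutation-only variation (no crossover):
per generation each of the top `population_size` candidates spawns
`n_children` mutation attempts; invalid chemistry, constraint violations
(15 heavy atoms, {C, N, O, F, S, Cl, Br} by default) and
synthetic-accessibility failures (fragment-contribution SA score over the
threshold, default 4.5) are rejections, not errors. "Move functional group"
is implemented as detach-a-terminal-substituent and reattach at a random
valid position — one admissible reading. A candidate is *accepted* only when
every ensemble member predicts inside [lo, hi]; the mean window score ranks
candidates. Ties break by SA score then SMILES for determinism. Four named
application windows (PEDOT, PPT, Li-ion additives, flow-battery anolytes)
ship as presets; converting them to the absolute scale goes through the
reference-electrode offsets, which are user configuration.

## Known limitations

No uncertainty quantification beyond the implicit ensemble gate; no learned
LR schedules beyond cosine; the autodiff engine is single-threaded NumPy and
sized for desk-scale studies, not for the full ~20k-molecule public data set
(supported, but hours of CPU); synthetic-accessibility scoring is a coarse
proxy for synthesizability; electrode offsets for Fc⁰/Fc⁺ and Li/Li⁺ are
convention-dependent inputs, not derived quantities.
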