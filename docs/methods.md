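# Methods

## The prediction problem

An NMR chemical shift δ (ppm) measures the resonance frequency of a
nucleus relative to a reference; it is exquisitely sensitive to the 3D
electronic environment of the atom. shiftgnn predicts per-atom ¹H and
¹³C shifts directly from conformer geometry with a message-passing
neural network, and supplies the surrounding workflow: dataset
construction and cleaning, staged transfer learning, Boltzmann averaging
over conformers, and shift-list comparison for structure elucidation.

## Environment graphs

A conformer (N atoms, Cartesian coordinates in Å) becomes a directed
graph whose edges are exactly the ordered atom pairs with d_ij strictly
below a cutoff (default 5.0 Å, an open interval). Each edge feature is
the distance expanded over a grid of Gaussian radial basis functions,

    e_ij[k] = exp(−(d_ij − k·μ)² / δ),   k = 0 … n_basis−1,

with defaults n_basis = 256, spacing μ = 0.1 Å and width δ = 0.04 Å².
The centers k·μ span 0–25.5 Å, comfortably covering every distance that
can occur under the cutoff; the width is chosen so adjacent Gaussians
overlap strongly (exp(−μ²/δ) = 0.78), giving a smooth, well-conditioned
encoding. Distances are computed in double precision and there are no
periodic images — isolated molecules only. Because the featurization
depends on coordinates only through pairwise distances, every model
built on it is invariant to rotations, translations and reflections, and
equivariant to atom relabeling; the test suite checks both properties
explicitly rather than trusting the construction.

## Network architecture

Atoms are embedded by element (vocabulary C, H, N, O, F, P, S, Cl) into
feature vectors h ∈ R^F, F = 256 by default. The network iterates T = 3
blocks of

* edge update: e′ = e + W₂·ssp(W₁·[h_i ‖ h_j ‖ e] + b₁) + b₂
  (two hidden layers per block, hence six edge-update layers in total);
* message: m_i = Σ_{j : d_ij < cutoff} h_j ⊙ f(e′_ij), where the filter
  f is a two-layer network on the edge feature;
* node update: h′ = h + two-layer transform of m_i;

followed by a fully connected readout 256→128→64→1 applied to every
atom, with predictions taken at the atoms of the target nucleus. The
activation is the shifted softplus ln(0.5·eˣ + 0.5) throughout — smooth,
zero at zero, the standard choice in this architecture family. Separate
models are trained per nucleus, since ¹³C and ¹H shifts live on very
different scales.

Every parameter tensor carries one of five group labels — embedding,
edge_update, message, node_update, readout — which is what the
transfer-learning stages freeze against.

## Implementation and numerics

The network, its gradients and the Adam training loop are implemented
directly over numpy with a ~200-line reverse-mode autodiff tape
(`shiftgnn._autodiff`); gradients are verified against central finite
differences in the tests (max relative error ~1e-5 on a full model).
Scatter-adds in the backward pass go through sparse-matrix products,
which on one CPU are an order of magnitude faster than `np.add.at`.

Parameters are stored and trained in float32 for CPU throughput;
inference (`forward`) upcasts to float64, so rigid-motion invariance of
predictions holds to ~1e-9 ppm. The output layers of all residual
branches are initialized 10× smaller than Glorot scale so activations
stay near the embedding scale at initialization — without this, the
neighbor sums amplify activations block after block and the first
training steps diverge.

Targets are z-score normalized with constants fitted once on the first
training set and stored with the parameters; later transfer stages reuse
the stored scale, so a readout retrained on offset labels sees exactly
the offset it must absorb. Training minimizes MAE (configurable to MSE)
with Adam at an initial learning rate of 1e-3, halved when the
validation loss has not improved for 10 epochs; minibatches are whole
molecules; the best-validation-epoch parameters are returned, with ties
resolved to the earliest epoch. Frozen tensors are skipped by the
optimizer entirely, so they come back bitwise identical — a contract the
tests assert, not an approximation.

## Transfer-learning stages

The staged regime mirrors how shift models are trained in practice: a
base model learns from plentiful computed labels on accurate geometries;
a first transfer stage (`readout_only`: embedding and all update blocks
frozen) adapts the readout to sparser, higher-fidelity experimental
labels; a second stage (`edge_update_only`: everything frozen except the
edge-update layers) adapts the network's interpretation of raw distances
when accurate geometries are replaced by cheap force-field ones. For the
default configuration the readout is only ~2.5% of the 1.62 M
parameters, so readout-only retraining freezes ~97.5% of the network;
the exact fraction is reported by `make_freeze_mask` rather than assumed.
Retraining restarts the optimizer (no momentum carry-over) and defaults
to a 10× smaller learning rate, the usual fine-tuning convention.

## Data preparation

* Structure filter: total formal charge 0, molecular weight strictly
  below 500 g/mol, elements within the supported set, optionally all
  stereocenters defined. Rejections are counted per reason.
* Diversity sampling: greedy farthest-neighbor (max-min) selection under
  Jaccard distance on Morgan fingerprints (radius 2, 2048 bits); the
  seeded first pick and lowest-index tie-break make it deterministic.
* Shielding→shift scaling: computed isotropic shieldings σ map to
  shifts by the empirical affine relations δ = 181.40 − 0.97σ (¹³C) and
  δ = 29.30 − 0.91σ (¹H). The coefficients are taken as constants and
  are overridable; refitting them is out of scope.
* Cleaning: paired computed/experimental shifts are pooled per nucleus,
  and a pair is discarded when its difference lies more than 1.5·IQR
  below Q1 or above Q3. Quartiles use the linear-interpolation
  convention and the bounds are inclusive, so a degenerate all-equal set
  is fully kept. Pooling across the dataset (not per molecule) is the
  default; a per-molecule variant exists behind a flag.
* Splits are at molecule level, deterministic given a seed, defaulting
  to 500 validation / 500 test structures.

## Conformer ensembles

Conformers come from seeded distance-geometry embedding followed by
MMFF94 optimization (via rdkit); energies are reported relative to the
ensemble minimum and near-duplicates (heavy-atom RMSD < 0.5 Å after
optimal superposition) are pruned keeping the lower-energy member.
Ensemble shifts are Boltzmann averages with weights
w_c ∝ exp(−E_c/RT), R = 1.98720425864083e-3 kcal/(mol·K), T = 298.15 K
by default (configurable, recorded in outputs); the minimum energy is
subtracted before exponentiation for stability. Only fast-exchange
averaging is modeled — no NMR-timescale exchange.

## Elucidation and reassignment

Candidates are scored against a spectrum by sorting both shift lists and
pairing by rank; for 1-to-1 matching under mean absolute difference this
is provably optimal, and the tests verify it against exhaustive
permutation search up to n = 8. A global mode assigns several spectra to
several candidates at once by minimizing the summed MAE (Hungarian
algorithm), which rescues cases where independent per-spectrum argmins
double-book one candidate. For assigned spectra, structures with
as-assigned MAE strictly above 3.5 ppm are flagged and their
experimental values optimally reordered; an optional mode restricts
swaps to within user-supplied atom classes (e.g. CH multiplicity), off
by default. Unequal list lengths are an error unless truncation is
explicitly allowed, because silent truncation can flip rankings.

## Synthetic fixtures and the label oracle

Real training labels come from quantum-chemical shielding calculations;
at desk scale the package instead ships deterministic fixtures and a
geometry-sensitive oracle,

    δ_i = b_Z(i) + Σ_{j≠i, d_ij < cutoff} c_Z(j)·exp(−d_ij/λ),

with b_C = 100 ppm, b_H = 5 ppm, c_Z = 10 ppm for all elements and
λ = 1.5 Å. The oracle is smooth, rigid-motion invariant and exactly a
function of the environment graph, so a model of this family can learn
it — which turns "can the pipeline learn geometry-dependent shifts?"
into a checkable statement. The fixtures are idealized geometries fixed
as constants in source (methane; anti/gauche butane; chair/boat
cyclohexane; cis/trans 1,3-dimethylcyclohexane; a valine-like molecule),
chosen so that stereochemically distinct structures share identical bond
lists while their distance multisets differ. The dimethylcyclohexane
pair differs most strongly at the axial methyl carbon (~4.3 ppm in
oracle labels), an analogue of the γ-gauche upfield shift that makes
cis/trans ring isomers distinguishable by ¹³C NMR in reality.

Training pools are built by cycling over the fixture conformers with
0.1 Å Gaussian coordinate jitter (thermal-displacement scale) plus a
random rigid motion per sample. The contaminated-pair generator draws
computed−experimental differences from Normal(0, σ) and displaces a
chosen fraction by ±magnitude at seeded positions, recording the planted
indices so cleaner recall can be scored exactly.

What the fixtures do *not* emulate: real shielding physics (ring
currents, heavy-atom effects, solvent), assignment noise structure, and
dataset-scale chemical diversity. Passing the desk-scale suite shows the
machinery — featurization, optimization, freezing, averaging, matching —
is correct and geometry-sensitive; it does not certify accuracy on real
spectra, which depends on training against real computed/experimental
datasets at full scale.

## Problem sizes and defaults used in validation

The acceptance suite trains one default-configuration ¹³C model
(F = 256, 3 blocks, 1.62 M parameters) on 200 oracle-labelled perturbed
fixture conformers (160 train / 20 validation / 20 held-out), 90 epochs
of minibatch Adam — about eight minutes on one CPU — reaching held-out
MAE below 10% of the label standard deviation (~0.65 vs 6.77 ppm in the
reference run). Invariance suites use 100 random rigid motions and 20
permutations; matching optimality uses 200 random instances up to n = 8;
cleaner recall uses 10 000 pairs with 5% planted ±15 ppm outliers.
Transfer contracts run on a 16-dimensional model, since they are
architecture-independent bitwise and offset-absorption properties.

## Known limitations

* Single-conformer inputs at prediction time are trusted as given; no
  automatic conformer search quality control (poor force-field
  geometries degrade predictions).
* The ¹H pipeline is functional but the desk-scale validation centers
  on ¹³C, matching where experimental-label refinement is most useful.
* Uncertainty estimation, joint multi-nucleus models and probabilistic
  assignment scores (DP4-style) are out of scope.
* Training is deterministic given seeds on a fixed BLAS; bitwise
  reproducibility across different BLAS builds is not guaranteed.
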