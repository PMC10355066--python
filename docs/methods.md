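# Methods

## Problem and model

The package regresses crystal density ρ (g/cm³) of CHON molecules from
SMILES. The representation is 3D-aware: a single ETKDG conformer supplies
coordinates, from which force-field-style geometric features are computed and
injected into graph attention.

**Curation.** Input tables are filtered by four criteria applied in order,
first failure reported: (1) elements within {C, H, O, N}; (2) at least one
carbon–nitrogen bond of any order; (3) a single fragment with zero net formal
charge — the operational proxy for excluding ionic and co-crystal entries,
chosen so that nitramines written with local +/− charges on the nitro group
(RDX, HMX, CL-20) are kept; (4) a 3D conformer can be embedded. Unparseable
SMILES are rejected under criterion 1 with a note rather than raising, so one
bad row never aborts a batch. Curation is idempotent.

**Conformers.** One ETKDG embedding per molecule with a fixed seed; no
ensemble, no force-field minimization. Hydrogens are explicit during
embedding and stripped afterwards — the heavy-atom graph carries the
attached-H count as a feature, which would be redundant if hydrogens were
nodes. Coordinates are in Å; embedding is bit-deterministic for a fixed
(SMILES, seed).

**Atom features (66 per atom).** Concatenation of: atom-type one-hot (38),
degree one-hot (6), chiral-type one-hot (4: unspecified / tetrahedral CW /
CCW / other), attached-H one-hot (6), hybridization one-hot (8: unspecified,
s, sp, sp², sp³, sp³d, sp³d², other), aromatic flag (1), atomic mass (1),
H-bond acceptor/donor flags (2, via the Lipinski SMARTS definitions). The
38-symbol atom-type vocabulary is a fixed documented list (H, C, N, O first,
then common organic/metallic elements alphabetically); an element outside it
raises rather than silently bucketing. Out-of-range ordinals (degree > 5,
H count > 5) clamp to the final bucket. Atomic mass is scaled by 1/100 so a
single raw feature cannot dominate the one-hot blocks.

**k-hop neighborhoods.** A hop-k neighbor of atom i is an atom reachable by a
simple path of exactly k bonds *and* at topological shortest-path distance
exactly k. The distance filter keeps the three neighborhoods disjoint — each
neighbor is attended to at exactly one hop, mirroring the bond/angle/torsion
split of a force field — while ring systems retain their force-field
multiplicity because features of multiple equal-length paths between the same
ordered pair are **summed** (as the energy terms sum over angles and
dihedrals), not averaged. In benzene each atom reaches its para partner by
two 3-bond paths; in cyclobutane the 3-bond path around the ring is excluded
because its endpoints are adjacent.

**Geometric features.** Hop 1: (l, l²). Hop 2: (θ, θ², r⁻¹, r⁻⁶, r⁻¹²) with
θ ∈ [0, π] the angle at the middle atom and r the endpoint distance. Hop 3:
(cos nφ, sin nφ for n = 1..3, r⁻¹, r⁻⁶, r⁻¹²) with φ the signed dihedral in
(−π, π] by the standard atan2-of-plane-normals convention, measured along the
stored path order. Signed dihedrals are kept because the sine terms of the
torsion expansion carry sign information; note that the standard convention
is invariant under path reversal (both plane normals and the central bond
flip), so all hop-3 slots are reversal-symmetric, while mirror reflection of
the conformer negates exactly the three sin slots. Distances are in Å with no
σ scaling — σ and ε live in the learned embedding weights. Endpoint distances
below 0.1 Å raise (r⁻¹² would overflow); a degenerate dihedral frame (three
collinear atoms) contributes zeros to the six trig slots with a warning
instead of propagating NaNs, since the non-bonded slots of that path remain
informative.

**Architecture.** Atom features are linearly embedded to d_model. Each of the
`n_ffi_layers` blocks computes, per hop k, multi-head attention of every atom
over its hop-k neighbor pairs with

    logit_ij = [(W_q h_i)·(W_k h_j) + w_e·e_ij] / √d_head
    message_ij = W_v h_j + W_m e_ij

where e_ij is the learned embedding of the pair's summed geometric features.
Pre-norm residual blocks are used throughout, so an atom with an empty hop-k
neighbor set (e.g. any atom of a diatomic at k = 2, 3) passes through that
hop unchanged. The three hop outputs are stacked behind a learnable output
token (CLS-style) and mixed by a standard pre-norm Transformer encoder —
1 layer by default, positional encoding off by default because the four
slots carry no meaningful order; the encoder is then permutation-equivariant
and the output-token state is invariant to hop-token order (tested). The
output-token state becomes the atom representation for the next block.
Readout is sum pooling by default (mean available) followed by a two-layer
MLP head. Pair lists are sorted internally, making the update bit-identical
under any permutation of the neighbor list.

**Numerical engine.** No GPU framework is assumed: the model runs on a small
reverse-mode autodiff engine over float64 NumPy arrays with broadcasted
arithmetic, batched matmul, gather/segment-sum (exact adjoints, used for the
sparse per-pair attention), and a numerically stabilized segment softmax
(per-source max subtracted as a detached constant). Every operation is
gradient-checked against central finite differences in the test suite.

## Training and evaluation

MSE loss, Adam (β = 0.9/0.999, ε = 1e−8), seeded Glorot initialization,
seeded minibatch shuffling, inverted dropout. Early stopping monitors
validation MAE with patience 10 and the best-validation weights are
restored. A non-finite loss aborts immediately with a diagnostic. Defaults:
30 epochs, batch 32, learning rate 3e−3 — chosen once for the desk-scale
synthetic task.

Splits are seeded random partitions with sizes round(0.8 N) / round(0.1 N) /
remainder. Metrics are MAE, RMSE and R² (R² reported as missing when the
true values have zero variance). Region evaluation bins by **true** density
into [1.8, ∞), [1.6, 1.8), [1.4, 1.6), (−∞, 1.4) — left-closed at every
boundary, so RDX at 1.806 is region 1 and a density of exactly 1.6 is
region 2. Error tiers are left-closed likewise: [0, 0.03) excellent,
[0.03, 0.05) informative, [0.05, 0.10) barely useful, [0.10, ∞) deceptive.
Multi-seed summaries report mean ± sample standard deviation (n−1
denominator); a single seed reports the mean with sd missing. Before using
an external test table, training records whose canonical SMILES occur in it
are removed.

## Synthetic data

The generator emulates the curated-table setting without licensed data: a
seeded grammar over carbon chains and nitrogen heterocycles decorated with
nitro / amino / cyano / hydroxy / carbonyl / ether groups, constructed so
every molecule satisfies curation criteria 1–3 by construction (conformer
embedding, criterion 4, succeeds for ≥ 99% in practice). The surrogate
target

    ρ = 0.9 + 0.5·(mean heavy-atom mass)/20 + 0.8·(N+O heavy-atom fraction) + N(0, 0.02²)

spans roughly 1.0–2.1 g/cm³ with nitro-rich molecules in the high-density
tail. Defaults are n = 500, seed 7, noise sd 0.02 g/cm³. The target is
deliberately compositional, not geometric: it is learnable by the network
yet computable exactly without conformers, enabling fast oracle checks, and
an ideal model can approach the noise floor MAE of σ√(2/π) ≈ 0.016 g/cm³.
What passing tests therefore show is that the pipeline learns a known
structure–property mapping end to end; they do not show that the geometric
attention terms capture real crystal-packing physics, and the synthetic set
has none of the conformational diversity, tautomer ambiguity or measurement
error of curated crystallographic data.

## Problem sizes and verification choices

The test suite and the acceptance script run the full pipeline at
n = 500 molecules, d_model = 32, 4 heads, 1 force-field block, mean readout,
dropout 0, ≤ 30 epochs — sizes chosen so a complete from-scratch run takes
seconds to a minute on one CPU while still separating a trained model from
the predict-the-mean baseline by a wide margin (≥ 30% MAE reduction is the
acceptance bar; observed runs give 60–75%). Mean readout is the natural
choice for the surrogate task because the target is a function of per-atom
averages. k-hop enumeration is verified exhaustively against a brute-force
path oracle on every connected graph with ≤ 7 nodes (the graph atlas) plus
200 seeded random connected 8-node graphs and the benzene/cyclobutane worked
cases; geometry is verified against law-of-cosines and projection-based
dihedral oracles at 1e−10 and rigid-motion invariance at 1e−8.

## Known limitations

- One conformer per molecule: conformer-ensemble effects on the geometric
  features are ignored, and an unlucky embedding is not retried.
- The 38-symbol atom vocabulary and the category orderings for chirality and
  hybridization are package conventions; models trained with different
  orderings are not weight-compatible.
- The H-bond feature pair is implemented as two independent (acceptor,
  donor) flags rather than a 2-class one-hot; an atom can be both, or
  neither.
- No tautomer/protomer handling, no CIF parsing, no uncertainty estimates,
  no hyperparameter search machinery.
- CPU-only float64 execution: fine at desk scale, not intended for
  10⁴-molecule training runs.
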