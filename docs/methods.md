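# Methods

## Overview

`gsnet` implements two E(3)-invariant graph neural networks for protein
property prediction and everything needed to exercise them end to end on
synthetic structures:

* **GSnet** operates on a *residue graph*: one node per residue, edges
  between residues whose Cα atoms lie within 15 Å. It predicts global
  properties — solvation free energy ΔG_sol (kJ/mol), radius of gyration
  R_g (Å), hydrodynamic radius R_h (Å), translational and rotational
  diffusion constants D_t (nm²/µs) and D_r (µs⁻¹), molecular volume V
  (nm³) — as well as molecular SASA, per-residue SASA and per-residue pKa
  shifts through different output heads.
* **aLCnet** operates on a *local atom graph*: every C/H/N/O/S atom within
  10 Å of the Cα of a residue of interest, edges between atoms within
  5 Å, at most 150 incoming edges per node (nearest kept, ties broken by
  atom serial). Its per-atom features include the partial charge, making
  it charge-aware; it predicts pKa shifts for the center residue.

All features are scalars invariant under rigid motions: type indices,
dihedral sin/cos/mask triplets, distances to the center of mass, charges,
and interatomic distances expanded on a Gaussian basis. Consequently the
full prediction pipeline is SE(3)-invariant by construction; under
reflection the signed dihedrals flip sign, which the tests assert
explicitly.

## Graph featurization

Residue nodes carry: an amino-acid embedding index (20 standard types plus
one generic index used by permissive parsing), a 15-vector of backbone and
side-chain dihedral encodings — (sin, cos, mask) for φ, ψ, χ1–χ3, with
sin = cos = 0 wherever the mask is 0 — and the Cα-to-center-of-mass
distance in Å. φ is masked at chain starts and after chain breaks, ψ at
chain ends; a chain break is a residue-numbering gap or a Cα–Cα distance
above 4.5 Å. χ angles are masked when the residue type defines none
(Gly, Ala) or the defining atoms are absent; missing atoms log a warning
and mask the angle rather than aborting.

Edge scalars d_ij are expanded on K = 300 Gaussians with centers μ_k
linearly spaced on [0, 15] Å (residue graph; spacing ≈ 0.05017 Å) or
[0, 5] Å (atom graph; spacing ≈ 0.0167 Å), σ equal to the spacing:
e_ij[k] = exp(−(d_ij − μ_k)²/2σ²). No normalization across components.
All cutoffs (15, 10, 5 Å) are inclusive; distances are computed in double
precision and features stored in single precision.

## Network architecture

Node encoders: learned 64-d embeddings for discrete inputs (residue type;
atom type for aLCnet), two-layer 64-d MLPs for continuous inputs (the
dihedral 15-vector and the center-of-mass distance for GSnet; the charge
for aLCnet), concatenated and reduced by an MLP with one hidden layer of
width 2·node_dim to the node width — 150 for GSnet, 75 for aLCnet.

Message passing is a transformer convolution. Per layer and head *c*, the
smeared edge vector is mapped through a learned affine map and a shifted
softplus, ssp(x) = ln(1+eˣ) − ln 2, to the per-head width; attention
logits are ⟨W_q h_i, W_k h_j + e_c,ij⟩/√d_head, softmax-normalized over
each receiver's in-neighbours; messages are α_ij (W_v h_j + e_c,ij). A
learned root transform of the receiver's own state is added to the
aggregated message (configurable via `root_term`; on by default — the
residual connection alone could carry the self contribution, but a root
term lets the layer rescale it), and the layer output is
LayerNorm(H + Ĥ) with learned affine and ε = 1e−5. GSnet uses 6 layers
with 1 head; aLCnet 3 layers with 3 heads.

Readouts: global heads use the element-wise mean μ over nodes; the
per-residue SASA head uses the node embedding h_i; the GSnet pKa head
concatenates [μ, h_i, μ_6, μ_8, μ_10, μ_12, μ_15] (1050-d), where μ_r
averages nodes within Cα distance r of residue i (self always included,
so no radius set is empty); the aLCnet pKa head concatenates
[μ, h_Cα, μ_residue] (225-d). The concatenation order is a frozen
convention — it is irrelevant to learnability but must be fixed for
reproducible checkpoints.

Output MLPs: global and per-residue heads have 4 linear layers with 1024
hidden channels and 3 ssp activations; pKa heads have 6 linear layers,
5 ssp activations and 6 dropout layers at 20% (dropout precedes each
linear layer; active only in training mode).

## Automatic differentiation

The networks run on a compact reverse-mode autodiff engine written on
numpy (`gsnet._autodiff`): dense algebra, elementwise maps, row
gather/scatter and segment reductions (segment softmax/sum implement
neighbourhood attention without materializing dense adjacency). Gradients
of every primitive are verified against central finite differences in the
test suite. Parameters default to single precision; `dtype="float64"`
is used in gradient-check tests.

## Training

Targets are z-scored with mean/sd fitted on the training split only
(masked-in values only; validation and test reuse the training statistics).
The loss is MSE averaged over masked-in entries: squared errors are
multiplied by the 0/1 availability mask before reduction, so a masked
ΔG_sol entry contributes exactly zero to the loss and to every parameter
gradient — an algebraic zero, asserted bitwise by finite differences.

Optimization is Adam at 1e−4, dropped to 1e−5 after epoch 50 by a
schedule that does not reset the optimizer moments (the alternative —
resetting moments at the switch — is defensible; not resetting keeps the
schedule a pure learning-rate change). Batch size 64. Early stopping
halts after 10 epochs without strict validation improvement (no minimum
delta); fixed-epoch regimes (10 for per-residue SASA, 100 for pKa) are
supported via `fixed_epochs`. Repeat-and-select training runs n (default
20) seeded repeats and selects the lowest validation loss, ties broken by
lowest repeat index; a top-k reporting mode returns mean ± SEM over the
k repeats with the best validation RMSE.

Transfer modes: `transfer_frozen` optimizes only the output head — every
encoder and message-passing parameter is bit-identical before and after
training; `transfer_finetune` loads pretrained weights and optimizes
everything. The four pKa-from-GSnet variants (original vs.
SASA-fine-tuned encoder × frozen vs. optimized) are expressible as
checkpoint choice × mode.

pKa heads are trained in **shift space**: the target is the deviation from
the residue type's reference (model-compound) pKa, and the reported pKa is
null + shift. This makes the null model exactly the zero function of the
head, so a zeroed head reproduces the null table bit-exactly — a useful
invariant. An `absolute=True` flag trains/reports absolute pKa instead.
Ensemble prediction over conformers is the arithmetic mean of per-member
predictions, per residue.

## Synthetic structures and proxy targets

The generator builds all-atom chains from ideal internal coordinates
(NeRF extension; N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, ω = 180°) in
three conformations: helix (φ = −57°, ψ = −47°), extended
(φ = ψ = 180°), and coil (per-residue draws from four Ramachandran
basins). Each residue gets N/CA/C/O, a Cβ and the first χ1-defining atom
where the type has them (so the χ-mask code paths are exercised), and
optionally amide/α hydrogens. Gaussian positional jitter (default
0.3 Å sd in datasets) breaks exact symmetry. Everything is a pure
function of the seed.

Stand-in global targets are closed-form proxies with documented constants:
R_g exact (mass-weighted); R_h = 1.29·R_g; D_t = 245.0/R_h[nm] nm²/µs and
D_r = 183.8/R_h[nm]³ µs⁻¹ (Stokes–Einstein/Debye in water at 298 K);
V = Σ 4/3·π·r_vdW³; ΔG_sol = −686·Σq²/R_h[Å] kJ/mol (Born-like). The
constants were chosen once so magnitudes fall in realistic protein ranges
(R_g tens of Å, D_t ~1–100 nm²/µs), which keeps target normalization
meaningful. Default datasets draw 16–48 residues per chain and mask
ΔG_sol out for 20% of records, mirroring partial solvation coverage in
real label sets. A simplified per-atom charge table (CHARMM-like backbone
values plus nominal side-chain stub charges) ships for the charge-aware
paths; it is a synthetic stand-in, not a force field.

What the generator does **not** emulate: real side-chain rotamer
diversity, packing, secondary-structure context beyond the three idealized
conformations, experimental coordinate error, or physically accurate
electrostatics/hydrodynamics. Passing tests therefore demonstrate that
the architectures, losses and pipelines behave as specified and can learn
geometry-determined targets — not that desk-scale training reaches
literature accuracy on real proteins, which requires large structure
corpora and reference labels out of scope here.

## Reference calculators

R_g is the mass-weighted root-mean-square distance to the center of mass.
SASA is Shrake–Rupley with a 1.4 Å probe and a deterministic golden-spiral
point set (default 960 points/atom; no RNG); radii come from PQR files
when present, else an element table (C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20 Å). Per-residue values sum to the molecular value exactly because
each atom's area is attributed to its residue. Point-sampled SASA is only
asymptotically rotation-invariant; at 960 points residual anisotropy is
below 1%. The null-pKa table defaults to common experimental reference
values (ASP 3.65, GLU 4.25, HIS 6.54, LYS 10.40, TYR 9.84, CYS 8.55) and
is configurable — these defaults are this package's choice of reference
scale.

## Leakage-aware splitting

Sequence identity is computed by global alignment (match +1, mismatch 0,
affine gaps −10 open / −0.5 extend, end gaps penalized) as
matches / alignment length, gap columns included in the denominator —
conventions differ slightly from common clustering tools and are fixed
here for determinism. Clustering is greedy longest-first at identity
> 0.5 against cluster representatives; members are aligned pairwise to
their representative, and "alignment column" means the representative
position a residue maps to (residues aligned to gaps are unmappable and
treated as dissimilar, with a warning). Two records are similar iff same
cluster ∧ same column ∧ same residue type. Splitting keeps internal
similarity in train, deduplicates validation internally (first seen kept)
and against train, and filters an independent test source against
train ∪ validation; a final exhaustive train×test scan is asserted empty
and reported. Behavioral parity with external clustering/alignment tools
is explicitly not claimed; the predicate's logic is what is tested.

## Problem sizes and numerical choices

Desk-scale defaults used by the benchmark suite and the acceptance
script, chosen as the package's own operating points: invariance checks
use 10 structures × 20 rigid motions; the learnability surrogate trains
GSnet-global1 on 200 synthetic structures (16–48 residues, hydrogens
omitted from the residue-graph dataset) for 20 epochs at learning rate
1e−3 with a 9:1 split, reporting validation Pearson r between predicted
and true R_g; the transfer contract runs 50 fixed epochs on 20 fixtures
of 8–16 residues. The surrogate's higher learning rate and short schedule
are its own regime — R_g is strongly determined by the
center-of-mass-distance node feature, so convergence is fast; the
training engine's defaults (1e−4 → 1e−5 at epoch 50) remain the standard
regime for multi-target training.

Degenerate inputs: single-residue structures yield graphs with no edges
(message passing reduces to the root term plus LayerNorm); fully masked
batches define the loss as 0 with a warning; empty radius-pool sets
cannot occur (self-inclusion); zero-variance targets refuse to normalize.

## Known limitations

* No GPU path; the numpy engine is single-threaded except for BLAS.
* mmCIF is not parsed; multi-model PDBs use the first model only.
* Hydrogens are consumed as given, never placed.
* The aLCnet selection includes atoms from all chains within 10 Å; whether
  to span chains in complexes is a convention, fixed here as inclusive.
* Greedy clustering depends on input order (longest-first, then input
  order) — deterministic, but not identical to external tools.
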