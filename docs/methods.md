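# Methods

## Problem and model

`liggen` implements a conditional, energy-guided generative model over
small-molecule ligands for a given protein target.  A ligand with at most
N heavy atoms is a pair of one-hot arrays: an atom matrix in {0,1}^(N×A)
over an element vocabulary {C, N, O, F, S, Cl} plus an explicit pad/empty
category, and a symmetric bond tensor in {0,1}^(N×N×B) over bond types
{no-bond, single, double, triple, aromatic}.  The generative model learns
P(y | x): given a protein, many plausible ligands.

Four networks are trained jointly, end to end:

* **Protein encoder** `x = Enc_τ(x_p)` — a deterministic map from a fixed
  size heavy-atom point cloud (coordinates in Å, element codes, validity
  mask) to a low-dimensional embedding.  Implemented as a shared per-atom
  MLP over `[0.05·coords ‖ one-hot(element)]` followed by masked mean⊕max
  pooling and a linear projection, so it is permutation-invariant and
  indifferent to padding.  The default embedding width is 16.
* **Generator** `ŷ = G_φ(x, z)` — early fusion `[x ‖ z]`, `z ~ N(0, I)`,
  through a linear stack, then two heads: atom logits (per-row softmax)
  and bond logits, symmetrised by averaging with their transpose before
  the per-pair softmax.  The dense output is discretised by a hard
  Gumbel-softmax sample (temperature 1.0, no annealing) with a
  straight-through gradient; bonds are sampled on the upper triangle and
  mirrored, the diagonal and all pad-involving pairs are forced to
  no-bond, so every sample is a valid one-hot graph by construction.
* **Critic** `D_ψ(y)` — an unbounded Wasserstein critic over ligand
  graphs only (no protein conditioning), built on the relational GNN
  stack below.  It accepts relaxed (dense) inputs so the gradient penalty
  is well defined.
* **Energy network** `E_θ(x, y)` — the same GNN stack, whose graph
  readout is concatenated with the protein embedding and passed through
  an MLP head to a scalar.  Low energy means the ligand is compatible
  with the target; the scalar is a learned surrogate for binding
  affinity, not a physical force-field energy.

## Relational GNN backbone

Message passing runs over one relation per bond type (no-bond excluded)
plus an optional self-loop relation (on by default) so isolated atoms
still receive their own message.  Two interchangeable layers:

* **Relational graph attention** (default).  Per relation r, a weight
  matrix W_r and attention vector a_r produce logits
  e_ij^(r) = LeakyReLU(a_r^T [W_r h_i ‖ W_r h_j]); a *single joint
  softmax per node* over all (relation, neighbour) pairs yields
  coefficients that sum to exactly one for every connected node, and
  h_i' = LeakyReLU(Σ_r Σ_j α_ij^(r) W_r h_j).  Isolated nodes receive
  all-zero coefficients.
* **Relational GCN** (baseline, no attention):
  h_i' = LeakyReLU(W_0 h_i + Σ_r mean_{j∈n_i^(r)} W_r h_j).

For dense inputs the 0/1 adjacencies are replaced by bond probabilities
as edge weights; the attention softmax weights each exponentiated logit
by its edge weight, which reduces to the hard formula on one-hot graphs
and stays differentiable down to the generator output.  LeakyReLU slope
is 0.2 throughout.  Graph-level readout concatenates the masked mean with
the masked feature-wise max of node features; the max uses a detached
additive shift to exclude pad rows (routing gradient through the shift
would scale it by the shift constant).

## Losses and training schedule

Per iteration, three stages with strictly disjoint parameter updates
(each stage owns its optimiser):

1. m critic steps (default 5) on
   `L_D = D(ŷ) − D(y) + λ(‖∇_x̂ D(x̂)‖₂ − 1)²` with λ = 10 and
   x̂ = εy + (1−ε)ŷ, ε ~ U[0,1], the gradient taken jointly over all atom
   and bond entries.  The penalty is an autodiff graph node, so critic
   parameters receive the required second-order gradients.
2. One energy step on `L_E = L_energy + α(E(x,y)² + E(x,ŷ)²)` with
   `L_energy = E(x,y) − E(x,ŷ)` (a single contrastive fake per real
   pair, bypassing the partition function) and α = 0.001.
3. One generator+encoder step on `L_G = −D(ŷ) + β·mean E(x,ŷ)` with
   β = 1 by default.

**Energy guidance (design choice).**  Composing the generator objective
with the contrastive loss verbatim would give the ŷ-term a negative
sign — the generator would then *raise* fake energies, cooperating with
the energy network's contrastive push until both saturate at the L2
equilibrium ±1/(2α) = ±500, at which point the energy term swamps the
critic signal and distribution matching degrades (we measured exactly
this failure on the synthetic dataset).  Since the point of the energy
network is to pull generation toward *compatible = low-energy* ligands,
the generator minimises the mean fake energy.  The energy network's own
update keeps the contrastive loss exactly as stated above.

Optimisation is Adam with betas (0.5, 0.999) (the usual adversarial
choice; the moments are not specified by the training recipe we follow),
learning rate 1e-4 dropping to 1e-5 at epoch 200, batch 64, up to 1,000
epochs at full scale.  Training stops early if any loss becomes
non-finite.  All randomness (minibatch choice, ε, z, Gumbel noise) flows
from one seeded generator, so traces are bit-reproducible.

## Preprocessing rules

* Ligands: hydrogens removed; molecules with more than N = 32 heavy atoms
  are trimmed by repeatedly deleting the atom with the current minimum
  bond degree (ties broken by the highest atom index) and recomputing
  degrees, until N atoms remain.  The iterative form (rather than a
  single sorted pass) better preserves connectivity; the tie rule makes
  it deterministic.
* Proteins: hydrogens removed; clouds standardised to exactly 4,096 atoms
  by keeping those nearest the ligand centroid (the unweighted mean of
  ligand heavy-atom coordinates before trimming) or zero-padding with a
  mask.
* Readers: RDKit for SDF/MOL2, Biopython for PDB.  Unparseable pairs are
  logged and skipped rather than aborting a dataset build.

## Synthetic paired data

The generator in `io_prep.generate_synthetic_dataset` emulates the data
model with a planted dependence so conditional learning is verifiable
without any external download.  Each pair draws a hidden class c
(default 6 classes, one per vocabulary element) that controls *both*
sides:

* protein: a Gaussian blob (σ = 3 Å) whose centre offset (12 Å along a
  class-specific axis) and element composition depend on c; the atom
  count varies between half and full budget (default 256 atoms at desk
  scale rather than 4,096, purely for speed);
* ligand: the heavy-atom count range tiles [2, N] by class, the element
  distribution concentrates 90% of its mass on a class-specific element,
  and bond types concentrate 90% on a class-specific bond type; bonds
  form a random spanning tree plus class-dependent extra edges.

Because class controls the joint (size, composition) law, a conditional
generator can read the class from the protein and match it, while an
unconditional one must carve all class modes out of its latent space at
once — with six well-separated joint modes this reliably degrades its
fit relative to the conditional model.  What this construction does
**not** emulate: real binding-site
geometry, chemically valid valences, and any physical protein-ligand
interaction — passing the trend tests shows the conditioning machinery
works, not that the model docks molecules.

## Evaluation

Each molecule is summarised by its atom-type counts over non-pad atoms
(the pad slot stays zero) concatenated with its bond-type counts over the
upper triangle, no-bond included — a permutation-invariant (A+B)-vector.
The Fréchet distance between Gaussian fits of real and generated feature
sets is ‖μ₁−μ₂‖² + tr(Σ₁+Σ₂−2(Σ₁Σ₂)^½), computed via the symmetric
eigendecomposition form of the trace term with a 1e-6 diagonal jitter
(count features can be rank-deficient on small batches); tiny negative
results are clamped to zero.  The exact featurisation behind the
published score is not recoverable from its description; counts are our
documented stand-in, chosen for well-conditioned covariances at
desk-scale batch sizes.

Two harnesses mirror the headline comparisons at desk scale:
`ablate_embedding_dim` trains one model per (embedding width, seed) with
the energy network dropped (β = 0, as in the original embedding
ablation), including the non-conditional x_dim = 0 baseline that builds
no encoder; `compare_backbones` runs paired GCN/GAT trainings differing
only in the backbone flag and returns full loss traces.

## Desk-scale study conditions

The trend tests run on one CPU with N = 9, x_dim = 8, z_dim = 8,
feat_dim = 16, 512 synthetic pairs over 6 classes, batch 32, 3 critic
steps, 300 iterations, learning rate 1e-3 decaying to 1e-4 at epoch 12
(the same decay-late schedule as the full-scale recipe, rescaled to the
shorter run).  These sizes are the package's chosen desk-scale protocol:
large enough for the Wasserstein critic to shape the generator, small
enough to iterate quickly.  The energy-gap runs use the full model
(β = 1) on the same dataset and schedule shape, shortened to 200
iterations with 2 critic steps: the contrastive energy race resolves
within the first few epochs, well before the generator finishes.

## Numerical choices and degenerate inputs

* Gumbel noise is clipped away from 0/1 before the double log; dense
  probabilities are floored at 1e-12 before taking logs.
* Attention softmax subtracts a constant per-node max over present edges
  for stability; nodes with no edges in any relation get all-zero
  coefficients (with self-loops enabled this never happens for real
  atoms).
* The gradient-penalty norm adds 1e-12 under the square root, so a
  critic with exactly zero gradient pays λ(1e-6 − 1)² ≈ λ within 1e-4.
* An all-pad protein cloud or an all-pad ligand readout is an error, not
  a silent zero.
* Degree normalisation in the GCN layer adds 1e-12 to the denominator;
  isolated nodes contribute W_0 h_i only.

## Autodiff engine

No deep-learning framework is part of the environment contract, so the
package carries a small reverse-mode autodiff engine (`liggen.autodiff`)
over float64 numpy arrays.  Backward rules are themselves composed of
tensor operations, which makes gradients differentiable — the critic's
gradient penalty needs d/dψ of ‖∇_x̂ D‖.  Only the operations the models
use are implemented; gradient correctness is tested against central
differences to first and second order.

## Known limitations

* Generated molecules are frequently disconnected; no connectivity
  penalty is applied, and no valence/chemistry checking is performed.
  SDF export flags disconnected outputs rather than fixing them.
* The learned energy is a relative, dimensionless score; only energy
  *differences* between real and fake ligands are meaningful.
* The Wasserstein critic sees ligands only; all protein information
  reaches the generator through the energy network and the adversarial
  pressure on the conditional generator, so a poorly trained energy
  network weakens conditioning pressure accordingly.
* Desk-scale trend results are stochastic; they are asserted as
  majorities over seeds, not per-seed guarantees.
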