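# Methods

`cfmdock` is a desk-scale generative model for rigid-body protein–protein
docking. Given the two unbound monomer structures of a complex, it samples
candidate bound conformations by integrating a learned flow from a broad
pose prior to the bound-pose distribution, and ranks the samples with a
learned confidence score. Every stage — synthetic data, featurization, the
pair-denoiser network, staged training, sampling, and DockQ evaluation — is
implemented and tested end to end on toy complexes small enough to train on
one CPU.

## State decomposition

A two-chain complex is decomposed, after a global RMSD alignment anchored
on the receptor CA atoms, into

* `c` — the ligand CA centroid (Å) in the receptor-anchored frame;
* `R` — the ligand orientation: the rotation carrying the ligand's
  *body-fixed* conformation (its internal coordinates expressed in the
  backbone frame of its own middle residue) into the anchored frame;
* `x̄` — per-chain internal coordinates, each chain individually
  Kabsch-aligned onto its counterpart in the reference complex.

`recompose(decompose(x)) = x` holds to ~1e-13 Å. Defining the body frame
from the ligand's own backbone (rather than from the reference's global
placement) makes the whole pipeline exactly equivariant: rigidly moving
the reference moves every sampled trajectory identically, which the test
suite checks to 1e-8 Å.

## Conditional flow

Training pairs a bound complex `x1` with a prior draw `x0`:

* translation: `c0 ~ N(receptor centroid, σ_tr² I₃)` with σ_tr = 15 Å by
  default — comparable to toy-complex diameters, so prior samples cover
  distinct binding sites. The noise vector is expressed in a backbone
  frame attached to the receptor, again for exact equivariance.
* rotation: Haar-uniform on SO(3), sampled via normalized 4-D Gaussian
  quaternions.
* internal coordinates: an unbound conformer drawn from a per-chain
  library of holo, apo-like and predicted-like structures; the mixed
  stages draw them with probabilities 20% / 40% / 40%.

The conditional path is the optimal-transport choice — linear in `c` and
`x̄`, the geodesic `R_t = R1·exp((1−t)·log(R1ᵀR0))` on SO(3) — with
conditional velocity `(x1 − x_t)/(1 − t)`. The network is parametrized as
a denoiser predicting `x̂1` rather than the velocity; the two views are
algebraically identical, and the suite checks that an Euler step with the
reparametrized velocity equals re-interpolation toward `x̂1` to 1e-9.

Inference integrates over a uniform grid `t_k = k/K` (K = 10 by default)
using denoise-and-reinterpolate with fraction `(t_{k+1}−t_k)/(1−t_k)`; the
final grid point jumps directly to the prediction, so `t = 1` is never fed
to the network and the `1/(1−t)` singularity is never evaluated. With an
oracle denoiser that always returns `x1`, the integrator lands on the bound
pose exactly (ligand CA-RMSD < 1e-6 Å for any K ≥ 1 and any seed).

The rotation path uses the right-translated convention; the left/right
choice is not fixed by the endpoint conditions, and the endpoint tests make
the convention observable. The `exp`/`log` maps switch to series limits
below 1e-7 rad and resolve near-π rotations through the symmetric-part
eigenvector branch.

## Synthetic toy complexes

The generator emulates the structure of a real docking corpus at toy scale:

* chains are self-avoiding persistent random walks with 3.8 Å CA virtual
  bonds; N, C, O and a virtual CB are placed with ideal geometry from
  local frames (glycines carry no CB);
* each chain plants a contiguous 6-residue *interface patch* whose
  composition is biased (85%) toward W/Y/R/F/H — the learnable docking
  signal, visible to the model through sequence channels;
* the bound pose faces the two patches, requires ≥ 6 CB–CB contacts under
  8 Å and forbids inter-chain atom pairs closer than 2.8 Å. The 8 Å
  generator contact is deliberately different from the 5 Å any-atom
  evaluation contact so the generator cannot leak the metric;
* unbound conformers apply smoothed correlated backbone noise plus one
  hinge rotation and are re-idealized: apo-like (σ = 0.4 Å, hinge 0.02
  rad) lands at 0.3–2 Å CA-RMSD from holo over seeds; predicted-like
  (σ = 0.9 Å, hinge 0.12 rad) is substantially larger, mirroring the
  holo/apo/predicted input hierarchy.

What the toy data does *not* emulate: side-chain packing, realistic
secondary structure, energetic frustration, size and stoichiometry of real
complexes, and binding-induced conformational change beyond smooth
perturbations. Passing tests therefore demonstrate that the method's
machinery is correct and that the model can learn a planted
sequence-plus-geometry signal — not that it would reach any particular
accuracy on real proteins.

## Featurization

Template-style pair features over the whole complex, inter-chain entries
included (nothing is masked out across chains): a 38-bin CB distogram over
[3.25, 50.75] Å with under/overflow bins, CA displacement unit vectors in
the row residue's backbone frame, CB and frame masks, residue-identity
pairs, clipped (±32) relative sequence offsets with a same-chain flag, and
— for the conditioning stream — 16 Fourier features of t. All geometric
channels are invariant under rigid motion of the complex (tested to 1e-6).
A `use_seq_embed` flag zeroes the identity channels without changing
shapes, reproducing the with/without-sequence-features ablation structure.

## Network

The docking module is a pair-representation stack (C = 32 channels):

* structure and conditioning embedders: linear projection + a two-block
  pair stack (triangle multiplicative updates out/in, triangle attention
  around start/end nodes, 4× transition);
* a four-block conditioned pair denoiser in which triangle attention and
  the transition are wrapped in adaptive layer normalization: scale and
  shift are predicted from the conditioning (zero-initialized, so each
  block starts as a plain layer norm) and a sigmoid gate rescales each
  residual branch (bias-initialized near 1 so signal flows from the
  start);
* a pose readout: for every ligand residue the inter-chain row is pooled
  and mapped to a local-frame displacement, composed of a free vector
  (scaled to a 10 Å range) and per-pair scalar coefficients multiplying
  the raw CA displacement vectors toward each receptor residue. The
  coefficients make "move residue i to an affine combination of receptor
  positions" linear in the readout weights, which in practice is what lets
  rotation converge as fast as translation. The displaced CA cloud gives
  the translation update (its centroid) and the rotation update (a
  least-squares frame fit of the body conformation onto the cloud,
  orthonormalized by two-vector Gram–Schmidt). All heads are
  zero-initialized: an untrained model is exactly the identity denoiser,
  and integration leaves the prior sample untouched;
* a confidence readout pooling the inter-chain block to a sigmoid scalar,
  trained to regress the DockQ of the model's own prediction — the
  sample-and-rank surrogate for an interface-confidence score;
* an optional bounded (≤ 3 Å per residue) deformation head
  (`readout_mode="rigid_deform"`); the default readout copies the input
  internal conformation unchanged, reflecting that rigid-internal
  inference is the method's realistic operating mode while keeping the
  internal-flexibility component of the state fully implemented and
  tested.

Because no GPU framework is assumed, the network runs on a small
reverse-mode autodiff engine written on numpy (`cfmdock.nn`): float32
tensors, einsum-based contractions dispatched to BLAS, composed
softmax/layer-norm, and Adam. Gradients are verified against central
finite differences both op-wise and end-to-end through the full training
loss. Inference uses a no-grad mode and batches all samples of a target
into one forward pass, which is what makes 20-sample docking tractable on
one CPU.

## Training

Three stages, as configured by `cfmdock.train.default_stages`:

1. holo-only inputs, docking module + pose readout trainable;
2. mixed 20/40/40% holo/apo/predicted conformer sampling, same scope
   (the acceptance run additionally opens the confidence head here, so the
   ranking score sees enough of its own prediction distribution);
3. same mixture, full fine-tuning including the confidence head.

Each step samples `t ~ U[0, 0.99)`, draws `x0`, forms `x_t`, predicts
`x̂1` and minimizes the structure loss. The default `fape_like` mode is a
clamped (10 Å) frame-aligned point error on the other chain's CA atoms —
rigid-invariant by construction — plus an *unclamped* coordinate term on
the predicted CA cloud. The clamp starves gradients whenever the pose is
far off (every local error saturates); the smooth cloud term keeps pulling
each residue toward its bound position from any distance and trains
translation and rotation at equal gradient scale. A `weighted_mse` mode
implements the plain conditional-flow-matching objective with its
`1/(1−t)²` weight and is used for unit-testing the weighting itself.
Optimizer: Adam with global gradient-norm clipping at 1.0 — single-sample
gradients over diverse complexes are heavy-tailed, and clipping is what
makes cross-complex generalization (rather than per-complex memorization)
emerge — learning rate 1e-3, batch 1; runs are bitwise reproducible given
(seed, config, manifest) in single-threaded numpy.

The confidence loss is a squared error between the head's output and the
DockQ of the recomposed one-step prediction, active in stage 3 only (its
targets are uninformative before the pose heads work).

## Evaluation

DockQ is computed on backbone+CB structures: contacts are any
represented-atom pairs under 5 Å, interfaces any-atom pairs under 10 Å,
iRMSD over native-interface backbone after interface superposition, LRMSD
over ligand backbone after receptor superposition, combined as
`(fnat + 1/(1+(iRMSD/1.5)²) + 1/(1+(LRMSD/8.5)²))/3` with strict class
thresholds 0.23 / 0.49 / 0.80. Using backbone+CB (the toy structures have
no side chains) is a documented divergence from heavy-atom DockQ; the
constants are unchanged. ps-iRMSD aligns each subunit individually on all
its backbone atoms by default (an `align_scope="interface"` variant is
exposed; the choice matters only when deformation is localized) and then
measures backbone RMSD over native-interface residues, so rigid subunit
motion contributes exactly zero.

Success rates: a target succeeds at Top-k if the best DockQ among its k
highest-confidence predictions exceeds the class threshold; the oracle
uses all predictions. Confidence intervals are 95% percentile bootstrap
over targets with 10,000 resamples (empirical coverage 0.93–0.97 at
nominal 95% in the calibration test). Paired method comparisons use the
one-sided Wilcoxon signed-rank test (scipy, zeros dropped).

## Problem sizes and numerical choices

The demonstration pipeline (README) uses 90 training complexes of 16–24
residues per chain and stage lengths (300, 300, 200); the acceptance test
trains the default four-block model on 400 complexes with stage lengths
(600, 100, 100) and docks 12 held-out targets with 20 samples and 10
integration steps. These sizes are the package's chosen desk-scale
operating point; the generator's signal strength (patch bias 0.85, patch
size 6) is fixed independently of them. Ties in confidence ranking break
by sample index; rotations read out in float32 are re-projected onto SO(3)
by SVD before re-entering the flow; the `1/(1−t)` factors are protected by
an ε = 0.01 training ceiling and by the grid never reaching 1.

## Known limitations

* The toy task is deliberately easy; nothing here estimates accuracy on
  real complexes.
* Held-out docking success is training-length-bound at the desk-scale
  operating point: the learning curve is still improving steeply when the
  default stage schedule ends, so the oracle success rate measured by the
  recovery test understates what the same model reaches with roughly twice
  the optimizer steps. Training length, not model capacity or the data
  signal, is the binding constraint on one CPU.
* Internal flexibility is implemented in the state and priors, but the
  default readout does not move internal coordinates (the deformation head
  is off); the flow's flexibility component is exercised by the priors and
  paths rather than learned deformation — mirroring the regime in which
  rigid-internal inference is the method's honest capability.
* The confidence head shares the known failure mode of sample-and-rank
  scoring: it can be overconfident on wrong poses, so Top-1 lags the
  oracle.
* The numpy autodiff engine is single-threaded and keeps whole graphs in
  memory; it is sized for toy problems only.
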