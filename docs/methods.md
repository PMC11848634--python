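# Methods

This note documents the models and procedures `contactseer` implements,
the parameters that matter, the synthetic data the test suite runs on, and
the design choices made where the design was genuinely open.

## Setting

Two single-cell modalities measured in *different* cells of one tissue:

* an scRNA expression matrix X_R ∈ ℝ^{N_R×K_R} (raw counts, per-cell
  subtype labels, gene coordinates),
* N_H per-cell scHi-C contact matrices over K_H genome-wide 10-kb bins.

The goal is a per-region predictor f: g → ĉ from a cell's expression
vector to the K_h × K_h contact matrix of a chosen region (K_h ≪ K_H),
plus downstream statistics computed on predicted maps.

## Association graph

Genes and bins are joined into a bipartite graph. For gene G and bin B on
the same chromosome, the distance is d = |s_G − s_B| if the (0-based,
half-open) intervals are disjoint, 0 if they overlap; different
chromosomes give d = ∞ and no edge. The weight is

    w(d) = ((d + 10000) / 10000)^(−0.75),

so w(0) = 1 and w decays with genomic distance (the exponent mirrors the
empirical distance decay of chromatin contact frequency). Construction is
a coordinate-sorted sweep emitting exactly the edges with d ≤ window
(default 1 Mb, where w < 0.03); the unit tests assert equality with a
brute-force all-pairs oracle on randomized instances. Touching half-open
intervals ([a,b) and [b,c)) count as disjoint; this convention is applied
uniformly because the alternative (closed intervals) leaves the touching
case ambiguous.

## Embeddings and pairing

RNA: genes with zero total count are dropped; highly variable genes are
ranked by clipped standardized variance against a mean–variance trend fit
with a degree-2 polynomial in log10 space (a dependency-free realization
of the variance-stabilizing HVG ranking); counts are normalized per cell
to the median total, log1p-transformed, z-scored per gene, and reduced by
PCA (K_D = 100 components by default, deterministic sign convention).
Hi-C: per-cell maps are band-normalized — within each diagonal band
|i−j|, a cell's entries are scaled so its band sum equals the cross-cell
mean band sum — making the features invariant to per-cell sequencing
depth; band features are then PCA-reduced. The diagonal band is excluded
by default because its large values dominate variance.

Co-embedding is pluggable. The built-in baseline projects each scHi-C
cell's bin-marginal vector through the graph weight matrix Wᵀ into a
pseudo-expression vector, pushes it through the RNA pipeline's fitted
normalization and PCA, and aligns the two blocks per component (both
centered; the Hi-C block rescaled to the RNA block's spread, preserving
the PCA variance weighting). This is a deterministic stand-in for
graph-guided variational co-embedding tools; any co-embedder with the same
signature can be registered.

Connectivities are a symmetric-union kNN graph (cosine distance,
k = 15): strength exp(−dist/σ_i) with σ_i the cell's mean neighbor
distance. Each scRNA cell is paired with the same-subtype scHi-C cell of
maximal connectivity; different-subtype candidates are masked to −1 and a
cell with no same-subtype candidate is dropped. Ties take the lowest
scHi-C index (the argmax is otherwise under-determined). Many-to-one
pairing is allowed: each scRNA cell picks independently. When the scHi-C
side carries no subtype labels, `transfer_labels` assigns each Hi-C cell
the majority label of its k nearest RNA cells in the joint space; the
type-matching experiments use transferred labels so the matching rate is a
genuine measurement rather than a tautology.

## Network

Input: the expression vector truncated to K_used = ⌊K_R/64⌋·64 genes
(dropping the lowest-total-count genes), reshaped to (8m, 8n) where
(m, n) is the most balanced factor pair of K_used/64, and cut into a
fixed 8×8 grid of 64 patches. Each patch is linearly embedded, position
embeddings added, and a pre-norm multi-head-attention transformer encoder
(default: dim 1024, depth 6, heads 8, mlp 2048) produces token features;
a per-token head maps each of the 64 token features to a latent vector
(width 1000), giving the set of latent vectors handed to the decoder.
The decoder is deliberately smaller (dim 512, depth 6, heads 8,
mlp 2048): a first fully connected layer projects each latent token to
the decoder width, a second transformer refines the 64 tokens, and a
final fully connected layer maps the flattened token features to the
N_c = K_h(K_h−1)/2 strictly-upper-triangle contact values. Keeping the
full token set between encoder and decoder (rather than pooling to one
vector) matters in practice: a single pooled bottleneck starves the
decoder of per-cell signal and training collapses onto the pseudo-bulk
predictor. A softplus keeps contacts non-negative (`linear_head` disables
it). The diagonal is excluded from the target by default — its large
values would dominate the loss — and restored as zero on reconstruction.

Numerical choices that matter in practice:

* **Initialization** is fan-in scaled (LeCun normal, std = 1/√fan_in) for
  all projection matrices and small (std 0.02) for position embeddings.
  With a fixed tiny init the deep stack starts in a regime where the
  input-dependent signal is orders of magnitude below the bias-driven
  signal and training collapses onto a constant (pseudo-bulk) predictor.
* **Input standardization**: per-gene log1p z-scoring, fitted on the
  training inputs, applied *inside* the differentiable forward graph so
  integrated gradients chain through it. Raw counts span two orders of
  magnitude and destabilize the first linear layer.
* **Desk-scale profile**: `scale` multiplies all width hyperparameters
  (rounded to a multiple of the head count); depth and heads are fixed.
  The tested profile is scale = 0.125 (encoder 128, latent 128, decoder
  64) with lr 1e-3 — the narrower network trains stably at a larger rate
  than the full-width default of 1e-4. Adam runs with β₂ = 0.99, which
  adapts the step size faster than the textbook 0.999 and suits the
  short desk-scale schedules.

## Loss and training

With o, ô ∈ ℝ^{N_b×N_c} the target and predicted upper-triangle vectors
of one batch and L_i = Σ_j (ô_ij − o_ij)² the per-sample squared-error
sum (a sum over interactions, not a mean), the training loss is

    L = (1/N_b) Σ_i (1 − e^(−L_i))^γ · L_i,    γ = 2.

The focal factor lies in [0, 1) and vanishes as a sample's error
approaches zero, so well-fit samples are down-weighted and γ = 0 recovers
plain MSE; the loss never exceeds the plain per-sample MSE-sum mean.
Optimization is Adam (β = 0.9/0.999); batches are reshuffled each epoch
from a seed-derived stream, so a run is bitwise reproducible on one
thread.

## Dynamics statistics

Cells are ordered by a stable ascending sort of pseudo-time t (ties keep
input order). With δc^i = c^{(i+1)} − c^{(i)} over the ordered stack:

* vibration score X_v(a,b) = mean_i |δc^i(a,b)| — the average magnitude
  of change of one interaction per pseudo-time step;
* switch score X_s(a,b) = fraction of steps with |δc^i(a,b)| strictly
  greater than X_v(a,b) — how often an interaction jumps past its own
  typical variability (a proportion in [0, 1]);
* the dynamic index ranks interactions by descending X_v (ties broken
  lexicographically); the top 5% are flagged by default.

Migration maps visualize where contacts sit along pseudo-time: positions
(i, j) are sampled from each ordered map with probability proportional to
contact value, jittered uniformly within one bin (±half a bin per axis,
i.e. a 10-kb range at 10-kb bins), and averaged per cell of an n-times
refined grid — cell (a, b) holds the mean pseudo-time of the points
falling in it (the normalizer is the number of points in that cell; a
global normalizer would confound occupancy with time). Empty cells are
NaN; a cubic interpolation onto a 10× grid gives the continuous version.

Chromatin volume: a pluggable reconstructor maps a contact map to 3D
coordinates; the baseline converts contacts to dissimilarities
d_ij = (c_ij + 1)^(−α) (α = 0.5) and embeds them by seeded
stress-majorization metric MDS (SMACOF). Stress MDS is used instead of
classical scaling because the truncated eigendecomposition of classical
scaling discards all structure beyond three components and produces
erratic volumes on near-uniform maps. The chromatin volume is the
convex-hull volume of the 16 (K_h) points; a pseudo-time-windowed series
(default 10 windows) reconstructs each window's pseudo-bulk and reports
volumes and their first differences.

## Integrated gradients

Attribution of predicted interaction j to gene i from the all-zero
baseline (no expression — the counterfactual "stable" chromatin state):

    IG_ij = g_i · ∫₀¹ ∂F_j(α·g)/∂g_i dα,

approximated by a midpoint Riemann sum (50 steps by default; completeness
Σ_i IG_i = F_j(g) − F_j(0) holds to O(1/steps)). Per-subtype regulator
scores sum signed IG values over the subtype's cells and all interactions
— by linearity the sum over all interactions needs one backward pass per
integration step — and are normalized by the maximum absolute score
(chosen over max signed value so a negative-dominant vector still
normalizes into [−1, 1]). Signs are kept by default because repressive
regulators are informative; `aggregate="abs"` sums magnitudes instead.

## Synthetic data

The generator emulates exactly the structure the method assumes, with
known ground truth. Each cell carries a discrete type, a pseudo-time
t ~ U(0,1), and a driver activity u ~ U(0,1). Defaults (the study
conditions for all tests): 2 types × 50 cells per modality, 128 genes on
a 1-Mb chromosome of 100 10-kb bins, a 16-bin target region.

* Expression: negative binomial (Gamma–Poisson, dispersion φ = 0.15)
  around gene base means (~Gamma, mean 5); each type's marker genes are up
  by fold-change 4. The driver gene's mean is 10·(1 + 3u).
* Contacts: Poisson around λ = 3/(1 + |i−j|) distance decay, a
  type-specific 6-bin TAD block at 6× contrast, a block whose contacts
  scale with (0.5 + t), three driven interactions with rate increased by
  0.8 × the driver's latent mean, and lognormal per-cell depth (σ = 0.2).
  The upper triangle is sampled and mirrored, so maps are exactly
  symmetric.
* Coupling across modalities: each type's markers are, by construction,
  the genes lying inside that type's TAD block, so the association graph
  transports the type signal between feature spaces — this is what makes
  unpaired integration work, as it does in real tissue where subtype
  expression programs and subtype chromatin architecture co-localize.
* `separation` ∈ [0, 1] scales marker fold-change and TAD contrast toward
  1; at 0 the types are statistically identical (matching should be at
  chance), at 1 they are well separated.
* `make_dataset` draws both modalities from the same cells (paired;
  used to train and to validate prediction); `make_unpaired` draws
  independent cells per modality (the realistic integration setting).

What the generator does *not* emulate: genome-scale gene counts, realistic
gene-length and contact-decay heterogeneity, batch effects, doublets, or
continuous cell-state mixtures. Passing tests therefore demonstrate the
pipeline's correctness and its qualitative behavior under the stated
generative assumptions, not performance on real tissue.

## Problem sizes and budgets

The tested configuration (100 training pairs, K_R = 128, K_h = 16,
scale = 0.125, batch 8) trains at a few seconds per epoch on one CPU
core; the end-to-end checks use 30 epochs, and the 4-sample overfit
capacity check uses 200. These sizes were chosen so the whole suite runs
on a laptop; the full-width configuration (scale = 1) is retained for
fidelity runs on real data.

A note on completeness: the IG gradient is exact (it matches central
finite differences to ~1e-10) and the midpoint Riemann sum converges to
F(g) − F(0) as steps grow (to numerical precision by a few thousand
steps). On trained networks of this architecture, however, the integrand
along the baseline path has high-frequency structure, so small step
counts (tens) can carry double-digit-percent quadrature error; analyses
that need tight completeness should raise ``steps``. Rankings of
aggregated attributions are far less sensitive to this error than the
per-vector sums.

## Known limitations

* The graph-projection co-embedder is linear; strongly nonlinear
  cross-modality relationships need a plugged-in co-embedder.
* At desk scale the network reliably learns pseudo-bulk structure and
  type-level differences; fine per-cell variation near the Poisson noise
  floor may require more epochs than the desk profile uses.
* The 3D reconstruction is a distance-embedding baseline; volumes are
  meaningful relatively (across pseudo-time windows), not absolutely.
* Pseudo-time is an input; the package does not infer trajectories.
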