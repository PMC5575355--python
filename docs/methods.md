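# Methods

## Model

A read-depth matrix **B** ∈ ℝ^{m×n} holds m samples (cells) over n genomic
bins, normalized so that the normal two-copy state maps to 0; copy-number
variants are then sparse deviations from 0. Two assumptions drive the
model: (i) variant signal is sparse after this normalization, and
(ii) related cells share copy-number patterns, so a good arrangement makes
adjacent rows similar. The estimate solves

    min_{X, P}  ‖P X − B‖²_F + α ‖X‖_{TV,ℓ1}

over permutation matrices P and signal matrices X, where the (TV, ℓ1) norm
is the per-column sum of absolute first differences along the sample axis.
The noise is modeled as zero-mean Gaussian. Real single-cell noise from
whole-genome amplification is over-dispersed relative to Gaussian; this
implementation follows the Gaussian model and does not attempt a
negative-binomial variant.

## Algorithm

With the splitting Y = DX the augmented Lagrangian

    L(P, Y, X) = α‖Y‖_{ℓ1,ℓ1} + ‖PX − B‖²_F + ⟨λ, DX − Y⟩ + (γ/2)‖DX − Y‖²_F

is minimized by exact alternating updates:

- **X**: `(2I + γDᵀD) X = 2PᵀB − Dᵀλ + γDᵀY`. With the circular
  first-order difference D (default) the system matrix is circulant and the
  solve is a per-column FFT, division by `2 + γ|K|²` (K = DFT of D's first
  column) and inverse FFT — O(m log m) per column. The open-boundary
  operator gives a symmetric tridiagonal system solved in banded form.
- **Y**: `S_{α/γ}(DX + λ/γ)` element-wise, the proximal map of the
  ℓ1 term.
- **P**: linear assignment with cost `C[i,k] = ‖X_k − B_i‖²`, solved
  exactly (Kuhn–Munkres / `scipy.optimize.linear_sum_assignment`). Because
  the assignment is a global optimum, the fidelity term never increases at
  this step. Zero-cost ties (exactly duplicated rows) are canonicalized
  toward the identity cycle-by-cycle so that X = B returns the identity
  ordering deterministically.
- **dual**: `λ ← λ + γ(DX − Y)` (standard augmented-Lagrangian ascent; the
  multiplier update is otherwise unconstrained by the model).

Initialization: P = identity, X⁰ = B, Y⁰ = DX⁰, λ⁰ = 0. The sweep order is
X, Y, P, λ. The solver contains no randomness.

### Why the parameters matter

The alternation has an unhelpful fixed point: with weak smoothing each
noisy row stays closest to its own denoised copy and the assignment step
returns the identity forever. Escaping it requires the X-step to form
*plateaus* spanning several samples, which the assignment step can then
populate with similar rows (each sweep re-sorting rows onto the current
plateau profile):

- **γ** sets the smoothing scale of the X-step — effective half-width
  ≈ √(γ/2) samples. Default `γ = 0.64·m` (≈ 6-sample smoothing at
  m = 100): wide enough to couple neighboring rows, narrower than a
  typical group. Values 25% larger or smaller degrade recovery on the
  benchmark.
- **α/γ** is the soft-threshold level. Default
  `α = 1.3·γ·mean(|ΔB|)` puts the threshold just above the typical
  adjacent-row absolute difference, so noise-scale differences collapse
  into plateaus while group-scale differences survive. The mean (not the
  median) of |ΔB| is used because on noiseless sparse data most
  differences are exactly zero and the median degenerates.
- **max_iters** default 1000; on the 100×300 benchmark arrangements lock
  in within ~150–300 sweeps. **tol** (1e−6) bounds the relative primal
  residual `‖DX − Y‖_F / max(‖DX‖, ‖Y‖, 1)` and relative objective change;
  a stall rule also stops the run when the ordering has not changed for
  `stall_window` (10) consecutive sweeps. On noisy data the assignment
  flickers among near-ties, so runs typically end at the iteration cap
  rather than the stall rule; the arrangement is stable long before.

### Rotation canonicalization

The circular TV energy is invariant to cyclic rotation of X's row space,
so the converged arrangement generically wraps one block across the seam.
The final ordering is rotated so that the largest adjacent raw-row jump
`‖B[o_i] − B[o_{i−1}]‖` sits at the display boundary. The jump is measured
on raw rows, not on the smoothed X, whose plateau transitions are smeared
over ~√(γ/2) samples and would misplace the cut.

### Segment-rearrangement polish

Row-level assignment moves cannot merge a group that has converged split
into two distant segments — that would need a coordinated block move
through higher-energy states. After the main loop the arrangement is cut
where adjacent raw rows jump by more than a threshold placed in the
largest gap of the sorted jump distribution. If this yields 3–7 segments,
all cyclic segment orders and orientations are enumerated and scored by
the summed ℓ1 distance across segment junctions; the best candidate is
refined with further sweeps and adopted only if its final energy is lower.
The pass is deterministic, a no-op for already-contiguous arrangements,
and disabled for the open boundary (`polish=False` turns it off
entirely).

With these defaults, on the standard benchmark (seeds 0–19) the solver
recovers all four groups as contiguous blocks in 20/20 noiseless runs
(block-ARI 1.0), 19/20 runs at SNR 3.57, 20/20 at SNR 2.82 and 20/20 at
SNR 1.55; each run takes on the order of a second.

## Synthetic data generator

The generator emulates the benchmark design used throughout validation:

- **Blocks**: n_groups (4) disjoint bin supports; all samples of group g
  carry amplitude g's value (defaults 1, 2, 3, 4) on support g and 0
  elsewhere. Rows from different groups are therefore exactly orthogonal,
  and rows within a group are identical before noise (an optional
  within-group jitter, default 0, relaxes this).
- **Noise**: i.i.d. zero-mean Gaussian. SNR is defined as the linear
  amplitude ratio sd(signal)/sd(noise) over all entries; the benchmark
  noise levels are SNR 3.57 (low), 2.82 (intermediate) and 1.55 (high).
  Given a target SNR the noise sd is set to sd(signal)/SNR and the
  achieved SNR is recomputed from the realized draw (within ~1% at
  100×300).
- **Irrelevant bins**: standard-normal columns inserted at uniformly
  random positions without replacement, with a mask recording them.
- **Shuffle**: a uniformly random row permutation, recorded as the
  ordering that restores the original.

What it does **not** emulate: over-dispersed amplification noise,
genome-coordinate structure (bins are abstract), GC or mappability biases,
or group intensity profiles with equal total signal. The last point
matters for baseline comparisons: with distinct per-group amplitudes on
equal-size supports, group row-sums are separated far beyond the row-sum
noise, so even a row-sum sort (the Quick Sort baseline) arranges the
groups correctly at all benchmark noise levels. Passing tests on this
generator therefore demonstrate recovery of orthogonal block structure
under Gaussian noise, not superiority over scalar sorting on intensity-
confounded designs, and not performance on real amplification noise.

## Laplacian-Score feature selection

Irrelevant bins (noise columns) are removed before solving by ranking each
bin's power of locality preservation on a sample graph: k-nearest-neighbor
graph (k = 5) under Euclidean distance, symmetrized, with heat-kernel
weights `S_ij = exp(−d²_ij/t)`; the bandwidth t defaults to the mean
squared kNN distance. For the degree matrix Deg and Laplacian L = Deg − S,
a feature column f centered by its degree-weighted mean scores
`(f̃ᵀLf̃)/(f̃ᵀDeg f̃)` — lower is more relevant. Zero-variance features
score +∞. Selection keeps the ⌈keep_fraction·n⌉ lowest-scoring bins in
their original order, breaking score ties toward lower bin indices. No
retention rule is implied by the model; `keep_fraction` is user-set (the
validation pipeline keeps 300/1300 on the 1,000-irrelevant-bin design and
recovers >80% true bins, typically 100%).

## Baselines and metrics

- **Quick Sort**: samples ordered by row sum (total aberration load),
  stable sort, ascending or descending.
- **Hierarchical clustering**: agglomerative on Euclidean distances
  (average linkage by default); the dendrogram leaf order is the
  arrangement and an n_clusters cut gives labels.
- **Metrics**: number of maximal runs of identical true labels along an
  arrangement (`count_label_blocks`; equals the group count iff recovery
  is perfect), the adjusted Rand index between contiguous-run assignment
  and true labels, and — for clusterings — the misclassification count
  under the optimal cluster-to-truth matching (linear assignment on the
  confusion matrix, hence invariant to label permutation).

## Numerical choices and degenerate inputs

- FFT output is validated: imaginary residue above `1e−8·‖X‖_F` raises a
  numerical-failure error naming the iteration.
- m = 2 and n = 1 are supported; an all-zero matrix converges immediately
  to X = 0 with the identity ordering.
- The assignment cost matrix is clipped at 0 to absorb rounding of
  `‖B_i‖² − 2B_iᵀX_k + ‖X_k‖²`.
- Matrices are serialized with 17 significant digits so a write/read round
  trip is bit-exact.

## Limitations

- The energy is non-convex in (X, P); the alternation finds a local
  minimum. The polish removes the dominant failure mode (a split group)
  but global optimality is not guaranteed — at low SNR one of twenty
  benchmark runs still ends with five blocks.
- Gaussian noise only; amplification bias in real single-cell data is
  heavier-tailed, and no claim is made about it.
- The P-step is O(m³) per sweep, the practical ceiling for sample count
  (m ≈ 100 is ~1 s for a full run; m in the thousands would need an
  approximate assignment).
- Real-data preprocessing (alignment, duplicate removal, binning, GC
  normalization) is upstream and out of scope; inputs are assumed
  normalized with two copies ↦ 0.
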