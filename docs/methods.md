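# Methods

## Model

A session is `q` aligned trials, each an `n`-species × `N_T`-time-point
recording.  Trials are vectorized species-major (columns grouped per species,
each group a full time course) and stacked into `X ∈ R^{q × n·N_T}`.  The
working assumption is that every row decomposes into a response common to
all trials plus a trial-specific aberration, modelled as

    X = L + S,   L low-rank,   S sparse,

and estimated by principal component pursuit,

    min ‖L‖* + λ‖S‖₁  s.t.  X = L + S,      λ = 1/√max(q, n·N_T).

The default λ is the universal weight from the pursuit recovery theory; it
can be scaled (e.g. ×0.8, a "20% discount") when the input is itself sparse
and the sparse penalty would otherwise absorb signal structure into `L`'s
rank.  The λ rule uses a square root; for the 50×20 reference geometry it
gives 1/√50 ≈ 0.141 and the discounted value 0.113.

Identifiability requires `L` incoherent (singular vectors spread out) and
`S`'s support scattered.  Sparse or eccentrically scaled inputs violate the
first condition.  The preprocessing step draws Ψ ∈ R^{m×n} with i.i.d.
N(0, 1/m) entries and applies `R = Ψᵀ ⊗ I_{N_T}` on the right: species
blocks are mixed, time columns never are.  The pursuit runs on `Y = X·R`;
with `m = n` and Ψ nonsingular (resampled until so) both components are
mapped back through `R⁻¹`, so `L̄ + S̄ = X` to solver tolerance.  With
`m < n` the results stay in projected space and are flagged, since no
canonical back-mapping of the sparse component exists under compression.
`R` is applied blockwise (`Y_j = Σ_i Ψ_{ji} X_i`); the dense Kronecker
matrix exists only as a test oracle.

Note the projection is a trade-off, not a free repair: a corrupted entry at
(trial, species i, time t) spreads across all m projected blocks at the
same (trial, t), so the projected corruption support grows by a factor of
up to n.  The method is therefore most effective when the corruption
fraction times n stays well below the pursuit's working range.

## Solver

Inexact augmented Lagrangian iteration:

    L ← SVT(X − S + Y/μ, 1/μ)          (singular-value thresholding)
    S ← soft(X − L + Y/μ, λ/μ)         (entrywise soft thresholding)
    Y ← Y + μ(X − L − S)

with μ₀ = 1.25/σ_max(X), dual start Y₀ = X / max(σ_max, ‖X‖_∞/λ), and μ
grown by 1.5 **only once the S-step has stabilised**
(μ·‖S_{k+1} − S_k‖_F/‖X‖_F < 1e-5).  Unconditional growth satisfies the
constraint quickly but freezes the L/S split far from the optimum, because
both proximal steps shrink like 1/μ; the conditional rule recovers planted
pairs to ~1e-7 where the unconditional variant stalls at ~1e-2.  Stopping:
relative Frobenius residual ≤ 1e-7 (default), cap 1000 iterations (the
harder synthetic benchmarks pass `max_iter=2000`); hitting the cap returns
the current iterate flagged unconverged.  SVD signs are fixed (largest-
magnitude entry of each left singular vector positive) so runs are
bit-reproducible.  "Rank of L" always means the number of singular values
above 1e-6·σ_max.

## Synthetic data

The generators define the study conditions; they emulate structure, not any
particular real dataset.

* **Sparse low-rank + corruption** (`gen_sparse_lowrank`,
  `add_sparse_corruption`): `X = U·Vᵀ` with Gaussian factors masked to 30%
  nonzeros per column (both factors), redrawn until the numerical rank
  equals the target exactly.  Defaults: q=50, n=2, N_T=10, rank 6,
  corruption on exactly ⌊0.05·q·n·N_T⌋ entries at ±4.5·RMS(X).  The
  amplitude makes ‖S_corruption‖_F ≈ ‖X‖_F at 5% support — corruption on
  the scale of the signal; with per-entry spikes much smaller than that,
  the convex optimum provably differs from the planted split (the solver
  attains a lower objective than the planted pair) and no pursuit
  implementation would report a matching sparse norm.
* **Neural trial tensors** (`gen_neural_trials`): per-neuron mean rates
  drawn from a skewed law on a 0–40 spikes/s range (the skew exponent is
  calibrated so the top-decile-mean/median ratio equals the requested
  eccentricity), a random subset of neurons active, shared nonnegative
  temporal templates scaled per neuron, optional Poisson spike binning.
* **Perturbation panels** (`simulate_perturbation_panel`): linearized
  network dynamics ẋ = A·x with one constant single-species forcing per
  perturbation, integrated by fixed-step RK4; row 0 is the wild type.  A
  must be stable (spectral abscissa < 0) unless explicitly overridden.
  Effects propagate through the network over time, so perturbing an
  upstream species moves downstream blocks but never the reverse.
* **Benchmark panels.**  `gen_subtype_panel` builds rows sharing a common
  rank-3 smooth response (coefficients jittered ±40% around a shared mean)
  plus subtype-specific aberration signatures: disjoint 16-column supports
  with fixed sign patterns, each row expressing a random 40% subset at
  ±1.5·RMS.  Raw row correlations are dominated by the common part and its
  jitter; the subtype signal is only separable after disentanglement.
  `gen_event_trials` builds exactly-rank-1 event-aligned trials (one
  smooth population signature, per-trial scale) with 5% of entries hit by
  ±8·RMS task-irrelevant spikes, and `embed_template_stream` plants the
  signature at known onsets in Gaussian noise at a given SNR
  (template RMS / noise SD).

What passing these benchmarks does **not** show: real recordings are not
exactly rank-1 (or rank-6), corruption is not i.i.d., and Poisson noise is
only a caricature of spiking variability.  The benchmarks test that the
machinery behaves as the theory predicts under its own assumptions.

## Detection and clustering

The template is the leading right singular vector of `L` (unit norm,
largest-magnitude entry positive); row-mean is available as an alternative.
Detection slides the template over a species-major stream window by window
and scores Pearson correlation (zero-variance windows score 0 and are
counted).  A detection event is a rising-edge threshold crossing — a
sustained excursion counts once.  For the ROC, an onset is a true positive
if a crossing falls within ±5 samples (default) or the onset itself lies
inside a suprathreshold excursion; crossings matched to no onset are false
positives; eligible negatives are the indices farther than the match window
from every onset.

Distances: `d_xy = 1 − Pearson` between raw rows (invariant to per-row
offset and positive scale, the reason it is standard for expression data);
`d_φψ` is the γ-weighted convex combination of the `L`-row and `S`-row
correlation distances, γ = 0.5 by default (equal weight; γ = 0 compares
common responses only, γ = 1 aberrations only).  All-zero sparse rows have
no correlation: two all-zero rows contribute sparse distance 0, a zero row
against a nonzero one contributes 1.  Clustering is scipy's agglomerative
linkage (average by default) on the condensed distance matrix, cut at k
clusters; a Newick export of the dendrogram is provided.

## Numerical choices and edge cases

* Zero input matrix → (0, 0) immediately, converged.
* λ extremes behave as expected: λ → large gives S → 0, λ → 0⁺ gives L → 0.
* `make_projection` resamples square Ψ with fresh sub-seeds until
  nonsingular; inversion warns when cond(Ψ) > 1e8.
* CSV/TSV matrices are written with 17 significant digits and parsed in
  round-trip mode, so text round trips are bit-exact; `.npz` archives embed
  the same metadata.  Every matrix travels with a JSON sidecar carrying
  (q, n, N_T, block layout, labels).
* Alignment windows are half-open 0-based `[onset−pre, onset+post)`;
  too-short trials are dropped and counted in the log.
* All generators and the solver are deterministic given seeds; named
  sub-streams are split from a single root seed.

## Known limitations

* Exact recovery at small matrix sizes (20×20) is not universal even for
  random incoherent instances; the test suite certifies planted pairs via a
  Dykstra-projection dual certificate before asserting exact recovery.
* Back-projection is only defined for square nonsingular Ψ; compressive
  mode returns projected-space components.
* The corruption-norm benchmark sizes (50×20, rank 6) sit far above the
  asymptotic pursuit regime (rank is 30% of the short dimension), so
  recovered ranks fluctuate by ±1 across seeds; only modal behaviour is
  asserted.
* No randomized/accelerated SVD: inputs are assumed small enough for dense
  LAPACK (thousands of columns at most).
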