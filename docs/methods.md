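# Methods

## Problem and scope

`hsiclass` re-implements, as a from-scratch inference engine, per-pixel
classification of hyperspectral skin-lesion cubes by three classifier
families: a one-vs-one RBF support-vector machine, a random forest, and
gradient-boosted decision trees. A cube is a `height x width x n_bands`
reflectance array with values in [0, 1]; each pixel's spectrum is
classified independently into one of five tissue/lesion classes. The
package covers **inference only**: models are loaded from JSON or
constructed synthetically, never trained — training, hyperparameter
search, and import of third-party binary model formats are out of scope.

The clinical dataset the design targets (snapshot-camera cubes of
50 × 50 pixels with 116 preprocessed bands over 450–950 nm, five
classes) is private. All quantitative guarantees in this repository are
therefore stated and verified on synthetic scenes with analytically
known ground truth (see below), never on clinical data.

## The three decision rules

**SVM.** For a pixel `x`, the engine evaluates the RBF kernel
`K(w_s, x) = exp(-γ ||w_s − x||²)` against every support vector `w_s`,
then forms one decision value per ordered class pair `(i, j)`, `i < j`,

```
d_ij = Σ_s coef(i,j,s) · K(w_s, x) + b_ij ,
```

and votes: `d_ij > 0` credits class `i`, otherwise (including exactly
zero, preserved deliberately from the serial reference procedure) class
`j`. The winner is the smallest class index attaining the maximum vote
count. The dual-coefficient storage follows the standard grouped
one-vs-one convention — an `(n_classes − 1) × n_sv` matrix where, for
pair `(i, j)`, coefficients of class-`i` support vectors are read from
row `j − 1` and those of class `j` from row `i` — the only widely used
convention consistent with that shape, and byte-compatible with what
libsvm-style trainers export (verified against a fitted scikit-learn
`SVC` in the test suite). Intercepts are stored per pair (length
`n(n−1)/2`); a shared scalar bias is the special case of a constant
vector.

**Random forest.** Trees are node arrays (feature, threshold, children,
leaf payload); traversal descends left iff `x[feature] ≤ threshold`
(the dominant CART convention; the boundary case is tested explicitly).
Each tree votes the argmax of its leaf's class-probability array and
the forest prediction is the most-voted class — hard voting, not
probability averaging, matching the serial reference procedure even
though averaging is more common elsewhere. The vote accumulator is an
order-independent integer tally, so the result provably equals the
sequential tally regardless of how tree evaluations are scheduled (the
testable content of an atomic-add accumulation).

**Gradient boosting.** The tree at position `e · n_classes + i` is
estimator `e` of class `i`; its single leaf value adds to the class
margin `Z[i]`. Probabilities are the soft-max
`P[i] = exp(Z[i]) / Σ_j exp(Z[j])`, computed max-shifted for overflow
safety (mathematically identical, since the common factor cancels), and
the prediction is the argmax. The class-fastest tree interleaving
matches what gradient-boosting trainers emit (verified against a fitted
XGBoost model in the test suite; the trainer's shared base score is a
uniform margin shift and cancels in the soft-max).

Every argmax in the package breaks ties toward the smallest class
index, uniformly across the three engines.

## Execution plans

The reference design runs these engines as data-parallel kernels. The
algorithmic content of its schedules is kept as pure functions:

- `launch_blocks(N, t) = ceil(N / t)` — block count for `N` work items
  at `t` threads per block (default 32, one warp). With the full-size
  clinical SVM's 47 220 support vectors this gives 1476 blocks.
- `pad_to_pow2(n)` — reduction buffer width (512 for 400 estimators).
- `sequential_reduce` — the sequential-addressing tree reduction:
  zero-pad to a power of two, then for each stride `s` halving from
  `width/2` to 1 do `S[t] += S[t+s]` for `t < s`. Zero padding makes it
  exact on integers; on reals it agrees with the direct sum to ≤ 1e−9
  relative (both are ~400-term sums of O(1) values).
- `plan_xgb_reduction(E, C)` — the 2-D grid: one x-block of
  `pad_to_pow2(E)` work items, `C` y-blocks (one per class).

Actual accelerator execution is a non-goal. Instead the cube
classifiers carry a **chunked-execution contract**: for every chunk
size, the batched path equals the per-pixel scalar loop label-for-label
(tested at chunk sizes 1, 7/13, 32, and whole-cube). The batched SVM
kernel uses the expanded form `||w−x||² = ||w||² + ||x||² − 2 w·x`
(clamped at zero against rounding residue); batched tree traversal
advances all pixels in lock-step from the root. Boosted margins are
accumulated in the same estimator order as the scalar loop, so the sums
are bitwise identical per pixel. An accelerator backend could consume
`LaunchPlan` objects unchanged.

## Canonical formats

Cubes and label maps use a two-file container: a flat little-endian
binary payload, band-interleaved-by-pixel (row-major pixels, so linear
pixel index `p = row · width + col`), plus a JSON sidecar declaring
dims, dtype, byte order and the band range. JSON is also the canonical
model format (`model_type` discriminator, arrays as nested lists;
Python's repr-based float encoding makes round-trips bit-exact). An
ENVI-header reader (bip/bil/bsq) is provided as an import convenience
only. Per-pixel min–max normalization to [0, 1] (constant spectra → all
zeros, making the function total and idempotent) is a documented
stand-in for the patient-level illumination normalization applied to
the clinical data by its own preprocessing pipeline, whose exact
procedure is external to this package.

## Synthetic study conditions

The generator's defaults mirror the clinical data's shape: 5 classes,
116 bands, 50 × 50 cubes, values in [0, 1].

- **Signatures** are clipped, mean-centred smoothed random walks
  (moving-average window 9 over uniform steps, rescaled so band-to-band
  increments stay below the smoothness bound, default 0.05) around
  distinct base reflectance levels (a random permutation of evenly
  spaced levels in [0.15, 0.85]). Clipping to [0, 1] is 1-Lipschitz and
  preserves the smoothness bound. Draws repeat (bounded at 100) until
  the smallest pairwise Euclidean distance reaches 0.5; with ≥ 12 bands
  the first draw essentially always succeeds, and at 116 bands typical
  separations are ≈ 2–3.
- **Scenes** assign a class per pixel (quadrants-plus-central-disc or
  uniform random layouts) and add i.i.d. Gaussian noise (default
  sd 0.02) to the class mean, clipped back to [0, 1] — the simplest
  noise model with a controllable SNR.
- **Constructed models.** The centroid SVM (one support vector per
  class, pairwise coefficients ±1, zero intercepts, γ = 10) is exactly
  a nearest-centroid classifier, because the RBF kernel is strictly
  decreasing in distance — giving a brute-force oracle for every
  prediction. The separating forests use axis-aligned midpoint splits
  on maximally separating bands, arranged as per-class membership
  chains (rf: a decision list over classes with one-hot leaves, 425
  trees by default; xgb: per-class indicator trees with leaf margin +1,
  400 estimators per class = 2000 trees). Successive estimators rotate
  through the candidate bands of each class pair (every band whose mean
  gap is at least half the best gap, order shuffled by seed), so under
  noise the ensemble averages several independent band checks.
  Construction is verified at build time: every noiseless class mean
  must classify to its class, else the signatures are rejected as
  inseparable.

What the synthetic scenes do **not** emulate: biophysical skin optics,
camera noise structure, spatial correlation, patient-level variability,
or class imbalance of real lesion data. Passing the recovery checks
demonstrates that the inference engines and their batching are correct
and that the constructed models behave as designed — it says nothing
about clinical classification accuracy.

## Verification strategy and problem sizes

The suite cross-checks every engine against an independent oracle:
exhaustive enumeration (all 2¹⁰ one-vs-one sign patterns; all 3-node
tree sentinel configurations), brute-force re-implementation
(nearest-centroid search, per-tree tally loops, term-by-term kernel
expansion), closed forms (soft-max of equal margins, kernel at zero
distance), and independently fitted reference models (scikit-learn SVC
decision values; per-tree predictions of a fitted random forest; soft-max
probabilities of a fitted XGBoost booster, to 2e−5 absolute — the
reference evaluates in float32). Hypothesis property tests cover the
bounded-kernel, vote-conservation, normalization-idempotence,
soft-max-shift and launch-geometry invariants with fixed seeds.

Recovery checks run at the full default geometry (50 × 50 × 116, five
classes, 425/2000 trees): noiseless scenes must classify at exactly
100% for all three engines, and at noise sd 0.02 the accuracy averaged
over five seeds must stay ≥ 95% (with the default separation ≥ 0.5 the
measured value is 100%: the nearest decision boundary sits several
noise standard deviations from every class mean). Oracle-equivalence
sweeps use 5 × 6-pixel cubes with 12-band models, 20 cubes per run —
sizes chosen so the whole suite completes in seconds while still
exercising chunk boundaries (chunk sizes 1, prime, warp-width, and
whole-cube).

## Numerical and degenerate-input choices

- Kernel values are computed in full double precision; no approximate
  or low-rank kernel paths.
- The batched squared distance is clamped at zero before
  exponentiation (the expanded form can go slightly negative for
  near-identical vectors).
- `d_ij = 0` votes for class `j` (the literal else-branch), a
  measure-zero case kept for fidelity.
- Leaf sentinel is −1 in `feature_idx` and both children; child indices
  must strictly exceed the parent's, which makes termination a static
  property checked at load (`validate_tree` also does a full traversal).
- Per-class accuracy of an absent class is reported as undefined
  (NaN/null), never zero, to avoid silently biased summaries.
- Empty reduction input is an error; a single element reduces to
  itself (width 1, no strides).

## Known limitations

- Wall-clock timings logged by the CLI are diagnostics only; no
  performance claim is made or tested (the reference design's speed-ups
  are hardware-bound and outside desk-scale reproduction).
- The min–max normalization stand-in is not the clinical preprocessing
  pipeline's procedure; cubes normalized differently will shift SVM
  kernel distances.
- Whether clinical random-forest leaves store class frequencies or
  one-hot indicators is unspecified upstream; both are representable in
  the payload vector and both are covered by tests.
- The synthetic fifth class is abstract; the clinical taxonomy's fifth
  class (beyond the four lesion types) is not identified in the source
  material.
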