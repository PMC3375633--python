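# Methods

## Problem setting

A voxelated expression atlas assigns every gene a spatial map: one
log₂-ratio value per occupied cell of a grid mask laid over a tissue
slice.  Genes themselves carry no target attribute, so the analysis is
reformulated over *pairs*: the sample is an unordered gene pair, the
features measure how the two maps differ, and the label is a functional
similarity computed from ontology annotations.  The learned model answers
"how functionally similar are two genes, given only where they are
expressed?", and its feature weights identify the voxels that carry that
signal.

## Grid masks and cell ordering

A mask declares the grid rectangle, the occupied cells, and the
hemisphere mirror pairing.  Cells are addressed `A1..`-style and ordered
row-major everywhere, so feature indices are stable across runs.  The
default pairing reflects column *j* onto column *n_cols+1−j* within each
row; a mask file may override it.  Cells whose mirror is unoccupied pass
through hemisphere averaging unchanged (treated as center cells), so the
pairing always partitions the occupied set even for asymmetric masks.

The reference geometry of the original atlas (68 voxels; 61 horizontal,
57 vertical, 53 diagonal neighbor pairs) was published only as a figure,
not machine-readably, so masks are configuration artifacts: the package
validates declared neighbor counts at load time but never guesses the
unpublished layout.  The reference *feature layout* (42 wavelet slots,
68 voxels, 3 statistics, 171 neighbor pairs → 455 slots) is likewise a
declared configuration; any concrete mask produces its own segment
lengths.

## Per-gene features

* **Hemisphere averaging** replaces each mirror pair by its mean,
  suppressing uncorrelated microarray noise by √2 under bilateral
  symmetry.
* **Wavelet features**: the averaged half-map is embedded in its bounding
  rectangle (unoccupied cells zero-filled, a deterministic choice), then
  decomposed with a multilevel 2-D DWT.  Defaults: Haar (db1), symmetric
  extension, level 3; all configurable.  Coefficients are concatenated
  coarsest-first (approximation, then per level the horizontal/vertical/
  diagonal detail bands, row-major).  A level is rejected as too large
  only when the approximation would collapse to 1×1 before the final
  level.
* **Voxel values**: the raw, un-averaged map.
* **Neighbor-pair features**: for each adjacent occupied pair (horizontal,
  vertical, both diagonals of every 2×2 block), the mean `(A+B)/2` and the
  gradient `|A−B|`, computed on the full un-averaged map.

Genes whose entire profile lies inside `[−1, 1]` (log₂ scale) are
discarded before analysis: a profile that never leaves the noise band
carries no signal.  A single strong voxel anywhere retains the gene.

## Labels: ontology similarity

Information content is `IC(t) = −ln(n(t)/N)` in nats, where `n(t)` counts
corpus genes annotated to `t` or any is-a descendant and `N` is the number
of annotated genes in the loaded annotation file (one namespace per
analysis; the log base cancels in Lin's ratio).  Annotations propagate
over is-a edges only.  Lin similarity is `2·IC(MICA)/(IC(f₁)+IC(f₂))`,
with the MICA the annotated common ancestor of maximal IC (ties broken by
term id) and the convention `sim = 0` when both terms have zero IC.  The
gene-pair label d_F averages the strictly positive cross-pair
similarities (Γ counts them) and is 0 when Γ = 0 or an annotation set is
empty (logged).  d_F is a *similarity*: 1 means identical function sets.

Binary class labels use a strict threshold: +1 iff d_F > τ (defaults:
τ = 0.3 for the full analysis, 0.67 for correlation-restricted subsets).

## Pair samples and subsets

Pair features are element-wise `|W₁ − W₂|`, with Pearson R, its two-sided
p-value (t distribution, n−2 df) and the Euclidean distance spliced in
after the voxel segment.  R/P/dE are computed on the raw voxel vectors by
default and on the wavelet coefficients for curve analyses (both
exposed).  Pairs are generated streaming — descriptors are computed once
per gene and pairs yielded lazily — so memory is linear in genes, not
quadratic.  Undefined R (constant map) is a NaN sentinel: such pairs are
excluded from curves and correlation filters, and enter training features
as 0 with a log record.  Correlation restriction keeps pairs with
R > ρ strictly (default ρ = 0.7).  A membership list (detected expression
profiles) may subset the genes before pairing; profile detection itself
is out of scope and consumed as input.

Train/test splits draw a seeded permutation with
|train| = round-half-up(fraction·n).

The correlation-vs-similarity curve bins R into left-closed, right-open
`[−1, 1]` bins of width 0.1 (last bin closed) and reports per-bin counts
and mean labels; empty bins carry NaN.

### Statistical form of the curve-trend check

Pair samples sharing a gene are dependent, so the monotonicity of the
curve's high-R tail is asserted statistically, not sample-exactly:
standard errors use the number of *distinct genes* per bin as the
effective sample size, adjacent-bin decreases are accepted when within
z = 2.576 (99%) standard errors of the difference, and the tail must
exceed the low-R baseline mean by the same margin.  At the generated
sample sizes the expected curve is non-decreasing but flat once bins are
dominated by within-archetype pairs, so exact per-bin monotonicity of
sample means is not a guaranteed property and is not asserted.

## Boosting

The weak classifier for feature *i* divides the feature's training
`[min, max]` into M uniform bins and attaches a ±1 label per bin — the
sign of the summed weight×class mass of the samples in the bin.  Rules
fixed for determinism:

* empty bins and exact zero-sum (tied) bins inherit the label of the
  nearest decided bin, distance ties toward the lower index; if no bin is
  decided, all take the global weighted-majority label;
* out-of-range values at prediction time clamp to the end bins (test
  values may exceed the training range);
* a constant feature degenerates to a single bin predicting the weighted
  majority and is never selected by the ensemble;
* feature-selection ties break to the lowest feature index and sample
  order is taken as given, making training bit-reproducible.

The boosting loop is standard discrete AdaBoost; ε_t ≥ 0.5 stops training
(an empty ensemble with a warning if it happens in round 1; an empty
ensemble scores 0 and classifies as the negative class).  α_t floors ε at
1e-10, and a zero-error round is included and then terminates training.
Because bin edges do not depend on the sample weights, bin assignments
are computed once; each round costs O(samples × features) via weighted
bin counts, which is what makes tens of thousands of samples × hundreds
of features tractable.

Defaults: M = 20 bins for classification, M = 100 for regression
(matching the two experimental regimes the method was designed around);
T = 1000 rounds.  Regression binarizes continuous labels in [0, 1] at a
threshold (label median when unset), boosts the binary problem, outputs
the logistic transform of the score, and reports RMSE against the
original labels.

Cumulated feature weights (Σ α_t per selected feature) rank features;
the report module maps voxel-segment indices to cell labels and
neighbor-pair indices to cell-pair labels for spatial interpretation.
Wavelet slots are reported without spatial mapping (each coefficient has
extended support).

## Synthetic data

The generator emulates the study conditions: a symmetric, connected
68-voxel mask carved from a 7×11 rectangle; archetype base maps drawn as
Gaussian fields smoothed with a 3×3 box kernel (so wavelet features are
informative), amplitude set (base_sd = 3.0 before smoothing) so profiles
clear the `[−1, 1]` noise filter; per-gene maps are base + i.i.d.
N(0, noise_sd).  Each archetype owns a disjoint subtree of a synthetic
is-a tree; a gene draws its 3 terms from its archetype's block with
probability `coupling`, else uniformly from all leaves.  Defaults
(345 genes — the size of the profile-associated subset the method
targets —, 5 archetypes, noise_sd 0.5, coupling 0.8, depth-4 ontology
with 5-way branching) were chosen once as plausible study conditions.
Everything is driven by one integer seed and bit-reproducible.

What the generator does *not* emulate: real GO topology (it uses balanced
trees with disjoint archetype blocks), annotation biases and evidence
codes, microarray normalization artifacts, spatial noise correlation, and
a continuum of map similarity — archetype membership is discrete, so the
similarity curve saturates at high R instead of rising all the way.
Passing tests therefore demonstrate correct mechanics and recoverability
under idealized coupling, not performance on real atlases.

## Problem sizes used in checks

The packaged checks run the full method at reduced scale, chosen as the
package's own test conditions: oracle equivalence on 200 samples × 10
features × 50 rounds; recovery on 64 genes (2,016 pairs, ~1,000 per
split) with 2 archetypes at noise 0.3; the curve on 120 genes (7,140
pairs); bookkeeping enumerations at the full 345-gene count.  The
streaming contract supports the 31M-pair full-atlas scale but it is not
exercised in tests.

## Known limitations

* Lin similarity is the only semantic measure implemented (no Resnik,
  Jiang–Conrath, Wang), and is-a is the only propagated relation
  (part-of is ignored by default).
* The exact half-grid rectangle that yields 42 level-3 coefficients for
  the original atlas is not derivable from the published material; the
  42-slot wavelet segment is a declared expectation, and generated masks
  produce their own (validated) lengths.
* The original atlas's neighbor counts (61/57/53) cannot be reproduced
  without the original mask figure; they are validated only when a mask
  file declares them.
* Binary classification and logistic regression only; no multiclass
  split, alternative boosting variants, or SVM baselines.
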