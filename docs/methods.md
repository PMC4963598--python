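# Methods

This note records the models, protocols, numerical conventions and design
choices behind `colonyqc`, and what its synthetic data can and cannot show.

## Problem and feature model

Three colony phenotypes are graded from grayscale microscopy images:
*good* (rounded, even translucent color, defined edges), *semigood*
(changed color/structure, edges still clear) and *bad* (partially lost
edges, vacuoles, three-dimensional areas). Classes are coded 1 = bad,
2 = good, 3 = semigood throughout.

Each image is represented by its **mean SIFT descriptor**: SIFT keypoints
are extracted at the backend's default parameters and the element-wise
mean of the n×128 descriptor matrix is the image's feature vector. The
mean is permutation-invariant and lies inside the element-wise envelope of
the descriptors; it discards keypoint locations and the descriptor
distribution's shape, which is the price of avoiding bag-of-features
clustering. The SIFT backend is `skimage.feature.SIFT`. Descriptor values
are backend-dependent, so no test or result pins absolute descriptor
numbers — only the dimension (128), determinism, and the aggregation
arithmetic are contractual. Images are rescaled to [0, 1] by the bit
depth of the source file before extraction; multi-channel images are
converted by Rec. 601 luminance. An image with zero keypoints raises an
error rather than contributing a zero row: real colony images always
produce keypoints, and silent zero rows would poison fold standardization.

## LS-SVM

Training solves the (m+1)-dimensional saddle-point system

    [0  yᵀ; y  Ω + I/C] [b; α] = [0; 1],  Ωᵢⱼ = yᵢyⱼK(xᵢ,xⱼ)

by one dense direct solve (`numpy.linalg.solve`). No iterative or sparse
solver is used: m stays in the hundreds, and exactness aids testing — the
residual of the assembled system is checked to < 1e−8 and Σαᵢyᵢ = 0 to
1e−10·m. The regularization enters as I/C on the diagonal, exactly as the
system is written. On the symmetric two-point toy (x = ±1, y = ±1, linear
kernel, no scaling) the closed form is α₁ = α₂ = C/(2C+1), b = 0, which
the tests verify to 1e−10.

Kernel conventions (the source protocol names the kernel families but not
their algebraic forms, so these are fixed here and documented prominently
because the 2⁻¹⁵…2¹⁵ grids interact with them):

* polynomial: inhomogeneous `(x·z + 1)^d`, d ∈ 2…6 — the offset avoids
  degenerate odd/even behavior;
* RBF: `exp(−‖x−z‖²/(2σ²))` with σ the width of the Gaussian.

A decision value of exactly 0 predicts +1 (deterministic, measure-zero tie
rule). **Autoscaling**: each binary classifier z-scores its own training
subset and applies the stored μ/σ to every test point; zero-variance
columns use σ = 1 so they contribute 0 after centering (this matters in
LOO folds of small data). Models serialize to JSON with repr-precision
floats, which round-trips IEEE doubles bit-exactly.

## Multiclass schemes

* **OVA**: M binaries, class i vs rest, each trained on all rows. A unique
  positive output decides. Otherwise the tied set is the set of positive
  classes, or *all* classes when every output is negative — the most
  conservative reading of "every classifier says rest". Ties go to the
  1-NN solver below. Winner-takes-all on the real outputs is available as
  an optional alternative policy (`tie_policy="wta"`), off by default.
* **OVO**: M(M−1)/2 pairwise binaries; pair (i, j), i < j, maps class i to
  +1 and trains only on those two classes' rows (autoscaled on that
  subset). Majority vote; vote ties go to the 1-NN solver. Votes always
  sum to M(M−1)/2.
* **DAGSVM**: training identical to OVO. Prediction evaluates the root
  pair, eliminates the loser, then pairs the two lowest-indexed surviving
  classes — exactly M−1 evaluations, no ties. For M = 3 the three
  structures correspond to the three root pairs. The "two lowest-indexed
  survivors" rule is this package's generalization beyond M = 3, where the
  original construction is only instantiated for three classes.
* **Binary-tree OVA**: node k separates elimination_order[k] from the
  not-yet-eliminated classes; the final node is a plain pair, making the
  last two classes interchangeable (M!/2 distinct trees, canonicalized by
  listing the smaller of the final pair).

**1-NN tie solver**: Euclidean nearest training row among the tied
classes, equidistant neighbors broken by lowest row index. It operates in
the *fold-level* standardized space (the fold's full training table), not
in any binary's pair-subset scaling: the tie solver is
classifier-independent, so a single consistent space is required. Whether
pairwise binaries should standardize over their two-class subset or the
full fold is genuinely open; per-classifier autoscaling (pair-subset) was
chosen as the reading most consistent with "autoscale per classifier", and
it does change results.

## k-NN

Seven distances — Chebyshev, cityblock, correlation, cosine, Euclidean,
standardized Euclidean, Spearman — and three weightings (equal, 1/d,
1/d²). The correlation/cosine/Spearman forms are 1 − similarity, with
average ranks on ties for Spearman; these are conventions of the
statistical software ecosystem, asserted against independent formulas in
tests. Standardized Euclidean uses the current training fold's per-feature
sample sd; since the protocol already z-scores folds, those scales are ≈1,
but both layers are retained for protocol fidelity. Edge cases: neighbors
at distance exactly 0 carry all weight under inverse weightings (no
infinities); the k-th-position distance tie is broken by lowest row index;
an exact class-score tie is broken by a seeded uniform choice. The tie RNG
stream is keyed by (rng_seed, CRC32 of the query vector's bytes), so
replays are bit-identical and results are invariant to the order in which
test points are evaluated.

## Baselines

Classification tree (Gini, binary splits, no depth limit, no pruning),
LDA, multinomial logistic regression (unpenalized LBFGS) and Gaussian
naive Bayes delegate to scikit-learn; settings are logged at fit time.
Naive Bayes with kernel-density estimation is implemented here: class
priors are training proportions; each class × feature pair gets a 1-D KDE
with normal, box, Epanechnikov or triangle kernel and normal-reference
bandwidth h = 0.9·min(sd, IQR/1.34)·n^(−1/5) (logged per fit; a
zero-spread feature falls back to h = 1). Posterior ties break toward the
lowest class index. LDA first verifies that the pooled within-class
covariance has full rank and raises otherwise — with 128 features and
~173 examples this is exactly the singular-covariance failure mode that
rules out QDA and the Mahalanobis discriminant, which are therefore not
implemented.

## Evaluation protocols

Plain LOO (baselines): per fold, fit the scaler on the N−1 training rows,
scale the held-out example by that μ/σ, fit, predict; measures are
computed once at the end. Nested LOO (k-NN, SVM schemes): an inner LOO
over each training fold scores every grid point with per-inner-fold
standardization; the highest inner accuracy wins, ties broken by canonical
grid order (ascending k; ascending C, then ascending σ) — deterministic
and favoring smoother models, since the source protocol does not say how
its ties were broken. The winner is refit on the whole training fold and
the held-out example predicted; selections are recorded per fold. One
shared grid point governs all sub-classifiers of a multiclass scheme;
per-binary tuning is deliberately not offered.

Grid points whose solver fails (e.g. ill-conditioning at extreme C) are
skipped and logged rather than fatal, so the full printed grid remains
traversable on arbitrary data; if the selected point fails at refit, the
next-best point is used. The protocol-level z-score is applied once per
fold; SVM autoscaling then operates on already-standardized data —
idempotent for OVA, a genuine re-centering for pair/node subsets. Outer
folds are independent; nothing in a fold depends on evaluation order.

Full grids are 31 C values, 961 (C, σ) pairs and 12 k values. An
exhaustive RBF sweep at N = 173 means 172 × 961 inner fits per outer fold;
tests and the acceptance script therefore run a reduced 5-point C grid
with the linear kernel at N = 60, which exercises every protocol path at
desk scale.

## Synthetic data

`generate_colony_image` renders one roughly elliptical colony (darker,
base intensity ≈0.55) on a lighter background (≈0.88): edge sharpness is
the Gaussian blur width of the colony boundary (sharp ⇒ sub-pixel, lost ⇒
~5% of the image scale); interior texture is band-limited noise scaled by
the heterogeneity knob and floored at 0.35; vacuoles are dark disks
(intensity 0.05, recoverable by thresholding below 0.25); bumps are bright
Gaussian domes. Class presets order the knobs as the phenotypes demand
(edge sharpness good > semigood > bad; heterogeneity good < semigood <
bad; vacuoles/bumps only outside good). Per-image seeds are base_seed +
index; every output is a pure function of its spec. Default size is
256×256 — SIFT cost scales with pixels and the class signal lives in
texture/edge statistics, not resolution; the native 1608×1208 is
supported. The default dataset composition is 41/74/58 (bad/good/
semigood), 173 images.

`generate_feature_table` draws per-class Gaussian rows. Default class
means spike two coordinates per class (at separation·sd/2 each, so
pairwise mean distance is exactly separation·sd, default 10·sd): distinct
axes give cosine/correlation a directional signal and two spiked
coordinates give rank-based Spearman a usable signal, which a single
spiked axis does not at d = 8. With d < 6 a single axis per class is used.

**What passing tests show — and do not.** The generator reproduces the
texture/edge statistics that separate the classes and the dataset's class
imbalance; it does not model feeder-cell layers, illumination gradients,
microscope optics, or the intra-class variability of real colonies (which
is not quantified anywhere; knob ranges are this package's choices).
Perfect recovery on 10·sd-separated blobs validates the *protocol and
implementations*, not real-world grading accuracy: published accuracies
on the real 173-image dataset are in the 35–62% range and cannot be
reproduced without those images. Rank-based k-NN measures may drop an
occasional example even on 10·sd blobs (Spearman sees only feature
orderings); the recovery criterion is ≥95%, and exact-100% unit tests use
a wider 20·sd margin.

## Known limitations

* SIFT descriptor values differ across backends; features extracted here
  are not numerically comparable to other implementations' output.
* The exhaustive 961-pair RBF nested LOO at N = 173 is computationally
  heavy by design (the protocol is quadratic in N per grid point); use
  reduced grids for exploration.
* DAG semantics for M > 3 and the M!/2 tree enumeration are documented
  generalizations; only M = 3 is exercised by the grading application.
* The KDE naive Bayes evaluates all training rows per query (O(n·d));
  fine at N ≤ a few hundred.
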