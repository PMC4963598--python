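# colonyqc

Automated quality grading of human induced pluripotent stem cell (iPSC)
colony images.

When iPSC colonies are cultured at scale, their quality must be monitored
continuously: only colonies of good morphology — rounded shape, even
translucent color, sharply defined edges — should be carried forward, while
colonies with changed internal structure (*semigood*) or with lost edges,
vacuoles and three-dimensional areas (*bad*) must be flagged. `colonyqc`
implements a complete texture-based grading pipeline for this three-class
problem, aimed at researchers comparing classifier designs for colony
quality control.

## Method

**Features.** Each grayscale microscopy image is reduced to a single
128-dimensional vector: the element-wise mean of all of its SIFT keypoint
descriptors. Averaging bypasses bag-of-features codebook construction
entirely — no clustering and no codebook size to tune.

**Least-Squares SVM.** The binary classifier is an LS-SVM: with training
pairs (xᵢ, yᵢ), yᵢ ∈ {−1, +1}, kernel K and regularization C, equality
constraints replace the hinge loss, so training reduces to one dense linear
system in (b, α),

```
[ 0   yᵀ        ] [ b ]   [ 0 ]
[ y   Ω + I/C   ] [ α ] = [ 1 ],      Ωᵢⱼ = yᵢ yⱼ K(xᵢ, xⱼ),
```

and the decision function is f(x) = sign(Σᵢ αᵢ yᵢ K(x, xᵢ) + b). Seven
kernels are supported: linear, polynomial of degrees 2–6 (form
(x·z + 1)^d), and Gaussian RBF exp(−‖x−z‖²/(2σ²)).

**Multiclass schemes.** Four decompositions over binary LS-SVMs:
one-versus-all and one-versus-one (with a 1-NN Euclidean tie solver over
the tied classes), DAGSVM (trained like OVO, predicting by class
elimination along a decision DAG — all three DAG structures for M = 3 are
enumerable), and binary-tree OVA (a chain of one-versus-rest nodes — all
three elimination orders enumerable). Structures are numbered 1–3 (DAG
root pairs bad/good, bad/semigood, good/semigood) and 4–6 (tree roots bad,
good, semigood).

**Baselines.** A distance-weighted k-NN with seven distance measures
(Chebyshev, cityblock, correlation, cosine, Euclidean, standardized
Euclidean, Spearman) and three weightings (equal, 1/d, 1/d²), plus
classification tree, LDA, multinomial logistic regression, and naive Bayes
with Gaussian or kernel-density (normal/box/Epanechnikov/triangle)
per-feature class densities.

**Evaluation.** Parameterless baselines run under plain leave-one-out
(LOO); k-NN and the SVM schemes run under *nested* LOO: an inner LOO on
each training fold selects k (odd, 1–23) or C, σ ∈ {2⁻¹⁵, …, 2¹⁵} by inner
accuracy, the winner is refit on the whole fold and the held-out example
is predicted. Every fold is z-score standardized by its own training
statistics; the held-out example never contributes to them. Reported
measures are per-class true positives, per-class true-positive rates, and
overall accuracy (trace of the confusion matrix over its total).

Because the original 173-image colony dataset is not publicly deposited,
the package ships a seeded synthetic generator that emulates the three
class morphologies (edge sharpness, texture heterogeneity, vacuoles,
bumps) and their 41/74/58 (bad/good/semigood) composition, plus an
abstract Gaussian feature-table generator for classifier tests.

## Worked example

```
$ colonyqc generate --n-bad 2 --n-good 2 --n-semigood 2 --size 128 --seed 0 --out-dir demo
wrote 6 images; manifest at demo/manifest.csv

$ colonyqc extract --manifest demo/manifest.csv --out demo/features.csv
wrote 6x128 feature table to demo/features.csv
```

Evaluate one arrangement — k-NN with Euclidean distance and equal weights
under nested LOO — on a synthetic 60-example feature table (config YAML):

```
$ cat demo/run.yaml
method: knn
measure: euclidean
weighting: equal
seed: 1
out_dir: demo/results
synthetic:
  n_per_class: [20, 20, 20]
  dim: 8

$ colonyqc run --config demo/run.yaml
        arrangement         Bad        Good    Semigood    ACC
knn-euclidean-equal 20 (100.0%) 20 (100.0%) 20 (100.0%) 100.0%
```

Each class column shows the true-positive count and rate — here all 20
bad, 20 good and 20 semigood examples are recovered, so nested-LOO
accuracy is 100% (the synthetic class means sit 10 standard deviations
apart, so perfect recovery is the expected outcome). `colonyqc sweep
--list` enumerates all 85 arrangements (7 kernels × 8 SVM schemes, 21 k-NN
combinations, 8 baselines); `colonyqc report` aggregates their results
CSVs.

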