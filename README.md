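# percepspace

Tools for recovering an interpretable, low-dimensional *psychological face
space* from pairwise similarity judgments.

Human observers can say how similar two faces look, but not what coordinate
system they use to judge it. `percepspace` estimates that coordinate system:
starting from any fixed image embedding (its own Active Appearance Model
front-end, or an external feature matrix), it learns a linear transformation
of the embedding such that squared Euclidean distance in the transformed
space reproduces mean human dissimilarity ratings — and uses rank-reducing
regularization to ask *how few* perceptual axes suffice.

It is written for computational cognitive scientists and psychophysicists
working with similarity-judgment data: the package covers the full path from
raw per-rater Likert scores to a fitted, eigendecomposed metric, plus the
analyses one runs on it (dimensionality curves, demographic subspaces,
group-centroid dissimilarities, downstream trait prediction, an MDS
baseline, and face synthesis along perceptual axes).

## The model

Each image *i* has an embedding **x**ᵢ ∈ ℝⁿ. Perceived dissimilarity is
modeled as the PSD quadratic form

    f(xᵢ, xⱼ) = (xᵢ − xⱼ)ᵀ W (xᵢ − xⱼ) + b,     W ⪰ 0,  b ≥ 0,

fit by least squares against mean normalized dissimilarity scores d̄(i,j) ∈
[0, 1], optionally penalized by

* `trace` — λ·tr(W) = λ·Σᵢλᵢ(W): drives eigenvalues to zero, i.e. prunes
  perceptual axes (the headline regularizer);
* `l1` — α·Σ|Wₖₗ| (elementwise), `l2` — α·tr(WᵀW) = α·Σᵢλᵢ²: standard
  alternatives that penalize the rotation as well as the scaling, kept for
  comparison;
* `none` — plain least squares.

Because W ⪰ 0 it diagonalizes as W = UᵀΛU: the rows of U are the perceptual
axes and z = Λ^½U x is the transformed face space in which plain Euclidean
distance (plus b) reproduces the model's predictions. The problem is convex;
it is solved by accelerated projected/proximal gradient descent on the PSD
cone (the prox of λ·tr(W) + PSD constraint is eigenvalue soft-thresholding;
the elementwise l1 penalty uses Davis–Yin three-operator splitting).

Raw ratings are 1–9 Likert similarity scores, two repetitions per pair, with
identical-image catch trials. The pipeline converts s → d = 10 − s, min–max
normalizes per rater, screens raters (catch failure, low volume, agreement
or response entropy more than 2 SD below the population mean), and averages
to d̄.

## Worked example

Everything below runs offline on synthetic data with known ground truth.

```
$ percepspace synth ratings --items 80 --dims 8 --rank 3 --raters 40 \
      --sigma 0.1 --seed 5 --out ratings.csv --truth truth.json \
      --features-out features.csv
4840 ratings from 40 raters -> ratings.csv

$ percepspace ratings --in ratings.csv --out dissim.csv --report raters.csv
thresholds: min_pairs=30 sd_cut=2.0 min_overlap=10; excluded 2/40 raters; 1370 pairs -> dissim.csv

$ percepspace fit --features features.csv --dissim dissim.csv --reg trace \
      --seed 9 --out model.npz
reg=trace chosen coefficient=0 validation c.c.=0.9512 test c.c.=0.9577 b=0.0472 effective rank=4 -> model.npz

$ percepspace curve --model model.npz --features features.csv --dissim dissim.csv --out curve.csv
full-model c.c.=0.9604; 99% reached at k=3 -> curve.csv
```

Reading the output: 2 of 40 simulated raters were screened out; the fitted
metric predicts held-out mean dissimilarities with Pearson c.c. 0.96; and
the truncation curve reaches 99% of that using only the top **3** eigen-axes
— exactly the rank of the metric planted by the generator. The analogous
image-side loop is `percepspace synth faces` → `aam build` → `aam encode`
(an AAM feature CSV usable as `--features`) and `aam traverse`, which
renders faces stepped along one perceptual axis at equal predicted
dissimilarity per step.

Library use mirrors the CLI: `percepspace.ratings` (screening +
aggregation), `percepspace.metric` (fitting, eigendecomposition, truncation
curves, coefficient line search), `percepspace.aam`, `percepspace.mds`,
`percepspace.downstream` (LDA subspaces, subspace-restricted fits,
group-centroid dissimilarities, 10-fold CV task comparisons), and
`percepspace.synthetic` (all generators).

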