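# Methods

## Model

Perceived dissimilarity between images *i* and *j* with embeddings
**x**ᵢ, **x**ⱼ ∈ ℝⁿ is modeled as

    f(xᵢ, xⱼ) = δᵀ W δ + b,   δ = xᵢ − xⱼ,   W ⪰ 0,  b ≥ 0.

The PSD constraint guarantees non-negative squared distances and an
eigendecomposition W = UᵀΛU whose rows of U are interpretable perceptual
axes with importances λ₁ ≥ … ≥ λₙ ≥ 0. The transformed space z = Λ^½U x
satisfies ‖zᵢ − zⱼ‖² + b = f(xᵢ, xⱼ) exactly at full rank, and truncating to
the top-k axes gives the k-dimensional face space whose quality is measured
by the truncation curve (held-out Pearson c.c. vs k).

Assumptions worth stating plainly: dissimilarity judgments are treated as
interval-scale data (mean Likert-derived scores, not ordinal ranks); the
perceptual metric is a single global quadratic form (no local or
context-dependent metric); and rater idiosyncrasy is handled by per-rater
normalization plus screening, not by a hierarchical model.

## Fitting

The objective is Σ(d̄ − δᵀWδ − b)² + penalty over W ⪰ 0, b ≥ 0, with penalty
λ·tr(W) (`trace`), α·Σ|Wₖₗ| (`l1`), α·tr(WᵀW) (`l2`), or none. All four are
convex. Solvers:

* `none`, `l2`, `trace`: FISTA with adaptive (function-value) restart. The
  gradient step uses a power-iteration bound on the Lipschitz constant of
  the quadratic loss; the prox is projection onto the PSD cone (eigenvalue
  clipping), which for the trace penalty becomes eigenvalue
  soft-thresholding at zero — the exact prox of λ·tr(·) + PSD indicator.
  The l2 penalty is smooth and enters the gradient.
* `l1`: Davis–Yin three-operator splitting, separating the PSD indicator
  (eigenvalue clipping) from the elementwise soft-threshold, with step 1/L.
* `diagonal=True` restricts W to a non-negative diagonal (axis rescaling
  without rotation); projection then clips the diagonal, and the l1 penalty
  coincides with the trace penalty.

Iterations stop when the relative objective change stays below `tol`
(default 1e−9) for 10 consecutive iterations (20 for Davis–Yin), capped at
`max_iter` (default 20 000). The best-objective iterate is returned, and the
fit must reach at least the trivial baseline (W = 0, b = mean d̄) or a
SolverError is raised. Offsets are kept non-negative by projection. A
configurable cap (`max_dense_dim`, default 200) guards the dense
eigendecomposition-per-iteration cost; larger feature spaces should be
reduced (e.g. by PCA) first.

Eigenvectors use a deterministic sign convention (first nonzero component
positive) and stable descending order so axes are reproducible across runs.
Effective rank counts eigenvalues ≥ 1e−6·λ₁ (a looser 1e−2·λ₁ threshold is
used when asking whether noise-level axes survived regularization).

The regularization coefficient is chosen by line search over a fixed grid
(default 0, 0.1, 1, 10, 100, 1000 — spanning negligible-to-dominant penalty
for loss scales arising from a few thousand pairs of [0,1] scores),
maximizing validation c.c. with ties going to the smaller coefficient. For
rank identification the plain argmax is too permissive: validation
prediction barely suffers from noise-level eigenvalues, so tiny spurious
axes survive. `select_coefficient(..., parsimony_se=k)` applies the
one-standard-error rule familiar from cross-validated lasso practice —
choose the largest coefficient whose validation c.c. is within k standard
errors (SE(r) ≈ (1 − r²)/√m over m validation pairs) of the best — which on
the canonical fixtures prunes the spectrum to exactly the planted rank.
Pair splits default to 8:1:1 train:validation:test over *pairs*; splitting
over *images* is available and is the right choice whenever the evaluation
must be free of item-level information reuse (see below).

## Ratings pipeline

Similarity s ∈ {1..9} converts to dissimilarity d = 10 − s. Each rater's
raw dissimilarities (both repetitions, catch trials excluded) are min–max
normalized to [0, 1] over all of that rater's ratings *before* any
averaging; the per-pair score d̄ is then the arithmetic mean over all
retained ratings of that pair. A rater whose ratings have zero range is
rejected (in a full pipeline such raters are caught earlier by the entropy
rule).

Screening applies four rules in order, each to the survivors of the
previous: (a) failed an identical-image catch trial; (b) fewer than 30
unique rated pairs; (c) leave-one-out agreement c.c. more than 2 SD below
the population mean; (d) response entropy (Shannon, nats, over the nine
Likert bins of raw scores) more than 2 SD below the population mean.
Agreement c.c. is computed on the raw 1–9 scale, averaging a rater's
repetitions per pair first, against the mean of all other raters on shared
pairs; it is undefined (and rule (c) does not apply) with fewer than 10
shared pairs or zero variance on either side. The population statistics for
(c) and (d) are frozen over the survivors of (a)+(b) rather than
re-estimated as raters drop, which makes screening idempotent and
order-stable. Thresholds (30 pairs, 2 SD, overlap 10) are config-exposed.

## AAM front-end

Shape features are L = 83 landmark coordinates; texture features are
grayscale values (ITU-R 601 luma) of the image piecewise-affinely warped so
its landmarks meet the dataset-mean landmarks. Design choices where
standard practice had to fill gaps:

* **Alignment.** Generalized Procrustes (translation + rotation + scale,
  no reflections) before averaging and PCA, since raw landmarks conflate
  pose with identity; the mean is re-anchored to the original centroid and
  scale so coordinates stay in pixel units.
* **Warping.** One Delaunay triangulation of the mean shape, reused for
  every warp in both directions. The map is computed from barycentric
  coordinates in the source geometry applied to the destination landmarks;
  degenerate source triangles raise an error naming the triangle, and
  decoded shapes with inverted triangles render with a warning. Sampling is
  bilinear; texture pixels are every integer coordinate inside the
  mean-shape hull.
* **Block balance.** Shape and texture blocks are each divided by the
  square root of their total training variance before the joint PCA so
  neither block dwarfs the other; a (near-)constant block is left unscaled
  rather than having its float noise amplified to unit variance.
* **Retention.** The smallest component count whose cumulative explained
  variance reaches the target (default 98%).

`decode` inverts the PCA and un-scales the blocks; `encode_parts` is its
exact algebraic inverse on the retained subspace. Feature traversal steps a
code x_mid ± s·Δ·u_k along metric eigen-axis k, so the predicted
dissimilarity from the middle face is b + (sΔ)²λ_k — identical for ±s, with
Δ chosen to hit a target first-step dissimilarity.

## MDS baseline

Observed d̄ values define a weighted graph; missing distances are completed
by Dijkstra shortest paths (observed entries are kept verbatim even when a
multi-hop path is shorter — only *missing* entries are estimated). Classical
(Torgerson) MDS double-centers the squared-distance matrix and embeds with
the top-k eigenpairs; negative eigenvalues (non-Euclidean data, common for
path-completed dissimilarities) are clipped to zero with a logged warning.
Whether held-out pairs are deleted before completion is the caller's choice;
the evaluation helpers here never include held-out pairs as edges.

## Synthetic worlds

The generator plants ground truth at the study conditions used throughout
the tests: standard-normal item embeddings; W* = UᵀΛU with a Haar-random
orthogonal U and *equal* nonzero eigenvalues summing to trace 0.25 (equal
strength keeps rank-recovery claims well-defined; an ill-conditioned random
factor model would make "the curve plateaus at the planted rank" depend on
the draw); offset b* = 0.4. Under these defaults true dissimilarities over
random pairs have mean b* + 0.5 and SD ≈ 0.32, so the canonical score noise
σ = 0.05 is a high-but-not-trivial SNR.

Simulated raters report gain·f* + bias + N(0, σ_r), mapped to the 1–9 scale
by one population affine map anchoring the 1st/99th percentiles of raw
values to scores 9 and 1 (keeping most mass on-scale while exercising
clipping), rounded and clipped; two repetitions per pair; attentive raters
answer catch trials "same" with top-of-scale scores, inattentive raters
click uniformly and fail catches half the time. Canonical fixture sizes
(hundreds of items, a few thousand pairs, tens of raters) keep any single
experiment under about a minute on one core.

Cartoon faces are smooth grayscale renders (ellipse head, shaded skin,
Gaussian-blot eyes/brows/nose/mouth) driven by five latent factors (face
width, eye spacing, mouth curvature, shading gradient, feature darkness)
with all 83 landmarks analytic in the factors. They exercise the warping
and joint-PCA code paths; they do not model real faces — no photographic
texture, no demographic structure, no landmark-detection noise — so AAM
tests establish correctness of the representation machinery, not
psychological validity on photographs.

What passing synthetic tests do *not* show about real data: real raters
violate the affine-plus-Gaussian noise model (sequence effects, criterion
drift), real dissimilarities can violate metric axioms beyond what a
quadratic form absorbs, and real embeddings are not isotropic Gaussian.

## Evaluation designs

* **Recovery study** (20 dims, planted rank 5, 400 items, 5 000 pairs,
  σ = 0.05): trace-regularized fit with validation-selected coefficient;
  reports ‖Ŵ−W*‖_F/‖W*‖_F (typically ≈ 0.03–0.05) and |b̂−b*|.
* **Dimensionality**: the truncation curve on held-out pairs reaches 99% of
  the full-model c.c. at the planted rank and clearly less with fewer axes.
* **Rater study** (50 attentive raters at σ_r = 0.3 plus planted
  inattentives): the fitted model's held-out c.c. against d̄ exceeds the
  mean leave-one-out inter-rater c.c. — the model pools all raters and
  interpolates through the feature space, which no single rater can.
* **Subspace restriction**: with a metric planted on a known 4-D subspace,
  fitting within the subspace preserves held-out prediction while fitting
  in the orthogonal complement destroys it. Evaluation pairs are drawn
  among images never seen in training: with shared images, a complement fit
  picks up *item-level* effects (training items whose support coordinates
  raise d̄ also have identifiable complement coordinates), inflating the
  null c.c. to ≈ 0.15 — leakage, not signal. Image-disjoint evaluation
  restores the null.
* **Exactness checks**: dimension contributions λ_k·mean((u_k·δ)²) plus b
  reproduce the mean prediction to 1e−8 relative tolerance; shortest-path
  completion is compared with an independent brute-force oracle on graphs
  with dyadic-rational weights so the agreement can be asserted bitwise.

## Known limitations

* The dense solver eigendecomposes an n×n matrix per iteration; n beyond a
  few hundred needs prior dimensionality reduction (hence the cap).
* The l1 path uses splitting with a fixed step; very large coefficients
  converge slowly compared to the trace prox.
* Classical MDS after path completion has no out-of-sample extension; its
  held-out evaluation is limited to distances between already-embedded
  items.
* LDA subspaces use a ridge-regularized within-class scatter (shrinkage
  1e−6·tr(S_w)/n), appropriate when dimensions approach sample counts but
  untested in the truly singular regime (more classes·dims than samples).
* Downstream task p-values are reported raw, without multiple-testing
  correction; treat them as descriptive.
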