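"""Mahalanobis metric learning for perceptual dissimilarity.

The model for the perceived dissimilarity of two faces with embeddings
``x_i, x_j`` is the PSD quadratic form

    f(x_i, x_j) = (x_i - x_j)^T W (x_i - x_j) + b,      W >= 0 (PSD), b >= 0.

``W`` is fit by least squares against mean human dissimilarity scores, with
optional trace, elementwise-l1, or squared-Frobenius (l2) regularization.
Trace regularization penalizes the sum of eigenvalues of ``W`` and so drives
its rank — the number of perceptual axes — down.

The problem is convex (quadratic loss over the PSD cone plus a convex
penalty). It is solved with accelerated projected/proximal gradient descent:
FISTA with projection onto the PSD cone when the penalty is smooth or
spectral (none, l2, trace — the prox of ``lam*tr(W)`` plus the PSD indicator
is eigenvalue soft-thresholding at zero), and Davis–Yin three-operator
splitting when the elementwise l1 penalty and the PSD constraint must be
proximated separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .ratings import DissimilarityTable

__all__ = [
    "FeatureSpace",
    "MetricModel",
    "FitConfig",
    "predict_dissimilarity",
    "fit_metric",
    "eigendecompose",
    "transform",
    "truncation_curve",
    "select_coefficient",
    "dimension_contributions",
    "split_pairs",
    "heldout_cc",
]

REGULARIZERS = ("none", "l1", "l2", "trace")


@dataclass
class FeatureSpace:
    """Per-image embedding vectors: ordered ids and one row of X per id."""

    ids: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise ValueError("X must be (n_images, n_dims) matching ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate image ids")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature values")
        self._index = {im: k for k, im in enumerate(self.ids)}

    @property
    def n_dims(self) -> int:
        return self.X.shape[1]

    def vector(self, image_id: str) -> np.ndarray:
        return self.X[self._index[str(image_id)]]

    def deltas(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        """Difference vectors x_i - x_j, one row per pair."""
        rows_i = [self._index[i] for i, _ in pairs]
        rows_j = [self._index[j] for _, j in pairs]
        return self.X[rows_i] - self.X[rows_j]

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.X, columns=[f"f{k}" for k in range(self.n_dims)])
        df.insert(0, "image_id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureSpace":
        import pandas as pd

        df = pd.read_csv(path, dtype={"image_id": str})
        ids = df["image_id"].tolist()
        return cls(ids, df.drop(columns=["image_id"]).to_numpy(float))


@dataclass
class FitConfig:
    """Solver and regularization settings for :func:`fit_metric`.

    regularizer: one of none/l1/l2/trace; coefficient: its weight (alpha for
    l1/l2, lambda for trace). ``grid`` is the coefficient grid scanned by
    :func:`select_coefficient`. ``diagonal`` restricts W to a non-negative
    diagonal (axis rescaling only, no rotation). ``max_dense_dim`` guards the
    dense eigendecomposition-per-iteration solver.
    """

    regularizer: str = "none"
    coefficient: float = 0.0
    tol: float = 1e-9
    max_iter: int = 20000
    grid: tuple[float, ...] = (0.0, 0.1, 1.0, 10.0, 100.0, 1000.0)
    seed: int = 0
    diagonal: bool = False
    max_dense_dim: int = 200

    def __post_init__(self) -> None:
        if self.regularizer not in REGULARIZERS:
            raise ValueError(f"regularizer must be one of {REGULARIZERS}")
        if self.coefficient < 0:
            raise ValueError("coefficient must be >= 0")
        g = tuple(float(v) for v in self.grid)
        if any(v < 0 for v in g) or list(g) != sorted(g):
            raise ValueError("grid values must be non-negative and sorted")
        self.grid = g


@dataclass
class MetricModel:
    """A fitted PSD metric: W = U^T diag(eigvals) U, offset b.

    ``U`` rows are the eigenvectors (perceptual axes), eigvals descending.
    """

    W: np.ndarray
    b: float
    U: np.ndarray
    eigvals: np.ndarray
    regularizer: str = "none"
    coefficient: float = 0.0
    ids: list[str] = field(default_factory=list)

    @property
    def n_dims(self) -> int:
        return self.W.shape[0]

    def effective_rank(self, rel_tol: float = 1e-6) -> int:
        if self.eigvals.size == 0 or self.eigvals[0] <= 0:
            return 0
        return int(np.sum(self.eigvals >= rel_tol * self.eigvals[0]))

    def penalty_value(self) -> float:
        """The penalty term evaluated at W (trace, l1 sum, or sum of squared eigenvalues)."""
        if self.regularizer == "trace":
            return float(np.trace(self.W))
        if self.regularizer == "l1":
            return float(np.abs(self.W).sum())
        if self.regularizer == "l2":
            return float(np.trace(self.W.T @ self.W))
        return 0.0

    def save(self, path) -> None:
        np.savez(
            path,
            W=self.W,
            b=np.float64(self.b),
            U=self.U,
            eigvals=self.eigvals,
            meta=np.frombuffer(
                json.dumps(
                    {
                        "regularizer": self.regularizer,
                        "coefficient": self.coefficient,
                        "ids": self.ids,
                        "format": "percepspace-metric-v1",
                        "numpy": np.__version__,
                    }
                ).encode(),
                dtype=np.uint8,
            ),
        )

    @classmethod
    def load(cls, path) -> "MetricModel":
        with np.load(path) as z:
            meta = json.loads(z["meta"].tobytes().decode())
            return cls(
                W=z["W"],
                b=float(z["b"]),
                U=z["U"],
                eigvals=z["eigvals"],
                regularizer=meta["regularizer"],
                coefficient=meta["coefficient"],
                ids=list(meta["ids"]),
            )


def predict_dissimilarity(model: MetricModel, x_i: np.ndarray, x_j: np.ndarray) -> float:
    """f(x_i, x_j) = (x_i-x_j)^T W (x_i-x_j) + b."""
    x_i = np.asarray(x_i, float)
    x_j = np.asarray(x_j, float)
    if x_i.shape != (model.n_dims,) or x_j.shape != (model.n_dims,):
        raise ValueError(f"expected vectors of dimension {model.n_dims}")
    d = x_i - x_j
    return float(d @ model.W @ d + model.b)


def predict_pairs(model: MetricModel, deltas: np.ndarray) -> np.ndarray:
    """Vectorized quadratic form over rows of difference vectors."""
    return np.einsum("pi,ij,pj->p", deltas, model.W, deltas) + model.b


def _pair_data(
    features: FeatureSpace, table: DissimilarityTable
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    pairs = table.pairs()
    missing = [p for p in pairs for im in p if im not in features._index]
    if missing:
        raise ValueError(f"pairs reference images absent from features, e.g. {missing[0]}")
    D = features.deltas(pairs)
    y = np.array([table.entries[p] for p in pairs])
    return D, y, pairs


def _eigh_desc(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with descending eigenvalues and a fixed sign convention."""
    vals, vecs = np.linalg.eigh((W + W.T) / 2)
    order = np.argsort(-vals, kind="stable")
    vals = vals[order]
    vecs = vecs[:, order]
    for k in range(vecs.shape[1]):
        col = vecs[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            vecs[:, k] = -col
    return vals, vecs


def _project_psd(W: np.ndarray, shrink: float = 0.0, diagonal: bool = False) -> np.ndarray:
    """Project onto the PSD cone; with shrink > 0, soft-threshold eigenvalues.

    This is the exact prox of ``shrink * tr(W) + PSD indicator`` (eigenvalue
    soft-thresholding at zero). With ``diagonal``, project onto non-negative
    diagonal matrices instead.
    """
    if diagonal:
        return np.diag(np.maximum(np.diag(W) - shrink, 0.0))
    vals, vecs = np.linalg.eigh((W + W.T) / 2)
    vals = np.maximum(vals - shrink, 0.0)
    return (vecs * vals) @ vecs.T


class SolverError(RuntimeError):
    """The metric fit failed to converge; carries the solver status."""


def _loss_and_grad(W, b, D, y):
    q = np.einsum("pi,ij,pj->p", D, W, D) + b
    r = q - y
    gW = 2.0 * (D * r[:, None]).T @ D
    gb = 2.0 * r.sum()
    return float(r @ r), (gW + gW.T) / 2, gb


def _lipschitz(D: np.ndarray, extra: float = 0.0, iters: int = 50, seed: int = 0) -> float:
    """Power-iteration bound on the Lipschitz constant of the quadratic loss gradient."""
    rng = np.random.default_rng(seed)
    n = D.shape[1]
    V = rng.standard_normal((n, n))
    V = (V + V.T) / 2
    c = 1.0
    lam = 1.0
    for _ in range(iters):
        q = np.einsum("pi,ij,pj->p", D, V, D) + c
        HV = 2.0 * (D * q[:, None]).T @ D
        HV = (HV + HV.T) / 2
        Hc = 2.0 * q.sum()
        lam = float(np.sqrt((HV * HV).sum() + Hc * Hc))
        if lam == 0:
            return 1.0 + extra
        V, c = HV / lam, Hc / lam
    return 1.05 * lam + extra


def _objective(W, b, D, y, regularizer, coeff):
    q = np.einsum("pi,ij,pj->p", D, W, D) + b
    loss = float(((q - y) ** 2).sum())
    if regularizer == "trace":
        return loss + coeff * float(np.trace(W))
    if regularizer == "l1":
        return loss + coeff * float(np.abs(W).sum())
    if regularizer == "l2":
        return loss + coeff * float((W * W).sum())
    return loss


def _fista(D, y, regularizer, coeff, tol, max_iter, diagonal):
    """FISTA with PSD projection; trace penalty enters through the prox."""
    n = D.shape[1]
    L = _lipschitz(D, extra=2 * coeff if regularizer == "l2" else 0.0)
    step = 1.0 / L
    # trace penalty enters through the prox (eigenvalue soft-threshold); for
    # diagonal non-negative W the l1 penalty coincides with the trace penalty
    if regularizer == "trace" or (regularizer == "l1" and diagonal):
        shrink = step * coeff
    else:
        shrink = 0.0
    W = np.zeros((n, n))
    b = max(float(y.mean()), 0.0)
    Wy, by = W.copy(), b
    t = 1.0
    best = (_objective(W, b, D, y, regularizer, coeff), W.copy(), b)
    prev_obj = best[0]
    stall = 0
    for it in range(max_iter):
        loss, gW, gb = _loss_and_grad(Wy, by, D, y)
        if regularizer == "l2":
            gW = gW + 2.0 * coeff * Wy
        W_new = _project_psd(Wy - step * gW, shrink=shrink, diagonal=diagonal)
        b_new = max(by - step * gb, 0.0)
        obj = _objective(W_new, b_new, D, y, regularizer, coeff)
        if obj > prev_obj:  # adaptive restart
            t = 1.0
            Wy, by = W.copy(), b
            prev_obj = _objective(W, b, D, y, regularizer, coeff)
            continue
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        Wy = W_new + ((t - 1) / t_new) * (W_new - W)
        by = b_new + ((t - 1) / t_new) * (b_new - b)
        W, b, t = W_new, b_new, t_new
        if obj < best[0]:
            best = (obj, W.copy(), b)
        rel = abs(prev_obj - obj) / max(abs(prev_obj), 1e-30)
        stall = stall + 1 if rel < tol else 0
        if stall >= 10:
            break
        prev_obj = obj
    return best[1], best[2], best[0], it + 1


def _davis_yin(D, y, coeff, tol, max_iter):
    """Davis–Yin splitting for loss + PSD indicator + elementwise l1 penalty."""
    n = D.shape[1]
    L = _lipschitz(D)
    gamma = 1.0 / L
    Z = np.zeros((n, n))
    zb = max(float(y.mean()), 0.0)
    best = (np.inf, Z.copy(), zb)
    prev_obj = np.inf
    stall = 0
    for it in range(max_iter):
        X1 = _project_psd(Z)
        xb1 = max(zb, 0.0)
        loss, gW, gb = _loss_and_grad(X1, xb1, D, y)
        Y = 2 * X1 - Z - gamma * gW
        X2 = np.sign(Y) * np.maximum(np.abs(Y) - gamma * coeff, 0.0)  # soft threshold
        xb2 = 2 * xb1 - zb - gamma * gb
        Z = Z + X2 - X1
        zb = zb + xb2 - xb1
        obj = _objective(X1, xb1, D, y, "l1", coeff)
        if obj < best[0]:
            best = (obj, X1.copy(), xb1)
        rel = abs(prev_obj - obj) / max(abs(prev_obj), 1e-30)
        stall = stall + 1 if rel < tol else 0
        if stall >= 20:
            break
        prev_obj = obj
    return best[1], best[2], best[0], it + 1


def fit_metric(
    features: FeatureSpace, table: DissimilarityTable, config: FitConfig | None = None
) -> MetricModel:
    """Fit (W, b) to mean dissimilarities by regularized least squares.

    Minimizes ``sum_(i,j) (dbar(i,j) - x_(i,j)^T W x_(i,j) - b)^2 + penalty``
    subject to W PSD and b >= 0, where x_(i,j) = x_i - x_j.
    """
    config = config or FitConfig()
    D, y, _ = _pair_data(features, table)
    n = D.shape[1]
    if n > config.max_dense_dim:
        raise ValueError(
            f"n_dims={n} exceeds the dense-solver cap ({config.max_dense_dim}); "
            "reduce dimensionality (e.g. PCA) or raise max_dense_dim"
        )
    if config.regularizer == "l1" and not config.diagonal:
        W, b, obj, iters = _davis_yin(D, y, config.coefficient, config.tol, config.max_iter)
    else:
        W, b, obj, iters = _fista(
            D, y, config.regularizer, config.coefficient, config.tol, config.max_iter, config.diagonal
        )
    baseline = float(((y - max(y.mean(), 0.0)) ** 2).sum()) if config.coefficient >= 0 else np.inf
    if obj > baseline + 1e-8 * max(baseline, 1.0):
        raise SolverError(
            f"fit did not reach the trivial baseline (obj={obj:.6g} > {baseline:.6g}) "
            f"after {iters} iterations"
        )
    W = _project_psd(W, diagonal=config.diagonal)
    vals, vecs = _eigh_desc(W)
    vals = np.maximum(vals, 0.0)
    return MetricModel(
        W=W,
        b=float(b),
        U=vecs.T,
        eigvals=vals,
        regularizer=config.regularizer,
        coefficient=config.coefficient,
        ids=list(features.ids),
    )


def eigendecompose(model: MetricModel) -> tuple[np.ndarray, np.ndarray]:
    """(U, eigvals) with W = U^T diag(eigvals) U, eigvals descending, clipped at 0."""
    vals, vecs = _eigh_desc(model.W)
    return vecs.T, np.maximum(vals, 0.0)


def transform(features: FeatureSpace, model: MetricModel, k: int | None = None) -> np.ndarray:
    """Embed images as z = diag(eigvals)^(1/2) U x restricted to the top-k axes.

    For k = n, squared Euclidean distance in z plus b reproduces the model's
    predicted dissimilarity exactly.
    """
    n = model.n_dims
    if k is None:
        k = n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    scale = np.sqrt(model.eigvals[:k])
    return (features.X @ model.U[:k].T) * scale


def heldout_cc(features: FeatureSpace, model: MetricModel, table: DissimilarityTable) -> float:
    """Pearson c.c. between model-predicted and observed dissimilarities."""
    D, y, _ = _pair_data(features, table)
    pred = predict_pairs(model, D)
    if np.std(y) == 0 or np.std(pred) == 0:
        raise ValueError("zero variance in predictions or held-out values; c.c. undefined")
    return float(stats.pearsonr(pred, y).statistic)


def truncation_curve(
    features: FeatureSpace,
    model: MetricModel,
    table_heldout: DissimilarityTable,
    target_fraction: float = 0.99,
) -> tuple[np.ndarray, int]:
    """Held-out prediction c.c. as a function of the number of axes kept.

    For each k, predictions use only the top-k eigen-axes of W (largest
    eigenvalues first). Returns the curve (length n) and the smallest k whose
    c.c. reaches ``target_fraction`` of the full-model c.c.
    """
    D, y, _ = _pair_data(features, table_heldout)
    if np.std(y) == 0:
        raise ValueError("held-out dissimilarities have zero variance; c.c. undefined")
    n = model.n_dims
    proj = D @ model.U.T  # pair deltas in the eigenbasis
    contrib = model.eigvals * proj**2  # per-axis additive distance terms
    cum = np.cumsum(contrib, axis=1) + model.b
    curve = np.empty(n)
    for k in range(n):
        pred = cum[:, k]
        curve[k] = stats.pearsonr(pred, y).statistic if np.std(pred) > 0 else 0.0
    full = curve[-1]
    reached = np.flatnonzero(curve >= target_fraction * full)
    k_star = int(reached[0]) + 1 if reached.size else n
    return curve, k_star


def select_coefficient(
    features: FeatureSpace,
    table_train: DissimilarityTable,
    table_val: DissimilarityTable,
    config: FitConfig,
    parsimony_se: float = 0.0,
) -> tuple[MetricModel, float, np.ndarray]:
    """Line search over the coefficient grid; keep the best validation c.c.

    Ties prefer the smallest coefficient. With ``parsimony_se > 0`` the
    one-standard-error rule is applied instead: choose the *largest*
    coefficient whose validation c.c. is within ``parsimony_se`` standard
    errors of the best (SE of a Pearson c.c. r over m pairs taken as
    (1 - r^2)/sqrt(m)), trading a statistically negligible amount of
    prediction for a sparser eigenspectrum. Returns (model fit at the chosen
    value, chosen coefficient, validation c.c. per grid point).
    """
    if not config.grid:
        raise ValueError("empty coefficient grid")
    ccs = np.empty(len(config.grid))
    models = []
    for k, coeff in enumerate(config.grid):
        m = fit_metric(features, table_train, replace(config, coefficient=coeff))
        models.append(m)
        ccs[k] = heldout_cc(features, m, table_val)
    best = int(np.argmax(ccs))  # argmax takes the first (smallest) on ties
    if parsimony_se > 0:
        tol = parsimony_se * (1 - ccs[best] ** 2) / np.sqrt(len(table_val))
        best = int(np.flatnonzero(ccs >= ccs[best] - tol)[-1])
    return models[best], config.grid[best], ccs


def dimension_contributions(
    features: FeatureSpace, model: MetricModel, pairs: list[tuple[str, str]]
) -> np.ndarray:
    """Mean predicted dissimilarity attributed to each eigen-axis.

    contribution_k = eigval_k * mean_pairs (u_k . (x_i - x_j))^2; the
    contributions plus b sum to the mean predicted dissimilarity exactly.
    """
    if not pairs:
        raise ValueError("empty pair set")
    D = features.deltas(pairs)
    proj = D @ model.U.T
    return model.eigvals * (proj**2).mean(axis=0)


def split_pairs(
    pairs: list[tuple[str, str]],
    fractions: tuple[float, float, float] = (8, 1, 1),
    seed: int = 0,
    by: str = "pairs",
) -> tuple[list, list, list]:
    """Split pairs into train/validation/test sets (default 8:1:1).

    ``by='pairs'`` splits the pair list directly; ``by='images'`` assigns
    images to the three sets and keeps only pairs internal to one set.
    """
    rng = np.random.default_rng(seed)
    f = np.asarray(fractions, float)
    f = f / f.sum()
    if by == "pairs":
        order = rng.permutation(len(pairs))
        n1 = int(round(f[0] * len(pairs)))
        n2 = int(round((f[0] + f[1]) * len(pairs)))
        idx = [order[:n1], order[n1:n2], order[n2:]]
        return tuple([pairs[i] for i in part] for part in idx)
    if by == "images":
        images = sorted({im for p in pairs for im in p})
        order = rng.permutation(len(images))
        n1 = int(round(f[0] * len(images)))
        n2 = int(round((f[0] + f[1]) * len(images)))
        groups = [set(images[i] for i in order[:n1]),
                  set(images[i] for i in order[n1:n2]),
                  set(images[i] for i in order[n2:])]
        return tuple([p for p in pairs if p[0] in g and p[1] in g] for g in groups)
    raise ValueError("by must be 'pairs' or 'images'")


def subset_table(table: DissimilarityTable, pairs: list[tuple[str, str]]) -> DissimilarityTable:
    """Restrict a dissimilarity table to a pair subset."""
    out = DissimilarityTable()
    for p in pairs:
        key = DissimilarityTable._key(*p)
        out.entries[key] = table.entries[key]
        out.n_ratings[key] = table.n_ratings.get(key, 1)
    return out
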