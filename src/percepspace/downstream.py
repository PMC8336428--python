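"""Evaluation of face representations beyond similarity prediction.

Covers the human inter-rater baseline, LDA demographic subspaces and
subspace-restricted metric fits, group-centroid dissimilarities, and
cross-validated linear prediction of categorical labels (LDA classifier) and
continuous attribute ratings (OLS), with paired fold-wise comparisons
between representations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .metric import FeatureSpace, FitConfig, MetricModel, fit_metric, heldout_cc, predict_dissimilarity
from .ratings import DissimilarityTable, compute_rater_cc, load_ratings

__all__ = [
    "SubspaceProjection",
    "human_baseline_cc",
    "lda_subspace",
    "project_features",
    "fit_metric_in_subspace",
    "group_dissimilarity",
    "evaluate_downstream",
]


@dataclass
class SubspaceProjection:
    """Orthonormal basis (rows) of a k-dimensional subspace of the feature space."""

    basis: np.ndarray  # (k, n)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.basis = np.atleast_2d(np.asarray(self.basis, float))
        G = self.basis @ self.basis.T
        if not np.allclose(G, np.eye(len(self.basis)), atol=1e-8):
            raise ValueError("basis rows must be orthonormal")

    @property
    def k(self) -> int:
        return self.basis.shape[0]

    def complement(self) -> "SubspaceProjection":
        """Orthonormal basis of the orthogonal complement."""
        n = self.basis.shape[1]
        full = np.eye(n)
        proj = full - self.basis.T @ self.basis
        q, r = np.linalg.qr(proj)
        keep = np.abs(np.diag(r)) > 1e-10
        return SubspaceProjection(q[:, keep].T, provenance=f"complement({self.provenance})")


def combine_subspaces(*projections: SubspaceProjection, provenance: str = "combined") -> SubspaceProjection:
    """Orthonormalized union of subspaces (e.g. gender axis + race subspace)."""
    stacked = np.vstack([p.basis for p in projections])
    q, r = np.linalg.qr(stacked.T)
    keep = np.abs(np.diag(r)) > 1e-10
    return SubspaceProjection(q[:, keep].T, provenance=provenance)


def human_baseline_cc(df: pd.DataFrame, min_overlap: int = 10) -> float:
    """Mean leave-one-out agreement c.c. over raters with a defined c.c.

    The human-consistency baseline: how well one rater's pair ratings
    correlate with the average of everyone else's on the same pairs.
    """
    df = load_ratings(df)
    ccs = []
    for rid in df["rater_id"].unique():
        c = compute_rater_cc(df, rid, min_overlap=min_overlap)
        if c is not None:
            ccs.append(c)
    if not ccs:
        raise ValueError("no rater has a defined leave-one-out c.c.")
    return float(np.mean(ccs))


def lda_subspace(features: FeatureSpace, labels: dict[str, str], k: int) -> SubspaceProjection:
    """Top-k LDA discriminant directions, orthonormalized.

    Solves the generalized eigenproblem S_b u = mu S_w u with a
    ridge-regularized within-class scatter (shrinkage 1e-6 * trace / n) so a
    singular S_w (more dimensions than samples per class) stays invertible.
    k may not exceed C - 1 for C classes.
    """
    ids = [i for i in features.ids if i in labels]
    y = np.array([labels[i] for i in ids])
    X = np.array([features.vector(i) for i in ids])
    classes = np.unique(y)
    C = len(classes)
    if C < 2:
        raise ValueError("need at least 2 classes")
    if k > C - 1:
        raise ValueError(f"k={k} exceeds C-1={C - 1} for {C} classes")
    n = X.shape[1]
    overall = X.mean(0)
    Sw = np.zeros((n, n))
    Sb = np.zeros((n, n))
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(0)
        Sw += (Xc - mu).T @ (Xc - mu)
        Sb += len(Xc) * np.outer(mu - overall, mu - overall)
    Sw += (1e-6 * np.trace(Sw) / n + 1e-12) * np.eye(n)
    # generalized eigenproblem via Cholesky whitening keeps the form symmetric
    Lc = np.linalg.cholesky(Sw)
    M = np.linalg.solve(Lc, np.linalg.solve(Lc, Sb).T).T
    vals, vecs = np.linalg.eigh((M + M.T) / 2)
    order = np.argsort(-vals)[:k]
    U = np.linalg.solve(Lc.T, vecs[:, order])  # back-transform generalized eigenvectors
    q, _ = np.linalg.qr(U)
    basis = q.T
    for r in range(basis.shape[0]):  # deterministic sign
        nz = np.flatnonzero(np.abs(basis[r]) > 1e-12)
        if nz.size and basis[r, nz[0]] < 0:
            basis[r] = -basis[r]
    return SubspaceProjection(basis, provenance=f"lda-{C}class")


def project_features(features: FeatureSpace, projection: SubspaceProjection) -> FeatureSpace:
    """Coordinates of the embeddings within the subspace."""
    return FeatureSpace(features.ids, features.X @ projection.basis.T)


def fit_metric_in_subspace(
    features: FeatureSpace,
    projection: SubspaceProjection,
    table: DissimilarityTable,
    config: FitConfig | None = None,
    table_heldout: DissimilarityTable | None = None,
    full_model: MetricModel | None = None,
) -> tuple[MetricModel, dict]:
    """Fit the metric using only coordinates within a subspace.

    Returns the model on projected coordinates plus a report dict; when
    held-out data and a full-space model are supplied, the report carries the
    held-out c.c. and its ratio to the full model's.
    """
    projected = project_features(features, projection)
    model = fit_metric(projected, table, config)
    report: dict = {"k": projection.k, "provenance": projection.provenance}
    if table_heldout is not None:
        cc = heldout_cc(projected, model, table_heldout)
        report["heldout_cc"] = cc
        if full_model is not None:
            full_cc = heldout_cc(features, full_model, table_heldout)
            report["full_cc"] = full_cc
            report["cc_ratio"] = cc / full_cc if full_cc != 0 else np.nan
    return model, report


def group_dissimilarity(
    features: FeatureSpace, model: MetricModel, groups: dict[str, str]
) -> pd.DataFrame:
    """Model-predicted dissimilarity between group-centroid feature vectors.

    Symmetric matrix over group labels; the diagonal equals the offset b.
    """
    labels = sorted(set(groups.values()))
    centroids = {}
    for lab in labels:
        members = [i for i in features.ids if groups.get(i) == lab]
        if not members:
            raise ValueError(f"group {lab!r} is empty")
        centroids[lab] = np.mean([features.vector(i) for i in members], axis=0)
    M = np.array(
        [[predict_dissimilarity(model, centroids[a], centroids[b]) for b in labels] for a in labels]
    )
    return pd.DataFrame(M, index=labels, columns=labels)


def _fold_scores_categorical(X, y, splits) -> np.ndarray:
    scores = []
    for tr, te in splits:
        clf = LinearDiscriminantAnalysis()
        clf.fit(X[tr], y[tr])
        scores.append(float(np.mean(clf.predict(X[te]) != y[te])))  # classification error
    return np.array(scores)


def _fold_scores_continuous(X, y, splits, score: str) -> np.ndarray:
    scores = []
    for tr, te in splits:
        reg = LinearRegression()
        reg.fit(X[tr], y[tr])
        pred = reg.predict(X[te])
        if score == "mse":
            scores.append(float(np.mean((pred - y[te]) ** 2)))
        else:
            if np.std(pred) == 0 or np.std(y[te]) == 0:
                scores.append(0.0)
            else:
                scores.append(float(stats.pearsonr(pred, y[te]).statistic))
    return np.array(scores)


def evaluate_downstream(
    representations: dict[str, FeatureSpace],
    categorical: dict[str, dict[str, str]] | None = None,
    continuous: dict[str, dict[str, float]] | None = None,
    folds: int = 10,
    seed: int = 0,
    continuous_score: str = "cc",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-validated linear prediction from each representation.

    Categorical tasks use an LDA classifier scored by classification error;
    continuous tasks use OLS scored by held-out Pearson c.c. (or MSE). All
    representations are evaluated on the same folds so comparisons are
    paired; the comparison table reports one-sided paired t-tests
    (alternative: representation A scores better than B) per task across
    folds. Returns (scores, comparisons): scores has per-fold means and SEMs.
    """
    categorical = categorical or {}
    continuous = continuous or {}
    reps = list(representations)
    ids_common = sorted(set.intersection(*(set(r.ids) for r in representations.values())))
    rows = []
    fold_scores: dict[tuple[str, str], np.ndarray] = {}

    for task, labels in categorical.items():
        ids = [i for i in ids_common if i in labels]
        y = np.array([labels[i] for i in ids])
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros(len(ids)), y))
        for rep in reps:
            X = np.array([representations[rep].vector(i) for i in ids])
            s = _fold_scores_categorical(X, y, splits)
            fold_scores[(rep, task)] = s
            rows.append({"representation": rep, "task": task, "kind": "categorical",
                         "metric": "error", "mean": s.mean(), "sem": stats.sem(s)})

    for task, values in continuous.items():
        ids = [i for i in ids_common if i in values]
        y = np.array([float(values[i]) for i in ids])
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(kf.split(np.zeros(len(ids))))
        for rep in reps:
            X = np.array([representations[rep].vector(i) for i in ids])
            s = _fold_scores_continuous(X, y, splits, continuous_score)
            fold_scores[(rep, task)] = s
            rows.append({"representation": rep, "task": task, "kind": "continuous",
                         "metric": continuous_score, "mean": s.mean(), "sem": stats.sem(s)})

    comparisons = []
    tasks = list(categorical) + list(continuous)
    higher_is_better = {t: False for t in categorical}
    higher_is_better.update({t: continuous_score != "mse" for t in continuous})
    for task in tasks:
        for a in reps:
            for b in reps:
                if a == b:
                    continue
                sa, sb = fold_scores[(a, task)], fold_scores[(b, task)]
                alt = "greater" if higher_is_better[task] else "less"
                res = stats.ttest_rel(sa, sb, alternative=alt)
                comparisons.append({"task": task, "better": a, "worse": b,
                                    "t": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows), pd.DataFrame(comparisons)
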