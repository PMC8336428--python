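"""Classical MDS baseline with shortest-path completion of missing dissimilarities.

Observed pair dissimilarities define an undirected weighted graph over
images. Unobserved pairwise distances are estimated as shortest-path lengths
through observed edges (the Isomap-style geodesic completion), after which
classical (Torgerson) MDS — double-centering and eigendecomposition of the
squared-distance matrix — embeds the images in a low-dimensional Euclidean
space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .ratings import DissimilarityTable

__all__ = ["DissimilarityGraph", "MDSEmbedding", "complete_distances", "classical_mds", "mds_heldout_cc"]


@dataclass
class DissimilarityGraph:
    """Observed dissimilarities as an undirected weighted graph."""

    nodes: list[str]
    edges: dict[tuple[str, str], float]

    @classmethod
    def from_table(cls, table: DissimilarityTable) -> "DissimilarityGraph":
        return cls(nodes=table.ids(), edges=dict(table.entries))

    def adjacency(self) -> csr_matrix:
        index = {n: k for k, n in enumerate(self.nodes)}
        rows, cols, vals = [], [], []
        for (i, j), d in self.edges.items():
            if i == j:
                continue
            if d < 0:
                raise ValueError(f"negative edge length {d} for pair ({i}, {j})")
            rows += [index[i], index[j]]
            cols += [index[j], index[i]]
            vals += [d, d]
        return csr_matrix((vals, (rows, cols)), shape=(len(self.nodes),) * 2)


@dataclass
class MDSEmbedding:
    """Centered coordinates per node, dimensions ordered by descending eigenvalue."""

    ids: list[str]
    coords: np.ndarray
    eigvals: np.ndarray

    def distances(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(-1))


def complete_distances(graph: DissimilarityGraph) -> np.ndarray:
    """Fill missing pairwise distances with shortest-path lengths.

    Observed entries are kept verbatim (even where a multi-hop path would be
    shorter); only missing entries are path-estimated. Raises on a
    disconnected graph, listing the components.
    """
    adj = graph.adjacency()
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        comps = [[graph.nodes[k] for k in np.flatnonzero(labels == c)] for c in range(n_comp)]
        raise ValueError(f"dissimilarity graph is disconnected: {n_comp} components {comps}")
    D = dijkstra(adj, directed=False)
    index = {n: k for k, n in enumerate(graph.nodes)}
    for (i, j), d in graph.edges.items():
        a, b = index[i], index[j]
        D[a, b] = D[b, a] = d
    np.fill_diagonal(D, 0.0)
    return D


def classical_mds(D: np.ndarray, k: int, ids: list[str] | None = None) -> MDSEmbedding:
    """Torgerson MDS: double-center -(1/2) J (D∘D) J and embed with top-k eigenpairs.

    Negative eigenvalues (non-Euclidean data) are clipped to zero with a
    warning; if fewer than k positive eigenvalues exist the effective
    dimension is reduced.
    """
    D = np.asarray(D, float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("D must be square, symmetric, with zero diagonal")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}]")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(-vals, kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    neg = vals[vals < -1e-10]
    if neg.size:
        warnings.warn(
            f"clipped {neg.size} negative Gram eigenvalues (largest magnitude {-neg.min():.3g}); "
            "input dissimilarities are non-Euclidean",
            stacklevel=2,
        )
    n_pos = int(np.sum(vals > 1e-12))
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; reducing embedding dimension from {k}", stacklevel=2)
    vals_k = np.maximum(vals[:k], 0.0)
    for c in range(k):  # deterministic sign: first nonzero component positive
        col = vecs[:, c]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            vecs[:, c] = -col
    coords = vecs[:, :k] * np.sqrt(vals_k)
    coords = coords - coords.mean(axis=0)
    return MDSEmbedding(ids=list(ids) if ids is not None else [str(i) for i in range(n)],
                        coords=coords, eigvals=vals)


def mds_heldout_cc(embedding: MDSEmbedding, table_heldout: DissimilarityTable) -> float:
    """Pearson c.c. between embedding Euclidean distances and held-out dissimilarities."""
    index = {n: k for k, n in enumerate(embedding.ids)}
    pairs = table_heldout.pairs()
    diffs = embedding.coords[[index[i] for i, _ in pairs]] - embedding.coords[[index[j] for _, j in pairs]]
    pred = np.sqrt((diffs**2).sum(1))
    y = np.array([table_heldout.entries[p] for p in pairs])
    if np.std(y) == 0 or np.std(pred) == 0:
        raise ValueError("zero variance; c.c. undefined")
    return float(stats.pearsonr(pred, y).statistic)
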