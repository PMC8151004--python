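"""Structural views of the document-similarity space.

Hierarchical clustering of score rows, 2-D multidimensional scaling with a
descriptive SVM separability score, and document-similarity networks
thresholded at multiple sparsity levels.  All operate on the same
Euclidean distance matrix the permutation test uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.manifold import smacof
from sklearn.metrics import f1_score
from sklearn.svm import SVC

__all__ = [
    "Dendrogram",
    "hierarchical_cluster",
    "Embedding2D",
    "mds_embed",
    "boundary_f1",
    "svm_boundary",
    "SimilarityNetwork",
    "build_network",
    "within_group_edge_fraction",
]

_LINKAGES = ("average", "complete", "ward")


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge sequence: (cluster_a, cluster_b, height) triples.

    Cluster ids follow the scipy convention: leaves are 0..n-1 and the i-th
    merge creates cluster n+i.
    """

    merges: tuple[tuple[int, int, float], ...]
    leaf_order: tuple[int, ...]
    linkage_method: str

    @property
    def n_leaves(self) -> int:
        return len(self.merges) + 1

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])


def hierarchical_cluster(D, linkage_method: str = "average") -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix.

    Ward linkage is valid here because all suite distances are Euclidean.
    """
    if linkage_method not in _LINKAGES:
        raise ValueError(
            f"linkage must be one of {_LINKAGES}, got {linkage_method!r}"
        )
    arr = np.asarray(D, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 documents")
    condensed = squareform(arr, checks=False)
    Z = linkage(condensed, method=linkage_method)
    merges = tuple(
        (int(min(a, b)), int(max(a, b)), float(h)) for a, b, h, _ in Z
    )
    return Dendrogram(
        merges=merges,
        leaf_order=tuple(int(i) for i in leaves_list(Z)),
        linkage_method=linkage_method,
    )


# ---------------------------------------------------------------------------
# Multidimensional scaling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Embedding2D:
    """2-D MDS coordinates with the achieved stress."""

    coords: np.ndarray  # (n, 2)
    stress: float
    seed: int | None
    doc_ids: tuple[str, ...] = ()

    def to_frame(self, textbooks=None, diseases=None) -> pd.DataFrame:
        frame = pd.DataFrame(self.coords, columns=["x", "y"])
        frame.insert(0, "doc_id", list(self.doc_ids) or range(len(frame)))
        if textbooks is not None:
            frame["textbook"] = list(textbooks)
        if diseases is not None:
            frame["disease"] = list(diseases)
        return frame


def _classical_mds(arr: np.ndarray) -> np.ndarray:
    """Torgerson double-centering eigen-embedding into 2 dimensions."""
    n = arr.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (arr**2) @ J
    w, v = np.linalg.eigh(Bmat)
    idx = np.argsort(w)[::-1][:2]
    return v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))


def mds_embed(
    D,
    seed: int | None = None,
    *,
    method: str = "metric",
    n_init: int = 8,
) -> Embedding2D:
    """Embed a distance matrix in the plane.

    ``metric`` (default) minimizes raw stress by SMACOF, best of ``n_init``
    seeded restarts; ``classical`` uses the Torgerson eigendecomposition.
    Exactly planar configurations reach stress ~0; an all-zero matrix
    collapses every point to the origin.
    """
    arr = np.asarray(D, dtype=float)
    n = arr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 documents to embed")
    doc_ids = tuple(D.index) if isinstance(D, pd.DataFrame) else ()

    if not arr.any():
        return Embedding2D(np.zeros((n, 2)), 0.0, seed, doc_ids)

    if method == "classical":
        coords = _classical_mds(arr)
        diff = squareform(
            np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1)),
            checks=False,
        ) - squareform(arr, checks=False)
        return Embedding2D(coords, float((diff**2).sum()), seed, doc_ids)
    if method != "metric":
        raise ValueError(f"unknown MDS method {method!r}")

    # SMACOF stress majorization, warm-started at the classical (Torgerson)
    # solution and refined; random restarts guard against local minima.
    best_coords, best_stress = None, np.inf
    warm = _classical_mds(arr)
    coords, stress = smacof(
        arr, metric=True, n_components=2, init=warm, n_init=1,
        max_iter=2000, eps=1e-15, random_state=seed, normalized_stress=False,
    )
    best_coords, best_stress = coords, stress
    if n_init > 1:
        coords, stress = smacof(
            arr, metric=True, n_components=2, n_init=n_init - 1,
            max_iter=2000, eps=1e-15, random_state=seed,
            normalized_stress=False,
        )
        if stress < best_stress:
            best_coords, best_stress = coords, stress
    return Embedding2D(best_coords, float(best_stress), seed, doc_ids)


# ---------------------------------------------------------------------------
# SVM separability (descriptive, as drawn in the figures)
# ---------------------------------------------------------------------------


def _fit_svm(coords: np.ndarray, y: np.ndarray) -> SVC:
    model = SVC(kernel="rbf", C=10.0, gamma=1.0)
    model.fit(coords, y)
    return model


def boundary_f1(points: Embedding2D | np.ndarray, labels) -> float:
    """F1 of an RBF-SVM (C=10, gamma=1) boundary drawn through the embedding.

    The score is computed on the fitting points themselves — a descriptive
    measure of how cleanly the boundary separates the two groups in the
    plane, not a predictive estimate.
    """
    coords = points.coords if isinstance(points, Embedding2D) else np.asarray(points)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    model = _fit_svm(coords, y)
    return float(f1_score(y, model.predict(coords), pos_label=classes[1]))


def svm_boundary(
    points: Embedding2D | np.ndarray,
    labels,
    *,
    grid_size: int = 200,
    margin: float = 0.5,
) -> tuple[float, pd.DataFrame]:
    """F1 plus a grid-sampled decision function for boundary plotting."""
    coords = points.coords if isinstance(points, Embedding2D) else np.asarray(points)
    y = np.asarray(labels)
    f1 = boundary_f1(coords, y)
    model = _fit_svm(coords, y)
    lo, hi = coords.min(0) - margin, coords.max(0) + margin
    gx, gy = np.meshgrid(
        np.linspace(lo[0], hi[0], grid_size), np.linspace(lo[1], hi[1], grid_size)
    )
    z = model.decision_function(np.column_stack([gx.ravel(), gy.ravel()]))
    grid = pd.DataFrame({"x": gx.ravel(), "y": gy.ravel(), "decision": z})
    return f1, grid


# ---------------------------------------------------------------------------
# Similarity networks
# ---------------------------------------------------------------------------


@dataclass
class SimilarityNetwork:
    """Documents as nodes; the closest pairs as edges.

    ``sparsity`` is the fraction of all C(n,2) possible edges retained;
    retained edges are exactly the smallest-distance pairs.
    """

    graph: nx.Graph
    sparsity: float
    doc_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "distance": d["distance"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "distance"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    D,
    sparsity: float,
    *,
    textbooks=None,
    diseases=None,
) -> SimilarityNetwork:
    """Threshold a distance matrix into an undirected similarity network.

    Retains the round(sparsity * C(n,2)) smallest-distance pairs (at least
    one edge for any positive sparsity); ties at the cutoff are broken by
    lexicographic (i, j) order.  Optional textbook/disease vectors become
    node attributes for grouping analyses and GraphML export.
    """
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    arr = np.asarray(D, dtype=float)
    n = arr.shape[0]
    ids = list(D.index) if isinstance(D, pd.DataFrame) else list(range(n))
    n_possible = n * (n - 1) // 2
    k = max(1, int(math.floor(sparsity * n_possible + 0.5)))

    pairs = [(arr[i, j], i, j) for i in range(n) for j in range(i + 1, n)]
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))

    g = nx.Graph()
    for idx, node in enumerate(ids):
        attrs = {}
        if textbooks is not None:
            attrs["textbook"] = str(list(textbooks)[idx])
        if diseases is not None:
            attrs["disease"] = str(list(diseases)[idx])
        g.add_node(node, **attrs)
    for d, i, j in pairs[:k]:
        g.add_edge(ids[i], ids[j], distance=float(d))
    return SimilarityNetwork(graph=g, sparsity=sparsity, doc_ids=tuple(map(str, ids)))


def within_group_edge_fraction(net: SimilarityNetwork, grouping: str) -> float:
    """Fraction of edges whose endpoints share the textbook/disease label."""
    if grouping not in ("textbook", "disease"):
        raise ValueError(f"grouping must be 'textbook' or 'disease', got {grouping!r}")
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges")
    same = sum(
        1
        for u, v in g.edges()
        if g.nodes[u].get(grouping) == g.nodes[v].get(grouping)
        and g.nodes[u].get(grouping) is not None
    )
    return same / g.number_of_edges()


def sparsity_sweep(
    D,
    sparsities=(0.02, 0.05, 0.10, 0.20),
    *,
    textbooks=None,
    diseases=None,
) -> pd.DataFrame:
    """Within-group edge fractions for both groupings across sparsity levels."""
    rows = []
    for s in sparsities:
        net = build_network(D, s, textbooks=textbooks, diseases=diseases)
        row = {"sparsity": s, "n_edges": net.n_edges}
        if textbooks is not None:
            row["textbook_fraction"] = within_group_edge_fraction(net, "textbook")
        if diseases is not None:
            row["disease_fraction"] = within_group_edge_fraction(net, "disease")
        rows.append(row)
    return pd.DataFrame(rows)
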