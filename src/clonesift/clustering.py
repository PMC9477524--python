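"""Spectral clustering of the similarity matrix and the recursion driver.

Each clustering step: shift the log-odds matrix so its minimum is zero
(a monotone transform turning it into a non-negative affinity), form the
symmetric normalized Laplacian L = I - D^{-1/2} S* D^{-1/2}, embed the
cells in its k smallest-eigenvalue eigenvectors, decide *whether* to
split with a Gaussian-mixture BIC comparison, and decide *how many* ways
to split (2-4) with a k-means inertia-gap rule.  The whole pipeline is
then re-run from the locus filter on every accepted child, because loci
rejected on the full population can become informative within a subset.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .locus_filter import FilterParams, FilterReport, select_informative_loci
from .pileup_io import Pileup
from .similarity import SimilarityMatrix, SimilarityParams, build_similarity_matrix

#: degree regularizer for cells with zero affinity row sums
EPS_DEGREE = 1e-12

#: BIC comparison needs at least this many cells to be meaningful
MIN_CELLS_FOR_SPLIT = 10

TERMINATION_REASONS = (
    "split",
    "bic_one_component",
    "too_small",
    "low_coverage",
    "max_depth",
    "no_signal",
)


@dataclass
class ClusterParams:
    n_eigenvectors: int = 6
    max_clusters: int = 4
    inertia_gap_factor: float = 0.75
    min_cluster_cells: int = 500
    min_pooled_coverage: float = 9.0
    max_depth: int = 10
    seed: int = 0
    kmeans_restarts: int = 10
    gmm_restarts: int = 5

    def __post_init__(self) -> None:
        if self.max_clusters < 2:
            raise ValueError("max_clusters must be >= 2")
        if not 0.0 < self.inertia_gap_factor < 1.0:
            raise ValueError("inertia_gap_factor must be in (0, 1)")
        if self.min_cluster_cells < 1:
            raise ValueError("min_cluster_cells must be >= 1")


@dataclass
class ClusterNode:
    """One node of the recursive clustering tree."""

    cell_ids: np.ndarray
    termination: str
    children: list["ClusterNode"] = field(default_factory=list)
    depth: int = 0
    n_informative: int = 0
    k_chosen: int = 1
    filter_report: Optional[FilterReport] = None
    eigen_embedding: Optional[np.ndarray] = None

    @property
    def is_leaf(self) -> bool:
        return self.termination != "split"

    def leaves(self) -> list["ClusterNode"]:
        if self.is_leaf:
            return [self]
        out: list[ClusterNode] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_labels(self, n_cells: int) -> np.ndarray:
        """Dense leaf index per cell (-1 for cells outside the tree)."""
        labels = np.full(n_cells, -1, dtype=np.int64)
        for i, leaf in enumerate(self.leaves()):
            labels[leaf.cell_ids] = i
        return labels

    def to_dict(self) -> dict:
        return {
            "n_cells": int(len(self.cell_ids)),
            "cell_ids": [int(c) for c in self.cell_ids],
            "termination": self.termination,
            "depth": self.depth,
            "n_informative": self.n_informative,
            "k_chosen": self.k_chosen,
            "children": [ch.to_dict() for ch in self.children],
        }


def normalize_similarity(S: np.ndarray) -> np.ndarray:
    """Entrywise shift so the smallest element becomes 0 (order-preserving)."""
    S = np.asarray(S, dtype=np.float64)
    if S.size == 0:
        return S.copy()
    return S - S.min()


def spectral_embed(S_star: np.ndarray, n_eigenvectors: int) -> np.ndarray:
    """Rows = cells, columns = eigenvectors of the symmetric normalized
    Laplacian for the k smallest eigenvalues, in ascending eigenvalue order.

    Deterministic up to sign; the sign is fixed by making each
    eigenvector's largest-magnitude entry positive.
    """
    S_star = np.asarray(S_star, dtype=np.float64)
    n = S_star.shape[0]
    if n_eigenvectors >= n:
        raise ValueError("need n_eigenvectors < n_cells")
    d = S_star.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d + EPS_DEGREE)
    lap = -S_star * inv_sqrt[:, None] * inv_sqrt[None, :]
    lap[np.diag_indices(n)] += 1.0
    _, vecs = eigh(lap, subset_by_index=[0, n_eigenvectors - 1])
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs


def laplacian_eigenvalues(S_star: np.ndarray) -> np.ndarray:
    """Full spectrum of the symmetric normalized Laplacian (diagnostics)."""
    S_star = np.asarray(S_star, dtype=np.float64)
    d = S_star.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d + EPS_DEGREE)
    lap = -S_star * inv_sqrt[:, None] * inv_sqrt[None, :]
    lap[np.diag_indices(len(d))] += 1.0
    return eigh(lap, eigvals_only=True)


def choose_num_clusters(
    embedding: np.ndarray, params: ClusterParams
) -> tuple[int, np.ndarray]:
    """Inertia-gap (elbow) rule for the number of clusters.

    Runs k-means for k = 1..max_clusters and takes the inertia decreases
    g_k = i_{k-1} - i_k with g_1 := 0.  k is increased as long as each
    gain remains substantial, g_k > factor * g_{k-1}; the chosen k is the
    largest for which the condition holds at every step up to k.  The
    k = 2 condition holds vacuously, so the minimum split is 2-way;
    whether to split at all is decided by :func:`should_split`.  (Taking
    the single largest k whose own condition holds would misfire once the
    gains flatten out - after a clean 2-way structure g_3 fails the test
    but g_4 ~ g_3 passes it - so the sequential form is used.)
    """
    n = len(embedding)
    if n < 2:
        return 1, np.zeros(n, dtype=np.int64)
    kmax = min(params.max_clusters, n)
    inertia = []
    assignments = []
    for k in range(1, kmax + 1):
        km = KMeans(
            n_clusters=k,
            n_init=params.kmeans_restarts,
            random_state=params.seed,
        ).fit(embedding)
        inertia.append(km.inertia_)
        assignments.append(km.labels_.astype(np.int64))
    gaps = [0.0]  # g_1
    for k in range(2, kmax + 1):
        gaps.append(inertia[k - 2] - inertia[k - 1])
    chosen = min(2, kmax)
    for k in range(2, kmax + 1):
        if gaps[k - 1] > params.inertia_gap_factor * gaps[k - 2]:
            chosen = k
        else:
            break
    return chosen, assignments[chosen - 1]


def should_split(embedding: np.ndarray, params: ClusterParams) -> tuple[bool, str]:
    """Gaussian-mixture BIC test for the presence of >= 2 clusters.

    Fits mixtures with 1..max_clusters diagonal-covariance components
    (seeded restarts) and refuses the split iff the single-component
    model attains the lowest BIC.
    """
    n = len(embedding)
    if n < MIN_CELLS_FOR_SPLIT:
        return False, "insufficient_data"
    bics = []
    for k in range(1, min(params.max_clusters, n) + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            n_init=params.gmm_restarts,
            random_state=params.seed,
        ).fit(embedding)
        bics.append(gm.bic(embedding))
    if int(np.argmin(bics)) == 0:
        return False, "bic_one_component"
    return True, "bic_multi_component"


def cluster_once(
    S: SimilarityMatrix, cluster_params: ClusterParams
) -> tuple[np.ndarray, int, np.ndarray]:
    """One clustering step on a prebuilt similarity matrix.

    Returns (labels over S.cells, k, embedding); k = 1 labels everything
    0 when the BIC test refuses the split.
    """
    S_star = normalize_similarity(S.matrix)
    embedding = spectral_embed(S_star, min(cluster_params.n_eigenvectors,
                                           max(S.n_cells - 1, 1)))
    ok, _ = should_split(embedding, cluster_params)
    if not ok:
        return np.zeros(S.n_cells, dtype=np.int64), 1, embedding
    k, labels = choose_num_clusters(embedding, cluster_params)
    return labels, k, embedding


def recursive_cluster(
    pileup: Pileup,
    filter_params: FilterParams,
    similarity_params: SimilarityParams,
    cluster_params: ClusterParams,
    cells: Optional[Sequence[int]] = None,
    keep_embeddings: bool = False,
) -> ClusterNode:
    """Recursively filter, embed and split until a termination criterion.

    At every node the locus filter is re-run on that node's cells only.
    A proposed split is rolled back (the node becomes a leaf) when any
    child would have fewer than ``min_cluster_cells`` cells or mean
    pooled coverage below ``min_pooled_coverage``.
    """
    if cells is None:
        cells = np.arange(pileup.n_cells, dtype=np.int64)
    cells = np.asarray(sorted(cells), dtype=np.int64)
    return _cluster_node(
        pileup, cells, filter_params, similarity_params, cluster_params, 0,
        keep_embeddings,
    )


def _cluster_node(
    pileup: Pileup,
    cells: np.ndarray,
    fp: FilterParams,
    sp: SimilarityParams,
    cp: ClusterParams,
    depth: int,
    keep_embeddings: bool,
) -> ClusterNode:
    node = ClusterNode(cell_ids=cells, termination="no_signal", depth=depth)
    if len(cells) == 0 or pileup.n_records == 0:
        return node
    if depth >= cp.max_depth:
        node.termination = "max_depth"
        return node
    if len(cells) < max(MIN_CELLS_FOR_SPLIT, 2 * cp.min_cluster_cells):
        node.termination = "too_small"
        return node

    sub = pileup.subset_cells(cells)
    info, report = select_informative_loci(sub, fp)
    node.filter_report = report
    node.n_informative = len(info)
    if len(info) == 0:
        return node  # no_signal
    S = build_similarity_matrix(sub, info, sp, cells=cells)
    if not np.any(S.matrix):
        return node  # no_signal

    S_star = normalize_similarity(S.matrix)
    embedding = spectral_embed(
        S_star, min(cp.n_eigenvectors, len(cells) - 1)
    )
    if keep_embeddings:
        node.eigen_embedding = embedding
    ok, reason = should_split(embedding, cp)
    if not ok:
        node.termination = "bic_one_component"
        return node
    k, labels = choose_num_clusters(embedding, cp)
    node.k_chosen = k
    children_cells = [cells[labels == j] for j in range(k)]

    for ch in children_cells:
        if len(ch) < cp.min_cluster_cells:
            node.termination = "too_small"
            return node
        if sub.mean_pooled_coverage(ch) < cp.min_pooled_coverage:
            node.termination = "low_coverage"
            return node

    node.termination = "split"
    node.children = [
        _cluster_node(pileup, ch, fp, sp, cp, depth + 1, keep_embeddings)
        for ch in children_cells
    ]
    return node


# ---------------------------------------------------------------------------
# Partition scoring
# ---------------------------------------------------------------------------


def partition_scores(
    labels_true: np.ndarray, labels_pred: np.ndarray
) -> tuple[float, float]:
    """(precision, recall) of a predicted partition under optimal matching.

    Predicted clusters are matched one-to-one to true classes by maximum
    overlap (Hungarian assignment on the contingency table).  Precision
    is the fraction of cells in matched clusters that belong to the
    matched class; recall is the fraction of all cells recovered by the
    matched clusters.  For equal numbers of clusters and classes both
    reduce to the optimally-matched accuracy.
    """
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    t_vals, t_idx = np.unique(labels_true, return_inverse=True)
    p_vals, p_idx = np.unique(labels_pred, return_inverse=True)
    cont = np.zeros((len(p_vals), len(t_vals)), dtype=np.int64)
    np.add.at(cont, (p_idx, t_idx), 1)
    rows, cols = linear_sum_assignment(-cont)
    matched = int(cont[rows, cols].sum())
    matched_pred_total = int(cont[rows, :].sum())
    precision = matched / matched_pred_total if matched_pred_total else 0.0
    recall = matched / len(labels_true) if len(labels_true) else 0.0
    return precision, recall


def write_tree(node: ClusterNode, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(node.to_dict(), fh, indent=1)
        fh.write("\n")
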