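"""Disorder clustering from binary gene presence/absence profiles.

Disorders are compared by the Jaccard index of their gene sets (shared
absences carry no information), clustered agglomeratively on the Jaccard
distance, validated by non-parametric bootstrap clusterwise stability
(resample disorders with replacement, recluster, match clusters by maximum
Jaccard similarity of their membership), and projected to two dimensions by
classical (Torgerson) multidimensional scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from comorbidnet.io_model import DisorderGeneTable

logger = logging.getLogger(__name__)

LINKAGES = ("average", "complete", "single")

STABLE_THRESHOLD = 0.6  # mean bootstrap Jaccard above -> stable
UNSTABLE_THRESHOLD = 0.5  # at or below -> unstable; between -> borderline


def jaccard_index(a: frozenset | set, b: frozenset | set) -> float:
    """|a ∩ b| / |a ∪ b|; undefined (error) when both sets are empty."""
    if not a and not b:
        raise ValueError("Jaccard index undefined for two empty sets")
    union = len(a | b)
    return len(a & b) / union


@dataclass(frozen=True)
class BinaryProfileMatrix:
    """Disorder-by-gene presence/absence matrix (rows in input order)."""

    df: pd.DataFrame  # bool values; index = disorders, columns = sorted genes

    @property
    def disorders(self) -> list[str]:
        return list(self.df.index)

    def row_set(self, disorder: str) -> frozenset[str]:
        row = self.df.loc[disorder]
        return frozenset(row.index[row.to_numpy(dtype=bool)])


@dataclass(frozen=True)
class DissimilarityMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass(frozen=True)
class DendrogramTree:
    """Agglomerative merge sequence (scipy linkage encoding) over disorders."""

    linkage_matrix: np.ndarray
    leaves: list[str]
    method: str


@dataclass(frozen=True)
class ClusterAssignment:
    k: int
    labels: dict[str, int]  # disorder -> cluster index (0-based, first-seen order)

    def members(self, cluster: int) -> frozenset[str]:
        return frozenset(d for d, c in self.labels.items() if c == cluster)

    def clusters(self) -> dict[int, frozenset[str]]:
        return {c: self.members(c) for c in sorted(set(self.labels.values()))}


@dataclass(frozen=True)
class StabilityReport:
    B: int
    seed: int
    clusters: dict[int, frozenset[str]]
    stability: dict[int, float]  # mean bootstrap Jaccard per original cluster
    dissolved: dict[int, int]  # runs with match <= 0.5


@dataclass(frozen=True)
class MdsEmbedding:
    labels: list[str]
    coords: np.ndarray  # (n, dims), centered at the origin
    eigenvalues: np.ndarray  # all eigenvalues, nonincreasing


def build_matrix(tables: DisorderGeneTable) -> BinaryProfileMatrix:
    """Binary gene presence/absence matrix; rows in input order, sorted gene columns."""
    if len(tables.entries) < 2:
        raise ValueError("need at least two disorders to build a profile matrix")
    genes = sorted(tables.gene_union())
    data = np.zeros((len(tables.entries), len(genes)), dtype=bool)
    gene_idx = {g: j for j, g in enumerate(genes)}
    for i, (_, gene_set) in enumerate(tables.entries.items()):
        for g in gene_set:
            data[i, gene_idx[g]] = True
    return BinaryProfileMatrix(pd.DataFrame(data, index=list(tables.entries), columns=genes))


def dissimilarity(matrix: BinaryProfileMatrix) -> DissimilarityMatrix:
    """Pairwise Jaccard distance (1 - Jaccard index) between disorder rows."""
    condensed = pdist(matrix.df.to_numpy(dtype=bool), metric="jaccard")
    return DissimilarityMatrix(matrix.disorders, squareform(condensed))


def hierarchical_cluster(d: DissimilarityMatrix, linkage: str = "average") -> DendrogramTree:
    """Agglomerative clustering of the dissimilarity matrix.

    ``average`` (UPGMA, default), ``complete`` or ``single`` linkage; ties in
    merge distance break deterministically by index order.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    Z = hierarchy.linkage(d.condensed(), method=linkage)
    return DendrogramTree(Z, list(d.labels), linkage)


def cut_tree(tree: DendrogramTree, k: int) -> ClusterAssignment:
    """Cut the dendrogram into exactly k clusters (the k-1 highest merges removed)."""
    n = len(tree.leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    raw = hierarchy.cut_tree(tree.linkage_matrix, n_clusters=k).ravel()
    # renumber clusters in first-appearance order for determinism
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf, c in zip(tree.leaves, raw):
        if c not in remap:
            remap[c] = len(remap)
        labels[leaf] = remap[c]
    return ClusterAssignment(k, labels)


def bootstrap_stability(
    matrix: BinaryProfileMatrix,
    k: int,
    B: int = 1000,
    linkage: str = "average",
    seed: int = 0,
) -> StabilityReport:
    """Clusterwise bootstrap stability of the k-cut.

    Per run: resample disorders with replacement, recluster the resample at k,
    and record for each original cluster C the maximum over bootstrap clusters
    C' of the Jaccard similarity between C restricted to the resample and C'.
    A run in which C does not intersect the resample contributes 0. The
    per-cluster stability is the mean over runs.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    d_full = dissimilarity(matrix)
    tree = hierarchical_cluster(d_full, linkage)
    original = cut_tree(tree, k).clusters()
    n = len(matrix.disorders)
    labels = np.array(matrix.disorders)
    rng = np.random.default_rng(seed)
    sums = {c: 0.0 for c in original}
    dissolved = {c: 0 for c in original}
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sub_d = d_full.d[np.ix_(idx, idx)]
        Z = hierarchy.linkage(squareform(sub_d, checks=False), method=linkage)
        k_eff = min(k, n)
        boot_raw = hierarchy.cut_tree(Z, n_clusters=k_eff).ravel()
        boot_clusters: dict[int, set[str]] = {}
        for pos, c in enumerate(boot_raw):
            boot_clusters.setdefault(int(c), set()).add(labels[idx[pos]])
        sampled = set(labels[idx])
        for c, members in original.items():
            present = members & sampled
            if not present:
                dissolved[c] += 1
                continue
            best = max(jaccard_index(present, bc) for bc in boot_clusters.values())
            sums[c] += best
            if best <= UNSTABLE_THRESHOLD:
                dissolved[c] += 1
    stability = {c: sums[c] / B for c in original}
    return StabilityReport(B=B, seed=seed, clusters=original, stability=stability, dissolved=dissolved)


def classify_stability(report: StabilityReport) -> dict[int, str]:
    """Label each cluster stable (> 0.6), unstable (<= 0.5) or borderline."""
    out = {}
    for c, s in report.stability.items():
        if s > STABLE_THRESHOLD:
            out[c] = "stable"
        elif s <= UNSTABLE_THRESHOLD:
            out[c] = "unstable"
        else:
            out[c] = "borderline"
    return out


def classical_mds(d: DissimilarityMatrix, dims: int = 2) -> MdsEmbedding:
    """Classical (Torgerson) MDS of the dissimilarity matrix.

    Double-center -1/2 d^2, eigendecompose, return the top ``dims``
    coordinates scaled by sqrt(eigenvalue). Negative eigenvalues among the
    retained dimensions are truncated to zero with a logged warning.
    """
    n = len(d.labels)
    if dims > n - 1:
        raise ValueError(f"dims={dims} exceeds n-1={n - 1}")
    d2 = np.asarray(d.d, dtype=float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    top = eigvals[:dims].copy()
    if (top < 0).any():
        logger.warning("negative eigenvalues in MDS truncated to zero: %s", top[top < 0])
        top = np.clip(top, 0.0, None)
    coords = eigvecs[:, :dims] * np.sqrt(top)
    return MdsEmbedding(list(d.labels), coords, eigvals)


def to_newick(tree: DendrogramTree) -> str:
    """Export the dendrogram as a Newick string (branch lengths from merge heights)."""
    root = hierarchy.to_tree(tree.linkage_matrix)
    leaves = tree.leaves

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            name = leaves[node.id].replace(" ", "_").replace(",", "_")
            return f"{name}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(root.left, root.dist)},{render(root.right, root.dist)});"
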