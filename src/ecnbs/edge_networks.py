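"""Edge-centric network construction.

Pipeline: edge vectors (edge values across subjects) -> edge-by-edge Pearson
correlation matrix (the "edge connectome") -> correlation-to-distance map
``d = 2 (1 - r)`` with range [0, 4] -> Gaussian affinity
``w = exp(-d^2 / (2 sigma^2))`` with a small floor -> normalized-cut spectral
partition into ``n`` edge-centric networks.  A k-means variant operating on
the rows of the edge connectome is provided as well.

Scale note: the affinity matrix is dense E x E.  This module targets desk
scale (E up to a few thousand); full-atlas edge counts (tens of thousands)
would need blocked computation, which is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .core import ConnectomeStack, EdgePartition

__all__ = [
    "EdgeConnectome",
    "SpectralConfig",
    "AlignmentReport",
    "build_edge_vectors",
    "build_edge_connectome",
    "corr_to_distance",
    "gaussian_affinity",
    "normalized_laplacian",
    "spectral_embedding",
    "normalized_cut_partition",
    "kmeans_edge_partition",
    "partition_alignment",
]


@dataclass
class EdgeConnectome:
    """E x E matrix of across-subject Pearson correlations between edges."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("edge connectome must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("edge connectome contains non-finite values")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("edge connectome must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("edge connectome must have unit diagonal")
        if v.min() < -1 - 1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("edge connectome entries must lie in [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]


@dataclass
class SpectralConfig:
    """Settings for the normalized-cut edge partition."""

    n_networks: int
    sigma: float = 0.252
    affinity_floor: float = 1e-12
    eig_tolerance: float = 0.0
    discretization: Literal["kmeans_embedding", "rotation"] = "kmeans_embedding"
    restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 2:
            raise ValueError(f"n_networks must be >= 2, got {self.n_networks}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.affinity_floor <= 0:
            raise ValueError("affinity_floor must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.discretization not in ("kmeans_embedding", "rotation"):
            raise ValueError(f"unknown discretization {self.discretization!r}")


def build_edge_vectors(stack: ConnectomeStack, undo_fisher: bool = False) -> np.ndarray:
    """Subjects-by-edges matrix of edge values (column k = edge k across subjects).

    With ``undo_fisher`` the values are inverse Fisher transformed (tanh)
    first, returning them to correlation units.
    """
    if stack.n_subjects < 3:
        raise ValueError(
            f"need at least 3 subjects to build edge vectors, got {stack.n_subjects}"
        )
    X = stack.values.copy()
    if undo_fisher:
        X = np.tanh(X)
    var = X.var(axis=0)
    dead = np.flatnonzero(var == 0)
    if dead.size:
        raise ValueError(
            f"edge(s) {dead[:10].tolist()} are constant across subjects; "
            "edge correlations are undefined"
        )
    return X


def build_edge_connectome(edge_vectors: np.ndarray) -> EdgeConnectome:
    """Pearson correlation between all pairs of edge vectors (columns)."""
    X = np.asarray(edge_vectors, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("edge vectors contain non-finite values")
    if np.any(X.var(axis=0) == 0):
        raise ValueError("constant edge vector; correlations undefined")
    C = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(C, 1.0)
    return EdgeConnectome(np.clip(C, -1.0, 1.0))


def corr_to_distance(r):
    """Affine correlation-to-distance map ``d = 2 (1 - r)`` with range [0, 4]."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    d = 2.0 * (1.0 - np.clip(r, -1.0, 1.0))
    return d if d.ndim else float(d)


def gaussian_affinity(d, config: SpectralConfig):
    """Gaussian kernel weight ``exp(-d^2 / (2 sigma^2))``, floored.

    The kernel peaks at 1 for zero distance; weights that underflow below
    ``config.affinity_floor`` are clamped to the floor, which keeps the
    affinity graph connected (single trivial Laplacian eigenvector).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    w = np.maximum(np.exp(-(d**2) / (2.0 * config.sigma**2)), config.affinity_floor)
    return w if w.ndim else float(w)


def normalized_laplacian(affinity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric normalized Laplacian of an affinity matrix.

    The diagonal of the affinity is zeroed before degrees are computed.
    Returns ``(L_sym, sqrt_degree)``.
    """
    W = np.array(affinity, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("affinity must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if np.any(W < 0):
        raise ValueError("affinity must be non-negative")
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("isolated vertex in affinity graph (zero degree)")
    ds = np.sqrt(deg)
    L = -W / np.outer(ds, ds)
    np.fill_diagonal(L, 1.0)
    return L, ds


def spectral_embedding(affinity: np.ndarray, n_components: int) -> np.ndarray:
    """First ``n_components`` non-trivial eigenvectors of the normalized Laplacian.

    The single smallest eigenpair (the trivial one, eigenvalue ~0 with
    eigenvector proportional to sqrt-degree) is dropped; rows of the returned
    embedding are normalized to unit length.
    """
    L, _ = normalized_laplacian(affinity)
    E = L.shape[0]
    if n_components + 1 > E:
        raise ValueError(
            f"requested {n_components} non-trivial eigenvectors but graph has {E} vertices"
        )
    _, vecs = scipy.linalg.eigh(L, subset_by_index=[0, n_components])
    emb = vecs[:, 1:]  # drop the trivial eigenvector
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return emb / norms


def _relabel_first_appearance(labels0: np.ndarray) -> np.ndarray:
    """Map arbitrary cluster labels to 1..k by order of first appearance."""
    _, first = np.unique(labels0, return_index=True)
    order = labels0[np.sort(first)]
    mapping = {old: new + 1 for new, old in enumerate(order)}
    return np.array([mapping[v] for v in labels0], dtype=int)


def _discretize_rotation(emb: np.ndarray, rng: np.random.Generator, n_iter: int = 100) -> np.ndarray:
    # Yu & Shi style alternating rotation/assignment on the spectral embedding.
    n, k = emb.shape
    X = emb / np.maximum(np.linalg.norm(emb, axis=1, keepdims=True), 1e-12)
    R = np.eye(k)
    # seed rotation from k well-spread rows
    idx = [int(rng.integers(n))]
    c = np.abs(X @ X[idx[0]])
    for _ in range(1, k):
        idx.append(int(np.argmin(c)))
        c = c + np.abs(X @ X[idx[-1]])
    R = np.linalg.qr(X[idx].T)[0]
    last = 0.0
    for _ in range(n_iter):
        labels = np.argmax(X @ R, axis=1)
        Z = np.zeros((n, k))
        Z[np.arange(n), labels] = 1.0
        U, s, Vt = np.linalg.svd(X.T @ Z)
        ncut_val = float(s.sum())
        R = U @ Vt
        if abs(ncut_val - last) < 1e-10:
            break
        last = ncut_val
    return np.argmax(X @ R, axis=1)


def normalized_cut_partition(
    affinity: np.ndarray, config: SpectralConfig
) -> EdgePartition:
    """Partition edges by normalized cut on an affinity matrix.

    Computes the symmetric normalized Laplacian, takes the ``n_networks``
    smallest non-trivial eigenvectors, row-normalizes the embedding and
    discretizes it (k-means by default, rotation-based optionally).  Labels
    are 1..n, every cluster non-empty.
    """
    E = np.asarray(affinity).shape[0]
    if config.n_networks >= E:
        raise ValueError(f"n_networks={config.n_networks} must be < number of edges {E}")
    emb = spectral_embedding(affinity, config.n_networks)
    k = config.n_networks
    if config.discretization == "kmeans_embedding":
        km = KMeans(
            n_clusters=k,
            n_init=config.restarts,
            random_state=config.seed,
        ).fit(emb)
        labels0 = km.labels_
        if np.unique(labels0).size < k:
            raise RuntimeError("k-means discretization produced an empty cluster")
    else:
        rng = np.random.default_rng(config.seed)
        labels0 = None
        for _ in range(config.restarts):
            cand = _discretize_rotation(emb, rng)
            if np.unique(cand).size == k:
                labels0 = cand
                break
        if labels0 is None:
            raise RuntimeError(
                f"rotation discretization left an empty cluster after {config.restarts} restarts"
            )
    return EdgePartition(_relabel_first_appearance(labels0), k, origin="edge_clustered")


def edge_partition_from_stack(
    stack: ConnectomeStack, config: SpectralConfig, undo_fisher: bool = True
) -> EdgePartition:
    """Full pipeline: stack -> edge connectome -> affinity -> normalized cut."""
    vectors = build_edge_vectors(stack, undo_fisher=undo_fisher)
    conn = build_edge_connectome(vectors)
    dist = corr_to_distance(conn.values)
    aff = gaussian_affinity(dist, config)
    return normalized_cut_partition(aff, config)


def kmeans_edge_partition(
    edge_connectome: EdgeConnectome, n: int, seed: int = 0, restarts: int = 10
) -> EdgePartition:
    """k-means on the rows of the edge connectome (greedy ++ seeding)."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if n >= edge_connectome.n_edges:
        raise ValueError("n must be smaller than the number of edges")
    km = KMeans(n_clusters=n, n_init=restarts, random_state=seed).fit(
        edge_connectome.values
    )
    if np.unique(km.labels_).size < n:
        raise RuntimeError("k-means produced an empty cluster")
    return EdgePartition(_relabel_first_appearance(km.labels_), n, origin="edge_clustered")


@dataclass
class AlignmentReport:
    """Agreement between two edge partitions."""

    ari: float
    #: for each network of partition a (id order), the largest fraction of its
    #: edges captured by any single network of partition b
    best_overlap: np.ndarray


def partition_alignment(a: EdgePartition, b: EdgePartition) -> AlignmentReport:
    """Adjusted Rand index and per-network best-overlap fractions (a vs b)."""
    if a.n_edges != b.n_edges:
        raise ValueError("partitions cover different numbers of edges")
    ari = float(adjusted_rand_score(a.labels, b.labels))
    overlaps = np.zeros(a.n_networks)
    for m in range(1, a.n_networks + 1):
        members = a.members(m)
        counts = np.bincount(b.labels[members])
        overlaps[m - 1] = counts.max() / members.size
    return AlignmentReport(ari, overlaps)
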