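"""Core data model: edge indexing, connectome stacks, phenotypes and partitions.

Every other module consumes these types.  The package-wide edge-ordering
convention is fixed here: edges are the strict upper triangle of a symmetric
connectivity matrix, enumerated 0-based and row-major, i.e. the edge (i, j)
with ``0 <= i < j < n_nodes`` has linear index

    k = i * (2 * n_nodes - i - 1) / 2 + (j - i - 1)

so a matrix with ``n`` nodes yields ``E = n * (n - 1) / 2`` edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "EdgeIndexer",
    "ConnectomeStack",
    "Phenotype",
    "NodePartition",
    "EdgePartition",
    "edge_index",
    "edge_pair",
    "vectorize",
    "devectorize",
    "node_partition_to_edge_groups",
]

#: tolerance used when checking that an input matrix is symmetric
SYMMETRY_TOL = 1e-8


def n_edges_for(n_nodes: int) -> int:
    """Number of strict-upper-triangle edges for ``n_nodes`` nodes."""
    return n_nodes * (n_nodes - 1) // 2


@dataclass(frozen=True)
class EdgeIndexer:
    """Bijection between node pairs ``(i, j)``, ``i < j``, and edge indices.

    Parameters
    ----------
    n_nodes
        Number of atlas nodes; must be at least 2.
    """

    n_nodes: int

    def __post_init__(self) -> None:
        if not (isinstance(self.n_nodes, (int, np.integer)) and self.n_nodes >= 2):
            raise ValueError(f"n_nodes must be an integer >= 2, got {self.n_nodes!r}")

    @property
    def n_edges(self) -> int:
        return n_edges_for(self.n_nodes)

    @cached_property
    def pairs(self) -> np.ndarray:
        """``(E, 2)`` array of node pairs in linear-index order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return np.column_stack(iu)

    def index(self, i: int, j: int) -> int:
        """Linear edge index of the node pair ``(i, j)`` with ``i < j``."""
        return edge_index(i, j, self.n_nodes)

    def pair(self, k: int) -> tuple[int, int]:
        """Inverse of :meth:`index`: node pair for a linear edge index."""
        return edge_pair(k, self.n_nodes)


def edge_index(i: int, j: int, n_nodes: int) -> int:
    """Row-major strict-upper-triangle rank of the node pair ``(i, j)``.

    Raises
    ------
    ValueError
        If ``i >= j`` or either index is out of range.
    """
    i = int(i)
    j = int(j)
    if not (0 <= i < j < n_nodes):
        raise ValueError(
            f"invalid node pair ({i}, {j}) for n_nodes={n_nodes}; need 0 <= i < j < n_nodes"
        )
    return i * (2 * n_nodes - i - 1) // 2 + (j - i - 1)


def edge_pair(k: int, n_nodes: int) -> tuple[int, int]:
    """Node pair ``(i, j)`` of linear edge index ``k``; inverse of :func:`edge_index`."""
    E = n_edges_for(n_nodes)
    k = int(k)
    if not 0 <= k < E:
        raise ValueError(f"edge index {k} out of range for n_nodes={n_nodes} (E={E})")
    # invert the row-major rank: find the largest i with offset(i) <= k
    # offset(i) = i*n - i*(i+1)/2 - i  (start of row i)
    i = int(
        np.floor((2 * n_nodes - 1 - np.sqrt((2 * n_nodes - 1) ** 2 - 8 * k)) / 2)
    )
    offset = i * (2 * n_nodes - i - 1) // 2
    # guard against floating-point slop at row boundaries
    while offset > k:
        i -= 1
        offset = i * (2 * n_nodes - i - 1) // 2
    while i + 1 < n_nodes - 1 and (i + 1) * (2 * n_nodes - i - 2) // 2 <= k:
        i += 1
        offset = i * (2 * n_nodes - i - 1) // 2
    j = k - offset + i + 1
    return i, j


def vectorize(matrix: np.ndarray, tol: float = SYMMETRY_TOL) -> np.ndarray:
    """Strict-upper-triangle vector of a symmetric matrix (diagonal discarded).

    Parameters
    ----------
    matrix
        Square symmetric matrix; asymmetry beyond ``tol`` is rejected.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if not np.all(np.abs(m - m.T) <= tol):
        worst = float(np.max(np.abs(m - m.T)))
        raise ValueError(f"matrix is not symmetric within {tol} (max deviation {worst:g})")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def devectorize(vec: np.ndarray, n_nodes: int) -> np.ndarray:
    """Symmetric matrix with zero diagonal whose upper triangle is ``vec``."""
    v = np.asarray(vec, dtype=float).ravel()
    E = n_edges_for(n_nodes)
    if v.size != E:
        raise ValueError(f"edge vector has length {v.size}, expected {E} for n_nodes={n_nodes}")
    out = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    out[iu] = v
    out += out.T
    return out


@dataclass
class ConnectomeStack:
    """Subjects-by-edges matrix of edge weights with a fixed node count.

    ``values[s, k]`` is the weight of edge ``k`` (see :class:`EdgeIndexer`) in
    subject ``s``, typically a Fisher-z transformed correlation.
    """

    values: np.ndarray
    n_nodes: int
    subject_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D (subjects x edges), got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectome stack contains non-finite values")
        E = n_edges_for(self.n_nodes)
        if self.values.shape[1] != E:
            raise ValueError(
                f"stack has {self.values.shape[1]} columns but n_nodes={self.n_nodes} "
                f"implies E={E}"
            )
        if self.subject_ids is not None:
            self.subject_ids = [str(s) for s in self.subject_ids]
            if len(self.subject_ids) != self.values.shape[0]:
                raise ValueError("subject_ids length does not match subject count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    @property
    def indexer(self) -> EdgeIndexer:
        return EdgeIndexer(self.n_nodes)

    def subset(self, subject_idx: np.ndarray) -> "ConnectomeStack":
        """New stack restricted to the given subject indices (order kept)."""
        ids = None
        if self.subject_ids is not None:
            ids = [self.subject_ids[i] for i in subject_idx]
        return ConnectomeStack(self.values[subject_idx], self.n_nodes, ids)

    @classmethod
    def from_matrices(
        cls,
        matrices: Sequence[np.ndarray],
        subject_ids: Sequence[str] | None = None,
    ) -> "ConnectomeStack":
        """Build a stack from per-subject square symmetric matrices."""
        if len(matrices) == 0:
            raise ValueError("no matrices supplied")
        n_nodes = np.asarray(matrices[0]).shape[0]
        rows = [vectorize(m) for m in matrices]
        return cls(np.vstack(rows), n_nodes, subject_ids)


@dataclass
class Phenotype:
    """Per-subject phenotype, either binary (two classes) or continuous.

    For a binary phenotype, ``level_labels`` orders the two classes; group
    differences throughout the package are signed as *first level minus
    second level*.  When not given, levels default to the sorted distinct
    values in descending order (so 0/1 coding yields ``(1, 0)``).
    """

    values: np.ndarray
    kind: Literal["binary", "continuous"]
    level_labels: tuple | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("phenotype values must be 1-D")
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        if self.kind == "continuous":
            self.values = self.values.astype(float)
            if not np.all(np.isfinite(self.values)):
                raise ValueError("continuous phenotype contains non-finite values")
        else:
            levels = np.unique(self.values)
            if levels.size != 2:
                raise ValueError(
                    f"binary phenotype must have exactly 2 distinct values, found {levels.size}"
                )
            if self.level_labels is None:
                self.level_labels = tuple(sorted(levels.tolist(), reverse=True))
            else:
                self.level_labels = tuple(self.level_labels)
                if set(self.level_labels) != set(levels.tolist()):
                    raise ValueError("level_labels do not match the values present")
            for lab in self.level_labels:
                if int(np.sum(self.values == lab)) < 2:
                    raise ValueError(f"binary class {lab!r} has fewer than 2 subjects")

    @property
    def n_subjects(self) -> int:
        return self.values.size

    @property
    def is_binary(self) -> bool:
        return self.kind == "binary"

    def group_indicator(self) -> np.ndarray:
        """Boolean mask of membership in the first (reference) class."""
        if not self.is_binary:
            raise ValueError("group_indicator is only defined for binary phenotypes")
        return np.asarray(self.values == self.level_labels[0])

    def subset(self, subject_idx: np.ndarray) -> "Phenotype":
        sub = self.values[subject_idx]
        if self.is_binary:
            return Phenotype(sub, "binary", self.level_labels)
        return Phenotype(sub, "continuous")


@dataclass
class NodePartition:
    """Assignment of nodes to ``N`` node-centric networks labeled 1..N."""

    labels: np.ndarray
    n_networks: int = field(default=0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("node labels must be a non-empty 1-D integer array")
        if self.n_networks == 0:
            self.n_networks = int(self.labels.max())
        present = np.unique(self.labels)
        expected = np.arange(1, self.n_networks + 1)
        if not np.array_equal(present, expected):
            raise ValueError(
                f"node partition must use every label 1..{self.n_networks}; found {present}"
            )

    @property
    def n_nodes(self) -> int:
        return self.labels.size


@dataclass
class EdgePartition:
    """Assignment of edges to ``M`` networks labeled 1..M.

    ``origin`` records whether the grouping was produced by clustering edges
    directly (``edge_clustered``) or induced from a node partition
    (``node_induced``).
    """

    labels: np.ndarray
    n_networks: int = field(default=0)
    origin: Literal["edge_clustered", "node_induced"] = "edge_clustered"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("edge labels must be a non-empty 1-D integer array")
        if self.n_networks == 0:
            self.n_networks = int(self.labels.max())
        present = np.unique(self.labels)
        expected = np.arange(1, self.n_networks + 1)
        if not np.array_equal(present, expected):
            raise ValueError(
                f"edge partition must use every label 1..{self.n_networks} "
                f"with no empty network; found {present}"
            )
        if self.origin not in ("edge_clustered", "node_induced"):
            raise ValueError(f"unknown partition origin {self.origin!r}")

    @property
    def n_edges(self) -> int:
        return self.labels.size

    def sizes(self) -> np.ndarray:
        """Edge count of each network, indexed by network id - 1."""
        return np.bincount(self.labels, minlength=self.n_networks + 1)[1:]

    def members(self, network_id: int) -> np.ndarray:
        """Edge indices belonging to a network."""
        return np.flatnonzero(self.labels == network_id)

    def membership_matrix(self, normalize: bool = False) -> np.ndarray:
        """``(M, E)`` indicator matrix; rows sum to 1 when ``normalize``."""
        A = np.zeros((self.n_networks, self.n_edges))
        A[self.labels - 1, np.arange(self.n_edges)] = 1.0
        if normalize:
            A /= A.sum(axis=1, keepdims=True)
        return A


def node_partition_to_edge_groups(
    partition: NodePartition, n_nodes: int | None = None
) -> EdgePartition:
    """Edge grouping induced by a node partition.

    Each edge is assigned to the unordered pair of node-network labels of its
    endpoints; with ``N`` node networks and every pairing realized this gives
    ``N * (N + 1) / 2`` groups (``N`` within-network plus ``N * (N - 1) / 2``
    between-network).  Group ids are deterministic: sorted by
    ``(min label, max label)``.
    """
    if n_nodes is not None and n_nodes != partition.n_nodes:
        raise ValueError(
            f"partition labels {partition.n_nodes} nodes but stack has {n_nodes}"
        )
    n = partition.n_nodes
    idx = EdgeIndexer(n)
    pairs = idx.pairs
    a = partition.labels[pairs[:, 0]]
    b = partition.labels[pairs[:, 1]]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    # encode unordered label pairs, then rank the realized ones
    codes = lo * (partition.n_networks + 1) + hi
    realized, edge_labels = np.unique(codes, return_inverse=True)
    part = EdgePartition(edge_labels + 1, int(realized.size), origin="node_induced")
    n_expected = partition.n_networks * (partition.n_networks + 1) // 2
    if realized.size < n_expected:
        warnings.warn(
            f"only {realized.size} of {n_expected} possible network pairings are "
            "realized by at least one edge",
            stacklevel=2,
        )
    return part
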