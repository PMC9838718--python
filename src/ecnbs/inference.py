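"""Inference procedures sharing one permutation engine.

Four procedures are provided:

* :func:`ecnbs` — within-network means of edge statistics over an
  edge-clustered partition, per-network permutation null (1000 relabelings by
  default), percentile p-values, Simes/Benjamini-Hochberg FDR correction;
* :func:`cnbs` — identical, but the edge grouping is induced from a node
  partition (N node networks -> N(N+1)/2 edge groups);
* :func:`nbs` — suprathreshold connected components (threshold t = 3.1 by
  default) with a max-component-size permutation null controlling FWER;
* :func:`edge_fdr` — parametric one-tailed edge p-values corrected with
  Storey q-values.

Conventions (documented, since they are choice points):

* permutation p-values use the add-one rule ``p = (1 + #{null >= obs}) /
  (1 + P)``, so p is valid and strictly positive; ties count against
  rejection;
* one phenotype relabeling per permutation is shared across all components,
  preserving cross-component dependence;
* the negative-direction null is the exact negation of the positive-direction
  null (same relabelings, negated statistics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import scipy.sparse
import scipy.stats
from scipy.sparse.csgraph import connected_components as _cc

from .core import ConnectomeStack, EdgePartition, NodePartition, Phenotype, node_partition_to_edge_groups
from .edgestats import T_CAP, EdgeStatVector, correlation_t, two_sample_t

__all__ = [
    "PermutationScheme",
    "NBSConfig",
    "InferenceResult",
    "permutation_null",
    "perm_pvalue",
    "bh_adjust",
    "storey_qvalues",
    "ecnbs",
    "cnbs",
    "nbs",
    "edge_fdr",
    "two_tailed_scan",
    "run_method",
]

Direction = Literal["positive", "negative"]


@dataclass
class PermutationScheme:
    """Permutation-null settings: P relabelings, seeded, shared across components."""

    n_permutations: int = 1000
    seed: int = 0
    shared_across_components: bool = True

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError(
                f"n_permutations must be >= 100, got {self.n_permutations}"
            )
        if not self.shared_across_components:
            raise ValueError(
                "only shared relabelings are supported: one permutation of the "
                "phenotype per iteration, reused for every component"
            )


@dataclass
class NBSConfig:
    """NBS settings: the t threshold and the component-size definition."""

    t_threshold: float = 3.1
    component_size: Literal["extent"] = "extent"

    def __post_init__(self) -> None:
        if self.t_threshold <= 0:
            raise ValueError(f"t_threshold must be positive, got {self.t_threshold}")
        if self.component_size != "extent":
            raise ValueError("only extent (edge-count) component size is supported")


@dataclass
class InferenceResult:
    """Per-component statistics, corrected p-values and detection flags."""

    level: Literal["edge", "cluster", "network"]
    component_ids: np.ndarray
    components: list[np.ndarray]  # member edge indices per component
    observed_stat: np.ndarray
    corrected_p: np.ndarray
    detected: np.ndarray
    direction: Direction
    alpha: float = 0.05
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.corrected_p = np.asarray(self.corrected_p, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.corrected_p.size and (
            self.corrected_p.min() < 0 or self.corrected_p.max() > 1
        ):
            raise ValueError("corrected p-values must lie in [0, 1]")
        if not np.array_equal(self.detected, self.corrected_p <= self.alpha):
            raise ValueError("detected flags must equal corrected_p <= alpha")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

def _permutation_indices(n: int, scheme: PermutationScheme) -> np.ndarray:
    rng = np.random.default_rng(scheme.seed)
    return np.array([rng.permutation(n) for _ in range(scheme.n_permutations)])


def _binary_t_matrix(X: np.ndarray, y01: np.ndarray, perm_idx: np.ndarray) -> np.ndarray:
    """Pooled two-sample t for each permutation row; shape (P, E).

    Sign convention: group coded 1 minus group coded 0.
    """
    n = y01.size
    G = y01[perm_idx].astype(float)  # (P, n)
    n1 = float(y01.sum())
    n2 = n - n1
    X2 = X**2
    S = X.sum(axis=0)
    SS = X2.sum(axis=0)
    S1 = G @ X
    SS1 = G @ X2
    m1 = S1 / n1
    m2 = (S - S1) / n2
    ss_within = (SS1 - n1 * m1**2) + ((SS - SS1) - n2 * m2**2)
    sp2 = np.maximum(ss_within, 0.0) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se == 0, 0.0, (m1 - m2) / np.where(se == 0, 1.0, se))
    return t


def _continuous_t_matrix(X: np.ndarray, y: np.ndarray, perm_idx: np.ndarray) -> np.ndarray:
    """Correlation t for each permutation row; shape (P, E)."""
    n = y.size
    yc = y - y.mean()
    Y = yc[perm_idx]  # (P, n)
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    denom = np.where(sx == 0, 1.0, sx * sy)
    r = (Y @ Xc) / denom
    r[:, sx == 0] = 0.0
    r = np.clip(r, -1.0, 1.0)
    sat = np.abs(r) >= 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    return np.where(sat, np.sign(r) * T_CAP, t)


def _perm_stat_matrix(
    stack: ConnectomeStack, phenotype: Phenotype, perm_idx: np.ndarray
) -> np.ndarray:
    """Positive-direction edge statistics for every permutation; (P, E)."""
    if phenotype.is_binary:
        y01 = phenotype.group_indicator().astype(int)
        return _binary_t_matrix(stack.values, y01, perm_idx)
    if phenotype.n_subjects < 4:
        raise ValueError("correlation statistic needs at least 4 subjects")
    return _continuous_t_matrix(stack.values, phenotype.values.astype(float), perm_idx)


def observed_edge_stats(
    stack: ConnectomeStack, phenotype: Phenotype, direction: Direction = "positive"
) -> EdgeStatVector:
    """Observed per-edge statistic matching the phenotype kind."""
    if phenotype.is_binary:
        return two_sample_t(stack, phenotype, direction)
    return correlation_t(stack, phenotype, direction)


def permutation_null(
    stack: ConnectomeStack,
    phenotype: Phenotype,
    statistic_kind: Literal["auto", "two_sample_t", "correlation_t"] = "auto",
    reduce: Callable[[np.ndarray], np.ndarray] | None = None,
    scheme: PermutationScheme | None = None,
    direction: Direction = "positive",
) -> np.ndarray:
    """Null matrix of per-component statistics, shape (components, P).

    For each of the P permutations, the phenotype is uniformly relabeled once
    and the edge statistics recomputed; ``reduce`` maps the (P, E) statistic
    matrix to (P, M) component statistics (identity when omitted).
    Reproducible from ``scheme.seed``.
    """
    scheme = scheme or PermutationScheme()
    if statistic_kind != "auto":
        expected = "two_sample_t" if phenotype.is_binary else "correlation_t"
        if statistic_kind != expected:
            raise ValueError(
                f"statistic_kind {statistic_kind!r} does not match phenotype kind"
            )
    perm_idx = _permutation_indices(phenotype.n_subjects, scheme)
    stat = _perm_stat_matrix(stack, phenotype, perm_idx)
    if direction == "negative":
        stat = -stat
    if reduce is not None:
        stat = reduce(stat)
    return np.asarray(stat).T  # components x permutations


def perm_pvalue(observed: float, null_samples: np.ndarray) -> float:
    """Add-one permutation p-value: ``(1 + #{null >= observed}) / (1 + P)``."""
    null_samples = np.asarray(null_samples, dtype=float).ravel()
    if null_samples.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(null_samples >= observed)) / (1 + null_samples.size))


def _perm_pvalues_rowwise(observed: np.ndarray, null_matrix: np.ndarray) -> np.ndarray:
    """Vectorized :func:`perm_pvalue` for per-component nulls (M x P)."""
    P = null_matrix.shape[1]
    count = (null_matrix >= observed[:, None]).sum(axis=1)
    return (1.0 + count) / (1.0 + P)


# ---------------------------------------------------------------------------
# multiple-testing primitives
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Simes/Benjamini-Hochberg step-up adjusted p-values.

    ``adj_(i) = min_{j >= i} m * p_(j) / j`` (clipped at 1), mapped back to
    input order; thresholding the output at q reproduces the classical
    step-up detection rule.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def storey_qvalues(p: np.ndarray, lambdas: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values with a smoothed pi0 estimate.

    pi0 is estimated as ``#{p > lambda} / (m (1 - lambda))`` on the grid
    lambda = 0.05, 0.10, ..., 0.90, smoothed with a cubic polynomial and
    evaluated at lambda = 0.90, then clamped to (0, 1].  q-values equal
    ``pi0 * bh_adjust(p)``.

    Returns ``(q, pi0)``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy(), 1.0
    if m < 100:
        warnings.warn(
            f"pi0 estimation is unreliable for {m} < 100 p-values", stacklevel=2
        )
    if lambdas is None:
        lambdas = np.arange(0.05, 0.9 + 1e-9, 0.05)
    pi0_grid = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if lambdas.size >= 4:
        coefs = np.polyfit(lambdas, pi0_grid, deg=3)
        pi0 = float(np.polyval(coefs, lambdas[-1]))
    else:
        pi0 = float(pi0_grid[-1])
    pi0 = min(pi0, 1.0)
    pi0 = max(pi0, 1.0 / m)  # keep strictly positive
    q = np.minimum(pi0 * bh_adjust(p), 1.0)
    return q, pi0


# ---------------------------------------------------------------------------
# procedures
# ---------------------------------------------------------------------------

def ecnbs(
    stack: ConnectomeStack,
    phenotype: Phenotype,
    partition: EdgePartition,
    scheme: PermutationScheme | None = None,
    alpha: float = 0.05,
    direction: Direction = "positive",
) -> InferenceResult:
    """Network-level inference constrained by an edge partition.

    Per network: mean of member edge statistics; permutation null of the same
    within-network mean; percentile p-value; BH correction across the M
    networks; detection at ``alpha``.
    """
    scheme = scheme or PermutationScheme()
    if partition.n_edges != stack.n_edges:
        raise ValueError("partition and stack edge counts differ")
    A = partition.membership_matrix(normalize=True)  # (M, E)
    obs_edge = observed_edge_stats(stack, phenotype, "positive").values
    obs = A @ obs_edge
    null = permutation_null(
        stack, phenotype, reduce=lambda S: S @ A.T, scheme=scheme, direction="positive"
    )
    if direction == "negative":
        obs, null = -obs, -null
    p = _perm_pvalues_rowwise(obs, null)
    q = bh_adjust(p)
    M = partition.n_networks
    return InferenceResult(
        level="network",
        component_ids=np.arange(1, M + 1),
        components=[partition.members(m) for m in range(1, M + 1)],
        observed_stat=obs,
        corrected_p=q,
        detected=q <= alpha,
        direction=direction,
        alpha=alpha,
        metadata={
            "method": "ecnbs",
            "n_permutations": scheme.n_permutations,
            "seed": scheme.seed,
            "partition_origin": partition.origin,
            "uncorrected_p": p,
        },
    )


def cnbs(
    stack: ConnectomeStack,
    phenotype: Phenotype,
    node_partition: NodePartition,
    scheme: PermutationScheme | None = None,
    alpha: float = 0.05,
    direction: Direction = "positive",
) -> InferenceResult:
    """Network-level inference over node-induced edge groupings.

    Identical to :func:`ecnbs` after converting the node partition to its
    N(N+1)/2 edge groups.
    """
    edge_groups = node_partition_to_edge_groups(node_partition)
    result = ecnbs(stack, phenotype, edge_groups, scheme, alpha, direction)
    result.metadata["method"] = "cnbs"
    result.metadata["n_node_networks"] = node_partition.n_networks
    return result


def _components_from_mask(
    mask: np.ndarray, pairs: np.ndarray, n_nodes: int
) -> list[np.ndarray]:
    """Connected components of the suprathreshold graph, as edge-index sets."""
    edges = np.flatnonzero(mask)
    if edges.size == 0:
        return []
    i = pairs[edges, 0]
    j = pairs[edges, 1]
    adj = scipy.sparse.coo_matrix(
        (np.ones(edges.size), (i, j)), shape=(n_nodes, n_nodes)
    )
    _, labels = _cc(adj, directed=False)
    comp_of_edge = labels[i]
    comps = []
    for c in np.unique(comp_of_edge):
        comps.append(edges[comp_of_edge == c])
    return comps


def _max_component_sizes(
    stat_matrix: np.ndarray, threshold: float, pairs: np.ndarray, n_nodes: int
) -> np.ndarray:
    """Max suprathreshold component edge count per permutation row (0 if none)."""
    P = stat_matrix.shape[0]
    out = np.zeros(P, dtype=int)
    masks = stat_matrix > threshold
    for p in range(P):
        edges = np.flatnonzero(masks[p])
        if edges.size == 0:
            continue
        i = pairs[edges, 0]
        j = pairs[edges, 1]
        adj = scipy.sparse.coo_matrix(
            (np.ones(edges.size), (i, j)), shape=(n_nodes, n_nodes)
        )
        _, labels = _cc(adj, directed=False)
        out[p] = int(np.bincount(labels[i]).max())
    return out


def nbs(
    stack: ConnectomeStack,
    phenotype: Phenotype,
    config: NBSConfig | None = None,
    scheme: PermutationScheme | None = None,
    alpha: float = 0.05,
    direction: Direction = "positive",
) -> InferenceResult:
    """Network-based statistic: max-component-size permutation inference.

    Suprathreshold edges (statistic strictly above ``t_threshold``) define an
    unweighted graph on the atlas nodes; each connected component's size is
    its edge count, compared against the null distribution of per-permutation
    maximum component sizes.
    """
    config = config or NBSConfig()
    scheme = scheme or PermutationScheme()
    pairs = stack.indexer.pairs
    obs = observed_edge_stats(stack, phenotype, direction).values
    comps = _components_from_mask(obs > config.t_threshold, pairs, stack.n_nodes)
    null_stats = permutation_null(stack, phenotype, scheme=scheme, direction=direction)
    null_max = _max_component_sizes(null_stats.T, config.t_threshold, pairs, stack.n_nodes)
    sizes = np.array([c.size for c in comps], dtype=float)
    p = np.array([perm_pvalue(s, null_max) for s in sizes])
    return InferenceResult(
        level="cluster",
        component_ids=np.arange(1, len(comps) + 1),
        components=comps,
        observed_stat=sizes,
        corrected_p=p,
        detected=p <= alpha if p.size else np.zeros(0, dtype=bool),
        direction=direction,
        alpha=alpha,
        metadata={
            "method": "nbs",
            "t_threshold": config.t_threshold,
            "component_size": config.component_size,
            "n_permutations": scheme.n_permutations,
            "seed": scheme.seed,
            "null_max_sizes": null_max,
        },
    )


def edge_fdr(
    stack: ConnectomeStack,
    phenotype: Phenotype,
    alpha: float = 0.05,
    direction: Direction = "positive",
) -> InferenceResult:
    """Edge-level inference: parametric one-tailed p with Storey q-values."""
    stat = observed_edge_stats(stack, phenotype, direction)
    p = scipy.stats.t.sf(stat.values, df=stat.df)
    q, pi0 = storey_qvalues(p)
    E = stack.n_edges
    return InferenceResult(
        level="edge",
        component_ids=np.arange(E),
        components=[np.array([k]) for k in range(E)],
        observed_stat=stat.values,
        corrected_p=q,
        detected=q <= alpha,
        direction=direction,
        alpha=alpha,
        metadata={"method": "edgefdr", "pi0": pi0, "uncorrected_p": p, "df": stat.df},
    )


def run_method(
    method: str,
    stack: ConnectomeStack,
    phenotype: Phenotype,
    direction: Direction,
    alpha: float = 0.05,
    edge_partition: EdgePartition | None = None,
    node_partition: NodePartition | None = None,
    nbs_config: NBSConfig | None = None,
    scheme: PermutationScheme | None = None,
) -> InferenceResult:
    """Dispatch one of the four procedures by name."""
    if method == "ecnbs":
        if edge_partition is None:
            raise ValueError("ecnbs requires an edge partition")
        return ecnbs(stack, phenotype, edge_partition, scheme, alpha, direction)
    if method == "cnbs":
        if node_partition is None:
            raise ValueError("cnbs requires a node partition")
        return cnbs(stack, phenotype, node_partition, scheme, alpha, direction)
    if method == "nbs":
        return nbs(stack, phenotype, nbs_config, scheme, alpha, direction)
    if method == "edgefdr":
        return edge_fdr(stack, phenotype, alpha, direction)
    raise ValueError(f"unknown method {method!r}")


def two_tailed_scan(
    stack: ConnectomeStack,
    phenotype: Phenotype,
    method: str,
    alpha: float = 0.05,
    **kwargs,
) -> tuple[np.ndarray, dict]:
    """Two-tailed full-sample scan: both directions at ``alpha / 2`` each.

    Returns a signed per-component map (+1 for a positive-direction rejection,
    -1 for negative, 0 otherwise) and a dict with both direction-specific
    results.  For NBS the map is at the edge level (edges of detected
    clusters); for the other methods it is per fixed component.
    """
    per_tail = alpha / 2.0
    res_pos = run_method(method, stack, phenotype, "positive", per_tail, **kwargs)
    res_neg = run_method(method, stack, phenotype, "negative", per_tail, **kwargs)
    if method == "nbs":
        signed = np.zeros(stack.n_edges, dtype=int)
        for res, sign in ((res_pos, 1), (res_neg, -1)):
            for comp, det in zip(res.components, res.detected):
                if det:
                    signed[comp] = sign
    else:
        signed = np.zeros(res_pos.n_components, dtype=int)
        signed[res_pos.detected] = 1
        both = res_pos.detected & res_neg.detected
        if np.any(both):
            raise RuntimeError(
                "a component was rejected in both directions; this should be impossible"
            )
        signed[res_neg.detected] = -1
    return signed, {"positive": res_pos, "negative": res_neg, "per_tail_alpha": per_tail}
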