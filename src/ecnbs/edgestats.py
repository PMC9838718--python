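"""Edge-level test statistics and effect sizes.

Two statistic families are provided, matching the two phenotype kinds:

* binary phenotype: pooled-variance two-sample t per edge, signed as first
  class minus second (see :class:`~ecnbs.core.Phenotype.level_labels`);
* continuous phenotype: per-edge Pearson correlation mapped to its t value,
  ``t = r * sqrt(n - 2) / sqrt(1 - r^2)``.

Both are oriented: ``direction="positive"`` tests the hypothesis that the
first class exceeds the second (or that the correlation is positive) and the
negative direction is the exact negation.  Effect sizes are pooled-SD
Cohen's d; a correlation r is converted via ``d = 2 r / sqrt(1 - r^2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import ConnectomeStack, EdgePartition, Phenotype

__all__ = [
    "EdgeStatVector",
    "EffectSizeVector",
    "two_sample_t",
    "correlation_t",
    "cohens_d",
    "pearson_r",
    "r_to_d",
    "d_to_r",
    "network_ground_truth",
    "edge_ground_truth",
]

Direction = Literal["positive", "negative"]

#: cap applied to t statistics when |r| = 1 makes the closed form infinite
T_CAP = 1e12


@dataclass
class EdgeStatVector:
    """Per-edge test statistic with its orientation and reference df."""

    values: np.ndarray
    direction: Direction
    df: int
    statistic_kind: Literal["two_sample_t", "correlation_t"]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("edge statistics contain non-finite values")


@dataclass
class EffectSizeVector:
    """Per-edge or per-network Cohen's d values."""

    values: np.ndarray
    level: Literal["edge", "network"]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("effect sizes contain non-finite values")


def _check_direction(direction: str) -> None:
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")


def _binary_groups(values: np.ndarray, phenotype: Phenotype):
    if not phenotype.is_binary:
        raise ValueError("binary phenotype required")
    mask = phenotype.group_indicator()
    g1 = values[mask]
    g2 = values[~mask]
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("each binary class needs at least 2 subjects")
    return g1, g2


def _pooled_stats(g1: np.ndarray, g2: np.ndarray):
    n1, n2 = g1.shape[0], g2.shape[0]
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    ss = g1.var(axis=0, ddof=1) * (n1 - 1) + g2.var(axis=0, ddof=1) * (n2 - 1)
    sp2 = ss / (n1 + n2 - 2)
    return n1, n2, m1, m2, sp2


def two_sample_t(
    stack: ConnectomeStack, phenotype: Phenotype, direction: Direction = "positive"
) -> EdgeStatVector:
    """Pooled-variance Student t per edge for a binary phenotype.

    Edges with zero pooled variance get statistic 0 (with a warning) so that
    whole-connectome scans never abort on a degenerate edge.
    """
    _check_direction(direction)
    g1, g2 = _binary_groups(stack.values, phenotype)
    n1, n2, m1, m2, sp2 = _pooled_stats(g1, g2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    dead = se == 0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} edge(s) have zero pooled variance; statistic set to 0",
            stacklevel=2,
        )
    t = np.where(dead, 0.0, np.divide(m1 - m2, se, out=np.zeros_like(se), where=~dead))
    if direction == "negative":
        t = -t
    return EdgeStatVector(t, direction, n1 + n2 - 2, "two_sample_t")


def pearson_r(stack: ConnectomeStack, phenotype: Phenotype) -> np.ndarray:
    """Per-edge Pearson correlation with a continuous phenotype."""
    if phenotype.kind != "continuous":
        raise ValueError("continuous phenotype required")
    y = phenotype.values.astype(float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; correlation undefined")
    n = y.size
    if stack.n_subjects != n:
        raise ValueError("stack and phenotype subject counts differ")
    X = stack.values
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    dead = sx == 0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} edge(s) are constant across subjects; r set to 0",
            stacklevel=2,
        )
    denom = np.where(dead, 1.0, sx * sy)
    r = (yc @ Xc) / denom
    r[dead] = 0.0
    return np.clip(r, -1.0, 1.0)


def correlation_t(
    stack: ConnectomeStack, phenotype: Phenotype, direction: Direction = "positive"
) -> EdgeStatVector:
    """Correlation t statistic per edge for a continuous phenotype.

    ``|r| = 1`` would make the closed form infinite; such edges are capped at
    ``+/- 1e12`` with a warning.
    """
    _check_direction(direction)
    n = phenotype.n_subjects
    if n < 4:
        raise ValueError(f"correlation statistic needs at least 4 subjects, got {n}")
    r = pearson_r(stack, phenotype)
    sat = np.abs(r) >= 1.0
    if np.any(sat):
        warnings.warn(
            f"{int(sat.sum())} edge(s) have |r| = 1; t capped at +/-{T_CAP:g}",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    t = np.where(sat, np.sign(r) * T_CAP, t)
    if direction == "negative":
        t = -t
    return EdgeStatVector(t, direction, n - 2, "correlation_t")


def cohens_d(stack_values: np.ndarray | ConnectomeStack, phenotype: Phenotype) -> EffectSizeVector:
    """Pooled-SD Cohen's d per edge, first class minus second.

    Accepts either a :class:`~ecnbs.core.ConnectomeStack` or a raw
    subjects-by-columns array (used for network-level subject means).
    """
    values = stack_values.values if isinstance(stack_values, ConnectomeStack) else np.asarray(stack_values, dtype=float)
    g1, g2 = _binary_groups(values, phenotype)
    _, _, m1, m2, sp2 = _pooled_stats(g1, g2)
    sp = np.sqrt(sp2)
    dead = sp == 0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} column(s) have zero pooled SD; d set to 0", stacklevel=2
        )
    d = np.where(dead, 0.0, np.divide(m1 - m2, sp, out=np.zeros_like(sp), where=~dead))
    return EffectSizeVector(d, "edge")


def r_to_d(r):
    """Cohen's d equivalent of a correlation r under the Delta = 2s convention.

    ``d = 2 r / sqrt(1 - r^2)``: an odd, strictly increasing map defined for
    ``|r| < 1``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| must be < 1 to convert to Cohen's d")
    out = 2.0 * r / np.sqrt(1.0 - r**2)
    return out if out.ndim else float(out)


def d_to_r(d):
    """Inverse of :func:`r_to_d`: ``r = d / sqrt(d^2 + 4)``."""
    d = np.asarray(d, dtype=float)
    out = d / np.sqrt(d**2 + 4.0)
    return out if out.ndim else float(out)


def edge_ground_truth(stack: ConnectomeStack, phenotype: Phenotype) -> EffectSizeVector:
    """Edge-level ground-truth effect sizes on the full sample.

    Cohen's d for binary phenotypes; for continuous phenotypes the per-edge
    Pearson r converted through :func:`r_to_d`.
    """
    if phenotype.is_binary:
        return cohens_d(stack, phenotype)
    r = pearson_r(stack, phenotype)
    # guard |r| = 1 (only possible with degenerate data)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    return EffectSizeVector(r_to_d(r), "edge")


def network_ground_truth(
    stack: ConnectomeStack, phenotype: Phenotype, partition: EdgePartition
) -> EffectSizeVector:
    """Network-level ground-truth effect sizes.

    Member edges are averaged per subject first, then the appropriate effect
    size (Cohen's d, or r converted to d) is computed on the subject-level
    network means.
    """
    if partition.n_edges != stack.n_edges:
        raise ValueError("partition and stack edge counts differ")
    A = partition.membership_matrix(normalize=True)  # (M, E)
    net_values = stack.values @ A.T  # subjects x M
    if phenotype.is_binary:
        d = cohens_d(net_values, phenotype).values
    else:
        y = phenotype.values.astype(float)
        if np.ptp(y) == 0:
            raise ValueError("phenotype is constant; correlation undefined")
        yc = y - y.mean()
        Xc = net_values - net_values.mean(axis=0)
        sx = np.sqrt((Xc**2).sum(axis=0))
        sy = np.sqrt((yc**2).sum())
        dead = sx == 0
        denom = np.where(dead, 1.0, sx * sy)
        r = (yc @ Xc) / denom
        r[dead] = 0.0
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        d = r_to_d(r)
    return EffectSizeVector(d, "network")
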