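"""Synthetic connectome stacks with planted edge communities and effects.

The generative model is additive Gaussian.  Edge ``e`` in community ``m`` has,
for subject ``s``,

    x[s, e] = baseline[e] + rho * F[m, s] + effect[m, s] + eps[s, e]

where ``F[m, .]`` is a standard-normal per-community subject factor shared by
all member edges (giving within-community covariation across subjects with
loading ``rho``), ``eps`` is independent ``N(0, noise_sd^2)`` noise, and the
phenotype effect is scaled so the *population* effect size of community ``m``
equals its target:

* binary target d: a mean shift ``delta = d * sigma_tot`` applied to the
  first class, where ``sigma_tot = sqrt(rho^2 + noise_sd^2)`` is the
  within-class SD, so the population pooled-SD Cohen's d is exactly ``d``;
* continuous target r: a slope ``beta = r * sigma_tot / sqrt(1 - r^2)`` on
  the standardized phenotype, making the population correlation exactly
  ``r``.

Baselines are drawn once per design from ``N(0.3, 0.1^2)`` (plausible
Fisher-z magnitudes; irrelevant to any statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .core import ConnectomeStack, EdgePartition, Phenotype, n_edges_for
from .edgestats import EffectSizeVector, cohens_d, pearson_r, r_to_d

__all__ = [
    "SyntheticDesign",
    "generate_stack",
    "generate_null_mode",
    "realized_effects",
    "planted_edge_effects",
    "blocked_edge_partition",
]


def blocked_edge_partition(n_nodes: int, n_communities: int) -> EdgePartition:
    """Contiguous equal-as-possible blocks of edge indices as communities.

    A convenience for building designs: communities are blocks in linear edge
    order, each with at least one edge.
    """
    E = n_edges_for(n_nodes)
    if not 1 <= n_communities <= E:
        raise ValueError(f"need 1 <= n_communities <= {E}, got {n_communities}")
    bounds = np.linspace(0, E, n_communities + 1).astype(int)
    labels = np.zeros(E, dtype=int)
    for m in range(n_communities):
        labels[bounds[m] : bounds[m + 1]] = m + 1
    return EdgePartition(labels, n_communities, origin="edge_clustered")


@dataclass
class SyntheticDesign:
    """Full description of one synthetic dataset.

    ``target_effects`` maps community id (1..M) to the target population
    effect size: Cohen's d for a binary phenotype, Pearson r for a continuous
    one.  Communities not listed get a zero effect.
    """

    n_nodes: int
    n_subjects: int
    true_partition: EdgePartition
    phenotype_kind: Literal["binary", "continuous"] = "binary"
    target_effects: Mapping[int, float] = field(default_factory=dict)
    community_coupling: float = 0.5
    class_fraction: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_partition.n_edges != n_edges_for(self.n_nodes):
            raise ValueError("true_partition does not cover the edges of n_nodes")
        if not 0.0 <= self.community_coupling < 1.0:
            raise ValueError("community_coupling must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.phenotype_kind not in ("binary", "continuous"):
            raise ValueError(f"unknown phenotype_kind {self.phenotype_kind!r}")
        if not 0.0 < self.class_fraction < 1.0:
            raise ValueError("class_fraction must lie in (0, 1)")
        M = self.true_partition.n_networks
        for m, eff in self.target_effects.items():
            if not 1 <= int(m) <= M:
                raise ValueError(f"target effect given for unknown community {m}")
            if self.phenotype_kind == "continuous" and abs(eff) >= 1.0:
                raise ValueError(
                    f"target correlation for community {m} must satisfy |r| < 1, got {eff}"
                )
        if self.phenotype_kind == "binary" and self.n_subjects >= 4:
            n1 = int(round(self.n_subjects * self.class_fraction))
            if n1 < 2 or self.n_subjects - n1 < 2:
                raise ValueError(
                    "class_fraction leaves fewer than 2 subjects in one class"
                )

    @property
    def sigma_total(self) -> float:
        """Within-class SD of any edge: sqrt(rho^2 + noise_sd^2)."""
        return float(np.hypot(self.community_coupling, self.noise_sd))

    def effect_vector(self) -> np.ndarray:
        """Per-community target effects as an array indexed by id - 1."""
        M = self.true_partition.n_networks
        out = np.zeros(M)
        for m, eff in self.target_effects.items():
            out[int(m) - 1] = float(eff)
        return out


def generate_stack(design: SyntheticDesign) -> tuple[ConnectomeStack, Phenotype]:
    """Draw one (stack, phenotype) pair from a design; bit-reproducible from seed."""
    rng = np.random.default_rng(design.seed)
    n, E = design.n_subjects, design.true_partition.n_edges
    M = design.true_partition.n_networks
    rho = design.community_coupling
    sigma_tot = design.sigma_total
    targets = design.effect_vector()

    if design.phenotype_kind == "binary":
        n1 = int(round(n * design.class_fraction))
        y01 = np.zeros(n, dtype=int)
        y01[rng.choice(n, size=n1, replace=False)] = 1
        phenotype = Phenotype(y01, "binary")  # level_labels -> (1, 0)
        # per-community mean shift applied to class 1, split symmetrically
        delta = targets * sigma_tot
        subj_effect = np.where(y01[:, None] == 1, 0.5, -0.5) * delta[None, :]  # n x M
    else:
        y = rng.standard_normal(n)
        phenotype = Phenotype(y, "continuous")
        z = (y - y.mean()) / y.std()
        beta = targets * sigma_tot / np.sqrt(1.0 - targets**2)
        subj_effect = z[:, None] * beta[None, :]  # n x M

    baseline = rng.normal(0.3, 0.1, size=E)
    F = rng.standard_normal((M, n))
    comm = design.true_partition.labels - 1  # edge -> community index
    values = (
        baseline[None, :]
        + rho * F[comm, :].T
        + subj_effect[:, comm]
        + rng.normal(0.0, design.noise_sd, size=(n, E))
    )
    stack = ConnectomeStack(values, design.n_nodes)
    return stack, phenotype


def generate_null_mode(
    stack: ConnectomeStack, phenotype: Phenotype, rng: np.random.Generator
) -> Phenotype:
    """Phenotype with subject order uniformly shuffled; connectomes untouched."""
    if phenotype.n_subjects != stack.n_subjects:
        raise ValueError("stack and phenotype subject counts differ")
    perm = rng.permutation(phenotype.n_subjects)
    return phenotype.subset(perm)


def planted_edge_effects(design: SyntheticDesign) -> EffectSizeVector:
    """Per-edge planted population effect sizes, in Cohen's d units.

    Binary targets are already d; continuous targets r are converted through
    the same r-to-d map used for estimated truth.
    """
    targets = design.effect_vector()
    if design.phenotype_kind == "continuous":
        targets = np.asarray(r_to_d(targets))
    comm = design.true_partition.labels - 1
    return EffectSizeVector(targets[comm], "edge")


def realized_effects(stack: ConnectomeStack, phenotype: Phenotype) -> EffectSizeVector:
    """Empirical per-edge effect sizes (d, or r converted to d).

    Convenience wrapper used to validate the generator's scaling.
    """
    if phenotype.is_binary:
        return cohens_d(stack, phenotype)
    r = pearson_r(stack, phenotype)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    return EffectSizeVector(r_to_d(r), "edge")
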