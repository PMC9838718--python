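"""Subsampling benchmark: power, FDR and FWER for the inference procedures.

One benchmark run draws ``repetitions`` random subsamples (sizes 40/80/120 by
default, 500 repetitions) from a full dataset, runs every requested method in
both one-tailed directions per repetition (standard mode) or a single
direction on a label-shuffled phenotype (weak-null mode), classifies each
detection against ground truth, and assembles the performance metrics.

Ground truth defaults to the full-sample effect sizes; with synthetic data
the planted effects can be used instead (``truth_source="planted"``).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import ConnectomeStack, EdgePartition, NodePartition, Phenotype, node_partition_to_edge_groups
from .edgestats import EffectSizeVector, edge_ground_truth, network_ground_truth
from .inference import InferenceResult, NBSConfig, PermutationScheme, run_method
from .synthetic import generate_null_mode

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkConfig",
    "CurveConfig",
    "DetectionRecord",
    "MethodMetrics",
    "MetricsReport",
    "subsample",
    "classify_detections",
    "nbs_edge_detections",
    "compute_power",
    "power_vs_effect_curve",
    "compute_fdr",
    "compute_fwer",
    "fwer_ci_halfwidth",
    "within_network_variance",
    "mean_within_network_variance",
    "run_benchmark",
]


@dataclass
class BenchmarkConfig:
    """Settings for one benchmark run."""

    subsample_sizes: Sequence[int] = (40, 80, 120)
    repetitions: int = 500
    alpha: float = 0.05
    methods: Sequence[str] = ("ecnbs",)
    stratified: bool = False
    mode: Literal["standard", "weak_null"] = "standard"
    truth_source: Literal["full_sample", "planted"] = "full_sample"
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.mode not in ("standard", "weak_null"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.truth_source not in ("full_sample", "planted"):
            raise ValueError(f"unknown truth_source {self.truth_source!r}")
        for m in self.methods:
            if m not in ("ecnbs", "cnbs", "nbs", "edgefdr"):
                raise ValueError(f"unknown method {m!r}")


@dataclass
class CurveConfig:
    """Sliding-window settings for the power-vs-effect-size curve."""

    window_width: float = 0.1
    overlap: float = 0.75

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")

    @property
    def step(self) -> float:
        return self.window_width * (1.0 - self.overlap)


@dataclass
class DetectionRecord:
    """Classified detections of one method in one repetition."""

    repetition: int
    method: str
    direction: str
    components: list[np.ndarray]
    is_true: np.ndarray  # per detected component

    @property
    def n_detections(self) -> int:
        return len(self.components)

    @property
    def n_false(self) -> int:
        return int((~self.is_true).sum())


def subsample(
    n_total: int,
    size: int,
    phenotype: Phenotype | None = None,
    stratified: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Subject indices drawn uniformly without replacement.

    With ``stratified`` (binary phenotype required) the per-class counts
    follow largest-remainder rounding of ``size * class_fraction`` so they
    sum exactly to ``size``, mirroring the full-cohort class proportions.
    """
    rng = rng or np.random.default_rng()
    if size > n_total:
        raise ValueError(f"subsample size {size} exceeds dataset size {n_total}")
    if not stratified:
        return rng.choice(n_total, size=size, replace=False)
    if phenotype is None or not phenotype.is_binary:
        raise ValueError("stratified subsampling requires a binary phenotype")
    mask = phenotype.group_indicator()
    counts = np.array([mask.sum(), (~mask).sum()], dtype=float)
    quotas = size * counts / n_total
    base = np.floor(quotas).astype(int)
    remainder = size - base.sum()
    order = np.argsort(-(quotas - base))
    base[order[:remainder]] += 1
    if np.any(base > counts.astype(int)):
        raise ValueError("a class is smaller than its stratified quota")
    if np.any(base < 2):
        raise ValueError("stratified quota leaves a class with < 2 subjects")
    idx1 = rng.choice(np.flatnonzero(mask), size=base[0], replace=False)
    idx2 = rng.choice(np.flatnonzero(~mask), size=base[1], replace=False)
    out = np.concatenate([idx1, idx2])
    rng.shuffle(out)
    return out


def classify_detections(
    result: InferenceResult,
    truth: EffectSizeVector,
    edge_truth: EffectSizeVector | None = None,
    repetition: int = 0,
    all_false: bool = False,
) -> DetectionRecord:
    """Label each detected component of a result as a true or false detection.

    Edge/network components: a detection is true iff the ground-truth effect
    is nonzero and its sign matches the tested direction.  NBS clusters: true
    iff at least one member edge would classify true (edge-level truth
    required).  ``all_false`` marks every detection false, used for weak-null
    runs where the null is true everywhere by construction.
    """
    if result.level == "cluster":
        if edge_truth is None:
            raise ValueError("cluster-level classification needs edge-level truth")
        if edge_truth.level != "edge":
            raise ValueError("edge_truth must be edge-level")
        ref = edge_truth.values
    else:
        expected = {"edge": "edge", "network": "network"}[result.level]
        if truth.level != expected:
            raise ValueError(
                f"truth level {truth.level!r} does not match result level {result.level!r}"
            )
        ref = truth.values
    sign = 1.0 if result.direction == "positive" else -1.0
    detected_idx = np.flatnonzero(result.detected)
    comps: list[np.ndarray] = []
    flags = []
    for k in detected_idx:
        comp = result.components[k]
        comps.append(comp)
        if all_false:
            flags.append(False)
        elif result.level == "cluster":
            flags.append(bool(np.any(sign * ref[comp] > 0)))
        else:
            cid = result.component_ids[k]
            # network ids are 1-based; edge ids are the edge indices themselves
            pos = cid - 1 if result.level == "network" else cid
            flags.append(bool(sign * ref[pos] > 0))
    return DetectionRecord(
        repetition=repetition,
        method=str(result.metadata.get("method", "?")),
        direction=result.direction,
        components=comps,
        is_true=np.asarray(flags, dtype=bool),
    )


def nbs_edge_detections(result: InferenceResult) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge detection flags from a cluster-level result.

    Every edge inside a detected cluster is flagged with the cluster's
    direction.  Returns ``(detected mask, n_edges-long +1/-1/0 signs)``.
    """
    if result.level != "cluster":
        raise ValueError("nbs_edge_detections requires a cluster-level result")
    n_edges = int(result.metadata.get("n_edges", 0))
    if n_edges == 0:
        n_edges = 1 + max((int(c.max()) for c in result.components if c.size), default=0)
    mask = np.zeros(n_edges, dtype=bool)
    signs = np.zeros(n_edges, dtype=int)
    s = 1 if result.direction == "positive" else -1
    for comp, det in zip(result.components, result.detected):
        if det:
            mask[comp] = True
            signs[comp] = s
    return mask, signs


def compute_power(
    true_counts: np.ndarray, repetitions: int
) -> tuple[np.ndarray, float]:
    """Per-component power (true detections / repetitions) and its mean."""
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    power = np.asarray(true_counts, dtype=float) / repetitions
    return power, float(power.mean()) if power.size else 0.0


def power_vs_effect_curve(
    effects: np.ndarray, powers: np.ndarray, config: CurveConfig | None = None
) -> pd.DataFrame:
    """Sliding-window mean power as a function of effect-size magnitude.

    Windows of ``window_width`` (default 0.1 in Cohen's d units) step by
    ``width * (1 - overlap)`` (default 0.025) from the smallest ``|d|``;
    each window reports the mean ``|d|`` and mean power of the components it
    contains.  Empty windows are omitted.
    """
    config = config or CurveConfig()
    effects = np.abs(np.asarray(effects, dtype=float))
    powers = np.asarray(powers, dtype=float)
    if effects.size != powers.size:
        raise ValueError("effects and powers must have equal length")
    if effects.size == 0:
        return pd.DataFrame(columns=["window_start", "mean_effect", "mean_power", "n"])
    start = effects.min()
    stop = effects.max()
    rows = []
    while start <= stop + 1e-12:
        in_win = (effects >= start) & (effects < start + config.window_width)
        if np.any(in_win):
            rows.append(
                {
                    "window_start": start,
                    "mean_effect": float(effects[in_win].mean()),
                    "mean_power": float(powers[in_win].mean()),
                    "n": int(in_win.sum()),
                }
            )
        start += config.step
    return pd.DataFrame(rows)


def compute_fdr(false_counts: np.ndarray, total_counts: np.ndarray) -> float:
    """Mean of per-repetition false/total detections; empty repetitions score 0."""
    false_counts = np.asarray(false_counts, dtype=float)
    total_counts = np.asarray(total_counts, dtype=float)
    if false_counts.size == 0:
        raise ValueError("at least one repetition required")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_rep = np.where(total_counts > 0, false_counts / np.maximum(total_counts, 1), 0.0)
    return float(per_rep.mean())


def compute_fwer(false_counts: np.ndarray) -> float:
    """Fraction of repetitions with at least one false detection."""
    false_counts = np.asarray(false_counts)
    if false_counts.size == 0:
        raise ValueError("at least one repetition required")
    return float((false_counts >= 1).mean())


def fwer_ci_halfwidth(nominal: float, repetitions: int) -> float:
    """95% normal-approximation CI half-width, in percentage points."""
    if not 0.0 < nominal < 1.0:
        raise ValueError("nominal rate must lie in (0, 1)")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    return float(1.96 * np.sqrt(nominal * (1.0 - nominal) / repetitions) * 100.0)


def within_network_variance(
    edge_truth: EffectSizeVector, partition: EdgePartition
) -> np.ndarray:
    """Sample variance (n-1 denominator) of member-edge effects per network.

    Single-edge networks get variance 0 by convention (logged).
    """
    if edge_truth.level != "edge":
        raise ValueError("edge-level truth required")
    if edge_truth.values.size != partition.n_edges:
        raise ValueError("truth vector and partition cover different edge counts")
    out = np.zeros(partition.n_networks)
    for m in range(1, partition.n_networks + 1):
        members = partition.members(m)
        if members.size < 2:
            logger.info("network %d has a single edge; variance set to 0", m)
            out[m - 1] = 0.0
        else:
            out[m - 1] = float(np.var(edge_truth.values[members], ddof=1))
    return out


def mean_within_network_variance(
    edge_truths: Sequence[EffectSizeVector], partition: EdgePartition
) -> np.ndarray:
    """Per-network variance averaged across several truth vectors (datasets)."""
    if len(edge_truths) == 0:
        raise ValueError("at least one truth vector required")
    stacked = np.vstack([within_network_variance(t, partition) for t in edge_truths])
    return stacked.mean(axis=0)


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------


@dataclass
class MethodMetrics:
    """Per-method summary for one subsample size."""

    method: str
    level: str
    n_components: int
    power: np.ndarray
    mean_power: float
    fdr: float
    fwer: float
    fwer_kind: Literal["strong", "weak"]
    truth: np.ndarray
    n_zero_truth: int
    records: list[DetectionRecord] = field(default_factory=list)


@dataclass
class MetricsReport:
    """All metrics from one benchmark run."""

    config: BenchmarkConfig
    per_size: dict[int, dict[str, MethodMetrics]]
    timing: dict[str, float]

    def summary(self) -> pd.DataFrame:
        rows = []
        for size, methods in self.per_size.items():
            for name, m in methods.items():
                rows.append(
                    {
                        "subsample_size": size,
                        "method": name,
                        "level": m.level,
                        "mean_power": m.mean_power,
                        "fdr": m.fdr,
                        f"{m.fwer_kind}_fwer": m.fwer,
                    }
                )
        return pd.DataFrame(rows)

    def weak_fwer(self, size: int, method: str) -> float:
        """Weak FWER; raises unless the run used ``mode='weak_null'``."""
        m = self.per_size[size][method]
        if m.fwer_kind != "weak":
            raise ValueError(
                "weak FWER requires records produced under mode='weak_null'"
            )
        return m.fwer

    def strong_fwer(self, size: int, method: str) -> float:
        """Strong FWER; raises unless the run used ``mode='standard'``."""
        m = self.per_size[size][method]
        if m.fwer_kind != "strong":
            raise ValueError("strong FWER requires records produced in standard mode")
        return m.fwer

    def curve(self, size: int, method: str, config: CurveConfig | None = None) -> pd.DataFrame:
        m = self.per_size[size][method]
        keep = m.truth != 0 if np.any(m.truth != 0) else np.ones_like(m.truth, bool)
        return power_vs_effect_curve(np.abs(m.truth[keep]), m.power[keep], config)


def _method_truths(
    method: str,
    stack: ConnectomeStack,
    phenotype: Phenotype,
    config: BenchmarkConfig,
    edge_partition: EdgePartition | None,
    node_partition: NodePartition | None,
    planted_edge_truth: EffectSizeVector | None,
    edge_truth: EffectSizeVector,
) -> tuple[str, EffectSizeVector, int]:
    """Component level, component-level truth and component count for a method."""
    if method in ("nbs", "edgefdr"):
        return ("edge" if method == "edgefdr" else "cluster", edge_truth, stack.n_edges)
    part = edge_partition if method == "ecnbs" else node_partition_to_edge_groups(node_partition)
    if config.truth_source == "planted":
        A = part.membership_matrix(normalize=True)
        net_truth = EffectSizeVector(A @ planted_edge_truth.values, "network")
    else:
        net_truth = network_ground_truth(stack, phenotype, part)
    return ("network", net_truth, part.n_networks)


def run_benchmark(
    stack: ConnectomeStack,
    phenotype: Phenotype,
    config: BenchmarkConfig,
    edge_partition: EdgePartition | None = None,
    node_partition: NodePartition | None = None,
    nbs_config: NBSConfig | None = None,
    planted_edge_truth: EffectSizeVector | None = None,
) -> MetricsReport:
    """Run the full subsampling benchmark and assemble a metrics report.

    In ``standard`` mode every repetition tests both one-tailed hypotheses
    and FWER is reported in the strong sense; in ``weak_null`` mode the
    phenotype is shuffled once per repetition before subsampling, a single
    (positive) hypothesis is tested, every detection counts false, and FWER
    is reported in the weak sense.
    """
    if "ecnbs" in config.methods and edge_partition is None:
        raise ValueError("ecnbs requires edge_partition")
    if "cnbs" in config.methods and node_partition is None:
        raise ValueError("cnbs requires node_partition")
    if config.truth_source == "planted" and planted_edge_truth is None:
        raise ValueError("truth_source='planted' requires planted_edge_truth")
    for size in config.subsample_sizes:
        if size >= stack.n_subjects:
            raise ValueError(
                f"subsample size {size} must be < dataset size {stack.n_subjects}"
            )

    if config.truth_source == "planted":
        edge_truth = planted_edge_truth
    else:
        edge_truth = edge_ground_truth(stack, phenotype)

    weak = config.mode == "weak_null"
    directions = ("positive",) if weak else ("positive", "negative")

    # fixed per-method component structure and truth
    meta = {
        m: _method_truths(
            m, stack, phenotype, config, edge_partition, node_partition,
            planted_edge_truth, edge_truth,
        )
        for m in config.methods
    }

    timing: dict[str, float] = {m: 0.0 for m in config.methods}

    per_size: dict[int, dict[str, MethodMetrics]] = {}
    for size in config.subsample_sizes:
        acc = {
            m: {
                "true_counts": np.zeros(meta[m][2], dtype=int),
                "false": np.zeros(config.repetitions, dtype=int),
                "total": np.zeros(config.repetitions, dtype=int),
                "records": [],
            }
            for m in config.methods
        }
        for rep in range(config.repetitions):
            # independent, individually reproducible child stream per repetition
            rng = np.random.default_rng([config.seed, size, rep])
            phen = generate_null_mode(stack, phenotype, rng) if weak else phenotype
            idx = subsample(stack.n_subjects, size, phen, config.stratified, rng)
            sub_stack = stack.subset(idx)
            sub_phen = phen.subset(idx)
            scheme = PermutationScheme(
                n_permutations=config.n_permutations,
                seed=int(rng.integers(2**31)),
            )
            for method in config.methods:
                level, truth, _ = meta[method]
                t0 = time.perf_counter()
                for direction in directions:
                    try:
                        result = run_method(
                            method, sub_stack, sub_phen, direction,
                            alpha=config.alpha,
                            edge_partition=edge_partition,
                            node_partition=node_partition,
                            nbs_config=nbs_config,
                            scheme=scheme,
                        )
                    except Exception as exc:  # pragma: no cover - context only
                        raise RuntimeError(
                            f"repetition {rep}, size {size}, method {method}: {exc}"
                        ) from exc
                    record = classify_detections(
                        result,
                        truth if level != "cluster" else edge_truth,
                        edge_truth=edge_truth,
                        repetition=rep,
                        all_false=weak,
                    )
                    a = acc[method]
                    a["records"].append(record)
                    a["false"][rep] += record.n_false
                    a["total"][rep] += record.n_detections
                    if not weak:
                        if method == "nbs":
                            # power for NBS is scored at the edge level
                            result.metadata["n_edges"] = stack.n_edges
                            mask, signs = nbs_edge_detections(result)
                            sgn = 1 if direction == "positive" else -1
                            good = mask & (sgn * edge_truth.values > 0)
                            a["true_counts"][good] += 1
                        else:
                            det = np.flatnonzero(result.detected)
                            for k in det:
                                cid = result.component_ids[k]
                                pos = cid - 1 if level == "network" else cid
                                sgn = 1 if direction == "positive" else -1
                                if sgn * truth.values[pos] > 0:
                                    a["true_counts"][pos] += 1
                timing[method] += time.perf_counter() - t0
            if (rep + 1) % 50 == 0:
                logger.info("size %d: repetition %d/%d", size, rep + 1, config.repetitions)

        per_size[size] = {}
        for method in config.methods:
            level, truth, n_comp = meta[method]
            a = acc[method]
            power, mean_power = compute_power(a["true_counts"], config.repetitions)
            comp_truth = edge_truth.values if method in ("nbs", "edgefdr") else truth.values
            nonzero = comp_truth != 0
            per_size[size][method] = MethodMetrics(
                method=method,
                level=level,
                n_components=n_comp,
                power=power,
                mean_power=float(power[nonzero].mean()) if np.any(nonzero) else 0.0,
                fdr=compute_fdr(a["false"], a["total"]),
                fwer=compute_fwer(a["false"]),
                fwer_kind="weak" if weak else "strong",
                truth=comp_truth,
                n_zero_truth=int((~nonzero).sum()),
                records=a["records"],
            )
    return MetricsReport(config=config, per_size=per_size, timing=timing)
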