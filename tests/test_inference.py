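import numpy as np
import pytest
import scipy.stats

from ecnbs.core import ConnectomeStack, EdgePartition, NodePartition, Phenotype
from ecnbs.edgestats import two_sample_t
from ecnbs.inference import (
    NBSConfig,
    PermutationScheme,
    bh_adjust,
    cnbs,
    ecnbs,
    edge_fdr,
    nbs,
    perm_pvalue,
    permutation_null,
    storey_qvalues,
    two_tailed_scan,
)
from ecnbs.inference import _components_from_mask
from ecnbs.synthetic import SyntheticDesign, blocked_edge_partition, generate_stack


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def bh_stepup_oracle(p, q):
    """Classical BH step-up rule: reject the largest i with p_(i) <= i*q/m.

    The condition is evaluated as ``p_(i) * m / i <= q`` so that floating-point
    rounding at exact-equality boundaries matches the adjusted-p convention.
    """
    m = len(p)
    order = np.argsort(p)
    ps = np.asarray(p)[order]
    k = 0
    for i in range(m):
        if ps[i] * m / (i + 1) <= q:
            k = i + 1
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def flood_fill_components(mask, pairs, n_nodes):
    """Brute-force connected components of the suprathreshold edge graph."""
    edges = [tuple(pairs[e]) + (e,) for e in np.flatnonzero(mask)]
    adj = {v: set() for v in range(n_nodes)}
    for i, j, _ in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen = set()
    comps = []
    for i, j, _ in edges:
        if i in seen:
            continue
        frontier = [i]
        nodes = set()
        while frontier:
            v = frontier.pop()
            if v in nodes:
                continue
            nodes.add(v)
            frontier.extend(adj[v] - nodes)
        seen |= nodes
        comps.append(
            frozenset(e for a, b, e in edges if a in nodes)
        )
    return {c for c in comps if c}


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

class TestPermutationNull:
    def test_identity_reduce_single_component_shape(self, null_data):
        stack, phen = null_data
        null = permutation_null(
            stack,
            phen,
            reduce=lambda S: S.mean(axis=1, keepdims=True),
            scheme=PermutationScheme(100, seed=0),
        )
        assert null.shape == (1, 100)

    def test_seed_determinism(self, null_data):
        stack, phen = null_data
        a = permutation_null(stack, phen, scheme=PermutationScheme(100, seed=5))
        b = permutation_null(stack, phen, scheme=PermutationScheme(100, seed=5))
        np.testing.assert_array_equal(a, b)

    def test_matches_direct_statistic(self, null_data):
        # each null row must equal the statistic computed on relabeled data
        stack, phen = null_data
        scheme = PermutationScheme(100, seed=2)
        null = permutation_null(stack, phen, scheme=scheme)
        rng = np.random.default_rng(2)
        perm0 = rng.permutation(phen.n_subjects)
        relabeled = Phenotype(phen.values[perm0], "binary", phen.level_labels)
        direct = two_sample_t(stack, relabeled).values
        np.testing.assert_allclose(null[:, 0], direct, atol=1e-10)

    def test_min_permutations_enforced(self):
        with pytest.raises(ValueError, match=">= 100"):
            PermutationScheme(50)

    def test_rank_uniformity_under_exchangeability(self):
        # observed statistic's rank among P nulls is uniform over {1..P+1}
        P = 100
        n_reps = 2000
        rng = np.random.default_rng(99)
        y = Phenotype(np.array([1, 1, 1, 1, 0, 0, 0, 0]), "binary")
        counts = np.zeros(P + 1, dtype=int)
        for rep in range(n_reps):
            X = rng.standard_normal((8, 3))
            stack = ConnectomeStack(X, 3)
            obs = two_sample_t(stack, y).values.mean()
            null = permutation_null(
                stack,
                y,
                reduce=lambda S: S.mean(axis=1, keepdims=True),
                scheme=PermutationScheme(P, seed=rep),
            )[0]
            p = perm_pvalue(obs, null)
            counts[int(round(p * (P + 1))) - 1] += 1
        chi2, pval = scipy.stats.chisquare(counts)
        assert pval > 0.01


class TestPermPvalue:
    def test_above_all_nulls(self):
        assert perm_pvalue(10.0, np.zeros(99)) == pytest.approx(0.01)

    def test_below_all_nulls(self):
        assert perm_pvalue(-10.0, np.zeros(99)) == 1.0

    def test_all_ties_count_against_rejection(self):
        assert perm_pvalue(1.0, np.ones(99)) == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            perm_pvalue(1.0, np.array([]))

    def test_super_uniform_validity(self):
        # P(p <= a) <= a (+ binomial slack) on a grid, under exchangeability
        rng = np.random.default_rng(7)
        n_reps = 2000
        P = 199
        ps = []
        for _ in range(n_reps):
            null = rng.standard_normal(P)
            obs = rng.standard_normal()
            ps.append(perm_pvalue(obs, null))
        ps = np.asarray(ps)
        for a in (0.01, 0.05, 0.1, 0.25, 0.5):
            emp = (ps <= a).mean()
            slack = 3 * np.sqrt(a * (1 - a) / n_reps)
            assert emp <= a + slack


class TestBHAdjust:
    def test_example_all_tied_at_max(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.42])), [0.42])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust(np.ones(7)), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10_000):
            m = int(rng.integers(1, 13))
            p = np.round(rng.uniform(size=m), 3)
            q = float(rng.choice([0.01, 0.05, 0.1, 0.2]))
            adj = bh_adjust(p)
            np.testing.assert_array_equal(adj <= q, bh_stepup_oracle(p, q))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        p = rng.uniform(size=200)
        _, adj_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), adj_sm, atol=1e-12)


class TestStoreyQvalues:
    def test_all_ones(self):
        q, pi0 = storey_qvalues(np.ones(200))
        assert pi0 == 1.0
        np.testing.assert_allclose(q, 1.0)

    def test_uniform_pi0_near_one(self):
        rng = np.random.default_rng(0)
        _, pi0 = storey_qvalues(rng.uniform(size=1000))
        assert abs(pi0 - 1.0) <= 0.1

    def test_identity_with_bh(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=500) ** 2
        q, pi0 = storey_qvalues(p)
        np.testing.assert_allclose(q, np.minimum(pi0 * bh_adjust(p), 1.0), atol=1e-10)

    def test_short_vector_warns(self):
        with pytest.warns(UserWarning, match="unreliable"):
            storey_qvalues(np.linspace(0.01, 1, 50))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([-0.1, 0.5]))


# ---------------------------------------------------------------------------
# ecNBS / cNBS
# ---------------------------------------------------------------------------

class TestEcnbs:
    def test_single_network_stat_is_global_mean(self, null_data):
        stack, phen = null_data
        part = EdgePartition(np.ones(stack.n_edges, dtype=int))
        res = ecnbs(stack, phen, part, PermutationScheme(100, seed=0))
        expected = two_sample_t(stack, phen).values.mean()
        assert res.observed_stat[0] == pytest.approx(expected, abs=1e-12)

    def test_network_stats_are_member_means(self, null_data, ten_community_partition):
        stack, phen = null_data
        res = ecnbs(stack, phen, ten_community_partition, PermutationScheme(100, seed=0))
        t = two_sample_t(stack, phen).values
        for m in range(1, 11):
            members = ten_community_partition.members(m)
            assert res.observed_stat[m - 1] == pytest.approx(
                t[members].mean(), abs=1e-12
            )

    def test_detects_planted_network(self, planted_data, ten_community_partition):
        stack, phen = planted_data
        res = ecnbs(stack, phen, ten_community_partition, PermutationScheme(1000, seed=0))
        assert res.detected[2]  # community 3 carries d = 0.8
        assert res.n_detected == 1

    def test_direction_symmetry(self, planted_data, ten_community_partition):
        stack, phen = planted_data
        swapped = Phenotype(phen.values, "binary", level_labels=(0, 1))
        a = ecnbs(stack, phen, ten_community_partition, PermutationScheme(200, seed=1), direction="positive")
        b = ecnbs(stack, swapped, ten_community_partition, PermutationScheme(200, seed=1), direction="negative")
        np.testing.assert_allclose(a.observed_stat, b.observed_stat, atol=1e-12)
        np.testing.assert_array_equal(a.corrected_p, b.corrected_p)
        np.testing.assert_array_equal(a.detected, b.detected)

    def test_seeded_determinism(self, null_data, ten_community_partition):
        stack, phen = null_data
        a = ecnbs(stack, phen, ten_community_partition, PermutationScheme(150, seed=4))
        b = ecnbs(stack, phen, ten_community_partition, PermutationScheme(150, seed=4))
        np.testing.assert_array_equal(a.corrected_p, b.corrected_p)

    def test_power_on_planted_network(self, ten_community_partition):
        # planted d = 0.8, n = 120: the carrying network is detected in
        # >= 80% of runs
        detections = 0
        runs = 100
        for seed in range(runs):
            design = SyntheticDesign(
                n_nodes=20,
                n_subjects=120,
                true_partition=ten_community_partition,
                phenotype_kind="binary",
                target_effects={3: 0.8},
                community_coupling=0.5,
                seed=seed,
            )
            stack, phen = generate_stack(design)
            res = ecnbs(stack, phen, ten_community_partition, PermutationScheme(250, seed=seed))
            detections += bool(res.detected[2])
        assert detections / runs >= 0.8


class TestCnbs:
    def test_ten_node_networks_give_55_pvalues(self, null_data):
        stack, phen = null_data
        node_part = NodePartition(np.repeat(np.arange(1, 11), 2))
        res = cnbs(stack, phen, node_part, PermutationScheme(100, seed=0))
        assert res.n_components == 55
        assert res.corrected_p.shape == (55,)

    def test_same_code_path_as_ecnbs(self, null_data):
        from ecnbs.core import node_partition_to_edge_groups

        stack, phen = null_data
        node_part = NodePartition(np.repeat(np.arange(1, 11), 2))
        edge_groups = node_partition_to_edge_groups(node_part)
        a = cnbs(stack, phen, node_part, PermutationScheme(100, seed=3))
        b = ecnbs(stack, phen, edge_groups, PermutationScheme(100, seed=3))
        np.testing.assert_array_equal(a.corrected_p, b.corrected_p)
        np.testing.assert_array_equal(a.observed_stat, b.observed_stat)

    def test_single_node_network_reduces_to_global_test(self, null_data):
        stack, phen = null_data
        node_part = NodePartition(np.ones(20, dtype=int))
        res = cnbs(stack, phen, node_part, PermutationScheme(100, seed=0))
        assert res.n_components == 1
        expected = two_sample_t(stack, phen).values.mean()
        assert res.observed_stat[0] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# NBS
# ---------------------------------------------------------------------------

class TestNbs:
    def test_no_suprathreshold_edges(self, null_data):
        stack, phen = null_data
        res = nbs(stack, phen, NBSConfig(t_threshold=50.0), PermutationScheme(100, seed=0))
        assert res.n_components == 0
        assert res.n_detected == 0

    def test_threshold_in_metadata(self, null_data):
        stack, phen = null_data
        res = nbs(stack, phen, scheme=PermutationScheme(100, seed=0))
        assert res.metadata["t_threshold"] == 3.1

    def test_pvalue_convention(self):
        # one observed component of 5 edges vs 99 permutation maxima all <= 3
        assert perm_pvalue(5, np.full(99, 3)) == pytest.approx(0.01)

    def test_components_match_flood_fill_oracle(self):
        from ecnbs.core import EdgeIndexer

        rng = np.random.default_rng(21)
        for n_nodes in (5, 10, 20):
            idx = EdgeIndexer(n_nodes)
            for _ in range(50):
                mask = rng.uniform(size=idx.n_edges) < 0.15
                comps = _components_from_mask(mask, idx.pairs, n_nodes)
                got = {frozenset(c.tolist()) for c in comps}
                want = flood_fill_components(mask, idx.pairs, n_nodes)
                assert got == want

    def test_detects_planted_component(self, ten_community_partition):
        # strong planted effect makes a detectable suprathreshold component
        design = SyntheticDesign(
            n_nodes=20,
            n_subjects=300,
            true_partition=ten_community_partition,
            phenotype_kind="binary",
            target_effects={1: 1.2},
            community_coupling=0.2,
            seed=5,
        )
        stack, phen = generate_stack(design)
        res = nbs(stack, phen, scheme=PermutationScheme(250, seed=0))
        assert res.n_detected >= 1
        detected_edges = np.concatenate(
            [c for c, d in zip(res.components, res.detected) if d]
        )
        planted = set(ten_community_partition.members(1).tolist())
        assert planted & set(detected_edges.tolist())

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            NBSConfig(t_threshold=0.0)


# ---------------------------------------------------------------------------
# edge-level + FDR
# ---------------------------------------------------------------------------

class TestEdgeFdr:
    def test_pvalues_match_t_survivor_function(self, tiny_stack, tiny_binary_phenotype):
        res = edge_fdr(tiny_stack, tiny_binary_phenotype)
        t = two_sample_t(tiny_stack, tiny_binary_phenotype)
        expected = scipy.stats.t.sf(t.values, df=4)
        np.testing.assert_allclose(res.metadata["uncorrected_p"], expected, atol=1e-10)

    def test_huge_effect_detected(self):
        # d = 3 at n = 120: detection in >= 95% of runs
        part = blocked_edge_partition(6, 3)
        hits = 0
        runs = 60
        for seed in range(runs):
            design = SyntheticDesign(
                n_nodes=6,
                n_subjects=120,
                true_partition=part,
                phenotype_kind="binary",
                target_effects={1: 3.0},
                community_coupling=0.0,
                noise_sd=1.0,
                seed=seed,
            )
            stack, phen = generate_stack(design)
            with pytest.warns(UserWarning, match="unreliable"):
                res = edge_fdr(stack, phen)
            planted = part.members(1)
            if np.all(res.detected[planted]):
                hits += 1
        assert hits / runs >= 0.95

    def test_level_and_components(self, null_data):
        stack, phen = null_data
        res = edge_fdr(stack, phen)
        assert res.level == "edge"
        assert res.n_components == stack.n_edges


# ---------------------------------------------------------------------------
# two-tailed scan
# ---------------------------------------------------------------------------

class TestTwoTailedScan:
    def test_null_data_mostly_zero(self, null_data, ten_community_partition):
        stack, phen = null_data
        signed, info = two_tailed_scan(
            stack, phen, "ecnbs",
            edge_partition=ten_community_partition,
            scheme=PermutationScheme(200, seed=0),
        )
        assert np.all(signed == 0)
        assert info["per_tail_alpha"] == 0.025

    def test_planted_positive_network_labeled(self, ten_community_partition):
        votes = np.zeros(10)
        runs = 30
        for seed in range(runs):
            design = SyntheticDesign(
                n_nodes=20,
                n_subjects=200,
                true_partition=ten_community_partition,
                phenotype_kind="binary",
                target_effects={3: 0.8},
                community_coupling=0.5,
                seed=seed,
            )
            stack, phen = generate_stack(design)
            # P = 1000 so the min achievable BH-corrected q (M/(P+1)) is
            # below the per-tail level of 0.025
            signed, _ = two_tailed_scan(
                stack, phen, "ecnbs",
                edge_partition=ten_community_partition,
                scheme=PermutationScheme(1000, seed=seed),
            )
            votes += signed == 1
        assert votes[2] / runs > 0.5
        assert np.all(votes[np.arange(10) != 2] / runs < 0.5)

    def test_no_component_labeled_both_ways(self, planted_data, ten_community_partition):
        stack, phen = planted_data
        signed, info = two_tailed_scan(
            stack, phen, "ecnbs",
            edge_partition=ten_community_partition,
            scheme=PermutationScheme(200, seed=1),
        )
        pos, neg = info["positive"], info["negative"]
        assert not np.any(pos.detected & neg.detected)

    def test_nbs_edge_level_map(self, null_data):
        stack, phen = null_data
        signed, _ = two_tailed_scan(
            stack, phen, "nbs", scheme=PermutationScheme(100, seed=0),
            nbs_config=NBSConfig(t_threshold=6.0),
        )
        assert signed.shape == (stack.n_edges,)
        assert np.all(signed == 0)
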