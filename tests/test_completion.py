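"""Completion engine: σ tables, dynamic programs, traceback, model surface."""

import math
from itertools import combinations

import numpy as np
import pytest

from grncomplete import (
    INFEASIBLE,
    CompletionSpec,
    ExpressionMatrix,
    GeneNetwork,
    NetworkCompletion,
    PerturbationConfig,
    SigmaTable,
    candidate_parents,
    complete_network,
    dp_add,
    dp_add_del,
    infer_network,
    node_error,
    perturb,
    sigma,
    traceback,
)

from .oracles import enumerate_global_optimum, enumerate_node_minimum, random_instance


@pytest.fixture(scope="module")
def toy_gold(toy_system):
    return toy_system.network


class TestCandidateParents:
    def test_set_difference(self):
        net = GeneNetwork(["g1", "g2", "g3"], [])
        assert candidate_parents(net, "g3") == {"g1", "g2"}
        assert candidate_parents(net, "g3", allow_self_loops=True) == {"g1", "g2", "g3"}

    def test_full_parent_set_leaves_nothing(self):
        net = GeneNetwork(["g1", "g2", "g3"], [("g1", "g3"), ("g2", "g3")])
        assert candidate_parents(net, "g3") == set()


class TestSigma:
    def test_no_budget_is_current_parent_error(self, toy_noisy_expr, toy_gold):
        spec = CompletionSpec(k=0, h=0, K=2, H=2)
        val, added, deleted = sigma(toy_noisy_expr, toy_gold, "g3", 0, 0, spec)
        assert added == () and deleted == ()
        assert val == pytest.approx(
            node_error(toy_noisy_expr, "g3", toy_gold.parents("g3"))
        )

    def test_cap_violations_are_infeasible(self, toy_noisy_expr, toy_gold):
        spec = CompletionSpec(k=5, h=5, K=2, H=2)
        assert sigma(toy_noisy_expr, toy_gold, "g3", 3, 0, spec)[0] == INFEASIBLE
        assert sigma(toy_noisy_expr, toy_gold, "g3", 0, 3, spec)[0] == INFEASIBLE
        # deleting more parents than the node has
        assert sigma(toy_noisy_expr, toy_gold, "g1", 0, 2, spec)[0] == INFEASIBLE

    def test_two_additions_recover_true_parents(self, toy_system, toy_solutions):
        """From an empty parent set, k_j = 2 picks exactly {g1, g2} with zero error."""
        noiseless = perturb(
            toy_solutions,
            PerturbationConfig(replicates_per_solution=50, noise_half_width=0.0, seed=0),
        )
        empty = GeneNetwork(toy_system.genes, [])
        spec = CompletionSpec(k=2, h=0, K=2, H=0)
        val, added, deleted = sigma(noiseless, empty, "g3", 2, 0, spec)
        assert set(added) == {"g1", "g2"}
        assert deleted == ()
        assert val == pytest.approx(0, abs=1e-15)

    def test_matches_enumeration_oracle(self, rng):
        expr, net = random_instance(rng, 4, 12)
        spec = CompletionSpec(k=2, h=2, K=2, H=2)
        for g in net.genes:
            for kj in range(3):
                for hj in range(3):
                    got = sigma(expr, net, g, kj, hj, spec)[0]
                    want = enumerate_node_minimum(expr, net, g, kj, hj, spec)
                    if math.isinf(want):
                        assert got == INFEASIBLE
                    else:
                        assert got == pytest.approx(want, rel=1e-12)

    def test_monotone_in_additions_without_deletions(self, rng):
        """σ(k_j, 0) is non-increasing in k_j while entries stay feasible."""
        for _ in range(5):
            expr, net = random_instance(rng, 5, 15)
            st = SigmaTable(expr, net, CompletionSpec(k=3, h=0, K=3, H=0))
            for g in net.genes:
                prev = None
                for kj in range(4):
                    v = st.entry(g, kj, 0).value
                    if v == INFEASIBLE:
                        break
                    if prev is not None:
                        assert v <= prev + 1e-9
                    prev = v

    def test_argmin_sets_disjoint_and_well_formed(self, rng):
        expr, net = random_instance(rng, 4, 12)
        st = SigmaTable(expr, net, CompletionSpec(k=2, h=2, K=2, H=2))
        for g in net.genes:
            for kj in range(3):
                for hj in range(3):
                    e = st.entry(g, kj, hj)
                    if not e.feasible:
                        assert e.added == () and e.deleted == ()
                        continue
                    assert set(e.added) <= candidate_parents(net, g)
                    assert set(e.deleted) <= set(net.parents(g))
                    assert not set(e.added) & set(e.deleted)

    def test_fit_count_matches_enumeration_size(self, rng):
        """Number of least-squares fits equals Σ C(deg, h_j)·C(cand, k_j) over feasible cells."""
        expr, net = random_instance(rng, 5, 10)
        spec = CompletionSpec(k=2, h=2, K=2, H=2)
        st = SigmaTable(expr, net, spec)
        st.compute_all()
        expected = 0
        for g in net.genes:
            deg = net.indegree(g)
            cand = len(candidate_parents(net, g))
            for kj in range(spec.K + 1):
                for hj in range(spec.H + 1):
                    if not 0 <= kj - hj + deg < net.n:
                        continue
                    if hj > deg or kj > cand:
                        continue
                    expected += math.comb(deg, hj) * math.comb(cand, kj)
        assert st.fit_count == expected


class TestDynamicPrograms:
    def test_zero_budget_sums_current_errors(self, toy_noisy_expr, toy_gold):
        spec = CompletionSpec(k=0, h=0, K=2, H=2)
        table = dp_add_del(toy_noisy_expr, toy_gold, spec)
        expected = sum(
            node_error(toy_noisy_expr, g, toy_gold.parents(g)) for g in toy_gold.genes
        )
        assert table.optimum == pytest.approx(expected, rel=1e-12)

    def test_add_only_matches_direct_decomposition(self, rng):
        """n = 3, k = 2, K = 2: DP equals the minimum over all six (k1,k2,k3)."""
        expr, net = random_instance(rng, 3, 10)
        spec = CompletionSpec(k=2, h=0, K=2, H=0)
        table = dp_add(expr, net, 2, spec)
        st = SigmaTable(expr, net, spec)
        decomps = [
            (k1, k2, 2 - k1 - k2)
            for k1 in range(3)
            for k2 in range(3 - k1)
        ]
        assert len(decomps) == 6
        best = min(
            sum(st.entry(g, kj, 0).value for g, kj in zip(net.genes, d))
            for d in decomps
        )
        assert table.optimum == pytest.approx(best, rel=1e-12)

    def test_dp_add_requires_no_deletions(self, rng):
        expr, net = random_instance(rng, 3, 8)
        with pytest.raises(ValueError):
            dp_add(expr, net, 1, CompletionSpec(k=1, h=1, K=2, H=2))

    def test_deletion_free_collapse(self, rng):
        """With h = 0 the two-budget DP reproduces the addition-only DP."""
        expr, net = random_instance(rng, 4, 12)
        spec = CompletionSpec(k=2, h=0, K=2, H=0)
        t_add = dp_add(expr, net, 2, spec)
        t_full = dp_add_del(expr, net, spec)
        np.testing.assert_allclose(
            t_add.D[:, 0, :], t_full.D[:, 0, :], rtol=1e-12
        )

    def test_matches_exhaustive_oracle(self, rng):
        """DP optimum equals brute-force enumeration on small instances."""
        for _ in range(8):
            n = int(rng.integers(2, 5))
            expr, net = random_instance(rng, n, 10)
            k = int(rng.integers(0, 3))
            h = int(rng.integers(0, 3 - (k > 1)))
            spec = CompletionSpec(k=k, h=h, K=2, H=2)
            table = dp_add_del(expr, net, spec)
            want = enumerate_global_optimum(expr, net, spec)
            if math.isinf(want):
                assert table.optimum == INFEASIBLE
            else:
                assert table.optimum == pytest.approx(want, rel=1e-10)

    def test_order_invariance(self, rng):
        expr, net = random_instance(rng, 5, 14)
        spec = CompletionSpec(k=1, h=1, K=2, H=2)
        base = dp_add_del(expr, net, spec).optimum
        for _ in range(4):
            perm = list(rng.permutation(net.genes))
            table = dp_add_del(expr.subset_genes(perm), net.reordered(perm), spec)
            assert table.optimum == pytest.approx(base, rel=1e-9)

    def test_overbudget_infeasible(self, toy_noisy_expr, toy_gold):
        """k > n·K makes every decomposition impossible."""
        spec = CompletionSpec(k=7, h=0, K=2, H=0)
        table = dp_add_del(toy_noisy_expr, toy_gold, spec)
        assert table.optimum == INFEASIBLE
        res = traceback(table)
        assert not res.feasible
        assert res.completed is None


class TestTracebackAndModel:
    def test_zero_budget_identity(self, toy_noisy_expr, toy_gold):
        res = NetworkCompletion(toy_noisy_expr, toy_gold).fit(k=0, h=0)
        assert res.feasible
        assert res.completed == toy_gold
        assert res.added_edges == frozenset() and res.deleted_edges == frozenset()

    def test_total_error_equals_dp_optimum_and_refit(self, rng):
        expr, net = random_instance(rng, 4, 16)
        res = NetworkCompletion(expr, net).fit(k=1, h=1)
        if not res.feasible:
            pytest.skip("random instance infeasible")
        assert res.total_error == pytest.approx(res.dp.optimum, rel=1e-12)
        direct = sum(
            node_error(expr, g, res.completed.parents(g)) for g in net.genes
        )
        assert res.total_error == pytest.approx(direct, rel=1e-10)

    def test_exact_modification_counts(self, rng):
        for _ in range(5):
            expr, net = random_instance(rng, 4, 12)
            k = int(rng.integers(0, 3))
            h = int(rng.integers(0, 3))
            res = NetworkCompletion(expr, net).fit(k=k, h=h)
            if res.feasible:
                assert len(res.added_edges) == k
                assert len(res.deleted_edges) == h

    def test_recovers_single_swap_damage(self, toy_system, toy_noisy_expr):
        """Delete one true edge, add one spurious: completion restores the gold net."""
        gold = toy_system.network
        damaged = gold.with_modifications(
            added={("g3", "g1")}, deleted={("g2", "g3")}
        )
        res = NetworkCompletion(toy_noisy_expr, damaged).fit(k=1, h=1)
        assert res.feasible
        # confirmed optimal by exhaustive search over all single-add/single-delete pairs
        best = (INFEASIBLE, None)
        for dele in damaged.edges:
            for u in damaged.genes:
                for v in damaged.genes:
                    if u == v or (u, v) in damaged.edges or (u, v) == dele:
                        continue
                    cand = damaged.with_modifications(added={(u, v)}, deleted={dele})
                    tot = sum(
                        node_error(toy_noisy_expr, g, cand.parents(g))
                        for g in cand.genes
                    )
                    if tot < best[0]:
                        best = (tot, cand)
        assert res.completed == best[1] == gold
        assert res.total_error == pytest.approx(best[0], rel=1e-12)

    def test_traceback_agrees_with_functional_surface(self, toy_noisy_expr, toy_gold):
        spec = CompletionSpec(k=1, h=1, K=2, H=2)
        res_fn = complete_network(toy_noisy_expr, toy_gold, spec)
        res_tb = traceback(dp_add_del(toy_noisy_expr, toy_gold, spec))
        assert res_fn.completed == res_tb.completed
        assert res_fn.total_error == pytest.approx(res_tb.total_error)

    def test_cap_guard(self, toy_noisy_expr, toy_gold):
        model = NetworkCompletion(toy_noisy_expr, toy_gold)
        with pytest.raises(ValueError, match="allow_large_caps"):
            model.fit(k=1, h=0, K=4, H=0)

    def test_summary_mentions_budgets(self, toy_noisy_expr, toy_gold):
        res = NetworkCompletion(toy_noisy_expr, toy_gold).fit(k=0, h=0)
        text = res.summary()
        assert "k=0 h=0" in text and "feasible" in text
        assert all(g in text for g in toy_gold.genes)


class TestInference:
    def test_zero_additions_yields_empty_network(self, toy_noisy_expr):
        res = infer_network(toy_noisy_expr, k=0)
        assert res.feasible
        assert res.completed.edges == frozenset()

    def test_toy_inference_finds_both_regulators_of_g3(self, toy_noisy_expr):
        """k = 2 additions land on the two true edges into g3.

        Self-loops are not addable, so the two source self-loops are out of
        reach; the only error-reducing additions are the true parents of g3
        (confirmed optimal by the exhaustive two-edge search below).
        """
        res = infer_network(toy_noisy_expr, k=2, K=2)
        assert res.feasible
        assert {("g1", "g3"), ("g2", "g3")} == set(res.completed.edges)
        genes = toy_noisy_expr.genes
        pairs = [
            (u, v) for u in genes for v in genes if u != v
        ]
        best = min(
            (
                sum(
                    node_error(
                        toy_noisy_expr,
                        g,
                        [u for (u, v) in (e1, e2) if v == g],
                    )
                    for g in genes
                ),
                (e1, e2),
            )
            for e1, e2 in combinations(pairs, 2)
        )
        assert set(best[1]) == set(res.completed.edges)
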