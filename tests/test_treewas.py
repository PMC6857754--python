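"""Tree scan: counting semantics, summary fits, exact sum-product posteriors."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mrphewas as mp
from mrphewas.treewas import TreePrior


def edges_frame(pairs):
    return pd.DataFrame(pairs, columns=["child", "parent"])


def enumerate_posteriors(parents, summaries, prior):
    """Brute-force marginal pp over all 2^n latent-state configurations.

    ``parents`` maps node -> parent (root absent). Independent oracle for the
    sum-product implementation.
    """
    nodes = list(summaries["node"])
    by_node = summaries.set_index("node")
    grid = np.asarray(prior.effect_grid, dtype=float)

    def node_lik(node, state):
        row = by_node.loc[node]
        if not row["estimable"] or not np.isfinite(row["se"]):
            return 1.0
        if state == 0:
            return stats.norm.pdf(row["b_hat"], 0.0, row["se"])
        return stats.norm.pdf(row["b_hat"], grid, row["se"]).mean()

    pi = np.array([1 - prior.pi1, prior.pi1])
    T = prior.rho * np.eye(2) + (1 - prior.rho) * pi[None, :]
    total = 0.0
    node_active = dict.fromkeys(nodes, 0.0)
    for states in itertools.product([0, 1], repeat=len(nodes)):
        s = dict(zip(nodes, states))
        weight = 1.0
        for node in nodes:
            if node in parents:
                weight *= T[s[parents[node]], s[node]]
            else:
                weight *= pi[s[node]]
            weight *= node_lik(node, s[node])
        total += weight
        for node in nodes:
            if s[node] == 1:
                node_active[node] += weight
    return {node: node_active[node] / total for node in nodes}


def tree_from_parents(parents, root, summaries, ids=None):
    pairs = [(child, parent) for child, parent in parents.items()]
    tree = mp.build_code_tree(edges_frame(pairs), cohort_ids=ids)
    assert tree.root == root
    return tree


class TestBuildCodeTree:
    def test_chain_union_aggregation(self):
        edges = edges_frame([("A", "root"), ("A1", "A")])
        records = pd.DataFrame({"individual_id": [0], "icd10_code": ["A1"]})
        tree = mp.build_code_tree(edges, records)
        assert tree.n_cases("A1") == tree.n_cases("A") == tree.n_cases("root") == 1

    def test_disjoint_siblings_sum_at_parent(self):
        edges = edges_frame([("A", "root"), ("B", "root")])
        records = pd.DataFrame({
            "individual_id": [0, 1, 2, 3, 4, 5, 6],
            "icd10_code": ["A", "A", "A", "B", "B", "B", "B"]})
        tree = mp.build_code_tree(edges, records)
        assert tree.n_cases("A") == 3 and tree.n_cases("B") == 4
        assert tree.n_cases("root") == 7

    def test_counts_match_set_union_oracle(self):
        rng = np.random.default_rng(61)
        parents = {f"n{i}": f"n{rng.integers(0, i)}" for i in range(1, 50)}
        edges = edges_frame(list(parents.items()))
        records = pd.DataFrame({
            "individual_id": rng.integers(0, 200, 400),
            "icd10_code": [f"n{v}" for v in rng.integers(0, 50, 400)]})
        tree = mp.build_code_tree(edges, records)
        direct = {n: set(records.loc[records["icd10_code"] == n,
                                     "individual_id"]) for n in tree.nodes}

        def descendants(node):
            out = set(direct[node])
            for child, parent in parents.items():
                if parent == node:
                    out |= descendants(child)
            return out

        for node in tree.nodes:
            assert tree.case_sets[node] == descendants(node)

    def test_cycle_rejected(self):
        edges = edges_frame([("A", "B"), ("B", "A")])
        with pytest.raises(ValueError):
            mp.build_code_tree(edges)

    def test_multiple_roots_rejected(self):
        edges = edges_frame([("A", "r1"), ("B", "r2")])
        with pytest.raises(ValueError, match="root"):
            mp.build_code_tree(edges)


class TestNodeSummaries:
    def test_null_z_scores_standard_normal(self):
        rng = np.random.default_rng(62)
        n = 3000
        ids = pd.Index(range(n))
        score = pd.Series(rng.normal(size=n), index=ids)
        # 40 independent phenotype nodes under the null, via a star tree
        pairs, recs_id, recs_code = [], [], []
        for i in range(40):
            pairs.append((f"L{i}", "root"))
            members = rng.choice(n, 300, replace=False)
            recs_id.extend(members)
            recs_code.extend([f"L{i}"] * 300)
        tree = mp.build_code_tree(
            edges_frame(pairs),
            pd.DataFrame({"individual_id": recs_id, "icd10_code": recs_code}),
            cohort_ids=ids)
        summ = mp.node_summaries(score, tree)
        z = (summ["b_hat"] / summ["se"]).dropna()
        leaves = summ[summ["node"] != "root"]
        z = (leaves["b_hat"] / leaves["se"]).to_numpy()
        assert abs(z.mean()) < 3 / np.sqrt(len(z))
        assert 0.6 < z.std() < 1.5

    def test_zero_case_node_inestimable(self):
        ids = pd.Index(range(100))
        score = pd.Series(np.random.default_rng(63).normal(size=100), index=ids)
        edges = edges_frame([("A", "root"), ("B", "root")])
        records = pd.DataFrame({"individual_id": [0, 1], "icd10_code": ["A", "A"]})
        tree = mp.build_code_tree(edges, records, cohort_ids=ids)
        summ = mp.node_summaries(score, tree).set_index("node")
        assert not summ.loc["B", "estimable"]

    def test_planted_effect_large_z(self):
        rng = np.random.default_rng(64)
        n = 5000
        ids = pd.Index(range(n))
        score = pd.Series(rng.normal(size=n), index=ids)
        y = mp.simulate_binary_outcome(score.to_numpy() * 0.43, 0.15, 2.5,
                                       seed=65)
        records = pd.DataFrame({"individual_id": ids[y.astype(bool)],
                                "icd10_code": "A"})
        tree = mp.build_code_tree(edges_frame([("A", "root")]), records,
                                  cohort_ids=ids)
        summ = mp.node_summaries(score, tree).set_index("node")
        assert abs(summ.loc["A", "b_hat"] / summ.loc["A", "se"]) > 4


class TestTreePosterior:
    def test_single_node_closed_form(self):
        prior = TreePrior(pi1=0.001, rho=0.99, effect_grid=(0.2, -0.2))
        summ = pd.DataFrame({"node": ["root"], "n_cases": [10],
                             "b_hat": [0.0], "se": [1.0], "estimable": [True]})
        # build a one-node tree directly (edge lists need >= 1 edge)
        import networkx as nx
        from mrphewas.treewas import CodeTree
        g = nx.DiGraph()
        g.add_node("root")
        tree = CodeTree(g, "root", {"root": set()})
        post = mp.tree_posterior(tree, summ, prior)
        l0 = stats.norm.pdf(0.0, 0.0, 1.0)
        l1 = stats.norm.pdf(0.0, np.array([0.2, -0.2]), 1.0).mean()
        expected = 0.001 * l1 / (0.999 * l0 + 0.001 * l1)
        assert post["pp_nonzero"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_seven_node_tree_matches_enumeration(self):
        rng = np.random.default_rng(66)
        parents = {"A": "root", "B": "root", "A1": "A", "A2": "A",
                   "B1": "B", "B2": "B"}
        nodes = ["root", "A", "B", "A1", "A2", "B1", "B2"]
        summ = pd.DataFrame({
            "node": nodes, "n_cases": 50,
            "b_hat": rng.normal(0, 0.3, len(nodes)),
            "se": rng.uniform(0.1, 0.5, len(nodes)),
            "estimable": True})
        prior = TreePrior(pi1=0.05, rho=0.9, effect_grid=(-0.3, 0.1, 0.4))
        tree = tree_from_parents(parents, "root", summ)
        post = mp.tree_posterior(tree, summ, prior).set_index("node")
        oracle = enumerate_posteriors(parents, summ, prior)
        for node in nodes:
            assert post.loc[node, "pp_nonzero"] == pytest.approx(
                oracle[node], abs=1e-10)

    def test_no_information_recovers_prior(self):
        parents = {"A": "root", "B": "root", "A1": "A"}
        summ = pd.DataFrame({"node": ["root", "A", "B", "A1"], "n_cases": 0,
                             "b_hat": np.nan, "se": np.nan,
                             "estimable": False})
        prior = TreePrior(pi1=0.01, rho=0.95)
        tree = tree_from_parents(parents, "root", summ)
        post = mp.tree_posterior(tree, summ, prior)
        np.testing.assert_allclose(post["pp_nonzero"], prior.pi1, atol=1e-12)

    def test_pp_monotone_in_z(self):
        import networkx as nx
        from mrphewas.treewas import CodeTree
        g = nx.DiGraph()
        g.add_node("root")
        tree = CodeTree(g, "root", {"root": set()})
        prior = TreePrior()
        pps = []
        for b in np.linspace(0, 2, 9):
            summ = pd.DataFrame({"node": ["root"], "n_cases": [10],
                                 "b_hat": [b], "se": [0.1],
                                 "estimable": [True]})
            pps.append(mp.tree_posterior(tree, summ, prior)
                       ["pp_nonzero"].iloc[0])
        # non-decreasing throughout (pp saturates at 1 in float for huge z)
        assert all(a <= b for a, b in zip(pps, pps[1:]))
        assert pps[0] < 0.01 < 0.99 < pps[-1]

    def test_child_order_invariance(self):
        rng = np.random.default_rng(67)
        parents = {"A": "root", "B": "root", "C": "root"}
        summ = pd.DataFrame({"node": ["root", "A", "B", "C"], "n_cases": 10,
                             "b_hat": rng.normal(size=4),
                             "se": rng.uniform(0.2, 0.5, 4),
                             "estimable": True})
        prior = TreePrior(pi1=0.02, rho=0.9)
        t1 = tree_from_parents(parents, "root", summ)
        t2 = tree_from_parents(dict(reversed(list(parents.items()))),
                               "root", summ)
        p1 = mp.tree_posterior(t1, summ, prior).set_index("node")["pp_nonzero"]
        p2 = mp.tree_posterior(t2, summ, prior).set_index("node")["pp_nonzero"]
        pd.testing.assert_series_equal(p1.sort_index(), p2.sort_index(),
                                       atol=1e-12, rtol=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_trees_match_enumeration(self, data):
        n = data.draw(st.integers(min_value=2, max_value=12))
        parent_idx = [data.draw(st.integers(0, i - 1)) for i in range(1, n)]
        parents = {f"n{i}": f"n{parent_idx[i - 1]}" for i in range(1, n)}
        b = [data.draw(st.floats(-1, 1)) for _ in range(n)]
        se = [data.draw(st.floats(0.05, 1.0)) for _ in range(n)]
        estimable = [data.draw(st.booleans()) for _ in range(n)]
        summ = pd.DataFrame({"node": [f"n{i}" for i in range(n)],
                             "n_cases": 10, "b_hat": b, "se": se,
                             "estimable": estimable})
        prior = TreePrior(pi1=0.1, rho=0.8, effect_grid=(-0.5, 0.25))
        tree = tree_from_parents(parents, "n0", summ)
        post = mp.tree_posterior(tree, summ, prior).set_index("node")
        oracle = enumerate_posteriors(parents, summ, prior)
        for node, expected in oracle.items():
            assert post.loc[node, "pp_nonzero"] == pytest.approx(
                expected, abs=1e-10)


class TestSignificantNodes:
    def test_all_below_published_maximum_empty(self):
        post = pd.DataFrame({"node": ["a", "b"], "pp_nonzero": [0.26, 0.10]})
        assert mp.significant_nodes(post) == []

    def test_single_hit(self):
        post = pd.DataFrame({"node": ["a", "b"], "pp_nonzero": [0.9, 0.1]})
        assert mp.significant_nodes(post) == ["a"]

    def test_threshold_strictly_exceeded(self):
        post = pd.DataFrame({"node": ["a"], "pp_nonzero": [0.75]})
        assert mp.significant_nodes(post, 0.75) == []

    def test_null_cohort_rarely_flags(self, cohort, toy_edges, score):
        tree = mp.build_code_tree(toy_edges, cohort.records,
                                  cohort_ids=cohort.ids)
        summ = mp.node_summaries(score, tree, cohort.covariates)
        post = mp.tree_posterior(tree, summ)
        assert mp.significant_nodes(post) == []
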