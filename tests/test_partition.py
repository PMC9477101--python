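"""Model-based recursive partitioning: instability tests, splits, pruning."""

import json

import numpy as np
import pytest

from bttrees import (
    Covariate,
    GroupSpec,
    TreeConfig,
    enumerate_patterns,
    fit_llbt,
    grow_tree,
    instability_test,
    loglik_and_scores,
    pattern_distribution,
    lambda_from_worth,
    predict_node,
    prune_aic,
    search_cutpoint,
    select_split_variable,
    tree_to_dict,
    tree_to_dot,
)
from bttrees.partition import InstabilityResult
from bttrees.rankings import PatternTable, pattern_to_ranking
from bttrees.simulate import covariates_from_frame, simulate_study

from .conftest import (
    FIVE_DECLS,
    FLAT,
    STEEP,
    homogeneous_design,
    planted_age_design,
)


def node_scores(items, lam, draws, pats):
    """Reduced per-subject scores at the MLE of a drawn pattern sample."""
    counts = {}
    for d in draws:
        counts[pats[d]] = counts.get(pats[d], 0) + 1
    fit = fit_llbt(PatternTable(items, counts))
    _, s = loglik_and_scores(fit, [pats[d] for d in draws])
    return s[:, :-1] - s[:, -1:]


class TestInstabilityTest:
    def test_constant_covariate_flags_no_variation(self, items5):
        rng = np.random.default_rng(0)
        pats = enumerate_patterns(5)
        draws = rng.integers(0, 120, size=200)
        scores = node_scores(items5, np.zeros(5), draws, pats)
        sids = [f"s{i}" for i in range(200)]
        cov = Covariate("const", "numeric", {s: 1.0 for s in sids})
        res = instability_test(scores, cov, sids, minsize=40)
        assert res.p_value == 1.0 and res.no_variation

    def test_type_one_error_rate_in_band(self, items5):
        """Independent covariate: ~5% rejections at alpha = 0.05."""
        rng = np.random.default_rng(42)
        lam = lambda_from_worth(np.array([0.3, 0.25, 0.2, 0.15, 0.1]))
        probs = pattern_distribution(lam)
        pats = enumerate_patterns(5)
        n, rejections = 400, 0
        for _ in range(400):
            draws = rng.choice(120, size=n, p=probs)
            scores = node_scores(items5, lam, draws, pats)
            sids = [f"s{i}" for i in range(n)]
            cov = Covariate(
                "z", "numeric", dict(zip(sids, rng.normal(size=n)))
            )
            rejections += instability_test(scores, cov, sids, 40).p_value < 0.05
        assert 0.02 <= rejections / 400 <= 0.09

    def test_power_against_two_regimes(self, items5):
        """Distinct worths above/below the covariate median: near-certain detection."""
        pats = enumerate_patterns(5)
        p_lo = pattern_distribution(lambda_from_worth(STEEP))
        p_hi = pattern_distribution(lambda_from_worth(FLAT))
        rng = np.random.default_rng(43)
        n = 600
        detected = 0
        for _ in range(100):
            z = rng.normal(size=n)
            med = np.median(z)
            draws = np.where(
                z <= med,
                rng.choice(120, size=n, p=p_lo),
                rng.choice(120, size=n, p=p_hi),
            )
            scores = node_scores(items5, np.zeros(5), draws, pats)
            sids = [f"s{i}" for i in range(n)]
            cov = Covariate("z", "numeric", dict(zip(sids, z)))
            detected += instability_test(scores, cov, sids, 40).p_value < 1e-4
        assert detected >= 95

    def test_nominal_covariate_uses_chisq(self, items5):
        rng = np.random.default_rng(1)
        pats = enumerate_patterns(5)
        draws = rng.integers(0, 120, size=300)
        scores = node_scores(items5, np.zeros(5), draws, pats)
        sids = [f"s{i}" for i in range(300)]
        cov = Covariate(
            "g", "nominal", {s: rng.choice(["x", "y", "z"]) for s in sids}
        )
        res = instability_test(scores, cov, sids, 40)
        assert res.test == "chisq" and 0 <= res.p_value <= 1

    def test_bonferroni_adjustment(self, items5):
        rng = np.random.default_rng(2)
        pats = enumerate_patterns(5)
        draws = rng.integers(0, 120, size=200)
        scores = node_scores(items5, np.zeros(5), draws, pats)
        sids = [f"s{i}" for i in range(200)]
        cov = Covariate("z", "numeric", {s: rng.normal() for s in sids})
        res = instability_test(scores, cov, sids, 40, n_tests=5)
        assert res.p_adjusted == pytest.approx(min(1.0, res.p_value * 5))


class TestSelectSplitVariable:
    def _res(self, name, p):
        return InstabilityResult(name, 1.0, p, p, "supLM")

    def test_none_when_all_above_alpha(self):
        assert select_split_variable([self._res("a", 0.5), self._res("b", 0.2)], 0.05) is None

    def test_picks_smallest(self):
        out = select_split_variable(
            [self._res("a", 0.04), self._res("b", 0.001)], 0.05
        )
        assert out == "b"

    def test_tie_breaks_by_declaration_order(self):
        out = select_split_variable(
            [self._res("first", 0.01), self._res("second", 0.01)], 0.05
        )
        assert out == "first"


class TestSearchCutpoint:
    def _subjects(self, items, worth, n, rng):
        probs = pattern_distribution(lambda_from_worth(worth))
        return rng.choice(120, size=n, p=probs)

    def test_forced_unique_cutpoint(self, items5):
        rng = np.random.default_rng(3)
        rows = self._subjects(items5, FLAT, 8, rng)
        sids = [f"s{i}" for i in range(8)]
        cov = Covariate("z", "numeric", dict(zip(sids, [1, 1, 1, 1, 2, 2, 2, 2.0])))
        rule = search_cutpoint(rows, cov, sids, minsize=4, items=items5)
        assert rule.cutpoint == 1.0

    def test_nominal_two_levels_single_partition(self, items5):
        rng = np.random.default_rng(4)
        rows = self._subjects(items5, FLAT, 100, rng)
        sids = [f"s{i}" for i in range(100)]
        cov = Covariate(
            "g", "nominal", {s: ("x" if i < 50 else "y") for i, s in enumerate(sids)}
        )
        rule = search_cutpoint(rows, cov, sids, minsize=10, items=items5)
        assert set(rule.left_categories) in ({"x"}, {"y"})

    def test_unsplittable_raises(self, items5):
        rng = np.random.default_rng(5)
        rows = self._subjects(items5, FLAT, 20, rng)
        sids = [f"s{i}" for i in range(20)]
        cov = Covariate("z", "numeric", {s: 1.0 for s in sids})
        with pytest.raises(ValueError, match="unsplittable"):
            search_cutpoint(rows, cov, sids, minsize=5, items=items5)

    def test_recovers_planted_cutpoint(self, items5):
        """Strong contrast at z = 0: the found cut lands next to it."""
        rng = np.random.default_rng(6)
        p_lo = pattern_distribution(lambda_from_worth(STEEP))
        p_hi = pattern_distribution(lambda_from_worth(FLAT))
        hits = 0
        for _ in range(10):
            z = np.sort(rng.normal(size=400))
            rows = np.where(
                z <= 0,
                rng.choice(120, size=400, p=p_lo),
                rng.choice(120, size=400, p=p_hi),
            )
            sids = [f"s{i}" for i in range(400)]
            cov = Covariate("z", "numeric", dict(zip(sids, z)))
            rule = search_cutpoint(rows, cov, sids, minsize=40, items=items5)
            # within one inter-observation gap of the true cut
            below = z[z <= 0]
            above = z[z > 0]
            lo = below[-2] if below.size >= 2 else z[0]
            hi = above[1] if above.size >= 2 else z[-1]
            hits += lo <= rule.cutpoint <= hi
        assert hits >= 9


class TestGrowTree:
    def test_small_sample_single_node(self, items5):
        design = homogeneous_design(items5, 60, seed=11)
        rankings, cov_df = simulate_study(design)
        covs = covariates_from_frame(cov_df, FIVE_DECLS)
        tree = grow_tree(rankings, covs, items5, TreeConfig(minsize=40))
        assert tree.root.is_terminal

    def test_planted_split_recovered(self, items5):
        design = planted_age_design(items5, 1000, seed=12)
        rankings, cov_df = simulate_study(design)
        covs = covariates_from_frame(cov_df, FIVE_DECLS)
        tree = grow_tree(rankings, covs, items5, TreeConfig(minsize=40))
        assert tree.root.split is not None
        assert tree.root.split.covariate == "age"
        assert abs(tree.root.split.cutpoint - 15) <= 1

    def test_partition_exactness_and_worth_sums(self, items5):
        design = planted_age_design(items5, 600, seed=13)
        rankings, cov_df = simulate_study(design)
        covs = covariates_from_frame(cov_df, FIVE_DECLS)
        tree = grow_tree(rankings, covs, items5, TreeConfig(minsize=40))
        for node in tree.nodes():
            if not node.is_terminal:
                assert sorted(node.left.subject_ids + node.right.subject_ids) == sorted(
                    node.subject_ids
                )
            assert node.fit.pi.sum() == pytest.approx(1, abs=1e-10)

    def test_missing_covariates_dropped_and_counted(self, items5):
        design = homogeneous_design(items5, 120, seed=14)
        rankings, cov_df = simulate_study(design)
        covs = covariates_from_frame(cov_df, FIVE_DECLS)
        covs[0].values[rankings[0].subject_id] = float("nan")
        del covs[1].values[rankings[1].subject_id]
        tree = grow_tree(rankings, covs, items5, TreeConfig(minsize=40))
        assert tree.n_dropped_missing == 2
        assert tree.root.n == 118

    def test_group_variable_never_splits(self, items5):
        design = planted_age_design(items5, 500, seed=15)
        rankings, cov_df = simulate_study(design)
        covs = covariates_from_frame(cov_df, FIVE_DECLS)
        rng = np.random.default_rng(0)
        mapping = {
            r.subject_id: ("expert" if rng.random() < 0.5 else "novice")
            for r in rankings
        }
        groups = GroupSpec(mapping, "novice")
        tree = grow_tree(rankings, covs, items5, TreeConfig(minsize=40), groups)
        assert all(rule.covariate != "group" for rule in tree.split_rules())
        for node in tree.terminal_nodes():
            assert set(node.fit.group_pi) == {"expert", "novice"}
            for pi in node.fit.group_pi.values():
                assert pi.sum() == pytest.approx(1, abs=1e-10)


class TestPruneAic:
    def test_single_node_unchanged(self, items5):
        design = homogeneous_design(items5, 100, seed=16)
        rankings, cov_df = simulate_study(design)
        covs = covariates_from_frame(cov_df, FIVE_DECLS)
        tree = grow_tree(rankings, covs, items5, TreeConfig(minsize=40, prune="none"))
        n_before = len(tree.nodes())
        prune_aic(tree)
        assert len(tree.nodes()) == n_before == 1

    def test_strong_split_survives(self, items5):
        design = planted_age_design(items5, 800, seed=17)
        rankings, cov_df = simulate_study(design)
        covs = covariates_from_frame(cov_df, FIVE_DECLS)
        tree = grow_tree(rankings, covs, items5, TreeConfig(minsize=40, prune="aic"))
        assert tree.root.split is not None

    def test_lenient_alpha_pruned_back_and_idempotent(self, items5):
        design = homogeneous_design(items5, 500, seed=18)
        rankings, cov_df = simulate_study(design)
        covs = covariates_from_frame(cov_df, FIVE_DECLS)
        grown = grow_tree(
            rankings, covs, items5, TreeConfig(alpha=0.5, minsize=40, prune="none")
        )
        n_grown = len(grown.terminal_nodes())

        def total_aic(t):
            return sum(nd.fit.aic for nd in t.terminal_nodes())

        aic_grown = total_aic(grown)
        pruned = prune_aic(grown)
        assert len(pruned.terminal_nodes()) <= n_grown
        assert total_aic(pruned) <= aic_grown
        once = [nd.id for nd in pruned.nodes()]
        prune_aic(pruned)
        assert [nd.id for nd in pruned.nodes()] == once


class TestPredictNode:
    def test_single_node_returns_root(self, items5):
        design = homogeneous_design(items5, 100, seed=19)
        rankings, cov_df = simulate_study(design)
        covs = covariates_from_frame(cov_df, FIVE_DECLS)
        tree = grow_tree(rankings, covs, items5, TreeConfig(minsize=40))
        node_id, worth = predict_node(tree, {"age": 99})
        assert node_id == tree.root.id
        np.testing.assert_allclose(worth, tree.root.fit.pi)

    def test_cutpoint_goes_left_and_routes_differ(self, items5):
        design = planted_age_design(items5, 1000, seed=20)
        rankings, cov_df = simulate_study(design)
        covs = covariates_from_frame(cov_df, FIVE_DECLS)
        tree = grow_tree(rankings, covs, items5, TreeConfig(minsize=40))
        assert tree.root.split is not None
        cut = tree.root.split.cutpoint
        base = {c.name: cov_df[c.name].iloc[0] for c in covs}
        at_cut = dict(base, age=cut)
        left_id, _ = predict_node(tree, at_cut)
        assert left_id in {nd.id for nd in _subtree_ids(tree.root.left)}
        young, _ = predict_node(tree, dict(base, age=10))
        old, _ = predict_node(tree, dict(base, age=20))
        assert young != old

    def test_missing_rule_covariate_raises(self, items5):
        design = planted_age_design(items5, 1000, seed=21)
        rankings, cov_df = simulate_study(design)
        covs = covariates_from_frame(cov_df, FIVE_DECLS)
        tree = grow_tree(rankings, covs, items5, TreeConfig(minsize=40))
        with pytest.raises(KeyError):
            predict_node(tree, {"game_time": 10.0})


def _subtree_ids(node):
    out = [node]
    if node.left is not None:
        out += _subtree_ids(node.left)
        out += _subtree_ids(node.right)
    return out


class TestTreeSerialization:
    def test_json_and_dot(self, items5, tmp_path):
        design = planted_age_design(items5, 600, seed=22)
        rankings, cov_df = simulate_study(design)
        covs = covariates_from_frame(cov_df, FIVE_DECLS)
        tree = grow_tree(rankings, covs, items5, TreeConfig(minsize=40))
        d = tree_to_dict(tree)
        json.dumps(d)  # must be serializable
        assert d["schema_version"] == 1
        assert d["items"] == ["a", "b", "c", "d", "e"]
        terminals = [nd for nd in d["nodes"] if nd["terminal"]]
        assert sum(nd["n"] for nd in terminals) == 600
        dot = tree_to_dot(tree)
        assert dot.startswith("digraph") and "worth" in dot
        dot_log = tree_to_dot(tree, log_scale=True)
        assert "log10" in dot_log
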