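"""CCF estimation, mixture clustering, exhaustive tree search, pruning and
serialization."""

import numpy as np
import pandas as pd
import pytest

from dipgevo.correction import CorrectedCounts
from dipgevo.clonetree import (estimate_ccf, cluster_mutations,
                               clusters_from_assignment, enumerate_trees,
                               score_tree, fit_tree, prune_tree, export_tree,
                               load_tree_json)


def _corrected(vaf_table, depth=10_000.0, exact=True):
    """CorrectedCounts from {mutation: {sample: vaf}}; exact real counts."""
    out = []
    for m, per_sample in vaf_table.items():
        for s, v in per_sample.items():
            out.append(CorrectedCounts(m, s, (1 - v) * depth, v * depth,
                                       "none", v))
    return out


class TestEstimateCCF:
    def test_clonal_diploid_het_ccf_one(self):
        ccf = estimate_ccf(_corrected({"m": {"S1": 0.5}}), round_counts=False)
        assert ccf.ccf.at["m", "S1"] == pytest.approx(1.0)

    def test_purity_scaling(self):
        ccf = estimate_ccf(_corrected({"m": {"S1": 0.1}}), purity={"S1": 0.8},
                           round_counts=False)
        assert ccf.ccf.at["m", "S1"] == pytest.approx(0.25)

    def test_cap_at_one(self):
        ccf = estimate_ccf(_corrected({"m": {"S1": 0.7}}), round_counts=False)
        assert ccf.ccf.at["m", "S1"] == 1.0

    def test_low_depth_flagged_missing(self):
        ccf = estimate_ccf(_corrected({"m": {"S1": 0.4}}, depth=5.0))
        assert bool(ccf.missing.at["m", "S1"])

    def test_invalid_purity_rejected(self):
        with pytest.raises(ValueError):
            estimate_ccf(_corrected({"m": {"S1": 0.5}}), purity={"S1": 0.0})


class TestClustering:
    def test_identical_frequencies_single_cluster(self):
        table = {f"m{i}": {"S1": 0.4, "S2": 0.4} for i in range(20)}
        res = cluster_mutations(estimate_ccf(_corrected(table, depth=4000)),
                                seed=0)
        assert res.k == 1

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_two_groups_perfectly_separated(self, seed):
        rng = np.random.default_rng(seed)
        table = {}
        samples = [f"S{j}" for j in range(6)]
        truth = {}
        for i in range(50):
            for grp, level in [(0, 0.5), (1, 0.1)]:
                m = f"g{grp}_m{i}"
                truth[m] = grp
                table[m] = {s: rng.binomial(4000, level) / 4000
                            for s in samples}
        ccf = estimate_ccf(_corrected(table, depth=4000))
        res = cluster_mutations(ccf, seed=seed)
        assert res.k == 2
        # oracle: assign by nearest group mean; must agree with EM labels
        for m, grp in truth.items():
            mean_v = np.mean(list(table[m].values()))
            oracle = 0 if abs(mean_v - 0.5) < abs(mean_v - 0.1) else 1
            assert oracle == grp
        split = {res.assignment[m] for m, g in truth.items() if g == 0}
        assert len(split) == 1  # group 0 lands in exactly one cluster
        split1 = {res.assignment[m] for m, g in truth.items() if g == 1}
        assert len(split1) == 1 and split != split1

    def test_branching_three_cluster_pattern(self):
        # truncal cluster plus two complementary subclonal clusters
        samples = [f"S{j}" for j in range(6)]
        table = {}
        for i in range(30):
            table[f"t{i}"] = {s: 0.4 for s in samples}
            table[f"b{i}"] = {s: (0.3 if j < 3 else 0.0)
                              for j, s in enumerate(samples)}
            table[f"c{i}"] = {s: (0.0 if j < 3 else 0.3)
                              for j, s in enumerate(samples)}
        res = cluster_mutations(estimate_ccf(_corrected(table, depth=4000)),
                                seed=4)
        assert res.k == 3

    def test_deterministic_given_seed(self):
        table = {f"m{i}": {"S1": 0.1 + 0.01 * i} for i in range(12)}
        ccf = estimate_ccf(_corrected(table, depth=1000))
        a = cluster_mutations(ccf, seed=9)
        b = cluster_mutations(ccf, seed=9)
        assert a.assignment == b.assignment and a.k == b.k


def _oracle_enumerate(k):
    """Independent recursive enumeration: pick the truncal clone, then grow
    the remaining labels one at a time onto any existing tumor node."""
    trees = []

    def grow(parent, remaining):
        if not remaining:
            trees.append(tuple(parent[i] for i in sorted(parent)))
            return
        nxt, rest = remaining[0], remaining[1:]
        for host in parent:
            grow({**parent, nxt: host}, rest)

    import itertools
    nodes = list(range(1, k + 1))
    for trunk in nodes:
        others = [n for n in nodes if n != trunk]
        for order in itertools.permutations(others):
            grow({trunk: 0}, list(order))
    return set(trees)


class TestEnumeration:
    def test_single_cluster(self):
        assert enumerate_trees(1) == [(0,)]

    def test_two_clusters_two_trees(self):
        assert set(enumerate_trees(2)) == {(0, 1), (2, 0)}

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_matches_independent_recursive_oracle(self, k):
        got = set(enumerate_trees(k))
        assert got == _oracle_enumerate(k)
        assert len(got) == k ** (k - 1)

    def test_k_limit_enforced(self):
        with pytest.raises(ValueError, match="exhaustive"):
            enumerate_trees(8)


TWO_SAMPLE_TABLE = {
    "a1": {"S1": 0.45, "S2": 0.40}, "a2": {"S1": 0.45, "S2": 0.40},
    "b1": {"S1": 0.25, "S2": 0.10}, "b2": {"S1": 0.25, "S2": 0.10},
    "c1": {"S1": 0.15, "S2": 0.25}, "c2": {"S1": 0.15, "S2": 0.25},
}
ASSIGN = {"a1": 1, "a2": 1, "b1": 2, "b2": 2, "c1": 3, "c2": 3}


class TestScoringAndFit:
    def _setup(self):
        ccf = estimate_ccf(_corrected(TWO_SAMPLE_TABLE), round_counts=False)
        clusters = clusters_from_assignment(ccf, ASSIGN)
        return ccf, clusters

    def test_consistent_frequencies_zero_violation(self):
        ccf, clusters = self._setup()
        logL, violation = score_tree((0, 1, 1), ccf, clusters)
        assert violation == pytest.approx(0.0)

    def test_infeasible_tree_positive_violation(self):
        ccf, clusters = self._setup()
        # nesting C under B violates in S1 (0.3 < 0.5 fine) and S2 (0.2 < 0.5)
        logL_chain, viol_chain = score_tree((0, 1, 2), ccf, clusters)
        assert viol_chain > 0

    def test_branching_tree_selected_with_mixing(self):
        # A=(0.9,0.8), B=(0.5,0.2), C=(0.3,0.5): neither subclone dominates
        # the other in both samples, so only the branching tree is feasible
        ccf, clusters = self._setup()
        tree = fit_tree(ccf, clusters)
        assert tree.parent == {1: 0, 2: 1, 3: 1}
        assert tree.violation_total == pytest.approx(0.0)
        assert tree.mixing.at[1, "S1"] == pytest.approx(0.9 - 0.8)
        assert tree.mixing.at["normal", "S1"] == pytest.approx(0.1)
        sums = tree.mixing.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_true_tree_beats_all_alternatives_when_unique_feasible(self):
        ccf, clusters = self._setup()
        best_logL, _ = score_tree((0, 1, 1), ccf, clusters)
        for cand in enumerate_trees(3):
            if cand == (0, 1, 1):
                continue
            logL, viol = score_tree(cand, ccf, clusters)
            assert logL - 100 * viol < best_logL - 1e-6

    def test_single_cluster_tree(self):
        table = {"m1": {"S1": 0.5}, "m2": {"S1": 0.5}}
        ccf = estimate_ccf(_corrected(table), round_counts=False)
        clusters = clusters_from_assignment(ccf, {"m1": 1, "m2": 1})
        tree = fit_tree(ccf, clusters)
        assert tree.parent == {1: 0}
        assert tree.mixing.at["normal", "S1"] == pytest.approx(0.0)

    def test_determinism_of_fit_and_serialization(self):
        ccf, clusters = self._setup()
        t1 = fit_tree(ccf, clusters)
        t2 = fit_tree(ccf, clusters)
        assert export_tree(t1, "json") == export_tree(t2, "json")


class TestPruneAndExport:
    def _tree(self):
        ccf = estimate_ccf(_corrected(TWO_SAMPLE_TABLE), round_counts=False)
        clusters = clusters_from_assignment(ccf, ASSIGN)
        return fit_tree(ccf, clusters)

    def test_threshold_zero_is_identity(self):
        tree = self._tree()
        pruned = prune_tree(tree, 0.0)
        assert pruned.parent == tree.parent

    def test_all_nodes_expressed_identity(self):
        tree = self._tree()
        pruned = prune_tree(tree, 0.05)
        assert pruned.parent == tree.parent

    def test_low_contribution_node_collapsed(self):
        table = dict(TWO_SAMPLE_TABLE)
        # a tiny leaf cluster: mixing below 0.05 in every sample
        table["d1"] = {"S1": 0.02, "S2": 0.02}
        assign = dict(ASSIGN, d1=4)
        ccf = estimate_ccf(_corrected(table), round_counts=False)
        clusters = clusters_from_assignment(ccf, assign)
        tree = fit_tree(ccf, clusters)
        low = tree.assignment["d1"]
        assert float(tree.mixing.loc[low].max()) < 0.05
        pruned = prune_tree(tree, 0.05)
        assert low not in pruned.parent
        host = tree.parent[low]
        assert "d1" in pruned.members_of(host)
        assert low in tree.parent  # fitted tree untouched

    def test_json_round_trip(self):
        tree = self._tree()
        back = load_tree_json(export_tree(tree, "json"))
        assert back.parent == tree.parent
        assert [c.members for c in back.clusters] == [c.members for c in tree.clusters]
        pd.testing.assert_frame_equal(back.mixing, tree.mixing)

    def test_dot_structure(self):
        dot = export_tree(self._tree(), "dot")
        assert dot.count(" -> ") == 3  # normal->trunk + two children
        assert dot.count("label=") == 4  # normal + 3 clones

    def test_newick_parses(self):
        import dendropy
        nwk = export_tree(self._tree(), "newick")
        t = dendropy.Tree.get(data=nwk, schema="newick")
        labels = {l.taxon.label if l.taxon else l.label
                  for l in t.leaf_node_iter()}
        assert len(labels) == 2  # the two sibling subclones

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError):
            export_tree(self._tree(), "nexus")
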