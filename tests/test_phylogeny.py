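"""Clone-tree reconstruction: rooting, greedy building vs brute force,
composition, distances, Newick serialization."""

import dendropy
import numpy as np
import pandas as pd
import pytest

import clonedyn as cd
from clonedyn.errors import InputError, ModelAssumptionError
from clonedyn.phylogeny import distance_matrix

from _oracles import feasible_trees


def make_cluster(cid, centers, n=150):
    cl = cd.CCFCluster(cid, dict(centers), members=[(cid, i, "A", "T") for i in range(n)])
    cl.n_private_mutations = n
    cd.classify_cluster(cl)
    return cl


P04_EDGES = frozenset({("C1", "C0"), ("C3", "C1"), ("C2", "C0"), ("C4", "C2")})


class TestInferRoot:
    def test_p04_root(self, p04_noiseless_clusters):
        root = cd.infer_root(p04_noiseless_clusters)
        assert root.cluster_id == "C0"
        assert root.centers == {"peritoneal": 1.0, "liver1": 1.0, "liver2": 1.0}

    def test_single_cluster(self):
        cl = make_cluster("C0", {"s": 1.0})
        assert cd.infer_root([cl]) is cl

    def test_two_clonal_clusters_rejected(self):
        clusters = [make_cluster("A", {"s": 1.0}), make_cluster("B", {"s": 0.95})]
        with pytest.raises(ModelAssumptionError):
            cd.infer_root(clusters)

    def test_no_clonal_cluster_rejected(self):
        with pytest.raises(ModelAssumptionError):
            cd.infer_root([make_cluster("A", {"s": 0.5, "t": 0.2})])


class TestBuildTree:
    def test_p04_topology_and_brute_force_uniqueness(self, p04_noiseless_clusters):
        tree = cd.build_tree(p04_noiseless_clusters)
        assert tree.edges() == P04_EDGES
        assert not tree.forced_root
        centers = {
            c.cluster_id: c.center_vector(["peritoneal", "liver1", "liver2"])
            for c in p04_noiseless_clusters
        }
        oracle = feasible_trees(centers, "C0", tol=0.10)
        assert oracle == [P04_EDGES]  # unique feasible tree

    def test_single_cluster_tree(self):
        tree = cd.build_tree([make_cluster("C0", {"s": 1.0})])
        assert tree.root_id == "C0" and tree.parent == {}

    def test_random_noiseless_trees_feasible_and_exact_when_unique(self):
        """On noiseless random scenarios the greedy tree is always within the
        brute-force feasible set, and equals the generating tree whenever
        brute force certifies the instance as uniquely identifiable."""
        rng = np.random.default_rng(123)
        unique_checked = 0
        for _ in range(50):
            sc = cd.random_scenario(rng, n_clones=6, n_samples=3)
            truth = frozenset(
                (c.clone_id, c.parent_id) for c in sc.clones if c.parent_id
            )
            clusters = [
                make_cluster(c.clone_id, c.per_sample_ccf, c.n_private_mutations)
                for c in sc.clones
            ]
            centers = {
                c.cluster_id: c.center_vector(sc.sample_ids) for c in clusters
            }
            oracle = feasible_trees(centers, "C0", tol=0.05)
            assert truth in oracle  # the generating tree is always feasible
            tree = cd.build_tree(clusters, sum_rule_tol=0.05)
            assert not tree.forced_root
            assert tree.edges() in oracle  # greedy output is itself feasible
            if len(oracle) == 1:
                unique_checked += 1
                assert tree.edges() == truth
        assert unique_checked >= 1

    def test_noisy_topology_recovery_rate(self, p04_scenario):
        """At 150x depth the full pipeline recovers the true topology in
        >= 90% of 50 simulation seeds."""
        purities = {s.sample_id: s.purity for s in p04_scenario.samples}
        segs = {s.sample_id: s.cn_profile for s in p04_scenario.samples}
        hits = 0
        for seed in range(50):
            calls = cd.simulate_all_biopsies(p04_scenario, seed)
            mat = cd.ccf_matrix(calls, purities, segs)
            try:
                res = cd.ClonalStructureModel(mat).fit()
            except ModelAssumptionError:
                continue
            if res.n_clusters != 5:
                continue
            depths = sorted(res.tree.depth(c.cluster_id) for c in res.clusters)
            if depths == [0, 1, 1, 2, 2] and not res.tree.forced_root:
                hits += 1
        assert hits >= 45

    def test_unplaceable_cluster_forced_to_root(self):
        clusters = [
            make_cluster("C0", {"s": 1.0, "t": 1.0}),
            make_cluster("C2", {"s": 0.7, "t": 0.4}),
            # overflows the root alongside C2 and cannot nest inside it
            make_cluster("C1", {"s": 0.85, "t": 0.0}),
        ]
        tree = cd.build_tree(clusters)
        assert tree.forced_root == {"C1"}
        tree.validate()  # forced nodes excluded from the sum-rule check


class TestComposition:
    def test_p04_peritoneal_60_40(self, p04_noiseless_clusters):
        tree = cd.build_tree(p04_noiseless_clusters)
        comp = cd.composition(tree, "peritoneal")
        assert comp.fractions["C1"] == pytest.approx(0.6)
        assert comp.fractions["C3"] == pytest.approx(0.4)
        assert comp.fractions["C0"] == pytest.approx(0.0)
        assert "C2" not in comp.fractions  # absent in this biopsy

    def test_p04_liver_single_clone(self, p04_noiseless_clusters):
        tree = cd.build_tree(p04_noiseless_clusters)
        comp = cd.composition(tree, "liver1")
        assert comp.fractions["C2"] == pytest.approx(1.0)

    def test_saturated_parent_has_zero_fraction(self):
        clusters = [
            make_cluster("C0", {"s": 1.0, "t": 1.0}),
            make_cluster("C1", {"s": 0.6, "t": 0.2}),
            make_cluster("C2", {"s": 0.4, "t": 0.8}),
        ]
        tree = cd.build_tree(clusters)
        comp = cd.composition(tree, "s")
        assert comp.fractions["C0"] == pytest.approx(0.0)
        assert comp.fractions["C1"] == pytest.approx(0.6)

    def test_fractions_sum_to_root_ccf(self, p04_noiseless_clusters):
        tree = cd.build_tree(p04_noiseless_clusters)
        for s in ("peritoneal", "liver1", "liver2"):
            total = sum(cd.composition(tree, s).fractions.values())
            assert total == pytest.approx(tree.ccf("C0", s), abs=0.1)


class TestBiopsyDistance:
    def frame(self, cols):
        return pd.DataFrame(cols)

    def test_identity(self):
        ccf = self.frame({"a": [1.0, 0.5, 0.0], "b": [1.0, 0.5, 0.0]})
        assert cd.biopsy_distance(ccf, "a", "b") == 0.0

    def test_normal_vs_fully_clonal_is_one(self):
        ccf = self.frame({"a": [1.0] * 20})
        assert cd.biopsy_distance(ccf, "normal", "a") == pytest.approx(1.0)

    def test_symmetry_and_triangle(self):
        rng = np.random.default_rng(4)
        ccf = self.frame({k: rng.uniform(0, 1, 50) for k in "abc"})
        dab = cd.biopsy_distance(ccf, "a", "b")
        assert dab == cd.biopsy_distance(ccf, "b", "a")
        assert dab <= cd.biopsy_distance(ccf, "a", "c") + cd.biopsy_distance(ccf, "c", "b") + 1e-12

    def test_empty_universe_rejected(self):
        with pytest.raises(InputError):
            cd.biopsy_distance(pd.DataFrame({"a": []}), "a", "normal")

    def test_p04_liver_lesions_closer_than_peritoneal(self, p04_matrix):
        """Longitudinal liver biopsies are far closer to each other than to
        the peritoneal metastasis."""
        dist = distance_matrix(p04_matrix.ccf)
        assert dist.loc["liver1", "liver2"] < dist.loc["liver1", "peritoneal"]
        assert dist.loc["normal", "peritoneal"] > 0


class TestNewick:
    def test_root_only(self):
        tree = cd.build_tree([make_cluster("C0", {"s": 1.0})])
        assert cd.to_newick(tree, branch_lengths=False) == "C0;"

    def test_p04_canonical_string(self, p04_noiseless_clusters):
        tree = cd.build_tree(p04_noiseless_clusters)
        assert cd.to_newick(tree, branch_lengths=False) == "((C3)C1,(C4)C2)C0;"

    def test_round_trip_topology(self, p04_noiseless_clusters):
        tree = cd.build_tree(p04_noiseless_clusters)
        parsed = dendropy.Tree.get(data=cd.to_newick(tree), schema="newick")
        edges = set()
        for node in parsed.preorder_node_iter():
            for child in node.child_nodes():
                edges.add((child.taxon.label if child.taxon else child.label,
                           node.taxon.label if node.taxon else node.label))
        assert edges == set(P04_EDGES)
        lengths = {
            (child.taxon.label if child.taxon else child.label): child.edge.length
            for node in parsed.preorder_node_iter()
            for child in node.child_nodes()
        }
        assert lengths["C3"] == 150  # branch length = private mutation count
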