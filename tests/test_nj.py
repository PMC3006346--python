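"""Neighbor-Joining construction, additivity recovery, newick, bootstrap."""

from __future__ import annotations

import io

import dendropy
import numpy as np
import pandas as pd
import pytest

import probmsc as pm
from conftest import make_table
from probmsc.njtree import nj


def _distances_from_random_tree(rng, labels):
    # agglomerate random clusters, tracking leaf->cluster-root distances
    clusters = [({l}, {l: 0.0}) for l in labels]
    splits: set[frozenset[str]] = set()
    dist = pd.DataFrame(0.0, index=labels, columns=labels)
    anchor = labels[0]
    n_total = len(labels)
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (sa, da), (sb, db) = clusters[i], clusters[j]
        la, lb = rng.uniform(0.05, 1.0, size=2)
        if len(clusters) == 2:
            la, lb = la, 0.0  # final join: single connecting edge
        for x, dx in da.items():
            for y, dy in db.items():
                d = dx + la + dy + lb
                dist.loc[x, y] = dist.loc[y, x] = d
        merged = sa | sb
        if 2 <= len(merged) <= n_total - 2:
            side = frozenset(merged) if anchor not in merged else frozenset(
                set(labels) - merged)
            splits.add(side)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((merged, {**{k: v + la for k, v in da.items()},
                                  **{k: v + lb for k, v in db.items()}}))
    return dist, splits


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        mat = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                           index=list("XYZ"), columns=list("XYZ"), dtype=float)
        tree = nj(mat)
        pl = tree.path_lengths()
        assert pl[frozenset("XY")] == pytest.approx(3.0)
        assert pl[frozenset("XZ")] == pytest.approx(4.0)
        assert pl[frozenset("YZ")] == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_recovery_from_additive_matrices(self, seed):
        """NJ is consistent: a matrix generated from a tree returns that tree,
        topology and path lengths both."""
        rng = np.random.default_rng(seed)
        labels = [f"T{i}" for i in range(rng.integers(5, 8))]
        dist, true_splits = _distances_from_random_tree(rng, labels)
        tree = nj(dist)
        assert tree.splits() == true_splits
        pl = tree.path_lengths()
        for x in labels:
            for y in labels:
                if x < y:
                    assert pl[frozenset((x, y))] == pytest.approx(
                        dist.loc[x, y], abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_topology_agrees_with_dendropy(self, seed):
        """Independent oracle: dendropy's NJ on noisy (non-additive) matrices
        must produce the same unrooted topology."""
        rng = np.random.default_rng(100 + seed)
        labels = [f"T{i}" for i in range(6)]
        dist, _ = _distances_from_random_tree(rng, labels)
        noisy = dist + rng.uniform(0, 0.02, size=dist.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy.values, 0.0)
        ours = nj(noisy)

        csv = "," + ",".join(labels) + "\n" + "\n".join(
            l + "," + ",".join(str(noisy.loc[l, m]) for m in labels) for l in labels)
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv))
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        anchor = min(labels)
        dsplits = set()
        for edge in dtree.preorder_edge_iter():
            if edge.head_node.is_leaf() or edge.head_node.parent_node is None:
                continue
            side = {t.taxon.label for t in edge.head_node.leaf_iter()}
            if 2 <= len(side) <= len(labels) - 2:
                dsplits.add(frozenset(side) if anchor not in side
                            else frozenset(set(labels) - side))
        assert ours.splits() == dsplits

    def test_newick_round_trips_through_dendropy(self, study_table):
        mat = pm.divergence_matrix(study_table, with_uncertainty=False).distance_frame()
        tree = nj(mat)
        newick = tree.newick()
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(tree.leaves())
        pdm = parsed.phylogenetic_distance_matrix()
        ours = tree.path_lengths()
        for t1 in pdm.taxon_iter():
            for t2 in pdm.taxon_iter():
                if t1.label < t2.label:
                    assert pdm.distance(t1, t2) == pytest.approx(
                        ours[frozenset((t1.label, t2.label))], rel=1e-4)

    def test_rejects_asymmetric_and_negative(self):
        bad = pd.DataFrame([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]],
                           index=list("abc"), columns=list("abc"), dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj(bad)
        neg = pd.DataFrame([[0, -1, 2], [-1, 0, 1], [2, 1, 0]],
                           index=list("abc"), columns=list("abc"), dtype=float)
        with pytest.raises(ValueError, match="non-negative"):
            nj(neg)

    def test_study_topology_recovered(self, study_table):
        """The normalized divergence matrix must yield (((S,F),(A,M)),O):
        canonical splits {S,F} and {S,F,O} (sides not containing the anchor
        leaf A)."""
        mat = pm.divergence_matrix(study_table, with_uncertainty=False).distance_frame()
        tree = nj(mat)
        assert tree.splits() == {frozenset({"S", "F"}), frozenset({"S", "F", "O"})}


class TestBootstrap:
    def test_unanimous_split_gets_full_support(self):
        rows = ([{"locus_id": f"L{i:03d}", "F": 2.0, "S": 2.0} for i in range(6)]
                + [{"locus_id": f"L{i:03d}", "A": 2.0, "M": 2.0} for i in range(6, 12)]
                + [{"locus_id": "L013", "S": 1.0, "A": 1.0},
                   {"locus_id": "L014", "F": 2.0, "S": 2.0, "A": 2.0, "M": 2.0}])
        table = make_table(rows)
        tree = pm.bootstrap_support(table, replicates=50, seed=0)
        supports = _collect_supports(tree)
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_support_is_binary(self, study_table):
        tree = pm.bootstrap_support(study_table, replicates=1, seed=3)
        assert set(_collect_supports(tree)) <= {0.0, 100.0}

    def test_sister_edges_majority_supported(self, study_table):
        """At the fitted demographic parameters both sister pairs must be
        recovered in the majority of bootstrap replicates."""
        tree = pm.bootstrap_support(study_table, replicates=200, seed=5)
        support = _support_by_split(tree)
        assert support[frozenset({"S", "F"})] > 50.0       # forest+savanna edge
        assert support[frozenset({"S", "F", "O"})] > 50.0  # Asian+mammoth edge


def _collect_supports(tree: pm.PhyloTree) -> list[float]:
    out = []

    def walk(node):
        if node.support is not None:
            out.append(node.support)
        for c in node.children:
            walk(c)

    walk(tree.root)
    return out


def _support_by_split(tree: pm.PhyloTree) -> dict[frozenset[str], float]:
    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)
    result = {}

    def walk(node):
        below = frozenset([node.name]) if node.is_leaf else frozenset().union(
            *(walk(c) for c in node.children))
        if node.support is not None and not node.is_leaf and node is not tree.root:
            side = all_leaves - below if anchor in below else below
            result[side] = node.support
        return below

    walk(tree.root)
    return result
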