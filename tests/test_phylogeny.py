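"""Distances, neighbor-joining, bootstrap and monophyly."""

import math

import dendropy
import numpy as np
import pytest

from markereval.alignment import Alignment, StrainEntry, StrainTable
from markereval.phylogeny import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    distance_matrix,
    jc69_distance,
    k2p_distance,
    newick_string,
    nj_tree,
    p_distance,
    read_newick,
    species_cluster_report,
    write_newick,
)

from oracles import (
    additive_matrix,
    all_topologies,
    ls_fit_sse,
    random_topology,
    topology_bipartitions,
)


def _table(mapping, types=()):
    return StrainTable(
        {sid: StrainEntry(sp, is_type_strain=sid in types) for sid, sp in mapping.items()}
    )


class TestDistances:
    def test_identical_sequences_are_zero(self):
        s = "ACGTACGTAC" * 5
        assert k2p_distance(s, s) == 0.0
        assert jc69_distance(s, s) == 0.0
        assert p_distance(s, s) == 0.0

    def test_k2p_closed_form(self):
        # 10 transitions + 5 transversions over 100 sites: P=0.1, Q=0.05
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        expected = -0.5 * math.log(0.75 * math.sqrt(0.9))
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.1702, abs=5e-5)

    def test_k2p_without_transversions_reduces(self):
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(1 - 0.2))

    def test_saturation_flagged(self):
        with pytest.raises(ValueError, match="saturated"):
            k2p_distance("AC" * 20, "CA" * 20)

    def test_correction_ordering(self):
        rng = np.random.default_rng(2)
        bases = "ACGT"
        a = "".join(rng.choice(list(bases), 500))
        b = list(a)
        for i in rng.choice(500, size=60, replace=False):
            b[i] = bases[(bases.index(b[i]) + int(rng.integers(1, 4))) % 4]
        b = "".join(b)
        p = p_distance(a, b)
        assert jc69_distance(a, b) >= p

    def test_corrections_agree_to_first_order(self):
        # at p <= 0.01 both corrections are within 5% of the p-distance
        a = "ACGT" * 250
        b = "GCGT" + "ACGT" * 249  # 1 transition in 1000 sites
        p = p_distance(a, b)
        assert p == 0.001
        assert jc69_distance(a, b) == pytest.approx(p, rel=0.05)
        assert k2p_distance(a, b) == pytest.approx(p, rel=0.05)

    def test_matrix_matches_pairwise_function(self):
        rng = np.random.default_rng(8)
        rows = ["".join(rng.choice(list("ACGT-"), 80)) for _ in range(5)]
        aln = Alignment([(f"s{i}", r) for i, r in enumerate(rows)])
        dm = distance_matrix(aln, model="k2p")
        for i in range(5):
            for j in range(i + 1, 5):
                try:
                    expected = k2p_distance(rows[i], rows[j])
                except ValueError:       # saturated pair → flagged, not raised
                    assert np.isnan(dm.d[i, j])
                else:
                    assert dm.d[i, j] == pytest.approx(expected)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids, d, "p"))
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive_recovery(self):
        # ((a:1,b:2):1,(c:3,d:1)) → d_ab=3 d_ac=5 d_ad=3 d_bc=6 d_bd=4 d_cd=4
        ids = ["a", "b", "c", "d"]
        D = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(ids, D, "p"))
        assert bipartitions(tree) == {frozenset({"c", "d"})}
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i < j:
                    assert pdm.patristic_distance(taxa[x], taxa[y]) == pytest.approx(D[i, j])

    def test_tie_break_is_deterministic(self):
        ids = ["a", "b", "c", "d"]
        D = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(DistanceMatrix(ids, D.copy(), "p"))
        t2 = nj_tree(DistanceMatrix(ids, D.copy(), "p"))
        assert newick_string(t1) == newick_string(t2)
        # lowest index pair joined first under total ties
        assert bipartitions(t1) == {frozenset({"c", "d"})}

    def test_negative_branch_clamped_with_warning(self):
        ids = ["a", "b", "c", "d"]
        D = np.array(
            [[0, 0.1, 1, 1], [0.1, 0, 1, 0.3], [1, 1, 0, 1], [1, 0.3, 1, 0]]
        )
        with pytest.warns(UserWarning, match="clamped"):
            tree = nj_tree(DistanceMatrix(ids, D, "p"))
        for node in tree.preorder_node_iter():
            if node.edge.length is not None:
                assert node.edge.length >= 0

    def test_undefined_distance_rejected(self):
        D = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError, match=r"\('a', 'b'\)"):
            nj_tree(DistanceMatrix(["a", "b", "c"], D, "k2p"))

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        edges = random_topology(n, rng)
        lengths = {e: rng.uniform(0.1, 1.0) for e in range(len(edges))}
        D = additive_matrix(edges, lengths, n)
        ids = [f"t{i}" for i in range(n)]
        tree = nj_tree(DistanceMatrix(ids, D, "p"))
        assert bipartitions(tree) == topology_bipartitions(edges, n, ids)

    def test_agrees_with_dendropy_nj(self):
        rng = np.random.default_rng(42)
        n = 7
        edges = random_topology(n, rng)
        lengths = {e: rng.uniform(0.1, 1.0) for e in range(len(edges))}
        D = additive_matrix(edges, lengths, n)
        ids = [f"t{i}" for i in range(n)]
        mine = nj_tree(DistanceMatrix(ids, D, "p"))
        csv = "," + ",".join(ids) + "\n"
        for i in range(n):
            csv += ids[i] + "," + ",".join(str(D[i, j]) for j in range(n)) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv))
        ref = pdm.nj_tree()
        ref_bips = bipartitions(ref)
        assert bipartitions(mine) == ref_bips


class TestBootstrap:
    def _congruent_alignment(self):
        # two 20-column blocks, both supporting abc | def
        a = "A" * 20 + "C" * 20
        b = "G" * 20 + "T" * 20
        return Alignment(
            [("a", a), ("b", a), ("c", a), ("d", b), ("e", b), ("f", b)]
        )

    def test_congruent_signal_gives_full_support(self):
        tree = bootstrap_support(self._congruent_alignment(), model="p", B=100, seed=1)
        supports = [
            float(n.label)
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.label is not None
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_are_binary(self):
        aln = _random_alignment(seed=3)
        tree = bootstrap_support(aln, model="p", B=1, seed=9)
        supports = {
            float(n.label)
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.label is not None
        }
        assert supports <= {0.0, 100.0}

    def test_fixed_seed_reproducible(self):
        aln = _random_alignment(seed=5)
        t1 = bootstrap_support(aln, B=30, seed=11)
        t2 = bootstrap_support(aln, B=30, seed=11)
        assert newick_string(t1) == newick_string(t2)

    def test_leaf_order_permutation_invariance(self):
        aln = _random_alignment(seed=6)
        perm = Alignment(list(reversed(aln.records)))
        s1 = _support_map(bootstrap_support(aln, B=25, seed=4))
        s2 = _support_map(bootstrap_support(perm, B=25, seed=4))
        assert s1 == s2


def _random_alignment(seed, n=6, L=120):
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, L)
    rows = []
    for i in range(n):
        seq = root.copy()
        idx = rng.choice(L, size=12 + 3 * i, replace=False)
        seq[idx] = (seq[idx] + rng.integers(1, 4, idx.size)) % 4
        rows.append("".join("ACGT"[c] for c in seq))
    return Alignment([(f"s{i}", r) for i, r in enumerate(rows)])


def _support_map(tree):
    from markereval.phylogeny import leaf_labels, node_support

    leaves = leaf_labels(tree)
    ref = min(leaves)
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out[side] = node_support(node)
    return out


class TestMonophyly:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_clean_clusters(self):
        tree = self._tree("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        rep = species_cluster_report(
            tree, _table({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        )
        assert rep["A"].is_monophyletic and rep["B"].is_monophyletic
        assert rep["A"].outliers == () and rep["B"].outliers == ()

    def test_interleaved_clusters(self):
        tree = self._tree("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        rep = species_cluster_report(
            tree, _table({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        )
        assert not rep["A"].is_monophyletic and not rep["B"].is_monophyletic
        assert len(rep["A"].outliers) == 1 and len(rep["B"].outliers) == 1

    def test_outlier_inside_other_cluster(self):
        tree = self._tree("(((a1:1,a2:1):1,(b1:1,x:1):1):1,(c1:1,c2:1):1);")
        rep = species_cluster_report(
            tree,
            _table(
                {"a1": "A", "a2": "A", "b1": "B", "x": "A", "c1": "C", "c2": "C"},
                types={"a1", "b1", "c1"},
            ),
        )
        assert not rep["A"].is_monophyletic
        assert rep["A"].outliers == ("x",)
        assert rep["B"].is_monophyletic is None  # single labeled strain

    def test_type_strain_anchors_tied_cores(self):
        # species D is split 1-vs-1; the core must keep the type strain
        tree = self._tree("(((d1:1,a1:1):1,(d2:1,a2:1):1):1,(b1:1,b2:1):1);")
        rep = species_cluster_report(
            tree,
            _table(
                {"d1": "D", "d2": "D", "a1": "A", "a2": "A", "b1": "B", "b2": "B"},
                types={"d1", "a1", "b1"},
            ),
        )
        assert rep["D"].outliers == ("d2",)

    def test_unassigned_leaves_do_not_break_monophyly(self):
        tree = self._tree("(((a1:1,u1:1):1,a2:1):1,(b1:1,b2:1):1);")
        rep = species_cluster_report(
            tree,
            _table({"a1": "A", "a2": "A", "u1": "unassigned", "b1": "B", "b2": "B"}),
        )
        assert rep["A"].is_monophyletic


class TestNewickIO:
    def test_roundtrip_topology_lengths_supports(self, tmp_path):
        aln = _random_alignment(seed=13)
        tree = bootstrap_support(aln, B=20, seed=2)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert bipartitions(back) == bipartitions(tree)
        assert _support_map(back) == _support_map(tree)
        pdm_a = {

            frozenset((t1.label, t2.label)): d
            for t1, t2, d in _pairwise_patristic(tree)
        }
        pdm_b = {
            frozenset((t1.label, t2.label)): d
            for t1, t2, d in _pairwise_patristic(back)
        }
        for key, d in pdm_a.items():
            assert pdm_b[key] == pytest.approx(d, abs=1e-6)

    def test_three_leaf_star(self, tmp_path):
        ids = ["a", "b", "c"]
        D = np.full((3, 3), 2.0) - 2.0 * np.eye(3)
        tree = nj_tree(DistanceMatrix(ids, D, "p"))
        s = newick_string(tree)
        assert s.count("(") == 1  # one central node, three pendant edges
        for label in ids:
            assert label in s


def _pairwise_patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            yield t1, t2, pdm.patristic_distance(t1, t2)


class TestLeastSquaresOracle:
    def test_generating_topology_is_ls_optimum(self):
        # exhaustive check on a 6-taxon additive matrix: only the generating
        # topology fits with zero residual
        rng = np.random.default_rng(0)
        n = 6
        edges = random_topology(n, rng)
        lengths = {e: rng.uniform(0.2, 1.0) for e in range(len(edges))}
        D = additive_matrix(edges, lengths, n)
        truth = topology_bipartitions(edges, n)
        best = None
        for cand in all_topologies(n):
            sse = ls_fit_sse(cand, n, D)
            key = topology_bipartitions(cand, n)
            if best is None or sse < best[0]:
                best = (sse, key)
        assert best[0] == pytest.approx(0.0, abs=1e-18)
        assert best[1] == truth
        ids = [str(i) for i in range(n)]
        tree = nj_tree(DistanceMatrix(ids, D, "p"))
        assert bipartitions(tree) == topology_bipartitions(edges, n, ids)
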