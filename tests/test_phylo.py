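import math

import dendropy
import numpy as np
import pytest

from g4therm.phylo import (
    SaturationError,
    bootstrap_support,
    distance_matrix,
    k2p_distance,
    leaf_bipartitions,
    midpoint_root,
    newick_string,
    nj_tree,
    parse_newick,
    read_newick,
    write_newick,
)
from g4therm.phylo import DistanceMatrix

from conftest import make_alignment


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGTACGTAC", "ACGTACGTAC") == 0.0

    def test_single_transition(self):
        # A<->G at one of 10 sites: P = 0.1, Q = 0
        d = k2p_distance("AAAAAAAAAA", "GAAAAAAAAA")
        assert d == pytest.approx(-0.5 * math.log(0.8), abs=1e-9)

    def test_single_transversion(self):
        d = k2p_distance("AAAAAAAAAA", "TAAAAAAAAA")
        assert d == pytest.approx(
            -0.5 * math.log(0.9) - 0.25 * math.log(0.8), abs=1e-9
        )

    def test_saturation_errors(self):
        with pytest.raises(SaturationError, match="saturation"):
            k2p_distance("AAAA", "GGGG")

    def test_saturation_cap_substitutes(self):
        assert k2p_distance("AAAA", "GGGG", cap=5.0) == 5.0

    def test_pairwise_deletion_of_gaps_and_n(self):
        # usable sites: positions 2-9 minus the N site -> 8 sites, 0 diffs
        a = "-CGTACGTAN"
        b = "ACGTACGTAC"
        assert k2p_distance(a, b) == 0.0

    def test_zero_usable_sites_errors(self):
        with pytest.raises(ValueError, match="usable"):
            k2p_distance("--NN", "AC--")

    def test_symmetric(self):
        a, b = "ACGTACGTAA", "ACGTACGTGG"
        assert k2p_distance(a, b) == k2p_distance(b, a)


class TestDistanceMatrix:
    def test_identical_records_zero_matrix(self):
        aln = make_alignment({"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"})
        dm = distance_matrix(aln)
        assert np.allclose(dm.values, 0.0)

    def test_hand_counted_pair(self):
        # a-b: one transition in 8; a-c: one transversion in 8
        aln = make_alignment({"a": "ACGTACGT", "b": "GCGTACGT", "c": "TCGTACGT"})
        dm = distance_matrix(aln).as_dataframe()
        assert dm.loc["a", "b"] == pytest.approx(-0.5 * math.log(1 - 0.25))
        assert dm.loc["a", "c"] == pytest.approx(
            -0.5 * math.log(1 - 0.125) - 0.25 * math.log(1 - 0.25)
        )

    def test_relabeling_invariance(self):
        rows = {"a": "ACGTACGT", "b": "GCGTACGT", "c": "TCGTACGT"}
        d1 = distance_matrix(make_alignment(rows)).as_dataframe()
        rows2 = {k: rows[k] for k in ["c", "a", "b"]}
        d2 = distance_matrix(make_alignment(rows2)).as_dataframe()
        assert np.allclose(d1.loc[["a", "b", "c"], ["a", "b", "c"]],
                           d2.loc[["a", "b", "c"], ["a", "b", "c"]])

    def test_needs_three_records(self):
        with pytest.raises(ValueError):
            distance_matrix(make_alignment({"a": "ACGT", "b": "ACGT"}))


# ---------------------------------------------------------------------------
# independent additive-tree oracle: random rooted binary (child, length)
# tuples; path distances by recursive leaf-depth accumulation
# ---------------------------------------------------------------------------


def random_tuple_tree(rng, n_leaves):
    nodes = [(f"t{i}",) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append((left, float(rng.uniform(0.05, 1.0)),
                      right, float(rng.uniform(0.05, 1.0))))
    return nodes[0]


def tuple_leaf_depths(node):
    if len(node) == 1:
        return {node[0]: 0.0}
    left, bl, right, br = node
    out = {}
    for leaf, d in tuple_leaf_depths(left).items():
        out[leaf] = d + bl
    for leaf, d in tuple_leaf_depths(right).items():
        out[leaf] = d + br
    return out


def tuple_path_matrix(node):
    """Leaf-to-leaf path-length matrix by summing depths below each MRCA."""
    if len(node) == 1:
        return {}, {node[0]: 0.0}
    left, bl, right, br = node
    dl, depths_l = tuple_path_matrix(left)
    dr, depths_r = tuple_path_matrix(right)
    depths_l = {k: v + bl for k, v in depths_l.items()}
    depths_r = {k: v + br for k, v in depths_r.items()}
    dists = dict(dl)
    dists.update(dr)
    for a, da in depths_l.items():
        for b, db in depths_r.items():
            dists[frozenset((a, b))] = da + db
    depths = {**depths_l, **depths_r}
    return dists, depths


def tuple_bipartitions(node, all_leaves):
    anchor = min(all_leaves)
    out = set()

    def leafset(nd):
        if len(nd) == 1:
            return frozenset([nd[0]])
        ls = leafset(nd[0]) | leafset(nd[2])
        if 2 <= len(ls) <= len(all_leaves) - 2:
            out.add(ls if anchor not in ls else all_leaves - ls)
        return ls

    leafset(node)
    return out


def dendropy_patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    return {
        frozenset((a.label, b.label)): pdm.patristic_distance(a, b)
        for i, a in enumerate(taxa)
        for b in taxa[i + 1 :]
    }


class TestNJ:
    def test_three_taxon_branch_lengths(self):
        dm = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
        )
        tree = nj_tree(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_recovers_additive_trees_exactly(self, rng):
        for rep in range(40):
            n = int(rng.integers(5, 9))
            tt = random_tuple_tree(rng, n)
            dists, _ = tuple_path_matrix(tt)
            labels = tuple(sorted({x for k in dists for x in k}))
            D = np.zeros((n, n))
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i != j:
                        D[i, j] = dists[frozenset((a, b))]
            tree = nj_tree(DistanceMatrix(labels, D))
            got = dendropy_patristic(tree)
            for key, want in dists.items():
                assert got[key] == pytest.approx(want, abs=1e-9)
            assert leaf_bipartitions(tree).keys() == tuple_bipartitions(
                tt, frozenset(labels)
            )

    def test_equidistant_four_taxa_zero_internal(self):
        D = np.full((4, 4), 0.5)
        np.fill_diagonal(D, 0.0)
        tree = nj_tree(DistanceMatrix(("A", "B", "C", "D"), D))
        internal = [
            nd.edge.length
            for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd is not tree.seed_node
        ]
        assert internal == pytest.approx([0.0])
        # deterministic tie-break: first pair (A, B) joined
        bip = leaf_bipartitions(tree)
        assert frozenset({"C", "D"}) in bip

    def test_matches_dendropy_nj_topology(self, rng):
        n = 8
        tt = random_tuple_tree(rng, n)
        dists, _ = tuple_path_matrix(tt)
        labels = sorted({x for k in dists for x in k})
        csv = "," + ",".join(labels) + "\n"
        for a in labels:
            row = [a]
            for b in labels:
                row.append("0" if a == b else str(dists[frozenset((a, b))]))
            csv += ",".join(row) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=io.StringIO(csv))
        ref = pdm.nj_tree()
        ref.is_rooted = False
        ref_bips = leaf_bipartitions(ref)
        ours = leaf_bipartitions(nj_tree(distancematrix_from(labels, dists)))
        assert ours.keys() == ref_bips.keys()

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("A", "B"), np.zeros((2, 2))))


def distancematrix_from(labels, dists):
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                D[i, j] = dists[frozenset((a, b))]
    return DistanceMatrix(tuple(labels), D)


class TestBootstrap:
    def _clade_alignment(self, rng, n_per_clade=4, length=300):
        """Two strongly divergent clades -> near-certain clade support."""
        base1 = "".join(rng.choice(list("ACGT"), length))
        base2 = _mutate(base1, rng, 60)  # 20% between-clade divergence
        rows = {}
        for k in range(n_per_clade):
            rows[f"a{k}"] = _mutate(base1, rng, 5)
            rows[f"b{k}"] = _mutate(base2, rng, 5)
        return make_alignment(rows)

    def test_strong_clade_high_support(self, rng):
        aln = self._clade_alignment(rng)
        tree = bootstrap_support(aln, B=100, seed=1)
        clade = frozenset(f"b{k}" for k in range(4))
        assert tree.bipartition_supports[clade] >= 0.95
        assert all(0 <= s <= 1 for s in tree.bipartition_supports.values())

    def test_fixed_seed_reproducible(self, rng):
        aln = self._clade_alignment(rng)
        t1 = bootstrap_support(aln, B=50, seed=7)
        t2 = bootstrap_support(aln, B=50, seed=7)
        assert newick_string(t1) == newick_string(t2)
        assert t1.bipartition_supports == t2.bipartition_supports

    def test_identical_sequences_no_resolved_bipartitions(self):
        aln = make_alignment({f"s{i}": "ACGTACGTAC" for i in range(4)})
        tree = bootstrap_support(aln, B=10, seed=0)
        assert tree.bipartition_supports == {}


def _mutate(s, rng, k):
    chars = list(s)
    for pos in rng.choice(len(chars), k, replace=False):
        chars[pos] = "ACGT"[int(rng.integers(4))]
    return "".join(chars)


class TestNewick:
    def test_parse_depths(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        tree.is_rooted = True
        depths = {}
        for leaf in tree.leaf_node_iter():
            d, nd = 0.0, leaf
            while nd.parent_node is not None:
                d += nd.edge.length
                nd = nd.parent_node
            depths[leaf.taxon.label] = d
        assert depths == {"A": 2.0, "B": 2.0, "C": 2.0}

    def test_round_trip(self, tmp_path):
        text = "((A:1.5,B:0.5):1.0,C:2.0,D:0.25);"
        p = tmp_path / "t.nwk"
        p.write_text(text + "\n")
        tree = read_newick(p)
        out = tmp_path / "o.nwk"
        write_newick(tree, out)
        assert newick_string(read_newick(out)) == newick_string(tree)

    def test_malformed_errors(self):
        with pytest.raises(ValueError, match="parse"):
            parse_newick("((A:1,B:1;")

    def test_missing_branch_length_defaults_zero(self):
        tree = parse_newick("((A,B:1):1,C:2);")
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["A"] == 0.0


def test_midpoint_root_sets_rooted_flag():
    tree = nj_tree(
        DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
        )
    )
    rooted = midpoint_root(tree)
    assert rooted.is_rooted and not tree.is_rooted
    assert len(rooted.seed_node.child_nodes()) == 2
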