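"""K2P distances, NJ reconstruction and bootstrap supports."""

from __future__ import annotations

import io as _io
import math

import dendropy
import numpy as np
import pytest

from mhclones import phylo
from mhclones.diversity import SiteAlignment

from conftest import mutate, random_seq


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random unrooted binary tree with positive lengths; returns
    (taxa, distance matrix, set of non-trivial bipartitions)."""
    def blen():
        return float(rng.uniform(0.1, 1.0))

    edges: dict[tuple[int, int], float] = {}
    next_id = n_leaves
    center = next_id
    next_id += 1
    for leaf in range(3):
        edges[(leaf, center)] = blen()
    for leaf in range(3, n_leaves):
        u, v = list(edges)[rng.integers(0, len(edges))]
        length = edges.pop((u, v))
        w = next_id
        next_id += 1
        split = float(rng.uniform(0.2, 0.8))
        edges[(u, w)] = length * split
        edges[(v, w)] = length * (1 - split)
        edges[(leaf, w)] = blen()

    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), ln in edges.items():
        adj.setdefault(u, []).append((v, ln))
        adj.setdefault(v, []).append((u, ln))

    def dists_from(src: int) -> dict[int, float]:
        out = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, ln in adj[node]:
                if nb not in out:
                    out[nb] = out[node] + ln
                    stack.append(nb)
        return out

    taxa = tuple(f"T{i}" for i in range(n_leaves))
    mat = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        d = dists_from(i)
        for j in range(n_leaves):
            mat[i, j] = d[j]

    ref = "T0"
    all_set = frozenset(taxa)
    bips = set()
    for (u, v), _ in edges.items():
        adj[u] = [(nb, ln) for nb, ln in adj[u] if nb != v]
        side = {f"T{k}" for k in dists_from(u) if k < n_leaves}
        adj[u].append((v, edges[(u, v)]))
        if ref in side:
            side = set(all_set) - side
        if 1 < len(side) < n_leaves - 1:
            bips.add(frozenset(side))
    return taxa, mat, bips


class TestK2P:
    def test_identical_sequences_zero(self):
        d = phylo.k2p_distance("ACGT" * 25, "ACGT" * 25)
        assert (d.p, d.q, d.d) == (0.0, 0.0, 0.0)

    def test_closed_form_value(self):
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85  # 10 transitions, 5 transversions
        d = phylo.k2p_distance(a, b)
        assert (d.p, d.q) == (0.10, 0.05)
        expected = -0.5 * math.log(1 - 2 * 0.10 - 0.05) - 0.25 * math.log(1 - 2 * 0.05)
        assert d.d == pytest.approx(expected)
        assert d.d == pytest.approx(0.17018, abs=5e-6)

    def test_distance_at_least_observed_divergence(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a = random_seq(rng, 300)
            k = int(rng.integers(1, 45))
            b = mutate(a, rng.choice(300, size=k, replace=False), rng)
            d = phylo.k2p_distance(a, b)
            assert d.d >= d.p + d.q - 1e-12

    def test_saturation_raises_naming_pair(self):
        with pytest.raises(phylo.SaturationError, match="x1.*x2"):
            phylo.k2p_distance("AAAA", "CCCC", names=("x1", "x2"))

    def test_jukes_cantor_limit_when_transversions_double_transitions(self):
        # q = 2p makes the two K2P rate classes equal, so the distance
        # collapses to the one-parameter correction of D = p + q
        a = "A" * 300
        b = "G" * 20 + "C" * 20 + "T" * 20 + "A" * 240  # p=20/300, q=40/300
        d = phylo.k2p_distance(a, b)
        big_d = d.p + d.q
        jc = -0.75 * math.log(1 - 4 * big_d / 3)
        assert d.q == pytest.approx(2 * d.p)
        assert d.d == pytest.approx(jc, abs=1e-12)

    def test_pairwise_deletion_of_ambiguous_sites(self):
        d = phylo.k2p_distance("ACGN", "ACGT")
        assert d.d == 0.0


class TestNJ:
    def test_four_taxon_additive_matrix_recovered(self):
        taxa = ("A", "B", "C", "D")
        mat = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = phylo.build_nj(phylo.DistanceMatrix(taxa, mat))
        assert phylo.bipartitions(tree) == {frozenset({"C", "D"})}
        pdm = tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    assert pdm.patristic_distance(tax[a], tax[b]) == pytest.approx(mat[i, j])

    def test_three_taxa_closed_form(self):
        mat = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = phylo.build_nj(phylo.DistanceMatrix(("A", "B", "C"), mat))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_random_additive_trees_recovered_exactly(self, n_leaves):
        for seed in range(10):
            rng = np.random.default_rng(1000 * n_leaves + seed)
            taxa, mat, bips = random_additive_tree(rng, n_leaves)
            tree = phylo.build_nj(phylo.DistanceMatrix(taxa, mat))
            assert phylo.bipartitions(tree) == bips
            pdm = tree.phylogenetic_distance_matrix()
            tax = {t.label: t for t in tree.taxon_namespace}
            for i in range(n_leaves):
                for j in range(i + 1, n_leaves):
                    assert pdm.patristic_distance(tax[taxa[i]], tax[taxa[j]]) == pytest.approx(
                        mat[i, j], abs=1e-9
                    )

    def test_agrees_with_dendropy_nj_topology(self):
        rng = np.random.default_rng(5)
        taxa, mat, _ = random_additive_tree(rng, 6)
        tree = phylo.build_nj(phylo.DistanceMatrix(taxa, mat))
        csv = "," + ",".join(taxa) + "\n"
        for i, t in enumerate(taxa):
            csv += t + "," + ",".join(f"{mat[i, j]:.10f}" for j in range(len(taxa))) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            _io.StringIO(csv), delimiter=","
        )
        other = pdm.nj_tree()
        assert phylo.bipartitions(tree) == phylo.bipartitions(other)

    def test_tie_breaking_is_deterministic(self):
        mat = np.ones((5, 5)) - np.eye(5)
        taxa = tuple("ABCDE")
        t1 = phylo.build_nj(phylo.DistanceMatrix(taxa, mat.copy()))
        t2 = phylo.build_nj(phylo.DistanceMatrix(taxa, mat.copy()))
        assert phylo.write_newick(t1) == phylo.write_newick(t2)

    def test_asymmetric_matrix_rejected(self):
        mat = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            phylo.DistanceMatrix(("A", "B", "C"), mat)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="at least 3"):
            phylo.build_nj(phylo.DistanceMatrix(("A", "B"), np.zeros((2, 2))))


def _two_clade_alignment(rng, n_diag=100):
    """Four taxa in two clades separated by many diagnostic transition sites."""
    base = random_seq(rng, 400)
    clade2 = mutate(base, range(0, n_diag), rng)
    a = base
    b = mutate(base, [390], rng)
    c = clade2
    d = mutate(clade2, [395], rng)
    return SiteAlignment.from_sequences(["A", "B", "C", "D"], [a, b, c, d], exon_boundary=200)


class TestBootstrap:
    def test_well_separated_clades_get_high_support(self):
        aln = _two_clade_alignment(np.random.default_rng(1))
        tree = phylo.bootstrap_support(aln, n_reps=200, seed=0)
        internal = [nd.label for nd in tree.preorder_node_iter()
                    if not nd.is_leaf() and nd.parent_node is not None and nd.label]
        assert internal and float(internal[0]) >= 99

    def test_zero_reps_returns_plain_tree(self):
        aln = _two_clade_alignment(np.random.default_rng(2))
        tree = phylo.bootstrap_support(aln, n_reps=0, seed=0)
        labels = [nd.label for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        assert all(lb is None for lb in labels)

    def test_seed_reproducibility(self):
        aln = _two_clade_alignment(np.random.default_rng(3))
        t1 = phylo.bootstrap_support(aln, n_reps=100, seed=42)
        t2 = phylo.bootstrap_support(aln, n_reps=100, seed=42)
        assert phylo.write_newick(t1) == phylo.write_newick(t2)

    def test_weak_branches_collapse_to_polytomy(self):
        # two taxa at negligible divergence inside one clade: the internal
        # branch separating them has ~no signal and must collapse
        rng = np.random.default_rng(4)
        base = random_seq(rng, 300)
        far = mutate(base, range(0, 60), rng)
        seqs = {"A": base, "B": base, "C": base, "D": far}
        aln = SiteAlignment.from_sequences(list(seqs), list(seqs.values()), exon_boundary=150)
        tree = phylo.bootstrap_support(aln, n_reps=100, seed=0, collapse_threshold=50)
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and node.parent_node is not None and node.label:
                assert float(node.label) > 50


class TestNewick:
    def test_three_taxon_shape(self):
        mat = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = phylo.build_nj(phylo.DistanceMatrix(("A", "B", "C"), mat))
        nwk = phylo.write_newick(tree)
        assert nwk.startswith("(") and nwk.rstrip().endswith(";")
        assert {"A", "B", "C"} <= set(nwk.replace("(", " ").replace(",", " ").replace(":", " ").split())

    def test_round_trip_preserves_bipartitions(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            taxa, mat, _ = random_additive_tree(rng, 7)
            tree = phylo.build_nj(phylo.DistanceMatrix(taxa, mat))
            back = phylo.read_newick(phylo.write_newick(tree))
            assert phylo.bipartitions(back) == phylo.bipartitions(tree)

    def test_full_polytomy_written_validly(self):
        aln = _two_clade_alignment(np.random.default_rng(6), n_diag=2)
        tree = phylo.bootstrap_support(aln, n_reps=50, seed=0, collapse_threshold=100)
        nwk = phylo.write_newick(tree)
        back = phylo.read_newick(nwk)
        assert sorted(lf.taxon.label for lf in back.leaf_node_iter()) == ["A", "B", "C", "D"]
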