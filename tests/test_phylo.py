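"""Progressive alignment, Poisson distances, NJ and bootstrap."""

import math

import numpy as np
import pytest

from ltrkit import (
    DistanceMatrix,
    MultipleAlignment,
    ValidationError,
    align_progressive,
    bootstrap_support,
    neighbor_joining,
    poisson_distance,
)
from ltrkit.phylo import Node, PhyloTree

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_peptide(rng, n):
    return "".join(AA[i] for i in rng.integers(0, 20, n))


def _mutate(rng, pep, rate):
    chars = list(pep)
    n = int(round(rate * len(chars)))
    for p in rng.choice(len(chars), size=n, replace=False):
        chars[p] = AA[int(rng.integers(0, 20))]
    return "".join(chars)


class TestAlignProgressive:
    def test_identical_pair_has_no_gaps(self):
        aln = align_progressive([("a", "MKVLAW"), ("b", "MKVLAW")])
        assert aln.rows == ("MKVLAW", "MKVLAW")

    def test_single_deletion_creates_one_gap_column(self):
        aln = align_progressive([("a", "ACDEFG"), ("b", "ACEFG")])
        assert aln.n_cols == 6
        assert sorted(aln.rows) == ["AC-EFG", "ACDEFG"]

    def test_degapping_recovers_inputs(self, panel):
        peps = [(e.id, e.peptide[:80]) for e in panel.entries if e.domain == "RT"][:5]
        aln = align_progressive(peps)
        for name, seq in peps:
            assert aln.degap(name) == seq

    def test_single_sequence_rejected(self):
        with pytest.raises(ValidationError):
            align_progressive([("a", "MKVLAW")])


class TestPoissonDistance:
    def test_identical_rows_are_zero(self):
        dm = poisson_distance(MultipleAlignment(("a", "b"), ("MKVL", "MKVL")))
        assert dm.matrix[0, 1] == 0.0

    def test_closed_form_quarter_difference(self):
        dm = poisson_distance(MultipleAlignment(("a", "b"), ("AAAA", "AAAT")))
        assert dm.matrix[0, 1] == pytest.approx(-math.log(0.75), abs=1e-12)

    def test_closed_form_half_difference(self):
        dm = poisson_distance(MultipleAlignment(("a", "b"), ("AARR", "AAKE")))
        assert dm.matrix[0, 1] == pytest.approx(math.log(2.0), abs=1e-12)

    def test_pairwise_deletion_ignores_gap_sites(self):
        dm = poisson_distance(MultipleAlignment(("a", "b"), ("AA--AA", "AAKKAT")))
        # shared sites: 4 ungapped columns, 1 mismatch
        assert dm.matrix[0, 1] == pytest.approx(-math.log(0.75), abs=1e-12)

    def test_disjoint_rows_error_names_pair(self):
        with pytest.raises(ValidationError, match="a.*b"):
            poisson_distance(MultipleAlignment(("a", "b"), ("AA--", "--KK")))

    def test_saturation_clamped(self):
        dm = poisson_distance(
            MultipleAlignment(("a", "b"), ("ACDEFGHIKLMNPQRSTVWY", "CDEFGHIKLMNPQRSTVWYA"))
        )
        assert dm.matrix[0, 1] == pytest.approx(-math.log(1 - 0.95))

    def test_monotone_and_bounded_below_by_p(self):
        ps = np.linspace(0.0, 0.9, 10)
        ds = [-math.log(1 - p) for p in ps]
        assert all(d >= p for d, p in zip(ds, ps))
        assert ds == sorted(ds)


def _random_additive_tree(rng, n_taxa):
    """Random binary unrooted tree with branch lengths; returns its
    patristic distance matrix."""
    names = [f"t{i}" for i in range(n_taxa)]
    # start with a star of 3, attach remaining taxa onto random edges
    dist = {frozenset((a, b)): 0.0 for a in names for b in names if a != b}
    # simpler: simulate by random sequence of joins (coalescent-like),
    # tracking leaf-to-all distances
    clusters = {name: [name] for name in names}
    below: dict[str, dict[str, float]] = {name: {name: 0.0} for name in names}
    d = {}
    items = sorted(clusters)
    while len(items) > 2:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        a, b = items[i], items[j]
        la, lb = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        for x, dx in below[a].items():
            for y, dy in below[b].items():
                d[frozenset((x, y))] = dx + la + dy + lb
        merged = {x: dx + la for x, dx in below[a].items()}
        merged.update({y: dy + lb for y, dy in below[b].items()})
        new = min(a, b)
        other = max(a, b)
        del below[a], below[b]
        below[new] = merged
        items = sorted(set(items) - {a, b} | {new})
    a, b = items
    lab = rng.uniform(0.2, 1.5)
    for x, dx in below[a].items():
        for y, dy in below[b].items():
            d[frozenset((x, y))] = dx + dy + lab
    mat = np.zeros((n_taxa, n_taxa))
    for i, x in enumerate(names):
        for j, y in enumerate(names):
            if i != j:
                mat[i, j] = d[frozenset((x, y))]
    return tuple(names), mat


def _patristic(tree: PhyloTree):
    """Leaf-to-leaf path lengths of an ltrkit tree."""
    dists = {}

    def walk(node: Node):
        if node.is_leaf:
            return {node.name: node.length}
        partials = [walk(c) for c in node.children]
        for i in range(len(partials)):
            for j in range(i + 1, len(partials)):
                for x, dx in partials[i].items():
                    for y, dy in partials[j].items():
                        dists[frozenset((x, y))] = dx + dy
        merged = {}
        for part in partials:
            merged.update({x: dx + node.length for x, dx in part.items()})
        return merged

    walk(tree.root)
    return dists


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        """Distances from ((A:1,B:2):1,(C:3,D:4)) are recovered exactly."""
        ids = ("A", "B", "C", "D")
        m = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(ids, m))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        pat = _patristic(tree)
        for i, x in enumerate(ids):
            for j in range(i + 1, 4):
                assert pat[frozenset((x, ids[j]))] == pytest.approx(m[i, j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        ids = ("a", "b", "c")
        m = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(ids, m))
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == pytest.approx({"a": 0.0, "b": 2.0, "c": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValidationError):
            neighbor_joining(DistanceMatrix(("a", "b"), np.zeros((2, 2))))

    @pytest.mark.parametrize("seed", range(6))
    def test_random_additive_trees_recovered_exactly(self, seed):
        """NJ is consistent on additive matrices: the generating tree's
        patristic distances are reproduced to numerical precision."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        ids, mat = _random_additive_tree(rng, n)
        tree = neighbor_joining(DistanceMatrix(ids, mat))
        pat = _patristic(tree)
        for i in range(n):
            for j in range(i + 1, n):
                assert pat[frozenset((ids[i], ids[j]))] == pytest.approx(
                    mat[i, j], abs=1e-9
                )

    def test_topology_agrees_with_skbio(self):
        """Independent NJ implementation (scikit-bio) yields the same
        bipartitions on a noisy matrix."""
        import skbio

        rng = np.random.default_rng(99)
        ids, mat = _random_additive_tree(rng, 7)
        noise = rng.uniform(-0.02, 0.02, size=mat.shape)
        noisy = mat + noise + noise.T
        np.fill_diagonal(noisy, 0.0)
        mine = neighbor_joining(DistanceMatrix(ids, noisy))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids))
        sk_splits = set()
        all_names = frozenset(ids)
        anchor = min(ids)
        for node in sk_tree.non_tips(include_self=False):
            clade = frozenset(t.name for t in node.tips())
            if 1 < len(clade) < len(ids) - 1:
                side = clade if anchor not in clade else all_names - clade
                sk_splits.add(side)
        assert mine.bipartitions() == sk_splits


class TestBootstrap:
    def _four_clade_alignment(self, seed=5, between=0.25, within=0.02, length=200):
        rng = np.random.default_rng(seed)
        root = _random_peptide(rng, length)
        peps = []
        for c in "ABCD":
            anc = _mutate(rng, root, between)
            for k in range(3):
                peps.append((f"{c}{k}", _mutate(rng, anc, within)))
        return align_progressive(peps)

    def test_planted_clades_get_high_support(self):
        aln = self._four_clade_alignment()
        tree = bootstrap_support(aln, replicates=200, seed=1)
        leaves = frozenset(tree.leaf_names())
        splits = tree.bipartitions()
        supports = {}

        def walk(n):
            if n.is_leaf:
                return frozenset([n.name])
            cl = frozenset().union(*(walk(c) for c in n.children))
            if n.support is not None:
                supports[cl] = n.support
            return cl

        walk(tree.root)
        for clade_name in "ABCD":
            clade = frozenset(f"{clade_name}{k}" for k in range(3))
            assert clade in splits or (leaves - clade) in splits
            support = supports.get(clade, supports.get(leaves - clade))
            assert support is not None and support >= 95.0

    def test_single_replicate_supports_are_zero_or_hundred(self):
        aln = self._four_clade_alignment(seed=6)
        tree = bootstrap_support(aln, replicates=1, seed=2)
        sups = [n.support for n in _internal_nodes(tree.root) if n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_same_seed_reproduces_supports(self):
        aln = self._four_clade_alignment(seed=7)
        t1 = bootstrap_support(aln, replicates=50, seed=3)
        t2 = bootstrap_support(aln, replicates=50, seed=3)
        assert t1.to_newick(with_supports=True) == t2.to_newick(with_supports=True)

    def test_zero_replicates_rejected(self):
        aln = self._four_clade_alignment(seed=8)
        with pytest.raises(ValidationError):
            bootstrap_support(aln, replicates=0)

    def test_newick_parses_with_skbio(self):
        import io

        import skbio

        aln = self._four_clade_alignment(seed=9)
        tree = bootstrap_support(aln, replicates=20, seed=4)
        parsed = skbio.TreeNode.read(io.StringIO(tree.to_newick(with_supports=True)))
        assert {t.name for t in parsed.tips()} == set(aln.ids)


def _internal_nodes(node):
    out = []
    if not node.is_leaf:
        out.append(node)
        for c in node.children:
            out.extend(_internal_nodes(c))
    return out
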