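"""Unit tests for alignment, distances, NJ and bootstrap."""

import numpy as np
import pytest

from malminer.phylo import (
    DistanceError,
    DistanceMatrix,
    MultipleAlignment,
    bootstrap_support,
    build_distance_matrix,
    dayhoff_distance,
    jukes_cantor_distance,
    neighbor_joining,
    p_distance,
    progressive_align,
    read_newick,
    write_newick,
)
from malminer.synthetic_data import random_additive_tree


class TestProgressiveAlign:
    def test_identical_pair_gap_free(self):
        aln = progressive_align([("a", "MKVLW"), ("b", "MKVLW")])
        assert aln.rows == ("MKVLW", "MKVLW")

    def test_single_gap_column(self):
        aln = progressive_align([("a", "MKV"), ("b", "MKAV")])
        assert sorted(aln.rows) == ["MK-V", "MKAV"]

    def test_identical_sequences_share_rows(self):
        aln = progressive_align(
            [("a", "MKVLWPG"), ("b", "MKVLWPG"), ("c", "MKALWPG")])
        assert aln.row("a") == aln.row("b")

    def test_all_residues_preserved(self):
        seqs = [("a", "MKVLW"), ("b", "MKAVW"), ("c", "MKW"), ("d", "AKVLW")]
        aln = progressive_align(seqs)
        for name, seq in seqs:
            assert aln.row(name).replace("-", "") == seq

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            progressive_align([("a", "MKV")])


class TestPDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ("AAAA", "AAAA", 0.0),
        ("AAAA", "AAAT", 0.25),
        ("A-AA", "ACAA", 0.0),  # gapped column skipped (3 comparable)
    ])
    def test_examples(self, a, b, expected):
        assert p_distance(a, b) == expected

    def test_no_comparable_columns(self):
        with pytest.raises(DistanceError):
            p_distance("--", "AA")


class TestJukesCantor:
    def test_zero_for_identical(self):
        assert jukes_cantor_distance("ACGT", "ACGT") == 0.0

    def test_expands_p_distance(self):
        assert jukes_cantor_distance("AAAAAAAACG", "AAAAAAAAGC") > 0.2

    def test_saturation_flagged(self):
        with pytest.raises(DistanceError, match="saturated"):
            jukes_cantor_distance("ACGTACGT", "CAGTGACA"[::-1])


class TestDayhoffDistance:
    def test_zero_for_identical(self):
        assert dayhoff_distance("MKVLW" * 10, "MKVLW" * 10) == 0.0

    def test_monotone_in_divergence(self, rng):
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
        def mutate(rate):
            out = list(base)
            for i in range(len(out)):
                if rng.random() < rate:
                    out[i] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
            return "".join(out)
        d1 = dayhoff_distance(base, mutate(0.1))
        d2 = dayhoff_distance(base, mutate(0.3))
        assert 0.0 < d1 < d2

    def test_expands_p_distance(self, rng):
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        other = list(base)
        for i in range(0, 200, 4):
            other[i] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
        other = "".join(other)
        if other != base:
            assert dayhoff_distance(base, other) >= p_distance(base, other)

    def test_matches_independent_implementation(self):
        # Frozen oracle values from phangorn::dist.ml(model="Dayhoff") on the
        # same 200-residue pairs (optimizer tolerance ~1e-4).
        rng = np.random.default_rng(42)
        aas = "ARNDCQEGHILKMFPSTWYV"
        base = "".join(rng.choice(list(aas), size=200))
        expected = {0.05: 0.064581453, 0.15: 0.247799028, 0.3: 0.470625046,
                    0.5: 1.070820280}
        for rate, oracle in expected.items():
            s = list(base)
            for i in range(len(s)):
                if rng.random() < rate:
                    s[i] = aas[rng.integers(20)]
            assert dayhoff_distance(base, "".join(s)) == \
                pytest.approx(oracle, abs=1e-3)

    def test_never_negative_even_when_all_sites_differ(self):
        try:
            d = dayhoff_distance("AAAAA", "RRRRR")
        except DistanceError:
            return  # saturation flag is an accepted outcome
        assert d >= 0.0


class TestDistanceMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_complete_deletion_drops_gapped_columns(self):
        aln = MultipleAlignment(("a", "b", "c"),
                                ("AKV-W", "AKVLW", "GKVLW"))
        pairwise = build_distance_matrix(aln, "p", "pairwise")
        complete = build_distance_matrix(aln, "p", "complete")
        assert pairwise.values[1, 2] == pytest.approx(0.2)
        assert complete.values[1, 2] == pytest.approx(0.25)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c"), d))
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_recovers_known_four_taxon_tree(self):
        # ((A:1,B:2):1,(C:3,D:4)) path-length matrix
        taxa = ("A", "B", "C", "D")
        d = np.array([
            [0.0, 3.0, 5.0, 6.0],
            [3.0, 0.0, 6.0, 7.0],
            [5.0, 6.0, 0.0, 7.0],
            [6.0, 7.0, 7.0, 0.0],
        ])
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        pd = tree.root.tip_tip_distances()
        ids = list(pd.ids)
        order = [ids.index(t) for t in taxa]
        assert np.allclose(np.asarray(pd.data)[np.ix_(order, order)], d)

    def test_equidistant_taxa_give_valid_equal_length_tree(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        tree = neighbor_joining(DistanceMatrix(tuple("abcde"), d))
        tips = {t.name: t.length for t in tree.root.tips()}
        assert len(tips) == n
        assert len(set(round(v, 12) for v in tips.values())) == 1

    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(
            DistanceMatrix(("a", "b"), np.array([[0.0, 0.4], [0.4, 0.0]])))
        assert sorted(t.length for t in tree.root.tips()) == [0.2, 0.2]

    def test_taxon_permutation_invariance(self, rng):
        _, dm = random_additive_tree(6, rng)
        perm = rng.permutation(6)
        permuted = DistanceMatrix(
            tuple(dm.taxa[i] for i in perm),
            dm.values[np.ix_(perm, perm)],
        )
        assert neighbor_joining(dm).bipartitions() == \
            neighbor_joining(permuted).bipartitions()

    def test_agrees_with_skbio_topology(self, rng):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as skbio_nj
        _, dm = random_additive_tree(7, rng)
        mine = neighbor_joining(dm).bipartitions()
        sk_root = skbio_nj(SkDM(dm.values, ids=list(dm.taxa)))
        taxa = frozenset(dm.taxa)
        anchor = min(taxa)
        sk_splits = set()
        for node in sk_root.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(taxa) - 2:
                sk_splits.add(side if anchor not in side else taxa - side)
        assert mine == sk_splits


def _related_alignment(rng, n_taxa=6, length=150, rate=0.08):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    base = "".join(rng.choice(list(aas), size=length))
    rows = []
    for i in range(n_taxa):
        s = list(base)
        for k in range(length):
            if rng.random() < rate * (1 + i) / n_taxa:
                s[k] = aas[rng.integers(20)]
        rows.append("".join(s))
    return MultipleAlignment(tuple(f"t{i}" for i in range(n_taxa)),
                             tuple(rows))


class TestBootstrap:
    def test_same_seed_same_supports(self, rng):
        aln = _related_alignment(rng)
        def supports(tree):
            return sorted(node.bootstrap
                          for node in tree.root.non_tips(include_self=False)
                          if hasattr(node, "bootstrap"))
        t1 = bootstrap_support(aln, n_reps=100, seed=5)
        t2 = bootstrap_support(aln, n_reps=100, seed=5)
        assert supports(t1) == supports(t2)

    def test_supports_bounded_and_signal_free_band(self, rng):
        # On a random (signal-free) alignment no split should be certain.
        aas = "ACDEFGHIKLMNPQRSTVWY"
        rows = tuple("".join(rng.choice(list(aas), size=100)) for _ in range(6))
        aln = MultipleAlignment(tuple(f"r{i}" for i in range(6)), rows)
        tree = bootstrap_support(aln, n_reps=200, seed=1)
        values = [node.bootstrap
                  for node in tree.root.non_tips(include_self=False)
                  if hasattr(node, "bootstrap")]
        assert values and all(0.0 <= v <= 100.0 for v in values)
        assert min(values) < 100.0

    def test_perfect_signal_gives_full_support(self):
        # Every column supports the same AB|CD split.
        aln = MultipleAlignment(
            ("A", "B", "C", "D"),
            ("AAAAAAAAAA", "AAAAAAAAAA", "RRRRRRRRRR", "RRRRRRRRRR"),
        )
        tree = bootstrap_support(aln, n_reps=50, seed=3)
        (node,) = [n for n in tree.root.non_tips(include_self=False)
                   if hasattr(n, "bootstrap")]
        assert node.bootstrap == 100.0

    def test_zero_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_support(_related_alignment(rng), n_reps=0, seed=1)


class TestNewick:
    def test_two_taxon_shape(self, tmp_path):
        tree = neighbor_joining(
            DistanceMatrix(("A", "B"), np.array([[0.0, 0.4], [0.4, 0.0]])))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        text = path.read_text().strip()
        assert text.endswith(";")
        assert "A:0.2" in text and "B:0.2" in text

    def test_roundtrip_topology_lengths_supports(self, tmp_path, rng):
        aln = _related_alignment(rng)
        tree = bootstrap_support(aln, n_reps=50, seed=2)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert back.bipartitions() == tree.bipartitions()
        assert back.has_supports
        orig = sorted(round(t.length, 10) for t in tree.root.tips())
        again = sorted(round(t.length, 10) for t in back.root.tips())
        assert orig == again
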