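"""Unit tests for candidate finding, cluster calling and geometry."""

import numpy as np
import pytest

from malminer._references import (
    activator_scaffold,
    glucosidase_scaffold,
    transporter_scaffold,
)
from malminer.cluster_mining import (
    DEFAULT_THRESHOLDS,
    MALCluster,
    annotate_cluster,
    default_references,
    find_candidates,
    find_clusters,
    find_divergent_pairs,
    telomere_distance,
)
from malminer.seq_io import Contig, GeneFeature

ROLE_SEQ = {
    "AG": glucosidase_scaffold,
    "AGT": transporter_scaffold,
    "ACT": activator_scaffold,
}


def make_genes(layout, contig_id="chr1", start=1000, gap=500):
    """Build genes + proteome from (role_or_None, strand[, product]) tuples;
    None plants a shuffled decoy."""
    rng = np.random.default_rng(1)
    genes, proteome = [], {}
    pos = start
    for i, entry in enumerate(layout):
        role, strand, product = (*entry, "")[:3]
        if role is None:
            protein = "".join(rng.permutation(list(glucosidase_scaffold())))
        else:
            protein = ROLE_SEQ[role]()
        length = 3 * len(protein) + 3
        gene = GeneFeature(f"g{i + 1}", contig_id, pos, pos + length - 1,
                           strand, ((pos, pos + length - 1),), product)
        genes.append(gene)
        proteome[gene.id] = protein
        pos += length + gap
    return genes, proteome


class TestFindCandidates:
    def test_self_match_full_identity_and_coverage(self):
        genes, proteome = make_genes([("AG", "+")])
        (cand,) = find_candidates(genes, proteome)
        assert (cand.role, cand.identity, cand.coverage) == ("AG", 100.0, 100.0)

    def test_shuffled_decoy_not_a_candidate(self):
        genes, proteome = make_genes([(None, "+")])
        assert find_candidates(genes, proteome) == []

    def test_keyword_rescues_weak_homology(self):
        genes, proteome = make_genes(
            [(None, "+", "Zn(2)-Cys(6) transcription factor")])
        (cand,) = find_candidates(genes, proteome)
        assert cand.role == "ACT"
        assert cand.keyword_hit
        assert cand.identity < DEFAULT_THRESHOLDS.identity_min

    def test_missing_protein_names_gene(self):
        genes, proteome = make_genes([("AG", "+")])
        with pytest.raises(KeyError, match="g1"):
            find_candidates(genes, {})

    def test_each_gene_reported_at_most_once(self):
        genes, proteome = make_genes([("AG", "+", "maltase")])
        assert len(find_candidates(genes, proteome)) == 1


class TestFindClusters:
    def scan(self, layout, **kwargs):
        genes, proteome = make_genes(layout, **kwargs)
        candidates = find_candidates(genes, proteome)
        return find_clusters(candidates, genes), genes, candidates

    def test_single_ag_is_not_a_cluster(self):
        clusters, _, _ = self.scan([("AG", "+")])
        assert clusters == []

    def test_adjacent_ag_agt_pair(self):
        clusters, _, _ = self.scan([("AG", "+"), ("AGT", "-")])
        assert len(clusters) == 1
        assert [m.role for m in clusters[0].members] == ["AG", "AGT"]

    def test_four_gene_cluster(self):
        clusters, _, _ = self.scan(
            [("ACT", "+"), ("AGT", "-"), ("AG", "+"), ("ACT", "-")])
        assert len(clusters) == 1
        assert len(clusters[0].members) == 4

    def test_no_ag_no_cluster(self):
        clusters, _, _ = self.scan([("AGT", "+"), ("ACT", "-")])
        assert clusters == []

    def test_large_gap_splits_runs(self):
        genes, proteome = make_genes(
            [("AG", "+"), ("AGT", "-")], gap=DEFAULT_THRESHOLDS.max_gap + 1)
        candidates = find_candidates(genes, proteome)
        assert find_clusters(candidates, genes) == []

    def test_permutation_invariance(self):
        genes, proteome = make_genes(
            [("AG", "+"), ("AGT", "-"), ("ACT", "+")])
        candidates = find_candidates(genes, proteome)
        forward = find_clusters(candidates, genes)
        backward = find_clusters(list(reversed(candidates)), genes)
        assert [c.member_ids for c in forward] == \
               [c.member_ids for c in backward]

    def test_intervening_noncandidate_does_not_break_run(self):
        clusters, _, _ = self.scan([("AG", "+"), (None, "+"), ("AGT", "-")])
        assert len(clusters) == 1
        assert clusters[0].intervening_gene_ids == ("g2",)


def _cluster_from(strand_pairs, coords):
    genes, proteome = [], {}
    members = []
    from malminer.cluster_mining import CandidateMALGene
    for i, ((start, end), strand) in enumerate(zip(coords, strand_pairs)):
        gene = GeneFeature(f"g{i + 1}", "chr1", start, end, strand,
                           ((start, end),))
        genes.append(gene)
        role = "AG" if i == 0 else "AGT"
        members.append(CandidateMALGene(gene, role, "ref", 1.0, 90.0, 90.0))
    span = (min(c[0] for c in coords), max(c[1] for c in coords))
    return MALCluster("chr1", tuple(members), span), genes


class TestDivergentPairs:
    def test_divergent_geometry_detected(self):
        cluster, genes = _cluster_from(["-", "+"], [(1000, 2000), (2500, 3500)])
        (pair,) = find_divergent_pairs(cluster, genes)
        assert (pair[0].gene.id, pair[1].gene.id) == ("g1", "g2")

    def test_same_strand_is_not_divergent(self):
        cluster, genes = _cluster_from(["+", "+"], [(1000, 2000), (2500, 3500)])
        assert find_divergent_pairs(cluster, genes) == []

    def test_convergent_pair_rejected(self):
        cluster, genes = _cluster_from(["+", "-"], [(1000, 2000), (2500, 3500)])
        assert find_divergent_pairs(cluster, genes) == []

    def test_wide_intergenic_region_rejected(self):
        cluster, genes = _cluster_from(["-", "+"], [(1000, 2000), (4100, 5000)])
        assert find_divergent_pairs(cluster, genes, max_promoter_span=2000) == []

    def test_strand_mirror_symmetry(self):
        length = 10_000
        cluster, genes = _cluster_from(["-", "+"], [(1000, 2000), (2500, 3500)])
        mirrored_coords = [(length + 1 - 3500, length + 1 - 2500),
                           (length + 1 - 2000, length + 1 - 1000)]
        mirrored, mgenes = _cluster_from(["-", "+"], mirrored_coords)
        assert len(find_divergent_pairs(cluster, genes)) == \
               len(find_divergent_pairs(mirrored, mgenes))


class TestClusterGeometry:
    @pytest.mark.parametrize("span,length,expected", [
        ((1, 500), 10_000, 0),
        ((100, 500), 10_000, 99),
        ((9000, 9900), 10_000, 100),
    ])
    def test_telomere_distance(self, span, length, expected):
        cluster, _ = _cluster_from(["-", "+"], [(span[0], span[0] + 10),
                                                (span[1] - 10, span[1])])
        assert telomere_distance(cluster, Contig("chr1", length)) == expected

    def test_span_outside_contig_rejected(self):
        cluster, _ = _cluster_from(["-", "+"], [(1000, 2000), (2500, 3500)])
        with pytest.raises(ValueError, match="outside contig"):
            telomere_distance(cluster, Contig("chr1", 3000))

    @pytest.mark.parametrize("start,subtelomeric", [(100, True), (410_000, False)])
    def test_subtelomeric_flag(self, start, subtelomeric):
        coords = [(start, start + 1000), (start + 1500, start + 2500)]
        cluster, genes = _cluster_from(["-", "+"], coords)
        annotated = annotate_cluster(cluster, Contig("chr1", 1_000_000), genes)
        assert annotated.subtelomeric is subtelomeric
        assert annotated.intron_counts == (0, 0)
        assert annotated.divergent_pairs == (("g1", "g2"),)


class TestClusterInvariants:
    def test_two_members_required(self):
        cluster, _ = _cluster_from(["-", "+"], [(1000, 2000), (2500, 3500)])
        with pytest.raises(ValueError, match=">= 2 members"):
            MALCluster("chr1", cluster.members[:1],
                       (1000, 2000))

    def test_ag_required(self):
        from dataclasses import replace
        cluster, _ = _cluster_from(["-", "+"], [(1000, 2000), (2500, 3500)])
        members = tuple(replace(m, role="AGT") for m in cluster.members)
        with pytest.raises(ValueError, match="AG member"):
            MALCluster("chr1", members, cluster.span)
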