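"""MAL gene-cluster detection in annotated genomes.

Candidate MAL genes are identified by global-alignment homology to
reference α-glucosidase (AG), α-glucoside transporter (AGT) and
MAL-activator (ACT) proteins, or by annotation keywords (e.g. a
"Zn(2)-Cys(6)" DNA-binding domain for activators).  A MAL cluster is a
maximal run of candidate genes on one contig with consecutive
candidate-to-candidate gaps below a configurable bound, containing at
least two members of which at least one encodes an AG.  Clusters are
annotated with their geometry: divergently transcribed gene pairs that
share a putative bidirectional promoter, distance from the nearer contig
end (subtelomeric or not), and per-member intron counts.

Genes intervening between candidates do not break a run as long as the
candidate-to-candidate gap stays within the bound; they are reported as
context in the JSON evidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from . import __version__
from ._references import (
    activator_scaffold,
    glucosidase_scaffold,
    transporter_scaffold,
)
from .seq_io import Contig, GeneFeature, count_introns
from .signatures import (
    DEFAULT_SCORING,
    ScoringParams,
    alignment_score,
    global_align,
)

ROLES = ("AG", "AGT", "ACT")

#: Annotation keywords that make a gene a candidate even without homology.
ROLE_KEYWORDS: Mapping[str, tuple[str, ...]] = {
    "AG": ("alpha-glucosidase", "maltase", "isomaltase", "glucoamylase"),
    "AGT": ("alpha-glucoside permease", "alpha-glucoside transporter",
            "maltose permease", "maltose transporter"),
    "ACT": ("zn(2)-cys(6)", "zn(2)cys(6)", "zn2-cys6", "mal-activator",
            "maltose fermentation regulatory"),
}


@dataclass(frozen=True)
class Thresholds:
    """Homology and geometry thresholds of the cluster scanner (bp and %)."""

    identity_min: float = 30.0  # % identity to the best reference
    coverage_min: float = 50.0  # % of the reference aligned
    max_gap: int = 10_000  # bp between consecutive candidate genes
    max_promoter_span: int = 2_000  # bp of shared bidirectional promoter
    subtelomeric_threshold: int = 50_000  # bp from the nearer contig end


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class ReferenceProtein:
    id: str
    role: str
    sequence: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"invalid role {self.role!r}")


def default_references() -> tuple[ReferenceProtein, ...]:
    """The bundled synthetic AG / AGT / ACT mining baits."""
    return (
        ReferenceProtein("AG_ref", "AG", glucosidase_scaffold()),
        ReferenceProtein("AGT_ref", "AGT", transporter_scaffold()),
        ReferenceProtein("ACT_ref", "ACT", activator_scaffold()),
    )


@dataclass(frozen=True)
class CandidateMALGene:
    """A gene assigned a MAL role by homology and/or annotation keyword."""

    gene: GeneFeature
    role: str
    best_reference: str
    score: float
    identity: float
    coverage: float
    keyword_hit: bool = False
    ambiguous_role: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"invalid role {self.role!r}")
        if not (0.0 <= self.identity <= 100.0 and 0.0 <= self.coverage <= 100.0):
            raise ValueError("identity/coverage must be percentages in [0, 100]")


@dataclass(frozen=True)
class MALCluster:
    """An ordered run of candidate MAL genes satisfying the cluster
    definition (>= 2 members, >= 1 unambiguous AG, one contig)."""

    contig_id: str
    members: tuple[CandidateMALGene, ...]
    span: tuple[int, int]
    divergent_pairs: tuple[tuple[str, str], ...] = ()
    telomere_distance: int | None = None
    subtelomeric: bool | None = None
    intron_counts: tuple[int, ...] = ()
    intervening_gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("cluster needs >= 2 members")
        if not any(m.role == "AG" and not m.ambiguous_role for m in self.members):
            raise ValueError("cluster needs >= 1 unambiguous AG member")
        contigs = {m.gene.contig_id for m in self.members}
        if contigs != {self.contig_id}:
            raise ValueError("cluster members must share one contig")
        starts = [m.gene.start for m in self.members]
        if starts != sorted(starts):
            raise ValueError("cluster members must be ordered by start")
        lo = min(m.gene.start for m in self.members)
        hi = max(m.gene.end for m in self.members)
        if self.span != (lo, hi):
            raise ValueError("span must cover exactly the member extent")

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(m.gene.id for m in self.members)


# ---------------------------------------------------------------------------
# Candidate finding
# ---------------------------------------------------------------------------

def _coverage(aln_query: str, aln_ref: str, ref_len: int) -> float:
    aligned = sum(1 for q, r in zip(aln_query, aln_ref)
                  if q != "-" and r != "-")
    return 100.0 * aligned / ref_len


def _keyword_role(product: str,
                  keywords: Mapping[str, tuple[str, ...]]) -> str | None:
    text = product.lower()
    for role in ROLES:
        if any(kw in text for kw in keywords.get(role, ())):
            return role
    return None


def find_candidates(annotation: Sequence[GeneFeature],
                    proteome: Mapping[str, str],
                    references: Sequence[ReferenceProtein] | None = None,
                    thresholds: Thresholds = DEFAULT_THRESHOLDS,
                    keywords: Mapping[str, tuple[str, ...]] = ROLE_KEYWORDS,
                    scoring: ScoringParams = DEFAULT_SCORING,
                    ) -> list[CandidateMALGene]:
    """Assign MAL roles to genes by best-reference homology and keywords.

    Each gene is aligned to every reference; the best-scoring reference
    passing the identity/coverage thresholds sets the role.  Score ties
    between references of different roles fall back to higher identity and,
    if still tied, the gene is flagged ``ambiguous_role`` (counted as a
    member but not as the required AG).  Genes whose ``product`` annotation
    matches a role keyword become candidates even below the homology
    thresholds.  A gene lacking a protein raises ``KeyError`` naming it.
    """
    references = tuple(references) if references is not None else default_references()
    candidates: list[CandidateMALGene] = []
    for gene in annotation:
        if gene.id not in proteome:
            raise KeyError(f"no protein sequence for gene {gene.id!r}")
        protein = proteome[gene.id]
        scores = [(alignment_score(protein, ref.sequence, scoring), ref)
                  for ref in references]
        best_score = max(s for s, _ in scores)
        tied = [ref for s, ref in scores if s == best_score]
        details = []
        for ref in tied:
            aln = global_align(protein, ref.sequence, scoring)
            details.append((ref, aln.identity,
                            _coverage(aln.aligned_a, aln.aligned_b,
                                      len(ref.sequence))))
        details.sort(key=lambda t: (-t[1], t[0].id))
        best_ref, identity, coverage = details[0]
        ambiguous = (len({ref.role for ref, ident, _ in details
                          if ident == details[0][1]}) > 1)

        passes = (identity >= thresholds.identity_min
                  and coverage >= thresholds.coverage_min)
        kw_role = _keyword_role(gene.product, keywords)
        if passes:
            candidates.append(CandidateMALGene(
                gene=gene, role=best_ref.role, best_reference=best_ref.id,
                score=best_score, identity=identity, coverage=coverage,
                keyword_hit=(kw_role == best_ref.role),
                ambiguous_role=ambiguous,
            ))
        elif kw_role is not None:
            candidates.append(CandidateMALGene(
                gene=gene, role=kw_role, best_reference=best_ref.id,
                score=best_score, identity=identity, coverage=coverage,
                keyword_hit=True, ambiguous_role=False,
            ))
    return candidates


# ---------------------------------------------------------------------------
# Cluster calling and geometry
# ---------------------------------------------------------------------------

def find_clusters(candidates: Sequence[CandidateMALGene],
                  annotation: Sequence[GeneFeature],
                  max_gap: int = DEFAULT_THRESHOLDS.max_gap,
                  ) -> list[MALCluster]:
    """Call MAL clusters as maximal candidate runs with gaps <= ``max_gap``.

    Runs with fewer than two members or without an unambiguous AG are
    discarded.  Output order is (contig, leftmost start); the result is
    invariant under permutation of the input candidates.
    """
    by_contig: dict[str, list[CandidateMALGene]] = {}
    for cand in candidates:
        by_contig.setdefault(cand.gene.contig_id, []).append(cand)

    gene_index = sorted(annotation, key=lambda g: (g.contig_id, g.start, g.id))
    clusters: list[MALCluster] = []
    for contig_id in sorted(by_contig):
        run: list[CandidateMALGene] = []
        ordered = sorted(by_contig[contig_id],
                         key=lambda c: (c.gene.start, c.gene.id))
        for cand in ordered:
            if run and cand.gene.start - run[-1].gene.end - 1 > max_gap:
                _close_run(run, contig_id, gene_index, clusters)
                run = []
            run.append(cand)
        _close_run(run, contig_id, gene_index, clusters)
    return clusters


def _close_run(run: list[CandidateMALGene], contig_id: str,
               gene_index: Sequence[GeneFeature],
               out: list[MALCluster]) -> None:
    if len(run) < 2:
        return
    if not any(m.role == "AG" and not m.ambiguous_role for m in run):
        return
    span = (min(m.gene.start for m in run), max(m.gene.end for m in run))
    member_ids = {m.gene.id for m in run}
    intervening = tuple(
        g.id for g in gene_index
        if g.contig_id == contig_id and g.id not in member_ids
        and g.start >= span[0] and g.end <= span[1]
    )
    out.append(MALCluster(contig_id=contig_id, members=tuple(run), span=span,
                          intervening_gene_ids=intervening))


def find_divergent_pairs(cluster: MALCluster,
                         annotation: Sequence[GeneFeature],
                         max_promoter_span: int = DEFAULT_THRESHOLDS.max_promoter_span,
                         ) -> list[tuple[CandidateMALGene, CandidateMALGene]]:
    """Pairs of cluster members transcribed divergently from a shared
    intergenic region.

    A pair qualifies when the two members are genomically adjacent (no
    annotated gene between them), the left gene is on ``-`` and the right
    on ``+`` (5' ends facing), and the intergenic distance is at most
    ``max_promoter_span``.
    """
    others = [g for g in annotation
              if g.contig_id == cluster.contig_id
              and g.id not in set(cluster.member_ids)]
    pairs = []
    for left, right in zip(cluster.members, cluster.members[1:]):
        if (left.gene.strand, right.gene.strand) != ("-", "+"):
            continue
        gap = right.gene.start - left.gene.end - 1
        if gap < 0 or gap > max_promoter_span:
            continue
        blocked = any(g.start > left.gene.end and g.end < right.gene.start
                      for g in others)
        if not blocked:
            pairs.append((left, right))
    return pairs


def telomere_distance(cluster: MALCluster, contig: Contig) -> int:
    """Distance (bp) of the cluster span from the nearer contig end."""
    start, end = cluster.span
    if start < 1 or end > contig.length:
        raise ValueError(
            f"cluster span {cluster.span} outside contig {contig.id!r} "
            f"of length {contig.length}"
        )
    return min(start - 1, contig.length - end)


def annotate_cluster(cluster: MALCluster, contig: Contig,
                     annotation: Sequence[GeneFeature],
                     thresholds: Thresholds = DEFAULT_THRESHOLDS) -> MALCluster:
    """Enrich a cluster with telomere distance, subtelomeric flag,
    divergent pairs and per-member intron counts."""
    dist = telomere_distance(cluster, contig)
    pairs = find_divergent_pairs(cluster, annotation,
                                 thresholds.max_promoter_span)
    return replace(
        cluster,
        telomere_distance=dist,
        subtelomeric=dist <= thresholds.subtelomeric_threshold,
        divergent_pairs=tuple((a.gene.id, b.gene.id) for a, b in pairs),
        intron_counts=tuple(count_introns(m.gene) for m in cluster.members),
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

CLUSTER_TSV_COLUMNS = (
    "contig", "span_start", "span_end", "n_members", "member_ids",
    "member_roles", "member_strands", "divergent_pairs", "telomere_distance",
    "subtelomeric", "intron_counts",
)


def write_cluster_tsv(clusters: Sequence[MALCluster], path,
                      header_meta: Mapping[str, object] | None = None) -> None:
    """One row per cluster; ``#``-prefixed header lines echo the run
    configuration so any report is reproducible from its own header."""
    with open(path, "w") as handle:
        handle.write(f"# malminer {__version__}\n")
        for key, value in (header_meta or {}).items():
            handle.write(f"# {key}={value}\n")
        handle.write("\t".join(CLUSTER_TSV_COLUMNS) + "\n")
        for cl in clusters:
            handle.write("\t".join((
                cl.contig_id, str(cl.span[0]), str(cl.span[1]),
                str(len(cl.members)), ",".join(cl.member_ids),
                ",".join(m.role for m in cl.members),
                ",".join(m.gene.strand for m in cl.members),
                ";".join(f"{a}|{b}" for a, b in cl.divergent_pairs) or ".",
                str(cl.telomere_distance),
                {True: "yes", False: "no", None: "."}[cl.subtelomeric],
                ",".join(str(n) for n in cl.intron_counts),
            )) + "\n")


def cluster_evidence(clusters: Sequence[MALCluster],
                     candidates: Sequence[CandidateMALGene],
                     thresholds: Thresholds,
                     extra: Mapping[str, object] | None = None) -> dict:
    """Full machine-readable evidence: clusters, all candidates (including
    unclustered ones) with scores/identities, and the thresholds used."""
    clustered = {gid for cl in clusters for gid in cl.member_ids}

    def cand_row(c: CandidateMALGene) -> dict:
        return {
            "gene_id": c.gene.id, "contig": c.gene.contig_id,
            "start": c.gene.start, "end": c.gene.end, "strand": c.gene.strand,
            "role": c.role, "best_reference": c.best_reference,
            "score": c.score, "identity": round(c.identity, 3),
            "coverage": round(c.coverage, 3), "keyword_hit": c.keyword_hit,
            "ambiguous_role": c.ambiguous_role,
            "clustered": c.gene.id in clustered,
        }

    return {
        "tool": f"malminer {__version__}",
        "thresholds": vars(thresholds) if not isinstance(thresholds, dict)
        else thresholds,
        **(dict(extra) if extra else {}),
        "clusters": [
            {
                "contig": cl.contig_id, "span": list(cl.span),
                "members": [cand_row(m) for m in cl.members],
                "divergent_pairs": [list(p) for p in cl.divergent_pairs],
                "telomere_distance": cl.telomere_distance,
                "subtelomeric": cl.subtelomeric,
                "intron_counts": list(cl.intron_counts),
                "intervening_gene_ids": list(cl.intervening_gene_ids),
            }
            for cl in clusters
        ],
        "candidates": [cand_row(c) for c in candidates],
    }


def write_cluster_json(clusters, candidates, thresholds, path,
                       extra: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as handle:
        json.dump(cluster_evidence(clusters, candidates, thresholds, extra),
                  handle, indent=2, sort_keys=False)
        handle.write("\n")


def scan_annotation(annotation: Sequence[GeneFeature],
                    proteome: Mapping[str, str],
                    contigs: Sequence[Contig],
                    references: Sequence[ReferenceProtein] | None = None,
                    thresholds: Thresholds = DEFAULT_THRESHOLDS,
                    scoring: ScoringParams = DEFAULT_SCORING,
                    ) -> tuple[list[MALCluster], list[CandidateMALGene]]:
    """End-to-end scan: candidates -> clusters -> geometry annotation."""
    contig_by_id = {c.id: c for c in contigs}
    candidates = find_candidates(annotation, proteome, references,
                                 thresholds, scoring=scoring)
    clusters = find_clusters(candidates, annotation, thresholds.max_gap)
    annotated = [
        annotate_cluster(cl, contig_by_id[cl.contig_id], annotation, thresholds)
        for cl in clusters
    ]
    return annotated, candidates
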