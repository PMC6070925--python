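"""Seeded synthetic genomes and proteins with known ground truth.

Everything the pipeline consumes can be generated here without downloads:
annotated contigs (FASTA + GFF3) carrying planted MAL clusters with
realistic geometry (divergent AG/AGT pairs facing a shared promoter,
optional activator genes, introns, controllable distance from the contig
end), hard-negative decoy genes, proteins with planted 9-residue
signatures, and random additive trees for testing distance-based tree
reconstruction.  A machine-readable truth document accompanies every
genome so scanner precision/recall can be scored exactly.  All
randomness flows from a single seed; identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from ._references import (
    ANCHOR_POSITIONS,
    activator_scaffold,
    glucosidase_scaffold,
    transporter_scaffold,
)
from .cluster_mining import DEFAULT_THRESHOLDS, default_references
from .phylo import DistanceMatrix, PhyloTree
from .seq_io import Contig, GeneFeature, write_fasta, write_gff3
from .signatures import (
    ReferenceSignatureSet,
    check_signature,
    extract_signature,
    load_reference_signatures,
    pairwise_identity,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class LayoutError(ValueError):
    """Raised when a requested genome layout cannot be realized."""


# ---------------------------------------------------------------------------
# Reverse translation
# ---------------------------------------------------------------------------

# Most-frequent yeast codon per amino acid.  The standard-code table spells
# leucine as CTG; the CTG-clade table spells serine as CTG (and leucine as
# TTG), so round-tripping through translation exercises the reassigned codon
# under both codes.
_CODON_STANDARD = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_CODON_CTG_CLADE = {**_CODON_STANDARD, "L": "TTG", "S": "CTG"}
_CODON_TABLES = {"standard": _CODON_STANDARD, "ctg_clade": _CODON_CTG_CLADE}


def reverse_translate(protein: str, code: str = "standard") -> str:
    """Protein to CDS using one fixed codon per amino acid, plus a TAA stop."""
    table = _CODON_TABLES[code]
    return "".join(table[aa] for aa in protein) + "TAA"


# ---------------------------------------------------------------------------
# Proteins with planted signatures
# ---------------------------------------------------------------------------

def _mutate(seq: str, rate: float, rng: np.random.Generator,
            frozen: frozenset[int] = frozenset()) -> str:
    """Substitute residues at ``rate`` per site, never touching ``frozen``
    (0-based) positions."""
    out = list(seq)
    for i in range(len(out)):
        if i in frozen or rng.random() >= rate:
            continue
        choices = [aa for aa in AMINO_ACIDS if aa != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def make_protein_with_signature(signature: str,
                                scaffold: str | None = None,
                                mutation_rate: float = 0.0,
                                seed: int | np.random.Generator = 0,
                                max_tries: int = 10) -> str:
    """Build a protein whose extracted signature equals ``signature``.

    Signature symbols are written into the anchor positions of the
    glucosidase scaffold; ``-`` deletes a short window covering that anchor
    so the alignment is forced to gap it.  Non-anchor residues are mutated
    at ``mutation_rate``; the result is verified by running
    :func:`~malminer.signatures.extract_signature` and rebuilt (up to
    ``max_tries`` times) if verification fails.
    """
    signature = check_signature(signature)
    scaffold = scaffold or glucosidase_scaffold()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    anchors0 = [p - 1 for p in ANCHOR_POSITIONS]  # 0-based
    anchor_set = set(anchors0)
    for _ in range(max_tries):
        residues = list(scaffold)
        deletions: set[int] = set()
        for pos0, symbol in zip(anchors0, signature):
            if symbol == "-":
                lo = pos0
                while lo > pos0 - 4 and lo - 1 >= 0 and lo - 1 not in anchor_set:
                    lo -= 1
                hi = pos0
                while (hi < pos0 + 4 and hi + 1 < len(residues)
                       and hi + 1 not in anchor_set):
                    hi += 1
                deletions.update(range(lo, hi + 1))
            else:
                residues[pos0] = symbol
        frozen = frozenset(anchor_set | deletions)
        mutated = _mutate("".join(residues), mutation_rate, rng, frozen)
        protein = "".join(aa for i, aa in enumerate(mutated)
                          if i not in deletions)
        if extract_signature(protein) == signature:
            return protein
    raise ValueError(
        f"could not realize signature {signature!r} at mutation rate "
        f"{mutation_rate} within {max_tries} attempts"
    )


def make_signature_dataset(refs: ReferenceSignatureSet | None = None,
                           per_label: int = 1,
                           mutation_rate: float = 0.0,
                           seed: int = 0,
                           ) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Labeled synthetic proteins drawn from the reference signatures.

    Returns ``(records, truth)`` where records are FASTA-ready
    ``(id, protein)`` tuples (``per_label`` per class) and truth maps each
    id to its intended specificity label.
    """
    if per_label < 1:
        raise ValueError("per_label must be >= 1")
    refs = refs or load_reference_signatures()
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    for label in ("maltase", "isomaltase", "maltase-isomaltase"):
        pool = [e for e in refs if e.label == label]
        for k in range(per_label):
            entry = pool[rng.integers(len(pool))]
            protein = make_protein_with_signature(
                entry.signature, mutation_rate=mutation_rate, seed=rng)
            rec_id = f"{label.replace('-', '_')}_{k + 1}"
            records.append((rec_id, protein))
            truth[rec_id] = label
    return records, truth


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterPlan:
    """Layout of one planted cluster: member roles in order, strands,
    intergenic gaps (bp, between consecutive members), intron counts per
    gene, target contig and optional fixed start coordinate."""

    roles: tuple[str, ...]
    strands: tuple[str, ...]
    gaps: tuple[int, ...]
    intron_counts: tuple[int, ...]
    contig_index: int = 0
    offset: int | None = None  # 1-based start of the first gene; None = auto

    def __post_init__(self) -> None:
        k = len(self.roles)
        if len(self.strands) != k or len(self.intron_counts) != k:
            raise ValueError("strands/intron_counts must match roles")
        if len(self.gaps) != max(k - 1, 0):
            raise ValueError("need one gap per adjacent member pair")
        if any(g < 0 for g in self.gaps):
            raise ValueError("gaps must be >= 0")
        if any(s not in "+-" for s in self.strands):
            raise ValueError("strands must be + or -")


@dataclass(frozen=True)
class SimulationConfig:
    n_contigs: int = 2
    contig_length: int = 200_000
    clusters: tuple[ClusterPlan, ...] = ()
    n_decoy_genes: int = 50
    decoy_identity_ceiling: float = 20.0  # % to every reference
    mutation_rate: float = 0.05  # per residue, outside signature anchors
    genetic_code: str = "standard"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        for plan in self.clusters:
            if plan.contig_index >= self.n_contigs:
                raise ValueError("cluster assigned to unknown contig")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Cluster layout pool used by :func:`default_config`.  Gaps under the
#: divergent-promoter span (2 kb) realize shared bidirectional promoters;
#: all layouts contain an AG, as the cluster definition requires.
_LAYOUT_POOL: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] = (
    (("AG", "AGT"), ("-", "+")),
    (("AGT", "AG"), ("-", "+")),
    (("ACT", "AG"), ("+", "+")),
    (("AG", "AGT", "ACT"), ("-", "+", "+")),
    (("AGT", "AG", "ACT"), ("-", "+", "-")),
)

#: The four-gene layout with a divergent AGT/AG pair between two
#: activators (the O. polymorpha-style cluster shape).
FOUR_GENE_LAYOUT = (("ACT", "AGT", "AG", "ACT"), ("+", "-", "+", "-"))


def default_config(seed: int = 0,
                   n_clusters: int | None = None) -> SimulationConfig:
    """Study-condition generator config: 2 contigs of 200 kb, 1-8 planted
    clusters (the first always the four-gene divergent layout), 50 decoys,
    5% non-anchor mutation."""
    rng = np.random.default_rng(seed)
    if n_clusters is None:
        n_clusters = int(rng.integers(1, 9))
    plans = []
    for c in range(n_clusters):
        roles, strands = (FOUR_GENE_LAYOUT if c == 0
                          else _LAYOUT_POOL[rng.integers(len(_LAYOUT_POOL))])
        gaps = []
        for left, right in zip(range(len(roles) - 1), range(1, len(roles))):
            divergent = (strands[left], strands[right]) == ("-", "+")
            gaps.append(int(rng.integers(300, 1800)) if divergent
                        else int(rng.integers(300, 8000)))
        introns = tuple(int(rng.integers(0, 4)) if rng.random() < 0.4 else 0
                        for _ in roles)
        plans.append(ClusterPlan(
            roles=roles, strands=strands, gaps=tuple(gaps),
            intron_counts=introns, contig_index=c % 2,
        ))
    return SimulationConfig(clusters=tuple(plans), seed=seed)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated genome, verifiable by re-reading the
    emitted FASTA/GFF3."""

    clusters: tuple[dict, ...]
    signatures: Mapping[str, dict]  # AG gene id -> {signature, label}
    seed: int
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "clusters": list(self.clusters),
            "signatures": dict(self.signatures),
            "seed": self.seed,
            "config": self.config,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2)
            handle.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(clusters=tuple(payload["clusters"]),
                   signatures=payload["signatures"],
                   seed=payload["seed"], config=payload["config"])


@dataclass(frozen=True)
class SyntheticGenome:
    contigs: tuple[Contig, ...]
    genes: tuple[GeneFeature, ...]
    proteome: Mapping[str, str]
    truth: SyntheticTruth

    def write(self, out_dir) -> dict[str, str]:
        """Write genome.fasta, annotation.gff3, proteome.fasta and
        truth.json; returns the path map."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "genome": os.path.join(out_dir, "genome.fasta"),
            "annotation": os.path.join(out_dir, "annotation.gff3"),
            "proteome": os.path.join(out_dir, "proteome.fasta"),
            "truth": os.path.join(out_dir, "truth.json"),
        }
        write_fasta(paths["genome"],
                    [(c.id, c.sequence) for c in self.contigs])
        write_gff3(paths["annotation"], self.contigs, self.genes)
        write_fasta(paths["proteome"], sorted(self.proteome.items()))
        self.truth.to_json(paths["truth"])
        return paths


def _gene_blueprint(protein: str, code: str, intron_count: int,
                    rng: np.random.Generator
                    ) -> tuple[str, tuple[tuple[int, int], ...]]:
    """Forward-orientation genomic gene sequence and 0-based relative exon
    intervals, with GT..AG introns between exon segments."""
    cds = reverse_translate(protein, code)
    if intron_count == 0:
        return cds, ((0, len(cds) - 1),)
    cuts = sorted(rng.choice(np.arange(1, len(cds)), size=intron_count,
                             replace=False))
    segments = [cds[a:b] for a, b in zip([0, *cuts], [*cuts, len(cds)])]
    seq_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    for i, segment in enumerate(segments):
        seq_parts.append(segment)
        exons.append((pos, pos + len(segment) - 1))
        pos += len(segment)
        if i < len(segments) - 1:
            intron = ("GT"
                      + "".join(rng.choice(list("ACGT"),
                                           size=int(rng.integers(40, 200))))
                      + "AG")
            seq_parts.append(intron)
            pos += len(intron)
    return "".join(seq_parts), tuple(exons)


def _mirror_exons(exons: Sequence[tuple[int, int]], length: int
                  ) -> tuple[tuple[int, int], ...]:
    return tuple(sorted((length - 1 - e, length - 1 - s) for s, e in exons))


def _make_decoy(rng: np.random.Generator, references, ceiling: float,
                max_tries: int = 25) -> str:
    """Composition-preserving shuffle of a reference protein, accepted only
    below the identity ceiling to every reference."""
    base = references[int(rng.integers(len(references)))].sequence
    for _ in range(max_tries):
        shuffled = "".join(rng.permutation(list(base)))
        if all(pairwise_identity(shuffled, ref.sequence) < ceiling
               for ref in references):
            return shuffled
    raise LayoutError("could not generate a decoy below the identity ceiling")


def _place_block(rng: np.random.Generator, contig_length: int, block_len: int,
                 occupied: list[tuple[int, int]], margin: int,
                 max_tries: int = 200) -> int:
    """1-based start for a block of ``block_len`` bp keeping ``margin`` bp
    clear of every occupied interval."""
    if block_len + 2 > contig_length:
        raise LayoutError("block longer than contig")
    for _ in range(max_tries):
        start = int(rng.integers(1, contig_length - block_len + 1))
        end = start + block_len - 1
        if all(end + margin < s or start - margin > e for s, e in occupied):
            return start
    raise LayoutError(
        f"cannot place a {block_len} bp block on a {contig_length} bp contig "
        f"with margin {margin} (layout too crowded)"
    )


def make_synthetic_genome(config: SimulationConfig) -> SyntheticGenome:
    """Simulate an annotated genome with planted MAL clusters and decoys.

    Cluster member proteins are mutated copies of the reference AG/AGT/ACT
    scaffolds (AGs carry a planted signature drawn from the curated
    reference table); genes are reverse-translated, optionally intronated
    and placed with the configured strands and intergenic gaps.  Clusters
    keep at least ``max_gap`` + 2 kb of clearance from each other so
    planted and called clusters correspond one-to-one.
    """
    rng = np.random.default_rng(config.seed)
    references = default_references()
    ref_by_role = {r.role: r for r in references}
    sig_refs = load_reference_signatures()
    cluster_margin = DEFAULT_THRESHOLDS.max_gap + 2_000

    contig_ids = [f"contig_{i + 1}" for i in range(config.n_contigs)]
    backgrounds = [
        rng.choice(list("ACGT"), size=config.contig_length,
                   p=(0.3, 0.2, 0.2, 0.3))
        for _ in contig_ids
    ]
    occupied: list[list[tuple[int, int]]] = [[] for _ in contig_ids]
    genes: list[GeneFeature] = []
    proteome: dict[str, str] = {}
    truth_clusters: list[dict] = []
    truth_signatures: dict[str, dict] = {}

    # --- planted clusters -------------------------------------------------
    for c_idx, plan in enumerate(config.clusters):
        member_seqs: list[tuple[str, str, tuple[tuple[int, int], ...]]] = []
        member_meta: list[dict] = []
        for m_idx, (role, strand, introns) in enumerate(
                zip(plan.roles, plan.strands, plan.intron_counts)):
            gene_id = f"MALC{c_idx + 1}_{role}{m_idx + 1}"
            if role == "AG":
                entry = sig_refs.entries[int(rng.integers(len(sig_refs)))]
                protein = make_protein_with_signature(
                    entry.signature, mutation_rate=config.mutation_rate,
                    seed=rng)
                truth_signatures[gene_id] = {
                    "signature": entry.signature, "label": entry.label,
                }
            else:
                protein = _mutate(ref_by_role[role].sequence,
                                  config.mutation_rate, rng)
            forward, rel_exons = _gene_blueprint(
                protein, config.genetic_code, introns, rng)
            if strand == "-":
                genomic = _revcomp(forward)
                rel_exons = _mirror_exons(rel_exons, len(forward))
            else:
                genomic = forward
            product = ""
            if role == "ACT" and rng.random() < 0.5:
                product = "Zn(2)-Cys(6) domain-containing protein"
            member_seqs.append((gene_id, genomic, rel_exons))
            member_meta.append({
                "id": gene_id, "role": role, "strand": strand,
                "introns": introns, "protein": protein, "product": product,
            })

        gene_lengths = [len(seq) for _, seq, _ in member_seqs]
        block_len = sum(gene_lengths) + sum(plan.gaps)
        contig_idx = plan.contig_index
        if plan.offset is not None:
            start = plan.offset
            end = start + block_len - 1
            if start < 1 or end > config.contig_length:
                raise LayoutError(
                    f"cluster {c_idx + 1} at offset {start} does not fit")
            if any(not (end + cluster_margin < s or start - cluster_margin > e)
                   for s, e in occupied[contig_idx]):
                raise LayoutError(
                    f"cluster {c_idx + 1} overlaps an earlier cluster")
        else:
            start = _place_block(rng, config.contig_length, block_len,
                                 occupied[contig_idx], cluster_margin)
        occupied[contig_idx].append((start, start + block_len - 1))

        cursor = start
        member_rows = []
        for (gene_id, genomic, rel_exons), meta, gap in zip(
                member_seqs, member_meta,
                [*plan.gaps, 0]):
            g_start = cursor
            g_end = cursor + len(genomic) - 1
            abs_exons = tuple((g_start + s, g_start + e) for s, e in rel_exons)
            gene = GeneFeature(
                id=gene_id, contig_id=contig_ids[contig_idx], start=g_start,
                end=g_end, strand=meta["strand"], exons=abs_exons,
                product=meta["product"],
            )
            genes.append(gene)
            proteome[gene_id] = meta["protein"]
            backgrounds[contig_idx][g_start - 1:g_end] = list(genomic)
            member_rows.append({**{k: meta[k] for k in
                                   ("id", "role", "strand", "introns")},
                                "start": g_start, "end": g_end})
            cursor = g_end + 1 + gap

        span = (member_rows[0]["start"], member_rows[-1]["end"])
        divergent = [
            [left["id"], right["id"]]
            for left, right in zip(member_rows, member_rows[1:])
            if (left["strand"], right["strand"]) == ("-", "+")
            and right["start"] - left["end"] - 1
            <= DEFAULT_THRESHOLDS.max_promoter_span
        ]
        truth_clusters.append({
            "contig": contig_ids[contig_idx],
            "span": list(span),
            "member_ids": [m["id"] for m in member_rows],
            "member_roles": [m["role"] for m in member_rows],
            "divergent_pairs": divergent,
            "telomere_distance": min(span[0] - 1,
                                     config.contig_length - span[1]),
            "intron_counts": [m["introns"] for m in member_rows],
        })

    # --- decoy genes ------------------------------------------------------
    for d_idx in range(config.n_decoy_genes):
        protein = _make_decoy(rng, references, config.decoy_identity_ceiling)
        forward, rel_exons = _gene_blueprint(protein, config.genetic_code,
                                             0, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            genomic = _revcomp(forward)
        else:
            genomic = forward
        contig_idx = int(rng.integers(config.n_contigs))
        start = _place_block(rng, config.contig_length, len(genomic),
                             occupied[contig_idx], margin=50)
        occupied[contig_idx].append((start, start + len(genomic) - 1))
        gene_id = f"DECOY{d_idx + 1}"
        genes.append(GeneFeature(
            id=gene_id, contig_id=contig_ids[contig_idx], start=start,
            end=start + len(genomic) - 1, strand=strand,
            exons=((start, start + len(genomic) - 1),),
            product="hypothetical protein",
        ))
        proteome[gene_id] = protein
        backgrounds[contig_idx][start - 1:start + len(genomic) - 1] = \
            list(genomic)

    contigs = tuple(
        Contig(id=cid, length=config.contig_length,
               sequence="".join(background))
        for cid, background in zip(contig_ids, backgrounds)
    )
    truth = SyntheticTruth(
        clusters=tuple(truth_clusters), signatures=truth_signatures,
        seed=config.seed, config=config.to_dict(),
    )
    return SyntheticGenome(contigs=contigs, genes=tuple(genes),
                           proteome=proteome, truth=truth)


def _revcomp(dna: str) -> str:
    from .seq_io import reverse_complement
    return reverse_complement(dna)


# ---------------------------------------------------------------------------
# Random additive trees (for testing distance-based reconstruction)
# ---------------------------------------------------------------------------

def random_additive_tree(n_taxa: int, rng: np.random.Generator,
                         branch_length_range: tuple[float, float] = (0.01, 1.0),
                         ) -> tuple[PhyloTree, DistanceMatrix]:
    """A random unrooted binary tree and its exact path-length matrix.

    Topology grows by attaching each new leaf to a uniformly chosen edge;
    every branch then gets an independent uniform length.  The returned
    matrix is additive by construction, so a consistent NJ implementation
    must recover the tree exactly.
    """
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    names = [f"T{i + 1}" for i in range(n_taxa)]
    root = TreeNode(children=[TreeNode(name=n) for n in names[:3]])
    for name in names[3:]:
        candidates = [n for n in root.traverse(include_self=False)]
        target = candidates[int(rng.integers(len(candidates)))]
        parent = target.parent
        parent.remove(target)
        joint = TreeNode(children=[target, TreeNode(name=name)])
        parent.append(joint)
    lo, hi = branch_length_range
    for node in root.traverse(include_self=False):
        node.length = float(lo + (hi - lo) * rng.random())
    dm = root.tip_tip_distances()
    ids = list(dm.ids)
    order = [ids.index(n) for n in names]
    values = np.asarray(dm.data)[np.ix_(order, order)]
    return (PhyloTree(root=root),
            DistanceMatrix(taxa=tuple(names), values=values))
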