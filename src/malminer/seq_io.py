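"""FASTA/GFF3 input-output and coding-sequence translation.

Coordinates are 1-based inclusive throughout (the GFF3 convention); any
half-open conversion happens only at report boundaries.  Two genetic codes
are supported: the standard nuclear code and the CTG-clade alternative
yeast code, in which codon CTG encodes serine instead of leucine.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Data import CodonTable
from Bio.Seq import Seq


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input."""


class GffFormatError(ValueError):
    """Raised for malformed or inconsistent GFF3 input."""


class TranslationError(ValueError):
    """Raised when a coding sequence cannot be translated."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contig:
    """A chromosome or scaffold; ``sequence`` is optional but, when present,
    must match ``length``."""

    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id!r}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.id!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass(frozen=True)
class GeneFeature:
    """A located, stranded gene with exon structure on a contig.

    ``start``/``end`` and each exon pair are 1-based inclusive genome
    coordinates; exons are sorted, non-overlapping and lie within the gene.
    """

    id: str
    contig_id: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    product: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"gene {self.id!r}: invalid span {self.start}-{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.id!r}: invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.id!r}: at least one exon required")
        prev_end = None
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"gene {self.id!r}: exon {s}-{e} reversed")
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.id!r}: exon {s}-{e} outside gene bounds")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"gene {self.id!r}: exons unsorted or overlapping")
            prev_end = e


def _build_code(code_id: str, table_id: int) -> "GeneticCode":
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return GeneticCode(id=code_id, mapping=mapping)


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon table (stops mapped to ``*``)."""

    id: str
    mapping: Mapping[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.mapping) != 64:
            raise ValueError("genetic code must map all 64 codons")


#: Standard nuclear genetic code (NCBI table 1).
STANDARD_CODE = _build_code("standard", 1)
#: Alternative yeast nuclear code of the CTG clade (NCBI table 12): CTG -> Ser.
CTG_CLADE_CODE = _build_code("ctg_clade", 12)

GENETIC_CODES = {"standard": STANDARD_CODE, "ctg_clade": CTG_CLADE_CODE}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(id, sequence)`` tuples.

    Sequences are uppercased and line wrapping is collapsed.  Duplicate ids,
    sequence data before the first header, empty records and empty files all
    raise :class:`FastaFormatError` naming the offending line.
    """
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    current_id: str | None = None
    current_seq: list[str] = []
    header_line = 0

    def _flush() -> None:
        if current_id is None:
            return
        if not current_seq:
            raise FastaFormatError(
                f"line {header_line}: record {current_id!r} has no sequence"
            )
        records.append((current_id, "".join(current_seq).upper()))

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current_seq = []
                header_line = lineno
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise FastaFormatError(f"line {lineno}: empty FASTA header")
                if current_id in seen:
                    raise FastaFormatError(
                        f"line {lineno}: duplicate record id {current_id!r} "
                        f"(first seen at line {seen[current_id]})"
                    )
                seen[current_id] = lineno
            else:
                if current_id is None:
                    raise FastaFormatError(
                        f"line {lineno}: sequence data before first '>' header"
                    )
                current_seq.append(line)
    _flush()
    if not records:
        raise FastaFormatError("line 1: empty FASTA file (no records)")
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]],
                width: int = 60) -> None:
    """Write records as wrapped FASTA with deterministic formatting."""
    with open(path, "w") as handle:
        for rec_id, seq in records:
            handle.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike,
              contigs: Sequence[Contig]) -> list[GeneFeature]:
    """Read gene models (gene + mRNA/exon/CDS children) from a GFF3 file.

    Returns one :class:`GeneFeature` per ``gene`` feature, with exon
    structure assembled from ``exon`` children (``CDS`` children are used
    when no exons are annotated).  Features on unknown contigs, dangling
    ``Parent`` references and coordinate violations raise
    :class:`GffFormatError` naming the feature.
    """
    contig_by_id = {c.id: c for c in contigs}
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise GffFormatError(f"cannot parse GFF3 {path}: {exc}") from exc

    known_ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent_id in feat.attributes.get("Parent", []):
            if parent_id not in known_ids:
                raise GffFormatError(
                    f"feature {feat.id!r}: dangling Parent {parent_id!r}"
                )
        if feat.strand not in {"+", "-"}:
            raise GffFormatError(f"feature {feat.id!r}: unknown strand {feat.strand!r}")
        if feat.end < feat.start:
            raise GffFormatError(f"feature {feat.id!r}: end < start")

    genes: list[GeneFeature] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        contig = contig_by_id.get(gene.seqid)
        if contig is None:
            raise GffFormatError(f"gene {gene.id!r}: unknown contig {gene.seqid!r}")
        if gene.end > contig.length:
            raise GffFormatError(
                f"gene {gene.id!r}: end {gene.end} beyond contig length "
                f"{contig.length}"
            )
        exons = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        if not exons:
            exons = sorted(
                (f.start, f.end) for f in db.children(gene, featuretype="CDS")
            )
        if not exons:
            raise GffFormatError(f"gene {gene.id!r}: no exon or CDS children")
        product = ""
        for holder in (gene, *db.children(gene, featuretype="mRNA")):
            for key in ("product", "Note", "description"):
                if key in holder.attributes:
                    product = holder.attributes[key][0]
                    break
            if product:
                break
        try:
            genes.append(GeneFeature(
                id=gene.id, contig_id=gene.seqid, start=gene.start,
                end=gene.end, strand=gene.strand, exons=tuple(exons),
                product=product,
            ))
        except ValueError as exc:
            raise GffFormatError(str(exc)) from exc
    return genes


def write_gff3(path: str | os.PathLike, contigs: Sequence[Contig],
               genes: Sequence[GeneFeature]) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon rows, deterministic order)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for contig in contigs:
            handle.write(f"##sequence-region {contig.id} 1 {contig.length}\n")
        for gene in sorted(genes, key=lambda g: (g.contig_id, g.start, g.id)):
            attrs = f"ID={gene.id}"
            if gene.product:
                attrs += f";product={gene.product}"
            base = (gene.contig_id, "malminer", "%s", str(gene.start),
                    str(gene.end), ".", gene.strand, ".")
            handle.write("\t".join(base).replace("%s", "gene") +
                         "\t" + attrs + "\n")
            mrna_id = f"{gene.id}.t1"
            handle.write(
                "\t".join((gene.contig_id, "malminer", "mRNA", str(gene.start),
                           str(gene.end), ".", gene.strand, ".",
                           f"ID={mrna_id};Parent={gene.id}")) + "\n")
            for i, (s, e) in enumerate(gene.exons, start=1):
                handle.write(
                    "\t".join((gene.contig_id, "malminer", "exon", str(s),
                               str(e), ".", gene.strand, ".",
                               f"ID={mrna_id}.exon{i};Parent={mrna_id}")) + "\n")


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

_VALID_NT = set("ACGTN")


def translate_cds(dna: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate a spliced coding sequence to protein.

    The terminal stop codon (if present) is stripped; an internal stop or a
    length not divisible by three raises :class:`TranslationError` naming
    the codon index.  ``N`` inside a codon translates to ``X``.
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise TranslationError(
            f"CDS length {len(dna)} is not divisible by 3"
        )
    bad = set(dna) - _VALID_NT
    if bad:
        raise TranslationError(f"invalid nucleotide(s) {sorted(bad)} in CDS")
    protein = []
    n_codons = len(dna) // 3
    for i in range(n_codons):
        codon = dna[3 * i:3 * i + 3]
        if "N" in codon:
            aa = "X"
        else:
            aa = code.mapping[codon]
        if aa == "*":
            if i == n_codons - 1:
                break  # terminal stop stripped
            raise TranslationError(f"internal stop codon at codon index {i}")
        protein.append(aa)
    return "".join(protein)


def extract_cds(gene: GeneFeature, contig_sequence: str) -> str:
    """Splice the coding sequence of a gene out of its contig sequence.

    Exon segments are concatenated in genome order and reverse-complemented
    for minus-strand genes, yielding the CDS in transcription order.
    """
    parts = [contig_sequence[s - 1:e] for (s, e) in gene.exons]
    cds = "".join(parts).upper()
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def count_introns(gene: GeneFeature) -> int:
    """Number of introns of a gene model (exon count minus one)."""
    return len(gene.exons) - 1


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())
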