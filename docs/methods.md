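# Methods

This note documents the models and procedures implemented in `malminer`,
the parameters that matter and their defaults, the numerical choices, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Coordinates, formats and genetic codes

All genomic coordinates are 1-based inclusive (the GFF3 convention),
everywhere in the package; half-open conversions happen only at report
boundaries. Gene models are read from GFF3 `gene` features with exon
structure from `exon` children (`CDS` children when no exons are
annotated); features on unknown contigs, dangling `Parent` references and
coordinate violations are rejected with errors naming the feature. Coding
sequences are spliced by concatenating exon segments in genome order and
reverse-complementing for minus-strand genes.

Two genetic codes are supported: the standard nuclear code and the
CTG-clade alternative yeast nuclear code (NCBI translation table 12), which
differs from the standard code only in translating CTG as serine. Several
CTG-clade table variants exist in the literature; table 12 is the canonical
CTG→Ser reassignment and is the one implemented. Ambiguity codes other than
N are rejected; a codon containing N translates to `X`, so unknown bases
degrade predictably instead of silently.

## Pairwise alignment and identity

Global (end-to-end) protein alignment uses BLOSUM62 with affine gap
penalties, open 10 and extend 0.5 (a gap of length L costs
10 + 0.5·(L−1); terminal gaps are penalized). The alignment engine is
Biopython's `PairwiseAligner`; among co-optimal alignments the aligner's
canonical first traceback is returned, which is deterministic for fixed
input — reruns always give the same alignment, and hence the same
extracted signatures. Percent identity is computed as identical columns
divided by alignment columns, **excluding terminal-gap columns**, so a
perfect prefix match against a longer sequence scores 100 %. Reference
coverage (used by the cluster scanner) is the fraction of reference
residues aligned to a residue of the query. These conventions are stated
because there is no universal definition of "percent identity"; both
numbers are echoed in every report.

## Cluster mining

Candidates are assigned one of three roles — AG (α-glucosidase), AGT
(α-glucoside transporter), ACT (Zn(2)-Cys(6) MAL-activator) — by
best-scoring global alignment against one reference protein per role,
subject to identity ≥ 30 % and coverage ≥ 50 % (defaults; both
configurable and logged per candidate). A gene whose `product` annotation
matches a role keyword (for instance "Zn(2)-Cys(6)" for activators) is
admitted as a candidate even below the homology thresholds, mirroring how
activators are typically recognized by domain annotation rather than
sequence similarity. Score ties between references of different roles fall
back to identity; if still tied the gene is flagged `ambiguous_role` and is
counted as a cluster member but cannot satisfy the AG requirement.

A cluster is a maximal run of candidates on one contig in which
consecutive candidates are separated by at most `max_gap` (default
10,000 bp), with ≥ 2 members and ≥ 1 unambiguous AG. The gap bound is a
proxy for "neighboring genes" — real cluster definitions in comparative
genomics are synteny-based rather than distance-based — and therefore
remains configurable. Non-candidate genes lying between candidates do not
break a run; their ids are listed in the JSON evidence. Unclustered
candidates are retained in the evidence rather than discarded.

Geometry annotations: a divergent pair is two genomically adjacent members
with the left gene on `-` and the right on `+` (5′ ends facing) and
intergenic distance ≤ `max_promoter_span` (default 2,000 bp — the typical
scale of a yeast bidirectional promoter). The telomere distance of a
cluster is `min(span_start − 1, contig_length − span_end)`; a cluster is
flagged subtelomeric when this distance is ≤ 50,000 bp. The 50 kb default
reflects common usage in yeast comparative genomics, where loci a few
hundred kb from the chromosome end are firmly non-subtelomeric; the
threshold is configurable and echoed in report headers because the
literature has no single agreed number.

## Signature extraction and classification

The nine residues bordering the GH13 α-glucosidase substrate-binding
pocket — positions 158, 216, 217, 218, 219, 278, 279, 307 and 411 in
S. cerevisiae IMA1 numbering — discriminate maltases, isomaltases and
promiscuous maltase-isomaltases. A query is globally aligned to the
reference scaffold and the query symbols in the columns of the nine anchor
positions form its signature; a gap at an anchor reads `-`, and this gap
convention applies uniformly to all nine anchors.

The bundled reference, and the scaffold to which all numbering is
anchored, is a **synthetic stand-in** for IMA1 (see
`malminer/_references.py`): a deterministic random 589-residue sequence
carrying the isomaltase signature residues Y158, V216, G217, S218, L219,
M278, Q279, D307, E411. Extraction against it returns `YVGSLMQDE` exactly,
and all internal position mapping is self-consistent. Signatures of real
proteins extracted against this scaffold will not correspond to their true
structural positions; to analyze real data, replace the profile's
reference sequence with the genuine IMA1 sequence (a one-line
`SignatureProfile` construction) — every downstream step is unchanged.

Classification follows a fixed rule order: (1) V216 → isomaltase — Val216
is the single key determinant of isomaltose-type activity, and every
characterized isomaltase carries it; (2) T216-V217 or A216-I217 → maltase —
motifs of characterized maltases of early-diverged yeasts, filamentous
fungi and bacilli; (3) V216-I217 → isomaltase — logically subsumed by rule
1 but retained so reports can show which motif matched; (4) otherwise the
signature is maltose-capable (e.g. T-A-G at 216–218, shared by maltases
and maltase-isomaltases) and the label comes from a nearest-reference vote:
the match count (identical non-gap symbols, 0–9) against every curated
reference labelled maltase or maltase-isomaltase, the maximum deciding.
Isomaltase references do not vote, because step 4 is only reached by
maltose-capable signatures. Ties across labels, and a gap at position 216,
are reported as `ambiguous` — never silently resolved. This single
procedure reproduces the curated label of all 34 bundled reference
signatures (verified in the acceptance suite).

One curiosity of the curated table: comparing the *Cf* AG1.1 row
(`MVCSLVGSQ`) against *Sc* IMA5 (`FVGSMVGSE`) position-by-position gives 5
matches, though the value is sometimes quoted as six; the package reports
the computed count.

## Phylograms

Multiple alignment is guide-tree progressive: pairwise global alignments
give 1 − fractional-identity distances, average-linkage clustering fixes
the merge order, and profiles are merged by affine-gap profile alignment
(column-column score = expected BLOSUM62 score over the columns' residue
frequencies; once a gap, always a gap). Traceback ties prefer substitution
over gaps deterministically. The profile DP is quadratic in sequence
length and intended for the tens-of-taxa, single-protein-family trees this
package builds, not for genome-scale alignment.

Distances: `p` (proportion of differing sites), `jc` (Jukes–Cantor
nucleotide correction, provided as the species-tree substitute for
composite-likelihood nucleotide distances, which are out of scope) and
`dayhoff` — the maximum-likelihood pairwise distance under the Dayhoff
(1978) empirical amino-acid model. The Dayhoff rate matrix is built from
the published exchangeabilities and equilibrium frequencies (as distributed
in PAML's `dayhoff.dat`), normalized to one expected substitution per site
at t = 1; the likelihood is maximized by bounded scalar optimization on
[1e−6, 10] substitutions/site with tolerance 1e−8, using the
eigendecomposition of the reversible rate matrix for fast P(t). Identical
rows return exactly 0. Pairs whose likelihood is still increasing at the
search bound are flagged as saturated and raise a distinct error rather
than returning a fabricated distance. The implementation was cross-checked
against an independent R implementation of the same model; agreement is
within the optimizers' tolerance (~1e−4) and frozen values are asserted in
the test suite. Gapped sites are handled by pairwise deletion by default;
complete deletion is a config switch. Pairwise deletion is the default
because divergent family members are often gappy enough that complete
deletion would discard most columns.

Neighbor joining is implemented directly (it is the core reconstruction
method here): standard Q-criterion agglomeration, with ties broken by the
lexicographically smallest pair of subtree labels so the topology is
independent of input order, and negative branch-length estimates clamped
to zero (clamping is logged). Two taxa yield a single edge split evenly;
three or more yield the standard trifurcating-root representation of an
unrooted tree. Because Q is assembled by floating-point subtraction, the
matrix is symmetrized explicitly before the minimum search (the two
triangles can differ by 1 ulp). On additive matrices the implementation
recovers the generating topology exactly and path lengths to < 1e−9
(asserted over 200 random 4–8 taxon trees); an independent NJ
implementation (scikit-bio) is used as a topology cross-check in the unit
tests.

Bootstrap: alignment columns are resampled with replacement; the support
of each internal edge of the reference tree is the percentage of replicate
NJ trees containing the same bipartition. Replicates with an undefined
distance (no comparable columns, saturation) are skipped and excluded from
the denominator. All resampling flows from one seed; identical seeds give
identical supports. The production default is 1000 replicates; tests and
the acceptance script use 100–200, which is ample for determinism and
sanity-band checks. Newick output carries branch lengths and supports as
internal-node labels and round-trips through the bundled reader.

## Synthetic data

The generator emulates the genomic structures the scanner is designed to
find: clusters of 2–4 genes with configured roles, strands, intergenic
gaps, intron counts and contig placement — including the four-gene
activator/AGT/AG/activator layout with a divergent AGT/AG pair — plus
hard-negative decoys. The default configuration (the condition under which
recovery statistics are quoted) is 2 contigs × 200 kb, 1–8 planted
clusters per genome with the four-gene layout always present, divergent
gaps of 0.3–1.8 kb, other gaps 0.3–8 kb, 50 decoy genes, and 5 %
per-residue mutation away from the reference proteins. Member proteins are
mutated copies of the role references; AG proteins carry a signature drawn
from the curated table, planted by writing its symbols into the scaffold's
anchor positions (a `-` symbol deletes a short window covering that
anchor) and verified by re-extraction. Decoys are composition-preserving
shuffles of reference proteins, accepted only below 20 % identity to every
reference, so they are hard negatives with realistic amino-acid
composition. Genes are reverse-translated with one fixed codon per amino
acid (the standard-code table spells Leu as CTG and the CTG-clade table
spells Ser as CTG, so translation round-trips exercise the reassigned
codon), intronated with GT..AG segments, and placed so that clusters keep
max_gap + 2 kb of clearance from each other; infeasible layouts fail
before anything is written. All outputs are byte-identical for a fixed
seed, and the emitted truth document records clusters, divergent pairs,
telomere distances, intron counts, planted signatures and the full config.

What the generator does **not** emulate: realistic codon usage and GC
structure, indel evolution, paralogy and pseudogenes, fragmented or
misannotated gene models, and homology at intermediate identity
(20–30 %) where threshold behavior is delicate. Perfect precision/recall
on these genomes therefore demonstrates the correctness of the scanning
logic — run merging, gap bounds, role assignment, geometry — not
robustness to the annotation noise of real assemblies.

## Problem sizes used in checks

Recovery statistics quoted by the acceptance script are computed at these
sizes: 10 synthetic genomes (20 in the test suite) for cluster
precision/recall; 100 planted proteins at 10 % mutation for signature
recovery; 200 random additive matrices for NJ consistency; ~3,900 sequence
pairs (exhaustive up to length 3 over a 4-letter alphabet, plus seeded
random pairs of lengths 4–6) for the alignment-score oracle; 200 bootstrap
replicates for the determinism check. The alignment oracle is an
independent memoized recursion over (position, position, previous move)
with the same scoring convention; exhaustive enumeration of *all* pairs up
to length 6 (~15 million pairs) is not attempted — the exhaustive short
pairs already cover every gap/terminal-gap topology the affine recurrence
distinguishes.

## Known limitations

- The signature scaffold is synthetic (see above); real-data use requires
  supplying the genuine reference sequence.
- Cluster membership is distance-based, not synteny-based; `max_gap` is a
  proxy with no biological constant behind it.
- The classifier's nearest-reference vote is only as good as the curated
  table; signatures far from every reference still receive the
  nearest label unless tied, and only ties are flagged ambiguous.
- GH31-family α-glucosidases are outside the classifier's scope (the
  signature system is GH13-specific); family gating is the caller's
  responsibility.
- Maximum-likelihood and Bayesian tree search, rooting and dating are out
  of scope; trees are unrooted NJ phylograms.
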