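"""Neighbor-joining phylograms of AG/AGT proteins with bootstrap support.

Distance-based pipeline: progressive multiple alignment over pairwise
global alignments, pairwise evolutionary distances (proportion of
differing sites, its Jukes-Cantor nucleotide correction, or a maximum
likelihood distance under the Dayhoff empirical amino-acid model),
neighbor joining with non-negative branch lengths, and bootstrap support
from column resampling.  Trees serialize to Newick with branch lengths
in substitutions per site and supports as internal-node labels.

Gapped sites are handled by pairwise deletion by default (each pair of
rows is compared over the columns where neither is gapped); complete
deletion (drop every column containing any gap) is available as an
option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform
from skbio import TreeNode

from . import _dayhoff
from .signatures import DEFAULT_SCORING, ScoringParams, global_align

logger = logging.getLogger("malminer.phylo")

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA20_INDEX = {aa: i for i, aa in enumerate(AA20)}


class DistanceError(ValueError):
    """Raised when a pairwise distance cannot be computed (no comparable
    columns, or saturation under the correction model)."""


# ---------------------------------------------------------------------------
# Multiple alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultipleAlignment:
    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise ValueError("alignment needs >= 2 taxa")
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError("taxon names must be unique")
        if len(self.rows) != len(self.taxa):
            raise ValueError("one row per taxon required")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@lru_cache(maxsize=4)
def _matrix20(name: str) -> np.ndarray:
    mat = substitution_matrices.load(name)
    out = np.zeros((20, 20))
    for i, a in enumerate(AA20):
        for j, b in enumerate(AA20):
            out[i, j] = mat[a, b]
    return out


def _profile_freqs(rows: Sequence[str]) -> np.ndarray:
    """Per-column residue frequency vectors (gaps and X excluded)."""
    ncol = len(rows[0])
    freqs = np.zeros((ncol, 20))
    for row in rows:
        for j, aa in enumerate(row):
            idx = _AA20_INDEX.get(aa)
            if idx is not None:
                freqs[j, idx] += 1.0
    totals = freqs.sum(axis=1, keepdims=True)
    np.divide(freqs, totals, out=freqs, where=totals > 0)
    return freqs


def _profile_align(rows_a: Sequence[str], rows_b: Sequence[str],
                   scoring: ScoringParams) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two alignment profiles.

    Column-column substitution score is the expected matrix score over the
    two columns' residue frequencies; traceback ties prefer substitution,
    then a gap in the second profile, then a gap in the first.
    """
    S = _profile_freqs(rows_a) @ _matrix20(scoring.matrix) @ _profile_freqs(rows_b).T
    n, m = S.shape
    go, ge = scoring.gap_open, scoring.gap_extend
    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap columns in profile B (consume A)
    Y = np.full((n + 1, m + 1), neg)  # gap columns in profile A (consume B)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, m + 1):
        Y[0, j] = -(go + (j - 1) * ge)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = prev + S[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            Y[i, j] = max(M[i, j - 1] - go, Y[i, j - 1] - ge, X[i, j - 1] - go)
    # traceback
    path: list[str] = []
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][n, m])
    # deterministic preference on exact ties: M > X > Y
    for cand in ("M", "X", "Y"):
        if {"M": M, "X": X, "Y": Y}[cand][n, m] == {"M": M, "X": X, "Y": Y}[state][n, m]:
            state = cand
            break
    while i > 0 or j > 0:
        path.append(state)
        if state == "M":
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand, val in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if np.isclose(val, target, rtol=0.0, atol=1e-9):
                    state = cand
                    break
        elif state == "X":
            target = X[i, j]
            i -= 1
            for cand, val in (("M", M[i, j] - go), ("X", X[i, j] - ge),
                              ("Y", Y[i, j] - go)):
                if np.isclose(val, target, rtol=0.0, atol=1e-9):
                    state = cand
                    break
        else:
            target = Y[i, j]
            j -= 1
            for cand, val in (("M", M[i, j] - go), ("Y", Y[i, j] - ge),
                              ("X", X[i, j] - go)):
                if np.isclose(val, target, rtol=0.0, atol=1e-9):
                    state = cand
                    break
    path.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for move in path:
        if move in ("M", "X"):
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if move in ("M", "Y"):
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


def progressive_align(seqs: Sequence[tuple[str, str]],
                      scoring: ScoringParams = DEFAULT_SCORING,
                      ) -> MultipleAlignment:
    """Guide-tree progressive multiple alignment.

    Pairwise global alignments give a distance matrix (one minus fractional
    identity); average-linkage clustering on it fixes the merge order; and
    profiles are merged by affine-gap profile alignment ("once a gap,
    always a gap").  Deterministic for a fixed input order.
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs >= 2 sequences")
    names = [n for n, _ in seqs]
    if len(names) != len(set(names)):
        raise ValueError("sequence names must be unique")
    if len(seqs) == 2:
        aln = global_align(seqs[0][1], seqs[1][1], scoring)
        return MultipleAlignment(taxa=tuple(names),
                                 rows=(aln.aligned_a, aln.aligned_b))

    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_align(seqs[i][1], seqs[j][1], scoring).identity
            dist[i, j] = dist[j, i] = 1.0 - ident / 100.0
    merges = linkage(squareform(dist, checks=False), method="average")

    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([name], [seq]) for i, (name, seq) in enumerate(seqs)
    }
    next_id = n
    for a_id, b_id, _, _ in merges:
        names_a, rows_a = profiles.pop(int(a_id))
        names_b, rows_b = profiles.pop(int(b_id))
        out_a, out_b = _profile_align(rows_a, rows_b, scoring)
        profiles[next_id] = (names_a + names_b, out_a + out_b)
        next_id += 1
    (merged_names, merged_rows), = profiles.values()
    order = [merged_names.index(name) for name in names]
    return MultipleAlignment(taxa=tuple(names),
                             rows=tuple(merged_rows[i] for i in order))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _comparable(row_a: str, row_b: str, alphabet: set[str]
                ) -> list[tuple[str, str]]:
    return [(a, b) for a, b in zip(row_a, row_b)
            if a in alphabet and b in alphabet]


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing sites under pairwise deletion."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    pairs = _comparable(row_a, row_b, set(AA20) | set("ACGTU"))
    if not pairs:
        raise DistanceError("no comparable (gap-free) columns")
    mismatches = sum(1 for a, b in pairs if a != b)
    return mismatches / len(pairs)


def jukes_cantor_distance(row_a: str, row_b: str) -> float:
    """Jukes-Cantor corrected nucleotide distance (substitutions/site)."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    pairs = _comparable(row_a.upper(), row_b.upper(), set("ACGTU"))
    if not pairs:
        raise DistanceError("no comparable nucleotide columns")
    p = sum(1 for a, b in pairs if a != b) / len(pairs)
    if p >= 0.75:
        raise DistanceError(f"saturated pair (p = {p:.3f} >= 0.75)")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


@lru_cache(maxsize=1)
def _dayhoff_model() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of the normalized Dayhoff rate matrix.

    Returns (pi, eigenvalues, left, right) such that
    ``P(t) = right @ diag(exp(lam * t)) @ left`` with rows/columns in
    Dayhoff order ARNDCQEGHILKMFPSTWYV.
    """
    pi = np.array(_dayhoff.FREQUENCIES)
    s = np.zeros((20, 20))
    k = 0
    for j in range(20):  # column-major lower triangle
        for i in range(j + 1, 20):
            s[i, j] = s[j, i] = _dayhoff.EXCHANGEABILITIES[k]
            k += 1
    rate = s * pi[np.newaxis, :]
    np.fill_diagonal(rate, 0.0)
    np.fill_diagonal(rate, -rate.sum(axis=1))
    mu = -(pi * np.diag(rate)).sum()
    rate /= mu  # one expected substitution per site at t = 1
    sq = np.sqrt(pi)
    sym = rate * sq[:, np.newaxis] / sq[np.newaxis, :]
    lam, vec = np.linalg.eigh((sym + sym.T) / 2.0)
    right = vec / sq[:, np.newaxis]
    left = vec.T * sq[np.newaxis, :]
    return pi, lam, left, right


_DAYHOFF_AA_INDEX = {aa: i for i, aa in enumerate(_dayhoff.AA_ORDER)}

#: Upper bound of the distance search (substitutions/site); pairs whose
#: likelihood still increases here are flagged as saturated.
DAYHOFF_MAX_DISTANCE = 10.0


def dayhoff_distance(row_a: str, row_b: str) -> float:
    """Maximum-likelihood pairwise distance under the Dayhoff model.

    Sites with a gap or ambiguous residue in either row are skipped
    (pairwise deletion).  Identical rows give 0; saturated pairs raise
    :class:`DistanceError`.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    counts = np.zeros((20, 20))
    for a, b in zip(row_a, row_b):
        ia, ib = _DAYHOFF_AA_INDEX.get(a), _DAYHOFF_AA_INDEX.get(b)
        if ia is not None and ib is not None:
            counts[ia, ib] += 1.0
    total = counts.sum()
    if total == 0:
        raise DistanceError("no comparable (gap-free) columns")
    if counts.trace() == total:
        return 0.0

    _, lam, left, right = _dayhoff_model()

    def neg_log_lik(t: float) -> float:
        p = (right * np.exp(lam * t)) @ left
        return -(counts * np.log(np.clip(p, 1e-300, None))).sum()

    res = minimize_scalar(neg_log_lik, bounds=(1e-6, DAYHOFF_MAX_DISTANCE),
                          method="bounded", options={"xatol": 1e-8})
    d = float(res.x)
    if d >= DAYHOFF_MAX_DISTANCE * 0.999:
        raise DistanceError(
            f"saturated pair (ML distance at search bound "
            f"{DAYHOFF_MAX_DISTANCE})"
        )
    return d


DISTANCE_FUNCTIONS: dict[str, Callable[[str, str], float]] = {
    "p": p_distance,
    "dayhoff": dayhoff_distance,
    "jc": jukes_cantor_distance,
}


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("distances must be finite and non-negative")

    def to_tsv(self, path) -> None:
        """Taxa header plus lower triangle, tab-separated."""
        with open(path, "w") as handle:
            handle.write("\t".join(self.taxa) + "\n")
            for i, taxon in enumerate(self.taxa):
                row = ["%.10g" % self.values[i, j] for j in range(i)]
                handle.write("\t".join([taxon, *row]).rstrip("\t") + "\n")


def build_distance_matrix(aln: MultipleAlignment, method: str = "dayhoff",
                          gap_handling: str = "pairwise") -> DistanceMatrix:
    """Pairwise distance matrix from an alignment.

    ``gap_handling='complete'`` drops every column containing a gap before
    any comparison; ``'pairwise'`` (default) skips gapped sites per pair.
    Saturated pairs propagate as :class:`DistanceError`.
    """
    fn = DISTANCE_FUNCTIONS[method]
    rows = list(aln.rows)
    if gap_handling == "complete":
        keep = [j for j in range(aln.n_columns)
                if all(r[j] != "-" for r in rows)]
        rows = ["".join(r[j] for j in keep) for r in rows]
    elif gap_handling != "pairwise":
        raise ValueError(f"unknown gap handling {gap_handling!r}")
    n = len(rows)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                values[i, j] = values[j, i] = fn(rows[i], rows[j])
            except DistanceError as exc:
                raise DistanceError(
                    f"pair ({aln.taxa[i]}, {aln.taxa[j]}): {exc}") from exc
    return DistanceMatrix(taxa=aln.taxa, values=values)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhyloTree:
    """An unrooted tree (rooted representation with a trifurcating root for
    >= 3 taxa), with branch lengths and optional bootstrap supports."""

    root: TreeNode
    has_supports: bool = False

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(t.name for t in self.root.tips()))

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each encoded as the side not containing the
        lexicographically smallest taxon."""
        return _bipartitions(self.root)


def _bipartitions(root: TreeNode) -> set[frozenset]:
    all_taxa = frozenset(t.name for t in root.tips())
    anchor = min(all_taxa)
    splits = set()
    for node in root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(all_taxa) - 2:
            continue
        if anchor in side:
            side = all_taxa - side
        splits.add(side)
    return splits


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.debug("clamping negative branch length %.3g at %s", length, context)
        return 0.0
    return length


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining on the Q-criterion.

    Q ties are broken by the lexicographically smallest pair of subtree
    labels (each subtree labelled by its smallest leaf name), making the
    topology independent of input taxon order.  Negative branch-length
    estimates are clamped to zero.
    """
    n = len(D.taxa)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in D.taxa]
    labels: list[str] = list(D.taxa)  # smallest leaf name per subtree
    d = D.values.astype(float).copy()
    d = (d + d.T) / 2.0  # exact symmetry so Q-ties pair across the diagonal

    if n == 2:
        half = d[0, 1] / 2.0
        for node in nodes:
            node.length = _clamp(half, "2-taxon edge")
        return PhyloTree(root=TreeNode(children=nodes))

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, np.newaxis] - r[np.newaxis, :]
        q = np.minimum(q, q.T)  # exact symmetry (subtraction order varies by 1 ulp)
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = [(i, j) for i in range(m) for j in range(i + 1, m)
                if q[i, j] == qmin]
        i, j = min(ties, key=lambda ij: tuple(sorted((labels[ij[0]],
                                                      labels[ij[1]]))))
        vi = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        nodes[i].length = _clamp(vi, f"join({labels[i]},{labels[j]})")
        nodes[j].length = _clamp(vj, f"join({labels[i]},{labels[j]})")
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_d = (d[i] + d[j] - d[i, j]) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)],
                       new_d[keep][np.newaxis, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, np.newaxis]])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = _clamp((dab + dac - dbc) / 2.0, "final star")
    b.length = _clamp((dab + dbc - dac) / 2.0, "final star")
    c.length = _clamp((dac + dbc - dab) / 2.0, "final star")
    return PhyloTree(root=TreeNode(children=[a, b, c]))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(aln: MultipleAlignment, n_reps: int, seed: int,
                      distance_fn: str = "p",
                      gap_handling: str = "pairwise") -> PhyloTree:
    """NJ tree of the alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each internal edge of the reference tree is the percentage of
    replicates whose NJ tree contains the same bipartition.  Replicates in
    which a distance is undefined (no comparable columns / saturation) are
    skipped and excluded from the denominator.  Identical seeds give
    identical supports.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ref_tree = neighbor_joining(
        build_distance_matrix(aln, distance_fn, gap_handling))
    rng = np.random.default_rng(seed)
    ncol = aln.n_columns
    counts: dict[frozenset, int] = {split: 0 for split in ref_tree.bipartitions()}
    completed = 0
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rep = MultipleAlignment(
            taxa=aln.taxa,
            rows=tuple("".join(row[k] for k in idx) for row in aln.rows),
        )
        try:
            rep_tree = neighbor_joining(
                build_distance_matrix(rep, distance_fn, gap_handling))
        except DistanceError:
            logger.debug("bootstrap replicate skipped (undefined distance)")
            continue
        completed += 1
        rep_splits = rep_tree.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    if completed == 0:
        raise DistanceError("all bootstrap replicates had undefined distances")

    all_taxa = frozenset(aln.taxa)
    anchor = min(all_taxa)
    for node in ref_tree.root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(all_taxa) - 2:
            continue
        key = side if anchor not in side else all_taxa - side
        support = 100.0 * counts[key] / completed
        node.bootstrap = support
        node.name = "%g" % round(support, 1)
    return PhyloTree(root=ref_tree.root, has_supports=True)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: PhyloTree, path) -> None:
    """Write Newick with branch lengths; bootstrap supports (when present)
    appear as internal-node labels."""
    tree.root.write(str(path), format="newick")


def read_newick(path) -> PhyloTree:
    root = TreeNode.read(str(path), format="newick", convert_underscores=False)
    has_supports = False
    for node in root.non_tips(include_self=False):
        if node.name is not None:
            try:
                node.bootstrap = float(node.name)
                has_supports = True
            except ValueError:
                pass
    return PhyloTree(root=root, has_supports=has_supports)
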