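"""Pairwise protein similarity and best-bidirectional-hit detection.

A desk-scale stand-in for proteome-wide BLASTp searches: Smith–Waterman
local alignment with affine gaps under BLOSUM62 (gap open 11, extend 1),
raw score ranking, and mutual-best-hit pairing between proteomes.  The
ambiguity residue X scores 0 against everything.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_MIN_SCORE = 40.0


@dataclass(frozen=True)
class Hit:
    """One query-vs-subject local alignment result."""

    query: str
    subject: str
    score: float
    identity: float


@dataclass(frozen=True)
class BBHPair:
    """A best bidirectional hit: each gene is the other's top match."""

    gene_a: str
    gene_b: str


@lru_cache(maxsize=None)
def blosum62_matrix():
    """BLOSUM62 with the X row/column zeroed (neutral ambiguity)."""
    mat = substitution_matrices.load("BLOSUM62")
    mat = mat.copy()
    for ch in mat.alphabet:
        mat["X", ch] = 0.0
        mat[ch, "X"] = 0.0
    return mat


def _make_aligner(matrix, gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _check_alphabet(seq: str, matrix, label: str) -> None:
    missing = set(seq) - set(matrix.alphabet)
    if missing:
        raise ValueError(f"residue(s) {sorted(missing)} in {label} absent from scoring matrix")


def local_align_score(
    seq_a: str,
    seq_b: str,
    matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[float, float]:
    """Smith–Waterman local alignment score and identity.

    Returns ``(score, identity)`` where identity is the fraction of
    identical residue pairs over all columns of the optimal local
    alignment (gap columns count against identity).  Score is >= 0;
    an empty optimal alignment has identity 0.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if matrix is None:
        matrix = blosum62_matrix()
    _check_alphabet(seq_a, matrix, "first sequence")
    _check_alphabet(seq_b, matrix, "second sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend, "local")
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return 0.0, 0.0
    aln = next(iter(aligner.align(seq_a, seq_b)))
    ident = matches = columns = 0
    for col_a, col_b in zip(*aln):
        columns += 1
        if col_a == col_b and col_a != "-":
            matches += 1
    ident = matches / columns if columns else 0.0
    return float(score), ident


def best_hits(
    query_proteome,
    target_proteome,
    min_score: float = DEFAULT_MIN_SCORE,
    matrix=None,
) -> dict[str, list[Hit]]:
    """Ranked hit lists per query against a target proteome.

    Hits below ``min_score`` are dropped.  Ties are broken by higher
    identity, then lexicographic subject id, so output is deterministic
    and independent of input order.
    """
    if not query_proteome or not target_proteome:
        raise ValueError("proteomes must be non-empty")
    if matrix is None:
        matrix = blosum62_matrix()
    result: dict[str, list[Hit]] = {}
    targets = sorted(target_proteome, key=lambda r: r.id)
    for q in query_proteome:
        hits = []
        for t in targets:
            score, ident = local_align_score(q.sequence, t.sequence, matrix=matrix)
            if score >= min_score:
                hits.append(Hit(q.id, t.id, score, ident))
        hits.sort(key=lambda h: (-h.score, -h.identity, h.subject))
        result[q.id] = hits
    return result


def find_bbh(
    proteome_a,
    proteome_b,
    min_score: float = DEFAULT_MIN_SCORE,
    matrix=None,
) -> set[BBHPair]:
    """Best bidirectional hits between two proteomes.

    A pair (a, b) is returned iff b is a's top-ranked hit in B and a is
    b's top-ranked hit in A.  No gene appears in more than one pair.
    """
    ab = best_hits(proteome_a, proteome_b, min_score=min_score, matrix=matrix)
    ba = best_hits(proteome_b, proteome_a, min_score=min_score, matrix=matrix)
    pairs = set()
    for a_id, hits in ab.items():
        if not hits:
            continue
        b_id = hits[0].subject
        back = ba.get(b_id)
        if back and back[0].subject == a_id:
            pairs.add(BBHPair(a_id, b_id))
    return pairs
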