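"""Internal pairwise-alignment helpers shared across modules.

Two complementary engines:

* :func:`best_diagonal_overlap` — exact k-mer seeding followed by gapless
  (band-0) extension along the best diagonal.  Identity is matches over
  overlap columns.  This is the workhorse for all-vs-all read comparison
  and overlap detection during assembly, where the substitution-dominated
  error model makes gapless comparison equivalent to full dynamic
  programming.
* :func:`local_dna` / :func:`local_protein` — full Smith-Waterman via
  Biopython's PairwiseAligner (DNA: +1/-2, gap -5/-2; protein: BLOSUM62,
  gap -11/-1), used where indel tolerance matters (rRNA screening,
  peptide-vs-proteome search).

Identity throughout = matches / alignment columns, gap columns included.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "revcomp",
    "kmer_set",
    "shares_kmer",
    "DiagonalOverlap",
    "best_diagonal_overlap",
    "LocalAlignment",
    "local_dna",
    "local_protein",
]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def kmer_set(seq: str, k: int) -> frozenset[str]:
    if len(seq) < k:
        return frozenset()
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def shares_kmer(kmers_a: frozenset[str], kmers_b: frozenset[str]) -> bool:
    return not kmers_a.isdisjoint(kmers_b)


@dataclass(frozen=True)
class DiagonalOverlap:
    """A gapless placement of ``b`` at ``offset`` relative to ``a``.

    ``matches``/``length`` are counted over the overlap columns only; N
    positions never count as matches.
    """

    offset: int
    matches: int
    length: int

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


def _overlap_at(a: str, b: str, offset: int) -> DiagonalOverlap:
    start_a = max(0, offset)
    end_a = min(len(a), offset + len(b))
    length = end_a - start_a
    if length <= 0:
        return DiagonalOverlap(offset, 0, 0)
    sub_a = a[start_a:end_a]
    sub_b = b[start_a - offset : end_a - offset]
    matches = sum(
        1 for x, y in zip(sub_a, sub_b) if x == y and x != "N"
    )
    return DiagonalOverlap(offset, matches, length)


def best_diagonal_overlap(
    a: str, b: str, k: int = 16, min_overlap: int = 1
) -> DiagonalOverlap | None:
    """Best gapless overlap of ``b`` against ``a`` among k-mer-seeded diagonals.

    Candidate offsets are the diagonals on which ``a`` and ``b`` share an
    exact k-mer; each is scored by match count over the full overlap and the
    best (most matches, then smallest |offset|, then smallest offset) is
    returned.  Returns None when no seeded diagonal reaches ``min_overlap``
    columns.
    """
    if len(a) < k or len(b) < k:
        return None
    pos_a: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        pos_a.setdefault(a[i : i + k], []).append(i)
    diagonals: set[int] = set()
    for j in range(len(b) - k + 1):
        word = b[j : j + k]
        if "N" in word:
            continue
        for i in pos_a.get(word, ()):
            diagonals.add(i - j)
    best: DiagonalOverlap | None = None
    for d in sorted(diagonals):
        cand = _overlap_at(a, b, d)
        if cand.length < min_overlap:
            continue
        if (
            best is None
            or cand.matches > best.matches
            or (
                cand.matches == best.matches
                and (abs(cand.offset), cand.offset) < (abs(best.offset), best.offset)
            )
        ):
            best = cand
    return best


@dataclass(frozen=True)
class LocalAlignment:
    """A local alignment: raw score, identity over columns, and spans."""

    score: float
    identity: float
    columns: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int


@lru_cache(maxsize=None)
def _dna_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


@lru_cache(maxsize=None)
def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _summarize(alignment, ambiguous: str) -> LocalAlignment:
    row_a, row_b = str(alignment[0]), str(alignment[1])
    columns = len(row_a)
    skip = "-" + ambiguous
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x not in skip)
    (a_blocks, b_blocks) = alignment.aligned
    a_start, a_end = int(a_blocks[0][0]), int(a_blocks[-1][1])
    b_start, b_end = int(b_blocks[0][0]), int(b_blocks[-1][1])
    identity = matches / columns if columns else 0.0
    return LocalAlignment(
        float(alignment.score), identity, columns, a_start, a_end, b_start, b_end
    )


def local_dna(a: str, b: str) -> LocalAlignment | None:
    """Best Smith-Waterman local alignment of two DNA strings (forward only)."""
    alignments = _dna_aligner().align(a, b)
    if not alignments or alignments.score <= 0:
        return None
    return _summarize(alignments[0], ambiguous="N")


def local_protein(a: str, b: str) -> LocalAlignment | None:
    """Best BLOSUM62 local alignment of two peptides; None if nothing scores > 0."""
    if not a or not b:
        return None
    try:
        alignments = _protein_aligner().align(a, b)
    except ValueError:
        # residues outside the matrix alphabet
        return None
    if not alignments or alignments.score <= 0:
        return None
    return _summarize(alignments[0], ambiguous="X*")
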