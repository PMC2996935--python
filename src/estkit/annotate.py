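"""Functional annotation of assembled transcripts.

Transcripts are conceptually translated in all six reading frames and each
frame is locally aligned (BLOSUM62, affine gaps) against a protein
reference set.  The resulting suite of hits is turned into a single
functional description by a relevance-scoring scheme over description
words: each word is weighted by the summed alignment quality of the
descriptions containing it, ubiquitous low-information words ("protein",
"similar", ...) are removed by a document-frequency stoplist, words with
weight above mean + 2*STD of the remaining weights are deemed significant,
and the description whose significant words sum highest wins.

GO terms come from a user-supplied protein-to-term table; a transcript
inherits every term linked to any protein it hits.  Provenance (embryo
only / adult CNS only / mixed) is classified from the source libraries of
the FULL read membership of a contig, redundant reads included.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from . import _align
from .seqio import parse_identifier

logger = logging.getLogger(__name__)

__all__ = [
    "TranslatedFrame",
    "ProteinHit",
    "DescriptionIndex",
    "AnnotationRecord",
    "six_frame_translate",
    "align_peptides",
    "build_description_index",
    "select_description",
    "assign_go",
    "count_by_category",
    "classify_provenance",
]

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_CODON_TABLE.forward_table)
_CODON_TO_AA.update({codon: "*" for codon in _CODON_TABLE.stop_codons})

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class TranslatedFrame:
    frame: int  # +1..+3 on the given strand, -1..-3 on the reverse complement
    peptide: str


def _translate(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(_CODON_TO_AA.get(codon, "X"))  # codons containing N -> X
    return "".join(out)


def six_frame_translate(seq: str) -> list[TranslatedFrame]:
    """Translate a DNA string in all six frames (standard genetic code).

    Stops are kept in-line as '*'; any codon containing N translates to X.
    Frames -1..-3 are the three frames of the reverse complement.
    """
    seq = seq.upper()
    rc = _align.revcomp(seq)
    frames = []
    for frame in FRAMES:
        template = seq if frame > 0 else rc
        offset = abs(frame) - 1
        frames.append(TranslatedFrame(frame, _translate(template[offset:])))
    return frames


# ---------------------------------------------------------------------------
# protein homology

@dataclass(frozen=True)
class ProteinHit:
    transcript_id: str
    protein_id: str
    description: str
    score: float
    identity: float
    aln_length: int
    frame: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("negative alignment score")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0,1]")


@dataclass(frozen=True)
class ProteinRef:
    """One reference protein: id, peptide sequence, free-text description."""

    id: str
    peptide: str
    description: str


def align_peptides(
    transcript_id: str,
    frames: Sequence[TranslatedFrame],
    proteins: Sequence[ProteinRef],
    score_cutoff: float = 50.0,
    seed_k: int = 4,
    brute_force: bool = False,
) -> list[ProteinHit]:
    """Align every frame against every reference protein; best frame per protein.

    Local BLOSUM62 alignment with affine gaps (-11/-1).  Frame/protein
    pairs are prefiltered by a shared exact amino-acid ``seed_k``-mer
    unless ``brute_force``.  Hits with score >= ``score_cutoff`` are
    returned ordered by (score desc, protein_id).
    """
    if not proteins:
        raise ValueError("empty protein reference set")
    frame_kmers = [_align.kmer_set(f.peptide, seed_k) for f in frames]
    hits: list[ProteinHit] = []
    for prot in proteins:
        prot_kmers = _align.kmer_set(prot.peptide, seed_k) if not brute_force else None
        best: tuple[float, _align.LocalAlignment, int] | None = None
        for frame, kmers in zip(frames, frame_kmers):
            if not brute_force and not _align.shares_kmer(kmers, prot_kmers):
                continue
            aln = _align.local_protein(frame.peptide, prot.peptide)
            if aln is None:
                continue
            if best is None or aln.score > best[0]:
                best = (aln.score, aln, frame.frame)
        if best is not None and best[0] >= score_cutoff:
            aln = best[1]
            hits.append(
                ProteinHit(
                    transcript_id,
                    prot.id,
                    prot.description,
                    aln.score,
                    aln.identity,
                    aln.columns,
                    best[2],
                )
            )
    hits.sort(key=lambda h: (-h.score, h.protein_id))
    return hits


# ---------------------------------------------------------------------------
# description relevance scoring

_TOKEN_RE = re.compile(r"[^0-9a-z]+")
MIN_TOKEN_LEN = 3


def tokenize(description: str) -> list[str]:
    """Lowercase, split on non-alphanumerics, drop tokens shorter than 3."""
    return [
        tok
        for tok in _TOKEN_RE.split(description.lower())
        if len(tok) >= MIN_TOKEN_LEN
    ]


@dataclass(frozen=True)
class DescriptionIndex:
    word_weights: Mapping[str, float]
    mean_w: float
    std_w: float
    significant: frozenset[str]
    stoplist: frozenset[str]


def build_description_index(
    hits: Sequence[ProteinHit],
    corpus_df: Mapping[str, float] | None = None,
    stop_quantile: float = 0.01,
    significance: str = "mean_plus_2std",
    min_vocab: int = 8,
) -> DescriptionIndex:
    """Weight description words by summed alignment quality of their hits.

    A word appearing in several hit descriptions receives the sum of those
    hits' scores (counted once per description).  Words whose corpus
    document frequency falls in the top ``stop_quantile`` are stoplisted as
    low-information; of the rest, words with weight above mean + 2*STD
    (or, with ``significance="2std"``, above 2*STD) are significant.

    ``corpus_df`` maps word -> document frequency over the whole reference
    description corpus; when omitted it is computed from the hits at hand.

    Degenerate cases: when fewer than ``min_vocab`` distinct words survive
    the stoplist, or when their weights are all equal, a weight-tail
    threshold has no discriminating power and every kept word counts as
    significant.
    """
    weights: dict[str, float] = {}
    docs: list[set[str]] = []
    for hit in hits:
        words = set(tokenize(hit.description))
        docs.append(words)
        for word in words:
            weights[word] = weights.get(word, 0.0) + hit.score

    if corpus_df is None:
        corpus_df = (
            {w: sum(w in d for d in docs) / len(docs) for w in weights} if docs else {}
        )
    stoplist: set[str] = set()
    if corpus_df:
        values = np.array(sorted(corpus_df.values()))
        cutoff = float(np.quantile(values, 1.0 - stop_quantile))
        # only words strictly in the top tail; in a flat corpus nothing is stopped
        stoplist = {w for w, f in corpus_df.items() if f > cutoff}

    kept = {w: s for w, s in weights.items() if w not in stoplist}
    if kept:
        arr = np.array(list(kept.values()), dtype=float)
        mean_w, std_w = float(arr.mean()), float(arr.std())
    else:
        mean_w = std_w = 0.0
    threshold = mean_w + 2 * std_w if significance == "mean_plus_2std" else 2 * std_w
    if std_w == 0.0 or len(kept) < min_vocab:
        significant = frozenset(kept)
    else:
        significant = frozenset(w for w, s in kept.items() if s > threshold)
    return DescriptionIndex(weights, mean_w, std_w, significant, frozenset(stoplist))


def corpus_document_frequencies(descriptions: Iterable[str]) -> dict[str, float]:
    """Document frequency of each token over a description corpus."""
    docs = [set(tokenize(d)) for d in descriptions]
    if not docs:
        return {}
    counts: dict[str, int] = {}
    for d in docs:
        for w in d:
            counts[w] = counts.get(w, 0) + 1
    return {w: c / len(docs) for w, c in counts.items()}


@dataclass(frozen=True)
class AnnotationRecord:
    transcript_id: str
    chosen_description: str
    description_score: float
    go_terms: frozenset[str] = frozenset()
    provenance: str = "mixed"  # embryo_only | adult_only | mixed


def select_description(
    hits: Sequence[ProteinHit], index: DescriptionIndex
) -> tuple[str, float]:
    """Pick the hit description whose significant words sum highest.

    Ties break toward the description with the higher best single-hit
    score, then lexicographically.  With no hits the description is empty
    with score 0.
    """
    if not hits:
        return "", 0.0
    best_hit_score: dict[str, float] = {}
    for hit in hits:
        best_hit_score[hit.description] = max(
            best_hit_score.get(hit.description, 0.0), hit.score
        )
    scored = []
    for desc, hit_score in best_hit_score.items():
        words = set(tokenize(desc))
        score = sum(index.word_weights[w] for w in words if w in index.significant)
        scored.append((-score, -hit_score, desc))
    scored.sort()
    neg_score, _, desc = scored[0]
    return desc, -neg_score


# ---------------------------------------------------------------------------
# GO and provenance

def assign_go(
    hits: Sequence[ProteinHit], protein_terms: Mapping[str, set[str]]
) -> frozenset[str]:
    """Union of GO ids linked to any protein the transcript hits.

    Hit proteins absent from the term table are skipped (and logged).
    """
    if not protein_terms:
        raise ValueError("empty GO term table")
    terms: set[str] = set()
    for hit in hits:
        linked = protein_terms.get(hit.protein_id)
        if linked is None:
            logger.debug("protein %s absent from GO term table", hit.protein_id)
            continue
        terms.update(linked)
    return frozenset(terms)


def count_by_category(
    assignments: Mapping[str, Iterable[str]],
    term_names: Mapping[str, str],
    keyword: str,
    provenance: Mapping[str, str],
):
    """Per-GO-term transcript counts, filtered by a name keyword.

    Terms whose name contains ``keyword`` (case-insensitive) get one row
    with total matched transcripts and the split by provenance class
    (embryo only / adult CNS only / both).  Returns a pandas DataFrame
    ordered by total descending then term id.
    """
    import pandas as pd

    keyword = keyword.lower()
    per_term: dict[str, list[str]] = {}
    for transcript, terms in assignments.items():
        for term in terms:
            per_term.setdefault(term, []).append(transcript)
    rows = []
    for term, transcripts in per_term.items():
        name = term_names.get(term, "")
        if keyword not in name.lower():
            continue
        classes = [provenance[t] for t in transcripts]
        rows.append(
            {
                "term_id": term,
                "term_name": name,
                "total": len(transcripts),
                "embryo": classes.count("embryo_only"),
                "adult_cns": classes.count("adult_only"),
                "both": classes.count("mixed"),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["term_id", "term_name", "total", "embryo", "adult_cns", "both"]
    )
    return frame.sort_values(["total", "term_id"], ascending=[False, True]).reset_index(
        drop=True
    )


def classify_provenance(member_ids: Iterable[str]) -> str:
    """Library-of-origin class from the FULL read membership of a transcript.

    All reads from the embryo library -> embryo_only; all from adult CNS ->
    adult_only; otherwise mixed.  Redundant (non-contributing) reads count.
    """
    libraries = {parse_identifier(mid).library for mid in member_ids}
    if not libraries:
        raise ValueError("no member ids")
    if libraries == {"embryo"}:
        return "embryo_only"
    if libraries == {"adult_cns"}:
        return "adult_only"
    return "mixed"
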