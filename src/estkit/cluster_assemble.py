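"""Transitive-closure binning and greedy consensus assembly.

Every masked EST is compared against every other (both strands).  Pairs
whose best alignment reaches an identity threshold are joined into "bins"
— the connected components of the pairwise-hit graph — so that reads
related through a chain of overlaps assemble together even when the chain
ends never align directly.  Each bin is then assembled independently by a
greedy overlap-layout-consensus procedure into contigs, singletons
(reads joining no contig) and problem sequences (reads with too many
ambiguous N bases to assemble).

Strict identity thresholds (95% within-contig by default) deliberately
keep close paralogs, genetic variants and splice variants apart as
separate transcripts rather than collapsing them.

All orderings are total (score, then lexicographic id), so binning and
assembly are fully deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from . import _align
from .preprocess import MaskedEST
from .seqio import contig_id

__all__ = [
    "PairwiseHit",
    "Bin",
    "Placement",
    "Contig",
    "AssemblyOutput",
    "AssemblyParams",
    "all_vs_all",
    "build_bins",
    "assemble_bin",
    "classify_contributing",
    "summarize_assembly",
]


@dataclass(frozen=True)
class PairwiseHit:
    """Best alignment between two reads: identity over columns, either strand."""

    query_id: str
    subject_id: str
    identity: float
    aln_length: int
    strand: str  # forward | reverse
    score: float

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValueError("self-hit")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0,1]")


@dataclass(frozen=True)
class Bin:
    members: frozenset[str]
    threshold: float


@dataclass(frozen=True)
class Placement:
    est_id: str
    start: int
    end: int
    strand: str  # forward | reverse


@dataclass
class Contig:
    id: str
    consensus: str
    members: tuple[Placement, ...]
    contributing: frozenset[str] = frozenset()


@dataclass
class AssemblyOutput:
    contigs: list[Contig]
    singletons: list[str]
    problems: list[tuple[str, str]]

    def member_ids(self) -> set[str]:
        ids: set[str] = set()
        for c in self.contigs:
            ids.update(p.est_id for p in c.members)
        ids.update(self.singletons)
        ids.update(est_id for est_id, _ in self.problems)
        return ids


@dataclass(frozen=True)
class AssemblyParams:
    min_overlap: int = 40
    min_identity: float = 0.95
    max_n_frac: float = 0.05
    seed_k: int = 16


# ---------------------------------------------------------------------------
# all-vs-all comparison

def all_vs_all(
    ests: Sequence[MaskedEST],
    min_identity: float = 0.80,
    min_aln_length: int = 100,
    seed_k: int = 16,
    brute_force: bool = False,
) -> list[PairwiseHit]:
    """One best hit per unordered read pair reaching identity and length floors.

    Pairs are seeded by a shared exact k-mer on either strand and scored by
    gapless extension along the best shared diagonal; with ``brute_force``
    unseeded pairs are additionally checked by full local dynamic
    programming on both strands.
    """
    live = [e for e in ests if not e.dropped]
    seqs = [e.record.bases for e in live]
    ids = [e.record.id for e in live]
    fwd = [_align.kmer_set(s, seed_k) for s in seqs]
    rc_seqs = [_align.revcomp(s) for s in seqs]
    rc = [_align.kmer_set(s, seed_k) for s in rc_seqs]
    hits: list[PairwiseHit] = []
    for i in range(len(live)):
        for j in range(i + 1, len(live)):
            best: tuple[float, float, int, str] | None = None  # score, identity, length, strand
            for strand, other, other_kmers in (
                ("forward", seqs[j], fwd[j]),
                ("reverse", rc_seqs[j], rc[j]),
            ):
                if _align.shares_kmer(fwd[i], other_kmers):
                    ov = _align.best_diagonal_overlap(seqs[i], other, k=seed_k)
                    if ov is not None and ov.length >= min_aln_length:
                        cand = (float(ov.matches), ov.identity, ov.length, strand)
                        if best is None or cand[0] > best[0]:
                            best = cand
                elif brute_force:
                    aln = _align.local_dna(seqs[i], other)
                    if aln is not None and aln.columns >= min_aln_length:
                        cand = (aln.score, aln.identity, aln.columns, strand)
                        if best is None or cand[0] > best[0]:
                            best = cand
            if best is not None and best[1] >= min_identity:
                hits.append(
                    PairwiseHit(ids[i], ids[j], best[1], best[2], best[3], best[0])
                )
    return hits


def build_bins(
    ids: Iterable[str], hits: Sequence[PairwiseHit], threshold: float
) -> list[Bin]:
    """Connected components of the hit graph at an identity threshold.

    Ids with no qualifying hit form singleton bins.  Output is
    deterministic: members sorted, bins ordered by smallest member id.
    """
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for hit in hits:
        if hit.identity >= threshold:
            if hit.query_id not in graph or hit.subject_id not in graph:
                raise ValueError("hit endpoint not in id set")
            graph.add_edge(hit.query_id, hit.subject_id)
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: min(c))
    return [Bin(c, threshold) for c in comps]


# ---------------------------------------------------------------------------
# greedy overlap-layout-consensus

@dataclass
class _Layout:
    """A growing contig: reads placed at offsets on a shared coordinate axis."""

    reads: list[tuple[str, str, int, str]]  # (est_id, oriented seq, offset, strand)
    consensus: str

    @property
    def key(self) -> str:
        return min(r[0] for r in self.reads)


def _consensus(reads: list[tuple[str, str, int, str]]) -> str:
    length = max(off + len(seq) for _, seq, off, _ in reads)
    counts = [Counter() for _ in range(length)]
    for _, seq, off, _ in reads:
        for i, base in enumerate(seq):
            if base != "N":
                counts[off + i][base] += 1
    out = []
    for col in counts:
        if not col:
            out.append("N")
            continue
        ranked = col.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out.append("N")  # ties are ambiguous
        else:
            out.append(ranked[0][0])
    return "".join(out)


def _flip(layout: _Layout) -> _Layout:
    length = len(layout.consensus)
    reads = [
        (rid, _align.revcomp(seq), length - (off + len(seq)),
         "reverse" if strand == "forward" else "forward")
        for rid, seq, off, strand in layout.reads
    ]
    return _Layout(reads, _align.revcomp(layout.consensus))


def _best_merge(
    a: _Layout, b: _Layout, params: AssemblyParams
) -> tuple[float, bool, int] | None:
    """Best qualifying overlap of b (possibly flipped) onto a.

    Returns (matches, flipped, offset) or None.
    """
    best = None
    for flipped, seq_b in ((False, b.consensus), (True, _align.revcomp(b.consensus))):
        ov = _align.best_diagonal_overlap(
            a.consensus, seq_b, k=params.seed_k, min_overlap=params.min_overlap
        )
        if ov is None or ov.length < params.min_overlap or ov.identity < params.min_identity:
            continue
        if best is None or ov.matches > best[0]:
            best = (float(ov.matches), flipped, ov.offset)
    return best


def assemble_bin(
    bin_ests: Sequence[MaskedEST], params: AssemblyParams = AssemblyParams()
) -> AssemblyOutput:
    """Assemble one bin into contigs, singletons and problem sequences.

    Reads whose N fraction exceeds ``max_n_frac`` are routed to problems
    ("ambiguous") before assembly.  The remaining reads are merged
    greedily: at each step the pair of layouts (single reads or growing
    contigs) with the highest-scoring overlap of >= ``min_overlap`` nt at
    >= ``min_identity`` is merged, consensus recomputed per column by
    majority with ties as N.  Reads joining no contig become singletons.
    """
    if not bin_ests:
        raise ValueError("empty bin")
    problems: list[tuple[str, str]] = []
    layouts: list[_Layout] = []
    for est in sorted(bin_ests, key=lambda e: e.record.id):
        seq = est.record.bases
        if seq.count("N") / len(seq) > params.max_n_frac:
            problems.append((est.record.id, "ambiguous"))
        else:
            layouts.append(_Layout([(est.record.id, seq, 0, "forward")], seq))

    while len(layouts) > 1:
        best = None  # (matches, key_a, key_b, i, j, flipped, offset)
        for i in range(len(layouts)):
            for j in range(i + 1, len(layouts)):
                merge = _best_merge(layouts[i], layouts[j], params)
                if merge is None:
                    continue
                matches, flipped, offset = merge
                cand = (
                    -matches,
                    min(layouts[i].key, layouts[j].key),
                    max(layouts[i].key, layouts[j].key),
                )
                if best is None or cand < best[0]:
                    best = (cand, i, j, flipped, offset)
        if best is None:
            break
        _, i, j, flipped, offset = best
        a, b = layouts[i], layouts[j]
        if flipped:
            b = _flip(b)
        shift = max(0, -offset)
        reads = [(rid, seq, off + shift, strand) for rid, seq, off, strand in a.reads]
        reads += [
            (rid, seq, off + offset + shift, strand) for rid, seq, off, strand in b.reads
        ]
        merged = _Layout(reads, _consensus(reads))
        layouts = [lay for idx, lay in enumerate(layouts) if idx not in (i, j)]
        layouts.append(merged)

    contigs: list[Contig] = []
    singletons: list[str] = []
    for lay in layouts:
        if len(lay.reads) == 1:
            singletons.append(lay.reads[0][0])
            continue
        members = tuple(
            Placement(rid, off, off + len(seq), strand)
            for rid, seq, off, strand in sorted(lay.reads, key=lambda r: (r[2], r[0]))
        )
        contig = Contig(contig_id(p.est_id for p in members), lay.consensus, members)
        contigs.append(classify_contributing(contig))
    contigs.sort(key=lambda c: c.id)
    singletons.sort()
    problems.sort()
    return AssemblyOutput(contigs, singletons, problems)


def classify_contributing(contig: Contig) -> Contig:
    """Mark members whose placement adds non-redundant sequence.

    A member is redundant iff its placed interval is contained within the
    placed interval of another single member; for exactly equal intervals
    the lexicographically smaller id contributes.
    """
    contributing = set()
    for p in contig.members:
        redundant = False
        for q in contig.members:
            if q.est_id == p.est_id:
                continue
            if q.start <= p.start and p.end <= q.end:
                if (q.start, q.end) != (p.start, p.end) or q.est_id < p.est_id:
                    redundant = True
                    break
        if not redundant:
            contributing.add(p.est_id)
    contig.contributing = frozenset(contributing)
    return contig


def summarize_assembly(outputs: Sequence[AssemblyOutput]) -> dict:
    """Histogram of transcripts by number of contributing ESTs, plus totals.

    Singletons and problem sequences count as single-EST transcripts, as in
    the standard contig-size table.
    """
    hist: Counter[int] = Counter()
    n_contigs = n_singletons = n_problems = 0
    for out in outputs:
        for contig in out.contigs:
            hist[len(contig.contributing)] += 1
            n_contigs += 1
        if out.singletons or out.problems:
            hist[1] += len(out.singletons) + len(out.problems)
        n_singletons += len(out.singletons)
        n_problems += len(out.problems)
    return {
        "histogram": dict(sorted(hist.items())),
        "n_contigs": n_contigs,
        "n_singletons": n_singletons,
        "n_problems": n_problems,
        "total": n_contigs + n_singletons + n_problems,
    }
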