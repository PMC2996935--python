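"""Read screening: quality filters, EST-feature masking, trimming, and merging.

Raw directional cDNA reads carry cloning artifacts around the biological
insert: an EcoRI adaptor and a library-identifying oligonucleotide tag at
the 5' junction, a NotI restriction site and anchored oligo-dT primer at
the 3' junction, and a poly(A) tail.  This module detects those features,
masks or trims them, applies three quality criteria (mean phred q > 25,
fraction of bases at q >= 20 above 50%, quality-trimmed insert longer than
100 nt), screens for ribosomal-RNA and E. coli contamination, and merges
clone pairs sequenced from both ends when they overlap.

Reads sequenced 3'->5' are reverse-complemented first
(:func:`orient_by_strategy`), so every downstream step sees transcripts in
forward orientation with the poly(A) tail on the 3' end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

from . import _align
from .seqio import SeqRecord, parse_identifier

__all__ = [
    "QualityUnavailableError",
    "ConfigurationError",
    "InputError",
    "QualityThresholds",
    "QualityAssessment",
    "MotifConfig",
    "FeatureAnnotation",
    "MaskedEST",
    "orient_by_strategy",
    "assess_quality",
    "find_motif",
    "low_complexity_intervals",
    "detect_features",
    "trim_and_mask",
    "screen_ecoli",
    "screen_rrna",
    "merge_clone_pairs",
]

FEATURE_LABELS = (
    "vector_site",
    "restriction_site",
    "adaptor",
    "polyA_tail",
    "polyA_signal",
    "library_tag",
    "ecoli_contaminant",
)

# artifact features are trimmed off read ends and masked internally;
# the polyadenylation signal is a transcript feature and is only annotated
_TERMINAL_LABELS = frozenset(
    {"vector_site", "restriction_site", "adaptor", "polyA_tail", "library_tag"}
)


class QualityUnavailableError(ValueError):
    """Quality-based assessment requested on a record without qualities."""


class ConfigurationError(ValueError):
    pass


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# quality

@dataclass(frozen=True)
class QualityThresholds:
    """The three read-level quality criteria, all strict inequalities.

    ``min_mean_q``: mean phred over the read must exceed this (default 25).
    ``min_frac_q20``: fraction of bases with q >= ``q_floor`` must exceed
    this (default 0.5, floor 20).  ``min_insert_len``: quality-trimmed
    length must exceed this (default 100 nt).  End trimming uses a sliding
    window of ``window`` nt whose mean must stay >= ``q_floor``.
    """

    min_mean_q: float = 25.0
    min_frac_q20: float = 0.5
    min_insert_len: int = 100
    q_floor: int = 20
    window: int = 20


@dataclass(frozen=True)
class QualityAssessment:
    mean_q: float
    frac_ge_q20: float
    trimmed_length: int
    trim_start: int
    trim_end: int
    pass_q: bool
    pass_frac: bool
    pass_len: bool

    @property
    def passes(self) -> bool:
        return self.pass_q and self.pass_frac and self.pass_len


def _quality_trim_bounds(quals: Sequence[int], window: int, floor: float) -> tuple[int, int]:
    """Longest contiguous region in which every length-``window`` sliding
    window has mean quality >= ``floor``; reads shorter than the window are
    kept whole iff their overall mean passes."""
    n = len(quals)
    if n < window:
        mean = sum(quals) / n if n else 0.0
        return (0, n) if mean >= floor else (0, 0)
    ok = []
    running = sum(quals[:window])
    ok.append(running >= floor * window)
    for i in range(1, n - window + 1):
        running += quals[i + window - 1] - quals[i - 1]
        ok.append(running >= floor * window)
    best = (0, 0)
    i = 0
    while i < len(ok):
        if ok[i]:
            j = i
            while j < len(ok) and ok[j]:
                j += 1
            start, end = i, j - 1 + window
            if end - start > best[1] - best[0]:
                best = (start, end)
            i = j
        else:
            i += 1
    bs, be = best
    # terminal bases below the floor inside the last/first window are trimmed too
    while be > bs and quals[be - 1] < floor:
        be -= 1
    while bs < be and quals[bs] < floor:
        bs += 1
    return bs, be


def assess_quality(
    record: SeqRecord, thresholds: QualityThresholds = QualityThresholds()
) -> QualityAssessment:
    """Evaluate the three quality criteria on a read with phred qualities.

    Mean quality and the q20 fraction are computed over the quality-trimmed
    region (the part of the read a base caller would report as usable);
    low-quality tails outside it count only through the trimmed-length
    criterion.
    """
    if record.quals is None:
        raise QualityUnavailableError(f"record {record.id!r} has no quality values")
    ts, te = _quality_trim_bounds(record.quals, thresholds.window, thresholds.q_floor)
    quals = record.quals[ts:te]
    if not quals:
        return QualityAssessment(0.0, 0.0, 0, ts, te, False, False, False)
    mean_q = sum(quals) / len(quals)
    frac = sum(1 for q in quals if q >= thresholds.q_floor) / len(quals)
    return QualityAssessment(
        mean_q=mean_q,
        frac_ge_q20=frac,
        trimmed_length=te - ts,
        trim_start=ts,
        trim_end=te,
        pass_q=mean_q > thresholds.min_mean_q,
        pass_frac=frac > thresholds.min_frac_q20,
        pass_len=(te - ts) > thresholds.min_insert_len,
    )


# ---------------------------------------------------------------------------
# features

@dataclass(frozen=True)
class MotifConfig:
    """Artifact motifs planted by library construction.

    ``oligo_dt_primer`` uses the literal syntax ``HEAD-N[lo-hi]-T`` for the
    anchored primer with a degenerate 6-10 nt spacer before the oligo-dT.
    Library tags are configuration values (each library's tag is a short
    unique oligonucleotide); the defaults here are the ones the synthetic
    generator plants.
    """

    adaptor: str = "AATTGGCACGAGG"
    restriction_site: str = "GCGGCCGC"  # NotI
    oligo_dt_primer: str = "TGTTACCATTCTGATGTTGGAGCGGCCGC-N[6-10]-T"
    polyA_signal: str = "AATAAA"
    # tags share no affixes with each other or the adaptor, so junction
    # sequence cannot spuriously spell a tag
    tag_by_library: dict[str, str] = field(
        default_factory=lambda: {"embryo": "CTCGTAGACT", "adult_cns": "GAGTCTGCAT"}
    )
    ecoli_kmers: frozenset[str] = frozenset()
    vector: str | None = None
    polyA_min_run: int = 12

    def __post_init__(self) -> None:
        for name in ("adaptor", "restriction_site", "polyA_signal"):
            motif = getattr(self, name)
            if not motif or set(motif) - set("ACGTN"):
                raise ConfigurationError(f"motif {name} must be non-empty DNA")


_PRIMER_RE = re.compile(r"^([ACGTN]+)-N\[(\d+)-(\d+)\]-T$")


@dataclass(frozen=True)
class FeatureAnnotation:
    """Feature intervals (0-based half-open) and the N-masked sequence."""

    intervals: tuple[tuple[int, int, str], ...]
    masked_bases: str

    def by_label(self, label: str) -> list[tuple[int, int]]:
        return [(s, e) for s, e, lab in self.intervals if lab == label]


def find_motif(seq: str, motif: str, max_mismatch: int = 0) -> list[tuple[int, int]]:
    """All occurrences of ``motif`` within ``max_mismatch`` substitutions.

    ``N`` in the motif matches any base; ``N`` in the sequence matches
    nothing (counts as a mismatch unless the motif position is N).
    """
    m = len(motif)
    hits = []
    for i in range(len(seq) - m + 1):
        mism = 0
        for a, b in zip(motif, seq[i : i + m]):
            if a != "N" and a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append((i, i + m))
    return hits


def _find_primer(seq: str, primer_spec: str, max_mismatch: int) -> list[tuple[int, int]]:
    m = _PRIMER_RE.match(primer_spec)
    if m is None:
        raise ConfigurationError(f"bad oligo-dT primer syntax {primer_spec!r}")
    head, lo, hi = m.group(1), int(m.group(2)), int(m.group(3))
    out = []
    for start, end in find_motif(seq, head, max_mismatch):
        # degenerate spacer of lo..hi arbitrary bases, then the anchoring T run
        for spacer in range(lo, hi + 1):
            t_pos = end + spacer
            if t_pos < len(seq) and seq[t_pos] == "T":
                t_end = t_pos
                while t_end < len(seq) and seq[t_end] == "T":
                    t_end += 1
                out.append((start, t_end))
                break
    return out


def _polya_tail(seq: str, min_run: int) -> tuple[int, int] | None:
    end = len(seq)
    start = end
    while start > 0 and seq[start - 1] == "A":
        start -= 1
    if end - start >= min_run:
        return (start, end)
    return None


def low_complexity_intervals(
    seq: str, window: int = 64, threshold: float = 2.5
) -> list[tuple[int, int]]:
    """DUST-like low-complexity windows, merged.

    Per window the score is sum over triplet counts c of c*(c-1)/2, divided
    by the number of triplet positions; windows scoring above ``threshold``
    are reported.  Random sequence scores near 1; homopolymer and short
    tandem runs score far higher.
    """
    n = len(seq)
    if n < 3:
        return []
    flagged: list[tuple[int, int]] = []
    step = max(1, window // 2)
    for start in range(0, max(1, n - 2), step):
        end = min(n, start + window)
        if end - start < 3:
            break
        counts: dict[str, int] = {}
        for i in range(start, end - 2):
            t = seq[i : i + 3]
            counts[t] = counts.get(t, 0) + 1
        npos = end - start - 2
        score = sum(c * (c - 1) / 2 for c in counts.values()) / npos
        if score > threshold:
            if flagged and start <= flagged[-1][1]:
                flagged[-1] = (flagged[-1][0], end)
            else:
                flagged.append((start, end))
    return flagged


def detect_features(
    record: SeqRecord, motifs: MotifConfig, max_mismatch: int = 1
) -> FeatureAnnotation:
    """Annotate every configured artifact motif occurrence on a read.

    The read is assumed forward-oriented (see :func:`orient_by_strategy`),
    so the poly(A) tail is sought as a terminal A-run on the 3' end.
    """
    seq = record.bases
    intervals: list[tuple[int, int, str]] = []
    for start, end in find_motif(seq, motifs.adaptor, max_mismatch):
        intervals.append((start, end, "adaptor"))
    for start, end in find_motif(seq, motifs.restriction_site, max_mismatch):
        intervals.append((start, end, "restriction_site"))
    for start, end in find_motif(seq, motifs.polyA_signal, 0):
        intervals.append((start, end, "polyA_signal"))
    for lib, tag in motifs.tag_by_library.items():
        for start, end in find_motif(seq, tag, max_mismatch):
            intervals.append((start, end, "library_tag"))
    for start, end in _find_primer(seq, motifs.oligo_dt_primer, max_mismatch):
        intervals.append((start, end, "vector_site"))
    if motifs.vector:
        for start, end in find_motif(seq, motifs.vector, max_mismatch):
            intervals.append((start, end, "vector_site"))
    tail = _polya_tail(seq, motifs.polyA_min_run)
    if tail is not None:
        intervals.append((tail[0], tail[1], "polyA_tail"))
    intervals.sort()
    masked = list(seq)
    for start, end, _ in intervals:
        for i in range(start, end):
            masked[i] = "N"
    return FeatureAnnotation(tuple(intervals), "".join(masked))


# ---------------------------------------------------------------------------
# masked ESTs

@dataclass
class MaskedEST:
    """A screened, trimmed EST ready for clustering (or dropped with a reason)."""

    record: SeqRecord
    features: FeatureAnnotation
    rrna_status: str = "clean"  # clean | rrna_suspect | rrna_gene
    dropped: bool = False
    drop_reason: str | None = None

    def __post_init__(self) -> None:
        if self.dropped and not self.drop_reason:
            raise ValueError("dropped EST must carry a reason")


def orient_by_strategy(record: SeqRecord) -> SeqRecord:
    """Reverse-complement 3'->5' reads so all reads run 5'->3' on the mRNA."""
    tag = parse_identifier(record.id)
    if tag.strategy == "three_to_five":
        quals = list(reversed(record.quals)) if record.quals is not None else None
        return replace(record, bases=_align.revcomp(record.bases), quals=quals)
    return record


def trim_and_mask(
    record: SeqRecord,
    qa: QualityAssessment | None,
    features: FeatureAnnotation,
    min_insert_len: int = 100,
    mask_low_complexity: bool = True,
    dust_threshold: float = 2.5,
) -> MaskedEST:
    """Trim terminal artifacts and low-quality ends; mask internal artifacts.

    ``qa`` may be None for pre-trimmed input without qualities, in which
    case only feature trimming applies.  Reads failing quality criteria or
    shorter than ``min_insert_len`` after trimming are dropped with a
    reason ("low_quality" / "short_insert").
    """
    if qa is not None and not (qa.pass_q and qa.pass_frac):
        return MaskedEST(record, features, dropped=True, drop_reason="low_quality")

    ts, te = (qa.trim_start, qa.trim_end) if qa is not None else (0, len(record.bases))
    terminal = sorted(
        (s, e) for s, e, lab in features.intervals if lab in _TERMINAL_LABELS
    )
    changed = True
    while changed:
        changed = False
        for s, e in terminal:
            if s <= ts < e:
                ts = e
                changed = True
            if s < te <= e:
                te = s
                changed = True
    if te <= ts:
        return MaskedEST(record, features, dropped=True, drop_reason="short_insert")

    masked = list(record.bases)
    for s, e, lab in features.intervals:
        if lab == "polyA_signal":
            continue
        for i in range(max(s, ts), min(e, te)):
            masked[i] = "N"
    if mask_low_complexity:
        # run the complexity filter on the peeled region only, so windows
        # straddling trimmed terminal artifacts (e.g. the poly(A) tail)
        # cannot bleed N into the insert
        for s, e in low_complexity_intervals(record.bases[ts:te], threshold=dust_threshold):
            for i in range(ts + s, ts + e):
                masked[i] = "N"
    # masked-out termini (e.g. a low-complexity window over the tail region)
    # carry no usable sequence: convert them to trimming
    while ts < te and masked[ts] == "N":
        ts += 1
    while te > ts and masked[te - 1] == "N":
        te -= 1
    insert = "".join(masked[ts:te])
    if len(insert) <= min_insert_len:
        return MaskedEST(record, features, dropped=True, drop_reason="short_insert")
    quals = record.quals[ts:te] if record.quals is not None else None
    trimmed = SeqRecord(record.id, insert, quals=quals, description=record.description)
    return MaskedEST(trimmed, features)


# ---------------------------------------------------------------------------
# contamination screens

def screen_ecoli(
    ests: Sequence[MaskedEST],
    ecoli_kmers: frozenset[str],
    k: int = 21,
    min_shared_frac: float = 0.20,
) -> list[MaskedEST]:
    """Drop reads sharing >= ``min_shared_frac`` of their k-mers with E. coli.

    The reference is a user-supplied exact k-mer set (k=21 default).
    """
    if not ecoli_kmers:
        return list(ests)
    out = []
    for est in ests:
        if est.dropped:
            out.append(est)
            continue
        words = _align.kmer_set(est.record.bases, k)
        if words and len(words & ecoli_kmers) / len(words) >= min_shared_frac:
            out.append(replace(est, dropped=True, drop_reason="ecoli_contaminant"))
        else:
            out.append(est)
    return out


def screen_rrna(
    ests: Sequence[MaskedEST],
    rrna_db: Sequence[SeqRecord],
    min_identity: float = 0.90,
    complete_coverage: float = 0.90,
    min_aln_length: int = 50,
    seed_k: int = 12,
    brute_force: bool = False,
) -> list[MaskedEST]:
    """Flag ESTs aligning to ribosomal RNA at >= ``min_identity``.

    An alignment covering >= ``complete_coverage`` of the EST marks it an
    rRNA gene; any shorter qualifying alignment of at least
    ``min_aln_length`` columns marks it an rRNA suspect (the length floor
    keeps chance micro-matches from qualifying).  Both strands are
    searched.  Candidate EST/reference pairs are prefiltered by a shared
    exact ``seed_k``-mer unless ``brute_force``.
    """
    if not rrna_db:
        raise ConfigurationError("rRNA reference database is empty")
    ref_kmers = [_align.kmer_set(ref.bases, seed_k) for ref in rrna_db]
    out = []
    for est in ests:
        if est.dropped:
            out.append(est)
            continue
        seq = est.record.bases
        status = "clean"
        for strand_seq in (seq, _align.revcomp(seq)):
            words = _align.kmer_set(strand_seq, seed_k)
            for ref, rk in zip(rrna_db, ref_kmers):
                if not brute_force and not _align.shares_kmer(words, rk):
                    continue
                aln = _align.local_dna(strand_seq, ref.bases)
                if aln is None or aln.identity < min_identity or aln.columns < min_aln_length:
                    continue
                coverage = (aln.a_end - aln.a_start) / len(seq)
                if coverage >= complete_coverage:
                    status = "rrna_gene"
                else:
                    status = max(status, "rrna_suspect", key=("clean", "rrna_suspect", "rrna_gene").index)
            if status == "rrna_gene":
                break
        out.append(replace(est, rrna_status=status))
    return out


# ---------------------------------------------------------------------------
# clone-pair merging

def merge_clone_pairs(
    ests: Sequence[MaskedEST],
    min_overlap: int = 40,
    min_identity: float = 0.95,
    seed_k: int = 16,
) -> list[MaskedEST]:
    """Merge 5' and 3' reads of the same clone when they overlap.

    Reads are expected forward-oriented (3'->5' reads already
    reverse-complemented).  When a clone has both reads and their best
    gapless overlap spans >= ``min_overlap`` nt at >= ``min_identity``, a
    single merged record (keeping the 5' read's identifier) replaces the
    pair; base disagreements resolve to the higher-quality base.  More
    than two reads for one clone is an input error.
    """
    by_clone: dict[tuple[str, str], dict[str, MaskedEST]] = {}
    passthrough: list[MaskedEST] = []
    order: list[tuple[str, str]] = []
    for est in ests:
        if est.dropped:
            passthrough.append(est)
            continue
        tag = parse_identifier(est.record.id)
        key = (tag.library, tag.clone_id)
        slot = by_clone.setdefault(key, {})
        if key not in order:
            order.append(key)
        if tag.strategy in slot:
            raise InputError(
                f"clone {tag.clone_id!r}: more than one {tag.strategy} read"
            )
        slot[tag.strategy] = est

    out: list[MaskedEST] = []
    for key in order:
        slot = by_clone[key]
        if len(slot) < 2:
            out.extend(slot.values())
            continue
        five, three = slot["five_to_three"], slot["three_to_five"]
        merged = _merge_pair(five, three, min_overlap, min_identity, seed_k)
        if merged is None:
            out.extend([five, three])
        else:
            out.append(merged)
    out.extend(passthrough)
    return out


def _merge_pair(
    five: MaskedEST, three: MaskedEST, min_overlap: int, min_identity: float, seed_k: int
) -> MaskedEST | None:
    a, b = five.record, three.record
    ov = _align.best_diagonal_overlap(a.bases, b.bases, k=seed_k, min_overlap=min_overlap)
    if ov is None or ov.length < min_overlap or ov.identity < min_identity:
        return None
    if ov.offset < 0:
        # 3' read should start downstream of the 5' read; a negative offset
        # would imply the fragments are inconsistent with directional cloning
        return None
    length = max(len(a.bases), ov.offset + len(b.bases))
    bases = []
    quals: list[int] = []
    qa = a.quals or [30] * len(a.bases)
    qb = b.quals or [30] * len(b.bases)
    for pos in range(length):
        in_a = pos < len(a.bases)
        jb = pos - ov.offset
        in_b = 0 <= jb < len(b.bases)
        if in_a and in_b:
            if a.bases[pos] == b.bases[jb]:
                bases.append(a.bases[pos])
                quals.append(max(qa[pos], qb[jb]))
            elif qb[jb] > qa[pos]:
                bases.append(b.bases[jb])
                quals.append(qb[jb])
            else:
                bases.append(a.bases[pos])
                quals.append(qa[pos])
        elif in_a:
            bases.append(a.bases[pos])
            quals.append(qa[pos])
        else:
            bases.append(b.bases[jb])
            quals.append(qb[jb])
    merged_record = SeqRecord(a.id, "".join(bases), quals=quals, description=a.description)
    features = FeatureAnnotation((), merged_record.bases)
    return MaskedEST(merged_record, features, rrna_status=five.rrna_status)
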