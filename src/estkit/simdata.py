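"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates two directionally cloned cDNA libraries (whole
embryo and adult CNS) sequenced 5'->3' and 3'->5', with the artifacts real
EST reads carry: EcoRI adaptor and library tag at the 5' junction, poly(A)
tail at the 3' end, substitution errors, phred-like quality decay toward
the 3' end of each read, paired clones sequenced from both ends, and
planted ribosomal-RNA and E. coli contaminant reads.  Every read is
recorded in a :class:`SyntheticTruth` ledger (origin coordinates, clone
pairing, contamination class, planted insert), so screening, assembly and
annotation can be scored against truth.

Transcripts are random coding sequences (5'UTR + ORF + 3'UTR) scrubbed of
artifact-look-alike motifs (adaptor, tags, poly(A) signal, >=12 nt
homopolymer runs), so planted decorations are unambiguous and exact insert
recovery is well-defined.  What the generator does NOT emulate: real codon
usage, splice variation, indel sequencing errors (available but off by
default), or chromatogram-level noise.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _align
from .annotate import ProteinRef
from .preprocess import MotifConfig
from .seqio import SeqRecord, SourceTag, format_identifier

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "Transcriptome",
    "generate_transcriptome",
    "generate_est_reads",
    "generate_proteomes",
    "make_rrna_db",
    "make_ecoli_genome",
    "table1_fixture",
    "table2_fixture",
    "table5_fixture",
    "emit_paper_fixtures",
]

_BASES = np.array(list("ACGT"))
_AA = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid, standard code (for back-translation)
_SYNONYMS: dict[str, list[str]] = {}
from Bio.Data import CodonTable as _CT

for _codon, _aa in _CT.unambiguous_dna_by_id[1].forward_table.items():
    _SYNONYMS.setdefault(_aa, []).append(_codon)
for _aa in _SYNONYMS:
    _SYNONYMS[_aa].sort()


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic libraries.

    Defaults emulate normalized directional EST libraries: ~1.8 kb
    transcripts (lognormal), ~600 nt reads, 1% substitution error, quality
    decaying from ~q40 to ~q10 along the read, 76% of reads 5'->3', 30% of
    clones sequenced from both ends, and a few percent rRNA / E. coli
    contaminant reads.
    """

    seed: int
    n_transcripts: int = 50
    transcript_len_mean: float = 1800.0  # lognormal parameters on the nt scale
    transcript_len_sigma: float = 0.30
    utr5_len: int = 60
    utr3_len: int = 150
    n_clones: Mapping[str, int] = field(
        default_factory=lambda: {"embryo": 100, "adult_cns": 100}
    )
    read_len_mean: float = 600.0
    read_len_sd: float = 80.0
    error_rate: float = 0.01
    indel_rate: float = 0.0
    decorations: bool = True
    polya_len: int = 20
    pair_fraction: float = 0.30
    five_prime_fraction: float = 0.76
    rrna_fraction: float = 0.02
    ecoli_fraction: float = 0.01
    q_start: float = 40.0
    q_end: float = 10.0
    q_jitter: float = 3.0
    divergence_schedule: tuple[float, ...] = (0.05, 0.2, 0.5)

    def __post_init__(self) -> None:
        for name in (
            "error_rate",
            "indel_rate",
            "pair_fraction",
            "five_prime_fraction",
            "rrna_fraction",
            "ecoli_fraction",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0,1]")


@dataclass
class SyntheticTruth:
    """Ground truth: where every emitted read came from."""

    transcripts: dict[str, str]
    read_origin: dict[str, tuple[str, int, int, str, str]]
    # read_id -> (transcript_id, start, end, strand, library)
    clone_pairs: dict[str, tuple[str, str]]
    contaminants: dict[str, str]  # read_id -> "rrna" | "ecoli"
    protein_sources: dict[str, str]  # transcript_id -> protein_id
    planted_insert: dict[str, str]  # read_id -> biological insert, oriented 5'->3'

    def all_read_ids(self) -> set[str]:
        return set(self.read_origin) | set(self.contaminants)


@dataclass
class Transcriptome:
    transcripts: dict[str, str]
    proteins: dict[str, str]  # protein_id -> peptide
    protein_of: dict[str, str]  # transcript_id -> protein_id


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, stream])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _scrub(seq: str, motifs: Sequence[str], max_run: int = 11) -> str:
    """Remove artifact-look-alike motifs and long homopolymer runs.

    Each motif occurrence has its middle base rotated (A->C->G->T->A);
    homopolymer runs are broken every ``max_run`` bases.  Deterministic.
    """
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(out)
        for motif in motifs:
            pos = s.find(motif)
            while pos != -1:
                mid = pos + len(motif) // 2
                out[mid] = rot[out[mid]]
                s = "".join(out)
                pos = s.find(motif)
                changed = True
        run_start = 0
        for i in range(1, len(out) + 1):
            if i == len(out) or out[i] != out[run_start]:
                if i - run_start > max_run:
                    for j in range(run_start + max_run, i, max_run + 1):
                        out[j] = rot[out[j]]
                    changed = True
                run_start = i
    return "".join(out)


def _artifact_motifs(motifs: MotifConfig) -> list[str]:
    primer_head = motifs.oligo_dt_primer.split("-")[0]
    return [
        motifs.adaptor,
        motifs.restriction_site,
        motifs.polyA_signal,
        primer_head,
        *motifs.tag_by_library.values(),
    ]


def generate_transcriptome(
    cfg: SimConfig, motifs: MotifConfig = MotifConfig()
) -> Transcriptome:
    """Random coding transcripts (5'UTR + ORF + 3'UTR) with source proteins.

    Random proteins are back-translated through uniformly chosen synonymous
    codons; mutual transcript identity stays far below 70% by construction
    of independent random sequences.  Reproducible from the seed.
    """
    rng = _rng(cfg.seed, 0)
    scrub_list = _artifact_motifs(motifs)
    transcripts: dict[str, str] = {}
    proteins: dict[str, str] = {}
    protein_of: dict[str, str] = {}
    for i in range(cfg.n_transcripts):
        tid = f"txn{i:04d}"
        pid = f"prot{i:04d}"
        total = int(
            rng.lognormal(np.log(cfg.transcript_len_mean), cfg.transcript_len_sigma)
        )
        orf_aa = max(60, (total - cfg.utr5_len - cfg.utr3_len) // 3 - 1)
        peptide = "M" + "".join(rng.choice(list(_AA), size=orf_aa - 1))
        codons = [_SYNONYMS[aa][rng.integers(len(_SYNONYMS[aa]))] for aa in peptide]
        orf = "".join(codons) + "TAA"
        seq = _random_dna(rng, cfg.utr5_len) + orf + _random_dna(rng, cfg.utr3_len)
        seq = _scrub(seq, scrub_list)
        if seq.endswith("A"):
            # keep the planted poly(A) tail boundary unambiguous
            seq = seq[:-1] + "C"
        transcripts[tid] = seq
        proteins[pid] = peptide
        protein_of[tid] = pid
    return Transcriptome(transcripts, proteins, protein_of)


def make_rrna_db(seed: int, n: int = 3, length: int = 1500) -> list[SeqRecord]:
    """A small synthetic ribosomal-RNA reference set (stand-in sequences)."""
    rng = _rng(seed, 3)
    names = ["rRNA_18S", "rRNA_28S", "rRNA_16S"]
    return [
        SeqRecord(names[i % len(names)] + (f"_{i // 3}" if i >= 3 else ""),
                  _random_dna(rng, length))
        for i in range(n)
    ]


def make_ecoli_genome(seed: int, length: int = 20000) -> str:
    """A synthetic bacterial-contaminant reference sequence (stand-in)."""
    return _random_dna(_rng(seed, 4), length)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _qualities(rng: np.random.Generator, n: int, cfg: SimConfig) -> list[int]:
    base = np.linspace(cfg.q_start, cfg.q_end, n)
    jitter = rng.normal(0.0, cfg.q_jitter, n)
    return [int(q) for q in np.clip(base + jitter, 2, 60)]


_CENTER_BY_LIB = {"embryo": "JGI", "adult_cns": "GEN"}


def generate_est_reads(
    transcriptome: Transcriptome,
    cfg: SimConfig,
    motifs: MotifConfig = MotifConfig(),
    rrna_db: Sequence[SeqRecord] | None = None,
    ecoli_genome: str | None = None,
) -> tuple[list[SeqRecord], SyntheticTruth]:
    """Emit decorated directional reads plus the truth ledger.

    Raw 5'->3' reads run adaptor + library tag + insert (+ poly(A) when the
    read reaches the clone's 3' end); raw 3'->5' reads are the reverse
    complement read in from the poly(A) end.  Substitution errors are
    applied to the biological insert at ``cfg.error_rate``; contaminant
    reads are windows of the rRNA / E. coli references.
    """
    if not transcriptome.transcripts:
        raise ValueError("empty transcriptome")
    rng = _rng(cfg.seed, 1)
    if rrna_db is None:
        rrna_db = make_rrna_db(cfg.seed)
    if ecoli_genome is None:
        ecoli_genome = make_ecoli_genome(cfg.seed)

    tids = sorted(transcriptome.transcripts)
    abundance = rng.lognormal(0.0, 1.0, len(tids))
    abundance /= abundance.sum()

    records: list[SeqRecord] = []
    truth = SyntheticTruth(
        transcripts=dict(transcriptome.transcripts),
        read_origin={},
        clone_pairs={},
        contaminants={},
        protein_sources=dict(transcriptome.protein_of),
        planted_insert={},
    )

    def decorate_f(insert: str, lib: str, reached_end: bool) -> tuple[str, int]:
        if not cfg.decorations:
            return insert, 0
        head = motifs.adaptor + motifs.tag_by_library[lib]
        tail = "A" * cfg.polya_len if reached_end else ""
        return head + insert + tail, len(head)

    def emit(lib: str, strategy: str, clone: str, insert: str, tid: str,
             t_start: int, t_end: int) -> str:
        read_len = max(120, int(rng.normal(cfg.read_len_mean, cfg.read_len_sd)))
        noisy = _mutate(rng, insert, cfg.error_rate)
        if strategy == "five_to_three":
            raw_full, head_len = decorate_f(noisy, lib, t_end == len(truth.transcripts[tid]))
            if read_len > head_len + len(noisy):
                raw = raw_full  # keep the full tail: a partial terminal A-run
                # would be indistinguishable from insert sequence
            else:
                raw = raw_full[:read_len]
            planted = noisy[: max(0, len(raw) - head_len)]
        else:
            tail = "A" * cfg.polya_len if cfg.decorations else ""
            raw_full = _align.revcomp(noisy + tail)
            raw = raw_full[:read_len]
            kept = max(0, read_len - len(tail))
            planted = noisy[-kept:] if kept else ""
        tag = SourceTag(lib, _CENTER_BY_LIB[lib], strategy, clone)
        rid = format_identifier(tag)
        records.append(SeqRecord(rid, raw, quals=_qualities(rng, len(raw), cfg)))
        truth.read_origin[rid] = (tid, t_start, t_end, strategy, lib)
        truth.planted_insert[rid] = planted
        return rid

    for lib in sorted(cfg.n_clones):
        n = cfg.n_clones[lib]
        n_rrna = int(round(n * cfg.rrna_fraction))
        n_ecoli = int(round(n * cfg.ecoli_fraction))
        n_real = n - n_rrna - n_ecoli
        for c in range(n_real):
            clone = f"{lib[:3]}{c:05d}"
            tid = tids[rng.choice(len(tids), p=abundance)]
            tseq = truth.transcripts[tid]
            # oligo-dT primed cDNA: the clone insert runs from a random start
            # to the transcript 3' end
            start = int(rng.integers(0, max(1, len(tseq) - 300)))
            insert = tseq[start:]
            paired = rng.random() < cfg.pair_fraction
            if paired:
                r5 = emit(lib, "five_to_three", clone, insert, tid, start, len(tseq))
                r3 = emit(lib, "three_to_five", clone, insert, tid, start, len(tseq))
                truth.clone_pairs[clone] = (r5, r3)
            else:
                strategy = (
                    "five_to_three"
                    if rng.random() < cfg.five_prime_fraction
                    else "three_to_five"
                )
                emit(lib, strategy, clone, insert, tid, start, len(tseq))
        for c in range(n_rrna):
            clone = f"{lib[:3]}rr{c:04d}"
            ref = rrna_db[int(rng.integers(len(rrna_db)))]
            w = min(len(ref.bases), max(200, int(rng.normal(cfg.read_len_mean, cfg.read_len_sd))))
            start = int(rng.integers(0, len(ref.bases) - w + 1))
            window = _mutate(rng, ref.bases[start : start + w], cfg.error_rate)
            tag = SourceTag(lib, _CENTER_BY_LIB[lib], "five_to_three", clone)
            rid = format_identifier(tag)
            records.append(SeqRecord(rid, window, quals=_qualities(rng, len(window), cfg)))
            truth.contaminants[rid] = "rrna"
        for c in range(n_ecoli):
            clone = f"{lib[:3]}ec{c:04d}"
            w = max(200, int(rng.normal(cfg.read_len_mean, cfg.read_len_sd)))
            start = int(rng.integers(0, len(ecoli_genome) - w))
            window = _mutate(rng, ecoli_genome[start : start + w], cfg.error_rate)
            tag = SourceTag(lib, _CENTER_BY_LIB[lib], "five_to_three", clone)
            rid = format_identifier(tag)
            records.append(SeqRecord(rid, window, quals=_qualities(rng, len(window), cfg)))
            truth.contaminants[rid] = "ecoli"
    return records, truth


def tiling_reads(
    transcripts: Mapping[str, str],
    seed: int,
    read_len: int = 500,
    step: int = 100,
    error_rate: float = 0.0,
    quality: int = 40,
) -> tuple[list[SeqRecord], dict[str, tuple[str, int, int]]]:
    """Undecorated reads tiling each transcript at uniform coverage.

    Reads of ``read_len`` start every ``step`` nt (coverage read_len/step),
    the last read anchored at the transcript 3' end; strands and libraries
    alternate deterministically.  Returns the reads plus a truth map
    read_id -> (transcript_id, start, end).  This is the controlled
    substrate for assembly-recovery properties: with ``error_rate`` 0 every
    read is an exact substring (or reverse complement) of its source.
    """
    rng = _rng(seed, 5)
    records: list[SeqRecord] = []
    origin: dict[str, tuple[str, int, int]] = {}
    libs = ("embryo", "adult_cns")
    n = 0
    for tid in sorted(transcripts):
        tseq = transcripts[tid]
        starts = list(range(0, max(1, len(tseq) - read_len), step))
        starts.append(max(0, len(tseq) - read_len))
        for start in starts:
            end = min(len(tseq), start + read_len)
            window = _mutate(rng, tseq[start:end], error_rate)
            lib = libs[n % 2]
            strategy = "five_to_three" if n % 3 else "three_to_five"
            if strategy == "three_to_five":
                window = _align.revcomp(window)
            tag = SourceTag(lib, _CENTER_BY_LIB[lib], strategy, f"tile{n:05d}")
            rid = format_identifier(tag)
            records.append(SeqRecord(rid, window, quals=[quality] * len(window)))
            origin[rid] = (tid, start, end)
            n += 1
    return records, origin


# ---------------------------------------------------------------------------
# proteomes, descriptions, GO

_NEURO_TERMS = [
    ("GO:0007409", "axonogenesis"),
    ("GO:0001764", "neuron migration"),
    ("GO:0030182", "neuron differentiation"),
    ("GO:0022008", "neurogenesis"),
    ("GO:0043005", "neuron projection"),
]
_OTHER_TERMS = [
    ("GO:0008152", "metabolic process"),
    ("GO:0006810", "transport"),
    ("GO:0005515", "protein binding"),
    ("GO:0016301", "kinase activity"),
    ("GO:0003677", "DNA binding"),
]


def _pseudo_word(rng: np.random.Generator, length: int = 8) -> str:
    return "".join(rng.choice(list("abcdefghijklmnopqrstuvwxyz"), size=length))


def generate_proteomes(
    transcriptome: Transcriptome,
    cfg: SimConfig,
    divergence_schedule: Sequence[float] | None = None,
) -> tuple[list[tuple[str, list[ProteinRef]]], pd.DataFrame]:
    """Derive k proteomes at increasing amino-acid divergence, plus a GO table.

    Each source protein gets a unique informative description word shared
    by its homologs across proteomes, plus ubiquitous filler words
    ("protein", "similar", "hypothetical") that a document-frequency
    stoplist should remove.  The GO table (term_id, term_name, protein_id)
    links proteins to terms, half of them "neuro"-named categories.
    Protein ids are stable across proteomes so GO links apply to any of
    them.  Divergence above 0.9 is rejected (alignability lost).
    """
    schedule = tuple(
        divergence_schedule if divergence_schedule is not None else cfg.divergence_schedule
    )
    if any(schedule[i] >= schedule[i + 1] for i in range(len(schedule) - 1)):
        raise ValueError("divergence schedule must be strictly increasing")
    if any(not 0.0 <= d <= 0.9 for d in schedule):
        raise ValueError("divergence must lie in [0, 0.9]")
    rng = _rng(cfg.seed, 2)
    pids = sorted(transcriptome.proteins)
    unique_words = {pid: _pseudo_word(rng) for pid in pids}
    filler = "hypothetical protein similar"

    proteomes: list[tuple[str, list[ProteinRef]]] = []
    for d in schedule:
        name = f"proteome_d{int(round(d * 100)):02d}"
        refs = []
        for pid in pids:
            peptide = transcriptome.proteins[pid]
            arr = list(peptide)
            n_mut = int(round(d * len(arr)))
            sites = rng.choice(len(arr), size=n_mut, replace=False) if n_mut else []
            for i in sites:
                choices = [a for a in _AA if a != arr[i]]
                arr[i] = choices[rng.integers(len(choices))]
            desc = f"{unique_words[pid]} {filler}"
            refs.append(ProteinRef(pid, "".join(arr), desc))
        proteomes.append((name, refs))

    all_terms = _NEURO_TERMS + _OTHER_TERMS
    rows = []
    for pid in pids:
        n_terms = int(rng.integers(1, 4))
        picks = rng.choice(len(all_terms), size=n_terms, replace=False)
        for t in picks:
            term_id, term_name = all_terms[t]
            rows.append({"term_id": term_id, "term_name": term_name, "protein_id": pid})
    go_table = pd.DataFrame(rows, columns=["term_id", "term_name", "protein_id"])
    return proteomes, go_table


# ---------------------------------------------------------------------------
# printed-table fixtures

def table1_fixture() -> pd.DataFrame:
    """Raw-read counts by sequencing center, library and strategy."""
    rows = [
        ("JGI", "embryo", "five_to_three", 13492),
        ("JGI", "embryo", "three_to_five", 13354),
        ("Genoscope", "adult_cns", "five_to_three", 87763),
        ("Iowa", "embryo", "five_to_three", 87),
        ("Iowa", "embryo", "three_to_five", 14995),
        ("Iowa", "adult_cns", "three_to_five", 3470),
    ]
    return pd.DataFrame(rows, columns=["source", "library", "strategy", "count"])


def table2_fixture() -> pd.DataFrame:
    """Contig counts by number of contributing ESTs (1..15, 16+)."""
    counts = [14522, 5778, 3541, 2413, 1852, 1283, 826, 469, 280, 138, 68, 30, 19, 7, 6, 0]
    labels = [str(i) for i in range(1, 16)] + ["16+"]
    return pd.DataFrame({"n_ests": labels, "n_contigs": counts})


def table5_fixture() -> pd.DataFrame:
    """Immune-relevant transcript counts by functional group and provenance."""
    rows = [
        ("PRR pathway proteins", 22, 1, 2, 19),
        ("Pattern recognition Receptors (PRRs)", 12, 1, 4, 7),
        ("Antimicrobial response factors (Effectors)", 11, 0, 2, 9),
        ("Complement system", 19, 0, 4, 15),
        ("Clotting and fibrinolytic cascades", 4, 1, 2, 1),
        ("Cytokines", 5, 0, 0, 5),
        ("Cluster of differentiation related molecules", 8, 0, 1, 7),
        ("Related to vertebrate adaptive immune system", 11, 1, 2, 8),
    ]
    return pd.DataFrame(
        rows, columns=["group", "total", "embryo_only", "adult_only", "mixed"]
    )


def emit_paper_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the packaged report-shape fixtures as TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("table1", table1_fixture()),
        ("table2", table2_fixture()),
        ("table5", table5_fixture()),
    ):
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths
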