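"""Summary tables and end-to-end pipeline orchestration.

The reporting layer reproduces the standard shapes of an EST project
report: raw-read counts cross-tabulated by center, library and strategy
(with integer-percent fractions, half-up rounding); the contig-size
histogram; an immune-panel table of transcripts matching curated keyword
groups, split by provenance.  :func:`run_pipeline` chains the stages
(simulate -> preprocess -> cluster -> assemble -> annotate -> compare ->
report) over a run directory; with identical config and inputs a re-run is
byte-identical, since no stage uses unseeded randomness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import _align, annotate, cluster_assemble, compare, preprocess, simdata
from .annotate import AnnotationRecord
from .seqio import SeqRecord, SourceTag, parse_identifier, read_fasta, read_qual, write_fasta, write_qual

logger = logging.getLogger(__name__)

__all__ = [
    "ReadStatsTable",
    "compute_read_stats",
    "read_stats_from_counts",
    "ImmunePanelTable",
    "DEFAULT_IMMUNE_PANEL",
    "build_immune_panel",
    "run_pipeline",
]


def percent_display(numerator: float, denominator: float) -> int:
    """Integer percent with half-up rounding (the display convention)."""
    if denominator == 0:
        return 0
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class ReadStatsTable:
    """Cross-tabulation of read counts with strategy/library fractions."""

    counts: pd.DataFrame  # columns: source, library, strategy, count
    grand_total: int
    by_strategy: dict[str, int]
    by_library: dict[str, int]
    pct_by_strategy: dict[str, int]
    pct_by_library: dict[str, int]


def read_stats_from_counts(counts: pd.DataFrame) -> ReadStatsTable:
    """Build the stats table from (source, library, strategy, count) rows."""
    total = int(counts["count"].sum())
    by_strategy = counts.groupby("strategy")["count"].sum().astype(int).to_dict()
    by_library = counts.groupby("library")["count"].sum().astype(int).to_dict()
    return ReadStatsTable(
        counts=counts.reset_index(drop=True),
        grand_total=total,
        by_strategy=by_strategy,
        by_library=by_library,
        pct_by_strategy={k: percent_display(v, total) for k, v in by_strategy.items()},
        pct_by_library={k: percent_display(v, total) for k, v in by_library.items()},
    )


def compute_read_stats(tags: Iterable[SourceTag]) -> ReadStatsTable:
    """Cross-tabulate source tags; order-invariant."""
    rows: dict[tuple[str, str, str], int] = {}
    for tag in tags:
        key = (tag.center, tag.library, tag.strategy)
        rows[key] = rows.get(key, 0) + 1
    counts = pd.DataFrame(
        [
            {"source": c, "library": l, "strategy": s, "count": n}
            for (c, l, s), n in sorted(rows.items())
        ],
        columns=["source", "library", "strategy", "count"],
    )
    if counts.empty:
        counts = pd.DataFrame(columns=["source", "library", "strategy", "count"])
        counts["count"] = counts["count"].astype(int)
    return read_stats_from_counts(counts)


# ---------------------------------------------------------------------------
# immune panel

# Curated keyword -> group mapping (editable configuration, not asserted
# truth): a transcript counts once, in the first group whose keyword list
# matches its chosen description.
DEFAULT_IMMUNE_PANEL: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("PRR pathway proteins", ("myd88", "irak", "traf", "nf-kappab", "tak1")),
    ("Pattern recognition Receptors (PRRs)", ("toll-like", "nod-like", "rig-i", "lectin")),
    ("Antimicrobial response factors (Effectors)", ("lumbricin", "theromacin", "destabilase", "antimicrobial")),
    ("Complement system", ("complement", "c1q", "c3", "macroglobulin")),
    ("Clotting and fibrinolytic cascades", ("fibrinogen", "plasminogen", "serpin", "thrombin")),
    ("Cytokines", ("cytokine", "emap", "interleukin")),
    ("Cluster of differentiation related molecules", ("cd45", "cd20", "cd19", "cd61")),
    ("Related to vertebrate adaptive immune system", ("rag-1", "calnexin", "calreticulin", "cathepsin")),
)


@dataclass
class ImmunePanelTable:
    table: pd.DataFrame  # group rows + TOTAL row; total/embryo_only/adult_only/mixed


def build_immune_panel(
    annotations: Sequence[AnnotationRecord],
    panel: Sequence[tuple[str, Sequence[str]]] = DEFAULT_IMMUNE_PANEL,
) -> ImmunePanelTable:
    """Count annotated transcripts per immune keyword group, by provenance.

    Each transcript is counted at most once, in the first matching group in
    declared order (case-insensitive substring match on the chosen
    description).
    """
    rows = {group: {"total": 0, "embryo_only": 0, "adult_only": 0, "mixed": 0} for group, _ in panel}
    for ann in annotations:
        desc = ann.chosen_description.lower()
        for group, keywords in panel:
            if any(kw.lower() in desc for kw in keywords):
                rows[group]["total"] += 1
                rows[group][ann.provenance] += 1
                break
    table = pd.DataFrame(
        [{"group": g, **vals} for g, vals in rows.items()],
        columns=["group", "total", "embryo_only", "adult_only", "mixed"],
    )
    total_row = {"group": "TOTAL", **{c: int(table[c].sum()) for c in ("total", "embryo_only", "adult_only", "mixed")}}
    table = pd.concat([table, pd.DataFrame([total_row])], ignore_index=True)
    return ImmunePanelTable(table)


# ---------------------------------------------------------------------------
# pipeline

STAGES = ("simulate", "preprocess", "cluster", "assemble", "annotate", "compare", "report")


class StageError(RuntimeError):
    pass


def run_pipeline(config: Mapping, outdir: str | Path, upto: str = "report") -> Path:
    """Execute the pipeline stages (in order, through ``upto``) into a run directory.

    ``config`` keys: ``seed`` (required when simulating), ``simulate``
    (SimConfig overrides), or ``reads_fasta``/``reads_qual``/``rrna_fasta``
    to run on existing inputs (the simulate stage is then skipped), plus
    threshold overrides ``bin_identity``, ``min_overlap``,
    ``min_aln_identity``, ``min_aln_length``, ``max_n_frac``,
    ``kmer_size``, ``score_cutoff``.  Each stage writes its artifacts and
    logs counts; a stage failure raises :class:`StageError` naming the
    stage, with earlier artifacts retained.
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    for stage in STAGES:
        if stage == "simulate" and "reads_fasta" in config:
            if upto == "simulate":
                break
            continue
        try:
            _STAGE_FUNCS[stage](config, outdir, state)
            logger.info("stage %s complete", stage)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        if stage == upto:
            break
    return outdir


def _stage_simulate(config: Mapping, outdir: Path, state: dict) -> None:
    sim_over = dict(config.get("simulate", {}))
    cfg = simdata.SimConfig(seed=int(config["seed"]), **sim_over)
    motifs = preprocess.MotifConfig()
    txome = simdata.generate_transcriptome(cfg, motifs)
    rrna_db = simdata.make_rrna_db(cfg.seed)
    ecoli = simdata.make_ecoli_genome(cfg.seed)
    reads, truth = simdata.generate_est_reads(txome, cfg, motifs, rrna_db, ecoli)
    write_fasta(reads, outdir / "reads.fasta")
    write_qual(reads, outdir / "reads.qual")
    write_fasta(rrna_db, outdir / "rrna.fasta")
    state.update(cfg=cfg, motifs=motifs, txome=txome, rrna_db=rrna_db, ecoli=ecoli,
                 reads=reads, truth=truth)


def _stage_preprocess(config: Mapping, outdir: Path, state: dict) -> None:
    motifs = state.get("motifs", preprocess.MotifConfig())
    if "reads" not in state:
        reads = read_fasta(config["reads_fasta"])
        if config.get("reads_qual"):
            reads = read_qual(config["reads_qual"], reads)
        state["reads"] = reads
        state["rrna_db"] = read_fasta(config["rrna_fasta"]) if config.get("rrna_fasta") else []
    reads = state["reads"]
    thresholds = preprocess.QualityThresholds()
    ests = []
    drop_rows = []
    feature_rows = []
    for rec in reads:
        oriented = preprocess.orient_by_strategy(rec)
        qa = preprocess.assess_quality(oriented, thresholds) if oriented.quals else None
        features = preprocess.detect_features(oriented, motifs)
        est = preprocess.trim_and_mask(oriented, qa, features)
        for s, e, lab in features.intervals:
            feature_rows.append({"id": rec.id, "start": s, "end": e, "label": lab})
        ests.append(est)
    ecoli = state.get("ecoli")
    if ecoli:
        ests = preprocess.screen_ecoli(ests, _align.kmer_set(ecoli, 21))
    if state.get("rrna_db"):
        ests = preprocess.screen_rrna(ests, state["rrna_db"])
    ests = preprocess.merge_clone_pairs(ests)
    live = [e for e in ests if not e.dropped and e.rrna_status != "rrna_gene"]
    for est in ests:
        if est.dropped:
            drop_rows.append({"id": est.record.id, "reason": est.drop_reason})
        elif est.rrna_status == "rrna_gene":
            drop_rows.append({"id": est.record.id, "reason": "rrna_gene"})
    write_fasta([e.record for e in live], outdir / "masked.fasta")
    pd.DataFrame(drop_rows, columns=["id", "reason"]).to_csv(
        outdir / "drops.tsv", sep="\t", index=False
    )
    pd.DataFrame(feature_rows, columns=["id", "start", "end", "label"]).to_csv(
        outdir / "features.tsv", sep="\t", index=False
    )
    state["ests"] = live
    logger.info("preprocess: %d/%d reads retained", len(live), len(reads))


def _stage_cluster(config: Mapping, outdir: Path, state: dict) -> None:
    ests = state["ests"]
    hits = cluster_assemble.all_vs_all(
        ests,
        min_identity=float(config.get("min_aln_identity", 0.80)),
        min_aln_length=int(config.get("min_aln_length", 100)),
        seed_k=int(config.get("kmer_size", 16)),
    )
    bins = cluster_assemble.build_bins(
        [e.record.id for e in ests], hits, float(config.get("bin_identity", 0.90))
    )
    pd.DataFrame(
        [
            {"bin": i, "est_id": mid}
            for i, b in enumerate(bins)
            for mid in sorted(b.members)
        ],
        columns=["bin", "est_id"],
    ).to_csv(outdir / "bins.tsv", sep="\t", index=False)
    state["bins"] = bins
    state["hits"] = hits


def _stage_assemble(config: Mapping, outdir: Path, state: dict) -> None:
    params = cluster_assemble.AssemblyParams(
        min_overlap=int(config.get("min_overlap", 40)),
        max_n_frac=float(config.get("max_n_frac", 0.05)),
        seed_k=int(config.get("kmer_size", 16)),
    )
    by_id = {e.record.id: e for e in state["ests"]}
    outputs = []
    for b in state["bins"]:
        outputs.append(
            cluster_assemble.assemble_bin([by_id[m] for m in sorted(b.members)], params)
        )
    summary = cluster_assemble.summarize_assembly(outputs)
    contig_records = []
    membership = []
    problems = []
    transcripts: dict[str, str] = {}
    members_of: dict[str, list[str]] = {}
    for out in outputs:
        for contig in out.contigs:
            contig_records.append(SeqRecord(contig.id, contig.consensus))
            transcripts[contig.id] = contig.consensus
            members_of[contig.id] = [p.est_id for p in contig.members]
            for p in contig.members:
                membership.append(
                    {
                        "contig_id": contig.id,
                        "est_id": p.est_id,
                        "offset": p.start,
                        "strand": p.strand,
                        "contributing": p.est_id in contig.contributing,
                    }
                )
        for sid in out.singletons:
            transcripts[sid] = by_id[sid].record.bases
            members_of[sid] = [sid]
        problems.extend(out.problems)
    write_fasta(contig_records, outdir / "contigs.fasta")
    pd.DataFrame(membership, columns=["contig_id", "est_id", "offset", "strand", "contributing"]).to_csv(
        outdir / "membership.tsv", sep="\t", index=False
    )
    pd.DataFrame(problems, columns=["est_id", "reason"]).to_csv(
        outdir / "problems.tsv", sep="\t", index=False
    )
    (outdir / "assembly_summary.json").write_text(json.dumps(summary, indent=1))
    state.update(assembly=outputs, assembly_summary=summary, transcripts=transcripts,
                 members_of=members_of)
    logger.info("assembly: %s", summary)


def _stage_annotate(config: Mapping, outdir: Path, state: dict) -> None:
    cfg = state.get("cfg")
    if "proteomes" not in state:
        if cfg is None or "txome" not in state:
            raise ValueError("annotation requires generated proteomes or none configured")
        proteomes, go_table = simdata.generate_proteomes(state["txome"], cfg)
        state["proteomes"], state["go_table"] = proteomes, go_table
    proteomes, go_table = state["proteomes"], state["go_table"]
    ref_name, refs = proteomes[0]  # least-diverged set is the annotation reference
    corpus_df = annotate.corpus_document_frequencies([r.description for r in refs])
    protein_terms: dict[str, set[str]] = {}
    for row in go_table.itertuples():
        protein_terms.setdefault(row.protein_id, set()).add(row.term_id)
    term_names = dict(zip(go_table["term_id"], go_table["term_name"]))
    cutoff = float(config.get("score_cutoff", 50.0))

    records: list[AnnotationRecord] = []
    all_hits: dict[str, dict[str, list]] = {}
    for tid in sorted(state["transcripts"]):
        seq = state["transcripts"][tid]
        frames = annotate.six_frame_translate(seq)
        per_proteome: dict[str, list] = {}
        for name, prots in proteomes:
            per_proteome[name] = annotate.align_peptides(tid, frames, prots, score_cutoff=cutoff)
        all_hits[tid] = per_proteome
        hits = per_proteome[ref_name]
        index = annotate.build_description_index(hits, corpus_df=corpus_df)
        desc, score = annotate.select_description(hits, index)
        go_terms = annotate.assign_go(hits, protein_terms) if hits else frozenset()
        provenance = annotate.classify_provenance(state["members_of"][tid])
        records.append(AnnotationRecord(tid, desc, score, go_terms, provenance))
    pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "description": r.chosen_description,
                "score": r.description_score,
                "go_ids": ",".join(sorted(r.go_terms)),
                "provenance": r.provenance,
            }
            for r in records
        ]
    ).to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    neuro = annotate.count_by_category(
        {r.transcript_id: r.go_terms for r in records},
        term_names,
        "neuro",
        {r.transcript_id: r.provenance for r in records},
    )
    neuro.to_csv(outdir / "go_neuro.tsv", sep="\t", index=False)
    state.update(annotations=records, all_hits=all_hits, term_names=term_names)


def _stage_compare(config: Mapping, outdir: Path, state: dict) -> None:
    proteome_names = [name for name, _ in state["proteomes"]]
    scores = {}
    idents = {}
    for tid, per_proteome in state["all_hits"].items():
        s = {}
        ident = {}
        for name, hits in per_proteome.items():
            if hits:
                s[name] = hits[0].score
                ident[name] = hits[0].identity
        if s:
            scores[tid] = s
            idents[tid] = ident
    ranks = compare.rank_best_matches(scores, proteome_names)
    hist = compare.identity_histogram(idents, proteome_names)
    ranks.to_csv(outdir / "rank_matrix.tsv", sep="\t")
    hist.counts.to_csv(outdir / "identity_histogram.tsv", sep="\t")
    state.update(rank_matrix=ranks, identity_hist=hist)


def _stage_report(config: Mapping, outdir: Path, state: dict) -> None:
    tags = [parse_identifier(r.id) for r in state["reads"]]
    stats = compute_read_stats(tags)
    stats.counts.to_csv(outdir / "read_stats.tsv", sep="\t", index=False)
    panel = build_immune_panel(state["annotations"])
    panel.table.to_csv(outdir / "immune_panel.tsv", sep="\t", index=False)
    summary = {
        "n_reads": stats.grand_total,
        "pct_by_strategy": stats.pct_by_strategy,
        "pct_by_library": stats.pct_by_library,
        "assembly": state["assembly_summary"],
        "n_annotated": sum(1 for r in state["annotations"] if r.chosen_description),
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    state["report"] = summary


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "cluster": _stage_cluster,
    "assemble": _stage_assemble,
    "annotate": _stage_annotate,
    "compare": _stage_compare,
    "report": _stage_report,
}
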