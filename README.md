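# estkit

EST transcriptome construction and annotation, as a tested, reusable
Python package.

Expressed sequence tags (ESTs) — single-pass reads from the ends of cDNA
clones — are still how transcriptomes get built for organisms without a
reference genome. Turning a hundred thousand raw reads from directional
embryo and adult-CNS libraries into a non-redundant, annotated transcript
set takes a chain of steps that are individually simple but easy to get
subtly wrong: artifact trimming, contamination screens, clustering reads
that belong to the same gene without collapsing close paralogs, consensus
assembly, and homology-based functional annotation. `estkit` implements
that chain end to end, with a synthetic-data generator that knows the
ground truth for every read, so each stage can be tested quantitatively
without any external database.

## What it does

- **Read screening** (`estkit.preprocess`): three quality criteria on
  phred values (mean q > 25 over the usable region, > 50% of bases at
  q ≥ 20, quality-trimmed insert > 100 nt); detection and trimming/masking
  of the EcoRI adaptor, NotI site, anchored oligo-dT primer with a
  degenerate N\[6–10\] spacer, library tags, poly(A) tails and signals;
  DUST-like low-complexity masking; rRNA screening (flagging reads that
  align ≥ 90% identity partially as *suspects*, near-completely as *rRNA
  genes*); an exact 21-mer *E. coli* screen; and merging of clone pairs
  sequenced from both ends when they overlap ≥ 40 nt at ≥ 95% identity.
- **Binning + assembly** (`estkit.cluster_assemble`): all-vs-all pairwise
  comparison on both strands (exact 16-mer seeding, gapless banded
  extension), then *bins* as connected components of the hit graph at an
  identity threshold (default 90%) — so reads chained by overlaps
  assemble together — and per-bin greedy overlap-layout-consensus
  assembly into contigs, singletons and "problem" reads (too many
  ambiguous N bases). Each contig carries a contribution ledger: a member
  read is redundant iff its placement is contained in another single
  member's placement.
- **Annotation** (`estkit.annotate`): six-frame conceptual translation,
  BLOSUM62 local alignment against protein reference sets, and a
  weighted-word relevance score to pick one functional description per
  transcript: each description word is weighted by the summed alignment
  scores of the descriptions containing it, ubiquitous low-information
  words ("protein", "similar", …) are removed by a document-frequency
  stoplist, words above mean + 2·STD are significant, and the description
  with the highest significant-word sum wins. GO terms are assigned
  through a protein↔term table; transcripts are classed embryo-only /
  adult-only / mixed from the libraries of their full read membership.
- **Comparison** (`estkit.compare`): per-transcript best-match ranks
  across k proteomes (which proteome matches best, second-best, …) and
  identity-decile histograms with per-proteome mean identity.
- **Synthetic data** (`estkit.simdata`): seeded generation of coding
  transcripts, decorated directional reads with substitution errors and
  3'-decaying qualities, clone pairs, planted rRNA/*E. coli*
  contaminants, proteomes at controlled amino-acid divergence,
  GO tables, and packaged report-shape table fixtures — all with a
  complete truth ledger.
- **Reporting + orchestration** (`estkit.report`, CLI `estkit`):
  cross-tabulated read statistics, contig-size histograms, a curated
  immune-keyword panel table, and a deterministic stage runner
  (`simulate → preprocess → cluster → assemble → annotate → compare →
  report`) that leaves every artifact in a run directory.

## Worked example

```bash
python examples/02_bin_and_assemble.py
```

```
160 reads tiling 10 transcripts at ~5x
540 pairwise hits -> 10 bins
assembly: {'histogram': {7: 1, 11: 1, 13: 1, 15: 2, 16: 1, 17: 1, 18: 1, 20: 1, 28: 1}, 'n_contigs': 10, 'n_singletons': 0, 'n_problems': 0, 'total': 10}
10 contig consensus sequences equal their source transcript exactly
```

Ten transcripts tiled by error-free reads at 5× produce exactly ten bins
(binning separates unrelated transcripts; transitive closure joins reads
that never align directly), and each bin assembles into one contig whose
consensus equals the source transcript base for base. The histogram keys
count contributing (non-redundant) reads per contig.

The other examples show screening (`01`), annotation with description
relevance scoring (`03`), multi-proteome ranking (`04`) and the
end-to-end pipeline (`05`); each prints the numbers it computes and what
they mean. The same pipeline runs from a shell:

```bash
estkit --seed 7 --outdir run all
```

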