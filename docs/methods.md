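# Methods

This note records the models, parameter choices and numerical conventions
behind `estkit`, and what the synthetic-data tests do and do not
demonstrate about real EST data.

## Read model and screening

Reads are single-pass sequences from directional cDNA clones. A clone
insert is flanked 5' by an EcoRI adaptor (`AATTGGCACGAGG`) and a short
library-identifying tag, and 3' by the poly(A) tail, NotI site
(`GCGGCCGC`) and the anchored oligo-dT primer
(`TGTTACCATTCTGATGTTGGAGCGGCCGC-N[6-10]-T`, a literal head, a 6–10 nt
degenerate spacer, then the dT anchor). Reads sequenced 3'→5' are
reverse-complemented first, so all downstream logic sees mRNA-forward
sequence with the tail on the right.

**Quality.** Three criteria gate every read: mean phred > 25, fraction of
bases at q ≥ 20 above 0.5, and quality-trimmed length > 100 nt (all
strict inequalities; a base at exactly q20 counts toward the fraction).
End trimming keeps the longest region in which every 20-nt sliding
window has mean ≥ 20, then shrinks terminal bases individually below
q20. Mean quality and the q20 fraction are evaluated over that trimmed
region: the criteria describe the usable part of a read, and low-quality
tails are accounted for once, through the length criterion, rather than
double-counted against the mean. All thresholds live in
`QualityThresholds`.

**Features.** Literal motifs are matched by sliding comparison within a
configurable substitution budget (default 1; `N` in a motif is a
wildcard). The poly(A) tail is the terminal A-run of ≥ 12 nt. Feature
intervals are 0-based half-open. Terminal artifact features (adaptor,
tag, restriction site, primer/vector, tail) are peeled off the read
ends iteratively; internal artifact occurrences are masked to N. The
poly(A) *signal* (`AATAAA`) is annotated but neither trimmed nor masked —
it is transcript sequence, not an artifact. Repeat masking is reduced to
a DUST-like low-complexity filter (triplet-count score over 64-nt
windows, threshold 2.5, computed on the peeled region so windows
straddling a trimmed tail cannot bleed N into the insert); no
species-specific repeat library is assumed. Masked-out termini are
converted to trimming, since terminal Ns carry no sequence information.

**Contamination.** The rRNA screen aligns each read (both strands,
k-mer-prefiltered) against an rRNA reference FASTA by full local DP; an
alignment at ≥ 90% identity covering ≥ 90% of the read marks an *rRNA
gene*, any other qualifying alignment of ≥ 50 columns an *rRNA suspect*.
The 50-column floor exists because a chance exact micro-match (≈ 12 nt)
otherwise scores identity 1.0. "Complete" = 90% read coverage is our
quantification of near-complete alignment. The *E. coli* screen drops
reads sharing ≥ 20% of their exact 21-mers with a user-supplied k-mer
set. Both screens run after trimming; the pipeline excludes rRNA-gene
reads from assembly and keeps suspects, flagged.

**Clone-pair merging.** After orientation, the 5' and 3' reads of a
clone are merged when their best gapless overlap spans ≥ 40 nt at ≥ 95%
identity; disagreements resolve to the higher-quality base, and the
merged record keeps the 5' identifier. Merging runs after quality and
feature trimming (the order is a design choice; trimming first means
overlaps are computed on clean sequence).

## Binning and assembly

**Pairwise comparison.** Identity is always matches / alignment columns,
gap columns included, ambiguous positions never matching. All-vs-all
read comparison seeds on shared exact 16-mers (either strand) and scores
the best shared diagonal gaplessly — a banded extension with band 0,
appropriate because the error model is substitution-dominated; a
brute-force flag adds full local DP for unseeded pairs. A hit requires
identity ≥ 0.80 over ≥ 100 columns by default; binning then keeps edges
at ≥ 0.90. Bins are the connected components of the hit graph (via
networkx; tests check against an independent union-find), with hitless
reads as singleton bins. Components, members and all orderings are
sorted, so output is deterministic. "Alignment above a threshold
quality" is operationalized as identity ∧ length because identity alone
is meaningless for micro-alignments; local (not global) identity is used.

**Assembly.** Each bin is assembled by greedy overlap-layout-consensus:
reads with N-fraction > 0.05 are routed to *problems* ("ambiguous")
first; then the pair of layouts with the highest-scoring overlap (≥ 40
nt, ≥ 95% identity, either orientation) merges, with consensus per
column by majority over covering reads — ties produce N, the same
ambiguity notion that defines problems. Merge order is total (match
count, then lexicographic smallest member ids), so assembly is fully
deterministic; there is no randomness anywhere in the pipeline. The
strict 95% within-contig threshold deliberately keeps close paralogs,
alleles and splice variants apart as separate transcripts rather than
collapsing them. Consensus is count-weighted, not phred-weighted — a
known simplification; per-base qualities influence only screening and
pair merging.

**Contribution.** On a finished contig, a member is *redundant* iff its
placed interval is contained in another single member's interval; for
exactly equal intervals the lexicographically smaller id contributes.
Contig identifiers are `ctg-` + 12 hex chars of a SHA-1 over the sorted
member ids — deterministic and order-independent. The contig-size
histogram counts transcripts by contributing reads, with singletons and
problems under size 1.

## Annotation

Translation uses the standard genetic code, keeps stops in-line as `*`,
and maps any codon containing N to X; frames −1..−3 translate the
reverse complement, giving exact strand symmetry. Peptide/protein
alignment is local BLOSUM62 with affine gaps (−11/−1), best frame per
protein, with an exact amino-acid 4-mer prefilter (and a brute-force
flag). "Alignment quality" in the description score is the raw alignment
score; identity × length is available as an alternative weighting.

Description scoring: tokens are lowercased, split on non-alphanumerics,
and dropped under 3 characters (no stemming). A word's weight is the sum
of scores of the hits whose descriptions contain it, once per
description. The stoplist is derived per corpus: words whose document
frequency lies in the top 1% quantile are discarded — this is what makes
"protein" or "similar" uninformative without any fixed word list. Of the
remaining words, those with weight > mean + 2·STD are significant; the
alternative reading, weight > 2·STD in absolute terms, is selectable
(`significance="2std"`) since the prose rule is ambiguous. Two
degenerate cases are defined explicitly: when weights are all equal or
fewer than 8 distinct words survive, the tail threshold has no
discriminating power and every kept word counts. A description's score
is the sum of its significant words' weights; ties break toward the
higher best single-hit score, then lexicographically. Selection is
invariant under positive rescaling of scores and permutation of hits.

GO assignment is a direct union: a transcript receives every term linked
to any protein it hits; there is no ontology-graph propagation.
Provenance classes (embryo-only / adult-only / mixed) are computed from
the **full** read membership of a transcript, redundant reads included —
a redundant read still proves the library expressed the transcript.

## Multi-proteome comparison

For each transcript, proteomes with a hit are ordered by best-hit score
(ties resolved by the declared proteome order, made explicit because no
natural rule exists) and assigned ranks 1..m; "best match" means highest
alignment score, not lowest E-value — no E-value statistics are in
scope. Identity histograms use half-open percent deciles with (90, 100]
last, and per-proteome mean identity in percent. Displayed percentages
throughout the reporting layer round half-up to integers.

## Synthetic data: what it emulates and what it does not

The generator emulates: lognormal transcript lengths (median ≈ 1.8 kb)
with a back-translated random ORF between UTRs; lognormal clone
abundances (the residual duplication left after library normalization);
oligo-dT-primed inserts that always reach the transcript 3' end; 5'→3'
and 3'→5' reads (76% five-prime by default) with ~600 nt reads; 30% of
clones paired; adaptor/tag/poly(A) decorations; uniform substitution
errors (1% default; indels available but off, because the consensus
contract is defined on substitutions); phred-like linear quality decay
q40 → q10 with Gaussian jitter (σ 3); and planted rRNA (2%) and
*E. coli* (1%) contaminant reads drawn from synthetic stand-in
references (`make_rrna_db`, `make_ecoli_genome` — labelled stand-ins,
not real sequences). Proteomes derive from the source proteins at a
strictly increasing divergence schedule (default 0.05/0.2/0.5), with one
unique informative description word per protein family plus ubiquitous
filler words the stoplist should remove, and a GO table that includes
"neuro"-named categories.

Transcripts are scrubbed of artifact-look-alike motifs (planted motifs,
poly(A) signal, homopolymer runs > 11, and a non-A final base) so
planted decorations are unambiguous and "exact insert recovery" is
well-defined. Real data offers no such guarantee: a genuine read can end
in genomic A-runs or contain adaptor-like sequence, and real quality
strings are not linear. Passing the recovery tests therefore shows the
trimming logic is correct under its stated conventions, not that those
conventions are optimal for any particular chromatogram pipeline. The
generator also does not emulate codon usage, splice variation, chimeric
clones, or indel-heavy error profiles; the assembler's accuracy numbers
apply to substitution-dominated data.

Determinism: every operation seeds `numpy.random.default_rng` from
(seed, stream-tag), so each stage is independently reproducible and full
runs are byte-identical under a fixed configuration.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run at desk scale, chosen so
each property is measured with comfortable margins: 100 random graphs of
up to 500 nodes for the binning oracle; 10 transcripts (~1.2 kb) tiled
at 5× by 400-nt reads, error-free and at 1% substitution error over
10–20 seeds, for assembly recovery; 50 random simulations for the
partition invariant; 1,000 random sequences for translation symmetry;
1,000 reads (300 planted rRNA at ≤ 5% mutation) for screening; and
200–500 short transcripts against three proteomes for rank structure.
The packaged table fixtures carry the printed report-shape counts and
are exercised purely arithmetically by the reporting layer.

## Known limitations

Greedy consensus assembly is not phrap: no quality-weighted consensus,
no repeat-aware layout, and "problem" classification covers only the
ambiguity (N-fraction) cause. Binning with gapless seeded extension can
miss pairs whose only homology is indel-riddled (the brute-force flag
closes this at quadratic cost). The immune keyword panel is editable
configuration, not curated truth. E-value calibration, ontology
reasoning and live database access are deliberately out of scope.
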