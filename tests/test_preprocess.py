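"""Quality screening, artifact masking/trimming, contamination screens, merging."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import as_est, make_id, mutate, random_dna
from estkit import _align
from estkit.preprocess import (
    InputError,
    MotifConfig,
    QualityUnavailableError,
    ConfigurationError,
    assess_quality,
    detect_features,
    find_motif,
    merge_clone_pairs,
    orient_by_strategy,
    screen_ecoli,
    screen_rrna,
    trim_and_mask,
)
from estkit.seqio import SeqRecord
from estkit.simdata import SimConfig, generate_est_reads, generate_transcriptome, make_rrna_db

MOTIFS = MotifConfig()


class TestAssessQuality:
    def test_high_quality_passes(self):
        rec = SeqRecord("EMB|JGI|F|c1", "ACGT" * 125, quals=[30] * 500)
        qa = assess_quality(rec)
        assert qa.passes and qa.mean_q == 30 and qa.frac_ge_q20 == 1.0

    def test_q20_counts_toward_fraction_but_fails_mean(self):
        rec = SeqRecord("EMB|JGI|F|c1", "ACGT" * 125, quals=[20] * 500)
        qa = assess_quality(rec)
        assert not qa.pass_q
        assert qa.pass_frac  # bases at exactly q20 count toward frac >= q20
        assert qa.pass_len

    def test_trimmed_length_exactly_100_fails_strictly(self):
        quals = [30] * 100 + [2] * 200
        rec = SeqRecord("EMB|JGI|F|c1", "A" * 300, quals=quals)
        qa = assess_quality(rec)
        assert qa.trimmed_length == 100
        assert not qa.pass_len  # "more than 100 bp" is strict

    def test_missing_quals_raises(self):
        with pytest.raises(QualityUnavailableError):
            assess_quality(SeqRecord("EMB|JGI|F|c1", "ACGT"))

    def test_low_quality_tail_is_trimmed(self):
        quals = [35] * 400 + [5] * 100
        rec = SeqRecord("EMB|JGI|F|c1", "ACGT" * 125, quals=quals)
        qa = assess_quality(rec)
        assert 380 <= qa.trimmed_length <= 400
        assert qa.trim_start == 0


class TestDetectFeatures:
    def test_adaptor_at_read_start(self, rng):
        seq = MOTIFS.adaptor + random_dna(rng, 200)
        ann = detect_features(SeqRecord("EMB|JGI|F|c1", seq), MOTIFS)
        assert (0, 13, "adaptor") in ann.intervals

    def test_terminal_polya_run(self, rng):
        seq = random_dna(rng, 200) + "A" * 25
        ann = detect_features(SeqRecord("EMB|JGI|F|c1", seq), MOTIFS)
        tails = ann.by_label("polyA_tail")
        assert len(tails) == 1
        start, end = tails[0]
        assert end == len(seq) and end - start >= 25

    def test_clean_read_annotation_empty(self, rng):
        # scrubbed random read: no motifs, exact matching only
        seq = random_dna(rng, 300).replace(MOTIFS.polyA_signal, "AATAAC")
        ann = detect_features(SeqRecord("EMB|JGI|F|c1", seq), MOTIFS, max_mismatch=0)
        assert ann.intervals == () or all(lab == "polyA_signal" for *_, lab in ann.intervals)
        if not ann.intervals:
            assert ann.masked_bases == seq

    def test_masking_preserves_length(self, rng):
        seq = MOTIFS.adaptor + random_dna(rng, 150) + "A" * 20
        ann = detect_features(SeqRecord("EMB|JGI|F|c1", seq), MOTIFS)
        assert len(ann.masked_bases) == len(seq)
        assert set(ann.masked_bases[:13]) == {"N"}

    def test_find_motif_with_mismatch(self):
        seq = "TTTT" + "AATTGGCACGAGG" + "TTTT"
        one_off = "TTTT" + "AATTGGCTCGAGG" + "TTTT"
        assert find_motif(seq, MOTIFS.adaptor, 0) == [(4, 17)]
        assert find_motif(one_off, MOTIFS.adaptor, 0) == []
        assert find_motif(one_off, MOTIFS.adaptor, 1) == [(4, 17)]

    def test_oligo_dt_primer_with_degenerate_spacer(self, rng):
        head = "TGTTACCATTCTGATGTTGGAGCGGCCGC"
        seq = random_dna(rng, 50) + head + "ACGTACGA" + "TTTTTT" + random_dna(rng, 40)
        ann = detect_features(SeqRecord("EMB|JGI|F|c1", seq), MOTIFS)
        sites = ann.by_label("vector_site")
        assert any(s == 50 for s, _ in sites)


class TestTrimAndMask:
    def _qa(self, n):
        return None  # feature-only trimming path

    def test_planted_layout_recovered(self, rng):
        # insert must not end in A or the poly(A) boundary is ambiguous
        insert = random_dna(rng, 299) + "C"
        seq = MOTIFS.adaptor + MOTIFS.tag_by_library["embryo"] + insert + "A" * 20
        rec = SeqRecord("EMB|JGI|F|c1", seq)
        est = trim_and_mask(rec, None, detect_features(rec, MOTIFS))
        assert not est.dropped
        assert est.record.bases == insert

    def test_short_insert_dropped(self, rng):
        rec = SeqRecord("EMB|JGI|F|c1", random_dna(rng, 80))
        est = trim_and_mask(rec, None, detect_features(rec, MOTIFS))
        assert est.dropped and est.drop_reason == "short_insert"

    def test_low_quality_read_dropped(self):
        rec = SeqRecord("EMB|JGI|F|c1", "ACGT" * 100, quals=[10] * 400)
        est = trim_and_mask(rec, assess_quality(rec), detect_features(rec, MOTIFS))
        assert est.dropped and est.drop_reason in ("low_quality", "short_insert")

    def test_trimming_never_lengthens_and_masking_preserves_length(self, rng):
        for _ in range(20):
            n = int(rng.integers(150, 500))
            rec = SeqRecord("EMB|JGI|F|c1", random_dna(rng, n))
            ann = detect_features(rec, MOTIFS)
            assert len(ann.masked_bases) == n
            est = trim_and_mask(rec, None, ann)
            if not est.dropped:
                assert len(est.record.bases) <= n

    def test_generator_truth_recovery_error_free(self):
        """Planted decorations are removed exactly on error-free reads."""
        cfg = SimConfig(
            seed=11,
            n_transcripts=10,
            n_clones={"embryo": 60, "adult_cns": 60},
            error_rate=0.0,
            q_start=40.0,
            q_end=40.0,
            q_jitter=0.0,
            rrna_fraction=0.0,
            ecoli_fraction=0.0,
        )
        txome = generate_transcriptome(cfg, MOTIFS)
        reads, truth = generate_est_reads(txome, cfg, MOTIFS)
        assert len(reads) >= 120
        n_checked = 0
        for rec in reads:
            oriented = orient_by_strategy(rec)
            qa = assess_quality(oriented)
            # error-free reads: exact motif matching is part of the condition
            est = trim_and_mask(oriented, qa, detect_features(oriented, MOTIFS, max_mismatch=0))
            planted = truth.planted_insert[rec.id]
            if len(planted) <= 100:
                continue
            assert not est.dropped, rec.id
            assert est.record.bases == planted, rec.id
            n_checked += 1
        assert n_checked >= 100


class TestScreens:
    def test_rrna_gene_suspect_clean(self, rng):
        db = make_rrna_db(seed=3)
        ref = db[0].bases
        gene = as_est(SeqRecord(make_id(1), ref[:500]))
        partial = as_est(
            SeqRecord(make_id(2), mutate(rng, ref[200:350], 0.05) + random_dna(rng, 350))
        )
        clean = as_est(SeqRecord(make_id(3), mutate(rng, ref[:400], 0.25)))
        out = screen_rrna([gene, partial, clean], db)
        assert [e.rrna_status for e in out] == ["rrna_gene", "rrna_suspect", "clean"]

    def test_empty_rrna_db_is_config_error(self, rng):
        with pytest.raises(ConfigurationError):
            screen_rrna([as_est(SeqRecord(make_id(1), random_dna(rng, 200)))], [])

    def test_reverse_strand_rrna_detected(self):
        db = make_rrna_db(seed=3)
        est = as_est(SeqRecord(make_id(1), _align.revcomp(db[1].bases[100:600])))
        assert screen_rrna([est], db)[0].rrna_status == "rrna_gene"

    def test_ecoli_kmer_screen(self, rng):
        genome = random_dna(rng, 5000)
        kmers = _align.kmer_set(genome, 21)
        contaminant = as_est(SeqRecord(make_id(1), genome[1000:1400]))
        other = as_est(SeqRecord(make_id(2), random_dna(rng, 400)))
        out = screen_ecoli([contaminant, other], kmers)
        assert out[0].dropped and out[0].drop_reason == "ecoli_contaminant"
        assert not out[1].dropped


class TestMergeClonePairs:
    def _pair(self, transcript, rng, err=0.0):
        five = mutate(rng, transcript[:600], err)
        three = mutate(rng, transcript[-500:], err)
        r5 = SeqRecord(make_id(1, strategy="five_to_three"), five, quals=[40] * len(five))
        r3 = SeqRecord(make_id(1, strategy="three_to_five"), three, quals=[40] * len(three))
        return as_est(r5), as_est(r3)

    def test_exact_overlap_merges_to_transcript(self, rng):
        transcript = random_dna(rng, 900)
        e5, e3 = self._pair(transcript, rng)
        merged = merge_clone_pairs([e5, e3])
        assert len(merged) == 1
        assert merged[0].record.bases == transcript

    def test_disjoint_reads_both_kept(self, rng):
        r5 = SeqRecord(make_id(2, strategy="five_to_three"), random_dna(rng, 300))
        r3 = SeqRecord(make_id(2, strategy="three_to_five"), random_dna(rng, 300))
        assert len(merge_clone_pairs([as_est(r5), as_est(r3)])) == 2

    def test_three_reads_per_clone_rejected(self, rng):
        recs = [
            SeqRecord(make_id(3, strategy="five_to_three"), random_dna(rng, 200)),
            SeqRecord(make_id(3, strategy="five_to_three"), random_dna(rng, 200)),
        ]
        with pytest.raises(InputError):
            merge_clone_pairs([as_est(r) for r in recs])

    def test_noisy_pairs_merge_close_to_truth(self, rng):
        """Clone pairs at 1% substitution error: >=95% merge, >=99% identity."""
        n_merged = 0
        identities = []
        for i in range(100):
            transcript = random_dna(rng, 900)
            e5, e3 = self._pair(transcript, rng, err=0.01)
            out = merge_clone_pairs([e5, e3])
            if len(out) == 1:
                n_merged += 1
                ov = _align.best_diagonal_overlap(transcript, out[0].record.bases)
                identities.append(ov.matches / len(transcript))
        assert n_merged >= 95
        assert np.mean(identities) >= 0.99
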