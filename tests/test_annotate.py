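"""Six-frame translation, homology hits, description scoring, GO, provenance."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_id, random_dna
from estkit import _align
from estkit.annotate import (
    ProteinHit,
    ProteinRef,
    align_peptides,
    assign_go,
    build_description_index,
    classify_provenance,
    corpus_document_frequencies,
    count_by_category,
    select_description,
    six_frame_translate,
    tokenize,
)
from estkit.simdata import SimConfig, generate_proteomes, generate_transcriptome

dna = st.text(alphabet="ACGTN", min_size=0, max_size=60)


class TestTranslation:
    def test_forward_frame(self):
        frames = {f.frame: f.peptide for f in six_frame_translate("ATGAAA")}
        assert frames[1] == "MK"

    def test_reverse_frame_strand_symmetry_example(self):
        frames = {f.frame: f.peptide for f in six_frame_translate("TTTCAT")}
        assert frames[-1] == "MK"

    def test_n_codon_is_x_and_stop_is_star(self):
        frames = {f.frame: f.peptide for f in six_frame_translate("ATGTAANNN")}
        assert frames[1] == "M*X"

    def test_short_sequence_no_error(self):
        frames = six_frame_translate("AT")
        assert all(f.peptide == "" for f in frames)

    @settings(max_examples=300, deadline=None)
    @given(seq=dna)
    def test_strand_symmetry_and_length_law(self, seq):
        fwd = {f.frame: f.peptide for f in six_frame_translate(seq)}
        rev = {f.frame: f.peptide for f in six_frame_translate(_align.revcomp(seq))}
        for k in (1, 2, 3):
            assert fwd[k] == rev[-k]
            assert fwd[-k] == rev[k]
            assert len(fwd[k]) == max(0, (len(seq) - (k - 1)) // 3)

    def test_strand_symmetry_bulk_random(self, rng):
        for _ in range(1000):
            seq = random_dna(rng, int(rng.integers(3, 120)))
            fwd = {f.frame: f.peptide for f in six_frame_translate(seq)}
            rev = {f.frame: f.peptide for f in six_frame_translate(_align.revcomp(seq))}
            assert all(fwd[k] == rev[-k] for k in (1, 2, 3))


def _back_translate(rng, peptide):
    from estkit.simdata import _SYNONYMS

    return "".join(_SYNONYMS[aa][rng.integers(len(_SYNONYMS[aa]))] for aa in peptide)


class TestAlignPeptides:
    def test_exact_subprotein_top_hit(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        protein = "".join(rng.choice(list(aas), size=120))
        transcript = "ATG" + _back_translate(rng, protein[10:110])
        frames = six_frame_translate(transcript)
        refs = [
            ProteinRef("target", protein, "target protein"),
            ProteinRef("decoy", "".join(rng.choice(list(aas), size=120)), "decoy"),
        ]
        hits = align_peptides("t1", frames, refs, score_cutoff=50)
        assert hits and hits[0].protein_id == "target"
        assert hits[0].identity == 1.0

    def test_noncoding_vs_unrelated_no_hits(self, rng):
        frames = six_frame_translate(random_dna(rng, 300))
        refs = [
            ProteinRef(f"p{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=150)), "x")
            for i in range(5)
        ]
        assert align_peptides("t1", frames, refs, score_cutoff=100) == []

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            align_peptides("t1", six_frame_translate("ATGAAA"), [])

    def test_divergent_source_recovered(self, rng):
        """Top hit recovers the source protein at 10% aa divergence."""
        cfg = SimConfig(seed=21, n_transcripts=20, transcript_len_mean=900.0)
        txome = generate_transcriptome(cfg)
        proteomes, _ = generate_proteomes(txome, cfg, divergence_schedule=(0.10,))
        _, refs = proteomes[0]
        recovered = 0
        for tid, pid in txome.protein_of.items():
            frames = six_frame_translate(txome.transcripts[tid])
            hits = align_peptides(tid, frames, refs, score_cutoff=50)
            if hits and hits[0].protein_id == pid:
                recovered += 1
        assert recovered >= 19


def _hit(desc, score, pid="p1", tid="t1"):
    return ProteinHit(tid, pid, desc, score, 0.9, 100, 1)


class TestDescriptionScoring:
    def test_single_hit_weights(self):
        index = build_description_index([_hit("sodium channel", 50.0)])
        assert index.word_weights == {"sodium": 50.0, "channel": 50.0}

    def test_shared_word_sums_scores(self):
        index = build_description_index(
            [_hit("kinase A1A", 10.0), _hit("kinase B1B", 30.0)]
        )
        assert index.word_weights["kinase"] == 40.0

    def test_single_hit_selected(self):
        hits = [_hit("sodium channel", 50.0)]
        index = build_description_index(hits)
        desc, _ = select_description(hits, index)
        assert desc == "sodium channel"

    def test_additivity_prefers_two_significant_words(self):
        hits = [_hit("alpha beta", 5.0, "p1"), _hit("beta", 5.0, "p2")]
        index = build_description_index(hits, stop_quantile=0.0)
        assert {"alpha", "beta"} <= index.significant
        desc, score = select_description(hits, index)
        assert desc == "alpha beta"
        assert score == pytest.approx(index.word_weights["alpha"] + index.word_weights["beta"])

    def test_no_hits_empty_record(self):
        index = build_description_index([])
        assert select_description([], index) == ("", 0.0)

    def _random_corpus(self, rng, n=20):
        words = [f"word{i:02d}" for i in range(30)]
        hits = []
        for i in range(n):
            k = int(rng.integers(1, 5))
            desc = " ".join(rng.choice(words, size=k, replace=False))
            hits.append(_hit(desc, float(rng.uniform(1, 100)), pid=f"p{i}"))
        return hits

    def test_significant_set_matches_bruteforce(self, rng):
        """mean + 2*STD significance agrees with direct recomputation."""
        for _ in range(50):
            hits = self._random_corpus(rng)
            index = build_description_index(hits, stop_quantile=0.0)
            weights = {}
            for h in hits:
                for w in set(tokenize(h.description)):
                    weights[w] = weights.get(w, 0.0) + h.score
            vals = np.array(list(weights.values()))
            cutoff = vals.mean() + 2 * vals.std()
            expected = {w for w, v in weights.items() if v > cutoff}
            if vals.std() > 0 and len(weights) >= 8:
                assert index.significant == expected

    def test_selection_invariant_under_scaling_and_permutation(self, rng):
        for _ in range(100):
            hits = self._random_corpus(rng)
            index = build_description_index(hits)
            desc, _ = select_description(hits, index)
            scaled = [
                ProteinHit(h.transcript_id, h.protein_id, h.description, h.score * 7,
                           h.identity, h.aln_length, h.frame)
                for h in hits
            ]
            index7 = build_description_index(scaled)
            desc7, _ = select_description(scaled, index7)
            assert desc7 == desc
            perm = [hits[i] for i in rng.permutation(len(hits))]
            descp, _ = select_description(perm, build_description_index(perm))
            assert descp == desc

    def test_stoplist_removes_ubiquitous_words(self, rng):
        corpus = [f"unique{i:02d} protein" for i in range(100)]
        df = corpus_document_frequencies(corpus)
        hits = [_hit("kinase protein", 10.0), _hit("channel protein", 90.0)]
        index = build_description_index(hits, corpus_df=df)
        assert "protein" in index.stoplist
        desc, _ = select_description(hits, index)
        assert desc == "channel protein"


class TestGoAndProvenance:
    def test_linked_terms_unioned(self):
        table = {"p1": {"GO:0007409"}, "p2": {"GO:0001764", "GO:0007409"}}
        hits = [_hit("x", 10.0, "p1"), _hit("y", 10.0, "p2")]
        assert assign_go(hits, table) == {"GO:0007409", "GO:0001764"}

    def test_missing_protein_skipped(self):
        assert assign_go([_hit("x", 10.0, "nope")], {"p1": {"GO:1"}}) == frozenset()

    def test_no_hits_empty_set(self):
        assert assign_go([], {"p1": {"GO:1"}}) == frozenset()

    def test_random_bipartite_matches_union_oracle(self, rng):
        for _ in range(20):
            table = {
                f"p{i}": {f"GO:{int(t)}" for t in rng.integers(0, 10, size=rng.integers(1, 4))}
                for i in range(15)
            }
            chosen = rng.choice(15, size=5, replace=False)
            hits = [_hit("d", 10.0, f"p{i}") for i in chosen]
            expected = set().union(*(table[f"p{i}"] for i in chosen))
            assert assign_go(hits, table) == expected

    def test_keyword_filter_counts(self):
        assignments = {"t1": {"GO:1", "GO:2"}, "t2": {"GO:2"}, "t3": {"GO:3"}}
        names = {"GO:1": "axonogenesis", "GO:2": "neuron migration", "GO:3": "transport"}
        prov = {"t1": "embryo_only", "t2": "mixed", "t3": "adult_only"}
        table = count_by_category(assignments, names, "neuro", prov)
        assert list(table["term_id"]) == ["GO:2"]
        row = table.iloc[0]
        assert row["total"] == 2 and row["embryo"] == 1 and row["both"] == 1
        assert row["total"] == row["embryo"] + row["adult_cns"] + row["both"]

    def test_keyword_without_match_empty(self):
        table = count_by_category({"t1": {"GO:1"}}, {"GO:1": "transport"}, "neuro", {"t1": "mixed"})
        assert table.empty

    def test_provenance_classes(self):
        emb = [make_id(1), make_id(2)]
        cns = [make_id(3, library="adult_cns")]
        assert classify_provenance(emb) == "embryo_only"
        assert classify_provenance(cns) == "adult_only"
        assert classify_provenance(emb + cns) == "mixed"
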