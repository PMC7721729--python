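"""Mention ingestion, complaint filtering and count aggregation."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenoclust import (
    ConceptVocabulary,
    MentionRecord,
    PatientConceptMatrix,
    aggregate_counts,
    filter_complaints,
    read_mentions,
)
from phenoclust.corpus import read_metadata, write_mentions, write_metadata

WHITELIST = frozenset({"Disease or Syndrome", "Sign or Symptom"})


def vocab_for(*concepts, types=("Disease or Syndrome",)):
    return ConceptVocabulary(
        entries={c: (f"name_{c}", frozenset(types)) for c in concepts},
        whitelist=WHITELIST,
    )


def mention(pid="P1", cid="C0004238", types=("Disease or Syndrome",), polarity="positive"):
    return MentionRecord(
        patient_id=pid, concept_id=cid, concept_name=f"name_{cid}",
        semantic_types=tuple(types), polarity=polarity,
    )


class TestMentionRecord:
    def test_rejects_empty_ids_and_bad_polarity(self):
        with pytest.raises(ValueError, match="patient_id"):
            mention(pid="")
        with pytest.raises(ValueError, match="concept_id"):
            mention(cid="")
        with pytest.raises(ValueError, match="polarity"):
            mention(polarity="denied")


class TestReadMentions:
    def test_empty_file_gives_empty_sequence(self, tmp_path):
        p = tmp_path / "m.jsonl"
        p.write_text("")
        assert read_mentions(p, "jsonl") == []

    def test_jsonl_roundtrip_preserves_order_and_fields(self, tmp_path):
        records = [mention(pid=f"P{i}") for i in range(3)]
        p = tmp_path / "m.jsonl"
        write_mentions(records, p, "jsonl")
        assert read_mentions(p, "jsonl") == records

    def test_tsv_roundtrip_with_multi_type(self, tmp_path):
        records = [mention(types=("Disease or Syndrome", "Finding"))]
        p = tmp_path / "m.tsv"
        write_mentions(records, p, "tsv")
        assert read_mentions(p, "tsv") == records

    def test_missing_field_names_line_number(self, tmp_path):
        p = tmp_path / "m.jsonl"
        lines = [
            json.dumps({"patient_id": "P1", "concept_id": "C1", "concept_name": "x",
                        "semantic_type": "Finding", "polarity": "positive"}),
            json.dumps({"patient_id": "P2", "concept_id": "C1", "concept_name": "x",
                        "semantic_type": "Finding"}),
        ]
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="line 2"):
            read_mentions(p, "jsonl")

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("")
        with pytest.raises(ValueError, match="format"):
            read_mentions(p, "csv")


class TestFilterComplaints:
    def test_positive_whitelisted_kept(self):
        v = vocab_for("C0004238")
        assert filter_complaints([mention()], v) == [mention()]

    def test_negated_mention_dropped(self):
        # "patient denies <complaint>" must not contribute to the profile
        v = vocab_for("C0004238")
        assert filter_complaints([mention(polarity="negative")], v) == []

    def test_non_complaint_type_dropped(self):
        v = vocab_for("C0004238")
        med = mention(types=("Pharmacologic Substance",))
        assert filter_complaints([med], v) == []

    def test_semantic_type_matching_is_case_insensitive(self):
        v = vocab_for("C0004238")
        assert filter_complaints([mention(types=("disease OR syndrome",))], v)

    def test_unknown_concept_warns_and_drops_by_default(self):
        v = vocab_for("C0000001")
        with pytest.warns(UserWarning, match="absent from vocabulary"):
            assert filter_complaints([mention(cid="C0099999")], v) == []

    def test_unknown_concept_strict_mode_raises(self):
        v = vocab_for("C0000001")
        with pytest.raises(ValueError, match="C0099999"):
            filter_complaints([mention(cid="C0099999")], v, on_unknown="error")

    @given(st.lists(st.tuples(st.sampled_from(["C1", "C2", "C3"]),
                              st.sampled_from(["positive", "negative"]),
                              st.sampled_from(["Disease or Syndrome", "Drug"])),
                    max_size=30))
    def test_idempotence(self, spec):
        v = vocab_for("C1", "C2", "C3")
        mentions = [mention(cid=c, polarity=pol, types=(t,)) for c, pol, t in spec]
        once = filter_complaints(mentions, v)
        assert filter_complaints(once, v) == once


class TestAggregateCounts:
    def make_meta(self, *pids):
        import pandas as pd
        return pd.DataFrame(
            {"age_years": 60.0, "sex": "F", "bmi": 25.0, "died_in_hospital": False,
             "icd10_codes": [frozenset({"I50"})] * len(pids)},
            index=pd.Index(pids, name="patient_id"),
        )

    def test_counting(self):
        meta = self.make_meta("A")
        mentions = [mention(pid="A", cid="C0004238")] * 2 + [mention(pid="A", cid="C0020538")]
        pcm = aggregate_counts(mentions, meta)
        assert pcm.concept_index == ("C0004238", "C0020538")
        assert pcm.to_dense().tolist() == [[2, 1]]

    def test_patient_without_mentions_gets_zero_row(self):
        meta = self.make_meta("A", "B")
        pcm = aggregate_counts([mention(pid="A")], meta)
        assert pcm.to_dense()[1].sum() == 0
        assert pcm.patient_index == ("A", "B")

    def test_disjoint_patients_block_diagonal(self):
        meta = self.make_meta("A", "B")
        pcm = aggregate_counts(
            [mention(pid="A", cid="C0000001"), mention(pid="B", cid="C0000002")], meta
        )
        assert pcm.to_dense().tolist() == [[1, 0], [0, 1]]

    def test_unknown_patient_raises_with_ids(self):
        meta = self.make_meta("A")
        with pytest.raises(ValueError, match="ZZZ"):
            aggregate_counts([mention(pid="ZZZ")], meta)

    @given(st.permutations(list(range(6))))
    def test_order_invariance_and_total(self, perm):
        meta = self.make_meta("A", "B")
        base = [
            mention(pid="A", cid="C1"), mention(pid="A", cid="C1"),
            mention(pid="A", cid="C2"), mention(pid="B", cid="C2"),
            mention(pid="B", cid="C3"), mention(pid="B", cid="C3"),
        ]
        shuffled = [base[i] for i in perm]
        pcm = aggregate_counts(shuffled, meta)
        assert pcm.counts.sum() == len(base)
        assert pcm.to_dense().tolist() == aggregate_counts(base, meta).to_dense().tolist()

    def test_drop_zero_patients(self):
        meta = self.make_meta("A", "B")
        pcm = aggregate_counts([mention(pid="A")], meta)
        reduced, excluded = pcm.drop_zero_patients()
        assert excluded == ["B"]
        assert reduced.patient_index == ("A",)


class TestPersistence:
    def test_matrix_market_roundtrip(self, tmp_path, small_bundle):
        pcm = small_bundle["counts"]
        pcm.save(tmp_path / "counts")
        back = PatientConceptMatrix.load(tmp_path / "counts")
        assert back.patient_index == pcm.patient_index
        assert back.concept_index == pcm.concept_index
        assert (back.counts != pcm.counts).nnz == 0

    def test_metadata_roundtrip(self, tmp_path, small_bundle):
        meta = small_bundle["meta"]
        write_metadata(meta, tmp_path / "meta.tsv")
        back = read_metadata(tmp_path / "meta.tsv")
        assert list(back.index) == list(meta.index)
        assert back["icd10_codes"].tolist() == meta["icd10_codes"].tolist()
        np.testing.assert_allclose(back["age_years"], meta["age_years"], atol=1e-9)

    def test_vocabulary_roundtrip(self, tmp_path, small_bundle):
        vocab = small_bundle["vocab"]
        vocab.to_files(tmp_path / "v.tsv", tmp_path / "w.txt")
        back = ConceptVocabulary.from_files(tmp_path / "v.tsv", tmp_path / "w.txt")
        assert back.whitelist == vocab.whitelist
        assert dict(back.entries) == dict(vocab.entries)

    def test_duplicate_concept_id_rejected(self, tmp_path):
        (tmp_path / "v.tsv").write_text("C1\tx\tFinding\nC1\ty\tFinding\n")
        (tmp_path / "w.txt").write_text("Finding\n")
        with pytest.raises(ValueError, match="duplicate"):
            ConceptVocabulary.from_files(tmp_path / "v.tsv", tmp_path / "w.txt")
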