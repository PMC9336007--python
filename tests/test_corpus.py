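"""Tokenization, BIO round-trips and argument-candidate construction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioevent.corpus import (
    ArgumentCandidate,
    Token,
    TriggerInstance,
    annotations_in_sentence,
    build_argument_candidates,
    decode_bio,
    encode_bio,
    fine_label_space,
    split_and_tokenize,
    to_coarse_label,
    to_fine_label,
)
from bioevent.standoff import Span, TriggerAnn
from bioevent.taxonomy import DEFAULT_TAXONOMY


class TestTokenization:
    def test_hyphenated_words_stay_single_tokens(self, nested_doc):
        (sent,) = split_and_tokenize(nested_doc)
        assert [t.text for t in sent] == [
            "Bmi-1", "over-expression", "is", "sufficient",
            "to", "promote", "tumorigenesis",
        ]

    def test_empty_document_yields_no_sentences(self):
        from bioevent.standoff import Document

        assert split_and_tokenize(Document("d", "   ")) == []

    def test_every_annotation_aligns_to_contiguous_tokens(self, small_corpus):
        from bioevent.corpus import align_span

        for doc in small_corpus:
            for sent in split_and_tokenize(doc):
                for ann in annotations_in_sentence(
                    sent, [*doc.entities, *doc.triggers]
                ):
                    loc = align_span(sent, ann.span)
                    assert loc is not None, (doc.doc_id, ann.id)
                    i, j = loc
                    assert " ".join(t.text for t in sent[i:j]) == ann.text

    def test_token_spans_cover_nonspace_text(self, small_corpus):
        doc = small_corpus[0]
        covered = set()
        for sent in split_and_tokenize(doc):
            for tok in sent:
                covered.update(range(tok.span.start, tok.span.end))
        for i, ch in enumerate(doc.text):
            assert (i in covered) == (not ch.isspace())


class TestBIO:
    def test_nested_example_labels(self, nested_doc):
        (sent,) = split_and_tokenize(nested_doc)
        inst = encode_bio(sent, nested_doc.triggers)
        assert list(inst.labels) == [
            "O", "B-Gene_expression", "O", "O", "O", "B-Positive_regulation", "O",
        ]

    def test_sentence_without_triggers_is_all_o(self, nested_doc):
        (sent,) = split_and_tokenize(nested_doc)
        assert set(encode_bio(sent, []).labels) == {"O"}

    def test_encode_decode_round_trip_on_corpus(self, small_corpus):
        for doc in small_corpus:
            for sent in split_and_tokenize(doc):
                gold = annotations_in_sentence(sent, doc.triggers)
                decoded = decode_bio(encode_bio(sent, gold))
                assert sorted(
                    (t.event_type, t.span.start, t.span.end) for t in decoded
                ) == sorted((t.event_type, t.span.start, t.span.end) for t in gold)

    def test_overlapping_triggers_keep_longer_span(self, nested_doc, caplog):
        (sent,) = split_and_tokenize(nested_doc)
        long = TriggerAnn("T8", "Binding", Span(0, 21), nested_doc.text[0:21])
        short = TriggerAnn("T9", "Death", Span(6, 21), nested_doc.text[6:21])
        inst = encode_bio(sent, [long, short])
        assert list(inst.labels[:2]) == ["B-Binding", "I-Binding"]

    @staticmethod
    def _oracle_decode(labels):
        """Independent linear run-scanner over the raw label strings."""
        runs, current = [], None
        for i, lab in enumerate(labels):
            if lab == "O":
                current = None
                continue
            prefix, ttype = lab.split("-", 1)
            if prefix == "B" or current is None or current[0] != ttype:
                current = (ttype, i, i + 1)
                runs.append(current)
            else:
                current = (current[0], current[1], i + 1)
                runs[-1] = current
        return runs

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.sampled_from(
                ["O", "B-Binding", "I-Binding", "B-Death", "I-Death", "I-Growth"]
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_decode_matches_run_scanner_oracle(self, labels):
        tokens = tuple(
            Token(f"w{i}", Span(2 * i, 2 * i + 1), i) for i in range(len(labels))
        )
        decoded = decode_bio(TriggerInstance(tokens, tuple(labels)))
        got = [
            (t.event_type, t.span.start // 2, (t.span.end + 1) // 2)
            for t in decoded
        ]
        assert got == self._oracle_decode(labels)


class TestCandidates:
    def test_nested_example_yields_five_candidates(self, nested_doc):
        (sent,) = split_and_tokenize(nested_doc)
        cands = build_argument_candidates(sent, nested_doc.triggers, nested_doc.entities)
        pairs = {(c.trigger.text, c.target.text) for c in cands}
        assert pairs == {
            ("over-expression", "Bmi-1"),
            ("over-expression", "tumorigenesis"),
            ("promote", "Bmi-1"),
            ("promote", "tumorigenesis"),
            ("promote", "over-expression"),
        }
        modes = {(c.trigger.text, c.mode) for c in cands}
        assert ("over-expression", "simple") in modes
        assert ("promote", "complex") in modes

    def test_no_entities_no_simple_candidates(self, nested_doc):
        (sent,) = split_and_tokenize(nested_doc)
        simple_only = [t for t in nested_doc.triggers if t.event_type == "Gene_expression"]
        assert build_argument_candidates(sent, simple_only, []) == []

    def test_candidate_count_formula_on_corpus(self, small_corpus):
        for doc in small_corpus:
            for sent in split_and_tokenize(doc):
                triggers = annotations_in_sentence(sent, doc.triggers)
                entities = annotations_in_sentence(sent, doc.entities)
                cands = build_argument_candidates(sent, triggers, entities)
                s = sum(
                    1 for t in triggers if not DEFAULT_TAXONOMY.is_complex(t.event_type)
                )
                c = len(triggers) - s
                e, t_all = len(entities), len(triggers)
                assert len(cands) == s * e + c * (e + t_all - 1)

    def test_simple_triggers_never_pair_with_triggers(self, small_corpus):
        for doc in small_corpus:
            for sent in split_and_tokenize(doc):
                cands = build_argument_candidates(
                    sent,
                    annotations_in_sentence(sent, doc.triggers),
                    annotations_in_sentence(sent, doc.entities),
                )
                for cand in cands:
                    if cand.mode == "simple":
                        assert not cand.target_is_event_trigger
                    assert cand.target.id != cand.trigger.id
                    assert cand.relevance_key == cand.trigger.id


class TestFineLabels:
    @pytest.mark.parametrize(
        "role,mode,expected",
        [
            ("Theme", "complex", "CTheme"),
            ("Cause", "complex", "CCause"),
            ("Theme", "simple", "Theme"),
            ("NONE", "simple", "NONE"),
            ("NONE", "complex", "NONE"),
        ],
    )
    def test_fine_label_mapping(self, role, mode, expected):
        assert to_fine_label(role, mode) == expected

    @pytest.mark.parametrize("mode", ["simple", "complex"])
    def test_round_trip_over_role_set(self, mode):
        for role in ("Theme", "Cause", "NONE"):
            assert to_coarse_label(to_fine_label(role, mode), mode) == role

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            to_fine_label("Agent", "simple")

    def test_label_spaces_start_with_none(self):
        assert fine_label_space("simple")[0] == "NONE"
        assert fine_label_space("complex") == ["NONE", "CTheme", "CCause"]
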