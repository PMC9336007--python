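"""Scoring: the P/R/F metric and exact one-to-one matching at all levels."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioevent.evaluation import (
    fscore_from_percent,
    match_events,
    match_triggers,
    prf,
    score_corpus,
)
from bioevent.standoff import Document, Span, TriggerAnn, parse_standoff
from bioevent.synthetic import GeneratorConfig, corrupt_predictions, generate_corpus

from conftest import NESTED_A1, NESTED_A2, NESTED_TXT


class TestPRF:
    def test_perfect_counts_give_unity(self):
        res = prf(5, 0, 0)
        assert (res.precision, res.recall, res.fscore) == (1.0, 1.0, 1.0)

    def test_zero_denominators_give_zero(self):
        res = prf(0, 0, 0)
        assert (res.precision, res.recall, res.fscore) == (0.0, 0.0, 0.0)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_fscore_equals_harmonic_formula(self, tp, fp, fn):
        res = prf(tp, fp, fn)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        expected = 2 * p * r / (p + r) if p + r else 0.0
        assert res.fscore == pytest.approx(expected)
        # the harmonic mean lies between min and max, equal to both when p == r
        if p + r:
            assert min(p, r) - 1e-12 <= res.fscore <= max(p, r) + 1e-12
        if p == r:
            assert res.fscore == pytest.approx(p)

    @given(st.integers(0, 100), st.integers(0, 100), st.integers(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_swapping_fp_fn_swaps_precision_recall(self, tp, fp, fn):
        a, b = prf(tp, fp, fn), prf(tp, fn, fp)
        assert a.precision == b.recall and a.recall == b.precision
        assert a.fscore == pytest.approx(b.fscore)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            prf(1, -1, 0)


class TestTriggerMatching:
    def _trig(self, ttype, start, end):
        return TriggerAnn(f"T{start}", ttype, Span(start, end), "x" * (end - start))

    def test_identical_sets_score_one(self):
        gold = [self._trig("Binding", 0, 4), self._trig("Death", 10, 15)]
        assert match_triggers(gold, list(gold)).fscore == 1.0

    def test_correct_span_wrong_type_counts_fp_and_fn(self):
        gold = [self._trig("Binding", 0, 4)]
        pred = [self._trig("Death", 0, 4)]
        res = match_triggers(gold, pred)
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_one_to_one_even_with_duplicate_predictions(self):
        gold = [self._trig("Binding", 0, 4)]
        pred = [self._trig("Binding", 0, 4), self._trig("Binding", 0, 4)]
        res = match_triggers(gold, pred)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    def test_approximate_mode_accepts_overlap(self):
        gold = [self._trig("Binding", 0, 4)]
        pred = [self._trig("Binding", 2, 6)]
        assert match_triggers(gold, pred).fscore == 0.0
        assert match_triggers(gold, pred, approximate=True).fscore == 1.0

    def test_corruption_recall_tracks_noise_rate(self):
        docs = generate_corpus(GeneratorConfig(n_sentences=1000, seed=23))
        q = 0.2
        preds = corrupt_predictions(docs, q, seed=4)
        total = prf(0, 0, 0)
        for doc, (triggers, _) in zip(docs, preds):
            total = total + match_triggers(doc.triggers, triggers)
        assert total.recall == pytest.approx(1 - q, abs=0.03)


def _brute_force_event_matching(gold_forms, pred_forms):
    """Maximum one-to-one matching by exhaustive injection enumeration."""
    best = 0
    idx = range(len(pred_forms))
    for k in range(min(len(gold_forms), len(pred_forms)), 0, -1):
        for gsub in itertools.combinations(range(len(gold_forms)), k):
            for psub in itertools.permutations(idx, k):
                if all(gold_forms[g] == pred_forms[p] for g, p in zip(gsub, psub)):
                    return k
    return best


class TestEventMatching:
    def test_identical_nested_document_scores_one(self, nested_doc):
        assert match_events(nested_doc, nested_doc).fscore == 1.0

    def test_wrong_inner_type_fails_outer_and_inner(self, nested_doc):
        a2 = NESTED_A2.replace(
            "T2\tGene_expression 6 21", "T2\tTranscription 6 21"
        ).replace("E1\tGene_expression:T2", "E1\tTranscription:T2")
        pred = parse_standoff(NESTED_TXT, NESTED_A1, a2, doc_id="pred")
        res = match_events(nested_doc, pred)
        assert res.tp == 0 and res.fp == 2 and res.fn == 2

    def test_agrees_with_brute_force_bipartite_oracle(self):
        from bioevent.evaluation import _canonical_events

        docs = generate_corpus(GeneratorConfig(n_sentences=40, seed=31))
        preds = corrupt_predictions(docs, 0.5, seed=5)
        # rebuild degraded documents containing only surviving gold events
        for doc, (triggers, _) in zip(docs, preds):
            alive = {t.id for t in triggers if t in doc.triggers}
            kept = [
                ev
                for ev in doc.events
                if ev.trigger in alive
                and all(not t.startswith("E") or t in {e.id for e in doc.events} for _, t in ev.args)
            ]
            kept_ids = {e.id for e in kept}
            kept = [
                ev for ev in kept
                if all(not t.startswith("E") or t in kept_ids for _, t in ev.args)
            ]
            pred_doc = Document(doc.doc_id, doc.text, doc.entities, doc.triggers, kept)
            if len(doc.events) > 6 or len(kept) > 6:
                continue
            res = match_events(doc, pred_doc)
            gold_forms = list(_canonical_events(doc).elements())
            pred_forms = list(_canonical_events(pred_doc).elements())
            assert res.tp == _brute_force_event_matching(gold_forms, pred_forms)

    def test_order_invariance(self, nested_doc):
        reversed_doc = Document(
            nested_doc.doc_id,
            nested_doc.text,
            nested_doc.entities,
            nested_doc.triggers,
            list(reversed(nested_doc.events)),
        )
        assert match_events(nested_doc, reversed_doc).fscore == 1.0


class TestPrintedTableArithmetic:
    """F recomputed from printed precision/recall pairs via the metric."""

    @pytest.mark.parametrize(
        "p,r,f",
        [
            (91.05, 44.68, 59.94),
            (90.24, 44.50, 59.61),
            (55.76, 59.16, 57.41),
        ],
    )
    def test_f_from_percent_pairs(self, p, r, f):
        assert fscore_from_percent(p, r) == pytest.approx(f, abs=0.005)

    def test_f_from_scaled_counts(self):
        # realize P=91.05%, R=44.68% as integer counts scaled by 10^4
        tp = int(round(9105 * 4468))
        fp = int(round((10000 - 9105) * 4468))
        fn = int(round(9105 * (10000 - 4468)))
        res = prf(tp, fp, fn)
        assert 100 * res.fscore == pytest.approx(59.94, abs=0.01)


def test_score_corpus_levels(small_corpus):
    same = score_corpus(small_corpus, small_corpus, "event")
    assert same.fscore == 1.0
    for level in ("trigger", "edge"):
        assert score_corpus(small_corpus, small_corpus, level).fscore == 1.0
    with pytest.raises(ValueError):
        score_corpus(small_corpus, small_corpus, "bogus")
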