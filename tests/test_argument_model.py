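"""Argument classifier: grouping, mode separation, training semantics."""

import math

import numpy as np
import pytest

from bioevent.argument_model import (
    ArgumentClassifier,
    ArgumentModelConfig,
    batch_by_relevance,
)
from bioevent.corpus import (
    annotations_in_sentence,
    build_argument_candidates,
    label_candidates_from_gold,
    split_and_tokenize,
)
from bioevent.embeddings import random_table
from bioevent.pipeline import corpus_vocabulary
from bioevent.synthetic import GeneratorConfig, generate_corpus
from bioevent.trigger_model import TrainConfig

TINY = ArgumentModelConfig(embedding_dim=12, hidden_size=10, n_layers=1, dropout=0.0)


@pytest.fixture(scope="module")
def arg_corpus():
    return generate_corpus(GeneratorConfig(n_sentences=10, seed=6))


@pytest.fixture(scope="module")
def arg_model(arg_corpus):
    table = random_table(corpus_vocabulary(arg_corpus), 12, seed=0)
    return ArgumentClassifier(table, config=TINY, seed=0)


def _candidates(doc):
    out = []
    for sent in split_and_tokenize(doc):
        cands = build_argument_candidates(
            sent,
            annotations_in_sentence(sent, doc.triggers),
            annotations_in_sentence(sent, doc.entities),
        )
        out.extend(label_candidates_from_gold(cands, doc))
    return out


class TestBatching:
    def test_nested_example_candidates_form_one_batch(self, nested_doc):
        cands = _candidates(nested_doc)
        batches = batch_by_relevance(cands, 64)
        assert len(batches) == 1
        sizes = {}
        for cand in batches[0]:
            sizes[cand.relevance_key] = sizes.get(cand.relevance_key, 0) + 1
        assert sorted(sizes.values()) == [2, 3]

    def test_partition_property_on_corpus(self, arg_corpus):
        for doc in arg_corpus:
            cands = _candidates(doc)
            if not cands:
                continue
            batches = batch_by_relevance(cands, 8)
            flat = [c for b in batches for c in b]
            assert len(flat) == len(cands)
            assert {id(c) for c in flat} == {id(c) for c in cands}
            for batch in batches:
                assert len(batch) <= 8
            # groups are never split across batches
            seen_in = {}
            for bi, batch in enumerate(batches):
                for cand in batch:
                    seen_in.setdefault(cand.relevance_key, set()).add(bi)
            assert all(len(s) == 1 for s in seen_in.values())

    def test_oversized_group_advises_larger_batch(self, nested_doc):
        cands = _candidates(nested_doc)
        with pytest.raises(ValueError, match="batch_size"):
            batch_by_relevance(cands, 2)


class TestClassification:
    def test_zero_head_weights_give_uniform_and_first_label(self, arg_model, nested_doc):
        for W, b in arg_model.heads.values():
            W.data[...] = 0.0
            b.data[...] = 0.0
        cands = _candidates(nested_doc)
        preds = arg_model.predict(cands)
        for pred in preds:
            labels = arg_model.label_spaces[pred.candidate.mode]
            assert pred.label == labels[0] == "NONE"
            assert pred.probability == pytest.approx(1 / len(labels))

    def test_mode_separation_of_label_spaces(self, arg_model, arg_corpus):
        for doc in arg_corpus:
            for pred in arg_model.predict(_candidates(doc)) if _candidates(doc) else []:
                if pred.candidate.mode == "simple":
                    assert not pred.label.startswith("C")
                assert pred.label in arg_model.label_spaces[pred.candidate.mode]

    def test_encode_candidate_is_deterministic(self, arg_model, nested_doc):
        cand = _candidates(nested_doc)[0]
        a = arg_model.encode_candidate(cand).data
        b = arg_model.encode_candidate(cand).data
        assert np.array_equal(a, b)

    def test_group_attention_weights_sum_to_one(self, arg_model, nested_doc):
        from bioevent.attention import sentence_attention

        cands = [c for c in _candidates(nested_doc) if c.mode == "complex"]
        vecs = [arg_model.encode_candidate(c) for c in cands]
        alpha, _ = sentence_attention(vecs, arg_model.sent_att_w)
        assert alpha.data.sum() == pytest.approx(1.0, abs=1e-9)

    def test_multi_level_output_matches_equation_composition(self, arg_model, nested_doc):
        """Group outputs equal softmax(W tanh(v_i * alpha_i) + b) computed by hand."""
        cands = [c for c in _candidates(nested_doc) if c.mode == "complex"]
        vecs = [arg_model.encode_candidate(c).data for c in cands]
        w = arg_model.sent_att_w.data
        scores = [float(w @ np.tanh(v)) for v in vecs]
        m = max(scores)
        exps = [math.exp(s - m) for s in scores]
        alpha = [e / sum(exps) for e in exps]
        W, b = (t.data for t in arg_model.heads["complex"])
        results = arg_model.classify_arguments(cands)
        for (cand, probs), v, a in zip(results, vecs, alpha):
            logits = np.tanh(v * a) @ W + b
            expect = np.exp(logits - logits.max())
            expect /= expect.sum()
            np.testing.assert_allclose(probs.data, expect, atol=1e-10, rtol=0)


class TestTraining:
    def test_empty_candidate_set_rejected(self):
        from bioevent.standoff import Document

        table = random_table(["a"], 12, seed=0)
        model = ArgumentClassifier(table, config=TINY, seed=0)
        with pytest.raises(ValueError):
            model.fit([Document("d", "no annotations here")])

    def test_simple_only_corpus_leaves_complex_head_untouched(self):
        docs = [
            d
            for d in generate_corpus(
                GeneratorConfig(n_sentences=30, complex_fraction=0.0, seed=9)
            )
        ]
        table = random_table(corpus_vocabulary(docs), 12, seed=1)
        model = ArgumentClassifier(table, config=TINY, seed=1)
        before = model.heads["complex"][0].data.copy()
        simple_before = model.heads["simple"][0].data.copy()
        model.fit(docs, TrainConfig(batch_size=16, epochs=2, learning_rate=1.0, seed=1))
        assert np.array_equal(model.heads["complex"][0].data, before)
        assert not np.array_equal(model.heads["simple"][0].data, simple_before)

    def test_gold_labeling_is_exhaustive_and_exclusive(self, arg_corpus):
        from bioevent.evaluation import edges_of_document

        for doc in arg_corpus:
            cands = _candidates(doc)
            labeled_pairs = {
                (c.trigger.id, c.target.id) for c in cands if c.fine_label != "NONE"
            }
            gold_edges = set()
            ev_index = doc.event_by_id()
            for ev in doc.events:
                for role, target in ev.args:
                    if target.startswith("E"):
                        target = ev_index[target].trigger
                    gold_edges.add((ev.trigger, target))
            assert labeled_pairs == gold_edges

    def test_same_seed_reproduces_training(self, arg_corpus):
        logs = []
        for _ in range(2):
            table = random_table(corpus_vocabulary(arg_corpus), 12, seed=4)
            model = ArgumentClassifier(table, config=TINY, seed=4)
            logs.append(
                model.fit(
                    arg_corpus,
                    TrainConfig(batch_size=16, epochs=2, learning_rate=1.0, seed=4),
                )
            )
        assert logs[0] == logs[1]


class TestCheckpoint:
    def test_save_load_preserves_predictions(self, arg_corpus, tmp_path):
        table = random_table(corpus_vocabulary(arg_corpus), 12, seed=8)
        model = ArgumentClassifier(table, config=TINY, seed=8)
        model.fit(
            arg_corpus, TrainConfig(batch_size=16, epochs=1, learning_rate=1.0, seed=8)
        )
        path = str(tmp_path / "args.npz")
        model.save(path)
        loaded = ArgumentClassifier.load(path)
        doc = arg_corpus[0]
        assert model.predict_edges(doc, doc.triggers) == loaded.predict_edges(
            doc, doc.triggers
        )
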