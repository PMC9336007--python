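"""End-to-end pipeline: representation -> triggers -> arguments -> assembly -> scores.

One configuration object drives the five stages and the ablation toggles
(sentence embeddings, word attention, multi-level attention, fine-grained
heads), so the model families compared in the ablation studies are all
reachable from a single YAML file.  Every stage is seeded and
single-threaded, so a pipeline run is reproducible bit for bit.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .argument_model import ArgumentClassifier, ArgumentModelConfig
from .assembly import assemble_document, train_filter
from .corpus import split_and_tokenize
from .embeddings import load_vectors, random_table
from .evaluation import PRF, score_corpus
from .standoff import Document, read_corpus_dir, write_corpus_dir
from .taxonomy import DEFAULT_TAXONOMY, EventTaxonomy
from .trigger_model import ModelConfig, TrainConfig, TriggerTagger

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    train_dir: str = ""
    test_dir: str = ""  # empty -> evaluate on the training documents
    vectors: str = ""  # word2vec text file; empty -> seeded random init
    out_dir: str = "pipeline_out"
    taxonomy_file: str = ""

    embedding_dim: int = 200
    hidden_size: int = 200
    n_layers: int = 2
    combine: str = "sum"
    dropout: float = 0.5

    use_sentence_embeddings: bool = True
    use_word_attention: bool = True
    use_multi_level_attention: bool = True
    fine_grained: bool = True
    use_structure_filter: bool = False

    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 0.001
    optimizer: str = "adadelta"
    seed: int = 0

    @classmethod
    def from_yaml_file(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            embedding_dim=self.embedding_dim,
            hidden_size=self.hidden_size,
            n_layers=self.n_layers,
            combine=self.combine,
            dropout=self.dropout,
            use_sentence_embeddings=self.use_sentence_embeddings,
            use_word_attention=self.use_word_attention,
        )

    def argument_config(self) -> ArgumentModelConfig:
        return ArgumentModelConfig(
            **asdict(self.model_config()),
            use_sentence_attention=self.use_multi_level_attention,
            fine_grained=self.fine_grained,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            optimizer=self.optimizer,
            seed=self.seed,
        )


def corpus_vocabulary(docs: list[Document]) -> list[str]:
    vocab: list[str] = []
    seen: set[str] = set()
    for doc in docs:
        for sent in split_and_tokenize(doc):
            for tok in sent:
                if tok.text not in seen:
                    seen.add(tok.text)
                    vocab.append(tok.text)
    return vocab


def build_embedding_table(config: PipelineConfig, train_docs: list[Document]):
    if config.vectors:
        return load_vectors(config.vectors, expected_dim=config.embedding_dim)
    return random_table(
        corpus_vocabulary(train_docs), config.embedding_dim, seed=config.seed
    )


@dataclass
class PipelineResult:
    trigger: PRF
    edge: PRF
    event: PRF
    predicted: list[Document] = field(default_factory=list)
    trigger_loss: list[float] = field(default_factory=list)
    argument_loss: list[float] = field(default_factory=list)

    def report(self) -> dict:
        out = {}
        for level in ("trigger", "edge", "event"):
            prf: PRF = getattr(self, level)
            p, r, f = prf.as_percent()
            out[level] = {
                "tp": prf.tp, "fp": prf.fp, "fn": prf.fn,
                "precision": round(p, 2), "recall": round(r, 2),
                "fscore": round(f, 2),
            }
        return out


def run_pipeline(
    config: PipelineConfig,
    *,
    train_docs: list[Document] | None = None,
    test_docs: list[Document] | None = None,
) -> PipelineResult:
    """Train both models, predict, assemble and score.

    Documents may be passed in memory (as the tests do) or read from the
    configured standoff directories.
    """
    taxonomy = (
        EventTaxonomy.from_yaml_file(config.taxonomy_file)
        if config.taxonomy_file
        else DEFAULT_TAXONOMY
    )
    t0 = time.perf_counter()
    if train_docs is None:
        train_docs = read_corpus_dir(config.train_dir, taxonomy=taxonomy)
    if test_docs is None:
        test_docs = (
            read_corpus_dir(config.test_dir, taxonomy=taxonomy)
            if config.test_dir
            else train_docs
        )
    if not train_docs:
        raise ValueError("empty training corpus")
    logger.info("stage corpus: %d train / %d test documents (%.2fs)",
                len(train_docs), len(test_docs), time.perf_counter() - t0)

    t0 = time.perf_counter()
    table = build_embedding_table(config, train_docs)
    logger.info("stage representation: |V|=%d d=%d (%.2fs)",
                len(table.vocabulary), table.dim, time.perf_counter() - t0)

    t0 = time.perf_counter()
    tagger = TriggerTagger(
        table, taxonomy=taxonomy, config=config.model_config(), seed=config.seed
    )
    trig_loss = tagger.fit(train_docs, config.train_config())
    logger.info("stage trigger: trained %d epochs (%.2fs)",
                config.epochs, time.perf_counter() - t0)

    t0 = time.perf_counter()
    arg_model = ArgumentClassifier(
        table, taxonomy=taxonomy, config=config.argument_config(), seed=config.seed
    )
    arg_loss = arg_model.fit(train_docs, config.train_config())
    logger.info("stage arguments: trained %d epochs (%.2fs)",
                config.epochs, time.perf_counter() - t0)

    structure_filter = None
    if config.use_structure_filter:
        structure_filter = train_filter(train_docs, taxonomy=taxonomy, seed=config.seed)

    t0 = time.perf_counter()
    predicted: list[Document] = []
    for doc in test_docs:
        bare = Document(doc.doc_id, doc.text, list(doc.entities), [], [])
        triggers = tagger.predict_triggers(bare)
        edges = arg_model.predict_edges(bare, triggers)
        predicted.append(
            assemble_document(
                bare, triggers, edges, taxonomy=taxonomy,
                structure_filter=structure_filter,
            )
        )
    logger.info("stage assembly: predicted %d documents (%.2fs)",
                len(predicted), time.perf_counter() - t0)

    result = PipelineResult(
        trigger=score_corpus(test_docs, predicted, "trigger"),
        edge=score_corpus(test_docs, predicted, "edge"),
        event=score_corpus(test_docs, predicted, "event"),
        predicted=predicted,
        trigger_loss=trig_loss,
        argument_loss=arg_loss,
    )
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        write_corpus_dir(
            predicted, os.path.join(config.out_dir, "predicted"), taxonomy=taxonomy
        )
        with open(
            os.path.join(config.out_dir, "report.json"), "w", encoding="utf-8"
        ) as fh:
            json.dump(result.report(), fh, indent=2)
    return result
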