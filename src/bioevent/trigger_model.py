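"""BIO trigger tagger: reading-gate BiLSTM + word attention + softmax.

Each sentence token is a trigger candidate.  The encoder consumes the
frozen and fine-tuned embedding streams (plus the sentence embedding d0
through the reading gate), word-level attention produces one attended
sentence context h*, and every token is classified from the concatenation
of its own encoder state h_i with h* — the reading that lets a single
attended sentence vector coexist with per-token labels.  Training minimizes
the summed cross-entropy over tokens and tags.

Ablation toggles reproduce the model family used in the published
comparisons: ``use_sentence_embeddings`` gates the d0/reading-gate pathway
(off -> plain two-stream BiLSTM), ``use_word_attention`` gates h*.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .attention import make_attention_params, word_attention
from .autodiff import (
    Tensor,
    collect_parameters,
    cross_entropy,
    dropout,
    softmax,
    stack,
)
from .corpus import (
    TriggerInstance,
    Token,
    annotations_in_sentence,
    decode_bio,
    encode_bio,
    resolve_trigger_text,
    split_and_tokenize,
)
from .embeddings import EmbeddingTable, init_tuned, sentence_embedding
from .optim import make_optimizer
from .rg_bilstm import BiLSTMParams, run_bilstm
from .standoff import Document, TriggerAnn
from .taxonomy import DEFAULT_TAXONOMY, EventTaxonomy

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Architecture switches; defaults follow the published configuration."""

    embedding_dim: int = 200
    hidden_size: int = 200
    n_layers: int = 2
    combine: str = "sum"
    dropout: float = 0.5
    use_sentence_embeddings: bool = True
    use_word_attention: bool = True


@dataclass
class TrainConfig:
    """Published training hyper-parameters as defaults.

    Note Adadelta's step is adaptive; ``learning_rate`` multiplies it
    (1.0 recovers the original parameter-free Adadelta).
    """

    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 0.001
    optimizer: str = "adadelta"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs and learning_rate must be positive")


def bio_tags(taxonomy: EventTaxonomy) -> list[str]:
    """Tag alphabet: O first, then B-t/I-t per event type (2*|types| + 1)."""
    tags = ["O"]
    for t in taxonomy.event_types:
        tags += [f"B-{t}", f"I-{t}"]
    return tags


def bio_tag_loss(probs: Tensor, onehot: np.ndarray) -> Tensor:
    """Summed cross-entropy  L = -sum_i sum_j t_i^j log p_i^j."""
    if probs.shape != onehot.shape:
        raise ValueError(f"shape mismatch {probs.shape} vs {onehot.shape}")
    return cross_entropy(probs, onehot)


class TriggerTagger:
    """Train and apply the BIO trigger identification model."""

    def __init__(
        self,
        pretrained: EmbeddingTable,
        *,
        taxonomy: EventTaxonomy = DEFAULT_TAXONOMY,
        config: ModelConfig | None = None,
        seed: int = 0,
    ):
        self.taxonomy = taxonomy
        self.config = config or ModelConfig()
        if pretrained.dim != self.config.embedding_dim:
            raise ValueError(
                f"embedding table dim {pretrained.dim} != configured "
                f"{self.config.embedding_dim}"
            )
        self.tags = bio_tags(taxonomy)
        self.pretrained = pretrained
        self.tuned = init_tuned(pretrained)
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.encoder = BiLSTMParams(
            cfg.embedding_dim, cfg.hidden_size, cfg.n_layers, rng, cfg.combine
        )
        enc_out = self.encoder.out_dim
        self.att_w = make_attention_params(enc_out, rng)
        clf_in = enc_out * 2 if cfg.use_word_attention else enc_out
        bound = np.sqrt(6.0 / (clf_in + len(self.tags)))
        self.W = Tensor(
            rng.uniform(-bound, bound, size=(clf_in, len(self.tags))),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(len(self.tags)), requires_grad=True)

    # -- forward ----------------------------------------------------------

    def _token_features(
        self,
        tokens: list[str],
        *,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        cfg = self.config
        x = self.pretrained.lookup(tokens)
        xp = self.tuned.lookup(tokens)
        d0 = sentence_embedding(x, xp) if cfg.use_sentence_embeddings else None
        H = run_bilstm(
            x,
            xp,
            d0,
            self.encoder,
            use_reading_gate=cfg.use_sentence_embeddings,
            dropout_rate=cfg.dropout,
            rng=rng,
            train=train,
        )
        if cfg.use_word_attention:
            ctx = word_attention(H.T, self.att_w).context
            ctx_rows = stack([ctx] * len(tokens), axis=0)
            from .autodiff import concat

            H = concat([H, ctx_rows], axis=1)
        if train and rng is not None:
            H = dropout(H, cfg.dropout, rng, train)
        return H

    def classify_tokens(
        self,
        tokens: list[str],
        *,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Per-token tag distributions, rows summing to one."""
        if not tokens:
            raise ValueError("cannot classify an empty sentence")
        feats = self._token_features(tokens, train=train, rng=rng)
        return softmax(feats @ self.W + self.b, axis=-1)

    def predict_tags(self, tokens: list[str]) -> list[str]:
        probs = self.classify_tokens(tokens).data
        return [self.tags[i] for i in probs.argmax(axis=1)]  # first max wins ties

    # -- training ---------------------------------------------------------

    def _instances(self, docs: list[Document]) -> list[TriggerInstance]:
        out = []
        for doc in docs:
            for sent in split_and_tokenize(doc):
                triggers = annotations_in_sentence(sent, doc.triggers)
                out.append(encode_bio(sent, triggers))
        return out

    def parameters(self) -> list[Tensor]:
        return collect_parameters(
            {
                "tuned": self.tuned.vectors,
                "encoder": [
                    [p.w_x, p.w_xp, p.w_h, p.b]
                    for pair in self.encoder.layers
                    for p in pair
                ]
                + ([self.encoder.d0_proj] if self.encoder.d0_proj is not None else []),
                "att": self.att_w if self.config.use_word_attention else [],
                "clf": [self.W, self.b],
            }
        )

    def _onehot(self, labels: tuple[str, ...]) -> np.ndarray:
        tag_index = {t: i for i, t in enumerate(self.tags)}
        out = np.zeros((len(labels), len(self.tags)))
        for i, lab in enumerate(labels):
            out[i, tag_index[lab]] = 1.0
        return out

    def fit(
        self, docs: list[Document], train_config: TrainConfig | None = None
    ) -> list[float]:
        """Train on gold-annotated documents; returns the per-epoch loss log."""
        tc = train_config or TrainConfig()
        instances = self._instances(docs)
        if not instances:
            raise ValueError("empty training corpus")
        rng = np.random.default_rng(tc.seed)
        params = self.parameters()
        opt = make_optimizer(tc.optimizer, params, tc.learning_rate)
        loss_log: list[float] = []
        order = np.arange(len(instances))
        for epoch in range(tc.epochs):
            t0 = time.perf_counter()
            rng.shuffle(order)
            total = 0.0
            for start in range(0, len(order), tc.batch_size):
                batch = [instances[i] for i in order[start : start + tc.batch_size]]
                opt.zero_grad()
                losses = []
                for inst in batch:
                    probs = self.classify_tokens(
                        [t.text for t in inst.tokens], train=True, rng=rng
                    )
                    losses.append(bio_tag_loss(probs, self._onehot(inst.labels)))
                batch_loss = losses[0]
                for l in losses[1:]:
                    batch_loss = batch_loss + l
                batch_loss.backward()
                opt.step()
                self.tuned.enforce_pad()
                total += float(batch_loss.data)
            mean_loss = total / len(instances)
            loss_log.append(mean_loss)
            logger.info(
                "trigger epoch %d: loss %.4f (%.2fs)",
                epoch,
                mean_loss,
                time.perf_counter() - t0,
            )
        return loss_log

    # -- prediction -------------------------------------------------------

    def predict_triggers(self, doc: Document) -> list[TriggerAnn]:
        """End-to-end tagging of one document back to character offsets."""
        used = [
            int(a.id[1:])
            for a in [*doc.entities, *doc.triggers]
            if a.id.startswith("T") and a.id[1:].isdigit()
        ]
        next_id = max(used, default=0) + 1
        out: list[TriggerAnn] = []
        for sent in split_and_tokenize(doc):
            tags = self.predict_tags([t.text for t in sent])
            decoded = decode_bio(TriggerInstance(tuple(sent), tuple(tags)))
            resolved = resolve_trigger_text(doc.text, decoded, id_start=next_id)
            next_id += len(resolved)
            out.extend(resolved)
        return out

    # -- checkpointing ----------------------------------------------------

    def _named_params(self) -> dict[str, Tensor]:
        named: dict[str, Tensor] = {"tuned": self.tuned.vectors}
        for li, (fwd, bwd) in enumerate(self.encoder.layers):
            for dname, cell in (("fwd", fwd), ("bwd", bwd)):
                for g in cell.w_x:
                    named[f"enc/{li}/{dname}/w_x/{g}"] = cell.w_x[g]
                    named[f"enc/{li}/{dname}/w_xp/{g}"] = cell.w_xp[g]
                    named[f"enc/{li}/{dname}/w_h/{g}"] = cell.w_h[g]
                    named[f"enc/{li}/{dname}/b/{g}"] = cell.b[g]
        if self.encoder.d0_proj is not None:
            named["enc/d0_proj"] = self.encoder.d0_proj
        named["att_w"] = self.att_w
        named["clf/W"] = self.W
        named["clf/b"] = self.b
        return named

    def save(self, path: str) -> None:
        """Self-describing checkpoint: config + vocabulary + all tensors."""
        meta = {
            "config": asdict(self.config),
            "taxonomy": self.taxonomy.to_yaml(),
            "vocabulary": self.pretrained.vocabulary,
            "tags": self.tags,
        }
        arrays = {k.replace("/", "__"): v.data for k, v in self._named_params().items()}
        arrays["pretrained"] = self.pretrained.vectors.data
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load(cls, path: str) -> "TriggerTagger":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode("utf-8"))
            arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
        table = EmbeddingTable(
            meta["vocabulary"], Tensor(arrays.pop("pretrained")), trainable=False
        )
        model = cls(
            table,
            taxonomy=EventTaxonomy.from_yaml(meta["taxonomy"]),
            config=ModelConfig(**meta["config"]),
        )
        for name, tensor in model._named_params().items():
            tensor.data[...] = arrays[name.replace("/", "__")]
        return model
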