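"""Fine-grained argument classifier with multi-level attention.

Every argument candidate (a trigger/target fragment) is encoded by the same
reading-gate BiLSTM used for triggers; word-level attention yields an
attended context, and the candidate's *instance vector* is the mean over
fragment positions of [h_j ; h*] plus two positional indicator features
(target-is-trigger, target-before-trigger) — the bag-like fragment alone
cannot encode orientation.  Candidates sharing a trigger ("relevant
arguments") are grouped; sentence-level attention weighs the group's
instance vectors against each other before classification.

Fine-grained detection keeps two disjoint label spaces and classifier
heads: plain roles (Theme, ...) for simple-event candidates and C-prefixed
roles (CTheme, CCause, ...) for complex-event candidates, trained jointly
with summed cross-entropy.  A single unioned head over coarse roles is
available as the non-fine-grained baseline.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass

import numpy as np

from .attention import (
    make_attention_params,
    pool_instance,
    sentence_attention,
    word_attention,
)
from .autodiff import (
    Tensor,
    collect_parameters,
    concat,
    cross_entropy,
    dropout,
    softmax,
)
from .corpus import (
    ArgumentCandidate,
    annotations_in_sentence,
    build_argument_candidates,
    fine_label_space,
    label_candidates_from_gold,
    split_and_tokenize,
    to_coarse_label,
)
from .embeddings import EmbeddingTable, init_tuned, sentence_embedding
from .optim import make_optimizer
from .rg_bilstm import BiLSTMParams, run_bilstm
from .standoff import Document, TriggerAnn
from .taxonomy import DEFAULT_TAXONOMY, EventTaxonomy
from .trigger_model import ModelConfig, TrainConfig

logger = logging.getLogger(__name__)


@dataclass
class ArgumentModelConfig(ModelConfig):
    use_sentence_attention: bool = True  # multi-level vs word-level only
    fine_grained: bool = True  # two heads vs one unioned coarse head
    residual_attention: bool = False


@dataclass
class ArgumentPrediction:
    candidate: ArgumentCandidate
    label: str  # fine label from the head matching the candidate's mode
    probability: float


def batch_by_relevance(
    candidates: list[ArgumentCandidate], batch_size: int
) -> list[list[ArgumentCandidate]]:
    """Partition candidates into batches without splitting relevance groups.

    Candidates sharing a relevance key stay contiguous and land in one
    batch; a group larger than ``batch_size`` is an error (raise the batch
    size).  Every candidate appears exactly once across the partition.
    """
    groups: dict[str, list[ArgumentCandidate]] = {}
    order: list[str] = []
    for cand in candidates:
        if cand.relevance_key not in groups:
            groups[cand.relevance_key] = []
            order.append(cand.relevance_key)
        groups[cand.relevance_key].append(cand)
    batches: list[list[ArgumentCandidate]] = []
    current: list[ArgumentCandidate] = []
    for key in order:
        group = groups[key]
        if len(group) > batch_size:
            raise ValueError(
                f"relevance group {key!r} has {len(group)} candidates; "
                f"increase batch_size (currently {batch_size})"
            )
        if len(current) + len(group) > batch_size and current:
            batches.append(current)
            current = []
        current.extend(group)
    if current:
        batches.append(current)
    return batches


class ArgumentClassifier:
    """Train and apply the fine-grained argument detection model."""

    def __init__(
        self,
        pretrained: EmbeddingTable,
        *,
        taxonomy: EventTaxonomy = DEFAULT_TAXONOMY,
        config: ArgumentModelConfig | None = None,
        seed: int = 0,
    ):
        self.taxonomy = taxonomy
        self.config = config or ArgumentModelConfig()
        if pretrained.dim != self.config.embedding_dim:
            raise ValueError(
                f"embedding table dim {pretrained.dim} != configured "
                f"{self.config.embedding_dim}"
            )
        self.pretrained = pretrained
        self.tuned = init_tuned(pretrained)
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.encoder = BiLSTMParams(
            cfg.embedding_dim, cfg.hidden_size, cfg.n_layers, rng, cfg.combine
        )
        enc_out = self.encoder.out_dim
        self.att_w = make_attention_params(enc_out, rng)
        token_dim = enc_out * 2 if cfg.use_word_attention else enc_out
        self.instance_dim = token_dim + 2  # + positional indicator flags
        self.sent_att_w = make_attention_params(self.instance_dim, rng)

        simple_roles = self._roles_for_mode("simple")
        complex_roles = self._roles_for_mode("complex")
        if cfg.fine_grained:
            self.label_spaces = {
                "simple": fine_label_space("simple", simple_roles),
                "complex": fine_label_space("complex", complex_roles),
            }
        else:
            union = list(dict.fromkeys([*simple_roles, *complex_roles]))
            shared = ["NONE"] + union
            self.label_spaces = {"simple": shared, "complex": shared}
        self.heads: dict[str, tuple[Tensor, Tensor]] = {}
        for mode in ("simple", "complex"):
            if not cfg.fine_grained and mode == "complex":
                self.heads["complex"] = self.heads["simple"]
                continue
            n_lab = len(self.label_spaces[mode])
            bound = np.sqrt(6.0 / (self.instance_dim + n_lab))
            self.heads[mode] = (
                Tensor(
                    rng.uniform(-bound, bound, size=(self.instance_dim, n_lab)),
                    requires_grad=True,
                ),
                Tensor(np.zeros(n_lab), requires_grad=True),
            )

    def _roles_for_mode(self, mode: str) -> list[str]:
        kinds = (
            self.taxonomy.simple_types if mode == "simple" else self.taxonomy.complex_types
        )
        roles: list[str] = []
        for t in kinds:
            for r in self.taxonomy.roles[t]:
                if r not in roles:
                    roles.append(r)
        return roles

    # -- encoding ---------------------------------------------------------

    def encode_candidate(
        self,
        cand: ArgumentCandidate,
        *,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Instance vector of one candidate (fragment -> pooled states + flags)."""
        if not cand.fragment:
            raise ValueError("candidate has an empty fragment")
        cfg = self.config
        tokens = [t.text for t in cand.fragment]
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
            from .autodiff import stack

            H = concat([H, stack([ctx] * len(tokens), axis=0)], axis=1)
        pooled = pool_instance(H)
        flags = np.array(
            [
                1.0 if cand.target_is_event_trigger else 0.0,
                1.0 if cand.target.span.start < cand.trigger.span.start else 0.0,
            ]
        )
        vec = concat([pooled, Tensor(flags)], axis=0)
        if train and rng is not None:
            vec = dropout(vec, cfg.dropout, rng, train)
        return vec

    # -- classification ---------------------------------------------------

    def _group_outputs(
        self,
        batch: list[ArgumentCandidate],
        *,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> list[tuple[ArgumentCandidate, Tensor]]:
        """Per-candidate final vectors after group-level attention."""
        out: list[tuple[ArgumentCandidate, Tensor]] = []
        i = 0
        while i < len(batch):
            j = i
            key = batch[i].relevance_key
            while j < len(batch) and batch[j].relevance_key == key:
                j += 1
            group = batch[i:j]
            vecs = [self.encode_candidate(c, train=train, rng=rng) for c in group]
            if self.config.use_sentence_attention:
                _, weighted = sentence_attention(
                    vecs,
                    self.sent_att_w,
                    relevance_keys=[c.relevance_key for c in group],
                    residual=self.config.residual_attention,
                )
            else:
                weighted = vecs
            out.extend(zip(group, weighted))
            i = j
        return out

    def classify_arguments(
        self,
        batch: list[ArgumentCandidate],
        *,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> list[tuple[ArgumentCandidate, Tensor]]:
        """Per-candidate fine-label distributions (rows sum to one)."""
        results = []
        for cand, vec in self._group_outputs(batch, train=train, rng=rng):
            W, b = self.heads[cand.mode]
            results.append((cand, softmax(vec @ W + b, axis=-1)))
        return results

    def predict(self, batch: list[ArgumentCandidate]) -> list[ArgumentPrediction]:
        preds = []
        for cand, probs in self.classify_arguments(batch):
            labels = self.label_spaces[cand.mode]
            k = int(probs.data.argmax())  # ties -> lowest label index
            preds.append(ArgumentPrediction(cand, labels[k], float(probs.data[k])))
        return preds

    # -- training ---------------------------------------------------------

    def _gold_candidates(self, docs: list[Document]) -> list[ArgumentCandidate]:
        cands: list[ArgumentCandidate] = []
        for doc in docs:
            for sent in split_and_tokenize(doc):
                triggers = annotations_in_sentence(sent, doc.triggers)
                entities = annotations_in_sentence(sent, doc.entities)
                sent_cands = build_argument_candidates(
                    sent, triggers, entities, taxonomy=self.taxonomy,
                    key_prefix=f"{doc.doc_id}/",
                )
                labeled = label_candidates_from_gold(sent_cands, doc)
                if not self.config.fine_grained:
                    labeled = [
                        ArgumentCandidate(
                            c.trigger,
                            c.target,
                            c.fragment,
                            c.mode,
                            to_coarse_label(c.fine_label, c.mode)
                            if c.fine_label != "NONE"
                            else "NONE",
                            c.relevance_key,
                        )
                        for c in labeled
                    ]
                cands.extend(labeled)
        return cands

    def parameters(self) -> list[Tensor]:
        head_params = []
        seen: set[int] = set()
        for W, b in self.heads.values():
            if id(W) not in seen:
                head_params += [W, b]
                seen.add(id(W))
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
                "satt": self.sent_att_w if self.config.use_sentence_attention else [],
                "heads": head_params,
            }
        )

    def _onehot(self, cand: ArgumentCandidate) -> np.ndarray:
        labels = self.label_spaces[cand.mode]
        vec = np.zeros(len(labels))
        vec[labels.index(cand.fine_label)] = 1.0
        return vec

    def fit(
        self, docs: list[Document], train_config: TrainConfig | None = None
    ) -> list[float]:
        """Train both heads jointly on gold-labeled candidates."""
        tc = train_config or TrainConfig()
        candidates = self._gold_candidates(docs)
        if not candidates:
            raise ValueError("no argument candidates derivable from corpus")
        rng = np.random.default_rng(tc.seed)
        opt = make_optimizer(tc.optimizer, self.parameters(), tc.learning_rate)
        loss_log: list[float] = []
        for epoch in range(tc.epochs):
            t0 = time.perf_counter()
            batches = batch_by_relevance(candidates, tc.batch_size)
            perm = rng.permutation(len(batches))
            total = 0.0
            for bi in perm:
                batch = batches[bi]
                opt.zero_grad()
                loss = None
                for cand, probs in self.classify_arguments(batch, train=True, rng=rng):
                    term = cross_entropy(probs, self._onehot(cand))
                    loss = term if loss is None else loss + term
                loss.backward()
                opt.step()
                self.tuned.enforce_pad()
                total += float(loss.data)
            mean_loss = total / len(candidates)
            loss_log.append(mean_loss)
            logger.info(
                "argument epoch %d: loss %.4f (%.2fs)",
                epoch,
                mean_loss,
                time.perf_counter() - t0,
            )
        return loss_log

    # -- edge prediction --------------------------------------------------

    def predict_edges(
        self,
        doc: Document,
        triggers: list[TriggerAnn],
        *,
        batch_size: int = 64,
    ) -> list[tuple[str, str, str, float]]:
        """(trigger id, target id, coarse role, probability) for non-NONE pairs."""
        edges: list[tuple[str, str, str, float]] = []
        for sent in split_and_tokenize(doc):
            sent_triggers = annotations_in_sentence(sent, triggers)
            entities = annotations_in_sentence(sent, doc.entities)
            cands = build_argument_candidates(
                sent, sent_triggers, entities, taxonomy=self.taxonomy,
                key_prefix=f"{doc.doc_id}/",
            )
            if not cands:
                continue
            for batch in batch_by_relevance(cands, max(batch_size, len(cands))):
                for pred in self.predict(batch):
                    if pred.label == "NONE":
                        continue
                    role = (
                        to_coarse_label(pred.label, pred.candidate.mode)
                        if self.config.fine_grained
                        else pred.label
                    )
                    edges.append(
                        (
                            pred.candidate.trigger.id,
                            pred.candidate.target.id,
                            role,
                            pred.probability,
                        )
                    )
        return edges

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
        named["satt_w"] = self.sent_att_w
        for mode in ("simple", "complex"):
            W, b = self.heads[mode]
            named[f"head/{mode}/W"] = W
            named[f"head/{mode}/b"] = b
        return named

    def save(self, path: str) -> None:
        meta = {
            "config": asdict(self.config),
            "taxonomy": self.taxonomy.to_yaml(),
            "vocabulary": self.pretrained.vocabulary,
        }
        arrays = {k.replace("/", "__"): v.data for k, v in self._named_params().items()}
        arrays["pretrained"] = self.pretrained.vectors.data
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path: str) -> "ArgumentClassifier":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode("utf-8"))
            arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
        table = EmbeddingTable(
            meta["vocabulary"], Tensor(arrays.pop("pretrained")), trainable=False
        )
        model = cls(
            table,
            taxonomy=EventTaxonomy.from_yaml(meta["taxonomy"]),
            config=ArgumentModelConfig(**meta["config"]),
        )
        for name, tensor in model._named_params().items():
            tensor.data[...] = arrays[name.replace("/", "__")]
        return model
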