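"""Tokenization, BIO trigger labeling and argument-candidate construction.

Trigger identification is cast as BIO sequence labeling over sentence tokens
(tag alphabet {O} plus {B-t, I-t} for each event type t).  Argument detection
is cast over *candidates*: sentence fragments spanning a trigger, a target
(entity, or another trigger for complex event types) and all tokens between
them.  Candidates carry a fine-grained label space — the plain role name for
simple-event candidates, a ``C``-prefixed role (Theme -> CTheme) for
complex-event candidates — and a relevance key (their trigger id) used to
group "relevant arguments" for sentence-level attention.

The tokenizer splits on whitespace and punctuation but keeps internal
hyphens and apostrophes, so "Bmi-1" and "over-expression" are single tokens
and stay aligned with standoff spans.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from .standoff import Document, Entity, Span, TriggerAnn
from .taxonomy import DEFAULT_TAXONOMY, EventTaxonomy

logger = logging.getLogger(__name__)

_TOKEN = re.compile(
    r"[A-Za-z0-9_](?:[A-Za-z0-9_'\-]*[A-Za-z0-9_])?"  # word, internal -/' kept
    r"|[^\sA-Za-z0-9_]"  # any other non-space char, alone
)
_SENT_TERMINAL = {".", "!", "?"}


class AlignmentError(ValueError):
    """An annotation span does not coincide with a contiguous token run."""


@dataclass(frozen=True)
class Token:
    text: str
    span: Span
    index: int  # position within its sentence


@dataclass(frozen=True)
class TriggerInstance:
    """A tokenized sentence with one BIO tag per token."""

    tokens: tuple[Token, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError("labels and tokens must have equal length")


Target = Union[Entity, TriggerAnn]


@dataclass(frozen=True)
class ArgumentCandidate:
    """A (trigger, target) pair with its middle-token fragment.

    ``mode`` is "complex" exactly when the trigger's event type is complex;
    trigger targets are only generated in complex mode.  ``relevance_key``
    is the trigger id: candidates sharing it are the "relevant arguments"
    that sentence-level attention couples.
    """

    trigger: TriggerAnn
    target: Target
    fragment: tuple[Token, ...]
    mode: str  # "simple" | "complex"
    fine_label: str = "NONE"
    relevance_key: str = ""

    @property
    def target_is_event_trigger(self) -> bool:
        return isinstance(self.target, TriggerAnn)


def tokenize(text: str, offset: int = 0) -> list[tuple[str, Span]]:
    """Token surface/span pairs; spans are absolute (document) offsets."""
    return [
        (m.group(0), Span(offset + m.start(), offset + m.end()))
        for m in _TOKEN.finditer(text)
    ]


def split_and_tokenize(doc: Document) -> list[list[Token]]:
    """Sentence-split and tokenize a document.

    Boundaries fall after sentence-terminal punctuation (. ! ?) and at
    newlines.  Any pair of adjacent sentences straddled by an annotation
    span is merged, so every entity/trigger lives in exactly one sentence.
    """
    raw = tokenize(doc.text)
    if not raw:
        return []

    sentences: list[list[tuple[str, Span]]] = [[]]
    for i, (text, span) in enumerate(raw):
        sentences[-1].append((text, span))
        is_last = i == len(raw) - 1
        if is_last:
            break
        boundary = text in _SENT_TERMINAL
        gap = doc.text[span.end : raw[i + 1][1].start]
        if "\n" in gap:
            boundary = True
        if boundary and sentences[-1]:
            sentences.append([])
    sentences = [s for s in sentences if s]

    spans = [ann.span for ann in [*doc.entities, *doc.triggers]]
    merged = True
    while merged and len(sentences) > 1:
        merged = False
        for k in range(len(sentences) - 1):
            boundary = sentences[k + 1][0][1].start
            if any(sp.start < boundary <= sp.end - 1 or
                   (sp.start < boundary and sp.end > boundary)
                   for sp in spans):
                sentences[k] = sentences[k] + sentences[k + 1]
                del sentences[k + 1]
                merged = True
                break

    return [
        [Token(text, span, idx) for idx, (text, span) in enumerate(sent)]
        for sent in sentences
    ]


def align_span(tokens: Sequence[Token], span: Span) -> tuple[int, int] | None:
    """Indices (i, j) such that tokens[i:j] exactly tile ``span``, else None."""
    covered = [t for t in tokens if t.span.start >= span.start and t.span.end <= span.end]
    if not covered:
        return None
    i, j = covered[0].index, covered[-1].index + 1
    if covered[0].span.start != span.start or covered[-1].span.end != span.end:
        return None
    if [t.index for t in covered] != list(range(i, j)):
        return None
    return i, j


def annotations_in_sentence(
    tokens: Sequence[Token], anns: Iterable
) -> list:
    """Annotations whose span falls inside this sentence's token extent."""
    if not tokens:
        return []
    lo, hi = tokens[0].span.start, tokens[-1].span.end
    return [a for a in anns if a.span.start >= lo and a.span.end <= hi]


def encode_bio(
    tokens: Sequence[Token], triggers: Iterable[TriggerAnn]
) -> TriggerInstance:
    """BIO-encode triggers over a sentence.

    Overlapping triggers cannot be expressed in BIO; the longer span wins
    and the other is dropped with a log message.  A trigger that does not
    align to a contiguous token run raises :class:`AlignmentError` naming
    the trigger.
    """
    kept: list[TriggerAnn] = []
    for trig in sorted(triggers, key=lambda t: (-len(t.span), t.span.start, t.id)):
        clash = next((k for k in kept if k.span.overlaps(trig.span)), None)
        if clash is not None:
            logger.warning(
                "dropping trigger %s (%s): overlaps %s", trig.id,
                trig.event_type, clash.id,
            )
            continue
        kept.append(trig)

    labels = ["O"] * len(tokens)
    for trig in kept:
        loc = align_span(tokens, trig.span)
        if loc is None:
            raise AlignmentError(
                f"trigger {trig.id} span [{trig.span.start}, {trig.span.end}) "
                f"does not align to tokens"
            )
        i, j = loc
        labels[i] = f"B-{trig.event_type}"
        for k in range(i + 1, j):
            labels[k] = f"I-{trig.event_type}"
    return TriggerInstance(tuple(tokens), tuple(labels))


def decode_bio(instance: TriggerInstance, id_prefix: str = "T") -> list[TriggerAnn]:
    """Recover trigger annotations from a BIO tag sequence.

    Maximal ``B-t (I-t)*`` runs become triggers of type t spanning from the
    first token's start to the last token's end.  A stray ``I-t`` with no
    compatible predecessor opens a new run (treated as ``B-t``), so any tag
    sequence decodes without error.
    """
    triggers: list[TriggerAnn] = []
    run_type: str | None = None
    run_start = run_end = -1

    def flush() -> None:
        # Surface text and ids are filled in later by resolve_trigger_text,
        # which has access to the document string.
        nonlocal run_type
        if run_type is not None:
            triggers.append(TriggerAnn("", run_type, Span(run_start, run_end), ""))
            run_type = None

    for tok, label in zip(instance.tokens, instance.labels):
        if label == "O":
            flush()
            continue
        prefix, _, ttype = label.partition("-")
        if prefix == "B" or run_type != ttype:
            flush()
            run_type = ttype
            run_start = tok.span.start
        run_end = tok.span.end
    flush()
    return triggers


def resolve_trigger_text(doc_text: str, triggers: list[TriggerAnn], id_start: int = 1000
                         ) -> list[TriggerAnn]:
    """Fill surface text (from the document) and fresh ids into decoded triggers."""
    out = []
    for k, trig in enumerate(triggers):
        out.append(
            TriggerAnn(
                f"T{id_start + k}",
                trig.event_type,
                trig.span,
                trig.span.slice(doc_text),
            )
        )
    return out


def to_fine_label(role: str, mode: str, *, role_set: Sequence[str] = ("Theme", "Cause")
                  ) -> str:
    """Map a coarse role to the fine-grained label space of ``mode``.

    Simple-mode candidates keep the plain role name; complex-mode candidates
    get a ``C`` prefix (Theme -> CTheme), keeping the two label spaces — and
    hence the two classifier heads — disjoint.  NONE maps to NONE in both.
    """
    if mode not in ("simple", "complex"):
        raise ValueError(f"unknown mode {mode!r}")
    if role == "NONE":
        return "NONE"
    if role not in role_set:
        raise ValueError(f"unknown role {role!r}")
    return role if mode == "simple" else "C" + role


def to_coarse_label(fine: str, mode: str, *, role_set: Sequence[str] = ("Theme", "Cause")
                    ) -> str:
    """Inverse of :func:`to_fine_label` per mode."""
    if mode not in ("simple", "complex"):
        raise ValueError(f"unknown mode {mode!r}")
    if fine == "NONE":
        return "NONE"
    role = fine if mode == "simple" else fine.removeprefix("C")
    if role not in role_set or (mode == "complex" and not fine.startswith("C")):
        raise ValueError(f"label {fine!r} not in {mode} label space")
    return role


def fine_label_space(mode: str, role_set: Sequence[str] = ("Theme", "Cause")
                     ) -> list[str]:
    """Ordered label alphabet for one classifier head; NONE is index 0."""
    return ["NONE"] + [to_fine_label(r, mode, role_set=role_set) for r in role_set]


def build_argument_candidates(
    tokens: Sequence[Token],
    triggers: Sequence[TriggerAnn],
    entities: Sequence[Entity],
    *,
    taxonomy: EventTaxonomy = DEFAULT_TAXONOMY,
    key_prefix: str = "",
) -> list[ArgumentCandidate]:
    """Enumerate within-sentence argument candidates.

    Simple-type triggers pair with every entity in the sentence; complex-type
    triggers pair with every entity and every *other* trigger (both
    directions), never with themselves.  With s simple triggers, c complex
    triggers (t = s + c total) and e entities this yields
    ``s*e + c*(e + t - 1)`` candidates.

    ``key_prefix`` (normally the document id) namespaces the relevance keys:
    annotation ids are only unique within one document, and relevance groups
    must never merge across documents when candidates are pooled for
    training.
    """
    out: list[ArgumentCandidate] = []
    for trig in triggers:
        mode = "complex" if taxonomy.is_complex(trig.event_type) else "simple"
        targets: list[Target] = list(entities)
        if mode == "complex":
            targets += [t for t in triggers if t.id != trig.id]
        for target in targets:
            out.append(
                ArgumentCandidate(
                    trigger=trig,
                    target=target,
                    fragment=_fragment(tokens, trig, target),
                    mode=mode,
                    relevance_key=f"{key_prefix}{trig.id}",
                )
            )
    return out


def _fragment(
    tokens: Sequence[Token], trig: TriggerAnn, target: Target
) -> tuple[Token, ...]:
    lo = min(trig.span.start, target.span.start)
    hi = max(trig.span.end, target.span.end)
    frag = tuple(t for t in tokens if t.span.start >= lo and t.span.end <= hi)
    if not frag:
        raise AlignmentError(
            f"empty fragment for ({trig.id}, {target.id}) in sentence"
        )
    return frag


def label_candidates_from_gold(
    candidates: Sequence[ArgumentCandidate], doc: Document
) -> list[ArgumentCandidate]:
    """Assign gold fine labels to candidates.

    A candidate's label is its (mode-prefixed) role when the gold events
    contain that (trigger, target, role) edge — where an event-valued gold
    argument is identified with its own trigger — and NONE otherwise.
    """
    ev_index = doc.event_by_id()
    edges: dict[tuple[str, str], str] = {}
    for ev in doc.events:
        for role, target in ev.args:
            if target.startswith("E"):
                inner = ev_index.get(target)
                if inner is None:
                    continue
                target = inner.trigger
            edges.setdefault((ev.trigger, target), role)

    out = []
    for cand in candidates:
        role = edges.get((cand.trigger.id, cand.target.id), "NONE")
        fine = to_fine_label(role, cand.mode) if role != "NONE" else "NONE"
        out.append(
            ArgumentCandidate(
                trigger=cand.trigger,
                target=cand.target,
                fragment=cand.fragment,
                mode=cand.mode,
                fine_label=fine,
                relevance_key=cand.relevance_key,
            )
        )
    return out
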