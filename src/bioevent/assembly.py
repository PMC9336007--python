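"""Post-processing: from predicted triggers and argument edges to events.

Assembly resolves nested structure by fixpoint iteration: round one builds
events for triggers whose arguments are all entities; later rounds may bind
an event-valued argument to an event already built for the target trigger;
iteration stops when no new event appears (at most one round per trigger).
Edges violating the taxonomy's role constraints are dropped up front, and
every assembled document passes structure validation by construction.

Edges sharing a trigger combine into events by type class:

* simple types — the single highest-probability Theme edge;
* Binding — all Theme edges merge into one multi-Theme event;
* Regulation family — one event per Theme edge, each paired with the
  highest-probability Cause edge if one exists.

An optional learned filter vets candidate structures.  It is a margin-based
linear classifier (hinge loss) over hashed sparse features from three
families: linear-span features (bag-of-words between the argument
extremes), argument-combination features (role pattern and per-role
counts), and argument-content features (target entity/event types and edge
labels).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np

from .corpus import Token, annotations_in_sentence, split_and_tokenize
from .standoff import Document, Entity, EventAnn, TriggerAnn
from .taxonomy import DEFAULT_TAXONOMY, EventTaxonomy

logger = logging.getLogger(__name__)

Edge = tuple[str, str, str, float]  # trigger id, target id, role, probability
ArgTarget = Union[Entity, "EventCandidate"]


@dataclass
class EventCandidate:
    trigger: TriggerAnn
    args: tuple[tuple[str, ArgTarget], ...]
    probability: float = 1.0

    def arg_spans(self) -> list[tuple[int, int]]:
        spans = [(self.trigger.span.start, self.trigger.span.end)]
        for _, target in self.args:
            if isinstance(target, EventCandidate):
                spans.extend(target.arg_spans())
            else:
                spans.append((target.span.start, target.span.end))
        return spans


@dataclass
class StructureFeatures:
    """The three feature families, as one sparse name->value map."""

    values: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


def extract_structure_features(
    candidate: EventCandidate, sentence: Sequence[Token]
) -> StructureFeatures:
    """Deterministic feature map for one candidate event structure."""
    feats: dict[str, float] = {}
    spans = candidate.arg_spans()
    lo = min(s for s, _ in spans)
    hi = max(e for _, e in spans)
    # linear span: bag-of-words strictly between the argument extremes
    for tok in sentence:
        if lo < tok.span.start and tok.span.end < hi:
            key = f"bow:{tok.text.lower()}"
            feats[key] = feats.get(key, 0.0) + 1.0
    # argument combination: role pattern + per-role counts
    roles = sorted(role for role, _ in candidate.args)
    feats[f"pattern:{'+'.join(roles) if roles else '(none)'}"] = 1.0
    for role in roles:
        key = f"count:{role}"
        feats[key] = feats.get(key, 0.0) + 1.0
    feats[f"trigger_type:{candidate.trigger.event_type}"] = 1.0
    # argument content: target types and edge labels
    for role, target in candidate.args:
        if isinstance(target, EventCandidate):
            feats[f"content:{role}:EVENT:{target.trigger.event_type}"] = 1.0
        else:
            feats[f"content:{role}:{target.etype}"] = 1.0
        feats[f"edge:{candidate.trigger.event_type}:{role}"] = 1.0
    return StructureFeatures(feats)


def hash_features(feats: StructureFeatures, dim: int = 1024) -> np.ndarray:
    """Deterministic (md5-based) feature hashing into a fixed-size vector."""
    vec = np.zeros(dim)
    for name, value in feats.values.items():
        h = int.from_bytes(hashlib.md5(name.encode("utf-8")).digest()[:8], "big")
        sign = 1.0 if (h >> 63) & 1 == 0 else -1.0
        vec[h % dim] += sign * value
    return vec


class StructureFilter:
    """Hinge-loss linear accept/reject classifier over hashed features."""

    def __init__(self, dim: int = 1024, seed: int = 0):
        from sklearn.linear_model import SGDClassifier

        self.dim = dim
        self._clf = SGDClassifier(
            loss="hinge", alpha=1e-4, max_iter=200, tol=1e-4, random_state=seed
        )
        self.fitted = False
        self.accept_all = False

    def fit(self, feature_maps: list[StructureFeatures], labels: list[int]) -> None:
        if len(set(labels)) < 2:
            logger.warning(
                "structure filter: only one class present; falling back to accept-all"
            )
            self.accept_all = True
            self.fitted = True
            return
        X = np.stack([hash_features(f, self.dim) for f in feature_maps])
        self._clf.fit(X, np.asarray(labels))
        self.fitted = True

    def accepts(self, feats: StructureFeatures) -> bool:
        if not self.fitted or self.accept_all:
            return True
        x = hash_features(feats, self.dim)[None, :]
        return bool(self._clf.predict(x)[0] == 1)

    def score(self, feats: StructureFeatures) -> float:
        if not self.fitted or self.accept_all:
            return 1.0
        return float(self._clf.decision_function(hash_features(feats, self.dim)[None, :])[0])


FilterLike = Union[StructureFilter, Callable[[StructureFeatures], bool], None]


def _filter_accepts(filt: FilterLike, feats: StructureFeatures) -> bool:
    if filt is None:
        return True
    if isinstance(filt, StructureFilter):
        return filt.accepts(feats)
    return bool(filt(feats))


def _build_for_trigger(
    trig: TriggerAnn,
    edges: list[Edge],
    ent_index: dict[str, Entity],
    built: dict[str, list[EventCandidate]],
    taxonomy: EventTaxonomy,
) -> list[EventCandidate] | None:
    """Candidate events for one trigger, or None if a referenced trigger
    has no built event yet (try again next round)."""
    etype = trig.event_type
    resolved: list[tuple[str, ArgTarget, float]] = []
    for _, target_id, role, prob in edges:
        if target_id in ent_index:
            resolved.append((role, ent_index[target_id], prob))
        else:
            if not taxonomy.allows_event_argument(etype, role):
                continue  # dropped earlier in principle; be safe
            sub = built.get(target_id)
            if sub is None:
                return None  # referenced trigger not resolved yet
            if not sub:
                continue  # target trigger yielded no event; edge unresolvable
            resolved.append((role, sub[0], prob))

    themes = sorted(
        [r for r in resolved if r[0] == "Theme"], key=lambda r: -r[2]
    )
    causes = sorted(
        [r for r in resolved if r[0] == "Cause"], key=lambda r: -r[2]
    )
    out: list[EventCandidate] = []
    if not themes:
        return out  # Theme is required for every MLEE type
    if etype == "Binding":
        args = tuple(("Theme", t) for _, t, _ in themes)
        out.append(EventCandidate(trig, args, min(p for _, _, p in themes)))
    elif etype in taxonomy.complex_types:  # Regulation family
        for _, theme_target, theme_p in themes:
            args: tuple = (("Theme", theme_target),)
            prob = theme_p
            if causes:
                args = args + (("Cause", causes[0][1]),)
                prob = min(prob, causes[0][2])
            out.append(EventCandidate(trig, args, prob))
    else:  # simple type: best Theme only
        _, target, prob = themes[0]
        out.append(EventCandidate(trig, (("Theme", target),), prob))
    return out


def assemble_events(
    triggers: Sequence[TriggerAnn],
    edges: Sequence[Edge],
    sentence: Sequence[Token],
    entities: Sequence[Entity],
    *,
    taxonomy: EventTaxonomy = DEFAULT_TAXONOMY,
    structure_filter: FilterLike = None,
    filter_per_round: bool = True,
) -> list[EventCandidate]:
    """Fixpoint assembly of (possibly nested) events within one sentence."""
    ent_index = {e.id: e for e in entities}
    trig_index = {t.id: t for t in triggers}
    by_trigger: dict[str, list[Edge]] = {t.id: [] for t in triggers}
    for edge in edges:
        tid, target_id, role, _ = edge
        trig = trig_index.get(tid)
        if trig is None:
            logger.info("dropping edge with unknown trigger %s", tid)
            continue
        if role not in taxonomy.permitted_roles(trig.event_type):
            logger.info(
                "dropping edge %s-%s: role %s not permitted for %s",
                tid, target_id, role, trig.event_type,
            )
            continue
        if target_id in trig_index and not taxonomy.allows_event_argument(
            trig.event_type, role
        ):
            logger.info(
                "dropping trigger-valued edge %s-%s for %s",
                tid, target_id, trig.event_type,
            )
            continue
        if target_id not in ent_index and target_id not in trig_index:
            logger.info("dropping edge with unknown target %s", target_id)
            continue
        by_trigger[tid].append(edge)

    built: dict[str, list[EventCandidate]] = {}
    pending = [t for t in triggers]
    rounds = 0
    while pending and rounds <= len(triggers):
        rounds += 1
        progressed = False
        still: list[TriggerAnn] = []
        for trig in pending:
            result = _build_for_trigger(
                trig, by_trigger[trig.id], ent_index, built, taxonomy
            )
            if result is None:
                still.append(trig)
                continue
            if filter_per_round and structure_filter is not None:
                result = [
                    ev
                    for ev in result
                    if _filter_accepts(
                        structure_filter, extract_structure_features(ev, sentence)
                    )
                ]
            built[trig.id] = result
            progressed = True
        if not progressed:
            break
        pending = still
    if pending:
        logger.info(
            "unresolved nested references for %d trigger(s): %s",
            len(pending), [t.id for t in pending],
        )

    events = [ev for evs in built.values() for ev in evs]
    if not filter_per_round and structure_filter is not None:
        events = [
            ev
            for ev in events
            if _filter_accepts(structure_filter, extract_structure_features(ev, sentence))
        ]
    # keep nested references only to surviving events
    surviving = {id(ev) for ev in events}
    events = [
        ev
        for ev in events
        if all(
            not isinstance(t, EventCandidate) or id(t) in surviving
            for _, t in ev.args
        )
    ]
    return events


def candidates_to_annotations(
    events: list[EventCandidate], id_start: int = 1
) -> list[EventAnn]:
    """Assign E-ids and flatten nested candidates into standoff events."""
    ids: dict[int, str] = {}
    ordered: list[EventCandidate] = []

    def visit(ev: EventCandidate) -> None:
        if id(ev) in ids:
            return
        for _, target in ev.args:
            if isinstance(target, EventCandidate):
                visit(target)
        ids[id(ev)] = f"E{id_start + len(ordered)}"
        ordered.append(ev)

    for ev in events:
        visit(ev)
    out = []
    for ev in ordered:
        args = tuple(
            (role, ids[id(t)] if isinstance(t, EventCandidate) else t.id)
            for role, t in ev.args
        )
        out.append(EventAnn(ids[id(ev)], ev.trigger.id, args))
    return out


def assemble_document(
    doc: Document,
    triggers: Sequence[TriggerAnn],
    edges: Sequence[Edge],
    *,
    taxonomy: EventTaxonomy = DEFAULT_TAXONOMY,
    structure_filter: FilterLike = None,
    filter_per_round: bool = True,
) -> Document:
    """Assemble per sentence and return a new document carrying the events."""
    out = Document(doc.doc_id, doc.text, list(doc.entities), list(triggers), [])
    next_eid = 1
    for sent in split_and_tokenize(out):
        sent_triggers = annotations_in_sentence(sent, triggers)
        sent_ids = {t.id for t in sent_triggers}
        sent_entities = annotations_in_sentence(sent, doc.entities)
        sent_edges = [e for e in edges if e[0] in sent_ids]
        events = assemble_events(
            sent_triggers,
            sent_edges,
            sent,
            sent_entities,
            taxonomy=taxonomy,
            structure_filter=structure_filter,
            filter_per_round=filter_per_round,
        )
        anns = candidates_to_annotations(events, id_start=next_eid)
        next_eid += len(anns)
        out.events.extend(anns)
    return out


def train_filter(
    docs: list[Document],
    *,
    taxonomy: EventTaxonomy = DEFAULT_TAXONOMY,
    seed: int = 0,
    dim: int = 1024,
) -> StructureFilter:
    """Fit the structure filter from gold events.

    Positives are the gold event structures; negatives are taxonomy-legal
    structures built by re-targeting gold events at other same-sentence
    entities (candidates that match no gold event).
    """
    feats: list[StructureFeatures] = []
    labels: list[int] = []
    for doc in docs:
        ent_index = doc.entity_by_id()
        trig_index = doc.trigger_by_id()
        ev_index = doc.event_by_id()
        for sent in split_and_tokenize(doc):
            sent_triggers = annotations_in_sentence(sent, doc.triggers)
            sent_entities = annotations_in_sentence(sent, doc.entities)
            sent_trigger_ids = {t.id for t in sent_triggers}
            gold_pairs = set()
            for ev in doc.events:
                if ev.trigger not in sent_trigger_ids:
                    continue
                # positive: the gold structure with entity/event-typed targets
                args = []
                ok = True
                for role, target in ev.args:
                    if target in ent_index:
                        args.append((role, ent_index[target]))
                        gold_pairs.add((ev.trigger, target))
                    elif target in ev_index:
                        inner = ev_index[target]
                        inner_trig = trig_index[inner.trigger]
                        args.append(
                            (role, EventCandidate(inner_trig, ()))
                        )
                        gold_pairs.add((ev.trigger, inner.trigger))
                    else:
                        ok = False
                if not ok:
                    continue
                cand = EventCandidate(trig_index[ev.trigger], tuple(args))
                feats.append(extract_structure_features(cand, sent))
                labels.append(1)
                # negatives: same trigger re-targeted at an unrelated entity
                for ent in sent_entities:
                    if (ev.trigger, ent.id) in gold_pairs:
                        continue
                    neg = EventCandidate(
                        trig_index[ev.trigger], (("Theme", ent),)
                    )
                    feats.append(extract_structure_features(neg, sent))
                    labels.append(0)
                    break  # one negative per gold event keeps classes balanced
    filt = StructureFilter(dim=dim, seed=seed)
    if not feats:
        logger.warning("structure filter: no training structures; accept-all")
        filt.accept_all = True
        filt.fitted = True
        return filt
    filt.fit(feats, labels)
    return filt
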