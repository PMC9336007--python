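"""Precision / recall / F-score at trigger, argument-edge and event level.

    P = TP / (TP + FP),  R = TP / (TP + FN),  F = 2PR / (P + R)

with each ratio defined as 0 when its denominator is 0.  Matching is
one-to-one and exact by default: a predicted trigger counts as a true
positive iff both its character span and its event type equal a gold
trigger's; events match iff their triggers match and their argument sets
match role-for-role, with event-valued arguments compared recursively.
Under exact matching, one-to-one assignment reduces to multiset
intersection of canonical forms, which is provably maximal.  An
approximate-span mode (spans need only overlap) is available behind a flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .standoff import Document, TriggerAnn


@dataclass(frozen=True)
class PRF:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fscore(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def __add__(self, other: "PRF") -> "PRF":
        return PRF(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    def as_percent(self) -> tuple[float, float, float]:
        return (100 * self.precision, 100 * self.recall, 100 * self.fscore)


def prf(tp: int, fp: int, fn: int) -> PRF:
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    return PRF(tp, fp, fn)


def fscore_from_percent(precision: float, recall: float) -> float:
    """F (in percent) from printed percentage P and R."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _counts_exact(gold: Counter, pred: Counter) -> PRF:
    tp = sum((gold & pred).values())
    return PRF(tp, sum(pred.values()) - tp, sum(gold.values()) - tp)


def _greedy_overlap(gold_items: list, pred_items: list, matches) -> PRF:
    """Greedy one-to-one matching under a soft predicate, deterministic order."""
    used = [False] * len(pred_items)
    tp = 0
    for g in gold_items:
        for k, p in enumerate(pred_items):
            if not used[k] and matches(g, p):
                used[k] = True
                tp += 1
                break
    return PRF(tp, len(pred_items) - tp, len(gold_items) - tp)


def match_triggers(
    gold: Sequence[TriggerAnn],
    predicted: Sequence[TriggerAnn],
    *,
    approximate: bool = False,
) -> PRF:
    """Span+type trigger matching (overlap suffices in approximate mode)."""
    if not approximate:
        to_key = lambda t: (t.event_type, t.span.start, t.span.end)
        return _counts_exact(
            Counter(map(to_key, gold)), Counter(map(to_key, predicted))
        )
    order = lambda t: (t.span.start, t.event_type)
    return _greedy_overlap(
        sorted(gold, key=order),
        sorted(predicted, key=order),
        lambda g, p: g.event_type == p.event_type and g.span.overlaps(p.span),
    )


def edges_of_document(doc: Document) -> list[tuple]:
    """Flatten events to (trigger span+type, role, target span) edges.

    Event-valued arguments are identified by the inner event's trigger
    span, so edge-level scoring does not require the inner structure to be
    correct.
    """
    trig_index = doc.trigger_by_id()
    ent_index = doc.entity_by_id()
    ev_index = doc.event_by_id()
    edges = []
    for ev in doc.events:
        trig = trig_index[ev.trigger]
        for role, target in ev.args:
            if target in ent_index:
                tspan = ent_index[target].span
            elif target in ev_index:
                tspan = trig_index[ev_index[target].trigger].span
            else:
                continue
            edges.append(
                (
                    trig.event_type,
                    trig.span.start,
                    trig.span.end,
                    role,
                    tspan.start,
                    tspan.end,
                )
            )
    return edges


def match_edges(
    gold: Document, predicted: Document, *, trigger_types: set[str] | None = None
) -> PRF:
    """Argument-edge matching, optionally restricted to some trigger types."""
    ge, pe = edges_of_document(gold), edges_of_document(predicted)
    if trigger_types is not None:
        ge = [e for e in ge if e[0] in trigger_types]
        pe = [e for e in pe if e[0] in trigger_types]
    return _counts_exact(Counter(ge), Counter(pe))


def _canonical_events(doc: Document) -> Counter:
    trig_index = doc.trigger_by_id()
    ent_index = doc.entity_by_id()
    ev_index = doc.event_by_id()
    memo: dict[str, tuple] = {}

    def canon(eid: str) -> tuple:
        if eid in memo:
            return memo[eid]
        ev = ev_index[eid]
        trig = trig_index[ev.trigger]
        args = []
        for role, target in ev.args:
            if target in ent_index:
                sp = ent_index[target].span
                args.append((role, ("ENT", sp.start, sp.end)))
            else:
                args.append((role, canon(target)))
        form = (
            trig.event_type,
            trig.span.start,
            trig.span.end,
            tuple(sorted(args, key=repr)),
        )
        memo[eid] = form
        return form

    return Counter(canon(ev.id) for ev in doc.events)


def match_events(gold: Document, predicted: Document) -> PRF:
    """Recursive exact event matching, one-to-one via multiset intersection."""
    return _counts_exact(_canonical_events(gold), _canonical_events(predicted))


def score_corpus(
    gold_docs: Sequence[Document],
    pred_docs: Sequence[Document],
    level: str = "event",
    *,
    trigger_types: set[str] | None = None,
) -> PRF:
    """Aggregate PRF over paired documents at the requested level."""
    if len(gold_docs) != len(pred_docs):
        raise ValueError("gold and predicted corpora differ in size")
    total = PRF(0, 0, 0)
    for g, p in zip(gold_docs, pred_docs):
        if level == "trigger":
            total = total + match_triggers(g.triggers, p.triggers)
        elif level == "edge":
            total = total + match_edges(g, p, trigger_types=trigger_types)
        elif level == "event":
            total = total + match_events(g, p)
        else:
            raise ValueError(f"unknown level {level!r}")
    return total
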