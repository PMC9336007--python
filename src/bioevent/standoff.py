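"""Reading, writing and validating BioNLP standoff annotation (.txt/.a1/.a2).

The standoff convention keeps the document text untouched and records
annotations by character offset: 0-based, end-exclusive offsets into the
UTF-8 decoded text.  ``.a1`` holds entity T-lines; ``.a2`` holds trigger
T-lines plus event E-lines whose arguments reference entities, triggers or
other events (nesting).  Repeated roles in an E-line carry the usual numeric
suffix (``Theme``, ``Theme2``, ...), which is stripped to the base role name
on parse and regenerated on write.

Events must form a DAG over E-ids: a cycle is a hard parse error because the
downstream recursive event matching and assembly assume acyclicity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx

from .taxonomy import DEFAULT_TAXONOMY, EventTaxonomy


class StandoffParseError(ValueError):
    """Malformed standoff line; message names the file kind and line number."""


class StandoffIntegrityError(ValueError):
    """Well-formed lines whose content violates document invariants."""


@dataclass(frozen=True, order=True)
class Span:
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def slice(self, text: str) -> str:
        return text[self.start : self.end]

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Entity:
    id: str
    etype: str
    span: Span
    text: str


@dataclass(frozen=True)
class TriggerAnn:
    id: str
    event_type: str
    span: Span
    text: str


@dataclass(frozen=True)
class EventAnn:
    id: str
    trigger: str  # TriggerAnn id
    args: tuple[tuple[str, str], ...]  # ordered (role, target id)


@dataclass
class Document:
    doc_id: str
    text: str
    entities: list[Entity] = field(default_factory=list)
    triggers: list[TriggerAnn] = field(default_factory=list)
    events: list[EventAnn] = field(default_factory=list)

    def entity_by_id(self) -> dict[str, Entity]:
        return {e.id: e for e in self.entities}

    def trigger_by_id(self) -> dict[str, TriggerAnn]:
        return {t.id: t for t in self.triggers}

    def event_by_id(self) -> dict[str, EventAnn]:
        return {e.id: e for e in self.events}


_T_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_E_LINE = re.compile(r"^(E\d+)\t(\S+):(T\d+)((?: \S+:\S+)*)\s*$")
_ROLE_SUFFIX = re.compile(r"^([A-Za-z_]+?)(\d*)$")


def _base_role(role: str) -> str:
    m = _ROLE_SUFFIX.match(role)
    if m is None:
        raise StandoffParseError(f"unparseable role name {role!r}")
    return m.group(1)


def _parse_t_line(line: str, lineno: int, kind: str):
    m = _T_LINE.match(line)
    if m is None:
        raise StandoffParseError(f"{kind} line {lineno}: malformed T-line: {line!r}")
    tid, ttype, start, end, surface = m.groups()
    try:
        span = Span(int(start), int(end))
    except ValueError as exc:
        raise StandoffParseError(f"{kind} line {lineno}: {exc}") from exc
    return tid, ttype, span, surface


def parse_standoff(
    txt_content: str,
    a1_content: str,
    a2_content: str | None = None,
    *,
    doc_id: str = "doc",
    taxonomy: EventTaxonomy = DEFAULT_TAXONOMY,
) -> Document:
    """Parse a standoff triple into a validated :class:`Document`.

    ``a2_content`` may be ``None`` / absent, yielding empty trigger and
    event collections (the common state before prediction).
    """
    doc = Document(doc_id=doc_id, text=txt_content)
    seen_ids: set[str] = set()

    for lineno, line in enumerate(a1_content.splitlines(), start=1):
        if not line.strip():
            continue
        tid, etype, span, surface = _parse_t_line(line, lineno, ".a1")
        _check_new_id(tid, seen_ids, ".a1", lineno)
        _check_span(doc.text, span, surface, tid)
        doc.entities.append(Entity(tid, etype, span, surface))

    event_lines: list[tuple[int, str, str, str, str]] = []
    if a2_content:
        for lineno, line in enumerate(a2_content.splitlines(), start=1):
            if not line.strip():
                continue
            if line.startswith("T"):
                tid, etype, span, surface = _parse_t_line(line, lineno, ".a2")
                _check_new_id(tid, seen_ids, ".a2", lineno)
                _check_span(doc.text, span, surface, tid)
                if etype not in taxonomy.event_types:
                    raise StandoffIntegrityError(
                        f"trigger {tid}: unknown event type {etype!r}"
                    )
                doc.triggers.append(TriggerAnn(tid, etype, span, surface))
            elif line.startswith("E"):
                m = _E_LINE.match(line)
                if m is None:
                    raise StandoffParseError(
                        f".a2 line {lineno}: malformed E-line: {line!r}"
                    )
                eid, etype, trig_id, rest = m.groups()
                _check_new_id(eid, seen_ids, ".a2", lineno)
                event_lines.append((lineno, eid, etype, trig_id, rest))
            else:
                raise StandoffParseError(
                    f".a2 line {lineno}: unsupported annotation: {line!r}"
                )

    trig_index = doc.trigger_by_id()
    ent_index = doc.entity_by_id()
    declared_events = {eid for _, eid, *_ in event_lines}
    for lineno, eid, etype, trig_id, rest in event_lines:
        trig = trig_index.get(trig_id)
        if trig is None:
            raise StandoffIntegrityError(
                f"event {eid}: dangling trigger reference {trig_id}"
            )
        if trig.event_type != etype:
            raise StandoffIntegrityError(
                f"event {eid}: declared type {etype} != trigger type "
                f"{trig.event_type}"
            )
        args: list[tuple[str, str]] = []
        for chunk in rest.split():
            role_raw, _, target = chunk.partition(":")
            if not target:
                raise StandoffParseError(
                    f".a2 line {lineno}: malformed argument {chunk!r}"
                )
            if target not in ent_index and target not in declared_events:
                raise StandoffIntegrityError(
                    f"event {eid}: dangling argument reference {target}"
                )
            args.append((_base_role(role_raw), target))
        doc.events.append(EventAnn(eid, trig_id, tuple(args)))

    _check_acyclic(doc)
    return doc


def _check_new_id(aid: str, seen: set[str], kind: str, lineno: int) -> None:
    if aid in seen:
        raise StandoffIntegrityError(f"{kind} line {lineno}: duplicate id {aid}")
    seen.add(aid)


def _check_span(text: str, span: Span, surface: str, aid: str) -> None:
    if span.end > len(text):
        raise StandoffIntegrityError(
            f"{aid}: span [{span.start}, {span.end}) exceeds text length "
            f"{len(text)}"
        )
    actual = span.slice(text)
    if actual != surface:
        raise StandoffIntegrityError(
            f"{aid}: span text {actual!r} != annotated text {surface!r}"
        )


def _event_graph(doc: Document) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(e.id for e in doc.events)
    for ev in doc.events:
        for _, target in ev.args:
            if target.startswith("E"):
                g.add_edge(ev.id, target)
    return g


def _check_acyclic(doc: Document) -> None:
    if not nx.is_directed_acyclic_graph(_event_graph(doc)):
        cycle = nx.find_cycle(_event_graph(doc))
        raise StandoffIntegrityError(f"event reference cycle: {cycle}")


def write_standoff(
    doc: Document, *, taxonomy: EventTaxonomy = DEFAULT_TAXONOMY
) -> tuple[str, str]:
    """Serialize a document back to ``(a1_content, a2_content)``.

    Annotation ids are preserved verbatim, so ``parse(write(doc))`` is the
    identity on valid documents and serialization is idempotent.
    """
    violations = validate_structure(doc, taxonomy=taxonomy)
    if violations:
        raise StandoffIntegrityError(
            "document violates invariants: " + "; ".join(violations)
        )
    a1_lines = [
        f"{e.id}\t{e.etype} {e.span.start} {e.span.end}\t{e.text}"
        for e in doc.entities
    ]
    a2_lines = [
        f"{t.id}\t{t.event_type} {t.span.start} {t.span.end}\t{t.text}"
        for t in doc.triggers
    ]
    trig_index = doc.trigger_by_id()
    for ev in doc.events:
        etype = trig_index[ev.trigger].event_type
        parts = [f"{ev.id}\t{etype}:{ev.trigger}"]
        role_counts: dict[str, int] = {}
        for role, target in ev.args:
            role_counts[role] = role_counts.get(role, 0) + 1
            suffix = "" if role_counts[role] == 1 else str(role_counts[role])
            parts.append(f"{role}{suffix}:{target}")
        a2_lines.append(" ".join(parts))
    a1 = "".join(line + "\n" for line in a1_lines)
    a2 = "".join(line + "\n" for line in a2_lines)
    return a1, a2


def validate_structure(
    doc: Document, *, taxonomy: EventTaxonomy = DEFAULT_TAXONOMY
) -> list[str]:
    """Check every document invariant; violations are data, not exceptions.

    Returns an empty list iff the document is fully valid.  Each violation
    names the offending annotation id and the rule it breaks.
    """
    out: list[str] = []
    seen: set[str] = set()
    for ann in [*doc.entities, *doc.triggers, *doc.events]:
        if ann.id in seen:
            out.append(f"{ann.id}: duplicate annotation id")
        seen.add(ann.id)

    for ann in [*doc.entities, *doc.triggers]:
        if ann.span.end > len(doc.text):
            out.append(f"{ann.id}: span exceeds document length")
        elif ann.span.slice(doc.text) != ann.text:
            out.append(f"{ann.id}: span text mismatch")

    for trig in doc.triggers:
        if trig.event_type not in taxonomy.event_types:
            out.append(f"{trig.id}: unknown event type {trig.event_type!r}")

    ent_ids = {e.id for e in doc.entities}
    trig_index = doc.trigger_by_id()
    event_ids = {e.id for e in doc.events}
    for ev in doc.events:
        trig = trig_index.get(ev.trigger)
        if trig is None:
            out.append(f"{ev.id}: dangling trigger reference {ev.trigger}")
            continue
        etype = trig.event_type
        permitted = (
            taxonomy.permitted_roles(etype)
            if etype in taxonomy.event_types
            else ()
        )
        roles_seen: list[str] = []
        for role, target in ev.args:
            roles_seen.append(role)
            if role not in permitted:
                out.append(f"{ev.id}: role {role} not permitted for {etype}")
            if target in event_ids:
                if not taxonomy.allows_event_argument(etype, role):
                    out.append(
                        f"{ev.id}: role {role} of {etype} may not take an "
                        f"event-valued argument"
                    )
            elif target not in ent_ids:
                out.append(f"{ev.id}: dangling argument reference {target}")
        if etype in taxonomy.event_types:
            for required in taxonomy.required_roles.get(etype, ()):
                if required not in roles_seen:
                    out.append(f"{ev.id}: missing required role {required}")

    if not nx.is_directed_acyclic_graph(_event_graph(doc)):
        cycle = nx.find_cycle(_event_graph(doc))
        offenders = sorted({a for a, _ in cycle})
        out.append(f"{','.join(offenders)}: event reference cycle")
    return out


# -- file-tree helpers -----------------------------------------------------


def read_document(stem: str, *, taxonomy: EventTaxonomy = DEFAULT_TAXONOMY) -> Document:
    """Read ``stem.txt`` / ``stem.a1`` / optional ``stem.a2`` from disk."""
    import os

    with open(stem + ".txt", "r", encoding="utf-8") as fh:
        txt = fh.read()
    with open(stem + ".a1", "r", encoding="utf-8") as fh:
        a1 = fh.read()
    a2 = None
    if os.path.exists(stem + ".a2"):
        with open(stem + ".a2", "r", encoding="utf-8") as fh:
            a2 = fh.read()
    return parse_standoff(
        txt, a1, a2, doc_id=os.path.basename(stem), taxonomy=taxonomy
    )


def read_corpus_dir(
    path: str, *, taxonomy: EventTaxonomy = DEFAULT_TAXONOMY
) -> list[Document]:
    """Read every ``*.txt`` (with siblings) under ``path``, sorted by name."""
    import glob
    import os

    docs = []
    for txt_path in sorted(glob.glob(os.path.join(path, "*.txt"))):
        docs.append(read_document(txt_path[:-4], taxonomy=taxonomy))
    return docs


def write_corpus_dir(
    docs: list[Document], path: str, *, taxonomy: EventTaxonomy = DEFAULT_TAXONOMY
) -> None:
    import os

    os.makedirs(path, exist_ok=True)
    for doc in docs:
        stem = os.path.join(path, doc.doc_id)
        a1, a2 = write_standoff(doc, taxonomy=taxonomy)
        with open(stem + ".txt", "w", encoding="utf-8") as fh:
            fh.write(doc.text)
        with open(stem + ".a1", "w", encoding="utf-8") as fh:
            fh.write(a1)
        with open(stem + ".a2", "w", encoding="utf-8") as fh:
            fh.write(a2)
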