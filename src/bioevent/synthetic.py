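"""Seed-reproducible synthetic standoff corpora for event extraction.

The generator emulates the statistical structure of a multi-level event
corpus without any real text: sentences with typed entities; simple events
(one trigger, one Theme); multi-Theme Binding events; Regulation-family
events whose Theme/Cause may be an entity or a nested event; and an
event-type skew dominated by the regulation family.  Crucially for the
sentence-embedding pathway, a configurable fraction of trigger words is
*ambiguous* — shared between two event types — and each use is
disambiguated deterministically by type-specific cue words placed elsewhere
in the sentence, so trigger typing is learnable from sentence context.

Sentences are token templates joined by single spaces, so every annotation
aligns exactly with whole tokens and every document round-trips through
standoff serialization unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .standoff import Document, Entity, EventAnn, Span, TriggerAnn, write_corpus_dir
from .taxonomy import DEFAULT_TAXONOMY, REGULATION_FAMILY, EventTaxonomy

# -- lexicons --------------------------------------------------------------

TRIGGER_LEXICON: dict[str, tuple[str, ...]] = {
    "Gene_expression": ("expressed", "over-expression", "production", "gene expression"),
    "Transcription": ("transcribed", "transcription"),
    "Phosphorylation": ("phosphorylation", "phosphorylated"),
    "Dephosphorylation": ("dephosphorylation",),
    "Catabolism": ("degradation", "catabolism"),
    "Synthesis": ("synthesis", "synthesized"),
    "Localization": ("localization", "secretion", "migration"),
    "Cell_proliferation": ("proliferation", "expansion"),
    "Development": ("development", "differentiation"),
    "Blood_vessel_development": ("angiogenesis", "vascularization", "neovascularization"),
    "Growth": ("enlargement", "hypertrophy"),
    "Death": ("apoptosis", "necrosis"),
    "Breakdown": ("degeneration", "rupture"),
    "Remodeling": ("remodeling", "reorganization"),
    "Planned_process": ("treatment", "administration", "injection"),
    "Binding": ("binding", "association", "ligation"),
    "Regulation": ("regulation", "modulation", "control"),
    "Positive_regulation": ("activation", "promote", "induces", "up-regulation"),
    "Negative_regulation": ("inhibition", "suppression", "down-regulation"),
}

#: trigger words shared between two event types; the sentence's cue words
#: decide which reading is correct.
AMBIGUOUS_TRIGGERS: dict[str, tuple[str, str]] = {
    "induction": ("Gene_expression", "Positive_regulation"),
    "formation": ("Blood_vessel_development", "Development"),
    "loss": ("Death", "Breakdown"),
    "turnover": ("Catabolism", "Remodeling"),
    "interaction": ("Binding", "Regulation"),
    "growth": ("Growth", "Cell_proliferation"),
    "targeting": ("Localization", "Negative_regulation"),
    "modification": ("Phosphorylation", "Planned_process"),
    "accumulation": ("Synthesis", "Transcription"),
}

CUE_LEXICON: dict[str, tuple[str, ...]] = {
    "Gene_expression": ("mRNA", "protein", "levels"),
    "Transcription": ("promoter", "transcript"),
    "Phosphorylation": ("kinase", "tyrosine"),
    "Dephosphorylation": ("phosphatase", "serine"),
    "Catabolism": ("proteasome", "lysosomal"),
    "Synthesis": ("ribosomal", "de-novo"),
    "Localization": ("nucleus", "membrane", "cytoplasm"),
    "Cell_proliferation": ("mitotic", "cell-cycle"),
    "Development": ("embryonic", "lineage"),
    "Blood_vessel_development": ("vessels", "capillary", "endothelial"),
    "Growth": ("size", "mass"),
    "Death": ("caspase", "viability"),
    "Breakdown": ("matrix", "collagen"),
    "Remodeling": ("architecture", "scaffold"),
    "Planned_process": ("patients", "dose", "surgery"),
    "Binding": ("complex", "affinity"),
    "Regulation": ("pathway", "feedback"),
    "Positive_regulation": ("role", "signaling", "enhancer"),
    "Negative_regulation": ("blockade", "antagonist"),
}

GENE_ENTITIES = (
    "Bmi-1", "TRAF2", "TRAF3", "CD40", "p53", "VEGF", "IL-2", "IL-6",
    "TNF-alpha", "NF-kappaB", "STAT3", "AKT1", "ERK2", "TGF-beta", "EGFR",
    "HIF-1alpha", "MMP-9", "BCL-2", "FGF2", "PDGF", "Notch1", "Wnt5a",
    "COX-2", "iNOS", "E-selectin", "CXCR4", "PTEN", "MYC",
)
CELL_ENTITIES = ("fibroblasts", "monocytes", "macrophages", "lymphocytes")
TISSUE_ENTITIES = ("endothelium", "epithelium")

FILLERS = (
    "the", "of", "was", "observed", "in", "detected", "by", "shown", "to",
    "is", "sufficient", "we", "found", "that", "through", "via", "these",
    "data", "show", "shows", "requires", "cells", "assays", "a", "dependent",
    "manner", "and", "marked", "significant", "but", "not", ".",
)

#: type skew: regulation family dominant among complex types, a long tail
#: of simple types, loosely imitating a multi-level corpus distribution.
COMPLEX_WEIGHTS = {
    "Positive_regulation": 0.35,
    "Negative_regulation": 0.25,
    "Regulation": 0.20,
    "Binding": 0.20,
}
SIMPLE_WEIGHTS = {
    "Gene_expression": 0.18,
    "Planned_process": 0.12,
    "Localization": 0.09,
    "Cell_proliferation": 0.07,
    "Development": 0.07,
    "Blood_vessel_development": 0.06,
    "Death": 0.06,
    "Growth": 0.05,
    "Breakdown": 0.05,
    "Remodeling": 0.05,
    "Synthesis": 0.04,
    "Transcription": 0.04,
    "Catabolism": 0.04,
    "Phosphorylation": 0.04,
    "Dephosphorylation": 0.04,
}


@dataclass
class GeneratorConfig:
    n_sentences: int = 500
    sentences_per_doc: int = 4
    ambiguity_rate: float = 0.3
    complex_fraction: float = 0.55
    nesting_prob: float = 0.35
    binding_multi_theme_prob: float = 0.4
    cause_prob: float = 0.6
    distractor_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "ambiguity_rate",
            "complex_fraction",
            "nesting_prob",
            "binding_multi_theme_prob",
            "cause_prob",
            "distractor_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_sentences < 0 or self.sentences_per_doc < 1:
            raise ValueError("invalid corpus size configuration")


def vocabulary() -> list[str]:
    """Every token the generator can emit (~small, keeps models desk-scale)."""
    words: list[str] = []

    def add(w: str) -> None:
        for tok in w.split(" "):
            if tok not in words:
                words.append(tok)

    for lex in TRIGGER_LEXICON.values():
        for w in lex:
            add(w)
    for w in AMBIGUOUS_TRIGGERS:
        add(w)
    for lex in CUE_LEXICON.values():
        for w in lex:
            add(w)
    for w in (*GENE_ENTITIES, *CELL_ENTITIES, *TISSUE_ENTITIES, *FILLERS):
        add(w)
    return words


# -- sentence recipes ------------------------------------------------------


@dataclass
class _Sentence:
    tokens: list[str] = field(default_factory=list)
    entities: list[tuple[str, int, int]] = field(default_factory=list)  # etype, lo, hi
    triggers: list[tuple[str, int, int]] = field(default_factory=list)  # event type, lo, hi
    # events: (trigger index, [(role, ("ent"|"ev", index))]); order = build order
    events: list[tuple[int, list[tuple[str, tuple[str, int]]]]] = field(
        default_factory=list
    )

    def add_entity(self, name: str, etype: str) -> int:
        lo = len(self.tokens)
        self.tokens.extend(name.split(" "))
        self.entities.append((etype, lo, len(self.tokens)))
        return len(self.entities) - 1

    def add_trigger(self, phrase: str, event_type: str) -> int:
        lo = len(self.tokens)
        self.tokens.extend(phrase.split(" "))
        self.triggers.append((event_type, lo, len(self.tokens)))
        return len(self.triggers) - 1

    def words(self, *toks: str) -> None:
        self.tokens.extend(toks)


def _pick(rng: np.random.Generator, seq):
    return seq[rng.integers(len(seq))]


#: neutral connective tokens for the mid-sentence span separating the cue
#: region (sentence-initial) from the event clause (sentence-final) —
#: emulates the long biomedical sentences in which sentence-level context,
#: not the trigger's immediate neighbours, resolves trigger ambiguity.
_FILLER_POOL = (
    "we", "observed", "that", "these", "data", "in", "the", "of", "was",
    "shown", "by", "a", "marked", "significant", "and", "cells", "found",
)


def _cue_prefix(s: "_Sentence", rng: np.random.Generator, cues: list[str],
                min_fill: int = 6, max_fill: int = 14) -> None:
    """Sentence-initial cue words followed by a variable neutral span."""
    s.words("in")
    for cue in cues:
        s.words(cue)
    s.words("assays")
    for _ in range(int(rng.integers(min_fill, max_fill + 1))):
        s.words(_pick(rng, _FILLER_POOL))


def _trigger_word(rng: np.random.Generator, etype: str, ambiguity_rate: float) -> str:
    shared = [w for w, types in AMBIGUOUS_TRIGGERS.items() if etype in types]
    if shared and rng.random() < ambiguity_rate:
        return _pick(rng, shared)
    return _pick(rng, TRIGGER_LEXICON[etype])


def _gene(rng: np.random.Generator, exclude: set[str] = frozenset()) -> str:
    while True:
        g = _pick(rng, GENE_ENTITIES)
        if g not in exclude:
            return g


def _simple_clause(
    s: _Sentence, rng: np.random.Generator, etype: str, cfg: GeneratorConfig
) -> int:
    """Append one simple event clause; returns the event index."""
    w = _trigger_word(rng, etype, cfg.ambiguity_rate)
    cues = [_pick(rng, CUE_LEXICON[etype]), _pick(rng, CUE_LEXICON[etype])]
    _cue_prefix(s, rng, cues)
    gene = _gene(rng)
    variant = rng.integers(3)
    if variant == 0:
        s.words("the")
        ti = s.add_trigger(w, etype)
        s.words("of")
        ei = s.add_entity(gene, "Gene_or_gene_product")
        s.words("was", "observed")
    elif variant == 1:
        ei = s.add_entity(gene, "Gene_or_gene_product")
        ti = s.add_trigger(w, etype)
        s.words("was", "detected")
    else:
        s.words("marked")
        ti = s.add_trigger(w, etype)
        s.words("of")
        ei = s.add_entity(gene, "Gene_or_gene_product")
    if rng.random() < cfg.distractor_prob:
        s.words("in")
        s.add_entity(_pick(rng, CELL_ENTITIES), "Cell")
    s.events.append((ti, [("Theme", ("ent", ei))]))
    return len(s.events) - 1


def _binding_clause(
    s: _Sentence, rng: np.random.Generator, cfg: GeneratorConfig
) -> int:
    w = _trigger_word(rng, "Binding", cfg.ambiguity_rate)
    cues = [_pick(rng, CUE_LEXICON["Binding"]), _pick(rng, CUE_LEXICON["Binding"])]
    _cue_prefix(s, rng, cues)
    g1 = _gene(rng)
    s.words("the")
    ti = s.add_trigger(w, "Binding")
    s.words("of")
    e1 = s.add_entity(g1, "Gene_or_gene_product")
    args: list[tuple[str, tuple[str, int]]] = [("Theme", ("ent", e1))]
    used = {g1}
    if rng.random() < cfg.binding_multi_theme_prob:
        s.words("to")
        g2 = _gene(rng, used)
        used.add(g2)
        s.add_entity(g2, "Gene_or_gene_product")
        args.append(("Theme", ("ent", len(s.entities) - 1)))
    if rng.random() < cfg.distractor_prob:
        # hard negative: a gene mention adjacent to the trigger clause
        # that takes part in no event
        s.words("but", "not")
        s.add_entity(_gene(rng, used), "Gene_or_gene_product")
    s.words("was", "shown")
    s.events.append((ti, args))
    return len(s.events) - 1


def _regulation_clause(
    s: _Sentence, rng: np.random.Generator, etype: str, cfg: GeneratorConfig
) -> int:
    w = _trigger_word(rng, etype, cfg.ambiguity_rate)
    cue = _pick(rng, CUE_LEXICON[etype])
    if rng.random() < cfg.nesting_prob:
        # nested: inner simple event as Theme or Cause of the outer event;
        # both types' cue words sit in the sentence-initial cue region
        inner_type = _pick(rng, tuple(SIMPLE_WEIGHTS))
        w_in = _trigger_word(rng, inner_type, cfg.ambiguity_rate)
        cue_in = _pick(rng, CUE_LEXICON[inner_type])
        _cue_prefix(s, rng, [cue, cue_in])
        g1 = _gene(rng)
        if rng.random() < 0.5:  # Cause-nested (over-expression promotes X)
            e1 = s.add_entity(g1, "Gene_or_gene_product")
            ti_in = s.add_trigger(w_in, inner_type)
            s.words("is", "sufficient", "to")
            ti = s.add_trigger(w, etype)
            e2 = s.add_entity(_gene(rng, {g1}), "Gene_or_gene_product")
            s.events.append((ti_in, [("Theme", ("ent", e1))]))
            inner_idx = len(s.events) - 1
            s.events.append(
                (ti, [("Theme", ("ent", e2)), ("Cause", ("ev", inner_idx))])
            )
        else:  # Theme-nested
            s.words("the")
            ti = s.add_trigger(w, etype)
            s.words("of", "the")
            ti_in = s.add_trigger(w_in, inner_type)
            s.words("of")
            e1 = s.add_entity(g1, "Gene_or_gene_product")
            s.events.append((ti_in, [("Theme", ("ent", e1))]))
            inner_idx = len(s.events) - 1
            args: list[tuple[str, tuple[str, int]]] = [("Theme", ("ev", inner_idx))]
            if rng.random() < cfg.cause_prob:
                s.words("by")
                ec = s.add_entity(_gene(rng, {g1}), "Gene_or_gene_product")
                args.append(("Cause", ("ent", ec)))
            s.events.append((ti, args))
        return len(s.events) - 1
    # flat regulation over entities
    _cue_prefix(s, rng, [cue, _pick(rng, CUE_LEXICON[etype])])
    g1 = _gene(rng)
    args = []
    if rng.random() < cfg.cause_prob:
        ec = s.add_entity(g1, "Gene_or_gene_product")
        args.append(("Cause", ("ent", ec)))
        s.words("shows")
    else:
        s.words("we", "show")
    s.words("the")
    ti = s.add_trigger(w, etype)
    s.words("of")
    g2 = _gene(rng, {g1})
    et = s.add_entity(g2, "Gene_or_gene_product")
    args.insert(0, ("Theme", ("ent", et)))
    if rng.random() < cfg.distractor_prob:
        s.words("but", "not")
        s.add_entity(_gene(rng, {g1, g2}), "Gene_or_gene_product")
    s.events.append((ti, args))
    return len(s.events) - 1


def _make_sentence(
    rng: np.random.Generator, etype: str, cfg: GeneratorConfig
) -> _Sentence:
    s = _Sentence()
    if etype == "Binding":
        _binding_clause(s, rng, cfg)
    elif etype in REGULATION_FAMILY:
        _regulation_clause(s, rng, etype, cfg)
    else:
        _simple_clause(s, rng, etype, cfg)
    s.words(".")
    return s


def _sample_types(rng: np.random.Generator, cfg: GeneratorConfig) -> list[str]:
    simple = list(SIMPLE_WEIGHTS)
    complex_ = list(COMPLEX_WEIGHTS)
    p_simple = np.array([SIMPLE_WEIGHTS[t] for t in simple])
    p_complex = np.array([COMPLEX_WEIGHTS[t] for t in complex_])
    types: list[str] = []
    all_types = simple + complex_
    for i in range(cfg.n_sentences):
        if cfg.n_sentences >= 100 and i < len(all_types):
            types.append(all_types[i])  # guarantee full type coverage
            continue
        if rng.random() < cfg.complex_fraction:
            types.append(complex_[rng.choice(len(complex_), p=p_complex)])
        else:
            types.append(simple[rng.choice(len(simple), p=p_simple)])
    return types


def generate_corpus(
    config: GeneratorConfig,
    *,
    taxonomy: EventTaxonomy = DEFAULT_TAXONOMY,
    out_dir: str | None = None,
) -> list[Document]:
    """Generate a corpus of documents (and optionally write standoff files)."""
    rng = np.random.default_rng(config.seed)
    types = _sample_types(rng, config)
    docs: list[Document] = []
    for d0 in range(0, len(types), config.sentences_per_doc):
        doc_types = types[d0 : d0 + config.sentences_per_doc]
        doc = _realize_document(
            rng, doc_types, config, doc_id=f"doc{d0 // config.sentences_per_doc:04d}"
        )
        docs.append(doc)
    if out_dir is not None:
        write_corpus_dir(docs, out_dir, taxonomy=taxonomy)
    return docs


def _realize_document(
    rng: np.random.Generator,
    sent_types: list[str],
    cfg: GeneratorConfig,
    doc_id: str,
) -> Document:
    text_parts: list[str] = []
    entities: list[Entity] = []
    triggers: list[TriggerAnn] = []
    events: list[EventAnn] = []
    offset = 0
    t_next = 1
    e_next = 1
    for etype in sent_types:
        s = _make_sentence(rng, etype, cfg)
        starts: list[int] = []
        pos = offset
        for k, tok in enumerate(s.tokens):
            starts.append(pos)
            pos += len(tok) + 1
        sent_text = " ".join(s.tokens)

        def span_of(lo: int, hi: int) -> Span:
            return Span(starts[lo], starts[hi - 1] + len(s.tokens[hi - 1]))

        ent_ids: list[str] = []
        for etype_e, lo, hi in s.entities:
            sp = span_of(lo, hi)
            entities.append(
                Entity(f"T{t_next}", etype_e, sp, " ".join(s.tokens[lo:hi]))
            )
            ent_ids.append(f"T{t_next}")
            t_next += 1
        trig_ids: list[str] = []
        for ttype, lo, hi in s.triggers:
            sp = span_of(lo, hi)
            triggers.append(
                TriggerAnn(f"T{t_next}", ttype, sp, " ".join(s.tokens[lo:hi]))
            )
            trig_ids.append(f"T{t_next}")
            t_next += 1
        ev_ids: list[str] = []
        for trig_idx, args in s.events:
            resolved = tuple(
                (role, ent_ids[i] if kind == "ent" else ev_ids[i])
                for role, (kind, i) in args
            )
            events.append(EventAnn(f"E{e_next}", trig_ids[trig_idx], resolved))
            ev_ids.append(f"E{e_next}")
            e_next += 1
        text_parts.append(sent_text)
        offset = pos
    return Document(doc_id, " ".join(text_parts), entities, triggers, events)


# -- controlled corruption -------------------------------------------------

Edge = tuple[str, str, str, float]


def corrupt_predictions(
    docs: list[Document], noise_rate: float, seed: int = 0
) -> list[tuple[list[TriggerAnn], list[Edge]]]:
    """Degrade gold annotations into imperfect 'predictions'.

    Each gold trigger is independently corrupted with probability
    ``noise_rate``: deleted or retyped (50/50).  Gold argument edges are
    corrupted the same way (deleted or role-flipped); edges of deleted
    triggers disappear with them.  ``noise_rate = 0`` reproduces gold.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    all_types = list(TRIGGER_LEXICON)
    out: list[tuple[list[TriggerAnn], list[Edge]]] = []
    for doc in docs:
        kept: list[TriggerAnn] = []
        alive: set[str] = set()
        retyped: set[str] = set()
        for trig in doc.triggers:
            if rng.random() < noise_rate:
                if rng.random() < 0.5:
                    continue  # deletion
                wrong = _pick(rng, [t for t in all_types if t != trig.event_type])
                kept.append(TriggerAnn(trig.id, wrong, trig.span, trig.text))
                alive.add(trig.id)
                retyped.add(trig.id)
                continue
            kept.append(trig)
            alive.add(trig.id)
        edges: list[Edge] = []
        ev_index = doc.event_by_id()
        for ev in doc.events:
            if ev.trigger not in alive:
                continue
            for role, target in ev.args:
                if target.startswith("E"):
                    inner = ev_index[target]
                    target = inner.trigger
                    if target not in alive:
                        continue
                if rng.random() < noise_rate:
                    if rng.random() < 0.5:
                        continue
                    role = "Cause" if role == "Theme" else "Theme"
                edges.append((ev.trigger, target, role, 1.0))
        out.append((kept, edges))
    return out
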