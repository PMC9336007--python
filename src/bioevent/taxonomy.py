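"""Event-type taxonomy and role configuration.

The taxonomy is configuration, not code: which event types exist, which of
them are *complex* (multi-argument, possibly event-valued arguments), and
which argument roles each type permits.  The default mirrors the MLEE corpus:
19 event types grouped into anatomical, molecular, general and planned
categories, with the complex types {Binding, Regulation, Positive_regulation,
Negative_regulation} dominating the event distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: The 19 MLEE event types.  Regulation-family types may take event-valued
#: Theme/Cause arguments; Binding may take multiple Theme entities.
MLEE_SIMPLE_TYPES: tuple[str, ...] = (
    "Cell_proliferation",
    "Development",
    "Blood_vessel_development",
    "Growth",
    "Death",
    "Breakdown",
    "Remodeling",
    "Synthesis",
    "Gene_expression",
    "Transcription",
    "Catabolism",
    "Phosphorylation",
    "Dephosphorylation",
    "Localization",
    "Planned_process",
)

MLEE_COMPLEX_TYPES: tuple[str, ...] = (
    "Binding",
    "Regulation",
    "Positive_regulation",
    "Negative_regulation",
)

REGULATION_FAMILY: frozenset[str] = frozenset(
    {"Regulation", "Positive_regulation", "Negative_regulation"}
)


@dataclass(frozen=True)
class EventTaxonomy:
    """Closed set of event types with their argument-role constraints.

    Parameters
    ----------
    simple_types, complex_types
        Partition of the event-type alphabet.  Complex types build events
        with multiple and/or event-valued arguments.
    roles
        Permitted role names per event type.  ``required_roles`` lists roles
        an assembled event must carry (Theme, for every MLEE type).
    event_valued_roles
        Roles that may point at another event rather than an entity, per
        type.  Empty for simple types.
    """

    simple_types: tuple[str, ...] = MLEE_SIMPLE_TYPES
    complex_types: tuple[str, ...] = MLEE_COMPLEX_TYPES
    roles: dict[str, tuple[str, ...]] = field(default_factory=dict)
    required_roles: dict[str, tuple[str, ...]] = field(default_factory=dict)
    event_valued_roles: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.simple_types) & set(self.complex_types)
        if overlap:
            raise ValueError(f"types in both classes: {sorted(overlap)}")
        if not self.roles:
            roles: dict[str, tuple[str, ...]] = {}
            required: dict[str, tuple[str, ...]] = {}
            event_valued: dict[str, tuple[str, ...]] = {}
            for t in self.simple_types:
                roles[t] = ("Theme",)
                required[t] = ("Theme",)
                event_valued[t] = ()
            roles["Binding"] = ("Theme",)
            required["Binding"] = ("Theme",)
            event_valued["Binding"] = ()
            for t in REGULATION_FAMILY & set(self.complex_types):
                roles[t] = ("Theme", "Cause")
                required[t] = ("Theme",)
                event_valued[t] = ("Theme", "Cause")
            object.__setattr__(self, "roles", roles)
            object.__setattr__(self, "required_roles", required)
            object.__setattr__(self, "event_valued_roles", event_valued)

    @property
    def event_types(self) -> tuple[str, ...]:
        return self.simple_types + self.complex_types

    @property
    def role_set(self) -> tuple[str, ...]:
        seen: list[str] = []
        for rs in self.roles.values():
            for r in rs:
                if r not in seen:
                    seen.append(r)
        return tuple(seen)

    def is_complex(self, event_type: str) -> bool:
        if event_type in self.complex_types:
            return True
        if event_type in self.simple_types:
            return False
        raise KeyError(f"unknown event type: {event_type!r}")

    def permitted_roles(self, event_type: str) -> tuple[str, ...]:
        return self.roles[event_type]

    def allows_event_argument(self, event_type: str, role: str) -> bool:
        return role in self.event_valued_roles.get(event_type, ())

    # -- serialization ----------------------------------------------------

    def to_yaml(self) -> str:
        payload = {
            "simple_types": list(self.simple_types),
            "complex_types": list(self.complex_types),
            "roles": {k: list(v) for k, v in self.roles.items()},
            "required_roles": {k: list(v) for k, v in self.required_roles.items()},
            "event_valued_roles": {
                k: list(v) for k, v in self.event_valued_roles.items()
            },
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "EventTaxonomy":
        payload = yaml.safe_load(text)
        return cls(
            simple_types=tuple(payload["simple_types"]),
            complex_types=tuple(payload["complex_types"]),
            roles={k: tuple(v) for k, v in payload.get("roles", {}).items()},
            required_roles={
                k: tuple(v) for k, v in payload.get("required_roles", {}).items()
            },
            event_valued_roles={
                k: tuple(v)
                for k, v in payload.get("event_valued_roles", {}).items()
            },
        )

    @classmethod
    def from_yaml_file(cls, path: str) -> "EventTaxonomy":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_yaml(fh.read())


DEFAULT_TAXONOMY = EventTaxonomy()
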