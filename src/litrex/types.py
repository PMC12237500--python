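"""Core domain types for document-level biomedical relation extraction.

The task is binary: given a document and a typed entity pair (head, tail),
decide whether the dataset's relation (chemical-induces-disease,
gene-disease association, drug-adverse-event, ...) holds.  Everything
downstream — question construction, knowledge retrieval, prompting,
scoring — operates on these containers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

BinaryLabel = Literal["positive", "negative"]
ParseStatus = Literal["parsed", "unparseable"]

_SLOT_RE = re.compile(r"\{(head|tail)\}")


@dataclass(frozen=True)
class RelationSchema:
    """A dataset's relation definition: entity types, label codes, wording.

    ``question_template`` must contain exactly one ``{head}`` and one
    ``{tail}`` slot; ``cot_template_ref`` names a chain-of-thought asset.
    ``negative_label`` may be None for corpora that annotate positives only.
    """

    dataset_name: str
    head_type: str
    tail_type: str
    positive_label: str
    question_template: str
    negative_label: Optional[str] = None
    cot_template_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if self.negative_label is not None and self.negative_label == self.positive_label:
            raise ValueError("positive_label and negative_label must differ")
        slots = [m.group(1) for m in _SLOT_RE.finditer(self.question_template)]
        if slots.count("head") != 1 or slots.count("tail") != 1:
            raise ValueError(
                "question_template must contain exactly one {head} and one {tail} slot: "
                f"{self.question_template!r}"
            )

    @property
    def label_codes(self) -> set[str]:
        codes = {self.positive_label}
        if self.negative_label is not None:
            codes.add(self.negative_label)
        return codes


@dataclass(frozen=True)
class EntityMention:
    """One textual occurrence of an entity.

    ``start``/``end`` are 0-based half-open character offsets into the
    passage at ``passage_index``.
    """

    surface: str
    start: int
    end: int
    passage_index: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.passage_index < 0:
            raise ValueError("passage_index must be >= 0")


@dataclass(frozen=True)
class Entity:
    """A normalized entity (e.g. a MeSH ID or gene symbol) with its mentions."""

    entity_id: str
    type: str
    mentions: tuple[EntityMention, ...]

    def __post_init__(self) -> None:
        if not self.mentions:
            raise ValueError(f"entity {self.entity_id!r} has no mentions")

    @property
    def canonical_surface(self) -> str:
        """Surface form used to fill question slots: the first mention's."""
        return self.mentions[0].surface


@dataclass(frozen=True)
class Document:
    doc_id: str
    title: str
    passages: tuple[str, ...]
    entities: tuple[Entity, ...]
    gold_labels: frozenset[tuple[str, str, str]]  # (head_id, tail_id, label code)

    def __post_init__(self) -> None:
        ids = {e.entity_id for e in self.entities}
        for head, tail, label in self.gold_labels:
            if head not in ids or tail not in ids:
                raise ValueError(
                    f"document {self.doc_id!r}: gold label ({head}, {tail}, {label}) "
                    "references an undeclared entity"
                )
        for ent in self.entities:
            for m in ent.mentions:
                if m.passage_index >= len(self.passages):
                    raise ValueError(
                        f"document {self.doc_id!r}: mention of {ent.entity_id!r} points at "
                        f"passage {m.passage_index} but only {len(self.passages)} exist"
                    )
                if m.end > len(self.passages[m.passage_index]):
                    raise ValueError(
                        f"document {self.doc_id!r}: mention span [{m.start}, {m.end}) of "
                        f"{ent.entity_id!r} exceeds passage length "
                        f"{len(self.passages[m.passage_index])}"
                    )

    def validate_labels(self, schema: RelationSchema) -> None:
        for _, _, label in self.gold_labels:
            if label not in schema.label_codes:
                raise ValueError(
                    f"document {self.doc_id!r}: unknown label code {label!r} "
                    f"(schema {schema.dataset_name!r} defines {sorted(schema.label_codes)})"
                )

    def entities_of_type(self, type_: str) -> tuple[Entity, ...]:
        return tuple(e for e in self.entities if e.type == type_)

    @property
    def full_text(self) -> str:
        return "\n".join((self.title, *self.passages)) if self.title else "\n".join(self.passages)


@dataclass(frozen=True)
class RelationInstance:
    """One candidate pair to classify, with its gold binary answer."""

    doc_id: str
    head: Entity
    tail: Entity
    gold: BinaryLabel

    def check_types(self, schema: RelationSchema) -> None:
        if self.head.type != schema.head_type or self.tail.type != schema.tail_type:
            raise ValueError(
                f"instance ({self.head.entity_id}, {self.tail.entity_id}) types "
                f"({self.head.type}, {self.tail.type}) do not match schema "
                f"({schema.head_type}, {schema.tail_type})"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.doc_id, self.head.entity_id, self.tail.entity_id)


@dataclass(frozen=True)
class Prediction:
    """A parsed model decision for one instance.

    When the completion could not be parsed, ``predicted`` holds the
    configured default label (negative unless overridden) and
    ``parse_status`` records the failure.
    """

    instance: RelationInstance
    predicted: BinaryLabel
    parse_status: ParseStatus = "parsed"
    raw_output_ref: Optional[str] = None


def instances_by_key(instances: Iterable[RelationInstance]) -> dict[tuple[str, str, str], RelationInstance]:
    out: dict[tuple[str, str, str], RelationInstance] = {}
    for inst in instances:
        if inst.key in out:
            raise ValueError(f"duplicate instance key {inst.key}")
        out[inst.key] = inst
    return out
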