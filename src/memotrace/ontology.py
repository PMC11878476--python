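"""Prodromal dementia symptom ontology, annotated notes, and standoff I/O.

The ontology has 9 entity types and 9 relation types.  Entities are the
clinical things written in a note: the memory-loss symptom itself (SX), a
dementia diagnosis mention (DX), temporal anchors and durations, worsening
status changes, co-occurring symptoms, cognitive test results, the family
caregiver relation, and cognition-enhancing medications (RX).  Relations
attach the satellite information to its SX/DX (or RX) trigger, e.g.
``HAS_DURATION_INFO`` links "memory loss" to "2 years".

Annotations are persisted in the BRAT standoff dialect: one ``.txt`` file
with the note text, one ``.ann`` file with ``T`` (entity) and ``R``
(relation) lines keyed by 0-based half-open character offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from enum import Enum
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import yaml

from .text import Token, tokenize

logger = logging.getLogger(__name__)


class EntityLabel(str, Enum):
    """The 9 entity types of the prodromal dementia ontology."""

    SX = "SX"                                  # memory loss symptom
    DX = "DX"                                  # dementia diagnosis
    TEMPORAL = "TEMPORAL"                      # calendar anchor
    DURATION = "DURATION"                      # elapsed-time expression
    STATUS_CHANGE_WORSE = "STATUS_CHANGE_WORSE"
    OTHER_SYMPTOM = "OTHER_SYMPTOM"
    COG_TEST_RESULT = "COG_TEST_RESULT"
    CAREGIVER_RELATION = "CAREGIVER_RELATION"
    RX = "RX"                                  # cognition-enhancing medication


class RelationLabel(str, Enum):
    """The 9 relation types linking satellite entities to their triggers."""

    HAS_COMPLAINT_DATE = "HAS_COMPLAINT_DATE"
    HAS_DIAGNOSIS_DATE = "HAS_DIAGNOSIS_DATE"
    HAS_OTHER_SYMPTOM_INFO = "HAS_OTHER_SYMPTOM_INFO"
    HAS_STATUS_CHANGE_INFO = "HAS_STATUS_CHANGE_INFO"
    HAS_DURATION_INFO = "HAS_DURATION_INFO"
    HAS_TEST_INFO = "HAS_TEST_INFO"
    HAS_CAREGIVER_INFO = "HAS_CAREGIVER_INFO"
    HAS_TREATMENT_INFO = "HAS_TREATMENT_INFO"
    HAS_EFFECTS = "HAS_EFFECTS"


#: Human-readable names as used in the clinical annotation guideline.
ENTITY_DISPLAY_NAMES: Dict[EntityLabel, str] = {
    EntityLabel.SX: "memory loss symptom (Sx)",
    EntityLabel.DX: "dementia diagnosis (Dx)",
    EntityLabel.TEMPORAL: "temporal",
    EntityLabel.DURATION: "duration",
    EntityLabel.STATUS_CHANGE_WORSE: "status change: worse",
    EntityLabel.OTHER_SYMPTOM: "other symptoms",
    EntityLabel.COG_TEST_RESULT: "cognitive test result",
    EntityLabel.CAREGIVER_RELATION: "caregiver relation",
    EntityLabel.RX: "cognition enhancing medication (Rx)",
}

RELATION_DISPLAY_NAMES: Dict[RelationLabel, str] = {
    RelationLabel.HAS_COMPLAINT_DATE: "has complaint date",
    RelationLabel.HAS_DIAGNOSIS_DATE: "has diagnosis date",
    RelationLabel.HAS_OTHER_SYMPTOM_INFO: "has other symptom information",
    RelationLabel.HAS_STATUS_CHANGE_INFO: "has status change information",
    RelationLabel.HAS_DURATION_INFO: "has duration information",
    RelationLabel.HAS_TEST_INFO: "has test information",
    RelationLabel.HAS_CAREGIVER_INFO: "has caregiver information",
    RelationLabel.HAS_TREATMENT_INFO: "has treatment information",
    RelationLabel.HAS_EFFECTS: "has effects",
}


class StandoffParseError(ValueError):
    """Malformed standoff line (carries the 1-based line number)."""


class AnnotationIntegrityError(ValueError):
    """Annotation contradicts the note text (offset/surface mismatch, bad ids)."""


class SchemaError(ValueError):
    """Label or relation not permitted by the ontology schema."""


@dataclass(frozen=True, order=True)
class Span:
    """0-based half-open character span ``[start, end)`` over code points."""

    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Entity:
    id: str
    label: EntityLabel
    span: Span
    surface: str


@dataclass(frozen=True)
class Relation:
    id: str
    label: RelationLabel
    head: str  # Entity id
    tail: str  # Entity id

    def __post_init__(self):
        if self.head == self.tail:
            raise ValueError(f"relation {self.id}: head == tail ({self.head})")


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    return datetime.strptime(str(value), "%Y-%m-%d").date()


@dataclass
class AnnotatedNote:
    """One clinical note with its metadata, entities and relations."""

    doc_id: str
    text: str
    patient_id: str = ""
    note_date: Optional[date] = None
    department: str = "other"
    entities: List[Entity] = field(default_factory=list)
    relations: List[Relation] = field(default_factory=list)

    def __post_init__(self):
        if self.note_date is not None:
            self.note_date = _parse_date(self.note_date)
        self.validate()

    def validate(self) -> None:
        ids: Set[str] = set()
        for e in self.entities:
            if e.id in ids:
                raise AnnotationIntegrityError(
                    f"{self.doc_id}: duplicate entity id {e.id}")
            ids.add(e.id)
            if e.span.end > len(self.text):
                raise AnnotationIntegrityError(
                    f"{self.doc_id}/{e.id}: span {e.span} exceeds text length "
                    f"{len(self.text)}")
            actual = self.text[e.span.start:e.span.end]
            if actual != e.surface:
                raise AnnotationIntegrityError(
                    f"{self.doc_id}/{e.id}: surface {e.surface!r} != text slice "
                    f"{actual!r} at [{e.span.start}, {e.span.end})")
        rids: Set[str] = set()
        for r in self.relations:
            if r.id in rids:
                raise AnnotationIntegrityError(
                    f"{self.doc_id}: duplicate relation id {r.id}")
            rids.add(r.id)
            for eid in (r.head, r.tail):
                if eid not in ids:
                    raise AnnotationIntegrityError(
                        f"{self.doc_id}/{r.id}: unresolved entity id {eid}")

    def entity_by_id(self, eid: str) -> Entity:
        for e in self.entities:
            if e.id == eid:
                return e
        raise KeyError(eid)

    def with_entities(self, entities: Sequence[Entity],
                      relations: Sequence[Relation] = ()) -> "AnnotatedNote":
        return AnnotatedNote(
            doc_id=self.doc_id, text=self.text, patient_id=self.patient_id,
            note_date=self.note_date, department=self.department,
            entities=list(entities), relations=list(relations))


Pair = Tuple[EntityLabel, EntityLabel]

#: Head/tail compatibility of the ontology graph.  SX and DX are the
#: triggers; satellites hang off them, except HAS_EFFECTS where the
#: medication is the head.
DEFAULT_COMPATIBILITY: Dict[RelationLabel, FrozenSet[Pair]] = {
    RelationLabel.HAS_COMPLAINT_DATE: frozenset(
        {(EntityLabel.SX, EntityLabel.TEMPORAL)}),
    RelationLabel.HAS_DIAGNOSIS_DATE: frozenset(
        {(EntityLabel.DX, EntityLabel.TEMPORAL)}),
    RelationLabel.HAS_OTHER_SYMPTOM_INFO: frozenset(
        {(EntityLabel.SX, EntityLabel.OTHER_SYMPTOM)}),
    RelationLabel.HAS_STATUS_CHANGE_INFO: frozenset(
        {(EntityLabel.SX, EntityLabel.STATUS_CHANGE_WORSE)}),
    RelationLabel.HAS_DURATION_INFO: frozenset(
        {(EntityLabel.SX, EntityLabel.DURATION)}),
    RelationLabel.HAS_TEST_INFO: frozenset(
        {(EntityLabel.SX, EntityLabel.COG_TEST_RESULT)}),
    RelationLabel.HAS_CAREGIVER_INFO: frozenset(
        {(EntityLabel.SX, EntityLabel.CAREGIVER_RELATION)}),
    RelationLabel.HAS_TREATMENT_INFO: frozenset(
        {(EntityLabel.SX, EntityLabel.RX)}),
    RelationLabel.HAS_EFFECTS: frozenset(
        {(EntityLabel.RX, EntityLabel.SX),
         (EntityLabel.RX, EntityLabel.STATUS_CHANGE_WORSE)}),
}


@dataclass
class OntologySchema:
    """Entity/relation label sets plus the relation compatibility map."""

    entity_labels: Tuple[EntityLabel, ...] = tuple(EntityLabel)
    relation_labels: Tuple[RelationLabel, ...] = tuple(RelationLabel)
    compatibility: Dict[RelationLabel, FrozenSet[Pair]] = field(
        default_factory=lambda: dict(DEFAULT_COMPATIBILITY))

    def __post_init__(self):
        for rel in self.relation_labels:
            if not self.compatibility.get(rel):
                raise SchemaError(f"relation {rel.value} has no compatible pair")

    def compatible(self, rel: RelationLabel, head: EntityLabel,
                   tail: EntityLabel) -> bool:
        return (head, tail) in self.compatibility.get(rel, frozenset())

    def relation_for(self, head: EntityLabel,
                     tail: EntityLabel) -> Optional[RelationLabel]:
        """The relation implied by a (head, tail) label pair, if unique."""
        hits = [r for r, pairs in self.compatibility.items()
                if (head, tail) in pairs]
        return hits[0] if len(hits) == 1 else (hits[0] if hits else None)

    def validate_note(self, note: AnnotatedNote) -> None:
        ents = {e.id: e for e in note.entities}
        for r in note.relations:
            if not self.compatible(r.label, ents[r.head].label,
                                   ents[r.tail].label):
                raise SchemaError(
                    f"{note.doc_id}/{r.id}: {r.label.value} incompatible with "
                    f"{ents[r.head].label.value} -> {ents[r.tail].label.value}")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "entity_labels": [e.value for e in self.entity_labels],
            "relation_labels": [r.value for r in self.relation_labels],
            "compatibility": {
                r.value: sorted([h.value, t.value] for h, t in pairs)
                for r, pairs in self.compatibility.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OntologySchema":
        return cls(
            entity_labels=tuple(EntityLabel(e) for e in d["entity_labels"]),
            relation_labels=tuple(RelationLabel(r) for r in d["relation_labels"]),
            compatibility={
                RelationLabel(r): frozenset(
                    (EntityLabel(h), EntityLabel(t)) for h, t in pairs)
                for r, pairs in d["compatibility"].items()
            },
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "OntologySchema":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Standoff I/O (BRAT dialect)
# ---------------------------------------------------------------------------

def parse_standoff(text: str, ann: str, *, doc_id: str = "doc",
                   patient_id: str = "", note_date=None,
                   department: str = "other",
                   schema: Optional[OntologySchema] = None) -> AnnotatedNote:
    """Parse a ``.ann`` standoff string against its note ``text``.

    Entity lines: ``T<k>\\t<LABEL> <start> <end>\\t<surface>``.
    Relation lines: ``R<k>\\t<LABEL> Arg1:T<i> Arg2:T<j>``.

    Raises :class:`StandoffParseError` for malformed lines (naming the line
    number), :class:`SchemaError` for unknown labels and
    :class:`AnnotationIntegrityError` when a surface string does not equal
    the text slice at its offsets.
    """
    entities: List[Entity] = []
    relations: List[Relation] = []
    for lineno, raw in enumerate(ann.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag.startswith("T"):
            if len(fields) != 3:
                raise StandoffParseError(
                    f"line {lineno}: expected 3 tab-separated fields, got "
                    f"{len(fields)}")
            parts = fields[1].split(" ")
            if len(parts) != 3:
                raise StandoffParseError(
                    f"line {lineno}: expected 'LABEL start end'")
            label_s, start_s, end_s = parts
            try:
                label = EntityLabel(label_s)
            except ValueError:
                raise SchemaError(
                    f"line {lineno}: unknown entity label {label_s!r}") from None
            try:
                span = Span(int(start_s), int(end_s))
            except ValueError as exc:
                raise StandoffParseError(f"line {lineno}: {exc}") from None
            entities.append(Entity(tag, label, span, fields[2]))
        elif tag.startswith("R"):
            if len(fields) != 2:
                raise StandoffParseError(
                    f"line {lineno}: expected 2 tab-separated fields")
            parts = fields[1].split(" ")
            if (len(parts) != 3 or not parts[1].startswith("Arg1:")
                    or not parts[2].startswith("Arg2:")):
                raise StandoffParseError(
                    f"line {lineno}: expected 'LABEL Arg1:Ti Arg2:Tj'")
            try:
                label = RelationLabel(parts[0])
            except ValueError:
                raise SchemaError(
                    f"line {lineno}: unknown relation label {parts[0]!r}"
                ) from None
            relations.append(Relation(tag, label, parts[1][5:], parts[2][5:]))
        else:
            raise StandoffParseError(
                f"line {lineno}: unsupported annotation type {tag!r}")
    note = AnnotatedNote(doc_id=doc_id, text=text, patient_id=patient_id,
                         note_date=note_date, department=department,
                         entities=entities, relations=relations)
    if schema is not None:
        schema.validate_note(note)
    return note


def write_standoff(note: AnnotatedNote) -> Tuple[str, str]:
    """Serialize a note to ``(text, ann)``; inverse of :func:`parse_standoff`."""
    lines = [
        f"{e.id}\t{e.label.value} {e.span.start} {e.span.end}\t{e.surface}"
        for e in note.entities
    ]
    lines += [
        f"{r.id}\t{r.label.value} Arg1:{r.head} Arg2:{r.tail}"
        for r in note.relations
    ]
    ann = "\n".join(lines)
    if lines:
        ann += "\n"
    return note.text, ann


# ---------------------------------------------------------------------------
# BIO conversion
# ---------------------------------------------------------------------------

@dataclass
class TaggedSequence:
    """Tokens with aligned BIO tags for one note."""

    doc_id: str
    tokens: List[Token]
    tags: List[str]

    def __post_init__(self):
        if len(self.tokens) != len(self.tags):
            raise ValueError("tokens and tags length mismatch")


def resolve_overlaps(entities: Sequence[Entity]) -> List[Entity]:
    """Drop entities overlapped by a longer (or equal, earlier) entity.

    Linear-chain tagging needs disjoint spans; the longer mention carries
    more information, so it wins.  Deterministic: sorted by (-length,
    start, id) and greedily accepted.
    """
    kept: List[Entity] = []
    for e in sorted(entities, key=lambda e: (-len(e.span), e.span.start, e.id)):
        if any(e.span.overlaps(k.span) for k in kept):
            logger.warning("dropping overlapping entity %s %r", e.id, e.surface)
            continue
        kept.append(e)
    return sorted(kept, key=lambda e: e.span.start)


def to_bio(note: AnnotatedNote, tokenizer=tokenize) -> TaggedSequence:
    """Project entity spans onto tokens as BIO tags.

    Spans that cut through a token are expanded outward to token
    boundaries, so every kept entity contributes exactly one ``B-`` tag.
    Overlapping entities are first resolved by :func:`resolve_overlaps`.
    """
    tokens = tokenizer(note.text)
    tags = ["O"] * len(tokens)
    for e in resolve_overlaps(note.entities):
        covered = [i for i, t in enumerate(tokens)
                   if t.start < e.span.end and e.span.start < t.end]
        if not covered:
            logger.warning("entity %s %r covers no token", e.id, e.surface)
            continue
        tags[covered[0]] = f"B-{e.label.value}"
        for i in covered[1:]:
            tags[i] = f"I-{e.label.value}"
    return TaggedSequence(note.doc_id, tokens, tags)


def bio_to_entities(text: str, tokens: Sequence[Token],
                    tags: Sequence[str]) -> List[Entity]:
    """Project contiguous ``B-L (I-L)*`` runs back to character-span entities."""
    entities: List[Entity] = []
    i, n = 0, len(tokens)
    k = 0
    while i < n:
        tag = tags[i]
        if tag.startswith("B-"):
            label = EntityLabel(tag[2:])
            j = i + 1
            while j < n and tags[j] == f"I-{label.value}":
                j += 1
            start, end = tokens[i].start, tokens[j - 1].end
            k += 1
            entities.append(
                Entity(f"T{k}", label, Span(start, end), text[start:end]))
            i = j
        else:
            i += 1
    return entities


def bio_tagset(labels: Sequence[EntityLabel] = tuple(EntityLabel)) -> List[str]:
    """Canonical ordered tag set: ``O`` then ``B-L``/``I-L`` per label."""
    tags = ["O"]
    for lab in labels:
        tags += [f"B-{lab.value}", f"I-{lab.value}"]
    return tags
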