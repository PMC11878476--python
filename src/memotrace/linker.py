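"""Rule-based relation linking: attach satellites to their triggers.

Satellite entities (temporal anchors, durations, worsening mentions,
other symptoms, test results, caregiver relations, and medications in
the treatment role) are linked to the nearest compatible head entity in
the same sentence within a configurable token distance, and the relation
label implied by the ontology's head/tail compatibility map is emitted.
SX and DX mentions are always triggers, never satellites, so each
satellite receives at most one head.

Tie-breaks are deterministic: nearest head by token distance, then SX
over other head types (complaints dominate the corpus), then the
leftmost head.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .evaluation import MetricReport, match_relations, metrics
from .ontology import (AnnotatedNote, Entity, EntityLabel, OntologySchema,
                       Relation, RelationLabel)
from .text import sentence_spans, tokenize

logger = logging.getLogger(__name__)

#: Entity types that act as satellites (relation tails).
SATELLITE_LABELS = frozenset({
    EntityLabel.TEMPORAL, EntityLabel.DURATION,
    EntityLabel.STATUS_CHANGE_WORSE, EntityLabel.OTHER_SYMPTOM,
    EntityLabel.COG_TEST_RESULT, EntityLabel.CAREGIVER_RELATION,
    EntityLabel.RX,
})


@dataclass
class LinkerConfig:
    max_token_distance: int = 20
    same_sentence: bool = True

    def __post_init__(self):
        if self.max_token_distance <= 0:
            raise ValueError("max_token_distance must be positive")


def _token_extent(entity: Entity, token_starts: Sequence[int],
                  token_ends: Sequence[int]) -> Tuple[int, int]:
    """Indices of the first and last token overlapped by the entity."""
    first = last = None
    for i, (s, e) in enumerate(zip(token_starts, token_ends)):
        if s < entity.span.end and entity.span.start < e:
            if first is None:
                first = i
            last = i
    if first is None:  # entity between tokens; anchor by char position
        first = last = sum(1 for s in token_starts
                           if s < entity.span.start)
    return first, last


def _token_distance(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    """Number of tokens strictly between two token extents (0 = adjacent)."""
    if a[1] < b[0]:
        return b[0] - a[1] - 1
    if b[1] < a[0]:
        return a[0] - b[1] - 1
    return 0


def link_relations(note: AnnotatedNote,
                   schema: Optional[OntologySchema] = None,
                   config: Optional[LinkerConfig] = None) -> List[Relation]:
    """Infer relations among a note's entities by nearest-head attachment.

    Deterministic and invariant to the order of ``note.entities``.
    Unlinkable satellites are logged and left unattached.
    """
    schema = schema or OntologySchema()
    config = config or LinkerConfig()
    tokens = tokenize(note.text)
    starts = [t.start for t in tokens]
    ends = [t.end for t in tokens]
    sents = sentence_spans(note.text)

    def sentence_of(e: Entity) -> int:
        for i, (s, end) in enumerate(sents):
            if s <= e.span.start < end:
                return i
        return -1

    entities = sorted(note.entities, key=lambda e: (e.span.start, e.id))
    extents = {e.id: _token_extent(e, starts, ends) for e in entities}
    sent_ids = {e.id: sentence_of(e) for e in entities}

    # Tail label -> list of (head label, relation) from the schema.
    tail_map: Dict[EntityLabel, List[Tuple[EntityLabel, RelationLabel]]] = {}
    for rel, pairs in schema.compatibility.items():
        for head_l, tail_l in pairs:
            if tail_l in SATELLITE_LABELS and head_l not in (tail_l,):
                tail_map.setdefault(tail_l, []).append((head_l, rel))

    relations: List[Relation] = []
    k = 0
    for sat in entities:
        options = tail_map.get(sat.label)
        if not options:
            continue
        head_labels = {h for h, _ in options}
        candidates = []
        for head in entities:
            if head.id == sat.id or head.label not in head_labels:
                continue
            if head.label in SATELLITE_LABELS and head.label == sat.label:
                continue
            if config.same_sentence and sent_ids[head.id] != sent_ids[sat.id]:
                continue
            dist = _token_distance(extents[head.id], extents[sat.id])
            if dist > config.max_token_distance:
                continue
            preference = 0 if head.label == EntityLabel.SX else 1
            candidates.append(
                (dist, preference, extents[head.id][0], head))
        if not candidates:
            logger.debug("satellite %s %r left unattached in %s",
                         sat.id, sat.surface, note.doc_id)
            continue
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        head = candidates[0][3]
        rel_label = next(r for h, r in options if h == head.label)
        k += 1
        relations.append(Relation(f"R{k}", rel_label, head.id, sat.id))
    return relations


def evaluate_relations(gold_note: AnnotatedNote,
                       pred_relations: Sequence[Relation],
                       pred_entities: Sequence[Entity]) -> MetricReport:
    """Score predicted relations of one note against its gold relations."""
    counts = match_relations(gold_note.relations, list(pred_relations),
                             gold_note.entities, list(pred_entities))
    return metrics(counts)
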