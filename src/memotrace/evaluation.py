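"""Span-level scoring of entity and relation extraction.

Precision is TP/(TP+FP), recall (sensitivity) is TP/(TP+FN), and the F1
score is their harmonic mean 2PR/(P+R); any zero denominator yields 0 so
sparse labels aggregate stably.  Matching between gold and predicted
entities is greedy 1:1 left-to-right: in ``exact`` mode a predicted entity
is a true positive iff its label and character span both equal an unmatched
gold entity; in ``overlap`` mode the labels must match and the spans must
intersect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .ontology import Entity, Relation


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class Scores:
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts


@dataclass
class MetricReport:
    """Per-label and micro-averaged precision/recall/F1."""

    per_label: Dict[str, Scores] = field(default_factory=dict)
    micro: Scores = field(
        default_factory=lambda: Scores(0.0, 0.0, 0.0, ConfusionCounts()))

    def to_dict(self) -> dict:
        def row(s: Scores) -> dict:
            return {"precision": s.precision, "recall": s.recall, "f1": s.f1,
                    "tp": s.counts.tp, "fp": s.counts.fp, "fn": s.counts.fn}
        return {"micro": row(self.micro),
                "per_label": {k: row(v) for k, v in self.per_label.items()}}


def prf(counts: ConfusionCounts) -> Scores:
    """Precision/recall/F1 from confusion counts (0 on empty denominators)."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return Scores(p, r, f1, counts)


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Cohort-table percentage, rounded to the reporting precision."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def match_entities(gold: Sequence[Entity], pred: Sequence[Entity],
                   mode: str = "exact") -> Dict[str, ConfusionCounts]:
    """Per-label confusion counts for one document.

    Gold entities with identical (label, span) duplicates are invalid.
    Predictions are scanned left-to-right; each consumes at most one gold.
    """
    if mode not in ("exact", "overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    seen = set()
    for g in gold:
        key = (g.label, g.span.start, g.span.end)
        if key in seen:
            raise ValueError(f"duplicate gold entity {key}")
        seen.add(key)

    counts: Dict[str, ConfusionCounts] = {}

    def bucket(label) -> ConfusionCounts:
        return counts.setdefault(label.value, ConfusionCounts())

    unmatched = sorted(gold, key=lambda e: (e.span.start, e.span.end))
    for p in sorted(pred, key=lambda e: (e.span.start, e.span.end)):
        hit = None
        for g in unmatched:
            if g.label != p.label:
                continue
            if mode == "exact":
                if g.span == p.span:
                    hit = g
                    break
            else:
                if g.span.overlaps(p.span):
                    hit = g
                    break
        if hit is not None:
            unmatched.remove(hit)
            bucket(p.label).tp += 1
        else:
            bucket(p.label).fp += 1
    for g in unmatched:
        bucket(g.label).fn += 1
    return counts


def merge_counts(per_doc: Iterable[Mapping[str, ConfusionCounts]]
                 ) -> Dict[str, ConfusionCounts]:
    total: Dict[str, ConfusionCounts] = {}
    for doc in per_doc:
        for label, c in doc.items():
            total[label] = total.get(label, ConfusionCounts()) + c
    return total


def metrics(counts: Mapping[str, ConfusionCounts]) -> MetricReport:
    """Build a :class:`MetricReport` from per-label counts."""
    report = MetricReport()
    micro = ConfusionCounts()
    for label in sorted(counts):
        report.per_label[label] = prf(counts[label])
        micro = micro + counts[label]
    report.micro = prf(micro)
    return report


def score_documents(gold_docs: Sequence[Sequence[Entity]],
                    pred_docs: Sequence[Sequence[Entity]],
                    mode: str = "exact") -> MetricReport:
    """Score aligned lists of per-document gold and predicted entities."""
    if len(gold_docs) != len(pred_docs):
        raise ValueError("gold and pred document counts differ")
    return metrics(merge_counts(
        match_entities(g, p, mode) for g, p in zip(gold_docs, pred_docs)))


def _relation_key(rel: Relation, ents: Mapping[str, Entity]) -> Tuple:
    h, t = ents[rel.head], ents[rel.tail]
    return (rel.label.value, h.label.value, h.span.start, h.span.end,
            t.label.value, t.span.start, t.span.end)


def match_relations(gold: Sequence[Relation], pred: Sequence[Relation],
                    gold_entities: Sequence[Entity],
                    pred_entities: Sequence[Entity]
                    ) -> Dict[str, ConfusionCounts]:
    """Per-label relation counts: TP iff label plus head and tail
    (label, span) all match a gold relation exactly."""
    ge = {e.id: e for e in gold_entities}
    pe = {e.id: e for e in pred_entities}
    try:
        gold_keys = [_relation_key(r, ge) for r in gold]
        pred_keys = [_relation_key(r, pe) for r in pred]
    except KeyError as exc:
        raise ValueError(f"relation references unknown entity id {exc}") from exc
    counts: Dict[str, ConfusionCounts] = {}

    def bucket(label: str) -> ConfusionCounts:
        return counts.setdefault(label, ConfusionCounts())

    remaining = list(gold_keys)
    for key in pred_keys:
        if key in remaining:
            remaining.remove(key)
            bucket(key[0]).tp += 1
        else:
            bucket(key[0]).fp += 1
    for key in remaining:
        bucket(key[0]).fn += 1
    return counts
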