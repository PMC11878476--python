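"""Span-level scoring: metric formulas, matching modes, properties."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memotrace.evaluation import (ConfusionCounts, f1_score, match_entities,
                                  match_relations, merge_counts, metrics,
                                  percent, prf, score_documents)
from memotrace.ontology import Entity, EntityLabel, Relation, RelationLabel, Span


def ent(label, start, end, i=0):
    return Entity(f"T{i}", label, Span(start, end), "x" * (end - start))


def test_f1_is_harmonic_mean_of_printed_scores():
    assert round(f1_score(0.97, 0.93), 2) == 0.95


def test_zero_counts_give_zero_metrics():
    s = prf(ConfusionCounts(0, 0, 0))
    assert (s.precision, s.recall, s.f1) == (0.0, 0.0, 0.0)


def test_hand_arithmetic_two_thirds():
    s = prf(ConfusionCounts(tp=2, fp=1, fn=1))
    assert s.precision == pytest.approx(2 / 3)
    assert s.recall == pytest.approx(2 / 3)
    assert s.f1 == pytest.approx(2 / 3)


def test_identical_gold_and_pred_is_perfect():
    gold = [ent(EntityLabel.SX, 0, 4, 1), ent(EntityLabel.DX, 6, 9, 2),
            ent(EntityLabel.RX, 12, 20, 3)]
    counts = match_entities(gold, gold)
    rep = metrics(counts)
    assert rep.micro.counts.tp == 3
    assert rep.micro.precision == rep.micro.recall == rep.micro.f1 == 1.0


def test_shifted_span_exact_vs_overlap():
    gold = [ent(EntityLabel.SX, 0, 4, 1), ent(EntityLabel.SX, 10, 14, 2),
            ent(EntityLabel.SX, 20, 24, 3)]
    pred = [ent(EntityLabel.SX, 1, 5, 1), ent(EntityLabel.SX, 11, 15, 2),
            ent(EntityLabel.SX, 21, 25, 3)]
    assert merge_total(match_entities(gold, pred, "exact")).tp == 0
    assert merge_total(match_entities(gold, pred, "overlap")).tp == 3


def merge_total(counts):
    total = ConfusionCounts()
    for c in counts.values():
        total = total + c
    return total


def brute_force_tp(gold, pred):
    """Optimal 1:1 TP count in exact mode by trying every injective
    assignment of predictions to gold items (small inputs only)."""
    def hit(g, p):
        return g.label == p.label and g.span == p.span

    best = 0
    g_idx = range(len(gold))
    for assign in itertools.product(list(g_idx) + [None], repeat=len(pred)):
        used = [a for a in assign if a is not None]
        if len(used) != len(set(used)):
            continue
        tp = sum(1 for p_i, g_i in enumerate(assign)
                 if g_i is not None and hit(gold[g_i], pred[p_i]))
        best = max(best, tp)
    return best


def test_exact_matching_equals_optimal_assignment():
    rng = np.random.default_rng(42)
    labels = [EntityLabel.SX, EntityLabel.DX]
    for _ in range(100):
        def rand_ents(n, off):
            out = []
            for i in range(n):
                start = int(rng.integers(0, 12))
                out.append(ent(labels[int(rng.integers(2))], start,
                               start + int(rng.integers(1, 4)), off + i))
            return out
        gold, pred = [], []
        for e in rand_ents(int(rng.integers(0, 6)), 0):
            if not any(g.label == e.label and g.span == e.span for g in gold):
                gold.append(e)
        pred = rand_ents(int(rng.integers(0, 6)), 100)
        counts = match_entities(gold, pred, "exact")
        assert merge_total(counts).tp == brute_force_tp(gold, pred)


def test_duplicate_gold_rejected():
    gold = [ent(EntityLabel.SX, 0, 4, 1), ent(EntityLabel.SX, 0, 4, 2)]
    with pytest.raises(ValueError):
        match_entities(gold, [])


def test_micro_equals_sum_of_labels():
    gold = [ent(EntityLabel.SX, 0, 4, 1), ent(EntityLabel.DX, 6, 9, 2)]
    pred = [ent(EntityLabel.SX, 0, 4, 1), ent(EntityLabel.DX, 7, 9, 2)]
    rep = metrics(match_entities(gold, pred))
    total = merge_total({k: v.counts for k, v in rep.per_label.items()})
    assert (rep.micro.counts.tp, rep.micro.counts.fp, rep.micro.counts.fn) \
        == (total.tp, total.fp, total.fn)


def test_swapping_gold_and_pred_swaps_precision_recall():
    gold = [ent(EntityLabel.SX, 0, 4, 1), ent(EntityLabel.SX, 10, 14, 2)]
    pred = [ent(EntityLabel.SX, 0, 4, 1), ent(EntityLabel.SX, 20, 24, 2),
            ent(EntityLabel.SX, 30, 34, 3)]
    a = metrics(match_entities(gold, pred))
    b = metrics(match_entities(pred, gold))
    assert a.micro.precision == pytest.approx(b.micro.recall)
    assert a.micro.recall == pytest.approx(b.micro.precision)


@settings(deadline=None, derandomize=True)
@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
def test_f1_between_min_and_mean(tp, fp, fn):
    s = prf(ConfusionCounts(tp, fp, fn))
    assert min(s.precision, s.recall) - 1e-12 <= s.f1
    assert s.f1 <= (s.precision + s.recall) / 2 + 1e-12


def test_relation_scoring_counts():
    e1 = ent(EntityLabel.SX, 0, 4, 1)
    e2 = ent(EntityLabel.DURATION, 6, 9, 2)
    e3 = ent(EntityLabel.RX, 12, 18, 3)
    gold = [Relation("R1", RelationLabel.HAS_DURATION_INFO, e1.id, e2.id),
            Relation("R2", RelationLabel.HAS_TREATMENT_INFO, e1.id, e3.id)]
    # one matched, one missed, one spurious
    pred = [Relation("R1", RelationLabel.HAS_DURATION_INFO, e1.id, e2.id),
            Relation("R2", RelationLabel.HAS_EFFECTS, e3.id, e1.id)]
    counts = match_relations(gold, pred, [e1, e2, e3], [e1, e2, e3])
    rep = metrics(counts)
    assert rep.micro.precision == pytest.approx(0.5)
    assert rep.micro.recall == pytest.approx(0.5)


def test_relation_scoring_empty_pred_zero_recall():
    e1 = ent(EntityLabel.SX, 0, 4, 1)
    e2 = ent(EntityLabel.DURATION, 6, 9, 2)
    gold = [Relation("R1", RelationLabel.HAS_DURATION_INFO, e1.id, e2.id)]
    rep = metrics(match_relations(gold, [], [e1, e2], []))
    assert rep.micro.recall == 0.0


def test_score_documents_requires_alignment():
    with pytest.raises(ValueError):
        score_documents([[]], [[], []])


def test_percent_matches_reported_precision():
    assert percent(146, 581) == 25.1
    with pytest.raises(ValueError):
        percent(1, 0)
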