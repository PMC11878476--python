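"""Cohort criteria, index dates, attrition bookkeeping."""

from datetime import date

import pandas as pd
import pytest

from memotrace.normalize import build_extraction_table
from memotrace.ontology import AnnotatedNote, Entity, EntityLabel, Span
from memotrace.phenotype import (CohortCriteria, PatientRecord,
                                 PhenotypeError, age_group,
                                 first_complaint_date, first_diagnosis_date,
                                 load_structured, select_cohort)

GER = "geriatrics"


def sx_note(doc_id, pid, when, text="Pt c/o memory loss at home."):
    s = text.index("memory loss")
    return AnnotatedNote(
        doc_id=doc_id, text=text, patient_id=pid, note_date=when,
        department=GER,
        entities=[Entity("T1", EntityLabel.SX, Span(s, s + 11),
                         "memory loss")])


def dx_note(doc_id, pid, when):
    text = "Assessment: dementia."
    return AnnotatedNote(
        doc_id=doc_id, text=text, patient_id=pid, note_date=when,
        department=GER,
        entities=[Entity("T1", EntityLabel.DX, Span(12, 20), "dementia")])


def patient(pid, visits, codes, birth_year=1930):
    return PatientRecord(patient_id=pid, birth_year=birth_year, sex="female",
                         race="white", insurance="medicare",
                         visits=visits, dx_codes=codes)


def dementia_codes(*dates):
    return [(d, "G30.9") for d in dates]


def _fixture():
    """Five patients: one failure per criterion plus one analysis member
    and one same-day member."""
    d = date
    notes = []
    patients = []

    # P1: analysis patient (passes everything, complaint < diagnosis).
    patients.append(patient("P1", [(d(2014, 3, 1), GER), (d(2015, 2, 1), GER)],
                            dementia_codes(d(2015, 2, 1), d(2015, 3, 1),
                                           d(2015, 4, 1))))
    notes += [sx_note("n1", "P1", d(2014, 3, 1)),
              dx_note("n2", "P1", d(2015, 2, 1))]

    # P2: only 2 distinct dementia-code dates -> fails criterion 1.
    patients.append(patient("P2", [(d(2014, 1, 1), GER), (d(2015, 1, 2), GER)],
                            dementia_codes(d(2015, 1, 2), d(2015, 2, 2))))
    notes += [sx_note("n3", "P2", d(2014, 1, 1)),
              dx_note("n4", "P2", d(2015, 1, 2))]

    # P3: missing 2014 entirely -> fails visit-per-year.
    patients.append(patient("P3", [(d(2013, 1, 5), GER), (d(2015, 1, 5), GER)],
                            dementia_codes(d(2015, 1, 5), d(2015, 2, 5),
                                           d(2015, 3, 5))))
    notes += [sx_note("n5", "P3", d(2013, 1, 5)),
              dx_note("n6", "P3", d(2015, 1, 5))]

    # P4: first visit on the diagnosis day -> fails visit-before-diagnosis.
    patients.append(patient("P4", [(d(2015, 5, 1), GER)],
                            dementia_codes(d(2015, 5, 1), d(2015, 6, 1),
                                           d(2015, 7, 1))))
    notes += [sx_note("n7", "P4", d(2015, 5, 1)),
              dx_note("n8", "P4", d(2015, 5, 1))]

    # P5: no memory-loss symptom note -> fails criterion 4.
    patients.append(patient("P5", [(d(2014, 6, 1), GER), (d(2015, 6, 1), GER)],
                            dementia_codes(d(2015, 6, 1), d(2015, 7, 1),
                                           d(2015, 8, 1))))
    notes += [dx_note("n9", "P5", d(2015, 6, 1))]

    # P6: same-day complaint and diagnosis -> included but not analyzed.
    patients.append(patient("P6", [(d(2014, 8, 1), GER), (d(2015, 8, 1), GER)],
                            dementia_codes(d(2015, 8, 1), d(2015, 9, 1),
                                           d(2015, 10, 1))))
    notes += [sx_note("n10", "P6", d(2015, 8, 1)),
              dx_note("n11", "P6", d(2015, 8, 1))]

    return patients, build_extraction_table(notes)


def test_fixture_attrition_one_exclusion_per_criterion():
    patients, extractions = _fixture()
    result = select_cohort(patients, extractions)
    assert result.exclusions == {
        "dementia_diagnosis": 1,
        "visit_per_year": 1,
        "visit_before_diagnosis": 1,
        "memory_loss_symptom": 1,
    }
    assert result.included == ["P1", "P6"]
    assert result.same_day_excluded == ["P6"]
    assert result.analysis == ["P1"]
    att = result.attrition()
    assert att["n_input"] == 6
    assert att["n_analysis"] == 1


def test_first_diagnosis_date_min_rule():
    codes = dementia_codes(date(2016, 3, 1), date(2016, 6, 1),
                           date(2016, 9, 1))
    p = patient("P1", [(date(2016, 1, 1), GER)], codes)
    ext = build_extraction_table([dx_note("n1", "P1", date(2016, 5, 15))])
    assert first_diagnosis_date(p, ext) == date(2016, 3, 1)


def test_first_diagnosis_date_note_only():
    p = patient("P1", [(date(2016, 1, 1), GER)], [])
    ext = build_extraction_table([dx_note("n1", "P1", date(2016, 5, 15))])
    assert first_diagnosis_date(p, ext) == date(2016, 5, 15)


def test_first_diagnosis_date_equal_sources():
    codes = dementia_codes(date(2016, 5, 15))
    p = patient("P1", [], codes)
    ext = build_extraction_table([dx_note("n1", "P1", date(2016, 5, 15))])
    assert first_diagnosis_date(p, ext) == date(2016, 5, 15)


def test_first_diagnosis_date_without_evidence_errors():
    p = patient("P1", [], [])
    ext = build_extraction_table([])
    with pytest.raises(PhenotypeError):
        first_diagnosis_date(p, ext)


def test_first_complaint_date_earliest_sx():
    p = patient("P1", [], [])
    ext = build_extraction_table([
        sx_note("n1", "P1", date(2015, 7, 1)),
        sx_note("n2", "P1", date(2015, 4, 1))])
    assert first_complaint_date(p, ext) == date(2015, 4, 1)


def test_unmapped_symptom_does_not_qualify():
    text = "Reports knee pain today."
    s = text.index("knee pain")
    note = AnnotatedNote(
        doc_id="n1", text=text, patient_id="P1", note_date=date(2015, 1, 1),
        department=GER,
        entities=[Entity("T1", EntityLabel.SX, Span(s, s + 9), "knee pain")])
    with pytest.raises(PhenotypeError):
        first_complaint_date(patient("P1", [], []),
                             build_extraction_table([note]))


def test_duplicate_patient_ids_rejected():
    patients, extractions = _fixture()
    with pytest.raises(ValueError, match="duplicate"):
        select_cohort(patients + [patients[0]], extractions)


def test_icd_prefix_matching():
    criteria = CohortCriteria.default()
    for code in ("G30.9", "F03.90", "331.0", "294.11", "g31.83"):
        assert criteria.is_dementia_code(code)
    for code in ("I10", "E11.9", "G40.9", "F32.9"):
        assert not criteria.is_dementia_code(code)
    assert criteria.min_code_dates == 3


def test_criteria_validation():
    with pytest.raises(ValueError):
        CohortCriteria(icd_prefixes=("G30",), min_code_dates=0)


def test_generator_cohort_recovered_exactly(small_dataset, small_extractions):
    result = select_cohort(small_dataset.patients, small_extractions)
    truth = small_dataset.truth_by_id()
    planted_analysis = {t.patient_id for t in small_dataset.truths
                        if t.membership == "analysis"}
    planted_same_day = {t.patient_id for t in small_dataset.truths
                        if t.membership == "same_day"}
    assert set(result.analysis) == planted_analysis
    assert set(result.same_day_excluded) == planted_same_day
    assert result.exclusions == {k: 1 for k in result.exclusions}
    for pid, (complaint, dx) in result.index_dates.items():
        t = truth[pid]
        assert complaint == t.first_complaint_date
        assert dx == t.first_dx_date


def test_age_groups():
    assert age_group(1960, date(2015, 1, 1)) == "<65"
    assert age_group(1945, date(2015, 1, 1)) == "65-74"
    assert age_group(1935, date(2015, 1, 1)) == "75-84"
    assert age_group(1925, date(2015, 1, 1)) == "85+"


def test_structured_io_round_trip(tmp_path, small_dataset):
    small_dataset.write(tmp_path)
    loaded = load_structured(tmp_path)
    by_id = {p.patient_id: p for p in loaded}
    for p in small_dataset.patients:
        q = by_id[p.patient_id]
        assert sorted(q.visits) == sorted(p.visits)
        assert sorted(q.dx_codes) == sorted(p.dx_codes)
        assert sorted(q.med_orders) == sorted(p.med_orders)
        assert q.insurance == p.insurance


def test_attrition_json(tmp_path):
    patients, extractions = _fixture()
    result = select_cohort(patients, extractions)
    path = tmp_path / "attrition.json"
    result.write_attrition(path)
    import json
    data = json.loads(path.read_text())
    assert data["exclusions"]["visit_per_year"] == 1
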