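"""Trajectory features, descriptive statistics, association models."""

from datetime import date

import numpy as np
import pytest

from memotrace.synthetic import (GeneratorConfig, sample_truths,
                                 truth_trajectories)
from memotrace.trajectory import (TrajectoryRecord, describe_intervals,
                                  fit_interval_model, fit_medication_model,
                                  records_to_frame)


def rec(pid="P1", interval=342, n=3, med=False, comploc="geriatrics",
        dxloc="geriatrics", age="85+", ins="medicare", cg=None):
    start = date(2015, 1, 1)
    from datetime import timedelta
    return TrajectoryRecord(
        patient_id=pid, first_complaint_date=start,
        first_dx_date=start + timedelta(days=interval),
        interval_days=interval, n_complaints=n, prior_med=med,
        complaint_location=comploc, dx_location=dxloc, age_group=age,
        insurance=ins, caregiver_group=cg)


def test_interval_is_whole_day_difference():
    r = rec(interval=342)
    assert (r.first_dx_date - r.first_complaint_date).days == 342


def test_same_day_interval_rejected():
    with pytest.raises(ValueError):
        rec(interval=0)
    with pytest.raises(ValueError):
        rec(n=0)


def test_describe_intervals_examples():
    records = [rec(pid=f"P{i}", interval=v, n=c)
               for i, (v, c) in enumerate([(1, 1), (342, 3), (1458, 18)])]
    d = describe_intervals(records)
    assert d["interval_days"]["median"] == 342
    assert d["interval_days"]["min"] == 1
    assert d["interval_days"]["max"] == 1458
    assert d["n_complaints"]["median"] == 3


def test_describe_single_record():
    d = describe_intervals([rec(interval=100, n=2)])
    for stat in ("median", "q1", "q3", "min", "max"):
        assert d["interval_days"][stat] == 100


def test_describe_tukey_hinges_inclusive():
    # n=5: lower half (incl. median) = [1,2,3] -> q1=2; upper -> q3=4
    records = [rec(pid=f"P{i}", interval=v) for i, v in
               enumerate([1, 2, 3, 4, 5])]
    d = describe_intervals(records)["interval_days"]
    assert (d["q1"], d["median"], d["q3"]) == (2, 3, 4)


def test_describe_order_invariance(rng):
    vals = rng.integers(1, 1000, size=31)
    a = describe_intervals([rec(pid=f"P{i}", interval=int(v))
                            for i, v in enumerate(vals)])
    b = describe_intervals([rec(pid=f"P{i}", interval=int(v))
                            for i, v in enumerate(sorted(vals))])
    assert a == b


def test_describe_empty_errors():
    with pytest.raises(ValueError):
        describe_intervals([])


def _cohort_records(n=4000, seed=0, **cfg_kwargs):
    cfg = GeneratorConfig(n_patients=n, seed=seed, **cfg_kwargs)
    return truth_trajectories(sample_truths(cfg, np.random.default_rng(seed)))


def test_reference_levels_emit_no_estimate():
    records = _cohort_records()
    result = fit_interval_model(records)
    for factor, ref in [("age_group", "85+"), ("insurance", "commercial"),
                        ("complaint_location", "primary_care"),
                        ("dx_location", "primary_care"),
                        ("caregiver_group", "husband")]:
        row = result.row(factor, ref)
        assert row.reference
        assert row.estimate is None and row.p is None


def test_interval_model_complete_case_for_caregiver():
    records = _cohort_records(n=2000)
    df = records_to_frame(records)
    n_complete = int(df["caregiver_group"].notna().sum())
    result = fit_interval_model(records)
    assert result.n_used == n_complete


def test_interval_model_needs_enough_records():
    with pytest.raises(ValueError):
        fit_interval_model([rec(cg="wife")] * 10)


def test_null_effects_cis_cover_zero_at_nominal_rate():
    """With all shifts zeroed, CIs should cover 0 ~95% of the time."""
    covered = total = 0
    zero = {"geriatrics": 0.0, "neurology": 0.0, "primary_care": 0.0,
            "other": 0.0}
    zero_cg = {k: 0.0 for k in ("wife", "daughter", "other_adult_children",
                                "other_family_support", "husband")}
    for seed in range(5):
        records = _cohort_records(
            n=3000, seed=seed, complaint_location_shifts=dict(zero),
            dx_location_shifts=dict(zero), caregiver_shifts=dict(zero_cg))
        result = fit_interval_model(records)
        for row in result.rows:
            if row.reference:
                continue
            total += 1
            covered += row.ci_low <= 0.0 <= row.ci_high
    assert covered / total >= 0.9


def test_medication_null_cis_cover_one():
    covered = total = 0
    for seed in range(5):
        records = _cohort_records(n=3000, seed=seed,
                                  medication_log_or=0.0)
        result = fit_medication_model(records)
        for row in result.rows:
            if row.reference:
                continue
            total += 1
            covered += row.ci_low <= 1.0 <= row.ci_high
    assert covered / total >= 0.9


def test_medication_single_class_outcome_errors():
    records = [rec(pid=f"P{i}", med=True, cg="wife", n=i % 5 + 1)
               for i in range(60)]
    with pytest.raises(ValueError, match="single-class"):
        fit_medication_model(records)


def test_medication_model_reports_odds_ratios():
    records = _cohort_records(n=6000)
    result = fit_medication_model(records)
    row = result.row("n_complaints", "")
    assert row.estimate > 0
    assert row.ci_low < row.estimate < row.ci_high
    assert result.model == "logistic"


def test_prior_med_strictly_before_diagnosis(small_dataset,
                                             small_extractions):
    """Structured orders on/after the diagnosis date never count."""
    from memotrace.phenotype import select_cohort
    from memotrace.trajectory import build_trajectories
    cohort = select_cohort(small_dataset.patients, small_extractions)
    records = {r.patient_id: r for r in build_trajectories(
        cohort, small_extractions, small_dataset.patients)}
    truth = small_dataset.truth_by_id()
    checked = 0
    for p in small_dataset.patients:
        if p.patient_id not in records:
            continue
        t = truth[p.patient_id]
        post_only = [d for d, drug in p.med_orders
                     if drug in ("donepezil", "memantine")
                     and d >= t.first_dx_date]
        if post_only and not t.prior_med:
            assert records[p.patient_id].prior_med is False
            checked += 1
    assert checked > 0


def test_report_rendering(tmp_path):
    from memotrace.trajectory import write_report
    records = _cohort_records(n=3000)
    results = write_report(records, tmp_path)
    assert (tmp_path / "results.json").exists()
    md = (tmp_path / "report.md").read_text()
    assert "Ref" in md and "n_complaints" in md
    assert results["interval_model"]["n_used"] > 0


def test_log_outcome_option():
    records = _cohort_records(n=2000)
    result = fit_interval_model(records, log_outcome=True)
    assert result.outcome == "log_interval"
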