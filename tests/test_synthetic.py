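"""Generator determinism, marginals, calibration, and noise knobs."""

import filecmp
import math

import numpy as np
import pytest
from scipy import stats

from memotrace.normalize import ConceptLexicon, UNMAPPED
from memotrace.ontology import EntityLabel
from memotrace.synthetic import (GeneratorConfig, NoiseKnobs,
                                 annotated_corpus,
                                 calibrate_interval_baseline,
                                 calibrate_medication_intercept,
                                 complaint_count_pmf, generate,
                                 sample_truths, shift_distribution,
                                 truth_trajectories)
from memotrace.templates import (CAREGIVER_TEMPLATES, MEDICATION_TEMPLATES,
                                 SurfaceSampler, fill_template)


def test_same_seed_byte_identical_directories(tmp_path):
    a = generate(GeneratorConfig(n_patients=30, seed=5))
    b = generate(GeneratorConfig(n_patients=30, seed=5))
    dir_a, dir_b = tmp_path / "a", tmp_path / "b"
    a.write(dir_a)
    b.write(dir_b)
    for name in ("patients.csv", "visits.csv", "diagnoses.csv",
                 "medications.csv", "notes_meta.csv", "ground_truth.json"):
        assert filecmp.cmp(dir_a / name, dir_b / name, shallow=False), name
    for f in (dir_a / "notes").iterdir():
        assert filecmp.cmp(f, dir_b / "notes" / f.name, shallow=False)


def test_distinct_seeds_distinct_corpora():
    a = generate(GeneratorConfig(n_patients=20, seed=1))
    b = generate(GeneratorConfig(n_patients=20, seed=2))
    assert [n.text for n in a.notes] != [n.text for n in b.notes]


def test_gold_offsets_slice_exactly(small_dataset):
    for note in small_dataset.notes:
        for e in note.entities:
            assert note.text[e.span.start:e.span.end] == e.surface


def test_tables_mutually_consistent(small_dataset):
    visit_keys = {(p.patient_id, d) for p in small_dataset.patients
                  for d, _ in p.visits}
    for note in small_dataset.notes:
        assert (note.patient_id, note.note_date) in visit_keys
    criteria_codes = {t.patient_id for t in small_dataset.truths}
    assert {p.patient_id for p in small_dataset.patients} == criteria_codes


def test_invalid_marginals_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(sex_probs={"female": 0.9, "male": 0.3})
    with pytest.raises(ValueError):
        GeneratorConfig(n_patients=3)
    with pytest.raises(ValueError):
        GeneratorConfig(same_day_rate=1.5)


def test_complaint_location_share_matches_marginal():
    cfg = GeneratorConfig(n_patients=3000, seed=17)
    truths = sample_truths(cfg, np.random.default_rng(17))
    share = np.mean([t.complaint_location == "geriatrics" for t in truths])
    assert abs(share - 0.53) < 0.03


def test_demographic_marginals():
    cfg = GeneratorConfig(n_patients=4000, seed=23)
    truths = sample_truths(cfg, np.random.default_rng(23))
    assert abs(np.mean([t.sex == "female" for t in truths]) - 0.656) < 0.03
    assert abs(np.mean([t.age_group == "85+" for t in truths]) - 0.542) < 0.03
    assert abs(np.mean([t.caregiver_group is None for t in truths])
               - 0.499) < 0.03
    regular = [t for t in truths if not t.membership.startswith("excluded")]
    assert abs(np.mean([t.membership == "same_day" for t in regular])
               - 0.204) < 0.03
    assert abs(np.mean([t.prior_med for t in truths]) - 0.251) < 0.03


def test_complaint_count_truncated_nb_median_and_range():
    cfg = GeneratorConfig()
    pmf = complaint_count_pmf(cfg)
    ks = np.arange(1, cfg.complaint_count_max + 1)
    cdf = np.cumsum(pmf)
    assert ks[int(np.searchsorted(cdf, 0.5))] == 3
    truths = sample_truths(GeneratorConfig(n_patients=2000, seed=31),
                           np.random.default_rng(31))
    counts = [t.n_complaints for t in truths]
    assert min(counts) >= 1 and max(counts) <= 18


def test_interval_baseline_calibration_hits_marginal_median():
    cfg = GeneratorConfig()
    baseline = calibrate_interval_baseline(cfg)
    # large-sample check of the mixture median against the target
    rng = np.random.default_rng(0)
    mixture = shift_distribution(cfg)
    probs = np.array([p for p, _ in mixture])
    shifts = np.array([s for _, s in mixture])
    cells = rng.choice(len(mixture), size=200_000, p=probs / probs.sum())
    sigma = cfg.interval_sigma
    noise = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=len(cells))
    draws = np.maximum(1, (baseline + shifts[cells]) * noise)
    assert abs(np.median(draws) - cfg.interval_median) \
        < 0.02 * cfg.interval_median


def test_medication_intercept_calibration():
    cfg = GeneratorConfig()
    b0 = calibrate_medication_intercept(cfg)
    pmf = complaint_count_pmf(cfg)
    ks = np.arange(1, cfg.complaint_count_max + 1)
    rate = float(np.sum(pmf / (1 + np.exp(-(b0 + cfg.medication_log_or * ks)))))
    assert rate == pytest.approx(cfg.medication_rate, abs=1e-6)


def test_abbreviation_knob_forces_dtr():
    rng = np.random.default_rng(3)
    sampler = SurfaceSampler(rng, NoiseKnobs(abbreviation_rate=1.0))
    template = CAREGIVER_TEMPLATES[0]
    text, ents, _ = fill_template(template, sampler,
                                  {"caregiver_relation": "daughter"})
    cg = [e for e in ents if e[0] == EntityLabel.CAREGIVER_RELATION][0]
    surface = cg[3]
    assert surface.lower() == "dtr"
    lex = ConceptLexicon.default()
    assert lex.normalize_caregiver(surface) == "daughter"


def test_brand_knob_forces_aricept():
    rng = np.random.default_rng(3)
    sampler = SurfaceSampler(rng, NoiseKnobs(brand_rate=1.0))
    template = MEDICATION_TEMPLATES[0]
    text, ents, _ = fill_template(template, sampler,
                                  {"medication": "donepezil"})
    rx = [e for e in ents if e[0] == EntityLabel.RX][0]
    assert rx[3] == "Aricept"
    assert ConceptLexicon.default().normalize_medication(rx[3]) == "donepezil"


def test_distractor_only_notes_have_no_entities(small_dataset):
    empties = [n for n in small_dataset.notes if not n.entities]
    assert empties  # symptom-excluded fixture patients produce them
    for n in empties:
        assert n.relations == []


def test_truth_trajectories_match_full_pipeline(small_dataset,
                                                small_extractions):
    from memotrace.phenotype import select_cohort
    from memotrace.trajectory import build_trajectories
    cohort = select_cohort(small_dataset.patients, small_extractions)
    full = {r.patient_id: r for r in build_trajectories(
        cohort, small_extractions, small_dataset.patients)}
    short = {r.patient_id: r for r in
             truth_trajectories(small_dataset.truths)}
    assert full == short


def test_annotated_corpus_covers_label_inventory():
    notes = annotated_corpus(150, seed=1)
    labels = {e.label for n in notes for e in n.entities}
    assert {EntityLabel.SX, EntityLabel.DX, EntityLabel.RX,
            EntityLabel.CAREGIVER_RELATION, EntityLabel.DURATION,
            EntityLabel.STATUS_CHANGE_WORSE}.issubset(labels)
    rels = {r.label for n in notes for r in n.relations}
    assert len(rels) >= 6
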