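"""Fully synthetic EHR with planted, recoverable ground truth.

The real study data are protected health information, so every module is
exercised against a generated stand-in: structured tables (demographics,
visits, diagnosis codes, medication orders) plus clinical notes with
gold standoff annotations.  Marginals and effects default to the study
cohort's published values:

* demographics, insurance, caregiver distribution (incl. ~50% missing);
* complaint/diagnosis department shares (geriatrics 53%/60.2%, primary
  care 31.8%/28.1%, neurology 6.7%/10.5%);
* complaint-to-diagnosis interval: log-normal (sigma 0.8) plus additive
  department and caregiver shifts, with the baseline calibrated so the
  marginal median equals the configured 342 days;
* complaint count: negative binomial truncated to 1..18 with median 3;
* prior-medication flag: logistic in the complaint count with
  per-complaint log-odds ln(1.148), intercept calibrated to a 25.1%
  marginal rate;
* a same-day complaint/diagnosis fraction of 20.4%.

Four excluded-by-design patients (one per cohort criterion) are always
present so attrition logic can be tested, and the per-patient ground
truth is serialized next to the data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .ontology import AnnotatedNote, write_standoff
from .phenotype import PatientRecord
from .templates import (CAREGIVER_TEMPLATES, COMPLAINT_TEMPLATES,
                        DX_TEMPLATES, MEDICATION_TEMPLATES, NoiseKnobs,
                        SurfaceSampler, render_note)

MONTH_NAMES = ("January", "February", "March", "April", "May", "June",
               "July", "August", "September", "October", "November",
               "December")

#: Caregiver groups with a planted canonical relation pool each.
CAREGIVER_GROUP_RELATIONS: Dict[str, Tuple[str, ...]] = {
    "husband": ("husband",),
    "wife": ("wife",),
    "daughter": ("daughter",),
    "other_adult_children": ("son", "son_in_law", "daughter_in_law",
                             "grandson", "granddaughter"),
    "other_family_support": ("nephew", "niece", "cousin", "brother",
                             "sister"),
}

DEMENTIA_CODES = ("G30.9", "F03.90", "G31.83", "F01.50", "331.0")
FILLER_CODES = ("I10", "E11.9", "M17.11", "J44.9")
FILLER_DRUGS = ("lisinopril", "metformin", "atorvastatin")


def _norm(probs: Dict[str, float]) -> Dict[str, float]:
    total = sum(probs.values())
    if total <= 0:
        raise ValueError("probabilities must sum to a positive value")
    if abs(total - 1.0) > 0.05:
        raise ValueError(f"probabilities sum to {total:.3f}, not ~1")
    return {k: v / total for k, v in probs.items()}


@dataclass
class GeneratorConfig:
    n_patients: int = 500
    seed: int = 42
    age_probs: Dict[str, float] = field(default_factory=lambda: {
        "<65": 0.055, "65-74": 0.108, "75-84": 0.294, "85+": 0.542})
    sex_probs: Dict[str, float] = field(default_factory=lambda: {
        "female": 0.656, "male": 0.344})
    race_probs: Dict[str, float] = field(default_factory=lambda: {
        "white": 0.876, "african_american": 0.057, "other": 0.067})
    insurance_probs: Dict[str, float] = field(default_factory=lambda: {
        "medicare": 0.609, "medicaid": 0.124, "commercial": 0.262,
        "none": 0.003})
    complaint_location_probs: Dict[str, float] = field(default_factory=lambda: {
        "geriatrics": 0.530, "primary_care": 0.318, "neurology": 0.067,
        "other": 0.085})
    dx_location_probs: Dict[str, float] = field(default_factory=lambda: {
        "geriatrics": 0.602, "primary_care": 0.281, "neurology": 0.105,
        "other": 0.012})
    caregiver_missing: float = 0.499
    caregiver_probs: Dict[str, float] = field(default_factory=lambda: {
        "husband": 0.089, "wife": 0.134, "daughter": 0.464,
        "other_adult_children": 0.172, "other_family_support": 0.141})
    # Interval model: log-normal baseline + additive shifts (days).
    interval_median: float = 342.0
    interval_sigma: float = 0.8
    complaint_location_shifts: Dict[str, float] = field(default_factory=lambda: {
        "geriatrics": -141.0, "neurology": -158.0, "primary_care": 0.0,
        "other": 81.0})
    dx_location_shifts: Dict[str, float] = field(default_factory=lambda: {
        "geriatrics": -152.9, "neurology": -82.2, "primary_care": 0.0,
        "other": 42.0})
    caregiver_shifts: Dict[str, float] = field(default_factory=lambda: {
        "wife": -249.6, "daughter": -176.8, "other_adult_children": -127.4,
        "other_family_support": -257.5, "husband": 0.0})
    # Complaint-count model: negative binomial truncated to [1, 18].
    complaint_nb_r: float = 2.0
    complaint_nb_mean: float = 3.6
    complaint_count_max: int = 18
    # Medication model: logit(P) = intercept + log_or * n_complaints.
    medication_log_or: float = math.log(1.148)
    medication_rate: float = 0.251
    same_day_rate: float = 0.204
    study_start: date = date(2010, 1, 1)
    complaint_latest: date = date(2015, 12, 31)
    noise: NoiseKnobs = field(default_factory=NoiseKnobs)
    n_planted_excluded: int = 4

    def __post_init__(self):
        if self.n_patients < self.n_planted_excluded + 2:
            raise ValueError("n_patients too small for the planted fixtures")
        for name in ("age_probs", "sex_probs", "race_probs",
                     "insurance_probs", "complaint_location_probs",
                     "dx_location_probs", "caregiver_probs"):
            setattr(self, name, _norm(getattr(self, name)))
        if not 0 <= self.caregiver_missing < 1:
            raise ValueError("caregiver_missing must be in [0, 1)")
        if not 0 <= self.same_day_rate < 1:
            raise ValueError("same_day_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# Deterministic calibration of the two planted intercepts
# ---------------------------------------------------------------------------

def shift_distribution(config: GeneratorConfig) -> List[Tuple[float, float]]:
    """(probability, total additive shift) over the categorical mixture."""
    caregiver = dict(config.caregiver_probs)
    items = []
    cg_levels = [(None, config.caregiver_missing)] + [
        (g, (1 - config.caregiver_missing) * p) for g, p in caregiver.items()]
    for cl, p_cl in config.complaint_location_probs.items():
        for dl, p_dl in config.dx_location_probs.items():
            for cg, p_cg in cg_levels:
                shift = (config.complaint_location_shifts.get(cl, 0.0)
                         + config.dx_location_shifts.get(dl, 0.0)
                         + (config.caregiver_shifts.get(cg, 0.0)
                            if cg else 0.0))
                items.append((p_cl * p_dl * p_cg, shift))
    return items


def calibrate_interval_baseline(config: GeneratorConfig) -> float:
    """Baseline cell mean (days) such that the marginal median interval
    equals ``interval_median``.

    The interval of a patient in mixture cell c is
    ``(baseline + shift_c) * exp(sigma Z - sigma^2/2)`` — a log-normal
    whose mean equals the cell mean exactly (mean-one multiplicative
    noise), so a linear model on days recovers the additive shifts
    without attenuation.  The cell median is ``mean * exp(-sigma^2/2)``;
    the marginal median is solved for by bisection on the baseline.
    """
    from scipy.special import ndtr
    mixture = shift_distribution(config)
    target = config.interval_median
    sigma = config.interval_sigma
    probs = np.array([p for p, s in mixture])
    shifts = np.array([s for p, s in mixture])
    log_target = math.log(target)

    def marginal_cdf(baseline: float) -> float:
        means = baseline + shifts
        ok = means > 1.0
        z = (log_target - np.log(means[ok]) + sigma ** 2 / 2) / sigma
        return float(np.sum(probs[ok] * ndtr(z)))

    lo = float(-shifts.min()) + 2.0
    hi = lo + 20.0 * target
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        # cdf decreases as the baseline grows; find cdf == 0.5
        if marginal_cdf(mid) > 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def complaint_count_pmf(config: GeneratorConfig) -> np.ndarray:
    """pmf over 1..complaint_count_max of the truncated negative binomial."""
    r, mean = config.complaint_nb_r, config.complaint_nb_mean
    p = r / (r + mean)
    ks = np.arange(1, config.complaint_count_max + 1)
    pmf = stats.nbinom.pmf(ks, r, p)
    return pmf / pmf.sum()


def calibrate_medication_intercept(config: GeneratorConfig) -> float:
    """Intercept making the marginal medication rate equal the target."""
    pmf = complaint_count_pmf(config)
    ks = np.arange(1, config.complaint_count_max + 1)

    def rate(b0: float) -> float:
        logits = b0 + config.medication_log_or * ks
        return float(np.sum(pmf / (1.0 + np.exp(-logits))))

    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if rate(mid) < config.medication_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Patient-level ground truth sampling
# ---------------------------------------------------------------------------

@dataclass
class PatientTruth:
    patient_id: str
    membership: str            # analysis | same_day | excluded:<criterion>
    age_group: str
    sex: str
    race: str
    insurance: str
    complaint_location: str
    dx_location: str
    caregiver_group: Optional[str]
    caregiver_relation: Optional[str]
    first_complaint_date: date
    first_dx_date: date
    interval_days: int
    n_complaints: int
    prior_med: bool
    medication: Optional[str]


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    patients: List[PatientRecord]
    notes: List[AnnotatedNote]
    truths: List[PatientTruth]
    planted: Dict[str, float]

    @property
    def ground_truth(self) -> dict:
        def enc(t: PatientTruth) -> dict:
            d = asdict(t)
            d["first_complaint_date"] = t.first_complaint_date.isoformat()
            d["first_dx_date"] = t.first_dx_date.isoformat()
            return d
        return {"planted": self.planted,
                "patients": [enc(t) for t in self.truths]}

    def truth_by_id(self) -> Dict[str, PatientTruth]:
        return {t.patient_id: t for t in self.truths}

    def notes_meta(self):
        import pandas as pd
        return pd.DataFrame(
            [{"doc_id": n.doc_id, "patient_id": n.patient_id,
              "note_date": n.note_date.isoformat(),
              "department": n.department} for n in self.notes])

    def structured_frames(self):
        import pandas as pd
        pats, visits, dxs, meds = [], [], [], []
        for p in self.patients:
            pats.append({"patient_id": p.patient_id,
                         "birth_year": p.birth_year, "sex": p.sex,
                         "race": p.race, "insurance": p.insurance})
            visits += [{"patient_id": p.patient_id, "date": d.isoformat(),
                        "department": dept} for d, dept in p.visits]
            dxs += [{"patient_id": p.patient_id, "date": d.isoformat(),
                     "icd_code": c} for d, c in p.dx_codes]
            meds += [{"patient_id": p.patient_id, "date": d.isoformat(),
                      "drug": drug} for d, drug in p.med_orders]
        return {"patients": pd.DataFrame(pats),
                "visits": pd.DataFrame(visits),
                "diagnoses": pd.DataFrame(dxs),
                "medications": pd.DataFrame(meds)}

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        (out / "notes").mkdir(parents=True, exist_ok=True)
        (out / "gold").mkdir(parents=True, exist_ok=True)
        for name, df in self.structured_frames().items():
            df.to_csv(out / f"{name}.csv", index=False)
        self.notes_meta().to_csv(out / "notes_meta.csv", index=False)
        for note in self.notes:
            text, ann = write_standoff(note)
            (out / "notes" / f"{note.doc_id}.txt").write_text(
                text, encoding="utf-8")
            (out / "gold" / f"{note.doc_id}.ann").write_text(
                ann, encoding="utf-8")
        with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.ground_truth, fh, indent=2)
        return out


def _sample_cat(rng: np.random.Generator, probs: Dict[str, float]) -> str:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys])
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


_AGE_RANGES = {"<65": (56, 64), "65-74": (65, 74), "75-84": (75, 84),
               "85+": (85, 94)}


def sample_truths(config: GeneratorConfig,
                  rng: np.random.Generator) -> List[PatientTruth]:
    """Sample per-patient planted ground truth (no text yet)."""
    baseline = calibrate_interval_baseline(config)
    med_b0 = calibrate_medication_intercept(config)
    count_pmf = complaint_count_pmf(config)
    ks = np.arange(1, config.complaint_count_max + 1)

    truths: List[PatientTruth] = []
    n_regular = config.n_patients - config.n_planted_excluded
    exclusion_kinds = ("dementia_diagnosis", "visit_per_year",
                       "visit_before_diagnosis", "memory_loss_symptom")
    for i in range(config.n_patients):
        pid = f"P{i + 1:05d}"
        age_group = _sample_cat(rng, config.age_probs)
        sex = _sample_cat(rng, config.sex_probs)
        race = _sample_cat(rng, config.race_probs)
        insurance = _sample_cat(rng, config.insurance_probs)
        comploc = _sample_cat(rng, config.complaint_location_probs)
        dxloc = _sample_cat(rng, config.dx_location_probs)
        if rng.random() < config.caregiver_missing:
            cg_group = cg_rel = None
        else:
            cg_group = _sample_cat(rng, config.caregiver_probs)
            pool = CAREGIVER_GROUP_RELATIONS[cg_group]
            cg_rel = pool[int(rng.integers(len(pool)))]

        if i < n_regular:
            same_day = rng.random() < config.same_day_rate
            membership = "same_day" if same_day else "analysis"
        else:
            kind = exclusion_kinds[i - n_regular]
            membership = f"excluded:{kind}"
            same_day = False

        if same_day:
            interval = 0
        else:
            shift = (config.complaint_location_shifts.get(comploc, 0.0)
                     + config.dx_location_shifts.get(dxloc, 0.0)
                     + (config.caregiver_shifts.get(cg_group, 0.0)
                        if cg_group else 0.0))
            sigma = config.interval_sigma
            noise = float(rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma))
            interval = max(1, int(round((baseline + shift) * noise)))
        if membership == "excluded:visit_per_year":
            interval = max(interval, 800)   # needs a skippable gap year

        window = (config.complaint_latest - config.study_start).days
        complaint = config.study_start + timedelta(
            days=int(rng.integers(0, window + 1)))
        dx = complaint + timedelta(days=interval)

        n_target = int(ks[int(rng.choice(len(ks), p=count_pmf))])
        n_complaints = max(1, min(n_target, max(interval, 1)))
        logit = med_b0 + config.medication_log_or * n_complaints
        prior_med = bool(rng.random() < 1.0 / (1.0 + math.exp(-logit)))
        medication = None
        if prior_med:
            generics = sorted({"donepezil", "memantine", "rivastigmine",
                               "galantamine"})
            medication = generics[int(rng.integers(len(generics)))]

        truths.append(PatientTruth(
            patient_id=pid, membership=membership, age_group=age_group,
            sex=sex, race=race, insurance=insurance,
            complaint_location=comploc, dx_location=dxloc,
            caregiver_group=cg_group, caregiver_relation=cg_rel,
            first_complaint_date=complaint, first_dx_date=dx,
            interval_days=interval, n_complaints=n_complaints,
            prior_med=prior_med, medication=medication))
    return truths


# ---------------------------------------------------------------------------
# Materialization: notes + structured tables per patient
# ---------------------------------------------------------------------------

def _birth_year(truth: PatientTruth, rng: np.random.Generator) -> int:
    lo, hi = _AGE_RANGES[truth.age_group]
    age = int(rng.integers(lo, hi + 1))
    return truth.first_dx_date.year - age


def _month_year(d: date) -> str:
    return f"{MONTH_NAMES[d.month - 1]} {d.year}"


def _pick_template(rng: np.random.Generator, templates) -> list:
    return [templates[int(rng.integers(len(templates)))]]


def _materialize_patient(truth: PatientTruth, config: GeneratorConfig,
                         rng: np.random.Generator, doc_counter: List[int]
                         ) -> Tuple[PatientRecord, List[AnnotatedNote]]:
    sampler = SurfaceSampler(rng, config.noise)
    excluded_kind = (truth.membership.split(":", 1)[1]
                     if truth.membership.startswith("excluded:") else None)
    record = PatientRecord(
        patient_id=truth.patient_id,
        birth_year=_birth_year(truth, rng),
        sex=truth.sex, race=truth.race, insurance=truth.insurance)
    notes: List[AnnotatedNote] = []

    def new_doc_id() -> str:
        doc_counter[0] += 1
        return f"N{doc_counter[0]:06d}"

    def add_note(note_date: date, department: str, templates: list,
                 context: Dict[str, str]) -> None:
        ctx = {"month_year": _month_year(note_date), **context}
        n_dist = (1 if rng.random() < config.noise.distractor_rate
                  or not templates else 0)
        before = int(rng.integers(0, n_dist + 1))
        text, entities, relations = render_note(
            templates, sampler, ctx,
            distractors_before=before, distractors_after=n_dist - before)
        notes.append(AnnotatedNote(
            doc_id=new_doc_id(), text=text, patient_id=truth.patient_id,
            note_date=note_date, department=department,
            entities=entities, relations=relations))
        record.visits.append((note_date, department))

    complaint, dx = truth.first_complaint_date, truth.first_dx_date
    interval = truth.interval_days

    # Complaint notes: first at the planted complaint date and department.
    if excluded_kind != "memory_loss_symptom":
        offsets = [0]
        if truth.n_complaints > 1 and interval > 1:
            extra = rng.choice(np.arange(1, interval),
                               size=min(truth.n_complaints - 1, interval - 1),
                               replace=False)
            offsets += sorted(int(o) for o in extra)
        for j, off in enumerate(offsets):
            note_date = complaint + timedelta(days=off)
            dept = (truth.complaint_location if j == 0 else
                    _sample_cat(rng, config.complaint_location_probs))
            templates = _pick_template(rng, COMPLAINT_TEMPLATES)
            context: Dict[str, str] = {}
            if j == 0 and truth.caregiver_relation is not None:
                templates = _pick_template(rng, CAREGIVER_TEMPLATES)
                context["caregiver_relation"] = truth.caregiver_relation
            if j == 0 and truth.prior_med:
                templates = templates + _pick_template(
                    rng, MEDICATION_TEMPLATES)
                context["medication"] = truth.medication
            add_note(note_date, dept, templates, context)
    else:
        # Distractor-only visit history instead of complaint notes.
        add_note(complaint, _sample_cat(rng, config.complaint_location_probs),
                 [], {})

    # Same-day patients still carry routine visit history before the
    # complaint/diagnosis day (otherwise they could not be outpatients).
    if interval == 0 and excluded_kind is None:
        record.visits.append(
            (complaint - timedelta(days=int(rng.integers(60, 300))),
             _sample_cat(rng, config.complaint_location_probs)))

    # Diagnosis note at the planted date and department.
    add_note(dx, truth.dx_location, _pick_template(rng, DX_TEMPLATES), {})

    # Structured dementia codes on >= 3 distinct dates from dx onwards
    # (only 2 for the dementia-definition excluded fixture).
    n_code_dates = 2 if excluded_kind == "dementia_diagnosis" else \
        3 + int(rng.integers(0, 3))
    for k in range(n_code_dates):
        code = DEMENTIA_CODES[int(rng.integers(len(DEMENTIA_CODES)))]
        code_date = dx + timedelta(days=30 * k)
        record.dx_codes.append((code_date, code))
        if k > 0:
            record.visits.append(
                (code_date, _sample_cat(rng, config.dx_location_probs)))
    # Unrelated codes for realism.
    record.dx_codes.append(
        (complaint, FILLER_CODES[int(rng.integers(len(FILLER_CODES)))]))

    # Medication orders.
    if truth.prior_med:
        order_date = complaint + timedelta(
            days=int(rng.integers(0, max(interval, 1))))
        record.med_orders.append((min(order_date, dx - timedelta(days=1))
                                  if interval > 0 else complaint,
                                  truth.medication))
    elif rng.random() < 0.3:
        # Post-diagnosis order only: must not count as prior medication.
        generic = sorted({"donepezil", "memantine"})[int(rng.integers(2))]
        record.med_orders.append(
            (dx + timedelta(days=int(rng.integers(0, 60))), generic))
    if rng.random() < 0.5:
        record.med_orders.append(
            (complaint, FILLER_DRUGS[int(rng.integers(len(FILLER_DRUGS)))]))

    # Filler visits: one per calendar year from first activity to dx year.
    first_year = min(d.year for d, _ in record.visits)
    gap_year = None
    if excluded_kind == "visit_per_year":
        candidates = [y for y in range(first_year + 1, dx.year)]
        gap_year = candidates[0] if candidates else None
    visit_years = {d.year for d, _ in record.visits}
    for year in range(first_year, dx.year + 1):
        if year == gap_year:
            continue
        if year not in visit_years:
            record.visits.append(
                (date(year, 6, 15),
                 _sample_cat(rng, config.complaint_location_probs)))
    if gap_year is not None:
        record.visits = [(d, dept) for d, dept in record.visits
                         if d.year != gap_year]
        notes = [n for n in notes if n.note_date.year != gap_year]
    if excluded_kind == "visit_before_diagnosis":
        # All activity collapses onto the diagnosis date.
        record.visits = [(dx, truth.dx_location)]
        notes = [n for n in notes if n.note_date >= dx]
    record.visits.sort()
    record.dx_codes.sort()
    record.med_orders.sort()
    return record, notes


def generate(config: Optional[GeneratorConfig] = None) -> SyntheticDataset:
    """Generate the full synthetic dataset (in memory; see
    :meth:`SyntheticDataset.write` for the on-disk layout)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    truths = sample_truths(config, rng)
    patients: List[PatientRecord] = []
    notes: List[AnnotatedNote] = []
    doc_counter = [0]
    for truth in truths:
        record, pnotes = _materialize_patient(truth, config, rng, doc_counter)
        patients.append(record)
        notes.extend(pnotes)
    planted = {
        "interval_median": config.interval_median,
        "interval_sigma": config.interval_sigma,
        "medication_or_per_complaint": math.exp(config.medication_log_or),
        "medication_rate": config.medication_rate,
        "same_day_rate": config.same_day_rate,
        "interval_baseline_mean_days": calibrate_interval_baseline(config),
        "medication_intercept": calibrate_medication_intercept(config),
    }
    return SyntheticDataset(config=config, patients=patients, notes=notes,
                            truths=truths, planted=planted)


def truth_trajectories(truths: Sequence[PatientTruth]):
    """Trajectory records straight from planted ground truth (analysis
    patients only).  The full-pipeline path recovers exactly these
    records (a tested invariant); this shortcut makes large Monte-Carlo
    parameter-recovery studies cheap."""
    from .trajectory import TrajectoryRecord
    return [TrajectoryRecord(
        patient_id=t.patient_id,
        first_complaint_date=t.first_complaint_date,
        first_dx_date=t.first_dx_date,
        interval_days=t.interval_days,
        n_complaints=t.n_complaints,
        prior_med=t.prior_med,
        complaint_location=t.complaint_location,
        dx_location=t.dx_location,
        age_group=t.age_group,
        insurance=t.insurance,
        caregiver_group=t.caregiver_group,
    ) for t in truths if t.membership == "analysis"]


def annotated_corpus(n_notes: int, seed: int,
                     noise: Optional[NoiseKnobs] = None
                     ) -> List[AnnotatedNote]:
    """A flat corpus of gold-annotated notes for tagger training/eval.

    Draws uniformly over all template families (complaint, caregiver,
    medication, diagnosis) with 1-2 content sentences per note plus
    distractors, without building patient structure.
    """
    rng = np.random.default_rng(seed)
    sampler = SurfaceSampler(rng, noise or NoiseKnobs())
    families = (COMPLAINT_TEMPLATES + CAREGIVER_TEMPLATES
                + MEDICATION_TEMPLATES + DX_TEMPLATES)
    relations = sorted(CAREGIVER_GROUP_RELATIONS.values(),
                       key=lambda pool: pool[0])
    all_relations = [r for pool in relations for r in pool]
    notes: List[AnnotatedNote] = []
    for i in range(n_notes):
        k = 1 + int(rng.random() < 0.4)
        templates = [families[int(rng.integers(len(families)))]
                     for _ in range(k)]
        note_date = date(2012, 1, 1) + timedelta(
            days=int(rng.integers(0, 2000)))
        context = {
            "caregiver_relation": all_relations[
                int(rng.integers(len(all_relations)))],
            "month_year": _month_year(note_date),
        }
        n_dist = 1 if rng.random() < 0.5 else 0
        before = int(rng.integers(0, n_dist + 1))
        text, entities, rels = render_note(
            templates, sampler, context,
            distractors_before=before, distractors_after=n_dist - before)
        notes.append(AnnotatedNote(
            doc_id=f"C{i + 1:05d}", text=text, patient_id=f"CP{i + 1:05d}",
            note_date=note_date, department="other",
            entities=entities, relations=rels))
    return notes
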