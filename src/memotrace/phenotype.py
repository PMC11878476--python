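"""Dementia cohort phenotyping from coded data plus NLP extractions.

The study cohort consists of patients who (1) received a dementia
diagnosis — coded on at least 3 distinct dates with a phenotyping ICD
code *and* documented as a DX mention in at least one note, (2) had at
least one outpatient visit in every calendar year of observation,
(3) had at least one visit before the diagnosis date, and (4) had a
memory-loss symptom documented in a note on or before the diagnosis
date.  Patients whose first complaint and first diagnosis fall on the
same day are kept in the included set but flagged out of the analysis
set, since their complaint-to-diagnosis interval is zero.

The diagnosis index date is the earlier of the first structured dementia
code date and the first DX-mention note date; the complaint index date
is the earliest note date carrying a symptom that normalizes to a
memory-loss concept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .normalize import SYMPTOM_CONCEPTS


@dataclass
class PatientRecord:
    """Structured EHR rows for one patient."""

    patient_id: str
    birth_year: int
    sex: str
    race: str
    insurance: str
    visits: List[Tuple[date, str]] = field(default_factory=list)
    dx_codes: List[Tuple[date, str]] = field(default_factory=list)
    med_orders: List[Tuple[date, str]] = field(default_factory=list)


@dataclass
class CohortCriteria:
    icd_prefixes: Tuple[str, ...]
    min_code_dates: int = 3
    require_visit_per_year: bool = True
    require_visit_before_dx: bool = True
    require_symptom_note: bool = True
    require_dx_note: bool = True

    def __post_init__(self):
        if self.min_code_dates < 1:
            raise ValueError("min_code_dates must be >= 1")
        self.icd_prefixes = tuple(str(p).upper() for p in self.icd_prefixes)

    @classmethod
    def default(cls) -> "CohortCriteria":
        path = resources.files("memotrace.resources") / "icd_dementia.yaml"
        with path.open(encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls(icd_prefixes=tuple(cfg["icd_prefixes"]),
                   min_code_dates=int(cfg["min_distinct_code_dates"]))

    @classmethod
    def from_yaml(cls, path) -> "CohortCriteria":
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls(icd_prefixes=tuple(cfg["icd_prefixes"]),
                   min_code_dates=int(cfg.get("min_distinct_code_dates", 3)))

    def is_dementia_code(self, code: str) -> bool:
        c = str(code).upper().strip()
        return any(c.startswith(p) for p in self.icd_prefixes)


@dataclass
class CohortResult:
    included: List[str]
    exclusions: Dict[str, int]          # criterion name -> count excluded
    same_day_excluded: List[str]
    analysis: List[str]
    index_dates: Dict[str, Tuple[date, date]]  # id -> (complaint, diagnosis)

    def attrition(self) -> dict:
        return {
            "n_input": sum(self.exclusions.values()) + len(self.included),
            "exclusions": dict(self.exclusions),
            "n_included": len(self.included),
            "n_same_day_excluded": len(self.same_day_excluded),
            "n_analysis": len(self.analysis),
        }

    def write_attrition(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.attrition(), fh, indent=2)


class PhenotypeError(ValueError):
    """Raised when an index date is requested without qualifying evidence."""


class ExtractionIndex:
    """Per-patient index over the extraction table (built once; cohort
    selection over thousands of patients would otherwise rescan the whole
    table per patient)."""

    def __init__(self, extractions: pd.DataFrame):
        df = extractions.copy()
        df["note_date"] = pd.to_datetime(df["note_date"]).dt.date
        self._groups: Dict[str, pd.DataFrame] = {
            str(pid): g for pid, g in df.groupby("patient_id")}

    def patient(self, patient_id: str) -> Optional[pd.DataFrame]:
        return self._groups.get(str(patient_id))

    def dates(self, patient_id: str, label: str,
              concepts: Optional[Sequence[str]] = None) -> List[date]:
        g = self._groups.get(str(patient_id))
        if g is None:
            return []
        sel = g["label"] == label
        if concepts is not None:
            sel &= g["canonical"].isin(concepts)
        return sorted(set(g.loc[sel, "note_date"]))


def _as_index(extractions) -> ExtractionIndex:
    if isinstance(extractions, ExtractionIndex):
        return extractions
    return ExtractionIndex(extractions)


def _extraction_dates(extractions, patient_id: str, label: str,
                      concepts: Optional[Sequence[str]] = None) -> List[date]:
    return _as_index(extractions).dates(patient_id, label, concepts)


def first_diagnosis_date(p: PatientRecord, extractions,
                         criteria: Optional[CohortCriteria] = None) -> date:
    """Earlier of the first structured dementia-code date and the first
    note date carrying a DX mention."""
    criteria = criteria or CohortCriteria.default()
    code_dates = sorted({d for d, c in p.dx_codes
                         if criteria.is_dementia_code(c)})
    note_dates = _extraction_dates(extractions, p.patient_id, "DX")
    candidates = ([code_dates[0]] if code_dates else []) + \
        ([note_dates[0]] if note_dates else [])
    if not candidates:
        raise PhenotypeError(
            f"{p.patient_id}: no dementia diagnosis evidence")
    return min(candidates)


def first_complaint_date(p: PatientRecord, extractions) -> date:
    """Earliest note date with an SX mention normalizing to a memory-loss
    concept."""
    dates = _extraction_dates(extractions, p.patient_id, "SX",
                              SYMPTOM_CONCEPTS)
    if not dates:
        raise PhenotypeError(
            f"{p.patient_id}: no normalized memory-loss symptom note")
    return dates[0]


def _meets_dementia_definition(p: PatientRecord, extractions,
                               criteria: CohortCriteria) -> bool:
    code_dates = {d for d, c in p.dx_codes if criteria.is_dementia_code(c)}
    if len(code_dates) < criteria.min_code_dates:
        return False
    if criteria.require_dx_note and not _extraction_dates(
            extractions, p.patient_id, "DX"):
        return False
    return True


def _visit_every_year(p: PatientRecord, dx_date: date) -> bool:
    years = {d.year for d, _ in p.visits}
    if not years:
        return False
    first = min(years)
    return all(y in years for y in range(first, dx_date.year + 1))


CRITERIA_ORDER = (
    "dementia_diagnosis",
    "visit_per_year",
    "visit_before_diagnosis",
    "memory_loss_symptom",
)


def select_cohort(patients: Sequence[PatientRecord], extractions,
                  criteria: Optional[CohortCriteria] = None) -> CohortResult:
    """Apply the four cohort criteria in order, then flag same-day
    complaint/diagnosis patients out of the analysis set.

    Exclusion counts are attributed to the first criterion a patient
    fails (Fig-1-style attrition), though the final included set is
    order-independent.
    """
    criteria = criteria or CohortCriteria.default()
    extractions = _as_index(extractions)
    seen = set()
    for p in patients:
        if p.patient_id in seen:
            raise ValueError(f"duplicate patient id {p.patient_id}")
        seen.add(p.patient_id)

    exclusions = {name: 0 for name in CRITERIA_ORDER}
    included: List[str] = []
    same_day: List[str] = []
    index_dates: Dict[str, Tuple[date, date]] = {}
    for p in patients:
        if not _meets_dementia_definition(p, extractions, criteria):
            exclusions["dementia_diagnosis"] += 1
            continue
        dx_date = first_diagnosis_date(p, extractions, criteria)
        if criteria.require_visit_per_year and not _visit_every_year(p, dx_date):
            exclusions["visit_per_year"] += 1
            continue
        if criteria.require_visit_before_dx and not any(
                d < dx_date for d, _ in p.visits):
            exclusions["visit_before_diagnosis"] += 1
            continue
        if criteria.require_symptom_note:
            try:
                complaint = first_complaint_date(p, extractions)
            except PhenotypeError:
                exclusions["memory_loss_symptom"] += 1
                continue
            if complaint > dx_date:
                exclusions["memory_loss_symptom"] += 1
                continue
        else:
            complaint = dx_date
        included.append(p.patient_id)
        index_dates[p.patient_id] = (complaint, dx_date)
        if complaint == dx_date:
            same_day.append(p.patient_id)
    analysis = [pid for pid in included if pid not in set(same_day)]
    return CohortResult(included=included, exclusions=exclusions,
                        same_day_excluded=same_day, analysis=analysis,
                        index_dates=index_dates)


# ---------------------------------------------------------------------------
# Structured-table I/O
# ---------------------------------------------------------------------------

def load_structured(directory) -> List[PatientRecord]:
    """Load patients/visits/diagnoses/medications CSVs into records.

    Expected columns: patients.csv (patient_id, birth_year, sex, race,
    insurance); visits.csv (patient_id, date, department); diagnoses.csv
    (patient_id, date, icd_code); medications.csv (patient_id, date,
    drug).
    """
    d = Path(directory)
    patients = pd.read_csv(d / "patients.csv", dtype={"patient_id": str})
    visits = pd.read_csv(d / "visits.csv", dtype={"patient_id": str},
                         parse_dates=["date"])
    diagnoses = pd.read_csv(d / "diagnoses.csv", dtype={"patient_id": str},
                            parse_dates=["date"])
    meds = pd.read_csv(d / "medications.csv", dtype={"patient_id": str},
                       parse_dates=["date"])
    records: Dict[str, PatientRecord] = {}
    for row in patients.itertuples():
        records[row.patient_id] = PatientRecord(
            patient_id=row.patient_id, birth_year=int(row.birth_year),
            sex=row.sex, race=row.race, insurance=row.insurance)
    for row in visits.itertuples():
        records[row.patient_id].visits.append(
            (row.date.date(), row.department))
    for row in diagnoses.itertuples():
        records[row.patient_id].dx_codes.append(
            (row.date.date(), row.icd_code))
    for row in meds.itertuples():
        records[row.patient_id].med_orders.append((row.date.date(), row.drug))
    return list(records.values())


def age_group(birth_year: int, at: date) -> str:
    """Age bin at the reference date: <65, 65-74, 75-84, 85+."""
    age = at.year - birth_year
    if age < 65:
        return "<65"
    if age < 75:
        return "65-74"
    if age < 85:
        return "75-84"
    return "85+"
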