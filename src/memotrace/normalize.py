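"""Standardization of heterogeneous surface forms to canonical concepts.

Clinical notes write the same thing many ways: "dtr" for daughter,
"Aricept" for donepezil, "forgetful" / "forgetfulness" / "forgetting
things".  This module maps symptom, caregiver and medication surface
forms onto closed canonical vocabularies through editable CSV lexicons
shipped with the package, and groups caregiver relations into the five
analysis categories (husband, wife, daughter, other adult children =
son/son-in-law/daughter-in-law/grandson/granddaughter, other family
support = nephew/niece/cousin/brother/sister).

Lookups are case- and whitespace-insensitive (hyphens fold to spaces).
Unknown surfaces return :data:`UNMAPPED` and are logged so the lexicons
can grow; they are never an error.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .ontology import AnnotatedNote, EntityLabel

logger = logging.getLogger(__name__)

UNMAPPED = "UNMAPPED"

#: Canonical memory-loss symptom concepts.
SYMPTOM_CONCEPTS = (
    "memory_loss",
    "forgetfulness",
    "short_term_memory_deficit",
    "confusion",
    "cognitive_impairment",
)

#: Canonical family caregiver relations.
CAREGIVER_RELATIONS = (
    "husband", "wife", "daughter", "son", "son_in_law", "daughter_in_law",
    "grandson", "granddaughter", "nephew", "niece", "cousin", "brother",
    "sister",
)

#: Canonical cognition-enhancing medication generics.
MEDICATION_GENERICS = ("donepezil", "memantine", "rivastigmine", "galantamine")


class CaregiverGroup(str, Enum):
    HUSBAND = "husband"
    WIFE = "wife"
    DAUGHTER = "daughter"
    OTHER_ADULT_CHILDREN = "other_adult_children"
    OTHER_FAMILY_SUPPORT = "other_family_support"


_CAREGIVER_GROUPING: Dict[str, CaregiverGroup] = {
    "husband": CaregiverGroup.HUSBAND,
    "wife": CaregiverGroup.WIFE,
    "daughter": CaregiverGroup.DAUGHTER,
    "son": CaregiverGroup.OTHER_ADULT_CHILDREN,
    "son_in_law": CaregiverGroup.OTHER_ADULT_CHILDREN,
    "daughter_in_law": CaregiverGroup.OTHER_ADULT_CHILDREN,
    "grandson": CaregiverGroup.OTHER_ADULT_CHILDREN,
    "granddaughter": CaregiverGroup.OTHER_ADULT_CHILDREN,
    "nephew": CaregiverGroup.OTHER_FAMILY_SUPPORT,
    "niece": CaregiverGroup.OTHER_FAMILY_SUPPORT,
    "cousin": CaregiverGroup.OTHER_FAMILY_SUPPORT,
    "brother": CaregiverGroup.OTHER_FAMILY_SUPPORT,
    "sister": CaregiverGroup.OTHER_FAMILY_SUPPORT,
}


def fold_surface(surface: str) -> str:
    """Lowercase, fold hyphens/underscores to spaces, collapse whitespace."""
    s = re.sub(r"[-_]", " ", surface.lower())
    return re.sub(r"\s+", " ", s).strip()


def _read_lexicon_csv(name: str) -> Dict[str, str]:
    path = resources.files("memotrace.resources.lexicons") / name
    out: Dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[fold_surface(row["surface"])] = row["canonical"]
    return out


@dataclass
class ConceptLexicon:
    """The three normalization maps plus the cognitive-test name map."""

    symptoms: Dict[str, str] = field(default_factory=dict)
    caregivers: Dict[str, str] = field(default_factory=dict)
    medications: Dict[str, str] = field(default_factory=dict)
    cognitive_tests: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ConceptLexicon":
        return cls(
            symptoms=_read_lexicon_csv("symptoms.csv"),
            caregivers=_read_lexicon_csv("caregivers.csv"),
            medications=_read_lexicon_csv("medications.csv"),
            cognitive_tests=_read_lexicon_csv("cognitive_tests.csv"),
        )

    @classmethod
    def from_dir(cls, directory) -> "ConceptLexicon":
        """Load site-local lexicons from a directory of the same four CSVs."""
        import pathlib
        d = pathlib.Path(directory)

        def read(name):
            out = {}
            with open(d / name, encoding="utf-8") as fh:
                for row in csv.DictReader(fh):
                    out[fold_surface(row["surface"])] = row["canonical"]
            return out

        return cls(read("symptoms.csv"), read("caregivers.csv"),
                   read("medications.csv"), read("cognitive_tests.csv"))

    def _lookup(self, table: Dict[str, str], surface: str,
                kind: str) -> str:
        key = fold_surface(surface)
        hit = table.get(key)
        if hit is None:
            logger.debug("unmapped %s surface %r", kind, surface)
            return UNMAPPED
        return hit

    def normalize_symptom(self, surface: str) -> str:
        """Surface form -> canonical memory-loss concept, or UNMAPPED."""
        return self._lookup(self.symptoms, surface, "symptom")

    def normalize_caregiver(self, surface: str) -> str:
        """Surface form -> canonical family relation, or UNMAPPED."""
        return self._lookup(self.caregivers, surface, "caregiver")

    def normalize_medication(self, surface: str) -> str:
        """Brand or generic surface -> generic name, or UNMAPPED."""
        return self._lookup(self.medications, surface, "medication")

    def normalize_test(self, surface: str) -> str:
        # Test-name mentions are normalized for entity support only; the
        # downstream trajectory analysis does not use them because their
        # prevalence in notes is too low to be informative.
        key = fold_surface(surface)
        for name, canon in self.cognitive_tests.items():
            if key.startswith(name):
                return canon
        return self._lookup(self.cognitive_tests, surface, "cognitive test")

    def normalize(self, label: EntityLabel, surface: str) -> str:
        if label == EntityLabel.SX:
            return self.normalize_symptom(surface)
        if label == EntityLabel.CAREGIVER_RELATION:
            return self.normalize_caregiver(surface)
        if label == EntityLabel.RX:
            return self.normalize_medication(surface)
        if label == EntityLabel.COG_TEST_RESULT:
            return self.normalize_test(surface)
        return ""


def group_caregiver(relation: str) -> CaregiverGroup:
    """Canonical relation -> analysis group (errors on UNMAPPED)."""
    try:
        return _CAREGIVER_GROUPING[relation]
    except KeyError:
        raise ValueError(
            f"cannot group non-canonical caregiver relation {relation!r}"
        ) from None


def build_extraction_table(notes: Iterable[AnnotatedNote],
                           lexicon: Optional[ConceptLexicon] = None
                           ) -> pd.DataFrame:
    """Flatten annotated notes into the normalized extraction table.

    One row per entity with columns doc_id, patient_id, note_date,
    department, entity_id, label, surface, canonical.  This table is the
    interface between the NLP stages and the phenotyper.
    """
    lexicon = lexicon or ConceptLexicon.default()
    rows = []
    for note in notes:
        for e in note.entities:
            rows.append({
                "doc_id": note.doc_id,
                "patient_id": note.patient_id,
                "note_date": note.note_date,
                "department": note.department,
                "entity_id": e.id,
                "label": e.label.value,
                "surface": e.surface,
                "canonical": lexicon.normalize(e.label, e.surface),
            })
    df = pd.DataFrame(rows, columns=["doc_id", "patient_id", "note_date",
                                     "department", "entity_id", "label",
                                     "surface", "canonical"])
    if len(df):
        df["note_date"] = pd.to_datetime(df["note_date"])
    return df
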