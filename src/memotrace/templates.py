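"""Sentence templates for the synthetic clinical-note generator.

Each template is a sequence of literal fragments and typed slots; filling
a template yields the sentence text, gold entities with exact character
offsets, and the gold relations among the slots.  Templates are written
so that every satellite entity has exactly one compatible head inside the
same sentence — the nearest-head geometry the rule-based linker assumes —
and surface forms are drawn from the shipped normalization lexicons,
including abbreviations ("dtr") and brand names ("Aricept") at
configurable rates, mimicking the surface variability of real notes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .ontology import Entity, EntityLabel, Relation, RelationLabel, Span

# Surface pools.  Symptom/medication/caregiver surfaces are all covered
# by the shipped lexicons (normalizer totality is a tested invariant).
SX_SURFACES = (
    "memory loss", "loss of memory", "memory problems", "memory lapses",
    "poor memory", "trouble remembering", "difficulty remembering",
    "forgetfulness", "forgetting things", "short term memory loss",
    "poor short term memory", "confusion", "episodes of confusion",
    "cognitive decline", "cognitive impairment", "memory impairment",
)

DX_SURFACES = (
    "dementia", "Alzheimer disease", "Alzheimer's disease",
    "vascular dementia", "senile dementia", "major neurocognitive disorder",
)

DURATION_SURFACES = (
    "2 years", "6 months", "3 months", "18 months", "a year",
    "several months", "3 weeks", "the past year",
)

STATUS_SURFACES = (
    "worsening", "getting worse", "progressively worse", "declining",
    "noticeably worse",
)

OTHER_SX_SURFACES = (
    "agitation", "insomnia", "anxiety", "apathy", "wandering at night",
    "irritability", "poor appetite",
)

TEST_SURFACES = (
    "MMSE score of 22", "MMSE 24/30", "MoCA score of 19", "MoCA 21/30",
    "SLUMS score of 20", "clock drawing test abnormal",
    "mini cog 2/5",
)

TEMPORAL_SURFACES = (
    "today", "last month", "earlier this year", "this week",
    "at the last visit",
)

#: canonical caregiver relation -> (display surface, optional abbreviation)
CAREGIVER_SURFACES: Dict[str, Tuple[str, Optional[str]]] = {
    "husband": ("husband", None),
    "wife": ("wife", None),
    "daughter": ("daughter", "dtr"),
    "son": ("son", None),
    "son_in_law": ("son-in-law", None),
    "daughter_in_law": ("daughter-in-law", "DIL"),
    "grandson": ("grandson", None),
    "granddaughter": ("granddaughter", "gdtr"),
    "nephew": ("nephew", None),
    "niece": ("niece", None),
    "cousin": ("cousin", None),
    "brother": ("brother", "bro"),
    "sister": ("sister", "sis"),
}

#: generic -> brand
MEDICATION_BRANDS = {
    "donepezil": "Aricept",
    "memantine": "Namenda",
    "rivastigmine": "Exelon",
    "galantamine": "Razadyne",
}

DISTRACTOR_SENTENCES = (
    "Knee pain stable on current regimen.",
    "Follows up for hypertension and diabetes.",
    "BP 132/78, HR 72, afebrile.",
    "Denies chest pain or shortness of breath.",
    "Medication list reviewed and reconciled.",
    "Lungs clear to auscultation bilaterally.",
    "Continues physical therapy for low back pain.",
    "Annual wellness visit, immunizations up to date.",
)


@dataclass(frozen=True)
class Slot:
    """A typed hole in a template; ``pool`` names the surface source."""

    label: EntityLabel
    pool: str


Part = Union[str, Slot]


@dataclass(frozen=True)
class Template:
    """Sentence skeleton plus the relations among its slots.

    ``relations`` holds ``(relation, head_slot, tail_slot)`` triples with
    slot positions counted over the slots in order of appearance.
    """

    name: str
    parts: Tuple[Part, ...]
    relations: Tuple[Tuple[RelationLabel, int, int], ...] = ()


def _sx(pool: str = "sx") -> Slot:
    return Slot(EntityLabel.SX, pool)


COMPLAINT_TEMPLATES: Tuple[Template, ...] = (
    Template("complaint_duration",
             ("Pt c/o ", _sx(), " for ",
              Slot(EntityLabel.DURATION, "duration"), "."),
             ((RelationLabel.HAS_DURATION_INFO, 0, 1),)),
    Template("complaint_plain",
             ("Patient reports ", _sx(), " at home."), ()),
    Template("complaint_status_duration",
             ("Reports ", _sx(), ", ",
              Slot(EntityLabel.STATUS_CHANGE_WORSE, "status"), " over ",
              Slot(EntityLabel.DURATION, "duration"), "."),
             ((RelationLabel.HAS_STATUS_CHANGE_INFO, 0, 1),
              (RelationLabel.HAS_DURATION_INFO, 0, 2))),
    Template("complaint_temporal",
             (_sx(), " first noticed ",
              Slot(EntityLabel.TEMPORAL, "temporal"), "."),
             ((RelationLabel.HAS_COMPLAINT_DATE, 0, 1),)),
    Template("complaint_other_symptom",
             ("Presents with ", _sx(), " along with ",
              Slot(EntityLabel.OTHER_SYMPTOM, "other"), "."),
             ((RelationLabel.HAS_OTHER_SYMPTOM_INFO, 0, 1),)),
    Template("complaint_test",
             ("Evaluated for ", _sx(), "; ",
              Slot(EntityLabel.COG_TEST_RESULT, "test"), "."),
             ((RelationLabel.HAS_TEST_INFO, 0, 1),)),
    Template("complaint_status",
             ("Notes ", _sx(), ", ",
              Slot(EntityLabel.STATUS_CHANGE_WORSE, "status"),
              " per family."),
             ((RelationLabel.HAS_STATUS_CHANGE_INFO, 0, 1),)),
)

CAREGIVER_TEMPLATES: Tuple[Template, ...] = (
    Template("caregiver_reports",
             (Slot(EntityLabel.CAREGIVER_RELATION, "caregiver"),
              " reports ", _sx(), " at home."),
             ((RelationLabel.HAS_CAREGIVER_INFO, 1, 0),)),
    Template("caregiver_accompanied",
             ("Accompanied by ",
              Slot(EntityLabel.CAREGIVER_RELATION, "caregiver"),
              " who describes ", _sx(), "."),
             ((RelationLabel.HAS_CAREGIVER_INFO, 1, 0),)),
    Template("caregiver_duration",
             ("Per ", Slot(EntityLabel.CAREGIVER_RELATION, "caregiver"),
              ", ", _sx(), " for ",
              Slot(EntityLabel.DURATION, "duration"), "."),
             ((RelationLabel.HAS_CAREGIVER_INFO, 1, 0),
              (RelationLabel.HAS_DURATION_INFO, 1, 2))),
)

MEDICATION_TEMPLATES: Tuple[Template, ...] = (
    Template("med_treatment",
             ("Started ", Slot(EntityLabel.RX, "rx"), " for ", _sx(), "."),
             ((RelationLabel.HAS_TREATMENT_INFO, 1, 0),)),
    Template("med_continue",
             ("Will continue ", Slot(EntityLabel.RX, "rx"),
              " at current dose."), ()),
    Template("med_effect",
             ("On ", Slot(EntityLabel.RX, "rx"), " but ",
              Slot(EntityLabel.STATUS_CHANGE_WORSE, "status"),
              " per family."),
             ((RelationLabel.HAS_EFFECTS, 0, 1),)),
)

DX_TEMPLATES: Tuple[Template, ...] = (
    Template("dx_assessment",
             ("Assessment: ", Slot(EntityLabel.DX, "dx"), "."), ()),
    Template("dx_temporal",
             ("Diagnosed with ", Slot(EntityLabel.DX, "dx"), " ",
              Slot(EntityLabel.TEMPORAL, "temporal"), "."),
             ((RelationLabel.HAS_DIAGNOSIS_DATE, 0, 1),)),
    Template("dx_consistent",
             ("Clinical picture consistent with ",
              Slot(EntityLabel.DX, "dx"), "."), ()),
)


@dataclass
class NoiseKnobs:
    """Rates of the surface-variability phenomena found in real notes."""

    abbreviation_rate: float = 0.3   # "dtr" instead of "daughter"
    brand_rate: float = 0.5          # "Aricept" instead of "donepezil"
    distractor_rate: float = 0.5     # unrelated sentence appended to a note


class SurfaceSampler:
    """Draws surface strings for slots, honouring the noise knobs."""

    def __init__(self, rng: np.random.Generator,
                 knobs: Optional[NoiseKnobs] = None):
        self.rng = rng
        self.knobs = knobs or NoiseKnobs()

    def _pick(self, seq: Sequence[str]) -> str:
        return seq[int(self.rng.integers(len(seq)))]

    def surface(self, pool: str, context: Dict[str, str]) -> str:
        if pool == "sx":
            return self._pick(SX_SURFACES)
        if pool == "dx":
            return self._pick(DX_SURFACES)
        if pool == "duration":
            return self._pick(DURATION_SURFACES)
        if pool == "status":
            return self._pick(STATUS_SURFACES)
        if pool == "other":
            return self._pick(OTHER_SX_SURFACES)
        if pool == "test":
            return self._pick(TEST_SURFACES)
        if pool == "temporal":
            month_year = context.get("month_year")
            options = TEMPORAL_SURFACES + ((f"in {month_year}",)
                                           if month_year else ())
            return self._pick(options)
        if pool == "caregiver":
            relation = context["caregiver_relation"]
            display, abbr = CAREGIVER_SURFACES[relation]
            if abbr is not None and self.rng.random() < self.knobs.abbreviation_rate:
                return abbr
            return display
        if pool == "rx":
            generic = context.get("medication") or self._pick(
                sorted(MEDICATION_BRANDS))
            if self.rng.random() < self.knobs.brand_rate:
                return MEDICATION_BRANDS[generic]
            return generic
        raise KeyError(f"unknown surface pool {pool!r}")


def fill_template(template: Template, sampler: SurfaceSampler,
                  context: Dict[str, str]
                  ) -> Tuple[str, List[Tuple[EntityLabel, int, int, str]],
                             List[Tuple[RelationLabel, int, int]]]:
    """Render one sentence.

    Returns the text, entity tuples ``(label, start, end, surface)`` with
    offsets relative to the sentence start, and the template's relations
    as slot-index pairs.
    """
    text_parts: List[str] = []
    entities: List[Tuple[EntityLabel, int, int, str]] = []
    pos = 0
    for part in template.parts:
        if isinstance(part, Slot):
            surface = sampler.surface(part.pool, context)
            if pos == 0:
                surface = surface[0].upper() + surface[1:]
            entities.append((part.label, pos, pos + len(surface), surface))
            text_parts.append(surface)
            pos += len(surface)
        else:
            text_parts.append(part)
            pos += len(part)
    return "".join(text_parts), entities, list(template.relations)


def render_note(templates: Sequence[Template], sampler: SurfaceSampler,
                context: Dict[str, str],
                distractors_before: int = 0, distractors_after: int = 0
                ) -> Tuple[str, List[Entity], List[Relation]]:
    """Assemble a note from sentence templates plus distractor sentences.

    Entities get document-unique ids ``T1..``, relations ``R1..``; every
    offset is exact by construction (and re-validated by the note model).
    """
    rng = sampler.rng
    sentences: List[Tuple[str, list, list]] = []
    for _ in range(distractors_before):
        sentences.append((sampler._pick(DISTRACTOR_SENTENCES), [], []))
    for template in templates:
        sentences.append(fill_template(template, sampler, context))
    for _ in range(distractors_after):
        sentences.append((sampler._pick(DISTRACTOR_SENTENCES), [], []))

    text_parts: List[str] = []
    entities: List[Entity] = []
    relations: List[Relation] = []
    offset = 0
    t_id = r_id = 0
    for sent_text, sent_entities, sent_relations in sentences:
        slot_ids: List[str] = []
        for label, s, e, surface in sent_entities:
            t_id += 1
            eid = f"T{t_id}"
            slot_ids.append(eid)
            entities.append(
                Entity(eid, label, Span(offset + s, offset + e), surface))
        for rel, head_i, tail_i in sent_relations:
            r_id += 1
            relations.append(
                Relation(f"R{r_id}", rel, slot_ids[head_i], slot_ids[tail_i]))
        text_parts.append(sent_text)
        offset += len(sent_text) + 1  # single joining space
    return " ".join(text_parts), entities, relations
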