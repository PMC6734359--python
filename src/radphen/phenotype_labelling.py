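"""Map non-negated disease mentions and their relations to the 24
document-level phenotype labels.

The label inventory crosses stroke type with location (deep vs cortical,
rendered "lobar" for bleeds) and age (recent vs old); presence phenotypes
(atrophy, small vessel disease, subdural haematoma, haemorrhagic
transformation) need only a non-negated mention in the body or conclusion.
A stroke mention lacking a complete (location, time) pair maps to that
stroke type's "underspecified" label.  A report carries a *set* of labels:
duplicate evidence yields one label, and negated or request-section mentions
yield nothing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .entity_annotation import Entity, Relation
from .types import DiseaseType, ModifierType

log = logging.getLogger(__name__)


class Phenotype(str, Enum):
    ATROPHY = "Atrophy"
    SMALL_VESSEL_DISEASE = "Small vessel disease"
    STROKE_UNDERSPECIFIED = "Stroke, underspecified"
    HAEMORRHAGIC_DEEP_OLD = "Haemorrhagic stroke, deep, old"
    HAEMORRHAGIC_DEEP_RECENT = "Haemorrhagic stroke, deep, recent"
    HAEMORRHAGIC_LOBAR_OLD = "Haemorrhagic stroke, lobar, old"
    HAEMORRHAGIC_LOBAR_RECENT = "Haemorrhagic stroke, lobar, recent"
    HAEMORRHAGIC_UNDERSPECIFIED = "Haemorrhagic stroke, underspecified"
    ISCHAEMIC_CORTICAL_OLD = "Ischaemic stroke, cortical, old"
    ISCHAEMIC_CORTICAL_RECENT = "Ischaemic stroke, cortical, recent"
    ISCHAEMIC_DEEP_OLD = "Ischaemic stroke, deep, old"
    ISCHAEMIC_DEEP_RECENT = "Ischaemic stroke, deep, recent"
    ISCHAEMIC_UNDERSPECIFIED = "Ischaemic stroke, underspecified"
    HAEMORRHAGIC_TRANSFORMATION = "Haemorrhagic transformation"
    SUBDURAL_HAEMATOMA = "Subdural haematoma"
    SAH_ANEURYSMAL = "Subarachnoid haemorrhage, aneurysmal"
    SAH_OTHER = "Subarachnoid haemorrhage, other"
    MICROBLEED_DEEP = "Microbleed, deep"
    MICROBLEED_LOBAR = "Microbleed, lobar"
    MICROBLEED_UNDERSPECIFIED = "Microbleed, underspecified"
    TUMOUR_GLIOMA = "Tumour, glioma"
    TUMOUR_MENINGIOMA = "Tumour, meningioma"
    TUMOUR_METASTASIS = "Tumour, metastasis"
    TUMOUR_OTHER = "Tumour, other"

    @property
    def slug(self) -> str:
        return re.sub(r"[^a-z0-9]+", "_", self.value.lower()).strip("_")


ALL_PHENOTYPES: tuple[Phenotype, ...] = tuple(Phenotype)
assert len(ALL_PHENOTYPES) == 24

_SLUG_TO_PHENOTYPE = {p.slug: p for p in Phenotype}


def phenotype_from_slug(slug: str) -> Phenotype:
    return _SLUG_TO_PHENOTYPE[slug]


#: Aggregate rows reported alongside the 24 labels when evaluating.
AGGREGATES: Mapping[str, tuple[Phenotype, ...]] = {
    "Any haemorrhagic stroke": (
        Phenotype.HAEMORRHAGIC_DEEP_OLD, Phenotype.HAEMORRHAGIC_DEEP_RECENT,
        Phenotype.HAEMORRHAGIC_LOBAR_OLD, Phenotype.HAEMORRHAGIC_LOBAR_RECENT,
        Phenotype.HAEMORRHAGIC_UNDERSPECIFIED,
    ),
    "Any ischaemic stroke": (
        Phenotype.ISCHAEMIC_CORTICAL_OLD, Phenotype.ISCHAEMIC_CORTICAL_RECENT,
        Phenotype.ISCHAEMIC_DEEP_OLD, Phenotype.ISCHAEMIC_DEEP_RECENT,
        Phenotype.ISCHAEMIC_UNDERSPECIFIED,
    ),
    "Any tumour": (
        Phenotype.TUMOUR_GLIOMA, Phenotype.TUMOUR_MENINGIOMA,
        Phenotype.TUMOUR_METASTASIS, Phenotype.TUMOUR_OTHER,
    ),
}


@dataclass
class LabelledReport:
    report_id: str
    labels: set[Phenotype] = field(default_factory=set)
    provenance: dict[Phenotype, tuple[str, ...]] = field(default_factory=dict)


_PRESENCE = {
    DiseaseType.ATROPHY: Phenotype.ATROPHY,
    DiseaseType.SMALL_VESSEL_DISEASE: Phenotype.SMALL_VESSEL_DISEASE,
    DiseaseType.SUBDURAL_HAEMATOMA: Phenotype.SUBDURAL_HAEMATOMA,
    DiseaseType.HAEMORRHAGIC_TRANSFORMATION: Phenotype.HAEMORRHAGIC_TRANSFORMATION,
}

_STROKE_GRID = {
    (DiseaseType.ISCHAEMIC_STROKE, "cortical", "old"): Phenotype.ISCHAEMIC_CORTICAL_OLD,
    (DiseaseType.ISCHAEMIC_STROKE, "cortical", "recent"): Phenotype.ISCHAEMIC_CORTICAL_RECENT,
    (DiseaseType.ISCHAEMIC_STROKE, "deep", "old"): Phenotype.ISCHAEMIC_DEEP_OLD,
    (DiseaseType.ISCHAEMIC_STROKE, "deep", "recent"): Phenotype.ISCHAEMIC_DEEP_RECENT,
    (DiseaseType.HAEMORRHAGIC_STROKE, "cortical", "old"): Phenotype.HAEMORRHAGIC_LOBAR_OLD,
    (DiseaseType.HAEMORRHAGIC_STROKE, "cortical", "recent"): Phenotype.HAEMORRHAGIC_LOBAR_RECENT,
    (DiseaseType.HAEMORRHAGIC_STROKE, "deep", "old"): Phenotype.HAEMORRHAGIC_DEEP_OLD,
    (DiseaseType.HAEMORRHAGIC_STROKE, "deep", "recent"): Phenotype.HAEMORRHAGIC_DEEP_RECENT,
}

_TUMOUR = {
    "glioma": Phenotype.TUMOUR_GLIOMA,
    "meningioma": Phenotype.TUMOUR_MENINGIOMA,
    "metastasis": Phenotype.TUMOUR_METASTASIS,
    "other": Phenotype.TUMOUR_OTHER,
    None: Phenotype.TUMOUR_OTHER,
}

_LOC = {ModifierType.LOC_DEEP: "deep", ModifierType.LOC_CORTICAL: "cortical"}
_TIME = {ModifierType.TIME_OLD: "old", ModifierType.TIME_RECENT: "recent"}

ELIGIBLE_SECTIONS = ("body", "conclusion")


def assign_labels(
    entities: Sequence[Entity],
    relations: Sequence[Relation] = (),
    report_id: str = "",
) -> LabelledReport:
    """Pure mapping from mark-up to the phenotype label set.

    Only non-negated disease mentions in the body or conclusion contribute;
    relations whose target is negated or ineligible are ignored (with a
    logged warning for negated targets, since they indicate an upstream
    inconsistency in hand-built annotation).
    """
    result = LabelledReport(report_id)

    def add(label: Phenotype, *support: Entity) -> None:
        result.labels.add(label)
        ids = tuple(e.id or f"E{i}" for i, e in enumerate(support))
        result.provenance.setdefault(label, ids)

    by_target: dict[int, list[Relation]] = {}
    for rel in relations:
        if rel.target.negated:
            log.warning("ignoring %s relation to negated mention %s",
                        rel.kind, rel.target.id or rel.target.etype.value)
            continue
        by_target.setdefault(id(rel.target), []).append(rel)

    aneurysmal_sentences = {
        e.sentence_index for e in entities
        if e.etype is ModifierType.MOD_ANEURYSMAL
    }

    for ent in entities:
        if not ent.is_disease or ent.negated:
            continue
        if ent.section_kind not in ELIGIBLE_SECTIONS:
            continue
        etype = ent.etype
        rels = by_target.get(id(ent), [])
        locs = sorted({_LOC[r.modifier.etype] for r in rels if r.modifier.etype in _LOC})
        times = sorted({_TIME[r.modifier.etype] for r in rels if r.modifier.etype in _TIME})
        mods = [r.modifier for r in rels]
        if etype in _PRESENCE:
            add(_PRESENCE[etype], ent)
        elif etype in (DiseaseType.ISCHAEMIC_STROKE, DiseaseType.HAEMORRHAGIC_STROKE):
            if locs and times:
                for loc in locs:
                    for time in times:
                        add(_STROKE_GRID[(etype, loc, time)], ent, *mods)
            else:
                under = (Phenotype.ISCHAEMIC_UNDERSPECIFIED
                         if etype is DiseaseType.ISCHAEMIC_STROKE
                         else Phenotype.HAEMORRHAGIC_UNDERSPECIFIED)
                add(under, ent, *mods)
        elif etype is DiseaseType.STROKE_UNSPECIFIED:
            add(Phenotype.STROKE_UNDERSPECIFIED, ent)
        elif etype is DiseaseType.MICROBLEED:
            if "deep" in locs:
                add(Phenotype.MICROBLEED_DEEP, ent, *mods)
            elif "cortical" in locs:
                add(Phenotype.MICROBLEED_LOBAR, ent, *mods)
            else:
                add(Phenotype.MICROBLEED_UNDERSPECIFIED, ent)
        elif etype is DiseaseType.SUBARACHNOID_HAEMORRHAGE:
            if ent.subtype == "aneurysmal" or ent.sentence_index in aneurysmal_sentences:
                add(Phenotype.SAH_ANEURYSMAL, ent)
            else:
                add(Phenotype.SAH_OTHER, ent)
        elif etype is DiseaseType.TUMOUR:
            add(_TUMOUR.get(ent.subtype, Phenotype.TUMOUR_OTHER), ent)
    return result
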