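"""Shared closed vocabularies and span primitives.

The disease and modifier inventories are the two entity families the
annotation scheme distinguishes: diseases are the findings a report can
assert (infarcts, bleeds, tumours, ...) and modifiers are the time/location
qualifiers that refine a stroke finding into a document-level phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class DiseaseType(str, Enum):
    """Finding categories recognised in report text."""

    ISCHAEMIC_STROKE = "ischaemic_stroke"
    HAEMORRHAGIC_STROKE = "haemorrhagic_stroke"
    STROKE_UNSPECIFIED = "stroke_unspecified"
    SUBARACHNOID_HAEMORRHAGE = "subarachnoid_haemorrhage"
    SUBDURAL_HAEMATOMA = "subdural_haematoma"
    MICROBLEED = "microbleed"
    HAEMORRHAGIC_TRANSFORMATION = "haemorrhagic_transformation"
    ATROPHY = "atrophy"
    SMALL_VESSEL_DISEASE = "small_vessel_disease"
    TUMOUR = "tumour"


class ModifierType(str, Enum):
    """Qualifier categories that attach to disease mentions."""

    TIME_RECENT = "time_recent"
    TIME_OLD = "time_old"
    LOC_DEEP = "loc_deep"
    LOC_CORTICAL = "loc_cortical"
    MOD_ANEURYSMAL = "mod_aneurysmal"


#: Tumour subtypes carried in the lexicon and surfaced as separate labels.
TUMOUR_SUBTYPES = ("glioma", "meningioma", "metastasis", "other")

#: Coarse part-of-speech tagset; downstream rules only consult
#: NOUN/VERB/ADJ/ADV/DET, the rest exist so every token gets a tag.
POS_TAGS = (
    "NOUN", "VERB", "ADJ", "ADV", "DET", "PREP", "CONJ", "NUM", "PUNCT", "OTHER",
)


@dataclass(frozen=True, order=True)
class Span:
    """0-based, half-open character interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end


def entity_type_from_string(name: str) -> tuple[DiseaseType | ModifierType, str | None]:
    """Parse an entity-type string, e.g. ``"tumour:metastasis"`` or
    ``"tumour_metastasis"`` -> (TUMOUR, "metastasis").  Plain names map to
    (type, None)."""
    name = name.strip().lower().replace(":", "_")
    for sub in TUMOUR_SUBTYPES:
        if name == f"tumour_{sub}":
            return DiseaseType.TUMOUR, sub
    try:
        return DiseaseType(name), None
    except ValueError:
        pass
    try:
        return ModifierType(name), None
    except ValueError:
        raise ValueError(f"unknown entity type: {name!r}") from None


def entity_type_to_string(etype: DiseaseType | ModifierType, subtype: str | None) -> str:
    if etype is DiseaseType.TUMOUR and subtype:
        return f"tumour_{subtype}"
    return etype.value
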