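"""Synthetic radiology-report corpus with gold annotations.

Real NHS report corpora sit behind data governance, so every other module
is exercised against generated reports that emulate their structure: a
request line (clinical question), a findings body rich in
negation and hedging, and a conclusion.  Each report samples a phenotype
label set from configurable prevalences (defaulting to the regional test-set
mix), realises every label with a findings sentence placing the disease term
and any required time/location modifiers (attributively inside the noun
phrase or predicatively after a copula), and injects negated distractor
findings plus neutral filler sentences.  Gold entities, relations, negation
flags and document labels are emitted with exact character offsets.

Two stress knobs mirror known failure modes of dictionary-based extraction:
``variant_rate`` swaps canonical terms for spelling/hyphenation variants
(which a correct lexicon still hits) and ``paraphrase_rate`` swaps disease
terms for out-of-lexicon paraphrases, which degrades per-mention recall by
roughly the paraphrase rate.

Generation is fully deterministic given the seed, and every generated report
is checked for self-consistency: running the label-assignment rules over the
gold mark-up must reproduce the intended label set exactly.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

from .corpus_io import (
    Report,
    StandoffDocument,
    StandoffEntity,
    StandoffRelation,
    write_standoff,
    zone_report,
)
from .entity_annotation import Entity, Relation
from .phenotype_labelling import Phenotype, assign_labels
from .text_processing import segment
from .types import DiseaseType, ModifierType, Span, entity_type_to_string

# ---------------------------------------------------------------------------
# Prevalence profiles

#: Regional hospital test-set mix: per-phenotype report counts out of 700.
#: Suppressed small cells are instantiated from the gold denominators
#: recoverable from the published per-phenotype sensitivities.
REGIONAL_TEST_COUNTS: Mapping[Phenotype, int] = {
    Phenotype.ATROPHY: 164,
    Phenotype.SMALL_VESSEL_DISEASE: 145,
    Phenotype.STROKE_UNDERSPECIFIED: 3,
    Phenotype.HAEMORRHAGIC_DEEP_OLD: 2,
    Phenotype.HAEMORRHAGIC_DEEP_RECENT: 2,
    Phenotype.HAEMORRHAGIC_LOBAR_OLD: 3,
    Phenotype.HAEMORRHAGIC_LOBAR_RECENT: 4,
    Phenotype.HAEMORRHAGIC_UNDERSPECIFIED: 15,
    Phenotype.ISCHAEMIC_CORTICAL_OLD: 26,
    Phenotype.ISCHAEMIC_CORTICAL_RECENT: 12,
    Phenotype.ISCHAEMIC_DEEP_OLD: 41,
    Phenotype.ISCHAEMIC_DEEP_RECENT: 4,
    Phenotype.ISCHAEMIC_UNDERSPECIFIED: 15,
    Phenotype.HAEMORRHAGIC_TRANSFORMATION: 2,
    Phenotype.SUBDURAL_HAEMATOMA: 8,
    Phenotype.SAH_ANEURYSMAL: 1,
    Phenotype.SAH_OTHER: 7,
    Phenotype.MICROBLEED_DEEP: 1,
    Phenotype.MICROBLEED_LOBAR: 1,
    Phenotype.MICROBLEED_UNDERSPECIFIED: 3,
    Phenotype.TUMOUR_GLIOMA: 3,
    Phenotype.TUMOUR_MENINGIOMA: 2,
    Phenotype.TUMOUR_METASTASIS: 37,
    Phenotype.TUMOUR_OTHER: 12,
}

REGIONAL_TEST_PREVALENCES: Mapping[Phenotype, float] = {
    p: c / 700 for p, c in REGIONAL_TEST_COUNTS.items()
}

#: Routine-practice mix (atrophy-heavy, microbleeds vanishingly rare):
#: per-phenotype report counts out of 110,695 unselected scans.
ROUTINE_COUNTS: Mapping[Phenotype, int] = {
    Phenotype.ATROPHY: 28_757,
    Phenotype.SMALL_VESSEL_DISEASE: 15_015,
    Phenotype.STROKE_UNDERSPECIFIED: 1_609,
    Phenotype.HAEMORRHAGIC_DEEP_OLD: 168,
    Phenotype.HAEMORRHAGIC_DEEP_RECENT: 397,
    Phenotype.HAEMORRHAGIC_LOBAR_OLD: 288,
    Phenotype.HAEMORRHAGIC_LOBAR_RECENT: 415,
    Phenotype.HAEMORRHAGIC_UNDERSPECIFIED: 5_702,
    Phenotype.ISCHAEMIC_CORTICAL_OLD: 4_385,
    Phenotype.ISCHAEMIC_CORTICAL_RECENT: 1_860,
    Phenotype.ISCHAEMIC_DEEP_OLD: 10_636,
    Phenotype.ISCHAEMIC_DEEP_RECENT: 771,
    Phenotype.ISCHAEMIC_UNDERSPECIFIED: 9_172,
    Phenotype.HAEMORRHAGIC_TRANSFORMATION: 279,
    Phenotype.SUBDURAL_HAEMATOMA: 2_272,
    Phenotype.SAH_ANEURYSMAL: 55,
    Phenotype.SAH_OTHER: 1_381,
    Phenotype.MICROBLEED_DEEP: 15,
    Phenotype.MICROBLEED_LOBAR: 5,
    Phenotype.MICROBLEED_UNDERSPECIFIED: 19,
    Phenotype.TUMOUR_GLIOMA: 667,
    Phenotype.TUMOUR_MENINGIOMA: 1_458,
    Phenotype.TUMOUR_METASTASIS: 2_621,
    Phenotype.TUMOUR_OTHER: 4_191,
}

ROUTINE_PREVALENCES: Mapping[Phenotype, float] = {
    p: c / 110_695 for p, c in ROUTINE_COUNTS.items()
}

PROFILES = {
    "regional-test": REGIONAL_TEST_PREVALENCES,
    "routine-practice": ROUTINE_PREVALENCES,
}


@dataclass
class SynthConfig:
    n_reports: int = 700
    phenotype_prevalences: Mapping[Phenotype, float] = field(
        default_factory=lambda: dict(REGIONAL_TEST_PREVALENCES)
    )
    negated_distractor_rate: float = 0.3
    variant_rate: float = 0.2
    paraphrase_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        rates = [self.negated_distractor_rate, self.variant_rate, self.paraphrase_rate]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("rates must be probabilities in [0, 1]")
        for p, prob in self.phenotype_prevalences.items():
            if p not in _TEMPLATES:
                raise ValueError(f"no sentence template for phenotype {p!r}")
            if not 0 <= prob <= 1:
                raise ValueError(f"prevalence for {p.value} outside [0, 1]")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_reports": self.n_reports,
                "phenotype_prevalences": {
                    p.slug: v for p, v in self.phenotype_prevalences.items()
                },
                "negated_distractor_rate": self.negated_distractor_rate,
                "variant_rate": self.variant_rate,
                "paraphrase_rate": self.paraphrase_rate,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SynthReport:
    report: Report
    gold: StandoffDocument
    labels: set[Phenotype]
    #: pipeline-level views of the gold mark-up, for direct rule checks
    entities: list[Entity] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Sentence construction

_A = DiseaseType  # short alias in tables below


@dataclass
class _GoldEnt:
    start: int
    end: int
    etype: DiseaseType | ModifierType
    subtype: Optional[str] = None
    negated: bool = False


@dataclass
class _SentenceGold:
    text: str
    entities: list[_GoldEnt]
    relations: list[tuple[str, int, int]]  # (kind, modifier idx, disease idx)


class _SB:
    """Tiny sentence builder tracking entity offsets while concatenating."""

    def __init__(self) -> None:
        self._parts: list[str] = []
        self._len = 0
        self.entities: list[_GoldEnt] = []
        self.relations: list[tuple[str, int, int]] = []

    def lit(self, text: str) -> "_SB":
        self._parts.append(text)
        self._len += len(text)
        return self

    def ent(self, surface: str, etype, subtype=None, negated=False) -> int:
        start = self._len
        self.lit(surface)
        self.entities.append(_GoldEnt(start, self._len, etype, subtype, negated))
        return len(self.entities) - 1

    def rel(self, kind: str, mod: int, dis: int) -> "_SB":
        self.relations.append((kind, mod, dis))
        return self

    def build(self) -> _SentenceGold:
        text = "".join(self._parts)
        # capitalise the first alphabetic character
        for i, c in enumerate(text):
            if c.isalpha():
                text = text[:i] + c.upper() + text[i + 1:]
                break
        return _SentenceGold(text, self.entities, self.relations)


def _art(word: str) -> str:
    return "an" if word[0].lower() in "aeiou" else "a"


def _pick(rng: random.Random, canonical: str, variants: Sequence[str], rate: float) -> str:
    if variants and rng.random() < rate:
        return rng.choice(list(variants))
    return canonical


# term pools: canonical first, then accepted spelling/lexical variants
_DIS_TERMS: dict[str, tuple[str, tuple[str, ...]]] = {
    "ischaemic": ("infarct", ("infarction", "ischaemic stroke", "cerebral infarct")),
    "haemorrhagic": ("haemorrhage", ("haematoma", "hemorrhage", "intracerebral haemorrhage")),
    "haemorrhagic_bare": ("haemorrhage", ("haematoma", "hemorrhage")),
    "stroke": ("stroke", ("CVA", "cerebrovascular accident")),
    "sah": ("subarachnoid haemorrhage", ("subarachnoid blood", "SAH")),
    "sdh": ("subdural haematoma", ("subdural collection", "subdural haemorrhage", "subdural hematoma")),
    "microbleed": ("microbleed", ("microhaemorrhage",)),
    "ht": ("haemorrhagic transformation", ("haemorrhagic conversion",)),
    "atrophy": ("atrophy", ("cerebral atrophy", "involution", "volume loss")),
    "svd": ("small vessel disease", ("leukoaraiosis", "microangiopathy", "white matter low attenuation")),
    "glioma": ("glioma", ("glioblastoma", "astrocytoma")),
    "meningioma": ("meningioma", ()),
    "metastases": ("metastases", ("secondary deposits", "metastatic deposits")),
    "mass": ("mass", ("tumour", "lesion", "mass lesion")),
}

#: out-of-lexicon paraphrases per disease slot (the unseen-phrasing stress)
_PARAPHRASES: dict[str, str] = {
    "ischaemic": "area of encephalomalacia",
    "haemorrhagic": "focus of extravasated density",
    "haemorrhagic_bare": "focus of extravasated density",
    "stroke": "cerebrovascular insult",
    "sah": "sulcal hyperdensity",
    "sdh": "crescentic extra-axial collection",
    "microbleed": "punctate susceptibility focus",
    "ht": "petechial change within the affected territory",
    "atrophy": "widening of the sulcal spaces",
    "svd": "confluent white matter change",
    "glioma": "infiltrative intrinsic process",
    "meningioma": "dural-based extra-axial growth",
    "metastases": "secondary neoplastic deposits",
    "mass": "enhancing focal abnormality",
}

_DIS_TYPE: dict[str, tuple[DiseaseType, Optional[str]]] = {
    "ischaemic": (_A.ISCHAEMIC_STROKE, None),
    "haemorrhagic": (_A.HAEMORRHAGIC_STROKE, None),
    "haemorrhagic_bare": (_A.HAEMORRHAGIC_STROKE, None),
    "stroke": (_A.STROKE_UNSPECIFIED, None),
    "sah": (_A.SUBARACHNOID_HAEMORRHAGE, None),
    "sdh": (_A.SUBDURAL_HAEMATOMA, None),
    "microbleed": (_A.MICROBLEED, None),
    "ht": (_A.HAEMORRHAGIC_TRANSFORMATION, None),
    "atrophy": (_A.ATROPHY, None),
    "svd": (_A.SMALL_VESSEL_DISEASE, None),
    "glioma": (_A.TUMOUR, "glioma"),
    "meningioma": (_A.TUMOUR, "meningioma"),
    "metastases": (_A.TUMOUR, "metastasis"),
    "mass": (_A.TUMOUR, "other"),
}

_TIME_TERMS = {
    "recent": ("acute", ("recent", "new")),
    "old": ("old", ("chronic", "established", "mature")),
}
_LOC_TERMS = {
    "deep": ("lacunar", ("thalamic", "basal ganglia", "deep")),
    "cortical": ("frontal", ("parietal", "temporal", "occipital")),
}
_TIME_TYPE = {"recent": ModifierType.TIME_RECENT, "old": ModifierType.TIME_OLD}
_LOC_TYPE = {"deep": ModifierType.LOC_DEEP, "cortical": ModifierType.LOC_CORTICAL}


def _disease(b: _SB, rng: random.Random, slot: str, cfg: SynthConfig) -> int:
    etype, subtype = _DIS_TYPE[slot]
    if rng.random() < cfg.paraphrase_rate:
        surface = _PARAPHRASES[slot]
    else:
        canon, variants = _DIS_TERMS[slot]
        surface = _pick(rng, canon, variants, cfg.variant_rate)
    return b.ent(surface, etype, subtype)


def _stroke_template(slot: str, loc: str, time: str):
    def make(rng: random.Random, cfg: SynthConfig) -> _SentenceGold:
        b = _SB()
        t_surf = _pick(rng, *_TIME_TERMS[time], cfg.variant_rate)
        l_surf = _pick(rng, *_LOC_TERMS[loc], cfg.variant_rate)
        side = rng.choice(["", "", "left ", "right "])
        form = rng.random()
        if form < 0.4:  # "Old left frontal infarct."
            ti = b.ent(t_surf, _TIME_TYPE[time])
            b.lit(" " + side)
            li = b.ent(l_surf, _LOC_TYPE[loc])
            b.lit(" ")
            di = _disease(b, rng, slot, cfg)
            b.lit(".")
        elif form < 0.75:  # "There is an old frontal infarct."
            b.lit(f"There is {_art(t_surf)} ")
            ti = b.ent(t_surf, _TIME_TYPE[time])
            b.lit(" " + side)
            li = b.ent(l_surf, _LOC_TYPE[loc])
            b.lit(" ")
            di = _disease(b, rng, slot, cfg)
            b.lit(".")
        else:  # predicative: "The frontal infarct is old."
            b.lit("The " + side)
            li = b.ent(l_surf, _LOC_TYPE[loc])
            b.lit(" ")
            di = _disease(b, rng, slot, cfg)
            b.lit(" is ")
            ti = b.ent(t_surf, _TIME_TYPE[time])
            b.lit(".")
        b.rel("time", ti, di).rel("location", li, di)
        return b.build()

    return make


def _simple_template(slot: str, forms: Sequence[str]):
    """Forms use ``{art}`` and ``{d}`` placeholders around a single disease
    mention; split on ``{d}`` to keep offsets exact."""

    def make(rng: random.Random, cfg: SynthConfig) -> _SentenceGold:
        b = _SB()
        form = rng.choice(list(forms))
        canon, variants = _DIS_TERMS[slot]
        para = rng.random() < cfg.paraphrase_rate
        surface = _PARAPHRASES[slot] if para else _pick(rng, canon, variants, cfg.variant_rate)
        pre, post = form.split("{d}")
        b.lit(pre.replace("{art}", _art(surface)))
        etype, subtype = _DIS_TYPE[slot]
        b.ent(surface, etype, subtype)
        b.lit(post)
        return b.build()

    return make


def _hs_under_template(rng: random.Random, cfg: SynthConfig) -> _SentenceGold:
    if rng.random() < 0.25 and cfg.paraphrase_rate == 0:
        # the hard construction: contrast cue rejecting the second mention
        b = _SB()
        b.lit("I suspect this reflects redistribution of the ")
        ti = b.ent("original", ModifierType.TIME_OLD)
        b.lit(" ")
        di = b.ent("haematoma", _A.HAEMORRHAGIC_STROKE)
        b.lit(" rather than ")
        tj = b.ent("new", ModifierType.TIME_RECENT)
        b.lit(" ")
        dj = b.ent("blood", _A.HAEMORRHAGIC_STROKE, negated=True)
        b.lit(".")
        b.rel("time", ti, di).rel("time", tj, dj)
        return b.build()
    return _simple_template(
        "haemorrhagic",
        ("There is {art} {d}.", "There is evidence of {art} {d}."),
    )(rng, cfg)


def _sah_other_template(rng: random.Random, cfg: SynthConfig) -> _SentenceGold:
    if rng.random() < 0.25 and cfg.paraphrase_rate == 0:
        b = _SB()
        b.lit("There is ")
        b.ent("blood in the subarachnoid spaces", _A.SUBARACHNOID_HAEMORRHAGE)
        b.lit(".")
        return b.build()
    return _simple_template(
        "sah", ("There is {d}.", "{d} is demonstrated.")
    )(rng, cfg)


def _sah_aneurysmal_template(rng: random.Random, cfg: SynthConfig) -> _SentenceGold:
    b = _SB()
    if rng.random() < 0.5:
        b.lit("There is ")
        b.ent("aneurysmal", ModifierType.MOD_ANEURYSMAL)
        b.lit(" ")
        _disease(b, rng, "sah", cfg)
        b.lit(".")
    else:
        _disease(b, rng, "sah", cfg)
        b.lit(" secondary to an ")
        b.ent("aneurysm", ModifierType.MOD_ANEURYSMAL)
        b.lit(".")
    return b.build()


def _microbleed_template(loc: Optional[str]):
    def make(rng: random.Random, cfg: SynthConfig) -> _SentenceGold:
        b = _SB()
        canon, variants = _DIS_TERMS["microbleed"]
        para = rng.random() < cfg.paraphrase_rate
        surface = (_PARAPHRASES["microbleed"] if para
                   else _pick(rng, canon, variants, cfg.variant_rate))
        b.lit(f"There is {_art('deep' if loc else surface)} " if loc
              else f"There is {_art(surface)} ")
        li = None
        if loc:
            l_surf = "deep" if loc == "deep" else "lobar"
            li = b.ent(l_surf, _LOC_TYPE[loc])
            b.lit(" ")
        di = b.ent(surface, _A.MICROBLEED)
        b.lit(".")
        if li is not None:
            b.rel("location", li, di)
        return b.build()

    return make


_TEMPLATES: dict[Phenotype, Callable[[random.Random, SynthConfig], _SentenceGold]] = {
    Phenotype.ATROPHY: _simple_template(
        "atrophy", ("There is generalised {d}.", "{d} is noted.")),
    Phenotype.SMALL_VESSEL_DISEASE: _simple_template(
        "svd", ("There are changes of {d}.", "Appearances reflect {d}.")),
    Phenotype.STROKE_UNDERSPECIFIED: _simple_template(
        "stroke", ("There is evidence of {art} {d}.", "Imaging features of {art} {d}.")),
    Phenotype.HAEMORRHAGIC_DEEP_OLD: _stroke_template("haemorrhagic_bare", "deep", "old"),
    Phenotype.HAEMORRHAGIC_DEEP_RECENT: _stroke_template("haemorrhagic_bare", "deep", "recent"),
    Phenotype.HAEMORRHAGIC_LOBAR_OLD: _stroke_template("haemorrhagic_bare", "cortical", "old"),
    Phenotype.HAEMORRHAGIC_LOBAR_RECENT: _stroke_template("haemorrhagic_bare", "cortical", "recent"),
    Phenotype.HAEMORRHAGIC_UNDERSPECIFIED: _hs_under_template,
    Phenotype.ISCHAEMIC_CORTICAL_OLD: _stroke_template("ischaemic", "cortical", "old"),
    Phenotype.ISCHAEMIC_CORTICAL_RECENT: _stroke_template("ischaemic", "cortical", "recent"),
    Phenotype.ISCHAEMIC_DEEP_OLD: _stroke_template("ischaemic", "deep", "old"),
    Phenotype.ISCHAEMIC_DEEP_RECENT: _stroke_template("ischaemic", "deep", "recent"),
    Phenotype.ISCHAEMIC_UNDERSPECIFIED: _simple_template(
        "ischaemic", ("There is {art} {d}.", "Appearances are consistent with {art} {d}.")),
    Phenotype.HAEMORRHAGIC_TRANSFORMATION: _simple_template(
        "ht", ("There is {d}.", "Appearances suggest {d}.")),
    Phenotype.SUBDURAL_HAEMATOMA: _simple_template(
        "sdh", ("There is {art} {d}.", "{d} is present.")),
    Phenotype.SAH_ANEURYSMAL: _sah_aneurysmal_template,
    Phenotype.SAH_OTHER: _sah_other_template,
    Phenotype.MICROBLEED_DEEP: _microbleed_template("deep"),
    Phenotype.MICROBLEED_LOBAR: _microbleed_template("cortical"),
    Phenotype.MICROBLEED_UNDERSPECIFIED: _microbleed_template(None),
    Phenotype.TUMOUR_GLIOMA: _simple_template(
        "glioma", ("There is {art} {d}.", "Appearances are in keeping with {art} {d}.")),
    Phenotype.TUMOUR_MENINGIOMA: _simple_template(
        "meningioma", ("{art} {d} is demonstrated.", "There is {art} {d}.")),
    Phenotype.TUMOUR_METASTASIS: _simple_template(
        "metastases", ("There are multiple {d}.", "Multiple {d} are demonstrated.")),
    Phenotype.TUMOUR_OTHER: _simple_template(
        "mass", ("There is {art} {d} in the left hemisphere.", "There is {art} {d}.")),
}


def _distractor(rng: random.Random) -> _SentenceGold:
    choice = rng.randrange(6)
    b = _SB()
    if choice == 0:
        b.lit("No ")
        b.ent("metastases", _A.TUMOUR, "metastasis", negated=True)
        b.lit(".")
    elif choice == 1:
        b.lit("No evidence of ")
        ti = b.ent("acute", ModifierType.TIME_RECENT)
        b.lit(" ")
        di = b.ent("haemorrhage", _A.HAEMORRHAGIC_STROKE, negated=True)
        b.lit(".")
        b.rel("time", ti, di)
    elif choice == 2:
        b.lit("Exclude ")
        b.ent("subdural bleed", _A.SUBDURAL_HAEMATOMA, negated=True)
        b.lit(".")
    elif choice == 3:
        b.lit("No ")
        b.ent("mass lesion", _A.TUMOUR, "other", negated=True)
        b.lit(" is seen.")
    elif choice == 4:
        b.lit("Diffusely sclerotic ")
        b.ent("metastases", _A.TUMOUR, "metastasis", negated=True)
        b.lit(" are much less likely.")
    else:
        b.lit("Appearances are clear of ")
        b.ent("subarachnoid blood", _A.SUBARACHNOID_HAEMORRHAGE, negated=True)
        b.lit(".")
    return b.build()


_FILLERS = (
    "The ventricular system is of normal calibre.",
    "Normal appearances of the posterior fossa.",
    "Grey-white matter differentiation is preserved.",
    "The orbits are unremarkable.",
    "No hydrocephalus.",
    "Midline structures are central.",
)

_REQUESTS = (
    "Sudden onset weakness.",
    "Confusion and reduced mobility.",
    "Fall with head injury.",
    "Worsening headache.",
    "Memory impairment.",
)


def _neutral_conclusion(rng: random.Random, has_findings: bool) -> _SentenceGold:
    b = _SB()
    if has_findings:
        b.lit(rng.choice(["Appearances as described above.", "Findings as above."]))
    else:
        b.lit("No ")
        b.ent("acute", ModifierType.TIME_RECENT)
        b.lit(" intracranial abnormality.")
    return b.build()


# ---------------------------------------------------------------------------
# Corpus generation


def _sample_labels(rng: random.Random, cfg: SynthConfig) -> list[Phenotype]:
    return [p for p in Phenotype
            if rng.random() < cfg.phenotype_prevalences.get(p, 0.0)]


def generate_report(rng: random.Random, cfg: SynthConfig, report_id: str) -> SynthReport:
    labels = _sample_labels(rng, cfg)
    body_sents: list[tuple[_SentenceGold, Optional[Phenotype]]] = [
        (_TEMPLATES[p](rng, cfg), p) for p in labels
    ]
    if rng.random() < cfg.negated_distractor_rate:
        body_sents.append((_distractor(rng), None))
    for _ in range(rng.randint(1, 3)):
        body_sents.append((_SentenceGold(rng.choice(_FILLERS), [], []), None))
    rng.shuffle(body_sents)

    if labels and rng.random() < 0.5:
        conc_label = rng.choice(labels)
        conclusion: tuple[_SentenceGold, Optional[Phenotype]] = (
            _TEMPLATES[conc_label](rng, cfg), conc_label)
    else:
        conclusion = (_neutral_conclusion(rng, bool(labels)), None)

    # assemble text with absolute offsets
    pieces: list[str] = []
    pos = 0
    entities: list[Entity] = []
    relations: list[Relation] = []
    sentence_counter = 0

    def append(text: str) -> None:
        nonlocal pos
        pieces.append(text)
        pos += len(text)

    def append_sentence(sg: _SentenceGold, section: str) -> None:
        nonlocal sentence_counter
        base = pos
        append(sg.text)
        ents_here: list[Entity] = []
        for ge in sg.entities:
            ents_here.append(Entity(
                etype=ge.etype,
                subtype=ge.subtype,
                span=Span(base + ge.start, base + ge.end),
                tok_span=(0, 1),
                sentence_index=sentence_counter,
                section_kind=section,
                surface=sg.text[ge.start: ge.end],
                negated=ge.negated,
            ))
        entities.extend(ents_here)
        for kind, mi, di in sg.relations:
            relations.append(Relation(kind, ents_here[mi], ents_here[di]))
        sentence_counter += 1

    append("CLINICAL DETAILS: ")
    append_sentence(_SentenceGold(rng.choice(_REQUESTS), [], []), "request")
    append("\n\nREPORT: ")
    for i, (sg, _label) in enumerate(body_sents):
        if i:
            append(" ")
        append_sentence(sg, "body")
    append("\n\nCONCLUSION: ")
    append_sentence(conclusion[0], "conclusion")
    append("\n")

    raw_text = "".join(pieces)
    report = zone_report(raw_text, report_id=report_id)

    gold = StandoffDocument(raw_text)
    for i, e in enumerate(entities, 1):
        e.id = f"T{i}"
        gold.entities.append(StandoffEntity(
            e.id, entity_type_to_string(e.etype, e.subtype), e.span, e.surface))
        if e.negated:
            gold.negations.add(e.id)
    for i, r in enumerate(relations, 1):
        gold.relations.append(
            StandoffRelation(f"R{i}", r.kind, r.modifier.id, r.target.id))
    intended = set(labels) | {conclusion[1]} if conclusion[1] else set(labels)
    gold.doc_labels = {p.slug for p in intended}
    gold.validate()

    sr = SynthReport(report, gold, intended, entities, relations)
    # the gold mark-up knowingly links modifiers to negated mentions
    # ("rather than new blood"); suppress the labeller's advisory warning
    # while running the self-consistency gate
    lbl_log = logging.getLogger("radphen.phenotype_labelling")
    level = lbl_log.level
    lbl_log.setLevel(logging.ERROR)
    try:
        derived = assign_labels(entities, relations, report_id).labels
    finally:
        lbl_log.setLevel(level)
    if derived != intended:
        raise AssertionError(
            f"{report_id}: gold mark-up derives {sorted(l.value for l in derived)} "
            f"but intended {sorted(l.value for l in intended)}"
        )
    return sr


def generate_corpus(config: SynthConfig) -> list[SynthReport]:
    """Deterministic corpus of reports with gold annotations.

    Raises if any generated report fails the self-consistency gate
    (labels derived from its own gold mark-up must equal the intended set).
    """
    config.validate()
    rng = random.Random(config.seed)
    width = len(str(config.n_reports))
    return [
        generate_report(rng, config, f"synth-{i:0{width}d}")
        for i in range(1, config.n_reports + 1)
    ]


def write_corpus(reports: Sequence[SynthReport], out_dir: str | Path,
                 config: Optional[SynthConfig] = None) -> Path:
    """Write ``.txt``/``.ann`` pairs, a labels JSON-lines file and the
    generating configuration to *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "labels.jsonl", "w", encoding="utf-8") as fh:
        for sr in reports:
            write_standoff(sr.gold, out_dir, sr.report.report_id)
            fh.write(json.dumps({
                "report_id": sr.report.report_id,
                "labels": sorted(p.value for p in sr.labels),
            }, sort_keys=True) + "\n")
    if config is not None:
        (out_dir / "config.json").write_text(config.to_json(), encoding="utf-8")
    return out_dir


def corpus_stats(reports: Sequence[Report],
                 gold: Sequence[StandoffDocument]) -> dict:
    """Summary counts: reports, sentences, tokens, entity and label totals,
    and per-phenotype label counts.  Additive over corpus concatenation."""
    from .phenotype_labelling import phenotype_from_slug
    from .types import entity_type_from_string

    if len(reports) != len(gold):
        raise ValueError("reports and gold must be parallel lists")
    stats = {
        "reports": len(reports),
        "sentences": 0,
        "tokens": 0,
        "disease_entities": 0,
        "modifier_entities": 0,
        "total_labels": 0,
        "per_phenotype": {p.value: 0 for p in Phenotype},
    }
    for rep, g in zip(reports, gold):
        for sec in rep.sections.values():
            sents = segment(sec.text, sec.span.start, sec.kind)
            stats["sentences"] += len(sents)
            stats["tokens"] += sum(len(s.tokens) for s in sents)
        for e in g.entities:
            etype, _sub = entity_type_from_string(e.type)
            if isinstance(etype, DiseaseType):
                stats["disease_entities"] += 1
            else:
                stats["modifier_entities"] += 1
        stats["total_labels"] += len(g.doc_labels)
        for slug in g.doc_labels:
            stats["per_phenotype"][phenotype_from_slug(slug).value] += 1
    return stats
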