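"""End-to-end annotation: zoning -> tokenisation -> tagging -> lemmatisation
-> NER -> negation -> relations -> document labels.

The stage order is fixed; each stage only consumes the mark-up of earlier
stages.  Request-section mentions are recognised (and exported) but never
contribute to labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .corpus_io import (
    Report,
    StandoffDocument,
    StandoffEntity,
    StandoffRelation,
    zone_report,
)
from .entity_annotation import (
    DEFAULT_RULES,
    Entity,
    Relation,
    RuleConfig,
    annotate_sentence,
)
from .lexicon import Lexicon, load_lexicon
from .phenotype_labelling import LabelledReport, assign_labels
from .text_processing import Chunk, Sentence, TaggerContract, chunk, prepare, rule_tag, segment
from .types import entity_type_to_string

log = logging.getLogger(__name__)

SECTION_ORDER = ("request", "body", "conclusion")


@dataclass
class AnnotatedReport:
    report: Report
    sentences: list[Sentence] = field(default_factory=list)
    chunks: list[list[Chunk]] = field(default_factory=list)
    entities: list[Entity] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    labelled: LabelledReport | None = None

    def to_standoff(self) -> StandoffDocument:
        doc = StandoffDocument(self.report.raw_text)
        for e in self.entities:
            doc.entities.append(StandoffEntity(
                e.id, entity_type_to_string(e.etype, e.subtype), e.span, e.surface
            ))
            if e.negated:
                doc.negations.add(e.id)
        for i, r in enumerate(self.relations, 1):
            doc.relations.append(
                StandoffRelation(f"R{i}", r.kind, r.modifier.id, r.target.id)
            )
        if self.labelled:
            doc.doc_labels = {p.slug for p in self.labelled.labels}
        return doc

    def to_record(self) -> dict:
        assert self.labelled is not None
        return {
            "report_id": self.report.report_id,
            "labels": sorted(p.value for p in self.labelled.labels),
            "entities": [
                {
                    "id": e.id,
                    "type": entity_type_to_string(e.etype, e.subtype),
                    "start": e.span.start,
                    "end": e.span.end,
                    "negated": e.negated,
                    "section": e.section_kind,
                }
                for e in self.entities
            ],
            "relations": [
                {"kind": r.kind, "modifier": r.modifier.id, "target": r.target.id}
                for r in self.relations
            ],
        }


def annotate_report(
    report: Report | str,
    lexicon: Lexicon | None = None,
    rules: RuleConfig = DEFAULT_RULES,
    tagger: TaggerContract = rule_tag,
) -> AnnotatedReport:
    """Run the full staged pipeline over one report (or raw text)."""
    if isinstance(report, str):
        report = zone_report(report)
    if lexicon is None:
        lexicon = load_lexicon()
    ann = AnnotatedReport(report)
    for kind in SECTION_ORDER:
        section = report.sections.get(kind)
        if section is None or not section.text:
            continue
        sents = segment(section.text, base_offset=section.span.start,
                        section_kind=kind)
        prepare(sents, tagger)
        ann.sentences.extend(sents)
    for si, sent in enumerate(ann.sentences):
        sent_chunks = chunk(sent)
        ann.chunks.append(sent_chunks)
        entities, relations = annotate_sentence(sent, lexicon, sent_chunks, si, rules)
        for e in entities:
            e.surface = report.raw_text[e.span.start: e.span.end]
        ann.entities.extend(entities)
        ann.relations.extend(relations)
    for i, e in enumerate(ann.entities, 1):
        e.id = f"T{i}"
    ann.labelled = assign_labels(ann.entities, ann.relations, report.report_id)
    return ann


def annotate_corpus(
    reports: list[Report],
    lexicon: Lexicon | None = None,
    rules: RuleConfig = DEFAULT_RULES,
) -> list[AnnotatedReport]:
    if lexicon is None:
        lexicon = load_lexicon()
    return [annotate_report(r, lexicon, rules) for r in reports]
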