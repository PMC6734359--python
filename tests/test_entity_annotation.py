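"""NER, negation detection and relation extraction rules."""

import pytest

from radphen.entity_annotation import (
    annotate_sentence,
    detect_negation,
    recognize_entities,
)
from radphen.text_processing import chunk, prepare, segment
from radphen.types import DiseaseType, ModifierType


def _annotated(text, lexicon):
    sent = prepare(segment(text))[0]
    chunks = chunk(sent)
    entities, relations = annotate_sentence(sent, lexicon, chunks)
    return sent, entities, relations


def _types(entities):
    return [e.etype for e in entities]


class TestRecognize:
    @pytest.mark.parametrize("text", [
        "subarachnoid haemorrhage",
        "subarachnoid blood",
        "SAH",
        "blood in the subarachnoid spaces",
    ])
    def test_sah_surface_forms(self, lexicon, text):
        _s, entities, _r = _annotated(f"There is {text}.", lexicon)
        diseases = [e for e in entities if e.is_disease]
        assert _types(diseases) == [DiseaseType.SUBARACHNOID_HAEMORRHAGE]

    def test_pattern_rule_extends_span(self, lexicon):
        text = "There is blood in the subarachnoid spaces."
        _s, entities, _r = _annotated(text, lexicon)
        (ent,) = [e for e in entities if e.is_disease]
        assert text[ent.span.start: ent.span.end] == "blood in the subarachnoid spaces"

    def test_no_lexicon_hits_gives_no_entities(self, lexicon):
        _s, entities, _r = _annotated("The ventricles are normal.", lexicon)
        assert entities == []

    def test_entities_never_overlap_and_are_deterministic(self, lexicon):
        text = "Old subdural haematoma and subarachnoid haemorrhage with microbleeds."
        _s, e1, _ = _annotated(text, lexicon)
        _s, e2, _ = _annotated(text, lexicon)
        assert [(e.etype, e.span) for e in e1] == [(e.etype, e.span) for e in e2]
        spans = sorted((e.span for e in e1), key=lambda s: s.start)
        for a, b in zip(spans, spans[1:]):
            assert a.end <= b.start

    def test_hyphenation_variants_recognised(self, lexicon):
        for surface in ("intracranial haemorrhage", "intra-cranial haemorrhage",
                        "intra cranial hemorrhage"):
            _s, entities, _r = _annotated(f"Large {surface} seen.", lexicon)
            assert DiseaseType.HAEMORRHAGIC_STROKE in _types(entities)


class TestNegation:
    @pytest.mark.parametrize("text,disease", [
        ("No metastases.", DiseaseType.TUMOUR),
        ("Exclude subdural bleed.", DiseaseType.SUBDURAL_HAEMATOMA),
        ("No evidence of acute haemorrhage.", DiseaseType.HAEMORRHAGIC_STROKE),
        ("Diffusely sclerotic metastases are much less likely.", DiseaseType.TUMOUR),
        ("Appearances are clear of subarachnoid blood.",
         DiseaseType.SUBARACHNOID_HAEMORRHAGE),
        ("Haemorrhage has been excluded.", DiseaseType.HAEMORRHAGIC_STROKE),
        ("An infarct is not seen.", DiseaseType.ISCHAEMIC_STROKE),
    ])
    def test_negated_contexts(self, lexicon, text, disease):
        _s, entities, _r = _annotated(text, lexicon)
        (ent,) = [e for e in entities if e.etype == disease]
        assert ent.negated

    @pytest.mark.parametrize("text", [
        "There is established small vessel disease.",
        "There is an acute infarct.",
        "Metastases are present.",
    ])
    def test_plain_assertions_not_negated(self, lexicon, text):
        _s, entities, _r = _annotated(text, lexicon)
        assert all(not e.negated for e in entities)

    def test_clause_boundary_blocks_trigger(self, lexicon):
        text = "No metastases, but there is an infarct."
        _s, entities, _r = _annotated(text, lexicon)
        by_type = {e.etype: e for e in entities if e.is_disease}
        assert by_type[DiseaseType.TUMOUR].negated
        assert not by_type[DiseaseType.ISCHAEMIC_STROKE].negated

    def test_rather_than_negates_rejected_half_only(self, lexicon):
        text = ("I suspect this reflects redistribution of the original "
                "haematoma rather than new blood.")
        _s, entities, _r = _annotated(text, lexicon)
        diseases = [e for e in entities if e.is_disease]
        assert [e.negated for e in diseases] == [False, True]

    def test_hedged_possibility_is_uncertain_not_negated(self, lexicon):
        _s, entities, _r = _annotated("Cannot exclude subdural haematoma.", lexicon)
        (ent,) = [e for e in entities if e.is_disease]
        assert not ent.negated and ent.uncertain
        _s, entities, _r = _annotated("Query infarct.", lexicon)
        (ent,) = [e for e in entities if e.is_disease]
        assert not ent.negated and ent.uncertain

    def test_modifiers_never_negated(self, lexicon):
        _s, entities, _r = _annotated("No evidence of acute haemorrhage.", lexicon)
        mods = [e for e in entities if e.is_modifier]
        assert mods and all(not m.negated for m in mods)

    def test_idempotent(self, lexicon):
        sent = prepare(segment("No metastases."))[0]
        chunks = chunk(sent)
        entities = recognize_entities(sent, lexicon)
        once = [e.negated for e in detect_negation(sent, entities, chunks)]
        twice = [e.negated for e in detect_negation(sent, entities, chunks)]
        assert once == twice == [True]


class TestRelations:
    def test_np_internal_time_and_location(self, lexicon):
        _s, entities, relations = _annotated("Right frontal chronic haemorrhage.", lexicon)
        kinds = sorted((r.kind, r.modifier.etype.value, r.target.etype.value)
                       for r in relations)
        assert kinds == [
            ("location", "loc_cortical", "haemorrhagic_stroke"),
            ("time", "time_old", "haemorrhagic_stroke"),
        ]

    def test_np_boundary_blocks_wrong_attachment(self, lexicon):
        text = ("I suspect this reflects redistribution of the original "
                "haematoma rather than new blood.")
        _s, entities, relations = _annotated(text, lexicon)
        links = {(r.modifier.surface or "", r.target.tok_span) for r in relations}
        new = [e for e in entities if e.etype is ModifierType.TIME_RECENT][0]
        haematoma = [e for e in entities
                     if e.is_disease and e.tok_span[0] < new.tok_span[0]][0]
        blood = [e for e in entities
                 if e.is_disease and e.tok_span[0] > new.tok_span[0]][0]
        targets_of_new = [r.target for r in relations if r.modifier is new]
        assert targets_of_new == [blood]
        old_targets = [r.target for r in relations
                       if r.modifier.etype is ModifierType.TIME_OLD]
        assert old_targets == [haematoma]

    def test_predicative_copula_links_to_subject(self, lexicon):
        _s, entities, relations = _annotated("The frontal infarct is old.", lexicon)
        assert {(r.kind, r.target.etype) for r in relations} == {
            ("location", DiseaseType.ISCHAEMIC_STROKE),
            ("time", DiseaseType.ISCHAEMIC_STROKE),
        }

    def test_proximity_rule_within_window(self, lexicon):
        _s, entities, relations = _annotated(
            "There is established small vessel disease.", lexicon)
        assert [(r.kind, r.target.etype) for r in relations] == [
            ("time", DiseaseType.SMALL_VESSEL_DISEASE)]

    def test_modifier_without_disease_yields_nothing(self, lexicon):
        _s, entities, relations = _annotated("No acute intracranial abnormality.", lexicon)
        assert relations == []
        assert any(e.etype is ModifierType.TIME_RECENT for e in entities)

    def test_each_modifier_links_at_most_once(self, lexicon):
        _s, entities, relations = _annotated(
            "Old frontal infarct and chronic parietal haemorrhage.", lexicon)
        mods = [r.modifier.id or id(r.modifier) for r in relations]
        counts = {id(r.modifier) for r in relations}
        assert len(counts) == len(relations)

    def test_kind_consistency(self, lexicon):
        _s, _e, relations = _annotated("Acute lacunar infarct.", lexicon)
        for r in relations:
            if r.modifier.etype in (ModifierType.TIME_OLD, ModifierType.TIME_RECENT):
                assert r.kind == "time"
            else:
                assert r.kind == "location"
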