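"""Named entity recognition, negation detection and relation extraction.

These are the rule stages between text processing and document labelling:
a longest-match lexicon scan produces typed disease/modifier mentions, a
trigger-and-scope pass flags negated disease mentions, and chunk-based rules
attach time/location modifiers to the disease mention they qualify.

Trigger lists, the proximity window and contrast cues are configuration, not
code: the conventions of clinical negation scoping (pre-triggers like "no"/
"exclude", post-triggers like "unlikely", clause boundaries at semicolons and
adversative conjunctions) vary by report style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .lexicon import Lexicon, lookup_longest
from .text_processing import Chunk, Sentence
from .types import DiseaseType, ModifierType, Span

log = logging.getLogger(__name__)


@dataclass
class Entity:
    etype: DiseaseType | ModifierType
    subtype: Optional[str]
    span: Span
    tok_span: tuple[int, int]  # half-open token indices within the sentence
    sentence_index: int
    section_kind: str
    surface: str
    negated: bool = False
    uncertain: bool = False
    id: str = ""

    @property
    def is_disease(self) -> bool:
        return isinstance(self.etype, DiseaseType)

    @property
    def is_modifier(self) -> bool:
        return isinstance(self.etype, ModifierType)


@dataclass(frozen=True)
class Relation:
    kind: str  # "time" | "location"
    modifier: Entity
    target: Entity

    def __post_init__(self) -> None:
        expected = "time" if self.modifier.etype in (
            ModifierType.TIME_RECENT, ModifierType.TIME_OLD
        ) else "location"
        if self.kind != expected:
            raise ValueError(f"relation kind {self.kind!r} inconsistent with "
                             f"modifier type {self.modifier.etype.value}")
        if self.modifier.sentence_index != self.target.sentence_index:
            raise ValueError("relation must stay within one sentence")


_REL_KIND = {
    ModifierType.TIME_RECENT: "time",
    ModifierType.TIME_OLD: "time",
    ModifierType.LOC_DEEP: "location",
    ModifierType.LOC_CORTICAL: "location",
}


@dataclass
class RuleConfig:
    """Tunable knobs for negation and relation rules."""

    pre_triggers: list[list[str]] = field(default_factory=lambda: [
        ["no"], ["without"], ["absence", "of"], ["exclude"], ["rule", "out"],
        ["free", "of"], ["clear", "of"],
    ])
    post_triggers: list[list[str]] = field(default_factory=lambda: [
        ["unlikely"], ["less", "likely"], ["not", "see"], ["not", "identify"],
        ["not", "demonstrate"], ["be", "exclude"],
    ])
    contrast_cues: list[list[str]] = field(default_factory=lambda: [
        ["rather", "than"], ["as", "opposed", "to"],
    ])
    uncertainty_pre: list[list[str]] = field(default_factory=lambda: [
        ["cannot", "exclude"], ["can", "not", "exclude"],
        ["could", "not", "exclude"], ["query"], ["?"], ["possible"],
    ])
    clause_breakers: list[str] = field(default_factory=lambda: [
        ";", "but", "although", "though", "whereas", "however",
    ])
    copulas: list[str] = field(default_factory=lambda: [
        "be", "appear", "remain", "look", "seem",
    ])
    proximity_window: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown rule option {key!r}")
            setattr(cfg, key, value)
        return cfg


DEFAULT_RULES = RuleConfig()

#: Prepositional paraphrase patterns: (anchor disease type, anchor lemma,
#: following lemma sequence, re-typed disease).  Covers "blood in the
#: subarachnoid space(s)", a phrasing the lexicon scan alone misses.
PARAPHRASE_PATTERNS: list[tuple[DiseaseType, str, tuple[str, ...], DiseaseType]] = [
    (DiseaseType.HAEMORRHAGIC_STROKE, "blood", ("in", "the", "subarachnoid", "space"),
     DiseaseType.SUBARACHNOID_HAEMORRHAGE),
    (DiseaseType.HAEMORRHAGIC_STROKE, "blood", ("within", "the", "subarachnoid", "space"),
     DiseaseType.SUBARACHNOID_HAEMORRHAGE),
]


def recognize_entities(
    sentence: Sentence,
    lexicon: Lexicon,
    sentence_index: int = 0,
) -> list[Entity]:
    """Left-to-right longest-match scan; matched tokens are consumed so
    entities never overlap.  Requires tagged+lemmatised tokens."""
    entities: list[Entity] = []
    toks = sentence.tokens
    i = 0
    while i < len(toks):
        hit = lookup_longest(sentence, lexicon, i)
        if hit is None:
            i += 1
            continue
        entry, (s, e) = hit
        span = Span(toks[s].span.start, toks[e - 1].span.end)
        entities.append(Entity(
            etype=entry.entity_type,
            subtype=entry.subtype,
            span=span,
            tok_span=(s, e),
            sentence_index=sentence_index,
            section_kind=sentence.section_kind,
            surface="",  # filled by caller with document text if needed
        ))
        i = e
    _apply_paraphrase_patterns(sentence, entities)
    return entities


def _apply_paraphrase_patterns(sentence: Sentence, entities: list[Entity]) -> None:
    toks = sentence.tokens
    for idx, ent in enumerate(entities):
        for etype, lemma, following, new_type in PARAPHRASE_PATTERNS:
            s, e = ent.tok_span
            if ent.etype is not etype or e - s != 1:
                continue
            if toks[s].lemma != lemma:
                continue
            n = len(following)
            if e + n > len(toks):
                continue
            if tuple(t.lemma for t in toks[e: e + n]) != following:
                continue
            entities[idx] = replace(
                ent,
                etype=new_type,
                subtype=None,
                tok_span=(s, e + n),
                span=Span(toks[s].span.start, toks[e + n - 1].span.end),
            )
            break


# ---------------------------------------------------------------------------
# Negation


def _match_at(lemmas: Sequence[str], pos: int, seq: Sequence[str]) -> bool:
    return lemmas[pos: pos + len(seq)] == list(seq)


def _clause_boundary_between(
    sentence: Sentence, start: int, end: int, config: RuleConfig
) -> bool:
    """True if a clause boundary separates token positions start..end."""
    toks = sentence.tokens
    for i in range(start, end):
        if toks[i].surface in (";",) or toks[i].lemma in config.clause_breakers:
            return True
        if toks[i].surface == ",":
            # a comma opens a new clause only if a finite verb follows it
            if any(toks[j].pos == "VERB" for j in range(i + 1, end)):
                return True
    return False


def detect_negation(
    sentence: Sentence,
    entities: list[Entity],
    chunks: list[Chunk],
    config: RuleConfig = DEFAULT_RULES,
) -> list[Entity]:
    """Set ``negated`` (diseases only) and ``uncertain`` flags in place.

    A disease mention is negated when a pre-trigger precedes it in the same
    clause, a post-trigger follows its noun phrase in the same clause, or it
    falls under the rejected half of a contrast cue ("rather than X").
    Hedged possibility ("cannot exclude X", "query X") is *not* negation; it
    sets the separate ``uncertain`` flag which labelling ignores.
    """
    lemmas = [t.lemma or t.surface.lower() for t in sentence.tokens]
    uncertain_spans: list[tuple[int, int]] = []  # scope start positions
    blocked_pre: set[int] = set()  # pre-trigger positions consumed by hedges
    for i in range(len(lemmas)):
        for useq in config.uncertainty_pre:
            if _match_at(lemmas, i, useq):
                uncertain_spans.append((i, i + len(useq)))
                for j in range(i, i + len(useq)):
                    blocked_pre.add(j)

    pre_positions: list[tuple[int, int]] = []  # (trigger_start, scope_start)
    for i in range(len(lemmas)):
        if i in blocked_pre:
            continue
        for seq in config.pre_triggers:
            if _match_at(lemmas, i, seq):
                pre_positions.append((i, i + len(seq)))
                break

    contrast_positions: list[int] = []
    for i in range(len(lemmas)):
        for cue in config.contrast_cues:
            if _match_at(lemmas, i, cue):
                contrast_positions.append(i + len(cue))

    for ent in entities:
        if not ent.is_disease:
            ent.negated = False
            continue
        s, e = ent.tok_span
        negated = False
        for trig_start, scope_start in pre_positions:
            if scope_start <= s and not _clause_boundary_between(
                sentence, scope_start, s, config
            ):
                negated = True
                break
        if not negated:
            np_end = e
            for ch in chunks:
                if ch.kind == "noun_phrase" and ch.token_range[0] <= s and e <= ch.token_range[1]:
                    np_end = ch.token_range[1]
                    break
            limit = len(lemmas)
            for seq in config.post_triggers:
                for i in range(np_end, limit - len(seq) + 1):
                    if _clause_boundary_between(sentence, np_end, i, config):
                        break
                    if _match_at(lemmas, i, seq):
                        negated = True
                        break
                if negated:
                    break
        if not negated:
            for cpos in contrast_positions:
                if cpos <= s and not _clause_boundary_between(
                    sentence, cpos, s, config
                ):
                    negated = True
                    break
        ent.negated = negated
        for us, ue in uncertain_spans:
            if ue <= s and not _clause_boundary_between(sentence, ue, s, config):
                ent.uncertain = True
            elif us >= e and s <= us <= e + 2:  # "? stroke" / trailing query
                ent.uncertain = True
    return entities


# ---------------------------------------------------------------------------
# Relations


def extract_relations(
    sentence: Sentence,
    entities: list[Entity],
    chunks: list[Chunk],
    config: RuleConfig = DEFAULT_RULES,
) -> list[Relation]:
    """Attach each time/location modifier to at most one disease mention.

    Precedence: (a) a modifier and disease inside the same noun phrase;
    (b) a predicative modifier after a copula links back to the subject's
    disease; (c) nearest disease within the proximity window, unless a
    contrast cue intervenes.
    """
    diseases = [e for e in entities if e.is_disease]
    modifiers = [e for e in entities if e.is_modifier and e.etype in _REL_KIND]
    if not diseases or not modifiers:
        return []
    lemmas = [t.lemma or t.surface.lower() for t in sentence.tokens]
    nps = [c for c in chunks if c.kind == "noun_phrase"]
    relations: list[Relation] = []

    def np_of(ent: Entity) -> Optional[Chunk]:
        s, e = ent.tok_span
        for ch in nps:
            if ch.token_range[0] <= s and e <= ch.token_range[1]:
                return ch
        return None

    def contrast_between(a: int, b: int) -> bool:
        lo, hi = min(a, b), max(a, b)
        for i in range(lo, hi):
            for cue in config.contrast_cues:
                if _match_at(lemmas, i, cue):
                    return True
        return False

    for mod in modifiers:
        kind = _REL_KIND[mod.etype]  # type: ignore[index]
        target: Optional[Entity] = None
        # (a) NP-internal
        np = np_of(mod)
        if np is not None:
            inside = [
                d for d in diseases
                if np.token_range[0] <= d.tok_span[0] and d.tok_span[1] <= np.token_range[1]
            ]
            if inside:
                after = [d for d in inside if d.tok_span[0] >= mod.tok_span[1]]
                target = min(
                    after or inside,
                    key=lambda d: abs(d.tok_span[0] - mod.tok_span[1]),
                )
        # (b) predicative: disease NP + copula + modifier
        if target is None:
            k = mod.tok_span[0] - 1
            while k >= 0 and sentence.tokens[k].pos == "ADV":
                k -= 1
            while k >= 0 and sentence.tokens[k].pos == "VERB" and lemmas[k] not in config.copulas:
                k -= 1
            if k >= 0 and lemmas[k] in config.copulas:
                before = [d for d in diseases if d.tok_span[1] <= k]
                if before:
                    cand = max(before, key=lambda d: d.tok_span[1])
                    if k - cand.tok_span[1] <= config.proximity_window:
                        target = cand
        # (c) proximity
        if target is None:
            def gap(d: Entity) -> int:
                if d.tok_span[0] >= mod.tok_span[1]:
                    return d.tok_span[0] - mod.tok_span[1]
                return mod.tok_span[0] - d.tok_span[1]

            candidates = [
                d for d in diseases
                if gap(d) <= config.proximity_window
                and not contrast_between(mod.tok_span[0], d.tok_span[0])
            ]
            if candidates:
                # ties broken toward the following mention ("old ... infarct")
                target = min(
                    candidates,
                    key=lambda d: (gap(d), 0 if d.tok_span[0] >= mod.tok_span[1] else 1),
                )
        if target is not None:
            relations.append(Relation(kind, mod, target))
    return relations


def annotate_sentence(
    sentence: Sentence,
    lexicon: Lexicon,
    chunks: list[Chunk],
    sentence_index: int = 0,
    config: RuleConfig = DEFAULT_RULES,
) -> tuple[list[Entity], list[Relation]]:
    """NER + negation + relations for one prepared sentence."""
    entities = recognize_entities(sentence, lexicon, sentence_index)
    detect_negation(sentence, entities, chunks, config)
    relations = extract_relations(sentence, entities, chunks, config)
    return entities, relations
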