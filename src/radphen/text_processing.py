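"""Sentence/token segmentation, coarse POS tagging, lemmatisation, chunking.

Radiology prose is short, abbreviation-dense and conventionalised, so a
dependency-free rule tagger over a coarse 10-tag set is sufficient for the
downstream negation and relation rules, which only consult the
NOUN/VERB/ADJ/ADV/DET classes.  Any external tagger can be injected through
the :data:`TaggerContract` (token surfaces in, equal-length tag list out).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable, Sequence

from .types import POS_TAGS, Span

TaggerContract = Callable[[Sequence[str]], Sequence[str]]


@dataclass
class Token:
    surface: str
    span: Span
    pos: str = "OTHER"
    lemma: str = ""


@dataclass
class Sentence:
    tokens: list[Token]
    span: Span
    section_kind: str = "body"


@dataclass(frozen=True)
class Chunk:
    kind: str  # "noun_phrase" | "verb_phrase"
    token_range: tuple[int, int]  # half-open indices into sentence.tokens
    head_index: int


# ---------------------------------------------------------------------------
# Segmentation

#: Words after which a full stop never ends a sentence.
DEFAULT_ABBREVIATIONS = frozenset(
    "e.g eg i.e ie vs cf etc dr mr mrs prof st no fig approx ca ct mri "
    "wk wks yr yrs".split()
)

_TOKEN_RE = re.compile(r"[A-Za-z]+(?:[-'][A-Za-z]+)*|\d+(?:\.\d+)?|\S")
_TERMINAL_RE = re.compile(r"[.!?]+")


def _tokenize(text: str, base: int) -> list[Token]:
    return [
        Token(m.group(), Span(base + m.start(), base + m.end()))
        for m in _TOKEN_RE.finditer(text)
    ]


def _sentence_breaks(text: str, abbreviations: frozenset[str]) -> list[int]:
    """Character offsets (into *text*) at which a new sentence starts."""
    breaks = []
    for m in _TERMINAL_RE.finditer(text):
        end = m.end()
        if end >= len(text):
            continue
        # decimal number: digit on both sides of a lone "."
        if (m.group() == "." and m.start() > 0 and text[m.start() - 1].isdigit()
                and text[end:end + 1].isdigit()):
            continue
        tail = text[end:]
        stripped = tail.lstrip()
        if not stripped:
            continue
        if not re.match(r"\s", tail):
            continue  # terminal punctuation must be followed by whitespace
        # protect abbreviations ("e.g.", "vs.", "CT.")
        prev = re.search(r"[A-Za-z.]+$", text[: m.start()])
        if prev and prev.group().lower().rstrip(".") in abbreviations:
            continue
        breaks.append(end)
    return breaks


def segment(
    section_text: str,
    base_offset: int = 0,
    section_kind: str = "body",
    abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS,
) -> list[Sentence]:
    """Split section text into sentences of tokens.

    Sentences end at terminal punctuation followed by whitespace, or at blank
    lines; abbreviations and decimal points do not split.  Token and sentence
    spans index into the parent document at ``base_offset``.
    """
    sentences: list[Sentence] = []
    # paragraphs: blank-line separated
    para_start = 0
    for para_m in re.finditer(r"\n\s*\n|\Z", section_text, flags=re.S):
        para = section_text[para_start: para_m.start()]
        offsets = [0] + _sentence_breaks(para, abbreviations) + [len(para)]
        for s, e in zip(offsets, offsets[1:]):
            tokens = _tokenize(para[s:e], base_offset + para_start + s)
            if tokens:
                span = Span(tokens[0].span.start, tokens[-1].span.end)
                sentences.append(Sentence(tokens, span, section_kind))
        para_start = para_m.end()
        if para_start >= len(section_text):
            break
    return sentences


# ---------------------------------------------------------------------------
# POS tagging

_DETS = frozenset("the a an this that these those any some each either neither".split())
_PREPS = frozenset(
    "of in on at by with within from to into onto over under through along "
    "across between adjacent near around during since for as up down".split()
)
_CONJS = frozenset("and or but nor although though whereas while than if because".split())
_VERBS = frozenset(
    "is are was were be been being am has have had do does did can could may "
    "might will would should appears appear appeared seems seem remains remain "
    "shows show shown demonstrates demonstrate suggests suggest represents "
    "represent reflects reflect suspect see seen lies lie arises arise looks "
    "look exclude excludes rule rules involve involves".split()
)
_ADVS = frozenset(
    "not very much more most also now still again there however rather less "
    "least too so then previously elsewhere".split()
)
_ADJS = frozenset(
    "old new deep acute recent chronic mature fresh early late small large "
    "left right prominent normal unremarkable mild moderate severe extensive "
    "multiple several bilateral unilateral diffuse focal patchy subtle likely "
    "unlikely present absent high low grey white significant original "
    "long-standing longstanding widespread scattered".split()
)
# nouns that suffix rules would otherwise mistag
_NOUNS = frozenset(
    "swelling finding findings imaging scanning report conclusion "
    "evidence appearance appearances change changes loss disease space spaces "
    "matter attenuation collection redistribution ganglia blood".split()
)

_ADJ_SUFFIXES = ("al", "ic", "ous", "ar", "oid", "ive", "ular", "ary")


def rule_tag(surfaces: Sequence[str]) -> list[str]:
    """Built-in coarse tagger: closed-class lists plus suffix heuristics."""
    tags: list[str] = []
    for i, w in enumerate(surfaces):
        lw = w.lower()
        if not any(c.isalnum() for c in w):
            tag = "PUNCT"
        elif re.fullmatch(r"\d+(?:\.\d+)?", w):
            tag = "NUM"
        elif lw in _DETS:
            tag = "DET"
        elif lw in _PREPS:
            tag = "PREP"
        elif lw in _CONJS:
            tag = "CONJ"
        elif lw in _VERBS:
            tag = "VERB"
        elif lw in _ADVS or (lw.endswith("ly") and len(lw) > 3):
            tag = "ADV"
        elif lw in _ADJS:
            tag = "ADJ"
        elif lw in _NOUNS:
            tag = "NOUN"
        elif lw.endswith(("ing", "ed")) and len(lw) > 4:
            # participle after a determiner/adjective acts nominally/adnominally
            tag = "NOUN" if tags and tags[-1] in ("DET", "ADJ") else "VERB"
        elif any(lw.endswith(s) for s in _ADJ_SUFFIXES) and len(lw) > 4:
            tag = "ADJ"
        else:
            tag = "NOUN"  # capitalised or unknown content words default to NOUN
        tags.append(tag)
    return tags


def pos_tag(sentences: Iterable[Sentence], tagger: TaggerContract = rule_tag) -> list[Sentence]:
    """Fill ``token.pos`` in place using *tagger*; returns the sentences.

    Raises ``ValueError`` if the tagger violates its contract (wrong length
    or a tag outside the coarse tagset).
    """
    out = []
    for sent in sentences:
        tags = list(tagger([t.surface for t in sent.tokens]))
        if len(tags) != len(sent.tokens):
            raise ValueError(
                f"tagger returned {len(tags)} tags for {len(sent.tokens)} tokens"
            )
        for tok, tag in zip(sent.tokens, tags):
            if tag not in POS_TAGS:
                raise ValueError(f"tagger produced unknown tag {tag!r}")
            tok.pos = tag
        out.append(sent)
    return out


# ---------------------------------------------------------------------------
# Lemmatisation

#: Irregular forms; surfaces are matched lowercase.
LEMMA_EXCEPTIONS = {
    "bled": "bleed",
    "is": "be", "are": "be", "was": "be", "were": "be", "am": "be",
    "been": "be", "being": "be",
    "seen": "see", "saw": "see", "shown": "show", "did": "do", "done": "do",
    "has": "have", "had": "have",
    "metastases": "metastasis", "foci": "focus", "lacunae": "lacuna",
    "ganglia": "ganglion", "sulci": "sulcus", "nuclei": "nucleus",
    "vertebrae": "vertebra",
}

# vocabulary consulted when undoing -ing/-ed (silent-e restoration)
_EVERBS = frozenset(
    "note involve reduce produce exclude include state describe cause "
    "reflect suggest demonstrate image enlarge resolve mature please".split()
)


def _lemmatize_noun(lw: str) -> str:
    if lw in LEMMA_EXCEPTIONS:
        return LEMMA_EXCEPTIONS[lw]
    if lw.endswith(("ss", "us", "is")) or len(lw) < 4:
        return lw
    if lw.endswith("ies"):
        return lw[:-3] + "y"
    if lw.endswith(("xes", "ches", "shes", "sses", "zes")):
        return lw[:-2]
    if lw.endswith("s"):
        return lw[:-1]
    return lw


def _undo_participle(stem: str) -> str:
    candidates = [stem]
    if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in "ls":
        candidates.append(stem[:-1])  # scanning -> scan
    candidates.append(stem + "e")  # involv -> involve
    for c in candidates[1:]:
        if c in _EVERBS:
            return c
    if stem in _EVERBS:
        return stem
    # default: bare stem, de-doubled if doubled consonant
    if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in "lse":
        return stem[:-1]
    return stem


def _lemmatize_verb(lw: str) -> str:
    if lw in LEMMA_EXCEPTIONS:
        return LEMMA_EXCEPTIONS[lw]
    if lw.endswith("ing") and len(lw) > 4:
        return _undo_participle(lw[:-3])
    if lw.endswith("ied") and len(lw) > 4:
        return lw[:-3] + "y"
    if lw.endswith("ed") and not lw.endswith("eed") and len(lw) > 3:
        return _undo_participle(lw[:-2])
    return _lemmatize_noun(lw)  # third-person -s


@lru_cache(maxsize=65536)
def lemmatize_word(surface: str, pos: str = "NOUN") -> str:
    """Canonical lowercase form of a single word given its coarse tag."""
    lw = surface.lower()
    if lw in LEMMA_EXCEPTIONS:
        return LEMMA_EXCEPTIONS[lw]
    if pos == "VERB":
        return _lemmatize_verb(lw)
    if pos == "NOUN":
        return _lemmatize_noun(lw)
    return lw


def lemmatize(sentences: Iterable[Sentence]) -> list[Sentence]:
    """Fill ``token.lemma`` in place (requires POS tags); returns sentences."""
    out = []
    for sent in sentences:
        for tok in sent.tokens:
            tok.lemma = lemmatize_word(tok.surface, tok.pos)
        out.append(sent)
    return out


# ---------------------------------------------------------------------------
# Chunking

_NP_INNER = ("ADJ", "NOUN", "NUM")


def chunk(sentence: Sentence) -> list[Chunk]:
    """Maximal non-recursive noun and verb phrases.

    Noun phrase: optional determiner, then a run of ADJ/NOUN/NUM containing at
    least one NOUN; head is the last NOUN.  Verb phrase: ADV* VERB+.  Every
    NOUN token ends up in exactly one noun phrase.
    """
    chunks: list[Chunk] = []
    toks = sentence.tokens
    i = 0
    while i < len(toks):
        start = i
        if toks[i].pos == "DET":
            i += 1
        run_start = i
        while i < len(toks) and toks[i].pos in _NP_INNER:
            i += 1
        noun_idx = [j for j in range(run_start, i) if toks[j].pos == "NOUN"]
        if noun_idx:
            chunks.append(Chunk("noun_phrase", (start, i), noun_idx[-1]))
            continue
        i = start
        adv_end = i
        while adv_end < len(toks) and toks[adv_end].pos == "ADV":
            adv_end += 1
        if adv_end < len(toks) and toks[adv_end].pos == "VERB":
            j = adv_end
            while j < len(toks) and toks[j].pos == "VERB":
                j += 1
            chunks.append(Chunk("verb_phrase", (i, j), j - 1))
            i = j
            continue
        i += 1
    return chunks


def prepare(sentences: list[Sentence], tagger: TaggerContract = rule_tag) -> list[Sentence]:
    """Tag and lemmatise in one pass (the usual pipeline call)."""
    return lemmatize(pos_tag(sentences, tagger))
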