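"""Domain dictionaries of disease and modifier terms with variant expansion.

Matching is longest-first over token sequences, by default comparing both
lemmas and lowercased surfaces so inflected mentions ("bleeds", "metastases")
hit single-entry variants.  Hyphenation/spacing variants of fusable prefixes
(intra-, extra-, peri-, sub-, infra-) and ae/e spelling pairs
(haemorrhage/hemorrhage) are generated automatically, mirroring how clinical
dictionaries balloon with near duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional

from .text_processing import Sentence, _TOKEN_RE, lemmatize_word
from .types import (
    DiseaseType,
    ModifierType,
    TUMOUR_SUBTYPES,
    entity_type_from_string,
)

Variant = tuple[str, ...]  # token sequence, lowercased surfaces

FUSABLE_PREFIXES = ("intra", "extra", "peri", "sub", "infra")


def _tokenize_variant(s: str) -> Variant:
    return tuple(m.group().lower() for m in _TOKEN_RE.finditer(s))


def _variant_lemmas(v: Variant) -> Variant:
    return tuple(lemmatize_word(w) for w in v)


@dataclass
class LexEntry:
    canonical: str
    entity_type: DiseaseType | ModifierType
    subtype: Optional[str] = None
    variants: set[Variant] = field(default_factory=set)
    match_on_lemma: bool = True
    order: int = 0  # file order, used for tie-breaking

    def __post_init__(self) -> None:
        canon = _tokenize_variant(self.canonical)
        if not self.variants:
            self.variants = {canon}
        self.variants.add(canon)


def expand_variants(entry: LexEntry) -> LexEntry:
    """Add hyphenation/spacing forms for fusable prefixes and ae/e spelling
    pairs.  Idempotent: expanding an expanded entry adds nothing."""
    out: set[Variant] = set()
    frontier = set(entry.variants)
    while frontier:
        new: set[Variant] = set()
        for v in frontier:
            out.add(v)
            for i, w in enumerate(v):
                for gen in _word_forms(w):
                    if gen != (w,):
                        new.add(v[:i] + gen + v[i + 1:])
        frontier = new - out
    entry.variants = out
    return entry


def _word_forms(w: str) -> list[tuple[str, ...]]:
    """Alternative renderings of a single variant token."""
    forms: list[tuple[str, ...]] = [(w,)]
    for p in FUSABLE_PREFIXES:
        rest = None
        if w.startswith(p + "-"):
            rest = w[len(p) + 1:]
        elif w.startswith(p) and len(w) > len(p) + 3:
            rest = w[len(p):]
        if rest and rest.isalpha():
            forms += [(p + rest,), (p + "-" + rest,), (p, rest)]
            break
    for form in list(forms):
        word = form[0] if len(form) == 1 else None
        if word and "ae" in word:
            forms.append((word.replace("ae", "e"),))
    return forms


@dataclass
class Lexicon:
    entries: list[LexEntry]
    index: dict[str, list[LexEntry]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.rebuild_index()

    def rebuild_index(self) -> None:
        self.index = {}
        seen: dict[Variant, LexEntry] = {}
        for entry in self.entries:
            for v in entry.variants:
                prior = seen.get(v)
                if prior is not None and (
                    prior.entity_type != entry.entity_type
                    or prior.subtype != entry.subtype
                ):
                    raise ValueError(
                        f"variant {' '.join(v)!r} claimed by both "
                        f"{prior.canonical!r} and {entry.canonical!r}"
                    )
                seen[v] = entry
                for key in {v[0], _variant_lemmas(v)[0]}:
                    self.index.setdefault(key, [])
                    if entry not in self.index[key]:
                        self.index[key].append(entry)

    def __len__(self) -> int:
        return len(self.entries)


def load_lexicon(path: str | Path | None = None, expand: bool = True) -> Lexicon:
    """Load a lexicon TSV (``canonical<TAB>entity_type<TAB>subtype<TAB>
    pipe-separated variants``); ``None`` loads the packaged default.

    Raises ``ValueError`` naming the offending line for unknown entity types,
    malformed rows, or variants claimed by two different entity types.
    """
    if path is None:
        ref = resources.files("radphen").joinpath("data/default_lexicon.tsv")
        text = ref.read_text(encoding="utf-8")
        source = "default_lexicon.tsv"
    else:
        text = Path(path).read_text(encoding="utf-8")
        source = str(path)
    entries: list[LexEntry] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 4:
            raise ValueError(f"{source}:{lineno}: expected 4 tab-separated columns")
        canonical, type_str, subtype, variants = (c.strip() for c in cols)
        try:
            etype, parsed_sub = entity_type_from_string(type_str)
        except ValueError as exc:
            raise ValueError(f"{source}:{lineno}: {exc}") from exc
        subtype = subtype or parsed_sub or None
        if subtype and not (
            etype is DiseaseType.TUMOUR and subtype in TUMOUR_SUBTYPES
        ) and not (
            etype is DiseaseType.SUBARACHNOID_HAEMORRHAGE
            and subtype in ("aneurysmal", "other")
        ):
            raise ValueError(f"{source}:{lineno}: invalid subtype {subtype!r}")
        entry = LexEntry(
            canonical=canonical,
            entity_type=etype,
            subtype=subtype,
            variants={_tokenize_variant(v) for v in variants.split("|") if v.strip()},
            order=len(entries),
        )
        if expand:
            expand_variants(entry)
        entries.append(entry)
    return Lexicon(entries)


def lookup_longest(
    sentence: Sentence, lexicon: Lexicon, position: int
) -> Optional[tuple[LexEntry, tuple[int, int]]]:
    """Longest variant (in tokens) matching at *position*; ties go to the
    entry earliest in file order.  Returns (entry, half-open token range)."""
    toks = sentence.tokens
    if position < 0 or position >= len(toks):
        return None
    first = toks[position]
    candidates: list[LexEntry] = []
    for key in {first.surface.lower(), first.lemma or first.surface.lower()}:
        candidates.extend(lexicon.index.get(key, []))
    best: tuple[int, int, LexEntry] | None = None  # (-len, order, entry)
    for entry in candidates:
        for v in entry.variants:
            n = len(v)
            if position + n > len(toks):
                continue
            if all(
                _token_matches(toks[position + i], v[i], entry.match_on_lemma)
                for i in range(n)
            ):
                key = (-n, entry.order)
                if best is None or key < (best[0], best[1]):
                    best = (-n, entry.order, entry)
    if best is None:
        return None
    return best[2], (position, position - best[0])


def _token_matches(token, vword: str, on_lemma: bool) -> bool:
    surf = token.surface.lower()
    if not on_lemma:
        return surf == vword
    lemma = token.lemma or surf
    return vword in (surf, lemma) or lemmatize_word(vword) in (surf, lemma)
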