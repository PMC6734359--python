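"""Report reading/writing, section zoning, and brat standoff interchange.

A UK-style radiology report has three zones: the *request* (the clinical
question), the *body* (the radiologist's findings) and the *conclusion*.
Zoning finds configurable section headings with case-insensitive regular
expressions; phenotype labelling later only trusts findings from the body
and conclusion.  Character offsets are 0-based half-open and counted after
normalising CRLF line endings to LF.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .types import Span

log = logging.getLogger(__name__)

SECTION_KINDS = ("request", "body", "conclusion")

#: Default heading vocabulary (heading word -> section kind).  The original
#: system's regexes are unpublished, so these follow conventional UK report
#: structure and are overridable by the caller.
DEFAULT_HEADING_PATTERNS: Mapping[str, str] = {
    "clinical details": "request",
    "clinical history": "request",
    "clinical indication": "request",
    "history": "request",
    "indication": "request",
    "request": "request",
    "report": "body",
    "findings": "body",
    "conclusion": "conclusion",
    "conclusions": "conclusion",
    "impression": "conclusion",
    "comment": "conclusion",
    "opinion": "conclusion",
}


@dataclass(frozen=True)
class Section:
    kind: str
    span: Span
    text: str


@dataclass
class Report:
    report_id: str
    raw_text: str
    sections: dict[str, Section]
    modality: str = "unknown"
    gold: "StandoffDocument | None" = None

    def section_text(self, kind: str) -> str:
        sec = self.sections.get(kind)
        return sec.text if sec else ""


# ---------------------------------------------------------------------------
# Zoning


def _compile_heading_re(patterns: Mapping[str, str]) -> re.Pattern[str]:
    alts = "|".join(
        re.escape(h) for h in sorted(patterns, key=len, reverse=True)
    )
    return re.compile(
        rf"^[ \t]*(?P<h>{alts})[ \t]*[:\-][ \t]*", re.IGNORECASE | re.MULTILINE
    )


def normalize_newlines(text: str) -> str:
    return text.replace("\r\n", "\n").replace("\r", "\n")


def zone_report(
    raw_text: str,
    heading_patterns: Mapping[str, str] = DEFAULT_HEADING_PATTERNS,
    report_id: str = "",
    modality: str = "unknown",
) -> Report:
    """Zone *raw_text* into request/body/conclusion sections.

    Text before any heading defaults to the body (or the request if an
    explicit body heading exists later).  A heading kind seen twice is
    treated as plain text the second time.  Missing sections are present
    with empty spans so callers can iterate the three kinds uniformly.
    """
    raw_text = normalize_newlines(raw_text)
    heading_re = _compile_heading_re(heading_patterns)
    matches = []
    seen: set[str] = set()
    for m in heading_re.finditer(raw_text):
        kind = heading_patterns[m.group("h").lower()]
        if kind in seen:
            continue
        seen.add(kind)
        matches.append((kind, m.start(), m.end()))

    sections: dict[str, Section] = {}

    def put(kind: str, start: int, end: int) -> None:
        sections[kind] = Section(kind, Span(start, end), raw_text[start:end])

    if not matches:
        put("body", 0, len(raw_text))
    else:
        first_start = matches[0][1]
        if first_start > 0 and raw_text[:first_start].strip():
            headed = {k for k, _, _ in matches}
            if "body" not in headed:
                put("body", 0, first_start)
            elif "request" not in headed:
                put("request", 0, first_start)
            # else: preamble stays unassigned, like heading text itself
        for i, (kind, _, content_start) in enumerate(matches):
            content_end = matches[i + 1][1] if i + 1 < len(matches) else len(raw_text)
            put(kind, content_start, content_end)

    for kind in SECTION_KINDS:
        if kind not in sections:
            end = len(raw_text)
            sections[kind] = Section(kind, Span(end, end), "")
    ordered = dict(
        sorted(sections.items(), key=lambda kv: (kv[1].span.start, kv[1].span.end))
    )
    return Report(report_id, raw_text, ordered, modality)


# ---------------------------------------------------------------------------
# brat standoff


@dataclass(frozen=True)
class StandoffEntity:
    id: str
    type: str
    span: Span
    surface: str


@dataclass(frozen=True)
class StandoffRelation:
    id: str
    kind: str  # "time" | "location"
    arg1: str  # modifier entity id
    arg2: str  # disease entity id


@dataclass
class StandoffDocument:
    text: str
    entities: list[StandoffEntity] = field(default_factory=list)
    relations: list[StandoffRelation] = field(default_factory=list)
    doc_labels: set[str] = field(default_factory=set)  # label slugs
    negations: set[str] = field(default_factory=set)  # negated entity ids

    def validate(self) -> None:
        ids = [e.id for e in self.entities]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate entity ids")
        known = set(ids)
        for e in self.entities:
            if e.span.end > len(self.text):
                raise ValueError(f"{e.id}: span outside text")
            if self.text[e.span.start: e.span.end] != e.surface:
                raise ValueError(f"{e.id}: surface does not match text at span")
        for r in self.relations:
            if r.arg1 not in known or r.arg2 not in known:
                raise ValueError(f"{r.id}: relation argument not an entity id")
        for eid in self.negations:
            if eid not in known:
                raise ValueError(f"negation attribute references unknown id {eid}")


def write_standoff(doc: StandoffDocument, path: str | Path, name: str) -> tuple[Path, Path]:
    """Write ``name.txt``/``name.ann`` under *path* (validated first).

    Document-level labels are emitted as attribute lines on the synthetic
    target ``DOC`` since brat has no native document annotation.
    """
    doc.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    txt_path = path / f"{name}.txt"
    ann_path = path / f"{name}.ann"
    txt_path.write_text(doc.text, encoding="utf-8")
    lines = []
    for e in doc.entities:
        lines.append(f"{e.id}\t{e.type} {e.span.start} {e.span.end}\t{e.surface}")
    for r in doc.relations:
        lines.append(f"{r.id}\t{r.kind} Arg1:{r.arg1} Arg2:{r.arg2}")
    a = 1
    for eid in _sort_ids(doc.negations):
        lines.append(f"A{a}\tNegation {eid}")
        a += 1
    for label in sorted(doc.doc_labels):
        lines.append(f"A{a}\tDocLabel DOC {label}")
        a += 1
    ann_path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return txt_path, ann_path


def _sort_ids(ids: Iterable[str]) -> list[str]:
    # sort T2 before T10
    def key(s: str) -> tuple:
        m = re.match(r"([A-Za-z]*)(\d+)$", s)
        return (m.group(1), int(m.group(2))) if m else (s, 0)

    return sorted(ids, key=key)


def read_standoff(txt_path: str | Path) -> StandoffDocument:
    """Read a brat ``.txt``/``.ann`` pair given the ``.txt`` path."""
    txt_path = Path(txt_path)
    ann_path = txt_path.with_suffix(".ann")
    text = normalize_newlines(txt_path.read_text(encoding="utf-8"))
    doc = StandoffDocument(text)
    if not ann_path.exists():
        return doc
    for lineno, line in enumerate(ann_path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        tag = fields[0]
        try:
            if tag.startswith("T"):
                etype, start, end = fields[1].split(" ")
                surface = fields[2] if len(fields) > 2 else ""
                doc.entities.append(
                    StandoffEntity(tag, etype, Span(int(start), int(end)), surface)
                )
            elif tag.startswith("R"):
                kind, a1, a2 = fields[1].split(" ")
                doc.relations.append(
                    StandoffRelation(tag, kind, a1.split(":")[1], a2.split(":")[1])
                )
            elif tag.startswith("A"):
                parts = fields[1].split(" ")
                if parts[0] == "Negation":
                    doc.negations.add(parts[1])
                elif parts[0] == "DocLabel":
                    doc.doc_labels.add(parts[2])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{ann_path}:{lineno}: malformed standoff line") from exc
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# Report reading


def read_reports(path: str | Path, format: str = "plain") -> list[Report]:
    """Read reports from *path*.

    ``plain``: a ``.txt`` file or a directory of ``.txt`` files, one report
    each.  ``standoff``: a directory of brat ``.txt``/``.ann`` pairs; gold
    annotations are attached to each report.  ``jsonl``: newline-delimited
    JSON records with ``report_id`` and ``text`` fields.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such input: {path}")
    reports: list[Report] = []
    if format == "jsonl":
        for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            rec = json.loads(line)
            reports.append(
                zone_report(
                    rec["text"],
                    report_id=str(rec.get("report_id", lineno)),
                    modality=rec.get("modality", "unknown"),
                )
            )
        return reports
    files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
    for f in files:
        try:
            text = f.read_text(encoding="utf-8")
        except OSError as exc:
            raise OSError(f"unreadable report file: {f}") from exc
        if not text.strip():
            log.warning("skipping empty report file %s", f)
            continue
        report = zone_report(text, report_id=f.stem)
        if format == "standoff":
            report.gold = read_standoff(f)
        reports.append(report)
    return reports


def write_labels_jsonl(records: Sequence[Mapping], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_labels_jsonl(path: str | Path) -> list[dict]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            out.append(json.loads(line))
    return out
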