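"""Reading and writing the patent-corpus tab-separated layouts.

Documents file: ``<doc_id>\\t<title>\\t<abstract>`` (one document per line).
Annotation / prediction file:
``<doc_id>\\t<T|A>\\t<start>\\t<end>\\t<text>\\t<class>[\\t<confidence>]``.

Offsets are 0-based, end-exclusive and counted in Unicode code points;
title (``T``) and abstract (``A``) are independent offset spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

RAW_CLASSES = (
    "ABBREVIATION",
    "FAMILY",
    "FORMULA",
    "IDENTIFIER",
    "MULTIPLE",
    "SYSTEMATIC",
    "TRIVIAL",
)
#: ATOM is an internal derived class, never read from gold annotations.
INTERNAL_CLASSES = RAW_CLASSES + ("ATOM",)

PASSAGES = ("T", "A")


class CorpusError(ValueError):
    """Malformed corpus file (wrong column count, bad numbers)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates an invariant."""


@dataclass(frozen=True)
class Mention:
    """A chemical mention anchored to one passage of a document.

    ``text`` must equal the passage substring ``[start:end)``; this is
    enforced whenever a mention is attached to a document.
    """

    passage: str  # "T" or "A"
    start: int
    end: int
    text: str
    raw_class: str
    composed_class: Optional[str] = None  # "Chem" | "Struct" | "Atom"
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.passage not in PASSAGES:
            raise ValidationError(f"passage must be T or A, got {self.passage!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid span [{self.start}, {self.end}) for {self.text!r}"
            )
        if self.raw_class not in INTERNAL_CLASSES:
            raise ValidationError(f"unknown mention class {self.raw_class!r}")

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.passage, self.start, self.end)


@dataclass
class Document:
    """One patent abstract record: id, title text, abstract text, mentions."""

    doc_id: str
    title: str
    abstract: str
    gold_mentions: list[Mention] = field(default_factory=list)
    predicted_mentions: list[Mention] = field(default_factory=list)

    def passage_text(self, passage: str) -> str:
        if passage == "T":
            return self.title
        if passage == "A":
            return self.abstract
        raise ValidationError(f"unknown passage code {passage!r}")

    def check_mention(self, m: Mention) -> None:
        text = self.passage_text(m.passage)
        if m.end > len(text):
            raise ValidationError(
                f"{self.doc_id}/{m.passage}: span [{m.start}, {m.end}) exceeds "
                f"passage length {len(text)}"
            )
        sub = text[m.start : m.end]
        if sub != m.text:
            raise ValidationError(
                f"{self.doc_id}/{m.passage}[{m.start}:{m.end}]: annotation text "
                f"{m.text!r} != passage substring {sub!r}"
            )


def read_documents(path: str | Path) -> list[Document]:
    """Parse a 3-column documents file into :class:`Document` records."""
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise CorpusError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(cols)}"
                )
            doc_id, title, abstract = cols
            if not doc_id:
                raise ValidationError(f"{path}:{lineno}: empty doc_id")
            if doc_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            docs.append(Document(doc_id=doc_id, title=title, abstract=abstract))
    return docs


def _parse_mention_row(cols: list[str], where: str, allow_confidence: bool) -> tuple[str, Mention]:
    n = len(cols)
    if n not in ((6, 7) if allow_confidence else (6,)):
        raise CorpusError(f"{where}: expected 6{' or 7' if allow_confidence else ''} columns, got {n}")
    doc_id, passage, start_s, end_s, text, cls = cols[:6]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise CorpusError(f"{where}: non-integer offsets {start_s!r}/{end_s!r}") from exc
    conf = 1.0
    if n == 7:
        try:
            conf = float(cols[6])
        except ValueError as exc:
            raise CorpusError(f"{where}: bad confidence {cols[6]!r}") from exc
        if not (0.0 <= conf <= 1.0):
            raise ValidationError(f"{where}: confidence {conf} outside [0, 1]")
    if cls not in RAW_CLASSES:
        raise ValidationError(f"{where}: unknown class token {cls!r}")
    try:
        mention = Mention(passage=passage, start=start, end=end, text=text, raw_class=cls, confidence=conf)
    except ValidationError as exc:
        raise ValidationError(f"{where}: {exc}") from exc
    return doc_id, mention


def read_annotations(path: str | Path, docs: list[Document]) -> list[Document]:
    """Attach gold mentions from a 6-column annotations file.

    Every row's doc_id must exist in ``docs`` and its text must match the
    passage substring. Returns ``docs`` (mutated in place) for chaining.
    """
    by_id = {d.doc_id: d for d in docs}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            doc_id, mention = _parse_mention_row(line.split("\t"), f"{path}:{lineno}", allow_confidence=False)
            doc = by_id.get(doc_id)
            if doc is None:
                raise ValidationError(f"{path}:{lineno}: unknown doc_id {doc_id!r}")
            doc.check_mention(mention)
            doc.gold_mentions.append(mention)
    return docs


def read_predictions(path: str | Path, docs: list[Document]) -> list[Document]:
    """Attach predicted mentions from a 6- or 7-column predictions file."""
    by_id = {d.doc_id: d for d in docs}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            doc_id, mention = _parse_mention_row(line.split("\t"), f"{path}:{lineno}", allow_confidence=True)
            doc = by_id.get(doc_id)
            if doc is None:
                raise ValidationError(f"{path}:{lineno}: unknown doc_id {doc_id!r}")
            doc.check_mention(mention)
            doc.predicted_mentions.append(mention)
    return docs


def _sort_key(doc_id: str, m: Mention) -> tuple:
    return (doc_id, PASSAGES.index(m.passage), m.start, m.end)


def write_documents(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(f"{d.doc_id}\t{d.title}\t{d.abstract}\n")


def write_annotations(docs: Iterable[Document], path: str | Path) -> None:
    """Write gold mentions in the 6-column layout (deterministic order)."""
    rows = []
    for d in docs:
        for m in d.gold_mentions:
            rows.append((_sort_key(d.doc_id, m), d.doc_id, m))
    rows.sort(key=lambda r: r[0])
    with open(path, "w", encoding="utf-8") as fh:
        for _, doc_id, m in rows:
            fh.write(f"{doc_id}\t{m.passage}\t{m.start}\t{m.end}\t{m.text}\t{m.raw_class}\n")


def write_predictions(docs: Iterable[Document], path: str | Path) -> None:
    """Write predicted mentions with a confidence column.

    The derived ATOM class never leaves the system: it is mapped back to
    FORMULA on output. Rows are sorted by (doc_id, passage T<A, start, end).
    """
    rows = []
    for d in docs:
        for m in d.predicted_mentions:
            d.check_mention(m)
            if m.raw_class == "ATOM":
                m = replace(m, raw_class="FORMULA")
            rows.append((_sort_key(d.doc_id, m), d.doc_id, m))
    rows.sort(key=lambda r: r[0])
    with open(path, "w", encoding="utf-8") as fh:
        for _, doc_id, m in rows:
            fh.write(
                f"{doc_id}\t{m.passage}\t{m.start}\t{m.end}\t{m.text}\t{m.raw_class}"
                f"\t{m.confidence:.6f}\n"
            )
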