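"""Document-level consistency refinement.

Strings the CRF recognized anywhere in a document (atoms excluded) are
re-scanned across the whole document by greedy maximum matching, so a
chemical name the model missed in one sentence is recovered if it was
found in another. Existing predictions are never altered: a candidate that
overlaps a previous mention is dropped.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

from nerchem.corpus_io import Document, Mention
from nerchem.label_codec import compose_class, representative_raw_class
from nerchem.tokenizer import tokenize_passage

#: Confidence assigned to mentions added by refinement (they were not
#: scored by the CRF on this occurrence).
REFINEMENT_CONFIDENCE = 0.5


def collect_strings(doc: Document) -> set[tuple[str, str]]:
    """Distinct (surface string, composed class) pairs among predictions,
    excluding Atom-derived mentions.

    A string predicted with two different classes keeps the class of its
    most frequent source mention; ties resolve to Chem.
    """
    votes: dict[str, Counter] = {}
    for m in doc.predicted_mentions:
        cls = m.composed_class or compose_class(m.raw_class)
        if cls == "Atom":
            continue
        votes.setdefault(m.text, Counter())[cls] += 1
    out = set()
    for text, counter in votes.items():
        best = max(counter.values())
        classes = sorted(c for c, n in counter.items() if n == best)
        cls = "Chem" if "Chem" in classes else classes[0]
        out.add((text, cls))
    return out


def _boundaries(passage_text: str, passage: str) -> tuple[set[int], set[int]]:
    starts, ends = set(), set()
    for sent in tokenize_passage(passage_text, passage):
        for sub in sent.sub_tokens:
            starts.add(sub.start)
            ends.add(sub.end)
    return starts, ends


def maximum_match_scan(
    passage_text: str,
    strings: Iterable[tuple[str, str]],
    passage: str = "A",
    case_sensitive: bool = True,
) -> list[Mention]:
    """Greedy left-to-right longest-match scan for known mention strings.

    Matches must start and end on sub-token boundaries (so "Ag" cannot
    fire inside "Agent") and are case-sensitive by default — chemical
    strings are case-meaningful ("Co" vs "CO"). Returned candidates are
    non-overlapping among themselves.
    """
    table = {}
    for text, cls in strings:
        if text:
            key = text if case_sensitive else text.casefold()
            table.setdefault(key, []).append(cls)
    if not table:
        return []
    by_len = sorted(table, key=len, reverse=True)
    haystack = passage_text if case_sensitive else passage_text.casefold()
    starts, ends = _boundaries(passage_text, passage)

    candidates: list[Mention] = []
    pos = 0
    n = len(passage_text)
    while pos < n:
        if pos not in starts:
            pos += 1
            continue
        hit = None
        for key in by_len:  # longest first
            end = pos + len(key)
            if end <= n and end in ends and haystack[pos:end] == key:
                hit = (key, end)
                break
        if hit is None:
            pos += 1
            continue
        key, end = hit
        cls = sorted(table[key])[0]
        candidates.append(
            Mention(
                passage=passage,
                start=pos,
                end=end,
                text=passage_text[pos:end],
                raw_class=representative_raw_class(cls),
                composed_class=cls,
                confidence=REFINEMENT_CONFIDENCE,
            )
        )
        pos = end
    return candidates


def merge(doc: Document, candidates: Iterable[Mention]) -> Document:
    """Add candidates that touch no existing prediction; never remove."""
    existing = list(doc.predicted_mentions)
    added = []
    for cand in candidates:
        if all(
            cand.passage != m.passage or cand.end <= m.start or cand.start >= m.end
            for m in existing
        ):
            added.append(cand)
    doc.predicted_mentions = sorted(
        existing + added, key=lambda m: (m.passage, m.start, m.end)
    )
    return doc


def refine_document(doc: Document, case_sensitive: bool = True) -> Document:
    """Full refinement pass over both passages of one document."""
    strings = collect_strings(doc)
    if not strings:
        return doc
    for passage in ("T", "A"):
        text = doc.passage_text(passage)
        if not text:
            continue
        candidates = maximum_match_scan(text, strings, passage, case_sensitive)
        merge(doc, candidates)
    return doc
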