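"""Sentence splitting, full tokenization and punctuation sub-tokenization.

Three aligned granularities are produced for every passage:

* *words* — whitespace-delimited spans;
* *full tokens* — words with sentence punctuation detached at the edges
  (hyphens and brackets inside chemical names stay attached);
* *sub-tokens* — full tokens split at every punctuation character, so that
  ``9-hydroxy-pyrido[1,2-a]pyrimidin-4-one`` yields the alphanumeric pieces
  ``9 hydroxy pyrido 1 2 a pyrimidin 4 one`` with the delimiters kept as
  their own (punctuation) sub-tokens.

All spans are 0-based, end-exclusive character offsets into the passage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

#: Delimiters used by the sub-tokenizer. Every occurrence becomes its own
#: single-character punctuation sub-token.
SUBTOKEN_PUNCT = set("-–,.;:()[]{}=/\\'\"+")

#: Sentence punctuation detached from word edges during full tokenization.
EDGE_PUNCT = set(",.;:!?\"'()")

#: Words after which a period does not end a sentence.
_ABBREVIATIONS = {
    "e.g",
    "i.e",
    "etc",
    "fig",
    "figs",
    "dr",
    "vs",
    "al",
    "no",
    "cf",
    "approx",
    "resp",
    "ref",
}

_SENT_BOUNDARY = re.compile(r"[.!?](?=\s+[A-Z0-9])")


@dataclass
class SubToken:
    text: str
    start: int
    end: int
    is_punct: bool
    parent_word: str = ""
    #: Index of the enclosing full token within the sentence; set by
    #: tokenize_full.
    token_index: int = -1
    #: True iff this is the first sub-token of its full token.
    token_initial: bool = True


@dataclass
class FullToken:
    text: str
    start: int
    end: int
    sub_tokens: list[SubToken] = field(default_factory=list)


@dataclass
class Sentence:
    passage: str  # "T" or "A"
    start: int
    end: int
    text: str
    words: list[tuple[int, int]] = field(default_factory=list)  # passage offsets
    full_tokens: list[FullToken] = field(default_factory=list)

    @property
    def sub_tokens(self) -> list[SubToken]:
        return [s for t in self.full_tokens for s in t.sub_tokens]


def _word_spans(text: str, offset: int) -> list[tuple[int, int]]:
    return [(m.start() + offset, m.end() + offset) for m in re.finditer(r"\S+", text)]


def split_sentences(passage_text: str, passage: str = "A") -> list[Sentence]:
    """Rule-based sentence boundary detection.

    A boundary is a sentence-final ``.``, ``!`` or ``?`` followed by
    whitespace and an uppercase letter or digit, unless the preceding word
    is a known abbreviation or a single letter (initials, element symbols at
    clause ends). Sentence spans tile the passage: each span runs up to the
    start of the next sentence, so offsets of all deeper layers stay global.
    """
    if not passage_text.strip():
        return []
    boundaries: list[int] = []
    for m in _SENT_BOUNDARY.finditer(passage_text):
        if passage_text[m.start()] == ".":
            prev = passage_text[: m.start()].rsplit(None, 1)
            word = prev[-1] if prev else ""
            bare = word.lstrip("(\"'").lower()
            if bare in _ABBREVIATIONS or re.fullmatch(r"[A-Za-z]", bare):
                continue
        boundaries.append(m.end())
    starts = [0] + boundaries
    ends = boundaries + [len(passage_text)]
    sentences = []
    for s, e in zip(starts, ends):
        if not passage_text[s:e].strip():
            continue
        sent = Sentence(passage=passage, start=s, end=e, text=passage_text[s:e])
        sent.words = _word_spans(sent.text, s)
        sentences.append(sent)
    # make spans tile exactly (fold leading whitespace into the previous span)
    for prev, nxt in zip(sentences, sentences[1:]):
        prev.end = nxt.start
        prev.text = passage_text[prev.start : prev.end]
    if sentences:
        sentences[0].start = 0
        sentences[-1].end = len(passage_text)
        sentences[0].text = passage_text[: sentences[0].end]
        sentences[-1].text = passage_text[sentences[-1].start :]
    return sentences


def _edge_split(word: str, start: int) -> list[tuple[str, int, int]]:
    """Detach leading/trailing sentence punctuation from one word span."""
    lo, hi = 0, len(word)
    leading, trailing = [], []
    while lo < hi and word[lo] in EDGE_PUNCT:
        leading.append((word[lo], start + lo, start + lo + 1))
        lo += 1
    while hi > lo and word[hi - 1] in EDGE_PUNCT:
        trailing.append((word[hi - 1], start + hi - 1, start + hi))
        hi -= 1
    core = [(word[lo:hi], start + lo, start + hi)] if hi > lo else []
    return leading + core + list(reversed(trailing))


def tokenize_full(sentence: Sentence) -> list[FullToken]:
    """Split the sentence into full tokens.

    Whitespace-delimited words keep internal hyphens and brackets; only the
    sentence punctuation at word edges (commas, final periods, quotes,
    enclosing parentheses) is detached into separate tokens.
    """
    tokens: list[FullToken] = []
    text = sentence.text
    base = sentence.start
    for ws, we in sentence.words:
        word = text[ws - base : we - base]
        for piece, ps, pe in _edge_split(word, ws):
            tokens.append(FullToken(text=piece, start=ps, end=pe))
    sentence.full_tokens = tokens
    for idx, tok in enumerate(tokens):
        tok.sub_tokens = sub_tokenize(tok)
        word = _enclosing_word(sentence, tok)
        for sub in tok.sub_tokens:
            sub.token_index = idx
            sub.parent_word = sub.text if sub.is_punct else word
    return tokens


def _enclosing_word(sentence: Sentence, tok: FullToken) -> str:
    for ws, we in sentence.words:
        if ws <= tok.start and tok.end <= we:
            return sentence.text[ws - sentence.start : we - sentence.start]
    return tok.text


def sub_tokenize(token: FullToken) -> list[SubToken]:
    """Split a full token at every punctuation delimiter.

    Each delimiter character becomes a punctuation sub-token; maximal runs
    of other characters are kept intact. The concatenation of the returned
    texts always reproduces the full token exactly.
    """
    subs: list[SubToken] = []
    run_start = 0
    text = token.text
    first = True

    def emit(lo: int, hi: int, punct: bool) -> None:
        nonlocal first
        subs.append(
            SubToken(
                text=text[lo:hi],
                start=token.start + lo,
                end=token.start + hi,
                is_punct=punct,
                token_initial=first,
            )
        )
        first = False

    for i, ch in enumerate(text):
        if ch in SUBTOKEN_PUNCT:
            if run_start < i:
                emit(run_start, i, False)
            emit(i, i + 1, True)
            run_start = i + 1
    if run_start < len(text):
        emit(run_start, len(text), False)
    return subs


def map_subtoken_to_word(sub: SubToken) -> str:
    """The whitespace-delimited word containing the sub-token.

    Punctuation sub-tokens map to themselves, so delimiter characters never
    acquire the surface features of the chemical expression around them.
    """
    return sub.text if sub.is_punct else sub.parent_word


def tokenize_passage(passage_text: str, passage: str = "A") -> list[Sentence]:
    """Sentence split + full tokenization + sub-tokenization in one call."""
    sentences = split_sentences(passage_text, passage)
    for sent in sentences:
        tokenize_full(sent)
    return sentences
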