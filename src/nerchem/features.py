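"""Per-sub-token feature extraction for the CRF recognizer.

Feature groups (toggled by name in the training configuration):

``baseline``
    digit-normalized word, POS tag, affixes, orthographic flags, word
    shapes and a +-2 conjunction window of neighbour words.
``bioNE``
    B/I/O label of biological named entities (DNA, RNA, protein,
    cell_line, cell_type) from a pluggable annotator, used to tell
    chemical mentions apart from other biomedical names.
``dictionary``
    B/I/O membership in chemical-name gazetteers (CTD chemicals, DrugBank
    drugs, and their union) found by greedy maximum matching over words.
``fulltoken_ortho``
    five regex flags evaluated on the *enclosing word*, restoring surface
    cues that sub-tokenization destroys (brackets, digit-comma pairs ...).
``fulltoken_boundary``
    whether the sub-token begins its full token (B) or continues it (I).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence

from nerchem.tokenizer import EDGE_PUNCT, Sentence, SubToken, map_subtoken_to_word

log = logging.getLogger(__name__)

FEATURE_GROUPS = ("baseline", "bioNE", "dictionary", "fulltoken_ortho", "fulltoken_boundary")

BIO_NE_TYPES = ("DNA", "RNA", "protein", "cell_line", "cell_type")

_GREEK = (
    "alpha beta gamma delta epsilon zeta eta theta iota kappa lambda mu nu "
    "xi omicron pi rho sigma tau upsilon phi chi psi omega"
).split()
_GREEK_RE = re.compile("|".join(_GREEK), re.IGNORECASE)

#: The five full-token orthographic patterns (applied with re.search).
FULLTOKEN_PATTERNS = {
    "SQUARE": re.compile(r"\[.*?\]"),
    "PARENTHESES": re.compile(r"\(.*?\)"),
    "TOKEN_COMMA": re.compile(r"\S+,\S+"),
    "NUM_COMMA": re.compile(r"\d,\d"),
    "NUM_DASH": re.compile(r"\d-\d"),
}

_DIGITS = re.compile(r"\d")


def word_feature(sub: SubToken | str) -> str:
    """Sub-token text with every decimal digit normalized to '1'."""
    text = sub if isinstance(sub, str) else sub.text
    return _DIGITS.sub("1", text)


def word_shape(text: str, collapse: bool = False) -> str:
    """Map uppercase to X, lowercase to x, digits to 1; keep the rest.

    With ``collapse`` True, adjacent identical shape characters merge, so
    ``Aspirin`` gives ``Xx`` and ``C9H8O4`` gives ``X1X1X1``.
    """
    out = []
    for ch in text:
        if ch.isupper():
            c = "X"
        elif ch.islower():
            c = "x"
        elif ch.isdigit():
            c = "1"
        else:
            c = ch
        if collapse and out and out[-1] == c:
            continue
        out.append(c)
    return "".join(out)


class PosTagger(Protocol):
    def tag(self, sub_tokens: Sequence[SubToken]) -> list[str]: ...


class SuffixRulePosTagger:
    """Deterministic POS tagging from suffix and character-class rules.

    A coarse tagger is enough here: POS acts as a low-resolution shape
    signal for the CRF, not as linguistic analysis.
    """

    _SUFFIX_RULES = (
        ("ing", "VBG"),
        ("ed", "VBD"),
        ("ly", "RB"),
        ("tion", "NN"),
        ("ment", "NN"),
        ("ness", "NN"),
        ("ous", "JJ"),
        ("ive", "JJ"),
        ("able", "JJ"),
        ("ic", "JJ"),
        ("al", "JJ"),
        ("s", "NNS"),
    )
    _CLOSED = {
        "the": "DT", "a": "DT", "an": "DT", "this": "DT", "these": "DT",
        "of": "IN", "in": "IN", "on": "IN", "for": "IN", "with": "IN",
        "by": "IN", "to": "TO", "and": "CC", "or": "CC", "is": "VBZ",
        "are": "VBP", "was": "VBD", "were": "VBD", "we": "PRP", "it": "PRP",
    }

    def tag(self, sub_tokens: Sequence[SubToken]) -> list[str]:
        tags = []
        for sub in sub_tokens:
            text = sub.text
            if sub.is_punct:
                tags.append("PUNCT")
            elif text.isdigit():
                tags.append("CD")
            elif text.lower() in self._CLOSED:
                tags.append(self._CLOSED[text.lower()])
            else:
                for suffix, tag in self._SUFFIX_RULES:
                    if len(text) > len(suffix) + 1 and text.lower().endswith(suffix):
                        tags.append(tag)
                        break
                else:
                    tags.append("NN")
        return tags


# ---------------------------------------------------------------------------
# Bio-NE providers


class BioNEProvider(Protocol):
    def spans(self, sentence: Sentence) -> list[tuple[int, int, str]]:
        """(start, end, type) character spans in passage offsets."""
        ...


class GazetteerBioNEProvider:
    """Maximum matching of biological entity names over sentence words."""

    def __init__(self, entries: dict[str, Iterable[str]]):
        self._index: dict[tuple[str, ...], str] = {}
        self.max_len = 1
        for ne_type, names in entries.items():
            if ne_type not in BIO_NE_TYPES:
                raise ValueError(f"unknown Bio-NE type {ne_type!r}")
            for name in names:
                key = _normalize_phrase(name)
                if key:
                    self._index[key] = ne_type
                    self.max_len = max(self.max_len, len(key))

    def spans(self, sentence: Sentence) -> list[tuple[int, int, str]]:
        out = []
        for i, j, key in _match_words(sentence, self._index, self.max_len):
            out.append((sentence.words[i][0], sentence.words[j - 1][1], self._index[key]))
        return out


class SidecarBioNEProvider:
    """Pre-computed Bio-NE spans loaded from a 5-column sidecar file.

    Layout per line: ``doc_id<TAB>T|A<TAB>start<TAB>end<TAB>type``.
    """

    def __init__(self, path: str | Path):
        self._spans: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 columns")
                doc_id, passage, start, end, ne_type = cols
                if ne_type not in BIO_NE_TYPES:
                    raise ValueError(f"{path}:{lineno}: unknown Bio-NE type {ne_type!r}")
                self._spans.setdefault((doc_id, passage), []).append(
                    (int(start), int(end), ne_type)
                )
        self.doc_id: Optional[str] = None  # set by the pipeline per document

    def spans(self, sentence: Sentence) -> list[tuple[int, int, str]]:
        spans = self._spans.get((self.doc_id or "", sentence.passage), [])
        return [s for s in spans if s[0] >= sentence.start and s[1] <= sentence.end]


def bio_ne_labels(sentence: Sentence, provider: Optional[BioNEProvider]) -> list[str]:
    """One B-type/I-type/O value per sub-token from the provider's spans."""
    subs = sentence.sub_tokens
    labels = ["O"] * len(subs)
    if provider is None:
        return labels
    try:
        spans = provider.spans(sentence)
    except Exception:  # provider failure degrades to all-O
        log.warning("Bio-NE provider failed on sentence at %d; emitting O", sentence.start)
        return labels
    for start, end, ne_type in spans:
        begin = True
        for k, sub in enumerate(subs):
            if sub.start >= start and sub.end <= end:
                labels[k] = ("B-" if begin else "I-") + ne_type
                begin = False
    return labels


# ---------------------------------------------------------------------------
# Dictionary lexicon features


def _normalize_word(word: str) -> str:
    return word.strip("".join(EDGE_PUNCT)).casefold()


def _normalize_phrase(phrase: str) -> tuple[str, ...]:
    return tuple(w for w in (_normalize_word(p) for p in phrase.split()) if w)


@dataclass
class DictionaryResource:
    """A chemical-name gazetteer: CTD chemical names or DrugBank drugs.

    Entries are indexed as tuples of case-folded, edge-punctuation-stripped
    words; the same normalization is applied to queries.
    """

    name: str  # e.g. "CTD_CHEM" or "DRUG"
    entries: set[str]
    _index: dict[tuple[str, ...], str] = field(init=False, repr=False)
    max_len: int = field(init=False, default=1)

    def __post_init__(self) -> None:
        self._index = {}
        for entry in self.entries:
            key = _normalize_phrase(entry)
            if key:
                self._index[key] = self.name
                self.max_len = max(self.max_len, len(key))
        if not self._index:
            log.warning("dictionary %s is empty; its features will all be O", self.name)

    @classmethod
    def from_file(cls, name: str, path: str | Path) -> "DictionaryResource":
        """Load one name per line; '#' starts a comment line."""
        entries = set()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    entries.add(line)
        return cls(name=name, entries=entries)

    def union(self, other: "DictionaryResource", name: str) -> "DictionaryResource":
        return DictionaryResource(name=name, entries=self.entries | other.entries)


def _match_words(
    sentence: Sentence, index: dict[tuple[str, ...], str], max_len: int
) -> list[tuple[int, int, tuple[str, ...]]]:
    """Greedy longest-match-first left-to-right scan over word indices.

    Returns non-overlapping (word_start, word_end_exclusive, key) triples.
    """
    base = sentence.start
    words = [
        _normalize_word(sentence.text[ws - base : we - base]) for ws, we in sentence.words
    ]
    matches = []
    i = 0
    n = len(words)
    while i < n:
        found = None
        for width in range(min(max_len, n - i), 0, -1):
            key = tuple(words[i : i + width])
            if all(key) and key in index:
                found = (i, i + width, key)
                break
        if found:
            matches.append(found)
            i = found[1]
        else:
            i += 1
    return matches


def dictionary_feature_values(
    sentence: Sentence, dictionary: DictionaryResource
) -> list[str]:
    """Per-sub-token B-<name>/I-<name>/O values for one dictionary."""
    subs = sentence.sub_tokens
    values = ["O"] * len(subs)
    for i, j, _key in _match_words(sentence, dictionary._index, dictionary.max_len):
        start = sentence.words[i][0]
        end = sentence.words[j - 1][1]
        begin = True
        for k, sub in enumerate(subs):
            if sub.start >= start and sub.end <= end:
                values[k] = ("B-" if begin else "I-") + dictionary.name
                begin = False
    return values


# ---------------------------------------------------------------------------
# Full-token orthographic + boundary features


def fulltoken_orthographic_features(word: str) -> dict[str, bool]:
    """Evaluate the five chemical-orthography regexes on an un-tokenized word."""
    return {name: bool(pat.search(word)) for name, pat in FULLTOKEN_PATTERNS.items()}


def boundary_feature(sub: SubToken) -> str:
    """B if the sub-token begins its full token, else I."""
    return "B" if sub.token_initial else "I"


# ---------------------------------------------------------------------------
# Row assembly


def baseline_features(
    sub: SubToken,
    sentence: Sentence,
    index: int,
    pos_tags: Optional[list[str]] = None,
    affix_lengths: range = range(1, 5),
    window: int = 2,
) -> dict[str, object]:
    """The word/POS/affix/orthographic/shape/conjunction feature block."""
    subs = sentence.sub_tokens
    if pos_tags is None:
        pos_tags = SuffixRulePosTagger().tag(subs)
    text = sub.text
    row: dict[str, object] = {
        "w": word_feature(sub),
        "pos": pos_tags[index],
        "shape": word_shape(text),
        "shape2": word_shape(text, collapse=True),
        "InitCap": text[:1].isupper(),
        "AllCaps": text.isupper() and text.isalpha(),
        "HasDigit": any(c.isdigit() for c in text),
        "AllDigit": text.isdigit(),
        "IsPunct": sub.is_punct,
        "HasGreek": bool(_GREEK_RE.search(text)),
    }
    for n in affix_lengths:
        row[f"pre{n}"] = word_feature(text[:n])
        row[f"suf{n}"] = word_feature(text[-n:])
    for off in range(-window, window + 1):
        if off == 0:
            continue
        j = index + off
        if 0 <= j < len(subs):
            row[f"w[{off:+d}]"] = word_feature(subs[j])
        else:
            row[f"w[{off:+d}]"] = "__BOS__" if j < 0 else "__EOS__"
    return row


_DICT_CACHE: dict[tuple[int, ...], tuple[DictionaryResource, ...]] = {}


def _resolve_dictionaries(
    dictionaries: tuple[DictionaryResource, ...]
) -> tuple[DictionaryResource, ...]:
    """CTD, DRUG and their union, with the union memoized across sentences."""
    key = tuple(id(d) for d in dictionaries)
    cached = _DICT_CACHE.get(key)
    if cached is None:
        resolved = {d.name: d for d in dictionaries}
        ctd = resolved.get("CTD_CHEM") or DictionaryResource("CTD_CHEM", set())
        drug = resolved.get("DRUG") or DictionaryResource("DRUG", set())
        cached = (ctd, drug, ctd.union(drug, "CHEM_OR_DRUG"))
        _DICT_CACHE.clear()  # keep at most one entry; resources rarely change
        _DICT_CACHE[key] = cached
    return cached


def extract_sentence_features(
    sentence: Sentence,
    toggles: Iterable[str] = FEATURE_GROUPS,
    dictionaries: Sequence[DictionaryResource] = (),
    bio_ne: Optional[BioNEProvider] = None,
    pos_tagger: Optional[PosTagger] = None,
) -> list[dict[str, object]]:
    """One feature row per sub-token, honouring the enabled feature groups."""
    toggles = set(toggles)
    unknown = toggles - set(FEATURE_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature groups: {sorted(unknown)}")
    subs = sentence.sub_tokens
    rows: list[dict[str, object]] = [{} for _ in subs]

    if "baseline" in toggles:
        tags = (pos_tagger or SuffixRulePosTagger()).tag(subs)
        for i, sub in enumerate(subs):
            rows[i].update(baseline_features(sub, sentence, i, pos_tags=tags))

    if "bioNE" in toggles:
        for i, value in enumerate(bio_ne_labels(sentence, bio_ne)):
            rows[i]["bioNE"] = value

    if "dictionary" in toggles:
        for dic in _resolve_dictionaries(tuple(dictionaries)):
            values = dictionary_feature_values(sentence, dic)
            for i, value in enumerate(values):
                rows[i][f"dict_{dic.name}"] = value

    if "fulltoken_ortho" in toggles:
        for i, sub in enumerate(subs):
            word = map_subtoken_to_word(sub)
            for name, flag in fulltoken_orthographic_features(word).items():
                rows[i][f"ft_{name}"] = flag

    if "fulltoken_boundary" in toggles:
        for i, sub in enumerate(subs):
            rows[i]["ft_bound"] = boundary_feature(sub)

    return rows


def rows_to_strings(rows: list[dict[str, object]]) -> list[list[str]]:
    """Flatten feature rows into 'name=value' strings for the CRF engine."""
    return [[f"{k}={v}" for k, v in row.items()] for row in rows]
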