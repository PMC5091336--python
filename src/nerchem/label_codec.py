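"""SOBIE label encoding/decoding and chemical class composition.

The seven corpus classes are merged by naming-convention similarity into
three composed classes:

* ``Chem``   — IDENTIFIER, FAMILY, TRIVIAL, ABBREVIATION;
* ``Struct`` — SYSTEMATIC, FORMULA, MULTIPLE;
* ``Atom``   — derived from short FORMULA mentions that are bare element
  symbols ("H", "Cu", "Ag"), to sharpen formula recognition.

Token labels combine the S/B/I/E/O span tags with the composed classes,
giving a 13-label alphabet: O plus {S,B,I,E} x {Chem,Struct,Atom}.
"""

from __future__ import annotations

import logging
import re
from typing import NamedTuple, Optional, Sequence

from nerchem.corpus_io import Mention, ValidationError
from nerchem.tokenizer import Sentence, SubToken

log = logging.getLogger(__name__)

COMPOSED_CLASSES = ("Chem", "Struct", "Atom")

_COMPOSE = {
    "IDENTIFIER": "Chem",
    "FAMILY": "Chem",
    "TRIVIAL": "Chem",
    "ABBREVIATION": "Chem",
    "SYSTEMATIC": "Struct",
    "FORMULA": "Struct",
    "MULTIPLE": "Struct",
    "ATOM": "Atom",
}

#: Representative raw class used when a mention is reconstructed from
#: predicted labels (the composed class is all the decoder knows).
_REPRESENTATIVE_RAW = {"Chem": "TRIVIAL", "Struct": "SYSTEMATIC", "Atom": "ATOM"}

#: The 118 IUPAC element symbols.
ELEMENT_SYMBOLS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr "
    "Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)

_ELEMENT_COUNT = re.compile(r"([A-Z][a-z]?)(\d*)")


class SobieLabel(NamedTuple):
    tag: str  # S | B | I | E | O
    cls: Optional[str]  # composed class, None iff tag == "O"

    def __str__(self) -> str:
        return "O" if self.tag == "O" else f"{self.tag}-{self.cls}"

    @classmethod
    def parse(cls, s: str) -> "SobieLabel":
        if s == "O":
            return cls("O", None)
        tag, _, c = s.partition("-")
        if tag not in "SBIE" or c not in COMPOSED_CLASSES:
            raise ValidationError(f"not a SOBIE label: {s!r}")
        return cls(tag, c)


OUTSIDE = SobieLabel("O", None)


def label_alphabet() -> list[SobieLabel]:
    """All 13 labels, in a fixed order (O first)."""
    return [OUTSIDE] + [
        SobieLabel(tag, cls) for cls in COMPOSED_CLASSES for tag in "SBIE"
    ]


def compose_class(raw: str) -> str:
    """Map one of the seven corpus classes to Chem or Struct."""
    if raw not in _COMPOSE:
        raise ValidationError(f"unknown raw class {raw!r}")
    return _COMPOSE[raw]


def representative_raw_class(composed: str) -> str:
    if composed not in _REPRESENTATIVE_RAW:
        raise ValidationError(f"unknown composed class {composed!r}")
    return _REPRESENTATIVE_RAW[composed]


def is_atom_mention(mention: Mention, tokens: Sequence[SubToken]) -> bool:
    """Whether a FORMULA mention should train as the Atom class.

    True iff the aligned token range is one full token of at most three
    characters whose every alphanumeric sub-token is a periodic-table
    element symbol, optionally digit-suffixed ("Cu", "H2"). Multi-element
    formulae like "C9H8O4" stay Struct.
    """
    if mention.raw_class != "FORMULA":
        return False
    i, j = align_mention(mention, tokens)
    span = tokens[i:j]
    token_ids = {t.token_index for t in span}
    if len(token_ids) != 1:
        return False
    if (span[-1].end - span[0].start) > 3:
        return False
    alnum = [t for t in span if not t.is_punct]
    if not alnum:
        return False
    for t in alnum:
        m = _ELEMENT_COUNT.fullmatch(t.text)
        if not m or m.group(1) not in ELEMENT_SYMBOLS:
            return False
    return True


def composed_class_for(mention: Mention, tokens: Sequence[SubToken]) -> str:
    if is_atom_mention(mention, tokens):
        return "Atom"
    return compose_class(mention.raw_class)


def align_mention(mention: Mention, tokens: Sequence[SubToken]) -> tuple[int, int]:
    """Smallest token index range [i, j) covering the mention span.

    Boundaries that cut a sub-token snap outward to whole sub-tokens (with
    a logged warning); a span covering no token raises.
    """
    i = j = None
    for k, tok in enumerate(tokens):
        if tok.end > mention.start and tok.start < mention.end:
            if i is None:
                i = k
            j = k + 1
    if i is None or j is None:
        raise ValidationError(
            f"mention [{mention.start}, {mention.end}) {mention.text!r} covers no token"
        )
    if tokens[i].start < mention.start or tokens[j - 1].end > mention.end:
        log.warning(
            "mention %r [%d, %d) cuts sub-token boundaries; snapped outward to [%d, %d)",
            mention.text, mention.start, mention.end, tokens[i].start, tokens[j - 1].end,
        )
    return i, j


def resolve_overlaps(mentions: Sequence[Mention]) -> list[Mention]:
    """Drop overlapping mentions within a passage: longest first, ties
    leftmost (annotation artifacts are rare; this keeps encoding total)."""
    kept: list[Mention] = []
    for m in sorted(mentions, key=lambda m: (-(m.end - m.start), m.start)):
        if all(
            m.passage != k.passage or m.end <= k.start or m.start >= k.end
            for k in kept
        ):
            kept.append(m)
    kept.sort(key=lambda m: (m.passage, m.start))
    return kept


def encode_sobie(sentence: Sentence, mentions: Sequence[Mention]) -> list[SobieLabel]:
    """Label every sub-token of the sentence against the given mentions.

    Mentions are filtered to those inside the sentence span; overlaps are
    resolved first. Singletons get S-cls; longer mentions get B, I..., E.
    Punctuation sub-tokens inside a mention are labelled like any interior
    token.
    """
    tokens = sentence.sub_tokens
    labels = [OUTSIDE] * len(tokens)
    inside = [
        m
        for m in mentions
        if m.passage == sentence.passage
        and m.start >= sentence.start
        and m.end <= sentence.end
    ]
    for m in resolve_overlaps(inside):
        i, j = align_mention(m, tokens)
        cls = composed_class_for(m, tokens)
        if j - i == 1:
            labels[i] = SobieLabel("S", cls)
        else:
            labels[i] = SobieLabel("B", cls)
            for k in range(i + 1, j - 1):
                labels[k] = SobieLabel("I", cls)
            labels[j - 1] = SobieLabel("E", cls)
    return labels


def decode_sobie(
    labels: Sequence[SobieLabel],
    tokens: Sequence[SubToken],
    passage: str,
    passage_text: str,
    merge_atom_runs: bool = True,
) -> list[Mention]:
    """Reconstruct mentions from a predicted label sequence.

    Well-formed S and B...E spans decode exactly (so decode(encode(M)) == M
    for aligned, non-overlapping M). Ill-formed runs are repaired
    permissively: any maximal contiguous same-class stretch not broken by
    an S/B boundary becomes one mention, which favours recall. Contiguous
    Atom-labelled tokens merge into one formula mention unless
    ``merge_atom_runs`` is False.
    """
    if len(labels) != len(tokens):
        raise ValidationError(
            f"label/token length mismatch: {len(labels)} != {len(tokens)}"
        )
    spans: list[tuple[int, int, str]] = []  # token index ranges
    cur_start: Optional[int] = None
    cur_cls: Optional[str] = None

    def flush(end_index: int) -> None:
        nonlocal cur_start, cur_cls
        if cur_start is not None:
            spans.append((cur_start, end_index, cur_cls))  # type: ignore[arg-type]
        cur_start = cur_cls = None

    for k, lab in enumerate(labels):
        if lab.tag == "O":
            flush(k)
        elif lab.tag == "S":
            flush(k)
            if (
                merge_atom_runs
                and lab.cls == "Atom"
                and spans
                and spans[-1][1] == k
                and spans[-1][2] == "Atom"
            ):
                spans[-1] = (spans[-1][0], k + 1, "Atom")
            else:
                spans.append((k, k + 1, lab.cls))
        elif lab.tag == "B":
            flush(k)
            cur_start, cur_cls = k, lab.cls
        else:  # I or E
            if cur_start is None or cur_cls != lab.cls:
                flush(k)  # repair: orphan I/E opens a new mention
                cur_start, cur_cls = k, lab.cls
            if lab.tag == "E":
                flush(k + 1)
    flush(len(labels))

    mentions = []
    for i, j, cls in spans:
        start, end = tokens[i].start, tokens[j - 1].end
        mentions.append(
            Mention(
                passage=passage,
                start=start,
                end=end,
                text=passage_text[start:end],
                raw_class=representative_raw_class(cls),
                composed_class=cls,
            )
        )
    return mentions
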