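import logging
import random

import pytest

from nerchem.corpus_io import Mention, ValidationError
from nerchem.label_codec import (
    SobieLabel,
    align_mention,
    compose_class,
    composed_class_for,
    decode_sobie,
    encode_sobie,
    is_atom_mention,
    label_alphabet,
    resolve_overlaps,
)
from nerchem.tokenizer import tokenize_passage


def _sentence(text, passage="A"):
    return tokenize_passage(text, passage)[0]


class TestComposeClass:
    @pytest.mark.parametrize(
        "raw, composed",
        [
            ("TRIVIAL", "Chem"),
            ("IDENTIFIER", "Chem"),
            ("FAMILY", "Chem"),
            ("ABBREVIATION", "Chem"),
            ("SYSTEMATIC", "Struct"),
            ("FORMULA", "Struct"),
            ("MULTIPLE", "Struct"),
        ],
    )
    def test_seven_class_merge(self, raw, composed):
        assert compose_class(raw) == composed

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError):
            compose_class("DRUG")


class TestAtomDerivation:
    def test_single_element_symbol_becomes_atom(self):
        sent = _sentence("Cu was reduced")
        m = Mention("A", 0, 2, "Cu", "FORMULA")
        assert composed_class_for(m, sent.sub_tokens) == "Atom"

    def test_multi_element_formula_stays_struct(self):
        sent = _sentence("C9H8O4 was pure")
        m = Mention("A", 0, 6, "C9H8O4", "FORMULA")
        assert composed_class_for(m, sent.sub_tokens) == "Struct"

    def test_non_formula_classes_untouched(self):
        sent = _sentence("menthol was pure")
        m = Mention("A", 0, 7, "menthol", "TRIVIAL")
        assert not is_atom_mention(m, sent.sub_tokens)
        assert composed_class_for(m, sent.sub_tokens) == "Chem"

    def test_digit_suffixed_symbol_is_atom(self):
        sent = _sentence("H2 gas evolved")
        m = Mention("A", 0, 2, "H2", "FORMULA")
        assert composed_class_for(m, sent.sub_tokens) == "Atom"

    def test_non_element_short_token_stays_struct(self):
        sent = _sentence("Xx was added")
        m = Mention("A", 0, 2, "Xx", "FORMULA")
        assert composed_class_for(m, sent.sub_tokens) == "Struct"


class TestLabelAlphabet:
    def test_exactly_thirteen_labels(self):
        labels = label_alphabet()
        assert len(labels) == 13 and len(set(labels)) == 13
        assert SobieLabel("O", None) in labels

    def test_string_round_trip(self):
        for lab in label_alphabet():
            assert SobieLabel.parse(str(lab)) == lab


class TestEncode:
    def test_singleton_mention(self):
        sent = _sentence("menthol cools skin")
        labels = encode_sobie(sent, [Mention("A", 0, 7, "menthol", "TRIVIAL")])
        assert str(labels[0]) == "S-Chem"
        assert all(str(l) == "O" for l in labels[1:])

    def test_long_mention_b_i_e_with_interior_punctuation(self):
        text = "9-hydroxy-pyrido[1,2-a]pyrimidin-4-one derivatives"
        sent = _sentence(text)
        labels = encode_sobie(sent, [Mention("A", 0, 38, text[:38], "SYSTEMATIC")])
        k = len([s for s in sent.sub_tokens if s.start < 38])
        tags = [str(l) for l in labels]
        assert tags[0] == "B-Struct" and tags[k - 1] == "E-Struct"
        assert tags[1 : k - 1] == ["I-Struct"] * (k - 2)
        assert tags[k:] == ["O"] * (len(tags) - k)

    def test_no_mentions_all_outside(self):
        sent = _sentence("nothing here at all")
        assert all(str(l) == "O" for l in encode_sobie(sent, []))


class TestDecode:
    def test_round_trip_singleton(self):
        text = "menthol cools skin"
        sent = _sentence(text)
        gold = [Mention("A", 0, 7, "menthol", "TRIVIAL")]
        labels = encode_sobie(sent, gold)
        decoded = decode_sobie(labels, sent.sub_tokens, "A", text)
        assert [(m.span, m.composed_class) for m in decoded] == [(("A", 0, 7), "Chem")]

    def test_missing_E_repaired_to_one_mention(self):
        text = "salicylic acid"
        sent = _sentence(text)
        labels = [SobieLabel("B", "Struct"), SobieLabel("I", "Struct")]
        (m,) = decode_sobie(labels, sent.sub_tokens, "A", text)
        assert m.span == ("A", 0, 14) and m.composed_class == "Struct"

    def test_all_outside_decodes_to_nothing(self):
        text = "no chemicals"
        sent = _sentence(text)
        labels = [SobieLabel("O", None)] * len(sent.sub_tokens)
        assert decode_sobie(labels, sent.sub_tokens, "A", text) == []

    def test_length_mismatch_rejected(self):
        sent = _sentence("a b")
        with pytest.raises(ValidationError):
            decode_sobie([SobieLabel("O", None)], sent.sub_tokens, "A", "a b")

    def test_adjacent_same_class_mentions_stay_separate(self):
        text = "menthol camphor"
        sent = _sentence(text)
        gold = [
            Mention("A", 0, 7, "menthol", "TRIVIAL"),
            Mention("A", 8, 15, "camphor", "TRIVIAL"),
        ]
        decoded = decode_sobie(encode_sobie(sent, gold), sent.sub_tokens, "A", text)
        assert [m.span for m in decoded] == [("A", 0, 7), ("A", 8, 15)]

    def test_decoded_mentions_never_overlap(self):
        text = "one two three four"
        sent = _sentence(text)
        rng = random.Random(7)
        alphabet = label_alphabet()
        for _ in range(200):
            labels = [rng.choice(alphabet) for _ in sent.sub_tokens]
            decoded = decode_sobie(labels, sent.sub_tokens, "A", text)
            spans = sorted((m.start, m.end) for m in decoded)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2


class TestAlign:
    def test_exact_boundaries(self):
        sent = _sentence("take menthol now")
        i, j = align_mention(Mention("A", 5, 12, "menthol", "TRIVIAL"), sent.sub_tokens)
        assert (sent.sub_tokens[i].start, sent.sub_tokens[j - 1].end) == (5, 12)

    def test_mid_token_boundary_snaps_outward_with_warning(self, caplog):
        sent = _sentence("take menthol now")
        with caplog.at_level(logging.WARNING, logger="nerchem.label_codec"):
            i, j = align_mention(Mention("A", 7, 12, "nthol", "TRIVIAL"), sent.sub_tokens)
        assert sent.sub_tokens[i].start == 5  # snapped out to token start
        assert "snapped" in caplog.text

    def test_mention_outside_tokens_rejected(self):
        sent = _sentence("short")
        with pytest.raises(ValidationError):
            align_mention(Mention("A", 40, 45, "xxxxx", "TRIVIAL"), sent.sub_tokens)


class TestResolveOverlaps:
    def test_longest_wins_ties_leftmost(self):
        a = Mention("A", 0, 10, "x" * 10, "TRIVIAL")
        b = Mention("A", 5, 12, "x" * 7, "TRIVIAL")
        c = Mention("A", 20, 27, "x" * 7, "TRIVIAL")
        kept = resolve_overlaps([b, a, c])
        assert [(m.start, m.end) for m in kept] == [(0, 10), (20, 27)]


def test_encode_decode_identity_on_random_mention_sets():
    """decode(encode(M)) == M for aligned, non-overlapping mention sets."""
    rng = random.Random(2024)
    words = ["aspirin", "menthol", "acid", "ester", "salt", "agent", "use", "B12"]
    for _ in range(300):
        text = " ".join(rng.choice(words) for _ in range(rng.randint(2, 10)))
        sent = _sentence(text)
        mentions = []
        used_until = -1
        for ws, we in sent.words:
            if ws <= used_until or rng.random() < 0.5:
                continue
            raw = rng.choice(["TRIVIAL", "SYSTEMATIC", "ABBREVIATION", "MULTIPLE"])
            mentions.append(Mention("A", ws, we, text[ws:we], raw))
            used_until = we  # leave a gap before the next mention
        labels = encode_sobie(sent, mentions)
        decoded = decode_sobie(labels, sent.sub_tokens, "A", text)
        expected = {(m.span, compose_class(m.raw_class)) for m in mentions}
        assert {(m.span, m.composed_class) for m in decoded} == expected
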