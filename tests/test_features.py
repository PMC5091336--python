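import random

import pytest

from nerchem.features import (
    DictionaryResource,
    GazetteerBioNEProvider,
    _match_words,
    _normalize_word,
    baseline_features,
    bio_ne_labels,
    boundary_feature,
    dictionary_feature_values,
    extract_sentence_features,
    fulltoken_orthographic_features,
    word_feature,
    word_shape,
)
from nerchem.tokenizer import tokenize_passage


def _sentence(text):
    return tokenize_passage(text)[0]


class TestWordFeature:
    @pytest.mark.parametrize(
        "text, expected",
        [("C9H8O4", "C1H1O1"), ("hydroxy", "hydroxy"), ("B12", "B11")],
    )
    def test_digit_normalization(self, text, expected):
        assert word_feature(text) == expected


class TestBaselineFeatures:
    def test_initcap_and_collapsed_shape(self):
        sent = _sentence("Aspirin relieves pain")
        row = baseline_features(sent.sub_tokens[0], sent, 0)
        assert row["InitCap"] is True
        assert row["shape2"] == "Xx"

    def test_formula_shape_by_hand(self):
        # oracle: apply upper->X lower->x digit->1 by hand: C9H8O4 -> X1X1X1
        sent = _sentence("C9H8O4 dissolved")
        row = baseline_features(sent.sub_tokens[0], sent, 0)
        assert row["HasDigit"] is True
        assert row["shape"] == "X1X1X1"
        assert word_shape("C9H8O4", collapse=True) == "X1X1X1"

    def test_sentence_initial_conjunction_sentinels(self):
        sent = _sentence("Aspirin relieves pain")
        row = baseline_features(sent.sub_tokens[0], sent, 0)
        assert row["w[-1]"] == "__BOS__" and row["w[-2]"] == "__BOS__"
        assert row["w[+1]"] == "relieves"

    def test_affixes_digit_normalized(self):
        sent = _sentence("B12 tablets")
        row = baseline_features(sent.sub_tokens[0], sent, 0)
        assert row["pre2"] == "B1" and row["suf1"] == "1"


class TestBioNE:
    def test_gazetteer_tags_known_protein(self):
        provider = GazetteerBioNEProvider({"protein": ["p53"]})
        sent = _sentence("The p53 protein binds")
        labels = bio_ne_labels(sent, provider)
        by_text = dict(zip([s.text for s in sent.sub_tokens], labels))
        assert by_text["p53"] == "B-protein"

    def test_outside_any_span_is_O(self):
        provider = GazetteerBioNEProvider({"protein": ["p53"]})
        sent = _sentence("The drug works")
        assert set(bio_ne_labels(sent, provider)) == {"O"}

    def test_multiword_entity_gets_B_then_I(self):
        provider = GazetteerBioNEProvider({"protein": ["tyrosine kinase"]})
        sent = _sentence("A tyrosine kinase inhibitor")
        labels = bio_ne_labels(sent, provider)
        assert labels[1:3] == ["B-protein", "I-protein"]

    def test_provider_failure_degrades_to_O(self):
        class Broken:
            def spans(self, sentence):
                raise RuntimeError("boom")

        sent = _sentence("The drug works")
        assert set(bio_ne_labels(sent, Broken())) == {"O"}

    def test_no_provider_is_all_O(self):
        assert set(bio_ne_labels(_sentence("a b"), None)) == {"O"}


class TestDictionaryFeatures:
    def test_three_word_entry_tagged_b_i_i(self):
        dic = DictionaryResource("CTD_CHEM", {"acetyl salicylic acid"})
        sent = _sentence("acetyl salicylic acid works")
        values = dictionary_feature_values(sent, dic)
        assert values[:3] == ["B-CTD_CHEM", "I-CTD_CHEM", "I-CTD_CHEM"]
        assert values[3] == "O"

    def test_longer_earlier_match_wins(self):
        dic = DictionaryResource("CTD_CHEM", {"salicylic acid", "acetyl salicylic acid"})
        sent = _sentence("acetyl salicylic acid works")
        values = dictionary_feature_values(sent, dic)
        assert values[0] == "B-CTD_CHEM" and values[1] == "I-CTD_CHEM"

    def test_no_entry_matches(self):
        dic = DictionaryResource("CTD_CHEM", {"menthol"})
        sent = _sentence("nothing chemical here")
        assert set(dictionary_feature_values(sent, dic)) == {"O"}

    def test_matching_is_case_insensitive_and_ignores_edge_punct(self):
        dic = DictionaryResource("CTD_CHEM", {"Aspirin"})
        sent = _sentence("Take aspirin, twice")
        values = dictionary_feature_values(sent, dic)
        assert "B-CTD_CHEM" in values

    def test_greedy_matching_equals_bruteforce_oracle(self):
        """Exhaustive check on random sentences of <= 12 words."""
        vocab = ["acid", "acetyl", "salicylic", "methyl", "ester", "salt", "the", "of"]
        rng = random.Random(42)
        for _ in range(300):
            words = [rng.choice(vocab) for _ in range(rng.randint(1, 12))]
            entries = set()
            for _ in range(rng.randint(1, 6)):
                k = rng.randint(1, 3)
                entries.add(" ".join(rng.choice(vocab) for _ in range(k)))
            dic = DictionaryResource("CTD_CHEM", entries)
            sent = _sentence(" ".join(words))
            got = [(i, j) for i, j, _ in _match_words(sent, dic._index, dic.max_len)]

            # oracle: enumerate all matching (i, width) pairs directly
            # against the entry strings, then apply greedy longest-leftmost
            norm = [_normalize_word(w) for w in words]
            entry_keys = {tuple(_normalize_word(p) for p in e.split()) for e in entries}
            candidates = {}
            for i in range(len(norm)):
                for j in range(i + 1, len(norm) + 1):
                    if tuple(norm[i:j]) in entry_keys:
                        candidates.setdefault(i, []).append(j)
            expected = []
            i = 0
            while i < len(norm):
                if i in candidates:
                    j = max(candidates[i])
                    expected.append((i, j))
                    i = j
                else:
                    i += 1
            assert got == expected


class TestFullTokenOrthographic:
    @pytest.mark.parametrize(
        "word, expected",
        [
            (
                "9-hydroxy-pyrido[1,2-a]pyrimidin-4-one",
                {"SQUARE": True, "NUM_COMMA": True, "NUM_DASH": False},
            ),
            ("1-deoxy-1,1-veratryl", {"NUM_COMMA": True, "SQUARE": False}),
            ("ether", {"SQUARE": False, "PARENTHESES": False, "TOKEN_COMMA": False,
                       "NUM_COMMA": False, "NUM_DASH": False}),
        ],
    )
    def test_patterns(self, word, expected):
        flags = fulltoken_orthographic_features(word)
        for name, value in expected.items():
            assert flags[name] is value, name


class TestBoundaryFeature:
    def test_first_subtoken_is_B_rest_I(self):
        sent = _sentence("9-hydroxy-pyrido derivatives")
        subs = sent.sub_tokens
        assert boundary_feature(subs[0]) == "B"  # "9"
        hydroxy = next(s for s in subs if s.text == "hydroxy")
        assert boundary_feature(hydroxy) == "I"

    def test_single_subtoken_token_is_B(self):
        sent = _sentence("derivatives")
        assert boundary_feature(sent.sub_tokens[0]) == "B"


class TestRowAssembly:
    def test_row_count_equals_subtoken_count_and_is_stable(self):
        sent = _sentence("Aspirin (C9H8O4) relieves pain.")
        dics = [DictionaryResource("CTD_CHEM", {"aspirin"})]
        rows1 = extract_sentence_features(sent, dictionaries=dics)
        rows2 = extract_sentence_features(sent, dictionaries=dics)
        assert len(rows1) == len(sent.sub_tokens)
        assert rows1 == rows2  # purity: identical inputs, identical rows

    def test_unknown_toggle_rejected(self):
        with pytest.raises(ValueError, match="unknown feature groups"):
            extract_sentence_features(_sentence("x"), toggles={"embeddings"})

    def test_toggles_control_row_keys(self):
        sent = _sentence("Aspirin helps")
        rows = extract_sentence_features(sent, toggles={"fulltoken_boundary"})
        assert set(rows[0]) == {"ft_bound"}
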