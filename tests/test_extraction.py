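import pytest
from hypothesis import given
from hypothesis import strategies as st

from bivalvelabel.extraction import (
    UNMATCHED,
    DateCandidate,
    extract_all,
    detect_purification,
    find_date_candidates,
    match_field,
    similarity,
)
from bivalvelabel.ocr import RawText


def levenshtein_oracle(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[len(b)]


def raw(text: str, tag: str = "greyscale") -> RawText:
    return RawText(text, tag)


class TestSimilarity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("mytilus", "mytilus", 1.0),
            ("myti1us", "mytilus", 1 - 1 / 7),
            ("abc", "xyz", 0.0),
            ("", "", 1.0),
            ("", "abc", 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert similarity(a, b) == pytest.approx(expected)

    @given(st.text("abcde ", max_size=10), st.text("abcde ", max_size=10))
    def test_matches_dp_oracle_and_is_symmetric(self, a, b):
        expected = (
            1.0
            if not a and not b
            else (1 - levenshtein_oracle(a, b) / max(len(a), len(b)) if a or b else 1.0)
        )
        assert similarity(a, b) == pytest.approx(expected)
        assert similarity(a, b) == pytest.approx(similarity(b, a))
        assert (similarity(a, b) == 1.0) == (a == b)


class TestMatchField:
    def test_exact_latin_name_matches_at_one(self, vocabularies):
        cand = match_field(raw("lote 4 Mytilus spp 500 g"), vocabularies["species"])
        assert (cand.value, cand.similarity) == ("mytilus_spp", 1.0)

    def test_corrupted_latin_token_matches_through_the_window(self, vocabularies):
        cand = match_field(raw("MEXILHAO Myti1us spp LOTE 4"), vocabularies["species"])
        assert cand.value == "mytilus_spp"
        assert cand.similarity == pytest.approx(1.0)  # the common name is intact

    def test_corrupted_only_form_scores_its_edit_distance(self, vocabularies):
        cand = match_field(raw("Myti1us spp LOTE 4"), vocabularies["species"])
        assert cand.value == "mytilus_spp"
        assert cand.similarity == pytest.approx(1 - 1 / 11)  # 'mytilus spp' len 11

    def test_nothing_above_threshold_is_unmatched_with_best_similarity(self, vocabularies):
        cand = match_field(raw("qqqq zzzz"), vocabularies["species"], threshold=0.6)
        assert cand.value == UNMATCHED
        assert 0.0 <= cand.similarity < 0.6

    @given(st.text(alphabet="abcdefghij mytilus0123/-.", max_size=30))
    def test_never_returns_a_value_outside_the_vocabulary(self, vocabularies, text):
        cand = match_field(raw(text), vocabularies["species"])
        assert cand.value == UNMATCHED or cand.value in vocabularies["species"].canonical_values


class TestDates:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("23/07", [(23, 7, None, "/")]),
            ("05-12-2017", [(5, 12, 2017, "-")]),
            ("03.04.17", [(3, 4, 2017, ".")]),  # two-digit year maps to 2000+yy
            ("45/13", []),  # day and month out of range
            ("05/12-17", []),  # mixed separators rejected outright
            ("1/1", [(1, 1, None, "/")]),
            ("Emb.: 23/07 Lote 12345", [(23, 7, None, "/")]),
            ("02/03 e depois 04.05.2018", [(2, 3, None, "/"), (4, 5, 2018, ".")]),
        ],
    )
    def test_pattern_examples(self, text, expected):
        got = [
            (d.day, d.month, d.explicit_year, d.separator)
            for d in find_date_candidates(raw(text))
        ]
        assert got == expected

    @given(st.text(alphabet="0123456789/-. a", max_size=25))
    def test_emitted_candidates_always_in_calendar_range(self, text):
        for cand in find_date_candidates(raw(text)):
            assert 1 <= cand.day <= 31
            assert 1 <= cand.month <= 12
            assert cand.separator in "/-."

    def test_candidate_construction_enforces_ranges(self):
        with pytest.raises(ValueError):
            DateCandidate(32, 1, None, "/")
        with pytest.raises(ValueError):
            DateCandidate(1, 13, None, "/")


class TestPurification:
    def test_exact_keyword_detected(self, purification_keywords):
        assert detect_purification(raw("produto depurado"), purification_keywords)

    def test_empty_text_is_negative(self, purification_keywords):
        assert not detect_purification(raw(""), purification_keywords)

    def test_single_substitution_still_detected_at_strict_threshold(self, purification_keywords):
        # similarity('depurudo', 'depurado') = 7/8 = 0.875 >= 0.85
        assert detect_purification(raw("produto depurudo"), purification_keywords, 0.85)

    def test_unrelated_text_not_detected(self, purification_keywords):
        assert not detect_purification(
            raw("zona de produção RIAV1 aquicultura"), purification_keywords
        )


class TestExtractAll:
    def test_noiseless_full_label_round_trip(self, vocabularies, purification_keywords):
        text = raw(
            "AMÊIJOA-BOA Ruditapes decussata\n"
            "Data de embalamento: 23/07/2017\n"
            "Zona: RIAV1\nAquicultura\nOrigem: Portugal\nProduto depurado"
        )
        ext = extract_all(text, vocabularies, purification_keywords)
        assert {v: c.value for v, c in ext.fields.items()} == {
            "species": "ruditapes_decussata",
            "zone": "RIAV1",
            "method": "aquaculture",
            "country": "portugal",
        }
        assert all(c.similarity == 1.0 for c in ext.fields.values())
        assert len(ext.date_candidates) == 1
        assert ext.purification_detected

    def test_date_only_text(self, vocabularies, purification_keywords):
        ext = extract_all(raw("23/07"), vocabularies, purification_keywords)
        assert all(c.value == UNMATCHED for c in ext.fields.values())
        assert [(d.day, d.month) for d in ext.date_candidates] == [(23, 7)]
        assert not ext.purification_detected

    def test_empty_text(self, vocabularies, purification_keywords):
        ext = extract_all(raw(""), vocabularies, purification_keywords)
        assert all(c.value == UNMATCHED for c in ext.fields.values())
        assert ext.date_candidates == ()
        assert not ext.purification_detected
        assert ext.date_vote is None
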