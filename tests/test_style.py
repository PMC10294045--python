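"""Complex language, passive voice, person-centred, density/diversity,
structure."""

import pytest
from hypothesis import given, settings, strategies as st

from healthlit import (
    Document,
    FixtureSpec,
    detect_passive,
    flag_complex_language,
    flag_person_centred,
    generate_fixture,
    lexical_density,
    lexical_diversity,
    suggest_alternatives,
    text_structure,
)
from healthlit.errors import EmptyDocumentError


class TestComplexLanguage:
    def test_adequate_flagged_with_suggestion(self, make_doc, lexicon):
        doc = make_doc("Everyone can benefit from adequate activity.")
        (h,) = flag_complex_language(doc, lexicon)
        assert h.text(doc.text) == "adequate"
        assert h.alternatives == ("enough",)
        assert "enough" in h.message

    def test_fissure_flagged_without_alternatives(self, make_doc, lexicon):
        doc = make_doc("A small fissure was found.")
        flags = [h for h in flag_complex_language(doc, lexicon)]
        (h,) = flags
        assert h.text(doc.text) == "fissure"
        assert h.alternatives == ()
        assert "no plain-language alternative" in h.message.lower()

    def test_common_word_not_flagged(self, make_doc, lexicon):
        assert flag_complex_language(make_doc("Drink more water."), lexicon) == []

    def test_lemma_family_matches(self, make_doc, lexicon):
        doc = make_doc("Eat adequately every day.")
        (h,) = flag_complex_language(doc, lexicon)
        assert h.text(doc.text) == "adequately"

    def test_multiword_term(self, make_doc, lexicon):
        doc = make_doc("A myocardial infarction is an emergency.")
        flags = flag_complex_language(doc, lexicon)
        assert any(h.text(doc.text) == "myocardial infarction" for h in flags)
        assert any("heart attack" in h.alternatives for h in flags)

    def test_exclusions_suppress_exactly_that_term(self, make_doc, lexicon):
        doc = make_doc("Diabetes care needs adequate planning for diabetes.")
        base = flag_complex_language(doc, lexicon)
        reduced = flag_complex_language(doc, lexicon, {"diabetes"})
        removed = [h for h in base if h not in reduced]
        assert all(h.text(doc.text).lower() == "diabetes" for h in removed)
        assert len(base) - len(reduced) == 2

    def test_highlight_span_matches_trigger(self, make_doc, lexicon):
        doc = make_doc("Utilise the renal clinic and notify the staff.")
        for h in flag_complex_language(doc, lexicon):
            assert doc.text[h.start : h.end].lower() in ("utilise", "renal", "notify")


class TestSuggestAlternatives:
    @pytest.mark.parametrize(
        "term, expected",
        [("adequate", ("enough",)), ("Adequate", ("enough",)), ("zzzz", ())],
    )
    def test_lookup(self, lexicon, term, expected):
        assert suggest_alternatives(term, lexicon) == expected

    def test_no_alternative_terms_return_empty(self, lexicon):
        assert suggest_alternatives("fissure", lexicon) == ()


class TestPassiveVoice:
    @pytest.mark.parametrize(
        "text, phrases",
        [
            ("The medicine was taken by the patient.", ["was taken"]),
            ("The patient took the medicine.", []),
            ("Your appointment may be changed.", ["be changed"]),
            ("The sample was quickly tested.", ["was quickly tested"]),
            ("It was being tested all day.", ["was being tested"]),
            ("You got asked to come back.", ["got asked"]),
        ],
    )
    def test_examples(self, make_doc, text, phrases):
        doc = make_doc(text)
        assert [h.text(doc.text) for h in detect_passive(doc)] == phrases

    def test_all_active_corpus_has_zero_flags(self, make_doc):
        text = generate_fixture(FixtureSpec(sentence_count=20, words_per_sentence=9, seed=5))
        assert detect_passive(make_doc(text)) == []

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_planted_count_recovered(self, make_doc, k):
        text = generate_fixture(
            FixtureSpec(sentence_count=10, words_per_sentence=9,
                        planted_passive_count=k, seed=k)
        )
        assert len(detect_passive(make_doc(text))) == k


class TestPersonCentred:
    def test_diabetic_flagged_with_preferred(self, make_doc, ruleset):
        doc = make_doc("Talk to the diabetic about insulin.")
        flags = flag_person_centred(doc, ruleset)
        assert any(h.alternatives == ("person with diabetes",) for h in flags)

    def test_case_insensitive(self, make_doc, ruleset):
        doc = make_doc("Diabetic patients need support.")
        assert flag_person_centred(doc, ruleset)

    def test_no_matches(self, make_doc, ruleset):
        assert flag_person_centred(make_doc("Eat well and sleep well."), ruleset) == []

    def test_multiword_pattern(self, make_doc, ruleset):
        doc = make_doc("She suffers from asthma.")
        flags = flag_person_centred(doc, ruleset)
        assert any(doc.text[h.start : h.end].lower() == "suffers from" for h in flags)


class TestDensityDiversity:
    def test_density_example(self, make_doc):
        assert lexical_density(make_doc("The patient took the medicine.")) == pytest.approx(0.6)

    def test_single_content_word(self, make_doc):
        assert lexical_density(make_doc("Run.")) == 1.0

    def test_no_content_words(self, make_doc):
        assert lexical_density(make_doc("of the and")) == 0.0

    def test_density_empty_errors(self, make_doc):
        with pytest.raises(EmptyDocumentError):
            lexical_density(make_doc(""))

    def test_ttr_example(self, make_doc):
        assert lexical_diversity(make_doc("the cat sat on the mat")) == pytest.approx(5 / 6)

    def test_single_type(self, make_doc):
        assert lexical_diversity(make_doc("no no no")) == pytest.approx(1 / 3)

    def test_all_distinct_short_text_is_one(self, make_doc):
        doc = make_doc("one two three four five six seven eight nine ten")
        assert lexical_diversity(doc) == 1.0

    def test_long_text_uses_moving_average(self, make_doc):
        # 60 tokens alternating two words: every 50-token window has 2 types
        doc = make_doc(" ".join(["salt water"] * 30))
        assert lexical_diversity(doc) == pytest.approx(2 / 50)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 1000), s=st.integers(1, 8), w=st.integers(3, 12))
    def test_bounds_on_generated_text(self, seed, s, w):
        doc = Document.from_text(
            generate_fixture(FixtureSpec(sentence_count=s, words_per_sentence=w, seed=seed))
        )
        assert 0.0 <= lexical_density(doc) <= 1.0
        d = lexical_diversity(doc)
        assert 0.0 < d <= 1.0
        words = [t.surface.lower() for t in doc.word_tokens]
        if len(words) < 50:
            assert (d == 1.0) == (len(set(words)) == len(words))


class TestStructure:
    def test_mean_words_per_paragraph(self, make_doc):
        ten = " ".join(["word"] * 10) + "."
        twenty = " ".join(["word"] * 20) + "."
        m = text_structure(make_doc(ten + "\n\n" + twenty))
        assert m.paragraph_count == 2
        assert m.mean_words_per_paragraph == pytest.approx(15.0)
        assert m.mean_sentences_per_paragraph == pytest.approx(1.0)

    def test_long_paragraph_flagged(self, make_doc):
        text = " ".join(["word"] * 120) + "."
        m = text_structure(make_doc(text), paragraph_word_limit=100)
        assert len(m.highlights) == 1

    def test_empty_text(self, make_doc):
        m = text_structure(make_doc(""))
        assert m.paragraph_count == 0 and m.highlights == ()
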