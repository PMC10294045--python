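"""Orchestration: config, assess, exclusion locality, pinning, comparison."""

import dataclasses

import pytest

from healthlit import (
    ALL_ASSESSMENTS,
    EditorConfig,
    FixtureSpec,
    Pinboard,
    assess,
    compare,
    generate_fixture,
    pin,
    set_exclusions,
    status_against_target,
)
from healthlit.errors import (
    ConfigurationError,
    EmptyDocumentError,
    ExclusionLimitError,
    SchemaVersionError,
)

TEXT = generate_fixture(
    FixtureSpec(
        sentence_count=12,
        words_per_sentence=10,
        polysyllables_per_sentence=2,
        planted_passive_count=2,
        planted_jargon=("fissure", "renal"),
        seed=42,
    )
)

ALL_ON = EditorConfig(enabled_assessments=frozenset(ALL_ASSESSMENTS))


class TestConfig:
    def test_defaults(self):
        cfg = EditorConfig()
        assert cfg.enabled_assessments == {
            "readability", "complex_language", "passive_voice",
        }
        assert cfg.target_grade == 8.0

    def test_unknown_assessment_rejected(self):
        with pytest.raises(ConfigurationError):
            EditorConfig(enabled_assessments=frozenset({"vibes"}))

    def test_empty_assessments_rejected(self):
        with pytest.raises(ConfigurationError):
            EditorConfig(enabled_assessments=frozenset())

    def test_set_exclusions_lowercases_and_limits(self):
        cfg = set_exclusions(EditorConfig(), {"Diabetes"})
        assert cfg.exclusions == {"diabetes"}
        with pytest.raises(ExclusionLimitError):
            set_exclusions(cfg, {"a", "b", "c", "d", "e", "f"})

    def test_toml_roundtrip(self, tmp_path):
        p = tmp_path / "config.toml"
        p.write_text(
            'schema_version = "1"\n'
            'enabled_assessments = ["readability"]\n'
            'exclusions = ["diabetes"]\n'
            "target_grade = 9.0\n"
        )
        cfg = EditorConfig.from_toml(p)
        assert cfg.enabled_assessments == {"readability"}
        assert cfg.target_grade == 9.0

    def test_toml_bad_version(self, tmp_path):
        p = tmp_path / "config.toml"
        p.write_text('schema_version = "99"\n')
        with pytest.raises(SchemaVersionError):
            EditorConfig.from_toml(p)


class TestAssess:
    def test_zero_polysyllable_fixture_hits_smog_floor(self):
        text = generate_fixture(FixtureSpec(sentence_count=30, words_per_sentence=8, seed=1))
        report = assess(text, ALL_ON)
        assert report.readability.grade == 3.1
        assert report.readability.long_word_highlights == ()

    def test_disabled_assessments_absent(self):
        report = assess(TEXT, EditorConfig(enabled_assessments=frozenset({"readability"})))
        assert set(report.global_summary) == {"readability"}
        assert report.style.passive_highlights is None
        assert report.style.complex_language_highlights is None

    def test_determinism_up_to_timestamp(self):
        r1 = assess(TEXT, ALL_ON)
        r2 = assess(TEXT, ALL_ON)
        assert r1.comparable_fields() == r2.comparable_fields()

    def test_empty_text_names_needy_assessments(self):
        with pytest.raises(EmptyDocumentError) as err:
            assess("", EditorConfig())
        assert "readability" in str(err.value)

    def test_highlights_sorted_and_from_enabled_categories(self):
        report = assess(TEXT, ALL_ON)
        starts = [h.start for h in report.highlights]
        assert starts == sorted(starts)
        allowed_prefixes = (
            "readability.", "complex_language", "passive_voice",
            "person_centred", "text_structure.",
        )
        assert all(h.category.startswith(allowed_prefixes) for h in report.highlights)

    def test_exclusion_locality(self):
        """Toggling an exclusion touches only complex-language flags for the
        excluded term and the revised grade."""
        base = assess(TEXT, ALL_ON)
        excl = assess(TEXT, set_exclusions(ALL_ON, {"fissure"}))
        # unchanged: everything except complex flags and revised grade
        assert excl.readability.raw_grade == base.readability.raw_grade
        assert excl.readability.long_word_highlights == base.readability.long_word_highlights
        assert excl.style.passive_highlights == base.style.passive_highlights
        assert excl.style.person_centred_highlights == base.style.person_centred_highlights
        assert excl.style.lexical_density == base.style.lexical_density
        assert excl.style.lexical_diversity == base.style.lexical_diversity
        # changed: exactly the flags on the excluded term disappear
        removed = [
            h for h in base.style.complex_language_highlights
            if h not in excl.style.complex_language_highlights
        ]
        assert removed and all(h.text(base.text).lower() == "fissure" for h in removed)
        assert base.readability.raw_revised_grade is None
        assert excl.readability.raw_revised_grade is not None

    def test_markdown_input_stripped(self):
        report = assess("# Heading\n\n- Take your **medicine** daily.\n",
                        EditorConfig(), markdown=True)
        assert "#" not in report.text and "**" not in report.text


class TestTarget:
    @pytest.mark.parametrize(
        "grade, target, status",
        [(7.9, 8.0, "met"), (9.5, 8.0, "not_met"), (8.0, 8.0, "met")],
    )
    def test_status(self, grade, target, status):
        assert status_against_target(grade, target) == status


class TestPinAndCompare:
    def test_pin_is_immutable_snapshot(self):
        board = pin(assess(TEXT, ALL_ON))
        before = board.baseline
        assess("Fresh words here.", EditorConfig())
        assert board.baseline is before
        with pytest.raises(dataclasses.FrozenInstanceError):
            board.baseline.__class__.__setattr__(board.baseline, "text", "x")

    def test_pin_is_single_slot(self):
        board = Pinboard()
        r1 = assess(TEXT, ALL_ON)
        r2 = assess("Other words here.", ALL_ON)
        board.pin(r1)
        board.pin(r2)
        assert board.baseline is r2

    def test_self_compare_is_all_zero(self):
        r = assess(TEXT, ALL_ON)
        delta = compare(r, r)
        assert all(v == 0 for v in delta.deltas.values())
        assert set(delta.directions.values()) == {"unchanged"}

    def test_grade_improvement_direction(self):
        before = assess(
            "Everyone can benefit from a healthy diet and adequate physical activity.",
            EditorConfig(),
        )
        after = assess(
            "Everyone can benefit from a healthy diet and enough physical activity.",
            EditorConfig(),
        )
        delta = compare(before, after)
        assert delta.deltas["grade"] < 0
        assert delta.directions["grade"] == "improved"
        assert delta.directions["complex_language_count"] == "improved"

    def test_compare_restricted_to_shared_metrics(self):
        r_all = assess(TEXT, ALL_ON)
        r_read = assess(TEXT, EditorConfig(enabled_assessments=frozenset({"readability"})))
        delta = compare(r_all, r_read)
        assert set(delta.deltas) == {"grade"}

    def test_schema_mismatch_rejected(self):
        r1 = assess(TEXT, ALL_ON)
        r2 = dataclasses.replace(r1, schema_version="99")
        with pytest.raises(SchemaVersionError):
            compare(r1, r2)
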