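"""Assessment orchestration: configuration, the full report, pinned
baselines and before/after comparison.

A report is a pure function of (text, configuration, resource files):
assessing the same text twice under the same configuration yields
field-identical reports apart from the timestamp. Comparison differences
raw (unrounded) values so incremental edits register even when the
displayed one-decimal scores tie.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

from . import messages
from .errors import (
    ConfigurationError,
    EmptyDocumentError,
    SchemaVersionError,
)
from .highlight import Highlight
from .readability import (
    DEFAULT_LONG_SENTENCE_WORDS,
    DEFAULT_MAX_LIST_ITEMS,
    ReadabilityResult,
    assess_readability,
    round_display,
    validate_exclusions,
)
from .resources import load_lexicon, load_ruleset, load_abbreviations
from .style import (
    DEFAULT_PARAGRAPH_WORD_LIMIT,
    StyleResult,
    detect_passive,
    flag_complex_language,
    flag_person_centred,
    lexical_density,
    lexical_diversity,
    text_structure,
)
from .text import Document

SCHEMA_VERSION = "1"

ALL_ASSESSMENTS = frozenset(
    {
        "readability",
        "complex_language",
        "passive_voice",
        "text_structure",
        "lexical_density_diversity",
        "person_centred",
    }
)

#: Assessments enabled out of the box; the rest are opt-in to limit
#: feedback overload for new users.
DEFAULT_ASSESSMENTS = frozenset({"readability", "complex_language", "passive_voice"})

DEFAULT_TARGET_GRADE = 8.0

# Assessments that need non-empty text to produce a score.
_SCORE_BEARING = frozenset(
    {"readability", "lexical_density_diversity", "complex_language", "passive_voice"}
)


@dataclass(frozen=True)
class EditorConfig:
    """Everything an assessment run depends on besides the text itself."""

    enabled_assessments: frozenset[str] = DEFAULT_ASSESSMENTS
    exclusions: frozenset[str] = frozenset()
    target_grade: float = DEFAULT_TARGET_GRADE
    long_sentence_words: int = DEFAULT_LONG_SENTENCE_WORDS
    max_list_items: int = DEFAULT_MAX_LIST_ITEMS
    paragraph_word_limit: int = DEFAULT_PARAGRAPH_WORD_LIMIT
    lexicon_path: str | None = None
    ruleset_path: str | None = None
    abbreviations_path: str | None = None
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        enabled = frozenset(self.enabled_assessments)
        unknown = enabled - ALL_ASSESSMENTS
        if unknown:
            raise ConfigurationError(
                f"unknown assessments: {sorted(unknown)} "
                f"(choose from {sorted(ALL_ASSESSMENTS)})"
            )
        if not enabled:
            raise ConfigurationError("at least one assessment must be enabled")
        if not self.target_grade > 0:
            raise ConfigurationError("target grade must be positive")
        for name in ("long_sentence_words", "max_list_items", "paragraph_word_limit"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        object.__setattr__(self, "enabled_assessments", enabled)
        object.__setattr__(self, "exclusions", validate_exclusions(self.exclusions))

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "enabled_assessments": sorted(self.enabled_assessments),
            "exclusions": sorted(self.exclusions),
            "target_grade": self.target_grade,
            "long_sentence_words": self.long_sentence_words,
            "max_list_items": self.max_list_items,
            "paragraph_word_limit": self.paragraph_word_limit,
            "lexicon_path": self.lexicon_path,
            "ruleset_path": self.ruleset_path,
            "abbreviations_path": self.abbreviations_path,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EditorConfig":
        version = str(d.get("schema_version", SCHEMA_VERSION))
        if version != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"unsupported config schema version {version!r} "
                f"(this release reads version {SCHEMA_VERSION})"
            )
        return cls(
            enabled_assessments=frozenset(
                d.get("enabled_assessments", sorted(DEFAULT_ASSESSMENTS))
            ),
            exclusions=frozenset(d.get("exclusions", ())),
            target_grade=float(d.get("target_grade", DEFAULT_TARGET_GRADE)),
            long_sentence_words=int(
                d.get("long_sentence_words", DEFAULT_LONG_SENTENCE_WORDS)
            ),
            max_list_items=int(d.get("max_list_items", DEFAULT_MAX_LIST_ITEMS)),
            paragraph_word_limit=int(
                d.get("paragraph_word_limit", DEFAULT_PARAGRAPH_WORD_LIMIT)
            ),
            lexicon_path=d.get("lexicon_path"),
            ruleset_path=d.get("ruleset_path"),
            abbreviations_path=d.get("abbreviations_path"),
        )

    @classmethod
    def from_toml(cls, path: str | Path) -> "EditorConfig":
        """Load configuration from a TOML file mirroring every CLI flag."""
        import tomllib

        try:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigurationError(f"invalid TOML in {path}: {exc}") from exc
        return cls.from_dict(data)


def set_exclusions(config: EditorConfig, words) -> EditorConfig:
    """Return a copy of ``config`` with the given excluded words (max 5).

    Exclusions affect complex-language flags and the revised grade only.
    """
    return replace(config, exclusions=validate_exclusions(words))


def status_against_target(raw_grade: float, target_grade: float = DEFAULT_TARGET_GRADE) -> str:
    """``met`` iff the raw grade is at or below the target (inclusive)."""
    return "met" if raw_grade <= target_grade else "not_met"


@dataclass(frozen=True)
class AssessmentReport:
    """Global scores, highlights and provenance for one text + config."""

    schema_version: str
    text_fingerprint: str
    created_at: str
    config: EditorConfig
    text: str
    readability: ReadabilityResult | None
    style: StyleResult
    global_summary: dict
    highlights: tuple[Highlight, ...]
    resource_versions: dict

    def comparable_fields(self) -> dict:
        """Everything but the timestamp, for purity checks."""
        d = self.__dict__.copy()
        d.pop("created_at")
        return d


def _fingerprint(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def assess(
    text: str | bytes,
    config: EditorConfig | None = None,
    *,
    markdown: bool = False,
) -> AssessmentReport:
    """Run every enabled assessment on ``text`` under ``config``.

    Disabled assessments are absent from the report rather than
    zero-filled. Raises :class:`EmptyDocumentError` when a score-bearing
    assessment is enabled and the text has no content.
    """
    if config is None:
        config = EditorConfig()
    enabled = config.enabled_assessments

    abbreviations = (
        load_abbreviations(config.abbreviations_path)
        if config.abbreviations_path
        else None
    )
    doc = Document.from_text(text, markdown=markdown, abbreviations=abbreviations)

    if not doc.word_tokens:
        needing = sorted(enabled & _SCORE_BEARING)
        if needing:
            raise EmptyDocumentError(
                "document has no words; these assessments need content: "
                + ", ".join(needing)
            )

    resource_versions: dict[str, str] = {}
    summary: dict[str, dict] = {}
    highlights: list[Highlight] = []

    readability_result: ReadabilityResult | None = None
    if "readability" in enabled:
        readability_result = assess_readability(
            doc,
            config.exclusions,
            long_sentence_words=config.long_sentence_words,
            max_list_items=config.max_list_items,
        )
        status = status_against_target(readability_result.raw_grade, config.target_grade)
        summary["readability"] = {
            "score": readability_result.grade,
            "status": status,
            "message": messages.render(
                f"grade.{status}",
                grade=readability_result.grade,
                target=round_display(config.target_grade),
            ),
            "polysyllable_count": readability_result.polysyllable_count,
            "sentence_count": readability_result.sentence_count,
            "long_sentences": len(readability_result.long_sentence_highlights),
            "long_words": len(readability_result.long_word_highlights),
            "long_lists": len(readability_result.list_highlights),
        }
        highlights.extend(readability_result.highlights)

    complex_hl = passive_hl = person_hl = None
    density = diversity = None
    structure = None

    if "complex_language" in enabled:
        lexicon = load_lexicon(config.lexicon_path)
        resource_versions["lexicon"] = lexicon.version
        complex_hl = tuple(flag_complex_language(doc, lexicon, config.exclusions))
        summary["complex_language"] = {
            "score": len(complex_hl),
            "status": None,
            "message": messages.render("complex_language.global", count=len(complex_hl)),
        }
        highlights.extend(complex_hl)

    if "passive_voice" in enabled:
        passive_hl = tuple(detect_passive(doc))
        summary["passive_voice"] = {
            "score": len(passive_hl),
            "status": None,
            "message": messages.render("passive_voice.global", count=len(passive_hl)),
        }
        highlights.extend(passive_hl)

    if "person_centred" in enabled:
        ruleset = load_ruleset(config.ruleset_path)
        resource_versions["ruleset"] = ruleset.version
        person_hl = tuple(flag_person_centred(doc, ruleset))
        summary["person_centred"] = {
            "score": len(person_hl),
            "status": None,
            "message": f"{len(person_hl)} person-centred language suggestions.",
        }
        highlights.extend(person_hl)

    if "lexical_density_diversity" in enabled:
        density = lexical_density(doc)
        diversity = lexical_diversity(doc)
        summary["lexical_density_diversity"] = {
            "score": round(density, 3),
            "status": None,
            "message": (
                f"Lexical density {density:.2f}; lexical diversity {diversity:.2f}."
            ),
            "diversity": round(diversity, 3),
        }

    if "text_structure" in enabled:
        structure = text_structure(doc, config.paragraph_word_limit)
        summary["text_structure"] = {
            "score": structure.paragraph_count,
            "status": None,
            "message": (
                f"{structure.paragraph_count} paragraphs; "
                f"{structure.mean_words_per_paragraph:.1f} words and "
                f"{structure.mean_sentences_per_paragraph:.1f} sentences per paragraph."
            ),
        }
        highlights.extend(structure.highlights)

    return AssessmentReport(
        schema_version=SCHEMA_VERSION,
        text_fingerprint=_fingerprint(doc.text),
        created_at=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        config=config,
        text=doc.text,
        readability=readability_result,
        style=StyleResult(
            complex_language_highlights=complex_hl,
            passive_highlights=passive_hl,
            person_centred_highlights=person_hl,
            lexical_density=density,
            lexical_diversity=diversity,
            structure=structure,
        ),
        global_summary=summary,
        highlights=tuple(sorted(highlights)),
        resource_versions=resource_versions,
    )


# ---------------------------------------------------------------------------
# Pinned baseline and comparison

#: Metrics differenced by compare(); all are lower-is-better here (the
#: grade target, fewer passive/complex constructions, lighter density and
#: more repetition all ease reading).
_COMPARED_METRICS = (
    "grade",
    "passive_count",
    "complex_language_count",
    "lexical_density",
    "lexical_diversity",
)


@dataclass(frozen=True)
class ComparisonDelta:
    """Per-metric current-minus-baseline differences with direction flags."""

    baseline_fingerprint: str
    current_fingerprint: str
    deltas: dict
    directions: dict  # metric -> improved | unchanged | worsened

    def to_dict(self) -> dict:
        return {
            "baseline_fingerprint": self.baseline_fingerprint,
            "current_fingerprint": self.current_fingerprint,
            "deltas": dict(self.deltas),
            "directions": dict(self.directions),
        }


def _metric_values(report: AssessmentReport) -> dict[str, float]:
    vals: dict[str, float] = {}
    if report.readability is not None:
        vals["grade"] = report.readability.raw_grade
    s = report.style
    if s.passive_highlights is not None:
        vals["passive_count"] = len(s.passive_highlights)
    if s.complex_language_highlights is not None:
        vals["complex_language_count"] = len(s.complex_language_highlights)
    if s.lexical_density is not None:
        vals["lexical_density"] = s.lexical_density
    if s.lexical_diversity is not None:
        vals["lexical_diversity"] = s.lexical_diversity
    return vals


def compare(baseline: AssessmentReport, current: AssessmentReport) -> ComparisonDelta:
    """Difference raw metric values: delta = current - baseline, exactly.

    Only metrics present in both reports are compared. A negative grade
    delta means the text improved.
    """
    if baseline.schema_version != current.schema_version:
        raise SchemaVersionError(
            f"cannot compare reports with schema versions "
            f"{baseline.schema_version!r} and {current.schema_version!r}"
        )
    base_vals = _metric_values(baseline)
    cur_vals = _metric_values(current)
    deltas: dict[str, float] = {}
    directions: dict[str, str] = {}
    for metric in _COMPARED_METRICS:
        if metric in base_vals and metric in cur_vals:
            delta = cur_vals[metric] - base_vals[metric]
            deltas[metric] = delta
            directions[metric] = (
                "unchanged" if delta == 0 else ("improved" if delta < 0 else "worsened")
            )
    return ComparisonDelta(
        baseline_fingerprint=baseline.text_fingerprint,
        current_fingerprint=current.text_fingerprint,
        deltas=deltas,
        directions=directions,
    )


class Pinboard:
    """Single-slot holder for a pinned baseline report.

    Pinning again replaces the previous baseline; the stored report is an
    immutable snapshot, so later edits never mutate it.
    """

    def __init__(self) -> None:
        self._baseline: AssessmentReport | None = None

    @property
    def baseline(self) -> AssessmentReport | None:
        return self._baseline

    def pin(self, report: AssessmentReport) -> AssessmentReport:
        self._baseline = report
        return report

    def unpin(self) -> None:
        self._baseline = None

    def compare(self, current: AssessmentReport) -> ComparisonDelta:
        if self._baseline is None:
            raise ConfigurationError("no baseline pinned")
        return compare(self._baseline, current)


def pin(report: AssessmentReport) -> Pinboard:
    """Convenience: a new single-slot pinboard holding ``report``."""
    board = Pinboard()
    board.pin(report)
    return board
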