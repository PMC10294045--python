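"""Report serialization and the printable summary.

The structured format is schema-versioned JSON with a lossless round
trip: ``read_report(write_report(r))`` equals ``r`` field for field. The
printable summary is a plain-text or Markdown document of global scores
only — no highlight spans — matching its record-keeping purpose; it is
the one place the exclusion-adjusted "revised" grade appears.
"""

from __future__ import annotations

import json
from pathlib import Path

from .engine import (
    SCHEMA_VERSION,
    AssessmentReport,
    ComparisonDelta,
    EditorConfig,
)
from .errors import ReportFormatError, SchemaVersionError
from .highlight import Highlight
from .readability import ReadabilityResult, round_display
from .style import StructureMetrics, StyleResult


# ---------------------------------------------------------------------------
# JSON (de)serialization

def _readability_to_dict(r: ReadabilityResult | None) -> dict | None:
    if r is None:
        return None
    return {
        "raw_grade": r.raw_grade,
        "grade": r.grade,
        "polysyllable_count": r.polysyllable_count,
        "sentence_count": r.sentence_count,
        "long_word_highlights": [h.to_dict() for h in r.long_word_highlights],
        "long_sentence_highlights": [h.to_dict() for h in r.long_sentence_highlights],
        "list_highlights": [h.to_dict() for h in r.list_highlights],
        "raw_revised_grade": r.raw_revised_grade,
        "revised_grade": r.revised_grade,
        "revised_polysyllable_count": r.revised_polysyllable_count,
    }


def _readability_from_dict(d: dict | None) -> ReadabilityResult | None:
    if d is None:
        return None
    return ReadabilityResult(
        raw_grade=d["raw_grade"],
        polysyllable_count=d["polysyllable_count"],
        sentence_count=d["sentence_count"],
        long_word_highlights=tuple(
            Highlight.from_dict(h) for h in d["long_word_highlights"]
        ),
        long_sentence_highlights=tuple(
            Highlight.from_dict(h) for h in d["long_sentence_highlights"]
        ),
        list_highlights=tuple(Highlight.from_dict(h) for h in d["list_highlights"]),
        raw_revised_grade=d.get("raw_revised_grade"),
        revised_polysyllable_count=d.get("revised_polysyllable_count"),
    )


def _maybe_highlights(value) -> tuple[Highlight, ...] | None:
    if value is None:
        return None
    return tuple(Highlight.from_dict(h) for h in value)


def _style_to_dict(s: StyleResult) -> dict:
    def dump(hl):
        return None if hl is None else [h.to_dict() for h in hl]

    structure = None
    if s.structure is not None:
        structure = {
            "paragraph_count": s.structure.paragraph_count,
            "mean_words_per_paragraph": s.structure.mean_words_per_paragraph,
            "mean_sentences_per_paragraph": s.structure.mean_sentences_per_paragraph,
            "highlights": [h.to_dict() for h in s.structure.highlights],
        }
    return {
        "complex_language_highlights": dump(s.complex_language_highlights),
        "passive_highlights": dump(s.passive_highlights),
        "person_centred_highlights": dump(s.person_centred_highlights),
        "lexical_density": s.lexical_density,
        "lexical_diversity": s.lexical_diversity,
        "structure": structure,
    }


def _style_from_dict(d: dict) -> StyleResult:
    structure = None
    if d.get("structure") is not None:
        sd = d["structure"]
        structure = StructureMetrics(
            paragraph_count=sd["paragraph_count"],
            mean_words_per_paragraph=sd["mean_words_per_paragraph"],
            mean_sentences_per_paragraph=sd["mean_sentences_per_paragraph"],
            highlights=tuple(Highlight.from_dict(h) for h in sd["highlights"]),
        )
    return StyleResult(
        complex_language_highlights=_maybe_highlights(d["complex_language_highlights"]),
        passive_highlights=_maybe_highlights(d["passive_highlights"]),
        person_centred_highlights=_maybe_highlights(d["person_centred_highlights"]),
        lexical_density=d["lexical_density"],
        lexical_diversity=d["lexical_diversity"],
        structure=structure,
    )


def report_to_dict(report: AssessmentReport) -> dict:
    return {
        "schema_version": report.schema_version,
        "text_fingerprint": report.text_fingerprint,
        "created_at": report.created_at,
        "config": report.config.to_dict(),
        "text": report.text,
        "readability": _readability_to_dict(report.readability),
        "style": _style_to_dict(report.style),
        "global_summary": report.global_summary,
        "highlights": [h.to_dict() for h in report.highlights],
        "resource_versions": report.resource_versions,
    }


def report_from_dict(d: dict) -> AssessmentReport:
    version = str(d.get("schema_version", ""))
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"unsupported report schema version {version!r} "
            f"(this release reads version {SCHEMA_VERSION})"
        )
    try:
        return AssessmentReport(
            schema_version=version,
            text_fingerprint=d["text_fingerprint"],
            created_at=d["created_at"],
            config=EditorConfig.from_dict(d["config"]),
            text=d["text"],
            readability=_readability_from_dict(d["readability"]),
            style=_style_from_dict(d["style"]),
            global_summary=d["global_summary"],
            highlights=tuple(Highlight.from_dict(h) for h in d["highlights"]),
            resource_versions=d["resource_versions"],
        )
    except (KeyError, TypeError) as exc:
        raise ReportFormatError(f"malformed report: missing or bad field ({exc})")


def write_report(report: AssessmentReport, path: str | Path) -> None:
    """Serialize a report to schema-versioned JSON."""
    Path(path).write_text(
        json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_report(path: str | Path) -> AssessmentReport:
    """Read a JSON report; raises with the path on malformed files."""
    path = Path(path)
    try:
        data = json.loads(path.read_text("utf-8"))
    except FileNotFoundError:
        raise ReportFormatError("report file not found", str(path))
    except json.JSONDecodeError as exc:
        raise ReportFormatError(
            f"invalid JSON at line {exc.lineno}: {exc.msg}", str(path)
        )
    if not isinstance(data, dict):
        raise ReportFormatError("report must be a JSON object", str(path))
    try:
        return report_from_dict(data)
    except SchemaVersionError:
        raise
    except ReportFormatError as exc:
        raise ReportFormatError(str(exc), str(path))


# ---------------------------------------------------------------------------
# Printable summary

_ASSESSMENT_TITLES = {
    "readability": "Readability (grade reading score)",
    "complex_language": "Complex language",
    "passive_voice": "Passive voice",
    "person_centred": "Person-centred language",
    "lexical_density_diversity": "Lexical density and diversity",
    "text_structure": "Text structure",
}

_METRIC_TITLES = {
    "grade": "Grade reading score",
    "passive_count": "Passive voice instances",
    "complex_language_count": "Complex language instances",
    "lexical_density": "Lexical density",
    "lexical_diversity": "Lexical diversity",
}


def _fmt_delta(metric: str, delta: float) -> str:
    if metric == "grade":
        return f"{delta:+.1f}"
    if metric in ("lexical_density", "lexical_diversity"):
        return f"{delta:+.3f}"
    return f"{delta:+d}" if float(delta).is_integer() else f"{delta:+.2f}"


def render_summary(
    report: AssessmentReport,
    comparison: ComparisonDelta | None = None,
    *,
    title: str = "Assessment summary",
    fmt: str = "text",
) -> str:
    """Render the printable summary (``fmt``: ``text`` or ``markdown``).

    Global scores only; the revised grade appears here — and only here —
    when excluded words are active.
    """
    if fmt not in ("text", "markdown"):
        raise ValueError(f"unknown summary format {fmt!r}")
    md = fmt == "markdown"
    lines: list[str] = []

    def heading(text: str) -> None:
        if md:
            lines.append(f"## {text}")
        else:
            lines.append(text)
            lines.append("-" * len(text))

    if md:
        lines.append(f"# {title}")
    else:
        lines.append(title)
        lines.append("=" * len(title))
    lines.append("")
    lines.append(f"Document fingerprint: {report.text_fingerprint[:12]}")
    lines.append("")

    for name in sorted(report.global_summary):
        info = report.global_summary[name]
        heading(_ASSESSMENT_TITLES.get(name, name))
        score = info["score"]
        status = info.get("status")
        if name == "readability":
            lines.append(f"Score: {score:.1f} (target: grade "
                         f"{round_display(report.config.target_grade):.1f}, "
                         f"{'met' if status == 'met' else 'not met'})")
        else:
            lines.append(f"Score: {score}")
        lines.append(info["message"])
        lines.append("")

    exclusions = sorted(report.config.exclusions)
    if exclusions and report.readability is not None:
        heading("Excluded words")
        lines.append("Excluded from complex language counts: " + ", ".join(exclusions))
        revised = report.readability.revised_grade
        if revised is not None:
            lines.append(
                f"Revised grade reading score without these words: {revised:.1f} "
                f"(headline score: {report.readability.grade:.1f})"
            )
            lines.append(
                "Note: excluding words from grade reading scores is not standard "
                "practice; the headline score above counts every word."
            )
        lines.append("")

    if comparison is not None:
        heading("Comparison with pinned baseline")
        for metric, delta in comparison.deltas.items():
            lines.append(
                f"{_METRIC_TITLES.get(metric, metric)}: "
                f"{_fmt_delta(metric, delta)} ({comparison.directions[metric]})"
            )
        lines.append("")

    if report.resource_versions:
        heading("Resources")
        for key in sorted(report.resource_versions):
            lines.append(f"{key} version: {report.resource_versions[key]}")
        lines.append("")

    return "\n".join(lines).rstrip() + "\n"
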