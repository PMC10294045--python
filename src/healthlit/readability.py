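"""SMOG readability: grade reading score, long-word / long-sentence /
long-list highlights, and the exclusion-adjusted "revised" grade.

The grade is the all-sentence SMOG generalization

    grade = 1.043 * sqrt(P * 30 / S) + 3.1291

where ``P`` counts polysyllabic word tokens (three or more syllables;
acronyms excluded) and ``S`` counts sentences. The 30-sentence
normalization makes the score well-defined for texts of any length. The
headline grade always counts every word; excluded words reduce ``P``
only in the *revised* variant, which by design is shown only in the
printable summary (excluding words from a grade score is not standard
practice).

Raw (unrounded) values are kept for comparisons; display values are
rounded half-up to one decimal place so small edits visibly move the
score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from . import messages
from .errors import EmptyDocumentError, ExclusionLimitError
from .highlight import Highlight
from .text import Document, Span, Token

SMOG_COEFFICIENT = 1.043
SMOG_SENTENCE_NORM = 30
SMOG_INTERCEPT = 3.1291

POLYSYLLABLE_MIN = 3
DEFAULT_LONG_SENTENCE_WORDS = 15
DEFAULT_MAX_LIST_ITEMS = 4
MAX_EXCLUSIONS = 5

_COORDINATORS = frozenset({"and", "or"})


def round_display(value: float, ndigits: int = 1) -> float:
    """Round half-up (so 8.25 -> 8.3), as displayed scores are."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def is_polysyllabic(token: Token) -> bool:
    """Word of >= 3 syllables; acronyms have no stable syllable reading."""
    return token.is_word and not token.is_acronym and token.syllables >= POLYSYLLABLE_MIN


def polysyllable_count(doc: Document, exclusions: frozenset[str] = frozenset()) -> int:
    return sum(
        1
        for t in doc.tokens
        if is_polysyllabic(t) and t.surface.lower() not in exclusions
    )


def smog_raw(polysyllables: int, sentences: int) -> float:
    """Closed-form SMOG from counts. Raises on an empty document."""
    if sentences <= 0:
        raise EmptyDocumentError("SMOG needs at least one sentence")
    if polysyllables < 0:
        raise ValueError("polysyllable count cannot be negative")
    return (
        SMOG_COEFFICIENT
        * math.sqrt(polysyllables * SMOG_SENTENCE_NORM / sentences)
        + SMOG_INTERCEPT
    )


def smog_grade(doc: Document) -> float:
    """Headline raw grade; counts all words, never applies exclusions."""
    return smog_raw(polysyllable_count(doc), len(doc.sentences))


def validate_exclusions(exclusions) -> frozenset[str]:
    words = frozenset(w.strip().lower() for w in exclusions if w and w.strip())
    if len(words) > MAX_EXCLUSIONS:
        raise ExclusionLimitError(
            f"at most {MAX_EXCLUSIONS} words may be excluded, got {len(words)}"
        )
    if any(" " in w for w in words):
        raise ExclusionLimitError("excluded entries must be single words")
    return words


def revised_smog_grade(doc: Document, exclusions) -> float:
    """Raw grade with excluded words removed from the polysyllable count.

    Case-insensitive token match; the sentence count is unchanged, so the
    revised grade can never exceed the headline grade.
    """
    words = validate_exclusions(exclusions)
    return smog_raw(polysyllable_count(doc, words), len(doc.sentences))


def flag_long_words(doc: Document) -> list[Highlight]:
    """One highlight per polysyllabic word (exclusions do not hide these)."""
    return [
        Highlight(
            t.start,
            t.end,
            "readability.long_word",
            messages.render(
                "readability.long_word", word=t.surface, syllables=t.syllables
            ),
        )
        for t in doc.tokens
        if is_polysyllabic(t)
    ]


def flag_long_sentences(
    doc: Document, word_threshold: int = DEFAULT_LONG_SENTENCE_WORDS
) -> list[Highlight]:
    out = []
    for span in doc.sentences:
        n = doc.sentence_word_count(span)
        if n > word_threshold:
            out.append(
                Highlight(
                    span[0],
                    span[1],
                    "readability.long_sentence",
                    messages.render("readability.long_sentence", words=n),
                )
            )
    return out


def _list_item_count(doc: Document, span: Span) -> int:
    """Comma-separated segments plus a final and/or segment.

    A sentence with no comma is never a list. When the text after the
    last comma contains a coordinator ("and"/"or") beyond its first word,
    that segment holds two items; a leading coordinator (Oxford comma)
    introduces a single item.
    """
    tokens = doc.tokens_in(span)
    comma_positions = [i for i, t in enumerate(tokens) if t.kind == "punct" and t.surface == ","]
    if not comma_positions:
        return 0
    items = len(comma_positions) + 1
    tail_words = [
        t.surface.lower()
        for t in tokens[comma_positions[-1] + 1 :]
        if t.counts_as_word
    ]
    if len(tail_words) > 1 and any(w in _COORDINATORS for w in tail_words[1:]):
        items += 1
    return items


def flag_long_lists(
    doc: Document, max_items: int = DEFAULT_MAX_LIST_ITEMS
) -> list[Highlight]:
    """Flag sentences listing more than ``max_items`` things in running text."""
    out = []
    for span in doc.sentences:
        items = _list_item_count(doc, span)
        if items > max_items:
            out.append(
                Highlight(
                    span[0],
                    span[1],
                    "readability.long_list",
                    messages.render(
                        "readability.long_list", items=items, max_items=max_items
                    ),
                )
            )
    return out


@dataclass(frozen=True)
class ReadabilityResult:
    """Grade reading score plus the in-text readability highlights.

    ``grade`` / ``revised_grade`` are display values (1 decimal place,
    half-up); the ``raw_*`` counterparts back comparisons.
    """

    raw_grade: float
    polysyllable_count: int
    sentence_count: int
    long_word_highlights: tuple[Highlight, ...] = ()
    long_sentence_highlights: tuple[Highlight, ...] = ()
    list_highlights: tuple[Highlight, ...] = ()
    raw_revised_grade: float | None = None
    revised_polysyllable_count: int | None = None

    @property
    def grade(self) -> float:
        return round_display(self.raw_grade)

    @property
    def revised_grade(self) -> float | None:
        if self.raw_revised_grade is None:
            return None
        return round_display(self.raw_revised_grade)

    @property
    def highlights(self) -> tuple[Highlight, ...]:
        return tuple(
            sorted(
                self.long_word_highlights
                + self.long_sentence_highlights
                + self.list_highlights
            )
        )


def assess_readability(
    doc: Document,
    exclusions=frozenset(),
    *,
    long_sentence_words: int = DEFAULT_LONG_SENTENCE_WORDS,
    max_list_items: int = DEFAULT_MAX_LIST_ITEMS,
) -> ReadabilityResult:
    """Run the full readability assessment on an annotated document."""
    words = validate_exclusions(exclusions)
    p = polysyllable_count(doc)
    s = len(doc.sentences)
    raw = smog_raw(p, s)
    revised_raw = None
    revised_p = None
    if words:
        revised_p = polysyllable_count(doc, words)
        revised_raw = smog_raw(revised_p, s)
    return ReadabilityResult(
        raw_grade=raw,
        polysyllable_count=p,
        sentence_count=s,
        long_word_highlights=tuple(flag_long_words(doc)),
        long_sentence_highlights=tuple(flag_long_sentences(doc, long_sentence_words)),
        list_highlights=tuple(flag_long_lists(doc, max_list_items)),
        raw_revised_grade=revised_raw,
        revised_polysyllable_count=revised_p,
    )
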