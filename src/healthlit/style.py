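"""Style assessments: complex language, passive voice, person-centred
language, lexical density/diversity, and text structure.

All detectors are rule-based and deterministic. Passive voice is a
heuristic (a be/get auxiliary followed within three word tokens by a past
participle) with no parser behind it; adjectival participles ("was
tired") will false-positive — a documented trade-off of a real-time
rule-based tool. Lexical diversity is a moving-average type-token ratio
(window 50) falling back to a plain type-token ratio for short texts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from . import messages
from ._wordlists import BE_FORMS, GET_FORMS
from .errors import EmptyDocumentError
from .highlight import Highlight
from .resources import Lexicon, LexiconEntry, Ruleset
from .text import Document, Token

MATTR_WINDOW = 50
DEFAULT_PARAGRAPH_WORD_LIMIT = 100
PASSIVE_PARTICIPLE_WINDOW = 3

CONTENT_TAGS = frozenset({"noun", "verb", "adjective", "adverb", "participle"})


# ---------------------------------------------------------------------------
# Complex language

def _lemma_candidates(word: str):
    """Case-folded surface first, then crude inflectional strips.

    Keeps "adequately" in the "adequate" family without a real lemmatizer.
    """
    w = word.lower()
    yield w
    if w.endswith("ies") and len(w) > 4:
        yield w[:-3] + "y"
    if w.endswith("es") and len(w) > 3:
        yield w[:-2]
        yield w[:-1]
    elif w.endswith("s") and len(w) > 3 and not w.endswith("ss"):
        yield w[:-1]
    if w.endswith("ed") and len(w) > 4:
        yield w[:-2]
        yield w[:-1]
    if w.endswith("ing") and len(w) > 5:
        yield w[:-3]
        yield w[:-3] + "e"
    if w.endswith("ly") and len(w) > 4:
        yield w[:-2]


def _match_entry(surface: str, lexicon: Lexicon) -> LexiconEntry | None:
    for cand in _lemma_candidates(surface):
        entry = lexicon.get(cand)
        if entry is not None:
            return entry
    return None


def _complex_message(entry: LexiconEntry, surface: str) -> str:
    if entry.alternatives:
        return messages.render(
            "complex_language.with_alternatives",
            term=surface,
            alternatives=", ".join(entry.alternatives),
        )
    return messages.render("complex_language.no_alternatives", term=surface)


def flag_complex_language(
    doc: Document, lexicon: Lexicon, exclusions=frozenset()
) -> list[Highlight]:
    """One highlight per lexicon match, leftmost-longest, minus exclusions.

    Multiword terms ("myocardial infarction") are matched over word-token
    n-grams before single words. A match is suppressed when either the
    matched surface word or the lexicon term is excluded.
    """
    exclusions = frozenset(w.lower() for w in exclusions)
    words = [t for t in doc.tokens if t.is_word]
    out: list[Highlight] = []
    i = 0
    max_n = max(1, lexicon.max_term_words)
    while i < len(words):
        matched = False
        for n in range(min(max_n, len(words) - i), 0, -1):
            group = words[i : i + n]
            if n > 1:
                phrase = " ".join(t.surface.lower() for t in group)
                entry = lexicon.get(phrase)
            else:
                entry = _match_entry(group[0].surface, lexicon)
            if entry is None:
                continue
            surfaces = {t.surface.lower() for t in group} | {entry.term}
            if not (surfaces & exclusions):
                span_text = doc.text[group[0].start : group[-1].end]
                out.append(
                    Highlight(
                        group[0].start,
                        group[-1].end,
                        "complex_language",
                        _complex_message(entry, span_text),
                        alternatives=entry.alternatives,
                    )
                )
            i += n
            matched = True
            break
        if not matched:
            i += 1
    return out


def suggest_alternatives(term: str, lexicon: Lexicon) -> tuple[str, ...]:
    """Plain-language alternatives for a term; empty when none are known.

    Display-only: the package never rewrites the user's text.
    """
    entry = lexicon.get(term)
    return entry.alternatives if entry is not None else ()


# ---------------------------------------------------------------------------
# Passive voice

def detect_passive(doc: Document) -> list[Highlight]:
    """Flag be/get auxiliary + past participle pairs, one per construction.

    The participle must follow the auxiliary within three word tokens of
    the same sentence ("was taken", "may be quickly changed"). Each
    matched participle is consumed, so chained auxiliaries ("was being
    tested") yield one highlight.
    """
    out: list[Highlight] = []
    for span in doc.sentences:
        words = [t for t in doc.tokens_in(span) if t.is_word]
        i = 0
        while i < len(words):
            tok = words[i]
            low = tok.surface.lower()
            if tok.coarse_tag == "aux" and (low in BE_FORMS or low in GET_FORMS):
                for j in range(i + 1, min(i + 1 + PASSIVE_PARTICIPLE_WINDOW, len(words))):
                    if words[j].coarse_tag == "participle":
                        phrase = doc.text[tok.start : words[j].end]
                        out.append(
                            Highlight(
                                tok.start,
                                words[j].end,
                                "passive_voice",
                                messages.render("passive_voice", phrase=phrase),
                            )
                        )
                        i = j
                        break
                    if words[j].coarse_tag not in ("aux", "adverb", "other"):
                        break  # a content word interrupts the verb group
            i += 1
    return out


# ---------------------------------------------------------------------------
# Person-centred language

def _rule_regex(pattern: str) -> re.Pattern:
    escaped = re.escape(pattern).replace(r"\ ", r"\s+")
    return re.compile(rf"\b{escaped}\b", re.IGNORECASE)


def flag_person_centred(doc: Document, ruleset: Ruleset) -> list[Highlight]:
    """Word-boundary, case-insensitive rule matches with preferred phrasing.

    Longer patterns win where they overlap shorter ones.
    """
    out: list[Highlight] = []
    taken: list[tuple[int, int]] = []
    for rule in sorted(ruleset.rules, key=lambda r: -len(r.pattern)):
        for m in _rule_regex(rule.pattern).finditer(doc.text):
            if any(m.start() < e and s < m.end() for s, e in taken):
                continue
            taken.append((m.start(), m.end()))
            out.append(
                Highlight(
                    m.start(),
                    m.end(),
                    "person_centred",
                    messages.render(
                        "person_centred",
                        preferred=rule.preferred,
                        rationale=rule.rationale,
                    ).strip(),
                    alternatives=(rule.preferred,),
                )
            )
    return sorted(out)


# ---------------------------------------------------------------------------
# Lexical density and diversity

def lexical_density(doc: Document) -> float:
    """Content words (nouns, non-auxiliary verbs, participles, adjectives,
    adverbs) as a fraction of all word tokens."""
    words = doc.word_tokens
    if not words:
        raise EmptyDocumentError("lexical density needs at least one word")
    content = sum(1 for t in words if t.coarse_tag in CONTENT_TAGS)
    return content / len(words)


def lexical_diversity(doc: Document, window: int = MATTR_WINDOW) -> float:
    """Moving-average type-token ratio over lowercased word tokens.

    Texts shorter than the window fall back to the plain type-token
    ratio, so tiny documents still get a well-defined score in (0, 1].
    """
    words = [t.surface.lower() for t in doc.word_tokens]
    if not words:
        raise EmptyDocumentError("lexical diversity needs at least one word")
    if len(words) < window:
        return len(set(words)) / len(words)
    total = 0.0
    n_windows = len(words) - window + 1
    counts: dict[str, int] = {}
    types = 0
    for w in words[:window]:
        counts[w] = counts.get(w, 0) + 1
    types = len(counts)
    total += types
    for i in range(1, n_windows):
        out_w, in_w = words[i - 1], words[i + window - 1]
        counts[out_w] -= 1
        if counts[out_w] == 0:
            del counts[out_w]
        counts[in_w] = counts.get(in_w, 0) + 1
        total += len(counts)
    return total / (n_windows * window)


# ---------------------------------------------------------------------------
# Text structure

@dataclass(frozen=True)
class StructureMetrics:
    paragraph_count: int
    mean_words_per_paragraph: float
    mean_sentences_per_paragraph: float
    highlights: tuple[Highlight, ...] = ()


def text_structure(
    doc: Document, paragraph_word_limit: int = DEFAULT_PARAGRAPH_WORD_LIMIT
) -> StructureMetrics:
    """Paragraph-level shape: counts, means, and over-long-paragraph flags."""
    paragraphs = doc.paragraphs
    if not paragraphs:
        return StructureMetrics(0, 0.0, 0.0, ())
    word_counts = []
    sentence_counts = []
    highlights = []
    for span in paragraphs:
        n_words = sum(1 for t in doc.tokens_in(span) if t.counts_as_word)
        n_sents = sum(1 for s in doc.sentences if s[0] >= span[0] and s[1] <= span[1])
        word_counts.append(n_words)
        sentence_counts.append(n_sents)
        if n_words > paragraph_word_limit:
            highlights.append(
                Highlight(
                    span[0],
                    span[1],
                    "text_structure.long_paragraph",
                    messages.render(
                        "text_structure.long_paragraph",
                        words=n_words,
                        limit=paragraph_word_limit,
                    ),
                )
            )
    n = len(paragraphs)
    return StructureMetrics(
        paragraph_count=n,
        mean_words_per_paragraph=sum(word_counts) / n,
        mean_sentences_per_paragraph=sum(sentence_counts) / n,
        highlights=tuple(highlights),
    )


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StyleResult:
    """Bundle of all style assessments actually run (None = not enabled)."""

    complex_language_highlights: tuple[Highlight, ...] | None = None
    passive_highlights: tuple[Highlight, ...] | None = None
    person_centred_highlights: tuple[Highlight, ...] | None = None
    lexical_density: float | None = None
    lexical_diversity: float | None = None
    structure: StructureMetrics | None = None
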