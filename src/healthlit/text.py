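"""Deterministic text model: normalization, tokenization, segmentation,
syllable counting and coarse grammatical tagging.

All downstream assessments consume the :class:`Document` produced here.
The pipeline is fully rule-based and deterministic: identical input bytes
always yield an identical document. Character offsets are 0-based,
half-open, and refer to the *normalized* text.

Syllable counts come from a shipped pronunciation table when the word is
listed there, and otherwise from a documented vowel-group fallback with
silent-e suppression and ``-le`` restoration; hyphenated compounds are
counted part by part. Medical vocabulary that the fallback mis-counts
(e.g. "diabetes", "cardiovascular") is covered by the table.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from functools import lru_cache

from . import _wordlists as wl
from .errors import HealthLitError, InputEncodingError
from .resources import default_abbreviations, default_syllable_table

Span = tuple[int, int]

# ---------------------------------------------------------------------------
# Normalization

_CHAR_MAP = str.maketrans(
    {
        "‘": "'",
        "’": "'",
        "‚": "'",
        "‛": "'",
        "“": '"',
        "”": '"',
        "„": '"',
        "–": "-",
        "—": "-",
        "‒": "-",
        "−": "-",
        " ": " ",
        "…": "...",
    }
)


def normalize_text(raw: str | bytes) -> str:
    """Normalize raw input: UTF-8 decode, NFC, LF line endings, ASCII quotes.

    Raises
    ------
    InputEncodingError
        If ``raw`` is a byte string that is not valid UTF-8.
    """
    if isinstance(raw, bytes):
        try:
            raw = raw.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise InputEncodingError(f"input is not valid UTF-8: {exc}") from exc
    text = unicodedata.normalize("NFC", raw)
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    return text.translate(_CHAR_MAP)


_MD_HEADING = re.compile(r"^(#{1,6})\s+", re.MULTILINE)
_MD_BULLET = re.compile(r"^(\s*)[-*+]\s+", re.MULTILINE)
_MD_EMPH = re.compile(r"(\*\*|__|\*|_)(\S(?:.*?\S)?)\1")
_MD_LINK = re.compile(r"\[([^\]]+)\]\([^)]*\)")
_MD_CODE = re.compile(r"`([^`]*)`")


def strip_markdown(text: str) -> str:
    """Strip light Markdown markup, keeping headings/bullets as plain lines."""
    text = _MD_HEADING.sub("", text)
    text = _MD_BULLET.sub(r"\1", text)
    text = _MD_LINK.sub(r"\1", text)
    text = _MD_CODE.sub(r"\1", text)
    while _MD_EMPH.search(text):
        text = _MD_EMPH.sub(r"\2", text)
    return text


# ---------------------------------------------------------------------------
# Tokenization

_TOKEN_RE = re.compile(
    r"""
    (?P<word>[A-Za-z]+(?:'[A-Za-z]+)*(?:-[A-Za-z0-9]+(?:'[A-Za-z]+)*)*)
  | (?P<num>\d+(?:[.,]\d+)*)
  | (?P<punct>[^\sA-Za-z0-9])
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class Token:
    """One token of the document.

    ``kind`` is ``word`` (alphabetic core, possibly hyphenated or with an
    apostrophe), ``numeral`` or ``punct``. Syllables are 0 for non-words.
    """

    surface: str
    start: int
    end: int
    kind: str  # word | numeral | punct
    syllables: int = 0
    coarse_tag: str = "other"  # noun verb aux participle adjective adverb other

    @property
    def span(self) -> Span:
        return (self.start, self.end)

    @property
    def is_word(self) -> bool:
        return self.kind == "word"

    @property
    def counts_as_word(self) -> bool:
        """Words and numerals both count toward sentence length."""
        return self.kind in ("word", "numeral")

    @property
    def is_acronym(self) -> bool:
        """All-caps alphabetic token of 2-5 characters (e.g. "CVD").

        Acronyms count as words for sentence length but are excluded from
        syllable-based long-word and polysyllable counts, because a letter
        string like "CVD" has no stable syllable reading.
        """
        s = self.surface
        return self.kind == "word" and 2 <= len(s) <= 5 and s.isalpha() and s.isupper()


def tokenize(text: str) -> list[Token]:
    """Split normalized text into word / numeral / punctuation tokens.

    Hyphenated compounds ("X-rays") and apostrophe contractions ("don't")
    stay single tokens; parenthesised acronyms yield separate bracket and
    word tokens.
    """
    tokens: list[Token] = []
    for m in _TOKEN_RE.finditer(text):
        kind = "word" if m.lastgroup == "word" else (
            "numeral" if m.lastgroup == "num" else "punct"
        )
        tokens.append(Token(m.group(), m.start(), m.end(), kind))
    return tokens


# ---------------------------------------------------------------------------
# Syllable counting

_SIBILANT_BEFORE_ES = frozenset("scxzgl")
_VOWELS = frozenset("aeiou")


def _vowel_groups(w: str) -> int:
    count = 0
    prev_vowel = False
    for i, ch in enumerate(w):
        is_vowel = ch in _VOWELS or (ch == "y" and i > 0 and w[i - 1] not in _VOWELS)
        if is_vowel and not prev_vowel:
            count += 1
        prev_vowel = is_vowel
    return count


def _fallback_syllables(word: str) -> int:
    w = "".join(ch for ch in word.lower() if ch.isalpha())
    if not w:
        return 1
    # consonant + "le(s)": the final -le is syllabic ("table", "people")
    if len(w) > 2 and w.endswith("le") and w[-3] not in _VOWELS:
        return max(1, _vowel_groups(w[:-2]) + 1)
    if len(w) > 3 and w.endswith("les") and w[-4] not in _VOWELS:
        return max(1, _vowel_groups(w[:-3]) + 1)
    if w.endswith("e") and len(w) > 2:
        w = w[:-1]  # silent e: "disease", "choice"
    elif w.endswith("es") and len(w) > 3 and w[-3] not in _SIBILANT_BEFORE_ES:
        w = w[:-2]  # "makes"; but "choices", "houses" keep the syllabic -es
    elif w.endswith("ed") and len(w) > 3 and w[-3] not in "td":
        w = w[:-2]  # "walked"; "wanted"/"needed" keep -ed
    return max(1, _vowel_groups(w))


@lru_cache(maxsize=None)
def count_syllables(word: str) -> int:
    """Syllable count for a word token surface (case-insensitive, >= 1).

    Dictionary lookup first; deterministic vowel-group fallback otherwise.
    Hyphenated compounds are the sum of their parts.
    """
    if not word or not any(ch.isalpha() for ch in word):
        raise HealthLitError(f"count_syllables expects a word, got {word!r}")
    key = word.lower()
    table = default_syllable_table()
    if key in table:
        return table[key]
    if "-" in key:
        parts = [p for p in key.split("-") if p]
        return sum(
            table.get(p, _fallback_syllables(p)) if any(c.isalpha() for c in p) else 1
            for p in parts
        )
    return _fallback_syllables(key)


# ---------------------------------------------------------------------------
# Sentence and paragraph segmentation

_BLANK_LINE = re.compile(r"\n[ \t]*\n")
_TERMINAL = frozenset(".!?")
_CLOSERS = frozenset("\"')]")


def segment_paragraphs(text: str) -> list[Span]:
    """Maximal runs of non-blank lines, as character spans."""
    spans: list[Span] = []
    pos = 0
    for m in _BLANK_LINE.finditer(text):
        if text[pos : m.start()].strip():
            spans.append(_trim(text, pos, m.start()))
        pos = m.end()
    if text[pos:].strip():
        spans.append(_trim(text, pos, len(text)))
    return spans


def _trim(text: str, start: int, end: int) -> Span:
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    return (start, end)


def segment_sentences(
    text: str,
    tokens: list[Token],
    abbreviations: frozenset[str] | None = None,
) -> list[Span]:
    """Sentence spans over the token stream.

    A sentence closes at terminal punctuation (``.!?``) followed by
    whitespace and a capital/digit/quote (or end of text), unless the
    period belongs to a known abbreviation ("Dr.", "e.g.") or a single
    initial. A line break also closes a sentence, so headings and bullet
    items without terminal punctuation form their own sentences.
    """
    if abbreviations is None:
        abbreviations = default_abbreviations()
    sentences: list[Span] = []
    current: list[Token] = []

    def close() -> None:
        if current and any(t.counts_as_word for t in current):
            sentences.append((current[0].start, current[-1].end))
        current.clear()

    i = 0
    n = len(tokens)
    while i < n:
        tok = tokens[i]
        if current and "\n" in text[current[-1].end : tok.start]:
            close()
        current.append(tok)
        if (
            tok.kind == "punct"
            and tok.surface in _TERMINAL
            and not (
                tok.surface == "." and _is_abbreviation_period(tokens, i, abbreviations)
            )
        ):
            # absorb trailing closers (quotes, brackets) into this sentence
            j = i + 1
            while (
                j < n
                and tokens[j].kind == "punct"
                and tokens[j].surface in _CLOSERS
                and tokens[j].start == tokens[j - 1].end
            ):
                current.append(tokens[j])
                j += 1
            nxt = tokens[j] if j < n else None
            if nxt is None or _starts_sentence(nxt):
                close()
                i = j
                continue
            if j > i + 1:  # boundary rejected: hand the absorbed closers back
                del current[-(j - i - 1) :]
        i += 1
    close()
    return sentences


def _starts_sentence(tok: Token) -> bool:
    s = tok.surface
    if tok.kind == "numeral":
        return True
    if tok.kind == "punct":
        return s in "\"'([" or s == "-"
    return s[0].isupper()


def _is_abbreviation_period(tokens: list[Token], i: int, abbreviations: frozenset[str]) -> bool:
    if i == 0:
        return False
    prev = tokens[i - 1]
    if prev.kind != "word" or prev.end != tokens[i].start:
        return False
    if len(prev.surface) == 1:
        return True  # initials, "e.g." / "i.e." letters
    return prev.surface.lower() in abbreviations


# ---------------------------------------------------------------------------
# Coarse tagging

def _tag_word(surface: str, prev_tag: str | None) -> str:
    low = surface.lower()
    if low in wl.BE_FORMS or low in wl.GET_FORMS or low in wl.OTHER_AUX:
        return "aux"
    if low in wl.FUNCTION_WORDS:
        return "other"
    if low in wl.IRREGULAR_PARTICIPLES:
        return "participle"
    if low in wl.IRREGULAR_PASTS:
        return "verb"
    if low in wl.COMMON_ADJECTIVES:
        return "adjective"
    if low in wl.COMMON_VERBS:
        return "verb"
    if low.endswith("ly") and len(low) > 3 and low not in wl.ADVERB_EXCEPTIONS:
        return "adverb"
    if low.endswith("ed") and len(low) > 3:
        return "participle"
    if low.endswith("ing") and len(low) > 4 and low not in wl.ING_NOUNS:
        return "verb"
    if low.endswith(wl.ADJECTIVE_SUFFIXES) and len(low) > 4:
        return "adjective"
    return "noun"


def annotate_tokens(tokens: list[Token]) -> list[Token]:
    """Fill ``coarse_tag`` (and syllables) on every word token.

    Deterministic rule cascade: closed-class lists first, then suffix
    rules, defaulting to noun. Auxiliaries of be/get (plus modals and
    have/do) are tagged ``aux``.
    """
    out: list[Token] = []
    prev_tag: str | None = None
    for tok in tokens:
        if tok.kind != "word":
            out.append(tok)
            continue
        tag = _tag_word(tok.surface, prev_tag)
        out.append(replace(tok, coarse_tag=tag, syllables=count_syllables(tok.surface)))
        prev_tag = tag
    return out


# ---------------------------------------------------------------------------
# Document

@dataclass(frozen=True)
class Document:
    """Immutable normalized text plus its segmentation and annotation.

    Invariants: every token span lies within exactly one sentence span;
    sentence spans are ordered and non-overlapping; all offsets are
    0-based half-open into ``text``.
    """

    text: str
    tokens: tuple[Token, ...]
    sentences: tuple[Span, ...]
    paragraphs: tuple[Span, ...]

    @classmethod
    def from_text(
        cls,
        raw: str | bytes,
        *,
        markdown: bool = False,
        abbreviations: frozenset[str] | None = None,
    ) -> "Document":
        """Run the full pipeline: normalize, tokenize, segment, annotate."""
        text = normalize_text(raw)
        if markdown:
            text = strip_markdown(text)
        tokens = annotate_tokens(tokenize(text))
        sentences = segment_sentences(text, list(tokens), abbreviations)
        paragraphs = segment_paragraphs(text)
        return cls(text, tuple(tokens), tuple(sentences), tuple(paragraphs))

    # -- convenience views ---------------------------------------------------

    @property
    def word_tokens(self) -> tuple[Token, ...]:
        return tuple(t for t in self.tokens if t.is_word)

    def tokens_in(self, span: Span) -> tuple[Token, ...]:
        start, end = span
        return tuple(t for t in self.tokens if t.start >= start and t.end <= end)

    def sentence_word_count(self, span: Span) -> int:
        return sum(1 for t in self.tokens_in(span) if t.counts_as_word)

    def sentence_text(self, span: Span) -> str:
        return self.text[span[0] : span[1]]
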