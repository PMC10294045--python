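"""Editable resource files: jargon lexicon, person-centred ruleset,
abbreviation list and pronunciation (syllable) table.

All four ship as plain-text files under ``healthlit/data`` and can be
replaced by user-supplied files of the same format:

* lexicon: TSV ``term<TAB>category<TAB>alternative;alternative;...``
  (alternatives may be empty) or an equivalent JSON list of objects with
  ``term``, ``category`` and ``alternatives`` keys;
* person-centred ruleset: TSV ``pattern<TAB>preferred<TAB>rationale``;
* abbreviations: one abbreviation per line (trailing period optional);
* syllable table: TSV ``word<TAB>count``.

Loaders validate every line and raise :class:`ResourceFormatError` with
the path and 1-based line number on the first malformed entry. Duplicate
terms keep the first occurrence and log a warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources as importlib_resources
from pathlib import Path

from .errors import ResourceFormatError

logger = logging.getLogger("healthlit.resources")

LEXICON_CATEGORIES = frozenset({"medical_jargon", "public_health_term", "uncommon_general"})


def data_path(name: str) -> Path:
    """Path of a shipped default resource file."""
    return Path(str(importlib_resources.files("healthlit").joinpath("data", name)))


@dataclass(frozen=True)
class LexiconEntry:
    """One complex-language term with its plain-language alternatives."""

    term: str
    category: str
    alternatives: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.term:
            raise ValueError("lexicon term must be non-empty")


@dataclass(frozen=True)
class PersonCentredRule:
    """A discouraged phrase and the person-first phrasing to prefer."""

    pattern: str
    preferred: str
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.pattern.lower() == self.preferred.lower():
            raise ValueError("rule pattern must differ from its preferred phrasing")


@dataclass(frozen=True)
class Lexicon:
    """Case-insensitive term -> entry mapping, plus provenance metadata."""

    entries: dict[str, LexiconEntry]
    source: str
    version: str

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, term: str) -> LexiconEntry | None:
        return self.entries.get(term.lower())

    @property
    def max_term_words(self) -> int:
        return max((t.count(" ") + 1 for t in self.entries), default=1)


@dataclass(frozen=True)
class Ruleset:
    rules: tuple[PersonCentredRule, ...]
    source: str
    version: str

    def __len__(self) -> int:
        return len(self.rules)


def _file_version(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:8]


def load_lexicon(path: str | Path | None = None) -> Lexicon:
    """Load a lexicon from TSV or JSON (by extension); default: shipped file."""
    path = Path(path) if path is not None else data_path("lexicon.tsv")
    if not path.exists():
        raise ResourceFormatError("lexicon file not found", str(path))
    if path.suffix.lower() == ".json":
        entries = _lexicon_from_json(path)
    else:
        entries = _lexicon_from_tsv(path)
    if not entries:
        logger.warning("lexicon %s is empty", path)
    return Lexicon(entries, source=str(path), version=_file_version(path))


def _add_lexicon_entry(
    entries: dict[str, LexiconEntry], entry: LexiconEntry, path: Path, line: int
) -> None:
    key = entry.term.lower()
    if key in entries:
        logger.warning(
            "%s:%d duplicate lexicon term %r ignored (first occurrence wins)",
            path, line, entry.term,
        )
        return
    entries[key] = entry


def _lexicon_from_tsv(path: Path) -> dict[str, LexiconEntry]:
    entries: dict[str, LexiconEntry] = {}
    for lineno, raw in enumerate(path.read_text("utf-8").splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (2, 3):  # alternatives column may be omitted
            raise ResourceFormatError(
                f"expected 2-3 tab-separated fields, got {len(fields)}", str(path), lineno
            )
        term, category = fields[0].strip(), fields[1].strip()
        alts = fields[2].strip() if len(fields) == 3 else ""
        if not term:
            raise ResourceFormatError("empty term", str(path), lineno)
        if category not in LEXICON_CATEGORIES:
            raise ResourceFormatError(
                f"unknown category {category!r} (expected one of "
                f"{sorted(LEXICON_CATEGORIES)})", str(path), lineno
            )
        alternatives = tuple(
            a.strip() for a in alts.split(";")
            if a.strip() and a.strip().lower() != term.lower()
        )
        _add_lexicon_entry(
            entries, LexiconEntry(term.lower(), category, alternatives), path, lineno
        )
    return entries


def _lexicon_from_json(path: Path) -> dict[str, LexiconEntry]:
    try:
        data = json.loads(path.read_text("utf-8"))
    except json.JSONDecodeError as exc:
        raise ResourceFormatError(f"invalid JSON: {exc.msg}", str(path), exc.lineno)
    if not isinstance(data, list):
        raise ResourceFormatError("lexicon JSON must be a list of objects", str(path))
    entries: dict[str, LexiconEntry] = {}
    for i, obj in enumerate(data, start=1):
        if not isinstance(obj, dict) or "term" not in obj or "category" not in obj:
            raise ResourceFormatError(
                f"entry {i}: each entry needs 'term' and 'category'", str(path)
            )
        term = str(obj["term"]).strip()
        category = str(obj["category"]).strip()
        if not term:
            raise ResourceFormatError(f"entry {i}: empty term", str(path))
        if category not in LEXICON_CATEGORIES:
            raise ResourceFormatError(
                f"entry {i}: unknown category {category!r}", str(path)
            )
        alternatives = tuple(
            str(a).strip() for a in obj.get("alternatives", [])
            if str(a).strip() and str(a).strip().lower() != term.lower()
        )
        _add_lexicon_entry(
            entries, LexiconEntry(term.lower(), category, alternatives), path, i
        )
    return entries


def load_ruleset(path: str | Path | None = None) -> Ruleset:
    """Load the person-centred language ruleset (TSV); default: shipped file."""
    path = Path(path) if path is not None else data_path("person_centred.tsv")
    if not path.exists():
        raise ResourceFormatError("ruleset file not found", str(path))
    rules: list[PersonCentredRule] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text("utf-8").splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise ResourceFormatError(
                f"expected 2-3 tab-separated fields, got {len(fields)}",
                str(path), lineno,
            )
        pattern = fields[0].strip()
        preferred = fields[1].strip()
        rationale = fields[2].strip() if len(fields) == 3 else ""
        if not pattern or not preferred:
            raise ResourceFormatError("empty pattern or preferred phrasing", str(path), lineno)
        if pattern.lower() == preferred.lower():
            raise ResourceFormatError(
                "pattern must differ from preferred phrasing", str(path), lineno
            )
        if pattern.lower() in seen:
            logger.warning("%s:%d duplicate rule pattern %r ignored", path, lineno, pattern)
            continue
        seen.add(pattern.lower())
        rules.append(PersonCentredRule(pattern.lower(), preferred, rationale))
    if not rules:
        logger.warning("ruleset %s is empty", path)
    return Ruleset(tuple(rules), source=str(path), version=_file_version(path))


def load_abbreviations(path: str | Path | None = None) -> frozenset[str]:
    """Abbreviations that do not end a sentence (lowercase, no period)."""
    path = Path(path) if path is not None else data_path("abbreviations.txt")
    if not path.exists():
        raise ResourceFormatError("abbreviation file not found", str(path))
    out = set()
    for raw in path.read_text("utf-8").splitlines():
        word = raw.strip().rstrip(".").lower()
        if word and not word.startswith("#"):
            out.add(word)
    return frozenset(out)


def load_syllable_table(path: str | Path | None = None) -> dict[str, int]:
    """word -> syllable count overrides for the counting fallback."""
    path = Path(path) if path is not None else data_path("syllables.tsv")
    if not path.exists():
        raise ResourceFormatError("syllable table not found", str(path))
    table: dict[str, int] = {}
    for lineno, raw in enumerate(path.read_text("utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ResourceFormatError(
                f"expected 2 tab-separated fields, got {len(fields)}", str(path), lineno
            )
        word, count = fields[0].strip().lower(), fields[1].strip()
        if not word or not count.isdigit() or int(count) < 1:
            raise ResourceFormatError("expected word<TAB>positive count", str(path), lineno)
        table[word] = int(count)
    return table


@lru_cache(maxsize=1)
def default_abbreviations() -> frozenset[str]:
    return load_abbreviations()


@lru_cache(maxsize=1)
def default_syllable_table() -> dict[str, int]:
    return load_syllable_table()
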