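"""Deterministic synthetic-text generator with exactly planted features.

The generator builds health-information-flavoured prose with known
ground truth: an exact sentence count, exact per-sentence word counts,
and exact numbers of planted polysyllabic words, passive constructions
and jargon terms. The word banks are curated so the planted counts stay
independent:

* filler words have at most two syllables, are not be/get auxiliaries or
  participles, and are absent from the shipped lexicon;
* the polysyllable bank holds words of three or more syllables that are
  absent from the lexicon;
* the jargon bank holds shipped-lexicon terms of at most two syllables,
  so planting jargon never changes the polysyllable count (custom terms
  with three or more syllables are rejected).

Same spec (including seed) always yields identical bytes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import FixtureSpecError
from .text import count_syllables

FILLER_WORDS = (
    "the", "you", "your", "team", "care", "plan", "help", "day", "food",
    "week", "home", "walk", "fruit", "milk", "water", "rest", "sleep",
    "warm", "safe", "fresh", "salt", "nurse", "clinic", "staff", "room",
    "door", "hand", "good", "slow", "deep", "breath", "chair", "desk",
    "note", "book", "page", "list", "time", "start", "keep", "with",
)

POLYSYLLABLE_WORDS = (
    "important", "hospital", "information", "community", "regularly",
    "understanding", "appointment", "emergency", "activity", "physical",
    "different", "remember", "family", "vegetables", "energy", "exercise",
    "medicine", "together", "tomorrow", "holiday",
)

PASSIVE_PARTICIPLES = (
    "tested", "given", "taken", "checked", "changed", "told", "shown",
    "washed", "moved", "helped", "asked", "called", "booked", "sent",
)

JARGON_WORDS = (
    "fissure", "renal", "lesion", "benign", "acute", "chronic",
    "gastric", "febrile", "oral",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Ground truth for one generated text.

    ``polysyllable_total``, when set, overrides the per-sentence count and
    is spread round-robin across sentences (useful for arbitrary (P, S)
    pairs). ``planted_jargon`` lists term occurrences; repeats plant the
    term more than once.
    """

    sentence_count: int
    words_per_sentence: int = 10
    polysyllables_per_sentence: int = 0
    polysyllable_total: int | None = None
    planted_passive_count: int = 0
    planted_jargon: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sentence_count < 0 or self.words_per_sentence < 1:
            raise FixtureSpecError("need sentence_count >= 0 and words_per_sentence >= 1")
        if self.polysyllables_per_sentence < 0 or self.planted_passive_count < 0:
            raise FixtureSpecError("planted counts must be non-negative")
        if self.polysyllable_total is not None and self.polysyllable_total < 0:
            raise FixtureSpecError("polysyllable_total must be non-negative")
        for term in self.planted_jargon:
            for word in term.split():
                if count_syllables(word) >= 3:
                    raise FixtureSpecError(
                        f"jargon term {term!r} has a word of 3+ syllables; it would "
                        "change the planted polysyllable count"
                    )

    @property
    def total_polysyllables(self) -> int:
        if self.polysyllable_total is not None:
            return self.polysyllable_total
        return self.sentence_count * self.polysyllables_per_sentence


def _distribute(total: int, bins: int) -> list[int]:
    """Round-robin split of ``total`` items over ``bins`` (first bins larger)."""
    base, extra = divmod(total, bins)
    return [base + (1 if i < extra else 0) for i in range(bins)]


def generate_fixture(spec: FixtureSpec) -> str:
    """Generate text realising ``spec`` exactly; pure function of the spec."""
    if spec.sentence_count == 0:
        if spec.total_polysyllables or spec.planted_passive_count or spec.planted_jargon:
            raise FixtureSpecError("cannot plant features in a zero-sentence text")
        return ""
    rng = random.Random(spec.seed)
    n = spec.sentence_count
    poly_per_sentence = _distribute(spec.total_polysyllables, n)
    passives_per_sentence = _distribute(spec.planted_passive_count, n)
    jargon_assignment: list[list[str]] = [[] for _ in range(n)]
    for i, term in enumerate(spec.planted_jargon):
        jargon_assignment[i % n].append(term)

    sentences: list[str] = []
    for i in range(n):
        units: list[list[str]] = []
        for _ in range(poly_per_sentence[i]):
            units.append([rng.choice(POLYSYLLABLE_WORDS)])
        for _ in range(passives_per_sentence[i]):
            units.append(["was", rng.choice(PASSIVE_PARTICIPLES)])
        for term in jargon_assignment[i]:
            units.append(term.split())
        used = sum(len(u) for u in units)
        if used > spec.words_per_sentence:
            raise FixtureSpecError(
                f"sentence {i + 1} needs {used} planted word slots but only "
                f"{spec.words_per_sentence} words per sentence are allowed"
            )
        units.extend([rng.choice(FILLER_WORDS)] for _ in range(spec.words_per_sentence - used))
        rng.shuffle(units)
        words = [w for unit in units for w in unit]
        sentence = " ".join(words)
        sentences.append(sentence[0].upper() + sentence[1:] + ".")
    return " ".join(sentences)
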