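"""Advice-string catalogue.

All user-facing feedback wording lives here so it can be edited in one
place without touching assessment logic. Keys are stable identifiers;
values are ``str.format`` templates.
"""

from __future__ import annotations

CATALOGUE: dict[str, str] = {
    "readability.long_word": (
        "'{word}' has {syllables} syllables. Try a shorter, everyday word."
    ),
    "readability.long_sentence": (
        "This sentence has {words} words. Try breaking it down into shorter sentences."
    ),
    "readability.long_sentence.global": "{count} sentences are long.",
    "readability.long_list": (
        "This sentence lists {items} things. Use dot points for lists of more than "
        "{max_items} things."
    ),
    "complex_language.with_alternatives": (
        "'{term}' may be unfamiliar. Try: {alternatives}."
    ),
    "complex_language.no_alternatives": (
        "'{term}' may be unfamiliar to readers. No plain-language alternative is "
        "listed; consider explaining it in everyday words."
    ),
    "complex_language.global": "{count} instances of complex language.",
    "passive_voice": (
        "'{phrase}' is passive voice. Say who does the action: for example, "
        "'the nurse gives the medicine' rather than 'the medicine is given'."
    ),
    "passive_voice.global": "{count} instances of passive voice.",
    "person_centred": "Prefer '{preferred}'. {rationale}",
    "text_structure.long_paragraph": (
        "This paragraph has {words} words. Try splitting it into shorter paragraphs "
        "of at most {limit} words."
    ),
    "grade.met": "Grade {grade} meets the grade {target} reading target.",
    "grade.not_met": "Grade {grade} is above the grade {target} reading target.",
}


def render(key: str, **kwargs) -> str:
    return CATALOGUE[key].format(**kwargs)
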