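"""Span-level highlights: the unit of in-text feedback.

A highlight ties a character span of the (normalized) document text to an
assessment category, a human-readable message, and optional suggested
alternatives. Spans are 0-based half-open intervals into the normalized
text, the same convention used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class Highlight:
    # field order gives span-start-first sorting; ties break deterministically
    start: int
    end: int
    category: str
    message: str
    alternatives: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def text(self, document_text: str) -> str:
        """The slice of the document this highlight covers."""
        return document_text[self.start : self.end]

    def to_dict(self) -> dict:
        return {
            "start": self.start,
            "end": self.end,
            "category": self.category,
            "message": self.message,
            "alternatives": list(self.alternatives),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Highlight":
        return cls(
            start=d["start"],
            end=d["end"],
            category=d["category"],
            message=d["message"],
            alternatives=tuple(d.get("alternatives", ())),
        )
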