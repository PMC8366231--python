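"""Lexicon entries, the phone inventory, and their tab-separated serialization.

A lexicon row is a word *type*: an identifier, a phonological transcription
with one symbol per phone (DISC-style), an optional base word, and an optional
morphological category.  Monomorphemic words carry neither base nor category;
derived words carry both.  Words whose bases are themselves complex
(multi-affix derivatives) are rejected at load time because the additive
semantic-vector construction is undefined for them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

BOUNDARY = "#"


@dataclass(frozen=True)
class PhonemeInventory:
    """A set of single-character phone symbols plus the reserved word boundary."""

    symbols: tuple[str, ...]
    boundary_symbol: str = BOUNDARY

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("phone inventory must be non-empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("phone symbols must be unique")
        if any(len(s) != 1 for s in self.symbols):
            raise ValueError("phone symbols must be single characters")
        if len(self.boundary_symbol) != 1:
            raise ValueError("boundary symbol must be a single character")
        if self.boundary_symbol in self.symbols:
            raise ValueError("boundary symbol must not be a phone symbol")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def validate_transcription(self, transcription: str) -> None:
        if not transcription:
            raise ValueError("empty transcription")
        for ch in transcription:
            if ch == self.boundary_symbol:
                raise ValueError(
                    f"boundary symbol {ch!r} may not occur inside a transcription"
                )
            if ch not in self.symbols:
                raise ValueError(f"illegal phone symbol {ch!r} in {transcription!r}")


@dataclass(frozen=True)
class LexiconEntry:
    """One word type: identifier, transcription, and morphological parentage."""

    word_id: str
    transcription: str
    base_id: str | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if len(self.transcription) < 1:
            raise ValueError("transcription must have at least one phone")
        if self.category is not None and self.base_id is None:
            raise ValueError(
                f"{self.word_id}: derived entries (category set) must name a base"
            )

    @property
    def is_derived(self) -> bool:
        return self.category is not None


def validate_lexicon(entries: Sequence[LexiconEntry]) -> None:
    """Check id uniqueness, base resolution, and single-affix structure.

    Derived words whose base is itself derived (multi-affix derivatives) are
    rejected: their semantic vectors have no defined additive construction.
    """
    by_id: dict[str, LexiconEntry] = {}
    for e in entries:
        if e.word_id in by_id:
            raise ValueError(f"duplicate word_id {e.word_id!r}")
        by_id[e.word_id] = e
    for e in entries:
        if e.base_id is None:
            continue
        base = by_id.get(e.base_id)
        if base is None:
            raise ValueError(f"{e.word_id}: base {e.base_id!r} not in lexicon")
        if base.is_derived:
            raise ValueError(
                f"{e.word_id}: base {e.base_id!r} is itself derived; "
                "multi-affix derivatives are not supported"
            )


def write_lexicon(entries: Iterable[LexiconEntry], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "word_id": e.word_id,
                "transcription": e.transcription,
                "base_id": e.base_id if e.base_id is not None else "",
                "category": e.category if e.category is not None else "",
            }
            for e in entries
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_lexicon(path: str | Path) -> list[LexiconEntry]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = [
        LexiconEntry(
            word_id=row.word_id,
            transcription=row.transcription,
            base_id=row.base_id or None,
            category=row.category or None,
        )
        for row in frame.itertuples()
    ]
    validate_lexicon(entries)
    return entries
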