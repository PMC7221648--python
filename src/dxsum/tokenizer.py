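"""Character-level tokenization for free-text discharge diagnoses.

Diagnoses are tokenized one character at a time against a fixed 100-symbol
inventory (space, digits, both letter cases, punctuation, and the ``^`` mask
symbol used by the cloze pretraining objective).  Characters outside the
inventory are replaced by spaces during preprocessing, and texts are truncated
to 1350 characters.  Word-unit segmentation (maximal letter runs, maximal
digit runs, singleton punctuation, maximal space runs) is shared by the
whole-word masking phase, the word-average probability cleanup, and the
word-level evaluation metrics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

MAX_CHARS = 1350
MASK_CHAR = "^"

# Canonical inventory: ' '=0, punctuation at 1-12 ('.'=11), digits '0'-'9' at
# 13-22, more punctuation at 23-29, 'A'-'Z' at 30-55, '^' at 56, 'a'-'z' at
# 57-82, remaining punctuation/symbols at 83-99.  The anchors ' '=0, '.'=11,
# '1'=14, 'B'=31, 'a'=57 are fixed; the rest of the inventory is a frozen
# package convention.
SYMBOLS: str = (
    " "
    + "!\"#$%&'()*"
    + "."
    + ","
    + "0123456789"
    + "+-/:;<="
    + "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    + MASK_CHAR
    + "abcdefghijklmnopqrstuvwxyz"
    + ">?@[\\]_`{|}~"
    + "°±×÷§"
)

CHAR_CLASSES = ("space", "punctuation", "digit", "uppercase", "lowercase", "mask")


def _class_of(ch: str) -> str:
    if ch == " ":
        return "space"
    if ch == MASK_CHAR:
        return "mask"
    if ch.isdigit():
        return "digit"
    if "A" <= ch <= "Z":
        return "uppercase"
    if "a" <= ch <= "z":
        return "lowercase"
    return "punctuation"


@dataclass(frozen=True)
class SymbolTable:
    """Bijection between the 100 retained characters and ids 0..99."""

    symbols: str

    def __post_init__(self) -> None:
        if len(self.symbols) != 100 or len(set(self.symbols)) != 100:
            raise ValueError("symbol table must contain exactly 100 distinct characters")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def _index(self) -> dict[str, int]:
        # computed lazily once; frozen dataclass so cache on the instance dict
        try:
            return object.__getattribute__(self, "_index_cache")
        except AttributeError:
            idx = {ch: i for i, ch in enumerate(self.symbols)}
            object.__setattr__(self, "_index_cache", idx)
            return idx

    def id_of(self, ch: str) -> int:
        try:
            return self._index[ch]
        except KeyError:
            raise KeyError(f"character {ch!r} is not in the symbol table") from None

    def char_of(self, i: int) -> str:
        if not 0 <= i < 100:
            raise ValueError(f"id {i} out of range [0, 99]")
        return self.symbols[i]

    def __contains__(self, ch: str) -> bool:
        return ch in self._index

    def class_of(self, ch: str) -> str:
        if ch not in self._index:
            raise KeyError(f"character {ch!r} is not in the symbol table")
        return _class_of(ch)

    @property
    def mask_id(self) -> int:
        return self.id_of(MASK_CHAR)

    def replacement_group(self, ch: str) -> str | None:
        """Pool a character may be swapped within (typos, cloze corruption).

        Letters (either case) swap with letters, digits with digits and
        punctuation with punctuation; spaces and the mask symbol have no
        replacement pool.
        """
        cls = self.class_of(ch)
        if cls in ("uppercase", "lowercase"):
            return "letter"
        if cls == "digit":
            return "digit"
        if cls == "punctuation":
            return "punctuation"
        return None

    def group_members(self, group: str) -> str:
        return "".join(
            ch for ch in self.symbols if self.replacement_group(ch) == group
        )

    # -- auditability ------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the table as a two-column (character, id) UTF-8 TSV."""
        lines = [f"{ch}\t{i}\n" for i, ch in enumerate(self.symbols)]
        Path(path).write_text("".join(lines), encoding="utf-8")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SymbolTable":
        chars: dict[int, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            ch, _, i = line.partition("\t")
            chars[int(i)] = ch
        return cls("".join(chars[i] for i in range(len(chars))))


def build_symbol_table() -> SymbolTable:
    """Return the canonical 100-symbol table (stable across runs)."""
    return SymbolTable(SYMBOLS)


_TABLE = build_symbol_table()
_KNOWN = set(SYMBOLS)


def preprocess(text: str, max_chars: int = MAX_CHARS) -> str:
    """Replace out-of-inventory characters by spaces and truncate.

    Letter case is preserved.  Truncation (default 1350 characters) happens
    after replacement; the two commute since replacement is per-character.
    """
    cleaned = "".join(ch if ch in _KNOWN else " " for ch in text)
    return cleaned[:max_chars]


def encode(text: str, table: SymbolTable | None = None) -> list[int]:
    """Map each character of a preprocessed text to its integer id."""
    table = table or _TABLE
    out = []
    for offset, ch in enumerate(text):
        if ch not in table:
            raise ValueError(
                f"character {ch!r} at offset {offset} is not in the symbol table; "
                "run preprocess() first"
            )
        out.append(table.id_of(ch))
    return out


def decode(ids: Iterable[int], table: SymbolTable | None = None) -> str:
    """Inverse of :func:`encode`."""
    table = table or _TABLE
    return "".join(table.char_of(int(i)) for i in ids)


@dataclass(frozen=True)
class WordUnit:
    """Half-open character interval [start, end) of one segmentation unit."""

    start: int
    end: int
    kind: str  # letter_run | digit_run | punct | space_run

    def __len__(self) -> int:
        return self.end - self.start


_UNIT_RE = re.compile(r"[A-Za-z]+|[0-9]+| +|.")


def segment_units(text: str) -> list[WordUnit]:
    """Tile a preprocessed text into word units.

    Maximal letter runs and digit runs are single units; every punctuation
    character (including ``^``) is its own unit; maximal space runs are
    single units.  The units tile [0, len(text)) with no gaps or overlaps.
    """
    units: list[WordUnit] = []
    for m in _UNIT_RE.finditer(text):
        ch = m.group(0)[0]
        if ch.isascii() and ch.isalpha():
            kind = "letter_run"
        elif ch.isdigit():
            kind = "digit_run"
        elif ch == " ":
            kind = "space_run"
        else:
            kind = "punct"
        units.append(WordUnit(m.start(), m.end(), kind))
    return units
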