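"""Generic tab-separated lexicon dictionaries.

Two layouts share one file format (``#`` comments allowed, case-folded):

* categorical — ``word<TAB>category``; words may be bigrams (two words
  separated by a single space).
* norms — ``word<TAB>norm_name<TAB>value`` with a numeric value.

A single file may mix both layouts; two-column lines populate
``categorical`` and three-column lines populate ``norms``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

#: The seven lexicon slots backing the lexicon-based features.
LEXICON_SLOTS = (
    "ANEW", "ANEW-Emo", "GI", "GALC", "LIWC", "EmoLex", "SenticNet",
)


class LexiconParseError(ValueError):
    """Raised on a malformed lexicon line; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass
class Lexicon:
    slot: str
    categorical: dict[str, set[str]] = field(default_factory=dict)
    norms: dict[str, dict[str, float]] = field(default_factory=dict)

    def categories(self) -> set[str]:
        out: set[str] = set()
        for cats in self.categorical.values():
            out |= cats
        return out

    def norm_names(self) -> set[str]:
        out: set[str] = set()
        for vals in self.norms.values():
            out |= set(vals)
        return out

    def words_in_category(self, category: str) -> set[str]:
        return {w for w, cats in self.categorical.items() if category in cats}

    def add(self, word: str, category: str) -> None:
        self.categorical.setdefault(word.lower(), set()).add(category)

    def add_norm(self, word: str, norm: str, value: float) -> None:
        self.norms.setdefault(word.lower(), {})[norm] = float(value)


def load_lexicon(path: str | Path, slot: str) -> Lexicon:
    """Load a TSV lexicon file into the given slot.

    Duplicate word/category pairs are deduplicated with a logged warning;
    a non-numeric norm value or a wrong column count raises
    :class:`LexiconParseError` with the offending line number.
    """
    if slot not in LEXICON_SLOTS:
        raise ValueError(f"unknown lexicon slot {slot!r}; expected one of {LEXICON_SLOTS}")
    path = Path(path)
    lex = Lexicon(slot=slot)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                word, category = parts[0].strip().lower(), parts[1].strip()
                if not word or not category:
                    raise LexiconParseError(path, lineno, "empty word or category")
                if category in lex.categorical.get(word, ()):
                    logger.warning("%s:%d: duplicate entry %r/%r", path, lineno, word, category)
                lex.add(word, category)
            elif len(parts) == 3:
                word, norm = parts[0].strip().lower(), parts[1].strip()
                try:
                    value = float(parts[2])
                except ValueError:
                    raise LexiconParseError(
                        path, lineno, f"non-numeric norm value {parts[2]!r}"
                    ) from None
                lex.add_norm(word, norm, value)
            else:
                raise LexiconParseError(
                    path, lineno, f"expected 2 or 3 tab-separated columns, got {len(parts)}"
                )
    return lex


def write_lexicon(lex: Lexicon, path: str | Path) -> None:
    """Write a lexicon in canonical (sorted) TSV form; round-trips with load."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for word in sorted(lex.categorical):
            for category in sorted(lex.categorical[word]):
                fh.write(f"{word}\t{category}\n")
        for word in sorted(lex.norms):
            for norm in sorted(lex.norms[word]):
                fh.write(f"{word}\t{norm}\t{lex.norms[word][norm]:g}\n")
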