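"""Happiness and category lexicons.

A happiness lexicon maps words to valence scores on the 1-9 scale used by
crowd-rated instruments such as labMT and ANEW (1 = saddest, 9 = happiest).
A category lexicon maps words to one or more semantic/linguistic category
labels (LIWC-style: e.g. ``negemo``, ``family``, ``ingest``).

Lexicons are stored lowercase and matched case-insensitively.  The neutral
"stop band" — scores strictly between 4 and 6 by default — is carried on the
happiness lexicon but is only applied at scoring time, never at load time,
so a loaded lexicon always round-trips unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Default neutral band: words with 4 < h < 6 are dropped from word-shift
#: scoring.  The comparison is strict, so h = 4.0 and h = 6.0 are retained.
DEFAULT_STOP_BAND: tuple[float, float] = (4.0, 6.0)

SCORE_MIN, SCORE_MAX = 1.0, 9.0


class LexiconError(ValueError):
    """Raised for malformed lexicon files."""


def _check_word(word: str, path, lineno: int) -> str:
    if not word or word != word.strip() or any(c.isspace() for c in word):
        raise LexiconError(
            f"{path}:{lineno}: lexicon word {word!r} must be non-empty and "
            "whitespace-free"
        )
    return word.lower()


@dataclass(frozen=True)
class HappinessLexicon:
    """Word -> happiness score map on the 1-9 scale.

    Parameters
    ----------
    name
        Short identifier used to label feature columns (``<name>_happy``).
    entries
        Mapping of lowercase word to score in [1, 9].
    stop_band
        ``(lower, upper)`` neutral band.  Words with
        ``lower < score < upper`` are excluded when a caller asks for
        band-filtered scoring; the entries themselves are never removed.
    """

    name: str
    entries: dict[str, float]
    stop_band: tuple[float, float] = DEFAULT_STOP_BAND

    def __post_init__(self) -> None:
        lo, hi = self.stop_band
        if lo > hi:
            raise LexiconError(f"stop band lower {lo} exceeds upper {hi}")
        for w, s in self.entries.items():
            if not (SCORE_MIN <= s <= SCORE_MAX):
                raise LexiconError(f"score {s} for {w!r} outside [1, 9]")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries

    def score(self, word: str) -> float | None:
        return self.entries.get(word.lower())

    def in_band(self, word: str) -> bool:
        """True if the word's score lies strictly inside the stop band."""
        s = self.entries.get(word.lower())
        if s is None:
            return False
        lo, hi = self.stop_band
        return lo < s < hi

    def banded_entries(self) -> dict[str, float]:
        """Entries with stop-band words removed (a view for scoring; the
        lexicon itself is not mutated)."""
        lo, hi = self.stop_band
        return {w: s for w, s in self.entries.items() if not (lo < s < hi)}

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for w, s in self.entries.items():
                fh.write(f"{w}\t{s}\n")


@dataclass(frozen=True)
class CategoryLexicon:
    """Word -> set-of-category-labels map (LIWC-style).

    ``categories`` preserves the order in which labels first appear in the
    source file, which fixes the feature-column order downstream.
    """

    name: str
    entries: dict[str, frozenset[str]]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        known = set(self.categories)
        for w, labels in self.entries.items():
            missing = labels - known
            if missing:
                raise LexiconError(
                    f"word {w!r} references unknown categories {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self, word: str) -> frozenset[str]:
        return self.entries.get(word.lower(), frozenset())

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            order = {c: i for i, c in enumerate(self.categories)}
            for w, labels in self.entries.items():
                lab = ",".join(sorted(labels, key=order.__getitem__))
                fh.write(f"{w}\t{lab}\n")


def load_happiness_lexicon(
    path: str | Path,
    stop_band: tuple[float, float] | None = DEFAULT_STOP_BAND,
    name: str | None = None,
) -> HappinessLexicon:
    """Load a two-column TSV ``word<TAB>score`` happiness lexicon.

    Duplicate words are deduplicated with last-occurrence-wins (logged).
    Scores must parse and lie in [1, 9]; malformed rows raise
    :class:`LexiconError` naming the offending line.
    """
    path = Path(path)
    entries: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LexiconError(
                    f"{path}:{lineno}: expected 'word<TAB>score', got {line!r}"
                )
            word = _check_word(parts[0], path, lineno)
            try:
                score = float(parts[1])
            except ValueError as exc:
                raise LexiconError(
                    f"{path}:{lineno}: score {parts[1]!r} is not a number"
                ) from exc
            if not (SCORE_MIN <= score <= SCORE_MAX):
                raise LexiconError(
                    f"{path}:{lineno}: score {score} outside [1, 9]"
                )
            if word in entries:
                logger.info("%s:%d: duplicate word %r, keeping last", path, lineno, word)
            entries[word] = score
    if not entries:
        raise LexiconError(f"{path}: empty happiness lexicon")
    return HappinessLexicon(
        name=name or path.stem,
        entries=entries,
        stop_band=stop_band if stop_band is not None else (0.0, 0.0),
    )


def load_category_lexicon(path: str | Path, name: str | None = None) -> CategoryLexicon:
    """Load a TSV ``word<TAB>label1,label2,...`` category lexicon.

    Duplicate word rows merge their label sets.  Category order follows
    first appearance in the file.
    """
    path = Path(path)
    entries: dict[str, set[str]] = {}
    categories: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LexiconError(
                    f"{path}:{lineno}: expected 'word<TAB>labels', got {line!r}"
                )
            word = _check_word(parts[0], path, lineno)
            labels = [lab.strip() for lab in parts[1].split(",") if lab.strip()]
            if not labels:
                raise LexiconError(f"{path}:{lineno}: empty label list for {word!r}")
            for lab in labels:
                if lab not in categories:
                    categories.append(lab)
            entries.setdefault(word, set()).update(labels)
    if not entries:
        raise LexiconError(f"{path}: empty category lexicon")
    return CategoryLexicon(
        name=name or path.stem,
        entries={w: frozenset(s) for w, s in entries.items()},
        categories=tuple(categories),
    )


def _bundled(filename: str) -> Path:
    return Path(str(resources.files("tweetscreen").joinpath("data", filename)))


def toy_happiness_lexicon(name: str = "toy_labmt") -> HappinessLexicon:
    """Bundled ~70-word happiness lexicon used by the synthetic generator
    and the test-suite.  Real analyses supply their own instrument files."""
    return load_happiness_lexicon(_bundled(f"{name}.tsv"), name=name)


def toy_category_lexicon() -> CategoryLexicon:
    """Bundled LIWC-style category lexicon over the toy happiness words."""
    return load_category_lexicon(_bundled("toy_categories.tsv"), name="toy_categories")
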