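"""Tandem-repeat word sets used to classify deviant regions.

The built-in families are defined for k=5:

* A-/C-/G-/T-rich — five patterns each with one free position
  (e.g. AAAAN, AAAN A, ...), i.e. four identical bases plus any fifth;
  20 pattern-substitution combinations, 16 distinct words after
  deduplicating the homopolymer.
* AT-rich — WWWWW (W = A or T), 32 words.
* GC-rich — SSSSS (S = G or C), 32 words.

Patterns may use the degenerate symbols N (any base), W ({A,T}) and
S ({C,G}); word lists are deduplicated before use so no word is counted
twice in a deviation sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

_SYMBOLS: dict[str, tuple[str, ...]] = {
    "A": ("A",),
    "C": ("C",),
    "G": ("G",),
    "T": ("T",),
    "N": ("A", "C", "G", "T"),
    "W": ("A", "T"),
    "S": ("C", "G"),
}


def expand_pattern(pattern: str) -> list[str]:
    """Cartesian expansion of a degenerate pattern, lexicographic order."""
    try:
        choices = [_SYMBOLS[ch] for ch in pattern]
    except KeyError as exc:
        raise ValueError(f"unknown pattern symbol {exc.args[0]!r} in {pattern!r}") from exc
    return sorted("".join(w) for w in product(*choices))


@dataclass(frozen=True)
class WordSet:
    """A named family of concrete k-mers expanded from degenerate patterns."""

    name: str
    patterns: tuple[str, ...]
    words: tuple[str, ...]  # deduplicated, sorted
    expansions: int  # pattern-substitution combinations before deduplication

    @classmethod
    def from_patterns(cls, name: str, patterns: list[str] | tuple[str, ...]) -> "WordSet":
        lengths = {len(p) for p in patterns}
        if len(lengths) != 1:
            raise ValueError(f"word set {name!r}: patterns have mixed lengths {lengths}")
        expanded: list[str] = []
        for p in patterns:
            expanded.extend(expand_pattern(p))
        return cls(
            name=name,
            patterns=tuple(patterns),
            words=tuple(sorted(set(expanded))),
            expansions=len(expanded),
        )

    @property
    def k(self) -> int:
        return len(self.patterns[0])


def _single_base_rich(base: str) -> list[str]:
    return ["".join(base if i != j else "N" for i in range(5)) for j in range(4, -1, -1)]


def builtin_word_sets(k: int = 5) -> list[WordSet]:
    """The six built-in tandem-repeat families (defined for k=5 only)."""
    if k != 5:
        raise ValueError(
            "built-in word sets are defined for k=5; define custom sets "
            "(load_word_sets) for other word sizes"
        )
    sets = [
        WordSet.from_patterns(f"{b}-rich", _single_base_rich(b)) for b in "ACGT"
    ]
    sets.append(WordSet.from_patterns("AT-rich", ["WWWWW"]))
    sets.append(WordSet.from_patterns("GC-rich", ["SSSSS"]))
    return sets


def load_word_sets(path: str | Path) -> list[WordSet]:
    """Load custom word sets from a two-column TSV (set name, pattern)."""
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns (name, pattern)")
            groups.setdefault(fields[0], []).append(fields[1])
    return [WordSet.from_patterns(name, pats) for name, pats in groups.items()]
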