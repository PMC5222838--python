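"""Semiotic patterns: repetition structures over 8 chord slots.

A pattern such as ``ABCD-BCDB`` is a *pattern with variables*: equal labels
must be instantiated by the same chord, distinct labels by distinct chords.
Patterns span two 4-slot halves. The study's construction rules are:

* the first half is either ``AABB``-shaped (two adjacent repeated pairs)
  or ``ABCD``-shaped (four distinct labels);
* an ``AABB``-shaped first half requires at least one successively repeated
  chord pair in the second half;
* an ``ABCD``-shaped first half forbids successive repeats *within* the
  second half (a repeat across the half boundary, as in ``ABCD-DABD``,
  is allowed — the stimulus set itself contains one).

Three categorical repetition features describe each pattern: the first-half
shape, the number of unique chords in the second half (1–4), and the
structural overlap — how many of the four positions carry the same label in
both halves, discretized to AllSame (4) / PartiallySame (1–2) /
AllDifferent (0). An overlap of 3 is impossible under the construction
rules and is treated as a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

__all__ = [
    "SemioticPattern",
    "FirstHalfStructure",
    "OverlapLevel",
    "RepetitionFeatures",
    "PatternError",
    "parse_pattern",
    "validate_pattern",
    "repetition_features",
    "load_pattern_list",
    "experiment_patterns",
]


class PatternError(ValueError):
    """Raised for malformed or rule-violating patterns."""


class FirstHalfStructure(str, Enum):
    AABB = "AABB"
    ABCD = "ABCD"


class OverlapLevel(str, Enum):
    ALL_SAME = "AllSame"
    PARTIALLY_SAME = "PartiallySame"
    ALL_DIFFERENT = "AllDifferent"


@dataclass(frozen=True)
class SemioticPattern:
    """Eight variable labels in two halves; text form ``XXXX-XXXX``."""

    slots: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.slots) != 8 or not all(
            len(s) == 1 and "A" <= s <= "Z" for s in self.slots
        ):
            raise PatternError(f"pattern needs 8 labels A–Z, got {self.slots!r}")

    @property
    def first_half(self) -> tuple[str, ...]:
        return self.slots[:4]

    @property
    def second_half(self) -> tuple[str, ...]:
        return self.slots[4:]

    @property
    def labels(self) -> tuple[str, ...]:
        """Distinct labels in order of first appearance."""
        seen: list[str] = []
        for s in self.slots:
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    def text(self) -> str:
        return "".join(self.slots[:4]) + "-" + "".join(self.slots[4:])

    def __str__(self) -> str:  # pragma: no cover
        return self.text()


def parse_pattern(text: str) -> SemioticPattern:
    """Parse ``XXXX-XXXX`` into a pattern (labels are positional identities)."""
    text = text.strip()
    if len(text) != 9 or text[4] != "-":
        raise PatternError(
            f"pattern must be 8 labels with a hyphen after slot 4, got {text!r}"
        )
    slots = tuple(text[:4]) + tuple(text[5:])
    return SemioticPattern(slots)


def _first_half_structure(p: SemioticPattern) -> FirstHalfStructure | None:
    a, b, c, d = p.first_half
    if a == b and c == d and a != c:
        return FirstHalfStructure.AABB
    if len({a, b, c, d}) == 4:
        return FirstHalfStructure.ABCD
    return None


def validate_pattern(p: SemioticPattern) -> tuple[bool, list[str]]:
    """Check the construction rules; returns (verdict, rule violations)."""
    problems: list[str] = []
    shape = _first_half_structure(p)
    if shape is None:
        problems.append("first half must be AABB-shaped or ABCD-shaped")
        return False, problems
    second = p.second_half
    has_adjacent_repeat = any(x == y for x, y in zip(second, second[1:]))
    if shape is FirstHalfStructure.AABB and not has_adjacent_repeat:
        problems.append(
            "AABB-first patterns need at least one successively repeated chord "
            "in the second half"
        )
    if shape is FirstHalfStructure.ABCD and has_adjacent_repeat:
        problems.append(
            "ABCD-first patterns may not have successive repeated chords "
            "in the second half"
        )
    return not problems, problems


@dataclass(frozen=True)
class RepetitionFeatures:
    """The three categorical repetition variables of a pattern."""

    first_half_structure: FirstHalfStructure
    second_half_unique: int
    structural_overlap_count: int
    structural_overlap_level: OverlapLevel


_OVERLAP_LEVELS = {
    0: OverlapLevel.ALL_DIFFERENT,
    1: OverlapLevel.PARTIALLY_SAME,
    2: OverlapLevel.PARTIALLY_SAME,
    4: OverlapLevel.ALL_SAME,
}


def repetition_features(p: SemioticPattern) -> RepetitionFeatures:
    """Compute the three categorical features of a valid pattern.

    Features are label-level properties of the semiotic structure, not of
    any chord instantiation.
    """
    ok, problems = validate_pattern(p)
    if not ok:
        raise PatternError(f"{p.text()}: " + "; ".join(problems))
    shape = _first_half_structure(p)
    assert shape is not None
    unique = len(set(p.second_half))
    overlap = sum(1 for x, y in zip(p.first_half, p.second_half) if x == y)
    if overlap not in _OVERLAP_LEVELS:
        raise PatternError(
            f"{p.text()}: structural overlap {overlap} is outside the study design"
        )
    return RepetitionFeatures(
        first_half_structure=shape,
        second_half_unique=unique,
        structural_overlap_count=overlap,
        structural_overlap_level=_OVERLAP_LEVELS[overlap],
    )


def load_pattern_list(path: str | Path) -> list[SemioticPattern]:
    """Read a pattern list file: one pattern per line, ``#`` comments."""
    patterns = []
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        ln = ln.split("#", 1)[0].strip()
        if ln:
            patterns.append(parse_pattern(ln))
    return patterns


def experiment_patterns() -> list[SemioticPattern]:
    """The 14 semiotic structures of the listening experiment (packaged)."""
    text = resources.files("tranceloop.data").joinpath("patterns.txt").read_text("utf-8")
    return [parse_pattern(ln.split("#", 1)[0].strip())
            for ln in text.splitlines()
            if ln.split("#", 1)[0].strip()]
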