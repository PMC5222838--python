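"""First-order viewpoint model over chord transitions.

Each transition between distinct chords is abstracted to the linked pair
⟨root interval on the line of fifths, mode shift⟩ — e.g. C major → D minor
is ⟨+2, Mm⟩ (a major second up, major to minor). Because the viewpoint is
relative, the trained model is invariant to diatonic transposition of the
corpus, which matters when the corpus is small.

Training appends each loop's first chord after its last (the wrap
transition), so that the model reflects looped listening. The information
content of a sequence e is I(e) = −log2 P(e); the per-chord IC of an
infinitely repeated loop reduces to I(e + e1)/ℓ, the IC of the sequence
extended by its first chord divided by the merged length ℓ.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .chords import ChordLoop, ChordSymbol, Mode

__all__ = [
    "ViewpointValue",
    "ViewpointModel",
    "SequenceIC",
    "viewpoint",
    "train",
    "merge_consecutive",
    "sequence_probability",
    "sequence_ic",
    "cyclic_average_ic",
]

logger = logging.getLogger(__name__)

_MODE_CODE = {Mode.MAJOR: "M", Mode.MINOR: "m"}


@dataclass(frozen=True, order=True)
class ViewpointValue:
    """Linked viewpoint value: root movement in fifths + mode shift.

    ``delta_fifths`` is next.root − prev.root on the line of fifths
    (+1 = perfect fifth up, +2 = major second up, −3 = minor third up);
    ``mode_pair`` is one of "MM", "Mm", "mM", "mm".
    """

    delta_fifths: int
    mode_pair: str

    def __post_init__(self) -> None:
        if self.mode_pair not in ("MM", "Mm", "mM", "mm"):
            raise ValueError(f"bad mode pair {self.mode_pair!r}")


def viewpoint(prev: ChordSymbol, next_: ChordSymbol) -> ViewpointValue:
    """Viewpoint value of a transition between two distinct chords."""
    if prev.root == next_.root and prev.mode == next_.mode:
        raise ValueError(f"self-transition {prev.token()} → {next_.token()} is undefined")
    return ViewpointValue(
        delta_fifths=next_.root_fifths - prev.root_fifths,
        mode_pair=_MODE_CODE[prev.mode] + _MODE_CODE[next_.mode],
    )


def merge_consecutive(chords: Sequence[ChordSymbol]) -> list[ChordSymbol]:
    """Collapse consecutive duplicate chords (the merged representation on
    which probabilities are defined — the corpus has no self-transitions)."""
    merged: list[ChordSymbol] = []
    for c in chords:
        if not merged or merged[-1] != c:
            merged.append(c)
    return merged


class ViewpointModel:
    """First-order transition distribution over viewpoint values.

    Unsmoothed by default: the generator only ever traverses observed
    values. For scoring arbitrary sequences, ``laplace_alphabet`` switches
    on add-one smoothing over a declared alphabet of viewpoint values
    (the union of the alphabet and the observed support).
    """

    def __init__(
        self,
        counts: Mapping[ViewpointValue, int],
        laplace_alphabet: Iterable[ViewpointValue] | None = None,
    ) -> None:
        self.counts: dict[ViewpointValue, int] = {
            v: int(n) for v, n in counts.items() if n > 0
        }
        if any(n < 0 for n in counts.values()):
            raise ValueError("negative transition count")
        self._total = sum(self.counts.values())
        self._alphabet: frozenset[ViewpointValue] | None = None
        if laplace_alphabet is not None:
            self._alphabet = frozenset(laplace_alphabet) | frozenset(self.counts)

    @property
    def support(self) -> frozenset[ViewpointValue]:
        return frozenset(self.counts)

    @property
    def smoothed(self) -> bool:
        return self._alphabet is not None

    def probability(self, value: ViewpointValue) -> float:
        """P(viewpoint value); 0 outside the support unless smoothed."""
        if self._alphabet is not None:
            if value not in self._alphabet:
                return 0.0
            return (self.counts.get(value, 0) + 1) / (self._total + len(self._alphabet))
        if self._total == 0:
            return 0.0
        return self.counts.get(value, 0) / self._total

    @property
    def probabilities(self) -> dict[ViewpointValue, float]:
        if self._alphabet is not None:
            return {v: self.probability(v) for v in sorted(self._alphabet)}
        return {v: self.probability(v) for v in sorted(self.counts)}

    def with_laplace(self, alphabet: Iterable[ViewpointValue]) -> "ViewpointModel":
        return ViewpointModel(self.counts, laplace_alphabet=alphabet)

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        lines = ["# delta_fifths\tmode_pair\tcount\tprobability"]
        for v in sorted(self.counts):
            lines.append(
                f"{v.delta_fifths}\t{v.mode_pair}\t{self.counts[v]}\t{self.probability(v):.12g}"
            )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ViewpointModel":
        counts: dict[ViewpointValue, int] = {}
        for ln in Path(path).read_text(encoding="utf-8").splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            dk, pair, n, _prob = ln.split("\t")
            counts[ViewpointValue(int(dk), pair)] = int(n)
        return cls(counts)


def _loop_transitions(chords: Sequence[ChordSymbol]) -> list[ViewpointValue]:
    """Viewpoint values of a loop's transitions including the wrap
    (last → first), mirroring the loop-effect augmentation used in training."""
    cyc = list(chords) + [chords[0]]
    return [viewpoint(a, b) for a, b in zip(cyc, cyc[1:])]


def train(loops: Iterable[ChordLoop]) -> ViewpointModel:
    """Train the first-order viewpoint model from a loop corpus.

    Each loop contributes its internal transitions plus the wrap transition
    from its last chord back to its first. Loops that collapse to a single
    chord after duplicate merging carry no transition and are skipped.
    """
    counts: dict[ViewpointValue, int] = {}
    for loop in loops:
        chords = merge_consecutive(loop.chords)
        if len(chords) > 1 and chords[0] == chords[-1]:
            chords = chords[:-1]  # seam duplicate would make an undefined wrap
        if len(chords) < 2:
            logger.warning(
                "skipping loop %r: single chord after merging, no transitions",
                loop.title,
            )
            continue
        for v in _loop_transitions(chords):
            counts[v] = counts.get(v, 0) + 1
    return ViewpointModel(counts)


def sequence_probability(chords: Sequence[ChordSymbol], model: ViewpointModel) -> float:
    """Model probability of a chord sequence: the product of transition
    probabilities over the merged representation. Out-of-support → 0."""
    merged = merge_consecutive(chords)
    if len(merged) < 2:
        raise ValueError("need at least two distinct chords")
    p = 1.0
    for a, b in zip(merged, merged[1:]):
        p *= model.probability(viewpoint(a, b))
    return p


@dataclass(frozen=True)
class SequenceIC:
    """Information content of a (cyclic) chord sequence, in bits.

    ``reachable`` is False when some transition lies outside the model's
    support, making the IC infinite; callers must check it rather than rely
    on a large sentinel.
    """

    total_ic: float
    per_chord_ic: float
    length: int
    reachable: bool = True


def sequence_ic(chords: Sequence[ChordSymbol], model: ViewpointModel) -> SequenceIC:
    """I(e) = −log2 P(e) on the merged sequence (non-cyclic).

    Accumulated in log space, so long sequences whose probability underflows
    a float still get a finite IC.
    """
    merged = merge_consecutive(chords)
    if len(merged) < 2:
        raise ValueError("need at least two distinct chords")
    total = 0.0
    for a, b in zip(merged, merged[1:]):
        p = model.probability(viewpoint(a, b))
        if p == 0.0:
            return SequenceIC(math.inf, math.inf, len(merged), reachable=False)
        total -= math.log2(p)
    return SequenceIC(total, total / len(merged), len(merged))


def cyclic_average_ic(chords: Sequence[ChordSymbol], model: ViewpointModel) -> SequenceIC:
    """Per-chord information content of the loop in the infinite-repetition
    limit: I(e + e1)/ℓ, the IC of the merged sequence extended by its first
    chord, divided by the merged length ℓ."""
    merged = merge_consecutive(chords)
    if len(merged) > 1 and merged[0] == merged[-1]:
        merged = merged[:-1]  # seam duplicate: the wrap is already explicit
    if len(merged) < 2:
        raise ValueError("need at least two distinct chords in the loop")
    ell = len(merged)
    total = 0.0
    for v in _loop_transitions(merged):
        p = model.probability(v)
        if p == 0.0:
            return SequenceIC(math.inf, math.inf, ell, reachable=False)
        total -= math.log2(p)
    return SequenceIC(total, total / ell, ell)
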