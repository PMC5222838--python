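"""Spelled chord symbols, the line of fifths, and the chord-loop corpus dialect.

Chords are *spelled*: C♯ and D♭ are distinct objects. All interval
arithmetic happens on the line of fifths (…, B♭=−2, F=−1, C=0, G=+1,
D=+2, …), the integer coordinate that also drives the spiral-array helix.
Chord quality is reduced to major/minor; an optional bass note records
inversions but plays no role in the statistical or tension models.

The corpus dialect is a plain-text file of blank-line-separated records::

    <title>
    <artist>
    <chord>:<duration-in-bars>
    ...

where a chord token is ``<root>[m][/bass]``, e.g. ``Dm``, ``F``, ``G/B``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Mode",
    "ChordSymbol",
    "ChordLoop",
    "CorpusSummary",
    "ChordParseError",
    "parse_pitch",
    "parse_chord",
    "fifths_index",
    "pitch_name",
    "read_corpus",
    "write_corpus",
    "corpus_summary",
    "is_tonally_consistent",
    "major_key_triads",
    "harmonic_minor_triads",
]

# Natural letters on the line of fifths, C = 0.
_LETTER_FIFTHS = {"F": -1, "C": 0, "G": 1, "D": 2, "A": 3, "E": 4, "B": 5}
_FIFTHS_LETTER = {v: k for k, v in _LETTER_FIFTHS.items()}

_SHARPS = "♯#"
_FLATS = "♭b"

_MAX_ACCIDENTALS = 2


class ChordParseError(ValueError):
    """Raised for malformed chord tokens or corpus records."""


class Mode(str, Enum):
    MAJOR = "major"
    MINOR = "minor"


def parse_pitch(text: str) -> tuple[str, int]:
    """Parse a spelled pitch class into (letter, accidental count).

    Accidentals: positive = sharps, negative = flats; at most two.
    Both unicode (♯/♭) and ASCII (#/b) accidentals are accepted.
    """
    if not text:
        raise ChordParseError("empty pitch token")
    letter = text[0].upper()
    if letter not in _LETTER_FIFTHS:
        raise ChordParseError(f"pitch letter {text[0]!r} outside A–G in {text!r}")
    acc = 0
    for ch in text[1:]:
        if ch in _SHARPS:
            if acc < 0:
                raise ChordParseError(f"mixed accidentals in {text!r}")
            acc += 1
        elif ch in _FLATS:
            if acc > 0:
                raise ChordParseError(f"mixed accidentals in {text!r}")
            acc -= 1
        else:
            raise ChordParseError(f"unexpected character {ch!r} in pitch {text!r}")
    if abs(acc) > _MAX_ACCIDENTALS:
        raise ChordParseError(f"more than {_MAX_ACCIDENTALS} accidentals in {text!r}")
    return letter, acc


def fifths_index(pitch: str | tuple[str, int]) -> int:
    """Line-of-fifths index of a spelled pitch class (C=0, G=+1, F=−1, …).

    Each sharp adds 7, each flat subtracts 7 from the natural letter's index,
    so the mapping is a bijection between supported spellings and integers.
    """
    letter, acc = parse_pitch(pitch) if isinstance(pitch, str) else pitch
    return _LETTER_FIFTHS[letter] + 7 * acc


def pitch_name(k: int, unicode_accidentals: bool = False) -> str:
    """Spelled pitch-class name for a line-of-fifths index (inverse of
    :func:`fifths_index`); supports at most two accidentals (k in −15..+19).
    """
    for acc in (0, 1, -1, 2, -2):
        base = k - 7 * acc
        if base in _FIFTHS_LETTER:
            letter = _FIFTHS_LETTER[base]
            if unicode_accidentals:
                return letter + ("♯" * acc if acc > 0 else "♭" * -acc)
            return letter + ("#" * acc if acc > 0 else "b" * -acc)
    raise ValueError(f"fifths index {k} outside the supported accidental range")


_CHORD_RE = re.compile(
    r"^(?P<root>[A-Ga-g][♯#♭b]*)(?P<minor>m)?(?:/(?P<bass>[A-Ga-g][♯#♭b]*))?$"
)


@dataclass(frozen=True, order=True)
class ChordSymbol:
    """A chord reduced to a spelled root and major/minor quality.

    ``bass`` marks an inversion; it is preserved through parsing and
    serialization but ignored by every analytic model (triads only).
    """

    root: str
    mode: Mode
    bass: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "root", _canonical_pitch(self.root))
        if self.bass is not None:
            object.__setattr__(self, "bass", _canonical_pitch(self.bass))

    @property
    def root_fifths(self) -> int:
        return fifths_index(self.root)

    @property
    def is_minor(self) -> bool:
        return self.mode is Mode.MINOR

    def token(self) -> str:
        """Canonical chord token: ``<root>[m][/bass]`` with ASCII accidentals."""
        out = self.root + ("m" if self.mode is Mode.MINOR else "")
        if self.bass is not None:
            out += "/" + self.bass
        return out

    def transposed(self, delta_fifths: int) -> "ChordSymbol":
        """The same chord moved ``delta_fifths`` steps along the line of fifths."""
        bass = None
        if self.bass is not None:
            bass = pitch_name(fifths_index(self.bass) + delta_fifths)
        return ChordSymbol(pitch_name(self.root_fifths + delta_fifths), self.mode, bass)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


def _canonical_pitch(text: str) -> str:
    letter, acc = parse_pitch(text)
    return letter + ("#" * acc if acc > 0 else "b" * -acc)


def parse_chord(text: str) -> ChordSymbol:
    """Parse a chord token of the form ``<root>[m][/bass]``.

    A trailing ``m`` marks a minor triad; anything else is major.
    """
    m = _CHORD_RE.match(text.strip())
    if m is None:
        raise ChordParseError(f"malformed chord token {text!r}")
    mode = Mode.MINOR if m.group("minor") else Mode.MAJOR
    return ChordSymbol(_canonical_pitch(m.group("root")), mode, bass=m.group("bass"))


@dataclass
class ChordLoop:
    """A duration-annotated cyclic chord sequence — one corpus record.

    Consecutive duplicate chords are merged on construction (durations
    summed); the loop seam (last == first) is merged only when
    ``merge_seam`` is set, since seam handling must be explicit.
    """

    title: str
    artist: str
    events: list[tuple[ChordSymbol, int]]

    def __init__(
        self,
        title: str,
        artist: str,
        events: Iterable[tuple[ChordSymbol, int]],
        merge_seam: bool = False,
    ) -> None:
        self.title = title
        self.artist = artist
        merged: list[tuple[ChordSymbol, int]] = []
        for chord, dur in events:
            if dur < 1 or int(dur) != dur:
                raise ValueError(
                    f"duration must be a positive integer number of bars, got {dur!r}"
                )
            if merged and merged[-1][0] == chord:
                merged[-1] = (chord, merged[-1][1] + int(dur))
            else:
                merged.append((chord, int(dur)))
        if merge_seam and len(merged) > 1 and merged[0][0] == merged[-1][0]:
            chord, dur = merged.pop()
            merged[0] = (chord, merged[0][1] + dur)
        self.events = merged

    @property
    def chords(self) -> list[ChordSymbol]:
        return [c for c, _ in self.events]

    @property
    def durations(self) -> list[int]:
        return [d for _, d in self.events]

    def n_chords(self) -> int:
        return len(self.events)

    def transposed(self, delta_fifths: int) -> "ChordLoop":
        return ChordLoop(
            self.title,
            self.artist,
            [(c.transposed(delta_fifths), d) for c, d in self.events],
        )


def read_corpus(path: str | Path, merge_seam: bool = False) -> list[ChordLoop]:
    """Read a chord-loop corpus file (blank-line-separated records).

    Consecutive duplicate chords within a record are merged, summing
    durations; record order is preserved.
    """
    text = Path(path).read_text(encoding="utf-8")
    loops: list[ChordLoop] = []
    records = [r for r in re.split(r"\n\s*\n", text) if r.strip()]
    for idx, record in enumerate(records):
        lines = [ln.strip() for ln in record.strip().splitlines() if ln.strip()]
        if len(lines) < 3:
            raise ChordParseError(
                f"record {idx}: expected title, artist and at least one chord line"
            )
        title, artist = lines[0], lines[1]
        events: list[tuple[ChordSymbol, int]] = []
        for ln in lines[2:]:
            if ":" not in ln:
                raise ChordParseError(f"record {idx} ({title!r}): missing ':' in {ln!r}")
            tok, dur_text = ln.rsplit(":", 1)
            try:
                dur = int(dur_text)
            except ValueError:
                raise ChordParseError(
                    f"record {idx} ({title!r}): bad duration {dur_text!r}"
                ) from None
            if dur <= 0:
                raise ChordParseError(
                    f"record {idx} ({title!r}): duration must be positive, got {dur}"
                )
            try:
                chord = parse_chord(tok)
            except ChordParseError as exc:
                raise ChordParseError(f"record {idx} ({title!r}): {exc}") from None
            events.append((chord, dur))
        loops.append(ChordLoop(title, artist, events, merge_seam=merge_seam))
    return loops


def write_corpus(loops: Sequence[ChordLoop], path: str | Path) -> None:
    """Serialize loops back to the corpus dialect."""
    blocks = []
    for loop in loops:
        lines = [loop.title, loop.artist]
        lines += [f"{c.token()}:{d}" for c, d in loop.events]
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n", encoding="utf-8")


# --- tonal consistency -----------------------------------------------------

def major_key_triads(tonic_fifths: int) -> frozenset[ChordSymbol]:
    """The six major/minor triads diatonic to a major key with the given
    tonic (the diminished vii° is excluded — it cannot occur in a
    major/minor-reduced corpus)."""
    t = tonic_fifths
    majors = [ChordSymbol(pitch_name(k), Mode.MAJOR) for k in (t - 1, t, t + 1)]
    minors = [ChordSymbol(pitch_name(k), Mode.MINOR) for k in (t + 2, t + 3, t + 4)]
    return frozenset(majors + minors)


def harmonic_minor_triads(tonic_fifths: int) -> frozenset[ChordSymbol]:
    """Major/minor triads of the harmonic-minor scale on the given (minor)
    tonic: i, iv, V, VI. The augmented III⁺ and the two diminished triads
    have no major/minor reduction and are excluded."""
    t = tonic_fifths
    minors = [ChordSymbol(pitch_name(k), Mode.MINOR) for k in (t, t - 1)]
    majors = [ChordSymbol(pitch_name(k), Mode.MAJOR) for k in (t + 1, t - 4)]
    return frozenset(minors + majors)


def is_tonally_consistent(loop: ChordLoop) -> bool:
    """True iff all chords of the loop fit a single diatonic major key or a
    single harmonic-minor key.

    Keys are scanned over a tonic window around the loop's own roots, which
    covers every spelled key that could possibly contain them.
    """
    chords = {ChordSymbol(c.root, c.mode) for c in loop.chords}
    ks = [c.root_fifths for c in chords]
    # any key containing a chord has its tonic within 4 fifths of that root;
    # tonics are clamped so derived triads stay within the spellable range
    for t in range(max(min(ks) - 4, -11), min(max(ks) + 4, 15) + 1):
        if chords <= major_key_triads(t) or chords <= harmonic_minor_triads(t):
            return True
    return False


@dataclass(frozen=True)
class CorpusSummary:
    n_loops: int
    n_chords: int
    minor_fraction: float
    tonal_consistency_fraction: float


def corpus_summary(loops: Sequence[ChordLoop]) -> CorpusSummary:
    """Headline corpus statistics: chord count, minor-chord fraction and the
    fraction of loops whose chords all fit one key."""
    if not loops:
        raise ValueError("corpus is empty")
    n_chords = sum(loop.n_chords() for loop in loops)
    n_minor = sum(1 for loop in loops for c in loop.chords if c.is_minor)
    n_consistent = sum(1 for loop in loops if is_tonally_consistent(loop))
    return CorpusSummary(
        n_loops=len(loops),
        n_chords=n_chords,
        minor_fraction=n_minor / n_chords,
        tonal_consistency_fraction=n_consistent / len(loops),
    )
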