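"""Standard MIDI File rendering of generated stimuli.

A packaged synthetic template — an arpeggiated 16th-note line, a sustained
pad and a bass, arranged in eight two-bar chord regions — stands in for a
produced anthem project. Rendering a stimulus re-pitches every template
note so that its *harmonic function* (root, third or fifth of the region's
chord) is preserved under the stimulus chord, in the octave closest to the
original pitch (ties resolve downward). Rhythm, velocities and track
structure are untouched, so two renders differ only in pitch bytes.

This module works in 12-TET pitch classes (enharmonic equality), unlike the
spelled-pitch analytic layer; the boundary is the chord → pitch-class
projection. The SMF codec covers exactly what the renderer needs: format 1,
tempo/time-signature/track-name metadata and note on/off events.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

from .chords import ChordSymbol, parse_chord, parse_pitch
from .generation import GeneratedStimulus

__all__ = [
    "NoteEvent",
    "MidiTrack",
    "Template",
    "classify_function",
    "snap_to_chord",
    "retarget_note",
    "render",
    "build_template",
    "write_smf",
    "read_smf",
]

PPQ = 480
TICKS_PER_BAR = 4 * PPQ  # 4/4 throughout
REGION_BARS = 2
REGION_TICKS = REGION_BARS * TICKS_PER_BAR
N_REGIONS = 8

_LETTER_SEMITONES = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}


def _pitch_class(pitch: str) -> int:
    letter, acc = parse_pitch(pitch)
    return (_LETTER_SEMITONES[letter] + acc) % 12


def triad_pitch_classes(chord: ChordSymbol) -> dict[str, int]:
    """12-TET pitch classes of a triad keyed by harmonic function."""
    root = _pitch_class(chord.root)
    third = (root + (3 if chord.is_minor else 4)) % 12
    return {"root": root, "third": third, "fifth": (root + 7) % 12}


@dataclass(frozen=True)
class NoteEvent:
    """One note: onset/duration in ticks, MIDI pitch, track index."""

    onset: int
    duration: int
    pitch: int
    track: int = 0
    velocity: int = 96
    harmonic_function: str | None = None

    def __post_init__(self) -> None:
        if self.onset < 0 or self.duration <= 0:
            raise ValueError("onset must be >= 0 and duration > 0")
        if not (0 <= self.pitch <= 127):
            raise ValueError(f"pitch {self.pitch} outside 0–127")


@dataclass
class MidiTrack:
    name: str
    channel: int
    notes: list[NoteEvent]


@dataclass
class Template:
    """An in-memory MIDI arrangement with chord-region annotations."""

    tracks: list[MidiTrack]
    region_chords: list[ChordSymbol]
    ppq: int = PPQ
    tempo_bpm: float = 138.0

    def __post_init__(self) -> None:
        if len(self.region_chords) != N_REGIONS:
            raise ValueError(
                f"template must annotate exactly {N_REGIONS} chord regions, "
                f"got {len(self.region_chords)}"
            )


def classify_function(pitch: int, chord: ChordSymbol) -> str:
    """"root"/"third"/"fifth" of the chord, or "nonchord"."""
    pc = pitch % 12
    for fn, chord_pc in triad_pitch_classes(chord).items():
        if pc == chord_pc:
            return fn
    return "nonchord"


def _nearest_with_pc(pitch: int, pc: int) -> int:
    """The pitch with the given pitch class nearest to ``pitch`` (tie →
    downward); always within 6 semitones."""
    best = None
    for candidate in range(pc, 128, 12):
        delta = abs(candidate - pitch)
        if best is None or delta < best[0] or (delta == best[0] and candidate < best[1]):
            best = (delta, candidate)
    assert best is not None
    return best[1]


def snap_to_chord(pitch: int, chord: ChordSymbol) -> int:
    """Move a non-chord pitch to the closest chord tone (tie → downward)."""
    cands = [_nearest_with_pc(pitch, pc) for pc in triad_pitch_classes(chord).values()]
    return min(cands, key=lambda c: (abs(c - pitch), c))


def retarget_note(note: NoteEvent, from_chord: ChordSymbol, to_chord: ChordSymbol) -> NoteEvent:
    """Re-pitch a note so its harmonic function is conserved under the new
    chord, in the octave minimizing the pitch change (tie → downward)."""
    fn = classify_function(note.pitch, from_chord)
    if fn == "nonchord":
        raise ValueError(
            f"pitch {note.pitch} is not a chord tone of {from_chord.token()}; "
            "snap non-chord notes before retargeting"
        )
    target_pc = triad_pitch_classes(to_chord)[fn]
    new_pitch = _nearest_with_pc(note.pitch, target_pc)
    return replace(note, pitch=new_pitch, harmonic_function=fn)


def render(stimulus: GeneratedStimulus, template: Template) -> Template:
    """Re-pitch the whole template under a stimulus's 8-region chord
    sequence. Non-chord notes are first snapped to the template chord, so
    every note has an unambiguous function; onsets, durations, velocities
    and track structure are untouched."""
    if len(stimulus.chords) != N_REGIONS:
        raise ValueError("stimulus must have exactly 8 chord slots")
    new_tracks = []
    for track in template.tracks:
        new_notes = []
        for note in track.notes:
            region = note.onset // REGION_TICKS
            if region >= N_REGIONS:
                raise ValueError(
                    f"note at tick {note.onset} lies beyond the {N_REGIONS}-region grid"
                )
            from_chord = template.region_chords[region]
            if classify_function(note.pitch, from_chord) == "nonchord":
                note = replace(note, pitch=snap_to_chord(note.pitch, from_chord))
            new_notes.append(retarget_note(note, from_chord, stimulus.chords[region]))
        new_tracks.append(MidiTrack(track.name, track.channel, new_notes))
    return Template(
        tracks=new_tracks,
        region_chords=list(stimulus.chords),
        ppq=template.ppq,
        tempo_bpm=template.tempo_bpm,
    )


# --- synthetic template ----------------------------------------------------

_DEFAULT_REGIONS = ("Dm", "F", "Am", "G", "Dm", "F", "Am", "G")


def build_template(region_chords: tuple[str, ...] = _DEFAULT_REGIONS) -> Template:
    """The packaged synthetic anthem template: bass (quarter-note roots),
    pad (sustained triads) and a 16th-note arpeggio, over eight two-bar
    regions at 138 BPM."""
    chords = [parse_chord(tok) for tok in region_chords]
    if len(chords) != N_REGIONS:
        raise ValueError(f"template needs {N_REGIONS} region chords")
    bass: list[NoteEvent] = []
    pad: list[NoteEvent] = []
    arp: list[NoteEvent] = []
    sixteenth = PPQ // 4
    for i, chord in enumerate(chords):
        start = i * REGION_TICKS
        pcs = triad_pitch_classes(chord)
        bass_pitch = 36 + pcs["root"]
        for q in range(REGION_BARS * 4):
            bass.append(NoteEvent(start + q * PPQ, PPQ, bass_pitch, track=1, velocity=100))
        for fn in ("root", "third", "fifth"):
            pad.append(NoteEvent(start, REGION_TICKS, 60 + pcs[fn], track=2, velocity=72))
        cycle = ("root", "fifth", "third", "fifth")
        for s in range(REGION_BARS * 16):
            pitch = 72 + pcs[cycle[s % 4]]
            arp.append(NoteEvent(start + s * sixteenth, sixteenth, pitch, track=3, velocity=88))
    return Template(
        tracks=[
            MidiTrack("bass", 0, bass),
            MidiTrack("pad", 1, pad),
            MidiTrack("arp", 2, arp),
        ],
        region_chords=chords,
    )


# --- SMF codec -------------------------------------------------------------

def _vlq(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(out))


def _track_chunk(events: list[tuple[int, bytes]]) -> bytes:
    """Events are (absolute tick, message bytes); stable-sorted by tick."""
    events = sorted(events, key=lambda e: e[0])
    data = bytearray()
    tick = 0
    for at, msg in events:
        data += _vlq(at - tick) + msg
        tick = at
    data += _vlq(0) + b"\xff\x2f\x00"  # end of track
    return b"MTrk" + struct.pack(">I", len(data)) + bytes(data)


def write_smf(template: Template, path: str | Path) -> None:
    """Write a format-1 Standard MIDI File (tempo track + one chunk per
    template track)."""
    chunks = []
    tempo = round(60_000_000 / template.tempo_bpm)
    meta: list[tuple[int, bytes]] = [
        (0, b"\xff\x58\x04\x04\x02\x18\x08"),  # 4/4
        (0, b"\xff\x51\x03" + tempo.to_bytes(3, "big")),
    ]
    chunks.append(_track_chunk(meta))
    for track in template.tracks:
        name = track.name.encode("ascii", "replace")
        events: list[tuple[int, bytes]] = [(0, b"\xff\x03" + _vlq(len(name)) + name)]
        status_on = 0x90 | (track.channel & 0x0F)
        status_off = 0x80 | (track.channel & 0x0F)
        for note in track.notes:
            events.append((note.onset, bytes([status_on, note.pitch, note.velocity])))
            events.append((note.onset + note.duration, bytes([status_off, note.pitch, 0])))
        chunks.append(_track_chunk(events))
    header = b"MThd" + struct.pack(">IHHH", 6, 1, len(chunks), template.ppq)
    Path(path).write_bytes(header + b"".join(chunks))


def read_smf(path: str | Path) -> Template:
    """Read a format-0/1 SMF produced by :func:`write_smf` (note on/off,
    tempo, track names; other events are skipped). Region chords are not
    recoverable from MIDI and are left as the default annotation."""
    data = Path(path).read_bytes()
    if data[:4] != b"MThd":
        raise ValueError("not a Standard MIDI File")
    _, fmt, ntrks, ppq = struct.unpack(">IHHH", data[4:14])
    pos = 14
    tempo_bpm = 120.0
    tracks: list[MidiTrack] = []
    for _ in range(ntrks):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError("bad track chunk")
        (length,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        chunk = data[pos + 8 : pos + 8 + length]
        pos += 8 + length
        notes, name, channel, tempo = _parse_track(chunk)
        if tempo is not None:
            tempo_bpm = 60_000_000 / tempo
        if notes:
            tracks.append(MidiTrack(name or f"track{len(tracks)}", channel, notes))
    for i, t in enumerate(tracks):
        t.notes = [replace(n, track=i + 1) for n in t.notes]
    return Template(
        tracks=tracks,
        region_chords=[parse_chord(tok) for tok in _DEFAULT_REGIONS],
        ppq=ppq,
        tempo_bpm=tempo_bpm,
    )


def _parse_track(chunk: bytes):
    i = 0
    tick = 0
    running = 0
    name = None
    channel = 0
    tempo = None
    open_notes: dict[int, list[tuple[int, int]]] = {}
    notes: list[NoteEvent] = []

    def read_vlq() -> int:
        nonlocal i
        v = 0
        while True:
            b = chunk[i]
            i += 1
            v = (v << 7) | (b & 0x7F)
            if not b & 0x80:
                return v

    while i < len(chunk):
        tick += read_vlq()
        status = chunk[i]
        if status & 0x80:
            i += 1
            running = status
        else:
            status = running
        if status == 0xFF:
            mtype = chunk[i]
            i += 1
            ln = read_vlq()
            payload = chunk[i : i + ln]
            i += ln
            if mtype == 0x03:
                name = payload.decode("ascii", "replace")
            elif mtype == 0x51:
                tempo = int.from_bytes(payload, "big")
        elif status in (0xF0, 0xF7):
            ln = read_vlq()
            i += ln
        else:
            kind = status & 0xF0
            channel = status & 0x0F
            if kind in (0x80, 0x90):
                pitch, vel = chunk[i], chunk[i + 1]
                i += 2
                if kind == 0x90 and vel > 0:
                    open_notes.setdefault(pitch, []).append((tick, vel))
                else:
                    if open_notes.get(pitch):
                        onset, vel_on = open_notes[pitch].pop(0)
                        notes.append(
                            NoteEvent(onset, tick - onset, pitch, velocity=vel_on)
                        )
            elif kind in (0xC0, 0xD0):
                i += 1
            else:
                i += 2
    notes.sort(key=lambda n: (n.onset, n.pitch))
    return notes, name, channel, tempo
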