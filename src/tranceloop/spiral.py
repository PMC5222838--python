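"""Spiral-array pitch helix and the Cloud Momentum tension measure.

Spelled pitch classes sit on a helix indexed by the line of fifths k:

    position(k) = (r·sin(kπ/2), r·cos(kπ/2), k·h)

so neighbours on the line of fifths are a quarter turn apart and a major
third (Δk = 4) lies directly above its root at height 4h. With the standard
calibration r = 1, h = √(2/15), tonal proximity becomes geometric
proximity. A chord is a *cloud* of the three triad points; its *center of
effect* (ce) is the cloud's geometric center. Cloud Momentum — the
Euclidean distance between the ces of two successive chords — is the
movement-in-tonal-space proxy for perceived tension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chords import ChordSymbol

__all__ = [
    "SpiralConfig",
    "pitch_position",
    "chord_cloud",
    "center_of_effect",
    "cloud_momentum",
    "average_cloud_momentum",
]

# Standard source-model weights (root, fifth, third) behind the optional
# weighted-ce switch; the default ce is the unweighted mean.
_STANDARD_WEIGHTS = (0.536, 0.274, 0.19)


@dataclass(frozen=True)
class SpiralConfig:
    """Helix calibration: radius ``r`` and rise per fifth ``h``.

    ``weighted_ce`` switches the center of effect from the unweighted mean
    (the default — all stimulus chords last equally long) to the source
    model's root/fifth/third weighting, for sensitivity analysis.
    """

    r: float = 1.0
    h: float = math.sqrt(2.0 / 15.0)
    weighted_ce: bool = False

    def __post_init__(self) -> None:
        if self.r <= 0 or self.h <= 0:
            raise ValueError("spiral radius and rise must be positive")


def pitch_position(k: int, cfg: SpiralConfig = SpiralConfig()) -> np.ndarray:
    """3D helix position of the spelled pitch class with fifths index k."""
    angle = k * math.pi / 2.0
    return np.array([cfg.r * math.sin(angle), cfg.r * math.cos(angle), k * cfg.h])


def _triad_fifths(chord: ChordSymbol) -> tuple[int, int, int]:
    """Fifths indices of (root, fifth, third) in spelled space: the fifth is
    one step up; the third is +4 (major) or −3 (minor)."""
    k = chord.root_fifths
    third = k + 4 if not chord.is_minor else k - 3
    return k, k + 1, third


def chord_cloud(chord: ChordSymbol, cfg: SpiralConfig = SpiralConfig()) -> np.ndarray:
    """The 3×3 array of helix points of a triad (root, fifth, third rows)."""
    return np.array([pitch_position(k, cfg) for k in _triad_fifths(chord)])


def center_of_effect(chord: ChordSymbol, cfg: SpiralConfig = SpiralConfig()) -> np.ndarray:
    """The ce of a chord's cloud: its geometric (or optionally weighted) center."""
    cloud = chord_cloud(chord, cfg)
    if cfg.weighted_ce:
        w = np.array(_STANDARD_WEIGHTS)
        return (w[:, None] * cloud).sum(axis=0) / w.sum()
    return cloud.mean(axis=0)


def cloud_momentum(
    c1: ChordSymbol, c2: ChordSymbol, cfg: SpiralConfig = SpiralConfig()
) -> float:
    """Euclidean distance between the ces of two chords (0 iff the spelled
    triads are identical)."""
    return float(np.linalg.norm(center_of_effect(c1, cfg) - center_of_effect(c2, cfg)))


def average_cloud_momentum(
    chords: Sequence[ChordSymbol],
    cfg: SpiralConfig = SpiralConfig(),
    cyclic: bool = False,
    skip_identical: bool = False,
) -> float:
    """Mean Cloud Momentum over successive chord pairs of a stimulus.

    Identical-chord pairs contribute 0 by default (they encode the
    stimulus's repetitiveness); ``skip_identical`` drops them from the mean
    instead. ``cyclic`` adds the wrap pair (last → first).
    """
    pairs = list(zip(chords, chords[1:]))
    if cyclic and len(chords) > 1:
        pairs.append((chords[-1], chords[0]))
    if not pairs:
        raise ValueError("need at least two chords")
    dists = [cloud_momentum(a, b, cfg) for a, b in pairs]
    if skip_identical:
        dists = [d for a_b, d in zip(pairs, dists) if a_b[0] != a_b[1]]
        if not dists:
            return 0.0
    return float(np.mean(dists))
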