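"""Synthetic inputs: a corpus emulator and a Likert ratings simulator.

No chord-loop corpus or participant ratings are distributed with the study
this package models, so both are emulated with the statistical structure
the analysis assumes:

* ``simulate_corpus`` draws tonally coherent 4–8-chord loops by a
  no-immediate-repeat weighted walk over one key's triads, targeting the
  corpus-level summary statistics (≈39% minor chords, ≈96% of loops in a
  single key) by construction;
* ``simulate_ratings`` draws per-participant 7-point enjoyment ratings as
  a noisy concave quadratic (Wundt-shaped) — or purely linear, or null —
  function of a z-scored complexity covariate, then averages per stimulus.

Both are bit-reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chords import (
    ChordLoop,
    ChordSymbol,
    Mode,
    harmonic_minor_triads,
    is_tonally_consistent,
    major_key_triads,
    pitch_name,
)

__all__ = [
    "CorpusSimConfig",
    "RatingsSimConfig",
    "simulate_corpus",
    "simulate_ratings",
]


@dataclass(frozen=True)
class CorpusSimConfig:
    """Corpus emulation: loop count/lengths and the target summary mix."""

    n_loops: int = 100
    min_length: int = 4
    max_length: int = 8
    min_duration: int = 1
    max_duration: int = 2
    minor_fraction: float = 0.39
    consistency_fraction: float = 0.96
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.minor_fraction <= 1.0):
            raise ValueError("minor_fraction must be in [0, 1]")
        if not (0.0 <= self.consistency_fraction <= 1.0):
            raise ValueError("consistency_fraction must be in [0, 1]")
        if self.min_length < 2 or self.max_length < self.min_length:
            raise ValueError("bad loop length range")


def _key_triads(tonic: int, minor: bool) -> list[ChordSymbol]:
    # one strictly consistent collection per loop: mixing natural- and
    # harmonic-minor triads would break the single-key property
    if minor:
        return sorted(harmonic_minor_triads(tonic))
    return sorted(major_key_triads(tonic))


def _walk_in_key(
    triads: list[ChordSymbol], length: int, minor_w: float, rng: np.random.Generator
) -> list[ChordSymbol]:
    """No-immediate-repeat walk, minor triads weighted ``minor_w`` against
    (1 − minor_w) for major, so the chord-mode mix hits its target in
    expectation."""
    out: list[ChordSymbol] = []
    for _ in range(length):
        cands = [c for c in triads if not out or c != out[-1]]
        w = np.array([minor_w if c.is_minor else 1.0 - minor_w for c in cands])
        out.append(cands[int(rng.choice(len(cands), p=w / w.sum()))])
    return out


def simulate_corpus(cfg: CorpusSimConfig = CorpusSimConfig()) -> list[ChordLoop]:
    """Draw a synthetic chord-loop corpus.

    Each loop lives in one random key (major or minor, mixed to hit the
    minor-chord target); a ``1 − consistency_fraction`` share of loops then
    get one chord replaced by an out-of-key triad, verified to actually
    break single-key consistency.
    """
    rng = np.random.default_rng(cfg.seed)
    n_inconsistent = int(round(cfg.n_loops * (1.0 - cfg.consistency_fraction)))
    spoil = np.zeros(cfg.n_loops, dtype=bool)
    if n_inconsistent:
        spoil[rng.choice(cfg.n_loops, size=n_inconsistent, replace=False)] = True

    loops: list[ChordLoop] = []
    for i in range(cfg.n_loops):
        tonic = int(rng.integers(-2, 6))  # spelled keys around the trance staples
        in_minor_key = bool(rng.random() < cfg.minor_fraction)
        triads = _key_triads(tonic, in_minor_key)
        length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        chords = _walk_in_key(triads, length, cfg.minor_fraction, rng)
        if spoil[i]:
            chords = _spoil(chords, rng)
        durations = rng.integers(cfg.min_duration, cfg.max_duration + 1, size=length)
        key_name = pitch_name(tonic) + ("m" if in_minor_key else "")
        loops.append(
            ChordLoop(
                title=f"Synthetic Anthem {i + 1:03d} ({key_name})",
                artist="Corpus Simulator",
                events=list(zip(chords, (int(d) for d in durations))),
            )
        )
    return loops


def _spoil(chords: list[ChordSymbol], rng: np.random.Generator) -> list[ChordSymbol]:
    """Replace one chord by a tonally foreign triad until the loop no longer
    fits any single key."""
    idx = int(rng.integers(len(chords)))
    for shift in (6, -6, 7, -7, 8, -8):
        cand = chords[idx].transposed(shift)
        if idx > 0 and cand == chords[idx - 1]:
            continue
        if idx + 1 < len(chords) and cand == chords[idx + 1]:
            continue
        trial = chords[:idx] + [cand] + chords[idx + 1 :]
        if not is_tonally_consistent(ChordLoop("t", "a", [(c, 1) for c in trial])):
            return trial
    return chords  # pathological loop; leave untouched


@dataclass(frozen=True)
class RatingsSimConfig:
    """Enjoyment ratings model: rating = a + b·z − c·z² + ε on a 1–7 scale.

    z is the z-scored complexity covariate; c > 0 yields the Wundt
    (inverted-U) regime, c = 0 with b > 0 the linear regime, b = c = 0 the
    null. Per-participant ratings are clipped to [1, 7] and rounded to the
    Likert grid before averaging. Defaults are sized so that, with 20
    participants and 56 stimuli, the quadratic fit on mean ratings lands in
    a moderate-R² regime rather than a near-deterministic one.
    """

    a: float = 4.2
    b: float = 0.25
    c: float = 0.30
    noise_sd: float = 1.8
    n_participants: int = 20
    round_to_likert: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("c must be >= 0 (concave or flat quadratic)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")

    def linear_mode(self) -> "RatingsSimConfig":
        from dataclasses import replace

        return replace(self, c=0.0)

    def null_mode(self) -> "RatingsSimConfig":
        from dataclasses import replace

        return replace(self, b=0.0, c=0.0)


def simulate_ratings(
    features: pd.DataFrame,
    cfg: RatingsSimConfig = RatingsSimConfig(),
    covariate: str = "cyclic_ic",
    include_participants: bool = False,
) -> pd.DataFrame:
    """Simulate enjoyment ratings for a per-stimulus feature table.

    ``features`` needs a ``stimulus_id`` column and the covariate column.
    Returns one row per stimulus with the mean ``enjoyment`` (and, when
    requested, the per-participant rating columns ``p01`` …).
    """
    if covariate not in features.columns:
        raise KeyError(f"covariate column {covariate!r} missing from features")
    x = features[covariate].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("covariate must take at least two distinct values")
    rng = np.random.default_rng(cfg.seed)
    z = (x - x.mean()) / x.std(ddof=1)
    mu = cfg.a + cfg.b * z - cfg.c * z**2
    raw = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(len(x), cfg.n_participants))
    if cfg.round_to_likert:
        raw = np.rint(raw)
    ratings = np.clip(raw, 1, 7)

    out = features[["stimulus_id"]].copy()
    if "pattern" in features.columns:
        out["pattern"] = features["pattern"]
    out[covariate] = x
    out["enjoyment"] = ratings.mean(axis=1)
    if include_participants:
        for j in range(cfg.n_participants):
            out[f"p{j + 1:02d}"] = ratings[:, j]
    return out
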