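import numpy as np
import pytest
from hypothesis import settings

import tranceloop as tl

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from tranceloop.simulate import CorpusSimConfig, simulate_corpus

TABLE2_TOKENS = ["Dm:1", "F:1", "Am:2", "Dm:1", "F:1", "Am:1", "G:1"]


@pytest.fixture
def anthem_loop() -> tl.ChordLoop:
    """A real-style corpus record: seven events, one merged Am:2."""
    events = []
    for tok in TABLE2_TOKENS:
        chord, dur = tok.split(":")
        events.append((tl.parse_chord(chord), int(dur)))
    return tl.ChordLoop("Velocity in French", "Adam Ellis", events)


@pytest.fixture
def anthem_model(anthem_loop) -> tl.ViewpointModel:
    return tl.train([anthem_loop])


@pytest.fixture
def synthetic_corpus() -> list[tl.ChordLoop]:
    return simulate_corpus(CorpusSimConfig(seed=11))


@pytest.fixture
def trained_model(synthetic_corpus) -> tl.ViewpointModel:
    return tl.train(synthetic_corpus)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_loop(rng: np.random.Generator, length: int | None = None) -> tl.ChordLoop:
    """A random no-immediate-repeat loop over a 3-fifths-wide triad pool."""
    from tranceloop.chords import ChordSymbol, Mode, pitch_name

    pool = [
        ChordSymbol(pitch_name(k), mode)
        for k in range(-3, 4)
        for mode in (Mode.MAJOR, Mode.MINOR)
    ]
    n = length or int(rng.integers(3, 8))
    chords: list = []
    while len(chords) < n:
        c = pool[int(rng.integers(len(pool)))]
        if not chords or chords[-1] != c:
            chords.append(c)
    return tl.ChordLoop("random", "rng", [(c, int(rng.integers(1, 3))) for c in chords])
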