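"""Constrained random-walk generation and low-IC selection."""

import itertools

import numpy as np
import pytest

import tranceloop as tl
from tranceloop.generation import (
    GenerationConfig,
    GenerationError,
    chord_vocabulary,
    diatonic_collection,
    generate_for_pattern,
    generate_stimuli,
    random_walk,
)
from tranceloop.viewpoints import cyclic_average_ic, merge_consecutive, viewpoint


def _toy_model():
    """Model trained on the single loop D→G→Bm→A (plus wrap)."""
    loop = tl.ChordLoop("toy", "t", [(tl.parse_chord(c), 1) for c in ["D", "G", "Bm", "A"]])
    return tl.train([loop])


def test_single_variable_pattern_trivially_succeeds():
    pattern = tl.SemioticPattern(tuple("AAAAAAAA"))
    stim = random_walk(
        pattern, tl.parse_chord("D"), _toy_model(), GenerationConfig(), np.random.default_rng(0)
    )
    assert stim is not None
    assert all(c == tl.parse_chord("D") for c in stim.chords)
    assert stim.cyclic_ic == 0.0


def test_forced_binding_on_toy_model():
    stim = random_walk(
        tl.parse_pattern("ABCD-ABCD"),
        tl.parse_chord("D"),
        _toy_model(),
        GenerationConfig(),
        np.random.default_rng(1),
    )
    assert stim is not None
    assert [c.token() for c in stim.chords] == ["D", "G", "Bm", "A", "D", "G", "Bm", "A"]
    assert stim.binding == {
        "A": tl.parse_chord("D"),
        "B": tl.parse_chord("G"),
        "C": tl.parse_chord("Bm"),
        "D": tl.parse_chord("A"),
    }


def _assert_stimulus_invariants(stim, cfg):
    assert len(stim.chords) == 8
    # same label ⇒ same chord; distinct labels ⇒ distinct chords
    for label, chord in stim.binding.items():
        for slot_label, slot_chord in zip(stim.pattern.slots, stim.chords):
            if slot_label == label:
                assert slot_chord == chord
    bound = list(stim.binding.values())
    assert len(bound) == len(set(bound))
    assert stim.chords[0] in cfg.start_chords


def test_walk_successes_satisfy_invariants(trained_model, rng):
    cfg = GenerationConfig(iterations=50)
    for text in ("AABB-AABB", "ABCD-EFGH", "ABCD-BCDB"):
        pattern = tl.parse_pattern(text)
        for start in cfg.start_chords:
            for _ in range(20):
                stim = random_walk(pattern, start, trained_model, cfg, rng)
                if stim is not None:
                    _assert_stimulus_invariants(stim, cfg)
                    ic = cyclic_average_ic(stim.chords, trained_model)
                    assert ic.reachable
                    assert stim.cyclic_ic == pytest.approx(ic.per_chord_ic)


def test_diatonic_filter_keeps_one_collection(trained_model, rng):
    # patterns needing at most 4 distinct chords fit the key without fallback
    cfg = GenerationConfig(iterations=50, diatonic_only=True)
    pattern = tl.parse_pattern("AABB-AABB")
    for start in cfg.start_chords:
        collection = diatonic_collection(start)
        for _ in range(20):
            stim = random_walk(pattern, start, trained_model, cfg, rng)
            if stim is not None:
                assert set(stim.chords) <= collection


def test_generate_for_pattern_returns_two_per_key_class(trained_model):
    cfg = GenerationConfig(iterations=300, random_seed=5)
    stimuli = generate_for_pattern(tl.parse_pattern("ABCD-ABCD"), trained_model, cfg)
    assert len(stimuli) == 4
    assert sum(not s.start_chord.is_minor for s in stimuli) == 2
    assert sum(s.start_chord.is_minor for s in stimuli) == 2
    for a, b in (stimuli[:2], stimuli[2:]):
        assert a.cyclic_ic <= b.cyclic_ic
        assert a.slot_difference(b) > cfg.near_duplicate_threshold


def test_generation_is_deterministic(trained_model):
    cfg = GenerationConfig(iterations=100, random_seed=9)
    pats = [tl.parse_pattern("AABB-AACC"), tl.parse_pattern("ABCD-EFAB")]
    a = generate_stimuli(pats, trained_model, cfg)
    b = generate_stimuli(pats, trained_model, cfg)
    assert [s.chords for s in a] == [s.chords for s in b]
    c = generate_stimuli(pats, trained_model, GenerationConfig(iterations=100, random_seed=10))
    assert [s.chords for s in a] != [s.chords for s in c]


def _enumerate_optimum(pattern, start, model):
    """Exhaustive search over injective bindings for the lowest cyclic IC."""
    labels = [l for l in pattern.labels if l != pattern.slots[0]]
    vocab = chord_vocabulary()
    best = None
    for combo in itertools.permutations(vocab, len(labels)):
        binding = {pattern.slots[0]: start, **dict(zip(labels, combo))}
        if len(set(binding.values())) != len(binding):
            continue
        chords = [binding[l] for l in pattern.slots]
        merged = merge_consecutive(chords)
        if any(
            model.probability(viewpoint(a, b)) == 0.0 for a, b in zip(merged, merged[1:])
        ):
            continue
        ic = cyclic_average_ic(chords, model)
        if ic.reachable and (best is None or ic.per_chord_ic < best):
            best = ic.per_chord_ic
    return best


@pytest.mark.parametrize("text", ["AABB-AABB", "AABB-AACC"])
def test_selection_is_ic_minimal_against_enumeration(trained_model, text):
    start = tl.parse_chord("D")
    pattern = tl.parse_pattern(text)  # one or two free labels → tractable
    optimum = _enumerate_optimum(pattern, start, trained_model)
    assert optimum is not None
    cfg = GenerationConfig(iterations=800, random_seed=3, diatonic_only=False)
    rng = np.random.default_rng(cfg.random_seed)
    best_walk = None
    for _ in range(cfg.iterations):
        stim = random_walk(pattern, start, trained_model, cfg, rng)
        if stim is not None and (best_walk is None or stim.cyclic_ic < best_walk):
            best_walk = stim.cyclic_ic
    assert best_walk == pytest.approx(optimum)


def test_near_duplicate_rule_replaces_second(trained_model):
    # with a huge threshold no pair can qualify → the selection must fail
    cfg = GenerationConfig(iterations=200, random_seed=2, near_duplicate_threshold=8)
    with pytest.raises(GenerationError):
        generate_for_pattern(tl.parse_pattern("AABB-AABB"), trained_model, cfg)
    cfg_ok = GenerationConfig(iterations=200, random_seed=2, near_duplicate_threshold=1)
    stimuli = generate_for_pattern(tl.parse_pattern("AABB-AABB"), trained_model, cfg_ok)
    assert len(stimuli) == 4


def test_failure_never_returns_partial_sequence():
    # a model with no transitions from the start chord's key
    loop = tl.ChordLoop("far", "t", [(tl.parse_chord(c), 1) for c in ["C#", "G#m"]])
    model = tl.train([loop])
    stim = random_walk(
        tl.parse_pattern("ABCD-EFGH"),
        tl.parse_chord("D"),
        model,
        GenerationConfig(),
        np.random.default_rng(0),
    )
    # either a full 8-slot success or None — nothing in between
    assert stim is None or len(stim.chords) == 8


def test_vocabulary_covers_start_key_collections():
    vocab = set(chord_vocabulary())
    for start in GenerationConfig().start_chords:
        assert diatonic_collection(start) <= vocab
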