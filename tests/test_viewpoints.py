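"""Viewpoint abstraction, model training, and (cyclic) information content."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tranceloop as tl
from tranceloop.viewpoints import ViewpointValue, merge_consecutive, sequence_ic

C, G, D = tl.parse_chord("C"), tl.parse_chord("G"), tl.parse_chord("D")


@pytest.mark.parametrize(
    "prev, nxt, delta, pair",
    [
        ("C", "Dm", 2, "Mm"),     # major second up, major→minor
        ("D", "Dm", 0, "Mm"),     # same root, mode flip
        ("Am", "F", -4, "mM"),
        ("C", "G", 1, "MM"),
        ("Em", "Am", -1, "mm"),
    ],
)
def test_viewpoint_values(prev, nxt, delta, pair):
    v = tl.viewpoint(tl.parse_chord(prev), tl.parse_chord(nxt))
    assert (v.delta_fifths, v.mode_pair) == (delta, pair)


def test_self_transition_is_undefined():
    with pytest.raises(ValueError):
        tl.viewpoint(D, D)


def test_train_two_chord_loop():
    loop = tl.ChordLoop("t", "a", [(C, 1), (G, 1)])
    m = tl.train([loop])
    assert m.counts == {ViewpointValue(1, "MM"): 1, ViewpointValue(-1, "MM"): 1}
    assert m.probability(ViewpointValue(1, "MM")) == pytest.approx(0.5)


def test_train_anthem_loop_tallies(anthem_loop, anthem_model):
    # hand enumeration: Dm→F, F→Am, Am→Dm, Dm→F, F→Am, Am→G, wrap G→Dm
    expected = {
        ViewpointValue(-3, "mM"): 2,
        ViewpointValue(4, "Mm"): 2,
        ViewpointValue(-1, "mm"): 1,
        ViewpointValue(-2, "mM"): 1,
        ViewpointValue(1, "Mm"): 1,
    }
    assert anthem_model.counts == expected
    assert sum(anthem_model.probabilities.values()) == pytest.approx(1.0, abs=1e-12)


def test_single_chord_loop_is_skipped(caplog):
    loop = tl.ChordLoop("solo", "a", [(C, 2), (C, 2)])
    other = tl.ChordLoop("t", "a", [(C, 1), (G, 1)])
    with caplog.at_level("WARNING"):
        m = tl.train([loop, other])
    assert sum(m.counts.values()) == 2
    assert any("solo" in rec.message for rec in caplog.records)


@given(st.integers(min_value=-5, max_value=5), st.integers(min_value=0, max_value=2**32 - 1))
@settings(max_examples=25, deadline=None)
def test_transposition_invariance(shift, seed):
    import numpy as np
    from conftest import random_loop

    rng = np.random.default_rng(seed)
    loops = [random_loop(rng) for _ in range(5)]
    m1 = tl.train(loops)
    m2 = tl.train([l.transposed(shift) for l in loops])
    assert m1.counts == m2.counts


def test_sequence_probability(anthem_loop, anthem_model):
    # product over the 6 internal transitions: (2/7)^4 · (1/7)^2
    p = tl.sequence_probability(anthem_loop.chords, anthem_model)
    assert p == pytest.approx((2 / 7) ** 4 * (1 / 7) ** 2)
    # a sequence with an unobserved transition has probability zero
    assert tl.sequence_probability([C, tl.parse_chord("F#m")], anthem_model) == 0.0


def test_two_chord_probability_is_single_factor():
    m = tl.train([tl.ChordLoop("t", "a", [(C, 1), (G, 1)])])
    assert tl.sequence_probability([C, G], m) == pytest.approx(0.5)


def test_cyclic_ic_closed_form():
    m = tl.train([tl.ChordLoop("t", "a", [(C, 1), (G, 1)])])
    ic = tl.cyclic_average_ic([C, G], m)
    assert ic.per_chord_ic == pytest.approx(1.0)  # (−log2 0.25)/2
    assert ic.length == 2


def test_degenerate_model_gives_zero_ic():
    # a model assigning probability 1 to every transition of the loop
    degenerate = tl.ViewpointModel({ViewpointValue(1, "MM"): 1})
    ic = tl.cyclic_average_ic([C, G], degenerate)
    assert not ic.reachable  # wrap G→C is a fourth up, unobserved
    # non-cyclic IC of a probability-1 path is exactly zero
    assert sequence_ic([C, G, D], degenerate).total_ic == pytest.approx(0.0)


def test_unreachable_wrap_is_flagged_not_large(anthem_model):
    seq = [tl.parse_chord("Dm"), tl.parse_chord("F")]  # wrap F→Dm unobserved
    ic = tl.cyclic_average_ic(seq, anthem_model)
    assert not ic.reachable
    assert math.isinf(ic.per_chord_ic)


def _repeated_ic_oracle(chords, model, n, closed):
    """Left side of the infinite-repetition limit: the per-chord IC of the
    loop unrolled n times, optionally closed by appending the first chord."""
    merged = merge_consecutive(chords)
    if merged[0] == merged[-1]:
        merged = merged[:-1]
    unrolled = merged * n + (merged[:1] if closed else [])
    return sequence_ic(unrolled, model).total_ic / (len(merged) * n)


def test_cyclic_ic_matches_repetition_limit(anthem_loop, anthem_model, rng):
    from conftest import random_loop

    cases = [(anthem_loop.chords, anthem_model)]
    for _ in range(10):
        loops = [random_loop(rng) for _ in range(4)]
        model = tl.train(loops)
        ic = tl.cyclic_average_ic(loops[0].chords, model)
        if ic.reachable:
            cases.append((loops[0].chords, model))
    assert len(cases) > 3
    for chords, model in cases:
        limit = tl.cyclic_average_ic(chords, model).per_chord_ic
        # open unrolling approaches the limit monotonically, at rate 1/n
        errs = {n: abs(_repeated_ic_oracle(chords, model, n, closed=False) - limit)
                for n in (2, 10, 50)}
        assert errs[2] >= errs[10] >= errs[50]
        assert errs[2] * 2 == pytest.approx(errs[50] * 50, rel=1e-9)
        # cyclically closed unrolling matches the limit exactly at every n
        for n in (1, 7, 50):
            assert abs(_repeated_ic_oracle(chords, model, n, closed=True) - limit) < 1e-9


def test_duplicate_merge_does_not_change_ic(anthem_loop, anthem_model):
    chords = anthem_loop.chords
    padded = [chords[0]] + chords[:2] + [chords[1]] + chords[2:]
    assert (
        tl.cyclic_average_ic(padded, anthem_model).per_chord_ic
        == tl.cyclic_average_ic(chords, anthem_model).per_chord_ic
    )


def test_laplace_smoothing_covers_unseen_values():
    m = tl.train([tl.ChordLoop("t", "a", [(C, 1), (G, 1)])])
    alphabet = [ViewpointValue(1, "MM"), ViewpointValue(-1, "MM"), ViewpointValue(2, "Mm")]
    sm = m.with_laplace(alphabet)
    assert sm.probability(ViewpointValue(2, "Mm")) == pytest.approx(1 / 5)
    assert sm.probability(ViewpointValue(1, "MM")) == pytest.approx(2 / 5)
    assert sum(sm.probabilities.values()) == pytest.approx(1.0)
    assert sm.probability(ViewpointValue(9, "mm")) == 0.0


def test_model_roundtrips_through_text(tmp_path, anthem_model):
    path = tmp_path / "model.tsv"
    anthem_model.save(path)
    again = tl.ViewpointModel.load(path)
    assert again.counts == anthem_model.counts
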