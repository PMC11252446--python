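"""Calling-rule tests, including exhaustive-enumeration oracles."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from y1hnet.calling import (
    CallStatus,
    call_ey1h,
    call_py1h,
    compute_pair_indices,
    filter_autoactive,
    score_quad,
)
from y1hnet.model import QuadReadout
from y1hnet.simulate import WorldParams, generate_world


def quad(levels, tf="TF1", pid="P1", growth=True):
    return QuadReadout(tf, pid, tuple(levels), mated_growth=growth)


# --- quad consensus ----------------------------------------------------------


@pytest.mark.parametrize(
    "levels,uniform,consensus",
    [
        ((2, 2, 2, 0), True, 2),
        ((0, 0, 0, 0), True, 0),
        ((3, 3, 1, 1), False, None),  # 2-2 tie is conservatively non-uniform
        ((1, 2, 3, 0), False, None),
    ],
)
def test_score_quad_examples(levels, uniform, consensus):
    result = score_quad(quad(levels))
    assert result.uniform is uniform
    assert result.consensus_level == consensus


def test_score_quad_matches_enumeration_oracle():
    """Exactly the 4-tuples with a level of multiplicity >= 3 are uniform."""
    for levels in itertools.product(range(4), repeat=4):
        oracle_uniform = any(levels.count(v) >= 3 for v in range(4))
        result = score_quad(quad(levels))
        assert result.uniform == oracle_uniform
        if oracle_uniform:
            (mode,) = [v for v in range(4) if levels.count(v) >= 3]
            assert result.consensus_level == mode


# --- single-TF calls ---------------------------------------------------------


def test_ey1h_three_active_colonies_is_positive():
    assert call_ey1h(quad((1, 2, 1, 0)), 0) is CallStatus.POSITIVE


def test_ey1h_silent_quad_is_negative():
    assert call_ey1h(quad((0, 0, 0, 0)), 0) is CallStatus.NEGATIVE


def test_ey1h_failed_mating_is_unscorable_not_negative():
    assert call_ey1h(quad((3, 3, 3, 3), growth=False), 0) is CallStatus.UNSCORABLE


def test_ey1h_activity_must_exceed_autoactive_background():
    # all colonies at the background level: no call on an autoactive bait
    assert call_ey1h(quad((2, 2, 2, 2)), 2) is CallStatus.NEGATIVE
    assert call_ey1h(quad((3, 3, 3, 0)), 2) is CallStatus.POSITIVE


def test_ey1h_binary_patterns_exactly_five_positive():
    """Brute force over all 2^4 activity patterns: C(4,3)+C(4,4) = 5 positive."""
    positives = 0
    for pattern in itertools.product((0, 1), repeat=4):
        if call_ey1h(quad(pattern), 0) is CallStatus.POSITIVE:
            positives += 1
    assert positives == 5


def test_ey1h_agrees_with_bruteforce_over_full_grid():
    """Independent oracle over every level quad x background level."""
    for levels in itertools.product(range(4), repeat=4):
        for bg in range(4):
            oracle = sum(1 for v in levels if v >= 1 and v > bg) >= 3
            got = call_ey1h(quad(levels), bg)
            assert (got is CallStatus.POSITIVE) == oracle


# --- ranking indices ---------------------------------------------------------


@pytest.mark.parametrize(
    "triple,expected",
    [
        ((3, 0, 0), (3, -3, -3)),
        ((0, 3, 0), (-3, 3, 0)),
        ((2, 2, 2), (0, 0, 0)),
    ],
)
def test_pair_indices(triple, expected):
    assert compute_pair_indices(*triple) == expected


# --- pair calls --------------------------------------------------------------


def pair_triple(lp, l1, l2, pid="P1"):
    return (
        quad((lp,) * 4, tf="A|B", pid=pid),
        quad((l1,) * 4, tf="A", pid=pid),
        quad((l2,) * 4, tf="B", pid=pid),
    )


def test_py1h_strong_pair_weak_monomers_is_cooperative():
    out = call_py1h(*pair_triple(3, 0, 1))
    assert out.verdict == "cooperative"
    assert out.antagonized_tfs == ()


def test_py1h_silent_pair_strong_monomer_is_antagonistic():
    out = call_py1h(*pair_triple(0, 3, 0))
    assert out.verdict == "antagonistic"
    assert out.antagonized_tfs == ("A",)


def test_py1h_consensus_triples_counts_match_enumeration():
    """Over all 64 consensus triples: 8 cooperative, 24 antagonistic, and the
    two verdicts are mutually exclusive by construction."""
    counts = {"cooperative": 0, "antagonistic": 0, "independent": 0, "none": 0}
    for lp, l1, l2 in itertools.product(range(4), repeat=3):
        out = call_py1h(*pair_triple(lp, l1, l2))
        counts[out.verdict] += 1
        # oracle: independent reimplementation of criteria 3-4
        coop = lp >= 2 and l1 <= 1 and l2 <= 1
        antag = lp <= 1 and (l1 >= 2 or l2 >= 2)
        assert not (coop and antag)
        assert (out.verdict == "cooperative") == coop
        assert (out.verdict == "antagonistic") == antag
    assert counts["cooperative"] == 8
    assert counts["antagonistic"] == 24


def test_py1h_nonuniform_quad_is_unscorable():
    p, t1, t2 = pair_triple(3, 0, 0)
    noisy = quad((3, 3, 0, 0), tf="A|B")
    assert call_py1h(noisy, t1, t2).verdict == "unscorable"


def test_py1h_failed_growth_is_unscorable():
    p, t1, t2 = pair_triple(3, 0, 0)
    assert call_py1h(p, quad((0,) * 4, tf="A", growth=False), t2).verdict == "unscorable"


def test_py1h_autoactive_control_is_unscorable():
    out = call_py1h(*pair_triple(3, 0, 0), pair_control=2)
    assert out.verdict == "unscorable"


def test_py1h_mismatched_promoters_raise():
    p, t1, _ = pair_triple(3, 0, 0)
    t2 = quad((0,) * 4, tf="B", pid="OTHER")
    with pytest.raises(ValueError, match="one promoter"):
        call_py1h(p, t1, t2)


# --- autoactivity filter ------------------------------------------------------


def test_filter_autoactive_thresholds(caplog):
    background = {
        "P0": score_quad(quad((0,) * 4, tf="")),
        "P3": score_quad(quad((3,) * 4, tf="")),
    }
    with caplog.at_level("WARNING"):
        retained = filter_autoactive(["P0", "P3", "Pmissing"], background)
    assert retained == ["P0"]
    assert "Pmissing" in caplog.text


def test_filter_autoactive_planted_count():
    """Default world: 150 baits, 18% autoactive -> 123 eligible for the pair screen."""
    world = generate_world(WorldParams(seed=3))
    background = {
        r.promoter_id: score_quad(r) for r in world.ey1h_readouts if r.is_control
    }
    retained = filter_autoactive(sorted(world.promoters), background)
    assert len(world.promoters) == 150
    assert len(retained) == 123
    assert set(retained) == set(world.promoters) - world.autoactive_promoters


# --- order invariance property ------------------------------------------------


@settings(max_examples=200, deadline=None)
@given(
    levels=st.lists(st.integers(0, 3), min_size=4, max_size=4),
    order=st.permutations([0, 1, 2, 3]),
    bg=st.integers(0, 3),
)
def test_calls_invariant_to_colony_order(levels, order, bg):
    shuffled = [levels[i] for i in order]
    assert call_ey1h(quad(levels), bg) == call_ey1h(quad(shuffled), bg)
    a, b = score_quad(quad(levels)), score_quad(quad(shuffled))
    assert (a.uniform, a.consensus_level, a.n_agreeing) == (
        b.uniform,
        b.consensus_level,
        b.n_agreeing,
    )
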