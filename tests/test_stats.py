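import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from y1hnet.calling import PairwiseOutcome
from y1hnet.model import MutationSummary, TFRecord
from y1hnet.stats import (
    bh_fdr,
    family_proportion_test,
    mutation_frequency,
    pair_events,
    pair_family_preference,
    proportion_test,
)


# --- two-proportion comparison ------------------------------------------------


def test_identical_proportions_not_significant():
    assert proportion_test(30, 100, 300, 1000) == pytest.approx(1.0, abs=0.01)


def test_enrichment_detected_and_fisher_concordant():
    p = proportion_test(30, 100, 10, 1000)
    fisher_p = sps.fisher_exact([[30, 70], [10, 990]])[1]
    assert p < 0.05 and fisher_p < 0.05


def test_proportion_test_symmetric_under_swap():
    assert proportion_test(30, 100, 10, 1000) == pytest.approx(
        proportion_test(10, 1000, 30, 100)
    )


def test_family_test_directions():
    from y1hnet.network import build_network
    from .conftest import make_promoter

    # network: 30 of 40 TFs are bZIP; array background: 32 of 100
    promoters, calls, array = {}, [], []
    for i in range(100):
        family = "bZIP" if i < 32 else "ZF-C2H2"
        array.append(TFRecord(f"T{i}", f"T{i}", family, "unknown"))
    for i in list(range(30)) + list(range(90, 100)):
        pid = f"G{i}.P1"
        promoters[pid] = make_promoter(pid, f"G{i}", 1000 + 10_000 * i, 3000 + 10_000 * i)
        calls.append((f"T{i}", pid, "eY1H"))
    net = build_network(calls, promoters, {r.tf_id: r for r in array})
    results = {r.family: r for r in family_proportion_test(net, array)}
    assert results["bZIP"].direction == "enriched"  # 30/40 vs 32/100
    assert results["ZF-C2H2"].direction == "depleted"
    assert results["bZIP"].count_in_foreground == 30


# --- pair-event preference ----------------------------------------------------


def outcome(verdict, tf1="A", tf2="B", antagonized=(), pid="P1"):
    return PairwiseOutcome(tf1, tf2, pid, verdict, tuple(antagonized))


def test_pair_events_expansion():
    events = pair_events(
        [
            outcome("cooperative"),
            outcome("antagonistic", antagonized=("A",)),
        ],
        {"A": "NHR", "B": "bHLH"},
    )
    rows = set(zip(events.tf_id, events.event_type))
    assert rows == {
        ("A", "cooperative"),
        ("B", "cooperative"),
        ("A", "antagonized"),
        ("B", "antagonist"),
    }


def test_family_with_only_cooperative_events_has_fraction_one():
    ann = {
        "A": TFRecord("A", "A", "NHR", "unknown"),
        "B": TFRecord("B", "B", "NHR", "unknown"),
        "C": TFRecord("C", "C", "bHLH", "unknown"),
        "D": TFRecord("D", "D", "bHLH", "unknown"),
    }
    outcomes = [outcome("cooperative", "A", "B")]
    outcomes += [outcome("antagonistic", "C", "D", antagonized=("C",))]
    frame = pair_family_preference(outcomes, ann)
    nhr = frame[frame.family == "NHR"].set_index("event_type")
    assert nhr.loc["cooperative", "fraction"] == 1.0


def test_fractions_sum_to_one_within_each_family(small_world):
    """Conservation across synthetic worlds' pair verdicts."""
    from y1hnet.calling import call_py1h, latest_day_readouts

    latest = latest_day_readouts(small_world.py1h_readouts)
    outcomes = []
    for (key, pid), readout in latest.items():
        if "|" not in key:
            continue
        tf1, tf2 = key.split("|")
        t1, t2 = latest.get((tf1, pid)), latest.get((tf2, pid))
        if t1 is None or t2 is None:
            continue
        outcomes.append(call_py1h(readout, t1, t2))
    ann = {t.tf_id: t for t in small_world.tfs}
    frame = pair_family_preference(outcomes, ann)
    if not frame.empty:
        sums = frame.groupby("family")["fraction"].sum()
        assert np.allclose(sums, 1.0)


def hypergeom_tail_p(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration of the 2x2 tables with the
    same margins, summing probabilities <= that of the observed table."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def table_p(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    observed = table_p(a)
    total = 0.0
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        p = table_p(x)
        if p <= observed * (1 + 1e-9):
            total += p
    return total


def test_fisher_matches_bruteforce_enumeration():
    for table in [(8, 2, 10, 40), (3, 7, 9, 1), (0, 5, 5, 0), (12, 13, 14, 15)]:
        expected = hypergeom_tail_p(*table)
        got = sps.fisher_exact([[table[0], table[1]], [table[2], table[3]]])[1]
        assert got == pytest.approx(expected, rel=1e-9)


@settings(max_examples=60, deadline=None)
@given(
    a=st.integers(0, 15),
    b=st.integers(0, 15),
    c=st.integers(0, 15),
    d=st.integers(0, 15),
)
def test_fisher_bruteforce_property(a, b, c, d):
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return
    got = sps.fisher_exact([[a, b], [c, d]])[1]
    assert got == pytest.approx(hypergeom_tail_p(a, b, c, d), rel=1e-8)


# --- mutation frequency -------------------------------------------------------


@pytest.mark.parametrize(
    "total,mutated,synonymous,expected",
    [(10, 3, 1, 0.2), (10, 0, 0, 0.0), (10, 10, 0, 1.0)],
)
def test_mutation_frequency_formula(total, mutated, synonymous, expected):
    s = MutationSummary("TF1", total, mutated, synonymous)
    assert mutation_frequency(s) == pytest.approx(expected)


def test_mutation_frequency_zero_cases_is_error():
    with pytest.raises(ValueError, match="undefined"):
        mutation_frequency(MutationSummary("TF1", 0, 0, 0))


# --- BH step-up ---------------------------------------------------------------


def bh_oracle(p):
    """Textbook step-up: q_(i) = min over j>=i of m*p_(j)/j."""
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = running
    return q


def test_bh_examples():
    assert bh_fdr([0.04]) == pytest.approx([0.04])
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
    st.sampled_from([0.01, 0.05, 0.1]),
)
def test_bh_matches_textbook_stepup(p_values, alpha):
    q = bh_fdr(p_values)
    expected = bh_oracle(np.asarray(p_values))
    assert np.allclose(q, expected)
    assert (q <= 1.0 + 1e-12).all()
    assert (q >= np.asarray(p_values) - 1e-12).all()
    assert np.array_equal(q <= alpha, expected <= alpha)
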