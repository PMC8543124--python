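"""Side-chain classes and the plateau/linear rule."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from aanet import (SIDE_CHAIN_CLASSES, classify_sidechain, classify_structure,
                   compute_profiles, detect_plateau, plateau_census,
                   generate_synthetic_structure, line_spec)
from conftest import oracle_segments

GRID9 = tuple(range(3, 12))


@pytest.mark.parametrize("code,expected", [("G", "small"), ("L", "medium"),
                                           ("W", "big"), ("T", "small"),
                                           ("H", "medium"), ("K", "big")])
def test_sidechain_class_lookup(code, expected):
    assert classify_sidechain(code) == expected


def test_sidechain_classes_partition_the_twenty_amino_acids():
    all_members = [aa for members in SIDE_CHAIN_CLASSES.values() for aa in members]
    assert len(all_members) == 20
    assert set(all_members) == set("ACDEFGHIKLMNPQRSTVWY")
    assert len(SIDE_CHAIN_CLASSES["small"]) == 8
    assert len(SIDE_CHAIN_CLASSES["medium"]) == 7
    assert len(SIDE_CHAIN_CLASSES["big"]) == 5


def test_sidechain_class_rejects_nonstandard():
    with pytest.raises(ValueError):
        classify_sidechain("X")


def test_steady_unit_growth_is_linear():
    call = detect_plateau(range(2, 11), GRID9)
    assert call.label == "linear"
    assert call.plateau_segments == ()
    assert call.symbol == "linear"


def test_zero_step_is_a_plateau_with_named_segment():
    degrees = [2, 4, 6, 6, 8, 10, 12, 14, 16]  # stall between c=5 and c=6
    call = detect_plateau(degrees, GRID9)
    assert call.label == "plateau"
    assert call.plateau_segments == ((5.0, 6.0),)
    assert call.symbol == "5"


def test_unit_step_counts_only_after_big_step():
    # delta sequence: 5, 1, 2, 2, 2, 2, 2, 2
    degrees = np.cumsum([3, 5, 1, 2, 2, 2, 2, 2, 2])
    call = detect_plateau(degrees, GRID9)
    assert call.label == "plateau"
    assert call.plateau_segments == ((4.0, 5.0),)
    # same unit step without the preceding burst: linear
    degrees = np.cumsum([3, 3, 1, 2, 2, 2, 2, 2, 2])
    assert detect_plateau(degrees, GRID9).label == "linear"


def test_rule_variants_differ_on_distant_burst():
    # burst at the first step, unit step much later
    degrees = np.cumsum([3, 5, 2, 2, 1, 2, 2, 2, 2])
    assert detect_plateau(degrees, GRID9, rule="strict").label == "linear"
    anyp = detect_plateau(degrees, GRID9, rule="any-preceding")
    assert anyp.label == "plateau"
    assert anyp.plateau_segments == ((6.0, 7.0),)


def test_consecutive_plateau_steps_merge():
    # deltas 5,1,0,1,4,4,4,4: the 1-after-5 and the 0 merge into one span;
    # the second unit step follows a zero step, so it does not extend it
    degrees = [3, 8, 9, 9, 10, 14, 18, 22, 26]
    call = detect_plateau(degrees, GRID9)
    assert call.plateau_segments == ((4.0, 6.0),)
    assert call.symbol == "4-6"


def test_input_validation():
    with pytest.raises(ValueError):
        detect_plateau([3, 2, 4], (3, 4, 5))
    with pytest.raises(ValueError):
        detect_plateau([3], (3,))
    with pytest.raises(ValueError):
        detect_plateau([1, 2, 3], (3, 4))
    with pytest.raises(ValueError):
        detect_plateau([1, 2, 3], (3, 4, 5), rule="loose")


@pytest.mark.parametrize("rule", ["strict", "any-preceding"])
def test_exhaustive_rule_oracle_agreement(rule):
    """Every monotone profile of length <= 6 with steps <= 4 agrees with the
    literal restatement of the rule."""
    for length in range(2, 7):
        cutoffs = tuple(range(3, 3 + length))
        for steps in itertools.product(range(5), repeat=length - 1):
            degrees = list(np.cumsum((2,) + steps))
            call = detect_plateau(degrees, cutoffs, rule=rule)
            expected = oracle_segments(degrees, cutoffs, rule=rule)
            assert list(call.plateau_segments) == expected
            assert (call.label == "plateau") == bool(expected)


def test_sampled_long_profiles_match_oracle():
    rng = np.random.default_rng(42)
    for _ in range(500):
        steps = rng.integers(0, 7, size=8)
        degrees = np.cumsum(np.concatenate([[rng.integers(0, 5)], steps]))
        for rule in ("strict", "any-preceding"):
            call = detect_plateau(degrees, GRID9, rule=rule)
            assert list(call.plateau_segments) == oracle_segments(
                degrees.tolist(), GRID9, rule=rule)


@given(
    start=st.integers(0, 6),
    steps=st.lists(st.integers(0, 6), min_size=2, max_size=7),
    tail=st.lists(st.integers(2, 3), min_size=1, max_size=4),
)
def test_tail_append_invariance(start, steps, tail):
    """Appending strictly growing values (steps >= 2) beyond the grid never
    changes the segments already found."""
    degrees = list(np.cumsum([start] + steps))
    cutoffs = tuple(range(3, 3 + len(degrees)))
    base = detect_plateau(degrees, cutoffs)
    extended = degrees + list(degrees[-1] + np.cumsum(tail))
    ext_cutoffs = tuple(range(3, 3 + len(extended)))
    ext = detect_plateau(extended, ext_cutoffs)
    assert list(ext.plateau_segments)[: len(base.plateau_segments)] == list(
        base.plateau_segments)


def test_labels_partition_residues(random_fixtures):
    structure = random_fixtures[0]
    calls = classify_structure(compute_profiles(structure))
    assert len(calls) == len(structure)
    assert all(c.label in ("plateau", "linear") for c in calls)
    census = plateau_census(calls)
    assert census["linear"] + census["degenerate"] + sum(
        census["ranges"].values()) == len(structure)


def test_isolated_residues_flagged_degenerate_and_excluded():
    s = generate_synthetic_structure(line_spec([0.0, 100.0, 200.0]), 0)
    calls = classify_structure(compute_profiles(s))
    assert all(c.label == "plateau" and c.degenerate for c in calls)
    census = plateau_census(calls)
    assert census["degenerate"] == 3
    assert census["ranges"] == {}
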