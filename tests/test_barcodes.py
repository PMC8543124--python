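"""1D/2D barcodes and the neighbor size-class decomposition."""

import numpy as np
import pytest

from aanet import (Atom, PlateauCall, Residue, ResidueKey, Structure,
                   build_aan, build_barcode_1d, build_barcode_2d,
                   classify_structure, compute_profiles,
                   decompose_profile_by_size, generate_synthetic_structure,
                   line_spec)

GRID = tuple(range(3, 12))


def _star_structure(center_type: str, neighbor_types: list[str], radius=4.0,
                    far=50.0):
    """One central residue, its neighbors on a sphere within the cutoff, and
    one remote residue that never connects."""
    residues = [Residue("A", 1, center_type,
                        [Atom("CA", "C", np.zeros(3))])]
    directions = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                           [0, 0, 1], [0, 0, -1]], dtype=float)
    for k, t in enumerate(neighbor_types):
        residues.append(Residue("A", k + 2, t,
                                [Atom("CA", "C", directions[k] * radius)]))
    residues.append(Residue("A", 99, "G",
                            [Atom("CA", "C", np.array([far, 0.0, 0.0]))]))
    return Structure("star", residues)


def _aans(structure, cutoffs=GRID):
    return {c: build_aan(structure, c) for c in cutoffs}


def test_all_small_neighbors_give_100_0_0():
    s = _star_structure("G", ["G", "A", "S", "T"])
    barcode = build_barcode_2d(s, _aans(s, (5,)))
    assert barcode.entry(0, 5) == pytest.approx((100.0, 0.0, 0.0))
    assert barcode.degrees[0, 0] == 4


def test_mixed_neighbors_percentages():
    s = _star_structure("G", ["G", "L", "F", "K"])
    barcode = build_barcode_2d(s, _aans(s, (5,)))
    assert barcode.entry(0, 5) == pytest.approx((25.0, 25.0, 50.0))


def test_degree_zero_cells_flagged_all_zero():
    s = _star_structure("G", ["G"])
    barcode = build_barcode_2d(s, _aans(s, (5,)))
    remote = len(s) - 1
    assert barcode.no_neighbors(remote, 5)
    assert barcode.entry(remote, 5) == pytest.approx((0.0, 0.0, 0.0))


def test_sum_rules_on_random_cluster(cluster10):
    aans = _aans(cluster10)
    barcode = build_barcode_2d(cluster10, aans)
    for i in range(len(cluster10)):
        decomp = decompose_profile_by_size(cluster10, aans, i)
        for ci, c in enumerate(GRID):
            assert decomp.total()[ci] == aans[c].node_degree(i)
            if barcode.degrees[i, ci] > 0:
                assert barcode.percentages[i, ci].sum() == pytest.approx(100.0)
            else:
                assert not barcode.percentages[i, ci].any()
    # components are individually non-decreasing with the cutoff
    decomp = decompose_profile_by_size(cluster10, aans, 0)
    for comp in (decomp.k_small, decomp.k_medium, decomp.k_big):
        assert np.all(np.diff(comp) >= 0)


def test_residue_order_permutation_leaves_content_unchanged(cluster10):
    barcode = build_barcode_2d(cluster10, _aans(cluster10))
    rng = np.random.default_rng(3)
    perm = rng.permutation(len(cluster10))
    shuffled = Structure("perm", [cluster10.residues[i] for i in perm])
    barcode_p = build_barcode_2d(shuffled, _aans(shuffled))
    by_key = {k: i for i, k in enumerate(barcode_p.residues)}
    for i, key in enumerate(barcode.residues):
        j = by_key[key]
        assert np.allclose(barcode.percentages[i], barcode_p.percentages[j])
        assert np.array_equal(barcode.degrees[i], barcode_p.degrees[j])


def test_barcode_1d_from_calls(cluster10):
    calls = classify_structure(compute_profiles(cluster10))
    barcode = build_barcode_1d(calls)
    assert len(barcode) == len(cluster10)
    assert [e[0] for e in barcode.entries] == cluster10.keys
    symbols = barcode.to_text().split(",")
    assert all(sym == call.symbol for sym, call in zip(symbols, calls))


def test_barcode_1d_symbol_conventions():
    key = ResidueKey("A", 1, "", "G")
    span = PlateauCall(key, "plateau", ((4.0, 6.0),), (4, 0, 0, 2), False)
    single = PlateauCall(key, "plateau", ((5.0, 6.0),), (2, 0, 2, 2), False)
    linear = PlateauCall(key, "linear", (), (2, 2, 2, 2), False)
    barcode = build_barcode_1d([span, single, linear])
    assert [e[2] for e in barcode.entries] == ["4-6", "5", "linear"]


def test_all_linear_toy_structure():
    # dense line, grid well inside its span: every residue keeps gaining
    # >= 2 neighbors per 1 Å step, so every profile is linear
    xs = [0.5 * k for k in range(21)]
    s = generate_synthetic_structure(line_spec(xs), 0)
    calls = classify_structure(compute_profiles(s, (3, 4, 5)))
    barcode = build_barcode_1d(calls)
    assert set(e[2] for e in barcode.entries) == {"linear"}


def test_glycine_line_decomposes_entirely_into_small(line9):
    structure, _ = line9
    aans = _aans(structure)
    decomp = decompose_profile_by_size(structure, aans, 0)
    assert np.array_equal(decomp.k_small,
                          [aans[c].node_degree(0) for c in GRID])
    assert not decomp.k_medium.any() and not decomp.k_big.any()


def test_invalid_residue_rejected(cluster10):
    aans = _aans(cluster10, (5,))
    with pytest.raises(ValueError):
        decompose_profile_by_size(cluster10, aans, 99)
    with pytest.raises(ValueError):
        decompose_profile_by_size(cluster10, aans,
                                  ResidueKey("Z", 1, "", "G"))


def test_neighbor_chain_restriction():
    residues = [
        Residue("A", 1, "G", [Atom("CA", "C", np.zeros(3))]),
        Residue("A", 2, "L", [Atom("CA", "C", np.array([3.0, 0, 0]))]),
        Residue("B", 1, "F", [Atom("CA", "C", np.array([0.0, 3.0, 0]))]),
    ]
    s = Structure("two-chain", residues)
    full = build_barcode_2d(s, _aans(s, (5,)))
    assert full.entry(0, 5) == pytest.approx((0.0, 50.0, 50.0))
    protein_only = build_barcode_2d(s, _aans(s, (5,)), neighbor_chains=("A",))
    assert protein_only.entry(0, 5) == pytest.approx((0.0, 100.0, 0.0))
    # ligand residue still present as a row
    assert len(protein_only.residues) == 3
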