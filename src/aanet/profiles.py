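"""Per-residue degree and weight profiles across a range of cutoffs.

Scanning the cutoff from 3 to 11 Å probes packing within chemical reach
(≤ 5 Å) and beyond it.  Because the edge set at a smaller cutoff is nested in
the edge set at a larger one, both the degree profile k_i(c) and the weight
profile w_i(c) are non-decreasing in c; this nesting also lets all cutoffs be
served by a single neighbor search at the maximum cutoff, with atom-pair
distances binned into the grid.  Equivalence with building each network
independently is a tested invariant of the package, not an assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import ResidueKey, Structure

#: the default integer cutoff grid, Å
DEFAULT_CUTOFFS: tuple[int, ...] = tuple(range(3, 12))


def _validate_cutoffs(cutoffs: Sequence[float]) -> np.ndarray:
    arr = np.asarray(cutoffs, dtype=float)
    if arr.size == 0:
        raise ValueError("cutoff list is empty")
    if arr[0] <= 0 or np.any(np.diff(arr) <= 0):
        raise ValueError("cutoffs must be positive and strictly increasing")
    return arr


@dataclass
class CutoffProfile:
    """Degree and weight of one residue at every cutoff of the grid."""

    residue_ref: ResidueKey
    cutoffs: tuple[float, ...]
    degrees: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.degrees = np.asarray(self.degrees, dtype=np.intp)
        self.weights = np.asarray(self.weights, dtype=np.intp)
        n = len(self.cutoffs)
        if self.degrees.shape != (n,) or self.weights.shape != (n,):
            raise ValueError("profile vectors must match the cutoff grid length")
        if np.any(self.degrees < 0) or np.any(self.weights < 0):
            raise ValueError("degrees and weights are non-negative counts")
        if np.any(np.diff(self.degrees) < 0) or np.any(np.diff(self.weights) < 0):
            raise ValueError("profiles must be non-decreasing in the cutoff")


def compute_profiles(
    structure: Structure,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    exclude_seq_adjacent: int = 0,
) -> list[CutoffProfile]:
    """One :class:`CutoffProfile` per residue, identical to building the
    network independently at every cutoff and reading degrees and weights."""
    grid = _validate_cutoffs(cutoffs)
    n = len(structure)
    coords, owner = structure.atom_table()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=float(grid[-1]), output_type="ndarray")

    degrees = np.zeros((n, grid.size), dtype=np.intp)
    weights = np.zeros((n, grid.size), dtype=np.intp)
    if len(pairs):
        ri = owner[pairs[:, 0]]
        rj = owner[pairs[:, 1]]
        dist = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        keep = ri != rj
        if exclude_seq_adjacent > 0:
            res = structure.residues
            chain = np.array([hash(r.chain_id) for r in res])
            seq = np.array([r.seq_num for r in res])
            same = (chain[ri] == chain[rj]) & (
                np.abs(seq[ri] - seq[rj]) <= exclude_seq_adjacent
            )
            keep &= ~same
        ri, rj, dist = ri[keep], rj[keep], dist[keep]
        lo = np.minimum(ri, rj)
        hi = np.maximum(ri, rj)
        pair_id = lo * n + hi
        for ci, c in enumerate(grid):
            within = dist <= c
            ids = pair_id[within]
            if ids.size == 0:
                continue
            uniq, counts = np.unique(ids, return_counts=True)
            ui = uniq // n
            uj = uniq % n
            np.add.at(weights[:, ci], ui, counts)
            np.add.at(weights[:, ci], uj, counts)
            np.add.at(degrees[:, ci], ui, 1)
            np.add.at(degrees[:, ci], uj, 1)

    grid_t = tuple(grid.tolist())
    return [
        CutoffProfile(structure.residues[i].key, grid_t, degrees[i], weights[i])
        for i in range(n)
    ]


def profiles_to_frame(profiles: Sequence[CutoffProfile]) -> pd.DataFrame:
    """Tidy table: chain, resnum, restype, cutoff, degree, weight."""
    rows = []
    for p in profiles:
        for c, k, w in zip(p.cutoffs, p.degrees, p.weights):
            rows.append(
                {
                    "chain": p.residue_ref.chain_id,
                    "resnum": p.residue_ref.seq_num,
                    "restype": p.residue_ref.res_type,
                    "cutoff": c,
                    "degree": int(k),
                    "weight": int(w),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class FitDiagnostics:
    """Ordinary-least-squares fit of a profile against the cutoff grid."""

    model: str  # "linear" | "quadratic"
    coefficients: tuple[float, ...]  # ascending powers: (a0, a1[, a2])
    r_squared: float
    zero_variance: bool = False


def fit_profile(
    values: Sequence[float],
    cutoffs: Sequence[float],
    model: str = "quadratic",
) -> FitDiagnostics:
    """Fit ``values`` as a linear or quadratic polynomial of the cutoff.

    R² is 1 − SS_res/SS_tot; a zero-variance response returns R² = 0 with the
    ``zero_variance`` flag set (nothing to explain).
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(cutoffs, dtype=float)
    if y.shape != x.shape:
        raise ValueError("values and cutoffs must have equal length")
    if model == "linear":
        degree = 1
        min_pts = 3
    elif model == "quadratic":
        degree = 2
        min_pts = 4
    else:
        raise ValueError(f"unknown model {model!r}")
    if y.size < min_pts:
        raise ValueError(f"{model} fit needs at least {min_pts} points, got {y.size}")

    design = np.vander(x, degree + 1, increasing=True)
    coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coeffs
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return FitDiagnostics(model, tuple(coeffs.tolist()), 0.0, zero_variance=True)
    r2 = 1.0 - ss_res / ss_tot
    return FitDiagnostics(model, tuple(coeffs.tolist()), float(np.clip(r2, 0.0, 1.0)))
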