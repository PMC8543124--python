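"""Naive brute-force network construction.

This module re-states the network definition as a literal double loop over
all inter-residue atom pairs.  It is the defining contract for
:func:`aanet.network.build_aan` (which uses a k-d tree) and is what fixture
sidecars are computed with.  It is deliberately simple and O((N·A)²); use it
on small structures only.
"""

from __future__ import annotations

import numpy as np

from .structure import Structure


def brute_force_edges(structure: Structure, cutoff: float) -> dict[tuple[int, int], int]:
    """Edge weights {(i, j): w_ij} with i < j, by enumerating every atom pair."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    res_coords = [np.array([a.coord for a in r.atoms]) for r in structure.residues]
    n = len(res_coords)
    edges: dict[tuple[int, int], int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            count = 0
            for ai in res_coords[i]:
                for aj in res_coords[j]:
                    if float(np.sqrt(np.sum((ai - aj) ** 2))) <= cutoff:
                        count += 1
            if count:
                edges[(i, j)] = count
    return edges


def brute_force_profiles(
    structure: Structure, cutoffs
) -> tuple[np.ndarray, np.ndarray]:
    """(degrees, weights) arrays of shape (n_residues, n_cutoffs)."""
    n = len(structure)
    cutoffs = list(cutoffs)
    degrees = np.zeros((n, len(cutoffs)), dtype=np.intp)
    weights = np.zeros((n, len(cutoffs)), dtype=np.intp)
    for ci, c in enumerate(cutoffs):
        for (i, j), w in brute_force_edges(structure, c).items():
            degrees[i, ci] += 1
            degrees[j, ci] += 1
            weights[i, ci] += w
            weights[j, ci] += w
    return degrees, weights
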