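"""Shared fixtures and independent oracles.

The oracles here deliberately re-state the definitions from scratch (plain
Python loops, no shared code with the package) so that agreement between the
package and the oracle is a meaningful check.
"""

from __future__ import annotations

import math
import random

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aanet import ClusterSpec, Structure, generate_synthetic_structure, run_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# --- oracle: brute-force network -----------------------------------------

def oracle_network(structure: Structure, cutoff: float) -> dict[tuple[int, int], int]:
    """Edge weights by a literal double loop over every atom pair."""
    edges: dict[tuple[int, int], int] = {}
    residues = structure.residues
    for i in range(len(residues)):
        for j in range(len(residues)):
            if j <= i:
                continue
            w = 0
            for a in residues[i].atoms:
                for b in residues[j].atoms:
                    if math.dist(tuple(a.coord), tuple(b.coord)) <= cutoff:
                        w += 1
            if w > 0:
                edges[(i, j)] = w
    return edges


def oracle_degrees_weights(edges: dict[tuple[int, int], int], n: int):
    degrees = [0] * n
    weights = [0] * n
    for (i, j), w in edges.items():
        degrees[i] += 1
        degrees[j] += 1
        weights[i] += w
        weights[j] += w
    return degrees, weights


# --- oracle: plateau rule -------------------------------------------------

def oracle_plateau_steps(degrees, rule: str = "strict") -> list[bool]:
    """Literal restatement: a step is plateau when the derivative is zero, or
    one right after (strict) / anywhere after (any-preceding) a step >= 4."""
    diffs = [degrees[t + 1] - degrees[t] for t in range(len(degrees) - 1)]
    steps = []
    for t, d in enumerate(diffs):
        if d == 0:
            steps.append(True)
        elif d == 1:
            if rule == "strict":
                steps.append(t >= 1 and diffs[t - 1] >= 4)
            else:
                steps.append(max(diffs[:t], default=0) >= 4)
        else:
            steps.append(False)
    return steps


def oracle_segments(degrees, cutoffs, rule: str = "strict"):
    steps = oracle_plateau_steps(degrees, rule)
    segments = []
    start = None
    for t, flag in enumerate(steps):
        if flag and start is None:
            start = t
        if not flag and start is not None:
            segments.append((cutoffs[start], cutoffs[t]))
            start = None
    if start is not None:
        segments.append((cutoffs[start], cutoffs[-1]))
    return segments


# --- structure fixtures ---------------------------------------------------

@pytest.fixture(scope="session")
def line9():
    structure, expected = run_fixture("line9", 0)
    return structure, expected


@pytest.fixture(scope="session")
def cluster10():
    structure, _ = run_fixture("cluster10", 1)
    return structure


@pytest.fixture(scope="session")
def random_fixtures():
    """20 random packed clusters, n <= 50 residues, varying atom counts."""
    rng = random.Random(20240711)
    specs = []
    for k in range(20):
        n = rng.randint(5, 50)
        apr = rng.randint(1, 4)
        box = max(8.0, (n * apr) ** (1 / 3) * 4.0)
        specs.append((ClusterSpec(n_residues=n, atoms_per_residue=apr,
                                  box_size=box, structure_id=f"rand{k}"),
                      rng.randint(0, 2**31 - 1)))
    return [generate_synthetic_structure(spec, seed) for spec, seed in specs]


TWO_RESIDUE_PDB = """\
ATOM      1  N   GLY A   1      -0.500   0.300   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       1.200   0.600   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.500   1.700   0.200  1.00  0.00           O
ATOM      5  N   ALA A   2       9.000   0.000   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2      10.000   0.000   0.000  1.00  0.00           C
ATOM      7  C   ALA A   2      11.000   0.800   0.100  1.00  0.00           C
ATOM      8  O   ALA A   2      11.900   0.500   0.700  1.00  0.00           O
ATOM      9  CB  ALA A   2      10.200  -1.400  -0.500  1.00  0.00           C
TER
END
"""


@pytest.fixture
def two_residue_pdb():
    return TWO_RESIDUE_PDB
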