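"""Synthetic structure generation for testing and demonstration.

Two recipes are supported: explicit per-residue atom coordinates (so degrees
and weights at every cutoff are hand-computable) and a random packed cluster
(n residues of a few atoms each, placed in a box with a minimum atom
separation, emulating the density of a folded protein core at ~the scale of
the cutoff grid).  Generation is deterministic for a given (spec, seed), and
every generated structure serializes to valid PDB text that round-trips
through the parser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import GenerationError
from .reference import brute_force_profiles
from .structure import Atom, Residue, Structure

_ATOM_NAMES = ("CA", "CB", "CG", "CD", "CE", "CZ", "CH", "CX")


@dataclass(frozen=True)
class ExplicitSpec:
    """Explicit residue/atom layout: one tuple per residue of
    (res_type, [(atom_name, (x, y, z)), ...])."""

    residues: tuple
    chain_id: str = "A"
    start_seq: int = 1
    structure_id: str = "explicit"


@dataclass(frozen=True)
class ClusterSpec:
    """Random packed cluster recipe.

    Defaults give a compact blob of 3-atom residues in a 15 Å box with a
    1.2 Å minimum atom separation — dense enough that the 3–11 Å cutoff grid
    produces non-trivial, strictly growing neighborhoods.
    """

    n_residues: int = 10
    atoms_per_residue: int = 3
    box_size: float = 15.0
    min_separation: float = 1.2
    res_types: Optional[tuple[str, ...]] = None
    structure_id: str = "cluster"
    max_tries: int = 20000


SyntheticSpec = Union[ExplicitSpec, ClusterSpec]


def line_spec(
    positions: Sequence[float], res_type: str = "G", structure_id: str = "line"
) -> ExplicitSpec:
    """Single-atom residues along the x axis at the given positions (Å)."""
    residues = tuple(
        (res_type, (("CA", (float(x), 0.0, 0.0)),)) for x in positions
    )
    return ExplicitSpec(residues=residues, structure_id=structure_id)


def generate_synthetic_structure(spec: SyntheticSpec, seed: int = 0) -> Structure:
    """Build a :class:`Structure` from a synthetic recipe, deterministically."""
    if isinstance(spec, ExplicitSpec):
        return _from_explicit(spec)
    if isinstance(spec, ClusterSpec):
        return _from_cluster(spec, seed)
    raise TypeError(f"unknown spec type {type(spec).__name__}")


def _from_explicit(spec: ExplicitSpec) -> Structure:
    residues = []
    for offset, (res_type, atoms) in enumerate(spec.residues):
        residues.append(
            Residue(
                chain_id=spec.chain_id,
                seq_num=spec.start_seq + offset,
                res_type=res_type,
                atoms=[Atom(name=n, element=n[0], coord=np.array(xyz, dtype=float))
                       for n, xyz in atoms],
            )
        )
    return Structure(spec.structure_id, residues,
                     {"source": "synthetic:explicit"})


def _from_cluster(spec: ClusterSpec, seed: int) -> Structure:
    rng = np.random.default_rng(seed)
    n_atoms = spec.n_residues * spec.atoms_per_residue
    placed = np.empty((n_atoms, 3))
    count = 0
    tries = 0
    min_sq = spec.min_separation**2
    while count < n_atoms:
        if tries >= spec.max_tries:
            raise GenerationError(
                f"could not place {n_atoms} atoms at separation "
                f">= {spec.min_separation} Å in a {spec.box_size} Å box "
                f"after {spec.max_tries} tries"
            )
        candidate = rng.uniform(0.0, spec.box_size, size=3)
        tries += 1
        if count and np.min(np.sum((placed[:count] - candidate) ** 2, axis=1)) < min_sq:
            continue
        # coordinates rounded to PDB precision so write/parse is lossless
        placed[count] = np.round(candidate, 3)
        count += 1

    if spec.res_types is not None:
        types = list(spec.res_types)
        if len(types) != spec.n_residues:
            raise GenerationError("res_types length must equal n_residues")
    else:
        alphabet = sorted("ACDEFGHIKLMNPQRSTVWY")
        types = [alphabet[t] for t in rng.integers(0, 20, size=spec.n_residues)]

    residues = []
    for i in range(spec.n_residues):
        atoms = [
            Atom(
                name=_ATOM_NAMES[a % len(_ATOM_NAMES)],
                element="C",
                coord=placed[i * spec.atoms_per_residue + a],
            )
            for a in range(spec.atoms_per_residue)
        ]
        residues.append(Residue(chain_id="A", seq_num=i + 1, res_type=types[i], atoms=atoms))
    return Structure(
        spec.structure_id,
        residues,
        {"source": f"synthetic:cluster(seed={seed})"},
    )


# --- named fixtures -------------------------------------------------------

def _line9(seed: int):
    xs = list(range(9))
    structure = generate_synthetic_structure(line_spec(xs, structure_id="line9"), seed)
    cutoffs = list(range(3, 12))
    expected = {
        "cutoffs": cutoffs,
        "degrees": [
            [min(p, c) + min(len(xs) - 1 - p, c) for c in cutoffs]
            for p in range(len(xs))
        ],
    }
    expected["weights"] = expected["degrees"]  # single-atom residues
    return structure, expected


def _line3(seed: int):
    structure = generate_synthetic_structure(
        line_spec([0.0, 4.0, 8.0], structure_id="line3"), seed
    )
    return structure, {
        "cutoffs": [5],
        "degrees": [[1], [2], [1]],
        "weights": [[1], [2], [1]],
    }


def _cluster(name: str, spec: ClusterSpec):
    def build(seed: int):
        structure = generate_synthetic_structure(spec, seed)
        cutoffs = list(range(3, 12))
        degrees, weights = brute_force_profiles(structure, cutoffs)
        return structure, {
            "cutoffs": cutoffs,
            "degrees": degrees.tolist(),
            "weights": weights.tolist(),
        }

    build.__name__ = name
    return build


FIXTURES = {
    "line9": _line9,
    "line3": _line3,
    "cluster10": _cluster("cluster10", ClusterSpec(structure_id="cluster10")),
    "cluster30": _cluster(
        "cluster30",
        ClusterSpec(n_residues=30, atoms_per_residue=3, box_size=22.0,
                    structure_id="cluster30"),
    ),
}


def run_fixture(name: str, seed: int = 0):
    """Build a registered fixture: returns (Structure, expected-values dict).

    The expected values are derived by hand (line fixtures, closed-form 1D
    geometry) or by the brute-force reference enumeration (clusters).
    """
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; registered: {sorted(FIXTURES)}"
        ) from None
    return builder(seed)
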