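"""Barcode representations of a structure's multi-scale neighborhoods.

The 1D barcode is the sequence-ordered string of plateau/linear labels (with
the plateau's cutoff range as symbol) — a compact summary of how every
position's amino-acid packing grows with the length scale.  The 2D barcode
resolves each position's neighborhood *composition*: for every residue and
every cutoff, the percentage of its neighbors falling in each side-chain size
class (small/medium/big).  The size-decomposed degree profile is the same
partition kept as counts, so the components always sum to the total degree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import CLASS_ORDER, PlateauCall, classify_sidechain
from .network import AminoAcidNetwork
from .structure import ResidueKey, Structure


@dataclass
class Barcode1D:
    entries: tuple[tuple[ResidueKey, str, str], ...]  # (residue, size class, symbol)

    def to_text(self) -> str:
        return ",".join(symbol for _, _, symbol in self.entries)

    def to_records(self) -> list[dict]:
        return [
            {
                "chain": key.chain_id,
                "resnum": key.seq_num,
                "restype": key.res_type,
                "side_chain_class": cls,
                "symbol": symbol,
            }
            for key, cls, symbol in self.entries
        ]

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_records(), **kwargs)

    def __len__(self) -> int:
        return len(self.entries)


def build_barcode_1d(calls: Sequence[PlateauCall]) -> Barcode1D:
    """Sequence-ordered barcode from per-residue plateau calls."""
    entries = []
    for call in calls:
        if call.residue_ref is None:
            raise ValueError("plateau calls must carry residue identities")
        entries.append(
            (call.residue_ref, classify_sidechain(call.residue_ref.res_type), call.symbol)
        )
    return Barcode1D(tuple(entries))


@dataclass
class Barcode2D:
    """Residue × cutoff matrix of neighbor size-class percentages.

    Percentages are stored at full precision; a residue with no neighbors at
    a cutoff gets an all-zero triple flagged ``no_neighbors`` so the matrix
    stays rectangular.
    """

    residues: tuple[ResidueKey, ...]
    cutoffs: tuple[float, ...]
    percentages: np.ndarray  # shape (n_residues, n_cutoffs, 3), class order small/medium/big
    degrees: np.ndarray  # shape (n_residues, n_cutoffs)

    def entry(self, i: int, cutoff: float) -> tuple[float, float, float]:
        ci = self.cutoffs.index(cutoff)
        return tuple(self.percentages[i, ci])

    def no_neighbors(self, i: int, cutoff: float) -> bool:
        return self.degrees[i, self.cutoffs.index(cutoff)] == 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, key in enumerate(self.residues):
            for ci, c in enumerate(self.cutoffs):
                p = self.percentages[i, ci]
                rows.append(
                    {
                        "chain": key.chain_id,
                        "resnum": key.seq_num,
                        "restype": key.res_type,
                        "cutoff": c,
                        "pct_small": p[0],
                        "pct_medium": p[1],
                        "pct_big": p[2],
                        "degree": int(self.degrees[i, ci]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class SizeDecomposedProfile:
    """Per-cutoff degree counts split by neighbor size class."""

    residue_ref: ResidueKey
    cutoffs: tuple[float, ...]
    k_small: np.ndarray
    k_medium: np.ndarray
    k_big: np.ndarray

    def total(self) -> np.ndarray:
        return self.k_small + self.k_medium + self.k_big


def _neighbor_class_counts(
    structure: Structure,
    aan: AminoAcidNetwork,
    i: int,
    neighbor_indices: Optional[set[int]] = None,
) -> np.ndarray:
    counts = np.zeros(3, dtype=np.intp)
    for j in aan.neighbors(i):
        if neighbor_indices is not None and j not in neighbor_indices:
            continue
        cls = classify_sidechain(structure.residues[j].res_type)
        counts[CLASS_ORDER.index(cls)] += 1
    return counts


def build_barcode_2d(
    structure: Structure,
    aans: Mapping[float, AminoAcidNetwork],
    neighbor_chains: Optional[Sequence[str]] = None,
) -> Barcode2D:
    """2D barcode from networks built on the same structure over a cutoff grid.

    ``neighbor_chains`` optionally restricts which chains may *contribute*
    neighbors (e.g. protein chains only), while every residue of the
    structure still gets a row.
    """
    cutoffs = tuple(sorted(aans))
    n = len(structure)
    allowed: Optional[set[int]] = None
    if neighbor_chains is not None:
        wanted = set(neighbor_chains)
        allowed = {i for i, r in enumerate(structure.residues) if r.chain_id in wanted}

    pct = np.zeros((n, len(cutoffs), 3), dtype=float)
    deg = np.zeros((n, len(cutoffs)), dtype=np.intp)
    for ci, c in enumerate(cutoffs):
        aan = aans[c]
        if aan.n_nodes != n:
            raise ValueError("network and structure disagree on residue count")
        for i in range(n):
            counts = _neighbor_class_counts(structure, aan, i, allowed)
            total = counts.sum()
            deg[i, ci] = total
            if total:
                pct[i, ci] = counts / total * 100.0
    return Barcode2D(tuple(structure.keys), cutoffs, pct, deg)


def decompose_profile_by_size(
    structure: Structure,
    aans: Mapping[float, AminoAcidNetwork],
    residue: int | ResidueKey,
) -> SizeDecomposedProfile:
    """Class-wise neighbor counts of one residue at every cutoff."""
    if isinstance(residue, ResidueKey):
        try:
            idx = structure.keys.index(residue)
        except ValueError:
            raise ValueError(f"residue {residue.label} not in structure") from None
    else:
        idx = residue
        if not 0 <= idx < len(structure):
            raise ValueError(f"residue index {idx} outside structure")
    cutoffs = tuple(sorted(aans))
    counts = np.zeros((len(cutoffs), 3), dtype=np.intp)
    for ci, c in enumerate(cutoffs):
        counts[ci] = _neighbor_class_counts(structure, aans[c], idx)
    return SizeDecomposedProfile(
        structure.residues[idx].key,
        cutoffs,
        counts[:, 0].copy(),
        counts[:, 1].copy(),
        counts[:, 2].copy(),
    )
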