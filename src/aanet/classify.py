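"""Side-chain size classes and plateau/linear classification of degree profiles.

Side-chain classes partition the 20 standard amino acids by extended
side-chain length: small (< 3 Å), medium (3–5 Å) and big (≥ 5 Å).  The sets
are fixed by definition, not recomputed from coordinates.

A residue's degree profile k(c) over consecutive integer cutoffs is
"plateau" when its growth stalls: a step of the discrete derivative
Δk(c) = k(c+1) − k(c) belongs to a plateau when Δk = 0, or when Δk = 1
immediately after a large step (Δk ≥ 4 at the preceding cutoff — the burst
of neighbors whose bulk then occupies the next shell).  Consecutive plateau
steps merge into one segment [c_start, c_end].  A profile with no plateau
segment is "linear".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .profiles import CutoffProfile
from .structure import ResidueKey

SIDE_CHAIN_CLASSES: dict[str, frozenset[str]] = {
    "small": frozenset("GAPSVITC"),
    "medium": frozenset("LEDHNQM"),
    "big": frozenset("FKRYW"),
}
CLASS_ORDER = ("small", "medium", "big")

_CODE_TO_CLASS = {
    aa: name for name, members in SIDE_CHAIN_CLASSES.items() for aa in members
}

#: threshold on the preceding derivative that licenses a unit step as plateau
PLATEAU_PRECEDING_STEP = 4

PLATEAU_RULES = ("strict", "any-preceding")


def classify_sidechain(res_type: str) -> str:
    """Size class ("small" | "medium" | "big") of a one-letter residue code."""
    try:
        return _CODE_TO_CLASS[res_type]
    except KeyError:
        raise ValueError(f"{res_type!r} is not a standard amino-acid code") from None


@dataclass
class PlateauCall:
    """Plateau/linear label of one degree profile, with diagnostics."""

    residue_ref: Optional[ResidueKey]
    label: str  # "plateau" | "linear"
    plateau_segments: tuple[tuple[float, float], ...]
    deltas: tuple[int, ...]
    degenerate: bool = False  # all-zero profile (isolated residue)

    def __post_init__(self) -> None:
        if (self.label == "plateau") != bool(self.plateau_segments):
            raise ValueError("plateau label iff at least one segment")

    @property
    def symbol(self) -> str:
        """Barcode symbol: segment-start cutoff for a one-step plateau,
        "start-end" for longer spans, "linear" otherwise.  Multiple disjoint
        segments show the first (lowest-cutoff) one."""
        if not self.plateau_segments:
            return "linear"
        start, end = self.plateau_segments[0]
        if end - start == 1:
            return _fmt(start)
        return f"{_fmt(start)}-{_fmt(end)}"

    @property
    def segment_ranges(self) -> tuple[str, ...]:
        return tuple(f"{_fmt(s)}-{_fmt(e)}" for s, e in self.plateau_segments)


def _fmt(c: float) -> str:
    return str(int(c)) if float(c).is_integer() else str(c)


def detect_plateau(
    degrees: Sequence[int],
    cutoffs: Sequence[float],
    rule: str = "strict",
    residue_ref: Optional[ResidueKey] = None,
) -> PlateauCall:
    """Classify one degree profile as plateau (with segments) or linear.

    Parameters
    ----------
    rule
        "strict": a unit step Δk = 1 counts as plateau only when the
        immediately preceding step is ≥ 4 (default).  "any-preceding": when
        any earlier step on the grid is ≥ 4.
    """
    if rule not in PLATEAU_RULES:
        raise ValueError(f"unknown plateau rule {rule!r}; choose from {PLATEAU_RULES}")
    k = np.asarray(degrees, dtype=np.intp)
    c = np.asarray(cutoffs, dtype=float)
    if k.shape != c.shape or k.size < 2:
        raise ValueError("degrees and cutoffs must have equal length >= 2")
    deltas = np.diff(k)
    if np.any(deltas < 0):
        raise ValueError("degree profile must be non-decreasing (edge-set nesting)")

    is_plateau_step = np.zeros(deltas.size, dtype=bool)
    for t in range(deltas.size):
        if deltas[t] == 0:
            is_plateau_step[t] = True
        elif deltas[t] == 1:
            if rule == "strict":
                is_plateau_step[t] = t > 0 and deltas[t - 1] >= PLATEAU_PRECEDING_STEP
            else:
                is_plateau_step[t] = bool(
                    np.any(deltas[:t] >= PLATEAU_PRECEDING_STEP)
                )

    segments: list[tuple[float, float]] = []
    t = 0
    while t < is_plateau_step.size:
        if is_plateau_step[t]:
            start = t
            while t + 1 < is_plateau_step.size and is_plateau_step[t + 1]:
                t += 1
            segments.append((float(c[start]), float(c[t + 1])))
        t += 1

    return PlateauCall(
        residue_ref=residue_ref,
        label="plateau" if segments else "linear",
        plateau_segments=tuple(segments),
        deltas=tuple(int(d) for d in deltas),
        degenerate=bool(np.all(k == 0)),
    )


def classify_structure(
    profiles: Sequence[CutoffProfile], rule: str = "strict"
) -> list[PlateauCall]:
    """One :class:`PlateauCall` per residue profile."""
    return [
        detect_plateau(p.degrees, p.cutoffs, rule=rule, residue_ref=p.residue_ref)
        for p in profiles
    ]


def plateau_census(calls: Sequence[PlateauCall]) -> dict:
    """Summary counts: plateau residues per first-segment range, linear
    residues, and degenerate (isolated, all-zero) profiles, which are
    excluded from the range counts."""
    ranges: Counter = Counter()
    linear = 0
    degenerate = 0
    for call in calls:
        if call.degenerate:
            degenerate += 1
        elif call.label == "linear":
            linear += 1
        else:
            s, e = call.plateau_segments[0]
            ranges[f"{_fmt(s)}-{_fmt(e)}"] += 1
    return {
        "ranges": dict(sorted(ranges.items())),
        "linear": linear,
        "degenerate": degenerate,
        "n_residues": len(calls),
    }
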