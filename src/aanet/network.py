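"""Amino Acid Network construction at a single distance cutoff.

The network G = (V, E) has one node per residue.  Two residues i and j are
linked when at least one atom of i and one atom of j lie within the cutoff
distance c (inclusive), and the link weight w_ij counts the number of such
atom pairs.  The node degree k_i (number of residue neighbors) measures
amino-acid packing; the node weight w_i = Σ_j w_ij measures atomic packing.

The pair search uses a k-d tree, but the contract is defined by brute-force
enumeration of all atom pairs; the two agree exactly because the tree query
is inclusive (distance ≤ c), matching the link definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure


@dataclass(frozen=True)
class Edge:
    i: int
    j: int
    weight: int

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("self-loops are not allowed")
        if self.i > self.j:
            raise ValueError("edges are stored with i < j")
        if self.weight < 1:
            raise ValueError("edge weight must be >= 1")


class AminoAcidNetwork:
    """Weighted undirected residue graph at one cutoff."""

    def __init__(self, structure_id: str, cutoff: float, n_nodes: int,
                 weights: dict[tuple[int, int], int]):
        self.structure_id = structure_id
        self.cutoff = cutoff
        self.n_nodes = n_nodes
        self._w = dict(weights)
        self._adj: dict[int, dict[int, int]] = {i: {} for i in range(n_nodes)}
        for (i, j), w in self._w.items():
            self._adj[i][j] = w
            self._adj[j][i] = w

    @property
    def edges(self) -> list[Edge]:
        return [Edge(i, j, w) for (i, j), w in sorted(self._w.items())]

    def edge_weight(self, i: int, j: int) -> int:
        """Weight of edge (i, j), 0 if absent."""
        self._check(i)
        self._check(j)
        return self._adj[i].get(j, 0)

    def neighbors(self, i: int) -> list[int]:
        self._check(i)
        return sorted(self._adj[i])

    def node_degree(self, i: int) -> int:
        self._check(i)
        return len(self._adj[i])

    def node_weight(self, i: int) -> int:
        self._check(i)
        return sum(self._adj[i].values())

    def degrees(self) -> np.ndarray:
        return np.array([len(self._adj[i]) for i in range(self.n_nodes)], dtype=np.intp)

    def weights(self) -> np.ndarray:
        return np.array([sum(self._adj[i].values()) for i in range(self.n_nodes)],
                        dtype=np.intp)

    def total_edge_weight(self) -> int:
        return sum(self._w.values())

    def __iter__(self) -> Iterator[Edge]:
        return iter(self.edges)

    def _check(self, i: int) -> None:
        if not 0 <= i < self.n_nodes:
            raise IndexError(f"residue index {i} outside [0, {self.n_nodes})")


def build_aan(structure: Structure, cutoff: float,
              exclude_seq_adjacent: int = 0) -> AminoAcidNetwork:
    """Build the amino-acid network of ``structure`` at ``cutoff`` Å.

    Parameters
    ----------
    cutoff
        Distance threshold, Å; atom pairs at distance exactly equal to the
        cutoff are counted (inclusive comparison).
    exclude_seq_adjacent
        When > 0, drop links between residues of the same chain whose
        sequence numbers differ by at most this value (sensitivity analysis;
        the default keeps peptide-bonded neighbors, as the link definition
        is purely distance-based).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not structure.residues:
        raise ValueError("structure has no residues")

    coords, owner = structure.atom_table()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=float(cutoff), output_type="ndarray")
    weights: dict[tuple[int, int], int] = {}
    if len(pairs):
        ri = owner[pairs[:, 0]]
        rj = owner[pairs[:, 1]]
        cross = ri != rj
        lo = np.minimum(ri[cross], rj[cross])
        hi = np.maximum(ri[cross], rj[cross])
        for i, j in zip(lo.tolist(), hi.tolist()):
            weights[(i, j)] = weights.get((i, j), 0) + 1

    if exclude_seq_adjacent > 0:
        res = structure.residues
        weights = {
            (i, j): w for (i, j), w in weights.items()
            if not (res[i].chain_id == res[j].chain_id
                    and abs(res[i].seq_num - res[j].seq_num) <= exclude_seq_adjacent)
        }

    return AminoAcidNetwork(structure.structure_id, cutoff, len(structure), weights)


def node_degree(aan: AminoAcidNetwork, i: int) -> int:
    """Number of distinct residues sharing an edge with residue ``i``."""
    return aan.node_degree(i)


def node_weight(aan: AminoAcidNetwork, i: int) -> int:
    """Sum of the weights of the links incident to residue ``i``."""
    return aan.node_weight(i)


def to_networkx(aan: AminoAcidNetwork, structure: Optional[Structure] = None):
    """Export as a networkx.Graph; node names are chain:resnum:restype labels
    when the structure is given, else bare indices."""
    import networkx as nx

    g = nx.Graph(structure_id=aan.structure_id, cutoff=aan.cutoff)
    if structure is not None:
        labels = [k.label for k in structure.keys]
    else:
        labels = [str(i) for i in range(aan.n_nodes)]
    for idx, lab in enumerate(labels):
        g.add_node(lab, index=idx)
    for e in aan.edges:
        g.add_edge(labels[e.i], labels[e.j], weight=e.weight)
    return g


def write_edge_list(aan: AminoAcidNetwork, structure: Structure) -> str:
    """Weighted edge list as TSV text (endpoint labels + weight)."""
    labels = [k.label for k in structure.keys]
    lines = ["source\ttarget\tweight"]
    for e in aan.edges:
        lines.append(f"{labels[e.i]}\t{labels[e.j]}\t{e.weight}")
    return "\n".join(lines) + "\n"


def write_graphml(aan: AminoAcidNetwork, structure: Structure, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(aan, structure), path)
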