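"""Internal structure model and PDB reading/writing.

A :class:`Structure` is an ordered list of residues, each holding its heavy
(or, optionally, all) atoms with Cartesian coordinates in Å.  The model keeps
only what the network construction needs: residue identity, atom coordinates,
and enough provenance to make a run reproducible.  Parsing is delegated to
Bio.PDB; writing emits fixed-column wwPDB v3.3 ATOM records so that any
structure round-trips through :func:`parse_structure` at the 3-decimal
coordinate precision of the format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .errors import EmptyStructureError, StructureFormatError

#: canonical 3-letter -> 1-letter table for the 20 standard amino acids
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
_HYDROGEN_ELEMENTS = {"H", "D"}


class ResidueKey(NamedTuple):
    """Stable identity of a residue inside one structure."""

    chain_id: str
    seq_num: int
    icode: str
    res_type: str

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.seq_num}{self.icode}:{self.res_type}"


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coordinates must be 3 finite numbers")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    res_type: str  # one-letter code
    atoms: list[Atom]
    icode: str = ""
    side_chain_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.res_type not in ONE_TO_THREE:
            raise ValueError(f"{self.res_type!r} is not a standard amino-acid code")
        if not self.atoms:
            raise ValueError(f"residue {self.key.label} has no atoms")

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.seq_num, self.icode, self.res_type)


@dataclass
class Structure:
    structure_id: str
    residues: list[Residue]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for res in self.residues:
            ident = (res.chain_id, res.seq_num, res.icode)
            if ident in seen:
                raise ValueError(f"duplicate residue identifier {ident}")
            seen.add(ident)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]

    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for res in self.residues:
            if res.chain_id not in out:
                out.append(res.chain_id)
        return out

    def ligand_chain_ids(self, max_residues: int = 10) -> list[str]:
        """Chains short enough to be peptide ligands rather than the protein.

        Only meaningful for multi-chain structures; with a single chain the
        result is empty.
        """
        if len(self.chain_ids()) < 2:
            return []
        counts: dict[str, int] = {}
        for res in self.residues:
            counts[res.chain_id] = counts.get(res.chain_id, 0) + 1
        return [c for c, n in counts.items() if n <= max_residues]

    def subset(self, chains: Iterable[str]) -> "Structure":
        wanted = set(chains)
        kept = [r for r in self.residues if r.chain_id in wanted]
        if not kept:
            raise EmptyStructureError(f"no residues left after restricting to chains {sorted(wanted)}")
        prov = dict(self.provenance)
        prov["chain_subset"] = sorted(wanted)
        return Structure(self.structure_id, kept, prov)

    def atom_table(self) -> tuple[np.ndarray, np.ndarray]:
        """All atom coordinates plus the residue index of each atom."""
        coords = np.concatenate([[a.coord for a in r.atoms] for r in self.residues])
        owner = np.concatenate(
            [np.full(len(r.atoms), i, dtype=np.intp) for i, r in enumerate(self.residues)]
        )
        return coords, owner

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclass(frozen=True)
class AtomSelectionPolicy:
    """Which atoms of a structure file enter the network model.

    Defaults reflect crystal-structure practice: heavy atoms only, the
    highest-occupancy alternate conformer, waters and non-peptide heteroatoms
    removed, first model of multi-model files, all peptide chains kept.
    """

    include_hydrogens: bool = False
    include_waters: bool = False
    chains: Optional[tuple[str, ...]] = None
    model_index: int = 0
    #: optional 3-letter -> 1-letter mapping for nonstandard residues, e.g. {"MSE": "M"}
    map_nonstandard: Optional[tuple[tuple[str, str], ...]] = None

    def nonstandard_table(self) -> dict[str, str]:
        return dict(self.map_nonstandard or ())


DEFAULT_POLICY = AtomSelectionPolicy()


def _select_altlocs(atoms) -> list:
    """Resolve alternate locations: keep the highest-occupancy conformer per
    atom name, ties broken by altloc label order."""
    by_name: dict[str, list] = {}
    order: list[str] = []
    for atom in atoms:
        name = atom.get_name()
        if name not in by_name:
            by_name[name] = []
            order.append(name)
        by_name[name].append(atom)
    chosen = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            chosen.append(group[0])
        else:
            chosen.append(
                min(group, key=lambda a: (-(a.get_occupancy() or 1.0), a.get_altloc()))
            )
    return chosen


def parse_structure(
    pdb_text: str,
    policy: AtomSelectionPolicy = DEFAULT_POLICY,
    structure_id: str = "structure",
) -> Structure:
    """Parse PDB-format text into a filtered :class:`Structure`.

    Only standard amino-acid residues that pass ``policy`` are kept; waters and
    non-amino-acid heteroatoms are dropped, nonstandard residues are skipped
    (and recorded in provenance) unless mapped via the policy.
    """
    parser = PDBParser(PERMISSIVE=True, QUIET=True)
    try:
        bio = parser.get_structure(structure_id, io.StringIO(pdb_text))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureFormatError(f"cannot parse PDB input: {exc}") from exc
    models = list(bio.get_models())
    if not models:
        raise StructureFormatError("input contains no coordinate model")
    if policy.model_index >= len(models):
        raise StructureFormatError(
            f"model {policy.model_index} requested but file has {len(models)} model(s)"
        )
    model = models[policy.model_index]

    nonstandard = policy.nonstandard_table()
    wanted_chains = set(policy.chains) if policy.chains else None
    residues: list[Residue] = []
    skipped: set[str] = set()

    for chain in model:
        chain_id = chain.id.strip() or "A"
        if wanted_chains is not None and chain_id not in wanted_chains:
            continue
        for res in chain:
            resname = res.get_resname().strip().upper()
            if resname in _WATER_NAMES:
                if not policy.include_waters:
                    continue
                skipped.add(resname)
                continue
            if resname in THREE_TO_ONE:
                one = THREE_TO_ONE[resname]
            elif resname in nonstandard:
                one = nonstandard[resname]
            else:
                skipped.add(resname)
                continue
            atoms: list[Atom] = []
            for bio_atom in _select_altlocs(res.get_unpacked_list()):
                element = (bio_atom.element or "").strip().upper()
                if not policy.include_hydrogens and element in _HYDROGEN_ELEMENTS:
                    continue
                occ = bio_atom.get_occupancy()
                atoms.append(
                    Atom(
                        name=bio_atom.get_name(),
                        element=element,
                        coord=np.array(bio_atom.get_coord(), dtype=float),
                        altloc=(bio_atom.get_altloc() or "").strip(),
                        occupancy=1.0 if occ is None else min(max(occ, 0.0), 1.0),
                    )
                )
            if not atoms:
                continue
            het, seq_num, icode = res.get_id()
            residues.append(
                Residue(
                    chain_id=chain_id,
                    seq_num=int(seq_num),
                    res_type=one,
                    atoms=atoms,
                    icode=icode.strip(),
                )
            )

    if not residues:
        raise EmptyStructureError("no standard amino-acid residues after filtering")

    provenance = {
        "source": structure_id,
        "policy": asdict(policy),
        "skipped_residue_names": sorted(skipped),
    }
    return Structure(structure_id, residues, provenance)


def write_structure(structure: Structure) -> str:
    """Serialize a structure to PDB-format text (ATOM records only).

    The output re-parses to an equivalent structure; coordinates are written
    at the format's native 3-decimal precision.
    """
    if not structure.residues:
        raise EmptyStructureError("cannot write a structure with no residues")
    lines: list[str] = []
    serial = 1
    prev_chain: Optional[str] = None
    for res in structure.residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = res.chain_id
        resname = ONE_TO_THREE[res.res_type]
        for atom in res.atoms:
            name = atom.name
            if len(name) < 4 and len(atom.element) <= 1:
                name_field = f" {name:<3}"
            else:
                name_field = f"{name:<4}"
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {name_field}{(atom.altloc or ' ')[:1]}{resname:>3} "
                f"{res.chain_id[:1]}{res.seq_num:4d}{(res.icode or ' ')[:1]}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def structures_equal(a: Structure, b: Structure, coord_tol: float = 5e-4) -> bool:
    """True when two structures agree in residue order, identity and
    coordinates (to ``coord_tol`` Å, default: PDB 3-decimal precision)."""
    if len(a) != len(b):
        return False
    for ra, rb in zip(a.residues, b.residues):
        if ra.key != rb.key or len(ra.atoms) != len(rb.atoms):
            return False
        for aa, ab in zip(ra.atoms, rb.atoms):
            if aa.name != ab.name:
                return False
            if np.max(np.abs(aa.coord - ab.coord)) > coord_tol:
                return False
    return True
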