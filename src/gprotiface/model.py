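"""Hierarchical coordinate model for GPCR-G protein complexes.

The model is deliberately small: chains of residues of atoms, with author
numbering (``seq_id`` + insertion code) as the canonical residue key and
coordinates in Angstrom throughout.  Generic-numbering annotations (BW for
receptors, CGN for Galpha, blade labels for Gbeta) are attached directly to
residues by :mod:`gprotiface.numbering`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

#: The 20 standard amino acids, three-letter codes.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Roles a chain can play in a receptor-G protein complex.
CHAIN_ROLES = ("receptor", "Galpha", "Gbeta", "Ggamma", "stabilizer", "other")

#: Unique roles: at most one chain each.
UNIQUE_ROLES = ("receptor", "Galpha", "Gbeta", "Ggamma")


class ModelError(ValueError):
    """Raised for domain-model invariant violations."""


@dataclass
class Atom:
    """A single atom with coordinates in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ModelError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ModelError(f"atom {self.name}: non-finite coordinates")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ModelError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(), self.occupancy, self.altloc)


@dataclass
class Residue:
    """One residue, keyed by author numbering (chain_id, seq_id, icode)."""

    chain_id: str
    seq_id: int
    icode: str
    name: str
    atoms: list[Atom]
    is_polymer: bool = True
    # attached by gprotiface.numbering.annotate; None when unmapped
    generic_label: Optional["object"] = None
    segment: Optional[str] = None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def copy(self) -> "Residue":
        r = Residue(
            self.chain_id,
            self.seq_id,
            self.icode,
            self.name,
            [a.copy() for a in self.atoms],
            self.is_polymer,
        )
        r.generic_label = self.generic_label
        r.segment = self.segment
        return r


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, seq_id: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.seq_id == seq_id and r.icode == icode:
                return r
        return None

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class Structure:
    """A single-model structure: ordered chains of residues of atoms."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    source_format: str = "PDB"

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ModelError(f"structure {self.id}: duplicate chain identifiers")

    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues():
            yield from r.atoms

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def copy(self) -> "Structure":
        return Structure(self.id, [c.copy() for c in self.chains], self.source_format)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with ``R x + t`` applied to every atom."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for atom in out.atoms():
            atom.position = R @ atom.position + t
        return out


@dataclass
class ChainRoleAssignment:
    """Maps chain ids of one structure to complex roles.

    At most one chain may hold each of the unique roles (receptor, Galpha,
    Gbeta, Ggamma); any number of chains may be 'stabilizer' or 'other'.
    """

    structure_id: str
    roles: dict[str, str]

    def __post_init__(self) -> None:
        for cid, role in self.roles.items():
            if role not in CHAIN_ROLES:
                raise ModelError(f"unknown role {role!r} for chain {cid}")
        for role in UNIQUE_ROLES:
            holders = [c for c, r in self.roles.items() if r == role]
            if len(holders) > 1:
                raise ModelError(f"role {role} assigned to multiple chains: {holders}")

    def chain_for(self, role: str) -> Optional[str]:
        for cid, r in self.roles.items():
            if r == role:
                return cid
        return None


@dataclass(frozen=True)
class ResidueRef:
    """Lightweight reference to a residue by author numbering."""

    chain_id: str
    seq_id: int
    icode: str = ""

    def resolve(self, s: Structure) -> Residue:
        chain = s.chain(self.chain_id)
        if chain is None:
            raise KeyError(f"no chain {self.chain_id!r} in structure {s.id}")
        res = chain.residue(self.seq_id, self.icode)
        if res is None:
            raise KeyError(
                f"no residue {self.seq_id}{self.icode} in chain {self.chain_id} of {s.id}"
            )
        return res
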