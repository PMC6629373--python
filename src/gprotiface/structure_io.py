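"""Reading, writing and selection policies for PDB / mmCIF coordinate files.

Parsing and serialisation are delegated to :mod:`gemmi`; this module maps
gemmi's hierarchy onto the package's domain model (:class:`~gprotiface.model.Structure`)
and fixes the selection policies used throughout the pipeline:

* only the first model of a multi-model file is kept;
* alternate locations are resolved to the highest-occupancy conformer
  (ties broken by lexicographically smallest altloc id);
* the polymer flag comes from the mmCIF entity classification, or for PDB
  from the ATOM/HETATM record combined with an amino-acid name check.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import gemmi

from .model import (
    Atom,
    Chain,
    ChainRoleAssignment,
    Residue,
    Structure,
)

__all__ = [
    "ParseError",
    "ContentError",
    "read_structure",
    "write_structure",
    "select_conformer",
    "strip_nonpolymer",
    "CohortManifestEntry",
    "read_manifest",
    "write_manifest",
]


class ParseError(ValueError):
    """File could not be parsed under the named standard."""


class ContentError(ValueError):
    """File parsed but does not contain usable content."""


_SUBTYPES = ("Gi/o", "Gs", "Gq/11", "Go-mini")
_RECEPTOR_CLASSES = ("A", "B")


def _is_amino_acid(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def _detect_format(path: Path, fmt: str) -> gemmi.CoorFormat:
    fmt = fmt.lower()
    if fmt == "pdb":
        return gemmi.CoorFormat.Pdb
    if fmt in ("mmcif", "cif"):
        return gemmi.CoorFormat.Mmcif
    if fmt == "auto":
        return gemmi.CoorFormat.Detect
    raise ValueError(f"unknown coordinate format {fmt!r}")


def read_structure(path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only the coordinates of the first model are retained.  Hydrogens and
    alternate locations are kept as parsed; resolve altlocs afterwards with
    :func:`select_conformer`.

    Raises
    ------
    ParseError
        If the file cannot be parsed under the named standard.
    ContentError
        If the file contains no polymer chain.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    try:
        st = gemmi.read_structure(str(path), format=_detect_format(path, format))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ContentError(f"{path}: no models")

    fmt_name = "mmCIF" if st.input_format == gemmi.CoorFormat.Mmcif else "PDB"
    chains: list[Chain] = []
    for gchain in st[0]:
        residues: list[Residue] = []
        for gres in gchain:
            entity_polymer = gres.entity_type == gemmi.EntityType.Polymer
            record_polymer = gres.het_flag != "H" and _is_amino_acid(gres.name)
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    position=(ga.pos.x, ga.pos.y, ga.pos.z),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    altloc="" if ga.altloc in ("\x00", " ", "") else ga.altloc,
                )
                for ga in gres
            ]
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    seq_id=gres.seqid.num,
                    icode="" if gres.seqid.icode in (" ", "\x00", "") else gres.seqid.icode,
                    name=gres.name,
                    atoms=atoms,
                    is_polymer=entity_polymer or record_polymer,
                )
            )
        if residues:
            chains.append(Chain(gchain.name, residues))

    structure = Structure(id=st.name or path.stem, chains=chains, source_format=fmt_name)
    if not any(r.is_polymer for r in structure.residues()):
        raise ContentError(f"{path}: no polymer chains")
    return structure


def write_structure(s: Structure, path, format: str = "PDB") -> None:
    """Write a structure as PDB or mmCIF.

    The emitted file reads back into an equal structure; coordinates round
    trip to the format precision (1e-3 A for PDB).
    """
    if not s.chains or all(len(c) == 0 for c in s.chains):
        raise ValueError(f"structure {s.id}: nothing to write")
    path = Path(path)
    fmt = format.lower()
    if fmt not in ("pdb", "mmcif", "cif"):
        raise ValueError(f"unknown coordinate format {format!r}")

    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    for chain in s.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            gres.het_flag = "A" if res.is_polymer else "H"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.altloc = atom.altloc or "\x00"
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    try:
        if fmt == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def select_conformer(s: Structure, policy: str = "max_occupancy") -> Structure:
    """Resolve alternate locations: keep one conformer per atom name.

    The retained conformer is the one with the highest occupancy; ties are
    broken by the lexicographically smallest altloc id.  Idempotent.
    """
    if policy != "max_occupancy":
        raise ValueError(f"unknown altloc policy {policy!r}")
    out = s.copy()
    for res in out.residues():
        by_name: dict[str, Atom] = {}
        order: list[str] = []
        for atom in res.atoms:
            if atom.name not in by_name:
                by_name[atom.name] = atom
                order.append(atom.name)
            else:
                kept = by_name[atom.name]
                # higher occupancy wins; tie -> smaller altloc id
                if (-atom.occupancy, atom.altloc) < (-kept.occupancy, kept.altloc):
                    by_name[atom.name] = atom
        res.atoms = [by_name[n] for n in order]
    return out


def strip_nonpolymer(s: Structure) -> Structure:
    """Drop waters, ligands, ions and detergent; keep polymer residues only.

    Chain order is preserved; chains left empty are removed.  Non-standard
    residues marked polymeric by the source file are retained.
    """
    out = s.copy()
    chains: list[Chain] = []
    for chain in out.chains:
        kept = [r for r in chain.residues if r.is_polymer]
        if kept:
            chains.append(Chain(chain.chain_id, kept))
    out.chains = chains
    return out


@dataclass
class CohortManifestEntry:
    """One row of a cohort manifest (tab-separated)."""

    structure_id: str
    path: str
    receptor_chain: str
    galpha_chain: str
    gbeta_chain: str
    ggamma_chain: str
    subtype: str
    receptor_class: str

    def roles(self) -> ChainRoleAssignment:
        mapping = {}
        for cid, role in (
            (self.receptor_chain, "receptor"),
            (self.galpha_chain, "Galpha"),
            (self.gbeta_chain, "Gbeta"),
            (self.ggamma_chain, "Ggamma"),
        ):
            if cid and cid != ".":
                mapping[cid] = role
        return ChainRoleAssignment(self.structure_id, mapping)


_MANIFEST_COLUMNS = [
    "structure_id",
    "path",
    "receptor_chain",
    "galpha_chain",
    "gbeta_chain",
    "ggamma_chain",
    "subtype",
    "receptor_class",
]


def read_manifest(path) -> list[CohortManifestEntry]:
    """Read a tab-separated cohort manifest; '#' lines are comments."""
    path = Path(path)
    entries: list[CohortManifestEntry] = []
    with open(path, newline="") as fh:
        rows = [
            row
            for row in csv.reader(fh, delimiter="\t")
            if row and not row[0].startswith("#")
        ]
    if not rows:
        raise ContentError(f"{path}: empty manifest")
    header = rows[0]
    if header != _MANIFEST_COLUMNS:
        raise ParseError(
            f"{path}: manifest header must be {_MANIFEST_COLUMNS}, got {header}"
        )
    for row in rows[1:]:
        if len(row) != len(_MANIFEST_COLUMNS):
            raise ParseError(f"{path}: bad manifest row {row}")
        entry = CohortManifestEntry(*row)
        if entry.subtype not in _SUBTYPES:
            raise ParseError(f"{path}: unknown subtype {entry.subtype!r}")
        if entry.receptor_class not in _RECEPTOR_CLASSES:
            raise ParseError(f"{path}: unknown receptor class {entry.receptor_class!r}")
        entries.append(entry)
    seen = set()
    for e in entries:
        if e.structure_id in seen:
            raise ParseError(f"{path}: duplicate structure_id {e.structure_id}")
        seen.add(e.structure_id)
    return entries


def write_manifest(entries: list[CohortManifestEntry], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_MANIFEST_COLUMNS)
        for e in entries:
            writer.writerow(
                [
                    e.structure_id,
                    e.path,
                    e.receptor_chain,
                    e.galpha_chain,
                    e.gbeta_chain,
                    e.ggamma_chain,
                    e.subtype,
                    e.receptor_class,
                ]
            )
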