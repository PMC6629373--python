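"""Receptor C-terminal tail interface characterization.

The receptor C-tail (distal to helix 8) is intrinsically disordered in
isolation; in a G-protein-bound complex part of it can stretch over the
cleft between Galpha and Gbeta.  This module extracts the modeled tail
residues over an author-numbered window, lists the Galpha and Gbeta
partners at the contact threshold, and computes the modeled-residue
accounting for the window (e.g. 12 of a 25-residue tail for bovine
rhodopsin, window 324-348, modeled 324-335).

Tail boundaries are construct-specific, so the shipped rhodopsin
definition (``gprotiface/data/rhodopsin_ctail.json``) is a default, not a
constraint: every operation accepts an explicit :class:`TailAnnotation`.
Phosphosites are static bookkeeping for cross-state comparison, not a
computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .contacts import Contact, ContactMap, residue_contacts
from .model import ChainRoleAssignment, Residue, Structure

__all__ = ["TailAnnotation", "TailInterfaceReport", "extract_tail", "tail_interface",
           "rhodopsin_tail_annotation"]


@dataclass
class TailAnnotation:
    """Author-numbered definition of a receptor C-tail."""

    receptor_id: str
    h8_end: int
    tail_range: tuple[int, int]
    full_length_tail: tuple[int, int]
    hinges: list[int] = field(default_factory=list)
    phosphosites: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tail_range = tuple(self.tail_range)
        self.full_length_tail = tuple(self.full_length_tail)
        fs, fe = self.full_length_tail
        ts, te = self.tail_range
        if not (fs <= ts <= te <= fe):
            raise ValueError("tail_range must lie within full_length_tail")
        if self.h8_end >= ts:
            raise ValueError("h8_end must precede the tail window")

    @property
    def full_length(self) -> int:
        return self.full_length_tail[1] - self.full_length_tail[0] + 1

    @classmethod
    def from_json(cls, path) -> "TailAnnotation":
        with open(path) as fh:
            payload = json.load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "TailAnnotation":
        return cls(
            receptor_id=payload["receptor_id"],
            h8_end=payload["h8_end"],
            tail_range=tuple(payload["tail_range"]),
            full_length_tail=tuple(payload["full_length_tail"]),
            hinges=list(payload.get("hinges", [])),
            phosphosites=list(payload.get("phosphosites", [])),
        )


def rhodopsin_tail_annotation() -> TailAnnotation:
    """The shipped bovine rhodopsin tail definition (window 324-348)."""
    with resources.files("gprotiface.data").joinpath("rhodopsin_ctail.json").open() as fh:
        return TailAnnotation._from_payload(json.load(fh))


@dataclass
class TailInterfaceReport:
    """Tail partners on Galpha/Gbeta plus the modeled-residue accounting."""

    receptor_id: str
    partners_galpha: list[Contact]
    partners_gbeta: list[Contact]
    modeled_count: int
    modeled_fraction: float
    tail_range: tuple[int, int]
    full_length_tail: tuple[int, int]
    threshold: float

    def to_dict(self) -> dict:
        def side(contact: Contact) -> dict:
            return {
                "chain": contact.res_b.chain_id,
                "seq_id": contact.res_b.seq_id,
                "name": contact.res_b.name,
                "generic_label": contact.res_b.generic_label,
                "segment": contact.res_b.segment,
                "tail_residue": f"{contact.res_a.name}{contact.res_a.seq_id}",
                "min_dist": round(contact.min_dist, 2),
            }

        return {
            "receptor_id": self.receptor_id,
            "tail_range": list(self.tail_range),
            "full_length_tail": list(self.full_length_tail),
            "modeled_count": self.modeled_count,
            "modeled_fraction": self.modeled_fraction,
            "threshold": self.threshold,
            "partners_galpha": [side(c) for c in self.partners_galpha],
            "partners_gbeta": [side(c) for c in self.partners_gbeta],
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def extract_tail(
    s: Structure, roles: ChainRoleAssignment, tail_def: TailAnnotation
) -> list[Residue]:
    """Ordered modeled residues of the receptor chain inside the tail window."""
    receptor_chain_id = roles.chain_for("receptor")
    if receptor_chain_id is None:
        raise ValueError(f"{s.id}: no chain assigned the receptor role")
    chain = s.chain(receptor_chain_id)
    if chain is None:
        raise ValueError(f"{s.id}: receptor chain {receptor_chain_id} absent")
    lo, hi = tail_def.tail_range
    residues = [r for r in chain.residues if lo <= r.seq_id <= hi]
    residues.sort(key=lambda r: (r.seq_id, r.icode))
    return residues


def tail_interface(
    s: Structure,
    roles: ChainRoleAssignment,
    tail_def: TailAnnotation,
    threshold: float = 4.0,
) -> TailInterfaceReport:
    """Contacts of the modeled tail with Galpha and Gbeta, plus accounting.

    Partner lists are exactly the rows of the full receptor-Galpha and
    receptor-Gbeta contact maps restricted to tail residues, computed with
    the standard contact policies.
    """
    tail_residues = extract_tail(s, roles, tail_def)
    modeled_count = len(tail_residues)
    lo, hi = tail_def.tail_range

    def tail_rows(cm: ContactMap) -> list[Contact]:
        return [c for c in cm.contacts if lo <= c.res_a.seq_id <= hi]

    partners: dict[str, list[Contact]] = {}
    for role in ("Galpha", "Gbeta"):
        if roles.chain_for(role) is None:
            partners[role] = []
            continue
        cm = residue_contacts(s, roles, pair=("receptor", role), threshold=threshold)
        partners[role] = tail_rows(cm)

    return TailInterfaceReport(
        receptor_id=tail_def.receptor_id,
        partners_galpha=partners["Galpha"],
        partners_gbeta=partners["Gbeta"],
        modeled_count=modeled_count,
        modeled_fraction=modeled_count / tail_def.full_length,
        tail_range=tail_def.tail_range,
        full_length_tail=tail_def.full_length_tail,
        threshold=threshold,
    )
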