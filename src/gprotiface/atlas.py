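"""Cross-complex contact conservation in generic coordinates.

Per-complex contact maps (receptor vs Galpha) are aggregated into an atlas
keyed by (Galpha generic position, receptor position-or-segment).  A pair
is *conserved* in a G-protein subtype group when it is present in every
member of the group (the fraction is configurable but defaults to 1.0),
and *subtype-specific* when it is conserved in exactly one group.  This is
the operation that recovers, for example, the Gi/o anchors at H5.24 and
H5.26 and the Gs anchors at H5.12/H5.17/H5.26 from a cohort of complexes.

Conservation is positional, never identity-based: the residue identities
at each position (e.g. Tyr vs Phe at H5.26) are carried along for the
report but are not required to match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .contacts import Contact, ContactMap

__all__ = [
    "CohortMember",
    "CohortSpec",
    "ConservationTable",
    "build_atlas",
    "subtype_specific_anchors",
    "position_partner_profile",
    "loop_interface_report",
]

SUBTYPES = ("Gi/o", "Gs", "Gq/11", "Go-mini")


@dataclass(frozen=True)
class CohortMember:
    complex_id: str
    subtype: str
    receptor_class: str = "A"


@dataclass
class CohortSpec:
    members: list[CohortMember]

    def __post_init__(self) -> None:
        ids = [m.complex_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate complex_ids in cohort")
        for m in self.members:
            if m.subtype not in SUBTYPES:
                raise ValueError(f"unknown subtype {m.subtype!r}")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for m in self.members:
            if m.subtype not in seen:
                seen.append(m.subtype)
        return seen

    def members_of(self, group: str) -> list[CohortMember]:
        return [m for m in self.members if m.subtype == group]


def _pair_key(contact: Contact, receptor_resolution: str) -> Optional[tuple[str, str]]:
    """Atlas key of a receptor(res_a)-Galpha(res_b) contact, or None.

    The Galpha side must carry a generic label; the receptor side is keyed
    by label or by segment depending on the resolution.
    """
    galpha = contact.res_b.generic_label
    if galpha is None:
        return None
    if receptor_resolution == "label":
        if contact.res_a.generic_label is None:
            return None
        return (galpha, contact.res_a.generic_label)
    if receptor_resolution == "segment":
        return (galpha, contact.res_a.segment or "unassigned")
    raise ValueError(f"unknown receptor resolution {receptor_resolution!r}")


@dataclass
class ConservationTable:
    """Presence matrix of (Galpha label, receptor key) pairs over a cohort."""

    cohort: CohortSpec
    receptor_resolution: str
    threshold: float
    # (galpha_label, receptor_key) -> complex_id -> '1' | '0' | 'U'
    presence: dict[tuple[str, str], dict[str, str]]
    # (galpha_label, receptor_key) -> complex_id -> residue identity strings
    identities: dict[tuple[str, str], dict[str, list[str]]]
    conserved_fraction: float = 1.0
    conserved_in: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.conserved_in:
            self.conserved_in = {key: self._conserved_groups(key) for key in self.presence}

    def _conserved_groups(self, key: tuple[str, str]) -> list[str]:
        groups = []
        row = self.presence[key]
        for group in self.cohort.groups:
            members = self.cohort.members_of(group)
            n_present = sum(1 for m in members if row.get(m.complex_id) == "1")
            if members and n_present / len(members) >= self.conserved_fraction:
                groups.append(group)
        return groups

    def conserved_pairs(self, group: str) -> set[tuple[str, str]]:
        if group not in self.cohort.groups:
            raise ValueError(f"group {group!r} not in cohort (has {self.cohort.groups})")
        return {key for key, groups in self.conserved_in.items() if group in groups}

    def to_dataframe(self) -> pd.DataFrame:
        member_ids = [m.complex_id for m in self.cohort.members]
        rows = []
        for (galpha, rkey), row in sorted(self.presence.items()):
            record = {"galpha_label": galpha, "receptor_key": rkey}
            for cid in member_ids:
                record[cid] = row.get(cid, "0")
            record["conserved_in"] = ",".join(self.conserved_in[(galpha, rkey)]) or "."
            rows.append(record)
        return pd.DataFrame(rows, columns=["galpha_label", "receptor_key", *member_ids,
                                           "conserved_in"])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# receptor_resolution: {self.receptor_resolution}\n")
            fh.write(f"# threshold_A: {self.threshold}\n")
            fh.write(f"# conserved_fraction: {self.conserved_fraction}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)


def build_atlas(
    maps: Mapping[str, ContactMap],
    cohort: CohortSpec,
    receptor_resolution: str = "segment",
    annotated_segments: Optional[Mapping[str, set]] = None,
    conserved_fraction: float = 1.0,
) -> ConservationTable:
    """Aggregate per-complex receptor-Galpha maps into a conservation table.

    All maps must have been computed at the same threshold with the same
    policies (mixed thresholds are non-comparable and rejected).  At
    segment resolution a pair is present in a complex iff at least one
    residue of that segment contacts the Galpha position there.

    ``annotated_segments`` maps complex_id to the receptor segments with
    modeled residues; when given, absence of a pair whose segment is not
    modeled in a complex is flagged ``U`` (unresolved) rather than ``0``,
    so absence-by-disorder stays distinguishable from absence-by-distance.
    ``U`` still counts as absent for conservation.
    """
    missing = [m.complex_id for m in cohort.members if m.complex_id not in maps]
    if missing:
        raise ValueError(f"cohort members without a contact map: {missing}")
    thresholds = {maps[m.complex_id].threshold for m in cohort.members}
    if len(thresholds) > 1:
        raise ValueError(f"mixed contact thresholds across maps: {sorted(thresholds)}")

    presence: dict[tuple[str, str], dict[str, str]] = {}
    identities: dict[tuple[str, str], dict[str, list[str]]] = {}
    for member in cohort.members:
        cm = maps[member.complex_id]
        for contact in cm.contacts:
            key = _pair_key(contact, receptor_resolution)
            if key is None:
                continue
            presence.setdefault(key, {})[member.complex_id] = "1"
            ident = (
                f"{contact.res_b.name}{contact.res_b.seq_id}-"
                f"{contact.res_a.name}{contact.res_a.seq_id}"
            )
            identities.setdefault(key, {}).setdefault(member.complex_id, []).append(ident)

    for key, row in presence.items():
        for member in cohort.members:
            if member.complex_id in row:
                continue
            flag = "0"
            if (
                receptor_resolution == "segment"
                and annotated_segments is not None
                and key[1] not in annotated_segments.get(member.complex_id, set())
            ):
                flag = "U"
            row[member.complex_id] = flag

    return ConservationTable(
        cohort=cohort,
        receptor_resolution=receptor_resolution,
        threshold=thresholds.pop() if thresholds else 0.0,
        presence=presence,
        identities=identities,
        conserved_fraction=conserved_fraction,
    )


def subtype_specific_anchors(
    table: ConservationTable, group: str
) -> pd.DataFrame:
    """Rows conserved in ``group`` and in no other group of the cohort.

    With a single-group cohort no specificity claim is possible: the
    conserved rows are returned with ``non_specific=True``.  Per-complex
    residue identities are attached (e.g. the Gly at H5.24 in each Gi/o
    member).
    """
    if group not in table.cohort.groups:
        raise ValueError(f"group {group!r} not in cohort (has {table.cohort.groups})")
    single_group = len(table.cohort.groups) < 2
    rows = []
    for key, groups in sorted(table.conserved_in.items()):
        if group not in groups:
            continue
        if not single_group and len(groups) > 1:
            continue  # conserved in another group too -> not specific
        galpha, rkey = key
        rows.append(
            {
                "galpha_label": galpha,
                "receptor_key": rkey,
                "group": group,
                "non_specific": single_group,
                "identities": {
                    m.complex_id: table.identities.get(key, {}).get(m.complex_id, [])
                    for m in table.cohort.members_of(group)
                },
            }
        )
    return pd.DataFrame(rows, columns=["galpha_label", "receptor_key", "group",
                                       "non_specific", "identities"])


def position_partner_profile(
    maps: Mapping[str, ContactMap],
    galpha_label: str,
    cohort: Optional[CohortSpec] = None,
) -> pd.DataFrame:
    """Receptor partners of one Galpha generic position, per complex.

    Partners are reported as generic labels where available, otherwise as
    ``chain:seq_id``; the receptor class is attached when a cohort is given
    so the profile reads class-stratified (e.g. H5.17 against 5.68 in
    class A vs 5.64 in class B).
    """
    classes = {m.complex_id: m.receptor_class for m in cohort.members} if cohort else {}
    rows = []
    for complex_id, cm in maps.items():
        partners = sorted(
            {
                c.res_a.generic_label or f"{c.res_a.chain_id}:{c.res_a.seq_id}"
                for c in cm.contacts
                if c.res_b.generic_label == galpha_label
            }
        )
        if partners:
            rows.append(
                {
                    "complex_id": complex_id,
                    "receptor_class": classes.get(complex_id, "."),
                    "partners": partners,
                }
            )
    return pd.DataFrame(rows, columns=["complex_id", "receptor_class", "partners"])


def loop_interface_report(
    maps: Mapping[str, ContactMap],
    cohort: CohortSpec,
    modeled_segments: Optional[Mapping[str, set]] = None,
) -> pd.DataFrame:
    """Galpha segments contacted by receptor ICL2 and ICL3, per complex.

    A loop with no modeled residues (per ``modeled_segments``) is reported
    as ``unresolved``; a modeled loop with no contacts is reported with an
    empty segment set — the two kinds of absence mean different things.
    """
    rows = []
    for member in cohort.members:
        cm = maps.get(member.complex_id)
        if cm is None:
            raise ValueError(f"no contact map for cohort member {member.complex_id}")
        record = {"complex_id": member.complex_id, "subtype": member.subtype}
        for loop in ("ICL2", "ICL3"):
            if (
                modeled_segments is not None
                and loop not in modeled_segments.get(member.complex_id, set())
            ):
                record[loop] = "unresolved"
                continue
            segments = sorted(
                {
                    c.res_b.segment or "unassigned"
                    for c in cm.contacts
                    if c.res_a.segment == loop
                }
            )
            record[loop] = segments
        rows.append(record)
    return pd.DataFrame(rows, columns=["complex_id", "subtype", "ICL2", "ICL3"])
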