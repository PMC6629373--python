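"""Synthetic coordinate fixtures with exact ground truth.

Every pipeline stage is testable without downloading a single deposited
structure: ideal helical chains stand in for transmembrane helices and the
Galpha alpha5 helix, inter-chain contacts are *planted* at controlled
minimum atomic distances, and whole cohorts of complexes share a planted
"conserved" contact pattern per G-protein subtype group plus per-complex
noise contacts.

Geometry of a planted contact: chains are laid out >=100 A apart so that
no unplanned inter-chain residue pair can fall below the 4.5 A separation
guarantee (a 0.5 A guard band around the 4.0 A detection threshold).  Each
planted pair is then realised by one probe atom added to the partner
residue, placed on the outward radial of the target residue at exactly the
requested distance.  Because the probe points away from the helix body,
neighbouring residues stay outside the guard band; a brute-force
post-verification enforces both guarantees and raises if a spec defeats
them.  The packing is deliberately unphysical — the contact criterion is
any-atom distance, which is all that matters here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .contacts import Contact, ContactMap, ContactSide
from .model import Atom, Chain, ChainRoleAssignment, Residue, ResidueRef, Structure
from .numbering import GenericLabel, NumberingMap, annotate, write_numbering_map
from .structure_io import CohortManifestEntry, write_manifest, write_structure

__all__ = [
    "HelixSpec",
    "PlantedContact",
    "PlantedComplexSpec",
    "CohortTruth",
    "PlacementError",
    "make_helix",
    "make_planted_complex",
    "make_cohort",
    "CohortResult",
    "brute_force_contacts",
    "receptor_template_map",
    "galpha_template_map",
    "RECEPTOR_TEMPLATE_SEGMENTS",
]

GUARD_BAND = 4.5  # minimum separation of non-planted inter-chain pairs, A
CHAIN_SPACING = 150.0  # A between chain origins


class PlacementError(ValueError):
    """Planted geometry cannot be constructed."""


@dataclass
class HelixSpec:
    """An ideal alpha-helical Calpha trace (optionally with pseudo side chains)."""

    n_res: int
    chain_id: str = "A"
    start_seq_id: int = 1
    rise: float = 1.5          # A per residue along the axis
    twist: float = 100.0       # degrees per residue
    ca_radius: float = 2.3     # A, Calpha distance from the helix axis
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    sidechain: bool = True     # emit one pseudo side-chain atom (CB) per residue
    cb_extra_radius: float = 1.5
    resnames: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if self.n_res < 1:
            raise ValueError("n_res must be >= 1")
        axis = np.asarray(self.axis, float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("axis must be non-zero")
        self.axis = tuple(axis / norm)
        if self.resnames is not None and len(self.resnames) != self.n_res:
            raise ValueError("resnames length must equal n_res")


def _helix_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to the axis."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def make_helix(spec: HelixSpec) -> Structure:
    """Build a single-chain ideal helix; deterministic for a given spec.

    Consecutive Calpha-Calpha distance is the helix chord
    ``sqrt(rise**2 + (2 r sin(twist/2))**2)``.
    """
    axis = np.asarray(spec.axis, float)
    origin = np.asarray(spec.origin, float)
    u, v = _helix_frame(axis)
    residues = []
    for i in range(spec.n_res):
        theta = np.deg2rad(spec.twist * i)
        radial = np.cos(theta) * u + np.sin(theta) * v
        ca = origin + spec.rise * i * axis + spec.ca_radius * radial
        atoms = [Atom("CA", "C", ca)]
        if spec.sidechain:
            cb = origin + spec.rise * i * axis + (spec.ca_radius + spec.cb_extra_radius) * radial
            atoms.append(Atom("CB", "C", cb))
        name = spec.resnames[i] if spec.resnames is not None else "ALA"
        residues.append(
            Residue(
                chain_id=spec.chain_id,
                seq_id=spec.start_seq_id + i,
                icode="",
                name=name,
                atoms=atoms,
                is_polymer=True,
            )
        )
    return Structure(id=f"helix_{spec.chain_id}", chains=[Chain(spec.chain_id, residues)])


@dataclass(frozen=True)
class PlantedContact:
    res_a: ResidueRef
    res_b: ResidueRef
    distance: float

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise PlacementError(f"planted distance must be positive, got {self.distance}")


@dataclass
class PlantedComplexSpec:
    complex_id: str
    chains: list[tuple[HelixSpec, str]]  # (helix, role)
    planted_contacts: list[PlantedContact] = field(default_factory=list)
    numbering: list[NumberingMap] = field(default_factory=list)
    truth_threshold: float = 4.0

    def roles(self) -> ChainRoleAssignment:
        return ChainRoleAssignment(
            self.complex_id, {spec.chain_id: role for spec, role in self.chains}
        )


def brute_force_contacts(
    s: Structure, chain_a: str, chain_b: str, threshold: float = 4.0
) -> dict[tuple, tuple[float, str, str]]:
    """All-pairs reference contact search (the oracle the k-d tree must match).

    Returns ``{(key_a, key_b): (min_dist, atom_a, atom_b)}`` over residue
    pairs with minimum heavy-atom distance strictly below the threshold.
    """
    ca = s.chain(chain_a)
    cb = s.chain(chain_b)
    out: dict[tuple, tuple[float, str, str]] = {}
    for ra in ca.residues:
        for rb in cb.residues:
            bestd, besta, bestb = np.inf, "", ""
            for aa in ra.heavy_atoms():
                for ab in rb.heavy_atoms():
                    d = float(np.linalg.norm(aa.position - ab.position))
                    if d < bestd:
                        bestd, besta, bestb = d, aa.name, ab.name
            if bestd < threshold:
                out[(ra.key, rb.key)] = (bestd, besta, bestb)
    return out


def _min_interchain_distances(s: Structure) -> dict[tuple, float]:
    """Minimum heavy-atom distance for every inter-chain residue pair."""
    from scipy.spatial.distance import cdist

    stacked = []
    for chain in s.chains:
        coords, owners = [], []
        for idx, res in enumerate(chain.residues):
            for atom in res.heavy_atoms():
                coords.append(atom.position)
                owners.append(idx)
        stacked.append((chain, np.asarray(coords), np.asarray(owners)))

    out: dict[tuple, float] = {}
    for i in range(len(stacked)):
        chain_a, ca, oa = stacked[i]
        for j in range(i + 1, len(stacked)):
            chain_b, cb, ob = stacked[j]
            if not len(ca) or not len(cb):
                continue
            dm = cdist(ca, cb)
            na, nb = len(chain_a.residues), len(chain_b.residues)
            mins = np.full((na, nb), np.inf)
            np.minimum.at(mins, (oa[:, None], ob[None, :]), dm)
            for ia in range(na):
                for ib in range(nb):
                    out[(chain_a.residues[ia].key, chain_b.residues[ib].key)] = float(mins[ia, ib])
    return out


def make_planted_complex(spec: PlantedComplexSpec) -> tuple[Structure, ContactMap]:
    """Assemble a multi-chain complex with contacts planted at exact distances.

    Returns the (annotated) structure and the ground-truth contact map:
    exactly the planted pairs whose target distance is below
    ``spec.truth_threshold``.  Raises :class:`PlacementError` on
    conflicting targets for the same residue pair or when post-hoc
    verification finds the construction violated the separation guarantee.
    """
    seen_pairs: dict[frozenset, float] = {}
    planted: list[PlantedContact] = []
    for pc in spec.planted_contacts:
        key = frozenset([pc.res_a, pc.res_b])
        if key in seen_pairs:
            if abs(seen_pairs[key] - pc.distance) > 1e-9:
                raise PlacementError(
                    f"conflicting targets for pair {pc.res_a}/{pc.res_b}: "
                    f"{seen_pairs[key]} vs {pc.distance}"
                )
            continue  # exact duplicate
        seen_pairs[key] = pc.distance
        planted.append(pc)

    # lay the chains out far apart
    chains: list[Chain] = []
    axes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for k, (hspec, _role) in enumerate(spec.chains):
        offset = np.array([CHAIN_SPACING * k, 0.0, 0.0])
        shifted = HelixSpec(
            n_res=hspec.n_res,
            chain_id=hspec.chain_id,
            start_seq_id=hspec.start_seq_id,
            rise=hspec.rise,
            twist=hspec.twist,
            ca_radius=hspec.ca_radius,
            origin=tuple(np.asarray(hspec.origin, float) + offset),
            axis=hspec.axis,
            sidechain=hspec.sidechain,
            cb_extra_radius=hspec.cb_extra_radius,
            resnames=hspec.resnames,
        )
        helix = make_helix(shifted)
        chains.append(helix.chains[0])
        axes[hspec.chain_id] = (np.asarray(shifted.origin, float), np.asarray(shifted.axis, float))

    structure = Structure(id=spec.complex_id, chains=chains)

    probe_counter: dict[tuple, int] = {}
    anchor_counter: dict[tuple, dict[str, list[int]]] = {}
    probe_names: dict[frozenset, tuple[str, str]] = {}
    for pc in planted:
        try:
            res_a = pc.res_a.resolve(structure)
            res_b = pc.res_b.resolve(structure)
        except KeyError as exc:
            raise PlacementError(str(exc)) from exc
        if res_a.chain_id == res_b.chain_id:
            raise PlacementError("planted contacts must be inter-chain")
        # outermost helix-body atom of the target residue, and its outward radial
        anchor = res_a.atom("CB") or res_a.atom("CA")
        if anchor is None:
            raise PlacementError(f"residue {pc.res_a} has no CA/CB anchor atom")
        origin_a, axis_a = axes[res_a.chain_id]
        along = np.dot(anchor.position - origin_a, axis_a)
        radial = anchor.position - (origin_a + along * axis_a)
        norm = np.linalg.norm(radial)
        if norm < 1e-9:
            raise PlacementError(f"residue {pc.res_a} lies on its helix axis")
        radial_u = radial / norm
        tangent_u = np.cross(axis_a, radial_u)
        # probes anchored on one residue but belonging to different partner
        # chains must stay >= GUARD_BAND apart (they form unplanned
        # inter-chain pairs): give each partner chain its own base direction
        # in the radial/tangential plane (0 / +90 / -90 degrees); same-chain
        # probes only need to avoid exact overlap (small 12-degree steps)
        per_chain = anchor_counter.setdefault(res_a.key, {})
        if res_b.chain_id not in per_chain:
            if len(per_chain) >= 3:
                raise PlacementError(
                    f"residue {pc.res_a} anchors probes to more than 3 partner chains"
                )
            per_chain[res_b.chain_id] = [len(per_chain), 0]
        c, j = per_chain[res_b.chain_id]
        per_chain[res_b.chain_id][1] += 1
        theta = np.deg2rad((0.0, 90.0, -90.0)[c] + 12.0 * j)
        direction = np.cos(theta) * radial_u + np.sin(theta) * tangent_u
        probe_pos = anchor.position + pc.distance * direction
        n = probe_counter.get(res_b.key, 0) + 1
        probe_counter[res_b.key] = n
        probe_name = f"XP{n}"
        res_b.atoms.append(Atom(probe_name, "C", probe_pos))
        probe_names[frozenset([pc.res_a, pc.res_b])] = (anchor.name, probe_name)

    if spec.numbering:
        annotate(structure, spec.numbering)

    # post-hoc verification of both guarantees
    planted_lookup = {
        frozenset([(pc.res_a.chain_id, pc.res_a.seq_id, pc.res_a.icode),
                   (pc.res_b.chain_id, pc.res_b.seq_id, pc.res_b.icode)]): pc.distance
        for pc in planted
    }
    for (key_a, key_b), dist in _min_interchain_distances(structure).items():
        target = planted_lookup.get(frozenset([key_a, key_b]))
        if target is None:
            if dist < GUARD_BAND:
                raise PlacementError(
                    f"unplanned pair {key_a}/{key_b} at {dist:.2f} A breaches the "
                    f"{GUARD_BAND} A separation guarantee"
                )
        elif abs(dist - target) > 1e-3:
            raise PlacementError(
                f"planted pair {key_a}/{key_b}: achieved {dist:.4f} A, target {target}"
            )

    truth_contacts = []
    for pc in sorted(planted,
                     key=lambda p: (p.res_a.chain_id, p.res_a.seq_id, p.res_a.icode,
                                    p.res_b.chain_id, p.res_b.seq_id)):
        if pc.distance >= spec.truth_threshold:
            continue
        res_a = pc.res_a.resolve(structure)
        res_b = pc.res_b.resolve(structure)
        atom_pair = probe_names[frozenset([pc.res_a, pc.res_b])]
        truth_contacts.append(
            Contact(
                ContactSide.from_residue(res_a),
                ContactSide.from_residue(res_b),
                min_dist=pc.distance,
                atom_pair=atom_pair,
            )
        )
    truth = ContactMap(
        complex_id=spec.complex_id,
        role_pair=("planted_a", "planted_b"),
        threshold=spec.truth_threshold,
        contacts=truth_contacts,
        provenance={"generator": "make_planted_complex"},
    )
    return structure, truth


# ---------------------------------------------------------------------------
# cohort generation: receptor/Galpha template with planted conservation truth
# ---------------------------------------------------------------------------

#: segment -> (start_seq, end_seq, BW helix prefix, BW start position)
#: a compact receptor template covering the cytoplasmic interface segments
RECEPTOR_TEMPLATE_SEGMENTS: dict[str, tuple[int, int, Optional[str], int]] = {
    "TM3": (1, 8, "3", 46),
    "ICL2": (9, 14, "34", 50),
    "TM5": (15, 26, "5", 61),
    "TM6": (27, 38, "6", 25),
    "TM7": (39, 46, "7", 50),
    "H8": (47, 54, "8", 47),
    "Ctail": (55, 60, None, 0),
}

GALPHA_START_SEQ = 329  # alpha5 = last 26 residues, H5.01-H5.26


def receptor_template_map(structure_id: str, chain_id: str = "R") -> NumberingMap:
    m = NumberingMap(structure_id, chain_id)
    for segment, (lo, hi, prefix, bw_start) in RECEPTOR_TEMPLATE_SEGMENTS.items():
        for seq in range(lo, hi + 1):
            label = None
            if prefix is not None:
                label = GenericLabel("BW", f"{prefix}.{bw_start + (seq - lo)}")
            m.add(seq, "", label, segment)
    return m


def galpha_template_map(structure_id: str, chain_id: str = "G") -> NumberingMap:
    m = NumberingMap(structure_id, chain_id)
    for i in range(26):
        m.add(GALPHA_START_SEQ + i, "", GenericLabel("CGN", f"H5.{i + 1:02d}"), "alpha5")
    return m


def _receptor_seq_for_key(key: str, rng: Optional[np.random.Generator]) -> int:
    """Resolve a receptor key (segment name or BW label) to a template seq_id."""
    if key in RECEPTOR_TEMPLATE_SEGMENTS:
        lo, hi, _, _ = RECEPTOR_TEMPLATE_SEGMENTS[key]
        if rng is None:
            return (lo + hi) // 2
        return int(rng.integers(lo, hi + 1))
    for segment, (lo, hi, prefix, bw_start) in RECEPTOR_TEMPLATE_SEGMENTS.items():
        if prefix is None:
            continue
        for seq in range(lo, hi + 1):
            if f"{prefix}.{bw_start + (seq - lo)}" == key:
                return seq
    raise PlacementError(f"receptor key {key!r} not in the synthetic template")


def _galpha_seq_for_label(label: str) -> int:
    if label.startswith("H5."):
        pos = int(label.split(".")[1])
        if 1 <= pos <= 26:
            return GALPHA_START_SEQ + pos - 1
    raise PlacementError(f"Galpha label {label!r} not in the synthetic template")


@dataclass
class CohortTruth:
    """Planted conservation ground truth for a synthetic cohort.

    Pairs are (Galpha generic label, receptor key), where the receptor key
    is a segment name or a BW label of the synthetic template.  The
    invariant — no noise pair present in every member of any group — is
    what prevents noise from masquerading as a conserved anchor.
    """

    conserved_pairs_by_group: dict[str, set]
    noise_pairs_by_member: dict[str, set] = field(default_factory=dict)

    def validate(self, members_by_group: dict[str, list[str]]) -> None:
        for group, member_ids in members_by_group.items():
            if not member_ids:
                continue
            conserved = self.conserved_pairs_by_group.get(group, set())
            noise_sets = [self.noise_pairs_by_member.get(cid, set()) for cid in member_ids]
            everywhere = set.intersection(*noise_sets) if noise_sets else set()
            bad = everywhere - conserved
            if bad:
                raise ValueError(
                    f"noise pairs present in every member of group {group}: {sorted(bad)}"
                )


@dataclass
class CohortResult:
    members: list  # (CohortMember-like tuple, Structure, [NumberingMap])
    truth: CohortTruth
    manifest: list[CohortManifestEntry]
    outdir: Optional[Path] = None


def make_cohort(
    n_per_group: int,
    groups: Sequence[str],
    truth: CohortTruth,
    seed: int,
    outdir=None,
    receptor_class_by_group: Optional[dict[str, str]] = None,
    n_noise_max: int = 6,
    contact_distance: float = 3.5,
) -> CohortResult:
    """Generate a cohort of synthetic complexes with a planted conserved pattern.

    Every member of a group contains its group's conserved pairs; each
    member additionally receives its own random noise pairs (at most
    ``n_noise_max``), drawn so that no noise pair occurs in every member
    of any group.  With ``outdir`` set, PDB files, numbering-map TSVs, a
    cohort manifest and the truth JSON are written side by side; the same
    seed always produces the same tree.
    """
    rng = np.random.default_rng(seed)
    classes = receptor_class_by_group or {}
    members_by_group = {
        group: [f"{group.replace('/', '')}-{i + 1}" for i in range(n_per_group)]
        for group in groups
    }

    user_noise = bool(truth.noise_pairs_by_member)
    if user_noise:
        truth.validate(members_by_group)
        noise_by_member = {k: set(v) for k, v in truth.noise_pairs_by_member.items()}
    else:
        # candidate noise pool: any (H5.xx, segment) pair not conserved anywhere
        all_conserved = set().union(*truth.conserved_pairs_by_group.values()) \
            if truth.conserved_pairs_by_group else set()
        segments = [s for s in RECEPTOR_TEMPLATE_SEGMENTS if s != "Ctail"]
        pool = [
            (f"H5.{i:02d}", seg)
            for i in range(1, 27)
            for seg in segments
            if (f"H5.{i:02d}", seg) not in all_conserved
        ]
        noise_by_member = {}
        for group in groups:
            for cid in members_by_group[group]:
                n_noise = int(rng.integers(0, n_noise_max + 1))
                picks = rng.choice(len(pool), size=min(n_noise, len(pool)), replace=False)
                noise_by_member[cid] = {pool[int(p)] for p in picks}
            # enforce the invariant: no noise pair in every group member
            ids = members_by_group[group]
            if len(ids) > 1:
                everywhere = set.intersection(*(noise_by_member[c] for c in ids))
            else:
                everywhere = set(noise_by_member[ids[0]])
            for pair in sorted(everywhere):
                victim = ids[int(rng.integers(0, len(ids)))]
                noise_by_member[victim].discard(pair)

    echo = CohortTruth(
        conserved_pairs_by_group={g: set(truth.conserved_pairs_by_group.get(g, set()))
                                  for g in groups},
        noise_pairs_by_member=noise_by_member,
    )
    echo.validate(members_by_group)

    results = []
    manifest_entries = []
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    for group in groups:
        conserved = sorted(echo.conserved_pairs_by_group.get(group, set()))
        for cid in members_by_group[group]:
            receptor = HelixSpec(n_res=60, chain_id="R", start_seq_id=1)
            galpha = HelixSpec(n_res=26, chain_id="G", start_seq_id=GALPHA_START_SEQ)
            maps = [receptor_template_map(cid), galpha_template_map(cid)]
            planted = []
            used_pairs = set()
            for galpha_label, rkey in conserved:
                rseq = _receptor_seq_for_key(rkey, rng=None)
                gseq = _galpha_seq_for_label(galpha_label)
                planted.append(PlantedContact(ResidueRef("R", rseq), ResidueRef("G", gseq),
                                              contact_distance))
                used_pairs.add((rseq, gseq))
            for galpha_label, rkey in sorted(noise_by_member.get(cid, set())):
                rseq = _receptor_seq_for_key(rkey, rng=rng)
                gseq = _galpha_seq_for_label(galpha_label)
                if (rseq, gseq) in used_pairs:
                    continue
                used_pairs.add((rseq, gseq))
                planted.append(PlantedContact(ResidueRef("R", rseq), ResidueRef("G", gseq),
                                              contact_distance))
            spec = PlantedComplexSpec(
                complex_id=cid,
                chains=[(receptor, "receptor"), (galpha, "Galpha")],
                planted_contacts=planted,
                numbering=maps,
            )
            structure, _truth_map = make_planted_complex(spec)
            results.append(((cid, group, classes.get(group, "A")), structure, maps))
            path = f"{cid}.pdb"
            manifest_entries.append(
                CohortManifestEntry(
                    structure_id=cid,
                    path=path,
                    receptor_chain="R",
                    galpha_chain="G",
                    gbeta_chain=".",
                    ggamma_chain=".",
                    subtype=group,
                    receptor_class=classes.get(group, "A"),
                )
            )
            if outdir is not None:
                write_structure(structure, outdir / path, format="PDB")
                write_numbering_map(maps, outdir / f"{cid}.numbering.tsv")

    if outdir is not None:
        write_manifest(manifest_entries, outdir / "manifest.tsv")
        payload = {
            "conserved_pairs_by_group": {
                g: sorted(map(list, pairs)) for g, pairs in echo.conserved_pairs_by_group.items()
            },
            "noise_pairs_by_member": {
                cid: sorted(map(list, pairs)) for cid, pairs in sorted(noise_by_member.items())
            },
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return CohortResult(members=results, truth=echo, manifest=manifest_entries, outdir=outdir)
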