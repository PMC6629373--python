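"""Generic residue numbering for receptors and G-protein subunits.

Three labelling schemes are supported:

* **BW** — Ballesteros-Weinstein receptor numbering, ``helix.position``
  (e.g. ``5.68``; ``12`` denotes the TM1-TM2/ICL1 region, ``8`` helix 8);
* **CGN** — common Galpha numbering, either the full
  ``domain.element.position`` form (``G.S6.02``) or the element shorthand
  (``H5.17``, ``H3.15``);
* **GBETA** — Gbeta beta-propeller blade annotation (``blade6``).

Labels and segment names are attached to residues from tab-separated
mapping tables, or transferred to a new sequence by pairwise global
alignment against an annotated reference.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import Align

from .model import Atom, Residue, Structure

__all__ = [
    "GenericLabel",
    "NumberingMap",
    "NumberingError",
    "RECEPTOR_SEGMENTS",
    "GALPHA_SEGMENTS",
    "GBETA_SEGMENTS",
    "load_numbering_map",
    "write_numbering_map",
    "annotate",
    "transfer_numbering",
    "select_by_labels",
    "LabelSelection",
    "label_set",
    "label_range",
]

RECEPTOR_SEGMENTS = frozenset(
    [f"TM{i}" for i in range(1, 8)]
    + ["H8", "ICL1", "ICL2", "ICL3", "ECL1", "ECL2", "ECL3", "Ctail", "Nterm"]
)
GALPHA_SEGMENTS = frozenset(
    ["alphaN", "alphaN_beta1", "beta1", "beta2_beta3", "alpha4_beta6", "alpha5", "H3", "Ras", "AH"]
)
GBETA_SEGMENTS = frozenset(f"blade{i}" for i in range(1, 8))
ALL_SEGMENTS = RECEPTOR_SEGMENTS | GALPHA_SEGMENTS | GBETA_SEGMENTS

_BW_RE = re.compile(r"^\d+\.\d+$")
# CGN: full form domain.element.position, or element shorthand like H5.17
_CGN_RE = re.compile(r"^(?:[A-Z]\.)?[A-Za-z]+\d*\.\d+$")
_GBETA_RE = re.compile(r"^blade[1-7]$")


class NumberingError(ValueError):
    """Raised for invalid labels, segments or mapping tables."""


@dataclass(frozen=True)
class GenericLabel:
    """A generic position label under one of the supported schemes."""

    scheme: str  # BW | CGN | GBETA
    text: str

    def __post_init__(self) -> None:
        if self.scheme == "BW":
            ok = bool(_BW_RE.match(self.text))
        elif self.scheme == "CGN":
            ok = bool(_CGN_RE.match(self.text))
        elif self.scheme == "GBETA":
            ok = bool(_GBETA_RE.match(self.text))
        else:
            raise NumberingError(f"unknown numbering scheme {self.scheme!r}")
        if not ok:
            raise NumberingError(f"label {self.text!r} does not match the {self.scheme} grammar")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.text


@dataclass
class NumberingMap:
    """Author residue numbers of one chain mapped to generic labels.

    ``entries`` maps ``(seq_id, icode)`` to ``(GenericLabel | None, segment)``.
    Each generic label may appear at most once per chain; a ``None`` label
    attaches only the segment (used e.g. for Gbeta blades, where one blade
    spans many residues).
    """

    structure_id: str
    chain_id: str
    entries: dict[tuple[int, str], tuple[Optional[GenericLabel], str]] = field(
        default_factory=dict
    )
    _label_texts: set = field(default_factory=set, repr=False, compare=False)

    def add(
        self, seq_id: int, icode: str, label: Optional[GenericLabel], segment: str
    ) -> None:
        key = (seq_id, icode)
        if key in self.entries:
            raise NumberingError(
                f"residue {seq_id}{icode} mapped twice in chain {self.chain_id}"
            )
        if segment not in ALL_SEGMENTS:
            raise NumberingError(f"unknown segment {segment!r}")
        if label is not None:
            if label.text in self._label_texts:
                raise NumberingError(
                    f"generic label {label.text} assigned twice in chain {self.chain_id}"
                )
            self._label_texts.add(label.text)
        self.entries[key] = (label, segment)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NumberingMap):
            return NotImplemented
        return (
            self.structure_id == other.structure_id
            and self.chain_id == other.chain_id
            and self.entries == other.entries
        )


def load_numbering_map(path, structure_id: str = "") -> list[NumberingMap]:
    """Read a tab-separated numbering table into per-chain maps.

    Columns: ``chain_id seq_id icode generic_label scheme segment``; icode
    '.' means blank; lines starting with '#' are comments.
    """
    path = Path(path)
    maps: dict[str, NumberingMap] = {}
    sid = structure_id or path.stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise NumberingError(f"{path}:{lineno}: expected 6 tab-separated fields")
            chain_id, seq_id, icode, text, scheme, segment = parts
            icode = "" if icode == "." else icode
            try:
                seq = int(seq_id)
            except ValueError as exc:
                raise NumberingError(f"{path}:{lineno}: bad seq_id {seq_id!r}") from exc
            label = None if text == "." else GenericLabel(scheme, text)
            m = maps.setdefault(chain_id, NumberingMap(sid, chain_id))
            try:
                m.add(seq, icode, label, segment)
            except NumberingError as exc:
                raise NumberingError(f"{path}:{lineno}: {exc}") from exc
    return list(maps.values())


def write_numbering_map(maps: Iterable[NumberingMap], path) -> None:
    """Write per-chain maps back to the tab-separated dialect."""
    with open(path, "w") as fh:
        fh.write("# chain_id\tseq_id\ticode\tgeneric_label\tscheme\tsegment\n")
        for m in maps:
            for (seq_id, icode), (label, segment) in sorted(m.entries.items()):
                text = label.text if label is not None else "."
                scheme = label.scheme if label is not None else "."
                fh.write(f"{m.chain_id}\t{seq_id}\t{icode or '.'}\t{text}\t{scheme}\t{segment}\n")


def annotate(s: Structure, maps: Iterable[NumberingMap]) -> list[str]:
    """Attach generic labels and segment names to residues, in place.

    Residues without a map entry stay unannotated.  Map entries pointing at
    residues absent from the coordinates (unmodeled regions are routine in
    deposited models) produce a warning-level report, returned as a list of
    messages.  Idempotent: re-annotating with the same maps is a no-op.
    """
    report: list[str] = []
    for m in maps:
        chain = s.chain(m.chain_id)
        if chain is None:
            msg = f"{s.id}: chain {m.chain_id} in map not present in structure"
            warnings.warn(msg)
            report.append(msg)
            continue
        index = {(r.seq_id, r.icode): r for r in chain.residues}
        for key, (label, segment) in m.entries.items():
            res = index.get(key)
            if res is None:
                what = label.text if label is not None else segment
                msg = f"{s.id}/{m.chain_id}: residue {key[0]}{key[1]} ({what}) not modeled"
                report.append(msg)
                continue
            if label is not None:
                res.generic_label = label
            res.segment = segment
    return report


_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def alignment_score(a: str, b: str) -> float:
    """Global affine-gap alignment score under the transfer parameters."""
    return _make_aligner().score(a, b)


def transfer_numbering(
    query_seq: str,
    ref_seq: str,
    ref_map: NumberingMap,
    min_identity: float = 0.3,
    structure_id: str = "",
    chain_id: str = "",
) -> NumberingMap:
    """Transfer labels from an annotated reference sequence to a query.

    Both sequences use the 20-letter amino-acid alphabet plus ``X``; map
    keys are interpreted as 1-based positions into ``ref_seq``, and the
    returned map is keyed by 1-based positions into ``query_seq``.  Labels
    are copied only across aligned (non-gap) columns.

    Raises :class:`NumberingError` when the alignment identity falls below
    ``min_identity``, since numbering transfer between distant sequences is
    unsafe.
    """
    if not query_seq or not ref_seq:
        raise NumberingError("sequences must be non-empty")
    for seq, which in ((query_seq, "query"), (ref_seq, "reference")):
        bad = set(seq.upper()) - _AA_ALPHABET
        if bad:
            raise NumberingError(f"{which} sequence contains invalid letters {sorted(bad)}")
    query_seq = query_seq.upper()
    ref_seq = ref_seq.upper()

    alignment = _make_aligner().align(query_seq, ref_seq)[0]
    aligned_pairs: list[tuple[int, int]] = []
    for (qs, qe), (rs, re_) in zip(*alignment.aligned):
        aligned_pairs.extend(zip(range(qs, qe), range(rs, re_)))
    if not aligned_pairs:
        raise NumberingError("sequences do not align")
    n_ident = sum(1 for q, r in aligned_pairs if query_seq[q] == ref_seq[r])
    identity = n_ident / max(len(query_seq), len(ref_seq))
    if identity < min_identity:
        raise NumberingError(
            f"alignment identity {identity:.2f} below floor {min_identity:.2f}; "
            "numbering transfer refused"
        )

    out = NumberingMap(structure_id or ref_map.structure_id, chain_id or ref_map.chain_id)
    ref_lookup = {seq_id: (label, segment) for (seq_id, _), (label, segment) in
                  ((k, v) for k, v in ref_map.entries.items())}
    for q, r in aligned_pairs:
        entry = ref_lookup.get(r + 1)
        if entry is not None:
            out.add(q + 1, "", entry[0], entry[1])
    return out


@dataclass
class LabelSelection:
    """Result of a label-driven residue/atom selection, in label order."""

    residues: list[Residue]
    atoms: list[Atom]
    missing: list[str]


def select_by_labels(
    s: Structure,
    labels: Sequence[str],
    atom_name: Optional[str] = None,
    chain_id: Optional[str] = None,
) -> LabelSelection:
    """Select annotated residues (or one named atom each) in label order.

    Labels that resolve to no modeled residue — or, with ``atom_name``, to a
    residue lacking that atom — are reported under ``missing`` rather than
    raising: unmodeled residues are routine.
    """
    by_label: dict[str, Residue] = {}
    pool = s.chain(chain_id).residues if chain_id else list(s.residues())
    for res in pool:
        if res.generic_label is not None:
            by_label.setdefault(res.generic_label.text, res)
    residues: list[Residue] = []
    atoms: list[Atom] = []
    missing: list[str] = []
    for text in labels:
        res = by_label.get(text)
        if res is None:
            missing.append(text)
            continue
        if atom_name is not None:
            atom = res.atom(atom_name)
            if atom is None:
                missing.append(text)
                continue
            atoms.append(atom)
        residues.append(res)
    return LabelSelection(residues=residues, atoms=atoms, missing=missing)


def _registry() -> dict[str, list[str]]:
    with resources.files("gprotiface.data").joinpath("label_sets.json").open() as fh:
        return json.load(fh)


def label_set(name: str) -> list[str]:
    """Look up a named label set from the shipped registry.

    Shipped sets include ``alpha5`` (H5.01-H5.26, the last 26 residues of
    Galpha), ``alpha5_frame`` (H5.11-H5.26, the superposition frame) and
    ``alpha5_hook`` (H5.22-H5.26, the C-terminal hook).
    """
    reg = _registry()
    if name not in reg:
        raise KeyError(f"unknown label set {name!r}; available: {sorted(reg)}")
    return list(reg[name])


def label_range(prefix: str, start: int, stop: int) -> list[str]:
    """Build labels like ``H5.11 .. H5.26`` (inclusive, zero-padded to 2)."""
    return [f"{prefix}.{i:02d}" for i in range(start, stop + 1)]
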