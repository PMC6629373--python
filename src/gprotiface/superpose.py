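"""Least-squares rigid-body superposition (Kabsch) on labeled Calpha sets.

The comparative analysis views every complex "from the G protein": each
structure is moved as a rigid body onto a reference by fitting the Calpha
atoms of the Galpha alpha5 positions H5.11-H5.26, the stretch that carries
the bulk of the receptor contacts.  The fit is the classic Kabsch solution
via SVD with a determinant sign correction so that only proper rotations
(no reflections) are returned; all frame atoms are weighted equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Structure
from .numbering import label_set, select_by_labels

__all__ = ["RigidTransform", "DegenerateGeometryError", "kabsch_fit", "superpose_on_alpha5",
           "SuperpositionResult"]

_ORTHO_TOL = 1e-6


class DegenerateGeometryError(ValueError):
    """Point set too small or too flat to define a unique rigid fit."""


@dataclass
class RigidTransform:
    """Proper rotation + translation mapping mobile coordinates onto a target.

    Applying the transform to a point x gives ``rotation @ x + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(self.rotation) - 1.0) > _ORTHO_TOL:
            raise ValueError("rotation must be proper (det +1)")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation must be orthonormal")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation, self.rmsd, self.n_atoms)

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd": self.rmsd,
            "n_atoms": self.n_atoms,
        }


def kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Fit the proper rigid motion minimizing RMSD of ``mobile`` onto ``target``.

    Point sets must be matched (same length, same order), contain at least
    three points, and be non-collinear.  Reflections are suppressed by the
    sign correction on the smallest singular direction.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape:
        raise ValueError(f"point sets differ in shape: {mobile.shape} vs {target.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be Nx3")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 matched points")

    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    X = mobile - cm
    Y = target - ct
    # collinearity check: second singular value of the centered set
    for pts, which in ((X, "mobile"), (Y, "target")):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] <= max(1e-8, 1e-8 * sv[0]):
            raise DegenerateGeometryError(f"{which} points are collinear or rank-deficient")

    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    moved = X @ R.T + ct
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return RigidTransform(R, t, rmsd, n)


@dataclass
class SuperpositionResult:
    """A complex moved into the reference frame plus the fit diagnostics."""

    structure: Structure
    transform: RigidTransform
    per_label_deviation: dict[str, float] = field(default_factory=dict)
    reference_id: str = ""
    frame_labels: list[str] = field(default_factory=list)


def superpose_on_alpha5(
    complex_structure: Structure,
    reference: Structure,
    frame_labels: list[str] | None = None,
) -> SuperpositionResult:
    """Move a whole complex into the reference frame fitted on alpha5 Calphas.

    Both structures must be annotated so that every frame label (default
    H5.11-H5.26) resolves to a Calpha atom; any missing label is a hard
    error naming the labels, keeping cross-complex frames comparable
    (no silent fit-on-subset).
    """
    labels = list(frame_labels) if frame_labels is not None else label_set("alpha5_frame")
    sel_mobile = select_by_labels(complex_structure, labels, atom_name="CA")
    sel_target = select_by_labels(reference, labels, atom_name="CA")
    missing = sorted(set(sel_mobile.missing) | set(sel_target.missing))
    if missing:
        raise ValueError(
            f"frame labels missing a Calpha in {complex_structure.id} or "
            f"{reference.id}: {missing}"
        )
    mobile = np.array([a.position for a in sel_mobile.atoms])
    target = np.array([a.position for a in sel_target.atoms])
    transform = kabsch_fit(mobile, target)
    moved = complex_structure.transformed(transform.rotation, transform.translation)
    deviations = {
        lab: float(np.linalg.norm(transform.apply(m) - t))
        for lab, m, t in zip(labels, mobile, target)
    }
    return SuperpositionResult(
        structure=moved,
        transform=transform,
        per_label_deviation=deviations,
        reference_id=reference.id,
        frame_labels=labels,
    )
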