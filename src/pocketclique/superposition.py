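"""Rigid-body superposition (Kabsch) and per-correspondence RMSD.

The transform is computed by SVD of the cross-covariance matrix with a
determinant sign correction, so the result is always a proper rotation
(det = +1); mirror images are never matched by reflection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .clique_matcher import CliqueCorrespondence
    from .structure_model import QueryStructure
    from .template_library import SiteTemplate


class SuperpositionError(ValueError):
    """Contract violation: mismatched or insufficient point sets."""


@dataclass(frozen=True, eq=False)
class RigidTransform:
    """Proper rigid motion ``x ↦ R·x + t`` (rotation then translation, Å)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise SuperpositionError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise SuperpositionError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise SuperpositionError("improper rotation (reflection) rejected")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


def kabsch(
    fixed: Sequence[Sequence[float]] | np.ndarray,
    moving: Sequence[Sequence[float]] | np.ndarray,
) -> tuple[RigidTransform, float]:
    """Least-squares proper-rotation superposition of ``moving`` onto ``fixed``.

    Returns the transform ``T`` minimising ``RMSD(fixed, T(moving))`` together
    with that minimised RMSD (Å).  Requires at least 3 points per set.
    """
    F = np.asarray(fixed, dtype=float)
    M = np.asarray(moving, dtype=float)
    if F.ndim != 2 or M.ndim != 2 or F.shape[1] != 3 or M.shape[1] != 3:
        raise SuperpositionError("point sets must be (n, 3) arrays")
    if F.shape[0] != M.shape[0]:
        raise SuperpositionError(
            f"point-set length mismatch: {F.shape[0]} vs {M.shape[0]}"
        )
    if F.shape[0] < 3:
        raise SuperpositionError("at least 3 point pairs are required")
    if not (np.isfinite(F).all() and np.isfinite(M).all()):
        raise SuperpositionError("points must be finite")

    cF = F.mean(axis=0)
    cM = M.mean(axis=0)
    H = (M - cM).T @ (F - cF)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cF - R @ cM
    transform = RigidTransform(rotation=R, translation=t)
    diff = transform.apply(M) - F
    msd = float((diff**2).sum() / F.shape[0])
    return transform, float(np.sqrt(max(msd, 0.0)))


def correspondence_points(
    corr: "CliqueCorrespondence",
    template: "SiteTemplate",
    query: "QueryStructure",
) -> tuple[np.ndarray, np.ndarray]:
    """Stack matched pseudo-atom coordinates (query = fixed, template = moving).

    Each matched residue pair contributes its Cα pair and, when the template
    residue is not glycine, its side-chain-centroid pair (glycine contributes
    Cα only — its centroid is not duplicated).
    """
    fixed: list[tuple[float, float, float]] = []
    moving: list[tuple[float, float, float]] = []
    for ti, qj in corr.pairs:
        t_res = template.residues[ti]
        q_res = query.residues[qj]
        fixed.append(q_res.ca_coord)
        moving.append(t_res.ca_coord)
        if t_res.aa_type != "GLY":
            fixed.append(q_res.sc_centroid)
            moving.append(t_res.sc_centroid)
    return np.asarray(fixed, dtype=float), np.asarray(moving, dtype=float)


def correspondence_rmsd(
    corr: "CliqueCorrespondence",
    template: "SiteTemplate",
    query: "QueryStructure",
) -> tuple[RigidTransform, float]:
    """Superpose the template's matched residues onto the query's.

    The RMSD is computed over the stacked pseudo-atoms of the matched
    residues only, not over whole chains.
    """
    fixed, moving = correspondence_points(corr, template, query)
    return kabsch(fixed, moving)
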