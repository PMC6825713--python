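"""Rigid-body superposition of aligned backbones (Kabsch least squares).

The optimal rotation minimising the coordinate RMSD between paired point
sets is obtained in closed form from the SVD of the covariance matrix, with
the usual determinant-sign correction excluding improper rotations.
Optional iterative trimming alternates fitting with re-selecting the pairs
inside a distance cutoff until the retained set is stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .align import PairAlignment
from .structure_io import BackboneChain

__all__ = [
    "RigidTransform",
    "SuperpositionReport",
    "SuperpositionError",
    "kabsch_fit",
    "superpose_aligned",
]


class SuperpositionError(ValueError):
    """Degenerate geometry or too few aligned pairs."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, applied as x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise SuperpositionError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise SuperpositionError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise SuperpositionError("rotation determinant must be +1 (no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def as_matrix(self) -> np.ndarray:
        out = np.eye(4)
        out[:3, :3] = self.rotation
        out[:3, 3] = self.translation
        return out

    def write(self, path: str | Path) -> None:
        """Dump as a plain-text 4x4 homogeneous matrix."""
        np.savetxt(path, self.as_matrix(), fmt="%.9f")


def kabsch_fit(points_a, points_b) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of ``points_a`` onto ``points_b``.

    Returns the transform T minimising sum ||T(a_k) - b_k||^2 and the
    resulting RMSD in the same units as the coordinates. Requires at least
    3 non-collinear pairs.
    """
    A = np.asarray(points_a, dtype=float)
    B = np.asarray(points_b, dtype=float)
    if A.shape != B.shape:
        raise SuperpositionError(f"point counts differ: {A.shape} vs {B.shape}")
    if A.ndim != 2 or A.shape[1] != 3:
        raise SuperpositionError("points must be (n, 3) arrays")
    if len(A) < 3:
        raise SuperpositionError(f"need >= 3 pairs to fit, got {len(A)}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    if np.linalg.matrix_rank(A0, tol=1e-8) < 2 or np.linalg.matrix_rank(B0, tol=1e-8) < 2:
        raise SuperpositionError("degenerate (collinear) point set")
    H = A0.T @ B0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    tf = RigidTransform(rotation=R, translation=t)
    rmsd = float(np.sqrt(np.mean(np.sum((tf.apply(A) - B) ** 2, axis=1))))
    return tf, rmsd


@dataclass
class SuperpositionReport:
    """Fit of the mobile chain onto the reference over an alignment."""

    transform: RigidTransform
    pair_distances: np.ndarray  # per aligned CA pair, under the final transform
    rmsd_all: float
    rmsd_fitted: float
    n_aligned: int
    n_fitted: int


def superpose_aligned(
    ref_chain: BackboneChain,
    mobile_chain: BackboneChain,
    alignment: PairAlignment,
    trim_cutoff: Optional[float] = None,
) -> SuperpositionReport:
    """Kabsch-fit the mobile chain onto the reference over aligned CA pairs.

    Alignment columns are (ref index, mobile index). With ``trim_cutoff``
    set (in Angstrom), iterate fit -> keep the pairs within the cutoff ->
    refit until the retained set reaches a fixed point; ``rmsd_all`` is
    then reported over all aligned pairs under the final transform and
    ``rmsd_fitted`` over the retained set.
    """
    pairs = [
        (i, j)
        for i, j in alignment.aligned_pairs()
        if ref_chain[i].coords_CA is not None and mobile_chain[j].coords_CA is not None
    ]
    if len(pairs) < 3:
        raise SuperpositionError(f"only {len(pairs)} aligned CA pairs; need >= 3")
    ref = np.array([ref_chain[i].coords_CA for i, _ in pairs])
    mob = np.array([mobile_chain[j].coords_CA for _, j in pairs])

    keep = np.ones(len(pairs), dtype=bool)
    tf, _ = kabsch_fit(mob, ref)
    if trim_cutoff is not None:
        if trim_cutoff <= 0:
            raise SuperpositionError("trim_cutoff must be positive")
        # each round re-selects from ALL pairs, so pairs dropped under an
        # early compromise fit can re-enter once the fit tightens; a seen-set
        # guard terminates the rare oscillating case
        seen: set[bytes] = set()
        while True:
            d = np.linalg.norm(tf.apply(mob) - ref, axis=1)
            new_keep = d <= trim_cutoff
            if new_keep.sum() < 3:
                raise SuperpositionError(
                    f"trimming at {trim_cutoff} A left {int(new_keep.sum())} pairs; need >= 3"
                )
            if np.array_equal(new_keep, keep) or new_keep.tobytes() in seen:
                keep = new_keep
                break
            seen.add(new_keep.tobytes())
            keep = new_keep
            tf, _ = kabsch_fit(mob[keep], ref[keep])

    d = np.linalg.norm(tf.apply(mob) - ref, axis=1)
    rmsd_all = float(np.sqrt(np.mean(d**2)))
    rmsd_fitted = float(np.sqrt(np.mean(d[keep] ** 2)))
    return SuperpositionReport(
        transform=tf,
        pair_distances=d,
        rmsd_all=rmsd_all,
        rmsd_fitted=rmsd_fitted,
        n_aligned=len(pairs),
        n_fitted=int(keep.sum()),
    )
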