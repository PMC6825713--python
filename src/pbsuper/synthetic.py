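"""Synthetic backbone construction from prescribed phi/psi torsions.

Chains are grown by internal-coordinate extension (NeRF-style placement)
with fixed Engh-Huber-like bond lengths and angles and a trans peptide bond
(omega = 180 deg); only the torsions vary. This gives exact, dependency-free
ground truth for the encoder, aligner and fitter: the rebuilt chain's
measured phi/psi reproduce the prescription to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structure_io import BackboneChain, Residue

__all__ = [
    "BOND_LENGTHS",
    "BOND_ANGLES",
    "TorsionSpec",
    "MutationPlan",
    "build_backbone",
    "perturb",
    "make_pair",
    "helix_spec",
    "strand_spec",
]

#: backbone bond lengths in Angstrom
BOND_LENGTHS = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
#: backbone bond angles in degrees
BOND_ANGLES = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7}
OMEGA = 180.0

IDEAL_HELIX = (-57.0, -47.0)
IDEAL_STRAND = (-120.0, 135.0)


@dataclass(frozen=True)
class TorsionSpec:
    """Per-residue (phi, psi) prescription in degrees.

    phi of the first residue and psi of the last are geometrically
    undefined and ignored during construction.
    """

    torsions: tuple[tuple[float, float], ...]

    def __post_init__(self):
        object.__setattr__(
            self,
            "torsions",
            tuple((float(p), float(s)) for p, s in self.torsions),
        )

    def __len__(self) -> int:
        return len(self.torsions)

    @classmethod
    def uniform(cls, n: int, phi: float, psi: float) -> "TorsionSpec":
        return cls(torsions=tuple((phi, psi) for _ in range(n)))


def helix_spec(n: int) -> TorsionSpec:
    """Ideal alpha-helix torsions (phi, psi) = (-57, -47)."""
    return TorsionSpec.uniform(n, *IDEAL_HELIX)


def strand_spec(n: int) -> TorsionSpec:
    """Extended beta-strand torsions (phi, psi) = (-120, 135)."""
    return TorsionSpec.uniform(n, *IDEAL_STRAND)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    theta = np.radians(angle_deg)
    # the (bc, m, n) frame below is left-handed w.r.t. the IUPAC torsion
    # sign measured by compute_dihedral, hence the negation
    tau = -np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(tau), np.sin(theta) * np.sin(tau)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(spec: TorsionSpec, chain_id: str = "A",
                   source_name: str = "synthetic") -> BackboneChain:
    """Grow an N/CA/C backbone realising the prescribed torsions.

    The resulting chain is complete and contiguous, numbered from 1; for
    any interior residue the measured phi/psi equal the prescription to
    numerical precision.
    """
    n = len(spec)
    if n < 1:
        raise ValueError("need at least one residue")
    coords: list[dict[str, np.ndarray]] = []
    # first residue in a canonical frame: N at origin, CA on +x, C in xy-plane
    N0 = np.zeros(3)
    CA0 = np.array([BOND_LENGTHS["N-CA"], 0.0, 0.0])
    ang = np.radians(180.0 - BOND_ANGLES["N-CA-C"])
    C0 = CA0 + BOND_LENGTHS["CA-C"] * np.array([np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": N0, "CA": CA0, "C": C0})
    for i in range(1, n):
        prev = coords[-1]
        psi_prev = spec.torsions[i - 1][1]
        phi_i = spec.torsions[i][0]
        Ni = _place(prev["N"], prev["CA"], prev["C"],
                    BOND_LENGTHS["C-N"], BOND_ANGLES["CA-C-N"], psi_prev)
        CAi = _place(prev["CA"], prev["C"], Ni,
                     BOND_LENGTHS["N-CA"], BOND_ANGLES["C-N-CA"], OMEGA)
        Ci = _place(prev["C"], Ni, CAi,
                    BOND_LENGTHS["CA-C"], BOND_ANGLES["N-CA-C"], phi_i)
        coords.append({"N": Ni, "CA": CAi, "C": Ci})
    residues = [
        Residue(seq_id=i + 1, aa="A",
                coords_N=c["N"], coords_CA=c["CA"], coords_C=c["C"])
        for i, c in enumerate(coords)
    ]
    return BackboneChain(chain_id=chain_id, residues=residues, source_name=source_name)


def perturb(chain: BackboneChain, sigma: float, seed: int) -> BackboneChain:
    """Add seeded isotropic Gaussian noise (std ``sigma`` A) to every atom."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = BackboneChain(chain_id=chain.chain_id, residues=[],
                        source_name=chain.source_name + "+noise")
    for r in chain.residues:
        def jitter(x: Optional[np.ndarray]) -> Optional[np.ndarray]:
            return None if x is None else x + rng.normal(0.0, sigma, 3)

        out.residues.append(
            Residue(seq_id=r.seq_id, insertion_code=r.insertion_code, aa=r.aa,
                    coords_N=jitter(r.coords_N), coords_CA=jitter(r.coords_CA),
                    coords_C=jitter(r.coords_C))
        )
    return out


@dataclass(frozen=True)
class MutationPlan:
    """Edits applied to a TorsionSpec to build a variant chain.

    substitutions maps 0-based residue index -> new (phi, psi); deletions
    is a list of (start, count) ranges removed from the variant (applied
    after substitutions, ranges indexed on the original spec).
    """

    substitutions: dict[int, tuple[float, float]] = field(default_factory=dict)
    deletions: tuple[tuple[int, int], ...] = ()


def make_pair(spec: TorsionSpec, plan: MutationPlan = MutationPlan()
              ) -> tuple[BackboneChain, BackboneChain]:
    """Base chain plus an edited variant with known ground truth."""
    n = len(spec)
    for idx in plan.substitutions:
        if not 0 <= idx < n:
            raise ValueError(f"substitution index {idx} out of range for length {n}")
    removed = np.zeros(n, dtype=bool)
    for start, count in plan.deletions:
        if count < 0 or not 0 <= start or start + count > n:
            raise ValueError(f"deletion ({start}, {count}) out of range for length {n}")
        removed[start : start + count] = True
    torsions = list(spec.torsions)
    for idx, (p, s) in plan.substitutions.items():
        torsions[idx] = (float(p), float(s))
    variant = [t for t, gone in zip(torsions, removed) if not gone]
    base = build_backbone(spec, chain_id="A", source_name="synthetic-base")
    if not variant:
        raise ValueError("edits removed every residue")
    var = build_backbone(TorsionSpec(torsions=tuple(variant)),
                         chain_id="B", source_name="synthetic-variant")
    return base, var
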