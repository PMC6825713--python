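from __future__ import annotations

import random

import numpy as np
import pytest

from pbsuper import (
    TorsionSpec,
    build_backbone,
    default_matrix,
    helix_spec,
    strand_spec,
)
from pbsuper.pb import PB_LETTERS
from pbsuper.synthetic import IDEAL_HELIX, IDEAL_STRAND


@pytest.fixture(scope="session")
def matrix():
    return default_matrix()


@pytest.fixture(scope="session")
def helix30():
    return build_backbone(helix_spec(30))


@pytest.fixture
def mixed_spec():
    """Helix-strand-helix, 50 residues: realistic secondary-structure mix."""
    return TorsionSpec(
        tuple([IDEAL_HELIX] * 20 + [IDEAL_STRAND] * 15 + [IDEAL_HELIX] * 15)
    )


def random_torsion_spec(rng: np.random.Generator, n: int) -> TorsionSpec:
    return TorsionSpec(
        tuple(
            (float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)))
            for _ in range(n)
        )
    )


def random_pb_string(rnd: random.Random, n: int, with_z: bool = True) -> str:
    alphabet = PB_LETTERS + ("Z" if with_z else "")
    return "".join(rnd.choice(alphabet) for _ in range(n))


def random_rigid(rng: np.random.Generator):
    """Uniform random proper rotation (QR-based) plus a random translation."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-20, 20, 3)
    return Q, t


# --- hand-written PDB fixture text ------------------------------------------

def pdb_atom_line(serial, name, resname, chain, seq, xyz,
                  altloc=" ", icode=" ", occ=1.0, record="ATOM"):
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:5d} {' ' + name.ljust(3):<4s}{altloc}{resname:<3s} "
        f"{chain}{seq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {name[0]:>2s}"
    )


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Hand-written 3-residue chain, all backbone atoms present."""
    coords = [
        (0.0, 0.0, 0.0), (1.458, 0.0, 0.0), (2.009, 1.422, 0.0),
        (3.332, 1.536, 0.0), (4.0, 2.8, 0.1), (5.4, 2.7, 0.6),
        (6.1, 3.8, 0.7), (7.5, 3.9, 1.2), (8.2, 5.1, 1.4),
    ]
    lines, serial = [], 1
    for ri, resname in enumerate(("ALA", "GLY", "SER"), start=1):
        for ai, name in enumerate(("N", "CA", "C")):
            lines.append(pdb_atom_line(serial, name, resname, "A", ri,
                                       coords[(ri - 1) * 3 + ai]))
            serial += 1
    lines += ["TER", "END"]
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
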