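"""Protein Block (PB) encoding of a protein backbone.

A structural alphabet of 16 pentapeptide prototypes (letters ``a``..``p``)
approximates local backbone conformation. Each prototype is an 8-vector of
reference torsions spanning five consecutive residues,

    psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1), psi(i+1), phi(i+2),

and a residue is assigned the letter whose prototype minimises the RMSDA
(root-mean-square deviation of wrapped angular differences) to its own
window. A chain of N residues yields N-4 letters: the two first and two last
positions, and any position whose window touches a missing residue or chain
break, carry the placeholder ``Z``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .structure_io import BackboneChain

__all__ = [
    "PB_LETTERS",
    "prototype_table",
    "DihedralSeries",
    "PBSequence",
    "DihedralError",
    "compute_dihedral",
    "compute_phi_psi",
    "assign_pb",
    "encode_chain",
    "write_pb_fasta",
    "read_pb_fasta",
]

PB_LETTERS = "abcdefghijklmnop"

#: window layout relative to the central residue i, as (offset, angle-kind)
WINDOW_LAYOUT = (
    (-2, "psi"), (-1, "phi"), (-1, "psi"), (0, "phi"),
    (0, "psi"), (1, "phi"), (1, "psi"), (2, "phi"),
)


class DihedralError(ValueError):
    """Degenerate geometry: a torsion is undefined (collinear atoms)."""


def prototype_table() -> np.ndarray:
    """The (16, 8) reference dihedral table, rows in letter order a..p."""
    return _PROTOTYPES.copy()


def _load_prototypes() -> np.ndarray:
    text = (resources.files("pbsuper") / "data" / "pb_prototypes.tsv").read_text()
    rows = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("pb\t"):
            continue
        parts = line.split()
        rows[parts[0]] = [float(v) for v in parts[1:]]
    table = np.array([rows[c] for c in PB_LETTERS], dtype=float)
    if table.shape != (16, 8):
        raise ValueError(f"malformed prototype table: shape {table.shape}")
    return table


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    cis (eclipsed) is 0, trans is 180; the result lies in (-180, 180].
    Raises :class:`DihedralError` when either bonded triple is collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DihedralError("torsion undefined: collinear or coincident atoms")
    m1 = np.cross(n1, b2 / b2n)
    angle = float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))
    if angle <= -180.0:
        angle += 360.0
    return angle


@dataclass
class DihedralSeries:
    """Per-residue phi/psi in degrees; NaN marks an undefined angle."""

    phi: np.ndarray
    psi: np.ndarray

    def __len__(self) -> int:
        return len(self.phi)


def compute_phi_psi(chain: BackboneChain) -> DihedralSeries:
    """Backbone phi/psi series for a chain.

    phi(i) uses C(i-1), N(i), CA(i), C(i) and needs residues i-1 and i
    bonded; psi(i) uses N(i), CA(i), C(i), N(i+1) and needs i and i+1
    bonded. Bonding requires complete residues, contiguous author
    numbering and a CA-CA distance within the chain-break cutoff.
    """
    n = len(chain)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    for i in range(n):
        r = chain[i]
        if not r.complete:
            continue
        if i > 0 and chain.bonded(i - 1):
            prev = chain[i - 1]
            try:
                phi[i] = compute_dihedral(prev.coords_C, r.coords_N, r.coords_CA, r.coords_C)
            except DihedralError:
                pass
        if i + 1 < n and chain.bonded(i):
            nxt = chain[i + 1]
            try:
                psi[i] = compute_dihedral(r.coords_N, r.coords_CA, r.coords_C, nxt.coords_N)
            except DihedralError:
                pass
    return DihedralSeries(phi=phi, psi=psi)


def _wrap(delta: np.ndarray) -> np.ndarray:
    return (delta + 180.0) % 360.0 - 180.0


def assign_pb(window) -> str:
    """Letter of the prototype nearest (in RMSDA) to an 8-angle window.

    Ties break alphabetically. Any non-finite angle in the window raises
    ValueError; the caller is expected to emit ``Z`` instead.
    """
    w = np.asarray(window, dtype=float)
    if w.shape != (8,):
        raise ValueError(f"window must have 8 angles, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("window incomplete: undefined dihedral present")
    rmsda = np.sqrt(np.mean(_wrap(_PROTOTYPES - w) ** 2, axis=1))
    return PB_LETTERS[int(np.argmin(rmsda))]


@dataclass
class PBSequence:
    """PB string co-indexed with the residues of its source chain."""

    letters: str
    source: Optional[BackboneChain] = None

    def __len__(self) -> int:
        return len(self.letters)

    def __str__(self) -> str:
        return self.letters

    @property
    def n_assigned(self) -> int:
        return sum(1 for c in self.letters if c != "Z")


def encode_chain(chain: BackboneChain) -> PBSequence:
    """Translate a chain into its PB sequence (length N, letters {a..p, Z}).

    A complete contiguous chain of length N gets exactly N-4 assigned
    letters; every window that overlaps a terminus, an incomplete residue,
    a numbering gap or a geometric chain break yields Z.
    """
    n = len(chain)
    series = compute_phi_psi(chain)
    letters = []
    for i in range(n):
        if i < 2 or i >= n - 2:
            letters.append("Z")
            continue
        window = []
        for off, kind in WINDOW_LAYOUT:
            arr = series.phi if kind == "phi" else series.psi
            window.append(arr[i + off])
        window = np.array(window)
        if np.all(np.isfinite(window)):
            letters.append(assign_pb(window))
        else:
            letters.append("Z")
    return PBSequence(letters="".join(letters), source=chain)


def write_pb_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write named PB (or amino-acid) strings as FASTA."""
    with open(path, "w") as fh:
        for name, s in seqs.items():
            fh.write(f">{name}\n")
            for k in range(0, len(s), width):
                fh.write(s[k : k + width] + "\n")


def read_pb_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {name: string} mapping."""
    out: dict[str, str] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name is not None:
            out[name] += line
    return out


_PROTOTYPES = _load_prototypes()
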