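"""Read protein structures into backbone-only chain objects and write them back.

Only the three backbone heavy atoms that determine phi/psi torsions (N, CA, C)
are retained; waters and ligands are dropped, and alternate locations are
resolved to the highest-occupancy conformer. Input may be PDB or mmCIF
(auto-detected); output is always PDB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import gemmi

__all__ = [
    "Residue",
    "BackboneChain",
    "StructureError",
    "read_structure",
    "write_superposed",
]

BACKBONE_ATOMS = ("N", "CA", "C")

#: maximum CA(i)-CA(i+1) distance for two residues to count as bonded;
#: beyond this the chain is treated as broken even if numbering is contiguous.
CHAIN_BREAK_DISTANCE = 4.5


class StructureError(ValueError):
    """Raised for unreadable files, unknown chains, or empty polymer content."""


@dataclass
class Residue:
    """One amino-acid residue reduced to its N/CA/C backbone atoms.

    ``seq_id``/``insertion_code`` keep the author numbering for reporting;
    positional indexing of the parent chain is dense and 0-based.
    """

    seq_id: int
    insertion_code: str = ""
    aa: str = "X"
    coords_N: Optional[np.ndarray] = None
    coords_CA: Optional[np.ndarray] = None
    coords_C: Optional[np.ndarray] = None

    @property
    def complete(self) -> bool:
        """True iff all three backbone atoms are present (finiteness enforced on read)."""
        return (
            self.coords_N is not None
            and self.coords_CA is not None
            and self.coords_C is not None
        )

    def label(self) -> str:
        return f"{self.seq_id}{self.insertion_code}".strip()


@dataclass
class BackboneChain:
    """Ordered residues of one polypeptide chain."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    source_name: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __getitem__(self, i: int) -> Residue:
        return self.residues[i]

    @property
    def n_complete(self) -> int:
        return sum(1 for r in self.residues if r.complete)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_array(self) -> np.ndarray:
        """(N, 3) CA coordinates; NaN rows where CA is absent."""
        out = np.full((len(self), 3), np.nan)
        for i, r in enumerate(self.residues):
            if r.coords_CA is not None:
                out[i] = r.coords_CA
        return out

    def bonded(self, i: int) -> bool:
        """Whether residues i and i+1 are consecutive in the polymer.

        Requires contiguous author numbering (same number with distinct
        insertion codes also counts) and a CA-CA distance within
        ``CHAIN_BREAK_DISTANCE``.
        """
        if i < 0 or i + 1 >= len(self.residues):
            return False
        a, b = self.residues[i], self.residues[i + 1]
        if not (a.complete and b.complete):
            return False
        dseq = b.seq_id - a.seq_id
        if dseq not in (0, 1):
            return False
        if dseq == 0 and a.insertion_code == b.insertion_code:
            return False
        return float(np.linalg.norm(b.coords_CA - a.coords_CA)) <= CHAIN_BREAK_DISTANCE


def _pick_conformer(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved by altloc label ('' before 'A' < 'B')
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def _one_letter(res_name: str, info: Optional[gemmi.ResidueInfo]) -> str:
    if info is not None and info.is_standard() and info.is_amino_acid():
        code = info.one_letter_code.upper()
        return code if code.isalpha() else "X"
    return "X"


def read_structure(
    path: str | Path,
    chain: Optional[str] = None,
    model_index: int = 0,
) -> BackboneChain:
    """Read one polypeptide chain from a PDB or mmCIF file.

    Parameters
    ----------
    path:
        Structure file; format detected from content/extension by gemmi.
    chain:
        Chain identifier. ``None`` selects the first chain that contains
        amino-acid residues.
    model_index:
        0-based model number (NMR ensembles etc.); default first model.

    Returns
    -------
    BackboneChain with waters/ligands removed, alternate locations reduced
    to the highest-occupancy conformer, and non-standard amino acids (MSE,
    ...) kept with ``aa='X'``.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if model_index < 0 or model_index >= len(st):
        raise StructureError(
            f"{path.name} has {len(st)} model(s); model_index {model_index} out of range"
        )
    model = st[model_index]

    candidates = [ch.name for ch in model]
    target = None
    if chain is None:
        for ch in model:
            if any(_is_amino(res) for res in ch):
                target = ch
                break
        if target is None:
            raise StructureError(f"no polymer (amino-acid) residues in {path.name}")
    else:
        for ch in model:
            if ch.name == chain:
                target = ch
                break
        if target is None:
            raise StructureError(
                f"chain {chain!r} not found in {path.name}; available: {candidates}"
            )

    out = BackboneChain(chain_id=target.name, source_name=path.name)
    for res in target:
        if res.is_water() or not _is_amino(res):
            continue
        info = gemmi.find_tabulated_residue(res.name)
        coords = {}
        for name in BACKBONE_ATOMS:
            atoms = [a for a in res if a.name == name]
            if not atoms:
                continue
            a = _pick_conformer(atoms)
            xyz = np.array([a.pos.x, a.pos.y, a.pos.z], dtype=float)
            if np.all(np.isfinite(xyz)):
                coords[name] = xyz
        out.residues.append(
            Residue(
                seq_id=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                aa=_one_letter(res.name, info),
                coords_N=coords.get("N"),
                coords_CA=coords.get("CA"),
                coords_C=coords.get("C"),
            )
        )
    if not out.residues:
        raise StructureError(
            f"chain {target.name!r} of {path.name} has no amino-acid residues"
        )
    return out


def _is_amino(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    return info is not None and info.is_amino_acid()


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def write_superposed(chain: BackboneChain, transform, path: str | Path) -> None:
    """Write the chain as a PDB file with ``transform`` applied to every atom.

    ``transform`` is any object with ``rotation`` (3x3) and ``translation``
    (3,) attributes, applied as ``x -> R @ x + t``. Author residue numbering
    and insertion codes are preserved.
    """
    R = np.asarray(transform.rotation, dtype=float)
    t = np.asarray(transform.translation, dtype=float)
    path = Path(path)
    lines = []
    serial = 1
    cid = (chain.chain_id or "A")[0]
    for res in chain.residues:
        resname = _THREE.get(res.aa, "UNK")
        for name, xyz in (
            ("N", res.coords_N),
            ("CA", res.coords_CA),
            ("C", res.coords_C),
        ):
            if xyz is None:
                continue
            x, y, z = R @ xyz + t
            pad_name = f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {pad_name:<4s} {resname:<3s} {cid}"
                f"{res.seq_id:4d}{(res.insertion_code or ' ')[:1]}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise StructureError(f"cannot write {path}: {exc}") from exc
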