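"""Alignment-quality scores: GDT_TS, GDT_PB, RMSD and PB identity.

GDT_TS follows the CASP convention: for each distance threshold (1, 2, 4,
8 Angstrom) find the largest fraction of aligned CA pairs that can be
superposed simultaneously within the threshold, then average the four
fractions and scale to 0-100. The per-threshold search is an iterative
refinement (seed superposition -> keep pairs within the threshold -> refit
-> repeat), seeded from the full pair set, from short consecutive segments,
and from the best superpositions found at tighter thresholds -- the latter
guarantees the per-threshold fractions are nondecreasing. The denominator
is the smaller of the two chains' complete-residue counts.

GDT_PB judges each aligned column by its PB substitution score instead of
a distance: the column score is normalised against the best score either
letter could achieve, and the four thresholds are the quartiles 0.25, 0.5,
0.75, 1.0 of that normalised similarity; the result is the mean of the
four fractions, in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import PairAlignment, SubstitutionMatrix
from .pb import PBSequence
from .structure_io import BackboneChain
from .superpose import SuperpositionError, kabsch_fit

__all__ = [
    "GDT_THRESHOLDS",
    "GDT_PB_QUARTILES",
    "ScorePanel",
    "gdt_ts",
    "gdt_pb",
    "pb_identity",
    "score_panel",
]

GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)
GDT_PB_QUARTILES = (0.25, 0.5, 0.75, 1.0)

# seed segment lengths for the iterative GDT superposition search
_SEED_LENGTHS = (3, 7)
_MAX_REFINE_ITER = 20


def _refine_count(
    ref: np.ndarray, mob: np.ndarray, seed_idx: np.ndarray, tau: float
) -> tuple[int, Optional[np.ndarray]]:
    """Iterate fit-on-subset / keep-within-tau; return the best count seen."""
    best_count, best_rot = 0, None
    idx = seed_idx
    seen: set[bytes] = set()
    for _ in range(_MAX_REFINE_ITER):
        try:
            tf, _ = kabsch_fit(mob[idx], ref[idx])
        except SuperpositionError:
            break
        d = np.linalg.norm(tf.apply(mob) - ref, axis=1)
        within = d <= tau
        count = int(within.sum())
        if count > best_count:
            best_count = count
            best_rot = np.column_stack([tf.rotation, tf.translation])
        key = within.tobytes()
        if count < 3 or key in seen:
            break
        seen.add(key)
        idx = np.flatnonzero(within)
    return best_count, best_rot


def gdt_ts(
    chain_a: BackboneChain,
    chain_b: BackboneChain,
    alignment: PairAlignment,
    thresholds: Sequence[float] = GDT_THRESHOLDS,
) -> tuple[float, list[float]]:
    """GDT_TS (0-100) and the per-threshold fractions for an alignment.

    chain_a is the reference; columns index (a, b). The denominator is
    min(complete residues of a, complete residues of b).
    """
    pairs = [
        (i, j)
        for i, j in alignment.aligned_pairs()
        if chain_a[i].coords_CA is not None and chain_b[j].coords_CA is not None
    ]
    if len(pairs) < 3:
        raise SuperpositionError(f"only {len(pairs)} aligned CA pairs; need >= 3")
    ref = np.array([chain_a[i].coords_CA for i, _ in pairs])
    mob = np.array([chain_b[j].coords_CA for _, j in pairs])
    n = len(pairs)
    denom = min(chain_a.n_complete, chain_b.n_complete)

    seeds = [np.arange(n)]
    for L in _SEED_LENGTHS:
        if L <= n:
            seeds.extend(np.arange(s, s + L) for s in range(0, n - L + 1))

    fractions: list[float] = []
    carried: list[np.ndarray] = []  # best transforms from tighter thresholds
    for tau in sorted(thresholds):
        best = 0
        best_rot = None
        for M in carried:
            d = np.linalg.norm(mob @ M[:, :3].T + M[:, 3] - ref, axis=1)
            best = max(best, int((d <= tau).sum()))
        for seed in seeds:
            count, rot = _refine_count(ref, mob, seed, tau)
            if count > best:
                best = count
                best_rot = rot
        if best_rot is not None:
            carried.append(best_rot)
        fractions.append(best / denom)
    order = np.argsort(np.argsort(thresholds))
    fractions = [fractions[k] for k in order]  # restore caller's threshold order
    return 100.0 * float(np.mean(fractions)), fractions


def _column_similarity(x: str, y: str, m: SubstitutionMatrix) -> float:
    """Normalised column similarity in [0, 1]: 1 for identical letters."""
    lo = float(m.scores.min())
    best = min(m.score(x, x), m.score(y, y))
    if best <= lo:
        return 0.0
    u = (m.score(x, y) - lo) / (best - lo)
    return float(np.clip(u, 0.0, 1.0))


def gdt_pb(
    pb_a: PBSequence,
    pb_b: PBSequence,
    alignment: PairAlignment,
    m: SubstitutionMatrix,
    quartiles: Sequence[float] = GDT_PB_QUARTILES,
) -> Optional[float]:
    """GDT-style score over PB substitution similarity, in [0, 1].

    Aligned columns where either letter is Z are excluded; returns None
    (undefined) when no scorable column remains.
    """
    a, b = pb_a.letters, pb_b.letters
    sims = [
        _column_similarity(a[i], b[j], m)
        for i, j in alignment.aligned_pairs()
        if a[i] != "Z" and b[j] != "Z"
    ]
    if not sims:
        return None
    sims_arr = np.array(sims)
    fractions = [float(np.mean(sims_arr >= q)) for q in quartiles]
    return float(np.mean(fractions))


def pb_identity(pb_a: PBSequence, pb_b: PBSequence, alignment: PairAlignment) -> Optional[float]:
    """Fraction of aligned non-Z columns whose PB letters are identical."""
    cols = [
        (pb_a.letters[i], pb_b.letters[j])
        for i, j in alignment.aligned_pairs()
        if pb_a.letters[i] != "Z" and pb_b.letters[j] != "Z"
    ]
    if not cols:
        return None
    return sum(1 for x, y in cols if x == y) / len(cols)


@dataclass
class ScorePanel:
    """All alignment-quality numbers for one superposition."""

    gdt_ts: float
    per_threshold_fractions: list[float]
    gdt_pb: Optional[float]
    rmsd_all: float
    rmsd_fitted: float
    n_aligned: int
    n_fitted: int
    pb_identity: Optional[float]
    thresholds: list[float] = field(default_factory=lambda: list(GDT_THRESHOLDS))

    def to_dict(self) -> dict:
        return {
            "gdt_ts": self.gdt_ts,
            "per_threshold_fractions": self.per_threshold_fractions,
            "thresholds_angstrom": self.thresholds,
            "gdt_pb": self.gdt_pb,
            "rmsd_all": self.rmsd_all,
            "rmsd_fitted": self.rmsd_fitted,
            "n_aligned": self.n_aligned,
            "n_fitted": self.n_fitted,
            "pb_identity": self.pb_identity,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps({"schema": "pbsuper-scores/1", **self.to_dict()}, **kwargs)

    def to_text(self) -> str:
        def fmt(v, spec=".3f"):
            return "undefined" if v is None else format(v, spec)

        lines = [
            f"aligned residue pairs : {self.n_aligned} (fitted: {self.n_fitted})",
            f"Ca RMSD (all pairs)   : {fmt(self.rmsd_all)} A",
            f"Ca RMSD (fitted set)  : {fmt(self.rmsd_fitted)} A",
            f"GDT_TS                : {fmt(self.gdt_ts, '.1f')}",
            "  fractions at "
            + ", ".join(f"{t:g} A" for t in self.thresholds)
            + " : "
            + ", ".join(f"{f:.3f}" for f in self.per_threshold_fractions),
            f"GDT_PB                : {fmt(self.gdt_pb)}",
            f"PB identity           : {fmt(self.pb_identity)}",
        ]
        return "\n".join(lines)


def score_panel(
    ref_chain: BackboneChain,
    mobile_chain: BackboneChain,
    pb_ref: PBSequence,
    pb_mobile: PBSequence,
    alignment: PairAlignment,
    matrix: SubstitutionMatrix,
    report,
) -> ScorePanel:
    """Aggregate every score for a finished pipeline run."""
    ts, fractions = gdt_ts(ref_chain, mobile_chain, alignment)
    return ScorePanel(
        gdt_ts=ts,
        per_threshold_fractions=fractions,
        gdt_pb=gdt_pb(pb_ref, pb_mobile, alignment, matrix),
        rmsd_all=report.rmsd_all,
        rmsd_fitted=report.rmsd_fitted,
        n_aligned=report.n_aligned,
        n_fitted=report.n_fitted,
        pb_identity=pb_identity(pb_ref, pb_mobile, alignment),
    )
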