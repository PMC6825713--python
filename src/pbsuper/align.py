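"""Pairwise alignment of PB sequences by dynamic programming.

The aligner is a global affine-gap (Gotoh) DP over the 16-letter PB
alphabet plus the placeholder ``Z``, driven by a 16x16 substitution matrix.
The two-pass strategy first aligns under stringent parameters (substitution
scores and gap penalties amplified by a large weight) to pick out anchors
-- runs of consecutively aligned, high-scoring columns -- then freezes the
anchors and completes the alignment of the intervening regions with the
ordinary, relaxed parameters.

Gap cost convention: a gap run of length L costs gap_open + (L-1) *
gap_extend (both non-positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .pb import PB_LETTERS, PBSequence, prototype_table

__all__ = [
    "SubstitutionMatrix",
    "PairAlignment",
    "Anchor",
    "AnchorParams",
    "AlignmentError",
    "load_matrix",
    "default_matrix",
    "global_align",
    "find_anchors",
    "anchored_align",
    "align_two_pass",
    "score_alignment",
    "alignment_tracks",
]

NEG_INF = float("-inf")


class AlignmentError(ValueError):
    """Malformed matrices, empty sequences or inconsistent anchors."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """16x16 PB similarity scores plus gap parameters.

    ``z_score`` is the fixed neutral score for any column involving the
    placeholder Z (default 0): Z carries no structural signal, so it
    neither rewards nor penalises.
    """

    scores: np.ndarray
    gap_open: float = -5.0
    gap_extend: float = -0.5
    z_score: float = 0.0

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (16, 16):
            raise AlignmentError(f"substitution matrix must be 16x16, got {s.shape}")
        if not np.allclose(s, s.T, atol=1e-9):
            raise AlignmentError("substitution matrix must be symmetric")
        off = s - np.diag(np.diag(s))
        if np.any(np.diag(s) < off.max(axis=1) - 1e-9):
            raise AlignmentError(
                "substitution matrix must be diagonal-dominant "
                "(self-substitution optimal in every row)"
            )
        if self.gap_open > 0 or self.gap_extend > 0:
            raise AlignmentError("gap penalties must be non-positive")
        object.__setattr__(self, "scores", s)

    def score(self, x: str, y: str) -> float:
        if x == "Z" or y == "Z":
            return self.z_score
        return float(self.scores[PB_LETTERS.index(x), PB_LETTERS.index(y)])

    @property
    def max_diagonal(self) -> float:
        return float(np.diag(self.scores).max())

    def with_gaps(self, gap_open: float, gap_extend: float) -> "SubstitutionMatrix":
        return replace(self, gap_open=gap_open, gap_extend=gap_extend)


def load_matrix(source: Union[str, Path, None] = None) -> SubstitutionMatrix:
    """Load a PB substitution matrix from a whitespace-separated table.

    The table has one-letter column headers (a..p, any order) and one
    header-labelled row per letter. ``None`` returns the bundled default.
    """
    if source is None:
        return default_matrix()
    path = Path(source)
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise AlignmentError(f"empty matrix file: {path}")
    header = lines[0].split()
    if sorted(header) != sorted(PB_LETTERS):
        raise AlignmentError(
            f"matrix header must contain exactly the 16 PB letters, got {header}"
        )
    if len(lines) != 17:
        raise AlignmentError(
            f"matrix must have 16 data rows, found {len(lines) - 1} in {path}"
        )
    scores = np.zeros((16, 16))
    seen = set()
    for ln in lines[1:]:
        parts = ln.split()
        letter, values = parts[0], parts[1:]
        if letter not in PB_LETTERS or letter in seen:
            raise AlignmentError(f"bad or duplicate row label {letter!r} in {path}")
        if len(values) != 16:
            raise AlignmentError(f"row {letter!r} has {len(values)} values, expected 16")
        seen.add(letter)
        i = PB_LETTERS.index(letter)
        for h, v in zip(header, values):
            scores[i, PB_LETTERS.index(h)] = float(v)
    return SubstitutionMatrix(scores=scores)


def default_matrix() -> SubstitutionMatrix:
    """The bundled default matrix (see data/pb_substitution.tsv header)."""
    with resources.as_file(
        resources.files("pbsuper") / "data" / "pb_substitution.tsv"
    ) as p:
        return load_matrix(p)


@dataclass
class PairAlignment:
    """Ordered alignment columns: (i, j) indices or None for a gap."""

    columns: list[tuple[Optional[int], Optional[int]]]
    score: float

    @property
    def n_aligned(self) -> int:
        return sum(1 for i, j in self.columns if i is not None and j is not None)

    def aligned_pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in self.columns if i is not None and j is not None]


@dataclass(frozen=True)
class Anchor:
    """A frozen run of consecutively aligned columns found under stringent scoring."""

    start_i: int
    start_j: int
    length: int
    segment_score: float

    @property
    def end_i(self) -> int:
        return self.start_i + self.length

    @property
    def end_j(self) -> int:
        return self.start_j + self.length


@dataclass(frozen=True)
class AnchorParams:
    """First-pass (stringent) configuration for anchor detection.

    weight amplifies both substitution scores and gap penalties in the
    stringent pass; score_fraction sets the per-column acceptance threshold
    as a fraction of the matrix's maximum diagonal entry; min_length is the
    shortest acceptable anchor (default 5 = one PB window).
    """

    weight: float = 10.0
    score_fraction: float = 0.8
    min_length: int = 5


def _letters(s: Union[str, PBSequence]) -> str:
    return s.letters if isinstance(s, PBSequence) else s


# traceback states, in tie-break precedence order: diagonal > up > left
_DIAG, _UP, _LEFT = 0, 1, 2


def global_align(
    s1: Union[str, PBSequence],
    s2: Union[str, PBSequence],
    m: SubstitutionMatrix,
    gap_open: Optional[float] = None,
    gap_extend: Optional[float] = None,
) -> PairAlignment:
    """Optimal global alignment under affine gap penalties (Gotoh DP).

    Traceback is deterministic with tie precedence diagonal > up > left,
    where "up" consumes a letter of ``s1`` against a gap.
    """
    a, b = _letters(s1), _letters(s2)
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    go = m.gap_open if gap_open is None else gap_open
    ge = m.gap_extend if gap_extend is None else gap_extend
    n, mm = len(a), len(b)

    sub = [[m.score(x, y) for y in b] for x in a]

    M = [[NEG_INF] * (mm + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (mm + 1) for _ in range(n + 1)]  # gap in s2 (up)
    Iy = [[NEG_INF] * (mm + 1) for _ in range(n + 1)]  # gap in s1 (left)
    # source state for each cell of each matrix
    bM = [[0] * (mm + 1) for _ in range(n + 1)]
    bX = [[0] * (mm + 1) for _ in range(n + 1)]
    bY = [[0] * (mm + 1) for _ in range(n + 1)]

    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = go + (i - 1) * ge
        bX[i][0] = _UP if i > 1 else _DIAG
    for j in range(1, mm + 1):
        Iy[0][j] = go + (j - 1) * ge
        bY[0][j] = _LEFT if j > 1 else _DIAG

    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], Ix[i], Iy[i]
        Mp, Xp, Yp = M[i - 1], Ix[i - 1], Iy[i - 1]
        bMi, bXi, bYi = bM[i], bX[i], bY[i]
        si = sub[i - 1]
        for j in range(1, mm + 1):
            # match state: best predecessor in tie order diag > up > left
            best, state = Mp[j - 1], _DIAG
            if Xp[j - 1] > best:
                best, state = Xp[j - 1], _UP
            if Yp[j - 1] > best:
                best, state = Yp[j - 1], _LEFT
            Mi[j] = best + si[j - 1]
            bMi[j] = state
            # up state (consume a[i-1] vs gap); opening from M or Iy
            open_x = max(Mp[j], Yp[j]) + go
            ext_x = Xp[j] + ge
            if open_x >= ext_x:
                Xi[j] = open_x
                bXi[j] = _DIAG if Mp[j] >= Yp[j] else _LEFT
            else:
                Xi[j] = ext_x
                bXi[j] = _UP
            # left state (consume b[j-1] vs gap)
            open_y = max(Mi[j - 1], Xi[j - 1]) + go
            ext_y = Yi[j - 1] + ge
            if open_y >= ext_y:
                Yi[j] = open_y
                bYi[j] = _DIAG if Mi[j - 1] >= Xi[j - 1] else _UP
            else:
                Yi[j] = ext_y
                bYi[j] = _LEFT

    # final state, tie order diag > up > left
    score, state = M[n][mm], _DIAG
    if Ix[n][mm] > score:
        score, state = Ix[n][mm], _UP
    if Iy[n][mm] > score:
        score, state = Iy[n][mm], _LEFT

    columns: list[tuple[Optional[int], Optional[int]]] = []
    i, j = n, mm
    while i > 0 or j > 0:
        if state == _DIAG:
            prev = bM[i][j]
            columns.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif state == _UP:
            prev = bX[i][j]
            columns.append((i - 1, None))
            i -= 1
        else:
            prev = bY[i][j]
            columns.append((None, j - 1))
            j -= 1
        state = prev
    columns.reverse()
    return PairAlignment(columns=columns, score=float(score))


def score_alignment(
    columns: Sequence[tuple[Optional[int], Optional[int]]],
    s1: Union[str, PBSequence],
    s2: Union[str, PBSequence],
    m: SubstitutionMatrix,
    gap_open: Optional[float] = None,
    gap_extend: Optional[float] = None,
) -> float:
    """Score an explicit column list under the aligner's conventions."""
    a, b = _letters(s1), _letters(s2)
    go = m.gap_open if gap_open is None else gap_open
    ge = m.gap_extend if gap_extend is None else gap_extend
    total = 0.0
    prev_gap_side = None  # 'i' = gap in s2, 'j' = gap in s1
    for i, j in columns:
        if i is not None and j is not None:
            total += m.score(a[i], b[j])
            prev_gap_side = None
        else:
            side = "i" if j is None else "j"
            total += ge if prev_gap_side == side else go
            prev_gap_side = side
    return total


def find_anchors(
    s1: Union[str, PBSequence],
    s2: Union[str, PBSequence],
    m: SubstitutionMatrix,
    params: AnchorParams = AnchorParams(),
) -> list[Anchor]:
    """Detect high-confidence aligned segments under stringent scoring.

    A first-pass global alignment is run with substitution scores and gap
    penalties multiplied by ``params.weight``; maximal runs of consecutive
    aligned columns whose (unweighted) per-column score reaches
    ``params.score_fraction * max_diagonal`` and whose length reaches
    ``params.min_length`` become anchors. Z columns never qualify.
    """
    a, b = _letters(s1), _letters(s2)
    stringent = SubstitutionMatrix(
        scores=m.scores * params.weight,
        gap_open=m.gap_open * params.weight,
        gap_extend=m.gap_extend * params.weight,
        z_score=m.z_score,
    )
    first = global_align(a, b, stringent)
    threshold = params.score_fraction * m.max_diagonal

    anchors: list[Anchor] = []
    run: list[tuple[int, int]] = []

    def flush():
        if len(run) >= params.min_length:
            seg = sum(m.score(a[i], b[j]) for i, j in run)
            anchors.append(
                Anchor(start_i=run[0][0], start_j=run[0][1],
                       length=len(run), segment_score=seg)
            )
        run.clear()

    for i, j in first.columns:
        ok = (
            i is not None
            and j is not None
            and a[i] != "Z"
            and b[j] != "Z"
            and m.score(a[i], b[j]) >= threshold
        )
        if ok and run and (i != run[-1][0] + 1 or j != run[-1][1] + 1):
            flush()
        if ok:
            run.append((i, j))
        else:
            flush()
    flush()
    return anchors


def _check_anchors(anchors: Sequence[Anchor], n1: int, n2: int) -> None:
    prev_i = prev_j = 0
    for a in sorted(anchors, key=lambda x: x.start_i):
        if a.start_i < prev_i or a.start_j < prev_j:
            raise AlignmentError("anchors overlap or cross")
        if a.end_i > n1 or a.end_j > n2:
            raise AlignmentError("anchor exceeds sequence bounds")
        prev_i, prev_j = a.end_i, a.end_j


def _gap_columns(i0: int, i1: int, j0: int, j1: int):
    cols: list[tuple[Optional[int], Optional[int]]] = []
    cols.extend((i, None) for i in range(i0, i1))
    cols.extend((None, j) for j in range(j0, j1))
    return cols


def anchored_align(
    s1: Union[str, PBSequence],
    s2: Union[str, PBSequence],
    m: SubstitutionMatrix,
    anchors: Sequence[Anchor],
    gap_open: Optional[float] = None,
    gap_extend: Optional[float] = None,
) -> PairAlignment:
    """Complete an alignment around frozen anchors with relaxed parameters.

    Anchor columns are kept verbatim; each inter-anchor (and flanking)
    region is aligned independently by :func:`global_align` with the given
    relaxed parameters. With no anchors this reduces exactly to
    :func:`global_align`.
    """
    a, b = _letters(s1), _letters(s2)
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    _check_anchors(anchors, len(a), len(b))
    ordered = sorted(anchors, key=lambda x: x.start_i)

    columns: list[tuple[Optional[int], Optional[int]]] = []
    ci = cj = 0
    for anc in ordered:
        seg_a, seg_b = a[ci:anc.start_i], b[cj:anc.start_j]
        if seg_a and seg_b:
            sub = global_align(seg_a, seg_b, m, gap_open, gap_extend)
            columns.extend(
                (ci + i if i is not None else None, cj + j if j is not None else None)
                for i, j in sub.columns
            )
        else:
            columns.extend(_gap_columns(ci, anc.start_i, cj, anc.start_j))
        columns.extend(
            (anc.start_i + k, anc.start_j + k) for k in range(anc.length)
        )
        ci, cj = anc.end_i, anc.end_j
    seg_a, seg_b = a[ci:], b[cj:]
    if seg_a and seg_b:
        sub = global_align(seg_a, seg_b, m, gap_open, gap_extend)
        columns.extend(
            (ci + i if i is not None else None, cj + j if j is not None else None)
            for i, j in sub.columns
        )
    else:
        columns.extend(_gap_columns(ci, len(a), cj, len(b)))

    total = score_alignment(columns, a, b, m, gap_open, gap_extend)
    return PairAlignment(columns=columns, score=total)


def align_two_pass(
    s1: Union[str, PBSequence],
    s2: Union[str, PBSequence],
    m: SubstitutionMatrix,
    anchor_params: AnchorParams = AnchorParams(),
) -> PairAlignment:
    """The full two-pass procedure: stringent anchor pass, then relaxed fill."""
    anchors = find_anchors(s1, s2, m, anchor_params)
    return anchored_align(s1, s2, m, anchors)


def alignment_tracks(
    alignment: PairAlignment,
    s1: str,
    s2: str,
    gap: str = "-",
) -> tuple[str, str]:
    """Render two gapped strings (one per sequence) from a column list."""
    t1 = "".join(s1[i] if i is not None else gap for i, _ in alignment.columns)
    t2 = "".join(s2[j] if j is not None else gap for _, j in alignment.columns)
    return t1, t2
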