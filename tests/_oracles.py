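"""Independent oracles used by the test suite.

Each routine here deliberately avoids the code path it checks: alignment
scores come from exhaustive enumeration, rotations from Horn's quaternion
method, PB assignment from a naive loop, and GDT_PB from a plain recount.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_align_score(a: str, b: str, score_fn, gap_open: float, gap_extend: float) -> float:
    """Exhaustive optimum over every global alignment of ``a`` and ``b``.

    A gap run of length L costs gap_open + (L-1)*gap_extend; runs on
    opposite sequences are separate runs even when adjacent.
    """
    best = -math.inf
    la, lb = len(a), len(b)

    stack = [(0, 0, None, 0.0)]
    while stack:
        i, j, last, acc = stack.pop()
        if i == la and j == lb:
            if acc > best:
                best = acc
            continue
        if i < la and j < lb:
            stack.append((i + 1, j + 1, "M", acc + score_fn(a[i], b[j])))
        if i < la:
            stack.append((i + 1, j, "X", acc + (gap_extend if last == "X" else gap_open)))
        if j < lb:
            stack.append((i, j + 1, "Y", acc + (gap_extend if last == "Y" else gap_open)))
    return best


def quaternion_fit_rmsd(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, float]:
    """Horn's closed-form absolute-orientation solution (unit quaternion).

    Returns the rotation matrix mapping centred A onto centred B and the
    post-fit RMSD; independent of the SVD-based Kabsch implementation.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    S = A0.T @ B0
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(K)
    w, x, y, z = eigvecs[:, np.argmax(eigvals)]
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    rmsd = float(np.sqrt(np.mean(np.sum((A0 @ R.T - B0) ** 2, axis=1))))
    return R, rmsd


def naive_nearest_prototype(window, prototypes: np.ndarray, letters: str) -> str:
    """Plain-loop nearest prototype by RMS of wrapped angular differences."""
    best_letter, best_val = None, math.inf
    for k, letter in enumerate(letters):
        acc = 0.0
        for a, b in zip(window, prototypes[k]):
            d = math.fmod(a - b + 180.0, 360.0)
            if d < 0:
                d += 360.0
            d -= 180.0
            acc += d * d
        val = math.sqrt(acc / 8.0)
        if val < best_val:  # strict: first (alphabetical) wins ties
            best_val, best_letter = val, letter
    return best_letter


def recount_gdt_pb(pb_a: str, pb_b: str, pairs, score_fn, matrix_min: float,
                   quartiles=(0.25, 0.5, 0.75, 1.0)) -> float | None:
    """Re-derive GDT_PB by explicit counting over aligned non-Z columns."""
    sims = []
    for i, j in pairs:
        x, y = pb_a[i], pb_b[j]
        if x == "Z" or y == "Z":
            continue
        best = min(score_fn(x, x), score_fn(y, y))
        if best <= matrix_min:
            sims.append(0.0)
        else:
            u = (score_fn(x, y) - matrix_min) / (best - matrix_min)
            sims.append(min(max(u, 0.0), 1.0))
    if not sims:
        return None
    total = 0.0
    for q in quartiles:
        total += sum(1 for u in sims if u >= q) / len(sims)
    return total / len(quartiles)
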