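"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by the most literal method available —
exhaustive enumeration, all-pairs scanning, or an alternative closed-form
solver — and never shares code with the implementation path it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def brute_force_alignment_score(
    a: str,
    b: str,
    score_fn,
    gap_open: float,
    gap_extend: float,
    end_gaps_free: bool,
) -> float:
    """Best global alignment score by enumerating every monotone path.

    A maximal gap run of length L costs gap_open + (L-1)*gap_extend; runs
    touching either end are free when end_gaps_free.  Exponential — only for
    short sequences.
    """
    n, m = len(a), len(b)
    best = float("-inf")

    def score_cols(cols) -> float:
        total = 0.0
        k = 0
        ncols = len(cols)
        while k < ncols:
            ca, cb = cols[k]
            if ca == "-" or cb == "-":
                which = 0 if ca == "-" else 1
                start = k
                while k < ncols and cols[k][which] == "-":
                    k += 1
                if not (end_gaps_free and (start == 0 or k == ncols)):
                    total -= gap_open + (k - start - 1) * gap_extend
            else:
                total += score_fn(ca, cb)
                k += 1
        return total

    stack = [(0, 0, [])]
    while stack:
        i, j, cols = stack.pop()
        if i == n and j == m:
            s = score_cols(cols)
            if s > best:
                best = s
            continue
        if i < n and j < m:
            stack.append((i + 1, j + 1, cols + [(a[i], b[j])]))
        if i < n:
            stack.append((i + 1, j, cols + [(a[i], "-")]))
        if j < m:
            stack.append((i, j + 1, cols + [("-", b[j])]))
    return best


def all_pairs_contacts(
    query_xyz: np.ndarray, other_xyz: np.ndarray, cutoff: float
) -> set[tuple[int, int]]:
    """Index pairs within cutoff by a dense O(N^2) distance matrix."""
    if len(query_xyz) == 0 or len(other_xyz) == 0:
        return set()
    d = cdist(query_xyz, other_xyz)
    qi, oi = np.nonzero(d <= cutoff)
    return set(zip(qi.tolist(), oi.tolist()))


def quaternion_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition via Horn's quaternion eigenvalue method.

    Returns (rotation matrix, rmsd).  Independent of the SVD/Kabsch route.
    """
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    Sxx, Sxy, Sxz = (P[:, 0] * Q[:, 0]).sum(), (P[:, 0] * Q[:, 1]).sum(), (P[:, 0] * Q[:, 2]).sum()
    Syx, Syy, Syz = (P[:, 1] * Q[:, 0]).sum(), (P[:, 1] * Q[:, 1]).sum(), (P[:, 1] * Q[:, 2]).sum()
    Szx, Szy, Szz = (P[:, 2] * Q[:, 0]).sum(), (P[:, 2] * Q[:, 1]).sum(), (P[:, 2] * Q[:, 2]).sum()
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(K)
    q = eigvecs[:, -1]  # quaternion for the largest eigenvalue
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    moved = P @ R.T
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum() / len(P)))
    return R, rmsd
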