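"""Independent oracles used to cross-check phnmr implementations.

These deliberately use different algorithms from the package code paths:
the quaternion characteristic-polynomial method for superposition RMSD,
exhaustive enumeration for global alignment, and permutation search for
bipartite matching.
"""

from __future__ import annotations

import itertools

import numpy as np


def quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares superposition RMSD via the Horn quaternion method.

    Builds the 4x4 key matrix from the coordinate cross-covariance; the
    largest eigenvalue gives the optimal residual in closed form, with no
    SVD and no explicit rotation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key)[-1]
    n = a.shape[0]
    msd = (np.sum(a**2) + np.sum(b**2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def enumerate_global_alignments(sa: str, sb: str, match, mismatch, gap_open,
                                gap_extend):
    """All global alignments of two short strings with their affine scores.

    Yields (pairs, score) where pairs is a tuple of (i, j) with None for
    gaps (1-based). Exponential; only for tiny strings.
    """

    def rec(i, j, pairs, score, prev_gap):
        if i == len(sa) and j == len(sb):
            yield tuple(pairs), score
            return
        if i < len(sa) and j < len(sb):
            s = match if sa[i] == sb[j] else mismatch
            yield from rec(i + 1, j + 1, pairs + [(i + 1, j + 1)], score + s, None)
        if i < len(sa):
            cost = gap_extend if prev_gap == "A" else gap_open
            yield from rec(i + 1, j, pairs + [(i + 1, None)], score + cost, "A")
        if j < len(sb):
            cost = gap_extend if prev_gap == "B" else gap_open
            yield from rec(i, j + 1, pairs + [(None, j + 1)], score + cost, "B")

    yield from rec(0, 0, [], 0.0, None)


def best_alignment_score(sa, sb, match=1.0, mismatch=0.0, gap_open=-10.0,
                         gap_extend=-0.5) -> float:
    return max(s for _p, s in
               enumerate_global_alignments(sa, sb, match, mismatch, gap_open,
                                           gap_extend))


def brute_force_assignment(cost: np.ndarray):
    """Minimum-cost one-to-one assignment by permutation search (n <= ~7).

    Returns (row->col mapping dict, total cost) assigning every row when
    rows <= cols.
    """
    n_rows, n_cols = cost.shape
    best_perm, best_cost = None, np.inf
    for cols in itertools.permutations(range(n_cols), n_rows):
        c = sum(cost[r, cols[r]] for r in range(n_rows))
        if c < best_cost:
            best_cost, best_perm = c, cols
    return {r: best_perm[r] for r in range(n_rows)}, float(best_cost)
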