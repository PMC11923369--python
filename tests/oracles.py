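"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (exhaustive
recursion, enumeration, dense quadrature) rather than sharing any code with
the implementation they check.
"""

from functools import lru_cache

import numpy as np


def frechet_recursive(curve_a, curve_b) -> float:
    """Discrete Frechet distance straight from the coupling recursion."""
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        d = float(np.linalg.norm(a[i] - b[j]))
        if i == 0 and j == 0:
            return d
        if i == 0:
            return max(rec(0, j - 1), d)
        if j == 0:
            return max(rec(i - 1, 0), d)
        return max(min(rec(i - 1, j), rec(i, j - 1), rec(i - 1, j - 1)), d)

    return rec(len(a) - 1, len(b) - 1)


def lcs_bruteforce(sequences) -> int:
    """Length of the longest substring common to all sequences, by
    enumerating substring sets with a binary search over the length."""
    shortest = min(sequences, key=len)
    lo, hi = 0, len(shortest)

    def exists(length: int) -> bool:
        if length == 0:
            return True
        candidates = {shortest[i:i + length]
                      for i in range(len(shortest) - length + 1)}
        for seq in sequences:
            candidates &= {seq[i:i + length]
                           for i in range(len(seq) - length + 1)}
            if not candidates:
                return False
        return True

    while lo < hi:
        mid = (lo + hi + 1) // 2
        if exists(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def lcs_all_longest(sequences) -> set[str]:
    """All longest common substrings, by enumeration."""
    length = lcs_bruteforce(sequences)
    if length == 0:
        return set()
    shortest = min(sequences, key=len)
    candidates = {shortest[i:i + length]
                  for i in range(len(shortest) - length + 1)}
    for seq in sequences:
        candidates &= {seq[i:i + length] for i in range(len(seq) - length + 1)}
    return candidates


def min_rmsd_rotation_grid(mobile, reference, n: int = 24) -> float:
    """Minimum RMSD over a dense grid of proper rotations (and the optimal
    translation, which is centroid matching)."""
    mob = np.asarray(mobile, float)
    ref = np.asarray(reference, float)
    mob = mob - mob.mean(axis=0)
    ref = ref - ref.mean(axis=0)
    best = np.inf
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    betas = np.linspace(0, np.pi, n // 2 + 1)
    for alpha in angles:
        ca, sa = np.cos(alpha), np.sin(alpha)
        rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        for beta in betas:
            cb, sb = np.cos(beta), np.sin(beta)
            ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            for gamma in angles:
                cg, sg = np.cos(gamma), np.sin(gamma)
                rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
                rot = rz1 @ ry @ rz2
                rmsd = np.sqrt(np.mean(np.sum((mob @ rot.T - ref) ** 2, axis=1)))
                best = min(best, rmsd)
    return float(best)


def rg_direct(coords, masses) -> float:
    """Radius of gyration straight from its definition."""
    coords = np.asarray(coords, float)
    masses = np.asarray(masses, float)
    com = np.average(coords, axis=0, weights=masses)
    return float(np.sqrt(np.average(np.sum((coords - com) ** 2, axis=1),
                                    weights=masses)))


def sasa_dense(coords, radii, probe: float, n_points: int = 20000) -> float:
    """SASA by dense uniform-random quadrature with a fixed RNG."""
    rng = np.random.default_rng(12345)
    coords = np.asarray(coords, float)
    expanded = np.asarray(radii, float) + probe
    total = 0.0
    for i in range(len(coords)):
        pts = rng.standard_normal((n_points, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = coords[i] + expanded[i] * pts
        free = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.sum((pts - coords[j]) ** 2, axis=1) > expanded[j] ** 2
        total += free.mean() * 4.0 * np.pi * expanded[i] ** 2
    return total
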