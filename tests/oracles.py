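"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths (and the acceleration structures) of
the package: nearest distances come from full O(n^2) pairwise matrices,
point-in-polygon from shapely, surface voxels from an explicit neighbor loop,
and Wilcoxon p-values from full 2^n sign enumeration.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def pairwise_nearest(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Min distance from each row of a to the rows of b; full matrix."""
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1)
    return np.sqrt(d2).min(axis=1)


def hausdorff_brute(a: np.ndarray, b: np.ndarray) -> float:
    return float(max(pairwise_nearest(a, b).max(), pairwise_nearest(b, a).max()))


def mdta_brute(a: np.ndarray, b: np.ndarray) -> float:
    dab = pairwise_nearest(a, b)
    dba = pairwise_nearest(b, a)
    return float((dab.sum() + dba.sum()) / (len(a) + len(b)))


def dice_brute(va: np.ndarray, vb: np.ndarray) -> float:
    inter = np.count_nonzero(va & vb)
    return 2.0 * inter / (np.count_nonzero(va) + np.count_nonzero(vb))


def surface_voxels_brute(v: np.ndarray) -> np.ndarray:
    """Indices of true voxels with a false-or-outside 6-neighbor; explicit loop."""
    out = []
    nx, ny, nz = v.shape
    for i, j, k in np.argwhere(v):
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz) or not v[ni, nj, nk]:
                out.append((i, j, k))
                break
    return np.asarray(out, dtype=int).reshape(-1, 3)


def _average_ranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def wilcoxon_exact_enum(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign assignments.

    Zero differences must be removed by the caller (classic zero handling).
    """
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0), "drop zeros before enumeration"
    n = len(d)
    ranks = _average_ranks(np.abs(d))
    w_obs = ranks[d > 0].sum()
    le = ge = 0
    for signs in product((0, 1), repeat=n):
        w = ranks[np.asarray(signs, dtype=bool)].sum()
        le += w <= w_obs + 1e-12
        ge += w >= w_obs - 1e-12
    total = 2 ** n
    return min(1.0, 2.0 * min(le / total, ge / total))
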