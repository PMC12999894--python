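"""Template-counting kernels for approximate and sample entropy.

Both statistics count pairs of m-length (and (m+1)-length) embedding vectors
whose Chebyshev distance is within a radius.  The counts are O(N^2); a
numba-jitted kernel with early-exit distance checks is used when numba is
importable, otherwise a vectorized numpy distance-matrix path.  Both paths are
exact (no approximation) and are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _apen_phi_counts(x: np.ndarray, m: int, r: float) -> np.ndarray:
    """Per-template match counts C_i (self-match included) at length m."""
    n = x.size
    nt = n - m + 1
    counts = np.zeros(nt, dtype=np.int64)
    for i in range(nt):
        for j in range(nt):
            ok = True
            for a in range(m):
                if abs(x[i + a] - x[j + a]) > r:
                    ok = False
                    break
            if ok:
                counts[i] += 1
    return counts


@njit(cache=False)
def _sampen_pair_counts(x: np.ndarray, m: int, r: float) -> np.ndarray:
    """[B, A]: ordered pair counts (i != j) matching at lengths m and m+1.

    Templates of both lengths are restricted to the N-m starting points so B
    and A are computed over the same template population.
    """
    n = x.size
    nt = n - m  # starting points with room for an (m+1)-template
    B = 0
    A = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            ok = True
            for a in range(m):
                if abs(x[i + a] - x[j + a]) > r:
                    ok = False
                    break
            if ok:
                B += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    A += 1
    out = np.empty(2, dtype=np.int64)
    out[0] = B
    out[1] = A
    return out


def _cheb_match_matrix(x: np.ndarray, m: int, r: float) -> np.ndarray:
    """Boolean matrix of Chebyshev template matches at length m (numpy path)."""
    n = x.size
    D = np.abs(x[:, None] - x[None, :])
    M = D[: n - m + 1, : n - m + 1].copy()
    for a in range(1, m):
        np.maximum(M, D[a : n - m + 1 + a, a : n - m + 1 + a], out=M)
    return M <= r


def apen_phi_counts(x: np.ndarray, m: int, r: float) -> np.ndarray:
    if HAVE_NUMBA:
        return _apen_phi_counts(np.ascontiguousarray(x, dtype=np.float64), m, r)
    return _cheb_match_matrix(x, m, r).sum(axis=1)


def sampen_pair_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    if HAVE_NUMBA:
        out = _sampen_pair_counts(np.ascontiguousarray(x, dtype=np.float64), m, r)
        return int(out[0]), int(out[1])
    n = x.size
    nt = n - m
    Mb = _cheb_match_matrix(x, m, r)[:nt, :nt]
    Ma = _cheb_match_matrix(x, m + 1, r)
    B = int(Mb.sum()) - nt  # drop self-matches on the diagonal
    A = int(Ma.sum()) - Ma.shape[0]
    return B, A
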