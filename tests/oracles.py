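"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive and shares no code with the package:
cubic-time alignment DP, triple-loop network adjustment, pairwise
Mann-Whitney AUC, a transposed-SVD shrinkage and a grid-search proximal
minimiser. Slow is fine; independent is the point.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_brute_force(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
    """O(n*m*L) local alignment: every cell tries every gap length explicitly.

    H[i][j] = best local alignment score ending at a[i-1], b[j-1]; a gap of
    length L costs gap_open + (L-1)*gap_extend. The empty alignment scores 0.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cand = H[i - 1][j - 1] + _BLOSUM62[a[i - 1], b[j - 1]]
            for L in range(1, i + 1):  # gap in b: skip L residues of a
                cand = max(cand, H[i - L][j] - (gap_open + (L - 1) * gap_extend))
            for L in range(1, j + 1):  # gap in a
                cand = max(cand, H[i][j - L] - (gap_open + (L - 1) * gap_extend))
            H[i][j] = max(0.0, cand)
            best = max(best, H[i][j])
    return best


def triple_loop_adjust(ks: np.ndarray, sim_sub: np.ndarray, sim_kin: np.ndarray,
                       t: float, mode: str) -> np.ndarray:
    """Literal enumeration of the adjustment rule over (k, s1, s2) / (k1, k2, s)."""
    m, n = ks.shape
    out = ks.copy()
    if mode in ("substrate", "both"):
        for k in range(m):
            for s1 in range(n):
                if ks[k, s1] == 1:
                    for s2 in range(n):
                        if s2 != s1 and sim_sub[s1, s2] > t:
                            out[k, s2] = 1
    if mode in ("kinase", "both"):
        for k1 in range(m):
            for s in range(n):
                if ks[k1, s] == 1:
                    for k2 in range(m):
                        if k2 != k1 and sim_kin[k1, k2] > t:
                            out[k2, s] = 1
    return out


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the probability a random positive outscores a random negative,
    ties counted one half — all positive/negative pairs compared explicitly."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def shrink_via_transpose(X: np.ndarray, tau: float) -> np.ndarray:
    """Independent soft-thresholding route: SVD of X^T via scipy, transposed back."""
    import scipy.linalg

    U, s, Vt = scipy.linalg.svd(X.T, full_matrices=False, lapack_driver="gesvd")
    shrunk = np.maximum(s - tau, 0.0)
    return ((U * shrunk) @ Vt).T


def nuclear_norm_2x2(a, b, c, d):
    """sigma1 + sigma2 of [[a, b], [c, d]] in closed form (vectorised)."""
    fro2 = a * a + b * b + c * c + d * d
    det = np.abs(a * d - b * c)
    return np.sqrt(fro2 + 2.0 * det)


def prox_grid_search_2x2(X: np.ndarray, tau: float, half_width: float = 1.5,
                         steps: int = 25, refinements: int = 3):
    """Minimise tau*||Z||_* + 0.5*||Z - X||_F^2 over 2x2 Z by nested grid search.

    Starts on a grid centred at X wide enough to contain 0 and every
    shrunken solution, then refines around the argmin. Returns (Z, objective,
    final grid spacing).
    """
    center = X.astype(float).ravel().copy()
    width = half_width
    best = None
    for _ in range(refinements + 1):
        axes = [np.linspace(center[i] - width, center[i] + width, steps) for i in range(4)]
        A, B, C, D = np.meshgrid(*axes, indexing="ij", sparse=True)
        obj = tau * nuclear_norm_2x2(A, B, C, D) + 0.5 * (
            (A - X[0, 0]) ** 2 + (B - X[0, 1]) ** 2 + (C - X[1, 0]) ** 2 + (D - X[1, 1]) ** 2
        )
        flat = np.argmin(obj)
        idx = np.unravel_index(flat, obj.shape)
        center = np.array([axes[i][idx[i]] for i in range(4)])
        best = obj[idx]
        spacing = 2.0 * width / (steps - 1)
        width = 2.0 * spacing  # zoom in around the incumbent
    Z = center.reshape(2, 2)
    return Z, float(best), spacing
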