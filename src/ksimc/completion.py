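"""Matrix completion of the heterogeneous system by singular value thresholding.

Filling in the unobserved entries of the block matrix M is posed as
low-rank recovery. Exact rank minimisation subject to agreeing with M on
the observed set Omega is NP-hard, so the convex surrogate

    minimise  tau * ||X||_*  +  1/2 * ||X||_F^2
    subject to  P_Omega(X) = P_Omega(M)

is solved instead (||.||_* the nuclear norm, P_Omega the projection that
zeroes entries outside Omega). The singular value thresholding (SVT)
iteration alternates the shrinkage operator D_tau — an SVD with every
singular value reduced by tau and floored at 0 — with a gradient step on
the dual variable:

    X_k = D_tau(Y_{k-1})
    Y_k = Y_{k-1} + delta * P_Omega(M - X_k)

kick-started at Y_0 = ceil(tau / (delta * ||P_Omega(M)||_2)) * delta * P_Omega(M)
so that the first shrinkage already produces a non-zero iterate. The step
size defaults to delta = (m+n)/|Omega| and the shrinkage threshold to
tau = 5*(m+n). Because M and Omega are symmetric here, every iterate is
symmetric; the kinase-substrate score block is still read out as the
average of the two off-diagonal blocks for robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse.linalg

from .network import HeteroSystem

__all__ = [
    "SVTParams",
    "CompletionResult",
    "SVTDivergenceError",
    "project_omega",
    "soft_threshold",
    "svt",
    "svt_complete",
    "extract_scores",
    "build_score_table",
]


class SVTDivergenceError(RuntimeError):
    """Raised when the SVT residual blows up instead of shrinking."""


@dataclass(frozen=True)
class SVTParams:
    """Solver knobs.

    ``tau="auto"`` resolves to 5*(m+n); ``delta="auto"`` to (m+n)/|Omega|
    and ``delta="auto_literature"`` to 1.2*(m+n)**2/|Omega|. The iteration
    stops when the relative residual on Omega drops below ``tol`` or after
    ``max_iter`` steps. ``y0_norm`` selects the norm in the kick-start
    multiplier (spectral by default). ``svd_backend="truncated"`` computes
    only the singular values above tau with an incremental-rank partial SVD,
    useful when the iterates stay low-rank on large systems.
    """

    tau: float | str = "auto"
    delta: float | str = "auto"
    max_iter: int = 500
    tol: float = 1e-4
    y0_norm: str = "spectral"
    svd_backend: str = "full"

    def __post_init__(self) -> None:
        if self.tau != "auto" and not (isinstance(self.tau, (int, float)) and self.tau > 0):
            raise ValueError(f"tau must be positive or 'auto', got {self.tau!r}")
        if self.delta not in ("auto", "auto_literature") and not (
            isinstance(self.delta, (int, float)) and self.delta > 0
        ):
            raise ValueError(f"delta must be positive, 'auto' or 'auto_literature', got {self.delta!r}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.y0_norm not in ("spectral", "frobenius"):
            raise ValueError(f"y0_norm must be 'spectral' or 'frobenius', got {self.y0_norm!r}")
        if self.svd_backend not in ("full", "truncated"):
            raise ValueError(f"svd_backend must be 'full' or 'truncated', got {self.svd_backend!r}")

    def resolve(self, shape: tuple[int, int], n_observed: int) -> tuple[float, float]:
        """Concrete (tau, delta) for a problem of the given shape and |Omega|."""
        if n_observed <= 0:
            raise ValueError("observation set is empty")
        # the square heterogeneous system has side m+n; a generic
        # rectangular problem uses n1+n2 in its place
        size = shape[0] if shape[0] == shape[1] else shape[0] + shape[1]
        tau = 5.0 * size if self.tau == "auto" else float(self.tau)
        if self.delta == "auto":
            delta = size / n_observed
        elif self.delta == "auto_literature":
            delta = 1.2 * size * size / n_observed
        else:
            delta = float(self.delta)
        return tau, delta


@dataclass
class CompletionResult:
    """Output of one completion run.

    ``M_star`` is the final iterate X_k; ``score_block`` the m x n
    kinase-substrate block (None when the solver was run on a generic
    matrix rather than a heterogeneous system); ``residual_trace`` holds
    ||P_Omega(M - X_k)||_F / ||P_Omega(M)||_F per iteration.
    """

    M_star: np.ndarray
    iterations: int
    residual_trace: list[float]
    converged: bool
    score_block: np.ndarray | None = None
    tau: float = 0.0
    delta: float = 0.0


def _as_mask(omega, shape: tuple[int, int]) -> np.ndarray:
    """Accept a boolean mask or an iterable of (i, j) pairs."""
    if isinstance(omega, np.ndarray) and omega.dtype == bool:
        if omega.shape != shape:
            raise ValueError(f"mask shape {omega.shape} does not match matrix shape {shape}")
        return omega
    mask = np.zeros(shape, dtype=bool)
    for i, j in omega:
        if not (0 <= i < shape[0] and 0 <= j < shape[1]):
            raise IndexError(f"index ({i}, {j}) out of range for shape {shape}")
        mask[i, j] = True
    return mask


def project_omega(X: np.ndarray, omega) -> np.ndarray:
    """P_Omega: keep entries indexed by omega, zero the rest. Linear, idempotent."""
    X = np.asarray(X, dtype=float)
    mask = _as_mask(omega, X.shape)
    return np.where(mask, X, 0.0)


def soft_threshold(X: np.ndarray, tau: float, backend: str = "full") -> np.ndarray:
    """Singular value shrinkage D_tau(X) = U diag((sigma_i - tau)+) V*.

    Shrinks every singular value by tau and floors at zero, so the output's
    nuclear norm never exceeds the input's. tau = 0 reproduces X up to
    SVD round-off.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("soft_threshold requires a finite matrix")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if backend == "truncated":
        return _soft_threshold_truncated(X, tau)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    shrunk = np.maximum(s - tau, 0.0)
    return (U * shrunk) @ Vt


def _soft_threshold_truncated(X: np.ndarray, tau: float) -> np.ndarray:
    """Partial-SVD shrinkage: compute singular triplets in increments of 10
    until one falls below tau (or the full spectrum is reached)."""
    kmax = min(X.shape) - 1
    if kmax < 1 or tau == 0.0:
        return soft_threshold(X, tau, backend="full")
    k = min(10, kmax)
    while True:
        U, s, Vt = scipy.sparse.linalg.svds(X, k=k)
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
        if s[-1] < tau or k == kmax:
            break
        k = min(k + 10, kmax)
    if k == kmax and s[-1] >= tau:
        return soft_threshold(X, tau, backend="full")
    shrunk = np.maximum(s - tau, 0.0)
    return (U * shrunk) @ Vt


def svt(
    M: np.ndarray,
    omega,
    params: SVTParams | None = None,
    *,
    check_symmetry: bool | None = None,
) -> CompletionResult:
    """Run the SVT iteration on a generic matrix with observation set omega.

    ``check_symmetry=None`` auto-enables the per-iterate symmetry assertion
    when both M and omega are symmetric (the heterogeneous-system case).
    Raises :class:`SVTDivergenceError` if the relative residual exceeds ten
    times its initial value.
    """
    params = params or SVTParams()
    M = np.asarray(M, dtype=float)
    if not np.isfinite(M).all():
        raise ValueError("input matrix must be finite")
    mask = _as_mask(omega, M.shape)
    n_obs = int(mask.sum())
    if n_obs == 0:
        raise ValueError("observation set Omega is empty")
    tau, delta = params.resolve(M.shape, n_obs)
    PM = np.where(mask, M, 0.0)
    norm_PM_F = np.linalg.norm(PM)
    if norm_PM_F == 0:
        raise ValueError("all observed entries are zero; nothing to complete")
    if check_symmetry is None:
        check_symmetry = (
            M.shape[0] == M.shape[1]
            and np.array_equal(M, M.T)
            and np.array_equal(mask, mask.T)
        )
    if params.y0_norm == "spectral":
        norm_for_k0 = scipy.sparse.linalg.svds(PM, k=1, return_singular_vectors=False)[0] \
            if min(PM.shape) > 2 else np.linalg.svd(PM, compute_uv=False)[0]
    else:
        norm_for_k0 = norm_PM_F
    k0 = ceil(tau / (delta * norm_for_k0))
    Y = k0 * delta * PM
    X = np.zeros_like(M)
    trace: list[float] = []
    converged = False
    for it in range(1, params.max_iter + 1):
        X = soft_threshold(Y, tau, backend=params.svd_backend)
        if check_symmetry and np.abs(X - X.T).max() > 1e-10:
            raise AssertionError("SVT iterate lost symmetry on a symmetric problem")
        R = np.where(mask, M - X, 0.0)
        resid = np.linalg.norm(R) / norm_PM_F
        trace.append(float(resid))
        if resid < params.tol:
            converged = True
            break
        if resid > 10.0 * trace[0] and it > 1:
            raise SVTDivergenceError(
                f"SVT diverged at iteration {it}: relative residual {resid:.3g} "
                f"exceeds 10x the initial {trace[0]:.3g} (tau={tau:.3g}, delta={delta:.3g})"
            )
        Y = Y + delta * R
    return CompletionResult(
        M_star=X,
        iterations=len(trace),
        residual_trace=trace,
        converged=converged,
        tau=tau,
        delta=delta,
    )


def svt_complete(hs: HeteroSystem, params: SVTParams | None = None) -> CompletionResult:
    """Complete a heterogeneous system and extract the kinase-substrate scores."""
    result = svt(hs.M, hs.omega, params, check_symmetry=True)
    result.score_block = extract_scores(result.M_star, hs.m, hs.n)
    return result


def extract_scores(M_star: np.ndarray, m: int, n: int) -> np.ndarray:
    """m x n kinase-substrate score block of a completed system matrix.

    The two off-diagonal blocks are averaged; for an exactly symmetric
    M_star this equals the top-right block, and the read-out is invariant
    under transposing M_star.
    """
    M_star = np.asarray(M_star, dtype=float)
    if M_star.shape != (m + n, m + n):
        raise ValueError(f"expected shape ({m + n}, {m + n}), got {M_star.shape}")
    return (M_star[:m, m:] + M_star[m:, :m].T) / 2.0


def build_score_table(
    scores: np.ndarray,
    kinase_ids: Sequence[str],
    substrate_ids: Sequence[str],
    known_pairs: Iterable[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Rank all kinase-substrate pairs by completed score.

    Descending score, ties broken lexicographically on
    (kinase_id, substrate_id); pairs already known in training are kept and
    flagged so downstream evaluation can include or exclude them explicitly.
    """
    scores = np.asarray(scores, dtype=float)
    m, n = len(kinase_ids), len(substrate_ids)
    if scores.shape != (m, n):
        raise ValueError(f"score block shape {scores.shape} does not match id counts ({m}, {n})")
    if not np.isfinite(scores).all():
        raise ValueError("score block contains non-finite values")
    known = frozenset(known_pairs)
    df = pd.DataFrame(
        {
            "kinase_id": np.repeat(list(kinase_ids), n),
            "substrate_id": list(substrate_ids) * m,
            "score": scores.ravel(),
        }
    )
    df["known"] = [
        (k, s) in known for k, s in zip(df["kinase_id"], df["substrate_id"])
    ]
    df = df.sort_values(
        by=["score", "kinase_id", "substrate_id"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df
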