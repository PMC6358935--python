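"""Bipartite interaction matrix, similarity adjustment and the heterogeneous system.

The kinase-substrate network is a binary m x n adjacency matrix M_KS. Before
completion it is optionally *adjusted*: when kinase k is known to act on
substrate s1 and another substrate s2 is sequence-similar to s1 (similarity
strictly greater than the threshold t, default 0.9), the pair (k, s2) is
added as well — similar substrates tend to be phosphorylated by similar
kinases. The adjusted network is then embedded with the two similarity
matrices into one symmetric (m+n) x (m+n) block matrix

    M = [[M_KK,   M_KS],
         [M_KS^T, M_SS]]

whose unobserved entries the completion solver fills in. The observation set
Omega marks which entries of M are constraints: both similarity blocks, plus
— under the default ``positives_only`` policy — only the 1-entries of the
interaction blocks, so the 0-entries are the unknowns being predicted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import InteractionList
from .similarity import SimilarityMatrix

__all__ = [
    "InteractionMatrix",
    "HeteroSystem",
    "build_interaction_matrix",
    "adjust_interactions",
    "assemble_hetero",
    "build_omega",
]


@dataclass(frozen=True)
class InteractionMatrix:
    """Binary m x n kinase-substrate adjacency with frozen node orderings."""

    kinase_ids: tuple[str, ...]
    substrate_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "kinase_ids", tuple(self.kinase_ids))
        object.__setattr__(self, "substrate_ids", tuple(self.substrate_ids))
        vals = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.kinase_ids), len(self.substrate_ids)):
            raise ValueError(f"values shape {vals.shape} does not match id counts")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")

    @property
    def m(self) -> int:
        return len(self.kinase_ids)

    @property
    def n(self) -> int:
        return len(self.substrate_ids)

    def pairs(self) -> frozenset[tuple[str, str]]:
        ki, si = np.nonzero(self.values)
        return frozenset((self.kinase_ids[i], self.substrate_ids[j]) for i, j in zip(ki, si))


def build_interaction_matrix(interactions: InteractionList) -> InteractionMatrix:
    """0/1 adjacency from a pair list; row/column order from the list's orderings."""
    kpos = {k: i for i, k in enumerate(interactions.kinase_ids)}
    spos = {s: j for j, s in enumerate(interactions.substrate_ids)}
    vals = np.zeros((interactions.m, interactions.n), dtype=np.int8)
    for k, s in interactions.pairs:
        vals[kpos[k], spos[s]] = 1
    if not vals.any():
        warnings.warn("interaction matrix has no known interactions; completion will have no signal")
    return InteractionMatrix(interactions.kinase_ids, interactions.substrate_ids, vals)


def adjust_interactions(
    ks: InteractionMatrix,
    sim_sub: SimilarityMatrix | None = None,
    sim_kin: SimilarityMatrix | None = None,
    t: float = 0.9,
    mode: str = "substrate",
) -> InteractionMatrix:
    """Propagate known edges along high-similarity nodes (single pass).

    Substrate mode: every 1 at (k, s1) induces a 1 at (k, s2) for each s2
    with sim(s1, s2) > t (strict). Kinase mode is the mirror rule. ``both``
    applies both rules to the *original* matrix — added edges never seed
    further additions, so the adjustment cannot cascade. Original 1s are
    always preserved; with t = 1.0 the strict inequality makes the
    adjustment the identity.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold t must be in [0, 1], got {t}")
    if mode not in ("substrate", "kinase", "both", "none"):
        raise ValueError(f"unknown adjust mode {mode!r}")
    if mode == "none":
        return ks
    orig = ks.values.astype(bool)
    out = orig.copy()
    if mode in ("substrate", "both"):
        if sim_sub is None:
            raise ValueError("substrate adjustment requires a substrate similarity matrix")
        if sim_sub.ids != ks.substrate_ids:
            raise ValueError("substrate similarity ids do not match interaction matrix columns")
        out |= orig @ (sim_sub.values > t)
    if mode in ("kinase", "both"):
        if sim_kin is None:
            raise ValueError("kinase adjustment requires a kinase similarity matrix")
        if sim_kin.ids != ks.kinase_ids:
            raise ValueError("kinase similarity ids do not match interaction matrix rows")
        out |= (sim_kin.values > t) @ orig
    return InteractionMatrix(ks.kinase_ids, ks.substrate_ids, out.astype(np.int8))


@dataclass(frozen=True)
class HeteroSystem:
    """The symmetric block matrix M with its observation mask.

    Rows/columns 0..m-1 are kinases, m..m+n-1 substrates. ``omega`` is a
    boolean mask of the same shape marking observed entries; it is always
    symmetric because M is.
    """

    M: np.ndarray
    omega: np.ndarray
    m: int
    n: int
    kinase_ids: tuple[str, ...]
    substrate_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        omega = np.asarray(self.omega, dtype=bool)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "kinase_ids", tuple(self.kinase_ids))
        object.__setattr__(self, "substrate_ids", tuple(self.substrate_ids))
        size = self.m + self.n
        if M.shape != (size, size) or omega.shape != (size, size):
            raise ValueError(f"expected ({size}, {size}) matrices, got M {M.shape}, omega {omega.shape}")
        if not np.array_equal(M, M.T):
            raise ValueError("heterogeneous matrix must be symmetric")
        if not np.array_equal(omega, omega.T):
            raise ValueError("observation mask must be symmetric")

    @property
    def size(self) -> int:
        return self.m + self.n

    @property
    def n_observed(self) -> int:
        return int(self.omega.sum())

    def omega_indices(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in zip(*np.nonzero(self.omega))}

    def interaction_block(self) -> np.ndarray:
        return self.M[: self.m, self.m :]


def build_omega(hs: HeteroSystem, policy: str = "positives_only") -> np.ndarray:
    """Observation mask for a heterogeneous system.

    ``positives_only``: both similarity blocks are fully observed and only
    the 1-entries of the interaction blocks are; interaction 0s stay free.
    ``all_bipartite``: every entry of M is observed (zeros pinned too; only
    useful with early stopping, kept for ablation).
    """
    m, n = hs.m, hs.n
    mask = np.zeros((m + n, m + n), dtype=bool)
    mask[:m, :m] = True
    mask[m:, m:] = True
    if policy == "positives_only":
        ones = hs.M[:m, m:] != 0
        mask[:m, m:] = ones
        mask[m:, :m] = ones.T
    elif policy == "all_bipartite":
        mask[:, :] = True
    else:
        raise ValueError(f"unknown omega policy {policy!r}")
    return mask


def assemble_hetero(
    sim_kin: SimilarityMatrix,
    ks_adjusted: InteractionMatrix,
    sim_sub: SimilarityMatrix,
    omega_policy: str = "positives_only",
) -> HeteroSystem:
    """Stack similarity and interaction blocks into the symmetric system matrix."""
    if sim_kin.ids != ks_adjusted.kinase_ids:
        raise ValueError("kinase similarity ids do not match interaction matrix rows")
    if sim_sub.ids != ks_adjusted.substrate_ids:
        raise ValueError("substrate similarity ids do not match interaction matrix columns")
    m, n = ks_adjusted.m, ks_adjusted.n
    M = np.zeros((m + n, m + n))
    M[:m, :m] = sim_kin.values
    M[m:, m:] = sim_sub.values
    M[:m, m:] = ks_adjusted.values
    M[m:, :m] = ks_adjusted.values.T
    hs = HeteroSystem(
        M=M,
        omega=np.ones((m + n, m + n), dtype=bool),
        m=m,
        n=n,
        kinase_ids=ks_adjusted.kinase_ids,
        substrate_ids=ks_adjusted.substrate_ids,
    )
    return HeteroSystem(
        M=M,
        omega=build_omega(hs, omega_policy),
        m=m,
        n=n,
        kinase_ids=ks_adjusted.kinase_ids,
        substrate_ids=ks_adjusted.substrate_ids,
    )
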