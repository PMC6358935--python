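"""Pairwise protein sequence similarity by Smith-Waterman local alignment.

Kinase-kinase and substrate-substrate similarity matrices are the two
diagonal blocks of the heterogeneous network, so they must be symmetric,
lie in [0, 1] and carry an exact unit diagonal. Raw local-alignment scores
(BLOSUM62, affine gaps: a gap of length L costs gap_open + (L-1)*gap_extend,
the EMBOSS ``water`` convention) are normalised by the geometric mean of the
two self-alignment scores:

    sim(a, b) = SW(a, b) / sqrt(SW(a, a) * SW(b, b))

which guarantees sim(a, a) = 1 and, with BLOSUM62's dominant diagonal,
values in [0, 1]. An EMBOSS-style percent-positive mode is available as an
alternative normalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import ProteinRecord

__all__ = [
    "AlignmentParams",
    "SimilarityMatrix",
    "smith_waterman_score",
    "normalized_similarity",
    "build_similarity_matrix",
]

#: Characters never scored, even though BLOSUM62 tables carry a '*' row.
_FORBIDDEN = frozenset("*-")


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme of the local alignment: substitution matrix + affine gaps."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend > 0:
            raise ValueError(
                f"require gap_open >= gap_extend > 0, got open={self.gap_open}, extend={self.gap_extend}"
            )

    @property
    def substitution_matrix(self):
        return _load_matrix(self.matrix_name)

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(self.substitution_matrix.alphabet) - _FORBIDDEN

    def make_aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.substitution_matrix
        # Biopython charges open_gap_score for the first gap position and
        # extend_gap_score for each further one: exactly the EMBOSS cost
        # gap_open + (L-1)*gap_extend for a gap of length L.
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


_MATRIX_CACHE: dict[str, object] = {}


def _load_matrix(name: str):
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = substitution_matrices.load(name)
    return _MATRIX_CACHE[name]


def _check_sequence(seq: str, params: AlignmentParams) -> None:
    if not seq:
        raise ValueError("cannot align an empty sequence")
    bad = set(seq) - params.alphabet
    if bad:
        raise ValueError(
            f"character {sorted(bad)[0]!r} is not scored by {params.matrix_name}"
        )


def smith_waterman_score(
    a: str, b: str, params: AlignmentParams | None = None, *, _aligner: PairwiseAligner | None = None
) -> float:
    """Optimal local alignment score of two sequences (affine gaps).

    Always >= 0: the empty alignment scores 0 and is admissible, so pairs
    with no positively scoring local alignment (e.g. single residues with a
    negative substitution score) return exactly 0.
    """
    params = params or AlignmentParams()
    _check_sequence(a, params)
    _check_sequence(b, params)
    aligner = _aligner if _aligner is not None else params.make_aligner()
    return max(0.0, float(aligner.score(a, b)))


def normalized_similarity(
    a: str,
    b: str,
    params: AlignmentParams | None = None,
    mode: str = "geometric",
) -> float:
    """Similarity in [0, 1] from local alignment.

    ``geometric`` (default): SW(a,b) / sqrt(SW(a,a) * SW(b,b)).
    ``percent_positive``: fraction of aligned columns of the optimal local
    alignment whose residue pair scores > 0 (EMBOSS "similarity" style).
    """
    params = params or AlignmentParams()
    if mode == "geometric":
        saa = smith_waterman_score(a, a, params)
        sbb = smith_waterman_score(b, b, params)
        if saa <= 0 or sbb <= 0:
            raise ValueError("sequence with non-positive self-alignment score cannot be normalised")
        return min(1.0, smith_waterman_score(a, b, params) / math.sqrt(saa * sbb))
    if mode == "percent_positive":
        return _percent_positive(a, b, params)
    raise ValueError(f"unknown normalisation mode {mode!r}")


def _percent_positive(a: str, b: str, params: AlignmentParams) -> float:
    _check_sequence(a, params)
    _check_sequence(b, params)
    aligner = params.make_aligner()
    if aligner.score(a, b) <= 0:
        return 0.0
    aln = next(iter(aligner.align(a, b)))
    mat = params.substitution_matrix
    positive = 0
    length = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for x, y in zip(a[sa:ea], b[sb:eb]):
            length += 1
            if mat[x, y] > 0:
                positive += 1
    # count gap columns between aligned segments toward the length
    blocks_a, blocks_b = aln.aligned
    for i in range(1, len(blocks_a)):
        length += (blocks_a[i][0] - blocks_a[i - 1][1]) + (blocks_b[i][0] - blocks_b[i - 1][1])
    return positive / length if length else 0.0


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric matrix of pairwise similarities in [0, 1], unit diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValueError(f"values shape {vals.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in similarity matrix")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(vals), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal must be exactly 1")
        if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def reindex(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Return the submatrix over ``ids``, in that order."""
        pos = {pid: i for i, pid in enumerate(self.ids)}
        try:
            idx = np.array([pos[i] for i in ids])
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not present in similarity matrix") from None
        return SimilarityMatrix(tuple(ids), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = tuple(str(c) for c in df.columns)
        if tuple(str(i) for i in df.index) != ids:
            raise ValueError(f"{path}: row and column ids differ")
        vals = df.to_numpy(dtype=float)
        vals = (vals + vals.T) / 2.0  # absorb round-trip rounding
        np.fill_diagonal(vals, 1.0)
        return cls(ids, vals)


def build_similarity_matrix(
    records: Sequence[ProteinRecord], params: AlignmentParams | None = None
) -> SimilarityMatrix:
    """All-vs-all normalised similarity over a record collection.

    Each unordered pair is aligned once; self-scores are cached. Quadratic in
    the number of records, which is fine at the hundreds-of-proteins scale
    this pipeline targets.
    """
    if not records:
        raise ValueError("need at least one record")
    params = params or AlignmentParams()
    ids = tuple(r.id for r in records)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    aligner = params.make_aligner()
    n = len(records)
    self_scores = np.empty(n)
    for i, rec in enumerate(records):
        try:
            self_scores[i] = smith_waterman_score(rec.sequence, rec.sequence, params, _aligner=aligner)
        except ValueError as exc:
            raise ValueError(f"cannot align {rec.id!r}: {exc}") from exc
        if self_scores[i] <= 0:
            raise ValueError(f"record {rec.id!r} has non-positive self-alignment score")
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                raw = smith_waterman_score(records[i].sequence, records[j].sequence, params, _aligner=aligner)
            except ValueError as exc:
                raise ValueError(f"cannot align pair ({ids[i]!r}, {ids[j]!r}): {exc}") from exc
            vals[i, j] = vals[j, i] = min(1.0, raw / math.sqrt(self_scores[i] * self_scores[j]))
    return SimilarityMatrix(ids, vals)
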