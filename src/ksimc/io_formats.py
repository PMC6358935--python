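"""External file formats and run configuration.

Everything the pipeline reads or writes on disk goes through this module:
FASTA sequence sets, two-column interaction lists, ranked score tables and
the key=value run configuration. Matrix row/column order is always the FASTA
input order — never alphabetical — so that matrices written by one stage can
be consumed by the next without an id join.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "InteractionList",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_interactions",
    "write_interactions",
    "write_scores",
    "file_digest",
]

ADJUST_MODES = ("substrate", "kinase", "both", "none")
OMEGA_POLICIES = ("positives_only", "all_bipartite")

#: Required columns of a ranked prediction table, in output order.
SCORE_COLUMNS = ("rank", "kinase_id", "substrate_id", "score", "known")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: an identifier plus its amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid protein id {self.id!r}: must be a non-empty token without whitespace")
        seq = "".join(self.sequence.split()).upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        if not seq.isalpha():
            bad = next(c for c in seq if not c.isalpha())
            raise ValueError(f"protein {self.id!r} contains non-letter character {bad!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class InteractionList:
    """Known kinase-substrate pairs over frozen node orderings.

    ``kinase_ids`` and ``substrate_ids`` fix the row/column order of every
    matrix built downstream; ``pairs`` is a set of (kinase_id, substrate_id)
    tuples, each referencing ids present in those lists.
    """

    pairs: frozenset[tuple[str, str]]
    kinase_ids: tuple[str, ...]
    substrate_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        object.__setattr__(self, "kinase_ids", tuple(self.kinase_ids))
        object.__setattr__(self, "substrate_ids", tuple(self.substrate_ids))
        kset, sset = set(self.kinase_ids), set(self.substrate_ids)
        if len(kset) != len(self.kinase_ids):
            raise ValueError("duplicate kinase ids")
        if len(sset) != len(self.substrate_ids):
            raise ValueError("duplicate substrate ids")
        for k, s in self.pairs:
            if k not in kset:
                raise ValueError(f"interaction references unknown kinase id {k!r}")
            if s not in sset:
                raise ValueError(f"interaction references unknown substrate id {s!r}")

    @property
    def m(self) -> int:
        return len(self.kinase_ids)

    @property
    def n(self) -> int:
        return len(self.substrate_ids)

    def with_pairs(self, pairs: Iterable[tuple[str, str]]) -> "InteractionList":
        """Same node orderings, different pair set."""
        return InteractionList(frozenset(pairs), self.kinase_ids, self.substrate_ids)


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of a full prediction run.

    t
        Similarity threshold for the network-adjustment step; an edge
        (k, s1) propagates to (k, s2) when sim(s1, s2) > t (strictly).
    tau
        Singular-value shrinkage threshold of the completion solver;
        ``"auto"`` resolves to 5*(m+n).
    delta
        Gradient step size; ``"auto"`` resolves to (m+n)/|Omega|,
        ``"auto_literature"`` to 1.2*(m+n)**2/|Omega|.
    tol, max_iter
        Stopping rule: relative residual on the observed entries below
        ``tol``, or ``max_iter`` iterations.
    adjust_mode
        Which side of the bipartite network the similarity adjustment
        rewires: substrate (default), kinase, both, or none.
    omega_policy
        Which entries of the heterogeneous matrix count as observed:
        ``positives_only`` (similarity blocks plus known interactions;
        interaction zeros are left free to be predicted) or
        ``all_bipartite`` (every entry pinned).
    """

    t: float = 0.9
    tau: float | str = "auto"
    delta: float | str = "auto"
    max_iter: int = 500
    tol: float = 1e-4
    adjust_mode: str = "substrate"
    omega_policy: str = "positives_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise ValueError(f"t must be in [0, 1], got {self.t}")
        if self.tau != "auto" and not (isinstance(self.tau, (int, float)) and self.tau > 0):
            raise ValueError(f"tau must be positive or 'auto', got {self.tau!r}")
        if self.delta not in ("auto", "auto_literature") and not (
            isinstance(self.delta, (int, float)) and self.delta > 0
        ):
            raise ValueError(f"delta must be positive, 'auto' or 'auto_literature', got {self.delta!r}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.adjust_mode not in ADJUST_MODES:
            raise ValueError(f"adjust_mode must be one of {ADJUST_MODES}, got {self.adjust_mode!r}")
        if self.omega_policy not in OMEGA_POLICIES:
            raise ValueError(f"omega_policy must be one of {OMEGA_POLICIES}, got {self.omega_policy!r}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a ``key = value`` text file; keyword overrides win."""
        values: dict = {}
        casts = {f.name: f for f in fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in casts:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if key in ("tau", "delta") and val in ("auto", "auto_literature"):
                values[key] = val
            elif key in ("max_iter", "seed"):
                values[key] = int(val)
            elif key in ("t", "tau", "delta", "tol"):
                values[key] = float(val)
            else:
                values[key] = val
        values.update(overrides)
        return cls(**values)

    def to_text(self) -> str:
        return "".join(f"{f.name} = {getattr(self, f.name)}\n" for f in fields(self))

    def updated(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into an ordered list of :class:`ProteinRecord`.

    Ids are the first whitespace-delimited token of each header; multi-line
    sequences are concatenated; input order is preserved. A duplicate id is
    a hard error (downstream matrices index nodes by id).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequences at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_interactions(
    path: str | Path,
    kinases: Sequence[ProteinRecord],
    substrates: Sequence[ProteinRecord],
) -> InteractionList:
    """Read a two-column (kinase_id, substrate_id) pair list.

    Tab- or comma-delimited, auto-detected from the first data line; lines
    starting with '#' are skipped; duplicate pairs collapse to one. Node
    orderings are taken from the FASTA record orders, and any id absent
    from them is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"interaction file not found: {path}")
    kinase_ids = tuple(r.id for r in kinases)
    substrate_ids = tuple(r.id for r in substrates)
    kset, sset = set(kinase_ids), set(substrate_ids)
    pairs: set[tuple[str, str]] = set()
    delim: str | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if delim is None:
            delim = _sniff_delimiter(line)
        cols = [c.strip() for c in line.split(delim)]
        if len(cols) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}: {raw!r}")
        k, s = cols
        if k not in kset:
            raise ValueError(f"{path}:{lineno}: unknown kinase id {k!r}")
        if s not in sset:
            raise ValueError(f"{path}:{lineno}: unknown substrate id {s!r}")
        pairs.add((k, s))
    if not pairs:
        warnings.warn(f"no interactions read from {path}")
    return InteractionList(frozenset(pairs), kinase_ids, substrate_ids)


def write_interactions(interactions: InteractionList, path: str | Path) -> None:
    """Write pairs as a sorted two-column TSV (deterministic order)."""
    with open(path, "w") as fh:
        for k, s in sorted(interactions.pairs):
            fh.write(f"{k}\t{s}\n")


def write_scores(
    scores: pd.DataFrame,
    path: str | Path,
    provenance: dict | None = None,
) -> None:
    """Write a ranked prediction table as TSV.

    Rows are sorted by descending score with ties broken lexicographically
    on (kinase_id, substrate_id), and ranks rewritten to match, so output
    is deterministic for a given score set. Optional provenance key/value
    pairs are emitted as '#'-prefixed header lines.
    """
    missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    out = scores.sort_values(
        by=["score", "kinase_id", "substrate_id"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        out.to_csv(fh, sep="\t", index=False, columns=list(SCORE_COLUMNS), float_format="%.10g")


def file_digest(path: str | Path) -> str:
    """SHA-256 digest of a file, for provenance headers."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
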