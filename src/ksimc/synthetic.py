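"""Synthetic benchmark instances with planted, recoverable structure.

Real kinase-substrate data couples two signals the pipeline exploits:
sequence similarity clusters (kinase families, substrate families) and a
sparse bipartite interaction network that is roughly block-structured over
those clusters — hence approximately low-rank. The generator plants exactly
that: one random ancestor sequence per cluster, members derived by i.i.d.
per-position substitutions, and interaction edges drawn with a high
within-cluster and a low between-cluster probability (a bipartite
stochastic block model, whose expected adjacency has rank equal to the
number of clusters). A fraction of the true edges is then hidden; a good
completion should rank these hidden edges above pairs that were never true.

Everything is a pure function of its seed. Default sizes (3 clusters,
8 kinases and 20 substrates per cluster, length-200 sequences, 5%
mutation, within/between link probabilities 0.8/0.02, 20% of edges hidden)
keep an end-to-end run at the seconds scale while leaving hundreds of
positives — enough for a stable ten-fold AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import InteractionList, ProteinRecord, write_fasta, write_interactions

__all__ = [
    "PlantedInstance",
    "generate_clustered_sequences",
    "generate_planted_network",
    "generate_planted_instance",
    "random_pairs",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedInstance:
    """A synthetic dataset with known ground truth.

    ``observed_interactions`` (a subset of ``true_interactions``) is what
    the pipeline gets to see; the hidden remainder is the recoverable
    signal. ``cluster_of_node`` maps every protein id to its planted
    cluster label.
    """

    kinases: tuple[ProteinRecord, ...]
    substrates: tuple[ProteinRecord, ...]
    true_interactions: frozenset[tuple[str, str]]
    observed_interactions: frozenset[tuple[str, str]]
    cluster_of_node: dict[str, int]
    seed: int

    def __post_init__(self) -> None:
        if not self.observed_interactions <= self.true_interactions:
            raise ValueError("observed interactions must be a subset of true interactions")
        clusters = set(self.cluster_of_node.values())
        kin_clusters = {self.cluster_of_node[r.id] for r in self.kinases}
        sub_clusters = {self.cluster_of_node[r.id] for r in self.substrates}
        if clusters - kin_clusters or clusters - sub_clusters:
            raise ValueError("every cluster needs at least one kinase and one substrate")

    @property
    def hidden_interactions(self) -> frozenset[tuple[str, str]]:
        return self.true_interactions - self.observed_interactions

    def interaction_list(self, observed_only: bool = True) -> InteractionList:
        pairs = self.observed_interactions if observed_only else self.true_interactions
        return InteractionList(
            pairs,
            tuple(r.id for r in self.kinases),
            tuple(r.id for r in self.substrates),
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit standard FASTA + TSV files so fixtures exercise the real I/O path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "kinase_fasta": outdir / "kinases.fasta",
            "substrate_fasta": outdir / "substrates.fasta",
            "interactions": outdir / "interactions.tsv",
            "truth": outdir / "interactions_true.tsv",
        }
        write_fasta(self.kinases, paths["kinase_fasta"])
        write_fasta(self.substrates, paths["substrate_fasta"])
        write_interactions(self.interaction_list(observed_only=True), paths["interactions"])
        write_interactions(self.interaction_list(observed_only=False), paths["truth"])
        return paths


def generate_clustered_sequences(
    n_clusters: int,
    per_cluster: int,
    length: int,
    mutation_rate: float,
    seed: int,
    prefix: str = "P",
) -> tuple[tuple[ProteinRecord, ...], dict[str, int]]:
    """Sequences in similarity clusters: one ancestor per cluster, members mutated.

    Each member copies its cluster ancestor and substitutes every position
    independently with probability ``mutation_rate`` (to a uniformly random
    *different* residue, so the rate is the realised divergence from the
    ancestor). Rate 0 gives identical copies, i.e. within-cluster
    similarity exactly 1.
    """
    if n_clusters < 1 or per_cluster < 1 or length < 1:
        raise ValueError("n_clusters, per_cluster and length must be positive")
    if not 0.0 <= mutation_rate < 0.5:
        raise ValueError("mutation_rate must be in [0, 0.5) for clusters to remain meaningful")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    records: list[ProteinRecord] = []
    labels: dict[str, int] = {}
    idx = 0
    for c in range(n_clusters):
        ancestor = rng.choice(alphabet, size=length)
        for _ in range(per_cluster):
            seq = ancestor.copy()
            mutate = rng.random(length) < mutation_rate
            if mutate.any():
                # draw a uniform *other* residue: offset by 1..19 mod 20
                offsets = rng.integers(1, len(alphabet), size=int(mutate.sum()))
                pos = {b: i for i, b in enumerate(alphabet.tolist())}
                cur = np.array([pos[b] for b in seq[mutate].tolist()])
                seq[mutate] = alphabet[(cur + offsets) % len(alphabet)]
            idx += 1
            rec = ProteinRecord(f"{prefix}{idx}", seq.tobytes().decode())
            records.append(rec)
            labels[rec.id] = c
    return tuple(records), labels


def generate_planted_network(
    kinases: Sequence[ProteinRecord],
    substrates: Sequence[ProteinRecord],
    cluster_of_node: Mapping[str, int],
    link_prob_within: float,
    link_prob_between: float,
    hide_fraction: float,
    seed: int,
) -> PlantedInstance:
    """Bipartite stochastic block model over pre-clustered proteins.

    An edge (k, s) is drawn Bernoulli(link_prob_within) when k and s share
    a cluster and Bernoulli(link_prob_between) otherwise; the expected
    adjacency is block-constant, hence low-rank. ``hide_fraction`` of the
    realised edges is withheld from the observed set.
    """
    if not link_prob_within > link_prob_between:
        raise ValueError("link_prob_within must exceed link_prob_between")
    if not (0.0 <= link_prob_between and link_prob_within <= 1.0):
        raise ValueError("link probabilities must lie in [0, 1]")
    if not 0.0 <= hide_fraction < 1.0:
        raise ValueError("hide_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    true_edges: list[tuple[str, str]] = []
    for krec in kinases:
        kc = cluster_of_node[krec.id]
        for srec in substrates:
            p = link_prob_within if cluster_of_node[srec.id] == kc else link_prob_between
            if rng.random() < p:
                true_edges.append((krec.id, srec.id))
    n_hide = int(round(hide_fraction * len(true_edges)))
    hidden_idx = set(rng.choice(len(true_edges), size=n_hide, replace=False).tolist()) if n_hide else set()
    observed = frozenset(e for i, e in enumerate(true_edges) if i not in hidden_idx)
    return PlantedInstance(
        kinases=tuple(kinases),
        substrates=tuple(substrates),
        true_interactions=frozenset(true_edges),
        observed_interactions=observed,
        cluster_of_node=dict(cluster_of_node),
        seed=seed,
    )


def generate_planted_instance(
    n_clusters: int = 3,
    kinases_per_cluster: int = 8,
    substrates_per_cluster: int = 20,
    length: int = 200,
    mutation_rate: float = 0.05,
    link_prob_within: float = 0.8,
    link_prob_between: float = 0.02,
    hide_fraction: float = 0.2,
    seed: int = 0,
) -> PlantedInstance:
    """Default end-to-end benchmark: clustered sequences + block-model network."""
    ss = np.random.SeedSequence(seed)
    seed_kin, seed_sub, seed_net = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    kinases, kin_labels = generate_clustered_sequences(
        n_clusters, kinases_per_cluster, length, mutation_rate, seed_kin, prefix="K"
    )
    substrates, sub_labels = generate_clustered_sequences(
        n_clusters, substrates_per_cluster, length, mutation_rate, seed_sub, prefix="S"
    )
    return generate_planted_network(
        kinases,
        substrates,
        {**kin_labels, **sub_labels},
        link_prob_within,
        link_prob_between,
        hide_fraction,
        seed_net,
    )


def random_pairs(
    kinase_ids: Sequence[str], substrate_ids: Sequence[str], n_pairs: int, seed: int
) -> frozenset[tuple[str, str]]:
    """Uniform random distinct pairs: the structure-free null for control runs."""
    total = len(kinase_ids) * len(substrate_ids)
    if n_pairs > total:
        raise ValueError(f"cannot draw {n_pairs} distinct pairs from {total}")
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n_pairs, replace=False)
    n = len(substrate_ids)
    return frozenset((kinase_ids[i // n], substrate_ids[i % n]) for i in flat)
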