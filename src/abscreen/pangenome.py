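"""Pan/core genome accumulation from ortholog cluster membership.

Ortholog clusters are taken as input (one row per gene: cluster_id,
genome_id, gene_id); singleton genes, which belong to no cluster, are
tracked separately and never enter the curves.  The core genome of a genome
subset is the set of clusters represented in *every* genome of the subset;
the pan genome is the set represented in *any*.  Accumulation curves
resample genome orders with replacement (200 draws by default) and report
per-k means with 2.5/97.5 percentile envelopes; a genome drawn twice within
one order adds nothing (core/pan over a multiset equal those over its
support).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class OrthologTable:
    """Cluster membership: cluster_id -> set of (genome_id, gene_id)."""

    clusters: dict[str, set[tuple[str, str]]]
    genomes: list[str]
    singletons: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        known = set(self.genomes)
        for cid, members in self.clusters.items():
            for pair in members:
                if pair in seen and seen[pair] != cid:
                    raise ValueError(
                        f"gene {pair} occurs in clusters {seen[pair]!r} and {cid!r}"
                    )
                seen[pair] = cid
                if pair[0] not in known:
                    raise ValueError(f"cluster {cid!r} references unknown "
                                     f"genome {pair[0]!r}")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]],
                     genomes: Sequence[str] | None = None) -> "OrthologTable":
        clusters: dict[str, set[tuple[str, str]]] = {}
        seen_genomes: list[str] = []
        for cid, genome, gene in records:
            clusters.setdefault(cid, set()).add((genome, gene))
            if genome not in seen_genomes:
                seen_genomes.append(genome)
        return cls(clusters, list(genomes) if genomes else seen_genomes)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 genomes: Sequence[str] | None = None) -> "OrthologTable":
        """Load from a TSV with columns cluster_id, genome_id, gene_id."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_records(
            df[["cluster_id", "genome_id", "gene_id"]].itertuples(index=False),
            genomes,
        )

    def clusters_of(self, genome: str) -> set[str]:
        return {
            cid for cid, members in self.clusters.items()
            if any(g == genome for g, _ in members)
        }


def core_pan_sets(t: OrthologTable, genome_subset: Sequence[str]
                  ) -> tuple[set[str], set[str]]:
    """(core, pan) cluster sets over a nonempty genome subset.

    Core clusters contain at least one gene from every genome in the
    subset; pan clusters contain a gene from any of them.
    """
    subset = set(genome_subset)
    if not subset:
        raise ValueError("genome subset must be nonempty")
    unknown = subset - set(t.genomes)
    if unknown:
        raise ValueError(f"unknown genomes: {sorted(unknown)}")
    core, pan = set(), set()
    for cid, members in t.clusters.items():
        present = {g for g, _ in members}
        if present & subset:
            pan.add(cid)
        if subset <= present:
            core.add(cid)
    return core, pan


@dataclass(frozen=True)
class AccumulationCurves:
    k: np.ndarray
    core_mean: np.ndarray
    core_lo: np.ndarray
    core_hi: np.ndarray
    pan_mean: np.ndarray
    pan_lo: np.ndarray
    pan_hi: np.ndarray
    n_resamples: int
    seed: int
    core_draws: np.ndarray = field(repr=False, default=None)
    pan_draws: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k, "core_mean": self.core_mean, "core_lo": self.core_lo,
             "core_hi": self.core_hi, "pan_mean": self.pan_mean,
             "pan_lo": self.pan_lo, "pan_hi": self.pan_hi}
        )


def _curve_for_order(cluster_sets: Mapping[str, set[str]],
                     order: Sequence[str]) -> tuple[list[int], list[int]]:
    core: set[str] | None = None
    pan: set[str] = set()
    seen: set[str] = set()
    core_sizes, pan_sizes = [], []
    for genome in order:
        if genome not in seen:
            seen.add(genome)
            sets = cluster_sets[genome]
            core = set(sets) if core is None else core & sets
            pan |= sets
        core_sizes.append(len(core or ()))
        pan_sizes.append(len(pan))
    return core_sizes, pan_sizes


def accumulation_curves(t: OrthologTable, n_resamples: int = 200,
                        seed: int = 0) -> AccumulationCurves:
    """Pan/core accumulation by resampling genome orders with replacement.

    For each draw a genome order of length N is sampled with replacement
    and core/pan sizes are recorded after each position (duplicates are
    idempotent).  Means and 2.5/97.5 percentile envelopes are reported per
    k; deterministic given ``seed``.
    """
    genomes = list(t.genomes)
    if len(genomes) < 2:
        raise ValueError("at least two genomes are required")
    cluster_sets = {g: t.clusters_of(g) for g in genomes}
    rng = np.random.default_rng(seed)
    n = len(genomes)
    core_draws = np.empty((n_resamples, n), dtype=int)
    pan_draws = np.empty((n_resamples, n), dtype=int)
    for i in range(n_resamples):
        order = [genomes[j] for j in rng.integers(0, n, size=n)]
        core_draws[i], pan_draws[i] = _curve_for_order(cluster_sets, order)
    return AccumulationCurves(
        k=np.arange(1, n + 1),
        core_mean=core_draws.mean(axis=0),
        core_lo=np.percentile(core_draws, 2.5, axis=0),
        core_hi=np.percentile(core_draws, 97.5, axis=0),
        pan_mean=pan_draws.mean(axis=0),
        pan_lo=np.percentile(pan_draws, 2.5, axis=0),
        pan_hi=np.percentile(pan_draws, 97.5, axis=0),
        n_resamples=n_resamples,
        seed=seed,
        core_draws=core_draws,
        pan_draws=pan_draws,
    )
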