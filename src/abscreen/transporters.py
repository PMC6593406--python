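"""Census of organic-substrate uptake transporter families.

Per-genome protein hits against a transporter classification database are
filtered with the standard best-hit thresholds (E < 1e-5, identity > 30%,
subject coverage > 70%), restricted to a shortlist of uptake-related
families/subfamilies, and tabulated into a genomes x families count matrix,
once for all hits and once restricted to proteins with predicted
transmembrane segments.  Genomes are then ordinated by nonmetric
multidimensional scaling (NMDS) on Bray-Curtis dissimilarities.

Transmembrane segments come from a sliding-window Kyte-Doolittle hydropathy
scan - an explicit, documented stand-in for HMM-based predictors; a
precomputed TM annotation table can be supplied instead and takes
precedence.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from sklearn.manifold import smacof

# Kyte-Doolittle hydropathy index.
KD_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

TM_WINDOW = 19
TM_THRESHOLD = 1.6

#: Small built-in shortlist of uptake-related TC families for demos/tests:
#: the ABC superfamily (uptake porters live under 3.A.1), TRAP-T, SSS, CNT,
#: DAACS and NSS.  Real analyses supply their own curated shortlist.
DEMO_UPTAKE_FAMILIES = {
    "3.A.1": "ABC",
    "2.A.56": "TRAP-T",
    "2.A.21": "SSS",
    "2.A.41": "CNT",
    "2.A.23": "DAACS",
    "2.A.22": "NSS",
}

_TC_ID_RE = re.compile(r"\d+\.[A-Z]\.\d+(?:\.\d+){0,2}")


def parse_tc_id(subject_id: str) -> str | None:
    """Extract a TC identifier (e.g. ``3.A.1.1.2``) from a subject id."""
    match = _TC_ID_RE.search(subject_id)
    return match.group(0) if match else None


def tc_family(tc_id: str, level: str = "family") -> str:
    """Truncate a TC id to family (3 components) or subfamily (4)."""
    n = {"family": 3, "subfamily": 4}[level]
    return ".".join(tc_id.split(".")[:n])


def _shortlist_match(tc_id: str, shortlist) -> str | None:
    """The shortlist entry a TC id falls under (most specific wins)."""
    parts = tc_id.split(".")
    for n in range(len(parts), 2, -1):
        prefix = ".".join(parts[:n])
        if prefix in shortlist:
            return prefix
    return None


def filter_transporter_hits(hits: pd.DataFrame,
                            subject_lengths: Mapping[str, int],
                            shortlist,
                            evalue_max: float = 1e-5,
                            min_identity: float = 30.0,
                            min_subject_cov: float = 70.0) -> pd.DataFrame:
    """Best-hit filter for protein-vs-transporter-database tabular hits.

    ``hits`` uses the 12-column m8 schema.  Per query the best-scoring hit
    passing E < evalue_max, identity > min_identity and subject coverage >
    min_subject_cov (all strict) AND whose family is in ``shortlist`` is
    kept.  Rows with unresolvable TC ids are dropped with a warning.  The
    result carries an extra ``family`` column with the matched shortlist
    entry.
    """
    df = hits.copy()
    tc_ids = df["sseqid"].map(parse_tc_id)
    bad = tc_ids.isna()
    if bad.any():
        warnings.warn(f"dropped {int(bad.sum())} hits with unresolvable TC ids")
        df, tc_ids = df[~bad], tc_ids[~bad]
    lengths = df["sseqid"].map(subject_lengths)
    span = (df["send"] - df["sstart"]).abs() + 1
    subject_cov = 100.0 * span / lengths
    family = tc_ids.map(lambda t: _shortlist_match(t, shortlist))
    keep = (
        (df["evalue"] < evalue_max)
        & (df["pident"] > min_identity)
        & (subject_cov > min_subject_cov)
        & family.notna()
    )
    df = df.assign(family=family)[keep]
    # Best-scoring hit per query; ties break to the smallest subject id.
    df = df.sort_values(["qseqid", "bitscore", "sseqid"],
                        ascending=[True, False, True])
    return df.drop_duplicates("qseqid", keep="first").reset_index(drop=True)


def predict_tm_segments(protein: str, window: int = TM_WINDOW,
                        threshold: float = TM_THRESHOLD
                        ) -> list[tuple[int, int]]:
    """Transmembrane segments by Kyte-Doolittle sliding-window hydropathy.

    A window whose mean hydropathy exceeds ``threshold`` marks a candidate
    segment; overlapping windows merge.  Returns half-open (start, end)
    residue intervals; sequences shorter than the window give no segments.
    """
    if not protein:
        raise ValueError("empty sequence")
    if len(protein) < window:
        return []
    values = np.array([KD_HYDROPATHY.get(aa, 0.0) for aa in protein])
    kernel = np.ones(window) / window
    means = np.convolve(values, kernel, mode="valid")
    segments: list[tuple[int, int]] = []
    for start in np.nonzero(means > threshold)[0]:
        end = int(start) + window
        if segments and start <= segments[-1][1]:
            segments[-1] = (segments[-1][0], end)
        else:
            segments.append((int(start), end))
    return segments


@dataclass
class FamilyCountMatrix:
    """Genomes x transporter-family counts, total and transmembrane-only."""

    counts_total: pd.DataFrame
    counts_tm: pd.DataFrame
    genome_size_orfs: dict[str, int]

    def __post_init__(self) -> None:
        if not self.counts_total.index.equals(self.counts_tm.index) or \
           not self.counts_total.columns.equals(self.counts_tm.columns):
            raise ValueError("total and TM matrices must share genomes/families")
        if (self.counts_tm.values > self.counts_total.values).any():
            raise ValueError("TM counts cannot exceed total counts")
        if (self.counts_total.values < 0).any():
            raise ValueError("negative counts")

    @property
    def genomes(self) -> list[str]:
        return list(self.counts_total.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts_total.columns)


def build_family_matrix(filtered_hits: Mapping[str, pd.DataFrame],
                        tm_proteins: Mapping[str, set[str]],
                        families: Sequence[str] | None = None,
                        genome_size_orfs: Mapping[str, int] | None = None
                        ) -> FamilyCountMatrix:
    """Tabulate per-genome family counts from filtered hits.

    ``filtered_hits`` maps genome_id to the output of
    :func:`filter_transporter_hits` (one row per ORF); ``tm_proteins`` maps
    genome_id to the set of ORF ids with at least one predicted TM segment.
    Families absent everywhere still appear as zero columns when listed in
    ``families``.
    """
    genomes = sorted(filtered_hits)
    fam_set = set(families or [])
    for df in filtered_hits.values():
        fam_set.update(df["family"])
    cols = sorted(fam_set)
    total = pd.DataFrame(0, index=genomes, columns=cols, dtype=int)
    tm = pd.DataFrame(0, index=genomes, columns=cols, dtype=int)
    for genome, df in filtered_hits.items():
        tm_ids = tm_proteins.get(genome, set())
        for fam, group in df.groupby("family"):
            total.loc[genome, fam] = len(group)
            tm.loc[genome, fam] = int(group["qseqid"].isin(tm_ids).sum())
    sizes = {g: (genome_size_orfs or {}).get(g, 0) for g in genomes}
    return FamilyCountMatrix(total, tm, sizes)


def bray_curtis_matrix(m: FamilyCountMatrix | pd.DataFrame | np.ndarray,
                       which: str = "total") -> np.ndarray:
    """Symmetric Bray-Curtis dissimilarity matrix over genomes.

    d(u, v) = sum|u_f - v_f| / sum(u_f + v_f); identical rows give 0, and a
    pair of all-zero rows is defined as 0 with a warning (no evidence of
    difference).
    """
    if isinstance(m, FamilyCountMatrix):
        counts = (m.counts_total if which == "total" else m.counts_tm).values
    elif isinstance(m, pd.DataFrame):
        counts = m.values
    else:
        counts = np.asarray(m)
    counts = counts.astype(float)
    if counts.shape[0] < 2:
        raise ValueError("at least two genomes are required")
    diffs = np.abs(counts[:, None, :] - counts[None, :, :]).sum(axis=2)
    sums = (counts[:, None, :] + counts[None, :, :]).sum(axis=2)
    zero_pairs = sums == 0
    if zero_pairs.sum() > counts.shape[0]:  # beyond the diagonal
        warnings.warn("all-zero row pair(s): Bray-Curtis defined as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(zero_pairs, 0.0, diffs / np.where(sums == 0, 1.0, sums))
    np.fill_diagonal(d, 0.0)
    return d


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    distance_metric: str
    n_restarts: int
    seed: int
    genome_ids: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        ids = self.genome_ids or tuple(
            f"g{i}" for i in range(self.coordinates.shape[0])
        )
        return pd.DataFrame(
            {"genome": ids, "x": self.coordinates[:, 0],
             "y": self.coordinates[:, 1]}
        )


def nmds_ordinate(d: np.ndarray, dims: int = 2, restarts: int = 2000,
                  seed: int = 0, max_iter: int = 300,
                  genome_ids: Sequence[str] = (),
                  distance_metric: str = "bray-curtis") -> OrdinationResult:
    """Nonmetric MDS minimising Kruskal stress-1, best of random restarts.

    Each restart runs SMACOF with monotone regression from a random start
    drawn from a seeded stream, so results are deterministic given ``seed``
    and the stress of the best configuration is non-increasing in
    ``restarts``.  Coordinates are centered (column means zero).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    squareform(d, checks=False)  # validity guard
    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=restarts)
    best_coords, best_stress = None, np.inf
    for s in restart_seeds:
        coords, stress = smacof(
            d, metric=False, n_components=dims, n_init=1, max_iter=max_iter,
            eps=1e-8, random_state=int(s), normalized_stress=True,
        )
        if stress < best_stress:
            best_coords, best_stress = coords, stress
    assert best_coords is not None
    best_coords = best_coords - best_coords.mean(axis=0)
    return OrdinationResult(
        coordinates=best_coords,
        stress=float(best_stress),
        distance_metric=distance_metric,
        n_restarts=restarts,
        seed=seed,
        genome_ids=tuple(genome_ids),
    )
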