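"""Reference-normalised FPKM screening and absence calling.

Read counts recruited to a panel are transformed to FPKM (fragments per
kilobase of reference per million reads) using three times the panel's mean
amino-acid length as the nucleotide reference length.  Target-panel FPKM is
then expressed relative to the median FPKM of the reference panels, which
are expected present in every genome: a target at least ``fold_threshold``
(default 50) times below that median is called absent outright; otherwise
the call falls back on where the candidate reads map in the binned assembly
(see :mod:`abscreen.attribution`) - a majority mapping outside the focal bin
still supports absence from the focal genome.

Two FPKM denominators exist, mirroring the two stages they serve: the
read-screening stage divides by *total* reads in the library (raw,
unassembled screening has no mapped universe), while the transcriptome
feature stage divides by reads *mapped* to the assembly.  Both are explicit
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .panels import PanelSet, mean_aa_length
from .search import ReadHit, ReadLibrary

if TYPE_CHECKING:  # pragma: no cover
    from .attribution import AttributionResult

DEFAULT_FOLD_THRESHOLD = 50.0

CALLS = ("absent", "present", "ambiguous")


@dataclass(frozen=True)
class PanelCoverageReport:
    library_id: str
    panel_id: str
    role: str
    n_reads: int
    fpkm: float
    relative_coverage: float | None = None
    call: str | None = None
    attributed_outside_fraction: float | None = None


def compute_fpkm(n_reads: int, mean_aa_length: float, total_reads: int) -> float:
    """FPKM with the 3x-mean-amino-acid-length reference rule.

    Reference length L = 3 * mean_aa_length nucleotides;
    FPKM = n_reads / (L / 1000) / (total_reads / 1e6).
    """
    if total_reads <= 0:
        raise ValueError("empty library: total_reads must be > 0")
    if mean_aa_length <= 0:
        raise ValueError("mean_aa_length must be > 0")
    ref_kb = 3.0 * mean_aa_length / 1000.0
    return n_reads / ref_kb / (total_reads / 1e6)


def screen_panels(hits: Iterable[ReadHit], ps: PanelSet,
                  lib: ReadLibrary | int) -> list[PanelCoverageReport]:
    """One coverage report per panel from best-filtered hits.

    ``hits`` must already be one-per-read (see
    :func:`abscreen.search.filter_best_hits`); each read counts for the
    panel holding its best hit only.  ``lib`` may be the library itself or
    the denominator read count.
    """
    if isinstance(lib, ReadLibrary):
        library_id, total = lib.library_id, lib.total_reads
    else:
        library_id, total = "library", int(lib)
    counts: dict[str, set[str]] = {p.panel_id: set() for p in ps}
    for hit in hits:
        if hit.panel_id in counts:
            counts[hit.panel_id].add(hit.read_id)
    return [
        PanelCoverageReport(
            library_id=library_id,
            panel_id=panel.panel_id,
            role=panel.role,
            n_reads=len(counts[panel.panel_id]),
            fpkm=compute_fpkm(len(counts[panel.panel_id]),
                              mean_aa_length(panel), total),
        )
        for panel in ps
    ]


def relative_coverage(target_fpkm: float,
                      reference_fpkms: Sequence[float]) -> float:
    """Ratio of a target FPKM to the median reference FPKM.

    The median of an even-length list is the mean of the middle two values.
    A zero reference median means the reference set was not detected at all,
    which signals an unusable library and raises.
    """
    if len(reference_fpkms) == 0:
        raise ValueError("at least one reference report is required")
    ref_median = float(np.median(reference_fpkms))
    if ref_median == 0.0:
        raise ValueError("reference set not detected (median FPKM is zero)")
    return target_fpkm / ref_median


def normalize_reports(reports: Sequence[PanelCoverageReport]
                      ) -> list[PanelCoverageReport]:
    """Fill ``relative_coverage`` on every report using the reference median."""
    ref_fpkms = [r.fpkm for r in reports if r.role == "reference"]
    if not ref_fpkms:
        raise ValueError("no reference panels among reports")
    return [
        replace(r, relative_coverage=relative_coverage(r.fpkm, ref_fpkms))
        for r in reports
    ]


def call_absence(report: PanelCoverageReport,
                 fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
                 attribution: "AttributionResult | None" = None
                 ) -> PanelCoverageReport:
    """Set the absence/presence call on a normalised coverage report.

    Coverage at or below 1/fold_threshold of the reference median -> absent.
    Otherwise, with read attribution available: a majority of candidate
    reads mapping outside the focal bin -> absent (from the focal genome),
    else present.  Without attribution the coverage alone is inconclusive ->
    ambiguous.
    """
    if report.relative_coverage is None:
        raise ValueError("relative_coverage must be computed before calling")
    frac = attribution.attributed_outside_fraction if attribution else None
    if report.relative_coverage <= 1.0 / fold_threshold:
        call = "absent"
    elif attribution is not None and frac is not None and frac > 0.5:
        call = "absent"
    elif attribution is not None and frac is not None:
        call = "present"
    else:
        call = "ambiguous"
    return replace(report, call=call, attributed_outside_fraction=frac)


def reports_frame(reports: Sequence[PanelCoverageReport]) -> pd.DataFrame:
    """Tabular form of coverage reports (TSV-ready)."""
    return pd.DataFrame(
        [
            (r.library_id, r.panel_id, r.role, r.n_reads, r.fpkm,
             r.relative_coverage, r.call, r.attributed_outside_fraction)
            for r in reports
        ],
        columns=["library_id", "panel_id", "role", "n_reads", "fpkm",
                 "relative_coverage", "call", "attributed_outside_fraction"],
    )


# ---------------------------------------------------------------------------
# Transcriptome feature expression


@dataclass(frozen=True)
class FeatureExpression:
    feature_id: str
    mapped_fragments: int
    feature_length_bp: int
    fpkm: float = 0.0
    percentile: float | None = None


def feature_fpkm(mapped_fragments: int, feature_length_bp: int,
                 total_mapped: int) -> float:
    """FPKM of a genomic feature: per kb of feature per million reads mapped."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    if feature_length_bp <= 0:
        raise ValueError("feature_length_bp must be > 0")
    return mapped_fragments / (feature_length_bp / 1000.0) / (total_mapped / 1e6)


def expression_percentile(features: Sequence[FeatureExpression],
                          total_mapped: int | None = None
                          ) -> list[FeatureExpression]:
    """Set FPKM (if needed) and mid-rank expression percentiles.

    Percentile = 100 * (rank - 1) / (n - 1) with ties assigned their mid
    rank, so the highest-expressed feature sits at 100, the lowest at 0, and
    an all-tied library at 50.  Requires at least two features.
    """
    if len(features) < 2:
        raise ValueError("at least two features are required")
    feats = list(features)
    if total_mapped is not None:
        feats = [
            replace(f, fpkm=feature_fpkm(f.mapped_fragments,
                                         f.feature_length_bp, total_mapped))
            for f in feats
        ]
    fpkms = np.array([f.fpkm for f in feats], dtype=float)
    ranks = rankdata(fpkms, method="average")
    percentiles = 100.0 * (ranks - 1.0) / (len(feats) - 1)
    return [replace(f, percentile=float(p)) for f, p in zip(feats, percentiles)]
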