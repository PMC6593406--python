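"""End-to-end screening of one read library against a panel set.

Ties the stages together: translated search -> per-read best-hit filter ->
per-panel FPKM -> reference-median normalisation -> absence call, with
candidate-read re-mapping onto a binned assembly for target panels whose
coverage is not already at least ``fold_threshold`` below the reference
median (re-mapping a panel whose coverage already meets the absence
criterion would add nothing, so it is skipped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .attribution import (AttributionResult, BinnedAssembly,
                          attribute_candidate_reads, map_reads_to_contigs)
from .coverage import (DEFAULT_FOLD_THRESHOLD, PanelCoverageReport,
                       call_absence, normalize_reports, screen_panels)
from .panels import PanelSet
from .search import (DEFAULT_MIN_SCORE, ReadHit, ReadLibrary,
                     filter_best_hits, search_reads)


@dataclass
class ScreenResult:
    reports: list[PanelCoverageReport]
    best_hits: list[ReadHit]
    attributions: dict[str, AttributionResult] = field(default_factory=dict)

    def report_for(self, panel_id: str) -> PanelCoverageReport:
        for r in self.reports:
            if r.panel_id == panel_id:
                return r
        raise KeyError(panel_id)


def screen_library(lib: ReadLibrary, ps: PanelSet,
                   assembly: BinnedAssembly | None = None, *,
                   hits: list[ReadHit] | None = None,
                   min_score: float = DEFAULT_MIN_SCORE,
                   evalue_max: float = 1e-5, min_identity: float = 30.0,
                   min_subject_cov: float = 0.0,
                   fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
                   map_min_identity: float = 0.97) -> ScreenResult:
    """Screen a library and call absence/presence per target panel.

    ``hits`` may carry pre-parsed external tabular hits, in which case the
    built-in search is skipped.  Reference panels retain a ``None`` call -
    they define the baseline and are not themselves under test.  Without an
    assembly, targets that fail the coverage criterion are ``ambiguous``.
    """
    if hits is None:
        hits = search_reads(lib, ps, min_score=min_score)
    best = filter_best_hits(hits, evalue_max=evalue_max,
                            min_identity=min_identity,
                            min_subject_cov=min_subject_cov)
    reports = normalize_reports(screen_panels(best, ps, lib))

    read_seq = None
    result = ScreenResult(reports=[], best_hits=best)
    for report in reports:
        if report.role != "target":
            result.reports.append(report)
            continue
        attribution = None
        needs_attribution = (
            report.relative_coverage is not None
            and report.relative_coverage > 1.0 / fold_threshold
            and assembly is not None
        )
        if needs_attribution:
            if read_seq is None:
                read_seq = {r.read_id: r.sequence for r in lib}
            candidates = [
                (h.read_id, read_seq[h.read_id])
                for h in best if h.panel_id == report.panel_id
            ]
            mapping = map_reads_to_contigs(candidates, assembly,
                                           min_identity=map_min_identity)
            attribution = attribute_candidate_reads(mapping, assembly,
                                                    report.panel_id)
            result.attributions[report.panel_id] = attribution
        result.reports.append(
            call_absence(report, fold_threshold=fold_threshold,
                         attribution=attribution)
        )
    return result
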