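"""Attribution of candidate reads to genome bins.

Reads recruited to a target panel are re-mapped onto the metagenome
assembly to decide whether the signal originates from the focal symbiont
bin or from co-occurring organisms.  The built-in mapper aligns each
candidate against every contig on both strands (edit-distance alignment via
edlib in infix mode, so the whole read must align) and accepts the best
placement at >= ``min_identity`` nucleotide identity; a SAM file produced
by an external mapper can substitute, with identity recomputed from the
CIGAR string and NM tag.

Unbinned contigs count as *outside* the focal bin when attributing mapped
reads, while unmapped reads carry no bin evidence and are excluded from the
attributed fraction's denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import edlib
import pysam
from Bio.SeqUtils import gc_fraction

from ._codon import revcomp

UNBINNED = "unbinned"

DEFAULT_MIN_IDENTITY = 0.97
DEFAULT_MIN_READ_COV = 0.9


@dataclass
class Contig:
    contig_id: str
    sequence: str
    gc: float | None = None
    mean_coverage: float = float("nan")

    def __post_init__(self) -> None:
        if self.gc is None:
            self.gc = gc_fraction(self.sequence) if self.sequence else 0.0


@dataclass
class BinnedAssembly:
    """A metagenome assembly with contig-to-bin assignments.

    Exactly one bin is designated focal (the symbiont of interest); contigs
    missing from ``bin_of`` belong to ``unbinned``.
    """

    contigs: list[Contig]
    bin_of: dict[str, str]
    focal_bin: str
    _rc_cache: dict[str, str] = field(default_factory=dict, repr=False,
                                      compare=False)

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError("contig_ids must be unique")
        bins = set(self.bin_of.values())
        if self.focal_bin not in bins:
            raise ValueError(f"focal bin {self.focal_bin!r} not among bins {bins}")

    def bin_for(self, contig_id: str) -> str:
        return self.bin_of.get(contig_id, UNBINNED)

    def sorted_contigs(self) -> list[Contig]:
        return sorted(self.contigs, key=lambda c: c.contig_id)


@dataclass(frozen=True)
class AttributionResult:
    """Partition of one panel's candidate reads by bin membership."""

    panel_id: str
    n_candidates: int
    n_inside_focal: int
    n_outside_focal: int
    n_unmapped: int

    def __post_init__(self) -> None:
        total = self.n_inside_focal + self.n_outside_focal + self.n_unmapped
        if total != self.n_candidates:
            raise ValueError("attribution counts do not partition the candidates")

    @property
    def attributed_outside_fraction(self) -> float | None:
        mapped = self.n_inside_focal + self.n_outside_focal
        if mapped == 0:
            return None
        return self.n_outside_focal / mapped


def map_reads_to_contigs(candidates: Iterable[tuple[str, str]],
                         asm: BinnedAssembly,
                         min_identity: float = DEFAULT_MIN_IDENTITY,
                         ) -> dict[str, str | None]:
    """Map candidate reads (read_id, sequence) to their best contig.

    Both strands are tested; the winning contig minimises the edit distance
    of an infix alignment of the *whole* read (read coverage is therefore
    100% by construction), subject to identity >= min_identity.  Distance
    ties break to the lexicographically smallest contig_id.  Reads with no
    acceptable placement map to ``None``; an empty assembly leaves every
    read unmapped.
    """
    contigs = asm.sorted_contigs()
    mapping: dict[str, str | None] = {}
    for read_id, seq in candidates:
        budget = int((1.0 - min_identity) * len(seq))
        best_dist, best_contig = None, None
        for contig in contigs:
            rc = asm._rc_cache.setdefault(contig.contig_id,
                                          revcomp(contig.sequence))
            for template in (contig.sequence, rc):
                res = edlib.align(seq, template, mode="HW", task="distance",
                                  k=budget)
                dist = res["editDistance"]
                if dist < 0:
                    continue
                if best_dist is None or dist < best_dist:
                    best_dist, best_contig = dist, contig.contig_id
        mapping[read_id] = best_contig
    return mapping


def mapping_from_sam(path: str | Path,
                     min_identity: float = DEFAULT_MIN_IDENTITY,
                     min_read_cov: float = DEFAULT_MIN_READ_COV,
                     ) -> dict[str, str | None]:
    """Read a read->contig mapping from a SAM file in lieu of the built-in
    mapper.

    Only primary alignments are considered.  Identity is recomputed as
    (aligned length - NM) / aligned length and read coverage as the aligned
    query span over the query length; placements failing either threshold
    are treated as unmapped.
    """
    mapping: dict[str, str | None] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_unmapped:
                mapping.setdefault(aln.query_name, None)
                continue
            aligned = aln.query_alignment_length
            qlen = aln.query_length or aln.infer_read_length() or 0
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            identity = (aligned - nm) / aligned if aligned else 0.0
            cov = aligned / qlen if qlen else 0.0
            if identity >= min_identity and cov >= min_read_cov:
                mapping[aln.query_name] = aln.reference_name
            else:
                mapping.setdefault(aln.query_name, None)
    return mapping


def attribute_candidate_reads(mapping: Mapping[str, str | None],
                              asm: BinnedAssembly,
                              panel_id: str) -> AttributionResult:
    """Partition mapped candidates by bin membership of their contig.

    Unbinned contigs count as outside the focal bin; unmapped reads are
    tallied separately and never enter the attributed fraction.
    """
    inside = outside = unmapped = 0
    for contig_id in mapping.values():
        if contig_id is None:
            unmapped += 1
        elif asm.bin_for(contig_id) == asm.focal_bin:
            inside += 1
        else:
            outside += 1
    return AttributionResult(
        panel_id=panel_id,
        n_candidates=len(mapping),
        n_inside_focal=inside,
        n_outside_focal=outside,
        n_unmapped=unmapped,
    )
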