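"""Synthetic communities with known gene-implantation truth.

The generator emulates the study design the screen was built for: a focal
symbiont genome dominating a single-host metagenome, a few low-abundance
contaminant genomes, a set of single-copy reference genes carried by the
focal genome at genome coverage, and target genes that are either absent
everywhere, present in the focal genome, or present only in a contaminant.
Short reads with i.i.d. substitution errors are drawn uniformly along each
genome, with genomes chosen proportionally to abundance x length, and every
read records its source genome and locus in a machine-readable truth table.

Implanted genes are back-translations of panel peptides with uniform-random
synonymous codons, so implanted copies share 100% amino-acid identity with
the panel but realistic sub-100% nucleotide identity with each other.
Errors are substitution-only (no indels), which keeps reading frames intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import _codon
from .attribution import BinnedAssembly, Contig
from .panels import PanelMember, PanelSet, ProteinPanel
from .search import ReadLibrary

# Synonymous codon lists per amino acid (standard code; stops excluded).
_SYNONYMS: dict[str, list[str]] = {}
for _codon_str, _aa in _codon.CODON_AA.items():
    if _aa != "*":
        _SYNONYMS.setdefault(_aa, []).append(_codon_str)
for _v in _SYNONYMS.values():
    _v.sort()


@dataclass
class SimGenome:
    genome_id: str
    sequence: str
    relative_abundance: float
    gc_target: float | None = None
    circular: bool = False


@dataclass(frozen=True)
class Implant:
    seq_id: str
    panel_id: str | None
    genome_id: str
    start: int
    strand: str  # '+' or '-'
    length_nt: int


@dataclass
class SyntheticCommunity:
    genomes: list[SimGenome]
    implants: list[Implant] = field(default_factory=list)
    seed: int = 0

    def genome(self, genome_id: str) -> SimGenome:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    def abundances(self) -> np.ndarray:
        return np.array([g.relative_abundance for g in self.genomes])


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated screen.

    ``expected_copies`` maps (seq_id, genome_id) to implanted copy number;
    ``expected_relative_coverage`` predicts each panel's coverage relative
    to the reference median under the uniform-start read model.
    """

    implants: list[Implant]
    expected_copies: dict[tuple[str, str], int]

    def copies_in(self, seq_id: str, genome_id: str) -> int:
        return self.expected_copies.get((seq_id, genome_id), 0)

    def expected_relative_coverage(self, community: SyntheticCommunity,
                                   ps: PanelSet) -> dict[str, float]:
        """Model-expected relative coverage per panel.

        Under uniform read starts, the expected read count over a gene is
        proportional to (genome sampling weight / genome length) x gene
        length; FPKM divides by 3 x the panel's mean peptide length, so for
        single-copy genes matching their panel length the focal-genome
        ratio is exactly 1.
        """
        lengths = np.array([len(g.sequence) for g in community.genomes])
        weights = community.abundances() * lengths
        weights = weights / weights.sum()
        by_genome = {g.genome_id: i for i, g in enumerate(community.genomes)}
        index = ps.member_index()
        density: dict[str, float] = {p.panel_id: 0.0 for p in ps}
        mean_len = {
            p.panel_id: sum(len(m) for m in p) / len(p.members) for p in ps
        }
        for implant in community.implants:
            if implant.seq_id not in index:
                continue
            panel_id, _ = index[implant.seq_id]
            gi = by_genome[implant.genome_id]
            density[panel_id] += (
                weights[gi] / lengths[gi] * implant.length_nt
                / (3.0 * mean_len[panel_id])
            )
        ref = [density[p.panel_id] for p in ps.reference_panels]
        ref_median = float(np.median(ref)) if ref else 0.0
        if ref_median == 0.0:
            raise ValueError("no reference genes implanted")
        return {pid: dens / ref_median for pid, dens in density.items()}


def simulate_community(lengths: Sequence[int], gc: Sequence[float],
                       abundances: Sequence[float], seed: int,
                       genome_ids: Sequence[str] | None = None
                       ) -> SyntheticCommunity:
    """Generate i.i.d. nucleotide genomes at target GC contents.

    Abundances are normalised to sum to one and must be positive.
    Reproducible given ``seed``.
    """
    if len(lengths) == 0:
        raise ValueError("at least one genome is required")
    if not (len(lengths) == len(gc) == len(abundances)):
        raise ValueError("lengths, gc and abundances must align")
    ab = np.asarray(abundances, dtype=float)
    if (ab <= 0).any() or not np.isfinite(ab.sum()) or ab.sum() <= 0:
        raise ValueError("abundances must be positive and normalizable")
    ab = ab / ab.sum()
    ids = list(genome_ids) if genome_ids else [
        f"genome{i}" for i in range(len(lengths))
    ]
    rng = np.random.default_rng(seed)
    genomes = []
    for gid, length, g, a in zip(ids, lengths, gc, ab):
        p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])  # A C G T
        codes = rng.choice(4, size=int(length), p=p).astype(np.uint8)
        genomes.append(SimGenome(gid, _codon.decode_dna(codes), float(a), g))
    return SyntheticCommunity(genomes, seed=seed)


def back_translate(peptide: str, rng: np.random.Generator) -> str:
    """Back-translate with uniform-random synonymous codons (no stop added)."""
    try:
        return "".join(
            _SYNONYMS[aa][rng.integers(len(_SYNONYMS[aa]))] for aa in peptide
        )
    except KeyError as exc:
        raise ValueError(f"cannot back-translate residue {exc}") from None


@dataclass(frozen=True)
class Placement:
    seq_id: str
    genome_id: str
    start: int
    strand: str = "+"


def implant_genes(community: SyntheticCommunity,
                  members: Sequence[PanelMember],
                  placements: Sequence[Placement],
                  seed: int | None = None,
                  panel_of: dict[str, str] | None = None) -> SyntheticTruth:
    """Write back-translated panel peptides into community genomes.

    Each placement implants one copy (its nucleotide length is exactly 3x
    the peptide length) on the stated strand; loci must fall within genome
    bounds and must not overlap other implants in the same genome.  The
    community is modified in place and the updated truth returned.
    """
    rng = np.random.default_rng(community.seed if seed is None else seed)
    peptides = {m.seq_id: m.sequence for m in members}
    occupied: dict[str, list[tuple[int, int]]] = {}
    for imp in community.implants:
        occupied.setdefault(imp.genome_id, []).append(
            (imp.start, imp.start + imp.length_nt)
        )
    for place in placements:
        if place.seq_id not in peptides:
            raise ValueError(f"unknown panel member {place.seq_id!r}")
        genome = community.genome(place.genome_id)
        length_nt = 3 * len(peptides[place.seq_id])
        end = place.start + length_nt
        if place.start < 0 or end > len(genome.sequence):
            raise ValueError(
                f"implant {place.seq_id} at {place.start} exceeds genome bounds"
            )
        for s, e in occupied.get(place.genome_id, []):
            if place.start < e and s < end:
                raise ValueError(
                    f"implant {place.seq_id} at {place.start} overlaps an "
                    f"existing implant"
                )
        coding = back_translate(peptides[place.seq_id], rng)
        insert = coding if place.strand == "+" else _codon.revcomp(coding)
        genome.sequence = (
            genome.sequence[: place.start] + insert + genome.sequence[end:]
        )
        panel_id = (panel_of or {}).get(place.seq_id)
        community.implants.append(
            Implant(place.seq_id, panel_id, place.genome_id, place.start,
                    place.strand, length_nt)
        )
        occupied.setdefault(place.genome_id, []).append((place.start, end))
    copies: dict[tuple[str, str], int] = {}
    for imp in community.implants:
        key = (imp.seq_id, imp.genome_id)
        copies[key] = copies.get(key, 0) + 1
    return SyntheticTruth(list(community.implants), copies)


def generate_reads(community: SyntheticCommunity, n_reads: int,
                   read_length: int = 100, error_rate: float = 0.0,
                   paired: bool = False, insert_size: int = 300,
                   seed: int = 0, library_id: str = "sim"
                   ) -> tuple[ReadLibrary, pd.DataFrame]:
    """Draw error-bearing reads from the community.

    Genomes are chosen proportionally to abundance x length; start
    positions are uniform; strands are equiprobable; substitution errors
    are i.i.d. at ``error_rate``.  For paired layout ``n_reads`` counts
    records (pairs contribute two), mates face inward over a fixed insert.
    Returns the library plus a per-read truth table (read_id, genome_id,
    start, strand).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    lengths = np.array([len(g.sequence) for g in community.genomes])
    if read_length > lengths.min():
        raise ValueError("read_length exceeds the shortest genome")
    if paired and n_reads % 2:
        raise ValueError("paired libraries need an even n_reads")
    if paired and insert_size > lengths.min():
        raise ValueError("insert_size exceeds the shortest genome")
    rng = np.random.default_rng(seed)
    weights = community.abundances() * lengths
    weights = weights / weights.sum()
    n_frags = n_reads // 2 if paired else n_reads
    genome_idx = rng.choice(len(lengths), size=n_frags, p=weights)
    span = insert_size if paired else read_length
    starts = (rng.random(n_frags) * (lengths[genome_idx] - span + 1)).astype(int)
    strands = rng.integers(0, 2, size=n_frags)  # 0 = forward

    encoded = [_codon.encode_dna(g.sequence) for g in community.genomes]
    if paired:
        mat = np.empty((n_reads, read_length), dtype=np.uint8)
        ids: list[str] = []
        rows = []
        for i in range(n_frags):
            gi, start, rev = int(genome_idx[i]), int(starts[i]), int(strands[i])
            frag = encoded[gi][start : start + insert_size]
            if rev:
                frag = _codon.revcomp_codes(frag)
            mat[2 * i] = frag[:read_length]
            mat[2 * i + 1] = _codon.revcomp_codes(frag[-read_length:])
            base = f"{library_id}.{i}"
            ids += [f"{base}/1", f"{base}/2"]
            strand = "-" if rev else "+"
            gid = community.genomes[gi].genome_id
            rows += [(f"{base}/1", gid, start, strand),
                     (f"{base}/2", gid, start, "-" if strand == "+" else "+")]
    else:
        mat = np.empty((n_reads, read_length), dtype=np.uint8)
        ids = [f"{library_id}.{i}" for i in range(n_reads)]
        rows = []
        for i in range(n_frags):
            gi, start, rev = int(genome_idx[i]), int(starts[i]), int(strands[i])
            read = encoded[gi][start : start + read_length]
            if rev:
                read = _codon.revcomp_codes(read)
            mat[i] = read
            rows.append((ids[i], community.genomes[gi].genome_id, start,
                         "-" if rev else "+"))

    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        offsets = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
        mat = np.where(err & (mat < 4), (mat + offsets) % 4, mat).astype(np.uint8)

    lib = ReadLibrary.from_matrix(library_id, ids, mat,
                                  layout="paired" if paired else "single")
    truth = pd.DataFrame(rows, columns=["read_id", "genome_id", "start",
                                        "strand"])
    return lib, truth


def write_fastq(lib: ReadLibrary, path: str | Path) -> None:
    """Write a library as plain FASTQ (uniform dummy qualities)."""
    with open(path, "w") as out:
        for rec in lib:
            qual = rec.quality or "I" * len(rec.sequence)
            out.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Canonical screening scenarios


def make_demo_panels(seed: int = 0, peptide_length: int = 300,
                     n_targets: int = 3, n_references: int = 5) -> PanelSet:
    """A synthetic PanelSet emulating the screening design.

    Target panels are proxies for diagnostic autotrophy enzymes (the first
    stands in for RuBisCO); each reference panel holds one expected-present
    enzyme, so the reference median is taken across panels exactly as across
    reference proteins.  Sequences are uniform-random peptides of one
    common length, which keeps target and reference FPKM directly
    comparable.
    """
    rng = np.random.default_rng(seed)
    residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    def random_peptide() -> str:
        return "".join(rng.choice(residues, size=peptide_length))

    target_names = ["RuBisCO_proxy", "AcsB_proxy", "ACL_proxy"][:n_targets]
    target_ecs = {"RuBisCO_proxy": ("4.1.1.39",), "AcsB_proxy": ("2.3.1.169",),
                  "ACL_proxy": ("2.3.3.8",)}
    panels = [
        ProteinPanel(
            panel_id=name, role="target", pathway_label="autotrophy key enzyme",
            members=[PanelMember(f"{name}_1", random_peptide(),
                                 target_ecs.get(name, ()))],
        )
        for name in target_names
    ]
    panels += [
        ProteinPanel(
            panel_id=f"ref{i + 1}", role="reference",
            pathway_label="TCA+p3HPB reference",
            members=[PanelMember(f"ref{i + 1}_1", random_peptide())],
        )
        for i in range(n_references)
    ]
    return PanelSet(panels)


@dataclass
class ScreenScenario:
    community: SyntheticCommunity
    panels: PanelSet
    library: ReadLibrary
    truth: SyntheticTruth
    read_truth: pd.DataFrame
    assembly: BinnedAssembly
    focal_genome: str


SCENARIO_KINDS = ("targets_absent", "target_in_contaminant", "target_in_focal")


def build_screen_scenario(kind: str, seed: int, n_reads: int = 200_000,
                          read_length: int = 100, genome_length: int = 50_000,
                          error_rate: float = 0.0) -> ScreenScenario:
    """Assemble one of the three canonical ground-truth scenarios.

    ``targets_absent``
        three genomes (focal at 80% abundance, two contaminants at 10%),
        reference genes single-copy in the focal genome, no target genes
        anywhere;
    ``target_in_contaminant``
        focal at 85%, a 5% contaminant carrying the RuBisCO proxy, a 10%
        bystander - the contamination scenario the bin-attribution step
        exists for;
    ``target_in_focal``
        as ``targets_absent`` but with the RuBisCO proxy single-copy in the
        focal genome (the presence control).
    """
    if kind not in SCENARIO_KINDS:
        raise ValueError(f"unknown scenario kind {kind!r}")
    panels = make_demo_panels(seed=seed)
    abundances = {"targets_absent": (0.80, 0.10, 0.10),
                  "target_in_contaminant": (0.85, 0.05, 0.10),
                  "target_in_focal": (0.80, 0.10, 0.10)}[kind]
    community = simulate_community(
        lengths=[genome_length] * 3, gc=[0.45, 0.55, 0.35],
        abundances=abundances, seed=seed,
        genome_ids=["focal", "contamA", "contamB"],
    )
    # Reference genes single-copy in the focal genome, well separated.
    placements = [
        Placement(f"ref{i + 1}_1", "focal", 2_000 + 2_500 * i,
                  "+" if i % 2 == 0 else "-")
        for i in range(len(panels.reference_panels))
    ]
    if kind == "target_in_contaminant":
        placements.append(Placement("RuBisCO_proxy_1", "contamA", 2_000, "+"))
    elif kind == "target_in_focal":
        # Near the genome end, well clear of the reference-gene block.
        target_len = 3 * len(panels.get("RuBisCO_proxy").members[0].sequence)
        placements.append(
            Placement("RuBisCO_proxy_1", "focal",
                      genome_length - target_len - 2_000, "+")
        )
    panel_of = {
        member.seq_id: panel.panel_id for panel in panels for member in panel
    }
    members = [member for panel in panels for member in panel]
    truth = implant_genes(community, members, placements, seed=seed + 1,
                          panel_of=panel_of)
    library, read_truth = generate_reads(
        community, n_reads=n_reads, read_length=read_length,
        error_rate=error_rate, seed=seed + 2, library_id=f"{kind}_s{seed}",
    )
    # A perfect one-contig-per-genome assembly with the focal bin designated.
    contigs = [Contig(f"contig_{g.genome_id}", g.sequence)
               for g in community.genomes]
    assembly = BinnedAssembly(
        contigs=contigs,
        bin_of={f"contig_{g.genome_id}": g.genome_id
                for g in community.genomes},
        focal_bin="focal",
    )
    return ScreenScenario(community, panels, library, truth, read_truth,
                          assembly, "focal")


def scenario_from_config(path: str | Path) -> ScreenScenario:
    """Build a scenario from a YAML config (kind, seed, sizes; seed required)."""
    with open(path) as handle:
        cfg = yaml.safe_load(handle)
    if "seed" not in cfg:
        raise ValueError("scenario config must declare a seed")
    return build_screen_scenario(
        kind=cfg.get("kind", "targets_absent"),
        seed=int(cfg["seed"]),
        n_reads=int(cfg.get("n_reads", 200_000)),
        read_length=int(cfg.get("read_length", 100)),
        genome_length=int(cfg.get("genome_length", 50_000)),
        error_rate=float(cfg.get("error_rate", 0.0)),
    )
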