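"""Curated protein panels for presence/absence screening.

A *panel* is a named set of protein sequences standing for one enzyme (or one
functional group of enzymes), keyed by EC number and/or an explicit list of
additional sequences.  Panels play one of two roles:

``target``
    diagnostic enzymes whose absence is under scrutiny (e.g. RuBisCO and the
    other key enzymes of the canonical autotrophic CO2-fixation pathways);
``reference``
    enzymes expected to be present in every genome of the clade (e.g. TCA
    cycle and partial 3-hydroxypropionate bi-cycle enzymes), which provide
    the coverage baseline that target coverage is normalised against.

Panels are loaded from protein FASTA files listed in a flat TSV manifest with
columns ``panel_id``, ``role``, ``pathway_label``, ``ec_numbers``
(semicolon-joined, may be empty) and ``fasta_path``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguous/rare residue codes folded into X so alignment scoring stays
#: within the BLOSUM alphabet.
AMBIGUOUS_RESIDUES = set("BZJUO")

ROLES = ("target", "reference")

MANIFEST_COLUMNS = ["panel_id", "role", "pathway_label", "ec_numbers", "fasta_path"]


class PanelError(ValueError):
    """Raised for malformed panels or panel sets."""


@dataclass(frozen=True)
class PanelMember:
    """One protein sequence in a panel."""

    seq_id: str
    sequence: str
    ec_numbers: tuple[str, ...] = ()

    @property
    def is_additional(self) -> bool:
        """True when selected via the explicit sequence list, not an EC key."""
        return not self.ec_numbers

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinPanel:
    panel_id: str
    role: str
    pathway_label: str
    members: list[PanelMember]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PanelError(f"panel {self.panel_id!r}: unknown role {self.role!r}")

    def __iter__(self) -> Iterator[PanelMember]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def total_residues(self) -> int:
        return sum(len(m) for m in self.members)


def mean_aa_length(panel: ProteinPanel) -> float:
    """Arithmetic mean amino-acid length of the panel members (residues).

    Three times this value is used downstream as the nucleotide reference
    length in the FPKM transform.
    """
    if not panel.members:
        raise PanelError(f"panel {panel.panel_id!r} is empty")
    return sum(len(m) for m in panel.members) / len(panel.members)


def clean_sequence(seq_id: str, raw: str) -> str:
    """Normalise a raw amino-acid string to the 20 canonical residues + X.

    Uppercases; strips ``*`` (stop) and gap characters with a warning; maps
    ambiguous residues (B, Z, J, U, O) to X with a warning.  Any other
    character is an error.
    """
    seq = raw.upper()
    stripped = seq.replace("*", "").replace("-", "").replace(".", "")
    if stripped != seq:
        warnings.warn(
            f"{seq_id}: stripped stop/gap characters from sequence", stacklevel=2
        )
        seq = stripped
    if any(ch in AMBIGUOUS_RESIDUES for ch in seq):
        warnings.warn(
            f"{seq_id}: ambiguous residues (B/Z/J/U/O) mapped to X", stacklevel=2
        )
        seq = "".join("X" if ch in AMBIGUOUS_RESIDUES else ch for ch in seq)
    bad = set(seq) - CANONICAL_RESIDUES - {"X"}
    if bad:
        raise PanelError(f"{seq_id}: invalid residues {sorted(bad)}")
    return seq


def _parse_ec_field(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ()
    text = str(value).strip()
    if not text:
        return ()
    return tuple(part.strip() for part in text.split(";") if part.strip())


def load_panel(fasta_path: str | Path, manifest_row: Mapping) -> ProteinPanel:
    """Load one panel from a protein FASTA plus its manifest record.

    The manifest row must declare ``panel_id``, ``role`` and
    ``pathway_label``; ``ec_numbers`` (semicolon-joined) applies to every
    member of the panel and may be empty for "additional sequence" panels.
    """
    fasta_path = Path(fasta_path)
    ecs = _parse_ec_field(manifest_row.get("ec_numbers"))
    members: list[PanelMember] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise PanelError(f"duplicate seq_id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        members.append(
            PanelMember(rec.id, clean_sequence(rec.id, str(rec.seq)), ecs)
        )
    if not members:
        raise PanelError(f"empty panel: no sequences in {fasta_path}")
    return ProteinPanel(
        panel_id=str(manifest_row["panel_id"]),
        role=str(manifest_row["role"]),
        pathway_label=str(manifest_row.get("pathway_label", "")),
        members=members,
    )


@dataclass
class PanelSet:
    """All panels of one screening run (targets plus the reference group)."""

    panels: list[ProteinPanel] = field(default_factory=list)

    def __iter__(self) -> Iterator[ProteinPanel]:
        return iter(self.panels)

    def __len__(self) -> int:
        return len(self.panels)

    def get(self, panel_id: str) -> ProteinPanel:
        for p in self.panels:
            if p.panel_id == panel_id:
                return p
        raise KeyError(panel_id)

    @property
    def target_panels(self) -> list[ProteinPanel]:
        return [p for p in self.panels if p.role == "target"]

    @property
    def reference_panels(self) -> list[ProteinPanel]:
        return [p for p in self.panels if p.role == "reference"]

    def member_index(self) -> dict[str, tuple[str, PanelMember]]:
        """Map seq_id -> (panel_id, member) over all panels."""
        idx: dict[str, tuple[str, PanelMember]] = {}
        for panel in self.panels:
            for member in panel:
                idx.setdefault(member.seq_id, (panel.panel_id, member))
        return idx

    @property
    def total_residues(self) -> int:
        return sum(p.total_residues for p in self.panels)


@dataclass(frozen=True)
class ValidationIssue:
    panel_id: str
    code: str
    message: str


def validate_panels(ps: PanelSet) -> list[ValidationIssue]:
    """Check PanelSet invariants; the report is empty iff the set is valid."""
    issues: list[ValidationIssue] = []
    seen_panels: set[str] = set()
    seen_seqs: dict[str, str] = {}
    for panel in ps:
        if panel.panel_id in seen_panels:
            issues.append(
                ValidationIssue(panel.panel_id, "duplicate_panel_id",
                                f"panel_id {panel.panel_id!r} occurs twice")
            )
        seen_panels.add(panel.panel_id)
        if not panel.members:
            issues.append(
                ValidationIssue(panel.panel_id, "empty_panel", "panel has no members")
            )
        for member in panel:
            if member.seq_id in seen_seqs and seen_seqs[member.seq_id] != panel.panel_id:
                issues.append(
                    ValidationIssue(
                        panel.panel_id, "duplicate_seq_id",
                        f"seq_id {member.seq_id!r} also appears in panel "
                        f"{seen_seqs[member.seq_id]!r}",
                    )
                )
            seen_seqs.setdefault(member.seq_id, panel.panel_id)
            bad = set(member.sequence) - CANONICAL_RESIDUES - {"X"}
            if bad:
                issues.append(
                    ValidationIssue(panel.panel_id, "invalid_residues",
                                    f"{member.seq_id}: {sorted(bad)}")
                )
    if not ps.reference_panels:
        issues.append(ValidationIssue("", "no_reference_set",
                                      "no panel with role=reference"))
    return issues


def validation_report_frame(issues: list[ValidationIssue]) -> pd.DataFrame:
    return pd.DataFrame(
        [(i.panel_id, i.code, i.message) for i in issues],
        columns=["panel_id", "code", "message"],
    )


def load_panel_set(manifest_path: str | Path) -> PanelSet:
    """Load a PanelSet from a TSV manifest; FASTA paths resolve relative to it."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t", dtype=str).fillna("")
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise PanelError(f"manifest missing columns: {sorted(missing)}")
    panels = []
    for _, row in table.iterrows():
        fasta = Path(row["fasta_path"])
        if not fasta.is_absolute():
            fasta = manifest_path.parent / fasta
        panels.append(load_panel(fasta, row))
    return PanelSet(panels)


def write_panel_set(ps: PanelSet, out_dir: str | Path,
                    manifest_name: str = "panels.tsv") -> Path:
    """Serialise a PanelSet to one FASTA per panel plus a TSV manifest.

    Returns the manifest path; ``load_panel_set`` on it round-trips the set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for panel in ps:
        fasta_name = f"{panel.panel_id}.faa"
        records = [
            SeqRecord(Seq(m.sequence), id=m.seq_id, description="")
            for m in panel
        ]
        SeqIO.write(records, str(out_dir / fasta_name), "fasta")
        ecs = sorted({ec for m in panel for ec in m.ec_numbers})
        rows.append(
            (panel.panel_id, panel.role, panel.pathway_label, ";".join(ecs),
             fasta_name)
        )
    manifest = out_dir / manifest_name
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        manifest, sep="\t", index=False
    )
    return manifest
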