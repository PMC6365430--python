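"""Readers, writers and summary statistics for strain-collection inputs.

All tabular inputs are UTF-8 TSV files with a header row.  Sequences are
FASTA; gene headers encode ``gene_id|contig|start|end|strand`` with 0-based
half-open coordinates.  A transcription of the published 44-strain
*Lactococcus lactis* metadata table ships with the package and is available
through :func:`bundled_strain_table`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

GENOTYPES = {"lactis", "cremoris", "other"}
PHENOTYPES = {"lactis", "cremoris", "diacetylactis", "unknown"}
NICHES = {"dairy", "non_dairy", "unknown"}
ASSEMBLY_STATUSES = {"complete", "draft"}


@dataclass(frozen=True)
class StrainMeta:
    """One strain's identity and genome-level metadata."""

    strain_id: str
    genotype: str
    phenotype: str
    origin: str
    genome_size_mb: float
    protein_count: int
    plasmid_kb: float
    assembly_status: str
    niche: str = "unknown"

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r} for {self.strain_id}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r} for {self.strain_id}")
        if self.niche not in NICHES:
            raise ValueError(f"unknown niche {self.niche!r} for {self.strain_id}")
        if self.assembly_status not in ASSEMBLY_STATUSES:
            raise ValueError(
                f"unknown assembly status {self.assembly_status!r} for {self.strain_id}"
            )
        if self.genome_size_mb <= 0:
            raise ValueError(f"genome size must be positive for {self.strain_id}")
        if self.protein_count <= 0:
            raise ValueError(f"protein count must be positive for {self.strain_id}")
        if self.plasmid_kb < 0:
            raise ValueError(f"plasmid content must be non-negative for {self.strain_id}")


@dataclass(frozen=True)
class GeneRecord:
    """A gene call: location, nucleotide and protein sequence, intactness.

    Coordinates are 0-based half-open on the contig; ``intact`` is
    ``"pseudo"`` when the encoded protein is incomplete (internal stop or a
    truncation detected downstream).
    """

    gene_id: str
    strain_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    nt_seq: str = ""
    aa_seq: str = ""
    intact: str = "intact"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad coordinates for {self.gene_id}: [{self.start},{self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.intact not in {"intact", "pseudo"}:
            raise ValueError(f"bad intactness {self.intact!r} for {self.gene_id}")
        if self.aa_seq and len(self.aa_seq) > (self.end - self.start) // 3 + 1:
            raise ValueError(f"protein longer than coding span for {self.gene_id}")


@dataclass(frozen=True)
class CoverageRecord:
    """Mean read depth of one contig, from any mapper."""

    strain_id: str
    contig_id: str
    length_bp: int
    mean_depth: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"non-positive length for contig {self.contig_id}")
        if self.mean_depth < 0:
            raise ValueError(f"negative depth for contig {self.contig_id}")


# ---------------------------------------------------------------------------
# strain metadata table

_STRAIN_COLUMNS = (
    "strain",
    "genotype",
    "phenotype",
    "origin",
    "genome_size_mb",
    "protein_count",
    "plasmid_kb",
    "status",
)


def read_strain_table(path: str | Path) -> list[StrainMeta]:
    """Read a strain metadata TSV into :class:`StrainMeta` records.

    The niche column is optional; when absent every strain's niche is
    ``"unknown"``.  Niche is deliberately never inferred from the free-text
    origin column — dairy/non-dairy assignment is curated metadata.
    """
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header row")
        missing = [c for c in _STRAIN_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        has_niche = "niche" in reader.fieldnames
        strains: list[StrainMeta] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):
            sid = row["strain"].strip()
            if sid in seen:
                raise ValueError(f"{path}: duplicate strain_id {sid!r}")
            seen.add(sid)
            try:
                size = float(row["genome_size_mb"])
                proteins = int(row["protein_count"])
                plasmid = float(row["plasmid_kb"])
            except ValueError as exc:
                raise ValueError(f"{path} row {i} ({sid}): non-numeric field: {exc}") from exc
            strains.append(
                StrainMeta(
                    strain_id=sid,
                    genotype=row["genotype"].strip(),
                    phenotype=row["phenotype"].strip(),
                    origin=row["origin"].strip(),
                    genome_size_mb=size,
                    protein_count=proteins,
                    plasmid_kb=plasmid,
                    assembly_status=row["status"].strip(),
                    niche=row["niche"].strip() if has_niche and row.get("niche") else "unknown",
                )
            )
    return strains


def write_strain_table(strains: Sequence[StrainMeta], path: str | Path) -> None:
    """Write strains back to the TSV schema accepted by :func:`read_strain_table`."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(list(_STRAIN_COLUMNS) + ["niche"])
        for s in strains:
            writer.writerow(
                [
                    s.strain_id,
                    s.genotype,
                    s.phenotype,
                    s.origin,
                    _trim_float(s.genome_size_mb),
                    s.protein_count,
                    _trim_float(s.plasmid_kb),
                    s.assembly_status,
                    s.niche,
                ]
            )


def _trim_float(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def bundled_strain_table() -> list[StrainMeta]:
    """The published 44-strain *L. lactis* metadata table shipped with the package."""
    ref = resources.files("lactopan.data").joinpath("strain_table.tsv")
    with resources.as_file(ref) as path:
        return read_strain_table(path)


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StrainSummary:
    """Collection-level genome statistics; sizes in Mb, rounded half-up."""

    n_strains: int
    mean_size_mb: float
    mean_proteins: int
    max_draft_size: Optional[float]
    min_draft_size: Optional[float]
    max_complete_size: Optional[float]
    min_complete_size: Optional[float]


def strain_summary_stats(
    strains: Sequence[StrainMeta], exclude: Iterable[str] = ()
) -> StrainSummary:
    """Mean genome size / protein count and draft vs complete size extremes.

    ``exclude`` drops strains by id before computing anything (e.g. a strain
    later found to belong to a different species).  Means are arithmetic,
    reported rounded half-up to 2 decimals (Mb) and to the nearest integer
    (proteins).  Min/max sizes are computed separately over draft-status and
    complete-status strains; a class with no members yields ``None``.
    """
    excluded = set(exclude)
    kept = [s for s in strains if s.strain_id not in excluded]
    if not kept:
        raise ValueError("no strains left after exclusion")
    sizes = [s.genome_size_mb for s in kept]
    drafts = [s.genome_size_mb for s in kept if s.assembly_status == "draft"]
    completes = [s.genome_size_mb for s in kept if s.assembly_status == "complete"]
    return StrainSummary(
        n_strains=len(kept),
        mean_size_mb=_round_half_up(sum(sizes) / len(kept), 2),
        mean_proteins=int(_round_half_up(sum(s.protein_count for s in kept) / len(kept), 0)),
        max_draft_size=max(drafts) if drafts else None,
        min_draft_size=min(drafts) if drafts else None,
        max_complete_size=max(completes) if completes else None,
        min_complete_size=min(completes) if completes else None,
    )


# ---------------------------------------------------------------------------
# coverage table

def read_coverage_table(path: str | Path) -> list[CoverageRecord]:
    """Read a per-contig coverage TSV (columns strain, contig, length, depth)."""
    records: list[CoverageRecord] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header row")
        missing = [c for c in ("strain", "contig", "length", "depth") if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(
                    CoverageRecord(
                        strain_id=row["strain"].strip(),
                        contig_id=row["contig"].strip(),
                        length_bp=int(row["length"]),
                        mean_depth=float(row["depth"]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} row {i}: {exc}") from exc
    return records


def write_coverage_table(records: Sequence[CoverageRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["strain", "contig", "length", "depth"])
        for r in records:
            writer.writerow([r.strain_id, r.contig_id, r.length_bp, _trim_float(r.mean_depth)])


def coverage_by_strain(records: Sequence[CoverageRecord]) -> dict[str, list[CoverageRecord]]:
    grouped: dict[str, list[CoverageRecord]] = {}
    for r in records:
        grouped.setdefault(r.strain_id, []).append(r)
    return grouped


# ---------------------------------------------------------------------------
# gene FASTA

def _parse_gene_header(header: str, path: str | Path) -> tuple[str, str, int, int, str]:
    parts = header.split("|")
    if len(parts) != 5:
        raise ValueError(
            f"{path}: header {header!r} is not gene_id|contig|start|end|strand"
        )
    gene_id, contig, start, end, strand = parts
    return gene_id, contig, int(start), int(end), strand


def has_internal_stop(aa_seq: str) -> bool:
    """True when a stop symbol occurs before the final position of the protein."""
    return "*" in aa_seq[:-1]


def read_gene_fasta(
    nt_path: str | Path, aa_path: str | Path, strain_id: str
) -> list[GeneRecord]:
    """Merge paired nucleotide/protein FASTA files into :class:`GeneRecord` lists.

    Both files must carry the same gene_id set with identical coordinates.
    A protein with an internal stop codon is flagged ``pseudo`` on read.
    """
    nt = {r.id.split("|")[0]: r for r in SeqIO.parse(str(nt_path), "fasta")}
    aa = {r.id.split("|")[0]: r for r in SeqIO.parse(str(aa_path), "fasta")}
    if set(nt) != set(aa):
        odd = sorted(set(nt) ^ set(aa))
        raise ValueError(f"gene_id mismatch between {nt_path} and {aa_path}: {odd}")
    genes: list[GeneRecord] = []
    for gene_id in sorted(nt):
        gid, contig, start, end, strand = _parse_gene_header(nt[gene_id].id, nt_path)
        aa_seq = str(aa[gene_id].seq)
        genes.append(
            GeneRecord(
                gene_id=gid,
                strain_id=strain_id,
                contig_id=contig,
                start=start,
                end=end,
                strand=strand,
                nt_seq=str(nt[gene_id].seq),
                aa_seq=aa_seq,
                intact="pseudo" if has_internal_stop(aa_seq) else "intact",
            )
        )
    return genes


def write_gene_fasta(genes: Sequence[GeneRecord], nt_path: str | Path, aa_path: str | Path) -> None:
    """Write paired nt/aa FASTA files in the header schema read_gene_fasta expects."""
    with open(nt_path, "w", encoding="utf-8") as nt_handle, open(
        aa_path, "w", encoding="utf-8"
    ) as aa_handle:
        for g in genes:
            header = f"{g.gene_id}|{g.contig_id}|{g.start}|{g.end}|{g.strand}"
            nt_handle.write(f">{header}\n{g.nt_seq}\n")
            aa_handle.write(f">{header}\n{g.aa_seq}\n")


def mark_pseudo(gene: GeneRecord) -> GeneRecord:
    return replace(gene, intact="pseudo")
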