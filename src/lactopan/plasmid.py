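"""Coverage-based plasmid contig classification.

Multi-copy replicons sequence deeper than the chromosome, so an elevated
contig read depth relative to the strain's chromosomal baseline is the
plasmid signal.  The baseline is the length-weighted median depth over the
strain's contigs — robust both to plasmid contigs themselves and to short
repeat-rich contigs.  Calls are scale-invariant: multiplying every depth of
a strain by a constant changes nothing.

Ortholog groups are assigned a plasmid origin by majority vote over their
member genes' contig calls, with ties going to plasmid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import CoverageRecord
from .pangenome import PresenceMatrix

DEFAULT_MIN_RATIO = 1.5
DEFAULT_MIN_LENGTH_BP = 2000


@dataclass(frozen=True)
class ContigCall:
    strain_id: str
    contig_id: str
    length_bp: int
    mean_depth: float
    coverage_ratio: float
    call: str  # plasmid | chromosome | unclassified
    reason: str = ""


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted median: smallest value whose cumulative weight reaches half."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, cum[-1] / 2.0)])


def coverage_ratios(records: Sequence[CoverageRecord]) -> dict[str, float]:
    """Per-contig depth divided by the strain's length-weighted median depth.

    All records must belong to one strain.  A zero baseline leaves every
    ratio undefined (empty mapping); callers then mark contigs unclassified.
    """
    if not records:
        raise ValueError("need at least one contig")
    strains = {r.strain_id for r in records}
    if len(strains) != 1:
        raise ValueError(f"records span multiple strains: {sorted(strains)}")
    baseline = weighted_median(
        [r.mean_depth for r in records], [r.length_bp for r in records]
    )
    if baseline == 0:
        return {}
    return {r.contig_id: r.mean_depth / baseline for r in records}


def classify_contigs(
    records: Sequence[CoverageRecord],
    min_ratio: float = DEFAULT_MIN_RATIO,
    min_length_bp: int = DEFAULT_MIN_LENGTH_BP,
    repeat_flags: Iterable[str] = (),
) -> list[ContigCall]:
    """Call each contig plasmid / chromosome / unclassified.

    Plasmid requires ratio >= ``min_ratio``, length >= ``min_length_bp`` and
    no repeat flag.  Repeat-flagged contigs (rRNA clusters, transposons,
    phages — supplied by the user in place of manual inspection) and contigs
    of strains with a zero depth baseline come back unclassified.
    """
    flagged = set(repeat_flags)
    ratios = coverage_ratios(records)
    calls: list[ContigCall] = []
    for r in records:
        ratio = ratios.get(r.contig_id)
        if ratio is None:
            calls.append(
                ContigCall(r.strain_id, r.contig_id, r.length_bp, r.mean_depth, 0.0,
                           "unclassified", "zero depth baseline")
            )
        elif r.contig_id in flagged:
            calls.append(
                ContigCall(r.strain_id, r.contig_id, r.length_bp, r.mean_depth, ratio,
                           "unclassified", "repeat")
            )
        elif ratio >= min_ratio and r.length_bp >= min_length_bp:
            calls.append(
                ContigCall(r.strain_id, r.contig_id, r.length_bp, r.mean_depth, ratio,
                           "plasmid", "elevated coverage")
            )
        elif ratio >= min_ratio:
            calls.append(
                ContigCall(r.strain_id, r.contig_id, r.length_bp, r.mean_depth, ratio,
                           "unclassified", "short contig")
            )
        else:
            calls.append(
                ContigCall(r.strain_id, r.contig_id, r.length_bp, r.mean_depth, ratio,
                           "chromosome", "")
            )
    return calls


def classify_all(
    records: Sequence[CoverageRecord],
    min_ratio: float = DEFAULT_MIN_RATIO,
    min_length_bp: int = DEFAULT_MIN_LENGTH_BP,
    repeat_flags: Iterable[str] = (),
) -> list[ContigCall]:
    """Classify a multi-strain coverage table, strain by strain."""
    by_strain: dict[str, list[CoverageRecord]] = {}
    for r in records:
        by_strain.setdefault(r.strain_id, []).append(r)
    calls: list[ContigCall] = []
    for strain in sorted(by_strain):
        calls.extend(
            classify_contigs(by_strain[strain], min_ratio, min_length_bp, repeat_flags)
        )
    return calls


def plasmid_og_fraction(
    matrix: PresenceMatrix,
    gene_contig: Mapping[str, tuple[str, str]],
    og_members: Mapping[str, Sequence[str]],
    calls: Sequence[ContigCall],
) -> dict:
    """Plasmid-origin OG set and its fraction of the pangenome.

    ``gene_contig`` maps gene_id -> (strain_id, contig_id); ``og_members``
    maps og_id -> member gene ids.  An OG is plasmid-origin when at least
    half of its members lie on plasmid-called contigs (ties favor plasmid).
    """
    call_map = {(c.strain_id, c.contig_id): c.call for c in calls}
    plasmid_ogs: set[str] = set()
    for og_id in matrix.og_ids:
        members = og_members.get(og_id, [])
        votes = 0
        for gene_id in members:
            if gene_id not in gene_contig:
                raise ValueError(f"gene {gene_id} has no contig mapping")
            key = gene_contig[gene_id]
            if key not in call_map:
                raise ValueError(f"contig {key} has no coverage call")
            if call_map[key] == "plasmid":
                votes += 1
        if members and votes * 2 >= len(members):
            plasmid_ogs.add(og_id)
    return {
        "plasmid_ogs": plasmid_ogs,
        "fraction": len(plasmid_ogs) / matrix.n_ogs if matrix.n_ogs else 0.0,
    }


def write_contig_calls(calls: Sequence[ContigCall], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["strain", "contig", "length", "depth", "ratio", "call", "reason"])
        for c in calls:
            writer.writerow(
                [c.strain_id, c.contig_id, c.length_bp, f"{c.mean_depth:.6g}",
                 f"{c.coverage_ratio:.6g}", c.call, c.reason]
            )
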