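"""End-to-end orchestration of the comparative-genomics stages.

The canonical chain is: protein similarity graph -> MCL ortholog groups ->
length-based pseudogene refinement -> tri-state presence matrix ->
(a) pan/core rarefaction, (b) single-copy-core supermatrix -> p-distance ->
neighbor-joining tree, (c) coverage-based plasmid calls -> plasmid OG
fraction, (d) gene-trait matching per label table.  Each function is usable
on its own; :func:`run_pipeline` wires them for a gene set laid out the way
:mod:`lactopan.synthetic_data` emits one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

from .io_formats import CoverageRecord, GeneRecord
from .orthology import (
    OrthologGroup,
    SimilarityGraph,
    build_similarity_graph,
    clusters_to_ogs,
    mcl_cluster,
)
from .pangenome import PresenceMatrix, build_presence_matrix, pan_core_curves
from .phylogeny import (
    Supermatrix,
    build_supermatrix,
    nj_tree,
    p_distance_matrix,
    select_single_copy_core,
)
from .plasmid import ContigCall, classify_all, plasmid_og_fraction
from .traits import call_pseudogenes, loo_predict, rank_discriminating_ogs, select_marker_set


@dataclass
class PipelineResult:
    strains: list[str]
    ogs: list[OrthologGroup]
    matrix: PresenceMatrix
    tree: Optional[dendropy.Tree]
    supermatrix: Optional[Supermatrix]
    contig_calls: list[ContigCall]
    plasmid_ogs: set[str]
    plasmid_fraction: float
    trait_results: dict[str, list]
    loo: dict[str, dict]


def cluster_genes(
    genes: Sequence[GeneRecord],
    strains: Sequence[str],
    inflation: float = 1.5,
    min_norm_score: float = 0.4,
    min_coverage: float = 0.5,
    length_fraction: float = 0.8,
) -> tuple[list[OrthologGroup], list[GeneRecord]]:
    """Similarity graph + MCL + pseudogene refinement; returns OGs and the
    gene list with updated intactness."""
    graph = build_similarity_graph(
        genes, min_norm_score=min_norm_score, min_coverage=min_coverage
    )
    partition = mcl_cluster(graph, inflation=inflation)
    ogs = clusters_to_ogs(partition, genes, strains)
    by_id = {g.gene_id: g for g in genes}
    refined = call_pseudogenes(
        {og.og_id: [by_id[gid] for gid in og.gene_ids] for og in ogs},
        length_fraction=length_fraction,
    )
    updated_genes = [g for members in refined.values() for g in members]
    ogs = clusters_to_ogs(partition, updated_genes, strains)
    return ogs, updated_genes


def core_alignment_blocks(
    ogs: Sequence[OrthologGroup],
    genes: Sequence[GeneRecord],
    strains: Sequence[str],
) -> dict[str, dict[str, str]]:
    """Per-OG nucleotide blocks for the single-copy core.

    Sequences within a block must already be aligned (equal length); this
    pipeline never aligns.  Unequal-length blocks are skipped — with real
    draft genomes those OGs would need an external aligner first.
    """
    by_id = {g.gene_id: g for g in genes}
    single_copy = select_single_copy_core(ogs, strains)
    blocks: dict[str, dict[str, str]] = {}
    for og in single_copy:
        block = {s: by_id[og.members[s][0]].nt_seq for s in strains}
        if len({len(seq) for seq in block.values()}) == 1:
            blocks[og.og_id] = block
    if not blocks:
        raise ValueError("no equal-length single-copy core blocks available")
    return blocks


def infer_core_tree(
    ogs: Sequence[OrthologGroup],
    genes: Sequence[GeneRecord],
    strains: Sequence[str],
    jc_correction: bool = False,
) -> tuple[dendropy.Tree, Supermatrix]:
    blocks = core_alignment_blocks(ogs, genes, strains)
    sm = build_supermatrix(blocks)
    d = p_distance_matrix(sm, jc_correction=jc_correction)
    return nj_tree(d, sm.strain_ids), sm


def run_pipeline(
    genes: Sequence[GeneRecord],
    strains: Sequence[str],
    coverage: Sequence[CoverageRecord] = (),
    label_tables: Mapping[str, Mapping[str, str]] | None = None,
    inflation: float = 1.5,
    min_norm_score: float = 0.4,
    min_coverage: float = 0.5,
    length_fraction: float = 0.8,
    plasmid_min_ratio: float = 1.5,
    plasmid_min_length_bp: int = 2000,
    n_perm: int = 999,
    seed: int = 0,
    infer_tree: bool = True,
) -> PipelineResult:
    strains = sorted(strains)
    ogs, genes = cluster_genes(
        genes, strains, inflation, min_norm_score, min_coverage, length_fraction
    )
    matrix = build_presence_matrix(ogs, strains)

    tree = sm = None
    if infer_tree and len(strains) >= 2:
        tree, sm = infer_core_tree(ogs, genes, strains)

    calls: list[ContigCall] = []
    plasmid_ogs: set[str] = set()
    fraction = 0.0
    if coverage:
        calls = classify_all(
            coverage, min_ratio=plasmid_min_ratio, min_length_bp=plasmid_min_length_bp
        )
        gene_contig = {g.gene_id: (g.strain_id, g.contig_id) for g in genes}
        og_members = {og.og_id: og.gene_ids for og in ogs}
        result = plasmid_og_fraction(matrix, gene_contig, og_members, calls)
        plasmid_ogs = result["plasmid_ogs"]
        fraction = result["fraction"]

    trait_results: dict[str, list] = {}
    loo: dict[str, dict] = {}
    for name, labels in (label_tables or {}).items():
        ranked = rank_discriminating_ogs(matrix, labels, n_perm=n_perm, seed=seed)
        trait_results[name] = ranked
        markers = [r.og_id for r in select_marker_set(ranked)]
        loo[name] = loo_predict(matrix, labels, markers)

    return PipelineResult(
        strains=strains,
        ogs=ogs,
        matrix=matrix,
        tree=tree,
        supermatrix=sm,
        contig_calls=calls,
        plasmid_ogs=plasmid_ogs,
        plasmid_fraction=fraction,
        trait_results=trait_results,
        loo=loo,
    )


def match_partition_to_truth(
    ogs: Sequence[OrthologGroup], families: Mapping[str, Sequence[str]]
) -> bool:
    """True when the clustering partition equals the planted gene families."""
    inferred = {frozenset(og.gene_ids) for og in ogs}
    truth = {frozenset(members) for members in families.values()}
    return inferred == truth


def og_for_family(
    ogs: Sequence[OrthologGroup], family_members: Sequence[str]
) -> Optional[str]:
    """The og_id whose member set equals a planted family, if any."""
    target = frozenset(family_members)
    for og in ogs:
        if frozenset(og.gene_ids) == target:
            return og.og_id
    return None
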