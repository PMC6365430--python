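"""All-vs-all protein similarity graph and Markov clustering into ortholog groups.

The similarity step scores every candidate protein pair by exact
Smith–Waterman local alignment (BLOSUM62, affine gaps), normalizes by the
smaller self-score so weights live in (0, 1], and keeps an edge when the
normalized score and the aligned coverage of the shorter sequence both clear
their thresholds.  A shared-k-mer prefilter skips pairs that cannot plausibly
align (no seeding, as in any heuristic search); it can be disabled.

Clustering is a from-scratch implementation of the Markov Cluster algorithm
(MCL): add self-loops, column-normalize to a stochastic matrix, then iterate
expansion (matrix squaring) and inflation (element-wise power + pruning +
renormalization) until the matrix stops changing.  Clusters are the weakly
connected components of the converged matrix's nonzero structure and always
form a partition of the input genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numba
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import GeneRecord

logger = logging.getLogger(__name__)

DEFAULT_INFLATION = 1.5
DEFAULT_MIN_NORM_SCORE = 0.4
DEFAULT_MIN_COVERAGE = 0.5
DEFAULT_PRUNE_THRESHOLD = 1e-5
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100

GAP_OPEN = 11  # cost of the first residue of a gap
GAP_EXTEND = 1  # cost of each further residue


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score(a: str, b: str) -> int:
    """Optimal Smith–Waterman local alignment score (BLOSUM62, gap 11/1).

    The score of a gap of length k is ``-(11 + (k-1))``.  Symmetric in its
    arguments; an empty sequence scores 0 by contract.
    """
    if not a or not b:
        return 0
    return int(_ALIGNER.score(a, b))


_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_CHAR_INDEX = {c: i for i, c in enumerate(_ALPHABET)}
_SUB_MATRIX = np.array(
    [[_BLOSUM62[a, b] for b in _ALPHABET] for a in _ALPHABET], dtype=np.float64
)


def _encode(seq: str) -> np.ndarray:
    # unknown characters score as X
    x = _CHAR_INDEX["X"]
    return np.array([_CHAR_INDEX.get(c, x) for c in seq], dtype=np.int64)


@numba.njit(cache=True)
def _gotoh_score_span(a, b, sub, gap_open, gap_ext):  # pragma: no cover - jit
    """Local affine-gap DP returning (score, aligned extent on sequence a).

    One rolling-row pass; each cell also carries the row where its local
    path started, so the aligned span on ``a`` falls out with the score.
    """
    n, m = a.shape[0], b.shape[0]
    NEG = -1e18
    prev_m = np.zeros(m + 1)
    prev_ga = np.full(m + 1, NEG)
    prev_gb = np.full(m + 1, NEG)
    prev_sm = np.zeros(m + 1, dtype=np.int32)
    prev_sa = np.zeros(m + 1, dtype=np.int32)
    prev_sb = np.zeros(m + 1, dtype=np.int32)
    cur_m = np.zeros(m + 1)
    cur_ga = np.full(m + 1, NEG)
    cur_gb = np.full(m + 1, NEG)
    cur_sm = np.zeros(m + 1, dtype=np.int32)
    cur_sa = np.zeros(m + 1, dtype=np.int32)
    cur_sb = np.zeros(m + 1, dtype=np.int32)
    best = 0.0
    best_span = 0
    for i in range(1, n + 1):
        cur_m[0] = 0.0
        cur_ga[0] = NEG
        cur_gb[0] = NEG
        cur_sm[0] = i  # empty path at column 0: consumption starts at row i+1
        cur_sa[0] = i
        cur_sb[0] = i
        for j in range(1, m + 1):
            # gap in b (consume a): move down a row
            if prev_m[j] - gap_open >= prev_ga[j] - gap_ext:
                cur_ga[j] = prev_m[j] - gap_open
                cur_sa[j] = prev_sm[j]
            else:
                cur_ga[j] = prev_ga[j] - gap_ext
                cur_sa[j] = prev_sa[j]
            # gap in a (consume b): move along the row
            if cur_m[j - 1] - gap_open >= cur_gb[j - 1] - gap_ext:
                cur_gb[j] = cur_m[j - 1] - gap_open
                cur_sb[j] = cur_sm[j - 1]
            else:
                cur_gb[j] = cur_gb[j - 1] - gap_ext
                cur_sb[j] = cur_sb[j - 1]
            s = sub[a[i - 1], b[j - 1]]
            v = prev_m[j - 1] + s
            start = prev_sm[j - 1]
            if prev_ga[j - 1] + s > v:
                v = prev_ga[j - 1] + s
                start = prev_sa[j - 1]
            if prev_gb[j - 1] + s > v:
                v = prev_gb[j - 1] + s
                start = prev_sb[j - 1]
            if v <= 0.0:
                v = 0.0
                start = i
            cur_m[j] = v
            cur_sm[j] = start
            if v > best:
                best = v
                best_span = i - start
        prev_m, cur_m = cur_m, prev_m
        prev_ga, cur_ga = cur_ga, prev_ga
        prev_gb, cur_gb = cur_gb, prev_gb
        prev_sm, cur_sm = cur_sm, prev_sm
        prev_sa, cur_sa = cur_sa, prev_sa
        prev_sb, cur_sb = cur_sb, prev_sb
    return best, best_span


def sw_score_and_span(a: str, b: str) -> tuple[int, int]:
    """Score plus the length of the aligned region on the shorter sequence."""
    if not a or not b:
        return 0, 0
    if len(a) > len(b):
        a, b = b, a
    score, span = _gotoh_score_span(
        _encode(a), _encode(b), _SUB_MATRIX, float(GAP_OPEN), float(GAP_EXTEND)
    )
    return int(score), int(span)


def self_score(a: str) -> int:
    """Score of aligning a sequence to itself: the sum of diagonal BLOSUM62 terms."""
    if not a:
        return 0
    codes = _encode(a)
    return int(_SUB_MATRIX[codes, codes].sum())


@dataclass
class SimilarityGraph:
    """Undirected weighted protein similarity graph with node→strain mapping."""

    graph: nx.Graph
    gene_strain: dict[str, str]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_weight(self, a: str, b: str) -> Optional[float]:
        data = self.graph.get_edge_data(a, b)
        return None if data is None else data["weight"]


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_similarity_graph(
    genes: Sequence[GeneRecord],
    min_norm_score: float = DEFAULT_MIN_NORM_SCORE,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    prefilter_k: Optional[int] = 4,
    prefilter_min_frac: float = 0.05,
) -> SimilarityGraph:
    """Score all protein pairs and keep edges above similarity/coverage cutoffs.

    Edge weight is ``sw(a, b) / min(sw(a, a), sw(b, b))`` — scale-free and at
    most 1.  An edge is kept when the weight is at least ``min_norm_score``
    and the aligned span covers at least ``min_coverage`` of the shorter
    sequence.  With ``prefilter_k`` set, a pair is aligned only when it
    shares at least ``max(3, prefilter_min_frac * k-mer count of the shorter
    sequence)`` k-mers — the seeding shortcut of any heuristic search; pass
    ``prefilter_k=None`` to force exact all-vs-all scoring.
    """
    if not genes:
        raise ValueError("need at least one gene")
    graph = nx.Graph()
    gene_strain: dict[str, str] = {}
    for g in genes:
        if g.gene_id in gene_strain:
            raise ValueError(f"duplicate gene_id {g.gene_id}")
        graph.add_node(g.gene_id)
        gene_strain[g.gene_id] = g.strain_id

    ordered = sorted(genes, key=lambda g: g.gene_id)
    encoded = {g.gene_id: _encode(g.aa_seq) for g in ordered if g.aa_seq}
    selfs = {
        gid: int(_SUB_MATRIX[codes, codes].sum()) for gid, codes in encoded.items()
    }
    kmers = (
        {g.gene_id: _kmer_set(g.aa_seq, prefilter_k) for g in ordered}
        if prefilter_k is not None
        else None
    )
    gap_open, gap_ext = float(GAP_OPEN), float(GAP_EXTEND)
    for i, ga in enumerate(ordered):
        for gb in ordered[i + 1 :]:
            if not ga.aa_seq or not gb.aa_seq:
                continue
            shorter = min(len(ga.aa_seq), len(gb.aa_seq))
            if kmers is not None and prefilter_k is not None:
                needed = max(
                    3, int(prefilter_min_frac * (shorter - prefilter_k + 1))
                )
                shared = len(kmers[ga.gene_id] & kmers[gb.gene_id])
                if shared < needed:
                    continue
            denom = min(selfs[ga.gene_id], selfs[gb.gene_id])
            if denom <= 0:
                continue
            ca, cb = encoded[ga.gene_id], encoded[gb.gene_id]
            if ca.shape[0] > cb.shape[0]:
                ca, cb = cb, ca
            score, span = _gotoh_score_span(ca, cb, _SUB_MATRIX, gap_open, gap_ext)
            if score <= 0:
                continue
            weight = score / denom
            if weight >= min_norm_score and span >= min_coverage * shorter:
                graph.add_edge(ga.gene_id, gb.gene_id, weight=min(weight, 1.0))
    return SimilarityGraph(graph=graph, gene_strain=gene_strain)


# ---------------------------------------------------------------------------
# Markov clustering

def _mcl_component(
    nodes: list[str],
    graph: nx.Graph,
    inflation: float,
    prune_threshold: float,
    max_iter: int,
    tol: float,
) -> tuple[list[list[str]], bool]:
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.subgraph(nodes).edges(data=True):
        m[index[a], index[b]] = data["weight"]
        m[index[b], index[a]] = data["weight"]
    # self-loops: max incident weight, floored to keep isolated nodes stochastic
    np.fill_diagonal(m, np.maximum(m.max(axis=0), 1e-6))
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune_threshold] = 0.0
        sums = inflated.sum(axis=0, keepdims=True)
        sums[sums == 0.0] = 1.0
        inflated /= sums
        if np.max(np.abs(inflated - m)) < tol:
            m = inflated
            converged = True
            break
        m = inflated

    structure = nx.Graph()
    structure.add_nodes_from(range(n))
    rows, cols = np.nonzero(m)
    structure.add_edges_from(zip(rows.tolist(), cols.tolist()))
    clusters = [sorted(nodes[i] for i in comp) for comp in nx.connected_components(structure)]
    return clusters, converged


def mcl_cluster(
    graph: SimilarityGraph,
    inflation: float = DEFAULT_INFLATION,
    prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> list[list[str]]:
    """Partition the similarity graph by Markov clustering.

    Runs independently per connected component (MCL can never merge
    disconnected components, so this is exact and keeps the matrices small).
    Returns clusters as sorted gene-id lists, sorted by smallest member.
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    if graph.graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    clusters: list[list[str]] = []
    for comp in nx.connected_components(graph.graph):
        comp_nodes = sorted(comp)
        if len(comp_nodes) == 1:
            clusters.append(comp_nodes)
            continue
        comp_clusters, converged = _mcl_component(
            comp_nodes, graph.graph, inflation, prune_threshold, max_iter, tol
        )
        if not converged:
            logger.warning(
                "MCL did not converge within %d iterations on a %d-node component; "
                "returning current partition",
                max_iter,
                len(comp_nodes),
            )
        clusters.extend(comp_clusters)
    clusters.sort(key=lambda c: c[0])
    return clusters


@dataclass
class OrthologGroup:
    """A cluster of genes across strains with per-strain presence state."""

    og_id: str
    members: dict[str, list[str]]  # strain_id -> gene_ids
    states: dict[str, str]  # strain_id -> present | pseudo | absent
    single_copy: bool

    def state(self, strain_id: str) -> str:
        return self.states.get(strain_id, "absent")

    @property
    def gene_ids(self) -> list[str]:
        return sorted(g for genes in self.members.values() for g in genes)


def clusters_to_ogs(
    partition: Sequence[Sequence[str]],
    genes: Sequence[GeneRecord],
    strains: Sequence[str],
) -> list[OrthologGroup]:
    """Turn an MCL partition into :class:`OrthologGroup` records.

    A strain's state is ``present`` when it has at least one intact member in
    the cluster, ``pseudo`` when all its members are pseudogenes, ``absent``
    otherwise.  OG ids are assigned from the sorted smallest member gene_id,
    so numbering is deterministic for a given clustering.
    """
    by_id = {g.gene_id: g for g in genes}
    covered = sorted(g for cluster in partition for g in cluster)
    if covered != sorted(by_id):
        raise ValueError("partition does not cover the gene set exactly")
    strain_list = list(strains)
    ogs: list[OrthologGroup] = []
    for cluster in sorted((sorted(c) for c in partition), key=lambda c: c[0]):
        members: dict[str, list[str]] = {}
        for gene_id in cluster:
            gene = by_id[gene_id]
            if gene.strain_id not in strain_list:
                raise ValueError(f"gene {gene_id} maps to unknown strain {gene.strain_id}")
            members.setdefault(gene.strain_id, []).append(gene_id)
        states: dict[str, str] = {}
        for strain_id in strain_list:
            strain_genes = members.get(strain_id, [])
            if not strain_genes:
                states[strain_id] = "absent"
            elif any(by_id[g].intact == "intact" for g in strain_genes):
                states[strain_id] = "present"
            else:
                states[strain_id] = "pseudo"
        single_copy = all(len(members.get(s, [])) == 1 for s in strain_list)
        ogs.append(
            OrthologGroup(
                og_id=f"OG_{cluster[0]}",
                members=members,
                states=states,
                single_copy=single_copy,
            )
        )
    return ogs


def write_og_table(
    ogs: Sequence[OrthologGroup], strains: Sequence[str], path: str | Path
) -> None:
    """OG table TSV: per-strain cells list gene ids, 'pseudo:' prefixed when the
    strain carries only pseudogene members, '-' when absent."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("og_id\t" + "\t".join(strains) + "\n")
        for og in ogs:
            cells = []
            for strain in strains:
                state = og.state(strain)
                if state == "absent":
                    cells.append("-")
                elif state == "pseudo":
                    cells.append("pseudo:" + ",".join(sorted(og.members[strain])))
                else:
                    cells.append(",".join(sorted(og.members[strain])))
            handle.write(og.og_id + "\t" + "\t".join(cells) + "\n")
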