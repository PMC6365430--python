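"""Core-SNP supermatrix construction and distance-based tree inference.

Single-copy core ortholog groups (one gene per strain) are the phylogenetic
markers.  From their per-OG nucleotide alignments, only the variable columns
are kept and concatenated into one "artificial sequence" per strain — the
supermatrix.  Pairwise p-distances (fraction of differing supermatrix
columns; optionally Jukes–Cantor corrected) feed Saitou–Nei neighbor
joining, which is exact on additive distance matrices.  Re-rooting places
the root on the branch separating a user-chosen outgroup from the rest.

Trees are dendropy objects throughout, serialized as Newick with 9-decimal
branch lengths.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .orthology import OrthologGroup

_UNAMBIGUOUS = set("ACGT")


def select_single_copy_core(
    ogs: Sequence[OrthologGroup], strains: Sequence[str]
) -> list[OrthologGroup]:
    """OGs carrying exactly one member (intact or pseudogene) in every strain."""
    selected = [
        og for og in ogs if all(len(og.members.get(s, [])) == 1 for s in strains)
    ]
    if not selected:
        raise ValueError(
            "no single-copy core OGs found; consider relaxing the similarity "
            "thresholds used for clustering"
        )
    return sorted(selected, key=lambda og: og.og_id)


@dataclass
class Supermatrix:
    """Concatenated variable columns from per-OG alignments, one row per strain."""

    strain_ids: list[str]
    sequences: dict[str, str]
    provenance: list[tuple[str, int]]  # (og_id, column index within that OG)

    @property
    def total_columns(self) -> int:
        return len(self.provenance)


def build_supermatrix(alignments: Mapping[str, Mapping[str, str]]) -> Supermatrix:
    """Concatenate variable alignment columns across OG blocks.

    A column is kept when it has at least two distinct residues among the
    strains and contains neither gaps nor ambiguity codes.  Blocks are
    processed in sorted og_id order, columns left to right, so the
    supermatrix is independent of input dict ordering.
    """
    if not alignments:
        raise ValueError("no alignment blocks given")
    og_ids = sorted(alignments)
    strain_set = sorted(alignments[og_ids[0]])
    parts: dict[str, list[str]] = {s: [] for s in strain_set}
    provenance: list[tuple[str, int]] = []
    for og_id in og_ids:
        block = alignments[og_id]
        if sorted(block) != strain_set:
            raise ValueError(f"block {og_id} has a different strain set")
        rows = [block[s].upper() for s in strain_set]
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"block {og_id} rows are not equal length")
        arr = np.array([list(r) for r in rows])
        for col in range(arr.shape[1]):
            column = arr[:, col]
            if not set(column) <= _UNAMBIGUOUS:
                continue
            if len(set(column)) < 2:
                continue
            provenance.append((og_id, col))
            for i, s in enumerate(strain_set):
                parts[s].append(column[i])
    return Supermatrix(
        strain_ids=strain_set,
        sequences={s: "".join(parts[s]) for s in strain_set},
        provenance=provenance,
    )


def p_distance_matrix(sm: Supermatrix, jc_correction: bool = False) -> np.ndarray:
    """Pairwise fraction of differing supermatrix columns.

    With ``jc_correction`` the p-distance is transformed to the Jukes–Cantor
    expected substitutions per site, ``-3/4 ln(1 - 4p/3)``.  Note that a
    p-distance matrix need not satisfy the triangle inequality.
    """
    if sm.total_columns == 0:
        raise ValueError("supermatrix has no variable columns")
    rows = np.array([list(sm.sequences[s]) for s in sm.strain_ids])
    n = len(sm.strain_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(rows[i] != rows[j]))
            if jc_correction:
                if p >= 0.75:
                    raise ValueError(
                        f"p-distance {p} between {sm.strain_ids[i]} and "
                        f"{sm.strain_ids[j]} is saturated; JC correction undefined"
                    )
                p = -0.75 * math.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return d


# ---------------------------------------------------------------------------
# neighbor joining


class _Node:
    __slots__ = ("label", "children", "min_leaf")

    def __init__(self, label=None, children=None, min_leaf=None):
        self.label = label
        self.children = children or []  # list of (node, branch_length)
        self.min_leaf = min_leaf if min_leaf is not None else label

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.9f}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(d: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Q-matrix ties are broken by the lexicographically smallest pair of
    smallest-descendant-leaf labels.  A negative pendant branch length is
    clamped to zero with the deficit moved to its sister branch, so the path
    length between the joined pair is preserved.  Returns an unrooted tree
    (trifurcating root node in the Newick serialization).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix and label list are inconsistent")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n < 2:
        raise ValueError("need at least two taxa")

    nodes = [_Node(label=lbl) for lbl in labels]
    dist = d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = dist.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((nodes[i].min_leaf, nodes[j].min_leaf))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * dist[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = _Node(
            children=[(nodes[i], li), (nodes[j], lj)],
            min_leaf=min(nodes[i].min_leaf, nodes[j].min_leaf),
        )
        new_dist = 0.5 * (dist[i] + dist[j] - dist[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        dist = np.vstack([dist[keep][:, keep], new_dist[keep]])
        dist = np.hstack([dist, np.append(new_dist[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    if len(nodes) == 2:
        half = dist[0, 1] / 2.0
        root = _Node(children=[(nodes[0], half), (nodes[1], half)])
    else:
        # three-point closed form
        la = (dist[0, 1] + dist[0, 2] - dist[1, 2]) / 2.0
        lb = (dist[0, 1] + dist[1, 2] - dist[0, 2]) / 2.0
        lc = (dist[0, 2] + dist[1, 2] - dist[0, 1]) / 2.0
        root = _Node(
            children=[
                (nodes[0], max(la, 0.0)),
                (nodes[1], max(lb, 0.0)),
                (nodes[2], max(lc, 0.0)),
            ]
        )
    newick = root.newick() + ";"
    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-unrooted")


# ---------------------------------------------------------------------------
# tree utilities


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as leaf-label sets, normalized to the side not
    containing the alphabetically first leaf."""
    all_leaves = leaf_labels(tree)
    ref = min(all_leaves)
    n = len(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds distance: symmetric difference of non-trivial bipartitions."""
    if leaf_labels(t1) != leaf_labels(t2):
        raise ValueError("trees have different leaf sets")
    return len(_bipartitions(t1) ^ _bipartitions(t2))


def reroot(tree: dendropy.Tree, outgroup: str | Iterable[str]) -> dendropy.Tree:
    """Root the tree on the branch separating the outgroup from everything else.

    The outgroup must be monophyletic in the unrooted tree (i.e. form one
    side of an existing branch); the root splits that branch length equally.
    """
    out = {outgroup} if isinstance(outgroup, str) else set(outgroup)
    all_leaves = leaf_labels(tree)
    if not out <= all_leaves:
        raise ValueError(f"outgroup leaves not in tree: {sorted(out - all_leaves)}")
    if out == all_leaves:
        raise ValueError("outgroup cannot contain every leaf")
    rooted = dendropy.Tree(tree)  # work on a clone
    rooted.is_rooted = True
    target = None
    for node in rooted.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if side == out or all_leaves - side == out:
            target = node
            break
    if target is None:
        raise ValueError(
            f"outgroup {sorted(out)} is not monophyletic: no branch separates it"
        )
    length = target.edge.length or 0.0
    rooted.reroot_at_edge(target.edge, length1=length / 2.0, length2=length / 2.0)
    return rooted


def tree_distance_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Patristic (path-length) leaf-to-leaf distances, labels sorted."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return labels, d


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    text = tree.as_string(
        schema="newick", real_value_format_specifier=".9f", suppress_rooting=True
    )
    Path(path).write_text(text, encoding="utf-8")


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_supermatrix(sm: Supermatrix, phylip_path: str | Path, provenance_path: str | Path) -> None:
    """Relaxed PHYLIP plus a per-column provenance TSV (og_id, column)."""
    with open(phylip_path, "w", encoding="utf-8") as handle:
        handle.write(f"{len(sm.strain_ids)} {sm.total_columns}\n")
        for s in sm.strain_ids:
            handle.write(f"{s}  {sm.sequences[s]}\n")
    with open(provenance_path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["position", "og_id", "og_column"])
        for pos, (og_id, col) in enumerate(sm.provenance):
            writer.writerow([pos, og_id, col])
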