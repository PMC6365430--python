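"""Pseudogene-aware gene-trait matching.

Each ortholog group (OG) is scored for how well its presence pattern
separates a binary strain label (subspecies genotype, dairy vs non-dairy
niche, any phenotype).  Pseudogenes are treated as an intermediate state:
a pseudogene cell is compatible with both presence and absence and never
contributes an error, so genome decay cannot mask an otherwise perfect
marker.  Significance comes from a permutation null (labels shuffled
jointly across OGs), corrected by Benjamini–Hochberg.  A leave-one-out
voting classifier over a selected marker set estimates how well the label
can be predicted from gene content alone.

For heatmap display, rows/columns are ordered by complete-linkage
hierarchical clustering on Manhattan or Euclidean distances over the
numeric encoding absent=0, pseudo=0.5, present=1.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneRecord, has_internal_stop
from .pangenome import ABSENT, PRESENT, PSEUDO, PresenceMatrix

logger = logging.getLogger(__name__)

ORIENT_A = "present->A"
ORIENT_B = "present->B"


@dataclass(frozen=True)
class OgTraitResult:
    og_id: str
    score: float
    orientation: str
    p_perm: float
    q_bh: float
    n_pseudo_neutral: int


def _validate_labels(y: np.ndarray) -> None:
    n_a = int((y == 0).sum())
    n_b = int((y == 1).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError(
            f"need at least 2 strains per class, got {n_a} in A and {n_b} in B"
        )


def _label_vector(strain_ids: Sequence[str], labels: Mapping[str, str]) -> np.ndarray:
    """-1 missing, 0 class A, 1 class B."""
    code = {"A": 0, "B": 1, "missing": -1}
    y = np.full(len(strain_ids), -1, dtype=int)
    for i, s in enumerate(strain_ids):
        lab = labels.get(s, "missing")
        if lab not in code:
            raise ValueError(f"label for {s} must be A, B or missing, got {lab!r}")
        y[i] = code[lab]
    return y


def _score_columns(cells: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized discrimination score per OG column.

    Pseudogene cells contribute no error under either orientation; the
    denominator is the number of labeled strains, so turning a cell pseudo
    can only remove errors, never shrink the scale.  Returns
    (scores, errA_leq_errB).
    """
    in_a = y == 0
    in_b = y == 1
    present = cells == PRESENT
    absent = cells == ABSENT
    err_a = present[in_b].sum(axis=0) + absent[in_a].sum(axis=0)
    err_b = present[in_a].sum(axis=0) + absent[in_b].sum(axis=0)
    n_labeled = int((in_a | in_b).sum())
    err = np.minimum(err_a, err_b)
    scores = 1.0 - err / n_labeled if n_labeled else np.ones(cells.shape[1])
    return scores, err_a <= err_b


def og_trait_score(states: Mapping[str, str], labels: Mapping[str, str]) -> dict:
    """Score one OG's tri-state pattern against a binary label.

    ``states`` maps strain -> present/pseudo/absent; ``labels`` maps strain
    -> A/B/missing.  The score is 1 minus the minimum (over the two
    orientations) error count divided by the number of labeled strains;
    pseudogene cells are neutral — compatible with both presence and
    absence, they contribute no error — and counted in ``n_pseudo_neutral``.
    """
    strains = sorted(states)
    code = {"absent": ABSENT, "pseudo": PSEUDO, "present": PRESENT}
    cells = np.array([[code[states[s]]] for s in strains], dtype=np.int8)
    y = _label_vector(strains, labels)
    _validate_labels(y)
    scores, a_best = _score_columns(cells, y)
    n_pseudo = int(((cells[:, 0] == PSEUDO) & (y >= 0)).sum())
    return {
        "score": float(scores[0]),
        "orientation": ORIENT_A if a_best[0] else ORIENT_B,
        "n_pseudo_neutral": n_pseudo,
    }


def rank_discriminating_ogs(
    matrix: PresenceMatrix,
    labels: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> list[OgTraitResult]:
    """Rank every OG by discrimination score with a permutation null.

    The label vector is permuted as a whole ``n_perm`` times (jointly across
    OGs, preserving between-OG correlation); the per-OG p-value is
    ``(1 + #{permuted score >= observed}) / (n_perm + 1)`` and q-values are
    Benjamini–Hochberg over all OGs.  Results sorted by score (desc), then
    p-value, then og_id.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    y = _label_vector(matrix.strain_ids, labels)
    _validate_labels(y)
    cells = matrix.cells
    observed, a_best = _score_columns(cells, y)
    n_pseudo = ((cells == PSEUDO) & (y >= 0)[:, None]).sum(axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(matrix.n_ogs, dtype=int)
    for _ in range(n_perm):
        perm_scores, _ = _score_columns(cells, rng.permutation(y))
        exceed += perm_scores >= observed
    p = (1.0 + exceed) / (n_perm + 1.0)
    q = multipletests(p, method="fdr_bh")[1]

    results = [
        OgTraitResult(
            og_id=matrix.og_ids[j],
            score=float(observed[j]),
            orientation=ORIENT_A if a_best[j] else ORIENT_B,
            p_perm=float(p[j]),
            q_bh=float(q[j]),
            n_pseudo_neutral=int(n_pseudo[j]),
        )
        for j in range(matrix.n_ogs)
    ]
    results.sort(key=lambda r: (-r.score, r.p_perm, r.og_id))
    return results


def select_marker_set(results: Sequence[OgTraitResult], top_n: int = 50) -> list[OgTraitResult]:
    """Markers for display: all perfect-score OGs when any exist, else top N."""
    perfect = [r for r in results if r.score == 1.0]
    return perfect if perfect else list(results[:top_n])


def loo_predict(
    matrix: PresenceMatrix,
    labels: Mapping[str, str],
    selected_ogs: Sequence[str],
) -> dict:
    """Leave-one-out label prediction by marker voting.

    For each held-out labeled strain, every selected OG refits its
    orientation on the remaining strains and votes according to the held-out
    strain's state (pseudo abstains, absence votes the opposite class).
    Majority wins; ties and all-abstain cases fall back to class A.
    """
    if not selected_ogs:
        raise ValueError("need at least one selected OG")
    y = _label_vector(matrix.strain_ids, labels)
    _validate_labels(y)
    og_pos = {og: j for j, og in enumerate(matrix.og_ids)}
    try:
        cols = np.array([og_pos[og] for og in selected_ogs])
    except KeyError as exc:
        raise ValueError(f"unknown OG {exc.args[0]!r}") from exc
    cells = matrix.cells[:, cols]
    labeled = np.nonzero(y >= 0)[0]
    predictions: dict[str, str] = {}
    errors = 0
    for i in labeled:
        train = y.copy()
        train[i] = -1
        _, a_best = _score_columns(cells, train)
        votes_a = 0
        votes_b = 0
        for j in range(cells.shape[1]):
            state = cells[i, j]
            if state == PSEUDO:
                continue
            present_class_a = a_best[j]
            if (state == PRESENT) == present_class_a:
                votes_a += 1
            else:
                votes_b += 1
        if votes_a == 0 and votes_b == 0:
            logger.warning(
                "all markers abstained for strain %s; defaulting to class A",
                matrix.strain_ids[i],
            )
        predicted = "A" if votes_a >= votes_b else "B"
        predictions[matrix.strain_ids[i]] = predicted
        if predicted != ("A" if y[i] == 0 else "B"):
            errors += 1
    return {"predictions": predictions, "error_rate": errors / len(labeled)}


def call_pseudogenes(
    og_members: Mapping[str, Sequence[GeneRecord]],
    length_fraction: float = 0.8,
) -> dict[str, list[GeneRecord]]:
    """Flag truncated OG members as pseudogenes.

    Within each OG of at least 3 members, a member is a pseudogene when its
    protein is shorter than ``length_fraction`` times the median length of
    the OG's intact members, or when it contains an internal stop.  Smaller
    OGs get only the internal-stop rule (a median over <3 members is not
    meaningful).
    """
    updated: dict[str, list[GeneRecord]] = {}
    for og_id, members in og_members.items():
        stops = [has_internal_stop(g.aa_seq) for g in members]
        if len(members) >= 3:
            intact_lengths = [
                len(g.aa_seq)
                for g, stop in zip(members, stops)
                if g.intact == "intact" and not stop
            ]
            median = float(np.median(intact_lengths)) if intact_lengths else 0.0
        else:
            median = 0.0
        new_members = []
        for g, stop in zip(members, stops):
            short = median > 0 and len(g.aa_seq) < length_fraction * median
            if stop or short:
                new_members.append(replace(g, intact="pseudo"))
            else:
                new_members.append(g)
        updated[og_id] = new_members
    return updated


# ---------------------------------------------------------------------------
# heatmap ordering


def numeric_encoding(matrix: PresenceMatrix) -> np.ndarray:
    """Absent 0, pseudo 0.5, present 1 — for distance computations only."""
    return matrix.cells.astype(float) / 2.0


def heatmap_order(
    data: np.ndarray, metric: str = "manhattan", linkage: str = "complete"
) -> dict:
    """Complete-linkage agglomerative leaf ordering of data rows.

    Ties in the merge step go to the pair with the smallest item indices.
    Returns the leaf order and the merge sequence (cluster index pairs with
    merge heights).  Only complete linkage is supported, matching the
    published heatmap protocol.
    """
    if metric not in {"manhattan", "euclidean"}:
        raise ValueError(f"unknown metric {metric!r}")
    if linkage != "complete":
        raise ValueError("only complete linkage is supported")
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    scipy_metric = "cityblock" if metric == "manhattan" else "euclidean"
    d = squareform(pdist(np.asarray(data, dtype=float), metric=scipy_metric))

    # active clusters: id -> member leaf order; distances kept complete-linkage
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(members) > 1:
        (i, j), height = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((i, j, height))
        merged = members.pop(i) + members.pop(j)
        for k in list(members):
            dik = dist.pop(tuple(sorted((i, k))))
            djk = dist.pop(tuple(sorted((j, k))))
            dist[(k, next_id)] = max(dik, djk)
        dist.pop((i, j))
        members[next_id] = merged
        next_id += 1
    leaf_order = members[next_id - 1]
    return {"leaf_order": leaf_order, "merges": merges}


def write_trait_results(results: Sequence[OgTraitResult], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["og_id", "score", "orientation", "p_perm", "q_bh", "n_pseudo_neutral"])
        for r in results:
            writer.writerow(
                [r.og_id, f"{r.score:.6g}", r.orientation, f"{r.p_perm:.6g}",
                 f"{r.q_bh:.6g}", r.n_pseudo_neutral]
            )


def read_trait_table(path: str | Path) -> dict[str, str]:
    """Trait TSV (columns strain, label) -> mapping; labels must be A/B/missing."""
    table: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or not {"strain", "label"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns strain, label")
        for row in reader:
            table[row["strain"].strip()] = row["label"].strip()
    return table


def write_trait_table(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["strain", "label"])
        for strain in sorted(labels):
            writer.writerow([strain, labels[strain]])
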