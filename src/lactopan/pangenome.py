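"""Tri-state presence matrix and pan/core rarefaction.

The presence matrix records, for every strain × ortholog group (OG) pair,
whether the strain carries an intact member (present), only pseudogene
members (pseudo), or no member at all (absent).  Pseudogenes count as
"non-absent" for pan/core membership: the pangenome is the union of OGs a
gene caller found, whether or not every copy still encodes a complete
protein.  An ``require_intact`` switch restricts core membership to intact
copies where that distinction matters.

Rarefaction draws random strain orderings and counts, after each added
strain, the OGs seen so far (pan) and the OGs seen in every strain so far
(core); means and standard deviations over orderings quantify the sampling
spread shown as the grey band of the classic pan/core figure.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .orthology import OrthologGroup

ABSENT, PSEUDO, PRESENT = 0, 1, 2
_STATE_CODE = {"absent": ABSENT, "pseudo": PSEUDO, "present": PRESENT}
_CODE_CELL = {ABSENT: "0", PSEUDO: "P", PRESENT: "1"}


@dataclass
class PresenceMatrix:
    """Strains × OGs tri-state matrix (0 absent, 1 pseudo, 2 present)."""

    strain_ids: list[str]
    og_ids: list[str]
    cells: np.ndarray  # int8, shape (n_strains, n_ogs)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.strain_ids), len(self.og_ids)):
            raise ValueError("matrix shape does not match strain/OG lists")
        if self.og_ids and not (self.cells > ABSENT).any(axis=0).all():
            empty = [og for og, ok in zip(self.og_ids, (self.cells > ABSENT).any(axis=0)) if not ok]
            raise ValueError(f"OGs absent in every strain: {empty}")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_ogs(self) -> int:
        return len(self.og_ids)

    def state(self, strain_id: str, og_id: str) -> str:
        i = self.strain_ids.index(strain_id)
        j = self.og_ids.index(og_id)
        return {v: k for k, v in _STATE_CODE.items()}[int(self.cells[i, j])]

    def strain_index(self, strain_ids: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.strain_ids)}
        try:
            return np.array([pos[s] for s in strain_ids], dtype=int)
        except KeyError as exc:
            raise ValueError(f"unknown strain {exc.args[0]!r}") from exc


def build_presence_matrix(
    ogs: Sequence[OrthologGroup], strains: Sequence[str]
) -> PresenceMatrix:
    """Fill a presence matrix from OG states; strains and OGs sorted."""
    strain_ids = sorted(strains)
    og_sorted = sorted(ogs, key=lambda og: og.og_id)
    known = set(strain_ids)
    for og in og_sorted:
        unknown = set(og.members) - known
        if unknown:
            raise ValueError(f"OG {og.og_id} references unknown strains {sorted(unknown)}")
    cells = np.zeros((len(strain_ids), len(og_sorted)), dtype=np.int8)
    for j, og in enumerate(og_sorted):
        for i, strain in enumerate(strain_ids):
            cells[i, j] = _STATE_CODE[og.state(strain)]
    return PresenceMatrix(strain_ids, [og.og_id for og in og_sorted], cells)


@dataclass
class RarefactionCurve:
    """Pan/core OG counts vs number of sampled strains, over random orderings."""

    k: np.ndarray
    pan_mean: np.ndarray
    pan_sd: np.ndarray
    core_mean: np.ndarray
    core_sd: np.ndarray
    n_permutations: int
    seed: int

    def plateau_k(self, fraction: float = 0.005) -> int | None:
        """First k where the mean pan increment drops below ``fraction`` of the
        total OG count (descriptive 'levels off' point); None if never."""
        total = self.pan_mean[-1]
        increments = np.diff(self.pan_mean)
        small = np.nonzero(increments < fraction * total)[0]
        return int(self.k[small[0] + 1]) if small.size else None


def _pan_core_single_order(nonabsent: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    seen = nonabsent[order]
    pan = np.logical_or.accumulate(seen, axis=0).sum(axis=1)
    core = np.logical_and.accumulate(seen, axis=0).sum(axis=1)
    return pan, core


def pan_core_curves(
    matrix: PresenceMatrix,
    n_permutations: int = 500,
    seed: int = 0,
    require_intact: bool = False,
) -> RarefactionCurve:
    """Rarefaction of pan and core genome size over random strain orderings."""
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    counted = matrix.cells >= (PRESENT if require_intact else PSEUDO)
    n = matrix.n_strains
    rng = np.random.default_rng(seed)
    pans = np.empty((n_permutations, n))
    cores = np.empty((n_permutations, n))
    for p in range(n_permutations):
        order = rng.permutation(n)
        pans[p], cores[p] = _pan_core_single_order(counted, order)
    return RarefactionCurve(
        k=np.arange(1, n + 1),
        pan_mean=pans.mean(axis=0),
        pan_sd=pans.std(axis=0, ddof=0),
        core_mean=cores.mean(axis=0),
        core_sd=cores.std(axis=0, ddof=0),
        n_permutations=n_permutations,
        seed=seed,
    )


def pan_core_exhaustive(
    matrix: PresenceMatrix, require_intact: bool = False
) -> RarefactionCurve:
    """Exact rarefaction over all N! strain orderings (small N only)."""
    from itertools import permutations

    counted = matrix.cells >= (PRESENT if require_intact else PSEUDO)
    n = matrix.n_strains
    orders = list(permutations(range(n)))
    pans = np.empty((len(orders), n))
    cores = np.empty((len(orders), n))
    for p, order in enumerate(orders):
        pans[p], cores[p] = _pan_core_single_order(counted, np.array(order))
    return RarefactionCurve(
        k=np.arange(1, n + 1),
        pan_mean=pans.mean(axis=0),
        pan_sd=pans.std(axis=0, ddof=0),
        core_mean=cores.mean(axis=0),
        core_sd=cores.std(axis=0, ddof=0),
        n_permutations=len(orders),
        seed=0,
    )


def core_and_group_ogs(
    matrix: PresenceMatrix,
    group: Iterable[str],
    require_intact: bool = False,
) -> dict:
    """Core, group-unique and group-pangenome OG sets for a strain subset.

    ``core``: OGs non-absent (intact-only under ``require_intact``) in every
    group member.  ``unique_to_group``: OGs carried by at least one group
    member and absent from every non-member.  ``group_pan_size``: OGs carried
    by at least one group member.
    """
    group_ids = sorted(set(group))
    if not group_ids:
        raise ValueError("group must be non-empty")
    idx = matrix.strain_index(group_ids)
    others = np.setdiff1d(np.arange(matrix.n_strains), idx)
    counted = matrix.cells >= (PRESENT if require_intact else PSEUDO)
    nonabsent = matrix.cells >= PSEUDO
    og_arr = np.array(matrix.og_ids)
    core_mask = counted[idx].all(axis=0)
    in_group = nonabsent[idx].any(axis=0)
    out_group = nonabsent[others].any(axis=0) if others.size else np.zeros(matrix.n_ogs, bool)
    return {
        "core": set(og_arr[core_mask]),
        "unique_to_group": set(og_arr[in_group & ~out_group]),
        "group_pan_size": int(in_group.sum()),
    }


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    """Matrix TSV with cells {0, P, 1} (absent, pseudo, present)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["strain"] + matrix.og_ids)
        for i, strain in enumerate(matrix.strain_ids):
            writer.writerow([strain] + [_CODE_CELL[int(c)] for c in matrix.cells[i]])


def read_presence_matrix(path: str | Path) -> PresenceMatrix:
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader)
        og_ids = header[1:]
        strains: list[str] = []
        rows: list[list[int]] = []
        decode = {v: k for k, v in _CODE_CELL.items()}
        for row in reader:
            strains.append(row[0])
            rows.append([decode[c] for c in row[1:]])
    return PresenceMatrix(strains, og_ids, np.array(rows, dtype=np.int8))


def write_rarefaction_curve(curve: RarefactionCurve, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["k", "pan_mean", "pan_sd", "core_mean", "core_sd"])
        for i in range(len(curve.k)):
            writer.writerow(
                [
                    int(curve.k[i]),
                    f"{curve.pan_mean[i]:.6g}",
                    f"{curve.pan_sd[i]:.6g}",
                    f"{curve.core_mean[i]:.6g}",
                    f"{curve.core_sd[i]:.6g}",
                ]
            )
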