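"""Simulated strain collections with known ground truth.

The generator emulates the structure of a two-subspecies *Lactococcus
lactis* collection: a pure-birth (Yule) strain phylogeny whose first split
defines two clades ("subspecies"), core genes evolving by Jukes–Cantor
nucleotide substitution along the tree, clade- and niche-specific accessory
gene families, pseudogenization (premature stop codons truncating the
encoded protein) concentrated in one subclade — the analogue of the eroded
dairy *cremoris*-phenotype genomes — and plasmid gene families carried by a
subset of strains on contigs with elevated sequencing depth.

Everything is seeded: the same config yields byte-identical output files.
Accessory gene sequences are drawn unrelated to the core so that similarity
clustering separates them without tuning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .io_formats import (
    CoverageRecord,
    GeneRecord,
    StrainMeta,
    write_coverage_table,
    write_gene_fasta,
    write_strain_table,
)
from .traits import write_trait_table

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODON_TABLE = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
    return _CODON_TABLE


def _translate(nt: str) -> str:
    """Translate up to (excluding) the first stop codon."""
    table = _codon_table()
    aa = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in _STOPS:
            break
        aa.append(table.get(codon, "X"))
    return "".join(aa)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated collection.

    ``subst_rate`` is the expected number of substitutions per site over the
    full (unit) root-to-tip depth of the tree.  ``pseudo_fraction`` is the
    per-(strain, core OG) probability of pseudogenization within the eroded
    subclade.  ``dairy_fraction_other_clade`` is the fraction of the second
    clade assigned to the dairy niche, mimicking dairy-adapted ssp. *lactis*
    strains.
    """

    n_strains: int = 12
    seed: int = 0
    n_core_ogs: int = 30
    gene_length_bp: int = 900
    subst_rate: float = 0.05
    n_clade_markers: int = 3
    n_niche_markers: int = 3
    pseudo_clade: Optional[tuple[str, ...]] = None  # default: larger subclade of clade A
    pseudo_fraction: float = 0.3
    plasmid_strains: Optional[tuple[str, ...]] = None  # default: the dairy strains
    n_plasmid_ogs: int = 5
    coverage_multiplier: float = 5.0
    base_depth: float = 50.0
    depth_noise_sd: float = 0.0
    dairy_fraction_other_clade: float = 0.25
    min_internal_branch: float = 0.01  # reject near-zero internal branches

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("need at least 2 strains")
        if self.gene_length_bp % 3 != 0:
            raise ValueError("gene length must be a multiple of 3")
        if not 0 <= self.pseudo_fraction <= 1:
            raise ValueError("pseudo_fraction must be in [0, 1]")
        if self.coverage_multiplier < 1:
            raise ValueError("coverage multiplier must be >= 1")
        if self.subst_rate < 0:
            raise ValueError("substitution rate must be non-negative")


class _Lineage:
    __slots__ = ("birth", "end", "children", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.end: float | None = None
        self.children: list["_Lineage"] = []
        self.label: str | None = None


def simulate_tree(n: int, seed: int) -> dendropy.Tree:
    """Yule (pure-birth) topology, ultrametric, normalized to unit depth.

    Leaves are labeled s01, s02, ... in preorder; the two children of the
    root define the clade split used for the subspecies analogue.
    """
    if n < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    root = _Lineage(0.0)
    active = [_Lineage(0.0), _Lineage(0.0)]
    root.children = list(active)
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        parent.end = t
        parent.children = [_Lineage(t), _Lineage(t)]
        active.extend(parent.children)
    t_final = t + rng.exponential(1.0 / n)
    for leaf in active:
        leaf.end = t_final

    width = max(2, len(str(n)))
    counter = [0]

    def label_preorder(node: _Lineage) -> None:
        if not node.children:
            counter[0] += 1
            node.label = f"s{counter[0]:0{width}d}"
        for child in node.children:
            label_preorder(child)

    label_preorder(root)

    def newick(node: _Lineage) -> str:
        if not node.children:
            return node.label
        inner = ",".join(
            f"{newick(c)}:{(c.end - c.birth) / t_final:.9f}" for c in node.children
        )
        return f"({inner})"

    return dendropy.Tree.get(data=newick(root) + ";", schema="newick", rooting="force-rooted")


def jc_expected_p(total_branch_length: float, rate: float) -> float:
    """Expected p-distance between sequences separated by the given path length."""
    return 0.75 * (1.0 - np.exp(-4.0 * total_branch_length * rate / 3.0))


def _random_coding_sequence(rng: np.random.Generator, length_bp: int) -> str:
    codons = []
    while len(codons) * 3 < length_bp:
        codon = "".join(_BASES[b] for b in rng.integers(0, 4, size=3))
        if codon not in _STOPS:
            codons.append(codon)
    return "".join(codons)


def _mutate(rng: np.random.Generator, seq: str, p: float) -> str:
    """Jukes–Cantor site mutation avoiding in-frame stop codons."""
    if p <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < p)[0]
    for site in hits:
        current = arr[site].decode()
        choices = [b for b in _BASES if b != current]
        arr[site] = choices[int(rng.integers(3))].encode()
    # resample substitutions that created an in-frame stop
    for site in hits:
        codon_start = (site // 3) * 3
        for _ in range(10):
            codon = arr[codon_start : codon_start + 3].tobytes().decode()
            if codon not in _STOPS:
                break
            original = seq[site]
            choices = [b for b in _BASES if b != original]
            arr[site] = choices[int(rng.integers(3))].encode()
        else:
            arr[site] = seq[site].encode()
    return arr.tobytes().decode()


def evolve_sequences(
    tree: dendropy.Tree,
    n_genes: int,
    length_bp: int,
    rate: float,
    seed: int,
    gene_prefix: str = "cog",
) -> dict[str, dict[str, str]]:
    """Evolve ``n_genes`` unlinked genes along the tree under Jukes–Cantor.

    Per-site substitution probability on a branch of length ``d`` is
    ``3/4 (1 - exp(-4 d rate / 3))``.  Root sequences are uniform random
    sense codons; substitutions creating stop codons are resampled.
    Returns gene_id -> strain -> nucleotide sequence.
    """
    if length_bp % 3 != 0:
        raise ValueError("gene length must be a multiple of 3")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_genes)))
    genes: dict[str, dict[str, str]] = {}
    for g in range(n_genes):
        gene_id = f"{gene_prefix}{g + 1:0{width}d}"
        root_seq = _random_coding_sequence(rng, length_bp)
        per_strain: dict[str, str] = {}

        def descend(node, seq: str) -> None:
            for child in node.child_nodes():
                p = jc_expected_p(child.edge.length or 0.0, rate)
                child_seq = _mutate(rng, seq, p)
                if child.is_leaf():
                    per_strain[child.taxon.label] = child_seq
                else:
                    descend(child, child_seq)

        descend(tree.seed_node, root_seq)
        genes[gene_id] = per_strain
    return genes


@dataclass
class GroundTruth:
    """Everything the pipeline is supposed to recover."""

    tree_newick: str
    clades: dict[str, str]  # strain -> A | B
    niche: dict[str, str]  # strain -> dairy | non_dairy
    clade_marker_families: dict[str, list[str]]  # family -> carrier strains
    niche_marker_families: dict[str, list[str]]
    plasmid_families: list[str]
    pseudogenized: list[tuple[str, str]]  # (strain, family)
    families: dict[str, list[str]]  # family -> member gene ids

    def to_json(self) -> str:
        payload = {
            "tree_newick": self.tree_newick,
            "clades": self.clades,
            "niche": self.niche,
            "clade_marker_families": self.clade_marker_families,
            "niche_marker_families": self.niche_marker_families,
            "plasmid_families": self.plasmid_families,
            "pseudogenized": [list(p) for p in self.pseudogenized],
            "families": self.families,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SimulatedDataset:
    config: SimConfig
    tree: dendropy.Tree
    truth: GroundTruth
    strains: list[str]
    genes: dict[str, list[GeneRecord]]  # strain -> gene records
    coverage: list[CoverageRecord]
    genotype_labels: dict[str, str]  # strain -> A/B (clade analogue of genotype)
    niche_labels: dict[str, str]  # strain -> A (dairy) / B (non-dairy)

    @property
    def all_genes(self) -> list[GeneRecord]:
        return [g for strain in self.strains for g in self.genes[strain]]


def _clades(tree: dendropy.Tree) -> tuple[list[str], list[str]]:
    children = tree.seed_node.child_nodes()
    side_a = sorted(leaf.taxon.label for leaf in children[0].leaf_iter())
    side_b = sorted(
        leaf.taxon.label
        for child in children[1:]
        for leaf in child.leaf_iter()
    )
    if len(side_a) > len(side_b):
        side_a, side_b = side_b, side_a
    return side_a, side_b


def _larger_subclade(tree: dendropy.Tree, clade: Sequence[str]) -> list[str]:
    """Leaves under the heavier child of the clade's ancestral node."""
    mrca = tree.mrca(taxon_labels=list(clade))
    children = mrca.child_nodes()
    if not children:
        return list(clade)
    subclades = [sorted(l.taxon.label for l in c.leaf_iter()) for c in children]
    subclades.sort(key=lambda s: (-len(s), s))
    return subclades[0]


def simulate(config: SimConfig) -> SimulatedDataset:
    """Generate a full strain collection with planted structure."""
    rng = np.random.default_rng(config.seed)
    # Reject degenerate topologies (deterministically, by redrawing with a
    # derived seed): the clade split must leave >= 2 strains on each side to
    # be usable as a binary trait, and internal branches must exceed
    # min_internal_branch — a branch carrying essentially zero expected
    # substitutions is unresolvable by any method and does not represent the
    # well-separated clades being emulated.
    for attempt in range(1000):
        tree = simulate_tree(config.n_strains, config.seed + 100_003 * attempt)
        clade_a, clade_b = _clades(tree)
        internal = [
            e.length
            for e in tree.preorder_edge_iter()
            if e.length is not None
            and e.head_node.parent_node is not None
            and not e.head_node.is_leaf()
        ]
        clades_ok = config.n_strains < 4 or min(len(clade_a), len(clade_b)) >= 2
        branches_ok = not internal or min(internal) >= config.min_internal_branch
        if clades_ok and branches_ok:
            break
    strains = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    clades = {s: ("A" if s in clade_a else "B") for s in strains}

    # niche: the first clade is entirely dairy (the cremoris analogue); a
    # configurable fraction of the other clade is dairy-adapted as well
    n_dairy_b = int(round(config.dairy_fraction_other_clade * len(clade_b)))
    dairy_b = sorted(rng.choice(clade_b, size=n_dairy_b, replace=False).tolist()) if n_dairy_b else []
    niche = {
        s: ("dairy" if s in clade_a or s in dairy_b else "non_dairy") for s in strains
    }
    dairy_strains = sorted(s for s in strains if niche[s] == "dairy")

    pseudo_clade = (
        list(config.pseudo_clade)
        if config.pseudo_clade is not None
        else _larger_subclade(tree, clade_a)
    )
    if not set(pseudo_clade) <= set(strains):
        raise ValueError("pseudo_clade contains unknown strains")
    plasmid_strains = (
        list(config.plasmid_strains)
        if config.plasmid_strains is not None
        else dairy_strains
    )
    if not set(plasmid_strains) <= set(strains):
        raise ValueError("plasmid_strains contains unknown strains")

    # core genes evolve along the tree; accessory families are unrelated
    core = evolve_sequences(
        tree, config.n_core_ogs, config.gene_length_bp, config.subst_rate,
        seed=int(rng.integers(2**31)), gene_prefix="cog",
    )

    accessory: dict[str, tuple[list[str], str]] = {}  # family -> (carriers, seq)

    def plant_family(name: str, carriers: Sequence[str]) -> None:
        accessory[name] = (sorted(carriers), _random_coding_sequence(rng, config.gene_length_bp))

    for m in range(config.n_clade_markers):
        plant_family(f"mka{m + 1:02d}", clade_a)
        plant_family(f"mkb{m + 1:02d}", clade_b)
    for m in range(config.n_niche_markers):
        plant_family(f"nic{m + 1:02d}", dairy_strains)
    plasmid_families = [f"pls{m + 1:02d}" for m in range(config.n_plasmid_ogs)]
    for name in plasmid_families:
        plant_family(name, plasmid_strains)

    # pseudogenization: premature stop truncating the protein to 30-70%
    pseudogenized: list[tuple[str, str]] = []
    pseudo_sites: dict[tuple[str, str], float] = {}
    for strain in sorted(pseudo_clade):
        for family in sorted(core):
            if rng.random() < config.pseudo_fraction:
                pseudogenized.append((strain, family))
                pseudo_sites[(strain, family)] = rng.uniform(0.3, 0.7)

    def maybe_truncate(strain: str, family: str, nt: str) -> str:
        u = pseudo_sites.get((strain, family))
        if u is None:
            return nt
        n_codons = len(nt) // 3
        stop_codon = min(max(int(u * n_codons), 1), n_codons - 2)
        return nt[: stop_codon * 3] + "TAA" + nt[(stop_codon + 1) * 3 :]

    genes: dict[str, list[GeneRecord]] = {}
    families: dict[str, list[str]] = {f: [] for f in list(core) + list(accessory)}
    for strain in strains:
        records: list[GeneRecord] = []
        pos = 0
        for family in sorted(core):
            nt = maybe_truncate(strain, family, core[family][strain])
            gene_id = f"{family}_{strain}"
            records.append(
                GeneRecord(
                    gene_id=gene_id, strain_id=strain, contig_id="c1",
                    start=pos, end=pos + len(nt), strand="+",
                    nt_seq=nt, aa_seq=_translate(nt),
                )
            )
            families[family].append(gene_id)
            pos += len(nt) + 100
        for family in sorted(accessory):
            carriers, seq = accessory[family]
            if strain not in carriers:
                continue
            contig = "p1" if family in plasmid_families else "c1"
            gene_id = f"{family}_{strain}"
            records.append(
                GeneRecord(
                    gene_id=gene_id, strain_id=strain, contig_id=contig,
                    start=pos, end=pos + len(seq), strand="+",
                    nt_seq=seq, aa_seq=_translate(seq),
                )
            )
            families[family].append(gene_id)
            pos += len(seq) + 100
        genes[strain] = records

    def depth(base: float) -> float:
        if config.depth_noise_sd > 0:
            return max(float(rng.normal(base, config.depth_noise_sd)), 0.0)
        return base

    coverage: list[CoverageRecord] = []
    for strain in strains:
        coverage.append(
            CoverageRecord(strain_id=strain, contig_id="c1", length_bp=2_000_000,
                           mean_depth=depth(config.base_depth))
        )
        if strain in plasmid_strains:
            coverage.append(
                CoverageRecord(strain_id=strain, contig_id="p1", length_bp=50_000,
                               mean_depth=depth(config.base_depth * config.coverage_multiplier))
            )

    tree_newick = tree.as_string(
        schema="newick", real_value_format_specifier=".9f", suppress_rooting=True
    ).strip()
    truth = GroundTruth(
        tree_newick=tree_newick,
        clades=clades,
        niche=niche,
        clade_marker_families={
            f: sorted(accessory[f][0]) for f in accessory if f.startswith("mk")
        },
        niche_marker_families={
            f: sorted(accessory[f][0]) for f in accessory if f.startswith("nic")
        },
        plasmid_families=plasmid_families,
        pseudogenized=sorted(pseudogenized),
        families={f: sorted(g) for f, g in families.items()},
    )
    genotype_labels = dict(clades)
    niche_labels = {s: ("A" if niche[s] == "dairy" else "B") for s in strains}
    return SimulatedDataset(
        config=config, tree=tree, truth=truth, strains=strains, genes=genes,
        coverage=coverage, genotype_labels=genotype_labels, niche_labels=niche_labels,
    )


def emit_dataset(dataset: SimulatedDataset, outdir: str | Path) -> list[Path]:
    """Write the full dataset to disk; byte-identical for identical configs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for strain in dataset.strains:
        nt_path = out / f"{strain}.fna"
        aa_path = out / f"{strain}.faa"
        write_gene_fasta(dataset.genes[strain], nt_path, aa_path)
        written += [nt_path, aa_path]

    metas = [
        StrainMeta(
            strain_id=s,
            genotype="cremoris" if dataset.genotype_labels[s] == "A" else "lactis",
            phenotype="unknown",
            origin="simulated",
            genome_size_mb=round(
                sum(len(g.nt_seq) for g in dataset.genes[s]) / 1e6, 4
            ),
            protein_count=len(dataset.genes[s]),
            plasmid_kb=50.0 if any(g.contig_id == "p1" for g in dataset.genes[s]) else 0.0,
            assembly_status="draft",
            niche=dataset.truth.niche[s],
        )
        for s in dataset.strains
    ]
    table_path = out / "strain_table.tsv"
    write_strain_table(metas, table_path)
    written.append(table_path)

    coverage_path = out / "coverage.tsv"
    write_coverage_table(dataset.coverage, coverage_path)
    written.append(coverage_path)

    genotype_path = out / "trait_genotype.tsv"
    write_trait_table(dataset.genotype_labels, genotype_path)
    niche_path = out / "trait_niche.tsv"
    write_trait_table(dataset.niche_labels, niche_path)
    written += [genotype_path, niche_path]

    tree_path = out / "true_tree.nwk"
    tree_path.write_text(dataset.truth.tree_newick + "\n", encoding="utf-8")
    truth_path = out / "ground_truth.json"
    truth_path.write_text(dataset.truth.to_json() + "\n", encoding="utf-8")
    written += [tree_path, truth_path]

    manifest_path = out / "manifest.txt"
    manifest_path.write_text(
        "\n".join(p.name for p in written) + "\n", encoding="utf-8"
    )
    written.append(manifest_path)
    return written
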