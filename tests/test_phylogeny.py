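"""Supermatrix assembly, p-distances, neighbor joining and tree utilities.

NJ correctness is checked two ways: exactness on additive matrices derived
from simulated trees (topology via RF, branch lengths via the induced
patristic metric), and topological agreement with scikit-bio's independent
NJ implementation on random perturbed matrices.
"""

import dendropy
import numpy as np
import pytest

from lactopan.phylogeny import (
    build_supermatrix,
    leaf_labels,
    nj_tree,
    p_distance_matrix,
    read_newick,
    reroot,
    rf_distance,
    select_single_copy_core,
    tree_distance_matrix,
    write_newick,
    write_supermatrix,
)
from lactopan.synthetic_data import simulate_tree
from conftest import make_og


# --------------------------------------------------------------------- core


def test_select_single_copy_core():
    strains = ["sA", "sB", "sC"]
    ogs = [
        make_og("OG_1", {s: [f"{s}_1"] for s in strains}, strains=strains),
        make_og("OG_2", {"sA": ["a"], "sB": ["b"]}, strains=strains),
        make_og("OG_3", {"sA": ["a1", "a2"], "sB": ["b"], "sC": ["c"]}, strains=strains),
        make_og("OG_4", {s: [f"{s}_4"] for s in strains}, pseudo={"sB"}, strains=strains),
    ]
    selected = select_single_copy_core(ogs, strains)
    assert [og.og_id for og in selected] == ["OG_1", "OG_4"]  # pseudo copies count

    with pytest.raises(ValueError, match="single-copy"):
        select_single_copy_core([ogs[1]], strains)


# -------------------------------------------------------------- supermatrix


def oracle_variable_columns(block: dict[str, str]) -> list[int]:
    """Independent per-block scan for gap-free variable columns."""
    strains = sorted(block)
    cols = []
    for i in range(len(block[strains[0]])):
        column = {block[s][i] for s in strains}
        if column <= set("ACGT") and len(column) >= 2:
            cols.append(i)
    return cols


def test_supermatrix_trivial_cases():
    sm = build_supermatrix({"og1": {"sA": "ACGT", "sB": "ACGT"}})
    assert sm.total_columns == 0

    sm = build_supermatrix({"og1": {"sA": "ACGT", "sB": "ACGA"}})
    assert sm.total_columns == 1
    assert sm.sequences == {"sA": "T", "sB": "A"}
    assert sm.provenance == [("og1", 3)]


def test_supermatrix_skips_gap_and_ambiguity_columns():
    sm = build_supermatrix({"og1": {"sA": "A-GTN", "sB": "ACCTA"}})
    # col0 invariant, col1 gapped, col2 variable, col3 invariant, col4 ambiguous
    assert sm.provenance == [("og1", 2)]


def test_supermatrix_three_blocks_matches_column_scan_oracle():
    rng = np.random.default_rng(2)
    strains = [f"s{i}" for i in range(4)]
    blocks = {}
    for og in ["og1", "og2", "og3"]:
        base = rng.choice(list("ACGT"), size=30)
        rows = {}
        for s in strains:
            seq = base.copy()
            hits = rng.random(30) < 0.2
            seq[hits] = rng.choice(list("ACGT"), size=int(hits.sum()))
            rows[s] = "".join(seq)
        blocks[og] = rows
    sm = build_supermatrix(blocks)
    expected = [
        (og, col) for og in sorted(blocks) for col in oracle_variable_columns(blocks[og])
    ]
    assert sm.provenance == expected
    # row order invariance: same matrix regardless of dict insertion order
    reversed_blocks = {og: dict(reversed(list(rows.items()))) for og, rows in reversed(list(blocks.items()))}
    assert build_supermatrix(reversed_blocks).sequences == sm.sequences


def test_supermatrix_errors(tmp_path):
    with pytest.raises(ValueError, match="strain set"):
        build_supermatrix({"og1": {"sA": "AC"}, "og2": {"sB": "AC"}})
    with pytest.raises(ValueError, match="equal length"):
        build_supermatrix({"og1": {"sA": "AC", "sB": "ACG"}})

    sm = build_supermatrix({"og1": {"sA": "ACGT", "sB": "ACGA"}})
    write_supermatrix(sm, tmp_path / "sm.phy", tmp_path / "cols.tsv")
    assert (tmp_path / "sm.phy").read_text().splitlines()[0] == "2 1"


def test_p_distance_matrix():
    sm = build_supermatrix(
        {"og1": {"sA": "AAAA", "sB": "AAAT", "sC": "TTTT"}}
    )
    # variable columns: all 4 (A vs T); sA-sB differ at 1 of 4
    d = p_distance_matrix(sm)
    assert d[0, 1] == pytest.approx(0.25)
    assert d[0, 2] == pytest.approx(1.0)
    assert np.allclose(np.diag(d), 0)

    with pytest.raises(ValueError, match="no variable"):
        p_distance_matrix(build_supermatrix({"og1": {"sA": "AC", "sB": "AC"}}))


# ----------------------------------------------------------------------- NJ


def test_nj_two_taxa_splits_distance():
    tree = nj_tree(np.array([[0.0, 0.4], [0.4, 0.0]]), ["A", "B"])
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths["A"] == pytest.approx(0.2)
    assert lengths["B"] == pytest.approx(0.2)


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = nj_tree(d, ["A", "B", "C"])
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_nj_four_taxa_recovers_known_tree():
    # additive distances from tree ((A:1,B:2):1,(C:3,D:4)) with internal 1
    labels = ["A", "B", "C", "D"]
    d = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )
    tree = nj_tree(d, labels)
    truth = dendropy.Tree.get(
        data="((A:1,B:2):1,C:3,D:4);", schema="newick",
        taxon_namespace=tree.taxon_namespace,
    )
    assert rf_distance(tree, truth) == 0
    _, inferred_d = tree_distance_matrix(tree)
    np.testing.assert_allclose(inferred_d, d, atol=1e-9)


@pytest.mark.parametrize("tree_seed", range(5))
def test_nj_exact_on_additive_matrices_from_simulated_trees(tree_seed):
    truth = simulate_tree(8, seed=tree_seed)
    labels, d = tree_distance_matrix(truth)
    inferred = nj_tree(d, labels)
    truth_same_ns = dendropy.Tree.get(
        data=truth.as_string(schema="newick"), schema="newick",
        taxon_namespace=inferred.taxon_namespace,
    )
    assert rf_distance(inferred, truth_same_ns) == 0
    _, d_inferred = tree_distance_matrix(inferred)
    np.testing.assert_allclose(d_inferred, d, atol=1e-9)


def test_nj_agrees_with_scikit_bio_on_noisy_matrices():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(9)
    for _ in range(3):
        truth = simulate_tree(7, seed=int(rng.integers(1000)))
        labels, d = tree_distance_matrix(truth)
        noise = rng.uniform(0, 0.02, size=d.shape)
        d_noisy = d + noise
        d_noisy = (d_noisy + d_noisy.T) / 2.0
        d_noisy = np.maximum(d_noisy, d_noisy.T)  # exact float symmetry
        np.fill_diagonal(d_noisy, 0.0)
        ours = nj_tree(d_noisy, labels)
        ref = skbio.tree.nj(skbio.DistanceMatrix(d_noisy, ids=labels))
        ref_dp = dendropy.Tree.get(
            data=str(ref), schema="newick", taxon_namespace=ours.taxon_namespace
        )
        assert rf_distance(ours, ref_dp) == 0


def test_nj_rejects_bad_input():
    with pytest.raises(ValueError, match="symmetric"):
        nj_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ["A", "B"])


# ------------------------------------------------------------------ reroot


def _quartet():
    return nj_tree(
        np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        ),
        ["A", "B", "C", "D"],
    )


def test_reroot_on_single_outgroup_leaf():
    rooted = reroot(_quartet(), "D")
    children = rooted.seed_node.child_nodes()
    sides = [sorted(l.taxon.label for l in c.leaf_iter()) for c in children]
    assert ["D"] in sides
    # root splits D's pendant branch equally
    d_node = next(c for c, s in zip(children, sides) if s == ["D"])
    other = next(c for c, s in zip(children, sides) if s != ["D"])
    assert d_node.edge.length == pytest.approx(other.edge.length)


def test_reroot_preserves_unrooted_topology():
    unrooted = _quartet()
    rooted = reroot(unrooted, {"C", "D"})
    back = dendropy.Tree.get(
        data=rooted.as_string(schema="newick"), schema="newick",
        taxon_namespace=unrooted.taxon_namespace,
    )
    assert rf_distance(unrooted, back) == 0


def test_reroot_errors():
    tree = _quartet()
    with pytest.raises(ValueError, match="every leaf"):
        reroot(tree, {"A", "B", "C", "D"})
    with pytest.raises(ValueError, match="monophyletic"):
        reroot(tree, {"A", "C"})  # A and C sit on opposite sides


# ---------------------------------------------------------------------- RF


def oracle_bipartitions(tree: dendropy.Tree) -> set:
    """Enumerate non-trivial splits by brute force over internal edges."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    splits = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is None or edge.head_node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        pair = frozenset({below, leaves - below})
        if min(len(s) for s in pair) >= 2:
            splits.add(pair)
    return splits


def test_rf_identical_and_conflicting_quartets():
    ns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick", taxon_namespace=ns)
    t2 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick", taxon_namespace=ns)
    t3 = dendropy.Tree.get(data="((A,C),(B,D));", schema="newick", taxon_namespace=ns)
    assert rf_distance(t1, t2) == 0
    assert rf_distance(t1, t3) == 2
    with pytest.raises(ValueError, match="leaf sets"):
        rf_distance(t1, dendropy.Tree.get(data="((A,B),(C,E));", schema="newick"))


@pytest.mark.parametrize("pair_seed", range(4))
def test_rf_matches_bipartition_enumeration_oracle(pair_seed):
    t1 = simulate_tree(8, seed=pair_seed)
    t2_raw = simulate_tree(8, seed=pair_seed + 50)
    t2 = dendropy.Tree.get(
        data=t2_raw.as_string(schema="newick"), schema="newick",
        taxon_namespace=t1.taxon_namespace,
    )
    expected = len(oracle_bipartitions(t1) ^ oracle_bipartitions(t2))
    assert rf_distance(t1, t2) == expected


def test_newick_round_trip(tmp_path):
    tree = _quartet()
    path = tmp_path / "tree.nwk"
    write_newick(tree, path)
    loaded = read_newick(path)
    loaded.migrate_taxon_namespace(tree.taxon_namespace)
    assert rf_distance(tree, loaded) == 0
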