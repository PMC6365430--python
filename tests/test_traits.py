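"""Gene-trait matching: discrimination scores, permutation p-values,
leave-one-out prediction, pseudogene calling and heatmap ordering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import matrix_from_rows
from lactopan.io_formats import GeneRecord
from lactopan.pangenome import PresenceMatrix
from lactopan.traits import (
    call_pseudogenes,
    heatmap_order,
    loo_predict,
    numeric_encoding,
    og_trait_score,
    rank_discriminating_ogs,
    read_trait_table,
    select_marker_set,
    write_trait_results,
    write_trait_table,
)


def _labels(a_strains, b_strains):
    labels = {s: "A" for s in a_strains}
    labels.update({s: "B" for s in b_strains})
    return labels


def test_perfect_split_scores_one():
    states = {"a1": "present", "a2": "present", "b1": "absent", "b2": "absent"}
    res = og_trait_score(states, _labels(["a1", "a2"], ["b1", "b2"]))
    assert res["score"] == 1.0
    assert res["orientation"] == "present->A"
    assert res["n_pseudo_neutral"] == 0


def test_constant_og_bounded_at_half_for_balanced_classes():
    states = {s: "present" for s in ["a1", "a2", "b1", "b2"]}
    res = og_trait_score(states, _labels(["a1", "a2"], ["b1", "b2"]))
    assert res["score"] == pytest.approx(0.5)  # 1 - min(|A|,|B|)/n


def test_pseudo_cells_are_neutral():
    states = {"a1": "present", "a2": "present", "b1": "absent", "b2": "pseudo"}
    res = og_trait_score(states, _labels(["a1", "a2"], ["b1", "b2"]))
    assert res["score"] == 1.0
    assert res["n_pseudo_neutral"] == 1


def test_score_invariant_under_label_swap():
    rng = np.random.default_rng(0)
    strains = [f"s{i}" for i in range(8)]
    for _ in range(20):
        states = {
            s: rng.choice(["present", "pseudo", "absent"]).item() for s in strains
        }
        labels = _labels(strains[:4], strains[4:])
        swapped = {s: ("A" if l == "B" else "B") for s, l in labels.items()}
        r1 = og_trait_score(states, labels)
        r2 = og_trait_score(states, swapped)
        assert r1["score"] == pytest.approx(r2["score"])
        assert r1["n_pseudo_neutral"] == r2["n_pseudo_neutral"]


@settings(max_examples=40, deadline=None)
@given(st.data())
def test_adding_pseudo_never_decreases_score(data):
    rng_states = data.draw(
        st.lists(st.sampled_from(["present", "absent"]), min_size=6, max_size=10)
    )
    strains = [f"s{i}" for i in range(len(rng_states))]
    half = len(strains) // 2
    labels = _labels(strains[:half], strains[half:])
    states = dict(zip(strains, rng_states))
    base = og_trait_score(states, labels)["score"]
    victim = data.draw(st.sampled_from(strains))
    states[victim] = "pseudo"
    assert og_trait_score(states, labels)["score"] >= base - 1e-12


def test_score_requires_two_strains_per_class():
    states = {"a1": "present", "b1": "absent", "b2": "absent"}
    with pytest.raises(ValueError, match="2 strains per class"):
        og_trait_score(states, _labels(["a1"], ["b1", "b2"]))


def test_planted_marker_ranks_first_with_minimal_p():
    """A perfect marker among random OGs gets rank 1, score 1, p = 1/(B+1)."""
    rng = np.random.default_rng(4)
    n = 20
    strains = [f"s{i:02d}" for i in range(n)]
    labels = _labels(strains[:10], strains[10:])
    cells = rng.integers(0, 3, size=(n, 200)).astype(np.int8)
    cells[:, cells.max(axis=0) == 0] = 2
    marker = np.array([2] * 10 + [0] * 10, dtype=np.int8)
    cells = np.column_stack([cells, marker])
    matrix = PresenceMatrix(strains, [f"og{j:03d}" for j in range(200)] + ["marker"], cells)
    results = rank_discriminating_ogs(matrix, labels, n_perm=999, seed=1)
    assert results[0].og_id == "marker"
    assert results[0].score == 1.0
    assert results[0].p_perm == pytest.approx(1 / 1000)
    # with 201 tests and a permutation floor of 1/1000, BH cannot go below
    # p * m / 1; the marker still carries the smallest q-value of the run
    assert results[0].q_bh == pytest.approx(0.201)
    assert results[0].q_bh == min(r.q_bh for r in results)


def test_permutation_p_enumerated_for_constant_og():
    """A constant OG's permuted score never changes, so p must be 1."""
    strains = [f"s{i}" for i in range(6)]
    matrix = matrix_from_rows({s: "1" for s in strains}, ["og1"])
    labels = _labels(strains[:3], strains[3:])
    results = rank_discriminating_ogs(matrix, labels, n_perm=99, seed=0)
    assert results[0].score == pytest.approx(0.5)
    assert results[0].p_perm == pytest.approx(1.0)


def test_bh_qvalues_monotone_in_p_rank():
    rng = np.random.default_rng(8)
    n = 12
    strains = [f"s{i:02d}" for i in range(n)]
    cells = rng.integers(0, 3, size=(n, 60)).astype(np.int8)
    cells[:, cells.max(axis=0) == 0] = 2
    matrix = PresenceMatrix(strains, [f"og{j}" for j in range(60)], cells)
    results = rank_discriminating_ogs(
        matrix, _labels(strains[: n // 2], strains[n // 2 :]), n_perm=99, seed=2
    )
    by_p = sorted(results, key=lambda r: r.p_perm)
    qs = [r.q_bh for r in by_p]
    assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))
    assert all(0 <= r.q_bh <= 1 for r in results)


def test_loo_perfect_markers_zero_error(small_dataset, small_pipeline):
    assert small_pipeline.loo["genotype"]["error_rate"] == 0.0
    assert small_pipeline.loo["niche"]["error_rate"] == 0.0


def test_loo_random_markers_near_chance():
    rng = np.random.default_rng(15)
    errors = []
    n = 16
    strains = [f"s{i:02d}" for i in range(n)]
    labels = _labels(strains[: n // 2], strains[n // 2 :])
    for _ in range(20):
        cells = rng.integers(0, 3, size=(n, 30)).astype(np.int8)
        cells[:, cells.max(axis=0) == 0] = 2
        matrix = PresenceMatrix(strains, [f"og{j}" for j in range(30)], cells)
        res = loo_predict(matrix, labels, matrix.og_ids[:5])
        errors.append(res["error_rate"])
    assert abs(np.mean(errors) - 0.5) <= 0.15


def test_loo_validation():
    strains = ["a1", "a2", "b1", "b2"]
    matrix = matrix_from_rows({s: "1" for s in strains}, ["og1"])
    with pytest.raises(ValueError, match="at least one"):
        loo_predict(matrix, _labels(["a1", "a2"], ["b1", "b2"]), [])
    with pytest.raises(ValueError, match="2 strains per class"):
        loo_predict(matrix, _labels(["a1"], ["b1", "b2", "a2"][:2]), ["og1"])


def _gene(gene_id, aa, intact="intact"):
    return GeneRecord(gene_id, "sA", "c1", 0, 3 * len(aa) + 3, "+",
                      nt_seq="", aa_seq=aa, intact=intact)


def test_call_pseudogenes_length_rule():
    full = "M" + "K" * 99
    members = [_gene("g1", full), _gene("g2", full), _gene("g3", full[:50])]
    updated = call_pseudogenes({"og1": members}, length_fraction=0.8)
    states = {g.gene_id: g.intact for g in updated["og1"]}
    assert states == {"g1": "intact", "g2": "intact", "g3": "pseudo"}


def test_call_pseudogenes_small_og_untouched_and_stops_always_flagged():
    full = "M" + "K" * 59
    updated = call_pseudogenes({"og1": [_gene("g1", full), _gene("g2", full[:20])]})
    assert all(g.intact == "intact" for g in updated["og1"])  # no median for n=2

    updated = call_pseudogenes({"og1": [_gene("g1", "MK*TLL"), _gene("g2", "MKTTLL")]})
    assert {g.gene_id: g.intact for g in updated["og1"]}["g1"] == "pseudo"


def test_call_pseudogenes_full_length_member_stays_intact():
    full = "M" + "K" * 99
    members = [_gene(f"g{i}", full) for i in range(4)]
    updated = call_pseudogenes({"og1": members})
    assert all(g.intact == "intact" for g in updated["og1"])


# ----------------------------------------------------------------- heatmap


def oracle_complete_linkage(d):
    """Brute-force agglomeration: at every step enumerate all cluster pairs and
    take the smallest complete-linkage distance, smallest indices first."""
    clusters = {i: (i,) for i in range(d.shape[0])}
    merges = []
    next_id = d.shape[0]
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            height = max(d[a, b] for a in clusters[i] for b in clusters[j])
            key = (height, i, j)
            if best is None or key < best:
                best = key
        height, i, j = best
        merges.append((i, j, height))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return merges


def test_heatmap_merge_sequence_matches_brute_force():
    rng = np.random.default_rng(21)
    data = rng.random((6, 4))
    from scipy.spatial.distance import pdist, squareform

    for metric, scipy_metric in [("manhattan", "cityblock"), ("euclidean", "euclidean")]:
        result = heatmap_order(data, metric=metric)
        d = squareform(pdist(data, metric=scipy_metric))
        expected = oracle_complete_linkage(d)
        assert [(i, j) for i, j, _ in result["merges"]] == [
            (i, j) for i, j, _ in expected
        ]
        for (_, _, h1), (_, _, h2) in zip(result["merges"], expected):
            assert h1 == pytest.approx(h2)


def test_heatmap_identical_rows_adjacent():
    data = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 1.0], [0.5, 0.5, 0.9]])
    order = heatmap_order(data, metric="manhattan")["leaf_order"]
    pos = {item: k for k, item in enumerate(order)}
    assert abs(pos[0] - pos[2]) == 1  # duplicate rows 0 and 2 end up side by side


def test_heatmap_manhattan_distance_value():
    data = np.array([[0.0, 1.0, 1.0], [1.0, 1.0, 0.0]])
    result = heatmap_order(data, metric="manhattan")
    assert result["merges"][0][2] == pytest.approx(2.0)


def test_heatmap_rejects_unknown_metric_and_tiny_input():
    with pytest.raises(ValueError, match="metric"):
        heatmap_order(np.zeros((3, 2)), metric="cosine")
    with pytest.raises(ValueError, match="at least 2"):
        heatmap_order(np.zeros((1, 2)))


def test_numeric_encoding_and_marker_selection():
    matrix = matrix_from_rows({"s1": "1P0", "s2": "011"}, ["a", "b", "c"])
    enc = numeric_encoding(matrix)
    np.testing.assert_allclose(enc, [[1.0, 0.5, 0.0], [0.0, 1.0, 1.0]])

    from lactopan.traits import OgTraitResult

    perfect = OgTraitResult("x", 1.0, "present->A", 0.01, 0.02, 0)
    lesser = OgTraitResult("y", 0.8, "present->A", 0.2, 0.3, 0)
    assert select_marker_set([perfect, lesser]) == [perfect]
    assert select_marker_set([lesser], top_n=1) == [lesser]


def test_trait_table_round_trip(tmp_path):
    labels = {"s1": "A", "s2": "B", "s3": "missing"}
    path = tmp_path / "trait.tsv"
    write_trait_table(labels, path)
    assert read_trait_table(path) == labels
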