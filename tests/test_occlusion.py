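"""Pair matching, distances, fold changes, population shift, class tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from naristat import (
    NormMatrix,
    PCAEmbedding,
    classify_or_sets,
    compare_groups,
    match_pairs,
    or_population_shift,
    pairwise_euclidean,
    pairwise_gene_logfc,
    per_or_summary,
)


def _meta(cells, naris):
    return pd.DataFrame(
        {
            "cell_id": cells,
            "naris": naris,
            "condition": "NA",
            "sample": "s",
            "genotype": "WT",
        }
    )


def _assign(cells, ors, confident=True):
    return pd.DataFrame(
        {
            "cell_id": cells,
            "assigned_or": ors,
            "max_count": 10,
            "second_count": 0,
            "tie": False,
            "confident": confident,
        }
    )


class TestMatchPairs:
    def test_three_by_two_gives_six_pairs(self):
        cells = [f"c{i}" for i in range(5)]
        pairs = match_pairs(
            _assign(cells, ["OrA"] * 5),
            _meta(cells, ["open", "open", "open", "closed", "closed"]),
        )
        assert len(pairs) == 6
        assert (pairs["or_id"] == "OrA").all()

    def test_or_missing_one_naris_is_skipped(self):
        cells = ["a", "b", "c", "d"]
        pairs = match_pairs(
            _assign(cells, ["OrA", "OrA", "OrB", "OrB"]),
            _meta(cells, ["open", "closed", "open", "open"]),
        )
        assert set(pairs["or_id"]) == {"OrA"}

    def test_no_matchable_ors_is_an_error(self):
        cells = ["a", "b"]
        with pytest.raises(ValueError, match="no matchable ORs"):
            match_pairs(_assign(cells, ["OrA", "OrB"]), _meta(cells, ["open", "open"]))

    def test_total_pairs_match_brute_force(self, rng):
        cells = [f"c{i}" for i in range(60)]
        ors = rng.choice(["OrA", "OrB", "OrC"], size=60)
        naris = rng.choice(["open", "closed"], size=60)
        assignments = _assign(cells, ors)
        meta = _meta(cells, naris)
        pairs = match_pairs(assignments, meta)
        expected = 0
        for or_id in ["OrA", "OrB", "OrC"]:
            n_o = int(((ors == or_id) & (naris == "open")).sum())
            n_c = int(((ors == or_id) & (naris == "closed")).sum())
            expected += n_o * n_c
        assert len(pairs) == expected

    def test_cap_subsamples_reproducibly(self):
        n = 40
        cells = [f"o{i}" for i in range(n)] + [f"x{i}" for i in range(n)]
        assignments = _assign(cells, ["OrA"] * 2 * n)
        meta = _meta(cells, ["open"] * n + ["closed"] * n)
        a = match_pairs(assignments, meta, max_pairs_per_or=1000, seed=5)
        b = match_pairs(assignments, meta, max_pairs_per_or=1000, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 1000
        c = match_pairs(assignments, meta, max_pairs_per_or=1000, seed=6)
        assert not a.equals(c)

    def test_nonconfident_cells_excluded(self):
        cells = ["a", "b", "c"]
        assignments = _assign(cells, ["OrA"] * 3, confident=[True, True, False])
        pairs = match_pairs(assignments, _meta(cells, ["open", "closed", "closed"]))
        assert len(pairs) == 1


class TestPairwiseEuclidean:
    def test_identical_coordinates_give_zero(self):
        emb = PCAEmbedding(["a", "b"], np.zeros((2, 3)), np.zeros(3))
        pairs = pd.DataFrame({"or_id": ["O"], "open_cell": ["a"], "closed_cell": ["b"]})
        assert pairwise_euclidean(emb, pairs)["euclid_dist"].iloc[0] == 0.0

    def test_three_four_five_triangle(self):
        emb = PCAEmbedding(["a", "b"], np.array([[0.0, 0.0], [3.0, 4.0]]), np.ones(2))
        pairs = pd.DataFrame({"or_id": ["O"], "open_cell": ["a"], "closed_cell": ["b"]})
        assert pairwise_euclidean(emb, pairs)["euclid_dist"].iloc[0] == pytest.approx(5.0)

    def test_matches_two_loop_oracle(self, rng):
        coords = rng.normal(size=(50, 10))
        cells = [f"c{i}" for i in range(50)]
        emb = PCAEmbedding(cells, coords, np.sort(coords.var(axis=0))[::-1])
        open_cells = rng.choice(cells[:25], size=100)
        closed_cells = rng.choice(cells[25:], size=100)
        pairs = pd.DataFrame(
            {"or_id": "O", "open_cell": open_cells, "closed_cell": closed_cells}
        )
        got = pairwise_euclidean(emb, pairs)["euclid_dist"].to_numpy()
        lookup = dict(zip(cells, coords))
        for k in range(100):
            d = 0.0
            for a, b in zip(lookup[open_cells[k]], lookup[closed_cells[k]]):
                d += (a - b) ** 2
            assert got[k] == pytest.approx(np.sqrt(d), abs=1e-9)

    def test_rotation_invariance(self, rng):
        coords = rng.normal(size=(20, 6))
        cells = [f"c{i}" for i in range(20)]
        pairs = pd.DataFrame(
            {
                "or_id": "O",
                "open_cell": rng.choice(cells, 40),
                "closed_cell": rng.choice(cells, 40),
            }
        )
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        ev = np.sort(coords.var(axis=0))[::-1]
        base = pairwise_euclidean(PCAEmbedding(cells, coords, ev), pairs)
        rotated = pairwise_euclidean(PCAEmbedding(cells, coords @ q, ev), pairs)
        np.testing.assert_allclose(
            base["euclid_dist"], rotated["euclid_dist"], atol=1e-6
        )

    def test_missing_cell_named(self):
        emb = PCAEmbedding(["a"], np.zeros((1, 2)), np.zeros(2))
        pairs = pd.DataFrame({"or_id": ["O"], "open_cell": ["a"], "closed_cell": ["zz"]})
        with pytest.raises(KeyError, match="zz"):
            pairwise_euclidean(emb, pairs)


class TestPairwiseGeneLogFC:
    def _norm(self, e_values):
        # store ln(1 + normalized counts), the NormMatrix convention
        values = np.log1p(np.asarray(e_values, dtype=float))
        cells = [f"c{i}" for i in range(values.shape[0])]
        return NormMatrix(cells, ["g"], values), cells

    def test_equal_expression_gives_zero(self):
        norm, cells = self._norm([[2.0], [2.0]])
        pairs = pd.DataFrame(
            {"or_id": ["O"], "open_cell": [cells[0]], "closed_cell": [cells[1]]}
        )
        out = pairwise_gene_logfc(norm, pairs, ["g"])
        assert out["logfc_g"].iloc[0] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        norm, cells = self._norm([[1.0], [3.0]])
        pairs = pd.DataFrame(
            {"or_id": ["O"], "open_cell": [cells[0]], "closed_cell": [cells[1]]}
        )
        out = pairwise_gene_logfc(norm, pairs, ["g"])
        # log2((1 + 3) / (1 + 1)) = 1
        assert out["logfc_g"].iloc[0] == pytest.approx(1.0)

    def test_swapping_naris_roles_negates_logfc(self):
        norm, cells = self._norm([[1.0], [3.0]])
        fwd = pd.DataFrame(
            {"or_id": ["O"], "open_cell": [cells[0]], "closed_cell": [cells[1]]}
        )
        rev = pd.DataFrame(
            {"or_id": ["O"], "open_cell": [cells[1]], "closed_cell": [cells[0]]}
        )
        a = pairwise_gene_logfc(norm, fwd, ["g"])["logfc_g"].iloc[0]
        b = pairwise_gene_logfc(norm, rev, ["g"])["logfc_g"].iloc[0]
        assert a == pytest.approx(-b)

    def test_missing_gene_listed(self):
        norm, cells = self._norm([[1.0], [2.0]])
        pairs = pd.DataFrame(
            {"or_id": ["O"], "open_cell": [cells[0]], "closed_cell": [cells[1]]}
        )
        with pytest.raises(KeyError, match="nope"):
            pairwise_gene_logfc(norm, pairs, ["nope"])


class TestPopulationShift:
    def test_balanced_counts_give_zero_shift(self):
        cells = ["a", "b", "c", "d"]
        table = or_population_shift(
            _assign(cells, ["OrA"] * 4), _meta(cells, ["open", "open", "closed", "closed"])
        )
        assert table["raw_shift"].iloc[0] == 0.0
        assert table["normalized_shift"].iloc[0] == 0.0

    def test_log1p_handles_zero_counts(self):
        cells = ["a", "b", "c"]
        table = or_population_shift(
            _assign(cells, ["OrA"] * 3), _meta(cells, ["closed", "closed", "closed"])
        )
        assert table["raw_shift"].iloc[0] == pytest.approx(np.log(4))

    def test_weights_sum_to_one(self, rng):
        n = 100
        cells = [f"c{i}" for i in range(n)]
        ors = rng.choice([f"Or{k}" for k in range(7)], size=n)
        naris = rng.choice(["open", "closed"], size=n)
        table = or_population_shift(_assign(cells, ors), _meta(cells, naris))
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_swapping_naris_labels_negates_raw_shift(self, rng):
        n = 60
        cells = [f"c{i}" for i in range(n)]
        ors = rng.choice(["OrA", "OrB"], size=n)
        naris = rng.choice(["open", "closed"], size=n)
        fwd = or_population_shift(_assign(cells, ors), _meta(cells, naris))
        flipped = np.where(naris == "open", "closed", "open")
        rev = or_population_shift(_assign(cells, ors), _meta(cells, flipped))
        np.testing.assert_allclose(fwd["raw_shift"], -rev["raw_shift"], atol=1e-12)

    def test_empty_assignments_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            or_population_shift(
                _assign([], []), _meta([], [])
            )


class TestClassifyOrSets:
    def test_rule_table(self):
        de = pd.DataFrame(
            {
                "gene": ["OrA", "OrB", "OrC"],
                "logfc": [1.2, -0.8, -0.5],
                "fdr": [0.01, 0.2, 0.001],
            }
        )
        table = classify_or_sets(de).set_index("or_id")["or_class"]
        assert table["OrA"] == "KO_plus"
        assert table["OrB"] == "na"  # fails FDR
        assert table["OrC"] == "KO_minus"


class TestCompareGroups:
    def test_identical_groups_are_not_distinguishable(self):
        values = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = pd.Series(["a"] * 3 + ["b"] * 3)
        out = compare_groups(values, groups)
        assert out["p_value"].iloc[0] > 0.99

    def test_exact_u_enumeration_for_separated_groups(self):
        values = pd.Series([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        groups = pd.Series(["lo"] * 3 + ["hi"] * 3)
        out = compare_groups(values, groups).iloc[0]
        # fully separated 3 vs 3: U = 0 for the smaller side, exact
        # two-sided p = 2 / C(6,3) = 0.1
        assert min(out["u_stat"], 9 - out["u_stat"]) == 0
        assert out["p_value"] == pytest.approx(0.1)

    def test_small_group_gives_na_with_warning(self):
        values = pd.Series([1.0, 5.0, 6.0])
        groups = pd.Series(["a", "b", "b"])
        out = compare_groups(values, groups)
        assert np.isnan(out["p_value"].iloc[0])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 nonempty groups"):
            compare_groups(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))


def test_distance_antisymmetry_under_naris_swap(rng):
    """Swapping open/closed labels leaves pair distances unchanged."""
    n = 30
    cells = [f"c{i}" for i in range(n)]
    coords = rng.normal(size=(n, 4))
    emb = PCAEmbedding(cells, coords, np.sort(coords.var(axis=0))[::-1])
    ors = rng.choice(["OrA", "OrB"], size=n)
    naris = rng.choice(["open", "closed"], size=n)
    assignments = _assign(cells, ors)
    fwd = pairwise_euclidean(emb, match_pairs(assignments, _meta(cells, naris)))
    flipped = np.where(naris == "open", "closed", "open")
    rev = pairwise_euclidean(emb, match_pairs(assignments, _meta(cells, flipped)))
    key = lambda df: df.assign(
        a=np.minimum(df["open_cell"], df["closed_cell"]),
        b=np.maximum(df["open_cell"], df["closed_cell"]),
    ).set_index(["or_id", "a", "b"])["euclid_dist"].sort_index()
    pd.testing.assert_series_equal(key(fwd), key(rev))


def test_subsample_median_distance_stable_across_seeds(rng):
    """With >= 1000 pairs retained, per-OR median distances agree within
    Monte-Carlo tolerance across subsampling seeds."""
    n = 60
    open_cells = [f"o{i}" for i in range(n)]
    closed_cells = [f"x{i}" for i in range(n)]
    cells = open_cells + closed_cells
    coords = rng.normal(size=(2 * n, 5)) + np.array([1.0, 0, 0, 0, 0])
    emb = PCAEmbedding(cells, coords, np.sort(coords.var(axis=0))[::-1])
    assignments = _assign(cells, ["OrA"] * 2 * n)
    meta = _meta(cells, ["open"] * n + ["closed"] * n)
    medians = []
    for seed in (1, 2):
        pairs = match_pairs(assignments, meta, max_pairs_per_or=1000, seed=seed)
        medians.append(
            pairwise_euclidean(emb, pairs)["euclid_dist"].median()
        )
    assert medians[0] == pytest.approx(medians[1], rel=0.10)


def test_per_or_summary_aggregates_medians(default_sc, default_prep, default_assignments):
    _config, _cm, meta, truth = default_sc
    pairs = match_pairs(default_assignments, meta, seed=1)
    pairs = pairwise_euclidean(default_prep.embedding, pairs)
    pairs = pairwise_gene_logfc(default_prep.norm, pairs, ["S100a5"])
    summary = per_or_summary(pairs, truth.or_classes)
    assert len(summary) == 60
    one = summary.iloc[0]
    sub = pairs.loc[pairs["or_id"] == one["or_id"]]
    assert one["median_euclid_dist"] == pytest.approx(sub["euclid_dist"].median())
    assert one["median_logfc_S100a5"] == pytest.approx(sub["logfc_S100a5"].median())
    assert one["n_pairs"] == len(sub)
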