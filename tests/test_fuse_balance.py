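"""Fusion widths, entropy scoring, top-k selection, SMOTE and Tomek links."""

import numpy as np
import pytest

from dermpipe.exceptions import DomainError
from dermpipe.fuse_balance import (
    DEEP_DIM,
    FUSED_DIM,
    HOG_DIM,
    entropy_scores,
    fuse,
    fuse_matrix,
    select_top_k,
    smote,
    smote_tomek,
    tomek_links,
)


def brute_force_tomek(X, y):
    """All-pairs mutual-1-NN check (independent of the kneighbors path)."""
    X = np.asarray(X, float)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    nearest = d.argmin(axis=1)
    return [
        (i, int(nearest[i]))
        for i in range(len(y))
        if int(nearest[i]) > i and int(nearest[int(nearest[i])]) == i and y[i] != y[int(nearest[i])]
    ]


class TestFuse:
    def test_fused_width_is_7876(self):
        row = fuse(np.ones(HOG_DIM), np.ones(DEEP_DIM))
        assert row.shape == (FUSED_DIM,) == (7876,)

    def test_order_hog_then_deep(self):
        row = fuse(np.full(HOG_DIM, 1.0), np.full(DEEP_DIM, 2.0))
        assert (row[:HOG_DIM] == 1.0).all() and (row[HOG_DIM:] == 2.0).all()

    def test_zero_in_zero_out(self):
        assert not fuse(np.zeros(HOG_DIM), np.zeros(DEEP_DIM)).any()

    def test_wrong_lengths_rejected(self):
        with pytest.raises(DomainError):
            fuse(np.ones(3), np.ones(4))

    def test_matrix_blocks(self):
        ff = fuse_matrix(np.ones((2, HOG_DIM)), np.zeros((2, DEEP_DIM)))
        assert ff.matrix.shape == (2, FUSED_DIM)
        assert ff.blocks == {"hog": (0, HOG_DIM), "deep": (HOG_DIM, FUSED_DIM)}


class TestEntropyScores:
    def test_constant_feature_scores_zero(self):
        x = np.column_stack([np.full(20, 5.0), np.arange(20.0)])
        scores = entropy_scores(x)
        assert scores[0] == 0.0 and scores[1] > 0.0

    def test_uniform_over_all_bins_scores_8_bits(self):
        x = np.arange(256.0)[:, None]
        assert entropy_scores(x, bins=256)[0] == pytest.approx(8.0)

    def test_two_equal_bins_score_one_bit(self):
        x = np.array([0.0] * 10 + [1.0] * 10)[:, None]
        assert entropy_scores(x, bins=256)[0] == pytest.approx(1.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(DomainError):
            entropy_scores(np.empty((0, 4)))


class TestSelectTopK:
    def test_default_selects_1186_of_7876(self):
        rng = np.random.default_rng(0)
        sel = select_top_k(rng.uniform(size=FUSED_DIM))
        assert len(sel.selected_idx) == 1186

    def test_tie_break_by_lowest_index(self):
        sel = select_top_k(np.ones(10), k=3)
        assert np.array_equal(sel.selected_idx, [0, 1, 2])

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=100)
        sel = select_top_k(scores, k=10)
        oracle = sorted(sorted(range(100), key=lambda i: (-scores[i], i))[:10])
        assert np.array_equal(sel.selected_idx, oracle)

    def test_k_too_large_rejected(self):
        with pytest.raises(DomainError):
            select_top_k(np.ones(5), k=6)

    def test_selection_deterministic(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=50)
        assert np.array_equal(select_top_k(scores, 7).selected_idx, select_top_k(scores, 7).selected_idx)


class TestSmote:
    def test_grows_minority_to_majority(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (5, 4)), rng.normal(5, 1, (10, 4))])
        y = np.array(["A"] * 5 + ["B"] * 10)
        reb = smote(X, y, k_neighbors=3, seed=1)
        _, counts = np.unique(reb.y, return_counts=True)
        assert counts.tolist() == [10, 10]
        assert reb.synthetic_flag.sum() == 5

    def test_synthetic_rows_are_convex_combinations(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (6, 5)), rng.normal(4, 1, (12, 5))])
        y = np.array(["A"] * 6 + ["B"] * 12)
        reb = smote(X, y, k_neighbors=3, seed=2)
        real_a = X[:6]
        for row in reb.X[reb.synthetic_flag]:
            found = False
            for i in range(6):
                for j in range(6):
                    if i == j:
                        continue
                    delta = real_a[j] - real_a[i]
                    u = (row - real_a[i]) @ delta / (delta @ delta)
                    if 0 <= u <= 1 and np.allclose(real_a[i] + u * delta, row, atol=1e-9):
                        found = True
            assert found

    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        y = np.array(["A"] * 5 + ["B"] * 5)
        reb = smote(X, y, k_neighbors=2, seed=0)
        assert np.array_equal(reb.X, X) and not reb.synthetic_flag.any()

    def test_singleton_class_rejected_by_name(self):
        X = np.zeros((3, 2))
        y = np.array(["A", "B", "B"])
        with pytest.raises(DomainError, match="A"):
            smote(X, y, k_neighbors=1, seed=0)

    def test_label_conservation_and_majority_untouched(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (4, 3)), rng.normal(6, 1, (9, 3))])
        y = np.array(["A"] * 4 + ["B"] * 9)
        reb = smote(X, y, k_neighbors=2, seed=5)
        assert (reb.y[reb.synthetic_flag] == "A").all()
        assert (reb.y == "B").sum() == 9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(3, 1, (8, 3))])
        y = np.array(["A"] * 5 + ["B"] * 8)
        assert np.array_equal(smote(X, y, 2, seed=9).X, smote(X, y, 2, seed=9).X)


class TestTomekLinks:
    def test_separated_clusters_no_links(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(10, 0.1, (10, 2))])
        y = np.array(["A"] * 10 + ["B"] * 10)
        assert tomek_links(X, y) == []

    def test_one_dimensional_example(self):
        X = np.array([[0.0], [0.4], [3.0], [3.5]])
        y = np.array(["A", "B", "A", "B"])
        # both (0, 0.4) and (3.0, 3.5) are mutual nearest neighbors across classes
        assert tomek_links(X, y) == [(0, 1), (2, 3)]
        assert brute_force_tomek(X, y) == [(0, 1), (2, 3)]

    def test_single_class_empty(self):
        X = np.random.default_rng(1).normal(size=(6, 2))
        assert tomek_links(X, np.array(["A"] * 6)) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = rng.choice(["A", "B"], size=40)
        assert sorted(tomek_links(X, y)) == sorted(brute_force_tomek(X, y))

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        y = rng.choice(["A", "B", "C"], size=30)
        links = tomek_links(X, y)
        as_set = {frozenset(p) for p in links}
        assert len(as_set) == len(links)  # each unordered pair listed once


class TestSmoteTomek:
    def test_separable_classes_identical_to_smote(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.2, (5, 3)), rng.normal(8, 0.2, (12, 3))])
        y = np.array(["A"] * 5 + ["B"] * 12)
        st = smote_tomek(X, y, k_neighbors=3, seed=1)
        sm = smote(X, y, k_neighbors=3, seed=1)
        assert st.removed_pairs == []
        assert np.array_equal(st.X, sm.X)

    def test_overlapping_gaussians_remove_link_members(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1.0, (15, 2)), rng.normal(1.0, 1.0, (25, 2))])
        y = np.array(["A"] * 15 + ["B"] * 25)
        st = smote_tomek(X, y, k_neighbors=3, seed=2)
        sm = smote(X, y, k_neighbors=3, seed=2)
        oracle_links = brute_force_tomek(sm.X, sm.y)
        assert len(st.removed_pairs) == len(oracle_links)
        assert len(st.y) == len(sm.y) - 2 * len(oracle_links)

    def test_imbalance_profile_rebalances_to_majority(self):
        """A scaled archive-like profile ends within 2% of the majority count."""
        profile = {"AK": 44, "BCC": 60, "BK": 80, "DF": 23, "MEL": 82, "MN": 151, "SCC": 25, "VASC": 20}
        rng = np.random.default_rng(4)
        X, y = [], []
        for i, (name, n) in enumerate(profile.items()):
            X.append(rng.normal(3.0 * i, 1.0, (n, 8)))
            y += [name] * n
        st = smote_tomek(np.vstack(X), np.array(y), k_neighbors=5, seed=3)
        _, counts = np.unique(st.y, return_counts=True)
        assert (np.abs(counts - 151) <= np.ceil(0.02 * 151)).all()
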