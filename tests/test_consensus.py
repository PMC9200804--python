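"""Consensus matrix construction, hierarchical cut, and K diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import dice as scipy_dice
from sklearn.metrics import adjusted_rand_score

from smmsubtypes.consensus import (
    KDiagnostics,
    build_consensus,
    canonicalize_labels,
    cut_consensus,
    dice_dissimilarity,
    dice_matrix,
    generalized_kl,
    k_diagnostics,
    select_k,
)
from smmsubtypes.simulate import generate_cohort
from .conftest import planted_config

import pandas as pd


class TestDice:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 1, 0], [1, 1, 0], 0.0),
            ([1, 0, 0], [0, 1, 0], 1.0),
            ([1, 1, 0], [1, 0, 1], 0.5),  # 1 - 2*1/(2+2)
            ([0, 0, 0], [0, 0, 0], 0.0),  # both all-zero: defined as 0
            ([0, 0], [1, 1], 1.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert dice_dissimilarity(a, b) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_dissimilarity([1, 0], [1, 0, 1])

    @given(
        st.lists(st.integers(0, 1), min_size=1, max_size=10),
        st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_scipy_and_is_symmetric(self, a, data):
        b = data.draw(st.lists(st.integers(0, 1), min_size=len(a), max_size=len(a)))
        d = dice_dissimilarity(a, b)
        assert 0 <= d <= 1
        assert d == pytest.approx(dice_dissimilarity(b, a))
        if sum(a) + sum(b) > 0:
            assert d == pytest.approx(float(scipy_dice(np.array(a, bool), np.array(b, bool))))

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(0)
        X = (rng.random((12, 8)) < 0.3).astype(int)
        D = dice_matrix(X)
        for i in range(12):
            for j in range(12):
                assert D[i, j] == pytest.approx(dice_dissimilarity(X[i], X[j]))


class TestConsensus:
    def two_block(self):
        return np.array([[1, 1, 0, 0]] * 3 + [[0, 0, 1, 1]] * 3)

    def test_diagonal_one_and_symmetric(self, block_matrix):
        res = build_consensus(block_matrix, K=2, n_runs=5, seed=0)
        np.testing.assert_allclose(np.diag(res.consensus), 1.0)
        np.testing.assert_allclose(res.consensus, res.consensus.T)
        assert res.consensus.min() >= 0 and res.consensus.max() <= 1

    def test_noiseless_blocks_give_binary_consensus(self):
        X = self.two_block()
        res = build_consensus(X, K=2, n_runs=10, seed=0)
        expected = np.zeros((6, 6))
        expected[:3, :3] = 1
        expected[3:, 3:] = 1
        np.testing.assert_allclose(res.consensus, expected)
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1], res.labels) == 1.0

    def test_single_run_rejected(self, block_matrix):
        with pytest.raises(ValueError, match="2 runs"):
            build_consensus(block_matrix, K=2, n_runs=1)

    def test_deterministic_per_master_seed(self, block_matrix):
        a = build_consensus(block_matrix, K=2, n_runs=5, seed=42)
        b = build_consensus(block_matrix, K=2, n_runs=5, seed=42)
        np.testing.assert_array_equal(a.consensus, b.consensus)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestCutConsensus:
    def test_perfect_blocks(self):
        C = np.zeros((6, 6))
        C[:4, :4] = 1
        C[4:, 4:] = 1
        labels = cut_consensus(C, 2)
        # canonical ids: larger cluster first
        assert labels.tolist() == [0, 0, 0, 0, 1, 1]

    def test_degenerate_cuts(self):
        C = np.eye(4)
        assert cut_consensus(C, 1).tolist() == [0, 0, 0, 0]
        assert sorted(cut_consensus(C, 4).tolist()) == [0, 1, 2, 3]
        with pytest.raises(ValueError):
            cut_consensus(C, 5)

    def test_patient_order_invariance_up_to_relabeling(self):
        cohort = generate_cohort(planted_config(n_patients=60, seed=2))
        X = cohort.matrix.values
        res = build_consensus(X, K=3, n_runs=10, seed=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.shape[0])
        labels_perm = cut_consensus(res.consensus[np.ix_(perm, perm)], 3)
        assert adjusted_rand_score(res.labels[perm], labels_perm) == 1.0

    def test_canonicalize_by_decreasing_size(self):
        assert canonicalize_labels([2, 2, 2, 0, 0, 1]).tolist() == [0, 0, 0, 1, 1, 2]
        # tie on size: lowest original id wins the lower canonical id
        assert canonicalize_labels([5, 5, 3, 3]).tolist() == [1, 1, 0, 0]


class TestKDiagnostics:
    def test_noiseless_planted_k_exact_at_truth(self):
        cfg = planted_config(
            n_patients=45, p_signature=1.0, p_background=0.0, seed=1,
            hyperdiploid_rates={s: (1.0 if s.startswith("HL") else 0.0)
                                for s in ("HL1", "HL2", "HL3", "HL4", "TL1", "TL2")},
        )
        cohort = generate_cohort(cfg)
        diag = k_diagnostics(cohort.matrix, k_range=[3], n_runs=8, seed=0)
        row = diag.table.iloc[0]
        assert row["best_residual"] == 0
        assert row["best_variance_explained"] == pytest.approx(1.0)
        assert row["kl"] == pytest.approx(0.0, abs=1e-4)
        assert row["silhouette"] == pytest.approx(1.0)

    def test_kl_nonnegative_and_zero_at_identity(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert generalized_kl(X, X) == pytest.approx(0.0, abs=1e-9)
        rng = np.random.default_rng(0)
        Y = rng.random((2, 2))
        assert generalized_kl(X, Y) >= 0 or generalized_kl(X, Y) == pytest.approx(0)

    def test_downsample_size_validation(self, block_matrix):
        with pytest.raises(ValueError):
            k_diagnostics(block_matrix, k_range=[2], downsample_sizes=[2], n_runs=2)

    def test_downsampling_stability_variance_shrinks(self):
        cohort = generate_cohort(planted_config(n_patients=160, seed=4))
        diag = k_diagnostics(
            cohort.matrix, k_range=[3], n_runs=8,
            downsample_sizes=[50, 100], n_downsamples=4, seed=0,
        )
        agg = diag.table[diag.table["size"].isin([50, 100])]
        var = agg.groupby("size")["silhouette"].var()
        assert var[100] <= var[50]


class TestSelectK:
    @staticmethod
    def diagnostics_from(table: pd.DataFrame) -> KDiagnostics:
        table = table.assign(size=100, replicate=0,
                             residual=0.0, variance_explained=1.0)
        return KDiagnostics(table=table, k_range=list(table["K"]), n_runs=10, seed=0)

    def test_largest_drop_with_flat_silhouette_selects_six(self):
        table = pd.DataFrame(
            {
                "K": range(2, 9),
                "kl": [100, 95, 90, 85, 40, 38, 36],  # largest drop 5 -> 6
                "silhouette": [0.5] * 7,
            }
        )
        sel = select_k(self.diagnostics_from(table))
        assert sel.K == 6
        assert "K=6" in sel.rationale

    def test_single_candidate_returned(self):
        table = pd.DataFrame({"K": [4], "kl": [10.0], "silhouette": [0.4]})
        assert select_k(self.diagnostics_from(table)).K == 4

    def test_low_silhouette_k_ineligible(self):
        table = pd.DataFrame(
            {
                "K": [2, 3, 4],
                "kl": [100, 40, 10],  # largest drop 2 -> 3, but sil too low there
                "silhouette": [0.6, 0.3, 0.58],
            }
        )
        assert select_k(self.diagnostics_from(table)).K == 4
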