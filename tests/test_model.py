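"""Core NMF: initialization, update rules vs loop oracles, divergence, fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blocknmf import (
    ConfigError,
    DimensionError,
    DomainError,
    NMF,
    RunConfig,
    fit_full,
    init_factors,
    kl_divergence,
    update_H,
    update_W,
)
from blocknmf.synthetic import make_planted

from conftest import oracle_kl, oracle_update_H, oracle_update_W, random_instance


class TestInitFactors:
    def test_seed_determinism(self):
        a = init_factors(8, 5, 3, seed=42)
        b = init_factors(8, 5, 3, seed=42)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)

    def test_strictly_positive(self):
        pair = init_factors(20, 15, 4, seed=0)
        assert (pair.W > 0).all() and (pair.H > 0).all()
        assert (pair.W <= 1).all() and (pair.H <= 1).all()

    def test_different_seeds_differ(self):
        a = init_factors(8, 5, 3, seed=1)
        b = init_factors(8, 5, 3, seed=2)
        assert (a.W != b.W).any()

    def test_sum_vectors_populated(self):
        pair = init_factors(8, 5, 3, seed=0)
        np.testing.assert_allclose(pair.col_sums_W, pair.W.sum(axis=0), rtol=1e-12)
        np.testing.assert_allclose(pair.row_sums_H, pair.H.sum(axis=1), rtol=1e-12)

    @pytest.mark.parametrize("n,m,k", [(3, 5, 4), (0, 5, 1), (5, 3, 4)])
    def test_invalid_shapes_rejected(self, n, m, k):
        with pytest.raises(ConfigError):
            init_factors(n, m, k, seed=0)


class TestUpdateRules:
    def test_fixed_point_H(self, worked):
        c = worked["fixed_point"]
        H1 = update_H(c["V"], c["W"], c["H"])
        np.testing.assert_allclose(H1, c["H"], rtol=1e-12)

    def test_fixed_point_W(self, worked):
        c = worked["fixed_point"]
        W1 = update_W(c["V"], c["W"], c["H"])
        np.testing.assert_allclose(W1, c["W"], rtol=1e-12)

    def test_column_mean_closed_form(self, worked):
        # W = ones(2x1): one H update lands on the column mean of V
        # regardless of the starting H.
        c = worked["column_mean"]
        for h0 in (0.1, 1.0, 7.3):
            H1 = update_H(c["V"], c["W"], np.array([[h0]]))
            np.testing.assert_allclose(H1, c["expected_H"], rtol=1e-12)

    def test_oracle_2x2_instance(self, worked):
        c = worked["oracle_2x2"]
        np.testing.assert_allclose(
            update_H(c["V"], c["W"], c["H"]),
            oracle_update_H(c["V"], c["W"], c["H"]),
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            update_W(c["V"], c["W"], c["H"]),
            oracle_update_W(c["V"], c["W"], c["H"]),
            rtol=1e-12,
        )

    def test_inputs_unmodified(self, rng):
        V, W, H = random_instance(rng)
        W0, H0 = W.copy(), H.copy()
        update_H(V, W, H)
        update_W(V, W, H)
        np.testing.assert_array_equal(W, W0)
        np.testing.assert_array_equal(H, H0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            update_H(np.ones((2, 3)), np.ones((2, 2)), np.ones((2, 2)))

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            update_H(-np.ones((2, 2)), np.ones((2, 1)), np.ones((1, 2)))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_transpose_duality(self, seed):
        # The two rules are the same rule with V transposed and roles swapped.
        rng = np.random.default_rng(seed)
        V, W, H = random_instance(rng)
        np.testing.assert_allclose(
            update_W(V, W, H), update_H(V.T, H.T, W.T).T, rtol=1e-12, atol=1e-300
        )

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_nonnegativity_closure(self, seed):
        rng = np.random.default_rng(seed)
        V, W, H = random_instance(rng)
        assert (update_H(V, W, H) >= 0).all()
        assert (update_W(V, W, H) >= 0).all()


class TestKLDivergence:
    def test_zero_at_exact_product(self, worked):
        c = worked["fixed_point"]
        assert kl_divergence(c["V"], c["W"], c["H"]) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_e(self):
        # V=[[1]], WH=[[e]]: 1*log(1/e) - 1 + e = e - 2
        val = kl_divergence(np.array([[1.0]]), np.array([[np.e]]), np.array([[1.0]]))
        assert val == pytest.approx(np.e - 2.0, rel=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(5):
            V, W, H = random_instance(rng, max_n=3, max_m=3, max_k=2)
            assert kl_divergence(V, W, H) == pytest.approx(
                oracle_kl(V, W, H), rel=1e-10
            )

    def test_infinite_when_support_uncovered(self):
        # WH = 0 where V > 0 -> +inf by convention
        V = np.array([[1.0, 0.0]])
        W = np.array([[1.0]])
        H = np.array([[0.0, 1.0]])
        assert kl_divergence(V, W, H) == float("inf")

    def test_zero_entries_of_V_contribute_only_WH(self):
        V = np.array([[0.0]])
        assert kl_divergence(V, np.array([[2.0]]), np.array([[1.5]])) == pytest.approx(3.0)

    def test_nonnegative(self, rng):
        for _ in range(10):
            V, W, H = random_instance(rng)
            assert kl_divergence(V, W, H) >= -1e-12


class TestFitFull:
    def test_monotone_on_exact_rank_data(self, rng):
        W0 = rng.random((30, 3)) + 0.1
        H0 = rng.random((3, 20)) + 0.1
        V = W0 @ H0
        cfg = RunConfig(rank=3, seed=1, max_iters=440, test_period=10 ** 9)
        _, report = fit_full(V, cfg, track_divergence=True)
        d = np.array(report.divergence_trace)
        assert (np.diff(d) <= 1e-9 * np.maximum(d[:-1], 1.0)).all()
        assert d[-1] <= d[0]

    def test_rank1_converges_to_stable_value(self, rng):
        V = rng.random((10, 6)) + 0.5
        cfg = RunConfig(rank=1, seed=3, max_iters=300, test_period=10 ** 9)
        _, report = fit_full(V, cfg, track_divergence=True)
        d = report.divergence_trace
        tail = np.abs(np.diff(d[-11:])) / max(abs(d[-1]), 1e-300)
        assert (tail < 1e-10).all()
        assert (np.diff(d) <= 1e-9 * np.maximum(np.abs(d[:-1]), 1.0)).all()

    def test_planted_two_cluster_recovery(self):
        from blocknmf import assignments_equivalent

        ds = make_planted(n=40, m=10, k=2, separation=10.0, noise_level=0.0, seed=5)
        cfg = RunConfig(rank=2, seed=5)
        _, report = fit_full(ds.V, cfg)
        assert assignments_equivalent(report.final_assignment, ds.labels_true)

    def test_determinism(self, rng):
        V = rng.random((20, 12)) + 0.1
        cfg = RunConfig(rank=3, seed=11, max_iters=50, test_period=10 ** 9)
        p1, _ = fit_full(V, cfg)
        p2, _ = fit_full(V, cfg)
        np.testing.assert_array_equal(p1.W, p2.W)
        np.testing.assert_array_equal(p1.H, p2.H)


class TestModelSurface:
    def test_fit_returns_results_with_summary(self):
        ds = make_planted(n=30, m=9, k=3, seed=2)
        res = NMF(ds.V, rank=3).fit(seed=2)
        text = res.summary()
        assert "Rank k" in text and "Stop reason" in text
        assert res.W.shape == (30, 3) and res.H.shape == (3, 9)
        assert len(res.sample_assignment()) == 9
        assert len(res.gene_assignment()) == 30

    def test_from_dataframe(self):
        pd = pytest.importorskip("pandas")
        df = pd.DataFrame(
            np.ones((4, 3)), index=list("abcd"), columns=["s1", "s2", "s3"]
        )
        model = NMF.from_dataframe(df, rank=2)
        assert model.data.row_labels == list("abcd")
        assert model.data.col_labels == ["s1", "s2", "s3"]

    def test_rank_bounds_enforced(self):
        with pytest.raises(ConfigError):
            NMF(np.ones((3, 3)), rank=4)
        with pytest.raises(ConfigError):
            NMF(np.ones((3, 3)), rank=0)

    def test_single_precision_fit_runs(self):
        ds = make_planted(n=20, m=8, k=2, seed=4)
        res = NMF(ds.V, rank=2).fit(seed=4, precision="single", max_iters=30,
                                    test_period=10 ** 9)
        assert res.W.dtype == np.float32
        assert np.isfinite(res.divergence)
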