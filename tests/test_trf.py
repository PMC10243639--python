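import numpy as np
import pytest

from glimpsetrf.trf import (
    REFERENCE_LAMBDAS,
    CVRidge,
    RegressorBank,
    build_lagged_design,
    contiguous_folds,
    crossval_predict,
    expand_group_lambdas,
    fit_banded_ridge,
    fit_trf,
    make_lag_frames,
    tune_lambdas_sequential,
)


def direct_banded_solve(X, Y, lam):
    """Independent oracle: penalized normal equations."""
    return np.linalg.solve(X.T @ X + np.diag(lam), X.T @ Y)


class TestLaggedDesign:
    def test_impulse_gives_shifted_identity(self):
        x = np.zeros((6, 1)); x[2, 0] = 1.0
        d = build_lagged_design(x, np.array([0, 1, 2]))
        assert d.shape == (6, 3)
        assert np.flatnonzero(d[:, 0]).tolist() == [2]
        assert np.flatnonzero(d[:, 1]).tolist() == [3]
        assert np.flatnonzero(d[:, 2]).tolist() == [4]

    def test_lag_zero_is_identity_copy(self, rng):
        x = rng.random((20, 3))
        assert np.array_equal(build_lagged_design(x, np.array([0])), x)

    def test_negative_lag_anticipates(self):
        x = np.zeros((6, 1)); x[3, 0] = 1.0
        d = build_lagged_design(x, np.array([-1]))
        assert np.flatnonzero(d[:, 0]).tolist() == [2]

    def test_lag_axis_in_frames(self):
        lags = make_lag_frames((0.0, 500.0), 100.0)
        assert lags.size == 51 and lags[0] == 0 and lags[-1] == 50
        disp = make_lag_frames((-100.0, 600.0), 100.0)
        assert disp.size == 71 and disp[0] == -10


class TestBandedRidge:
    @pytest.mark.parametrize("n,p,groups", [(50, 8, 2), (120, 24, 3), (200, 40, 5)])
    def test_matches_normal_equation_oracle(self, rng, n, p, groups):
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, 4))
        lam = np.repeat(10.0 ** rng.uniform(-2, 3, groups),
                        np.diff(np.linspace(0, p, groups + 1).astype(int)))
        w = fit_banded_ridge(X, Y, lam)
        assert np.allclose(w, direct_banded_solve(X, Y, lam), atol=1e-8)

    def test_equal_lambda_is_textbook_ridge(self, rng):
        X = rng.standard_normal((50, 8))
        y = rng.standard_normal((50, 1))
        lam = np.full(8, 3.7)
        w = fit_banded_ridge(X, y, lam)
        assert np.allclose(w, np.linalg.solve(X.T @ X + 3.7 * np.eye(8), X.T @ y),
                           atol=1e-8)

    def test_huge_lambda_silences_a_group(self, rng):
        X = rng.standard_normal((100, 10))
        y = X[:, :5] @ rng.standard_normal((5, 1))
        lam = np.concatenate([np.full(5, 1e-6), np.full(5, 1e12)])
        w = fit_banded_ridge(X, y, lam)
        assert np.abs(w[5:]).max() < 1e-8
        reduced = direct_banded_solve(X[:, :5], y, np.full(5, 1e-6))
        assert np.allclose(w[:5], reduced, atol=1e-6)

    def test_orthonormal_design_small_lambda_limit(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((60, 6)))
        y = rng.standard_normal((60, 1))
        w = fit_banded_ridge(Q, y, np.full(6, 1e-12))
        assert np.allclose(w, Q.T @ y, atol=1e-9)

    def test_rejects_nonpositive_lambda_and_nonfinite(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            fit_banded_ridge(X, np.ones(10), np.array([1.0, 0.0]))
        Xb = X.copy(); Xb[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_banded_ridge(Xb, np.ones(10), np.array([1.0, 1.0]))


def _small_bank(rng, n=1200, k1=2, k2=2):
    bank = RegressorBank(100.0)
    bank.add("a", rng.standard_normal((n, k1)))
    bank.add("b", rng.standard_normal((n, k2)))
    return bank


class TestCrossValidation:
    def test_noiseless_response_is_recovered(self, rng):
        bank = _small_bank(rng)
        lags = np.arange(0, 5)
        design = build_lagged_design(bank.stacked(), lags)
        w = rng.standard_normal((design.shape[1], 3))
        y = design @ w
        z = crossval_predict(bank, y, {"a": 1e-6, "b": 1e-6}, lags)
        assert np.tanh(np.nanmean(z)) > 0.99

    def test_independent_response_scores_near_zero(self, rng):
        bank = _small_bank(rng)
        y = rng.standard_normal((bank.n_frames, 3))
        z = crossval_predict(bank, y, {"a": 1.0, "b": 1.0}, np.arange(0, 5))
        assert abs(np.nanmean(z)) < 3.0 / np.sqrt(bank.n_frames / 5)

    def test_fisher_transform_value(self):
        assert np.arctanh(0.5) == pytest.approx(0.54930614)

    def test_affine_invariance_of_scores(self, rng):
        bank = _small_bank(rng)
        lags = np.arange(0, 4)
        design = build_lagged_design(bank.stacked(), lags)
        y = design @ rng.standard_normal((design.shape[1], 2)) \
            + 0.5 * rng.standard_normal((bank.n_frames, 2))
        lams = {"a": 1.0, "b": 1.0}
        z1 = crossval_predict(bank, y, lams, lags)
        z2 = crossval_predict(bank, 3.0 * y + 11.0, lams, lags)
        assert np.allclose(z1, z2, atol=1e-10)

    def test_folds_are_contiguous_blocks(self):
        folds = contiguous_folds(100, 5)
        assert folds == [(0, 20), (20, 40), (40, 60), (60, 80), (80, 100)]
        with pytest.raises(ValueError):
            contiguous_folds(100, 1)

    def test_fit_trf_weight_layout_and_backscaling(self, rng):
        bank = _small_bank(rng, n=2000)
        lags = np.arange(0, 6)
        design = build_lagged_design(bank.stacked(), lags)
        w_true = np.zeros((design.shape[1], 1))
        w_true[7] = 2.0      # feature 1, lag 1 (feature-major, lag-minor)
        y = design @ w_true
        fit = fit_trf(bank, y, {"a": 1e-6, "b": 1e-6}, lags, n_folds=None)
        assert fit.weights.shape == (6, 4, 1)
        assert fit.weights[1, 1, 0] == pytest.approx(2.0, rel=1e-3)
        # residual weights only reflect the zero-padded first lag frames
        mask = np.ones_like(fit.weights, bool); mask[1, 1, 0] = False
        assert np.abs(fit.weights[mask]).max() < 1e-3


class TestLambdaTuning:
    def test_informative_group_gets_smaller_lambda(self, rng):
        n = 3000
        info = rng.standard_normal((n, 3))
        noise = rng.standard_normal((n, 3))
        y = info @ rng.standard_normal(3) + 0.5 * rng.standard_normal(n)
        bank = RegressorBank(100.0).add("info", info).add("noise", noise)
        tuned = tune_lambdas_sequential(bank, y[:, None], np.arange(0, 4))
        assert tuned["info"] < tuned["noise"]

    def test_tuning_is_deterministic(self, rng):
        bank = _small_bank(rng, n=800)
        y = bank["a"] @ np.ones(2) + rng.standard_normal(800)
        lags = np.arange(0, 3)
        t1 = tune_lambdas_sequential(bank, y[:, None], lags, n_folds=3)
        t2 = tune_lambdas_sequential(bank, y[:, None], lags, n_folds=3)
        assert t1 == t2

    def test_reference_lambda_table(self):
        assert REFERENCE_LAMBDAS == {
            "spectrogram": 42.7,
            "glimpsed_edges": 13.5,
            "masked_edges": 10.0,
            "glimpsed_phoneme_onsets": 31.6,
            "masked_phoneme_onsets": 17.8,
            "glimpsed_phonetic": 144.0,
            "masked_phonetic": 215.0,
            "word_onsets": 31.6,
        }

    def test_expand_group_lambdas(self, rng):
        bank = _small_bank(rng, n=100, k1=2, k2=3)
        lags = np.arange(0, 2)
        lam = expand_group_lambdas(bank, lags, {"a": 2.0, "b": 5.0})
        assert lam.tolist() == [2.0] * 4 + [5.0] * 6

    def test_empty_bank_raises(self):
        bank = RegressorBank(100.0)
        with pytest.raises(ValueError):
            bank.n_frames
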