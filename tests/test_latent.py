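import numpy as np
import pandas as pd
import pytest

from evodet import (
    fit_pcr,
    fit_pls,
    pcr_variance_decomposition,
    predict_response,
    score_predictions,
    select_components,
    vip_scores,
)
from evodet.latent import LatentModel, LatentModelError, one_se_select

from _oracles import ols_predictions


def random_xy(rng, n=120, p=6, noise=0.5):
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y


class TestFitPls:
    def test_single_predictor_equals_ls_slope(self, rng):
        x = rng.standard_normal(60)
        y = 1.7 * x + 0.2 * rng.standard_normal(60)
        m = fit_pls(x[:, None], y, 1)
        xc, yc = x - x.mean(), y - y.mean()
        assert m.coef[0] == pytest.approx((xc @ yc) / (xc @ xc), rel=1e-12)

    def test_exact_linear_signal_interpolated(self, rng):
        X = rng.standard_normal((50, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0])
        m = fit_pls(X, y, 4)
        fitted = predict_response(m, X)
        assert np.sqrt(np.mean((y - fitted) ** 2)) < 1e-8

    def test_duplicated_predictors_get_equal_first_weights(self, rng):
        x = rng.standard_normal(40)
        X = np.column_stack([x, x])
        y = x + 0.1 * rng.standard_normal(40)
        m = fit_pls(X, y, 1)
        assert m.weights[0, 0] == pytest.approx(m.weights[1, 0], rel=1e-12)

    def test_component_bound_enforced(self, rng):
        X, y = random_xy(rng, n=20, p=5)
        with pytest.raises(LatentModelError, match="n_components"):
            fit_pls(X, y, 6)

    def test_zero_variance_column_rejected(self, rng):
        X, y = random_xy(rng, n=30, p=3)
        X[:, 1] = 4.0
        with pytest.raises(LatentModelError, match="zero-variance"):
            fit_pls(X, y, 2)

    def test_training_r2_nondecreasing_in_components(self, rng):
        X, y = random_xy(rng, n=100, p=8)
        r2 = [fit_pls(X, y, A).training_r2 for A in range(1, 9)]
        assert np.all(np.diff(r2) >= -1e-12)


class TestFitPcr:
    def test_full_rank_equals_ols(self, rng):
        X, y = random_xy(rng, n=80, p=5)
        m = fit_pcr(X, y, 5)
        assert np.allclose(predict_response(m, X), ols_predictions(X, y, X), atol=1e-6)

    def test_orthogonal_columns_align_with_components(self, rng):
        n = 200
        X = np.zeros((n, 3))
        X[:, 0] = 3.0 * rng.standard_normal(n)
        X[:, 1] = 2.0 * rng.standard_normal(n)
        X[:, 2] = 1.0 * rng.standard_normal(n)
        y = X[:, 0] + rng.standard_normal(n)
        m = fit_pcr(X, y, 3)
        # loading columns ~ coordinate axes in descending variance order
        for a in range(3):
            assert np.abs(m.loadings[:, a]).argmax() == a

    def test_null_response_has_near_zero_test_r2(self):
        r = np.random.default_rng(99)
        X = r.standard_normal((500, 10))
        y = r.standard_normal(500)
        m = fit_pcr(X[:250], y[:250], 10)
        test = score_predictions(y[250:], predict_response(m, X[250:]))
        assert abs(test.variance_explained) < 0.1
        assert fit_pcr(X, y, 10).training_r2 < 0.08


class TestModelStructure:
    @pytest.mark.parametrize("fit", [fit_pls, fit_pcr])
    def test_scores_orthogonal(self, fit, rng):
        X, y = random_xy(rng, n=150, p=10)
        m = fit(X, y, 6)
        gram = m.scores.T @ m.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_pls_weight_columns_unit_norm(self, rng):
        X, y = random_xy(rng)
        m = fit_pls(X, y, 4)
        assert np.allclose(np.linalg.norm(m.weights, axis=0), 1.0, atol=1e-12)

    def test_pcr_loadings_orthonormal(self, rng):
        X, y = random_xy(rng)
        m = fit_pcr(X, y, 4)
        assert np.allclose(m.loadings.T @ m.loadings, np.eye(4), atol=1e-10)

    @pytest.mark.parametrize("fit", [fit_pls, fit_pcr])
    def test_sign_flip_leaves_everything_invariant(self, fit, rng):
        X, y = random_xy(rng)
        m = fit(X, y, 3)
        flipped = LatentModel(
            method=m.method,
            n_components=m.n_components,
            variable_names=m.variable_names,
            loadings=m.loadings * np.array([1, -1, 1]),
            scores=m.scores * np.array([1, -1, 1]),
            q=m.q * np.array([1, -1, 1]),
            ss=m.ss,
            x_mean=m.x_mean,
            y_mean=m.y_mean,
            coef=m.coef,
            weights=None if m.weights is None else m.weights * np.array([1, -1, 1]),
        )
        assert np.allclose(predict_response(flipped, X), predict_response(m, X))
        if m.method == "PLS":
            assert np.allclose(vip_scores(flipped), vip_scores(m))
        else:
            assert np.allclose(pcr_variance_decomposition(flipped), pcr_variance_decomposition(m))


class TestPredict:
    def test_mean_level_row_predicts_training_mean(self, rng):
        X, y = random_xy(rng)
        X = X - X.mean(axis=0)
        m = fit_pls(X, y, 3)
        assert predict_response(m, np.zeros((1, X.shape[1])))[0] == pytest.approx(y.mean())

    def test_name_based_alignment(self, rng):
        X, y = random_xy(rng, p=4)
        df = pd.DataFrame(X, columns=["a", "b", "c", "d"])
        m = fit_pls(df, y, 2)
        shuffled = df[["d", "b", "a", "c"]]
        assert np.allclose(predict_response(m, shuffled), predict_response(m, df))

    def test_column_mismatch_named(self, rng):
        X, y = random_xy(rng, p=3)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        m = fit_pls(df, y, 2)
        bad = df.rename(columns={"c": "z"})
        with pytest.raises(LatentModelError, match="missing=\\['c'\\]"):
            predict_response(m, bad)


class TestScorePredictions:
    def test_perfect_and_null_predictors(self, rng):
        y = rng.standard_normal(30)
        perfect = score_predictions(y, y)
        assert perfect.rmse == 0.0 and perfect.variance_explained == 1.0
        null = score_predictions(y, np.full_like(y, y.mean()))
        assert null.variance_explained == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_case(self):
        fm = score_predictions([0.0, 2.0], [1.0, 1.0])
        assert fm.rmse == 1.0
        assert fm.variance_explained == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(LatentModelError, match="mismatch"):
            score_predictions([1.0, 2.0], [1.0])


class TestSelectComponents:
    def test_one_se_hand_trace(self):
        # min at A=2 (1.95), threshold 2.05; A=1 (2.0) qualifies, A=0 (3.0) not
        assert one_se_select([3.0, 2.0, 1.95, 1.96], [0.1] * 4) == 1

    def test_zero_se_degenerates_to_argmin(self):
        assert one_se_select([3.0, 2.0, 1.95, 1.96], [0.0] * 4) == 2

    def test_pure_noise_prefers_intercept_only(self):
        picks = []
        for seed in range(1, 11):
            r = np.random.default_rng(seed)
            X = r.standard_normal((300, 10))
            y = r.standard_normal(300)
            picks.append(select_components(X, y, max_A=10, seed=seed).selected)
        assert np.bincount(picks).argmax() == 0

    def test_strong_signal_selects_at_least_one(self, rng):
        X, y = random_xy(rng, n=200, p=8, noise=0.3)
        sel = select_components(X, y, max_A=8, seed=1)
        assert sel.selected >= 1
        assert sel.rmsep.shape == (9,)
        assert np.all(sel.rmsep >= 0)

    def test_deterministic_under_seed(self, rng):
        X, y = random_xy(rng)
        a = select_components(X, y, max_A=5, seed=3)
        b = select_components(X, y, max_A=5, seed=3)
        assert np.array_equal(a.rmsep, b.rmsep) and a.selected == b.selected

    def test_invalid_max_components_rejected(self, rng):
        X, y = random_xy(rng)
        with pytest.raises(LatentModelError, match="max_A"):
            select_components(X, y, max_A=0)


class TestVip:
    def _one_component_model(self, weights, ss=0.4):
        w = np.asarray(weights, float)[:, None]
        p = len(weights)
        return LatentModel(
            method="PLS",
            n_components=1,
            variable_names=[f"x{i}" for i in range(p)],
            loadings=w.copy(),
            scores=np.zeros((3, 1)),
            q=np.array([1.0]),
            ss=np.array([ss]),
            x_mean=np.zeros(p),
            y_mean=0.0,
            coef=np.zeros(p),
            weights=w,
        )

    def test_worked_two_variable_case(self):
        vip = vip_scores(self._one_component_model([0.8, 0.6]))
        assert vip["x0"] == pytest.approx(np.sqrt(1.28), abs=1e-10)  # ~1.1314
        assert vip["x1"] == pytest.approx(np.sqrt(0.72), abs=1e-10)  # ~0.8485

    def test_equal_weights_give_unit_vip(self):
        p = 5
        vip = vip_scores(self._one_component_model([1 / np.sqrt(p)] * p))
        assert np.allclose(vip, 1.0)

    def test_single_variable_vip_is_one(self, rng):
        x = rng.standard_normal(50)
        y = 0.5 * x + rng.standard_normal(50)
        assert vip_scores(fit_pls(x[:, None], y, 1)).iloc[0] == pytest.approx(1.0)

    def test_mean_square_is_one_over_random_fits(self):
        for seed in range(12):
            r = np.random.default_rng(seed)
            n, p = int(r.integers(30, 100)), int(r.integers(2, 12))
            X = r.standard_normal((n, p))
            y = X @ r.standard_normal(p) + r.standard_normal(n)
            A = int(r.integers(1, min(n - 1, p) + 1))
            vip = vip_scores(fit_pls(X, y, A))
            assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-8)

    def test_pcr_model_rejected(self, rng):
        X = rng.standard_normal((40, 3))
        y = X[:, 0] + rng.standard_normal(40)
        with pytest.raises(LatentModelError, match="PLS"):
            vip_scores(fit_pcr(X, y, 2))


class TestPcrDecomposition:
    def test_symmetric_loadings_split_evenly(self):
        s = 1 / np.sqrt(2)
        m = LatentModel(
            method="PCR",
            n_components=1,
            variable_names=["a", "b"],
            loadings=np.array([[s], [s]]),
            scores=np.zeros((3, 1)),
            q=np.array([1.0]),
            ss=np.array([0.4]),  # component explains 40% of y variance
            x_mean=np.zeros(2),
            y_mean=0.0,
            coef=np.zeros(2),
        )
        dec = pcr_variance_decomposition(m)
        assert dec["a"] == pytest.approx(20.0) and dec["b"] == pytest.approx(20.0)

    def test_sums_to_training_r2(self):
        for seed in range(12):
            r = np.random.default_rng(100 + seed)
            n, p = int(r.integers(30, 100)), int(r.integers(2, 12))
            X = r.standard_normal((n, p))
            y = X @ r.standard_normal(p) + r.standard_normal(n)
            A = int(r.integers(1, min(n - 1, p) + 1))
            m = fit_pcr(X, y, A)
            assert pcr_variance_decomposition(m).sum() / 100 == pytest.approx(
                m.training_r2, abs=1e-8
            )

    def test_zero_loading_variable_gets_zero(self, rng):
        n = 300
        X = np.column_stack([rng.standard_normal(n) * 3, rng.standard_normal(n)])
        y = X[:, 0] + 0.1 * rng.standard_normal(n)
        m = fit_pcr(X, y, 1)
        dec = pcr_variance_decomposition(m)
        # second variable barely loads on the single retained component
        assert dec.iloc[1] < 0.02 * dec.iloc[0]

    def test_corrupted_loadings_rejected(self, rng):
        X, y = (rng.standard_normal((40, 3)), rng.standard_normal(40))
        m = fit_pcr(X, y, 2)
        m.loadings = m.loadings * 2.0
        with pytest.raises(LatentModelError, match="orthonormal"):
            pcr_variance_decomposition(m)


class TestFullRankEquivalence:
    def test_pls_pcr_ols_agree(self):
        r = np.random.default_rng(7)
        n, p = 200, 10
        X = r.standard_normal((n, p))
        y = X @ r.standard_normal(p) + 0.5 * r.standard_normal(n)
        ols = ols_predictions(X, y, X)
        for fit in (fit_pls, fit_pcr):
            m = fit(X, y, p)
            assert np.allclose(predict_response(m, X), ols, atol=1e-6)
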