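import numpy as np
import pytest

from speechtrf.design import (DEFAULT_LAMBDA_GRID, MasterDesign, SetDesign,
                              lag_grid, lagged_matrix)
from speechtrf.features import FeatureMatrix
from speechtrf.trf import (TemporalResponseFunction, cv_fit, generic_model,
                           prediction_gain, ridge_fit)

FS = 50.0


def fm(values, groups=None):
    values = np.atleast_2d(values)
    return FeatureMatrix(values, FS, groups)


class TestLaggedDesign:
    def test_lag_count_for_600ms_window_at_50hz(self):
        assert len(lag_grid((0, 600), 50.0)) == 30

    def test_design_width_is_dims_times_lags(self, rng):
        X = rng.random((100, 40))
        D = lagged_matrix(X, lag_grid((0, 600), 50.0))
        assert D.shape == (100, 1200)

    def test_lag_one_column_is_shifted_with_leading_zero(self, rng):
        x = rng.random((20, 1))
        D = lagged_matrix(x, np.array([1, 2]))
        assert D[0, 0] == 0.0
        np.testing.assert_allclose(D[1:, 0], x[:-1, 0])
        np.testing.assert_allclose(D[2:, 1], x[:-2, 0])

    def test_empty_lag_grid_rejected(self):
        with pytest.raises(ValueError):
            lag_grid((0, 5), 50.0)  # shorter than one sample


class TestRidgeFit:
    def test_orthonormal_design_identity(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((50, 5)))
        y = rng.standard_normal((50, 2))
        W, _ = ridge_fit(Q, y, 0.0, fit_intercept=False)
        np.testing.assert_allclose(W, Q.T @ y, atol=1e-10)

    def test_matches_explicit_normal_equations(self, rng):
        D = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        lam = 0.7
        W, bias = ridge_fit(D, y, lam)
        Dc = D - D.mean(axis=0)
        yc = y - y.mean()
        brute = np.linalg.solve(Dc.T @ Dc + lam * np.eye(5), Dc.T @ yc)
        np.testing.assert_allclose(W[:, 0], brute, atol=1e-10)

    def test_monotone_shrinkage(self, rng):
        D = rng.standard_normal((60, 8))
        y = rng.standard_normal(60)
        norms = [np.linalg.norm(ridge_fit(D, y, lam)[0])
                 for lam in (0.0, 1.0, 100.0, 1e6)]
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * norms[0]

    def test_singular_at_lambda_zero_raises(self, rng):
        col = rng.standard_normal((30, 1))
        D = np.hstack([col, col])  # exactly collinear
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            ridge_fit(D, rng.standard_normal(30), 0.0)


def simulate_linear(rng, n_trials=4, n_times=600, n_dims=3, n_ch=2,
                    noise=0.0):
    lags = lag_grid((0, 600), FS)
    W = rng.standard_normal((n_dims * len(lags), n_ch))
    feats, eeg = [], []
    for _ in range(n_trials):
        X = rng.standard_normal((n_times, n_dims))
        D = lagged_matrix(X, lags)
        feats.append(fm(X))
        eeg.append(D @ W + noise * rng.standard_normal((n_times, n_ch)))
    return feats, eeg, W, lags


class TestCrossValidation:
    def test_noiseless_fit_recovers_weights_and_predicts(self, rng):
        feats, eeg, W, lags = simulate_linear(rng)
        model = TemporalResponseFunction(eeg, feats)
        res = model.fit_cv()
        assert res.score.per_trial.shape[0] == 4
        assert res.score.mean_r > 0.95
        wflat = np.transpose(res.weights, (2, 1, 0)).reshape(W.shape)
        assert np.corrcoef(wflat.ravel(), W.ravel())[0, 1] > 0.999

    def test_two_trials_give_two_folds(self, rng):
        feats, eeg, _, _ = simulate_linear(rng, n_trials=2)
        res = TemporalResponseFunction(eeg, feats).fit_cv()
        assert res.score.per_trial.shape[0] == 2
        assert len(res.lambda_per_fold) == 2

    def test_heldout_trial_does_not_touch_training_weights(self, rng):
        """Poisoning check: corrupting the held-out trial leaves that
        fold's fitted weights (scored on it) unchanged."""
        feats, eeg, _, _ = simulate_linear(rng, n_trials=4, noise=0.5)
        master = MasterDesign(feats)
        sd = SetDesign(master, list(master.groups))
        res_a = cv_fit(sd, master.cross_products(eeg), inner="loo")
        eeg_poison = [e.copy() for e in eeg]
        eeg_poison[3] += 13.0 * rng.standard_normal(eeg[3].shape)
        res_b = cv_fit(sd, master.cross_products(eeg_poison), inner="loo")
        # lambda chosen for fold 3 depends only on training trials 0-2
        assert res_a.lambda_per_fold[3] == res_b.lambda_per_fold[3]
        # the fold-3 score changes only through the corrupted evaluation
        # data, not through the (unchanged) training weights
        assert not np.allclose(res_a.score.per_trial[3],
                               res_b.score.per_trial[3])

    def test_inner_loo_and_holdout_agree_on_easy_data(self, rng):
        feats, eeg, _, _ = simulate_linear(rng, noise=0.01)
        master = MasterDesign(feats)
        sd = SetDesign(master, list(master.groups))
        st = master.cross_products(eeg)
        r1 = cv_fit(sd, st, inner="holdout").score.mean_r
        r2 = cv_fit(sd, st, inner="loo").score.mean_r
        assert abs(r1 - r2) < 0.05


class TestPredict:
    def test_zero_input_gives_bias_only(self, rng):
        feats, eeg, _, _ = simulate_linear(rng)
        res = TemporalResponseFunction(eeg, feats).fit(1.0)
        zero = fm(np.zeros((50, 3)))
        pred = res.predict(zero)
        np.testing.assert_allclose(pred, np.broadcast_to(res.bias, pred.shape))

    def test_linearity(self, rng):
        feats, eeg, _, _ = simulate_linear(rng)
        res = TemporalResponseFunction(eeg, feats).fit(1.0)
        X = fm(rng.random((80, 3)))
        aX = fm(3.0 * X.values)
        lhs = res.predict(aX) - res.bias
        rhs = 3.0 * (res.predict(X) - res.bias)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_group_mismatch_raises(self, rng):
        feats, eeg, _, _ = simulate_linear(rng)
        res = TemporalResponseFunction(eeg, feats).fit(1.0)
        other = FeatureMatrix(np.zeros((10, 2)), FS, {"Q": slice(0, 2)})
        with pytest.raises(ValueError):
            res.predict(other)

    def test_matches_training_set_fitted_values(self, rng):
        """Refit check: predict() on a training trial equals the ridge
        fitted values computed by explicit normal equations."""
        feats, eeg, _, lags = simulate_linear(rng, n_trials=2, n_times=300,
                                              noise=0.3)
        lam = 10.0
        res = TemporalResponseFunction(eeg, feats).fit(lam)
        # explicit solve on the z-scored lagged design
        master = MasterDesign(feats)
        D = np.vstack(master.D)
        Y = np.vstack(eeg)
        W, bias = ridge_fit(D, Y, lam)
        pred_explicit = (master.D[0] @ W + bias)[None]
        np.testing.assert_allclose(res.predict(feats[0])[None],
                                   pred_explicit, atol=1e-6)


class TestGenericModel:
    def test_average_of_identical_models_is_identity(self, rng):
        feats, eeg, _, _ = simulate_linear(rng)
        res = TemporalResponseFunction(eeg, feats).fit(1.0)
        avg = generic_model([res, res, res])
        np.testing.assert_allclose(avg.weights, res.weights)
        np.testing.assert_allclose(avg.bias, res.bias)

    def test_average_of_opposite_models_is_zero(self, rng):
        feats, eeg, _, _ = simulate_linear(rng)
        res = TemporalResponseFunction(eeg, feats).fit(1.0)
        neg = generic_model([res])
        neg.weights = -neg.weights
        neg.bias = -neg.bias
        avg = generic_model([res, neg])
        np.testing.assert_allclose(avg.weights, 0.0, atol=1e-12)

    def test_shape_mismatch_raises(self, rng):
        feats, eeg, _, _ = simulate_linear(rng)
        a = TemporalResponseFunction(eeg, feats).fit(1.0)
        feats2, eeg2, _, _ = simulate_linear(rng, n_dims=2)
        b = TemporalResponseFunction(eeg2, feats2).fit(1.0)
        with pytest.raises(ValueError):
            generic_model([a, b])


def test_prediction_gain_requires_identical_folds(rng):
    feats, eeg, _, _ = simulate_linear(rng)
    r1 = TemporalResponseFunction(eeg, feats).fit_cv().score
    r2 = TemporalResponseFunction(eeg[:3], feats[:3]).fit_cv().score
    with pytest.raises(ValueError, match="fold"):
        prediction_gain(r1, r2)
    gain = prediction_gain(r1, r1)
    np.testing.assert_allclose(gain, 0.0)


def test_eigen_path_matches_plain_ridge(rng):
    """Oracle equivalence: the cached eigendecomposition solver agrees with
    a brute-force normal-equations solve on a tiny system."""
    feats, eeg, _, _ = simulate_linear(rng, n_trials=2, n_times=200,
                                       n_dims=1, noise=0.2)
    lam = 5.0
    res = TemporalResponseFunction(eeg, feats).fit(lam)
    master = MasterDesign(feats)
    W, bias = ridge_fit(np.vstack(master.D), np.vstack(eeg), lam)
    w_raw = W / master.col_sigma[:, None]
    got = np.transpose(res.weights, (2, 1, 0)).reshape(W.shape)
    np.testing.assert_allclose(got, w_raw, atol=1e-10)
    np.testing.assert_allclose(
        res.bias, bias - (master.col_mu / master.col_sigma) @ W, atol=1e-8)


def test_sentence_shuffled_null_for_prediction_correlation(lang):
    """A TRF predicts the EEG from the true regressors better than from
    sentence-shuffled regressors (permutation null, N=100 shuffles)."""
    import numpy as np
    from speechtrf.features import shuffle_sentences
    from speechtrf.languages import sample_transcript
    from speechtrf.montage import make_montage
    from speechtrf.pipeline import FEATURE_SETS
    from speechtrf.synthetic import (build_stimulus_features,
                                     make_ground_truth_kernels,
                                     simulate_subject_eeg)

    montage = make_montage(8)
    trs = [sample_transcript(lang, 30.0, seed=40 + t) for t in range(3)]
    feats = [build_stimulus_features(lang, tr, 50.0, seed=50 + t)
             .select(FEATURE_SETS["ALL"]) for t, tr in enumerate(trs)]
    kern = make_ground_truth_kernels("L1", lang, montage, fs=50.0,
                                     lang_seed=1)
    eeg = simulate_subject_eeg(feats, kern, 10.0, np.random.default_rng(3))
    res = TemporalResponseFunction(eeg, feats).fit_cv()
    r_true = res.score.mean_r

    rng = np.random.default_rng(11)

    def mean_r(pred, y):
        return np.mean([np.corrcoef(pred[:, c], y[:, c])[0, 1]
                        for c in range(y.shape[1])])

    null = []
    for _ in range(100):
        shuffled = shuffle_sentences(feats[0], trs[0], rng)
        null.append(mean_r(res.predict(shuffled), eeg[0]))
    assert r_true > np.percentile(null, 95)
    assert abs(np.mean(null)) < 0.1
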