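"""Ridge-regularised temporal response function (TRF) estimation.

The model is the statsmodels-style pair :class:`TemporalResponseFunction`
(built from EEG trials and a stimulus :class:`~speechtrf.features.FeatureMatrix`)
and :class:`TRFResults` (weights, regularisation, cross-validated
prediction scores, ``summary()``).

Estimation solves, per channel, ``w = (D'D + lambda I)^-1 D'y`` on a
lagged design with an unpenalised intercept (columns and responses are
centred on the training fold; stimulus features are z-scored per
recording).  The regularisation parameter is tuned on the training fold
of each leave-one-trial-out iteration over a log-spaced grid, and the
final model is refit on all trials at the modal tuned value.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .design import (DEFAULT_LAMBDA_GRID, MasterDesign, SetDesign,
                     SubjectStats, lag_grid, lagged_matrix)
from .features import FeatureMatrix

_EPS = 1e-12


@dataclass
class PredictionScore:
    """Pearson prediction correlations per channel, with per-trial detail."""

    per_trial: np.ndarray  # (n_trials, n_channels)

    @property
    def r_per_channel(self) -> np.ndarray:
        return self.per_trial.mean(axis=0)

    @property
    def mean_r(self) -> float:
        return float(self.per_trial.mean())


@dataclass
class TRFResults:
    """Fitted TRF: weights are (n_channels, n_lags, n_dims) in raw feature
    units; ``bias`` is per channel."""

    weights: np.ndarray
    bias: np.ndarray
    lambda_: float
    lags: np.ndarray
    lag_window_ms: tuple[float, float]
    fs: float
    groups: dict[str, slice]
    score: PredictionScore | None = None
    lambda_per_fold: list[float] = field(default_factory=list)
    channel_names: list[str] | None = None

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def lag_times_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.fs

    def group_weights(self, name: str) -> np.ndarray:
        """(n_channels, n_lags, group_dims) weight block of one feature group."""
        if name not in self.groups:
            raise KeyError(f"feature group {name!r} not in model")
        return self.weights[:, :, self.groups[name]]

    def predict(self, features: FeatureMatrix) -> np.ndarray:
        """Linear prediction of EEG (n_times, n_channels) for one trial."""
        names = list(self.groups)
        if any(n not in features.groups for n in names):
            raise ValueError("feature groups do not match the model")
        X = features.select(names).values
        if X.shape[1] != self.weights.shape[2]:
            raise ValueError("feature dimensionality does not match the model")
        D = lagged_matrix(X, self.lags)
        # design columns are dim-major: weights transpose to (dims, lags, ch)
        wflat = np.transpose(self.weights, (2, 1, 0)).reshape(D.shape[1], -1)
        return D @ wflat + self.bias[None, :]

    def summary(self) -> str:
        lines = ["Temporal response function (ridge)",
                 "=" * 42,
                 f"channels:        {self.n_channels}",
                 f"lag window (ms): ({self.lag_window_ms[0]:g}, "
                 f"{self.lag_window_ms[1]:g}], {len(self.lags)} lags "
                 f"@ {self.fs:g} Hz",
                 f"lambda:          {self.lambda_:g}"]
        if self.lambda_per_fold:
            lines.append(f"fold lambdas:    {[f'{l:g}' for l in self.lambda_per_fold]}")
        if self.score is not None:
            lines.append(f"CV prediction r: {self.score.mean_r:+.4f} "
                         f"(mean over {self.score.per_trial.shape[0]} trials x "
                         f"{self.n_channels} channels)")
        lines.append("feature groups (dims, RMS weight):")
        for g, sl in self.groups.items():
            block = self.weights[:, :, sl]
            lines.append(f"  {g:<5} {sl.stop - sl.start:>3}  "
                         f"{np.sqrt(np.mean(block ** 2)):.4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# plain ridge solver (small-system oracle surface)

def ridge_fit(D: np.ndarray, Y: np.ndarray, lam: float,
              fit_intercept: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Solve ``(D'D + lam I) w = D'Y`` per channel, intercept unpenalised.

    Returns (weights (K, n_channels), bias (n_channels,)).  Raises for a
    singular system at lam = 0.
    """
    D = np.atleast_2d(np.asarray(D, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if D.shape[0] != Y.shape[0]:
        raise ValueError("row counts of design and response differ")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if fit_intercept:
        mx, my = D.mean(axis=0), Y.mean(axis=0)
        Dc, Yc = D - mx, Y - my
    else:
        mx = np.zeros(D.shape[1])
        my = np.zeros(Y.shape[1])
        Dc, Yc = D, Y
    G = Dc.T @ Dc + lam * np.eye(D.shape[1])
    if lam == 0:
        cond = np.linalg.cond(G)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "normal equations are singular at lambda=0; use lambda>0")
    W = np.linalg.solve(G, Dc.T @ Yc)
    bias = my - mx @ W
    return W, bias


# ---------------------------------------------------------------------------
# fold-cached estimation on shared designs

def _centered_C(st: SubjectStats, excl: frozenset, fold) -> tuple[np.ndarray, np.ndarray]:
    train = [t for t in range(len(st.C)) if t not in excl]
    C = np.sum([st.C[t] for t in train], axis=0)
    ysum = np.sum([st.ysum[t] for t in train], axis=0)
    ybar = ysum / fold.n
    Cc = C - np.outer(fold.m * fold.n, ybar)
    return Cc, ybar


def _solve_eigen(fold, Ct: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0 and fold.omega.min() < 1e-10 * max(fold.omega.max(), 1.0):
        raise np.linalg.LinAlgError(
            "normal equations are singular at lambda=0; use lambda>0")
    return Ct / (fold.omega[:, None] + lam)


def _score_trial(Wt: np.ndarray, Gt_j: np.ndarray, st_j: np.ndarray,
                 Ct_j: np.ndarray, ysum_j: np.ndarray, yss_j: np.ndarray,
                 N_j: int, warn: bool = True) -> np.ndarray:
    """Pearson r per channel of the trial-j prediction, from sufficient
    statistics in the fold eigenbasis."""
    a = (st_j[:, None] * Wt).sum(axis=0)
    b = (Ct_j * Wt).sum(axis=0)
    q = (Wt * (Gt_j @ Wt)).sum(axis=0)
    cov = b - a * ysum_j / N_j
    vy = yss_j - ysum_j ** 2 / N_j
    vp = np.maximum(q - a ** 2 / N_j, 0.0)
    denom = np.sqrt(vp * np.maximum(vy, 0.0))
    bad = denom <= _EPS * max(N_j, 1)
    if warn and bad.any():
        warnings.warn("constant prediction or response on some channels; "
                      "their r is set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(bad, 0.0, cov / np.where(bad, 1.0, denom))
    return np.clip(r, -1.0, 1.0)


def _fit_fold(sd: SetDesign, st: SubjectStats, excl: frozenset, lam: float):
    fold = sd.eig(excl)
    Cc, ybar = _centered_C(st, excl, fold)
    Ct = fold.V.T @ Cc
    Wt = _solve_eigen(fold, Ct, lam)
    return fold, Wt, ybar


def _results_from_fold(sd: SetDesign, fold, Wt: np.ndarray, ybar: np.ndarray,
                       lam: float, channel_names=None) -> TRFResults:
    master = sd.master
    w_z = fold.V @ Wt  # (K, n_channels), dim-major rows
    n_dims = len(sd.dims)
    n_lags = master.n_lags
    sigma = master.col_sigma[sd.cols]
    mu = master.col_mu[sd.cols]
    w_raw = w_z / sigma[:, None]
    weights = np.transpose(w_raw.reshape(n_dims, n_lags, -1), (2, 1, 0))
    bias = ybar - fold.m @ w_z - (mu / sigma) @ w_z
    return TRFResults(weights=weights, bias=bias, lambda_=float(lam),
                      lags=master.lags.copy(),
                      lag_window_ms=master.lag_window_ms, fs=master.fs,
                      groups=dict(sd.groups), channel_names=channel_names)


def cv_fit(sd: SetDesign, stats: SubjectStats,
           lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
           inner: str = "holdout", channel_names=None) -> TRFResults:
    """Leave-one-trial-out cross-validated TRF fit.

    For each held-out trial the regularisation parameter is tuned within
    the training fold (``inner='holdout'``: one training trial reserved
    for validation; ``inner='loo'``: full inner leave-one-out), the model
    is refit on the training fold at the tuned value and scored on the
    held-out trial.  The final model is refit on all trials at the modal
    fold-wise lambda.
    """
    st = sd.slice_stats(stats)
    n = sd.n_trials
    if n < 2:
        raise ValueError("cross-validation needs at least 2 trials")
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    lam_sel: list[float] = []
    rows = np.zeros((n, st.n_channels))
    for i in range(n):
        train = [t for t in range(n) if t != i]
        if len(train) >= 2:
            if inner == "holdout":
                inner_pairs = [((i - 1) % n,)]
                inner_pairs = [(frozenset({i, j[0]}), j[0]) for j in inner_pairs]
            elif inner == "loo":
                inner_pairs = [(frozenset({i, j}), j) for j in train]
            else:
                raise ValueError("inner must be 'holdout' or 'loo'")
            mean_r = np.zeros(grid.size)
            for excl, j in inner_pairs:
                fold = sd.eig(excl)
                Cc, _ = _centered_C(st, excl, fold)
                Ct = fold.V.T @ Cc
                Gt_j, st_j = sd.eval_stats(excl, j)
                Ct_j = fold.V.T @ st.C[j]
                for li, lam in enumerate(grid):
                    Wt = _solve_eigen(fold, Ct, lam)
                    r = _score_trial(Wt, Gt_j, st_j, Ct_j, st.ysum[j],
                                     st.yss[j], st.N[j], warn=False)
                    mean_r[li] += float(r.mean())
            lam_i = float(grid[int(np.argmax(mean_r))])
        else:
            lam_i = float(np.median(grid))  # 2-trial degenerate case
        lam_sel.append(lam_i)
        excl = frozenset({i})
        fold, Wt, _ = _fit_fold(sd, st, excl, lam_i)
        Gt_i, st_i = sd.eval_stats(excl, i)
        Ct_i = fold.V.T @ st.C[i]
        rows[i] = _score_trial(Wt, Gt_i, st_i, Ct_i, st.ysum[i], st.yss[i],
                               st.N[i])
    counts = Counter(lam_sel)
    top = max(counts.values())
    lam_star = min(l for l, c in counts.items() if c == top)
    fold, Wt, ybar = _fit_fold(sd, st, frozenset(), lam_star)
    res = _results_from_fold(sd, fold, Wt, ybar, lam_star, channel_names)
    res.score = PredictionScore(rows)
    res.lambda_per_fold = lam_sel
    return res


def fit_at(sd: SetDesign, stats: SubjectStats, lam: float,
           channel_names=None) -> TRFResults:
    """Fit on all trials at a fixed regularisation value."""
    st = sd.slice_stats(stats)
    fold, Wt, ybar = _fit_fold(sd, st, frozenset(), lam)
    return _results_from_fold(sd, fold, Wt, ybar, lam, channel_names)


def zspace_flat_weights(res: TRFResults, sd: SetDesign) -> np.ndarray:
    """Express raw-unit weights in the design's z-scored column space."""
    wflat = np.transpose(res.weights, (2, 1, 0)).reshape(sd.K, -1)
    return wflat * sd.master.col_sigma[sd.cols][:, None]


def score_weights(sd: SetDesign, stats: SubjectStats, res: TRFResults
                  ) -> PredictionScore:
    """Prediction correlations of fixed weights (e.g. a generic model) on a
    subject's recording, per trial and channel."""
    st = sd.slice_stats(stats)
    W = zspace_flat_weights(res, sd)
    rows = np.zeros((sd.n_trials, st.n_channels))
    for j in range(sd.n_trials):
        a = st.ysum[j] * 0 + (sd.s[j][:, None] * W).sum(axis=0)
        b = (st.C[j] * W).sum(axis=0)
        q = (W * (sd.G[j] @ W)).sum(axis=0)
        cov = b - a * st.ysum[j] / st.N[j]
        vy = st.yss[j] - st.ysum[j] ** 2 / st.N[j]
        vp = np.maximum(q - a ** 2 / st.N[j], 0.0)
        denom = np.sqrt(vp * np.maximum(vy, 0.0))
        bad = denom <= _EPS * st.N[j]
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[j] = np.where(bad, 0.0, cov / np.where(bad, 1.0, denom))
    return PredictionScore(np.clip(rows, -1.0, 1.0))


# ---------------------------------------------------------------------------
# public model surface

class TemporalResponseFunction:
    """Forward encoding model from stimulus features to multichannel EEG.

    Parameters
    ----------
    eeg_trials
        List of (n_times, n_channels) arrays, one per trial.
    feature_trials
        Matching list of :class:`FeatureMatrix` trials (shared stimulus).
    lag_window_ms
        Half-open response window ``(t1, t1 + t_win]`` in milliseconds.
    """

    def __init__(self, eeg_trials: list[np.ndarray],
                 feature_trials: list[FeatureMatrix],
                 lag_window_ms: tuple[float, float] = (0.0, 600.0),
                 channel_names: list[str] | None = None,
                 design: MasterDesign | None = None):
        if len(eeg_trials) != len(feature_trials):
            raise ValueError("trial counts of EEG and features differ")
        self.master = design or MasterDesign(feature_trials, lag_window_ms)
        self.set_design = SetDesign(self.master, list(self.master.groups))
        self.stats = self.master.cross_products(eeg_trials)
        self.channel_names = channel_names

    def fit(self, lam: float) -> TRFResults:
        """Fit on all trials at a fixed ridge parameter."""
        return fit_at(self.set_design, self.stats, lam, self.channel_names)

    def fit_cv(self, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
               inner: str = "holdout") -> TRFResults:
        """Leave-one-trial-out cross-validated fit with lambda tuning."""
        return cv_fit(self.set_design, self.stats, lambda_grid, inner,
                      self.channel_names)


def cross_validate(feature_trials: list[FeatureMatrix],
                   eeg_trials: list[np.ndarray],
                   lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
                   inner: str = "holdout") -> TRFResults:
    """Functional wrapper around :class:`TemporalResponseFunction`."""
    model = TemporalResponseFunction(eeg_trials, feature_trials)
    return model.fit_cv(lambda_grid, inner)


def predict_eeg(res: TRFResults, features: FeatureMatrix) -> np.ndarray:
    return res.predict(features)


def prediction_gain(score_with: PredictionScore,
                    score_without: PredictionScore) -> np.ndarray:
    """Per-channel increase in prediction r when extra features are added.

    Both scores must come from identical folds (same trial partition)."""
    if score_with.per_trial.shape != score_without.per_trial.shape:
        raise ValueError("fold mismatch between the two scores")
    return score_with.r_per_channel - score_without.r_per_channel


def generic_model(models: list[TRFResults]) -> TRFResults:
    """Group-average TRF: element-wise mean of weights and biases."""
    if not models:
        raise ValueError("need at least one model")
    first = models[0]
    for m in models[1:]:
        if m.weights.shape != first.weights.shape or list(m.groups) != list(first.groups):
            raise ValueError("models have mismatching shapes or feature maps")
        if not np.array_equal(m.lags, first.lags):
            raise ValueError("models have mismatching lag grids")
    return TRFResults(
        weights=np.mean([m.weights for m in models], axis=0),
        bias=np.mean([m.bias for m in models], axis=0),
        lambda_=float(np.mean([m.lambda_ for m in models])),
        lags=first.lags.copy(), lag_window_ms=first.lag_window_ms,
        fs=first.fs, groups=dict(first.groups),
        channel_names=first.channel_names)
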