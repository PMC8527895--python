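"""Proficiency decoding from TRF-derived features.

Each subject is described by 26 scalar features: 9 derived from TRF model
weights (rank-1 multilinear PCA scores and fixed-window weight means),
5 from subject-specific EEG prediction correlations, and 12 from
generic-model (group-average TRF) prediction correlations (4 groups x 3
predictor sets).  A support vector regression with an RBF kernel decodes
the CEFR level (1-6) with leave-one-subject-out cross-validation;
backward elimination prunes the feature set on the out-of-fold MSE.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR


# ---------------------------------------------------------------------------
# multilinear PCA

def mpca_first_component(tensor: np.ndarray, n_iter: int = 200,
                         tol: float = 1e-12) -> np.ndarray:
    """Per-subject scores of the best rank-1 multilinear fit.

    ``tensor`` is subjects x mode2 [x mode3 [x mode4]].  Alternating least
    squares fits ``X ~ u (x) v (x) w`` with unit-norm non-subject modes;
    the returned subject scores are ``u`` carrying the scale.  The sign is
    fixed so that the scores correlate positively with the projection of
    the subject-mean slice.
    """
    X = np.asarray(tensor, dtype=float)
    if X.ndim < 2:
        raise ValueError("tensor must have at least 2 modes")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if not np.any(X):
        raise ValueError("all-zero tensor has no principal component")
    modes = [np.linalg.svd(_unfold(X, ax), full_matrices=False)[0][:, 0]
             for ax in range(1, X.ndim)]
    u = _contract(X, dict(enumerate(modes, start=1)))
    prev = np.inf
    for _ in range(n_iter):
        uhat = u / max(np.linalg.norm(u), 1e-300)
        for ax in range(1, X.ndim):
            vecs = {0: uhat}
            vecs.update({a: modes[a - 1] for a in range(1, X.ndim) if a != ax})
            v = _contract(X, vecs)
            nv = np.linalg.norm(v)
            if nv == 0:
                raise ValueError("degenerate tensor in MPCA iteration")
            modes[ax - 1] = v / nv
        u = _contract(X, dict(enumerate(modes, start=1)))
        err = float(np.linalg.norm(u))
        if abs(err - prev) <= tol * max(err, 1.0):
            break
        prev = err
    mean_proj = float(_contract(X.mean(axis=0),
                                {a - 1: m for a, m in enumerate(modes, start=1)}))
    if mean_proj < 0:
        u = -u
        modes[0] = -modes[0]
    return u


def _unfold(X: np.ndarray, axis: int) -> np.ndarray:
    return np.moveaxis(X, axis, 0).reshape(X.shape[axis], -1)


def _contract(X: np.ndarray, vectors: dict[int, np.ndarray]) -> np.ndarray:
    """Contract X with one vector per listed axis (highest axes first, so
    the stored axis numbers stay valid)."""
    out = X
    for ax in sorted(vectors, reverse=True):
        out = np.tensordot(out, vectors[ax], axes=(ax, 0))
    return out


# ---------------------------------------------------------------------------
# weight summaries

def window_summary(trf_weights: np.ndarray, lag_times_ms: np.ndarray,
                   window_ms: tuple[float, float],
                   channel_names: list[str], electrodes: list[str],
                   clip: bool = False) -> float:
    """Mean TRF weight over a latency window and an electrode set.

    ``trf_weights`` is (n_channels, n_lags[, dims]).  With ``clip=True``
    the window is intersected with the available lag range instead of
    raising when it extends beyond it.
    """
    lo, hi = window_ms
    if clip:
        lo = max(lo, float(lag_times_ms.min()))
        hi = min(hi, float(lag_times_ms.max()))
    mask = (lag_times_ms >= lo) & (lag_times_ms <= hi)
    if not mask.any() or lo < lag_times_ms.min() - 1e-9 \
            or hi > lag_times_ms.max() + 1e-9:
        raise ValueError("window outside the model lag range")
    missing = [e for e in electrodes if e not in channel_names]
    if missing:
        raise KeyError(f"electrodes {missing} absent")
    ci = [channel_names.index(e) for e in electrodes]
    block = trf_weights[ci][:, mask]
    return float(block.mean())


# ---------------------------------------------------------------------------
# decoding

def svr_loo_decode(features: np.ndarray, labels: np.ndarray,
                   C: float = 1.0, epsilon: float = 0.1
                   ) -> tuple[np.ndarray, float, float]:
    """Leave-one-subject-out SVR (RBF kernel) decoding of a continuous
    label.  Features are standardised on the training fold only.

    Returns (out-of-fold predictions, MSE, Pearson r).  Predictions are
    continuous (decimal) values, not restricted to the label levels.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    n = len(y)
    if n < 6:
        raise ValueError("need at least 6 subjects for decoding")
    preds = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        scaler = StandardScaler().fit(X[tr])
        model = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma="scale")
        model.fit(scaler.transform(X[tr]), y[tr])
        preds[i] = model.predict(scaler.transform(X[i][None]))[0]
    mse = float(np.mean((preds - y) ** 2))
    if np.ptp(y) == 0 or np.std(preds) == 0:
        return preds, mse, float("nan")
    r = float(sstats.pearsonr(preds, y)[0])
    return preds, mse, r


def backward_eliminate(features: np.ndarray, labels: np.ndarray,
                       feature_names: list[str] | None = None,
                       min_improvement: float = 0.05
                       ) -> tuple[list[int], list[tuple[int | None, float]]]:
    """Greedy backward elimination on the out-of-fold decoding MSE.

    At each step the feature whose removal lowers the MSE most is dropped;
    elimination stops when the best removal improves the current MSE by
    less than ``min_improvement`` (relative).  Returns the surviving
    feature indices and the elimination trace [(removed_index, mse), ...]
    starting with (None, initial mse).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    selected = list(range(X.shape[1]))
    _, mse, _ = svr_loo_decode(X[:, selected], y)
    trace: list[tuple[int | None, float]] = [(None, mse)]
    while len(selected) > 1:
        best_mse, best_idx = np.inf, None
        for idx in selected:
            cand = [j for j in selected if j != idx]
            _, m, _ = svr_loo_decode(X[:, cand], y)
            if m < best_mse:
                best_mse, best_idx = m, idx
        if best_mse >= mse * (1.0 - min_improvement):
            break
        selected.remove(best_idx)
        trace.append((best_idx, best_mse))
        mse = best_mse
    return selected, trace


def threshold_binary_accuracy(predictions: np.ndarray, labels: np.ndarray,
                              threshold: float = 3.5) -> float:
    """A-vs-C accuracy of thresholded continuous predictions.

    Subjects with label <= 2 are A-level, >= 5 are C-level; predictions
    strictly above the threshold classify as C (ties go to A).
    """
    preds = np.asarray(predictions, float)
    y = np.asarray(labels, float)
    mask = (y <= 2) | (y >= 5)
    if not (y[mask] <= 2).any() or not (y[mask] >= 5).any():
        raise ValueError("need both A-level and C-level subjects")
    truth_c = y[mask] >= 5
    pred_c = preds[mask] > threshold
    return float(np.mean(truth_c == pred_c))


def permutation_baseline_classify(features: np.ndarray, labels: np.ndarray,
                                  n_shuffles: int = 100, seed: int = 0,
                                  C: float = 1.0
                                  ) -> tuple[float, float, np.ndarray]:
    """LOO SVM binary classification accuracy and its shuffled-label
    baseline (95th percentile over ``n_shuffles`` permutations)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least 2 subjects")
    rng = np.random.default_rng(seed)

    def loo_accuracy(yy: np.ndarray) -> float:
        n = len(yy)
        correct = 0
        for i in range(n):
            tr = np.arange(n) != i
            if len(np.unique(yy[tr])) < 2:
                continue
            scaler = StandardScaler().fit(X[tr])
            clf = SVC(kernel="rbf", C=C, gamma="scale")
            clf.fit(scaler.transform(X[tr]), yy[tr])
            correct += int(clf.predict(scaler.transform(X[i][None]))[0] == yy[i])
        return correct / n

    accuracy = loo_accuracy(y)
    null = np.array([loo_accuracy(rng.permutation(y))
                     for _ in range(n_shuffles)])
    return accuracy, float(np.percentile(null, 95)), null
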