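"""Lagged design matrices for temporal response function estimation.

The TRF design holds time-shifted copies of every stimulus feature.  For a
lag window ``(t1, t1 + t_win]`` (half-open, so a 0-600 ms window at 50 Hz
yields 30 lags), the design column for feature dimension d and lag l is
``x_d(t - l)`` with zero padding at trial onsets.

Because every subject of a cohort hears the same stimulus, the stimulus
side of the normal equations (per-trial Gram matrices, fold-wise
eigendecompositions, column sums) is shared.  :class:`MasterDesign` caches
those quantities once over the full 43-dimension descriptor;
:class:`SetDesign` views a column subset (a descriptor set such as ALL or
EXT) with its own fold caches.  Per-subject data enter only through
cross-products, held in :class:`SubjectStats`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix

#: regularisation grid: 13 points log-spaced over 1e-2 .. 1e10
DEFAULT_LAMBDA_GRID = np.logspace(-2, 10, 13)


def lag_grid(lag_window_ms: tuple[float, float] = (0.0, 600.0),
             fs: float = 50.0) -> np.ndarray:
    """Sample lags in the half-open window ``(t1, t2]`` (ms)."""
    t1, t2 = lag_window_ms
    if not (-2000 < t1 < 2000 and -2000 < t2 <= 2000) or t2 <= t1:
        raise ValueError("lag window must be increasing and within ±2000 ms")
    first = int(np.floor(t1 * fs / 1000.0)) + 1
    last = int(np.round(t2 * fs / 1000.0))
    if last < first:
        raise ValueError("empty lag grid: window too short for this fs")
    return np.arange(first, last + 1)


def lagged_matrix(X: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """(T, d) -> (T, d * n_lags); columns ordered dim-major (lags contiguous
    within a dimension).  Out-of-range samples are zero."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T, d = X.shape
    out = np.zeros((T, d * len(lags)))
    for di in range(d):
        for li, lag in enumerate(lags):
            col = di * len(lags) + li
            if lag >= 0:
                out[lag:, col] = X[:T - lag, di] if lag < T else 0.0
            else:
                out[:T + lag, col] = X[-lag:, di] if -lag < T else 0.0
    return out


@dataclass
class EigFold:
    """Eigendecomposition of a centred training-fold Gram matrix."""

    omega: np.ndarray  # (K,) eigenvalues, clipped at 0
    V: np.ndarray      # (K, K)
    m: np.ndarray      # (K,) training column means
    n: int             # training sample count


class MasterDesign:
    """Shared, z-scored, lagged stimulus design over all trials."""

    def __init__(self, feature_trials: list[FeatureMatrix],
                 lag_window_ms: tuple[float, float] = (0.0, 600.0)):
        if not feature_trials:
            raise ValueError("need at least one trial")
        fs = feature_trials[0].fs
        self.fs = fs
        self.groups = dict(feature_trials[0].groups)
        self.lag_window_ms = tuple(lag_window_ms)
        self.lags = lag_grid(lag_window_ms, fs)
        self.n_lags = len(self.lags)
        raw = [np.asarray(t.values, dtype=float) for t in feature_trials]
        self.n_dims = raw[0].shape[1]
        lagged = [lagged_matrix(t, self.lags) for t in raw]
        cat = np.vstack(lagged)
        # z-scoring is per lagged column so that the zero padding at trial
        # onsets stays inside the column span (pre-trial silence)
        self.col_mu = cat.mean(axis=0)
        sd = cat.std(axis=0)
        self.col_sigma = np.where(sd > 0, sd, 1.0)
        self.D = [(d - self.col_mu) / self.col_sigma for d in lagged]
        self.N = [d.shape[0] for d in self.D]
        self.G = None  # master Grams computed on demand by SetDesign
        self.s = [d.sum(axis=0) for d in self.D]

    @property
    def n_trials(self) -> int:
        return len(self.D)

    def master_grams(self) -> list[np.ndarray]:
        if self.G is None:
            self.G = [d.T @ d for d in self.D]
        return self.G

    def dim_indices(self, group_names: list[str]) -> np.ndarray:
        missing = [g for g in group_names if g not in self.groups]
        if missing:
            raise KeyError(f"missing feature groups: {missing}")
        return np.concatenate([np.arange(self.groups[g].start,
                                         self.groups[g].stop)
                               for g in group_names])

    def column_indices(self, dims: np.ndarray) -> np.ndarray:
        nl = self.n_lags
        return np.concatenate([np.arange(d * nl, (d + 1) * nl) for d in dims])

    def cross_products(self, eeg_trials: list[np.ndarray]) -> "SubjectStats":
        """Per-trial cross-products of one subject's EEG with the design."""
        if len(eeg_trials) != self.n_trials:
            raise ValueError("EEG trial count does not match the design")
        C, ysum, yss = [], [], []
        for D, Y in zip(self.D, eeg_trials):
            Y = np.atleast_2d(np.asarray(Y, dtype=float))
            if Y.shape[0] != D.shape[0]:
                raise ValueError("EEG trial length does not match the design")
            C.append(D.T @ Y)
            ysum.append(Y.sum(axis=0))
            yss.append((Y ** 2).sum(axis=0))
        return SubjectStats(C, ysum, yss, list(self.N))


@dataclass
class SubjectStats:
    """Per-trial sufficient statistics of one subject's EEG."""

    C: list[np.ndarray]      # (K_master, n_channels) per trial
    ysum: list[np.ndarray]   # (n_channels,)
    yss: list[np.ndarray]    # (n_channels,)
    N: list[int]

    @property
    def n_channels(self) -> int:
        return self.C[0].shape[1]


class SetDesign:
    """Column subset of a master design with fold-level caches."""

    def __init__(self, master: MasterDesign, group_names: list[str]):
        self.master = master
        self.group_names = list(group_names)
        self.dims = master.dim_indices(self.group_names)
        self.cols = master.column_indices(self.dims)
        grams = master.master_grams()
        ix = np.ix_(self.cols, self.cols)
        self.G = [g[ix] for g in grams]
        self.s = [s[self.cols] for s in master.s]
        self.N = list(master.N)
        self.K = len(self.cols)
        # group slices within the subset, dim-major like the master
        self.groups: dict[str, slice] = {}
        start = 0
        for g in self.group_names:
            width = master.groups[g].stop - master.groups[g].start
            self.groups[g] = slice(start, start + width)
            start += width
        self._eig: dict[frozenset, EigFold] = {}
        self._eval: dict[tuple[frozenset, int], tuple[np.ndarray, np.ndarray]] = {}

    @property
    def n_trials(self) -> int:
        return len(self.G)

    def slice_stats(self, stats: SubjectStats) -> SubjectStats:
        return SubjectStats([c[self.cols] for c in stats.C],
                            stats.ysum, stats.yss, stats.N)

    def eig(self, excl: frozenset = frozenset()) -> EigFold:
        excl = frozenset(excl)
        if excl not in self._eig:
            train = [t for t in range(self.n_trials) if t not in excl]
            if not train:
                raise ValueError("no training trials left")
            n = sum(self.N[t] for t in train)
            s = np.sum([self.s[t] for t in train], axis=0)
            m = s / n
            G = np.sum([self.G[t] for t in train], axis=0)
            Gc = G - n * np.outer(m, m)
            omega, V = np.linalg.eigh(Gc)
            self._eig[excl] = EigFold(np.clip(omega, 0.0, None), V, m, n)
        return self._eig[excl]

    def eval_stats(self, excl: frozenset, j: int
                   ) -> tuple[np.ndarray, np.ndarray]:
        """(V' G_j V, V' s_j) for scoring trial j under fold ``excl``."""
        key = (frozenset(excl), j)
        if key not in self._eval:
            f = self.eig(excl)
            self._eval[key] = (f.V.T @ self.G[j] @ f.V, f.V.T @ self.s[j])
        return self._eval[key]

    def clear_cache(self) -> None:
        self._eig.clear()
        self._eval.clear()
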