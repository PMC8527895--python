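"""Offline EEG conditioning: band-pass filtering, downsampling, and
variance-based bad-channel replacement by spherical-spline interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.special import eval_legendre

from .features import _resample_ratio
from .montage import Montage

TARGET_FS = 50.0
BAND = (1.0, 15.0)


@dataclass
class EEGRecording:
    """Multi-trial multichannel EEG with a sensor montage."""

    trials: list[np.ndarray]  # each (n_times, n_channels)
    fs: float
    montage: Montage

    def __post_init__(self) -> None:
        self.trials = [np.atleast_2d(np.asarray(t, dtype=float))
                       for t in self.trials]
        n_ch = {t.shape[1] for t in self.trials}
        if len(n_ch) != 1 or n_ch.pop() != self.montage.n_channels:
            raise ValueError("all trials must share the montage channel set")

    @property
    def n_channels(self) -> int:
        return self.montage.n_channels

    def concatenated(self) -> np.ndarray:
        return np.vstack(self.trials)


def bandpass_downsample(rec: EEGRecording, band: tuple[float, float] = BAND,
                        fs_out: float = TARGET_FS) -> EEGRecording:
    """Zero-phase Butterworth band-pass (order 2+2) then anti-aliased
    resampling to ``fs_out``.  Output length is round(len * fs_out / fs).
    """
    if rec.fs < 2 * band[1]:
        raise ValueError(f"sampling rate {rec.fs} Hz too low for a "
                         f"{band[1]} Hz band edge")
    sos = signal.butter(2, band, btype="bandpass", fs=rec.fs, output="sos")
    up, down = _resample_ratio(fs_out, rec.fs)
    out = []
    for trial in rec.trials:
        filt = signal.sosfiltfilt(sos, trial, axis=0)
        out.append(signal.resample_poly(filt, up, down, axis=0,
                                        window=("kaiser", 5.0)))
    return replace(rec, trials=out, fs=fs_out)


# ---------------------------------------------------------------------------
# spherical-spline interpolation (Perrin-style)

def _g_matrix(cosang: np.ndarray, m: int = 4, n_terms: int = 20) -> np.ndarray:
    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n ** m * (n + 1.0) ** m) / (4 * np.pi)
    cosang = np.clip(cosang, -1.0, 1.0)
    out = np.zeros_like(cosang, dtype=float)
    for ni, ci in zip(n, coef):
        out += ci * eval_legendre(ni, cosang)
    return out


def spherical_spline_interpolate(data: np.ndarray, pos_good: np.ndarray,
                                 pos_bad: np.ndarray, m: int = 4,
                                 reg: float = 1e-5) -> np.ndarray:
    """Interpolate bad-channel time courses from good channels.

    ``data`` is (n_times, n_good); positions are unit-sphere coordinates.
    Spline order ``m`` and ridge term ``reg`` follow the package defaults.
    """
    G = _g_matrix(pos_good @ pos_good.T, m=m)
    n = G.shape[0]
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + reg * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    rhs = np.vstack([data.T, np.zeros((1, data.shape[0]))])
    sol = np.linalg.solve(A, rhs)
    c, c0 = sol[:n], sol[n]
    Gb = _g_matrix(pos_bad @ pos_good.T, m=m)
    return (Gb @ c + c0[None, :]).T


def interpolate_bad_channels(rec: EEGRecording, ratio: float = 3.0,
                             n_neighbors: int = 6
                             ) -> tuple[EEGRecording, list[str]]:
    """Replace channels whose variance exceeds ``ratio`` times the mean
    variance of their ``n_neighbors`` nearest neighbours.

    Returns the cleaned recording and the list of replaced channel names.
    Aborts if more than half the channels are flagged.
    """
    data = rec.concatenated()
    var = data.var(axis=0)
    pos = rec.montage.pos3d
    n_ch = rec.n_channels
    if n_ch < 5:
        raise ValueError("need at least 4 good channels for interpolation")
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    neigh = np.argsort(d2, axis=1)[:, :n_neighbors]
    bad = np.where(var > ratio * var[neigh].mean(axis=1))[0]
    if len(bad) == 0:
        return rec, []
    if len(bad) > n_ch // 2:
        raise ValueError(f"{len(bad)} of {n_ch} channels flagged bad; "
                         "recording quality too poor to interpolate")
    good = np.setdiff1d(np.arange(n_ch), bad)
    out = []
    for trial in rec.trials:
        fixed = trial.copy()
        fixed[:, bad] = spherical_spline_interpolate(
            trial[:, good], pos[good], pos[bad])
        out.append(fixed)
    names = [rec.montage.names[i] for i in bad]
    return replace(rec, trials=out), names
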