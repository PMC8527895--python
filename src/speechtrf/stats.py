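"""Group-level statistics and TRF component metrics.

Point-by-point one-way ANOVA with Benjamini-Hochberg FDR correction over
(lag, electrode) points; N1-P2 peak-to-peak amplitudes; trough latency in
a late window; cosine distance of a subject's TRF to a group-mean TRF;
rank correlation; and a fixed-effects three-way ANOVA (proficiency x
latency x electrode) with a Greenhouse-Geisser-style adjustment of the
latency factor when sphericity is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests


@dataclass
class SignificanceMask:
    f_stat: np.ndarray   # (n_lags, n_electrodes)
    p_values: np.ndarray
    q_values: np.ndarray
    mask: np.ndarray     # boolean, q < alpha
    alpha: float = 0.05


def pointwise_anova_fdr(weights_by_group: list[np.ndarray],
                        alpha: float = 0.05) -> SignificanceMask:
    """One-way fixed-effects ANOVA at every (lag, electrode) point.

    Each entry of ``weights_by_group`` is (n_subjects, n_lags, n_electrodes)
    (or any matching trailing shape).  BH-FDR is applied across all tested
    points jointly.
    """
    if len(weights_by_group) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.shape[0] < 2 for g in weights_by_group):
        raise ValueError("each group needs at least 2 subjects")
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = sstats.f_oneway(*weights_by_group, axis=0)
    p = np.where(np.isfinite(p), p, 1.0)
    flat = p.ravel()
    rej, q, _, _ = multipletests(flat, alpha=alpha, method="fdr_bh")
    return SignificanceMask(np.where(np.isfinite(f), f, 0.0), p,
                            q.reshape(p.shape), rej.reshape(p.shape), alpha)


def peak_to_peak(trf_curve: np.ndarray, lag_times_ms: np.ndarray,
                 n1_window: tuple[float, float] = (50.0, 150.0),
                 p2_window: tuple[float, float] = (150.0, 300.0)) -> float:
    """N1-P2 complex amplitude: (max in the P2 window) - (min in the N1
    window) of an electrode-averaged TRF lag curve."""
    curve = np.asarray(trf_curve, float)
    if curve.ndim == 2:  # (n_channels, n_lags) -> electrode average
        curve = curve.mean(axis=0)
    for w in (n1_window, p2_window):
        if w[0] < lag_times_ms.min() - 1e-9 or w[1] > lag_times_ms.max() + 1e-9:
            raise ValueError("search window outside the lag range")
    n1 = curve[(lag_times_ms >= n1_window[0]) & (lag_times_ms <= n1_window[1])]
    p2 = curve[(lag_times_ms >= p2_window[0]) & (lag_times_ms <= p2_window[1])]
    return float(p2.max() - n1.min())


def trough_latency(trf_curve: np.ndarray, lag_times_ms: np.ndarray,
                   window_ms: tuple[float, float] = (300.0, 600.0)
                   ) -> tuple[float, bool]:
    """Latency of the largest negative TRF magnitude within the window.

    Ties resolve to the earliest latency.  The flag is False when the
    window contains no negative value (the argmin latency is still
    returned)."""
    curve = np.asarray(trf_curve, float)
    mask = (lag_times_ms >= window_ms[0]) & (lag_times_ms <= window_ms[1])
    if not mask.any():
        raise ValueError("window outside the lag range")
    seg = curve[mask]
    times = lag_times_ms[mask]
    i = int(np.argmin(seg))  # argmin returns the first (earliest) minimum
    return float(times[i]), bool(seg[i] < 0)


def cosine_distance_to_group(subject_trf: np.ndarray,
                             reference_trfs: list[np.ndarray] | np.ndarray
                             ) -> float:
    """1 - cosine similarity between a subject TRF and the element-wise
    mean reference TRF, flattened over electrodes and latencies."""
    if isinstance(reference_trfs, (list, tuple)):
        ref = np.mean([np.asarray(t, float) for t in reference_trfs], axis=0)
    else:
        ref = np.asarray(reference_trfs, float)
    a = np.asarray(subject_trf, float).ravel()
    b = ref.ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm TRF in cosine distance")
    return float(1.0 - a @ b / (na * nb))


def rank_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (ties mid-ranked) with p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined rank correlation")
    rho, p = sstats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# three-way fixed-effects ANOVA on TRF weights

def threeway_anova(weights_by_group: dict[str, np.ndarray],
                   lag_times_ms: np.ndarray,
                   electrodes: list[str]) -> pd.DataFrame:
    """Proficiency x latency x electrode fixed-effects ANOVA (type II).

    ``weights_by_group[g]`` is (n_subjects, n_lags, n_electrodes).  When
    Mauchly's test rejects sphericity across latency levels, a
    Greenhouse-Geisser epsilon (computed from the subject x latency
    covariance of electrode-averaged weights) scales the degrees of
    freedom and p-values of effects involving latency.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rows = []
    for g, W in weights_by_group.items():
        n_s, n_l, n_e = W.shape
        for s in range(n_s):
            for li in range(n_l):
                for ei in range(n_e):
                    rows.append((g, f"t{li}", electrodes[ei], W[s, li, ei]))
    df = pd.DataFrame(rows, columns=["group", "latency", "electrode", "w"])
    model = smf.ols("w ~ C(group) * C(latency) * C(electrode)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    # sphericity over latency: epsilon from electrode-averaged per-subject
    # latency profiles, pooled over groups
    profiles = np.vstack([W.mean(axis=2) for W in weights_by_group.values()])
    eps = _gg_epsilon(profiles)
    table["gg_epsilon"] = np.nan
    for effect in table.index:
        if "latency" in effect and effect != "Residual":
            d1 = table.loc[effect, "df"] * eps
            d2 = table.loc["Residual", "df"] * eps
            f = table.loc[effect, "F"]
            table.loc[effect, "PR(>F)"] = sstats.f.sf(f, d1, d2)
            table.loc[effect, "gg_epsilon"] = eps
    return table


def _gg_epsilon(profiles: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of subjects x levels data."""
    S = np.cov(profiles, rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    num = (k * (mean_diag - S.mean())) ** 2
    den = (k - 1) * (np.sum(S ** 2) - 2 * k * np.sum(S.mean(axis=1) ** 2)
                     + k ** 2 * S.mean() ** 2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))
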