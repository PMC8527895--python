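"""Plotting helpers for TRF weights and phoneme distance maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pdm import PhonemeMap  # noqa: E402
from .trf import TRFResults  # noqa: E402


def plot_trf(res: TRFResults, group: str, electrode: str = "Cz", ax=None):
    """Lag curves of one feature group's TRF weights at one electrode."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    if res.channel_names is None or electrode not in res.channel_names:
        raise KeyError(f"electrode {electrode!r} absent from the model")
    ci = res.channel_names.index(electrode)
    W = res.group_weights(group)[ci]
    for d in range(W.shape[1]):
        ax.plot(res.lag_times_ms, W[:, d], lw=1)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("TRF weight (a.u.)")
    ax.set_title(f"TRF {group} @ {electrode}")
    return ax


def plot_pdm(pmap: PhonemeMap, ax=None, color="C0"):
    """Scatter of the first two PDM dimensions with phoneme labels."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    xy = pmap.coords[:, :2]
    ax.scatter(xy[:, 0], xy[:, 1], s=12, color=color)
    for p, (x, y) in zip(pmap.phonemes, xy):
        ax.annotate(p, (x, y), fontsize=9, xytext=(2, 2),
                    textcoords="offset points")
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    return ax
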