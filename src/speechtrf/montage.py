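"""Synthetic EEG sensor layouts.

Channel positions are needed by the bad-channel interpolation (spherical
splines) and by topography-aware summaries.  The default layout is a
32-channel 10-20-style montage holding the five midline sites used by the
component analyses (Fpz, Fz, Cz, Pz, Oz); a denser layout is generated on
demand by adding Fibonacci-disc filler sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MIDLINE = ("Fpz", "Fz", "Cz", "Pz", "Oz")

# name -> (x, y) on the unit disc, nose along +y
_STD32 = {
    "Fp1": (-0.31, 0.95), "Fpz": (0.0, 1.0), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.43, 0.55), "Fz": (0.0, 0.50),
    "F4": (0.43, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.62, 0.28), "FC1": (-0.22, 0.26), "FC2": (0.22, 0.26),
    "FC6": (0.62, 0.28),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.62, -0.28), "CP1": (-0.22, -0.26), "CP2": (0.22, -0.26),
    "CP6": (0.62, -0.28),
    "P7": (-0.81, -0.59), "P3": (-0.43, -0.55), "Pz": (0.0, -0.50),
    "P4": (0.43, -0.55), "P8": (0.81, -0.59),
    "PO3": (-0.35, -0.80), "POz": (0.0, -0.75), "PO4": (0.35, -0.80),
    "O1": (-0.31, -0.95), "Oz": (0.0, -1.0), "O2": (0.31, -0.95),
}


@dataclass
class Montage:
    """Named sensor set with disc (2-D) and unit-sphere (3-D) coordinates."""

    names: list[str]
    pos2d: np.ndarray  # (n, 2), unit disc
    pos3d: np.ndarray = field(default=None)  # (n, 3), unit sphere

    def __post_init__(self) -> None:
        self.pos2d = np.asarray(self.pos2d, dtype=float)
        if self.pos3d is None:
            self.pos3d = disc_to_sphere(self.pos2d)
        if len(self.names) != len(self.pos2d):
            raise ValueError("names and positions disagree in length")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"electrode {name!r} not in montage") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)


def disc_to_sphere(pos2d: np.ndarray, max_polar: float = 0.48 * np.pi) -> np.ndarray:
    """Map disc coordinates onto the upper unit sphere (vertex at disc centre)."""
    pos2d = np.asarray(pos2d, dtype=float)
    r = np.linalg.norm(pos2d, axis=1)
    theta = np.clip(r, 0.0, 1.0) * max_polar
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[:, None] > 0, pos2d / np.maximum(r, 1e-12)[:, None], 0.0)
    xy = np.sin(theta)[:, None] * unit
    z = np.cos(theta)
    return np.column_stack([xy, z])


def make_montage(n_channels: int = 32) -> Montage:
    """Standard 32-channel layout; larger counts add Fibonacci filler sites."""
    names = list(_STD32)
    pos = np.array([_STD32[n] for n in names], dtype=float)
    if n_channels < len(names):
        # keep midline sites, then fill by original order
        keep = [n for n in MIDLINE if n in names]
        for n in names:
            if len(keep) >= n_channels:
                break
            if n not in keep:
                keep.append(n)
        keep = [n for n in names if n in keep]
        idx = [names.index(n) for n in keep]
        return Montage(keep, pos[idx])
    if n_channels > len(names):
        extra = n_channels - len(names)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        k = np.arange(1, extra + 1)
        r = 0.92 * np.sqrt(k / (extra + 1.0))
        ang = k * golden
        filler = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        names = names + [f"E{33 + i:02d}" for i in range(extra)]
        pos = np.vstack([pos, filler])
    return Montage(names, pos)
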