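"""Phoneme distance maps (PDMs).

Phonetic-feature TRF weights are projected from the 19-dimensional
articulatory-feature space to the phoneme domain (multiplying by the
phoneme-by-feature indicator table), embedded by classical
(Torgerson) multidimensional scaling with time latencies as dimensions,
and aligned across groups/subjects to a common native-listener space by
Procrustes analysis.  Distances in the aligned space proxy the neural
discriminability of phoneme contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trf import TRFResults


@dataclass
class PhonemeMap:
    phonemes: list[str]
    coords: np.ndarray                  # (n_phonemes, k)
    eigenvalues: np.ndarray | None = None
    alignment: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=self.phonemes,
                            columns=[f"x{i + 1}" for i in range(self.k)])


def phoneme_projection(trf: TRFResults, feature_table: pd.DataFrame,
                       electrode: str | list[str] = "Cz",
                       phonemes: list[str] | None = None) -> np.ndarray:
    """Project Phn TRF weights to per-phoneme responses.

    Returns (n_phonemes, n_lags * n_electrodes): row p is the lag response
    predicted for phoneme p, i.e. the feature-indicator row times the 19
    feature kernels.  ``electrode`` may be a single name (the default Cz)
    or a list of names whose responses are concatenated along the lag
    axis (multi-electrode maps average down estimation noise).
    """
    electrodes = [electrode] if isinstance(electrode, str) else list(electrode)
    if trf.channel_names is None:
        raise KeyError("model has no channel names")
    missing = [e for e in electrodes if e not in trf.channel_names]
    if missing:
        raise KeyError(f"electrodes {missing} absent from the model")
    phonemes = list(phonemes) if phonemes is not None else list(feature_table.index)
    table = feature_table.loc[phonemes].to_numpy(float)
    blocks = []
    for e in electrodes:
        W = trf.group_weights("Phn")[trf.channel_names.index(e)]  # (lags, 19)
        blocks.append(table @ W.T)
    return np.hstack(blocks)


def classical_mds(X: np.ndarray, k: int | None = None, max_k: int = 10,
                  is_distance: bool = False) -> PhonemeMap:
    """Torgerson classical MDS of objects x dimensions data (or a distance
    matrix).  Coordinates are the top positive-eigenvalue axes scaled by
    the square-rooted eigenvalues."""
    X = np.asarray(X, dtype=float)
    if is_distance:
        D = X
    else:
        if X.shape[0] < 3:
            raise ValueError("need at least 3 objects")
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff ** 2).sum(-1))
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12
    n_pos = int(pos.sum())
    k_eff = min(k if k is not None else max_k, max_k, n_pos)
    if k is not None and k_eff < k:
        warnings.warn(f"only {k_eff} positive-eigenvalue axes available; "
                      f"k reduced from {k}")
    coords = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])[None, :]
    return PhonemeMap([str(i) for i in range(n)], coords,
                      eigenvalues=vals[:k_eff])


def mds_map(trf_projection: np.ndarray, phonemes: list[str],
            k: int | None = None) -> PhonemeMap:
    m = classical_mds(trf_projection, k=k)
    m.phonemes = list(phonemes)
    return m


def procrustes_align(source: PhonemeMap, target: PhonemeMap,
                     scaling: bool = True) -> tuple[PhonemeMap, float]:
    """Align ``source`` to ``target`` by translation, orthogonal
    rotation/reflection and (optionally) isotropic scaling.

    Returns the aligned map and the disparity: the residual sum of squares
    normalised by the centred norm of the target configuration.
    """
    if source.phonemes != target.phonemes:
        raise ValueError("maps must cover identical phoneme sets")
    if source.k != target.k:
        raise ValueError("maps must share dimensionality")
    X = np.asarray(target.coords, float)
    Y = np.asarray(source.coords, float)
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - mx, Y - my
    normX = np.linalg.norm(X0)
    normY = np.linalg.norm(Y0)
    if normX == 0 or normY == 0:
        raise ValueError("degenerate (single-point) configuration")
    U, s, Vt = np.linalg.svd(Y0.T @ X0)
    R = U @ Vt
    scale = s.sum() / normY ** 2 if scaling else 1.0
    Z = scale * Y0 @ R + mx
    disparity = float(np.sum((Z - X) ** 2) / normX ** 2)
    aligned = PhonemeMap(list(source.phonemes), Z,
                         eigenvalues=source.eigenvalues,
                         alignment={"rotation": R, "scale": scale,
                                    "translation": mx - scale * my @ R})
    return aligned, disparity


def average_l1_space(l1_maps: list[PhonemeMap], n_iter: int = 2
                     ) -> PhonemeMap:
    """Reference space: per-subject native maps mutually aligned (seed map =
    first subject) and averaged; one refinement pass re-aligns to the mean."""
    if not l1_maps:
        raise ValueError("need at least one native map")
    ref = l1_maps[0]
    for _ in range(n_iter):
        aligned = [procrustes_align(m, ref)[0] for m in l1_maps]
        ref = PhonemeMap(list(ref.phonemes),
                         np.mean([m.coords for m in aligned], axis=0))
    return ref


def l1_l2_phoneme_distance(l2_map: PhonemeMap, l1_reference: PhonemeMap
                           ) -> tuple[np.ndarray, float]:
    """Per-phoneme Euclidean distances between an aligned L2 map and the
    native reference, plus their mean."""
    if l2_map.phonemes != l1_reference.phonemes:
        raise ValueError("maps must cover identical phoneme sets")
    d = np.linalg.norm(l2_map.coords - l1_reference.coords, axis=1)
    return d, float(d.mean())


def contrast_distances(map_: PhonemeMap, pairs: list[tuple[str, str]],
                       l1_reference: PhonemeMap) -> dict[tuple[str, str], float]:
    """Pairwise phoneme distances normalised by the native-map distance of
    the same pair.  Pairs with (near-)zero native distance are excluded."""
    out = {}
    for p, q in pairs:
        if p not in map_.phonemes or q not in map_.phonemes:
            raise KeyError(f"pair ({p}, {q}) not fully contained in the map")
        i, j = map_.phonemes.index(p), map_.phonemes.index(q)
        d = float(np.linalg.norm(map_.coords[i] - map_.coords[j]))
        ref = float(np.linalg.norm(l1_reference.coords[i]
                                   - l1_reference.coords[j]))
        if ref <= 1e-12:
            warnings.warn(f"pair ({p}, {q}) has zero native distance; excluded")
            continue
        out[(p, q)] = d / ref
    return out
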