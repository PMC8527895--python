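"""Stimulus regressors for speech-EEG encoding models.

Implements the full descriptor family: an auditory spectrogram ``S`` (16
bands), broadband envelope ``E``, half-rectified envelope derivative
``Ed``, phoneme onsets ``Pon``, vowel/consonant onsets ``Pvc`` (2 dims),
phonetic articulatory step functions ``Phn`` (19 dims), phonotactic
probability regressors ``Pt`` (2 dims: prefix probability and its change),
and onset-locked semantic dissimilarity ``Sem``.  The two canonical
descriptor sets are

* ``ALL`` = [E, Ed, Pvc, Pon, Pt, Sem]  (8 columns), and
* ``EXT`` = [S, Ed, Phn, Pon, Pt, Sem]  (40 columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .languages import PHONETIC_FEATURES, EmbeddingTable, StimulusTranscript
from .phonotactics import PhonotacticGrammar

#: canonical group order and widths of the master descriptor
GROUP_DIMS = {"S": 16, "E": 1, "Ed": 1, "Pon": 1, "Pvc": 2, "Phn": 19,
              "Pt": 2, "Sem": 1}

DESCRIPTOR_SETS = {
    "ALL": ["E", "Ed", "Pvc", "Pon", "Pt", "Sem"],
    "EXT": ["S", "Ed", "Phn", "Pon", "Pt", "Sem"],
}


@dataclass
class FeatureMatrix:
    """Time x feature array at a fixed sampling rate with named groups."""

    values: np.ndarray
    fs: float
    groups: dict[str, slice] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaN")
        if not self.groups:
            self.groups = {"X": slice(0, self.values.shape[1])}
        cols = sorted((s.start, s.stop) for s in self.groups.values())
        if cols[0][0] != 0 or cols[-1][1] != self.values.shape[1] or any(
                a[1] != b[0] for a, b in zip(cols, cols[1:])):
            raise ValueError("group slices must partition the columns")

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]

    def group(self, name: str) -> np.ndarray:
        return self.values[:, self.groups[name]]

    def select(self, names: list[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.groups]
        if missing:
            raise KeyError(f"missing feature groups: {missing}")
        parts, groups, start = [], {}, 0
        for n in names:
            block = self.group(n)
            parts.append(block)
            groups[n] = slice(start, start + block.shape[1])
            start += block.shape[1]
        return FeatureMatrix(np.hstack(parts), self.fs, groups)

    @staticmethod
    def concat(blocks: dict[str, "FeatureMatrix | np.ndarray"], fs: float
               ) -> "FeatureMatrix":
        parts, groups, start = [], {}, 0
        n_times = None
        for name, block in blocks.items():
            arr = block.values if isinstance(block, FeatureMatrix) else np.atleast_2d(block)
            if arr.ndim == 1:
                arr = arr[:, None]
            if n_times is None:
                n_times = arr.shape[0]
            if arr.shape[0] != n_times:
                raise ValueError("blocks differ in length")
            parts.append(arr)
            groups[name] = slice(start, start + arr.shape[1])
            start += arr.shape[1]
        return FeatureMatrix(np.hstack(parts), fs, groups)


# ---------------------------------------------------------------------------
# acoustics

def auditory_spectrogram(audio: np.ndarray, rate: float, fs_out: float = 50.0,
                         n_filters: int = 128, n_out_bands: int = 16,
                         fmin: float = 100.0) -> FeatureMatrix:
    """Cochlear-style spectrogram of a mono waveform.

    Three stages approximate a peripheral auditory model: (1) a bank of
    ``n_filters`` band-pass filters log-spaced between ``fmin`` and
    0.4*rate, (2) a hair-cell stage (half-wave rectification, 30 Hz
    low-pass, cube-root compression), and (3) a lateral inhibitory
    network (half-rectified first difference across frequency).  Band
    envelopes are resampled to ``fs_out`` and averaged into
    ``n_out_bands`` output bands.
    """
    if rate < 8000:
        raise ValueError("audio rate must be >= 8 kHz")
    audio = np.asarray(audio, dtype=float).ravel()
    if not np.any(audio):
        warnings.warn("silent audio: spectrogram is all zero")
        n_out = int(round(len(audio) * fs_out / rate))
        return FeatureMatrix(np.zeros((n_out, n_out_bands)), fs_out,
                             {"S": slice(0, n_out_bands)})
    edges = np.geomspace(fmin, 0.4 * rate, n_filters + 1)
    sos_lp = signal.butter(2, 30.0, fs=rate, output="sos")
    bands = np.empty((len(audio), n_filters))
    for k in range(n_filters):
        sos = signal.butter(2, (edges[k], edges[k + 1]), btype="bandpass",
                            fs=rate, output="sos")
        y = signal.sosfilt(sos, audio)
        y = np.maximum(y, 0.0)                       # hair cell: rectify
        y = signal.sosfiltfilt(sos_lp, y)            # low-pass 30 Hz
        bands[:, k] = np.cbrt(np.maximum(y, 0.0))    # compressive nonlinearity
    # lateral inhibition: half-rectified derivative along frequency
    lin = np.maximum(np.diff(bands, axis=1, prepend=bands[:, :1]), 0.0)
    up, down = _resample_ratio(fs_out, rate)
    env = signal.resample_poly(lin, up, down, axis=0, window=("kaiser", 5.0))
    env = np.maximum(env, 0.0)
    step = n_filters // n_out_bands
    out = env.reshape(env.shape[0], n_out_bands, step).mean(axis=2)
    return FeatureMatrix(out, fs_out, {"S": slice(0, n_out_bands)})


def _resample_ratio(fs_out: float, fs_in: float) -> tuple[int, int]:
    from fractions import Fraction
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return frac.numerator, frac.denominator


def broadband_envelope(S: FeatureMatrix) -> FeatureMatrix:
    """Mean of the band envelopes across frequency."""
    vals = S.group("S") if "S" in S.groups else S.values
    if vals.shape[1] < 1:
        raise ValueError("need at least one band")
    return FeatureMatrix(vals.mean(axis=1, keepdims=True), S.fs,
                         {"E": slice(0, 1)})


def envelope_derivative(E: FeatureMatrix) -> FeatureMatrix:
    """Half-wave rectified first difference of the broadband envelope."""
    e = E.values[:, 0]
    d = np.zeros_like(e)
    d[1:] = np.maximum(0.0, np.diff(e))
    return FeatureMatrix(d[:, None], E.fs, {"Ed": slice(0, 1)})


# ---------------------------------------------------------------------------
# phoneme-level regressors

def time_to_sample(t: float | np.ndarray, fs: float) -> np.ndarray:
    """Nearest sample index; exact ties resolve toward the earlier sample."""
    return np.ceil(np.asarray(t) * fs - 0.5).astype(int)


def _n_samples(tr: StimulusTranscript, fs: float) -> int:
    return int(round(tr.duration * fs))


def phoneme_onsets(tr: StimulusTranscript, fs: float) -> FeatureMatrix:
    """Impulse vector with a single 1 at each phoneme onset sample."""
    if not tr.phones:
        raise ValueError("transcript has no phonemes")
    n = _n_samples(tr, fs)
    out = np.zeros((n, 1))
    idx = time_to_sample(np.array([p.start for p in tr.phones]), fs)
    idx = np.clip(idx, 0, n - 1)
    if len(np.unique(idx)) != len(idx):
        raise ValueError("two phoneme onsets map to one sample; fs too low")
    out[idx, 0] = 1.0
    return FeatureMatrix(out, fs, {"Pon": slice(0, 1)})


def vowel_consonant(tr: StimulusTranscript, fs: float,
                    feature_table: pd.DataFrame) -> FeatureMatrix:
    """Two onset vectors restricted to vowels / consonants (sum == Pon)."""
    pon = phoneme_onsets(tr, fs).values[:, 0]
    out = np.zeros((len(pon), 2))
    idx = time_to_sample(np.array([p.start for p in tr.phones]), fs)
    idx = np.clip(idx, 0, len(pon) - 1)
    for p, i in zip(tr.phones, idx):
        if p.symbol not in feature_table.index:
            raise KeyError(f"phoneme {p.symbol!r} not in the feature table")
        col = 0 if feature_table.loc[p.symbol, "syllabic"] else 1
        out[i, col] = 1.0
    return FeatureMatrix(out, fs, {"Pvc": slice(0, 2)})


def phonetic_feature_matrix(tr: StimulusTranscript, fs: float,
                            feature_table: pd.DataFrame) -> FeatureMatrix:
    """19 binary step functions: feature j is 1 while a carrying phoneme lasts."""
    n = _n_samples(tr, fs)
    out = np.zeros((n, len(PHONETIC_FEATURES)))
    for p in tr.phones:
        if p.symbol not in feature_table.index:
            raise KeyError(f"phoneme {p.symbol!r} not in the feature table")
        s0 = int(np.clip(time_to_sample(p.start, fs), 0, n - 1))
        s1 = int(np.clip(time_to_sample(p.end, fs), s0 + 1, n))
        row = feature_table.loc[p.symbol, PHONETIC_FEATURES].to_numpy(float)
        out[s0:s1] = np.maximum(out[s0:s1], row[None, :])
    return FeatureMatrix(out, fs, {"Phn": slice(0, len(PHONETIC_FEATURES))})


def phonotactic_regressors(tr: StimulusTranscript, grammar: PhonotacticGrammar,
                           fs: float) -> FeatureMatrix:
    """Prefix phonotactic probability (Pt1) and its change (Pt2).

    At the onset sample of the k-th phoneme of a word, Pt1 carries the
    MaxEnt probability of the prefix ph_1..k; Pt2 carries the change
    P(ph_1..k) - P(ph_1..k-1) and is zero at word-initial phonemes.
    """
    n = _n_samples(tr, fs)
    out = np.zeros((n, 2))
    for w in tr.words:
        syms = tr.word_symbols(w)
        if not syms:
            raise ValueError("empty word in transcript")
        prev_p = None
        for k in range(1, len(syms) + 1):
            p = grammar.prob(syms[:k])
            phone = tr.phones[w.phone_span[0] + k - 1]
            i = int(np.clip(time_to_sample(phone.start, fs), 0, n - 1))
            out[i, 0] = p
            if k >= 2:
                out[i, 1] = p - prev_p
            prev_p = p
    return FeatureMatrix(out, fs, {"Pt": slice(0, 2)})


def semantic_dissimilarity(tr: StimulusTranscript, emb: EmbeddingTable,
                           fs: float) -> FeatureMatrix:
    """1 - Pearson(word vector, context mean) at content-word onsets.

    The context is the average embedding of the preceding content words of
    the sentence; a sentence-initial word is correlated with the average
    embedding of the previous sentence's (content) words.  The very first
    content word of the passage has no context and receives the mean of
    all other dissimilarity values.
    """
    n = _n_samples(tr, fs)
    out = np.zeros((n, 1))
    values: list[tuple[int, float | None]] = []
    prev_sentence_vecs: list[np.ndarray] = []
    for w0, w1 in tr.sentence_spans:
        sent_vecs: list[np.ndarray] = []
        for w in tr.words[w0:w1]:
            if not w.content:
                continue
            if w.text not in emb:
                raise KeyError(f"content word {w.text!r} missing from embeddings")
            v = emb.vector(w.text)
            context = sent_vecs if sent_vecs else prev_sentence_vecs
            i = int(np.clip(time_to_sample(w.start, fs), 0, n - 1))
            if context:
                values.append((i, 1.0 - _pearson(v, np.mean(context, axis=0))))
            else:
                values.append((i, None))  # no prior context anywhere
            sent_vecs.append(v)
        if sent_vecs:
            prev_sentence_vecs = sent_vecs
    known = [val for _, val in values if val is not None]
    fill = float(np.mean(known)) if known else 0.0
    for i, val in values:
        out[i, 0] = fill if val is None else val
    return FeatureMatrix(out, fs, {"Sem": slice(0, 1)})


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


# ---------------------------------------------------------------------------
# descriptor assembly

def assemble_descriptor(features: FeatureMatrix | dict, set_name: str
                        ) -> FeatureMatrix:
    """Column-stack the named groups of the ``ALL`` or ``EXT`` set."""
    if set_name not in DESCRIPTOR_SETS:
        raise ValueError(f"unknown descriptor set {set_name!r}")
    names = DESCRIPTOR_SETS[set_name]
    if isinstance(features, dict):
        fs = next(iter(features.values())).fs
        missing = [n for n in names if n not in features]
        if missing:
            raise KeyError(f"missing feature groups: {missing}")
        if any(abs(features[n].fs - fs) > 1e-9 for n in names):
            raise ValueError("feature groups have differing sampling rates")
        return FeatureMatrix.concat({n: features[n] for n in names}, fs)
    return features.select(names)


def shuffle_sentences(features: FeatureMatrix, tr: StimulusTranscript,
                      rng: np.random.Generator) -> FeatureMatrix:
    """Permute the sentence-aligned segments of a feature matrix.

    Used as a permutation null for prediction correlations: a TRF scored
    against sentence-shuffled regressors should predict at chance.  The
    matrix is cut at sentence onsets (each segment runs to the next
    sentence's onset, so trailing pauses travel with their sentence) and
    the segments are reordered; total length is unchanged.
    """
    n = features.n_times
    starts = [tr.words[w0].start for w0, _ in tr.sentence_spans]
    cuts = sorted({int(np.clip(time_to_sample(s, features.fs), 0, n))
                   for s in starts} | {0, n})
    segments = [features.values[a:b] for a, b in zip(cuts, cuts[1:])]
    order = rng.permutation(len(segments))
    return FeatureMatrix(np.vstack([segments[i] for i in order]),
                         features.fs, dict(features.groups))
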