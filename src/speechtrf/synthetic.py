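"""Synthetic speech-EEG cohorts with planted proficiency effects.

The generator emulates the group design of a second-language (L2)
listening study: learners at CEFR levels A1-C2 (encoded 1-6) and a native
(L1) reference group all hear the same stimulus.  EEG is simulated as the
convolution of known per-feature kernels with the stimulus regressors
plus mixed 1/f ("pink") and white noise.  Three effects are planted:

* the semantic-dissimilarity kernel deepens and its trough shifts earlier
  with proficiency (the L1 trough sits near 360 ms);
* the phonotactic kernel carries an early (~120 ms) negative component
  only for L2 listeners, largest at low proficiency, on top of a late
  (~370 ms) component that deepens with proficiency;
* responses to phonemes unique to the target language interpolate between
  the response of the nearest shared phoneme (full assimilation, naive
  listener) and a distinct pattern (native listener).

All randomness flows through explicit seeds; identical configurations
reproduce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .design import lag_grid, lagged_matrix
from .features import (FeatureMatrix, broadband_envelope, envelope_derivative,
                       phoneme_onsets, phonetic_feature_matrix,
                       phonotactic_regressors, semantic_dissimilarity,
                       vowel_consonant)
from .languages import (StimulusTranscript, ToyLanguagePair,
                        make_toy_languages, sample_transcript)
from .montage import Montage, make_montage

GROUPS = ("A", "B", "C", "L1")
#: coarse-group default proficiency scalars (CEFR levels 1-6; L1 is beyond)
GROUP_PROFICIENCY = {"A": 1.5, "B": 3.5, "C": 5.5, "L1": 7.0}


@dataclass
class EffectConfig:
    """Amplitudes (arbitrary EEG units) and latencies (ms) of the planted
    kernel components."""

    env_components: tuple = ((60.0, 40.0, 0.6), (110.0, 50.0, -1.0),
                             (200.0, 70.0, 0.8))  # (latency, width, amp)
    env_deriv_scale: float = 0.5
    spectro_scale: float = 0.35
    onset_amp: float = 0.45
    onset_latency: float = 70.0
    vowel_amp: float = 0.35
    vowel_latency: float = 100.0
    consonant_amp: float = 0.3
    consonant_latency: float = 140.0
    # phonotactics: late component (deepens with proficiency) and an early
    # ~120 ms component present only in non-native listeners
    pt_late_latency: float = 370.0
    pt_late_width: float = 80.0
    pt_late_base: float = 0.3
    pt_late_slope: float = 0.08
    pt_early_latency: float = 120.0
    pt_early_width: float = 35.0
    pt_early_base: float = 0.95
    pt_early_slope: float = 0.13
    # semantic dissimilarity: trough deepens and moves earlier with
    # proficiency; native listeners peak at ~360 ms
    sem_base_amp: float = 0.35
    sem_slope_amp: float = 0.11
    sem_latency_intercept: float = 540.0
    sem_latency_slope: float = 30.0
    sem_width: float = 70.0
    sem_l1_amp: float = 1.1
    sem_l1_latency: float = 360.0
    phoneme_response_amp: float = 0.6

    def jittered(self, rng: np.random.Generator, sd: float,
                 latency_sd_ms: float = 12.0) -> "EffectConfig":
        """Inter-subject variant: amplitudes scaled by 1+N(0, sd), component
        latencies shifted by N(0, latency_sd_ms)."""
        def a(x):
            return x * float(1.0 + rng.normal(0.0, sd))

        def t(x):
            return x + float(rng.normal(0.0, latency_sd_ms))

        return replace(
            self,
            env_components=tuple((t(l), w, a(amp))
                                 for l, w, amp in self.env_components),
            onset_amp=a(self.onset_amp), vowel_amp=a(self.vowel_amp),
            consonant_amp=a(self.consonant_amp),
            pt_late_base=a(self.pt_late_base),
            pt_early_base=a(self.pt_early_base),
            pt_late_latency=t(self.pt_late_latency),
            pt_early_latency=t(self.pt_early_latency),
            sem_base_amp=a(self.sem_base_amp),
            sem_l1_amp=a(self.sem_l1_amp),
            sem_latency_intercept=t(self.sem_latency_intercept),
            sem_l1_latency=t(self.sem_l1_latency),
            phoneme_response_amp=a(self.phoneme_response_amp),
        )


@dataclass
class GroundTruthKernels:
    """Planted per-feature-group kernels, (n_channels, n_lags, group_dims)."""

    kernels: dict[str, np.ndarray]
    group: str
    proficiency_scalar: float
    effect_config: EffectConfig
    lags: np.ndarray
    fs: float

    def stacked(self, group_names: list[str]) -> np.ndarray:
        return np.concatenate([self.kernels[g] for g in group_names], axis=2)


@dataclass
class CohortConfig:
    n_per_group: int = 8
    trial_duration_s: float = 60.0
    n_trials: int = 6
    snr_db: float = 0.0
    inter_subject_kernel_sd: float = 0.1
    n_channels: int = 32
    fs: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2 (cross-validation)")
        if self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be positive")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    level: int | None          # CEFR level 1-6; None for native listeners
    eeg: list[np.ndarray]      # (n_times, n_channels) per trial
    fs: float
    kernels: GroundTruthKernels | None = None
    decoding_features: np.ndarray | None = None

    @property
    def proficiency(self) -> float:
        return float(self.level) if self.level is not None else GROUP_PROFICIENCY["L1"]


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    stimulus: list[FeatureMatrix]          # per-trial master feature matrices
    transcripts: list[StimulusTranscript]
    lang: ToyLanguagePair
    montage: Montage
    config: CohortConfig

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]

    @property
    def l2_subjects(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group != "L1"]


# ---------------------------------------------------------------------------
# kernel construction

def _bump(lag_ms: np.ndarray, latency: float, width: float, amp: float
          ) -> np.ndarray:
    return amp * np.exp(-0.5 * ((lag_ms - latency) / width) ** 2)


def _topography(montage: Montage, center_xy: tuple[float, float],
                spread: float = 0.75) -> np.ndarray:
    d2 = ((montage.pos2d - np.asarray(center_xy)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2 * spread ** 2))


def assimilation_fraction(group: str, proficiency: float) -> float:
    """0 = unique phonemes fully assimilated to the nearest shared phoneme
    (naive listener); 1 = fully distinct (native listener)."""
    if group == "L1":
        return 1.0
    return float(np.clip((proficiency - 1.5) / 5.5, 0.0, 1.0))


def _phoneme_curves(lang: ToyLanguagePair, lag_ms: np.ndarray, amp: float,
                    seed: int) -> dict[str, np.ndarray]:
    """Smooth per-phoneme lag curves, distinct per phoneme, shared across
    groups (keyed only by the language seed)."""
    rng = np.random.default_rng(seed)
    basis = np.stack([_bump(lag_ms, lat, 55.0, 1.0)
                      for lat in (80.0, 160.0, 260.0, 380.0)])
    inventory = sorted(set(lang.inventory_l1) | set(lang.inventory_l2))
    return {p: amp * rng.normal(0.0, 1.0, size=len(basis)) @ basis
            for p in inventory}


def nearest_shared_phoneme(lang: ToyLanguagePair, phoneme: str) -> str:
    """Closest shared phoneme by Hamming distance on the 19-d feature rows;
    ties break lexicographically."""
    row = lang.feature_table.loc[phoneme].to_numpy(int)
    best = min(sorted(lang.shared),
               key=lambda s: (int(np.sum(
                   lang.feature_table.loc[s].to_numpy(int) != row)), s))
    return best


def planted_phoneme_responses(lang: ToyLanguagePair, lag_ms: np.ndarray,
                              group: str, proficiency: float,
                              effects: EffectConfig, lang_seed: int
                              ) -> dict[str, np.ndarray]:
    """Per-phoneme lag responses with the assimilation effect planted."""
    curves = _phoneme_curves(lang, lag_ms, effects.phoneme_response_amp,
                             lang_seed)
    alpha = assimilation_fraction(group, proficiency)
    out: dict[str, np.ndarray] = {}
    for p in lang.inventory_l2:
        if p in lang.unique_l2:
            near = nearest_shared_phoneme(lang, p)
            out[p] = (1.0 - alpha) * curves[near] + alpha * curves[p]
        else:
            out[p] = curves[p]
    return out


def make_ground_truth_kernels(group: str, lang: ToyLanguagePair,
                              montage: Montage,
                              effects: EffectConfig | None = None,
                              proficiency: float | None = None,
                              fs: float = 50.0,
                              lag_window_ms: tuple[float, float] = (0.0, 600.0),
                              lang_seed: int = 0) -> GroundTruthKernels:
    """Planted kernels for one group (or one subject, via ``effects``)."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    effects = effects or EffectConfig()
    if proficiency is None:
        proficiency = GROUP_PROFICIENCY[group]
    lags = lag_grid(lag_window_ms, fs)
    lag_ms = lags * 1000.0 / fs
    nL = len(lags)
    nC = montage.n_channels
    topo_c = _topography(montage, (0.0, 0.2))    # centro-frontal
    topo_cp = _topography(montage, (0.0, -0.3))  # centro-parietal
    topo_o = _topography(montage, (0.0, -0.7))   # occipital

    k: dict[str, np.ndarray] = {}
    env = np.sum([_bump(lag_ms, l, w, a) for l, w, a in effects.env_components],
                 axis=0)
    k["E"] = (topo_c[:, None] * env[None, :])[:, :, None]
    k["Ed"] = effects.env_deriv_scale * k["E"]
    band_gain = np.exp(-0.5 * ((np.arange(16) - 7.5) / 4.0) ** 2)
    k["S"] = (effects.spectro_scale * topo_o[:, None, None]
              * env[None, :, None] * band_gain[None, None, :])
    k["Pon"] = (effects.onset_amp
                * topo_c[:, None] * _bump(lag_ms, effects.onset_latency, 40.0,
                                          1.0)[None, :])[:, :, None]
    pvc = np.zeros((nC, nL, 2))
    pvc[:, :, 0] = (effects.vowel_amp * topo_cp[:, None]
                    * _bump(lag_ms, effects.vowel_latency, 45.0, 1.0)[None, :])
    pvc[:, :, 1] = (effects.consonant_amp * topo_c[:, None]
                    * _bump(lag_ms, effects.consonant_latency, 45.0, 1.0)[None, :])
    k["Pvc"] = pvc

    # phonotactics: late negative component for everyone (deeper with
    # proficiency); early ~120 ms component only for L2 listeners
    p_eff = min(proficiency, 6.0)
    late = _bump(lag_ms, effects.pt_late_latency, effects.pt_late_width,
                 -(effects.pt_late_base + effects.pt_late_slope * p_eff))
    if group == "L1":
        early = np.zeros_like(lag_ms)
    else:
        early_amp = max(effects.pt_early_base
                        - effects.pt_early_slope * p_eff, 0.0)
        early = _bump(lag_ms, effects.pt_early_latency, effects.pt_early_width,
                      -early_amp)
    pt_curve = late + early
    pt = np.zeros((nC, nL, 2))
    pt[:, :, 0] = topo_c[:, None] * pt_curve[None, :]
    pt[:, :, 1] = 0.5 * topo_cp[:, None] * pt_curve[None, :]
    k["Pt"] = pt

    # semantic dissimilarity trough
    if group == "L1":
        sem = _bump(lag_ms, effects.sem_l1_latency, effects.sem_width,
                    -effects.sem_l1_amp)
    else:
        lat = effects.sem_latency_intercept - effects.sem_latency_slope * p_eff
        sem = _bump(lag_ms, lat, effects.sem_width,
                    -(effects.sem_base_amp + effects.sem_slope_amp * p_eff))
    k["Sem"] = (topo_cp[:, None] * sem[None, :])[:, :, None]

    # phonetic features: minimum-norm kernels reproducing the planted
    # per-phoneme responses through the feature indicator table
    responses = planted_phoneme_responses(lang, lag_ms, group, proficiency,
                                          effects, lang_seed)
    phon_order = [p for p in lang.feature_table.index
                  if p in lang.inventory_l2]
    table = lang.feature_table.loc[phon_order].to_numpy(float)
    R = np.stack([responses[p] for p in phon_order])       # (n_phon, nL)
    W19 = np.linalg.pinv(table) @ R                        # (19, nL)
    k["Phn"] = topo_c[:, None, None] * W19.T[None, :, :]   # (nC, nL, 19)

    return GroundTruthKernels(k, group, float(proficiency), effects, lags, fs)


# ---------------------------------------------------------------------------
# EEG simulation

def pink_white_noise(n_times: int, n_channels: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise, 1/f and white mixed 50/50 in power."""
    white = rng.standard_normal((n_times, n_channels))
    spec = np.fft.rfft(rng.standard_normal((n_times, n_channels)), axis=0)
    f = np.fft.rfftfreq(n_times)
    scale = np.where(f > 0, 1.0 / np.sqrt(np.maximum(f, 1e-12)), 0.0)
    pink = np.fft.irfft(spec * scale[:, None], n=n_times, axis=0)
    sd = pink.std(axis=0)
    pink = pink / np.where(sd > 0, sd, 1.0)
    return np.sqrt(0.5) * pink + np.sqrt(0.5) * white


def clean_eeg(feature_trials: list[FeatureMatrix],
              kernels: GroundTruthKernels) -> list[np.ndarray]:
    """Noise-free forward model: per-trial convolution of the kernels with
    the stimulus regressors."""
    groups = list(feature_trials[0].groups)
    missing = [g for g in groups if g not in kernels.kernels]
    if missing:
        raise ValueError(f"kernels missing feature groups: {missing}")
    W = kernels.stacked(groups)                  # (nC, nL, n_dims)
    nC, nL, nD = W.shape
    wflat = np.transpose(W, (2, 1, 0)).reshape(nD * nL, nC)
    out = []
    for fm in feature_trials:
        if fm.n_dims != nD:
            raise ValueError("feature dimensionality does not match kernels")
        D = lagged_matrix(fm.values, kernels.lags)
        out.append(D @ wflat)
    return out


def noise_scale_for(clean: list[np.ndarray], snr_db: float) -> np.ndarray:
    """Per-channel noise standard deviation giving ``snr_db`` against the
    signal variance of ``clean``."""
    sig_power = np.vstack(clean).var(axis=0)
    noise_sd = np.sqrt(sig_power / (10.0 ** (snr_db / 10.0)))
    return np.where(sig_power > 0, noise_sd, 1.0)


def simulate_subject_eeg(feature_trials: list[FeatureMatrix],
                         kernels: GroundTruthKernels, snr_db: float,
                         rng: np.random.Generator,
                         noise_sd: np.ndarray | None = None
                         ) -> list[np.ndarray]:
    """Forward-simulate EEG trials: convolution of the planted kernels with
    the stimulus regressors plus pink+white noise at ``snr_db``.

    ``noise_sd`` fixes the per-channel noise amplitude externally (a cohort
    scales noise against a common reference so that planted group effects
    do not leak into the noise level); by default the subject's own signal
    variance sets the scale.
    """
    clean = clean_eeg(feature_trials, kernels)
    if np.isinf(snr_db):
        return clean
    if noise_sd is None:
        noise_sd = noise_scale_for(clean, snr_db)
    nC = clean[0].shape[1]
    return [c + pink_white_noise(c.shape[0], nC, rng) * noise_sd[None, :]
            for c in clean]


def build_stimulus_features(lang: ToyLanguagePair, tr: StimulusTranscript,
                            fs: float, seed: int) -> FeatureMatrix:
    """Master 43-dimension feature matrix for one transcript.

    The spectrogram is synthesised directly from the transcript (each
    phoneme carries a fixed random 16-band spectral profile shaped by an
    attack/decay envelope); E and Ed derive from it exactly as for real
    audio.
    """
    rng = np.random.default_rng(seed)
    n = int(round(tr.duration * fs))
    inventory = sorted(set(lang.inventory_l1) | set(lang.inventory_l2))
    profiles = {p: 0.2 + rng.random(16) for p in inventory}
    S = np.zeros((n, 16))
    for ph in tr.phones:
        s0 = int(np.clip(np.ceil(ph.start * fs - 0.5), 0, n - 1))
        s1 = int(np.clip(np.ceil(ph.end * fs - 0.5), s0 + 1, n))
        length = s1 - s0
        envelope = np.minimum(np.linspace(0.3, 1.5, length), 1.0)
        S[s0:s1] += envelope[:, None] * profiles[ph.symbol][None, :]
    Sfm = FeatureMatrix(S, fs, {"S": slice(0, 16)})
    E = broadband_envelope(Sfm)
    blocks = {
        "S": Sfm, "E": E, "Ed": envelope_derivative(E),
        "Pon": phoneme_onsets(tr, fs),
        "Pvc": vowel_consonant(tr, fs, lang.feature_table),
        "Phn": phonetic_feature_matrix(tr, fs, lang.feature_table),
        "Pt": phonotactic_regressors(tr, lang.grammar_l2, fs),
        "Sem": semantic_dissimilarity(tr, lang.embeddings, fs),
    }
    return FeatureMatrix.concat(blocks, fs)


def group_levels(group: str, n: int) -> list[int]:
    """CEFR sub-levels for n subjects of a coarse group (half low, half high)."""
    base = {"A": 1, "B": 3, "C": 5}[group]
    return [base + (1 if i >= (n + 1) // 2 else 0) for i in range(n)]


def simulate_cohort(cfg: CohortConfig, lang: ToyLanguagePair | None = None,
                    effects: EffectConfig | None = None) -> Cohort:
    """Simulate a full multi-group cohort listening to a shared stimulus."""
    effects = effects or EffectConfig()
    rng = np.random.default_rng(cfg.seed)
    lang = lang or make_toy_languages(seed=cfg.seed)
    montage = make_montage(cfg.n_channels)
    transcripts = [sample_transcript(lang, cfg.trial_duration_s,
                                     seed=cfg.seed * 1000 + t)
                   for t in range(cfg.n_trials)]
    stimulus = [build_stimulus_features(lang, tr, cfg.fs,
                                        seed=cfg.seed * 1000 + 500 + t)
                for t, tr in enumerate(transcripts)]
    # fixed cohort noise level: referenced to the unjittered mid-proficiency
    # forward model so that noise amplitude does not covary with group
    noise_sd = None
    if not np.isinf(cfg.snr_db):
        ref_kern = make_ground_truth_kernels("B", lang, montage, effects,
                                             fs=cfg.fs, lang_seed=cfg.seed)
        noise_sd = noise_scale_for(clean_eeg(stimulus, ref_kern), cfg.snr_db)
    subjects: list[SubjectRecord] = []
    for group in GROUPS:
        levels = (group_levels(group, cfg.n_per_group)
                  if group != "L1" else [None] * cfg.n_per_group)
        for i, level in enumerate(levels):
            sub_eff = (effects if cfg.inter_subject_kernel_sd == 0
                       else effects.jittered(rng, cfg.inter_subject_kernel_sd))
            prof = float(level) if level is not None else None
            kern = make_ground_truth_kernels(
                group, lang, montage, sub_eff, proficiency=prof, fs=cfg.fs,
                lang_seed=cfg.seed)
            eeg = simulate_subject_eeg(stimulus, kern, cfg.snr_db, rng,
                                       noise_sd=noise_sd)
            subjects.append(SubjectRecord(
                subject_id=f"{group}{i:02d}", group=group, level=level,
                eeg=eeg, fs=cfg.fs, kernels=kern))
    return Cohort(subjects, stimulus, transcripts, lang, montage, cfg)
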