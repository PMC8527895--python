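"""End-to-end cohort analysis.

Runs the full hierarchy on a (simulated or loaded) cohort: per-subject
TRF fits for the canonical descriptor sets, subject-specific and
generic-model prediction scores, phoneme distance maps, the 26-dimension
decoding feature table, SVR proficiency decoding with controls, and the
group-level component statistics.

All subjects hear the same stimulus, so the stimulus side of every
descriptor set (lagged designs, fold Gram eigendecompositions) is
computed once and shared across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DEFAULT_LAMBDA_GRID, MasterDesign, SetDesign
from .decoding import (mpca_first_component, svr_loo_decode,
                       threshold_binary_accuracy, window_summary)
from .pdm import (PhonemeMap, average_l1_space, contrast_distances,
                  l1_l2_phoneme_distance, mds_map, phoneme_projection,
                  procrustes_align)
from .stats import (cosine_distance_to_group, pointwise_anova_fdr,
                    rank_correlation, trough_latency)
from .synthetic import Cohort, nearest_shared_phoneme
from .trf import (PredictionScore, TRFResults, cv_fit, fit_at, generic_model,
                  prediction_gain, score_weights)

#: descriptor sets fitted per subject (names refer to master feature groups)
FEATURE_SETS = {
    "ALL": ["E", "Ed", "Pvc", "Pon", "Pt", "Sem"],
    "EXT": ["S", "Ed", "Phn", "Pon", "Pt", "Sem"],
    "Env": ["E"],
    "Phn": ["Phn"],
    "Pt": ["Pt"],
    "Sem": ["Sem"],
    "EnvdSgr": ["S", "Ed"],
    "PhnEnvdSgr": ["S", "Ed", "Phn"],
}

#: sets kept alive for generic-model scoring
_GENERIC_SETS = ("Env", "Sem", "EnvdSgr", "PhnEnvdSgr")
GENERIC_PREDICTORS = ("env", "gain", "sem")

FEATURE_NAMES = (
    ["w_env_mpca", "w_pon_mpca", "w_phn_mpca", "w_pt_mpca", "w_sem_mpca",
     "w_sgr_mpca", "w_pt_early_win", "w_pt_late_win", "w_sem_late_win",
     "r_env", "r_phn", "r_pt", "r_sem", "r_phn_gain"]
    + [f"g_{g}_{p}" for g in ("A", "B", "C", "L1") for p in GENERIC_PREDICTORS]
)

PDM_DIMS = 4
MIDLINE_STATS = ["Oz", "Pz", "Cz", "Fz", "Fpz"]


@dataclass
class DecodingReport:
    predictions: np.ndarray
    labels: np.ndarray
    mse: float
    pearson_r: float
    permuted_r: float
    a_vs_c_accuracy: float
    n_permutations: int


@dataclass
class PDMReport:
    group_maps: dict[str, PhonemeMap]
    l1_reference: PhonemeMap
    subject_distances: pd.DataFrame       # subject, group, level, mean_dist
    new_contrast_ratios: dict[str, float]     # group -> mean ratio
    shared_contrast_ratios: dict[str, list[float]]
    new_pairs: list[tuple[str, str]]
    shared_pairs: list[tuple[str, str]]


@dataclass
class CohortAnalysis:
    cohort: Cohort
    trf: dict[str, dict[str, TRFResults]]            # set -> subject -> fit
    scores: dict[str, dict[str, PredictionScore]]
    gain: dict[str, np.ndarray]                      # subject -> per-channel
    generic: dict[str, pd.DataFrame]                 # subject -> 4x3 r table
    features: pd.DataFrame                           # 26 features + labels
    decoding: DecodingReport | None
    pdms: PDMReport
    component_stats: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Cohort analysis", "=" * 42,
                 f"subjects: {len(self.cohort.subjects)} "
                 f"({len(self.cohort.l2_subjects)} L2)",
                 f"trials:   {len(self.cohort.stimulus)}"]
        for name in ("ALL", "EXT"):
            r = np.mean([s.mean_r for s in self.scores[name].values()])
            lines.append(f"mean CV prediction r ({name}): {r:+.4f}")
        if self.decoding is not None:
            d = self.decoding
            lines += [f"proficiency decoding: r={d.pearson_r:+.3f}, "
                      f"MSE={d.mse:.3f}",
                      f"A-vs-C accuracy (threshold 3.5): "
                      f"{d.a_vs_c_accuracy:.0%}",
                      f"permuted-label control r: {d.permuted_r:+.3f}"]
        rho = self.component_stats.get("sem_trough_spearman")
        if rho is not None:
            lines.append(f"Sem trough latency vs proficiency: "
                         f"Spearman rho={rho:+.3f}")
        for g in ("A", "B", "C"):
            m = self.pdms.subject_distances.query("group == @g")["mean_dist"]
            lines.append(f"mean L1-L2 PDM distance, group {g}: {m.mean():.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------

def fit_cohort_trfs(cohort: Cohort,
                    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
                    inner: str = "holdout",
                    set_names: list[str] | None = None):
    """Fit every descriptor set for every subject on the shared design.

    Returns (results, scores, gain, generic) as used by
    :func:`analyze_cohort`."""
    master = MasterDesign(cohort.stimulus)
    stats = {s.subject_id: master.cross_products(s.eeg)
             for s in cohort.subjects}
    names = [s.subject_id for s in cohort.subjects]
    chan = cohort.montage.names
    results: dict[str, dict[str, TRFResults]] = {}
    scores: dict[str, dict[str, PredictionScore]] = {}
    keep: dict[str, SetDesign] = {}
    for set_name in (set_names or FEATURE_SETS):
        sd = SetDesign(master, FEATURE_SETS[set_name])
        results[set_name] = {}
        scores[set_name] = {}
        for sid in names:
            res = cv_fit(sd, stats[sid], lambda_grid, inner,
                         channel_names=chan)
            results[set_name][sid] = res
            scores[set_name][sid] = res.score
        if set_name == "EXT":
            # companion fits at a common lambda: group comparisons of TRF
            # weights (PDMs) must not inherit group differences in the
            # tuned regularisation strength, and shrinkage bias (leakage
            # between correlated regressor groups) should be as small as
            # the data support — hence the minimum tuned lambda
            lam_common = float(min(results["EXT"][sid].lambda_
                                   for sid in names))
            results["EXT_common"] = {
                sid: fit_at(sd, stats[sid], lam_common, channel_names=chan)
                for sid in names}
        sd.clear_cache()
        if set_name in _GENERIC_SETS:
            keep[set_name] = sd
        del sd

    gain, generic = {}, {}
    if "PhnEnvdSgr" in scores and "EnvdSgr" in scores:
        gain = {sid: prediction_gain(scores["PhnEnvdSgr"][sid],
                                     scores["EnvdSgr"][sid])
                for sid in names}
    if all(sn in keep for sn in _GENERIC_SETS):
        generic = {sid: generic_predict_scores(
            sid, cohort, results, stats, keep) for sid in names}
    return results, scores, gain, generic


def generic_predict_scores(subject_id: str, cohort: Cohort,
                           results: dict, stats: dict,
                           set_designs: dict[str, SetDesign]) -> pd.DataFrame:
    """Per-channel-averaged prediction r of the four group-average models
    for the three generic predictor sets, with the subject left out.

    Returns a (group x predictor) table of scalars; the per-channel
    vectors are attached as ``.attrs['per_channel']``.
    """
    per_channel: dict[tuple[str, str], np.ndarray] = {}
    table = {}
    for group in ("A", "B", "C", "L1"):
        members = [s.subject_id for s in cohort.by_group(group)
                   if s.subject_id != subject_id]
        if not members:
            raise ValueError(f"group {group} empty after leaving the "
                             "subject out")
        row = {}
        gen = {sn: generic_model([results[sn][m] for m in members])
               for sn in _GENERIC_SETS}
        for pred in GENERIC_PREDICTORS:
            if pred == "env":
                sc = score_weights(set_designs["Env"], stats[subject_id],
                                   gen["Env"])
                vec = sc.r_per_channel
            elif pred == "sem":
                sc = score_weights(set_designs["Sem"], stats[subject_id],
                                   gen["Sem"])
                vec = sc.r_per_channel
            else:  # phoneme-level gain of the generic models
                with_ = score_weights(set_designs["PhnEnvdSgr"],
                                      stats[subject_id], gen["PhnEnvdSgr"])
                without = score_weights(set_designs["EnvdSgr"],
                                        stats[subject_id], gen["EnvdSgr"])
                vec = prediction_gain(with_, without)
            per_channel[(group, pred)] = vec
            row[pred] = float(vec.mean())
        table[group] = row
    df = pd.DataFrame(table).T[list(GENERIC_PREDICTORS)]
    df.attrs["per_channel"] = per_channel
    return df


# ---------------------------------------------------------------------------
# decoding feature table

def build_decoding_features(cohort: Cohort, results: dict, scores: dict,
                            gain: dict, generic: dict) -> pd.DataFrame:
    """Assemble the 26 named decoding features for every subject.

    Cross-subject compressions (MPCA) are computed over the whole cohort;
    window summaries are per subject.  Rows carry group and CEFR level.
    """
    subjects = cohort.subjects
    sids = [s.subject_id for s in subjects]
    chan = cohort.montage.names
    need = {"ALL", "EXT", "Env", "Phn", "Pt", "Sem"}
    missing = sorted(need - set(results))
    if missing:
        raise ValueError(f"missing TRF ingredients for feature table: "
                         f"{missing}")
    allres = results["ALL"]
    extres = results["EXT"]
    lag_ms = allres[sids[0]].lag_times_ms

    def stack(set_name: str, group: str) -> np.ndarray:
        return np.stack([results[set_name][sid].group_weights(group)
                         for sid in sids])

    cols: dict[str, np.ndarray] = {}
    cols["w_env_mpca"] = mpca_first_component(stack("ALL", "E")[..., 0])
    cols["w_pon_mpca"] = mpca_first_component(stack("ALL", "Pon")[..., 0])
    cols["w_phn_mpca"] = mpca_first_component(stack("EXT", "Phn"))
    cols["w_pt_mpca"] = mpca_first_component(stack("ALL", "Pt"))
    cols["w_sem_mpca"] = mpca_first_component(stack("ALL", "Sem")[..., 0])
    # EEG responsiveness across the 16 bands: collapse Sgr weights over lags
    cols["w_sgr_mpca"] = mpca_first_component(stack("EXT", "S").mean(axis=2))
    win = dict(channel_names=chan, electrodes=["Fz", "Cz", "Oz"], clip=True)
    cols["w_pt_early_win"] = np.array(
        [window_summary(allres[sid].group_weights("Pt"), lag_ms,
                        (80.0, 140.0), **win) for sid in sids])
    cols["w_pt_late_win"] = np.array(
        [window_summary(allres[sid].group_weights("Pt"), lag_ms,
                        (300.0, 700.0), **win) for sid in sids])
    cols["w_sem_late_win"] = np.array(
        [window_summary(allres[sid].group_weights("Sem"), lag_ms,
                        (300.0, 700.0), **win) for sid in sids])
    for fname, set_name in (("r_env", "Env"), ("r_phn", "Phn"),
                            ("r_pt", "Pt"), ("r_sem", "Sem")):
        mat = np.stack([scores[set_name][sid].r_per_channel for sid in sids])
        cols[fname] = mpca_first_component(mat)
    cols["r_phn_gain"] = mpca_first_component(
        np.stack([gain[sid] for sid in sids]))
    for group in ("A", "B", "C", "L1"):
        for pred in GENERIC_PREDICTORS:
            mat = np.stack([generic[sid].attrs["per_channel"][(group, pred)]
                            for sid in sids])
            cols[f"g_{group}_{pred}"] = mpca_first_component(mat)

    df = pd.DataFrame(cols, index=sids)[FEATURE_NAMES]
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("non-finite decoding feature encountered")
    df["group"] = [s.group for s in subjects]
    df["level"] = [np.nan if s.level is None else s.level for s in subjects]
    return df


def decode_proficiency(features: pd.DataFrame, n_permutations: int = 20,
                       seed: int = 0) -> DecodingReport:
    """LOO SVR decoding of the CEFR level of the L2 subjects, with a
    permuted-label control and the threshold-3.5 A-vs-C accuracy.

    The control trains on permuted labels and correlates the out-of-fold
    predictions with the *true* labels (mean over permutations): under
    exchangeability this has expectation exactly 0, whereas correlating
    with the permuted labels themselves inherits the negative bias of
    leave-one-out mean prediction.
    """
    l2 = features.dropna(subset=["level"])
    X = l2[FEATURE_NAMES].to_numpy(float)
    y = l2["level"].to_numpy(float)
    preds, mse, r = svr_loo_decode(X, y)
    rng = np.random.default_rng(seed)
    null_rs = []
    for _ in range(n_permutations):
        null_preds, _, _ = svr_loo_decode(X, rng.permutation(y))
        if np.std(null_preds) == 0:
            null_rs.append(0.0)
        else:
            null_rs.append(float(np.corrcoef(null_preds, y)[0, 1]))
    acc = threshold_binary_accuracy(preds, y)
    return DecodingReport(preds, y, mse, r, float(np.mean(null_rs)), acc,
                          n_permutations)


# ---------------------------------------------------------------------------
# phoneme distance maps

def build_pdms(cohort: Cohort, results: dict,
               electrode: str | list[str] = tuple(MIDLINE_STATS),
               k: int = PDM_DIMS) -> PDMReport:
    lang = cohort.lang
    table = lang.feature_table
    phonemes = [p for p in table.index if p in lang.inventory_l2]
    ext = results.get("EXT_common", results["EXT"])

    def subject_map(res: TRFResults) -> PhonemeMap:
        proj = phoneme_projection(res, table, electrode, phonemes)
        return mds_map(proj, phonemes, k=k)

    maps = {s.subject_id: subject_map(ext[s.subject_id])
            for s in cohort.subjects}
    ref = average_l1_space([maps[s.subject_id]
                            for s in cohort.by_group("L1")])
    rows = []
    for s in cohort.subjects:
        aligned, _ = procrustes_align(maps[s.subject_id], ref)
        _, mean_d = l1_l2_phoneme_distance(aligned, ref)
        rows.append((s.subject_id, s.group, s.level, mean_d))
    dist = pd.DataFrame(rows, columns=["subject", "group", "level",
                                       "mean_dist"]).set_index("subject")

    new_pairs = [(u, nearest_shared_phoneme(lang, u)) for u in lang.unique_l2]
    shared_sorted = sorted(lang.shared)
    shared_pairs = [(p, q) for i, p in enumerate(shared_sorted)
                    for q in shared_sorted[i + 1:]]
    # contrast ratios are computed on the raw (unaligned) group maps:
    # pairwise distances are invariant to the rotation/translation part of
    # the alignment, and the Procrustes scale factor would otherwise shrink
    # mismatched (assimilated) configurations wholesale
    raw_maps = {group: subject_map(generic_model(
        [ext[s.subject_id] for s in cohort.by_group(group)]))
        for group in ("L1", "A", "B", "C")}
    new_ratio: dict[str, float] = {}
    shared_ratio: dict[str, list[float]] = {}
    for group in ("A", "B", "C", "L1"):
        ratios = contrast_distances(raw_maps[group], new_pairs,
                                    raw_maps["L1"])
        new_ratio[group] = float(np.mean(list(ratios.values())))
        ratios = contrast_distances(raw_maps[group], shared_pairs,
                                    raw_maps["L1"])
        shared_ratio[group] = list(ratios.values())
    group_maps = {g: procrustes_align(m, ref)[0]
                  for g, m in raw_maps.items()}
    return PDMReport(group_maps, ref, dist, new_ratio, shared_ratio,
                     new_pairs, shared_pairs)


# ---------------------------------------------------------------------------
# component statistics

def component_statistics(cohort: Cohort, results: dict) -> dict:
    chan = cohort.montage.names
    cz = chan.index("Cz")
    allres = results["ALL"]
    lag_ms = allres[cohort.subjects[0].subject_id].lag_times_ms
    lat, levels = [], []
    for s in cohort.l2_subjects:
        curve = allres[s.subject_id].group_weights("Sem")[cz, :, 0]
        t, _ = trough_latency(curve, lag_ms, (300.0, 600.0))
        lat.append(t)
        levels.append(s.level)
    rho, p = rank_correlation(levels, lat)
    l1_sem = [allres[s.subject_id].group_weights("Sem")
              for s in cohort.by_group("L1")]
    cosine = {
        g: float(np.mean([cosine_distance_to_group(
            allres[s.subject_id].group_weights("Sem"), l1_sem)
            for s in cohort.by_group(g)]))
        for g in ("A", "B", "C")}
    mids = [chan.index(e) for e in MIDLINE_STATS if e in chan]
    sem_by_group = [np.stack([allres[s.subject_id].group_weights("Sem")[mids, :, 0].T
                              for s in cohort.by_group(g)])
                    for g in ("A", "B", "C")]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask = pointwise_anova_fdr(sem_by_group)
    return {"sem_trough_latency": dict(zip(
                [s.subject_id for s in cohort.l2_subjects], lat)),
            "sem_trough_spearman": rho,
            "sem_trough_spearman_p": p,
            "sem_cosine_by_group": cosine,
            "sem_anova": mask}


# ---------------------------------------------------------------------------

def analyze_cohort(cohort: Cohort,
                   lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
                   inner: str = "holdout", decode: bool = True,
                   n_permutations: int = 20, seed: int = 0
                   ) -> CohortAnalysis:
    """Run the full analysis hierarchy on a cohort."""
    results, scores, gain, generic = fit_cohort_trfs(cohort, lambda_grid,
                                                     inner)
    features = build_decoding_features(cohort, results, scores, gain, generic)
    report = (decode_proficiency(features, n_permutations, seed)
              if decode else None)
    pdms = build_pdms(cohort, results)
    comp = component_statistics(cohort, results)
    return CohortAnalysis(cohort, results, scores, gain, generic, features,
                          report, pdms, comp)


# ---------------------------------------------------------------------------
# convolution-oracle kernel recovery

def kernel_recovery(seed: int = 0, n_trials: int = 10,
                    trial_duration_s: float = 60.0, n_channels: int = 8,
                    snr_db: float = np.inf) -> dict:
    """Noiseless forward-simulation / refit consistency check.

    Simulates one subject with known kernels, fits the ALL-set TRF by
    cross-validation, and correlates fitted against planted weights for
    every identifiable impulse response.  Because Pon equals the sum of
    the two Pvc columns by construction, the Pon/Pvc split is not
    identifiable; the comparison therefore uses the total vowel-onset and
    consonant-onset responses (Pon + vowel, Pon + consonant) alongside
    E, Ed, Pt1, Pt2 and Sem.
    """
    from .synthetic import CohortConfig, make_toy_languages, \
        make_ground_truth_kernels, simulate_subject_eeg, \
        build_stimulus_features, sample_transcript
    from .montage import make_montage

    cfg = CohortConfig(n_per_group=1, trial_duration_s=trial_duration_s,
                       n_trials=n_trials, snr_db=snr_db,
                       n_channels=n_channels, seed=seed)
    lang = make_toy_languages(seed=seed)
    montage = make_montage(n_channels)
    transcripts = [sample_transcript(lang, trial_duration_s,
                                     seed=seed * 1000 + t)
                   for t in range(n_trials)]
    stimulus = [build_stimulus_features(lang, tr, cfg.fs,
                                        seed=seed * 1000 + 500 + t)
                for t, tr in enumerate(transcripts)]
    kern = make_ground_truth_kernels("L1", lang, montage, fs=cfg.fs,
                                     lang_seed=seed)
    rng = np.random.default_rng(seed + 7)
    # drive the EEG with exactly the fitted descriptor so the refit is a
    # pure convolution-inversion check
    all_only = [fm.select(FEATURE_SETS["ALL"]) for fm in stimulus]
    eeg = simulate_subject_eeg(all_only, kern, snr_db, rng)

    master = MasterDesign(stimulus)
    sd = SetDesign(master, FEATURE_SETS["ALL"])
    stats = master.cross_products(eeg)
    res = cv_fit(sd, stats, channel_names=montage.names)

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        a, b = a.ravel(), b.ravel()
        return float(np.corrcoef(a, b)[0, 1])

    fitted = {g: res.group_weights(g) for g in FEATURE_SETS["ALL"]}
    true = {g: kern.kernels[g] for g in FEATURE_SETS["ALL"]}
    out = {
        "E": corr(fitted["E"], true["E"]),
        "Ed": corr(fitted["Ed"], true["Ed"]),
        "Pt1": corr(fitted["Pt"][..., 0], true["Pt"][..., 0]),
        "Pt2": corr(fitted["Pt"][..., 1], true["Pt"][..., 1]),
        "Sem": corr(fitted["Sem"], true["Sem"]),
        "vowel_onset": corr(fitted["Pon"][..., 0] + fitted["Pvc"][..., 0],
                            true["Pon"][..., 0] + true["Pvc"][..., 0]),
        "consonant_onset": corr(fitted["Pon"][..., 0] + fitted["Pvc"][..., 1],
                                true["Pon"][..., 0] + true["Pvc"][..., 1]),
    }
    return {"per_feature_correlation": out,
            "min_feature_correlation": min(out.values()),
            "mean_prediction_r": res.score.mean_r,
            "lambda": res.lambda_}


def null_anova_calibration(n_runs: int = 100, seed: int = 0,
                           n_subjects: int = 8, n_lags: int = 30,
                           n_electrodes: int = 5) -> float:
    """Average fraction of (lag, electrode) points flagged by the
    point-wise ANOVA + BH-FDR on fully null group data."""
    rng = np.random.default_rng(seed)
    fractions = []
    for _ in range(n_runs):
        groups = [rng.standard_normal((n_subjects, n_lags, n_electrodes))
                  for _ in range(3)]
        mask = pointwise_anova_fdr(groups)
        fractions.append(mask.mask.mean())
    return float(np.mean(fractions))
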