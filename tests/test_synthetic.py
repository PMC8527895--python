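import numpy as np
import pytest

from speechtrf.design import lag_grid
from speechtrf.montage import make_montage
from speechtrf.pipeline import FEATURE_SETS
from speechtrf.synthetic import (CohortConfig, EffectConfig, clean_eeg,
                                 build_stimulus_features,
                                 make_ground_truth_kernels,
                                 nearest_shared_phoneme,
                                 pink_white_noise, simulate_cohort,
                                 simulate_subject_eeg)

FS = 50.0


@pytest.fixture(scope="module")
def montage():
    return make_montage(8)


def kernels_for(lang, montage, group, proficiency=None):
    return make_ground_truth_kernels(group, lang, montage,
                                     proficiency=proficiency, fs=FS,
                                     lang_seed=1)


class TestGroundTruthKernels:
    def test_unknown_group_rejected(self, lang, montage):
        with pytest.raises(ValueError):
            kernels_for(lang, montage, "Z")

    def test_l1_has_no_early_phonotactic_component(self, lang, montage):
        lag_ms = lag_grid((0, 600), FS) * 1000.0 / FS
        near120 = np.abs(lag_ms - 120.0) < 40.0
        l1 = kernels_for(lang, montage, "L1").kernels["Pt"]
        a = kernels_for(lang, montage, "A").kernels["Pt"]
        # late component is shared; the early window separates the groups
        late = np.abs(lag_ms - 370.0) < 40.0
        assert np.abs(l1[:, near120]).max() < 0.1 * np.abs(l1[:, late]).max()
        assert np.abs(a[:, near120]).max() > np.abs(l1[:, near120]).max()

    def test_semantic_trough_scales_with_proficiency(self, lang, montage):
        a = kernels_for(lang, montage, "A").kernels["Sem"]
        c = kernels_for(lang, montage, "C").kernels["Sem"]
        assert np.abs(c).max() > np.abs(a).max()

    def test_semantic_trough_latency_decreases_with_proficiency(self, lang,
                                                                montage):
        lag_ms = lag_grid((0, 600), FS) * 1000.0 / FS
        lats = []
        for p in (1, 3, 6):
            k = kernels_for(lang, montage, "C", proficiency=p).kernels["Sem"]
            cz = np.abs(k[:, :, 0]).sum(axis=1).argmax()
            lats.append(lag_ms[np.argmin(k[cz, :, 0])])
        assert lats[0] > lats[1] > lats[2]

    def test_group_a_assimilates_unique_phonemes(self, lang, montage):
        """At the lowest proficiency the projected response of a unique
        phoneme equals that of its nearest shared phoneme."""
        k = kernels_for(lang, montage, "A")
        table = lang.feature_table
        phonemes = [p for p in table.index if p in lang.inventory_l2]
        W = k.kernels["Phn"][0]  # any channel
        proj = table.loc[phonemes].to_numpy(float) @ W.T
        for u in lang.unique_l2:
            near = nearest_shared_phoneme(lang, u)
            iu, inear = phonemes.index(u), phonemes.index(near)
            np.testing.assert_allclose(proj[iu], proj[inear], atol=1e-10)

    def test_l1_unique_phonemes_are_distinct(self, lang, montage):
        k = kernels_for(lang, montage, "L1")
        table = lang.feature_table
        phonemes = [p for p in table.index if p in lang.inventory_l2]
        ci = 2
        proj = table.loc[phonemes].to_numpy(float) @ k.kernels["Phn"][ci].T
        for u in lang.unique_l2:
            near = nearest_shared_phoneme(lang, u)
            iu, inear = phonemes.index(u), phonemes.index(near)
            assert np.linalg.norm(proj[iu] - proj[inear]) > 0.1


class TestSimulateSubjectEEG:
    def feats(self, lang, n_trials=2, duration=10.0):
        from speechtrf.languages import sample_transcript
        out = []
        for t in range(n_trials):
            tr = sample_transcript(lang, duration, seed=100 + t)
            fm = build_stimulus_features(lang, tr, FS, seed=200 + t)
            out.append(fm.select(FEATURE_SETS["ALL"]))
        return out

    def test_noiseless_limit_is_exact_convolution(self, lang, montage):
        feats = self.feats(lang)
        kern = kernels_for(lang, montage, "B")
        eeg = simulate_subject_eeg(feats, kern, np.inf,
                                   np.random.default_rng(0))
        # independent convolution oracle on one channel / one feature dim
        X = feats[0].values
        y_manual = np.zeros(X.shape[0])
        W = kern.stacked(list(feats[0].groups))
        ci = 3
        for d in range(X.shape[1]):
            full = np.convolve(X[:, d], np.r_[0, W[ci, :, d]])
            y_manual += full[:X.shape[0]]
        np.testing.assert_allclose(eeg[0][:, ci], y_manual, atol=1e-9)

    def test_zero_kernels_give_pure_noise_with_stated_variance(self, lang,
                                                               montage):
        feats = self.feats(lang)
        kern = kernels_for(lang, montage, "B")
        for g in kern.kernels:
            kern.kernels[g] = np.zeros_like(kern.kernels[g])
        eeg = simulate_subject_eeg(feats, kern, 0.0,
                                   np.random.default_rng(0),
                                   noise_sd=np.full(montage.n_channels, 2.0))
        var = np.vstack(eeg).var(axis=0)
        np.testing.assert_allclose(var, 4.0, rtol=0.15)

    def test_fixed_seed_reproduces_recording(self, lang, montage):
        feats = self.feats(lang)
        kern = kernels_for(lang, montage, "B")
        a = simulate_subject_eeg(feats, kern, 0.0, np.random.default_rng(5))
        b = simulate_subject_eeg(feats, kern, 0.0, np.random.default_rng(5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_snr_scaling(self, lang, montage):
        feats = self.feats(lang)
        kern = kernels_for(lang, montage, "B")
        clean = clean_eeg(feats, kern)
        noisy = simulate_subject_eeg(feats, kern, 0.0,
                                     np.random.default_rng(1))
        noise = np.vstack(noisy) - np.vstack(clean)
        sig = np.vstack(clean)
        snr = 10 * np.log10(sig.var(axis=0).mean() / noise.var(axis=0).mean())
        assert abs(snr) < 1.5  # ~0 dB

    def test_missing_feature_group_rejected(self, lang, montage):
        feats = self.feats(lang)
        kern = kernels_for(lang, montage, "B")
        del kern.kernels["Sem"]
        with pytest.raises(ValueError, match="Sem"):
            simulate_subject_eeg(feats, kern, 0.0, np.random.default_rng(0))


class TestPinkWhiteNoise:
    def test_unit_variance_and_one_over_f_slope(self):
        rng = np.random.default_rng(0)
        x = pink_white_noise(20000, 4, rng)
        np.testing.assert_allclose(x.var(axis=0), 1.0, rtol=0.1)
        f = np.fft.rfftfreq(20000)
        spec = np.abs(np.fft.rfft(x[:, 0])) ** 2
        lo = spec[(f > 0.001) & (f < 0.01)].mean()
        hi = spec[(f > 0.1) & (f < 0.5)].mean()
        assert lo > 3 * hi  # low frequencies dominate


class TestSimulateCohort:
    def test_counts_and_labels(self):
        cfg = CohortConfig(n_per_group=2, trial_duration_s=8.0, n_trials=2,
                           seed=3)
        cohort = simulate_cohort(cfg)
        assert len(cohort.subjects) == 8
        groups = {s.group for s in cohort.subjects}
        assert groups == {"A", "B", "C", "L1"}
        for s in cohort.subjects:
            assert len(s.eeg) == 2
            if s.group == "L1":
                assert s.level is None
            else:
                assert 1 <= s.level <= 6

    def test_zero_jitter_shares_kernels_within_level(self):
        cfg = CohortConfig(n_per_group=2, trial_duration_s=8.0, n_trials=2,
                           inter_subject_kernel_sd=0.0, snr_db=np.inf, seed=3)
        cohort = simulate_cohort(cfg)
        l1 = cohort.by_group("L1")
        for g in l1[0].kernels.kernels:
            np.testing.assert_array_equal(l1[0].kernels.kernels[g],
                                          l1[1].kernels.kernels[g])

    def test_identical_seeds_give_bit_identical_cohorts(self):
        cfg = CohortConfig(n_per_group=1, trial_duration_s=8.0, n_trials=2,
                           seed=9)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for sa, sb in zip(a.subjects, b.subjects):
            for x, y in zip(sa.eeg, sb.eeg):
                np.testing.assert_array_equal(x, y)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_per_group=0)
        with pytest.raises(ValueError):
            CohortConfig(n_trials=1)
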