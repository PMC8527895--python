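import numpy as np
import pytest

from speechtrf.features import (FeatureMatrix, assemble_descriptor,
                                auditory_spectrogram, broadband_envelope,
                                envelope_derivative, phoneme_onsets,
                                phonetic_feature_matrix,
                                phonotactic_regressors,
                                semantic_dissimilarity, time_to_sample,
                                vowel_consonant)
from speechtrf.languages import (EmbeddingTable, Phone, StimulusTranscript,
                                 Word)
from speechtrf.phonotactics import Constraint, PhonotacticGrammar
from speechtrf.synthetic import build_stimulus_features

FS = 50.0


def toy_transcript(symbols, durations, content=None, words=None):
    """Transcript with one sentence; ``words`` is a list of phone-index
    spans, defaulting to one word per phoneme."""
    phones, t = [], 0.0
    for s, d in zip(symbols, durations):
        phones.append(Phone(s, t, t + d))
        t += d
    spans = words or [(i, i + 1) for i in range(len(symbols))]
    ws = []
    for k, (i0, i1) in enumerate(spans):
        ws.append(Word(f"w{k}", (i0, i1),
                       True if content is None else content[k],
                       phones[i0].start, phones[i1 - 1].end))
    return StimulusTranscript(phones, ws, [(0, len(ws))], t)


class TestEnvelope:
    def test_broadband_envelope_is_band_mean(self, rng):
        S = FeatureMatrix(rng.random((40, 16)), FS, {"S": slice(0, 16)})
        E = broadband_envelope(S)
        np.testing.assert_allclose(E.values[:, 0], S.values.mean(axis=1))

    def test_single_band_passthrough(self):
        S = FeatureMatrix(np.arange(10.0)[:, None], FS, {"S": slice(0, 1)})
        np.testing.assert_allclose(broadband_envelope(S).values[:, 0],
                                   np.arange(10.0))

    def test_derivative_hand_example(self):
        E = FeatureMatrix(np.array([0, 1, 0.5, 2.0])[:, None], FS,
                          {"E": slice(0, 1)})
        np.testing.assert_allclose(envelope_derivative(E).values[:, 0],
                                   [0, 1, 0, 1.5])

    def test_derivative_of_decreasing_envelope_is_zero(self):
        E = FeatureMatrix(np.linspace(5, 0, 20)[:, None], FS,
                          {"E": slice(0, 1)})
        assert not envelope_derivative(E).values.any()


class TestOnsets:
    def test_one_impulse_per_phoneme(self):
        tr = toy_transcript(list("abcabcabca"), [0.1] * 10)
        pon = phoneme_onsets(tr, FS)
        assert pon.values.sum() == 10

    def test_nearest_sample_rounding(self):
        # onset at 1.013 s at 50 Hz -> sample 51 (nearest)
        assert time_to_sample(1.013, FS) == 51
        # exact tie resolves toward the earlier sample
        assert time_to_sample(0.03, FS) == 1

    def test_onset_collision_raises(self):
        tr = toy_transcript(["a", "b"], [0.001, 0.1])
        with pytest.raises(ValueError, match="fs too low"):
            phoneme_onsets(tr, FS)


class TestVowelConsonant:
    def test_columns_sum_to_onsets(self, lang, transcript):
        pon = phoneme_onsets(transcript, FS).values[:, 0]
        pvc = vowel_consonant(transcript, FS, lang.feature_table).values
        np.testing.assert_allclose(pvc.sum(axis=1), pon)

    def test_all_vowel_transcript_has_empty_consonant_column(self, lang):
        vowel = lang.inventory_l2[0]
        assert lang.is_vowel(vowel)
        tr = toy_transcript([vowel] * 5, [0.1] * 5)
        pvc = vowel_consonant(tr, FS, lang.feature_table).values
        assert not pvc[:, 1].any()
        assert pvc[:, 0].sum() == 5

    def test_unknown_phoneme_raises(self, lang):
        tr = toy_transcript(["@@"], [0.1])
        with pytest.raises(KeyError):
            vowel_consonant(tr, FS, lang.feature_table)


class TestPhoneticFeatures:
    def test_step_function_spans_phoneme_duration(self, lang):
        sym = lang.inventory_l2[2]
        tr = toy_transcript([sym], [0.1])
        phn = phonetic_feature_matrix(tr, FS, lang.feature_table)
        row = lang.feature_table.loc[sym]
        for j, fname in enumerate(lang.feature_table.columns):
            expected = 5 if row[fname] else 0  # 100 ms at 50 Hz
            assert phn.values[:, j].sum() == expected

    def test_abutting_phonemes_sharing_feature_form_contiguous_run(self, lang):
        cons = [p for p in lang.inventory_l2 if not lang.is_vowel(p)][:2]
        tr = toy_transcript(cons, [0.1, 0.1])
        phn = phonetic_feature_matrix(tr, FS, lang.feature_table)
        j = list(lang.feature_table.columns).index("consonantal")
        col = phn.values[:, j]
        on = np.flatnonzero(col)
        assert np.array_equal(on, np.arange(on[0], on[-1] + 1))


class TestPhonotacticRegressors:
    def grammar(self):
        return PhonotacticGrammar([Constraint(("a", "b"), 1.0),
                                   Constraint(("b",), 0.5)], ["a", "b", "c"])

    def test_prefix_probability_marks(self):
        tr = toy_transcript(list("abc"), [0.1] * 3, words=[(0, 3)])
        g = self.grammar()
        pt = phonotactic_regressors(tr, g, FS)
        onsets = np.flatnonzero(pt.values[:, 0])
        assert len(onsets) == 3  # one Pt1 mark per phoneme
        np.testing.assert_allclose(
            pt.values[onsets, 0],
            [g.prob(("a",)), g.prob(("a", "b")), g.prob(("a", "b", "c"))])
        # Pt2 zero at word-initial phoneme, differences after
        assert pt.values[onsets[0], 1] == 0.0
        assert pt.values[onsets[1], 1] == pytest.approx(
            g.prob(("a", "b")) - g.prob(("a",)))

    def test_single_phoneme_word_has_zero_pt2(self):
        tr = toy_transcript(["c"], [0.1])
        pt = phonotactic_regressors(tr, self.grammar(), FS)
        assert not pt.values[:, 1].any()
        assert (pt.values[:, 0] > 0).sum() == 1

    def test_pt1_values_in_unit_interval(self, lang, transcript):
        pt = phonotactic_regressors(transcript, lang.grammar_l2, FS)
        marks = pt.values[pt.values[:, 0] > 0, 0]
        assert len(marks) == len(transcript.phones)
        assert (marks <= 1.0).all() and (marks > 0.0).all()


class TestSemanticDissimilarity:
    def test_word_equal_to_context_mean_scores_zero(self):
        emb = EmbeddingTable({"w0": np.array([1.0, 2, 3, 4]),
                              "w1": np.array([2.0, 4, 6, 8]),
                              "w2": np.array([1.5, 3, 4.5, 6])}, dim=4)
        tr = toy_transcript(list("abc"), [0.2] * 3)
        sem = semantic_dissimilarity(tr, emb, FS)
        # w1 and w2 are perfectly correlated with their context mean, and
        # the no-context fill (mean of the others) is then also zero
        np.testing.assert_allclose(sem.values, 0.0, atol=1e-12)

    def test_hand_computed_three_word_sentence(self):
        v0 = np.array([1.0, 0, 0, 1])
        v1 = np.array([0.0, 1, 1, 1])
        v2 = np.array([1.0, 1, 0, 0])
        emb = EmbeddingTable({"w0": v0, "w1": v1, "w2": v2}, dim=4)
        tr = toy_transcript(list("abc"), [0.2] * 3)
        sem = semantic_dissimilarity(tr, emb, FS)

        def dis(v, ctx):
            c = np.mean(ctx, axis=0)
            vc, cc = v - v.mean(), c - c.mean()
            return 1 - vc @ cc / np.linalg.norm(vc) / np.linalg.norm(cc)

        i1 = int(np.ceil(0.2 * FS - 0.5))
        i2 = int(np.ceil(0.4 * FS - 0.5))
        assert sem.values[i1, 0] == pytest.approx(dis(v1, [v0]))
        assert sem.values[i2, 0] == pytest.approx(dis(v2, [v0, v1]))
        # first word of the passage: mean of the other values
        assert sem.values[0, 0] == pytest.approx(
            np.mean([sem.values[i1, 0], sem.values[i2, 0]]))

    def test_values_within_zero_two(self, lang, transcript):
        sem = semantic_dissimilarity(transcript, lang.embeddings, FS)
        vals = sem.values[sem.values != 0]
        assert ((vals >= 0) & (vals <= 2)).all()

    def test_missing_content_word_raises(self):
        emb = EmbeddingTable({"w1": np.zeros(3)}, dim=3)
        tr = toy_transcript(["a"], [0.1])
        with pytest.raises(KeyError):
            semantic_dissimilarity(tr, emb, FS)


class TestAssembleDescriptor:
    def test_column_counts(self, lang, transcript):
        master = build_stimulus_features(lang, transcript, FS, seed=0)
        assert assemble_descriptor(master, "ALL").n_dims == 8
        assert assemble_descriptor(master, "EXT").n_dims == 40

    def test_group_slices_round_trip(self, lang, transcript):
        master = build_stimulus_features(lang, transcript, FS, seed=0)
        ext = assemble_descriptor(master, "EXT")
        for name in ("S", "Ed", "Phn", "Pon", "Pt", "Sem"):
            np.testing.assert_array_equal(ext.group(name), master.group(name))

    def test_missing_group_listed_in_error(self, lang, transcript):
        blocks = {"E": FeatureMatrix(np.zeros((10, 1)), FS, {"E": slice(0, 1)})}
        with pytest.raises(KeyError, match="Pon"):
            assemble_descriptor(blocks, "ALL")


class TestAuditorySpectrogram:
    def test_silence_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="silent"):
            S = auditory_spectrogram(np.zeros(16000), 16000.0)
        assert not S.values.any()
        assert S.values.shape == (50, 16)

    def test_pure_tone_energy_concentrates_in_matching_band(self):
        rate = 16000.0
        t = np.arange(int(rate * 2)) / rate
        edges = np.geomspace(100.0, 0.4 * rate, 129)
        centers = np.sqrt(edges[:-1] * edges[1:])
        tone_band = 40  # a mid filterbank band
        audio = np.sin(2 * np.pi * centers[tone_band] * t)
        S = auditory_spectrogram(audio, rate)
        profile = S.values.mean(axis=0)
        assert abs(int(np.argmax(profile)) - tone_band // 8) <= 1

    def test_amplitude_monotonicity(self):
        rate = 16000.0
        t = np.arange(int(rate)) / rate
        audio = np.sin(2 * np.pi * 440 * t)
        lo = auditory_spectrogram(audio, rate).values
        hi = auditory_spectrogram(2 * audio, rate).values
        assert hi.mean() > lo.mean()
        assert (lo >= 0).all()
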