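import dataclasses
from collections import Counter

import numpy as np
import pytest
from scipy import signal

from speechtrf.containers import centroparietal_gain, make_sphere_layout
from speechtrf.features import build_impulse_series, FeatureImpulseSeries
from speechtrf.synthetic import (
    CohortSpec,
    FluencyLink,
    GroupParams,
    KernelSpec,
    LexiconSpec,
    NoiseSpec,
    TranscriptSpec,
    generate_cohort,
    generate_corpus,
    generate_embeddings,
    generate_transcript,
    kernel_waveform,
    pink_noise,
    simulate_subject_eeg,
)


class TestEmbeddings:
    def test_similarity_one_gives_identical_category_vectors(self):
        emb = generate_embeddings(
            LexiconSpec(vocab_size=4, embed_dim=8, n_categories=2,
                        within_category_similarity=1.0, seed=0)
        )
        # words 0 and 2 share category 0
        v0, v2 = emb.get("w0000"), emb.get("w0002")
        np.testing.assert_array_equal(v0, v2)
        r = np.corrcoef(v0, v2)[0, 1]
        assert r == pytest.approx(1.0)

    def test_default_dim_is_300(self):
        emb = generate_embeddings(LexiconSpec(vocab_size=5, n_categories=1, seed=0))
        assert emb.dim == 300

    def test_within_exceeds_between_cosine_brute_force(self):
        spec = LexiconSpec(vocab_size=100, embed_dim=32, n_categories=5,
                           within_category_similarity=0.7, seed=1)
        emb = generate_embeddings(spec)
        V = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
        cats = np.arange(100) % 5
        within, between = [], []
        for i in range(100):
            for j in range(i + 1, 100):
                (within if cats[i] == cats[j] else between).append(V[i] @ V[j])
        assert np.mean(within) > np.mean(between)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            LexiconSpec(vocab_size=3, embed_dim=8, n_categories=5, seed=0)

    def test_deterministic(self):
        spec = LexiconSpec(vocab_size=20, embed_dim=8, n_categories=4, seed=9)
        a, b = generate_embeddings(spec), generate_embeddings(spec)
        np.testing.assert_array_equal(a.vectors, b.vectors)


class TestCorpus:
    def test_zero_temperature_repeats_sentence(self, embeddings):
        sents = generate_corpus(embeddings, n_sentences=6, transition_temperature=0.0,
                                seed=0, mean_sentence_len=8, start_word="w0000")
        assert all(s == sents[0] for s in sents)
        counts = Counter()
        for s in sents:
            for i in range(len(s) - 4):
                counts[tuple(s[i : i + 5])] += 1
        assert set(counts.values()) == {6}  # every observed 5-gram: count = n

    def test_seed_reproducible(self, embeddings):
        a = generate_corpus(embeddings, 50, 0.5, seed=4)
        b = generate_corpus(embeddings, 50, 0.5, seed=4)
        assert a == b

    def test_empty_corpus_error(self, embeddings):
        with pytest.raises(ValueError, match="n_sentences"):
            generate_corpus(embeddings, 0, 0.5, seed=0)


class TestTranscript:
    def test_word_count_at_rate(self, corpus):
        spec = TranscriptSpec(duration_s=720.0, words_per_minute=190.0, seed=5)
        toks = generate_transcript(spec, corpus)
        expected = 720.0 * 190.0 / 60.0  # 2280
        assert abs(len(toks) - expected) / expected < 0.10

    def test_onsets_strictly_increasing(self, transcript):
        onsets = np.array([t.onset_s for t in transcript])
        assert np.all(np.diff(onsets) > 0)

    def test_sentence_ids_nondecreasing(self, transcript):
        sids = [t.sentence_id for t in transcript]
        assert all(b >= a for a, b in zip(sids, sids[1:]))

    def test_mean_duration_near_target(self, corpus):
        spec = TranscriptSpec(duration_s=400.0, seed=8)  # > 500 words at 190 wpm
        toks = generate_transcript(spec, corpus)
        durs = np.array([t.offset_s - t.onset_s for t in toks if t.is_content])
        assert durs.size >= 500
        sem = durs.std(ddof=1) / np.sqrt(durs.size)
        assert abs(durs.mean() - 0.334) < 2 * sem + 0.334 * 0.02

    def test_durations_floored(self, transcript):
        durs = [t.offset_s - t.onset_s for t in transcript]
        assert min(durs) >= 0.05


def unit_impulse(sample, n, fs, name="f"):
    v = np.zeros(n)
    v[sample] = 1.0
    return FeatureImpulseSeries(name, v, fs, {sample: (0,)})


class TestSimulateSubject:
    fs = 100.0
    n = 600

    def kernel(self, amp=-1.0, lat=200.0, topo=(1.0, 0.5, 0.25)):
        return KernelSpec("f", lat, 50.0, amp, topo)

    def test_noiseless_single_impulse_reproduces_kernel(self):
        imp = unit_impulse(50, self.n, self.fs)
        kern = self.kernel()
        rec, shared = simulate_subject_eeg(
            [imp], [kern], NoiseSpec(), self.fs, 3, seed=0, kernel_support_ms=500.0
        )
        wav = kernel_waveform(kern, self.fs, 500.0)
        for ch, gain in enumerate(kern.topography):
            np.testing.assert_allclose(
                rec.data[ch, 50 : 50 + wav.size], gain * wav, atol=1e-12
            )
        assert not shared.any()

    def test_two_close_impulses_equal_sum_of_shifted_kernels(self):
        imp = FeatureImpulseSeries("f", np.zeros(self.n), self.fs)
        imp.values[[50, 60]] = [1.0, 2.0]
        kern = self.kernel()
        rec, _ = simulate_subject_eeg(
            [imp], [kern], NoiseSpec(), self.fs, 3, seed=0, kernel_support_ms=500.0
        )
        # brute-force convolution oracle
        wav = kernel_waveform(kern, self.fs, 500.0)
        oracle = np.zeros(self.n)
        for s, h in [(50, 1.0), (60, 2.0)]:
            seg = wav[: self.n - s]
            oracle[s : s + seg.size] += h * seg
        np.testing.assert_allclose(rec.data[0], oracle * 1.0, atol=1e-12)

    def test_zero_kernel_output_uncorrelated_with_features(self, rng):
        imp = FeatureImpulseSeries("f", np.zeros(self.n), self.fs)
        onsets = rng.choice(self.n - 60, 40, replace=False)
        imp.values[onsets] = rng.uniform(0.2, 1.0, 40)
        kern = self.kernel(amp=0.0)
        rec, _ = simulate_subject_eeg(
            [imp], [kern], NoiseSpec(white_sd=1.0), self.fs, 3, seed=7,
            kernel_support_ms=500.0,
        )
        pred = signal.fftconvolve(imp.values, kernel_waveform(
            self.kernel(amp=-1.0), self.fs, 500.0))[: self.n]
        obs = abs(np.corrcoef(rec.data[0], pred)[0, 1])
        null = []
        for _ in range(1000):
            null.append(abs(np.corrcoef(rng.permutation(rec.data[0]), pred)[0, 1]))
        assert obs < np.quantile(null, 0.95)

    def test_energy_bookkeeping(self, rng):
        """Variance of noiseless output equals the explicit convolution sum."""
        imp = FeatureImpulseSeries("f", np.zeros(self.n), self.fs)
        imp.values[rng.choice(self.n - 60, 30, replace=False)] = 1.0
        kern = self.kernel()
        rec, _ = simulate_subject_eeg(
            [imp], [kern], NoiseSpec(), self.fs, 3, seed=0, kernel_support_ms=500.0
        )
        wav = kernel_waveform(kern, self.fs, 500.0)
        explicit = np.convolve(imp.values, wav)[: self.n]
        for ch, gain in enumerate(kern.topography):
            v1, v2 = rec.data[ch].var(), (gain * explicit).var()
            assert abs(v1 - v2) <= 1e-10 * max(v2, 1e-30)

    def test_reproducible(self):
        imp = unit_impulse(10, self.n, self.fs)
        kern = self.kernel()
        a, _ = simulate_subject_eeg([imp], [kern], NoiseSpec(white_sd=1.0, pink_sd=0.5),
                                    self.fs, 3, seed=42, kernel_support_ms=500.0)
        b, _ = simulate_subject_eeg([imp], [kern], NoiseSpec(white_sd=1.0, pink_sd=0.5),
                                    self.fs, 3, seed=42, kernel_support_ms=500.0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_fs_mismatch_error(self):
        imp = unit_impulse(10, self.n, self.fs)
        kern = KernelSpec("f", 200.0, 50.0, -1.0, (1.0, 1.0, 1.0), fs=128.0)
        with pytest.raises(ValueError, match="Hz"):
            simulate_subject_eeg([imp], [kern], NoiseSpec(), self.fs, 3, seed=0)


def test_pink_noise_spectrum_slope(rng):
    x = pink_noise(rng, (4, 8192))
    f = np.fft.rfftfreq(8192)
    p = np.abs(np.fft.rfft(x, axis=-1)).mean(axis=0)
    lo = p[(f > 0.001) & (f < 0.01)].mean()
    hi = p[(f > 0.1) & (f < 0.5)].mean()
    assert lo > 10 * hi  # 1/f amplitude: low frequencies dominate
    assert x.std(axis=-1) == pytest.approx(np.ones(4), abs=1e-9)


def cohort_stimuli(n_samples=800, fs=100.0, seed=0):
    rng = np.random.default_rng(seed)
    stim = []
    for name in ("dissimilarity", "surprisal", "onset"):
        v = np.zeros(n_samples)
        onsets = rng.choice(n_samples - 80, 40, replace=False)
        v[onsets] = rng.uniform(0.2, 1.0, 40)
        stim.append(FeatureImpulseSeries(name, v, fs))
    return [stim]


class TestCohort:
    def base_spec(self, **kw):
        defaults = dict(
            n_per_group=2, n_trials=1, fs=100.0, n_channels=8,
            kernel_support_ms=600.0, noise=NoiseSpec(white_sd=0.1),
        )
        defaults.update(kw)
        return CohortSpec(**defaults)

    def test_exchangeable_groups_when_manipulation_off(self):
        spec = self.base_spec(seed=3)
        subjects, truth = generate_cohort(spec, cohort_stimuli())
        gains = {g: [s.dissimilarity_gain for s in truth.by_group(g)]
                 for g in ("younger", "older")}
        lats = {g: [s.latency_ms["dissimilarity"] for s in truth.by_group(g)]
                for g in ("younger", "older")}
        assert gains["younger"] == gains["older"] == [1.0, 1.0]
        assert lats["younger"] == lats["older"]

    def test_older_group_shift_and_gain_applied(self):
        spec = self.base_spec(
            group_params={
                "younger": GroupParams(),
                "older": GroupParams(latency_shift_ms=74.0, dissimilarity_gain=0.3,
                                     age_range=(55.0, 77.0)),
            },
            seed=4,
        )
        subjects, truth = generate_cohort(spec, cohort_stimuli())
        old = truth.by_group("older")[0]
        young = truth.by_group("younger")[0]
        assert old.latency_ms["surprisal"] - young.latency_ms["surprisal"] == 74.0
        assert old.kernels["dissimilarity"]["amplitude"] == pytest.approx(
            0.3 * young.kernels["dissimilarity"]["amplitude"]
        )

    def test_fluency_strictly_increasing_in_gain(self):
        spec = self.base_spec(
            n_per_group=6,
            group_params={
                "younger": GroupParams(dissimilarity_gain_sd=0.2),
                "older": GroupParams(dissimilarity_gain_sd=0.2,
                                     age_range=(55.0, 77.0)),
            },
            fluency_link=FluencyLink(intercept=20.0, slope=5.0, noise_sd=0.0),
            seed=5,
        )
        _, truth = generate_cohort(spec, cohort_stimuli())
        pairs = sorted((s.dissimilarity_gain, s.fluency_semantic)
                       for s in truth.subjects)
        fl = [f for _, f in pairs]
        assert fl == sorted(fl) and len(set(fl)) == len(fl)

    def test_shift_outside_window_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            self.base_spec(
                group_params={
                    "younger": GroupParams(),
                    "older": GroupParams(latency_shift_ms=300.0),
                },
            )

    def test_paper_design_scale_accepted(self):
        spec = self.base_spec(
            n_per_group=19, kernel_support_ms=800.0,
            group_params={
                "younger": GroupParams(),
                "older": GroupParams(latency_shift_ms=74.0,
                                     age_range=(55.0, 77.0)),
            },
        )
        assert spec.n_per_group == 19

    def test_cohort_deterministic(self):
        spec = self.base_spec(seed=11)
        a, ta = generate_cohort(spec, cohort_stimuli())
        b, tb = generate_cohort(spec, cohort_stimuli())
        np.testing.assert_array_equal(a[0].recordings[0].data,
                                      b[0].recordings[0].data)
        assert ta.subjects[0] == tb.subjects[0]

    def test_ground_truth_json_roundtrip(self, tmp_path):
        spec = self.base_spec(seed=12)
        _, truth = generate_cohort(spec, cohort_stimuli())
        path = tmp_path / "gt.json"
        truth.to_json(path)
        back = type(truth).from_json(path)
        assert back.subjects == truth.subjects
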