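import numpy as np
import pytest
from scipy import signal

from speechtrf.containers import (
    ChannelLayout,
    EEGRecording,
    MASTOID,
    SCALP,
    make_sphere_layout,
    read_eeg_h5,
    write_eeg_h5,
)
from speechtrf.mcca import mcca_denoise, mcca_fit
from speechtrf.preprocess import (
    bandpass,
    detect_bad_channels,
    downsample,
    interpolate_channels,
    rereference,
)


def rec_from(data, fs=128.0, roles=None):
    return EEGRecording(data=np.atleast_2d(np.asarray(data, float)), fs=fs,
                        channel_roles=roles or [])


class TestDownsample:
    def test_sine_amplitude_preserved(self):
        t = np.arange(0, 20, 1 / 512)
        x = np.sin(2 * np.pi * 0.5 * t)
        out = downsample(rec_from([x], fs=512.0), 128.0)
        mid = out.data[0, 200:-200]  # avoid filter edges
        assert out.fs == 128.0
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_identity_when_equal_fs(self):
        r = rec_from([np.arange(100.0)])
        assert downsample(r, 128.0) is r

    def test_sample_count(self):
        r = rec_from([np.zeros(1000)], fs=512.0)
        out = downsample(r, 128.0)
        assert abs(out.n_samples - 1000 * 128 // 512) <= 1

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            downsample(rec_from([np.zeros(10)], fs=128.0), 256.0)


class TestBandpass:
    def test_dc_removed(self):
        r = rec_from([np.full(2000, 5.0)])
        out = bandpass(r)
        assert np.abs(out.data[0, 200:-200]).max() < 1e-3 * 5.0

    def test_passband_sine_amplitude(self):
        t = np.arange(0, 30, 1 / 128)
        r = rec_from([np.sin(2 * np.pi * 4.0 * t)])
        out = bandpass(r, 0.5, 8.0, order=4)
        measured = np.abs(out.data[0, 500:-500]).max()
        # oracle: squared Butterworth magnitude (two passes) at 4 Hz
        sos = signal.butter(4, [0.5, 8.0], btype="bandpass", fs=128.0, output="sos")
        _, h = signal.sosfreqz(sos, worN=[4.0], fs=128.0)
        expected = np.abs(h[0]) ** 2
        assert measured == pytest.approx(expected, rel=0.05)
        assert measured == pytest.approx(1.0, rel=0.05)

    def test_zero_phase_pulse_peak_unshifted(self):
        x = np.zeros(4000)
        x[2000] = 1.0
        x = signal.windows.gaussian(4000, std=20)  # symmetric pulse at 2000
        out = bandpass(rec_from([np.roll(x, 2000 - 2000)]))
        assert int(np.argmax(out.data[0])) == int(np.argmax(x))

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            bandpass(rec_from([np.zeros(100)]), 8.0, 0.5)


class TestBadChannels:
    def test_equal_sds_none_flagged(self, rng):
        data = rng.standard_normal((8, 500))
        data /= data.std(axis=1, keepdims=True)
        assert not detect_bad_channels(rec_from(data)).any()

    def test_high_sd_channel_flagged_hand_check(self, rng):
        data = rng.standard_normal((32, 2000))
        data /= data.std(axis=1, keepdims=True)
        data[5] *= 3.0
        rec = rec_from(data)
        bad = detect_bad_channels(rec)
        # hand evaluation of the leave-one-out criterion for channel 5
        sds = rec.data.std(axis=1)
        loo = (sds.sum() - sds[5]) / 31
        assert sds[5] > 2.5 * loo
        assert bad[5] and bad.sum() == 1

    def test_flat_channel_flagged_by_lower_bound(self, rng):
        data = rng.standard_normal((8, 500))
        data[3] = 0.0
        bad = detect_bad_channels(rec_from(data))
        assert bad[3]

    def test_all_bad_is_error(self, rng):
        # sds 1 / 10 / 100: every channel violates the rule against the others
        data = rng.standard_normal((3, 500))
        data /= data.std(axis=1, keepdims=True)
        data *= np.array([[1.0], [10.0], [100.0]])
        with pytest.raises(ValueError, match="unusable"):
            detect_bad_channels(rec_from(data))

    def test_needs_three_channels(self):
        with pytest.raises(ValueError):
            detect_bad_channels(rec_from(np.zeros((2, 10))))


class TestInterpolation:
    def test_duplicate_location_reconstructed(self, rng):
        layout, _ = make_sphere_layout(16, n_mastoids=0)
        pos = layout.positions.copy()
        pos[0] = pos[1]  # bad channel exactly at a clean channel's site
        layout = ChannelLayout(pos)
        smooth = np.cos(np.linspace(0, 4, 16))[:, None] * np.sin(
            np.linspace(0, 6, 200)
        )[None, :]
        rec = rec_from(smooth)
        mask = np.zeros(16, bool)
        mask[0] = True
        rec.data[0] = 99.0
        rec.data[1] = smooth[1]
        out = interpolate_channels(rec, layout, mask)
        np.testing.assert_allclose(out.data[0], out.data[1], atol=1e-6)

    def test_spatially_constant_field(self):
        layout, _ = make_sphere_layout(12, n_mastoids=0)
        data = np.ones((12, 50)) * 3.3
        rec = rec_from(data)
        mask = np.zeros(12, bool)
        mask[4] = True
        rec.data[4] = -1.0
        out = interpolate_channels(rec, layout, mask)
        np.testing.assert_allclose(out.data[4], 3.3, atol=1e-8)
        np.testing.assert_allclose(out.data[~mask], data[~mask])  # untouched

    def test_dipolar_pattern_leave_one_out(self):
        layout, _ = make_sphere_layout(32, n_mastoids=0)
        dip = np.array([0.2, -0.3, 0.93])
        dip /= np.linalg.norm(dip)
        spatial = layout.positions @ dip  # smooth dipolar field
        tc = np.sin(np.linspace(0, 10, 300))
        data = spatial[:, None] * tc[None, :]
        corrs = []
        for ch in range(0, 32, 5):
            rec = rec_from(data.copy())
            mask = np.zeros(32, bool)
            mask[ch] = True
            rec.data[ch] = 0.0
            out = interpolate_channels(rec, layout, mask)
            corrs.append(np.corrcoef(out.data[ch], data[ch])[0, 1])
        assert min(corrs) > 0.95

    def test_too_few_clean_channels(self):
        layout, _ = make_sphere_layout(5, n_mastoids=0)
        rec = rec_from(np.ones((5, 10)))
        mask = np.array([True, True, False, False, False])
        with pytest.raises(ValueError, match="clean"):
            interpolate_channels(rec, layout, mask[:5] | np.array(
                [False, False, True, False, False]))


class TestRereference:
    def roles(self):
        return [SCALP, SCALP, SCALP, MASTOID, MASTOID]

    def test_hand_example(self):
        data = np.array([[3.0], [1.0], [5.0], [1.0], [5.0]])
        out = rereference(rec_from(data, roles=self.roles()))
        np.testing.assert_allclose(out.data[:3, 0], [0.0, -2.0, 2.0])

    def test_mastoid_mean_zero_everywhere(self, rng):
        data = rng.standard_normal((5, 100))
        out = rereference(rec_from(data, roles=self.roles()))
        np.testing.assert_allclose(out.data[3:].mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        r = rec_from(rng.standard_normal((5, 50)), roles=self.roles())
        once = rereference(r)
        twice = rereference(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_missing_mastoids(self, rng):
        with pytest.raises(ValueError, match="mastoid"):
            rereference(rec_from(rng.standard_normal((3, 10))))


def test_pipeline_linearity(rng):
    """Filtering + referencing are linear operators (fixed masks)."""
    roles = [SCALP] * 6 + [MASTOID] * 2
    X = rng.standard_normal((8, 1024))
    Y = rng.standard_normal((8, 1024))
    a, b = 1.7, -0.4

    def chain(d):
        return rereference(bandpass(rec_from(d, roles=roles))).data

    np.testing.assert_allclose(
        chain(a * X + b * Y), a * chain(X) + b * chain(Y), atol=1e-8
    )


class TestMCCA:
    def test_identical_subjects_cc1_shared(self, rng):
        x = rng.standard_normal((6, 400))
        recs = {f"s{i}": x.copy() for i in range(4)}
        model = mcca_fit(recs, n_pc=4, n_cc=4)
        scores = {
            sid: (x.T - model.means[sid]) @ model.subject_transform(sid)[:, 0]
            for sid in recs
        }
        vals = list(scores.values())
        total = sum(
            abs(np.corrcoef(vals[0], v)[0, 1]) for v in vals
        )
        assert total == pytest.approx(4.0, abs=1e-6)

    def test_independent_noise_below_permutation_bound(self, rng):
        recs = {f"s{i}": rng.standard_normal((6, 500)) for i in range(4)}
        model = mcca_fit(recs, n_pc=4, n_cc=4)
        # inter-subject correlation of CC1 between first two subjects
        a = (recs["s0"].T - model.means["s0"]) @ model.subject_transform("s0")[:, 0]
        b = (recs["s1"].T - model.means["s1"]) @ model.subject_transform("s1")[:, 0]
        obs = abs(np.corrcoef(a, b)[0, 1])
        null = [
            abs(np.corrcoef(rng.permutation(a), b)[0, 1]) for _ in range(500)
        ]
        # same-length white series: shared variance should sit near the null
        assert obs < np.quantile(null, 0.99) + 0.15

    def test_planted_shared_sine_recovered(self, rng):
        t = np.linspace(0, 20, 2000)
        s = np.sin(2 * np.pi * 1.3 * t)
        recs = {}
        for i in range(5):
            mix = rng.standard_normal(8)
            noise = rng.standard_normal((8, 2000))
            recs[f"s{i}"] = np.outer(mix, s) * np.sqrt(0.5) + noise
        model = mcca_fit(recs, n_pc=8, n_cc=8)
        cc1 = model.canonical_scores(
            {k: v for k, v in recs.items()}
        )[:, 0]
        assert abs(np.corrcoef(cc1, s)[0, 1]) > 0.95

    def test_full_retention_equals_pca_reconstruction(self, rng):
        X = rng.standard_normal((6, 300))
        recs = {"a": X, "b": rng.standard_normal((6, 300))}
        model = mcca_fit(recs, n_pc=3, n_cc=6)
        den = mcca_denoise(X, model, subject_id="a", n_cc=model.n_components)
        # oracle: rank-3 PCA reconstruction
        Xc = X.T - X.T.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        pca = (Xc @ Vt[:3].T) @ Vt[:3] + X.T.mean(axis=0)
        np.testing.assert_allclose(den, pca.T, atol=1e-8)

    def test_denoising_improves_planted_signal(self, rng):
        t = np.linspace(0, 20, 2000)
        s = np.sin(2 * np.pi * 1.1 * t)
        clean, noisy = {}, {}
        for i in range(5):
            mix = rng.standard_normal(8)
            clean[f"s{i}"] = np.outer(mix, s) * np.sqrt(0.5)
            noisy[f"s{i}"] = clean[f"s{i}"] + rng.standard_normal((8, 2000))
        model = mcca_fit(noisy, n_pc=8, n_cc=2)
        for sid in noisy:
            den = mcca_denoise(noisy[sid], model, subject_id=sid)
            before = np.linalg.norm(noisy[sid] - clean[sid])
            after = np.linalg.norm(den - clean[sid])
            assert after < before

    def test_zero_input_zero_output(self, rng):
        recs = {"a": rng.standard_normal((4, 200)), "b": rng.standard_normal((4, 200))}
        model = mcca_fit(recs, n_pc=3, n_cc=3)
        out = mcca_denoise(np.zeros((4, 200)), model, subject_id="a")
        # centered projection of a constant-zero signal stays constant
        assert np.allclose(out - out.mean(axis=1, keepdims=True), 0.0, atol=1e-10)

    def test_unknown_subject(self, rng):
        recs = {"a": rng.standard_normal((4, 100)), "b": rng.standard_normal((4, 100))}
        model = mcca_fit(recs, n_pc=2, n_cc=2)
        with pytest.raises(KeyError):
            mcca_denoise(np.zeros((4, 100)), model, subject_id="zz")

    def test_rank_deficiency_reduces_with_warning(self, rng):
        x = rng.standard_normal((2, 100))
        low_rank = np.vstack([x, x.sum(axis=0, keepdims=True)])  # rank 2, 3 ch
        with pytest.warns(UserWarning, match="rank"):
            mcca_fit({"a": low_rank, "b": rng.standard_normal((3, 100))},
                     n_pc=3, n_cc=3)

    def test_roundtrip_is_projection(self, rng):
        recs = {"a": rng.standard_normal((5, 300)), "b": rng.standard_normal((5, 300))}
        model = mcca_fit(recs, n_pc=4, n_cc=3)
        once = mcca_denoise(recs["a"], model, subject_id="a")
        twice = mcca_denoise(once, model, subject_id="a")
        np.testing.assert_allclose(once, twice, atol=1e-8)


def test_eeg_h5_roundtrip(tmp_path, rng):
    recs = [
        EEGRecording(rng.standard_normal((4, 50)), fs=128.0,
                     channel_roles=[SCALP, SCALP, MASTOID, MASTOID],
                     subject_id="s1", trial_id=t)
        for t in range(2)
    ]
    path = tmp_path / "eeg.h5"
    write_eeg_h5(path, recs)
    back = read_eeg_h5(path)
    assert len(back) == 2
    np.testing.assert_array_equal(back[0].data, recs[0].data)
    assert back[0].channel_roles == recs[0].channel_roles
    assert back[1].trial_id == 1
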