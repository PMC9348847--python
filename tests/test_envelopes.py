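"""Envelope extraction: filtering, normalisation, epoching, z-scoring."""

import numpy as np
import pandas as pd
import pytest

from moodrisk import (
    BANDS,
    BandSpec,
    RawRecording,
    band_envelope,
    bipolar_rereference,
    epoch,
    postprocess_envelope,
    zscore_epochs,
)
from moodrisk.envelopes import EnvelopeSeries


def _raw(signal, fs=512.0, labels=None, events=None):
    signal = np.atleast_2d(signal)
    labels = labels or [f"s{i}" for i in range(signal.shape[0])]
    if events is None:
        events = pd.DataFrame({"label": [], "time": []})
    return RawRecording(signal=signal, sampling_rate=fs, site_labels=labels, events=events)


class TestBandSpec:
    def test_sub_band_partition(self):
        bga = BANDS["bga"]
        subs = bga.sub_bands
        assert len(subs) == 10
        assert subs[0] == (50.0, 60.0)
        assert subs[-1] == (140.0, 150.0)

    def test_all_band_definitions(self):
        assert {BANDS[b].name for b in BANDS} == {"bga", "gamma", "beta", "alpha", "theta"}
        assert len(BANDS["gamma"].sub_bands) == 4
        assert len(BANDS["beta"].sub_bands) == 4
        assert len(BANDS["alpha"].sub_bands) == 5
        assert len(BANDS["theta"].sub_bands) == 4

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            BandSpec("x", 10.0, 5.0, 1.0)
        with pytest.raises(ValueError):
            BandSpec("x", 10.0, 20.0, 7.0)  # step does not divide the band


class TestBipolarRereference:
    def test_chain_differences(self):
        fs = 100.0
        n = 500
        rows = np.vstack([np.full(n, 1.0), np.full(n, 3.0), np.full(n, 7.0)])
        raw = _raw(rows, fs=fs, labels=["a1", "a2", "a3"])
        out = bipolar_rereference(raw, {"a": ["a1", "a2", "a3"]})
        assert out.site_labels == ["a1-a2", "a2-a3"]
        np.testing.assert_allclose(out.signal[0], -2.0)
        np.testing.assert_allclose(out.signal[1], -4.0)

    def test_common_signal_cancels(self):
        rng = np.random.default_rng(0)
        common = rng.standard_normal(400)
        raw = _raw(np.vstack([common, common]), fs=100.0, labels=["b1", "b2"])
        out = bipolar_rereference(raw, {"b": ["b1", "b2"]})
        np.testing.assert_allclose(out.signal[0], 0.0, atol=1e-12)

    def test_singleton_dropped_with_warning(self):
        raw = _raw(np.zeros((2, 300)), fs=100.0, labels=["a1", "c1"])
        with pytest.warns(UserWarning, match="single contact"):
            out = bipolar_rereference(raw, {"a": ["a1"], "c": ["c1"]})
        assert out.n_sites == 0


class TestBandEnvelope:
    fs = 512.0

    def test_session_mean_is_100(self):
        rng = np.random.default_rng(1)
        raw = _raw(rng.standard_normal((2, int(10 * self.fs))), fs=self.fs)
        env = band_envelope(raw, "bga")
        np.testing.assert_allclose(env.values.mean(axis=1), 100.0, rtol=1e-9)

    def test_pure_tone_envelope_flat_in_single_sub_band(self):
        # one sub-band isolates the filter + Hilbert stage from the
        # per-sub-band normalisation
        t = np.arange(int(12 * self.fs)) / self.fs
        raw = _raw(np.sin(2 * np.pi * 100.0 * t), fs=self.fs)
        env = band_envelope(raw, BandSpec("tone", 95.0, 105.0, 10.0))
        mid = env.values[0, int(2 * self.fs) : int(10 * self.fs)]
        assert mid.std() / mid.mean() < 0.05
        assert mid.mean() > 100.0  # edges dip, so the interior sits above the mean

    def test_amplitude_modulation_tracked(self):
        # broadband carrier so every sub-band carries the modulation
        rng = np.random.default_rng(11)
        t = np.arange(int(12 * self.fs)) / self.fs
        am = 1.0 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
        raw = _raw(am * rng.standard_normal(t.size), fs=self.fs)
        env = postprocess_envelope(band_envelope(raw, "bga"))
        t_env = np.arange(env.values.shape[1]) / env.sampling_rate
        am_env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.5 * t_env)
        sl = slice(200, 1000)  # skip edges
        assert np.corrcoef(env.values[0, sl], am_env[sl])[0, 1] > 0.9

    def test_normalisation_is_scale_invariant(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(8 * self.fs))
        e1 = band_envelope(_raw(x, fs=self.fs), "bga").values
        e2 = band_envelope(_raw(5.0 * x, fs=self.fs), "bga").values
        np.testing.assert_allclose(e1, e2, rtol=1e-9)

    def test_out_of_band_tone_rejected(self):
        t = np.arange(int(10 * self.fs)) / self.fs
        rng = np.random.default_rng(3)
        tone = 10.0 * np.sin(2 * np.pi * 20.0 * t)  # strong beta tone
        noise = 0.5 * rng.standard_normal(t.size)
        env_beta = band_envelope(_raw(tone + noise, fs=self.fs), "beta")
        env_bga = band_envelope(_raw(tone + noise, fs=self.fs), "bga")
        # the tone dominates beta (high peak-to-mean) but not broadband gamma
        assert env_beta.values.max() > env_bga.values.max()

    def test_sampling_rate_too_low(self):
        raw = _raw(np.zeros(1000), fs=200.0)
        with pytest.raises(ValueError, match="too low"):
            band_envelope(raw, "bga")


class TestPostprocess:
    def test_constant_envelope_unchanged(self):
        env = EnvelopeSeries(np.full((1, 5120), 100.0), 512.0, ["s0"])
        out = postprocess_envelope(env)
        assert out.sampling_rate == 100.0
        np.testing.assert_allclose(out.values, 100.0)

    def test_output_rate_and_length(self):
        env = EnvelopeSeries(np.random.default_rng(0).random((2, 5120)) + 100, 512.0, ["a", "b"])
        out = postprocess_envelope(env)
        assert out.values.shape == (2, 1000)  # 10 s at 100 Hz
        assert out.sampling_rate == 100.0

    def test_smoothing_reduces_variance(self):
        rng = np.random.default_rng(4)
        env = EnvelopeSeries(100 + rng.standard_normal((1, 5120)), 512.0, ["s0"])
        out = postprocess_envelope(env)
        assert out.values.std() < env.values.std() / 2

    def test_too_short_recording(self):
        env = EnvelopeSeries(np.ones((1, 50)), 512.0, ["s0"])
        with pytest.raises(ValueError, match="shorter"):
            postprocess_envelope(env)


class TestEpoch:
    def _series(self, n=3000, n_sites=2, fs=100.0):
        # values encode the sample index so epoch content is verifiable
        vals = np.tile(np.arange(n, dtype=float), (n_sites, 1))
        return EnvelopeSeries(vals, fs, [f"s{i}" for i in range(n_sites)])

    def test_four_second_window_has_401_samples(self):
        env = self._series()
        ep = epoch(env, [10.0, 20.0], (-4.0, 0.0))
        assert ep.data.shape == (2, 2, 401)
        assert ep.times[0] == pytest.approx(-4.0)
        assert ep.times[-1] == pytest.approx(0.0)

    def test_epoch_content_matches_grid(self):
        env = self._series()
        ep = epoch(env, [10.0], (-1.0, 1.0))
        # at 100 Hz, t=10 s is sample 1000; window spans samples 900..1100
        np.testing.assert_array_equal(ep.data[0, 0], np.arange(900, 1101))

    def test_out_of_bounds_trial_excluded(self):
        env = self._series(n=1000)
        with pytest.warns(UserWarning, match="excluded"):
            ep = epoch(env, [1.0, 5.0], (-2.0, 0.0))
        assert ep.n_trials == 1
        np.testing.assert_array_equal(ep.trial_indices, [1])

    def test_all_excluded_gives_empty_tensor(self):
        env = self._series(n=300)
        with pytest.warns(UserWarning):
            ep = epoch(env, [0.5], (-2.0, 0.0))
        assert ep.data.shape == (0, 2, 201)

    def test_invalid_window(self):
        with pytest.raises(ValueError, match="window"):
            epoch(self._series(), [10.0], (0.0, -1.0))


class TestZscore:
    def _epochs(self, n_trials=20, n_sites=2, n_t=50, seed=0):
        rng = np.random.default_rng(seed)
        env = EnvelopeSeries(
            100 + rng.standard_normal((n_sites, 10000)), 100.0, ["a", "b"][:n_sites]
        )
        times = 5.0 + 4.0 * np.arange(n_trials)
        return epoch(env, times, (-0.25, 0.25))

    def test_per_sample_definition(self):
        ep = self._epochs()
        z = zscore_epochs(ep)
        np.testing.assert_allclose(z.data.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.data.std(axis=0), 1.0, rtol=1e-12)
        assert z.zscored

    def test_zero_sd_names_site_and_sample(self):
        ep = self._epochs()
        ep.data[:, 1, 7] = 42.0
        with pytest.raises(ValueError, match=r"site b, sample 7"):
            zscore_epochs(ep)

    def test_pooled_mode(self):
        ep = self._epochs()
        z = zscore_epochs(ep, per_sample=False)
        np.testing.assert_allclose(z.data.mean(axis=(0, 2)), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.data.std(axis=(0, 2)), 1.0, rtol=1e-12)

    def test_needs_two_trials(self):
        ep = self._epochs(n_trials=1)
        with pytest.raises(ValueError, match="at least 2"):
            zscore_epochs(ep)


class TestRecordingIO:
    def test_h5_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        events = pd.DataFrame({"label": ["choice", "feedback"], "time": [1.0, 2.0]})
        raw = RawRecording(
            signal=rng.standard_normal((2, 1000)),
            sampling_rate=256.0,
            site_labels=["x1", "x2"],
            events=events,
            site_roles={"x1": "positive", "x2": "null"},
        )
        path = tmp_path / "rec.h5"
        raw.save(path)
        back = RawRecording.load(path)
        np.testing.assert_array_equal(back.signal, raw.signal)
        assert back.sampling_rate == 256.0
        assert back.site_labels == ["x1", "x2"]
        assert back.site_roles == {"x1": "positive", "x2": "null"}
        pd.testing.assert_frame_equal(back.events, events)

    def test_event_beyond_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            _raw(np.zeros(100), fs=100.0, events=pd.DataFrame({"label": ["e"], "time": [5.0]}))
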