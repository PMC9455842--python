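import numpy as np
import pandas as pd
import pytest
from scipy import signal as sp_signal

from memdecode import preprocess as pp
from memdecode.synthgen import (
    RawRecording,
    SourceScenario,
    TrialTiming,
    generate_behavior,
    generate_raw,
)
from .conftest import make_epochs


def _raw(data, fs=1000.0, events=None):
    return RawRecording(data=data, fs=fs, events=events or [])


class TestDownsample:
    def test_quarter_rate_quarters_samples(self, rng):
        raw = _raw(rng.standard_normal((4, 4000)), events=[(1000, 1)])
        out = pp.downsample(raw, 250.0)
        assert out.fs == 250.0
        assert abs(out.n_samples - 1000) <= 1
        assert out.events[0][0] == 250

    def test_dc_preserved(self):
        raw = _raw(np.full((2, 4000), 7.0))
        out = pp.downsample(raw, 250.0)
        mid = out.data[:, 100:-100]  # away from filter edges
        assert np.allclose(mid, 7.0, atol=1e-6)

    def test_in_band_sinusoid_survives(self):
        t = np.arange(4000) / 1000.0
        raw = _raw(np.sin(2 * np.pi * 5 * t)[None, :])
        out = pp.downsample(raw, 250.0)
        t2 = np.arange(out.n_samples) / 250.0
        ref = np.sin(2 * np.pi * 5 * t2)
        mid = slice(100, out.n_samples - 100)
        assert np.max(np.abs(out.data[0, mid] - ref[mid])) < 0.01

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            pp.downsample(_raw(np.zeros((1, 100))), 2000.0)


class TestBandpass:
    def test_60hz_attenuated_by_more_than_20db(self):
        # long signal: the 0.5 Hz high-pass transient spans seconds
        t = np.arange(40000) / 1000.0
        raw = _raw(np.sin(2 * np.pi * 60 * t)[None, :])
        out = pp.bandpass(raw, 0.5, 40.0, order=5)
        mid = slice(15000, 25000)
        atten_db = 20 * np.log10(np.abs(out.data[0, mid]).max() / 1.0)
        assert atten_db < -20.0
        # two zero-phase passes square the single-pass response
        _, h = sp_signal.sosfreqz(
            sp_signal.butter(5, [0.5, 40], btype="bandpass", fs=1000.0, output="sos"),
            worN=[60.0], fs=1000.0,
        )
        assert 40 * np.log10(np.abs(h[0])) < -20.0

    def test_passband_amplitude_within_2pct(self):
        t = np.arange(40000) / 1000.0
        raw = _raw(np.sin(2 * np.pi * 10 * t)[None, :])
        out = pp.bandpass(raw, 0.5, 40.0, order=5)
        assert abs(np.abs(out.data[0, 15000:25000]).max() - 1.0) < 0.02

    def test_zero_in_zero_out(self):
        out = pp.bandpass(_raw(np.zeros((3, 1000))), 0.5, 40.0)
        assert np.all(out.data == 0)

    def test_zero_phase_no_group_delay(self):
        t = np.arange(5000) / 1000.0
        clean = np.sin(2 * np.pi * 10 * t)
        out = pp.bandpass(_raw(clean[None, :]), 0.5, 40.0, order=5)
        xc = np.correlate(out.data[0, 1000:4000], clean[1000:4000], mode="full")
        lag = np.argmax(xc) - (len(xc) // 2)
        assert lag == 0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            pp.bandpass(_raw(np.zeros((1, 100)), fs=100.0), 0.5, 60.0)


class TestRereference:
    def test_channel_means_vanish(self, rng):
        es = make_epochs(rng.standard_normal((4, 8, 100)) * 50)
        out = pp.rereference_average(es)
        scale = np.abs(es.data).max()
        assert np.abs(out.data.mean(axis=1)).max() < 1e-9 * scale

    def test_idempotent(self, rng):
        es = make_epochs(rng.standard_normal((2, 6, 50)))
        once = pp.rereference_average(es)
        twice = pp.rereference_average(once)
        assert np.allclose(once.data, twice.data)

    def test_two_channel_closed_form(self):
        a = np.arange(20.0)
        b = -2 * a + 3
        es = make_epochs(np.stack([a, b])[None, :, :])
        out = pp.rereference_average(es)
        assert np.allclose(out.data[0, 0], (a - b) / 2)
        assert np.allclose(out.data[0, 1], (b - a) / 2)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            pp.rereference_average(make_epochs(np.zeros((1, 1, 10))))


class TestEpoching:
    def test_500_samples_per_trial_at_250hz(self, rng):
        events = [(500, 1), (1500, 1), (2500, 1)]
        raw = _raw(rng.standard_normal((4, 4000)), fs=250.0, events=events)
        es = pp.epoch(raw, window_ms=(-1000.0, 1000.0))
        assert es.data.shape == (3, 4, 500)
        assert es.t0_offset_ms == -1000.0

    def test_edge_event_dropped_with_metadata(self, rng):
        events = [(10, 1), (1500, 1)]
        raw = _raw(rng.standard_normal((2, 4000)), fs=250.0, events=events)
        rows = pd.DataFrame({"word_id": [1, 2], "phase": "encoding", "is_old": True})
        es = pp.epoch(raw, rows, window_ms=(-1000.0, 1000.0))
        assert es.n_trials == 1
        assert list(es.meta.word_id) == [2]

    def test_all_covered_events_kept(self, rng):
        events = [(300 + 260 * i, 1) for i in range(50)]
        raw = _raw(rng.standard_normal((2, 14000)), fs=250.0, events=events)
        es = pp.epoch(raw, window_ms=(-1000.0, 40.0))
        assert es.n_trials == 50


class TestBaselineAndRejection:
    def test_constant_trial_zeroed(self):
        es = make_epochs(np.full((1, 3, 100), 7.0))
        assert np.allclose(pp.baseline_correct(es).data, 0.0)

    def test_zero_mean_unchanged_and_offset_removed(self):
        t = np.arange(200)
        sin = np.sin(2 * np.pi * t / 50)
        sin -= sin.mean()
        es = make_epochs((sin + 3.0)[None, None, :])
        out = pp.baseline_correct(es)
        assert np.allclose(out.data[0, 0], sin, atol=1e-12)
        assert np.allclose(pp.baseline_correct(out).data, out.data)

    def test_rejection_is_strict_exceedance(self):
        data = np.zeros((3, 2, 50))
        data[0, 0, 10] = 250.0
        data[1, 1, 5] = 200.0  # exactly at threshold: kept
        es = make_epochs(data)
        kept, rejected = pp.reject_amplitude(es, 200.0)
        assert list(rejected) == [0]
        assert kept.n_trials == 2
        assert len(kept.meta) == 2

    def test_planted_artifact_fraction_binomial(self, small_montage, small_leadfield):
        """artifact_rate=0.2 over 1000 trials: rejected fraction within 3 s.e."""
        n = 1000
        beh = generate_behavior(n, 10, seed=11)
        sc = SourceScenario(artifact_rate=0.2, snr_db=0.0, seed=11)
        timing = TrialTiming(pre_ms=280.0, stim_ms=300.0, iti_ms=60.0)
        raw = generate_raw(small_montage, small_leadfield, beh, sc, fs=250.0, trial_timing=timing)
        es = pp.epoch(raw, window_ms=(-280.0, 300.0))
        _, rejected = pp.reject_amplitude(es, 200.0)
        frac = len(rejected) / n
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) < 3 * se


class TestInterpolation:
    def test_constant_topography_reproduced(self, montage62, rng):
        es = make_epochs(np.full((2, 62, 30), 4.2))
        out = pp.interpolate_channels(es, ["Cz", "Fp1"], montage62)
        assert np.allclose(out.data, 4.2, atol=1e-3)

    def test_smooth_dipolar_topography_recovered(self, montage62):
        # smooth field: potential ∝ z-coordinate of each electrode
        topo = montage62.positions @ np.array([0.3, -0.2, 0.9])
        data = np.tile(topo[:, None], (1, 20))[None, :, :]
        es = make_epochs(data.copy())
        bad = "Cz"
        i = montage62.index(bad)
        es.data[:, i, :] = 0.0
        out = pp.interpolate_channels(es, [bad], montage62)
        assert np.abs(out.data[0, i, 0] - topo[i]) < 0.1 * np.abs(topo[i])

    def test_empty_bad_list_is_identity(self, montage62, rng):
        es = make_epochs(rng.standard_normal((2, 62, 10)))
        out = pp.interpolate_channels(es, [], montage62)
        assert np.array_equal(out.data, es.data)

    def test_good_channels_untouched(self, montage62, rng):
        es = make_epochs(rng.standard_normal((1, 62, 5)))
        out = pp.interpolate_channels(es, ["Pz"], montage62)
        i = montage62.index("Pz")
        mask = np.arange(62) != i
        assert np.array_equal(out.data[:, mask], es.data[:, mask])

    def test_unknown_channel_rejected(self, montage62, rng):
        es = make_epochs(rng.standard_normal((1, 62, 5)))
        with pytest.raises(ValueError):
            pp.interpolate_channels(es, ["NoSuch"], montage62)


class TestLabeling:
    @pytest.mark.parametrize(
        "phase,is_old,conf,expected",
        [
            ("encoding", True, 4, "remembered"),
            ("encoding", True, 3, "remembered"),
            ("encoding", True, 2, "forgotten"),
            ("encoding", True, 1, "forgotten"),
            ("retrieval", True, 4, "remembered"),
            ("retrieval", True, 1, "forgotten"),
            ("retrieval", False, 3, "false_remembered"),
            ("retrieval", False, 1, "unlabeled"),
        ],
    )
    def test_confidence_rules(self, phase, is_old, conf, expected, rng):
        es = make_epochs(rng.standard_normal((1, 2, 10)))
        es.meta = pd.DataFrame({"word_id": [1], "phase": [phase], "is_old": [is_old]})
        behavior = pd.DataFrame(
            {
                "word_id": [1],
                "phase": ["retrieval"],
                "is_old": [is_old],
                "judgment": ["NA"],
                "confidence": [float(conf)],
                "rt_ms": [500.0],
            }
        )
        out = pp.label_trials(es, behavior)
        assert out.labels[0] == expected

    def test_metadata_alignment_preserved_through_chain(self, small_montage, small_leadfield):
        beh = generate_behavior(20, 8, seed=4)
        sc = SourceScenario(artifact_rate=0.3, snr_db=0.0, seed=4)
        timing = TrialTiming(pre_ms=280.0, stim_ms=300.0, iti_ms=60.0)
        raw = generate_raw(small_montage, small_leadfield, beh, sc, fs=250.0, trial_timing=timing)
        es, rejected = pp.run_preprocess(
            raw, beh, small_montage, target_fs=None, window_ms=(-280.0, 300.0)
        )
        assert es.n_trials + len(rejected) == 20
        enc = beh[beh.phase == "encoding"].reset_index(drop=True)
        expected_ids = np.delete(enc.word_id.to_numpy(), rejected)
        assert np.array_equal(es.meta.word_id.to_numpy(), expected_ids)
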