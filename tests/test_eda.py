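"""EDA pipeline: preprocessing, CDA, TTP, feature extraction."""

import numpy as np
import pytest

from conftest import make_eda_channel
from painsig.eda import (
    SCREvent, analyze_ttp, decompose_cda, detect_scr_cda, extract_eda_features,
    preprocess_eda, EDA_FEATURES,
)
from painsig.io import SignalChannel


class TestPreprocess:
    def test_dc_invariance(self):
        ch = SignalChannel(np.full(18000, 2.0), 100.0, "uS")
        out = preprocess_eda(ch)
        np.testing.assert_allclose(out.samples, 2.0, atol=1e-6)

    def test_powerline_tone_attenuated_40db(self):
        fs = 200.0
        t = np.arange(0, 120, 1 / fs)
        ch = SignalChannel(2.0 + 0.5 * np.sin(2 * np.pi * 50 * t), fs, "uS")
        out = preprocess_eda(ch)
        # residual oscillation around DC must be >= 40 dB below the tone
        resid = np.std(out.samples[100:-100])
        assert resid < 0.5 / np.sqrt(2) / 100

    def test_resampling_contract(self):
        ch = SignalChannel(np.full(18000, 1.0), 100.0, "uS")
        out = preprocess_eda(ch)
        assert out.fs == 10.0
        assert abs(len(out.samples) / out.fs - 180.0) <= 1 / out.fs

    def test_rejects_wrong_units(self):
        with pytest.raises(ValueError, match="uS"):
            preprocess_eda(SignalChannel(np.ones(5000), 100.0, "mV"))

    def test_too_short_for_filter(self):
        with pytest.raises(ValueError, match="warm-up"):
            preprocess_eda(SignalChannel(np.ones(10), 100.0, "uS"))


class TestCDA:
    def test_single_scr_tonic_and_phasic_recovery(self):
        pre = preprocess_eda(make_eda_channel([30.0], [1.0], level=2.0))
        dec = decompose_cda(pre)
        assert np.abs(dec.tonic - 2.0).max() <= 0.1
        assert dec.phasic.max() == pytest.approx(1.0, rel=0.1)

    def test_reconstruction_invariant(self):
        pre = preprocess_eda(make_eda_channel([30.0, 90.0], [0.8, 0.4], level=3.0))
        dec = decompose_cda(pre)
        rmse = np.sqrt(np.mean((dec.tonic + dec.phasic - pre.samples) ** 2))
        assert rmse <= 0.05 * np.ptp(pre.samples)

    def test_driver_nonnegative(self):
        pre = preprocess_eda(make_eda_channel([40.0], [0.6], level=2.0,
                                              noise_sd=0.01,
                                              rng=np.random.default_rng(5)))
        dec = decompose_cda(pre)
        assert dec.driver.min() >= -1e-8

    def test_tonic_slowly_varying(self):
        pre = preprocess_eda(make_eda_channel([30.0, 70.0, 120.0], [0.5, 1.0, 0.7],
                                              level=2.0, slope=0.001))
        dec = decompose_cda(pre)
        tv = lambda x: np.sum(np.abs(np.diff(x)))
        assert tv(dec.tonic) <= tv(pre.samples)

    def test_pure_tonic_drift_null_phasic(self):
        pre = preprocess_eda(make_eda_channel([], [], level=2.0, slope=0.002,
                                              vlf_amp=0.2))
        dec = decompose_cda(pre)
        assert dec.driver.max() <= 0.05
        assert detect_scr_cda(dec) == []

    def test_five_impulse_count_recovery(self):
        onsets = [20.0, 50.0, 80.0, 110.0, 150.0]
        amps = [0.3, 0.8, 0.5, 0.25, 1.0]
        pre = preprocess_eda(make_eda_channel(onsets, amps, level=2.0))
        events = detect_scr_cda(decompose_cda(pre))
        assert len(events) == 5
        est_on = [e.onset_s for e in events]
        assert est_on == sorted(est_on)
        np.testing.assert_allclose([e.amplitude for e in events], amps, rtol=0.12)

    def test_threshold_boundary_excludes_subthreshold(self):
        pre = preprocess_eda(make_eda_channel([60.0], [0.04], level=2.0))
        dec = decompose_cda(pre)
        assert detect_scr_cda(dec, amp_threshold=0.05) == []
        assert len(detect_scr_cda(dec, amp_threshold=0.01)) == 1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        pre = preprocess_eda(make_eda_channel(
            [20.0, 45.0, 90.0, 140.0], [0.08, 0.3, 0.06, 0.5],
            level=2.0, noise_sd=0.01, rng=rng))
        dec = decompose_cda(pre)
        counts = [len(detect_scr_cda(dec, amp_threshold=th))
                  for th in (0.01, 0.05, 0.1, 0.3, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_requires_cda_decomposition(self):
        pre = preprocess_eda(make_eda_channel([30.0], [0.5]))
        dec = decompose_cda(pre)
        dec.method = "TTP"
        with pytest.raises(ValueError, match="CDA"):
            detect_scr_cda(dec)


class TestTTP:
    def test_monotone_ramp_empty(self):
        t = np.arange(0, 180, 0.1)
        ch = SignalChannel(1.0 + 0.01 * t, 10.0, "uS")
        assert analyze_ttp(ch) == []

    def test_two_isolated_scrs_within_ten_percent(self):
        pre = preprocess_eda(make_eda_channel([40.0, 120.0], [0.5, 0.8], level=2.0))
        events = analyze_ttp(pre)
        assert len(events) == 2
        assert events[0].amplitude == pytest.approx(0.5, rel=0.1)
        assert events[1].amplitude == pytest.approx(0.8, rel=0.1)

    def test_noise_below_threshold_empty(self):
        rng = np.random.default_rng(3)
        pre = preprocess_eda(make_eda_channel([], [], level=2.0, noise_sd=0.005,
                                              rng=rng))
        assert analyze_ttp(pre, amp_threshold=0.05) == []

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        pre = preprocess_eda(make_eda_channel(
            [25.0, 60.0, 100.0, 150.0], [0.07, 0.3, 0.9, 0.12],
            level=2.0, noise_sd=0.01, rng=rng))
        counts = [len(analyze_ttp(pre, amp_threshold=th))
                  for th in (0.01, 0.05, 0.1, 0.5)]
        assert counts == sorted(counts, reverse=True)

    def test_rise_time_window_applied(self):
        # a very slow artificial rise (sigmoid over 20 s) is not an SCR
        t = np.arange(0, 180, 0.1)
        slow = 2.0 + 0.5 / (1 + np.exp(-(t - 90) / 8.0)) - 0.2 * np.exp(-t / 40)
        ch = SignalChannel(slow, 10.0, "uS")
        assert analyze_ttp(ch, window=(1.0, 5.0)) == []


class TestFeatures:
    def test_empty_event_lists(self):
        feats = extract_eda_features([], [])
        assert feats["nSCR_CDA"] == 0 and feats["nSCR_TTP"] == 0
        for name in EDA_FEATURES:
            if not name.startswith("nSCR"):
                assert np.isnan(feats[name])

    def test_hand_computed_example(self):
        events = [SCREvent(10.0, 12.0, 0.2, "TTP"),
                  SCREvent(30.0, 32.0, 0.4, "TTP"),
                  SCREvent(60.0, 62.0, 0.6, "TTP")]
        feats = extract_eda_features([], events)
        assert feats["nSCR_TTP"] == 3
        assert feats["maxSCR_TTP"] == pytest.approx(0.6)
        assert feats["minSCR_TTP"] == pytest.approx(0.2)
        assert feats["meanSCR_TTP"] == pytest.approx(0.4)
        assert feats["maxOnsetInt_TTP"] == pytest.approx(30.0)
        assert feats["minOnsetInt_TTP"] == pytest.approx(20.0)
        assert feats["meanOnsetInt_TTP"] == pytest.approx(25.0)

    def test_single_event_interval_stats_missing(self):
        ev = [SCREvent(10.0, 12.0, 0.3, "CDA")]
        feats = extract_eda_features(ev, [])
        assert feats["nSCR_CDA"] == 1
        assert feats["maxSCR_CDA"] == feats["minSCR_CDA"] == feats["meanSCR_CDA"] == 0.3
        assert np.isnan(feats["maxOnsetInt_CDA"])

    def test_amplitude_ordering_invariant(self):
        rng = np.random.default_rng(2)
        events = sorted(
            (SCREvent(float(o), float(o) + 2.0, float(a), "CDA")
             for o, a in zip(rng.uniform(0, 170, 8), rng.uniform(0.05, 1.0, 8))),
            key=lambda e: e.onset_s)
        feats = extract_eda_features(events, [])
        assert feats["minSCR_CDA"] <= feats["meanSCR_CDA"] <= feats["maxSCR_CDA"]

    def test_unsorted_events_rejected(self):
        events = [SCREvent(30.0, 32.0, 0.4, "TTP"), SCREvent(10.0, 12.0, 0.2, "TTP")]
        with pytest.raises(ValueError, match="sorted"):
            extract_eda_features([], events)
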