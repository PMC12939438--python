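import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from painsig.eda import analyze_ttp, decompose_cda, detect_scr_cda, preprocess_eda
from painsig.io import SignalChannel
from painsig.synthetic import TonicParams, synthesize_eda

settings.register_profile(
    "painsig", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("painsig")


def make_eda_channel(onsets, amps, level=2.0, noise_sd=0.0, fs=100.0,
                     duration=180.0, rng=None, **tonic_kw):
    trace = synthesize_eda(onsets, amps, TonicParams(level=level, **tonic_kw),
                           noise_sd, fs, duration, rng=rng)
    return SignalChannel(trace, fs, "uS")


@pytest.fixture(scope="session")
def scr_recovery_sim():
    """Fifty synthetic patients with known SCR trains, both scorers applied.

    Conditions: SCR amplitudes 0.2-1.0 uS, inter-onset gaps >= 8 s,
    measurement noise 0.01 uS, drifting tonic baseline.
    """
    rng = np.random.default_rng(20240901)
    results = []
    for _ in range(50):
        n = rng.integers(3, 15)
        onsets = 5 + np.cumsum(rng.uniform(8, 16, size=n))
        onsets = onsets[onsets < 170]
        amps = rng.uniform(0.2, 1.0, size=onsets.size)
        tonic = dict(level=float(rng.uniform(1, 6)),
                     slope=float(rng.uniform(-1e-3, 1e-3)),
                     vlf_amp=float(rng.uniform(0, 0.15)),
                     vlf_freq=float(rng.uniform(0.008, 0.02)))
        ch = make_eda_channel(onsets, amps, noise_sd=0.01, rng=rng, **tonic)
        pre = preprocess_eda(ch)
        dec = decompose_cda(pre)
        cda_events = detect_scr_cda(dec)
        ttp_events = analyze_ttp(pre)
        rel_err = np.nan
        if len(cda_events) == onsets.size:
            est = np.array([e.amplitude for e in cda_events])
            rel_err = float(np.mean(np.abs(est - amps) / amps))
        results.append({"n_true": int(onsets.size), "n_cda": len(cda_events),
                        "n_ttp": len(ttp_events), "amp_rel_err": rel_err})
    return results
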