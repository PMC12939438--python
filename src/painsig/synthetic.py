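"""Synthetic cohorts with known autonomic ground truth.

Generates covariate tables and paired ECG/EDA recordings that emulate a
resting-state cancer-pain cohort: 3-minute recordings, EDA built from a
slowly drifting tonic level plus a train of Bateman-shaped skin conductance
responses (SCRs) and Gaussian noise, and an RR series with controllable
low-frequency / high-frequency spectral modulation (optionally rendered to
a template ECG for end-to-end R-peak detection tests).

Group effects are injectable and default to the directions reported for
this population: mixed-pain patients produce fewer and smaller SCRs than
nociceptive or neuropathic patients, and mild-pain patients show the
largest maximum SCR amplitudes.  Heart-rate-variability parameters carry no
group effect by default (HRV did not discriminate pain groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Recording, SignalChannel
from .kernel import DEFAULT_TAU1, DEFAULT_TAU2, bateman

PAIN_INTENSITY_CLASSES = ("mild", "moderate", "severe")
PAIN_TYPES = ("nociceptive", "neuropathic", "mixed")

#: Cohort marginals calibrated to the study population (n = 64; the pain
#: intensity breakdown sums to 63 evaluable patients and is normalized).
DEFAULT_PAIN_INTENSITY_PROBS = {"mild": 19 / 63, "moderate": 16 / 63, "severe": 28 / 63}
DEFAULT_PAIN_TYPE_PROBS = {"nociceptive": 41 / 64, "neuropathic": 14 / 64, "mixed": 9 / 64}
DEFAULT_COVARIATE_PROBS = {"btcp": 28 / 64, "bone_metastases": 23 / 64, "med_over_60": 34 / 64}
DEFAULT_CANCER_TYPE_PROBS = {
    "breast": 6 / 64, "gastrointestinal": 11 / 64, "lung": 10 / 64,
    "bone_soft_tissue": 11 / 64, "other": 26 / 64,
}
DEFAULT_ECOG_PROBS = {1: 33 / 64, 2: 11 / 64, 3: 7 / 64, 4: 13 / 64}

NRS_RANGES = {"mild": (1, 3), "moderate": (4, 6), "severe": (7, 10)}

COHORT_COLUMNS = ["patient_id", "age", "sex", "cancer_type", "nrs",
                  "pain_intensity_class", "pain_type", "btcp",
                  "bone_metastases", "med_over_60", "ecog"]


@dataclass
class TonicParams:
    """Slow tonic skin-conductance baseline: linear drift + very-low-frequency sine."""

    level: float = 2.0          # uS
    slope: float = 0.0          # uS / s
    vlf_amp: float = 0.0        # uS
    vlf_freq: float = 0.015     # Hz
    vlf_phase: float = 0.0      # rad

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return (self.level + self.slope * t
                + self.vlf_amp * np.sin(2 * np.pi * self.vlf_freq * t + self.vlf_phase))


@dataclass
class EffectConfig:
    """Per-group autonomic parameters.

    SCR rates per pain type come from the reported 3-minute SCR counts
    (about 35, 39.5 and 5 responses for nociceptive, neuropathic and mixed
    pain); amplitude medians encode the mixed-pain amplitude deficit, and
    the intensity multiplier the larger responses of mild-pain patients.
    """

    scr_rate_per_min: Mapping[str, float] = field(default_factory=lambda: {
        "nociceptive": 11.7, "neuropathic": 13.2, "mixed": 1.7})
    scr_amp_median_us: Mapping[str, float] = field(default_factory=lambda: {
        "nociceptive": 0.30, "neuropathic": 0.30, "mixed": 0.18})
    scr_amp_log_sigma: float = 0.6
    amp_multiplier_by_intensity: Mapping[str, float] = field(default_factory=lambda: {
        "mild": 2.2, "moderate": 1.0, "severe": 0.8})
    tonic_level_mean_us: float = 4.0
    tonic_level_sd_us: float = 1.5
    eda_noise_sd_us: float = 0.01
    rr_mean_s: Mapping[str, float] = field(default_factory=lambda: {
        t: 0.85 for t in PAIN_TYPES})
    rr_lf_amp_s: float = 0.03
    rr_hf_amp_s: float = 0.025
    rr_lf_freq: float = 0.1
    rr_hf_freq: float = 0.25
    rr_jitter_sd_s: float = 0.01
    ecg_noise_sd_mv: float = 0.01


@dataclass
class CohortSpec:
    """Everything needed to draw one reproducible synthetic cohort."""

    n_patients: int
    seed: int
    duration_s: float = 180.0
    fs_ecg: float = 1000.0
    fs_eda: float = 100.0
    pain_intensity_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIN_INTENSITY_PROBS))
    pain_type_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIN_TYPE_PROBS))
    covariate_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PROBS))
    effects: EffectConfig = field(default_factory=EffectConfig)
    min_scr_gap_s: float = 1.0
    render_ecg: bool = True

    def validate(self) -> None:
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients > 0):
            raise ValueError(f"n_patients must be a positive integer, got {self.n_patients}")
        if self.seed is None:
            raise ValueError("seed is required")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        for name, fs in (("fs_ecg", self.fs_ecg), ("fs_eda", self.fs_eda)):
            if fs <= 0:
                raise ValueError(f"{name} must be positive, got {fs}")
        for name, dist in (("pain_intensity_probs", self.pain_intensity_probs),
                           ("pain_type_probs", self.pain_type_probs)):
            vals = np.array(list(dist.values()), dtype=float)
            if np.any(vals < 0) or np.any(vals > 1):
                raise ValueError(f"{name} contains probabilities outside [0, 1]")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9 (sum={vals.sum()!r})")
        for key, p in self.covariate_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"covariate_probs[{key!r}] outside [0, 1]: {p}")
        for t, r in self.effects.scr_rate_per_min.items():
            if r < 0:
                raise ValueError(f"effects.scr_rate_per_min[{t!r}] must be >= 0, got {r}")
        for t, m in self.effects.scr_amp_median_us.items():
            if m <= 0:
                raise ValueError(f"effects.scr_amp_median_us[{t!r}] must be > 0, got {m}")
        if self.effects.scr_amp_log_sigma <= 0:
            raise ValueError("effects.scr_amp_log_sigma must be > 0")
        for t, rr in self.effects.rr_mean_s.items():
            if not (0.3 < rr < 2.0):
                raise ValueError(f"effects.rr_mean_s[{t!r}] must lie in (0.3, 2.0) s, got {rr}")


@dataclass
class GroundTruth:
    """Per-patient generative truth used as an oracle in recovery tests."""

    patient_id: str
    scr_onsets_s: np.ndarray
    scr_amplitudes_us: np.ndarray
    tonic_us: np.ndarray
    rr_s: np.ndarray

    def __post_init__(self) -> None:
        onsets = np.asarray(self.scr_onsets_s, dtype=float)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("SCR onsets must be strictly increasing")
        amps = np.asarray(self.scr_amplitudes_us, dtype=float)
        if amps.size and np.any(amps <= 0):
            raise ValueError("SCR amplitudes must be positive")


# ---------------------------------------------------------------------------
# Signal synthesis primitives
# ---------------------------------------------------------------------------

def synthesize_eda(onsets_s, amplitudes_us, tonic: TonicParams, noise_sd: float,
                   fs: float, duration_s: float, tau1: float = DEFAULT_TAU1,
                   tau2: float = DEFAULT_TAU2, rng: np.random.Generator | None = None
                   ) -> np.ndarray:
    """Sampled EDA trace: tonic + sum of unit-peak Bateman SCRs + noise (uS).

    The kernel's unit-peak normalization makes each injected amplitude equal
    the noise-free peak height of an isolated SCR.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    amps = np.asarray(amplitudes_us, dtype=float)
    if onsets.size and np.any(np.diff(onsets) < 0):
        raise ValueError("onsets must be sorted")
    if onsets.shape != amps.shape:
        raise ValueError("onsets and amplitudes must have matching shapes")
    if fs < 4:
        raise ValueError(f"fs must be >= 4 Hz, got {fs}")
    t = np.arange(0.0, duration_s, 1.0 / fs)
    trace = tonic.evaluate(t)
    for o, a in zip(onsets, amps):
        trace = trace + a * bateman(t - o, tau1, tau2)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        trace = trace + rng.normal(0.0, noise_sd, size=t.size)
    return trace


def synthesize_rr(mean_rr: float, lf_amp: float = 0.0, hf_amp: float = 0.0,
                  lf_freq: float = 0.1, hf_freq: float = 0.25,
                  jitter_sd: float = 0.0, duration_s: float = 180.0,
                  seed: int | np.random.Generator | None = None) -> np.ndarray:
    """RR interval series (s) with sinusoidal LF/HF modulation plus jitter.

    ``RR_k = mean_rr + lf_amp sin(2 pi f_lf t_k) + hf_amp sin(2 pi f_hf t_k) + e_k``
    evaluated at the cumulative beat times ``t_k``; generation stops once the
    cumulative time reaches ``duration_s``.
    """
    if mean_rr <= 0:
        raise ValueError(f"mean_rr must be positive, got {mean_rr}")
    if abs(lf_amp) + abs(hf_amp) + 4 * jitter_sd >= mean_rr:
        raise ValueError("modulation amplitudes too large: RR intervals could become nonpositive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rr: list[float] = []
    t = 0.0
    while True:
        val = (mean_rr + lf_amp * np.sin(2 * np.pi * lf_freq * t)
               + hf_amp * np.sin(2 * np.pi * hf_freq * t))
        if jitter_sd > 0:
            val += rng.normal(0.0, jitter_sd)
        if val <= 0:
            raise ValueError("parameters produced a nonpositive RR interval")
        if t + val > duration_s:
            break
        rr.append(val)
        t += val
    return np.asarray(rr)


def _gauss(t: np.ndarray, amp: float, center: float, width: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def render_ecg(rr_s, fs: float, duration_s: float, r_amp=1.0,
               noise_sd: float = 0.0, rng: np.random.Generator | None = None,
               first_beat_s: float = 0.5) -> np.ndarray:
    """Template ECG (mV): P-QRS-T complexes placed at cumulative RR times.

    ``r_amp`` may be a scalar or a per-beat array (e.g. to test adaptive
    detector thresholds with amplitude steps).  Morphology is schematic, not
    pathophysiological.
    """
    rr = np.asarray(rr_s, dtype=float)
    beats = first_beat_s + np.concatenate([[0.0], np.cumsum(rr)])
    beats = beats[beats < duration_s - 0.4]
    r_amp = np.asarray(r_amp, dtype=float)
    if r_amp.ndim == 0:
        amps = np.full(beats.shape, float(r_amp))
    else:
        if r_amp.size < beats.size:
            raise ValueError("per-beat r_amp shorter than the number of beats")
        amps = r_amp[:beats.size]
    t = np.arange(0.0, duration_s, 1.0 / fs)
    ecg = np.zeros_like(t)
    for b, a in zip(beats, amps):
        w = (t > b - 0.35) & (t < b + 0.55)
        tw = t[w]
        ecg[w] += (_gauss(tw, 0.12 * a, b - 0.20, 0.025)     # P
                   + _gauss(tw, -0.08 * a, b - 0.028, 0.010)  # Q
                   + _gauss(tw, 1.00 * a, b, 0.012)           # R
                   + _gauss(tw, -0.14 * a, b + 0.030, 0.010)  # S
                   + _gauss(tw, 0.30 * a, b + 0.30, 0.060))   # T
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        ecg = ecg + rng.normal(0.0, noise_sd, size=t.size)
    return ecg


def poisson_onsets(rate_per_min: float, duration_s: float, min_gap_s: float,
                   rng: np.random.Generator, edge_s: float = 2.0) -> np.ndarray:
    """Homogeneous Poisson SCR onsets thinned to a minimum gap.

    Events are kept inside ``[edge_s, duration_s - edge_s]`` so every SCR
    rise is fully contained in the recording.
    """
    if rate_per_min < 0:
        raise ValueError("rate must be >= 0")
    span = duration_s - 2 * edge_s
    if rate_per_min == 0 or span <= 0:
        return np.empty(0)
    n = rng.poisson(rate_per_min / 60.0 * span)
    times = np.sort(rng.uniform(edge_s, duration_s - edge_s, size=n))
    kept: list[float] = []
    for x in times:
        if not kept or x - kept[-1] >= min_gap_s:
            kept.append(x)
    return np.asarray(kept)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _draw_categorical(rng: np.random.Generator, probs: Mapping) -> object:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def generate_cohort(spec: CohortSpec
                    ) -> tuple[pd.DataFrame, list[Recording], list[GroundTruth]]:
    """Draw a full cohort: covariate table, recordings, and ground truth.

    Deterministic in ``spec.seed``: the same spec yields bit-identical
    outputs.  With ``spec.render_ecg=False`` the ECG channel is omitted
    (the true RR series remains available in the ground truth), which makes
    large EDA-only simulation studies much cheaper.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    eff = spec.effects
    rows = []
    recordings: list[Recording] = []
    truths: list[GroundTruth] = []
    t_eda = np.arange(0.0, spec.duration_s, 1.0 / spec.fs_eda)
    for i in range(spec.n_patients):
        pid = f"P{i + 1:03d}"
        intensity = _draw_categorical(rng, spec.pain_intensity_probs)
        ptype = _draw_categorical(rng, spec.pain_type_probs)
        lo, hi = NRS_RANGES[intensity]
        rows.append({
            "patient_id": pid,
            "age": int(np.clip(round(rng.normal(61, 13.3)), 18, 95)),
            "sex": "male" if rng.random() < 41 / 64 else "female",
            "cancer_type": _draw_categorical(rng, DEFAULT_CANCER_TYPE_PROBS),
            "nrs": int(rng.integers(lo, hi + 1)),
            "pain_intensity_class": intensity,
            "pain_type": ptype,
            "btcp": bool(rng.random() < spec.covariate_probs["btcp"]),
            "bone_metastases": bool(rng.random() < spec.covariate_probs["bone_metastases"]),
            "med_over_60": bool(rng.random() < spec.covariate_probs["med_over_60"]),
            "ecog": _draw_categorical(rng, DEFAULT_ECOG_PROBS),
        })
        # --- EDA ---
        onsets = poisson_onsets(eff.scr_rate_per_min[ptype], spec.duration_s,
                                spec.min_scr_gap_s, rng)
        amp_median = (eff.scr_amp_median_us[ptype]
                      * eff.amp_multiplier_by_intensity[intensity])
        amps = rng.lognormal(np.log(amp_median), eff.scr_amp_log_sigma, size=onsets.size)
        tonic = TonicParams(
            level=float(max(0.5, rng.normal(eff.tonic_level_mean_us, eff.tonic_level_sd_us))),
            slope=float(rng.uniform(-0.001, 0.001)),
            vlf_amp=float(rng.uniform(0.0, 0.15)),
            vlf_freq=float(rng.uniform(0.008, 0.02)),
            vlf_phase=float(rng.uniform(0, 2 * np.pi)),
        )
        eda = synthesize_eda(onsets, amps, tonic, eff.eda_noise_sd_us,
                             spec.fs_eda, spec.duration_s, rng=rng)
        # --- RR / ECG ---
        rr = synthesize_rr(eff.rr_mean_s[ptype], eff.rr_lf_amp_s, eff.rr_hf_amp_s,
                           eff.rr_lf_freq, eff.rr_hf_freq, eff.rr_jitter_sd_s,
                           spec.duration_s, seed=rng)
        channels = {"eda": SignalChannel(eda, spec.fs_eda, "uS")}
        if spec.render_ecg:
            ecg = render_ecg(rr, spec.fs_ecg, spec.duration_s,
                             noise_sd=eff.ecg_noise_sd_mv, rng=rng)
            channels["ecg"] = SignalChannel(ecg, spec.fs_ecg, "mV")
        recordings.append(Recording(pid, channels))
        truths.append(GroundTruth(pid, onsets, amps, tonic.evaluate(t_eda), rr))
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return cohort, recordings, truths


def simulate_null_feature_table(n_patients: int, rng: np.random.Generator,
                                feature_names: Sequence[str]
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Covariates plus feature values drawn iid across all patients.

    Because feature values are independent of every grouping variable, any
    group comparison on this table is a draw from the null hypothesis; used
    for type-I-error calibration of the statistics layer without paying for
    signal synthesis.
    """
    spec = CohortSpec(n_patients=n_patients, seed=0)
    cohort_rows = []
    for i in range(n_patients):
        intensity = _draw_categorical(rng, spec.pain_intensity_probs)
        lo, hi = NRS_RANGES[intensity]
        cohort_rows.append({
            "patient_id": f"P{i + 1:03d}",
            "age": int(np.clip(round(rng.normal(61, 13.3)), 18, 95)),
            "sex": "male" if rng.random() < 41 / 64 else "female",
            "cancer_type": "other",
            "nrs": int(rng.integers(lo, hi + 1)),
            "pain_intensity_class": intensity,
            "pain_type": _draw_categorical(rng, spec.pain_type_probs),
            "btcp": bool(rng.random() < spec.covariate_probs["btcp"]),
            "bone_metastases": bool(rng.random() < spec.covariate_probs["bone_metastases"]),
            "med_over_60": bool(rng.random() < spec.covariate_probs["med_over_60"]),
            "ecog": 1,
        })
    cohort = pd.DataFrame(cohort_rows, columns=COHORT_COLUMNS)
    feats = {"patient_id": cohort["patient_id"]}
    for name in feature_names:
        if name.startswith("nSCR"):
            feats[name] = rng.poisson(20, size=n_patients).astype(float)
        else:
            feats[name] = rng.lognormal(0.0, 0.8, size=n_patients)
    return pd.DataFrame(feats), cohort
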