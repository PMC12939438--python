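"""Heart rate variability pipeline: R-peak detection and HRV features.

R-peaks are found with the classic Pan-Tompkins stage chain (5-15 Hz
band-pass, derivative, squaring, 150 ms moving-window integration, dual
adaptive thresholds with a 200 ms refractory period and RR-gap search-back),
then refined to the nearest band-passed extremum.  The RR (inter-beat
interval) series is screened for artifacts and summarized by time-domain
statistics (mean HR, SDNN, RMSSD) and Welch band powers on a uniformly
resampled 4 Hz tachogram (VLF 0.0033-0.04 Hz, LF 0.04-0.15 Hz,
HF 0.15-0.36 Hz) plus the LF/HF sympatho-vagal balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .io import SignalChannel

#: physiological RR acceptance band (s)
RR_BAND = (0.3, 2.0)
#: spectral bands (Hz); the HF upper edge follows the study definition
VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.36)

HRV_FEATURES = ["mean_hr", "sdnn", "rmssd", "vlf_power", "lf_power",
                "hf_power", "lf_hf_ratio"]

MIN_BEATS = 10
MIN_SPECTRAL_SPAN_S = 120.0


class HRVError(ValueError):
    """Raised when a recording is unusable for HRV analysis."""


@dataclass
class RRSeries:
    """Artifact-screened RR interval series.

    ``rr[k]`` is the interval (s) beginning at onset time ``t[k]``;
    ``n_beats`` counts the underlying R-peaks.
    """

    rr: np.ndarray
    t: np.ndarray
    n_beats: int

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.rr.shape != self.t.shape:
            raise ValueError("rr and t must have matching lengths")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("onset times must be strictly increasing")

    @property
    def span_s(self) -> float:
        return float(self.t[-1] + self.rr[-1] - self.t[0]) if self.rr.size else 0.0


# ---------------------------------------------------------------------------
# R-peak detection (Pan-Tompkins stage chain)
# ---------------------------------------------------------------------------

def detect_r_peaks(channel: SignalChannel, refractory_s: float = 0.2,
                   integration_s: float = 0.15) -> np.ndarray:
    """Detect R-peak sample indices in a single-lead ECG channel."""
    if channel.units != "mV":
        raise HRVError(f"ECG detection expects mV, got {channel.units!r}")
    fs = channel.fs
    if fs < 100:
        raise HRVError(f"ECG sampling rate must be >= 100 Hz, got {fs}")
    x = channel.samples
    if x.size < fs or float(np.std(x)) == 0.0:
        raise HRVError("flat or too-short ECG: no beats detectable")

    b, a = sps.butter(2, [5.0, 15.0], btype="band", fs=fs)
    bp = sps.filtfilt(b, a, x)
    deriv = np.gradient(bp) * fs
    mwi = uniform_filter1d(deriv ** 2, size=max(1, int(round(integration_s * fs))))

    refr = max(1, int(round(refractory_s * fs)))
    cand, _ = sps.find_peaks(mwi, distance=refr)
    if cand.size == 0:
        raise HRVError("no candidate peaks in integrated signal")

    # adaptive dual thresholds, initialized from the first two seconds
    init = mwi[: int(2 * fs)] if mwi.size > 2 * fs else mwi
    spki = float(np.max(init)) * 0.5
    npki = float(np.mean(init)) * 0.5
    accepted: list[int] = []
    rr_hist: list[float] = []
    missed: list[int] = []  # sub-threshold candidates since the last beat

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    for c in cand:
        v = mwi[c]
        rr_avg = float(np.mean(rr_hist[-8:])) if rr_hist else None
        # search-back: no beat for > 1.66 RR averages -> revisit missed peaks
        if accepted and rr_avg is not None and (c - accepted[-1]) > 1.66 * rr_avg * fs:
            above = [m for m in missed if mwi[m] > 0.5 * threshold1()]
            if above:
                m = max(above, key=lambda i: mwi[i])
                if m - accepted[-1] >= refr:
                    rr_hist.append((m - accepted[-1]) / fs)
                    accepted.append(m)
                    spki = 0.25 * mwi[m] + 0.75 * spki
                missed = []
        if v > threshold1():
            if accepted and c - accepted[-1] < refr:
                continue
            if accepted:
                rr_hist.append((c - accepted[-1]) / fs)
            accepted.append(int(c))
            spki = 0.125 * v + 0.875 * spki
            missed = []
        else:
            npki = 0.125 * v + 0.875 * npki
            missed.append(int(c))

    # refine to the band-passed extremum near each integrated-signal peak
    half = int(round(0.075 * fs))
    refined = []
    for c in accepted:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.unique(refined)
    # enforce refractory after refinement
    peaks: list[int] = []
    for r in refined:
        if peaks and r - peaks[-1] < refr:
            if np.abs(bp[r]) > np.abs(bp[peaks[-1]]):
                peaks[-1] = int(r)
            continue
        peaks.append(int(r))
    if len(peaks) < MIN_BEATS:
        raise HRVError(f"only {len(peaks)} beats detected; recording unusable")
    return np.asarray(peaks)


# ---------------------------------------------------------------------------
# RR series
# ---------------------------------------------------------------------------

def build_rr(peaks: np.ndarray, fs: float, band: tuple[float, float] = RR_BAND,
             rel_tol: float = 0.3, median_window: int = 11) -> RRSeries:
    """RR intervals from R-peak indices, with artifact screening.

    Intervals outside the physiological band, or deviating more than
    ``rel_tol`` from the running median of recent accepted intervals, are
    dropped (no interpolation in the time-domain series).
    """
    peaks = np.asarray(peaks)
    if peaks.size < MIN_BEATS + 1:
        raise HRVError(f"need at least {MIN_BEATS + 1} peaks, got {peaks.size}")
    rr_all = np.diff(peaks) / fs
    t_all = peaks[:-1] / fs
    rr, t = [], []
    for ti, ri in zip(t_all, rr_all):
        if not (band[0] < ri < band[1]):
            continue
        if len(rr) >= 5:
            med = float(np.median(rr[-median_window:]))
            if abs(ri - med) > rel_tol * med:
                continue
        rr.append(float(ri))
        t.append(float(ti))
    if not rr:
        raise HRVError("all RR intervals rejected by artifact screening")
    return RRSeries(np.asarray(rr), np.asarray(t), n_beats=len(rr) + 1)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def time_domain_features(rrs: RRSeries) -> dict[str, float]:
    """Mean HR (bpm), SDNN (ms, sample SD), RMSSD (ms)."""
    if rrs.n_beats < MIN_BEATS:
        raise HRVError(f"need at least {MIN_BEATS} beats, got {rrs.n_beats}")
    rr = rrs.rr
    mean_hr = 60.0 / float(np.mean(rr))
    sdnn = float(np.std(rr, ddof=1)) * 1000.0
    d = np.diff(rr)
    rmssd = float(np.sqrt(np.mean(d ** 2))) * 1000.0 if d.size else 0.0
    return {"mean_hr": mean_hr, "sdnn": sdnn, "rmssd": rmssd}


def frequency_domain_features(rrs: RRSeries, fs_interp: float = 4.0,
                              segment_s: float = 60.0) -> dict[str, float]:
    """Welch band powers (ms^2) on a uniformly interpolated tachogram.

    The RR series is linearly interpolated to ``fs_interp`` Hz (gaps from
    dropped beats are bridged by the interpolation), mean-removed, and a
    Welch periodogram with Hann segments of ``segment_s`` seconds at 50%
    overlap is integrated over the VLF/LF/HF bands by the trapezoid rule.
    """
    if rrs.span_s < MIN_SPECTRAL_SPAN_S:
        raise HRVError(
            f"RR span {rrs.span_s:.1f}s below the {MIN_SPECTRAL_SPAN_S:.0f}s floor "
            "for spectral analysis")
    grid = np.arange(rrs.t[0], rrs.t[-1], 1.0 / fs_interp)
    tach_ms = np.interp(grid, rrs.t, rrs.rr) * 1000.0
    tach_ms = tach_ms - tach_ms.mean()
    nperseg = min(int(segment_s * fs_interp), tach_ms.size)
    f, pxx = sps.welch(tach_ms, fs=fs_interp, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2, detrend="constant")

    def band_power(lo: float, hi: float) -> float:
        m = (f >= lo) & (f <= hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(pxx[m], f[m]))

    vlf = band_power(*VLF_BAND)
    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    ratio = lf / hf if hf > 0 else float("nan")
    return {"vlf_power": vlf, "lf_power": lf, "hf_power": hf, "lf_hf_ratio": ratio}


def extract_hrv_features(rrs: RRSeries) -> dict[str, float]:
    """All seven HRV scalars for one patient."""
    out = time_domain_features(rrs)
    out.update(frequency_domain_features(rrs))
    return out
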