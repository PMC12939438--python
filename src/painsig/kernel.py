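"""Canonical skin-conductance impulse response (Bateman function).

A single sudomotor burst produces a skin conductance response (SCR) whose
shape is well described by a difference of exponentials,

    B(t) = exp(-t / tau2) - exp(-t / tau1),   t >= 0,  tau1 < tau2,

with a fast rise governed by ``tau1`` and a slow recovery governed by
``tau2``.  Both the synthetic-signal generator and the continuous
decomposition analysis (CDA) use this kernel.  It is normalized to unit
peak so that an isolated SCR of injected amplitude ``a`` has a noise-free
peak height of exactly ``a`` above the tonic baseline.
"""

from __future__ import annotations

import numpy as np

#: Default rise / decay time constants (s); conventional values from the
#: skin-conductance deconvolution literature.
DEFAULT_TAU1 = 0.75
DEFAULT_TAU2 = 2.0


def bateman_peak_time(tau1: float = DEFAULT_TAU1, tau2: float = DEFAULT_TAU2) -> float:
    """Time at which the (unnormalized) Bateman function attains its maximum."""
    _check_taus(tau1, tau2)
    return float(np.log(tau2 / tau1) * tau1 * tau2 / (tau2 - tau1))


def bateman(t, tau1: float = DEFAULT_TAU1, tau2: float = DEFAULT_TAU2):
    """Unit-peak Bateman function evaluated at times ``t`` (s).

    Values at ``t < 0`` are zero (causal kernel).
    """
    _check_taus(tau1, tau2)
    t = np.asarray(t, dtype=float)
    tp = bateman_peak_time(tau1, tau2)
    peak = np.exp(-tp / tau2) - np.exp(-tp / tau1)
    out = np.where(t >= 0.0, np.exp(-np.clip(t, 0.0, None) / tau2)
                   - np.exp(-np.clip(t, 0.0, None) / tau1), 0.0)
    return out / peak


def sampled_kernel(fs: float, tau1: float = DEFAULT_TAU1, tau2: float = DEFAULT_TAU2,
                   rel_cutoff: float = 1e-4, max_len_s: float = 40.0) -> np.ndarray:
    """Discretized unit-peak kernel at sampling rate ``fs``.

    The kernel is truncated once its tail falls below ``rel_cutoff`` of the
    peak (or at ``max_len_s``, whichever comes first).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    # decay tail: exp(-t/tau2)/peak_norm <= rel_cutoff
    tp = bateman_peak_time(tau1, tau2)
    peak = np.exp(-tp / tau2) - np.exp(-tp / tau1)
    t_end = min(max_len_s, -tau2 * np.log(rel_cutoff * peak))
    t = np.arange(0.0, t_end, 1.0 / fs)
    return bateman(t, tau1, tau2)


def _check_taus(tau1: float, tau2: float) -> None:
    if not (0 < tau1 < tau2):
        raise ValueError(
            f"Bateman time constants require 0 < tau1 < tau2, got tau1={tau1}, tau2={tau2}")
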