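# Methods

`painsig` analyzes two autonomic biosignals recorded at rest in cancer
patients — finger electrodermal activity (EDA, in µS) and single-lead ECG —
and asks whether scalar features of those signals differ across
self-reported pain intensity classes (mild / moderate / severe on the 0–10
NRS) and clinically assigned pain types (nociceptive / neuropathic /
mixed).  This note describes the models and procedures, their parameters,
the synthetic cohort used for validation, and the numerical choices made
where the design was open.

## EDA model and decomposition

Skin conductance is modeled as

    y(t) = tonic(t) + Σ_i a_i · B(t − t_i) + ε(t)

where `tonic` is a slowly varying sympathetic baseline, each skin
conductance response (SCR) is a scaled copy of the Bateman impulse
response `B(t) = exp(−t/τ₂) − exp(−t/τ₁)` (rise constant τ₁ = 0.75 s,
recovery constant τ₂ = 2.0 s, conventional values in the deconvolution
literature), and ε is measurement noise.  `B` is normalized to unit peak,
so an isolated SCR of amplitude `a` rises exactly `a` µS above baseline.

**Preprocessing.** Zero-phase 4th-order Butterworth low-pass at 1 Hz, then
polyphase resampling to the 10 Hz working rate; negative conductance is
clipped at zero (with a warning if more than 1 % of samples clip).

**Continuous decomposition analysis (CDA).** The preprocessed trace is
deconvolved with the discretized Bateman kernel under a nonnegativity
constraint on the driver, solved as a nonnegative least-squares problem by
monotone FISTA on the FFT-implemented convolution operator.  Numerical
details that matter:

* the preprocessing low-pass response is folded into the kernel before
  deconvolution — recorded SCRs are filtered Bateman shapes, and
  deconvolving with the raw kernel would convert that mismatch into
  ringing sidelobes of the driver;
* the discrete Bateman kernel has an exact rational inverse (a
  second-order difference), which supplies the warm start, so the solver
  typically reaches float-precision reconstruction in a fraction of a
  second per 3-minute recording;
* a constant pad of one kernel length is prepended and masked out of the
  objective: a causal kernel cannot represent the standing conductance
  level at the very first samples;
* the kernel time constants are fixed; no per-recording re-optimization of
  τ₁, τ₂ is performed.

The tonic driver is estimated as a robust rolling low percentile (25th,
20 s window) of the smoothed driver — robust both to impulse mass above
the inter-impulse baseline and to the narrow driver dropouts that follow
large impulses — and smoothed over 10 s.  Any remaining very-slow residual
of the phasic component (below roughly 1/60 Hz) is reassigned to the tonic
component via a 60 s zero-phase moving average; this bleeds only a few
percent of an individual SCR's mass while keeping baseline drift out of
the phasic channel.  By construction tonic + phasic reconstructs the
preprocessed signal to solver tolerance.

**SCR scoring, CDA route.** Local maxima of the phasic component with
prominence ≥ half the amplitude threshold are candidate responses; each is
scored by its rise above the preceding phasic trough, with the onset at
the 10 %-rise point.  A candidate is kept when the rise reaches the
amplitude threshold (default 0.05 µS, the conventional minimum SCR
amplitude; configurable because it directly drives the count) and
completes within 5 s — residual baseline drift rises far more slowly than
a sudomotor burst, so the rise-time gate separates the two without an
absolute level test.

**SCR scoring, TTP route.** Classic trough-to-peak (min–max) scoring on
the preprocessed trace: each local maximum is paired with its preceding
local minimum; the response is kept when peak − trough reaches the same
amplitude threshold and the trough-to-peak rise time falls in a 1–5 s
window (unstated in the source methodology; these bounds bracket the
kernel's ~1.2 s rise after filtering).  Peaks sharing a trough resolve to
the larger response.

**Features (14).** Per method (CDA, TTP): SCR count; max, min and mean SCR
amplitude; max, min and mean inter-onset interval.  "Onset interval" is
read as the interval between successive onsets (not onset-to-peak
latency); interval statistics require at least two responses and are
encoded as NaN otherwise, amplitude statistics require at least one.

## HRV model

**R-peak detection.** The classic Pan–Tompkins stage chain: 5–15 Hz
band-pass (2nd-order Butterworth, zero-phase), derivative, squaring,
150 ms moving-window integration, dual adaptive thresholds with a 200 ms
refractory period and search-back when no beat appears within 1.66 running
RR averages.  Detections are refined to the nearest band-passed extremum
within ±75 ms.  Recordings yielding fewer than 10 beats are rejected.

**RR screening.** Intervals outside 0.3–2.0 s, or deviating more than 30 %
from the running median of recent accepted intervals, are dropped without
interpolation (time-domain statistics use only accepted beats; the
spectral tachogram bridges gaps by interpolation).

**Features (7).** Mean HR (bpm), SDNN (sample SD of RR, ms), RMSSD (ms);
Welch band powers on the RR tachogram linearly interpolated to 4 Hz,
mean-removed, Hann segments of 60 s at 50 % overlap, trapezoid-integrated
over VLF 0.0033–0.04 Hz, LF 0.04–0.15 Hz, HF 0.15–0.36 Hz (the HF upper
edge follows the study definition; it is wider than the conventional
0.4 Hz band edge), plus LF/HF.  The 4 Hz / 60 s / 50 % choices are the
smallest configuration that resolves the 0.04 Hz band edge while giving
at least two Welch segments in a 3-minute recording; spectral analysis
refuses RR spans under 120 s.

## Statistical layer

Features are non-normal in at least some subgroups (screened per group
with Shapiro–Wilk, reported but not acted on), so all comparisons are
nonparametric:

* **Kruskal–Wallis** on pooled midranks with the tie-correction divisor;
  p from the upper χ² tail at k − 1 df.  Degenerate inputs (empty group,
  all values identical) raise rather than returning a value.
* **Dunn's post hoc** z-tests, `z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)
  (1/n_i + 1/n_j))` with tie term `T = Σ(t³−t)/(12(N−1))`, two-sided
  normal p-values (Dunn's standard form).
* **Benjamini–Hochberg** step-up adjustment within the family of the
  k(k−1)/2 pairwise comparisons of one feature under one grouping — not
  pooled across features, matching how adjusted values accompany raw ones
  in the source reports.  Raw and adjusted p-values are reported side by
  side at a 0.05 flagging threshold.

`run_comparisons` applies every feature × grouping (pain intensity, pain
type) overall and within each level of the clinical strata (bone
metastases, breakthrough cancer pain, morphine-equivalent dose class).
Missing feature values are dropped per feature (pairwise deletion, which
preserves n for the features that exist); a stratum that leaves a
comparison undefined produces an explicit not-computable row, never a
silent omission.  Group location is summarized by the median with IQR
reported as the single number Q3 − Q1.

These three procedures are implemented in the package and cross-checked
in the test suite against independent oracles: a brute-force rank
computation of H on tie-free data, `scipy.stats.kruskal` under ties, the
identity z² = H for two groups, and `statsmodels`' BH implementation.

## Synthetic cohort

The generator draws covariate tables and paired signals with known ground
truth so that every stage is testable without clinical recordings.

* **Covariates** follow the study cohort's marginals (n = 64): pain type
  64.1 / 21.9 / 14.1 % (nociceptive / neuropathic / mixed), pain intensity
  30.2 / 25.4 / 44.4 % (mild / moderate / severe, normalized over the 63
  evaluable patients), BTCP 43.8 %, bone metastases 35.9 %, MED > 60
  53.1 %, age ≈ N(61, 13.3²), 64 % male, plus cancer type and ECOG with
  the reported frequencies.  NRS is drawn uniformly inside its class band.
* **EDA**: tonic = level (≈ N(4, 1.5²) µS) + small linear drift + a
  very-low-frequency sine (≤ 0.15 µS, 0.008–0.02 Hz), exercising
  tonic/phasic separation without confounding detection; SCR onsets from a
  homogeneous Poisson process thinned to a 1 s minimum gap; amplitudes
  log-normal; Gaussian noise (default SD 0.01 µS); sampled at 100 Hz.
* **Group effects** (the defaults are the study conditions, not free
  dials): SCR rates per pain type 11.7 / 13.2 / 1.7 per minute — the
  reported 3-minute SCR counts of about 35, 39.5 and 5 — with amplitude
  medians 0.30 / 0.30 / 0.18 µS, and intensity amplitude multipliers
  2.2 / 1.0 / 0.8 (mild / moderate / severe) reproducing the direction of
  the larger responses in mild pain.  HRV parameters carry no group
  effect, since HRV did not discriminate the pain groups.
* **RR / ECG**: RR series = mean RR + LF and HF sinusoidal modulation +
  jitter; optionally rendered to a schematic P-QRS-T template ECG at
  1000 Hz for end-to-end detector tests.  Rendering can be disabled for
  EDA-only simulation studies.
* 3-minute recordings throughout (all analyses assume recordings trimmed
  to a common shortest length).

What the generator does **not** emulate: motion and electrode artifacts,
respiration-coupled HF dynamics, realistic or pathological ECG morphology,
skin-temperature and hydration effects on EDA, and between-patient
correlation structure beyond the injected group effects.  Passing recovery
and power tests therefore demonstrate correctness of the algorithms under
the stated generative model, not clinical performance on real recordings.

## Validation summary (all recomputed by the test suite / acceptance script)

* SCR count recovery: both scorers reproduce the injected count exactly in
  ≥ 90 % of 50 synthetic patients (amplitudes 0.2–1.0 µS, gaps ≥ 8 s,
  noise 0.01 µS) and never deviate by more than one response; mean
  amplitude error a few percent.
* RR recovery: mean |ΔRR| well under 5 ms across 20 rendered ECGs.
* A single-tone RR modulation concentrates ≥ 90 % of in-band power in the
  correct band.
* On null cohorts (features independent of groupings) the Kruskal–Wallis
  layer rejects at 5 % ± 2 % across 500 cohorts; the per-feature rates sit
  inside a 3.3σ binomial region — the mean across the 21 features is the
  primary calibration check because twenty-one simultaneous ±2 % bands at
  500 draws would false-alarm on a correct implementation with roughly
  even odds.
* At n = 64 with the default effects, the pain-type comparison of the SCR
  count is significant in well over 80 % of seeds, with the two
  mixed-vs-other pairs carrying the smallest adjusted p-values.

Simulation sizes (50 patients, 20 ECGs, 500 null cohorts, 10–12 power
seeds) keep the whole validation run in a few minutes on one CPU while
leaving the binomial margins quoted above.

## Known limitations

* The CDA kernel is fixed; recordings whose SCR shape departs strongly
  from τ₁ = 0.75 s / τ₂ = 2.0 s will show biased amplitudes (counts are
  more robust).
* Closely overlapping SCRs (gaps ≲ 1–2 s) merge in both scorers; counts in
  very high-rate recordings are conservative.
* Three minutes is short for frequency-domain HRV, particularly VLF; band
  powers are reported but carry wide uncertainty at this duration.
* The OpenSignals reader supports the JSON-header tab-separated text
  dialect written by this package; vendor files with other header layouts
  may need an adapter.
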