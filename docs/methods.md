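# Methods

`microdls` models, end to end, a dynamic-light-scattering (DLS) skin sensor
used for continuous microcirculatory monitoring in neonates: the physics
that turns microvascular blood motion into a fluctuating detector intensity,
the signal processing that turns that intensity into the monitor's channels
(TBF, RBV, five relative haemodynamic indices, DLS heart rate), and the
clinical event analysis built on those channels (stability screening,
analysis-window selection, heart-rate-deceleration detection, change-onset
marking, lead/lag and AUC statistics, cohort comparisons). Because no real
recordings are publicly available, a synthetic-data module generates full
cohorts with a known ground truth; everything downstream is validated
against that truth and against closed-form spectral oracles.

## Optical model

The microvasculature under the probe is reduced to five shear-rate
compartments. Wall shear rate in skin vessels spans roughly 10 1/s in veins
to 2000 1/s in the smallest arteries, and is inversely related to vessel
diameter, so compartment (band) 1 represents the smallest, highest-shear
vessels and band 5 the largest, lowest-shear ones. Default band edges are
log-spaced over [10, 2000] 1/s — the range spans two decades and the true
device edges are unpublished.

Light scattered from moving red cells decorrelates at a rate set by the
local velocity gradient. Each compartment k contributes a complex field
E_k(t) modelled as a circular complex Ornstein–Uhlenbeck process with

* stationary power N_k — the compartment's "number of scatterers" weight
  (volume fraction, arbitrary units), and
* field autocorrelation exp(−2π f_k |τ|) with corner frequency
  f_k = κ·γ̇_k, where γ̇_k is the compartment's mean shear and κ (default
  3.0 Hz·s) maps shear to spectral half-width. κ = 3.0 places the highest
  default corner (6000 Hz) inside the device's printed 0–9000 Hz range.

Detection is heterodyne: a strong static field E_s (light scattered from
immobile tissue, E_s = g·√ΣN_k with gain g = 10) mixes with the blood
field, so the intensity

    I(t) = |E_s + Σ_k E_k(t)|² + η(t)

has a dominant AC term 2·E_s·Re(ΣE_k) whose one-sided PSD is the weighted
Lorentzian mixture

    S(f) = Σ_k 4 E_s² N_k f_k / (π (f² + f_k²)).

The homodyne term |ΣE|² contributes a fraction ≈ ΣN/(2E_s²) ≈ 0.5 % of the
AC power at g = 10 and is ignored by the oracle but present in simulation.

The OU update is the exact discretization E ← aE + √(N(1−a²))·ζ with
a = exp(−2π f_k/fs), so no step-size error accumulates; coefficients vary
per sample when the scene is time-varying (a numba kernel performs the
scan). Sampling at fs = 20 kHz satisfies Nyquist for the 9000 Hz analysis
edge, but the sampled process's spectrum is the Lorentzian folded across all
Nyquist images — exactly the AR(1) spectrum

    S(f) = Σ_k 4 E_s² N_k (1−a_k²) / (fs (1 − 2a_k cos(2πf/fs) + a_k²)).

`theoretical_psd(..., sampled=True)` returns this form and is the oracle
used when testing quantities estimated from simulated samples; the
continuous Lorentzian form is used for closed-form values (for a 1 kHz
corner the band mean frequency on [30, 9000] Hz is 1540.2 Hz). At a 1 kHz
corner, fold-back shifts band-integrated moments by 6–19 %, which is why
the distinction matters.

## Channel definitions

All channels derive from a mean-removed Welch estimate (Hann taper, 0.25-s
segments, 50 % overlap, one-sided density) of the intensity, restricted to
the analysis band [30, 9000] Hz. The 30 Hz floor excludes the DC/pulsatile
baseline; 9000 Hz is the printed device limit. With band moments
m0 = ∫S df and m1 = ∫f·S df:

* **TBF** (total blood flow, AU) = m1, the laser-Doppler perfusion
  convention: first moment ∝ scatterer count × characteristic velocity.
* **RBV** (relative blood velocity, Hz) = m1/m0, the mean spectral
  frequency, invariant to uniform scaling of the N_k and bounded by the
  analysis band. The unit is reported as Hz: the printed values (~1400–1600,
  range "0 to approximately 9000") read as frequencies, and the source's
  "Hz⁻¹" is treated as a typographical artefact.
* **relHI 1..5** = band-wise first moments over the five band frequency
  intervals, normalized to sum to one — each index is one vessel class's
  share of total flow, in [0, 1]. No noise-floor subtraction is applied
  before normalization (configurable).
* **DLS heart rate**: the perfusion waveform (m1 on 0.2-s windows hopping
  0.04 s) carries the pulsatile modulation; per second the dominant
  frequency of the trailing 10-s block in 1.0–4.5 Hz (zero-padded FFT with
  parabolic peak refinement) × 60 gives bpm. Blocks without a prominent
  peak (peak/median band power < 10) and the first 10 s are missing.

TBF/RBV come from non-overlapping 1-s windows (1 Hz logging); relHIs from
100-ms windows hopping 10 ms (100 Hz). The 100-ms window is the shortest
giving a 10 Hz spectral resolution floor; the device's true window is
unpublished.

## Event pipeline

* **Stability**: a second is stable iff |HR_DLS − HR_ECG| ≤ max(10 % of
  HR_ECG, 5 bpm) — the ECG-monitor accuracy clause of IEC 60601-2-27 —
  and both channels are present. The tolerance is configurable since the
  source invokes the standard without printing numbers.
* **Decelerations**: per session, candidate runs with HR below
  (median − 30 bpm) for ≥ 2 s; runs separated by < 10 s merge. The onset is
  refined by walking backwards while the trace keeps descending by
  ≥ 2 bpm/s (the last plateau second before the consistent decline); the
  end is the first second back within 5 bpm of the median sustained 5 s.
  A fixed return-to-median margin was tried for the onset as well and
  rejected: ordinary heart-rate variability (sd ≈ 3 bpm) dips below any
  fixed margin for seconds at a time and drags onsets several seconds
  early. The depth criterion (30 bpm below the per-patient median) is the
  published definition; the run/merge/refinement rules are this package's
  additions since only the depth was published.
* **Windows**: event windows are the 240 s centred on each onset, dropped
  if they cross the session edge; the stable window is the first contiguous
  240-s run of stable, deceleration-free seconds after the first 60 s
  (sensor-placement artefact), skipping any overlap with event windows.
  Windows are pairwise disjoint by construction.
* **Onset marking** stands in for the study's two human raters: per band,
  baseline mean and SD over the first 60 s of the event window; the relHI
  onset is the earliest time any band deviates > 3 SD from its baseline for
  2 s (200 consecutive 10-ms samples), searched up to 60 s after the HR
  onset; the excursion ends when all bands are back within 3 SD for 5 s.
  The SpO₂ onset requires SpO₂ < baseline − max(3 SD, 2 %-points) for 3 s.
  Lead = HR onset − relHI onset; lag = SpO₂ onset − HR onset. All
  thresholds are parameters; agreement with human marking cannot be
  validated without the original data.
* **AUC**: with the relHI value at the marked onset as baseline,
  AUC = 0.01 s × Σ|x − baseline| over the marked period (AU·s).
* **Summaries**: per-band mean and sample SD (n−1) per window; missing
  rows omitted (missing-completely-at-random policy).

## Statistics

Paired t-tests over all 10 location pairs with Bonferroni correction
(threshold 0.05/10 = 0.005); Wilcoxon signed-rank for stable-vs-event
contrasts and rank-sum for group contrasts, two-sided throughout. The
signed-rank exact path (n ≤ 25) builds the null distribution of W⁺ by
dynamic programming over sign assignments on doubled mid-ranks, so ties are
handled exactly; the rank-sum exact path (min n ≤ 10, no ties) counts rank
subsets. Larger samples use normal approximations with tie corrections.
Exactness is verified against brute-force enumeration in the tests. The
linear mixed model relating RBV to heart rate is deliberately not fitted
here; the pipeline exports the analysis-ready paired
RBV/HR/GA/location table for external fitting.

## Synthetic cohort

The generator's defaults mirror the published cohort: 31 subjects;
per-location session availability 31/31/28/12/28 (forehead, upper
extremity, thorax, abdomen, lower extremity), chosen so that a fully stable
frames-mode cohort reproduces the published included-point counts
(130 sessions × 240 = 31,200); HR medians ~ N(153, 8) clipped to
[130, 180] bpm; gestational age ~ U(28, 42) weeks; 15-min sessions;
per-session event probability 19/130 (≈ 19 events cohort-wide, ≥ 1 event
for roughly half the subjects).

Event parameters: drop = 30 + log-normal (median 42 bpm, σ = 0.8,
truncated at 111 bpm — the published median and range). Lead and lag times
are drawn through monotone piecewise-linear quantile functions pinned at
the published quartiles (lead 13.5/22.0/27.0 s, lag 5.0/9.0/15.3 s) with
tail anchors at (4, 45) s and (1, 35) s respectively, so medians and IQRs
are matched by construction; a gamma family was considered and rejected
because the lead quartiles are left-skewed (lower spread 8.5 s > upper
spread 5 s), which no right-skewed positive family can reproduce.

HR traces are the subject median plus AR(1) noise (sd 3 bpm, lag-1
correlation 0.9); during an event the trace follows the lower envelope of
the noisy baseline and a deterministic curve (5-s descent, hold at
median − drop, 10-s recovery), making the injected nadir exact. SpO₂ sits
at 96 ± 1.5 % and dips by 8–20 %-points starting lag seconds after the HR
onset. Events keep 120 s from session edges (so their windows fit) and
300 s from each other.

The microvascular redistribution driving the relHI change ramps the
compartment volume fractions linearly (5-s attack starting lead seconds
before the HR onset, 10-s release after the event) towards
base × (6.0, 2.0, 0.5, 0.15, 2.5) — flow shifted into the smallest and
largest vessel classes at the expense of the mid-size ones. The magnitude
is chosen so the excursion is unambiguous against baseline variability
(≈ 10–15 baseline SDs), as the published example event is; with that
margin the 3-SD marker fires ≈ 1–1.5 s into the attack ramp, the dominant
term in the ≈ 1.5 s systematic shortening of recovered lead times.

Two generation modes: **raw** runs the full physics chain (including a
movement artefact — band-limited 0.1–5 Hz random gain — over the first
60 s); **frames** emits the channels directly from the closed-form band
moments of the scene state, with HR_DLS ≡ HR_ECG and small configurable
relHI/TBF noise (1 % relative default, giving stable-window relHI SDs of
0.002–0.005, the scale the study reports). Frames mode makes count-based
pipeline tests exact and fast; raw mode exercises the estimator chain.

Location compartment mixes are weighted towards the low-shear compartments
so the five relHIs spread over ≈ 0.05–0.35. Profiles with a very low
smallest-vessel share (≈ 0.19, as the study reports) are unreachable under
this model: the f-weighted Lorentzian tails put a floor under the
high-frequency bands' flow share regardless of the compartment weights.
This is a known structural limitation — the real device's band estimator
is unpublished and plausibly suppresses out-of-band tails.

## What the synthetic data do not show

Passing tests demonstrate internal consistency (simulator ↔ analytic
spectra, generator ↔ detector/marker recovery, counts ↔ selection rules),
not clinical validity: real signals contain photon noise, probe-pressure
and perfusion drifts, artefacts beyond the first minute, and rater
judgement that the 3-SD proxy cannot emulate. The published clinical
magnitudes (per-location TBF/RBV levels, Table-level relHI medians, the
observed 22.0-s lead) depend on undeposited patient data and are emulated
as study conditions, not reproduced as results.

## Numerical choices and problem sizes

Welch segments of 0.25 s balance variance against the 4 Hz resolution
floor; band moments use trapezoid integration with edge interpolation;
relHI frames use rectangle integration on the 10 Hz-resolution rfft grid.
Baseline SDs in onset marking are floored at 1e−4 to survive constant
synthetic baselines. Degenerate inputs (zero spectra, all-zero differences,
empty groups) return missing values or degenerate results rather than
raising, except where the contract demands an error. Test and validation
problem sizes — 60-s oracle scenes, a 1000-window randomized battery,
a 26-session / 52-event recovery cohort — were chosen as the smallest
sizes at which the checked statistics are stable.
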