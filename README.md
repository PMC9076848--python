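# microdls

Simulation and analysis of **dynamic-light-scattering (DLS) microcirculation
monitoring** in neonates. A miniaturized DLS skin sensor infers
microvascular blood motion from the temporal decorrelation of coherent
light scattered by moving red blood cells; this package implements both
sides of that instrument: a physics-grounded simulator of the raw detector
signal, and the processing pipeline that turns it into clinical channels
and event statistics.

It is aimed at researchers in physiological signal processing who need a
fully synthetic, ground-truthed testbed for microcirculatory event
analysis — no patient data are required or included.

## Model

The skin microvasculature is modelled as five shear-rate compartments
(band 1 = smallest vessels, highest shear ~2000 s⁻¹; band 5 = largest
vessels, ~10 s⁻¹). Compartment *k* contributes a complex
Ornstein–Uhlenbeck scattered field with power *N<sub>k</sub>* and corner
frequency *f<sub>k</sub> = κ·γ̇<sub>k</sub>*; heterodyne mixing with a
static tissue field *E<sub>s</sub>* makes the intensity PSD a weighted
Lorentzian mixture

$$S(f) = \sum_k \frac{4 E_s^2 N_k f_k}{\pi (f^2 + f_k^2)}.$$

From the spectrum over the 30–9000 Hz analysis band the extractor computes
(laser-Doppler moment conventions, band moments
$m_0=\int S\,df$, $m_1=\int f S\,df$):

| channel | definition | rate |
|---|---|---|
| TBF (total blood flow, AU) | $m_1$ | 1 Hz |
| RBV (relative blood velocity, Hz) | $m_1/m_0$ | 1 Hz |
| relHI 1–5 | band-wise $m_1$, normalized to sum to 1 | 100 Hz |
| DLS heart rate (bpm) | dominant 1.0–4.5 Hz modulation of the perfusion waveform | 1 Hz |

The event pipeline screens DLS-vs-ECG heart-rate agreement
(|Δ| ≤ max(10 %, 5 bpm)), selects a 240-s stable window (after discarding
the first 60 s) plus a 240-s window around each heart-rate deceleration
(≥ 30 bpm below the per-subject median), marks relHI-change and
desaturation onsets against a 3-SD baseline rule, and summarises lead
times, per-band AUC and stable-vs-event contrasts (Wilcoxon tests, paired
t-tests with Bonferroni threshold 0.005). A synthetic-cohort module
generates 31-subject, 130-session cohorts with known deceleration ground
truth. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from microdls import (sample_cohort, generate_session, analyze_bundle,
                      DecelSpec)

subject = sample_cohort(seed=1)[0]
event = DecelSpec(hr_onset=400.0, drop=42.0, duration=20.0,
                  relhi_lead=22.0, spo2_lag=9.0)
bundle = generate_session(subject, "forehead", seed=5, events=[event])
analysis = analyze_bundle(bundle)
for w in analysis.windows:
    print(f"window {w.kind}: [{w.start:.0f}, {w.end:.0f}) s")
det = analysis.events[0]
print(f"deceleration: onset {det.hr_onset:.0f} s, drop {det.drop:.1f} bpm")
m = analysis.marks[0]
print(f"relHI change lead {m.lead:.2f} s before HR onset; "
      f"SpO2 lag {m.spo2_lag:.1f} s; AUC band1 {m.auc[0]:.3f} AU*s")
print("stable relHI means:", np.round(analysis.stable_summary.band_mean, 3))
```

prints

```
window stable: [520, 760) s
window event: [280, 520) s
deceleration: onset 400 s, drop 41.1 bpm
relHI change lead 21.04 s before HR onset; SpO2 lag 10.0 s; AUC band1 2.301 AU*s
stable relHI means: [0.347 0.287 0.205 0.115 0.045]
```

The injected deceleration (onset 400 s, 42 bpm drop, relHI redistribution
starting 22 s earlier, desaturation 9 s later) is recovered from the
channels alone: the detector finds the onset at 400 s with a 41.1 bpm drop
(the 0.9 bpm difference is the sampling error of the session HR median),
the relHI change is marked 21.0 s before the onset, and the deceleration's
240-s analysis window pushes the stable window past itself to [520, 760) s.

A command-line pipeline wraps the same stages:

```sh
microdls simulate --out frames/ --seed 4            # synthetic cohort
microdls extract  --raw session.h5 --out channels/  # raw HDF5 -> channel CSVs
microdls analyze  --frames frames/ --out analysis/  # windows, events, marks
microdls report   --analysis analysis/ --out report/
```

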