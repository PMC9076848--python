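"""Synthetic cohort and session generator.

Real recordings from the study population are not publicly deposited, so
every pipeline stage is exercised against synthetic sessions whose event
structure mirrors the published cohort statistics:

* 1 Hz ECG heart rate around a per-infant median (cohort median 153 bpm),
  1 Hz SpO2 around 96 %;
* heart-rate decelerations: drops of at least 30 bpm below the per-infant
  median (median drop 42 bpm, observed range 30–111), preceded by a
  microvascular flow redistribution with a median lead of 22.0 s
  (IQR 13.5–27.0) and followed by a desaturation lagging the onset by a
  median of 9.0 s (IQR 5.0–15.3);
* 15-minute sessions per measurement location, with a movement artefact in
  the first 60 s after sensor placement (raw mode).

Two generation modes exist.  ``raw`` runs the full physics chain
(scene -> OU simulator -> channel extractor); ``frames`` emits the channel
frames directly from the closed-form Lorentzian band moments of the scene
state, which makes count-based pipeline tests exact and fast.

Lead and lag times are drawn through quantile-anchored samplers: monotone
piecewise-linear quantile functions pinned at the published quartiles, so
the generated median and IQR match the targets by construction.  (The
published lead quartiles are left-skewed — lower spread 8.5 s versus upper
spread 5 s — which no standard right-skewed positive family reproduces.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scene import (Compartment, DecelSpec, ShearBand, SceneTimeline, SimConfig,
                    build_scene_timeline, make_default_bands)
from .simulator import (RawDLSSignal, apply_movement_artifact,
                        lorentzian_band_moments, simulate_intensity)

__all__ = [
    "SubjectProfile",
    "CohortConfig",
    "SessionBundle",
    "sample_cohort",
    "sample_decel_events",
    "generate_physio_trace",
    "generate_session",
    "generate_cohort_sessions",
    "LOCATIONS",
]

LOCATIONS = ("forehead", "upper_extremity", "thorax", "abdomen", "lower_extremity")

# Location-specific compartment volume-fraction mixes (AU weights, bands 1..5).
# Weighted towards the low-shear compartments so the five relHIs spread over
# roughly 0.05-0.35 (the f-weighted Lorentzian tails put a floor under the
# high-frequency bands); the forehead total is scaled down so its TBF sits
# clearly below the other sites, and the lower extremity has a reduced
# band-4 share with a more separated profile.
_LOCATION_MIX = {
    "forehead": (0.032, 0.080, 0.44, 1.04, 2.08),
    "upper_extremity": (0.050, 0.120, 0.60, 1.40, 2.70),
    "thorax": (0.045, 0.110, 0.58, 1.35, 2.65),
    "abdomen": (0.050, 0.110, 0.62, 1.45, 2.60),
    "lower_extremity": (0.050, 0.120, 0.70, 0.80, 3.10),
}

# Quantile anchors (probability, value in s): quartiles are the published
# ones; the tail anchors extend them to plausible extremes.
_LEAD_ANCHORS = ((0.0, 4.0), (0.25, 13.5), (0.5, 22.0), (0.75, 27.0), (1.0, 45.0))
_LAG_ANCHORS = ((0.0, 1.0), (0.25, 5.0), (0.5, 9.0), (0.75, 15.3), (1.0, 35.0))

DROP_MEDIAN = 42.0  # bpm above the 30-bpm floor: 30 + lognormal(median 12)
DROP_MAX = 111.0
DROP_SIGMA = 0.8


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    ga_weeks: float
    hr_median: float
    locations: tuple[str, ...]
    pda: bool = False
    phototherapy: bool = False

    def __post_init__(self) -> None:
        if not (100 <= self.hr_median <= 200):
            raise ValueError("hr_median outside the plausible neonatal range")
        if not self.locations:
            raise ValueError("subject must have at least one location")


@dataclass
class CohortConfig:
    """Cohort sampling configuration; defaults mirror the published cohort."""

    n_subjects: int = 31
    availability: dict = field(default_factory=lambda: {
        "forehead": 31, "upper_extremity": 31, "thorax": 28,
        "abdomen": 12, "lower_extremity": 28,
    })
    hr_median_mean: float = 153.0
    hr_median_sd: float = 8.0
    hr_median_clip: tuple[float, float] = (130.0, 180.0)
    ga_range: tuple[float, float] = (28.0, 42.0)
    p_pda: float = 3 / 31
    p_phototherapy: float = 8 / 31
    # per-session event occurrence: Bernoulli(p) gives ~19 events over the
    # 130 preset sessions and >= 1 event for ~15/31 subjects
    p_event_per_session: float = 19 / 130
    events_per_session: int | None = None  # fixed count override
    session_duration: float = 900.0
    min_event_separation: float = 300.0
    event_edge_margin: float = 120.0


@dataclass
class SessionBundle:
    """One subject-location session with its ground truth."""

    subject: SubjectProfile
    location: str
    mode: str
    hemo: pd.DataFrame
    relhi: pd.DataFrame
    physio: pd.DataFrame
    truth: list[DecelSpec]
    cfg: SimConfig
    bands: list[ShearBand]
    timeline: SceneTimeline | None = None
    raw: RawDLSSignal | None = None


def sample_cohort(config: CohortConfig | None = None, seed: int = 0) -> list[SubjectProfile]:
    """Draw a cohort; deterministic under (config, seed)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    n = config.n_subjects
    for loc, avail in config.availability.items():
        if avail > n:
            raise ValueError(f"availability for {loc} exceeds cohort size")
    has_loc = {loc: set(rng.choice(n, size=avail, replace=False))
               for loc, avail in config.availability.items()}
    hr = np.clip(rng.normal(config.hr_median_mean, config.hr_median_sd, n),
                 *config.hr_median_clip)
    ga = rng.uniform(*config.ga_range, n)
    pda = rng.uniform(size=n) < config.p_pda
    photo = rng.uniform(size=n) < config.p_phototherapy
    cohort = []
    for i in range(n):
        locs = tuple(loc for loc in LOCATIONS if i in has_loc.get(loc, ()))
        cohort.append(SubjectProfile(
            subject_id=f"S{i + 1:03d}", ga_weeks=float(ga[i]),
            hr_median=float(hr[i]), locations=locs,
            pda=bool(pda[i]), phototherapy=bool(photo[i])))
    return cohort


def _sample_anchored(rng: np.random.Generator, anchors, size: int) -> np.ndarray:
    ps = np.array([p for p, _ in anchors])
    qs = np.array([q for _, q in anchors])
    return np.interp(rng.uniform(size=size), ps, qs)


def _sample_drop(rng: np.random.Generator, size: int) -> np.ndarray:
    out = np.empty(size)
    for i in range(size):
        d = np.inf
        while d > DROP_MAX:
            d = 30.0 + rng.lognormal(np.log(DROP_MEDIAN - 30.0), DROP_SIGMA)
        out[i] = d
    return out


def sample_decel_events(profile: SubjectProfile, config: CohortConfig | None = None,
                        seed: int = 0, duration: float | None = None) -> list[DecelSpec]:
    """Sample the deceleration schedule for one session.

    Events keep at least `event_edge_margin` from the session edges (so the
    surrounding 240-s analysis window always fits) and at least
    `min_event_separation` between onsets.  If placement is infeasible,
    fewer events are returned with a warning.
    """
    config = config or CohortConfig()
    duration = config.session_duration if duration is None else duration
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE7]))
    if config.events_per_session is not None:
        n_events = config.events_per_session
    else:
        n_events = int(rng.uniform() < config.p_event_per_session)
    if n_events == 0:
        return []
    lo = config.event_edge_margin
    hi = duration - config.event_edge_margin
    if hi <= lo:
        warnings.warn("session too short for any event window")
        return []
    onsets: list[float] = []
    tries = 0
    while len(onsets) < n_events and tries < 200 * n_events:
        cand = rng.uniform(lo, hi)
        if all(abs(cand - o) >= config.min_event_separation for o in onsets):
            onsets.append(cand)
        tries += 1
    if len(onsets) < n_events:
        warnings.warn("could not place all requested events; returning fewer")
    onsets.sort()
    m = len(onsets)
    drops = _sample_drop(rng, m)
    leads = _sample_anchored(rng, _LEAD_ANCHORS, m)
    lags = _sample_anchored(rng, _LAG_ANCHORS, m)
    durations = rng.uniform(10.0, 30.0, m)
    spo2_drops = np.clip(rng.normal(12.0, 3.0, m), 8.0, 20.0)
    return [DecelSpec(hr_onset=float(o), drop=float(d), duration=float(du),
                      relhi_lead=float(le), spo2_lag=float(la),
                      spo2_drop=float(sd))
            for o, d, du, le, la, sd in zip(onsets, drops, durations, leads, lags, spo2_drops)]


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float = 0.9) -> np.ndarray:
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i - 1]
    return x


def generate_physio_trace(profile: SubjectProfile, events: list[DecelSpec],
                          duration: float = 900.0, seed: int = 0,
                          hr_noise_sd: float = 3.0,
                          spo2_noise_sd: float = 1.5) -> pd.DataFrame:
    """1 Hz ECG heart rate and SpO2 with the events' deterministic signatures.

    The HR baseline is the subject's median plus AR(1) noise (sd 3 bpm,
    lag-1 correlation 0.9).  During an event the trace follows the lower
    envelope of the noisy baseline and a deterministic deceleration curve
    (5-s descent to hr_median - drop, hold, 10-s recovery), so the injected
    nadir is exact.  SpO2 dips by spo2_drop starting spo2_lag seconds after
    the HR onset (1.5-s descent, 20-s recovery).
    """
    n = int(round(duration))
    for a, b in zip(events, events[1:]):
        if b.hr_onset < a.hr_end + 10.0:
            raise ValueError("overlapping deceleration events")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1]))
    t = np.arange(n, dtype=float)
    hr = profile.hr_median + _ar1(rng, n, hr_noise_sd)
    spo2 = 96.0 + _ar1(rng, n, spo2_noise_sd)
    for ev in events:
        floor = profile.hr_median - ev.drop
        curve = np.full(n, np.inf)
        seg = (t >= ev.hr_onset) & (t < ev.hr_onset + 5.0)
        curve[seg] = profile.hr_median - ev.drop * (t[seg] - ev.hr_onset) / 5.0
        seg = (t >= ev.hr_onset + 5.0) & (t < ev.hr_end)
        curve[seg] = floor
        seg = (t >= ev.hr_end) & (t < ev.hr_end + 10.0)
        curve[seg] = floor + (profile.hr_median - floor) * (t[seg] - ev.hr_end) / 10.0
        hr = np.minimum(hr, curve)

        s_start = ev.hr_onset + ev.spo2_lag
        s_end = ev.hr_end + ev.spo2_lag
        dip = np.zeros(n)
        seg = (t >= s_start) & (t < s_start + 1.5)
        dip[seg] = ev.spo2_drop * (t[seg] - s_start) / 1.5
        seg = (t >= s_start + 1.5) & (t < s_end)
        dip[seg] = ev.spo2_drop
        seg = (t >= s_end) & (t < s_end + 20.0)
        dip[seg] = ev.spo2_drop * (1.0 - (t[seg] - s_end) / 20.0)
        spo2 = spo2 - dip
    hr = np.clip(hr, 40.0, 250.0)
    spo2 = np.clip(spo2, 40.0, 100.0)
    return pd.DataFrame({"t": t, "hr_ecg": hr, "spo2": spo2})


def _frames_channels(timeline: SceneTimeline, cfg: SimConfig,
                     bands: list[ShearBand], duration: float,
                     physio: pd.DataFrame, rng: np.random.Generator,
                     relhi_noise_rel: float = 0.01,
                     hemo_noise_rel: float = 0.01,
                     hr_dls_noise_sd: float = 0.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Oracle-exact channels from closed-form Lorentzian band moments."""
    e_static = cfg.static_field_gain * np.sqrt(
        float(np.mean(timeline.volume_fraction.sum(axis=1))))

    def band_m1(vf, sh, lo, hi):
        fc = cfg.kappa * sh
        C = 4.0 * e_static**2 * vf * fc / np.pi
        return (C / 2.0 * np.log((hi**2 + fc**2) / (lo**2 + fc**2))).sum(axis=1)

    # 1 Hz TBF / RBV at window midpoints
    n_sec = int(round(duration))
    t1 = np.arange(n_sec, dtype=float)
    vf, sh, _ = timeline.interpolate(t1 + 0.5)
    fc = cfg.kappa * sh
    C = 4.0 * e_static**2 * vf * fc / np.pi
    m1 = (C / 2.0 * np.log((cfg.f_analysis_hi**2 + fc**2)
                           / (cfg.f_analysis_lo**2 + fc**2))).sum(axis=1)
    m0 = (C / fc * (np.arctan(cfg.f_analysis_hi / fc)
                    - np.arctan(cfg.f_analysis_lo / fc))).sum(axis=1)
    tbf = m1 * (1.0 + hemo_noise_rel * rng.standard_normal(n_sec))
    rbv = np.where(m0 > 0, m1 / m0, np.nan)
    rbv = np.clip(rbv * (1.0 + hemo_noise_rel * rng.standard_normal(n_sec)),
                  cfg.f_analysis_lo, cfg.f_analysis_hi)
    hr_dls = physio["hr_ecg"].to_numpy()[:n_sec].astype(float)
    if hr_dls_noise_sd > 0:
        hr_dls = hr_dls + hr_dls_noise_sd * rng.standard_normal(n_sec)
    hemo = pd.DataFrame({"t": t1, "tbf": tbf, "rbv": rbv, "hr_dls": hr_dls})

    # 100 Hz relHIs
    n_rel = int(round((duration - 0.1) / 0.01)) + 1
    t100 = np.arange(n_rel) * 0.01
    vf, sh, _ = timeline.interpolate(t100)
    order = sorted(bands, key=lambda b: b.index)
    hi_vals = np.column_stack([band_m1(vf, sh, b.freq_lo, b.freq_hi) for b in order])
    if relhi_noise_rel > 0:
        noise = relhi_noise_rel * hi_vals.mean() * rng.standard_normal(hi_vals.shape)
        hi_vals = np.clip(hi_vals + noise, 0.0, None)
    total = hi_vals.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(total > 0, hi_vals / total, np.nan)
    relhi = pd.DataFrame({"t": t100} | {f"relhi{b.index}": rel[:, j]
                                        for j, b in enumerate(order)})
    return hemo, relhi


def generate_session(profile: SubjectProfile, location: str,
                     duration: float = 900.0, cfg: SimConfig | None = None,
                     seed: int = 0, mode: str = "frames",
                     events: list[DecelSpec] | None = None,
                     cohort_config: CohortConfig | None = None,
                     bands: list[ShearBand] | None = None,
                     relhi_noise_rel: float = 0.01,
                     hr_dls_noise_sd: float = 0.0) -> SessionBundle:
    """Generate one subject-location session.

    mode "raw" runs scene -> OU simulation (with a movement artefact over the
    first 60 s) -> extractor; mode "frames" emits channels from the analytic
    band moments with hr_dls = hr_ecg (plus optional noise).  The injected
    DecelSpecs are returned as ground truth.
    """
    if location not in profile.locations:
        raise ValueError(f"subject {profile.subject_id} has no {location} session")
    if mode not in ("raw", "frames"):
        raise ValueError("mode must be 'raw' or 'frames'")
    cfg = cfg or SimConfig()
    bands = bands or make_default_bands(kappa=cfg.kappa, f_clip_hi=cfg.f_analysis_hi)
    if events is None:
        events = sample_decel_events(profile, cohort_config, seed=seed, duration=duration)
    physio = generate_physio_trace(profile, events, duration, seed=seed)

    mix = _LOCATION_MIX[location]
    comps = [Compartment(band_index=b.index, volume_fraction=mix[b.index - 1],
                         mean_shear=float(np.sqrt(b.shear_lo * b.shear_hi)))
             for b in sorted(bands, key=lambda b: b.index)]
    timeline = build_scene_timeline(comps, physio["hr_ecg"].to_numpy(), events,
                                    duration, cfg, bands=bands)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA5]))
    if mode == "frames":
        hemo, relhi = _frames_channels(timeline, cfg, bands, duration, physio, rng,
                                       relhi_noise_rel=relhi_noise_rel,
                                       hr_dls_noise_sd=hr_dls_noise_sd)
        raw = None
    else:
        from .extractor import extract_channels

        sim_cfg = cfg if cfg.seed is not None else SimConfig(
            **{**cfg.__dict__, "seed": int(rng.integers(2**31))})
        raw = simulate_intensity(timeline, sim_cfg)
        raw = apply_movement_artifact(raw, [(0.0, min(60.0, duration))],
                                      seed=int(rng.integers(2**31)))
        hemo, relhi = extract_channels(raw, sim_cfg, bands)
    return SessionBundle(subject=profile, location=location, mode=mode,
                         hemo=hemo, relhi=relhi, physio=physio,
                         truth=list(events), cfg=cfg, bands=bands,
                         timeline=timeline, raw=raw)


def generate_cohort_sessions(config: CohortConfig | None = None, seed: int = 0,
                             mode: str = "frames",
                             cfg: SimConfig | None = None,
                             no_events: bool = False,
                             relhi_noise_rel: float = 0.01):
    """Yield SessionBundles for every subject-location pair in the cohort."""
    config = config or CohortConfig()
    cohort = sample_cohort(config, seed=seed)
    for i, subject in enumerate(cohort):
        for j, location in enumerate(subject.locations):
            s = int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0] % (2**31))
            events = [] if no_events else None
            yield generate_session(subject, location,
                                   duration=config.session_duration, cfg=cfg,
                                   seed=s, mode=mode, events=events,
                                   cohort_config=config,
                                   relhi_noise_rel=relhi_noise_rel)
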