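"""Shear-rate-stratified microvascular scene construction.

The microcirculation is modelled as a small number of shear-rate compartments
("bands"): band 1 collects the smallest, highest-shear arterial vessels
(shear up to ~2000 1/s) and the last band the largest, lowest-shear venous
vessels (~10 1/s).  Each compartment contributes scattered light whose
spectral half-width is proportional to its shear rate, so a shear band maps
linearly onto a spectral band through the proportionality ``kappa`` (Hz·s).

A :class:`SceneTimeline` holds the time-varying state of every compartment
(volume fraction, i.e. number-of-scatterers weight, and mean shear) sampled on
a regular control grid, together with the integrated cardiac phase used for
pulsatile modulation.  Timelines are what the raw-signal simulator and the
oracle-exact channel generator both consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ShearBand",
    "Compartment",
    "SimConfig",
    "SceneTimeline",
    "DecelSpec",
    "make_default_bands",
    "shear_to_corner_freq",
    "build_scene_timeline",
    "scene_to_yaml",
    "scene_from_yaml",
]


@dataclass(frozen=True)
class ShearBand:
    """One shear-rate compartment boundary set.

    ``index`` runs 1..n with 1 = smallest vessels = highest shear, matching
    the inverse relation between vessel diameter and wall shear rate.
    Frequency edges are the shear edges scaled by ``kappa`` and clipped to
    the analysis band.
    """

    index: int
    shear_lo: float
    shear_hi: float
    freq_lo: float
    freq_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.shear_lo < self.shear_hi):
            raise ValueError(f"band {self.index}: need 0 <= shear_lo < shear_hi")
        if not (0 <= self.freq_lo < self.freq_hi):
            raise ValueError(f"band {self.index}: need 0 <= freq_lo < freq_hi")


@dataclass(frozen=True)
class Compartment:
    """A population of scatterers inside one shear band."""

    band_index: int
    volume_fraction: float
    mean_shear: float

    def __post_init__(self) -> None:
        if self.volume_fraction < 0:
            raise ValueError("volume_fraction must be >= 0")
        if self.mean_shear < 0:
            raise ValueError("mean_shear must be >= 0")


@dataclass
class SimConfig:
    """Simulator / extractor configuration.

    kappa : Hz·s
        Proportionality between shear rate and the Lorentzian corner
        (half-width) frequency of a compartment's field correlation.
    f_analysis_lo, f_analysis_hi : Hz
        Spectral analysis band; the upper edge is the device's printed
        0–9000 Hz range, the lower edge excludes the DC/pulsatile baseline.
    fs_raw : Hz
        Raw detector sampling rate; must satisfy Nyquist for the analysis band.
    static_field_gain : dimensionless
        Strength of the static (tissue) field relative to sqrt(total
        scatterer weight); >= 10 keeps detection in the heterodyne regime.
    """

    kappa: float = 3.0
    f_analysis_lo: float = 30.0
    f_analysis_hi: float = 9000.0
    fs_raw: float = 20000.0
    static_field_gain: float = 10.0
    noise_sd: float = 0.0
    seed: int | None = None
    m_v: float = 0.10  # pulsatile modulation depth of mean shear
    m_n: float = 0.05  # pulsatile modulation depth of volume fraction
    control_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.fs_raw < 2 * self.f_analysis_hi:
            raise ValueError(
                f"fs_raw={self.fs_raw} violates Nyquist for f_analysis_hi={self.f_analysis_hi}"
            )
        if not (0 <= self.f_analysis_lo < self.f_analysis_hi):
            raise ValueError("need 0 <= f_analysis_lo < f_analysis_hi")


def shear_to_corner_freq(shear: float | np.ndarray, kappa: float) -> float | np.ndarray:
    """Map a shear rate (1/s) to the Lorentzian corner frequency kappa * shear (Hz)."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if np.any(np.asarray(shear) < 0):
        raise ValueError("shear must be non-negative")
    return kappa * shear


def make_default_bands(
    n_bands: int = 5,
    shear_lo: float = 10.0,
    shear_hi: float = 2000.0,
    kappa: float = 3.0,
    f_clip_lo: float = 0.0,
    f_clip_hi: float = 9000.0,
) -> list[ShearBand]:
    """Log-spaced shear bands covering [shear_lo, shear_hi].

    Band 1 is the highest-shear (smallest-vessel) band.  Frequency edges are
    ``kappa`` times the shear edges, clipped to [f_clip_lo, f_clip_hi].
    """
    if n_bands < 2:
        raise ValueError("need at least 2 bands")
    if not (0 < shear_lo < shear_hi):
        raise ValueError("need 0 < shear_lo < shear_hi")
    edges = np.geomspace(shear_lo, shear_hi, n_bands + 1)
    bands = []
    for i in range(n_bands):
        # band index 1 corresponds to the top shear interval
        idx = n_bands - i
        lo, hi = edges[i], edges[i + 1]
        f_lo = float(np.clip(shear_to_corner_freq(lo, kappa), f_clip_lo, f_clip_hi))
        f_hi = float(np.clip(shear_to_corner_freq(hi, kappa), f_clip_lo, f_clip_hi))
        bands.append(ShearBand(index=idx, shear_lo=float(lo), shear_hi=float(hi),
                               freq_lo=f_lo, freq_hi=f_hi))
    bands.sort(key=lambda b: b.index)
    return bands


@dataclass
class DecelSpec:
    """Ground-truth description of one injected heart-rate deceleration.

    The microvascular redistribution starts ``relhi_lead`` seconds before the
    heart-rate onset; the desaturation starts ``spo2_lag`` seconds after it.
    ``redistribution`` holds multiplicative factors applied to the five
    compartment volume fractions during the event.
    """

    hr_onset: float
    drop: float
    duration: float
    relhi_lead: float
    spo2_lag: float
    spo2_drop: float = 8.0
    redistribution: tuple[float, ...] = (6.0, 2.0, 0.5, 0.15, 2.5)

    def __post_init__(self) -> None:
        if self.drop < 30:
            raise ValueError("a deceleration is defined by a drop >= 30 bpm")
        if self.relhi_lead < 0:
            raise ValueError("relhi_lead must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if any(f < 0 for f in self.redistribution):
            raise ValueError("redistribution factors must be >= 0")

    @property
    def hr_end(self) -> float:
        return self.hr_onset + self.duration


@dataclass
class SceneTimeline:
    """Per-compartment state sampled on a regular control grid.

    Attributes
    ----------
    t : (n,) seconds, strictly increasing, spacing 1/control_rate
    volume_fraction : (n, K)
    mean_shear : (n, K) 1/s
    phase : (n,) cardiac phase in cycles, non-decreasing, dphi/dt = HR/60
    """

    t: np.ndarray
    volume_fraction: np.ndarray
    mean_shear: np.ndarray
    phase: np.ndarray
    control_rate: float
    bands: list[ShearBand] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timeline timestamps must be strictly increasing")
        if np.any(self.volume_fraction < 0):
            raise ValueError("volume fractions must be non-negative")
        if np.any(np.diff(self.phase) < 0):
            raise ValueError("cardiac phase must be non-decreasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def n_compartments(self) -> int:
        return self.volume_fraction.shape[1]

    def interpolate(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Piecewise-linear state (volume_fraction, mean_shear, phase) at times t."""
        t = np.asarray(t, dtype=float)
        K = self.n_compartments
        vf = np.empty((t.size, K))
        sh = np.empty((t.size, K))
        for k in range(K):
            vf[:, k] = np.interp(t, self.t, self.volume_fraction[:, k])
            sh[:, k] = np.interp(t, self.t, self.mean_shear[:, k])
        ph = np.interp(t, self.t, self.phase)
        return vf, sh, ph


def _ramp_profile(t: np.ndarray, start: float, end: float,
                  attack: float, release: float) -> np.ndarray:
    """0->1 linear attack at `start`, hold, 1->0 linear release after `end`."""
    r = np.zeros_like(t)
    up = (t >= start) & (t < start + attack)
    r[up] = (t[up] - start) / attack
    hold = (t >= start + attack) & (t < end)
    r[hold] = 1.0
    down = (t >= end) & (t < end + release)
    r[down] = 1.0 - (t[down] - end) / release
    return r


def build_scene_timeline(
    compartments: Sequence[Compartment],
    hr_trace: np.ndarray,
    events: Sequence[DecelSpec],
    duration: float,
    cfg: SimConfig,
    bands: Sequence[ShearBand] | None = None,
    attack: float = 5.0,
    release: float = 10.0,
) -> SceneTimeline:
    """Build the control-rate timeline driving a session.

    ``hr_trace`` is the 1 Hz heart-rate series (bpm) starting at t=0; the
    cardiac phase is its time integral / 60.  During each event the
    compartment volume fractions ramp linearly (over ``attack`` seconds,
    beginning ``relhi_lead`` seconds before the heart-rate onset) towards the
    event's redistribution vector, and ramp back over ``release`` seconds
    after the event ends.  Pulsatile modulation multiplies mean shear by
    (1 + m_v sin(2 pi phase)) and volume fraction by (1 + m_n sin(2 pi phase)).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    hr_trace = np.asarray(hr_trace, dtype=float)
    if hr_trace.size < int(np.ceil(duration)) + 1:
        # extend by holding the last value so interp covers [0, duration]
        pad = int(np.ceil(duration)) + 1 - hr_trace.size
        if pad > hr_trace.size:
            raise ValueError("hr_trace must cover the session duration")
        hr_trace = np.concatenate([hr_trace, np.full(pad, hr_trace[-1])])
    for ev in events:
        if not (0 <= ev.hr_onset <= duration and ev.hr_end <= duration):
            raise ValueError(f"event at {ev.hr_onset}s lies outside the session")

    K = len(compartments)
    n = int(round(duration * cfg.control_rate)) + 1
    t = np.arange(n) / cfg.control_rate

    base_vf = np.array([c.volume_fraction for c in compartments], dtype=float)
    base_sh = np.array([c.mean_shear for c in compartments], dtype=float)

    vf = np.tile(base_vf, (n, 1))
    for ev in events:
        factors = np.asarray(ev.redistribution, dtype=float)
        if factors.size != K:
            raise ValueError("redistribution vector length must match compartments")
        target = base_vf * factors
        if target.sum() <= 0:
            raise ValueError("redistribution annihilates all volume fractions")
        r = _ramp_profile(t, ev.hr_onset - ev.relhi_lead, ev.hr_end, attack, release)
        vf += np.outer(r, target - base_vf)
    if np.any(vf < 0):
        raise ValueError("negative volume fraction after redistribution")

    # cardiac phase: trapezoid integral of HR/60 over the control grid
    hr_t = np.arange(hr_trace.size, dtype=float)
    hr_c = np.interp(t, hr_t, hr_trace)
    dt = 1.0 / cfg.control_rate
    phase = np.concatenate([[0.0], np.cumsum((hr_c[1:] + hr_c[:-1]) / 2 / 60.0 * dt)])

    mod = np.sin(2 * np.pi * phase)
    sh = np.tile(base_sh, (n, 1)) * (1.0 + cfg.m_v * mod)[:, None]
    vf = vf * (1.0 + cfg.m_n * mod)[:, None]

    return SceneTimeline(t=t, volume_fraction=vf, mean_shear=sh, phase=phase,
                         control_rate=cfg.control_rate,
                         bands=list(bands) if bands is not None else [])


# ---------------------------------------------------------------------------
# YAML serialization


def scene_to_yaml(bands: Sequence[ShearBand], compartments: Sequence[Compartment],
                  cfg: SimConfig) -> str:
    """Serialize bands, compartments and config to the documented YAML schema."""
    doc = {
        "bands": [asdict(b) for b in bands],
        "compartments": [asdict(c) for c in compartments],
        "kappa": cfg.kappa,
        "fs_raw": cfg.fs_raw,
        "analysis_band": [cfg.f_analysis_lo, cfg.f_analysis_hi],
        "static_field_gain": cfg.static_field_gain,
        "noise_sd": cfg.noise_sd,
        "modulation": {"m_v": cfg.m_v, "m_n": cfg.m_n},
        "control_rate": cfg.control_rate,
        "seed": cfg.seed,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def scene_from_yaml(text: str) -> tuple[list[ShearBand], list[Compartment], SimConfig]:
    doc = yaml.safe_load(text)
    bands = [ShearBand(**b) for b in doc["bands"]]
    comps = [Compartment(**c) for c in doc["compartments"]]
    cfg = SimConfig(
        kappa=doc["kappa"],
        f_analysis_lo=doc["analysis_band"][0],
        f_analysis_hi=doc["analysis_band"][1],
        fs_raw=doc["fs_raw"],
        static_field_gain=doc.get("static_field_gain", 10.0),
        noise_sd=doc.get("noise_sd", 0.0),
        seed=doc.get("seed"),
        m_v=doc.get("modulation", {}).get("m_v", 0.10),
        m_n=doc.get("modulation", {}).get("m_n", 0.05),
        control_rate=doc.get("control_rate", 100.0),
    )
    return bands, comps, cfg
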