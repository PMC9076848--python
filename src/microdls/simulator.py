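"""Raw DLS detector-signal synthesis.

Each shear compartment contributes a complex scattered field modelled as a
complex Ornstein–Uhlenbeck (OU) process: stationary variance equal to the
compartment's volume fraction N_k (number-of-scatterers weight) and field
autocorrelation exp(-2 pi f_k |tau|), where f_k = kappa * mean_shear_k is
the Lorentzian corner frequency.  Detection is heterodyne: a strong static
field E_s scattered from immobile tissue mixes with the fluctuating blood
field, so the dominant AC term of the intensity

    I(t) = | E_s + sum_k E_k(t) |^2 + eta(t)

is 2 E_s Re(sum_k E_k), whose one-sided power spectral density is the
weighted Lorentzian mixture

    S(f) = sum_k 4 E_s^2 N_k f_k / (pi (f^2 + f_k^2)).

`theoretical_psd` and the closed-form band moments below serve as the
analytic oracle for the channel extractor; `simulate_intensity` produces the
sampled signal with an exact OU discretization (time-varying coefficients
follow the scene timeline sample by sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .scene import SceneTimeline, SimConfig

__all__ = [
    "RawDLSSignal",
    "SpectralEstimate",
    "simulate_intensity",
    "theoretical_psd",
    "lorentzian_band_moments",
    "apply_movement_artifact",
    "save_raw_hdf5",
    "load_raw_hdf5",
]

_CHUNK = 1 << 20  # samples per simulation chunk (bounds memory)


@dataclass
class RawDLSSignal:
    """Uniformly sampled detector intensity (arbitrary units, >= 0)."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class SpectralEstimate:
    """One-sided power spectral density on a frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray
    window_length: float = 0.0
    n_segments: int = 0


@njit(cache=True)
def _ou_scan(a, s, zr, zi, state_r, state_i, out_r, out_i):  # pragma: no cover
    """Exact AR(1) scan with per-sample coefficients, summed over compartments."""
    n, K = a.shape
    for i in range(n):
        tr = 0.0
        ti = 0.0
        for k in range(K):
            state_r[k] = a[i, k] * state_r[k] + s[i, k] * zr[i, k]
            state_i[k] = a[i, k] * state_i[k] + s[i, k] * zi[i, k]
            tr += state_r[k]
            ti += state_i[k]
        out_r[i] = tr
        out_i[i] = ti


def simulate_intensity(timeline: SceneTimeline, cfg: SimConfig,
                       duration: float | None = None) -> RawDLSSignal:
    """Synthesize the detector intensity for a scene timeline.

    The OU update per sample is exact: E <- a E + sqrt(N (1 - a^2)) z with
    a = exp(-2 pi f_k / fs) and z circular complex standard normal, so no
    discretization error accumulates regardless of fs.  The static field is
    E_s = static_field_gain * sqrt(mean total volume fraction), real and
    constant.  White Gaussian detector noise (sd = noise_sd) is added and
    the intensity clipped at zero.
    """
    if cfg.seed is None:
        raise ValueError("cfg.seed must be set: raw simulation is a reproducibility contract")
    if cfg.fs_raw < 2 * cfg.f_analysis_hi:
        raise ValueError("fs_raw below Nyquist for the analysis band")
    if duration is None:
        duration = timeline.duration
    if duration > timeline.duration + 1e-9:
        raise ValueError("timeline does not cover the requested duration")

    fs = cfg.fs_raw
    n = int(round(duration * fs))
    K = timeline.n_compartments
    rng = np.random.default_rng(cfg.seed)

    total_n = float(np.mean(timeline.volume_fraction.sum(axis=1)))
    e_static = cfg.static_field_gain * np.sqrt(total_n)

    # stationary initialization at the first state
    vf0, sh0, _ = timeline.interpolate(np.array([0.0]))
    state_r = rng.standard_normal(K) * np.sqrt(vf0[0] / 2.0)
    state_i = rng.standard_normal(K) * np.sqrt(vf0[0] / 2.0)

    intensity = np.empty(n, dtype=np.float64)
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        m = stop - start
        tt = (np.arange(start, stop) + 1) / fs
        vf, sh, _ = timeline.interpolate(tt)
        f_k = cfg.kappa * sh
        a = np.exp(-2.0 * np.pi * f_k / fs)
        s = np.sqrt(np.maximum(vf, 0.0) / 2.0 * (1.0 - a * a))
        zr = rng.standard_normal((m, K))
        zi = rng.standard_normal((m, K))
        out_r = np.empty(m)
        out_i = np.empty(m)
        _ou_scan(a, s, zr, zi, state_r, state_i, out_r, out_i)
        chunk = (e_static + out_r) ** 2 + out_i**2
        if cfg.noise_sd > 0:
            chunk += cfg.noise_sd * rng.standard_normal(m)
        intensity[start:stop] = chunk
    np.clip(intensity, 0.0, None, out=intensity)
    return RawDLSSignal(samples=intensity, fs=fs, seed=cfg.seed,
                        meta={"e_static": e_static, "n_compartments": K})


def theoretical_psd(volume_fractions: np.ndarray, corner_freqs: np.ndarray,
                    cfg: SimConfig, n_grid: int = 4096,
                    f_max: float | None = None,
                    sampled: bool = False) -> SpectralEstimate:
    """Closed-form one-sided PSD of the heterodyne term 2 E_s Re(sum E_k).

    With ``sampled=False`` (default) this is the continuous-time Lorentzian
    mixture S(f) = sum_k 4 E_s^2 N_k f_k / (pi (f^2 + f_k^2)); integrating
    over [0, inf) returns the AC variance 2 E_s^2 sum_k N_k.

    With ``sampled=True`` it is the exact spectrum of the discretely sampled
    heterodyne term — the AR(1) spectrum

        S(f) = sum_k 4 E_s^2 N_k (1 - a_k^2) / (fs (1 - 2 a_k cos(2 pi f/fs) + a_k^2)),
        a_k = exp(-2 pi f_k / fs),

    which equals the Lorentzian folded across all Nyquist images and is the
    ground truth for spectra estimated from simulated samples (a detector
    sampling without an anti-alias filter sees exactly this fold-back).
    """
    vf = np.asarray(volume_fractions, dtype=float)
    fc = np.asarray(corner_freqs, dtype=float)
    if np.any(vf < 0):
        raise ValueError("volume fractions must be non-negative")
    if np.any(fc <= 0):
        raise ValueError("corner frequencies must be positive")
    e_static = cfg.static_field_gain * np.sqrt(vf.sum())
    if f_max is None:
        f_max = cfg.fs_raw / 2
    f = np.linspace(0.0, f_max, n_grid)
    S = np.zeros_like(f)
    if sampled:
        fs = cfg.fs_raw
        w = 2.0 * np.pi * f / fs
        for N_k, f_k in zip(vf, fc):
            a = np.exp(-2.0 * np.pi * f_k / fs)
            S += 4.0 * e_static**2 * N_k * (1.0 - a * a) / (
                fs * (1.0 - 2.0 * a * np.cos(w) + a * a))
    else:
        for N_k, f_k in zip(vf, fc):
            S += 4.0 * e_static**2 * N_k * f_k / (np.pi * (f**2 + f_k**2))
    return SpectralEstimate(frequencies=f, power=S)


def lorentzian_band_moments(N: float, f_c: float, f_lo: float, f_hi: float,
                            e_static: float = 1.0) -> tuple[float, float]:
    """Exact band moments (m0, m1) of one heterodyne Lorentzian component.

    For S(f) = C / (f^2 + f_c^2) with C = 4 e_static^2 N f_c / pi:
        m0 = (C / f_c) (atan(f_hi/f_c) - atan(f_lo/f_c))
        m1 = (C / 2) ln((f_hi^2 + f_c^2) / (f_lo^2 + f_c^2))
    """
    if f_c <= 0:
        raise ValueError("corner frequency must be positive")
    C = 4.0 * e_static**2 * N * f_c / np.pi
    m0 = C / f_c * (np.arctan(f_hi / f_c) - np.arctan(f_lo / f_c))
    m1 = C / 2.0 * np.log((f_hi**2 + f_c**2) / (f_lo**2 + f_c**2))
    return float(m0), float(m1)


def apply_movement_artifact(raw: RawDLSSignal,
                            schedule: list[tuple[float, float]],
                            seed: int | None = None,
                            depth: float = 0.5,
                            f_lo: float = 0.1,
                            f_hi: float = 5.0) -> RawDLSSignal:
    """Multiply the intensity by a random low-frequency gain inside intervals.

    The gain is 1 + depth * band-limited (f_lo..f_hi) unit-variance noise,
    clipped so intensity stays non-negative.  Overlapping intervals are
    merged (with a warning); intervals must lie within the signal.
    """
    import warnings
    from scipy import signal as sps

    if not schedule:
        return RawDLSSignal(samples=raw.samples.copy(), fs=raw.fs, t0=raw.t0,
                            seed=raw.seed, meta=dict(raw.meta))
    ivs = sorted((float(a), float(b)) for a, b in schedule)
    for a, b in ivs:
        if b <= a:
            raise ValueError("artifact interval has non-positive duration")
        if a < raw.t0 - 1e-9 or b > raw.t0 + raw.duration + 1e-9:
            raise ValueError("artifact interval outside signal span")
    merged = [list(ivs[0])]
    overlap = False
    for a, b in ivs[1:]:
        if a < merged[-1][1]:
            overlap = True
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    if overlap:
        warnings.warn("overlapping artifact intervals merged")

    rng = np.random.default_rng(raw.seed if seed is None else seed)
    out = raw.samples.copy()
    sos = sps.butter(2, [f_lo, f_hi], btype="band", fs=raw.fs, output="sos")
    for a, b in merged:
        i0 = int(round((a - raw.t0) * raw.fs))
        i1 = int(round((b - raw.t0) * raw.fs))
        noise = sps.sosfilt(sos, rng.standard_normal(i1 - i0))
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
        gain = np.clip(1.0 + depth * noise, 0.0, None)
        out[i0:i1] *= gain
    return RawDLSSignal(samples=out, fs=raw.fs, t0=raw.t0, seed=raw.seed,
                        meta={**raw.meta, "artifact_intervals": merged})


# ---------------------------------------------------------------------------
# HDF5 container: /dls/intensity with fs, t0, seed attributes


def save_raw_hdf5(path, raw: RawDLSSignal, config_hash: str = "") -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("dls/intensity", data=raw.samples.astype(np.float32))
        ds.attrs["fs"] = raw.fs
        ds.attrs["t0"] = raw.t0
        ds.attrs["seed"] = -1 if raw.seed is None else raw.seed
        ds.attrs["config_hash"] = config_hash


def load_raw_hdf5(path) -> RawDLSSignal:
    import h5py

    with h5py.File(path, "r") as h5:
        ds = h5["dls/intensity"]
        seed = int(ds.attrs["seed"])
        return RawDLSSignal(
            samples=np.asarray(ds[...], dtype=np.float64),
            fs=float(ds.attrs["fs"]),
            t0=float(ds.attrs["t0"]),
            seed=None if seed < 0 else seed,
            meta={"config_hash": str(ds.attrs.get("config_hash", ""))},
        )
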