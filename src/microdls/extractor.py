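"""Device-side channel extraction from raw DLS intensity.

Reproduces the monitor's output channels from the sampled detector signal:

* **TBF** (total blood flow, AU) — the first spectral moment of the intensity
  PSD over the analysis band.  In the laser-Doppler convention the first
  moment is proportional to (number of moving scatterers) x (characteristic
  velocity), i.e. perfusion.
* **RBV** (relative blood velocity, Hz) — the normalized first moment
  m1/m0, a mean spectral frequency that tracks scatterer velocity and is
  invariant to the number of scatterers.  Bounded by the analysis band, whose
  upper edge is the device's printed ~9000 Hz limit.
* **relHI 1..5** — band-wise first moments over the five shear-band
  frequency intervals, normalized to sum to one: the relative contribution
  of each vessel-size class's flow to total flow.  Index 1 = smallest
  vessels = highest frequency band.
* **DLS heart rate** — dominant frequency (1.0–4.5 Hz) of the pulsatile
  perfusion waveform, reported in bpm on a 1 Hz grid.

TBF/RBV/HR are logged at 1 Hz from non-overlapping 1-s windows; relHIs at
100 Hz from 100-ms windows sliding in 10-ms hops.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .scene import ShearBand, SimConfig
from .simulator import RawDLSSignal, SpectralEstimate

__all__ = [
    "estimate_psd",
    "compute_moments",
    "compute_tbf",
    "compute_rbv",
    "compute_relhi",
    "estimate_dls_hr",
    "extract_channels",
    "write_hemo_csv",
    "write_relhi_csv",
    "read_hemo_csv",
    "read_relhi_csv",
]

# relHI / HR framing constants (seconds)
RELHI_WINDOW = 0.10
RELHI_HOP = 0.01
HR_WINDOW = 0.2
HR_HOP = 0.04
HR_BLOCK = 10.0
HR_BAND = (1.0, 4.5)


class SpectralMoments(tuple):
    """(m0, m1) band moments of a one-sided PSD."""

    __slots__ = ()

    def __new__(cls, m0: float, m1: float):
        return super().__new__(cls, (float(m0), float(m1)))

    @property
    def m0(self) -> float:
        return self[0]

    @property
    def m1(self) -> float:
        return self[1]


def estimate_psd(samples: np.ndarray, fs: float, window_length: float = 0.25,
                 overlap: float = 0.5) -> SpectralEstimate:
    """Mean-removed Welch PSD (Hann taper, one-sided density).

    Scaling is Parseval-consistent: the integral of the density over
    frequency approximates the signal variance.
    """
    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    nperseg = int(round(window_length * fs))
    step = max(1, int(round(nperseg * (1.0 - overlap))))
    if x.size < nperseg + step:
        raise ValueError("window too short: need at least 2 Welch segments")
    f, S = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg - step, detrend="constant",
                     return_onesided=True, scaling="density")
    n_segments = 1 + (x.size - nperseg) // step
    return SpectralEstimate(frequencies=f, power=S,
                            window_length=window_length, n_segments=n_segments)


def compute_moments(psd: SpectralEstimate, f_lo: float, f_hi: float) -> SpectralMoments:
    """Band moments m0 = int S df and m1 = int f S df by trapezoid.

    The band edges are interpolated onto the estimate grid so results vary
    smoothly with (f_lo, f_hi).
    """
    if f_lo >= f_hi:
        raise ValueError("empty frequency band")
    f = np.asarray(psd.frequencies, dtype=float)
    S = np.asarray(psd.power, dtype=float)
    lo = max(f_lo, f[0])
    hi = min(f_hi, f[-1])
    if lo >= hi:
        raise ValueError("band does not intersect the PSD grid")
    inside = (f > lo) & (f < hi)
    fb = np.concatenate([[lo], f[inside], [hi]])
    Sb = np.concatenate([[np.interp(lo, f, S)], S[inside], [np.interp(hi, f, S)]])
    m0 = np.trapezoid(Sb, fb)
    m1 = np.trapezoid(fb * Sb, fb)
    return SpectralMoments(m0, m1)


def compute_tbf(psd: SpectralEstimate, cfg: SimConfig, gain: float = 1.0) -> float:
    """Total blood flow: gain x first spectral moment over the analysis band."""
    return gain * compute_moments(psd, cfg.f_analysis_lo, cfg.f_analysis_hi).m1


def compute_rbv(psd: SpectralEstimate, cfg: SimConfig) -> float:
    """Relative blood velocity: m1/m0 (Hz); NaN when the band holds no power."""
    m0, m1 = compute_moments(psd, cfg.f_analysis_lo, cfg.f_analysis_hi)
    if m0 <= 0:
        return float("nan")
    return m1 / m0


def _validate_bands(bands: Sequence[ShearBand]) -> list[ShearBand]:
    ordered = sorted(bands, key=lambda b: b.freq_lo)
    for a, b in zip(ordered, ordered[1:]):
        if b.freq_lo < a.freq_hi - 1e-9:
            raise ValueError(f"bands {a.index} and {b.index} overlap in frequency")
    return list(bands)


def compute_relhi(psd: SpectralEstimate, bands: Sequence[ShearBand]) -> np.ndarray:
    """Relative haemodynamic indices: band first moments normalized to 1.

    Returned in band-index order (index 1 first).  All-NaN when total band
    flow is zero.
    """
    bands = _validate_bands(bands)
    order = sorted(bands, key=lambda b: b.index)
    hi_vals = np.array([compute_moments(psd, b.freq_lo, b.freq_hi).m1 for b in order])
    total = hi_vals.sum()
    if total <= 0:
        return np.full(len(order), np.nan)
    return hi_vals / total


def _frame_band_m1(x: np.ndarray, fs: float, window: float, hop: float,
                   weights: np.ndarray, nperseg: int,
                   batch: int = 4096) -> np.ndarray:
    """Per-frame band-weighted first moments via batched windowed periodograms.

    `weights` has shape (n_rfft_bins, n_bands); each column integrates
    f * S(f) over one band (rectangle rule, density scaling).
    """
    step = int(round(hop * fs))
    n_frames = (x.size - nperseg) // step + 1
    if n_frames < 1:
        raise ValueError("signal shorter than one frame")
    taper = sps.get_window("hann", nperseg)
    # density scaling for a tapered periodogram
    scale = 2.0 / (fs * (taper**2).sum())
    out = np.empty((n_frames, weights.shape[1]))
    for start in range(0, n_frames, batch):
        stop = min(start + batch, n_frames)
        idx = (np.arange(start, stop) * step)[:, None] + np.arange(nperseg)[None, :]
        frames = x[idx]
        frames = (frames - frames.mean(axis=1, keepdims=True)) * taper
        spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2 * scale
        spec[:, 0] /= 2.0
        if nperseg % 2 == 0:
            spec[:, -1] /= 2.0
        out[start:stop] = spec @ weights
    return out


def _band_weight_matrix(freqs: np.ndarray, intervals: list[tuple[float, float]],
                        df: float) -> np.ndarray:
    """Columns integrate f*S over [lo, hi) on a uniform rfft grid."""
    W = np.zeros((freqs.size, len(intervals)))
    for j, (lo, hi) in enumerate(intervals):
        sel = (freqs >= lo) & (freqs < hi)
        W[sel, j] = freqs[sel] * df
    return W


def estimate_dls_hr(raw: RawDLSSignal, cfg: SimConfig,
                    peak_ratio_min: float = 10.0) -> pd.Series:
    """DLS heart rate (bpm) on the integer-second grid.

    The pulsatile perfusion waveform is the band first moment m1 computed on
    0.2-s windows hopping every 0.04 s (25 Hz).  Each second, the dominant
    frequency of the mean-removed waveform over the trailing 10-s block is
    located in 1.0–4.5 Hz by zero-padded FFT with parabolic peak refinement.
    Seconds before the first full block, or blocks whose spectral peak is not
    prominent (peak/median power < `peak_ratio_min`), are reported missing.
    """
    if raw.duration < HR_BLOCK:
        raise ValueError("need at least 10 s of signal for HR estimation")
    fs = raw.fs
    nperseg = int(round(HR_WINDOW * fs))
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    df = fs / nperseg
    W = _band_weight_matrix(freqs, [(cfg.f_analysis_lo, cfg.f_analysis_hi)], df)
    wave = _frame_band_m1(raw.samples, fs, HR_WINDOW, HR_HOP, W, nperseg)[:, 0]
    wave_fs = 1.0 / HR_HOP
    centers = np.arange(wave.size) * HR_HOP + HR_WINDOW / 2.0

    n_sec = int(math.floor(raw.duration))
    t_grid = np.arange(n_sec)
    hr = np.full(n_sec, np.nan)
    nfft = 8192
    f_pad = np.fft.rfftfreq(nfft, 1.0 / wave_fs)
    band = (f_pad >= HR_BAND[0]) & (f_pad <= HR_BAND[1])
    for t in range(int(HR_BLOCK), n_sec):
        sel = (centers > t - HR_BLOCK) & (centers <= t)
        block = wave[sel]
        if block.size < 2 or np.ptp(block) == 0:
            continue
        block = block - block.mean()
        spec = np.abs(np.fft.rfft(block * np.hanning(block.size), nfft)) ** 2
        sb = spec[band]
        peak = int(np.argmax(sb))
        med = np.median(sb)
        if med <= 0 or sb[peak] / med < peak_ratio_min:
            continue
        # parabolic refinement on log power
        gi = np.flatnonzero(band)[peak]
        if 0 < gi < f_pad.size - 1:
            y0, y1, y2 = np.log(spec[gi - 1 : gi + 2] + 1e-300)
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        else:
            delta = 0.0
        f_peak = f_pad[gi] + delta * (f_pad[1] - f_pad[0])
        hr[t] = 60.0 * f_peak
    return pd.Series(hr, index=t_grid, name="hr_dls")


def extract_channels(raw: RawDLSSignal, cfg: SimConfig,
                     bands: Sequence[ShearBand]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract (HemoFrame1Hz, RelHIFrame) from a raw signal.

    TBF and RBV come from non-overlapping 1-s windows on the integer-second
    grid; relHIs from 100-ms windows with a 10-ms hop; DLS-HR per
    :func:`estimate_dls_hr`.  Partial trailing windows are dropped.
    """
    if raw.duration < 11.0:
        raise ValueError("need at least 11 s of signal")
    bands = _validate_bands(bands)
    fs = raw.fs
    n_sec = int(math.floor(raw.duration))
    spw = int(round(fs))

    tbf = np.empty(n_sec)
    rbv = np.empty(n_sec)
    for t in range(n_sec):
        psd = estimate_psd(raw.samples[t * spw : (t + 1) * spw], fs)
        m0, m1 = compute_moments(psd, cfg.f_analysis_lo, cfg.f_analysis_hi)
        tbf[t] = m1
        rbv[t] = m1 / m0 if m0 > 0 else np.nan
    hr = estimate_dls_hr(raw, cfg)
    hemo = pd.DataFrame({"t": np.arange(n_sec, dtype=float), "tbf": tbf,
                         "rbv": rbv, "hr_dls": hr.to_numpy()})

    nperseg = int(round(RELHI_WINDOW * fs))
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    df = fs / nperseg
    order = sorted(bands, key=lambda b: b.index)
    W = _band_weight_matrix(freqs, [(b.freq_lo, b.freq_hi) for b in order], df)
    hi_vals = _frame_band_m1(raw.samples, fs, RELHI_WINDOW, RELHI_HOP, W, nperseg)
    total = hi_vals.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(total > 0, hi_vals / total, np.nan)
    t_rel = np.arange(rel.shape[0]) * RELHI_HOP
    relhi = pd.DataFrame({"t": t_rel} | {f"relhi{b.index}": rel[:, j]
                                         for j, b in enumerate(order)})
    return hemo, relhi


# ---------------------------------------------------------------------------
# CSV interchange (times in seconds from session start, 6-decimal fixed point,
# missing values as empty fields)


def write_hemo_csv(path, hemo: pd.DataFrame) -> None:
    hemo.to_csv(path, index=False, float_format="%.6f", na_rep="")


def write_relhi_csv(path, relhi: pd.DataFrame) -> None:
    relhi.to_csv(path, index=False, float_format="%.6f", na_rep="")


def read_hemo_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_relhi_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
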