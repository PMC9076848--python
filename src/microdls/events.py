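"""Event analysis: stability screening, deceleration detection, window
selection, change-onset marking and per-window summaries.

The analysis follows the clinical pipeline: DLS-derived heart rate is
screened against ECG heart rate using the ECG-monitor accuracy clause
(agreement within 10 % or 5 bpm, whichever is greater); the first contiguous
240 s of stable, deceleration-free data (after discarding the first 60 s of
each recording) form the stable analysis window, and each heart-rate
deceleration — a drop of at least 30 bpm below the per-subject median —
contributes a 240-s window centred on its onset.  Within event windows the
onset of the microvascular (relHI) redistribution and of the desaturation
are marked by a baseline-deviation rule standing in for the study's manual
annotation, and the relHI excursion is summarised as the cumulative absolute
deviation from its onset value (AUC, AU·s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StabilityMask",
    "DecelEvent",
    "AnalysisWindow",
    "EventMarks",
    "SegmentSummary",
    "stability_mask",
    "detect_decelerations",
    "select_windows",
    "mark_event_onsets",
    "compute_auc",
    "summarize_segment",
    "compute_lead_lag",
]

WINDOW_LEN = 240.0  # s
BASELINE_LEN = 60.0  # s of each event window used as pre-event baseline
RELHI_DT = 0.01  # s


@dataclass
class DecelEvent:
    hr_onset: float
    hr_end: float
    min_hr: float
    drop: float

    def __post_init__(self) -> None:
        if self.hr_onset >= self.hr_end:
            raise ValueError("hr_onset must precede hr_end")


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open 240-s interval [start, end), stable or event-centred."""

    kind: str  # "stable" | "event"
    start: float
    end: float

    def __post_init__(self) -> None:
        if abs((self.end - self.start) - WINDOW_LEN) > 1e-9:
            raise ValueError("analysis windows are 240 s long")


@dataclass
class EventMarks:
    hr_onset: float
    relhi_onset: float = np.nan
    relhi_end: float = np.nan
    spo2_onset: float = np.nan
    auc: np.ndarray = field(default_factory=lambda: np.full(5, np.nan))
    lead: float = np.nan
    spo2_lag: float = np.nan


@dataclass
class SegmentSummary:
    window: AnalysisWindow
    band_mean: np.ndarray
    band_sd: np.ndarray
    n_samples: int


def _as_series(x) -> pd.Series:
    if isinstance(x, pd.Series):
        return x
    if isinstance(x, pd.DataFrame):
        raise TypeError("pass a Series, not a DataFrame")
    return pd.Series(np.asarray(x, dtype=float))


def stability_mask(hr_dls, hr_ecg) -> pd.Series:
    """IEC-style agreement screen: stable iff |hr_dls - hr_ecg| <= max(10% ECG, 5 bpm).

    Seconds where either channel is missing are unstable.  Inputs must share
    an aligned 1 Hz grid (same index).
    """
    d = _as_series(hr_dls)
    e = _as_series(hr_ecg)
    if len(d) != len(e) or not np.array_equal(d.index.to_numpy(), e.index.to_numpy()):
        raise ValueError("hr_dls and hr_ecg must share an aligned 1 Hz grid")
    tol = np.maximum(0.10 * e.to_numpy(), 5.0)
    ok = np.abs(d.to_numpy() - e.to_numpy()) <= tol
    ok &= np.isfinite(d.to_numpy()) & np.isfinite(e.to_numpy())
    return pd.Series(ok, index=e.index, name="stable")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [i, j) index runs of consecutive True."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_decelerations(hr_ecg, min_drop: float = 30.0, min_run: int = 2,
                         merge_gap: float = 10.0, onset_margin: float = 5.0,
                         sustain: int = 5, descent_min: float = 2.0) -> list[DecelEvent]:
    """Detect heart-rate decelerations on a 1 Hz ECG series.

    A deceleration is a drop of at least `min_drop` bpm below the session
    median.  Candidate runs below (median - min_drop) lasting >= `min_run` s
    are kept; runs separated by less than `merge_gap` s merge.  The onset is
    refined by walking backwards from the run start while the trace keeps
    descending by at least `descent_min` bpm/s — the last plateau second
    before the consistent decline.  (Walking back to the last second within
    a fixed margin of the median instead is not robust: ordinary beat-to-beat
    variability dips a few bpm below any fixed margin and drags the onset
    seconds early.)  The end is the first second after the run back within
    `onset_margin` bpm of the median for >= `sustain` s.
    """
    s = _as_series(hr_ecg)
    hr = s.to_numpy(dtype=float)
    t = s.index.to_numpy(dtype=float)
    if not np.any(np.isfinite(hr)):
        raise ValueError("heart-rate series is entirely missing")
    m = float(np.nanmedian(hr))
    below = np.where(np.isfinite(hr), hr < m - min_drop, False)
    runs = [(i, j) for i, j in _runs(below) if j - i >= min_run]
    merged: list[list[int]] = []
    for i, j in runs:
        if merged and t[i] - t[merged[-1][1] - 1] < merge_gap:
            merged[-1][1] = j
        else:
            merged.append([i, j])

    events = []
    near = np.isfinite(hr) & (hr >= m - onset_margin)
    for i, j in merged:
        k = i
        while k > 0 and np.isfinite(hr[k - 1]) and hr[k - 1] - hr[k] >= descent_min:
            k -= 1
        i_on = max(k, 0)
        i_end = None
        for k in range(j, hr.size):
            if near[k] and np.all(near[k : min(k + sustain, hr.size)]):
                i_end = k
                break
        if i_end is None:
            i_end = hr.size - 1
        seg = hr[i_on : i_end + 1]
        min_hr = float(np.nanmin(seg))
        drop = m - min_hr
        if drop >= min_drop and t[i_end] > t[i_on]:
            events.append(DecelEvent(hr_onset=float(t[i_on]), hr_end=float(t[i_end]),
                                     min_hr=min_hr, drop=float(drop)))
    return events


def select_windows(mask: pd.Series, events: list[DecelEvent], session_span: float,
                   exclude_first: float = 60.0) -> list[AnalysisWindow]:
    """Select the stable window and the event windows of a session.

    Event windows are [onset - 120, onset + 120), dropped if they extend
    beyond the session (or overlap an earlier event window).  The stable
    window is the first contiguous 240-s run starting at or after
    `exclude_first` in which every second is stable, deceleration-free and
    outside every event window.  Absence of such a run yields no stable
    window; the returned windows are pairwise disjoint.
    """
    event_windows: list[AnalysisWindow] = []
    for ev in sorted(events, key=lambda e: e.hr_onset):
        a, b = ev.hr_onset - WINDOW_LEN / 2, ev.hr_onset + WINDOW_LEN / 2
        if a < 0 or b > session_span:
            continue
        if any(a < w.end and w.start < b for w in event_windows):
            warnings.warn("overlapping event windows; keeping the earlier one")
            continue
        event_windows.append(AnalysisWindow("event", a, b))

    t = mask.index.to_numpy(dtype=float)
    ok = mask.to_numpy(dtype=bool).copy()
    ok &= t >= exclude_first
    ok &= t < session_span
    for w in event_windows:
        ok &= ~((t >= w.start) & (t < w.end))
    for ev in events:
        ok &= ~((t >= ev.hr_onset) & (t <= ev.hr_end))

    stable: list[AnalysisWindow] = []
    need = int(WINDOW_LEN)
    run = 0
    for i in range(t.size):
        run = run + 1 if ok[i] else 0
        if run >= need:
            start = t[i - need + 1]
            cand = AnalysisWindow("stable", start, start + WINDOW_LEN)
            if not any(cand.start < w.end and w.start < cand.end for w in event_windows):
                stable = [cand]
                break
            run = 0  # overlapped an event window; restart the search
    return stable + event_windows


def _first_persistent(flags: np.ndarray, need: int) -> int | None:
    """Index where `flags` first holds for `need` consecutive samples."""
    if flags.size < need:
        return None
    x = flags.astype(np.int32)
    c = np.convolve(x, np.ones(need, dtype=np.int32), mode="valid")
    hits = np.flatnonzero(c == need)
    return int(hits[0]) if hits.size else None


def compute_auc(values: np.ndarray, t: np.ndarray, onset: float, end: float,
                dt: float = RELHI_DT) -> float:
    """Cumulative absolute deviation from the onset value over [onset, end).

    The sample at the marked onset is the baseline; AUC = dt * sum |x - x0|
    over samples in the marked period (AU·s).
    """
    values = np.asarray(values, dtype=float)
    t = np.asarray(t, dtype=float)
    if onset < t[0] - 1e-9 or onset > t[-1] + 1e-9:
        raise ValueError("onset outside the series")
    if end <= onset:
        raise ValueError("end must follow onset")
    i0 = int(np.searchsorted(t, onset - 1e-9))
    baseline = values[i0]
    sel = (t >= onset - 1e-9) & (t < end - 1e-9)
    dev = np.abs(values[sel] - baseline)
    return float(dt * np.nansum(dev))


def mark_event_onsets(relhi: pd.DataFrame, spo2: pd.Series,
                      window: AnalysisWindow, event: DecelEvent,
                      n_sd: float = 3.0, persist_s: float = 2.0,
                      calm_s: float = 5.0, spo2_persist_s: float = 3.0,
                      sd_floor: float = 1e-4) -> EventMarks:
    """Mark the relHI-change and desaturation onsets inside an event window.

    Stand-in for the study's manual annotation: each band's baseline mean and
    SD come from the first 60 s of the window; the relHI onset is the
    earliest time (any band) deviating from its baseline by more than
    `n_sd` SDs for `persist_s` seconds, searched up to 60 s past the
    heart-rate onset.  The excursion ends when all bands have returned
    within `n_sd` SDs for `calm_s` seconds (after both the relHI onset and
    the heart-rate end), else at the window end.  The SpO2 onset is the first
    second at or after the heart-rate onset with SpO2 below
    (baseline mean - max(n_sd * SD, 2 %)) sustained `spo2_persist_s` seconds.
    """
    if window.kind != "event":
        raise ValueError("onset marking applies to event windows")
    t = relhi["t"].to_numpy(dtype=float)
    cols = [c for c in relhi.columns if c.startswith("relhi")]
    X = relhi[cols].to_numpy(dtype=float)
    base_sel = (t >= window.start) & (t < window.start + BASELINE_LEN)
    if base_sel.sum() < 2:
        raise ValueError("event window not covered by the relHI frame")
    mu = np.nanmean(X[base_sel], axis=0)
    sd = np.nanstd(X[base_sel], axis=0, ddof=1)
    if np.any(sd < sd_floor):
        warnings.warn("zero baseline SD floored")
        sd = np.maximum(sd, sd_floor)

    marks = EventMarks(hr_onset=event.hr_onset)
    search = (t >= window.start + BASELINE_LEN) & (t < event.hr_onset + BASELINE_LEN)
    need = int(round(persist_s / RELHI_DT))
    t_search = t[search]
    onset_idx: list[float] = []
    dev = np.abs(X[search] - mu) > n_sd * sd
    for b in range(len(cols)):
        i = _first_persistent(dev[:, b], need)
        if i is not None:
            onset_idx.append(t_search[i])
    if onset_idx:
        marks.relhi_onset = float(min(onset_idx))
        marks.lead = event.hr_onset - marks.relhi_onset

        t_from = max(marks.relhi_onset, event.hr_end)
        tail = (t > t_from) & (t < window.end)
        calm = np.all(np.abs(X[tail] - mu) <= n_sd * sd, axis=1)
        j = _first_persistent(calm, int(round(calm_s / RELHI_DT)))
        marks.relhi_end = float(t[tail][j]) if j is not None else float(window.end)

        auc = np.full(len(cols), np.nan)
        for b in range(len(cols)):
            auc[b] = compute_auc(X[:, b], t, marks.relhi_onset, marks.relhi_end)
        marks.auc = auc

    ts = spo2.index.to_numpy(dtype=float)
    sv = spo2.to_numpy(dtype=float)
    sb = (ts >= window.start) & (ts < window.start + BASELINE_LEN)
    mu_s = np.nanmean(sv[sb])
    sd_s = np.nanstd(sv[sb], ddof=1)
    thresh = mu_s - max(n_sd * sd_s, 2.0)
    cand = ts >= event.hr_onset
    low = np.where(np.isfinite(sv[cand]), sv[cand] < thresh, False)
    k = _first_persistent(low, int(round(spo2_persist_s)))
    if k is not None:
        marks.spo2_onset = float(ts[cand][k])
        marks.spo2_lag = marks.spo2_onset - event.hr_onset
    return marks


def summarize_segment(relhi: pd.DataFrame, window: AnalysisWindow) -> SegmentSummary:
    """Per-band mean and sample SD (ddof=1) over the window; missing omitted."""
    t = relhi["t"].to_numpy(dtype=float)
    cols = sorted(c for c in relhi.columns if c.startswith("relhi"))
    sel = (t >= window.start) & (t < window.end)
    X = relhi.loc[sel, cols].to_numpy(dtype=float)
    valid = np.isfinite(X).sum(axis=0)
    if np.any(valid < 2):
        raise ValueError("fewer than 2 samples in the window")
    return SegmentSummary(window=window,
                          band_mean=np.nanmean(X, axis=0),
                          band_sd=np.nanstd(X, axis=0, ddof=1),
                          n_samples=int(sel.sum()))


def compute_lead_lag(marks: list[EventMarks]) -> dict:
    """Median and IQR of the relHI lead and the SpO2 lag over marked events."""
    leads = np.array([m.lead for m in marks if np.isfinite(m.lead)])
    lags = np.array([m.spo2_lag for m in marks if np.isfinite(m.spo2_lag)])

    def q(x):
        if x.size == 0:
            return {"n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan}
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"n": int(x.size), "median": float(med), "q1": float(q1), "q3": float(q3)}

    return {"lead": q(leads), "spo2_lag": q(lags)}
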