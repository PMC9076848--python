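"""Stability screening, deceleration detection, window selection and marking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from microdls.events import (AnalysisWindow, DecelEvent, compute_auc,
                             compute_lead_lag, detect_decelerations,
                             mark_event_onsets, select_windows, stability_mask,
                             summarize_segment)


def _series(values):
    v = np.asarray(values, dtype=float)
    return pd.Series(v, index=np.arange(v.size, dtype=float))


class TestStabilityMask:
    def test_ten_percent_rule(self):
        ecg = _series([150.0, 150.0, 150.0])
        dls = _series([160.0, 170.0, 150.0])
        m = stability_mask(dls, ecg)
        # |10| <= 15 stable; |20| > 15 unstable
        assert m.tolist() == [True, False, True]

    def test_five_bpm_floor_at_low_rates(self):
        ecg = _series([40.0, 40.0])
        dls = _series([44.0, 46.0])
        assert stability_mask(dls, ecg).tolist() == [True, False]

    def test_missing_channel_is_unstable(self):
        ecg = _series([150.0, 150.0])
        dls = _series([np.nan, 150.0])
        assert stability_mask(dls, ecg).tolist() == [False, True]

    def test_identical_channels_all_stable(self):
        ecg = _series(150.0 + np.sin(np.arange(100)))
        assert stability_mask(ecg.copy(), ecg).all()

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError):
            stability_mask(_series([1, 2, 3]), _series([1, 2]))


def _trace_with_dip(median=153.0, dip_to=120.0, dip_len=10, n=600, at=300):
    hr = np.full(n, median)
    hr[at:at + dip_len] = dip_to
    return _series(hr)


class TestDetectDecelerations:
    def test_dip_below_threshold_detected(self):
        events = detect_decelerations(_trace_with_dip(153.0, 120.0))
        assert len(events) == 1
        assert events[0].drop == pytest.approx(33.0)
        assert events[0].hr_onset == pytest.approx(299.0, abs=1.0)

    def test_shallow_dip_ignored(self):
        assert detect_decelerations(_trace_with_dip(153.0, 130.0)) == []

    def test_single_second_spike_ignored(self):
        assert detect_decelerations(_trace_with_dip(153.0, 100.0, dip_len=1)) == []

    def test_nearby_runs_merge_into_one_event(self):
        hr = np.full(600, 150.0)
        hr[300:305] = 110.0
        hr[308:313] = 110.0  # 3-s gap, below the 10-s merge threshold
        events = detect_decelerations(_series(hr))
        assert len(events) == 1
        assert events[0].hr_end >= 312.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            detect_decelerations(_series(np.full(200, np.nan)))


def _full_mask(n=900):
    return pd.Series(np.ones(n, dtype=bool), index=np.arange(n, dtype=float))


class TestSelectWindows:
    def test_fully_stable_session_takes_first_window_after_exclusion(self):
        ws = select_windows(_full_mask(), [], 900.0)
        assert len(ws) == 1
        assert (ws[0].kind, ws[0].start, ws[0].end) == ("stable", 60.0, 300.0)

    def test_mid_session_event_pushes_stable_window_past_it(self):
        # [60, 300) would overlap the event window on [280, 300), so the
        # stable search resumes after the event window
        ev = DecelEvent(hr_onset=400.0, hr_end=420.0, min_hr=110.0, drop=40.0)
        ws = select_windows(_full_mask(), [ev], 900.0)
        kinds = {(w.kind, w.start, w.end) for w in ws}
        assert ("event", 280.0, 520.0) in kinds
        assert ("stable", 520.0, 760.0) in kinds

    def test_late_event_leaves_stable_window_unchanged(self):
        ev = DecelEvent(hr_onset=700.0, hr_end=720.0, min_hr=110.0, drop=40.0)
        ws = select_windows(_full_mask(), [ev], 900.0)
        kinds = {(w.kind, w.start, w.end) for w in ws}
        assert ("stable", 60.0, 300.0) in kinds
        assert ("event", 580.0, 820.0) in kinds

    def test_early_event_pushes_stable_window_past_it(self):
        ev = DecelEvent(hr_onset=200.0, hr_end=220.0, min_hr=110.0, drop=40.0)
        ws = select_windows(_full_mask(), [ev], 900.0)
        kinds = {(w.kind, w.start, w.end) for w in ws}
        assert ("event", 80.0, 320.0) in kinds
        assert ("stable", 320.0, 560.0) in kinds

    def test_event_window_clipped_out_near_session_edge(self):
        ev = DecelEvent(hr_onset=60.0, hr_end=80.0, min_hr=110.0, drop=40.0)
        ws = select_windows(_full_mask(), [ev], 900.0)
        assert all(w.kind == "stable" for w in ws)

    def test_no_stable_run_yields_no_stable_window(self):
        mask = _full_mask(900)
        mask.iloc[::200] = False  # unstable every 200 s: no 240-s run
        ws = select_windows(mask, [], 900.0)
        assert [w for w in ws if w.kind == "stable"] == []

    def test_windows_pairwise_disjoint_on_random_sessions(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            mask = pd.Series(rng.uniform(size=900) > 0.05,
                             index=np.arange(900, dtype=float))
            onsets = np.sort(rng.uniform(0, 900, rng.integers(0, 4)))
            events = [DecelEvent(hr_onset=float(o), hr_end=float(o) + 15.0,
                                 min_hr=110.0, drop=40.0)
                      for o in onsets if np.all(np.abs(onsets - o) >= 300) or True]
            events = [e for i, e in enumerate(events)
                      if all(e.hr_onset - events[j].hr_onset >= 300 for j in range(i))]
            ws = select_windows(mask, events, 900.0)
            for i, a in enumerate(ws):
                assert a.end - a.start == pytest.approx(240.0)
                for b in ws[i + 1:]:
                    assert a.end <= b.start or b.end <= a.start


def _relhi_frame(duration=520.0, n_bands=5, noise_sd=0.002, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 0.01)
    base = np.array([0.35, 0.28, 0.20, 0.12, 0.05])[:n_bands]
    X = base + noise_sd * rng.standard_normal((t.size, n_bands))
    return t, X

def _to_df(t, X):
    return pd.DataFrame({"t": t} | {f"relhi{b + 1}": X[:, b]
                                    for b in range(X.shape[1])})


class TestMarkEventOnsets:
    WINDOW = AnalysisWindow("event", 280.0, 520.0)
    EVENT = DecelEvent(hr_onset=400.0, hr_end=420.0, min_hr=110.0, drop=40.0)

    def _spo2(self, lag=None, drop=10.0, seed=1):
        rng = np.random.default_rng(seed)
        t = np.arange(900, dtype=float)
        s = 96.0 + 0.5 * rng.standard_normal(900)
        if lag is not None:
            start = 400.0 + lag
            s[(t >= start) & (t < start + 25.0)] -= drop
        return pd.Series(s, index=t)

    def test_constant_relhi_gives_missing_onset(self):
        t, X = _relhi_frame()
        marks = mark_event_onsets(_to_df(t, X), self._spo2(), self.WINDOW, self.EVENT)
        assert np.isnan(marks.relhi_onset)
        assert np.isnan(marks.lead)

    def test_injected_step_recovers_lead(self):
        t, X = _relhi_frame()
        step_at = 400.0 - 22.0
        X[t >= step_at, 0] += 0.02  # +10 sigma step in band 1
        marks = mark_event_onsets(_to_df(t, X), self._spo2(), self.WINDOW, self.EVENT)
        assert marks.lead == pytest.approx(22.0, abs=1.0)

    def test_spo2_lag_recovered(self):
        t, X = _relhi_frame()
        X[t >= 378.0, 0] += 0.02
        marks = mark_event_onsets(_to_df(t, X), self._spo2(lag=9.0),
                                  self.WINDOW, self.EVENT)
        assert marks.spo2_lag == pytest.approx(9.0, abs=1.0)

    def test_auc_positive_for_sustained_excursion(self):
        t, X = _relhi_frame()
        X[(t >= 378.0) & (t < 430.0), 0] += 0.02
        marks = mark_event_onsets(_to_df(t, X), self._spo2(), self.WINDOW, self.EVENT)
        assert np.isfinite(marks.auc).all()
        assert marks.auc[0] > 0

    def test_zero_baseline_sd_floored_with_warning(self):
        t, X = _relhi_frame(noise_sd=0.0)
        X[t >= 378.0, 0] += 0.02
        with pytest.warns(UserWarning):
            marks = mark_event_onsets(_to_df(t, X), self._spo2(), self.WINDOW, self.EVENT)
        assert np.isfinite(marks.relhi_onset)


class TestComputeAuc:
    def test_constant_series_zero(self):
        t = np.arange(0.0, 30.0, 0.01)
        assert compute_auc(np.full(t.size, 0.2), t, 0.0, 30.0) == 0.0

    def test_step_closed_form(self):
        """0.02 step lasting 10 s inside a 30-s marked period -> 0.200 AU*s."""
        t = np.arange(0.0, 30.0, 0.01)
        x = np.zeros(t.size)
        x[(t >= 10.0) & (t < 20.0)] += 0.02
        assert compute_auc(x, t, 0.0, 30.0) == pytest.approx(0.200, abs=1e-9)

    def test_onset_outside_series_rejected(self):
        t = np.arange(0.0, 10.0, 0.01)
        with pytest.raises(ValueError):
            compute_auc(np.zeros(t.size), t, 20.0, 25.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(offset=st.floats(-5.0, 5.0), scale=st.floats(0.1, 10.0))
    def test_translation_invariance_and_homogeneity(self, offset, scale):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 20.0, 0.01)
        x = rng.uniform(0.0, 1.0, t.size)
        base = compute_auc(x, t, 0.0, 20.0)
        assert compute_auc(x + offset, t, 0.0, 20.0) == pytest.approx(base, rel=1e-9)
        scaled = x[0] + scale * (x - x[0])
        assert compute_auc(scaled, t, 0.0, 20.0) == pytest.approx(scale * base, rel=1e-9)


class TestSummarizeSegment:
    def test_constant_series(self):
        t = np.arange(0.0, 300.0, 0.01)
        X = np.full((t.size, 5), 0.2)
        s = summarize_segment(_to_df(t, X), AnalysisWindow("stable", 0.0, 240.0))
        assert np.allclose(s.band_mean, 0.2)
        assert np.allclose(s.band_sd, 0.0)

    def test_alternating_values_sample_sd(self):
        t = np.arange(0.0, 300.0, 0.01)
        X = np.tile(np.array([[0.1], [0.3]]), (t.size // 2, 5))
        s = summarize_segment(_to_df(t, X), AnalysisWindow("stable", 0.0, 240.0))
        assert np.allclose(s.band_mean, 0.2)
        assert np.allclose(s.band_sd, 0.1, atol=1e-4)

    def test_means_sum_to_one_when_rows_do(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 300.0, 0.01)
        X = rng.dirichlet(np.ones(5), t.size)
        s = summarize_segment(_to_df(t, X), AnalysisWindow("stable", 0.0, 240.0))
        assert s.band_mean.sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_rows_omitted(self):
        t = np.arange(0.0, 300.0, 0.01)
        X = np.full((t.size, 5), 0.2)
        X[100:200] = np.nan
        s = summarize_segment(_to_df(t, X), AnalysisWindow("stable", 0.0, 240.0))
        assert np.allclose(s.band_mean, 0.2)


class TestLeadLag:
    def test_odd_sample_median(self):
        from microdls.events import EventMarks
        marks = [EventMarks(hr_onset=0.0, lead=v) for v in (20.0, 22.0, 25.0)]
        assert compute_lead_lag(marks)["lead"]["median"] == 22.0

    def test_single_event_degenerate_iqr(self):
        from microdls.events import EventMarks
        ll = compute_lead_lag([EventMarks(hr_onset=0.0, lead=22.0)])
        assert ll["lead"]["median"] == 22.0
        assert ll["lead"]["q1"] == ll["lead"]["q3"] == 22.0

    def test_empty_summary(self):
        ll = compute_lead_lag([])
        assert ll["lead"]["n"] == 0
        assert np.isnan(ll["lead"]["median"])
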