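"""Session orchestration and cohort-level report tables.

`analyze_session` runs the full event pipeline on one session's channel
frames; `build_cohort_report` aggregates the per-session results into the
report tables: included-point counts per location, pairwise location
comparisons of TBF/RBV, the per-band stable-versus-deceleration summary
(median/IQR of window means, SDs and AUC with signed-rank p-values), the
lead/lag summary, and the analysis-ready paired RBV/HR/GA/location table for
external mixed-model fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import (AnalysisWindow, DecelEvent, EventMarks, SegmentSummary,
                     WINDOW_LEN, compute_lead_lag, detect_decelerations,
                     mark_event_onsets, select_windows, stability_mask,
                     summarize_segment)
from .stats import pairwise_location_ttests, wilcoxon_signed_rank

__all__ = ["SessionAnalysis", "analyze_session", "build_cohort_report",
           "write_report", "write_provenance"]


@dataclass
class SessionAnalysis:
    subject_id: str
    location: str
    ga_weeks: float
    pda: bool
    phototherapy: bool
    windows: list[AnalysisWindow]
    events: list[DecelEvent]
    marks: list[EventMarks]
    stable_summary: SegmentSummary | None
    event_summaries: list[SegmentSummary]
    hemo: pd.DataFrame
    physio: pd.DataFrame
    stable_mask: pd.Series

    @property
    def included_points(self) -> int:
        return int(WINDOW_LEN) if self.stable_summary is not None else 0


def analyze_session(hemo: pd.DataFrame, relhi: pd.DataFrame, physio: pd.DataFrame,
                    subject_id: str = "", location: str = "", ga_weeks: float = np.nan,
                    pda: bool = False, phototherapy: bool = False,
                    exclude_first: float = 60.0) -> SessionAnalysis:
    """Run stability screening, window selection and event marking on one session."""
    hr_dls = pd.Series(hemo["hr_dls"].to_numpy(), index=hemo["t"].to_numpy())
    n = len(hemo)
    hr_ecg = pd.Series(physio["hr_ecg"].to_numpy()[:n], index=physio["t"].to_numpy()[:n])
    spo2 = pd.Series(physio["spo2"].to_numpy(), index=physio["t"].to_numpy())
    mask = stability_mask(hr_dls, hr_ecg)
    events = detect_decelerations(hr_ecg)
    span = float(hemo["t"].iloc[-1]) + 1.0
    windows = select_windows(mask, events, span, exclude_first=exclude_first)

    stable_summary = None
    event_summaries = []
    marks = []
    for w in windows:
        if w.kind == "stable":
            stable_summary = summarize_segment(relhi, w)
        else:
            ev = min(events, key=lambda e: abs(e.hr_onset - (w.start + WINDOW_LEN / 2)))
            marks.append(mark_event_onsets(relhi, spo2, w, ev))
            event_summaries.append(summarize_segment(relhi, w))
    return SessionAnalysis(subject_id=subject_id, location=location,
                           ga_weeks=ga_weeks, pda=pda, phototherapy=phototherapy,
                           windows=windows, events=events, marks=marks,
                           stable_summary=stable_summary,
                           event_summaries=event_summaries,
                           hemo=hemo, physio=physio, stable_mask=mask)


def analyze_bundle(bundle, exclude_first: float = 60.0) -> SessionAnalysis:
    """Convenience wrapper for synthetic SessionBundles."""
    return analyze_session(bundle.hemo, bundle.relhi, bundle.physio,
                           subject_id=bundle.subject.subject_id,
                           location=bundle.location,
                           ga_weeks=bundle.subject.ga_weeks,
                           pda=bundle.subject.pda,
                           phototherapy=bundle.subject.phototherapy,
                           exclude_first=exclude_first)


def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return (np.nan, np.nan, np.nan)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q1), float(q3)


def build_cohort_report(analyses: list[SessionAnalysis], n_bands: int = 5) -> dict:
    """Aggregate per-session analyses into the cohort report tables."""
    if not analyses:
        raise ValueError("empty cohort")

    # (a) included-point counts
    counts = {}
    for a in analyses:
        counts[a.location] = counts.get(a.location, 0) + a.included_points
    counts_df = pd.DataFrame(
        [{"location": loc, "included_points": n} for loc, n in sorted(counts.items())]
        + [{"location": "total", "included_points": sum(counts.values())}])

    # (b) per-subject per-location channel means over stable (norm-compliant) data
    rows = []
    for a in analyses:
        ok = a.stable_mask.to_numpy()
        for ch in ("tbf", "rbv"):
            vals = a.hemo[ch].to_numpy()[ok[: len(a.hemo)]]
            if np.isfinite(vals).any():
                rows.append({"subject": a.subject_id, "location": a.location,
                             "channel": ch, "value": float(np.nanmean(vals))})
    chan_df = pd.DataFrame(rows)
    comparisons = []
    for ch in ("tbf", "rbv"):
        sub = chan_df[chan_df["channel"] == ch]
        if sub["location"].nunique() >= 2:
            for c in pairwise_location_ttests(sub):
                comparisons.append({"channel": ch, "loc_a": c.pair[0], "loc_b": c.pair[1],
                                    "mean_diff": c.mean_diff, "t": c.statistic,
                                    "p": c.p, "n": c.n, "threshold": c.threshold,
                                    "significant": c.significant, "note": c.note})
    comp_df = pd.DataFrame(comparisons)

    # (c) per-band stable vs deceleration summary with signed-rank p-values
    stable_by_subj: dict[str, list] = {}
    for a in analyses:
        if a.stable_summary is not None:
            stable_by_subj.setdefault(a.subject_id, []).append(a.stable_summary)
    event_rows = [(a.subject_id, s, m) for a in analyses
                  for s, m in zip(a.event_summaries, a.marks)]
    table_rows = []
    for b in range(n_bands):
        s_means = np.array([np.mean([s.band_mean[b] for s in lst])
                            for lst in stable_by_subj.values()])
        s_sds = np.array([np.mean([s.band_sd[b] for s in lst])
                          for lst in stable_by_subj.values()])
        e_means = np.array([s.band_mean[b] for _, s, _ in event_rows])
        e_sds = np.array([s.band_sd[b] for _, s, _ in event_rows])
        aucs = np.array([m.auc[b] for _, _, m in event_rows])

        # paired per subject: stable value vs mean over that subject's events
        ev_by_subj: dict[str, list] = {}
        for sid, s, _ in event_rows:
            ev_by_subj.setdefault(sid, []).append(s)
        paired = [sid for sid in stable_by_subj if sid in ev_by_subj]
        p_mean = p_sd = np.nan
        if paired:
            sm = [np.mean([s.band_mean[b] for s in stable_by_subj[sid]]) for sid in paired]
            em = [np.mean([s.band_mean[b] for s in ev_by_subj[sid]]) for sid in paired]
            ssd = [np.mean([s.band_sd[b] for s in stable_by_subj[sid]]) for sid in paired]
            esd = [np.mean([s.band_sd[b] for s in ev_by_subj[sid]]) for sid in paired]
            p_mean = wilcoxon_signed_rank(np.array(sm), np.array(em)).p
            p_sd = wilcoxon_signed_rank(np.array(ssd), np.array(esd)).p

        row = {"band": b + 1}
        for name, arr in (("stable_mean", s_means), ("stable_sd", s_sds),
                          ("event_mean", e_means), ("event_sd", e_sds),
                          ("auc", aucs)):
            med, q1, q3 = _median_iqr(arr)
            row |= {f"{name}_median": med, f"{name}_q1": q1, f"{name}_q3": q3}
        row |= {"p_mean": p_mean, "p_sd": p_sd,
                "n_events": int(len(event_rows)), "n_stable": int(len(stable_by_subj))}
        table_rows.append(row)
    table2_df = pd.DataFrame(table_rows)

    # (d) lead / lag summary
    all_marks = [m for a in analyses for m in a.marks]
    ll = compute_lead_lag(all_marks)
    lead_lag_df = pd.DataFrame([
        {"quantity": "relhi_lead", **ll["lead"]},
        {"quantity": "spo2_lag", **ll["spo2_lag"]},
    ])

    # (e) analysis-ready paired RBV/HR/GA/location table (stable-window rows)
    lmm_rows = []
    for a in analyses:
        if a.stable_summary is None:
            continue
        w = a.stable_summary.window
        t = a.hemo["t"].to_numpy()
        sel = (t >= w.start) & (t < w.end)
        hr_ecg = a.physio.set_index("t")["hr_ecg"]
        for _, r in a.hemo.loc[sel].iterrows():
            lmm_rows.append({"subject": a.subject_id, "location": a.location,
                             "ga_weeks": a.ga_weeks, "t": r["t"],
                             "rbv": r["rbv"], "hr_ecg": hr_ecg.get(r["t"], np.nan)})
    lmm_df = pd.DataFrame(lmm_rows)

    return {"counts": counts_df, "location_comparisons": comp_df,
            "table2_analogue": table2_df, "lead_lag": lead_lag_df,
            "lmm_table": lmm_df}


def write_report(report: dict, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")


def write_provenance(path, seed: int | None, config: dict | None = None) -> None:
    """JSON provenance record: config hash, seed, package versions."""
    import hashlib
    import sys

    from . import __version__

    cfg_text = json.dumps(config or {}, sort_keys=True, default=str)
    record = {
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "config": config,
        "microdls_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
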