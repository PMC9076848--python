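"""Randomized output-contract battery.

Simulates a large number of short stationary windows with random compartment
mixes and shear rates, extracts the channels for each, and collects the
quantities whose contracts the device documentation pins down: every relHI
must lie in [0, 1] with the five indices summing to one, and RBV cannot
exceed the 9000 Hz upper edge of the detection range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .extractor import compute_relhi, compute_rbv, estimate_psd
from .scene import Compartment, SimConfig, build_scene_timeline, make_default_bands
from .simulator import simulate_intensity

__all__ = ["randomized_window_battery"]


def randomized_window_battery(n_windows: int = 1000, seed: int = 0,
                              window_s: float = 1.0,
                              cfg: SimConfig | None = None) -> pd.DataFrame:
    """Simulate `n_windows` random stationary scenes and extract relHI/RBV.

    Per window: volume fractions ~ U(0.05, 2), mean shears log-uniform
    within each band, heart rate U(100, 200) bpm with the default pulsatile
    modulation.  Returns one row per window with the extracted relHIs, their
    sum, and RBV.  Deterministic under `seed`.
    """
    base = cfg or SimConfig()
    bands = make_default_bands(kappa=base.kappa, f_clip_hi=base.f_analysis_hi)
    order = sorted(bands, key=lambda b: b.index)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_windows):
        vf = rng.uniform(0.05, 2.0, len(order))
        shear = np.array([np.exp(rng.uniform(np.log(b.shear_lo), np.log(b.shear_hi)))
                          for b in order])
        hr = float(rng.uniform(100, 200))
        w_cfg = SimConfig(**{**base.__dict__, "seed": int(rng.integers(2**31))})
        comps = [Compartment(band_index=b.index, volume_fraction=float(v),
                             mean_shear=float(s))
                 for b, v, s in zip(order, vf, shear)]
        tl = build_scene_timeline(comps, np.full(int(window_s) + 2, hr), [],
                                  window_s, w_cfg)
        raw = simulate_intensity(tl, w_cfg)
        psd = estimate_psd(raw.samples, w_cfg.fs_raw)
        rel = compute_relhi(psd, order)
        rbv = compute_rbv(psd, w_cfg)
        rows.append({"window": i, "rbv": rbv, "relhi_sum": float(np.nansum(rel)),
                     **{f"relhi{b.index}": rel[j] for j, b in enumerate(order)}})
    return pd.DataFrame(rows)
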