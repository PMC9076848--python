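import numpy as np
import pytest

from microdls.scene import Compartment, SimConfig, build_scene_timeline, make_default_bands
from microdls.simulator import simulate_intensity


@pytest.fixture(scope="session")
def default_bands():
    return make_default_bands(kappa=3.0, f_clip_hi=9000.0)


@pytest.fixture(scope="session")
def single_lorentzian_60s():
    """60-s stationary single-compartment signal, corner frequency 1 kHz."""
    cfg = SimConfig(seed=7, m_v=0.0, m_n=0.0)
    comps = [Compartment(band_index=1, volume_fraction=1.0, mean_shear=1000.0 / 3.0)]
    tl = build_scene_timeline(comps, np.full(70, 120.0), [], 60.0, cfg)
    return simulate_intensity(tl, cfg), cfg


@pytest.fixture(scope="session")
def multi_compartment_60s(default_bands):
    """60-s stationary five-compartment signal with a realistic mix."""
    cfg = SimConfig(seed=11, m_v=0.0, m_n=0.0)
    mix = (0.05, 0.12, 0.6, 1.4, 2.7)
    order = sorted(default_bands, key=lambda b: b.index)
    comps = [Compartment(band_index=b.index, volume_fraction=mix[b.index - 1],
                         mean_shear=float(np.sqrt(b.shear_lo * b.shear_hi)))
             for b in order]
    tl = build_scene_timeline(comps, np.full(70, 120.0), [], 60.0, cfg)
    return simulate_intensity(tl, cfg), cfg, comps
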