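import numpy as np
import pandas as pd
import pytest

from ulvaphen.imaging import AreaSeries, Photoperiod, WellLayout
from ulvaphen.synthetic import NoiseConfig, SimConfig


@pytest.fixture
def tiny_config():
    """2 strains x 2 discs, 2 days, small wells: fast end-to-end runs."""
    return SimConfig(
        seed=1,
        n_strains=2,
        discs_per_strain=2,
        days=2,
        well_diameter_mm=25.0,
        calibration_mm_per_px=0.4,
    )


@pytest.fixture
def quiet_config(tiny_config):
    """Same geometry with every noise source switched off."""
    cfg = SimConfig(
        **{
            **tiny_config.__dict__,
            "noise": tiny_config.noise.zeroed(),
        }
    )
    return cfg


def render_disc(radius_px, image_px=120, bg=0.15, fg=0.75, mesh_pitch=0, mesh_width=0):
    """Anti-aliased disc test image (uint8), optionally mesh-occluded."""
    c = image_px / 2.0
    yy, xx = np.mgrid[0:image_px, 0:image_px].astype(float)
    cov = np.clip(radius_px + 0.5 - np.hypot(yy - c, xx - c), 0.0, 1.0)
    img = bg + (fg - bg) * cov
    if mesh_pitch and mesh_width:
        lines = np.arange(image_px) % mesh_pitch < mesh_width
        img[lines, :] = bg
        img[:, lines] = bg
    return np.round(img * 255).astype(np.uint8)


def single_well_layout(image_px=120, well_radius_px=50.0):
    c = image_px / 2.0
    return WellLayout(rows=1, cols=1, centers_px=np.array([[c, c]]), well_radius_px=well_radius_px)


def make_series(t_min, areas, photoperiod=None, flags=None):
    """AreaSeries from raw arrays, phases labelled from the clock."""
    pp = photoperiod or Photoperiod()
    df = pd.DataFrame(
        {
            "t_min": np.asarray(t_min, dtype=float),
            "phase": [pp.phase_at(t) for t in t_min],
            "area_mm2": np.asarray(areas, dtype=float),
            "flag": flags if flags is not None else ["ok"] * len(t_min),
        }
    )
    return AreaSeries(disc_id="d0", strain_id="s0", data=df, photoperiod=pp)


@pytest.fixture
def exponential_series():
    """Noiseless 3-day series sampled every 30 min, day 5%/night 10%."""
    pp = Photoperiod()
    t = np.arange(15.0, 3 * 1440.0, 30.0)
    g_day, g_night = 0.05, 0.10
    light = 720.0
    full = np.floor(t / 1440.0)
    tau = t - full * 1440.0
    day_p = (full * light + np.minimum(tau, light)) / light
    night_p = (full * light + np.maximum(tau - light, 0.0)) / light
    areas = 113.1 * np.exp(g_day * day_p + g_night * night_p)
    return make_series(t, areas, pp)
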