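"""Synthetic data generator for the disc-growth phenotyping pipeline.

Emulates the physical platform so that every downstream stage can be
tested against known ground truth: tanks imaged every 5 min under a
12 h:12 h photoperiod, ~36 discs of ~12 mm diameter held under a nylon
mesh in gridded wells, discs growing exponentially with distinct day
and night rates, strain panels in which carbohydrates accumulate by day
and are consumed at night while nitrate accumulates at night coupled to
growth, and a 47-metabolite GC-MS-like matrix with planted growth
correlations.

Growth is exponential within each phase with instantaneous switching at
lights-on/off, so the phase-specific specific growth rates (SGR,
100*ln(A2/A1) percent per period) of the generated discs are exact by
construction. All randomness flows from a single integer seed;
per-disc, per-strain and per-metabolite substreams are derived by fixed
seed offsets so outputs are reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .imaging import FrameStack, Photoperiod, WellLayout
from .metabolites import CATALOGUE, METABOLITE_CLASS

__all__ = [
    "NoiseConfig",
    "PanelConfig",
    "MetaboliteConfig",
    "SimConfig",
    "GroundTruth",
    "simulate_disc_stack",
    "simulate_strain_panel",
    "simulate_metabolite_matrix",
]

BACKGROUND_INTENSITY = 0.15
DISC_INTENSITY = 0.75


@dataclass
class NoiseConfig:
    """Imaging noise model (free parameters of the simulator).

    ``pixel_sd`` is additive Gaussian noise on the [0, 1] intensity
    scale, ``jitter_px`` the half-range of per-frame uniform disc
    translation inside the well (water movement), ``mesh_width_px`` /
    ``mesh_pitch_px`` the background-coloured retaining-mesh grid drawn
    over the image, and ``flicker`` the relative amplitude of
    multiplicative per-frame illumination fluctuation.
    """

    pixel_sd: float = 0.02
    jitter_px: float = 1.5
    mesh_width_px: int = 1
    mesh_pitch_px: int = 9
    flicker: float = 0.03

    def zeroed(self) -> "NoiseConfig":
        return NoiseConfig(pixel_sd=0.0, jitter_px=0.0, mesh_width_px=0, mesh_pitch_px=self.mesh_pitch_px, flicker=0.0)


@dataclass
class PanelConfig:
    """Strain-panel generator: biochemistry at end of day / end of night.

    Units: carbohydrates in umol glucose equivalents per g DW, nitrate
    in mg NO3-N per g DW, ash in % DW, RGR in mg.mg-1.d-1. Defaults are
    anchored to the aggregate study values: RGR 0.209 +- 0.062, ash
    23.072 +- 4.142, night/daily SGR ratio 65.450 +- 10.825, starch ~50x
    sucrose at end of day, ~80% of night-accumulated nitrate consumed
    by day.
    """

    rgr_mean: float = 0.209
    rgr_sd: float = 0.062
    sgr_daily_mean: float = 13.473
    sgr_daily_sd: float = 5.214
    sgr_rgr_corr: float = 0.6
    night_ratio_mean: float = 65.450
    night_ratio_sd: float = 10.825
    ash_mean_pct: float = 23.072
    ash_sd_pct: float = 4.142
    sucrose_eod_mean: float = 10.0
    starch_sucrose_ratio: float = 50.0
    abundance_cv: float = 0.3
    starch_consumed_frac: float = 0.55
    sucrose_consumed_frac: float = 0.5
    consumed_frac_sd: float = 0.15
    nitrate_eon_mean: float = 2.5
    nitrate_log_sd: float = 0.45
    nitrate_rgr_coupling: float = 0.8
    nitrate_consumed_frac: float = 0.8
    nitrate_consumed_sd: float = 0.05


@dataclass
class MetaboliteConfig:
    """GC-MS-like matrix generator with planted ground-truth structure.

    ``planted_eod``/``planted_eon`` map metabolite names to association
    signs (+1/-1) with strain RGR; the defaults mirror the biomarkers
    of the study system (glycine and methionine positive at end of day;
    threonic acid, myo-inositol and raffinose negative; glycine and
    arginine positive and threonic acid negative at end of night).
    ``night_consumed`` metabolites drop ``night_fold``-fold overnight.
    ``abundance_sigma`` is the log-scale dispersion; 0 makes the matrix
    noiseless.
    """

    planted_eod: dict[str, int] = field(
        default_factory=lambda: {
            "glycine": +1,
            "methionine": +1,
            "threonic acid": -1,
            "myo-inositol": -1,
            "raffinose": -1,
        }
    )
    planted_eon: dict[str, int] = field(
        default_factory=lambda: {
            "glycine": +1,
            "arginine": +1,
            "threonic acid": -1,
        }
    )
    target_rho: float = 0.9
    night_consumed: tuple[str, ...] = (
        "glucose",
        "fructose",
        "sucrose",
        "maltose",
        "trehalose",
        "ribose",
        "xylose",
        "galactose",
        "glycerol",
        "malic acid",
        "citric acid",
        "succinic acid",
        "fumaric acid",
        "pyruvic acid",
        "glyceric acid",
        "alanine",
        "serine",
    )
    night_fold: float = 4.0
    abundance_sigma: float = 0.4


@dataclass
class SimConfig:
    """Full simulator configuration; ``seed`` fixes every output."""

    seed: int = 0
    n_strains: int = 6
    discs_per_strain: int = 6
    light_hours: float = 12.0
    dark_hours: float = 12.0
    frame_interval_min: float = 5.0
    days: int = 6
    image_size: tuple[int, int] | None = None
    calibration_mm_per_px: float = 0.35
    initial_disc_diameter_mm: float = 12.0
    initial_diameter_cv: float = 0.04
    well_diameter_mm: float = 35.0
    sgr_day_mean: float = 4.837
    sgr_day_sd: float = 1.99
    sgr_night_mean: float = 8.636
    sgr_night_sd: float = 3.265
    disc_sgr_sd: float = 0.5
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    metabolites: MetaboliteConfig = field(default_factory=MetaboliteConfig)

    def __post_init__(self) -> None:
        if self.light_hours + self.dark_hours != 24.0:
            raise ValueError("photoperiod hours must sum to 24")
        for name in ("n_strains", "discs_per_strain", "days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "frame_interval_min",
            "calibration_mm_per_px",
            "initial_disc_diameter_mm",
            "well_diameter_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sgr_day_sd < 0 or self.sgr_night_sd < 0 or self.disc_sgr_sd < 0:
            raise ValueError("sgr standard deviations must be non-negative")
        if self.image_size is not None and (self.image_size[0] <= 0 or self.image_size[1] <= 0):
            raise ValueError("image_size must be positive")

    @property
    def photoperiod(self) -> Photoperiod:
        return Photoperiod(self.light_hours, self.dark_hours)

    @property
    def n_discs(self) -> int:
        return self.n_strains * self.discs_per_strain

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["noise"] = NoiseConfig(**doc.get("noise", {}))
        doc["panel"] = PanelConfig(**doc.get("panel", {}))
        met = doc.get("metabolites", {})
        if "night_consumed" in met:
            met["night_consumed"] = tuple(met["night_consumed"])
        doc["metabolites"] = MetaboliteConfig(**met)
        if doc.get("image_size") is not None:
            doc["image_size"] = tuple(doc["image_size"])
        return cls(**doc)


@dataclass
class GroundTruth:
    """Known truth behind a simulated dataset.

    ``discs``: per-disc true day/night SGR (% per period, log scale),
    initial area, well and strain assignment, escape flag.
    ``strains``: per-strain RGR, SGRs, ash, carbohydrate/nitrate pools
    and consumed fractions. ``metabolite_effects``: planted (metabolite,
    timepoint, sign, target rho) associations; ``night_consumed``: the
    planted overnight-consumed metabolite set.
    """

    config: SimConfig
    discs: pd.DataFrame | None = None
    strains: pd.DataFrame | None = None
    metabolite_effects: pd.DataFrame | None = None
    night_consumed: list[str] | None = None

    def area_at(self, disc_id: str, t_min: float | np.ndarray) -> np.ndarray:
        """Analytic disc area (mm^2): A0 * exp(sum of phase rates x time)."""
        if self.discs is None:
            raise ValueError("no disc ground truth available")
        row = self.discs.set_index("disc_id").loc[disc_id]
        t = np.asarray(t_min, dtype=float)
        light_min = self.config.light_hours * 60.0
        cycle_min = 1440.0
        full = np.floor(t / cycle_min)
        tau = t - full * cycle_min
        day_periods = (full * light_min + np.minimum(tau, light_min)) / light_min
        night_periods = (full * (cycle_min - light_min) + np.maximum(tau - light_min, 0.0)) / (
            cycle_min - light_min
        )
        g = (row["sgr_day_pct"] / 100.0) * day_periods + (row["sgr_night_pct"] / 100.0) * night_periods
        return row["initial_area_mm2"] * np.exp(g)


# ---------------------------------------------------------------------------
# image stack simulation


def make_layout(config: SimConfig) -> tuple[WellLayout, tuple[int, int]]:
    """Grid layout for the configured number of discs, and image size."""
    n = config.n_discs
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    r_well = config.well_diameter_mm / 2.0 / config.calibration_mm_per_px
    pad = 3.0
    pitch = 2.0 * r_well + 2.0 * pad
    centers = np.array(
        [
            (pad + r_well + (i // cols) * pitch, pad + r_well + (i % cols) * pitch)
            for i in range(n)
        ]
    )
    h = int(np.ceil(rows * pitch + 2 * pad))
    w = int(np.ceil(cols * pitch + 2 * pad))
    if config.image_size is not None:
        h, w = config.image_size
        if centers[:, 0].max() + r_well + pad > h or centers[:, 1].max() + r_well + pad > w:
            raise ValueError("configured image_size cannot hold the well grid")
    layout = WellLayout(
        rows=rows,
        cols=cols,
        centers_px=centers,
        well_radius_px=r_well,
        well_ids=[f"well{i:02d}" for i in range(n)],
    )
    return layout, (h, w)


def _draw_disc_truth(config: SimConfig) -> pd.DataFrame:
    rows = []
    for s in range(config.n_strains):
        rng_s = np.random.default_rng([config.seed, 10, s])
        day_mean = config.sgr_day_mean + config.sgr_day_sd * rng_s.standard_normal()
        night_mean = config.sgr_night_mean + config.sgr_night_sd * rng_s.standard_normal()
        for k in range(config.discs_per_strain):
            d = s * config.discs_per_strain + k
            rng_d = np.random.default_rng([config.seed, 11, d])
            g_day = day_mean + config.disc_sgr_sd * rng_d.standard_normal()
            g_night = night_mean + config.disc_sgr_sd * rng_d.standard_normal()
            diam = config.initial_disc_diameter_mm * (
                1.0 + config.initial_diameter_cv * rng_d.standard_normal()
            )
            rows.append(
                {
                    "disc_id": f"tank1_well{d:02d}",
                    "well_id": f"well{d:02d}",
                    "strain_id": f"strain{s:02d}",
                    "sgr_day_pct": g_day,
                    "sgr_night_pct": g_night,
                    "initial_area_mm2": np.pi * (diam / 2.0) ** 2,
                    "escaped": False,
                }
            )
    return pd.DataFrame(rows)


def _paint_disc(canvas: np.ndarray, cy: float, cx: float, r: float, well: tuple[float, float, float]) -> None:
    """Add anti-aliased disc coverage into ``canvas`` (in place).

    Coverage per pixel is clip(r + 0.5 - dist, 0, 1), a sub-pixel edge
    model whose summed area converges to pi r^2; the disc is clipped to
    the physical well circle.
    """
    h, w = canvas.shape
    y0 = max(int(np.floor(cy - r)) - 1, 0)
    y1 = min(int(np.ceil(cy + r)) + 2, h)
    x0 = max(int(np.floor(cx - r)) - 1, 0)
    x1 = min(int(np.ceil(cx + r)) + 2, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1, dtype=float)[:, None]
    xx = np.arange(x0, x1, dtype=float)[None, :]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    cov = np.clip(r + 0.5 - dist, 0.0, 1.0)
    wy, wx, wr = well
    dist_w = np.sqrt((yy - wy) ** 2 + (xx - wx) ** 2)
    cov *= np.clip(wr + 0.5 - dist_w, 0.0, 1.0)
    canvas[y0:y1, x0:x1] += (DISC_INTENSITY - BACKGROUND_INTENSITY) * cov


def simulate_disc_stack(config: SimConfig) -> tuple[FrameStack, GroundTruth]:
    """Render a time-lapse stack of growing discs with known truth.

    Each disc is a filled, anti-aliased circle whose area follows
    A(t) = A0 exp(g_phase t) with phase-specific log rates; additive
    pixel noise, per-frame translation jitter, background-coloured mesh
    occlusion and multiplicative flicker are applied as configured.
    Discs grown beyond the well boundary are flagged in
    ``stack.metadata["escaped_discs"]`` (and clipped at the well wall),
    never raised as an exception.
    """
    layout, (h, w) = make_layout(config)
    discs = _draw_disc_truth(config)
    gt = GroundTruth(config=config, discs=discs)

    total_min = config.days * 1440.0
    n_frames = int(round(total_min / config.frame_interval_min))
    timestamps = np.arange(n_frames) * config.frame_interval_min

    # pre-draw nuisance streams in a fixed order
    rng_jitter = np.random.default_rng([config.seed, 1])
    rng_flicker = np.random.default_rng([config.seed, 2])
    rng_noise = np.random.default_rng([config.seed, 3])
    nz = config.noise
    if nz.jitter_px > 0:
        jitter = rng_jitter.uniform(-nz.jitter_px, nz.jitter_px, size=(n_frames, config.n_discs, 2))
    else:
        jitter = np.zeros((n_frames, config.n_discs, 2))
    if nz.flicker > 0:
        flicker = 1.0 + nz.flicker * rng_flicker.standard_normal(n_frames)
    else:
        flicker = np.ones(n_frames)

    mesh = None
    if nz.mesh_width_px > 0 and nz.mesh_pitch_px > 0:
        yy = np.arange(h) % nz.mesh_pitch_px < nz.mesh_width_px
        xx = np.arange(w) % nz.mesh_pitch_px < nz.mesh_width_px
        mesh = yy[:, None] | xx[None, :]

    cal = config.calibration_mm_per_px
    # radius trajectory per disc per frame, in px
    areas = np.stack([gt.area_at(d, timestamps) for d in discs["disc_id"]])
    radii_px = np.sqrt(areas / np.pi) / cal

    escaped = radii_px.max(axis=1) + nz.jitter_px > layout.well_radius_px
    if escaped.any():
        gt.discs.loc[escaped, "escaped"] = True

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    centers = layout.centers_px
    for f in range(n_frames):
        canvas = np.full((h, w), BACKGROUND_INTENSITY)
        for d in range(config.n_discs):
            cy = centers[d, 0] + jitter[f, d, 0]
            cx = centers[d, 1] + jitter[f, d, 1]
            _paint_disc(canvas, cy, cx, radii_px[d, f], (centers[d, 0], centers[d, 1], layout.well_radius_px))
        if mesh is not None:
            canvas[mesh] = BACKGROUND_INTENSITY
        canvas *= flicker[f]
        if nz.pixel_sd > 0:
            canvas += nz.pixel_sd * rng_noise.standard_normal((h, w))
        np.clip(canvas, 0.0, 1.0, out=canvas)
        frames[f] = np.round(canvas * 255.0).astype(np.uint8)

    stack = FrameStack(
        frames=frames,
        timestamps_min=timestamps,
        layout=layout,
        calibration_mm_per_px=cal,
        tank_id="tank1",
        metadata={
            "well_to_strain": dict(zip(discs["well_id"], discs["strain_id"])),
            "escaped_discs": discs.loc[discs["escaped"], "disc_id"].tolist(),
        },
    )
    return stack, gt


# ---------------------------------------------------------------------------
# strain panel simulation


def _lognoise(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return float(np.exp(sigma * rng.standard_normal() - 0.5 * sigma**2))


def simulate_strain_panel(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-strain biochemistry at end of day (EOD) and end of night (EON).

    Carbohydrates (starch, sucrose; umol glucose equivalents / g DW)
    peak at EOD and a strain-specific fraction is consumed overnight;
    nitrate (mg N / g DW) peaks at EON, log-coupled to the strain's true
    RGR with configurable strength, and a ~80% fraction is consumed by
    day. Ash, protein and pigments are uncoupled nuisance traits.
    """
    p = config.panel
    rows, truth = [], []
    for s in range(config.n_strains):
        rng = np.random.default_rng([config.seed, 20, s])
        rgr = float(np.clip(p.rgr_mean + p.rgr_sd * rng.standard_normal(), 0.05, 0.45))
        z = (rgr - p.rgr_mean) / p.rgr_sd if p.rgr_sd > 0 else 0.0
        eps = rng.standard_normal()
        sgr_daily = float(
            np.clip(
                p.sgr_daily_mean
                + p.sgr_daily_sd * (p.sgr_rgr_corr * z + np.sqrt(1 - p.sgr_rgr_corr**2) * eps),
                1.0,
                30.0,
            )
        )
        ratio = float(np.clip(p.night_ratio_mean + p.night_ratio_sd * rng.standard_normal(), 10.0, 95.0))
        sgr_night = sgr_daily * ratio / 100.0
        ash = float(np.clip(p.ash_mean_pct + p.ash_sd_pct * rng.standard_normal(), 5.0, 45.0))

        sucrose_eod = p.sucrose_eod_mean * _lognoise(rng, p.abundance_cv)
        starch_eod = sucrose_eod * p.starch_sucrose_ratio * _lognoise(rng, p.abundance_cv)
        f_starch = float(np.clip(p.starch_consumed_frac + p.consumed_frac_sd * rng.standard_normal(), 0.0, 1.0))
        f_sucrose = float(np.clip(p.sucrose_consumed_frac + p.consumed_frac_sd * rng.standard_normal(), 0.0, 1.0))

        nit_eps = rng.standard_normal()
        nitrate_eon = p.nitrate_eon_mean * np.exp(
            p.nitrate_log_sd * (p.nitrate_rgr_coupling * z + nit_eps) - 0.5 * p.nitrate_log_sd**2
        )
        f_nitrate = float(
            np.clip(p.nitrate_consumed_frac + p.nitrate_consumed_sd * rng.standard_normal(), 0.0, 1.0)
        )

        protein = float(np.clip(65.0 + 17.0 * rng.standard_normal(), 20.0, 120.0))
        chl_a = float(np.clip(2.0 + 0.4 * rng.standard_normal(), 0.2, 5.0))
        chl_b = float(np.clip(1.0 + 0.25 * rng.standard_normal(), 0.1, 3.0))
        carotenoids = float(np.clip(0.6 + 0.15 * rng.standard_normal(), 0.05, 2.0))

        sid = f"strain{s:02d}"
        rows.append(
            {
                "strain_id": sid,
                "ash_pct": ash,
                "starch_eod": starch_eod,
                "starch_eon": starch_eod * (1.0 - f_starch),
                "sucrose_eod": sucrose_eod,
                "sucrose_eon": sucrose_eod * (1.0 - f_sucrose),
                "nitrate_eon": nitrate_eon,
                "nitrate_eod": nitrate_eon * (1.0 - f_nitrate),
                "protein_mg_gdw": protein,
                "chl_a_mg_gdw": chl_a,
                "chl_b_mg_gdw": chl_b,
                "carotenoids_mg_gdw": carotenoids,
            }
        )
        truth.append(
            {
                "strain_id": sid,
                "rgr": rgr,
                "sgr_daily_pct": sgr_daily,
                "sgr_night_pct": sgr_night,
                "night_daily_ratio_pct": ratio,
                "ash_pct": ash,
                "starch_eod": starch_eod,
                "starch_consumed_frac": f_starch,
                "sucrose_eod": sucrose_eod,
                "sucrose_consumed_frac": f_sucrose,
                "nitrate_eon": nitrate_eon,
                "nitrate_consumed_frac": f_nitrate,
            }
        )
    panel = pd.DataFrame(rows)
    gt = GroundTruth(config=config, strains=pd.DataFrame(truth))
    return panel, gt


# ---------------------------------------------------------------------------
# metabolite matrix simulation


def simulate_metabolite_matrix(
    config: SimConfig, rgr: np.ndarray | pd.Series
) -> tuple[pd.DataFrame, GroundTruth]:
    """47-metabolite x strain x {EOD, EON} relative-abundance matrix.

    Planted metabolites carry a monotone log-normal association with
    ``rgr`` at the configured target Spearman strength and sign; the
    planted night-consumed set drops ``night_fold``-fold overnight.
    Returned in long format (``strain_id, metabolite, class, timepoint,
    value``) together with the planted ground truth.
    """
    m = config.metabolites
    rgr = np.asarray(rgr, dtype=float)
    if rgr.shape != (config.n_strains,):
        raise ValueError("rgr must have one value per strain")
    for name in list(m.planted_eod) + list(m.planted_eon) + list(m.night_consumed):
        if name not in CATALOGUE:
            raise ValueError(f"unknown metabolite {name!r}: not in the 47-name catalogue")

    sd = rgr.std()
    z = (rgr - rgr.mean()) / sd if sd > 0 else np.zeros_like(rgr)
    rho = m.target_rho
    mix = np.sqrt(max(0.0, 1.0 - rho**2))

    rows = []
    effects = []
    for j, met in enumerate(CATALOGUE):
        rng = np.random.default_rng([config.seed, 30, j])
        mu = np.log(100.0) + 0.8 * rng.standard_normal()
        fold = m.night_fold if met in m.night_consumed else 1.0
        for timepoint, planted in (("EOD", m.planted_eod), ("EON", m.planted_eon)):
            eps = rng.standard_normal(config.n_strains)
            sign = planted.get(met)
            latent = (sign * rho * z + mix * eps) if sign is not None else eps
            values = np.exp(mu - (np.log(fold) if timepoint == "EON" else 0.0) + m.abundance_sigma * latent)
            if sign is not None:
                effects.append(
                    {"metabolite": met, "timepoint": timepoint, "sign": sign, "target_rho": rho}
                )
            for s in range(config.n_strains):
                rows.append(
                    {
                        "strain_id": f"strain{s:02d}",
                        "metabolite": met,
                        "class": METABOLITE_CLASS[met],
                        "timepoint": timepoint,
                        "value": values[s],
                    }
                )
    matrix = pd.DataFrame(rows)
    gt = GroundTruth(
        config=config,
        metabolite_effects=pd.DataFrame(effects, columns=["metabolite", "timepoint", "sign", "target_rho"]),
        night_consumed=list(m.night_consumed),
    )
    return matrix, gt
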