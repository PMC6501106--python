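"""Image analysis for disc-based growth phenotyping.

Turns raw time-lapse frame stacks of *Ulva* discs held in gridded well
plates into per-disc area time series: 30-min temporal consensus,
per-well segmentation, pixel-to-mm calibration, photoperiod phase
labelling and QC.

The segmentation strategy is deliberately simple and robust to the two
dominant artefacts of a tank-top camera rig: global illumination flicker
(handled by per-well Otsu thresholding, which is invariant to monotone
intensity changes) and the nylon retaining mesh occluding the disc
(handled by morphological closing and hole filling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import convex_hull_image, disk

__all__ = [
    "Photoperiod",
    "WellLayout",
    "FrameStack",
    "AreaSeries",
    "build_consensus",
    "segment_discs",
    "extract_area_series",
    "qc_series",
]


class ImagingError(ValueError):
    """Raised for invalid imaging inputs (empty windows, bad shapes...)."""


@dataclass(frozen=True)
class Photoperiod:
    """A light:dark clock anchored at lights-on (t = 0 minutes).

    A sample falling exactly on a phase boundary is assigned to the
    phase that is *ending* there, so an end-of-day sample belongs to the
    day and an end-of-night sample to the night.
    """

    light_hours: float = 12.0
    dark_hours: float = 12.0

    def __post_init__(self) -> None:
        if self.light_hours <= 0 or self.dark_hours <= 0:
            raise ValueError("photoperiod phases must be positive")

    @property
    def cycle_min(self) -> float:
        return 60.0 * (self.light_hours + self.dark_hours)

    @property
    def light_min(self) -> float:
        return 60.0 * self.light_hours

    def phase_at(self, t_min: float) -> str:
        """Return ``"day"`` or ``"night"`` for a time in minutes."""
        tau = float(t_min) % self.cycle_min
        if tau == 0.0:
            return "night"  # the previous night is ending at lights-on
        return "day" if tau <= self.light_min else "night"

    def boundaries(self, t_end_min: float) -> np.ndarray:
        """All phase-boundary times in [0, t_end_min]."""
        bounds = [0.0]
        t = 0.0
        while True:
            t += self.light_min
            if t > t_end_min:
                break
            bounds.append(t)
            t += self.cycle_min - self.light_min
            if t > t_end_min:
                break
            bounds.append(t)
        return np.asarray(bounds)


@dataclass
class WellLayout:
    """Grid of circular wells on the camera image, in pixel coordinates.

    ``centers_px`` is an (n_wells, 2) array of (row, col) pixel centres,
    row-major from the top-left well.
    """

    rows: int
    cols: int
    centers_px: np.ndarray
    well_radius_px: float
    well_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers_px = np.asarray(self.centers_px, dtype=float)
        if self.centers_px.ndim != 2 or self.centers_px.shape[1] != 2:
            raise ValueError("centers_px must be (n, 2)")
        if self.well_radius_px <= 0:
            raise ValueError("well_radius_px must be positive")
        if not self.well_ids:
            self.well_ids = [f"well{i:02d}" for i in range(len(self.centers_px))]
        if len(self.well_ids) != len(self.centers_px):
            raise ValueError("well_ids length mismatch")

    @property
    def n_wells(self) -> int:
        return len(self.centers_px)

    def to_json(self, path: str | Path, calibration_mm_per_px: float | None = None) -> None:
        doc = {
            "rows": self.rows,
            "cols": self.cols,
            "centers_px": self.centers_px.tolist(),
            "well_radius_px": self.well_radius_px,
            "well_ids": self.well_ids,
        }
        if calibration_mm_per_px is not None:
            doc["calibration_mm_per_px"] = calibration_mm_per_px
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "WellLayout":
        doc = json.loads(Path(path).read_text())
        return cls(
            rows=doc["rows"],
            cols=doc["cols"],
            centers_px=np.asarray(doc["centers_px"], dtype=float),
            well_radius_px=doc["well_radius_px"],
            well_ids=list(doc["well_ids"]),
        )


@dataclass
class FrameStack:
    """Ordered time-lapse frames of one tank with layout and calibration.

    ``frames`` is a (T, H, W) or (T, H, W, 3) array, or a list of 2D/3D
    arrays of identical shape. Timestamps are minutes since experiment
    start (lights-on).
    """

    frames: np.ndarray | Sequence[np.ndarray]
    timestamps_min: np.ndarray
    layout: WellLayout
    calibration_mm_per_px: float
    tank_id: str = "tank1"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps_min = np.asarray(self.timestamps_min, dtype=float)
        if len(self.frames) != len(self.timestamps_min):
            raise ValueError("one timestamp per frame required")
        if len(self.frames) == 0:
            raise ValueError("empty frame stack")
        if np.any(np.diff(self.timestamps_min) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        shape0 = np.asarray(self.frames[0]).shape
        for f in self.frames:
            if np.asarray(f).shape != shape0:
                raise ValueError("all frames must share dimensions")
        if self.calibration_mm_per_px <= 0:
            raise ValueError("calibration must be positive")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class AreaSeries:
    """Per-disc segmented-area time series with phase annotation.

    ``data`` columns: ``t_min`` (minutes since lights-on), ``phase``
    (day/night), ``area_mm2``, ``flag`` ("ok", "empty", "unstable",
    "masked").
    """

    disc_id: str
    strain_id: str | None
    data: pd.DataFrame
    photoperiod: Photoperiod = field(default_factory=Photoperiod)

    def __post_init__(self) -> None:
        required = {"t_min", "phase", "area_mm2", "flag"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"AreaSeries data needs columns {sorted(required)}")
        if (self.data["area_mm2"].dropna() < 0).any():
            raise ValueError("areas must be non-negative")

    def valid(self) -> pd.DataFrame:
        d = self.data
        return d[(d["flag"] == "ok") & (d["area_mm2"] > 0)]

    def normalized(self) -> pd.Series:
        """Area relative to the first valid point (disc size ratio)."""
        v = self.valid()
        if v.empty:
            raise ImagingError("no valid points to normalize against")
        return self.data["area_mm2"] / v["area_mm2"].iloc[0]

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "disc_id", self.disc_id)
        out.insert(1, "strain_id", self.strain_id)
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# consensus


def build_consensus(frames: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel arithmetic mean of the frames in one time window.

    Mirrors merging every image of a 30-min segment into a single
    consensus image, suppressing transient noise from water movement.
    Output is floating point regardless of input dtype.
    """
    if len(frames) == 0:
        raise ImagingError("no frames in consensus window")
    shape0 = np.asarray(frames[0]).shape
    for f in frames:
        if np.asarray(f).shape != shape0:
            raise ImagingError("consensus frames must share dimensions")
    acc = np.zeros(shape0, dtype=np.float64)
    for f in frames:
        acc += np.asarray(f, dtype=np.float64)
    return acc / len(frames)


# ---------------------------------------------------------------------------
# segmentation


def _to_intensity(image: np.ndarray) -> np.ndarray:
    """Map an image to a float foreground-intensity plane in ~[0, 1].

    RGB images use the excess-green index 2G - R - B (discs are green);
    grayscale images are used as-is. Integer dtypes are scaled by their
    max value.
    """
    img = np.asarray(image)
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float64) / np.iinfo(image.dtype).max
    else:
        img = img.astype(np.float64)
    if img.ndim == 3:
        if img.shape[2] < 3:
            raise ImagingError("colour images must have 3 channels")
        img = 2.0 * img[..., 1] - img[..., 0] - img[..., 2]
    elif img.ndim != 2:
        raise ImagingError("image must be 2D or RGB")
    return img


def segment_discs(
    image: np.ndarray,
    layout: WellLayout,
    *,
    mesh_bridge_px: int = 1,
    min_contrast: float = 0.08,
    fill_convex: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment one disc per well and report its filled pixel area.

    Within each well circle the intensity histogram is thresholded by
    Otsu's method; mesh-line gaps are bridged by morphological closing
    (structuring disk of radius ``mesh_bridge_px``) and hole filling,
    and the largest connected component is kept. Because excised discs
    are convex, mesh-occluded pixels are then recovered by adding the
    background-level ("dark") pixels inside the component's convex
    hull (``fill_convex``); mid-level anti-aliased edge pixels are not
    added, so the hull does not inflate the rim. Pixels outside well
    circles are ignored. Wells whose foreground/background contrast
    falls below ``min_contrast`` (on the ~[0, 1] intensity scale) are
    reported as empty with area 0 rather than as errors.

    Returns a label map (well index + 1 marks each disc) and a table
    with columns ``well_id, area_px, flag``.
    """
    img = _to_intensity(image)
    h, w = img.shape
    labels = np.zeros((h, w), dtype=np.int32)
    rows = []
    r_well = layout.well_radius_px
    footprint = disk(mesh_bridge_px) if mesh_bridge_px > 0 else None
    for i, (cy, cx) in enumerate(layout.centers_px):
        y0 = max(int(np.floor(cy - r_well)) - 1, 0)
        y1 = min(int(np.ceil(cy + r_well)) + 2, h)
        x0 = max(int(np.floor(cx - r_well)) - 1, 0)
        x1 = min(int(np.ceil(cx + r_well)) + 2, w)
        if y0 >= y1 or x0 >= x1:
            raise ImagingError("well layout extends outside the image")
        sub = img[y0:y1, x0:x1]
        yy, xx = np.mgrid[y0:y1, x0:x1]
        in_well = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_well**2
        vals = sub[in_well]
        area, flag = 0, "empty"
        if vals.size and np.ptp(vals) > 1e-12:
            th = threshold_otsu(vals)
            mu_bg = vals[vals <= th].mean()
            contrast = vals[vals > th].mean() - mu_bg
            # re-anchor at the midpoint of the two class means: unlike the
            # raw Otsu cut this is stable across frames, so the included
            # anti-aliased edge ring does not wander between windows
            th = mu_bg + 0.5 * contrast
            raw = (sub > th) & in_well
            if raw.any() and (~raw & in_well).any():
                if contrast >= min_contrast:
                    fg = raw
                    if footprint is not None:
                        fg = ndi.binary_closing(fg, structure=footprint) & in_well
                    fg = ndi.binary_fill_holes(fg)
                    comp = cc_label(fg)
                    if comp.max() > 0:
                        largest = np.argmax(np.bincount(comp.ravel())[1:]) + 1
                        keep = raw & (comp == largest)
                        if fill_convex and keep.any():
                            # occluded mesh pixels sit at background level
                            # inside the disc hull; recover them without
                            # absorbing mid-level anti-aliased edge pixels
                            dark = sub < mu_bg + 0.1 * contrast
                            hull = convex_hull_image(keep)
                            keep = keep | (hull & ~raw & dark & in_well)
                        area = int(keep.sum())
                        flag = "ok"
                        labels[y0:y1, x0:x1][keep] = i + 1
        rows.append({"well_id": layout.well_ids[i], "area_px": area, "flag": flag})
    return labels, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# series extraction


def extract_area_series(
    stack: FrameStack,
    photoperiod: Photoperiod | None = None,
    *,
    window_min: float = 30.0,
    mesh_bridge_px: int = 1,
    min_contrast: float = 0.08,
    drop_fraction: float = 0.5,
) -> list[AreaSeries]:
    """Extract one calibrated area series per well from a frame stack.

    Frames are grouped into half-open windows ``[t0 + k*window,
    t0 + (k+1)*window)`` anchored at the first frame, averaged into a
    consensus image, segmented per well, and converted to mm**2 with the
    stack calibration. Each consensus point is timestamped at the window
    midpoint and phase-labelled from the photoperiod clock. Points whose
    area drops by more than ``drop_fraction`` relative to the previous
    valid point are flagged "unstable" (disc escape or folding).
    """
    if photoperiod is None:
        photoperiod = Photoperiod()
    t = stack.timestamps_min
    t0 = t[0]
    idx = np.floor((t - t0) / window_min).astype(int)
    n_windows = idx.max() + 1
    strain_map = stack.metadata.get("well_to_strain", {})

    records: dict[str, list[dict]] = {wid: [] for wid in stack.layout.well_ids}
    cal2 = stack.calibration_mm_per_px**2
    for k in range(n_windows):
        members = np.nonzero(idx == k)[0]
        if members.size == 0:
            continue
        consensus = build_consensus([stack.frames[j] for j in members])
        t_mid = t0 + (k + 0.5) * window_min
        _, table = segment_discs(
            consensus,
            stack.layout,
            mesh_bridge_px=mesh_bridge_px,
            min_contrast=min_contrast,
        )
        phase = photoperiod.phase_at(t_mid)
        for _, row in table.iterrows():
            records[row["well_id"]].append(
                {
                    "t_min": t_mid,
                    "phase": phase,
                    "area_mm2": row["area_px"] * cal2,
                    "flag": row["flag"],
                }
            )

    out = []
    for wid in stack.layout.well_ids:
        df = pd.DataFrame(records[wid])
        # flag sudden collapses relative to the last valid area
        prev = None
        flags = df["flag"].to_list()
        for j, (a, f) in enumerate(zip(df["area_mm2"], flags)):
            if f != "ok":
                continue
            if prev is not None and a < (1.0 - drop_fraction) * prev:
                flags[j] = "unstable"
            else:
                prev = a
        df["flag"] = flags
        out.append(
            AreaSeries(
                disc_id=f"{stack.tank_id}_{wid}",
                strain_id=strain_map.get(wid),
                data=df,
                photoperiod=photoperiod,
            )
        )
    return out


# ---------------------------------------------------------------------------
# QC


def qc_series(
    series: AreaSeries,
    *,
    jump_factor: float = 3.0,
    max_masked_fraction: float = 0.2,
    median_window: int = 5,
) -> tuple[AreaSeries | None, dict]:
    """Mask low-quality points; exclude series with too many of them.

    Points already flagged by segmentation and points deviating from a
    centred rolling median by more than ``jump_factor`` (either way) are
    masked. If more than ``max_masked_fraction`` of points end up
    masked the series is excluded (``None`` returned) with the reason
    recorded in the report.
    """
    if series.data.empty:
        raise ImagingError("empty series")
    df = series.data.copy()
    n = len(df)
    masked = df["flag"] != "ok"

    area = df["area_mm2"].where(~masked)
    ref = area.rolling(median_window, center=True, min_periods=1).median()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df["area_mm2"] / ref
    jump = (~masked) & ((ratio > jump_factor) | (ratio < 1.0 / jump_factor))
    df.loc[jump, "flag"] = "masked"
    masked = df["flag"] != "ok"

    report: dict = {
        "disc_id": series.disc_id,
        "n_points": int(n),
        "n_masked": int(masked.sum()),
        "masked_fraction": float(masked.sum() / n),
        "excluded": False,
    }
    if report["masked_fraction"] > max_masked_fraction:
        report["excluded"] = True
        report["reason"] = "insufficient valid points"
        return None, report
    cleaned = AreaSeries(
        disc_id=series.disc_id,
        strain_id=series.strain_id,
        data=df,
        photoperiod=series.photoperiod,
    )
    return cleaned, report
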