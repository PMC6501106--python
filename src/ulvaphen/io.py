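"""Disk formats: PNG/TIFF frame directories with JSON layout sidecars.

Frames are written one file per timepoint as
``<tank>_<ISO8601 timestamp>.png`` next to a ``layout.json`` sidecar
holding the well grid and the mm-per-pixel calibration; timestamps are
recovered from the filenames on reading.
"""

from __future__ import annotations

import json
import re
from datetime import datetime, timedelta
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .imaging import FrameStack, WellLayout

__all__ = ["write_frames", "read_frames"]

_DEFAULT_T0 = datetime(2018, 6, 1, 8, 0, 0)  # lights-on
_STAMP_RE = re.compile(r"^(?P<tank>.+)_(?P<stamp>\d{4}-\d{2}-\d{2}T\d{2}[-:]\d{2}[-:]\d{2})\.(png|tif|tiff)$")


def write_frames(
    stack: FrameStack,
    directory: str | Path,
    *,
    start: datetime = _DEFAULT_T0,
    fmt: str = "png",
) -> Path:
    """Write a stack as one image per frame plus a layout sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for frame, t in zip(stack.frames, stack.timestamps_min):
        stamp = (start + timedelta(minutes=float(t))).strftime("%Y-%m-%dT%H-%M-%S")
        iio.imwrite(directory / f"{stack.tank_id}_{stamp}.{fmt}", np.asarray(frame))
    sidecar = directory / "layout.json"
    stack.layout.to_json(sidecar, calibration_mm_per_px=stack.calibration_mm_per_px)
    meta = directory / "metadata.json"
    meta.write_text(json.dumps({"tank_id": stack.tank_id, **stack.metadata}, indent=1))
    return directory


def read_frames(directory: str | Path) -> FrameStack:
    """Load a frame directory written by :func:`write_frames`."""
    directory = Path(directory)
    layout_path = directory / "layout.json"
    doc = json.loads(layout_path.read_text())
    layout = WellLayout.from_json(layout_path)
    calibration = doc.get("calibration_mm_per_px")
    if calibration is None:
        raise ValueError("layout sidecar lacks calibration_mm_per_px")

    entries = []
    tank_id = None
    for f in sorted(directory.iterdir()):
        m = _STAMP_RE.match(f.name)
        if not m:
            continue
        tank_id = m.group("tank")
        stamp = m.group("stamp").replace(":", "-")  # accept ISO colons too
        entries.append((datetime.strptime(stamp, "%Y-%m-%dT%H-%M-%S"), f))
    if not entries:
        raise ValueError(f"no frame files found in {directory}")
    entries.sort()
    t0 = entries[0][0]
    frames = [iio.imread(f) for _, f in entries]
    timestamps = np.array([(t - t0).total_seconds() / 60.0 for t, _ in entries])

    metadata = {}
    meta_path = directory / "metadata.json"
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text())
        tank_id = metadata.pop("tank_id", tank_id)
    return FrameStack(
        frames=frames,
        timestamps_min=timestamps,
        layout=layout,
        calibration_mm_per_px=calibration,
        tank_id=tank_id or "tank1",
        metadata=metadata,
    )
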