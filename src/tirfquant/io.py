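"""File I/O: TIFF stacks, ROI masks and polygons, metadata, tidy tables."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .traces import FootprintTrace, ImageStack, polygon_to_mask

__all__ = [
    "load_stack",
    "save_stack",
    "load_mask",
    "save_mask",
    "load_polygon_masks",
    "load_metadata",
    "trace_to_frame",
]


def load_stack(
    path: str | Path,
    channel_label: str = "",
    frame_interval: float = 10.0,
    start_time: float = 0.0,
) -> ImageStack:
    """Read a multi-page TIFF as a (time, height, width) ImageStack."""
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(
        frames=np.asarray(frames, dtype=float),
        channel_label=channel_label,
        frame_interval=frame_interval,
        start_time=start_time,
    )


def save_stack(path: str | Path, stack: ImageStack) -> None:
    tifffile.imwrite(path, stack.frames.astype(np.float32))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask image (PNG or TIFF); any nonzero pixel is True."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    if img.ndim == 3:  # collapse RGB(A)
        img = img[..., :3].max(axis=-1)
    return np.asarray(img) > 0


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    data = (np.asarray(mask, dtype=bool) * np.uint8(255))
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def load_polygon_masks(
    path: str | Path, shape: tuple[int, int]
) -> dict[str, np.ndarray]:
    """Rasterize polygon ROIs from a CSV with columns roi_id, vertex_index, x, y.

    Coordinates are 0-based pixels, x = column, y = row.  Returns one
    boolean mask per roi_id.
    """
    table = pd.read_csv(path)
    required = {"roi_id", "vertex_index", "x", "y"}
    if not required.issubset(table.columns):
        raise ValueError(f"polygon CSV must have columns {sorted(required)}")
    masks = {}
    for roi_id, group in table.groupby("roi_id", sort=False):
        vertices = (
            group.sort_values("vertex_index")[["x", "y"]].to_numpy(dtype=float)
        )
        masks[str(roi_id)] = polygon_to_mask(vertices, shape)
    return masks


def load_metadata(path: str | Path) -> dict:
    """Read a YAML metadata file (channel labels, frame interval, timing)."""
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise ValueError("metadata file must contain a mapping")
    return meta


def trace_to_frame(trace: FootprintTrace, cell_id: str, channel: str) -> pd.DataFrame:
    """Tidy one trace: cell_id, channel, time_s, raw, background, corrected, normalized."""
    return pd.DataFrame(
        {
            "cell_id": cell_id,
            "channel": channel,
            "time_s": trace.time,
            "raw": trace.raw,
            "background": trace.background,
            "corrected": trace.corrected,
            "normalized": trace.normalized,
        }
    )
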