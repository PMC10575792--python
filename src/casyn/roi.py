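"""Disc-ROI measurement over co-registered fluorescence and ion images.

ROIs are discs (default radius 6 px, 113 interior pixels) placed at
hand-picked centers; for every channel the pixel mean over the disc is
recorded, background-subtracted.  Downstream filters: ROIs whose
background-subtracted 40Ca signal is indistinguishable from background
noise are dropped, and the remainder can be split into calcium-binding /
non-binding groups at a mean-counts threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROI",
    "ROIOutOfBoundsError",
    "disc_offsets",
    "disc_mask",
    "measure_rois",
    "filter_low_ca",
    "split_binding_groups",
]

CA_CHANNEL = "Ca40"


class ROIOutOfBoundsError(ValueError):
    pass


@dataclass(frozen=True)
class ROI:
    """Disc region of interest: center in (row, col) pixels, radius in px."""

    roi_id: int
    row: int
    col: int
    radius: int = 6

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")


def disc_offsets(radius: int) -> np.ndarray:
    """Integer (di, dj) offsets with di^2 + dj^2 <= radius^2.

    The boundary is inclusive; a radius-6 disc contains exactly 113 pixels.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(radius)
    di, dj = np.mgrid[-r:r + 1, -r:r + 1]
    keep = di * di + dj * dj <= radius * radius
    return np.column_stack([di[keep], dj[keep]])


def disc_mask(shape: tuple[int, int], center: tuple[int, int],
              radius: int) -> np.ndarray:
    """Boolean image mask of the disc; errors if the disc leaves the image."""
    off = disc_offsets(radius)
    rows = off[:, 0] + center[0]
    cols = off[:, 1] + center[1]
    h, w = shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= w:
        raise ROIOutOfBoundsError(
            f"disc at {center} radius {radius} exceeds image {shape}")
    mask = np.zeros(shape, dtype=bool)
    mask[rows, cols] = True
    return mask


def measure_rois(
    channels: Mapping[str, np.ndarray],
    rois: Sequence[ROI],
    background: Mapping[str, float],
) -> pd.DataFrame:
    """Background-subtracted per-ROI disc means, one column per channel.

    Every channel image must share shape and registration.  Backgrounds are
    per-channel scalars (typically means over user-designated background
    pixels).  Negative results are legitimate — noise below background.
    """
    if not channels:
        raise ValueError("no channels given")
    shapes = {np.asarray(a).shape for a in channels.values()}
    if len(shapes) > 1:
        raise ValueError(f"channel images differ in shape: {shapes}")
    shape = shapes.pop()
    missing = set(channels) - set(background)
    if missing:
        raise ValueError(f"missing background for channels: {sorted(missing)}")
    rows = []
    for roi in rois:
        off = disc_offsets(roi.radius)
        rr = off[:, 0] + roi.row
        cc = off[:, 1] + roi.col
        if (rr.min() < 0 or cc.min() < 0
                or rr.max() >= shape[0] or cc.max() >= shape[1]):
            raise ROIOutOfBoundsError(
                f"ROI {roi.roi_id} at ({roi.row}, {roi.col}) radius "
                f"{roi.radius} exceeds image {shape}")
        rec = {"roi_id": roi.roi_id}
        for name, img in channels.items():
            rec[name] = float(np.asarray(img)[rr, cc].mean()) - float(
                background[name])
        rows.append(rec)
    return pd.DataFrame(rows)


def filter_low_ca(
    table: pd.DataFrame,
    sigma_bg: float,
    channel: str = CA_CHANNEL,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Flag ROIs whose 40Ca signal is at or below background noise.

    Background-subtracted 40Ca intensities are modeled as zero-mean normal
    noise with SD ``sigma_bg`` (estimated from background samples); ROIs
    with value <= +1 sigma are flagged removed.  ``two_sided=True`` instead
    removes |value| <= sigma, keeping signals significantly *below*
    background too.  Returns a copy with a boolean ``retained`` column.
    """
    if not sigma_bg > 0:
        raise ValueError("sigma_bg must be positive")
    if channel not in table.columns:
        raise KeyError(f"channel {channel!r} not in table")
    out = table.copy()
    v = out[channel].to_numpy(dtype=float)
    if two_sided:
        out["retained"] = np.abs(v) > sigma_bg
    else:
        out["retained"] = v > sigma_bg
    return out


def split_binding_groups(
    table: pd.DataFrame,
    threshold: float = 2.0,
    channel: str = CA_CHANNEL,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Partition ROIs into Ca-binding (> threshold mean counts) and the rest.

    Returns (binding, non_binding, fractions); the default threshold of 2
    mean 40Ca counts per ROI separates regions rich in calcium-binding
    proteins from the bulk of the cell.
    """
    if len(table) == 0:
        raise ValueError("empty ROI table")
    if channel not in table.columns:
        raise KeyError(f"channel {channel!r} not in table")
    high = table[table[channel] > threshold]
    low = table[table[channel] <= threshold]
    n = float(len(table))
    fractions = {"binding": len(high) / n, "non_binding": len(low) / n}
    return high.reset_index(drop=True), low.reset_index(drop=True), fractions
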