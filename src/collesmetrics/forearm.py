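"""Forearm boundary tracing, width lines and swelling ratios.

On the pre-processed (vertical-forearm) image the outer soft-tissue boundary
is traced row by row below the lunate landmark with Canny edges; eight
horizontal width lines are laid out at 1 cm physical spacing and ten ratios
are formed between them. Soft-tissue swelling after a fracture changes the
width profile near the wrist relative to the shaft, which the ratios are
designed to capture; because every reported quantity is a ratio, the pixel
units cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation as nd_binary_dilation
from scipy.ndimage import median_filter

from .config import CannyConfig, WidthConfig
from .preprocess import _auto_canny

RATIO_NAMES = (
    "W1 / W4",
    "W2 / W4",
    "W3 / W4",
    "W5 / W4",
    "W6 / W4",
    "W7 / W4",
    "W8 / W4",
    "Min width / Max width",
    "W1+W8 / W4+W5",
    "W1+W2 / W7+W8",
)


@dataclass
class WidthSet:
    """Eight forearm widths (pixels), W1 most distal (closest to the wrist)."""

    widths_px: np.ndarray
    line_rows: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.widths_px = np.asarray(self.widths_px, dtype=float)
        self.line_rows = np.asarray(self.line_rows, dtype=int)
        if self.widths_px.shape != (8,) or self.line_rows.shape != (8,):
            raise ValueError("a WidthSet holds exactly 8 width lines")
        if not np.all(self.widths_px > 0):
            raise ValueError("forearm widths must be positive")
        if not np.all(np.diff(self.line_rows) > 0):
            raise ValueError("width line rows must be strictly increasing")


def trace_forearm_boundaries(
    image: np.ndarray,
    lunate: tuple[float, float],
    width_cfg: WidthConfig | None = None,
    canny_cfg: CannyConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Outermost left/right forearm edge columns for each row at and below
    the lunate row.

    Edges bordering exactly-zero pixels (collimator mask, rotation fill) are
    ignored: the exposed field is always strictly positive, so those edges
    delimit artefacts, not anatomy. Rows where no edge pair is found are
    interpolated from neighbours; more than ``max_missing_frac`` missing rows
    is an error. Both boundaries are median-smoothed over
    ``smooth_window_rows`` rows.
    """
    width_cfg = width_cfg or WidthConfig()
    canny_cfg = canny_cfg or CannyConfig()
    image = np.asarray(image, dtype=float)
    r_lun = int(round(lunate[0]))
    if not 0 <= r_lun < image.shape[0] - 1:
        raise ValueError("lunate landmark outside image")

    edges = _auto_canny(image, canny_cfg)
    near_zero = nd_binary_dilation(image == 0, iterations=3)
    edges &= ~near_zero

    region = edges[r_lun:, :]
    n_rows = region.shape[0]
    left = np.full(n_rows, np.nan)
    right = np.full(n_rows, np.nan)
    for i in range(n_rows):
        cols = np.flatnonzero(region[i])
        if cols.size >= 2:
            left[i] = cols[0]
            right[i] = cols[-1]
    missing = np.isnan(left)
    if missing.mean() > width_cfg.max_missing_frac:
        raise ValueError(
            f"forearm boundary not found ({missing.mean():.0%} of rows have "
            "no edge pair)"
        )
    idx = np.arange(n_rows)
    good = ~missing
    left = np.interp(idx, idx[good], left[good])
    right = np.interp(idx, idx[good], right[good])
    w = width_cfg.smooth_window_rows
    left = median_filter(left, size=w, mode="nearest")
    right = median_filter(right, size=w, mode="nearest")
    return left, right


def measure_widths(
    boundaries: tuple[np.ndarray, np.ndarray],
    lunate: tuple[float, float],
    spacing_mm: float,
    cfg: WidthConfig | None = None,
) -> WidthSet:
    """Sample the 8 width lines: line 1 sits ``first_line_offset_mm`` below
    the lunate row, lines 2-8 each ``line_spacing_mm`` (1 cm) further."""
    cfg = cfg or WidthConfig()
    left, right = boundaries
    r_lun = int(round(lunate[0]))
    gap = int(round(cfg.line_spacing_mm / spacing_mm))
    first = int(round(cfg.first_line_offset_mm / spacing_mm))
    offsets = first + gap * np.arange(8)
    if offsets[-1] >= left.shape[0]:
        raise ValueError(
            "insufficient forearm extent: 8 width lines need "
            f"{offsets[-1] + 1} traced rows, have {left.shape[0]}"
        )
    widths = right[offsets] - left[offsets]
    return WidthSet(widths_px=widths, line_rows=r_lun + offsets, spacing_mm=spacing_mm)


def compute_ratios(widthset: WidthSet) -> dict[str, float]:
    """The ten named swelling ratios of the width family."""
    w = widthset.widths_px
    if np.any(w <= 0):
        raise ValueError("cannot form ratios with non-positive widths")
    w1, w2, w3, w4, w5, w6, w7, w8 = w
    return {
        "W1 / W4": w1 / w4,
        "W2 / W4": w2 / w4,
        "W3 / W4": w3 / w4,
        "W5 / W4": w5 / w4,
        "W6 / W4": w6 / w4,
        "W7 / W4": w7 / w4,
        "W8 / W4": w8 / w4,
        "Min width / Max width": np.min(w) / np.max(w),
        "W1+W8 / W4+W5": (w1 + w8) / (w4 + w5),
        "W1+W2 / W7+W8": (w1 + w2) / (w7 + w8),
    }
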