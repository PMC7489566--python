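"""Intensity-profile texture of the distal radius.

From the radial styloid, two straight sampling lines are laid out at 30 and
45 degrees from the styloid-to-lunate baseline, rotated in the sense that
carries them into the radius. Each line is sampled at 1 px steps with
bilinear interpolation and terminated where the intensity drops sharply —
the edge of the radius, where the ray leaves bone for the dark inter-bone
gap. Five statistics per line (full-line slope, short-segment slope, raw and
detrended standard deviation, and length) quantify the intensity trend and
texture of the bone crossed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from ._geometry import rotate_direction
from .config import ProfileConfig

logger = logging.getLogger(__name__)

PROFILE_STAT_NAMES = (
    "Slope profile 1 (full line)",
    "Slope profile 2 (full line)",
    "Slope profile 1 (short segment)",
    "Slope profile 2 (short segment)",
    "Std profile 1",
    "Std profile 2",
    "Std profile 1 adjusted",
    "Std profile 2 adjusted",
    "Distance profile 1",
    "Distance profile 2",
)


@dataclass
class ProfileTrace:
    angle_offset_deg: float
    positions_px: np.ndarray
    intensity: np.ndarray
    terminated: bool
    origin: tuple[float, float] = (0.0, 0.0)
    direction: tuple[float, float] = (0.0, 0.0)  # unit (row, col)

    def __post_init__(self) -> None:
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.positions_px.size < 5:
            raise ValueError("profile trace needs at least 5 samples")


@dataclass
class ProfileStats:
    slope_full: float
    slope_short: float
    std_raw: float
    std_adjusted: float
    distance: float


def _sample_ray(
    image: np.ndarray, origin: np.ndarray, direction: np.ndarray, step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear samples along origin + t*direction until the image border."""
    h, w = image.shape
    # parametric distance to each border along the ray
    t_max = np.inf
    for coord, d, limit in (
        (origin[0], direction[0], h - 1),
        (origin[1], direction[1], w - 1),
    ):
        if d > 1e-12:
            t_max = min(t_max, (limit - coord) / d)
        elif d < -1e-12:
            t_max = min(t_max, -coord / d)
    if not np.isfinite(t_max) or t_max <= 0:
        return np.array([]), np.array([])
    t = np.arange(0.0, t_max, step)
    rows = origin[0] + t * direction[0]
    cols = origin[1] + t * direction[1]
    values = map_coordinates(
        np.asarray(image, dtype=float), [rows, cols], order=1, mode="constant"
    )
    return t, values


def trace_profile(
    image: np.ndarray,
    lunate: tuple[float, float],
    styloid: tuple[float, float],
    offset_deg: float,
    cfg: ProfileConfig | None = None,
    force_sense: int | None = None,
) -> ProfileTrace:
    """Trace one profile line from the styloid.

    The baseline runs from the styloid to the lunate; the profile direction
    is the baseline rotated by ``offset_deg`` in the sense that enters the
    bone, auto-resolved by comparing the mean of the first 10 samples of the
    two candidate senses (``force_sense`` = +1/-1 overrides). Termination:
    the first sample below ``edge_drop_frac`` x the median of the first
    quarter of the border-limited ray.
    """
    if offset_deg not in (30, 45):
        raise ValueError("offset_deg must be 30 or 45")
    cfg = cfg or ProfileConfig()
    image = np.asarray(image, dtype=float)
    sty = np.asarray(styloid, dtype=float)
    baseline = np.asarray(lunate, dtype=float) - sty
    norm = np.linalg.norm(baseline)
    if norm == 0:
        raise ValueError("lunate and styloid landmarks coincide")
    baseline /= norm

    candidates = {}
    for sense in (+1, -1):
        direction = rotate_direction(baseline, sense * offset_deg)
        t, values = _sample_ray(image, sty, direction, cfg.step_px)
        candidates[sense] = (direction, t, values)
    if force_sense is None:
        score = {
            s: (v[:10].mean() if v.size else -np.inf)
            for s, (_, _, v) in candidates.items()
        }
        sense = max(score, key=score.get)
    else:
        sense = force_sense
    direction, t, values = candidates[sense]
    if t.size < 5:
        raise ValueError("profile immediately terminated (ray leaves the image)")

    quarter = max(5, t.size // 4)
    reference = float(np.median(values[:quarter]))
    positive = image[image > 0]
    floor = float(np.median(positive)) if positive.size else 0.0
    if float(np.mean(values[:10])) <= floor:
        raise ValueError(
            "profile immediately terminated (styloid does not sit on bone)"
        )

    threshold = cfg.edge_drop_frac * reference
    below = np.flatnonzero(values < threshold)
    terminated = below.size > 0
    end = int(below[0]) if terminated else t.size
    if end < 5:
        raise ValueError("profile immediately terminated (edge too close)")
    return ProfileTrace(
        angle_offset_deg=float(offset_deg),
        positions_px=t[:end],
        intensity=values[:end],
        terminated=terminated,
        origin=(float(sty[0]), float(sty[1])),
        direction=(float(direction[0]), float(direction[1])),
    )


def detrend(trace: ProfileTrace) -> np.ndarray:
    """Residuals of the least-squares line fit of intensity vs position
    (zero mean, zero slope)."""
    coeffs = np.polyfit(trace.positions_px, trace.intensity, 1)
    return trace.intensity - np.polyval(coeffs, trace.positions_px)


def profile_statistics(
    trace: ProfileTrace, cfg: ProfileConfig | None = None
) -> ProfileStats:
    """Slopes, standard deviations and length of one profile trace.

    The short segment is the leading ``short_segment_frac`` of the samples
    from the styloid end. Standard deviations use the n-1 normalisation, so
    the detrended value can never exceed the raw one.
    """
    cfg = cfg or ProfileConfig()
    pos, val = trace.positions_px, trace.intensity
    slope_full = float(np.polyfit(pos, val, 1)[0])
    n_short = max(2, int(round(cfg.short_segment_frac * pos.size)))
    slope_short = float(np.polyfit(pos[:n_short], val[:n_short], 1)[0])
    std_raw = float(np.std(val, ddof=1))
    std_adjusted = float(np.std(detrend(trace), ddof=1))
    return ProfileStats(
        slope_full=slope_full,
        slope_short=slope_short,
        std_raw=std_raw,
        std_adjusted=std_adjusted,
        distance=float(pos.size),
    )


def measure_profiles(
    image: np.ndarray,
    lunate: tuple[float, float],
    styloid: tuple[float, float],
    cfg: ProfileConfig | None = None,
) -> dict[str, float]:
    """Both profile lines (1 = 30 deg, 2 = 45 deg) as named statistics."""
    out: dict[str, float] = {}
    for idx, offset in ((1, 30), (2, 45)):
        trace = trace_profile(image, lunate, styloid, offset, cfg)
        stats = profile_statistics(trace, cfg)
        out[f"Slope profile {idx} (full line)"] = stats.slope_full
        out[f"Slope profile {idx} (short segment)"] = stats.slope_short
        out[f"Std profile {idx}"] = stats.std_raw
        out[f"Std profile {idx} adjusted"] = stats.std_adjusted
        out[f"Distance profile {idx}"] = stats.distance
    return out
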