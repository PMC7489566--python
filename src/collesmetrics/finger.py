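"""Middle-finger metacarpal radiogrammetry.

A square region of interest around the metacarpal landmark is aligned so the
finger runs vertically, then the intensities are projected down the columns.
A long bone seen end-on in projection shows the classic two-peak signature:
bright cortical shells at the sides, a dimmer trabecular core between them.
The cortical/trabecular partition of that 1-D profile gives the trabecular-
to-total area ratio (a thinning cortex — as in osteoporosis — raises it) and
the overall bone width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from ._geometry import rotate_image
from .config import CannyConfig, FingerConfig, HoughConfig
from .preprocess import detect_orientation


@dataclass
class FingerProfile:
    """Projected intensity profile across the finger with its key points."""

    columns: np.ndarray
    intensity: np.ndarray
    edges: tuple[float, float] | None = None
    cortical_peaks: tuple[float, float] | None = None
    centre: float | None = None


@dataclass
class FingerMetrics:
    width_finger_px: float
    trabecular_total_ratio: float

    def __post_init__(self) -> None:
        if not self.width_finger_px > 0:
            raise ValueError("finger width must be positive")
        if not 0 < self.trabecular_total_ratio < 1:
            raise ValueError("trabecular/total ratio must lie in (0, 1)")


def extract_finger_roi(
    image: np.ndarray,
    finger_landmark: tuple[float, float],
    spacing_mm: float,
    cfg: FingerConfig | None = None,
    canny_cfg: CannyConfig | None = None,
    hough_cfg: HoughConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Square ROI centred on the landmark, rotated so the finger axis is
    vertical; returns (roi, local_rotation_deg).

    The axis is the strongest Hough line over Canny edges inside the ROI
    (the cortical shells are the dominant straight features). When no line
    is found the ROI is used unrotated.
    """
    cfg = cfg or FingerConfig()
    image = np.asarray(image, dtype=float)
    half = int(round(cfg.roi_side_mm / spacing_mm / 2))
    r, c = int(round(finger_landmark[0])), int(round(finger_landmark[1]))
    if (
        r - half < 0
        or c - half < 0
        or r + half + 1 > image.shape[0]
        or c + half + 1 > image.shape[1]
    ):
        raise ValueError(
            f"finger ROI of side {2 * half + 1} px around ({r}, {c}) exceeds "
            f"image bounds {image.shape}"
        )
    roi = image[r - half : r + half + 1, c - half : c + half + 1]
    hough_cfg = hough_cfg or HoughConfig(n_peaks=1)
    angle = detect_orientation(roi, canny_cfg, hough_cfg)
    if angle != 0.0:
        roi = rotate_image(roi, -angle)
    return roi, angle


def project_profile(roi: np.ndarray) -> FingerProfile:
    """Mean intensity down each column of the (vertically aligned) ROI.

    Zero-filled pixels introduced by the local rotation are excluded from the
    column means so the profile reflects anatomy only.
    """
    roi = np.asarray(roi, dtype=float)
    weights = (roi > 0).astype(float)
    counts = weights.sum(axis=0)
    sums = roi.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    # if the ROI is genuinely zero-valued (degenerate), fall back to plain mean
    if not np.any(counts > 0):
        intensity = roi.mean(axis=0)
    return FingerProfile(columns=np.arange(roi.shape[1], dtype=float), intensity=intensity)


def _cross_up(x: np.ndarray, y: np.ndarray, level: float, lo: int, hi: int) -> float:
    """Sub-pixel position of the first upward crossing of ``level`` scanning
    from index lo toward hi (hi exclusive, lo<hi scans right, else left)."""
    step = 1 if hi > lo else -1
    prev = lo
    for i in range(lo + step, hi, step):
        if y[prev] < level <= y[i]:
            frac = (level - y[prev]) / (y[i] - y[prev])
            return x[prev] + frac * (x[i] - x[prev])
        prev = i
    raise ValueError("profile never crosses the requested level")


def _cross_down(x: np.ndarray, y: np.ndarray, level: float, lo: int, step: int) -> float:
    """Sub-pixel position where y falls below ``level`` walking from lo."""
    prev = lo
    i = lo + step
    while 0 <= i < len(y):
        if y[i] < level <= y[prev]:
            frac = (y[prev] - level) / (y[prev] - y[i])
            return x[prev] + frac * (x[i] - x[prev])
        prev = i
        i += step
    raise ValueError("profile never falls below the requested level")


def segment_cortical_trabecular(
    profile: FingerProfile, cfg: FingerConfig | None = None
) -> FingerMetrics:
    """Partition the two-peak finger profile into cortical and trabecular
    intervals.

    Bone edges: outermost crossings of the half-way level between the
    background (median of the outer columns) and the cortical peak value.
    Cortical peaks: the two most prominent interior maxima. The trabecular
    interval is bounded by the points where the profile falls to the midpoint
    between each cortical peak and the central plateau minimum. The area
    ratio reduces to an interval-length ratio because both regions share the
    ROI height.
    """
    cfg = cfg or FingerConfig()
    x = np.asarray(profile.columns, dtype=float)
    y = np.asarray(profile.intensity, dtype=float)
    n = y.size
    if n < 8:
        raise ValueError("profile too short")
    n_bg = max(1, int(round(cfg.background_frac * n / 2)))
    background = float(np.median(np.concatenate([y[:n_bg], y[-n_bg:]])))

    dyn = float(np.ptp(y))
    if dyn == 0:
        raise ValueError("cortical peaks not found (flat profile)")
    peaks, props = find_peaks(y, prominence=cfg.peak_prominence_frac * dyn)
    if peaks.size < 2:
        raise ValueError("cortical peaks not found")
    # two tallest prominent maxima, in left-right order
    top2 = peaks[np.argsort(y[peaks])[-2:]]
    p_left, p_right = int(top2.min()), int(top2.max())
    if p_left == p_right:
        raise ValueError("cortical peaks not found")

    half_left = (background + y[p_left]) / 2.0
    half_right = (background + y[p_right]) / 2.0
    edge_left = _cross_up(x, y, half_left, 0, p_left + 1)
    edge_right = _cross_up(x, y, half_right, n - 1, p_right - 1)

    centre_min = float(np.min(y[p_left : p_right + 1]))
    trab_left = _cross_down(x, y, (y[p_left] + centre_min) / 2.0, p_left, +1)
    trab_right = _cross_down(x, y, (y[p_right] + centre_min) / 2.0, p_right, -1)

    profile.edges = (edge_left, edge_right)
    profile.cortical_peaks = (float(x[p_left]), float(x[p_right]))
    profile.centre = (float(x[p_left]) + float(x[p_right])) / 2.0

    width = edge_right - edge_left
    ratio = (trab_right - trab_left) / width
    return FingerMetrics(width_finger_px=float(width), trabecular_total_ratio=float(ratio))


def measure_finger(
    image: np.ndarray,
    finger_landmark: tuple[float, float],
    spacing_mm: float,
    cfg: FingerConfig | None = None,
) -> FingerMetrics:
    """Convenience composition: ROI extraction, projection, segmentation."""
    roi, _ = extract_finger_roi(image, finger_landmark, spacing_mm, cfg)
    profile = project_profile(roi)
    return segment_cortical_trabecular(profile, cfg)
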