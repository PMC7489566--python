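"""Automatic radiograph pre-processing.

Two artefacts of routine emergency-department acquisition are corrected
before any measurement: the forearm is rarely vertical in the frame, and the
x-ray collimator leaves exactly-zero regions outside the exposed field.

Orientation is estimated from the central third of the image (where the
radius and ulna dominate): Canny edges, then a straight-line Hough
transform; the median angle of the strongest line peaks, measured from the
vertical axis, is the forearm inclination. The image is rotated back by that
angle on an enlarged canvas. Collimator regions are the exactly-zero
connected components touching the image border (pixels inside the exposed
field are low but never exactly zero), dilated to swallow the bright
collimation lines at their rim.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import canny
from skimage.filters import sobel, threshold_otsu
from scipy.ndimage import binary_dilation
from skimage.measure import label
from skimage.morphology import disk
from skimage.transform import hough_line, hough_line_peaks

from ._geometry import rotate_image, transform_points
from .config import CannyConfig, CollimatorConfig, HoughConfig, PipelineConfig
from .io import Radiograph

logger = logging.getLogger(__name__)


@dataclass
class PreprocessResult:
    image: Radiograph                 # rotated, collimator-masked
    rotation_deg: float               # forearm inclination that was corrected
    collimator_mask: np.ndarray       # pre-rotation frame, True = removed
    hough_lines: list = field(default_factory=list)
    pre_rotation_shape: tuple[int, int] = (0, 0)

    def transform_landmarks(self, points: np.ndarray) -> np.ndarray:
        """Map (row, col) points given on the original image onto the
        rotated output canvas."""
        return transform_points(points, self.pre_rotation_shape, -self.rotation_deg)


def extract_central_region(radiograph: Radiograph) -> tuple[np.ndarray, tuple[int, int]]:
    """Central third in both axes; returns (subimage, (row_off, col_off)).

    Start indices floor R/3 and lengths ceil R/3, so the three thirds tile
    the image.
    """
    pixels = radiograph.pixels
    r0 = pixels.shape[0] // 3
    c0 = pixels.shape[1] // 3
    rlen = -(-pixels.shape[0] // 3)
    clen = -(-pixels.shape[1] // 3)
    return pixels[r0 : r0 + rlen, c0 : c0 + clen], (r0, c0)


def _auto_canny(image: np.ndarray, cfg: CannyConfig) -> np.ndarray:
    """Canny with hysteresis thresholds derived from the gradient histogram."""
    image = np.asarray(image, dtype=float)
    grad = sobel(image)
    if np.ptp(grad) == 0:
        return np.zeros(image.shape, dtype=bool)
    high = threshold_otsu(grad)
    return canny(
        image,
        sigma=cfg.sigma,
        low_threshold=cfg.low_frac * high,
        high_threshold=high,
    )


def detect_orientation(
    subimage: np.ndarray,
    canny_cfg: CannyConfig | None = None,
    hough_cfg: HoughConfig | None = None,
    return_lines: bool = False,
):
    """Median angle (degrees from vertical, in (-90, 90]) of the strongest
    Hough lines over the Canny edges of ``subimage``.

    Falls back to 0 with a warning when no line peak is found (flat or
    featureless region), so downstream stages still run unrotated.
    """
    canny_cfg = canny_cfg or CannyConfig()
    hough_cfg = hough_cfg or HoughConfig()

    edges = _auto_canny(subimage, canny_cfg)
    lines: list[dict] = []
    angle = 0.0
    if edges.any():
        step = math.radians(hough_cfg.theta_res_deg)
        thetas = np.arange(-math.pi / 2, math.pi / 2, step)
        accum, theta, rho = hough_line(edges, theta=thetas)
        min_angle_bins = max(1, int(round(hough_cfg.min_angle_deg / hough_cfg.theta_res_deg)))
        votes, peak_theta, peak_rho = hough_line_peaks(
            accum,
            theta,
            rho,
            num_peaks=hough_cfg.n_peaks,
            min_distance=hough_cfg.min_distance_px,
            min_angle=min_angle_bins,
        )
        if len(peak_theta):
            angles = np.degrees(np.asarray(peak_theta))
            angles = np.where(angles <= -90.0, angles + 180.0, angles)
            # ties in vote count resolved toward the smaller |angle|
            order = np.lexsort((np.abs(angles), -np.asarray(votes)))
            angles = angles[order]
            lines = [
                {"angle_deg": float(a), "rho": float(r), "votes": int(v)}
                for a, r, v in zip(
                    angles, np.asarray(peak_rho)[order], np.asarray(votes)[order]
                )
            ]
            angle = float(np.median(angles))
    if not lines:
        logger.warning("no Hough line peaks found; assuming the forearm is vertical")
    if return_lines:
        return angle, lines
    return angle


def rotate_to_vertical(radiograph: Radiograph, angle_deg: float) -> Radiograph:
    """Rotate the image by ``-angle_deg`` about its centre (bilinear, canvas
    enlarged, fill 0) so a feature inclined by ``angle_deg`` becomes vertical."""
    if not -90 < angle_deg <= 90:
        raise ValueError("rotation angle must lie in (-90, 90]")
    rotated = rotate_image(radiograph.pixels, -angle_deg)
    return Radiograph(
        rotated,
        radiograph.spacing_mm,
        case_id=radiograph.case_id,
        meta=dict(radiograph.meta),
    )


def detect_collimator_mask(
    radiograph: Radiograph, cfg: CollimatorConfig | None = None
) -> np.ndarray:
    """Exactly-zero connected components touching the border, dilated.

    Zero blobs in the interior (e.g. burnt-in annotations) are left alone:
    only regions outside the collimated field touch the frame.
    """
    cfg = cfg or CollimatorConfig()
    zeros = radiograph.pixels == 0
    if not zeros.any():
        return np.zeros(radiograph.shape, dtype=bool)
    lbl = label(zeros, connectivity=2)
    border_labels = np.unique(
        np.concatenate([lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]])
    )
    border_labels = border_labels[border_labels != 0]
    if border_labels.size == 0:
        return np.zeros(radiograph.shape, dtype=bool)
    mask = np.isin(lbl, border_labels)
    if cfg.dilation_px > 0:
        mask = binary_dilation(mask, structure=disk(cfg.dilation_px))
    return mask


def preprocess(
    radiograph: Radiograph, config: PipelineConfig | None = None
) -> PreprocessResult:
    """Full pre-processing: collimator removal, orientation detection from
    the central third, rotation to vertical."""
    config = config or PipelineConfig()
    mask = detect_collimator_mask(radiograph, config.collimator)
    masked = radiograph.pixels.astype(float).copy()
    masked[mask] = 0.0
    working = Radiograph(
        masked, radiograph.spacing_mm, case_id=radiograph.case_id,
        meta=dict(radiograph.meta),
    )
    sub, _ = extract_central_region(working)
    angle, lines = detect_orientation(
        sub, config.canny, config.hough, return_lines=True
    )
    rotated = rotate_to_vertical(working, angle)
    return PreprocessResult(
        image=rotated,
        rotation_deg=angle,
        collimator_mask=mask,
        hough_lines=lines,
        pre_rotation_shape=radiograph.shape,
    )
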