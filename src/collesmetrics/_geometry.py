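"""Shared rotation operator used by preprocessing and the phantom renderer.

A single affine convention keeps image content, landmark coordinates and
ground-truth geometry in lock-step: ``rotate_image(im, a)`` rotates the
*content* so that a feature that was vertical acquires a Hough normal angle
of ``a`` degrees, and ``transform_points`` applies the identical forward map
to (row, col) coordinates.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.transform import AffineTransform, warp


def _rotation_transform(
    shape: tuple[int, int], angle_deg: float
) -> tuple[AffineTransform, tuple[int, int]]:
    """Forward transform (x=col, y=row) and enlarged output shape."""
    rows, cols = shape
    theta = math.radians(angle_deg)
    new_cols = int(math.ceil(abs(cols * math.cos(theta)) + abs(rows * math.sin(theta))))
    new_rows = int(math.ceil(abs(rows * math.cos(theta)) + abs(cols * math.sin(theta))))
    centre = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    new_centre = np.array([(new_cols - 1) / 2.0, (new_rows - 1) / 2.0])
    tf = (
        AffineTransform(translation=-centre)
        + AffineTransform(rotation=theta)
        + AffineTransform(translation=new_centre)
    )
    return tf, (new_rows, new_cols)


def rotate_image(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate ``image`` content by ``angle_deg`` with bilinear interpolation.

    The canvas is enlarged so no content is cropped; uncovered pixels are 0.
    ``angle_deg == 0`` is a bit-identical fast path.
    """
    if angle_deg == 0:
        return image.copy()
    tf, out_shape = _rotation_transform(image.shape, angle_deg)
    return warp(
        np.asarray(image, dtype=float),
        inverse_map=tf.inverse,
        output_shape=out_shape,
        order=1,
        cval=0.0,
        preserve_range=True,
    )


def transform_points(
    points: np.ndarray, shape: tuple[int, int], angle_deg: float
) -> np.ndarray:
    """Map (row, col) points through the same rotation applied to the image.

    ``shape`` is the shape of the image *before* rotation.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if angle_deg == 0:
        out = pts.copy()
    else:
        tf, _ = _rotation_transform(shape, angle_deg)
        xy = pts[:, ::-1]  # (row, col) -> (x, y)
        out = tf(xy)[:, ::-1]
    return out if np.asarray(points).ndim == 2 else out[0]


def rotate_direction(direction_rc: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a (row, col) direction vector by ``angle_deg`` (same convention)."""
    theta = math.radians(angle_deg)
    dr, dc = float(direction_rc[0]), float(direction_rc[1])
    # rotation acts on (x=col, y=row): x' = x cos - y sin ; y' = x sin + y cos
    dc2 = dc * math.cos(theta) - dr * math.sin(theta)
    dr2 = dc * math.sin(theta) + dr * math.cos(theta)
    return np.array([dr2, dc2])
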