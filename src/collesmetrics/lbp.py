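"""Local Binary Pattern texture of the distal radius.

The texture region of interest is placed automatically from the two wrist
landmarks: starting at the radial styloid, a fixed distance along the
styloid-to-lunate direction and a fixed distance proximally (down the
image) lands the ROI on trabecular bone of the distal radius.

The descriptor is the rotation-invariant uniform LBP over the 3x3
neighbourhood (8 neighbours, radius 1): each neighbour is thresholded
against the centre (ties count as 1), the resulting 8-bit circular pattern
is mapped to one of 10 classes — uniform patterns (at most two circular
0/1 transitions) map to their number of set bits (classes 0-8), all others
to class 9 — and the class counts are returned as a normalised histogram
"LBP 1" … "LBP 10". The coding depends only on intensity *order*, so the
histogram is invariant to any strictly increasing intensity transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LbpConfig

LBP_NAMES = tuple(f"LBP {k}" for k in range(1, 11))

# circular neighbour offsets (row, col), starting east, counterclockwise
# (north = decreasing row)
_OFFSETS = (
    (0, 1),
    (-1, 1),
    (-1, 0),
    (-1, -1),
    (0, -1),
    (1, -1),
    (1, 0),
    (1, 1),
)


def _riu2_table() -> np.ndarray:
    """Map each 8-bit pattern to its rotation-invariant uniform class."""
    table = np.empty(256, dtype=np.int64)
    for pattern in range(256):
        bits = [(pattern >> k) & 1 for k in range(8)]
        transitions = sum(bits[k] != bits[(k + 1) % 8] for k in range(8))
        table[pattern] = sum(bits) if transitions <= 2 else 9
    return table


_RIU2 = _riu2_table()


@dataclass
class LbpHistogram:
    """Normalised 10-bin riu2 LBP histogram."""

    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (10,):
            raise ValueError("an LBP histogram has exactly 10 coefficients")
        if np.any(self.coefficients < 0) or not np.isclose(
            self.coefficients.sum(), 1.0
        ):
            raise ValueError("LBP coefficients must be a normalised histogram")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(LBP_NAMES, self.coefficients))


def locate_texture_roi(
    image: np.ndarray,
    lunate: tuple[float, float],
    styloid: tuple[float, float],
    spacing_mm: float,
    cfg: LbpConfig | None = None,
) -> np.ndarray:
    """Crop the square texture ROI anchored on the styloid.

    Centre = styloid + a·u + b·p, with u the unit vector toward the lunate,
    p the proximal (image-down) unit vector, a = ``offset_along_mm`` and
    b = ``offset_proximal_mm``; side = ``roi_side_mm``.
    """
    cfg = cfg or LbpConfig()
    image = np.asarray(image, dtype=float)
    lun = np.asarray(lunate, dtype=float)
    sty = np.asarray(styloid, dtype=float)
    u = lun - sty
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("lunate and styloid landmarks coincide")
    u /= norm
    centre = (
        sty
        + (cfg.offset_along_mm / spacing_mm) * u
        + (cfg.offset_proximal_mm / spacing_mm) * np.array([1.0, 0.0])
    )
    half = int(round(cfg.roi_side_mm / spacing_mm / 2))
    r, c = int(round(centre[0])), int(round(centre[1]))
    r0, r1 = r - half, r + half + 1
    c0, c1 = c - half, c + half + 1
    if r0 < 0 or c0 < 0 or r1 > image.shape[0] or c1 > image.shape[1]:
        raise ValueError(
            f"texture ROI rows {r0}:{r1}, cols {c0}:{c1} exceed image bounds "
            f"{image.shape}; need {half} px margin around ({r}, {c})"
        )
    return image[r0:r1, c0:c1]


def compute_lbp_histogram(roi: np.ndarray) -> LbpHistogram:
    """Vectorised riu2 LBP histogram of all interior pixels of ``roi``."""
    roi = np.asarray(roi, dtype=float)
    if roi.shape[0] < 16 or roi.shape[1] < 16:
        raise ValueError("texture ROI must be at least 16x16 px")
    centre = roi[1:-1, 1:-1]
    pattern = np.zeros(centre.shape, dtype=np.int64)
    for bit, (dr, dc) in enumerate(_OFFSETS):
        neighbour = roi[1 + dr : roi.shape[0] - 1 + dr, 1 + dc : roi.shape[1] - 1 + dc]
        pattern |= (neighbour >= centre).astype(np.int64) << bit
    classes = _RIU2[pattern]
    counts = np.bincount(classes.ravel(), minlength=10).astype(float)
    return LbpHistogram(coefficients=counts / counts.sum())
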