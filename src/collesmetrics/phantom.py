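"""Synthetic wrist-radiograph phantoms with known ground truth.

The phantom reproduces the features the measurement pipeline depends on,
at their real physical scale (geometry is specified in millimetres and
rendered at the requested pixel spacing):

* an exactly-zero collimator frame around a low, strictly positive field;
* a vertical forearm soft-tissue band with a prescribed width profile;
* radius and ulna as bright near-parallel bone bands (the orientation cues)
  separated by a darker inter-bone gap, the radius reaching further
  distally and carrying the styloid at its tip;
* a lunate blob distal to the radius;
* a middle-finger metacarpal with bright cortical shells and a dimmer
  trabecular core;
* Gaussian-smoothed noise texture on trabecular bone.

The assembled scene is rendered vertical and then rotated with the *same*
bilinear operator the pre-processing stage uses, so end-to-end recovery
errors measure detection accuracy, not rendering mismatch. No x-ray physics
(scatter, beam hardening, heel effect) is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._geometry import rotate_direction, rotate_image, transform_points
from .io import GROUP_LABELS, MEASUREMENT_NAMES, LandmarkSet, Radiograph


@dataclass
class PhantomParams:
    """Generating parameters; defaults give a 180 x 140 mm field at
    0.2 mm/px with a moderately rotated forearm."""

    shape: tuple[int, int] = (900, 700)
    spacing_mm: float = 0.2
    rotation_deg: float = 12.0
    width_profile_px: tuple[float, ...] = (320, 310, 302, 298, 296, 296, 298, 300)
    cortical_px: int = 8            # finger cortical shell thickness
    trabecular_px: int = 17         # finger trabecular half-width
    bone_intensity: float = 200.0
    soft_intensity: float = 60.0
    background_intensity: float = 20.0
    noise_sd: float = 8.0
    texture_scale: float = 2.0      # correlation length of trabecular noise
    collimator_border_px: int = 40
    finger_angle_deg: float = 0.0   # finger tilt relative to the forearm
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.width_profile_px) != 8:
            raise ValueError("width_profile_px must list 8 widths")
        if not self.bone_intensity > self.background_intensity:
            raise ValueError("bone must be brighter than background")
        if min(self.background_intensity, self.soft_intensity) <= 0:
            raise ValueError("field intensities must be strictly positive")


@dataclass
class PhantomTruth:
    """Ground truth matching one generated phantom (final-image coordinates
    for landmarks; masks are in the pre-rotation render frame)."""

    landmarks: LandmarkSet
    rotation_deg: float
    widths_px: np.ndarray
    finger_ratio: float
    finger_width_px: float
    profile_distances: dict[float, float]
    radius_mask: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    landmarks_prerotation: LandmarkSet | None = None


def _px(mm: float, spacing: float) -> int:
    return int(round(mm / spacing))


def generate_phantom(params: PhantomParams | None = None) -> tuple[Radiograph, PhantomTruth]:
    """Render one phantom radiograph and its ground truth."""
    p = params or PhantomParams()
    H, W = p.shape
    s = p.spacing_mm
    frame = p.collimator_border_px
    rng = np.random.default_rng(p.seed)

    lunate_row = frame + _px(50, s)
    centre_col = W // 2
    radius_c0 = centre_col - _px(18, s)
    radius_c1 = radius_c0 + _px(22, s)
    ulna_c0 = centre_col + _px(14, s)
    ulna_c1 = ulna_c0 + _px(14, s)
    radius_top = lunate_row + _px(2, s)
    ulna_top = lunate_row + _px(10, s)
    bones_bottom = H - frame - _px(2, s)
    forearm_top = lunate_row - _px(1, s)
    blob_centre = (lunate_row - _px(4, s), centre_col + _px(1, s))
    blob_radius = _px(4.4, s)
    styloid = (radius_top + _px(1, s), radius_c0 + _px(2, s))
    lunate_lm = (lunate_row - _px(1, s), centre_col + _px(1, s))
    finger_centre = (frame + _px(24, s), centre_col + _px(16, s))
    finger_half_len = _px(20, s)
    finger_half_w = p.trabecular_px + p.cortical_px

    if (
        bones_bottom <= ulna_top
        or finger_centre[0] - finger_half_len < frame
        or ulna_c1 >= W - frame
        or lunate_row + _px(5 + 70, s) >= bones_bottom
    ):
        raise ValueError("phantom anatomy does not fit the requested frame")

    img = np.full((H, W), p.background_intensity, dtype=float)
    rr, cc = np.mgrid[0:H, 0:W]

    # forearm soft band with the prescribed width profile
    gap = _px(10, s)
    line_rows = lunate_row + _px(5, s) + gap * np.arange(8)
    widths = np.interp(
        np.arange(H), line_rows, np.asarray(p.width_profile_px, dtype=float)
    )
    half_w = widths / 2.0
    forearm = (rr >= forearm_top) & (rr <= bones_bottom) & (
        np.abs(cc - centre_col) < half_w[rr]
    )
    img[forearm] = p.soft_intensity

    radius = (
        (rr >= radius_top) & (rr <= bones_bottom) & (cc >= radius_c0) & (cc < radius_c1)
    )
    ulna = (rr >= ulna_top) & (rr <= bones_bottom) & (cc >= ulna_c0) & (cc < ulna_c1)
    blob = (rr - blob_centre[0]) ** 2 + (cc - blob_centre[1]) ** 2 <= blob_radius**2
    img[radius] = p.bone_intensity
    img[ulna] = p.bone_intensity
    img[blob] = p.bone_intensity

    # finger metacarpal: signed distance from its (possibly tilted) axis
    axis = rotate_direction(np.array([1.0, 0.0]), p.finger_angle_deg)
    dr = rr - finger_centre[0]
    dc = cc - finger_centre[1]
    along = dr * axis[0] + dc * axis[1]
    across = -dr * axis[1] + dc * axis[0]
    in_len = np.abs(along) <= finger_half_len
    finger_bone = in_len & (np.abs(across) <= finger_half_w)
    finger_trab = in_len & (np.abs(across) <= p.trabecular_px)
    finger_cort = finger_bone & ~finger_trab
    img[finger_cort] = p.bone_intensity * 1.1
    img[finger_trab] = p.bone_intensity * 0.7

    # trabecular texture: smoothed white noise, renormalised to noise_sd
    if p.noise_sd > 0:
        noise = gaussian_filter(rng.standard_normal((H, W)), p.texture_scale)
        noise *= p.noise_sd / noise.std()
        textured = radius | ulna | blob | finger_trab
        img[textured] = np.maximum(img[textured] + noise[textured], 1.0)

    # exactly-zero collimator frame
    if frame > 0:
        img[:frame, :] = 0.0
        img[-frame:, :] = 0.0
        img[:, :frame] = 0.0
        img[:, -frame:] = 0.0

    # ground-truth profile distances: ray-march the radius mask from the
    # styloid along the baseline rotated by +/-30 and +/-45 degrees, keeping
    # the sense that enters the bone
    sty = np.asarray(styloid, dtype=float)
    baseline = np.asarray(lunate_lm, dtype=float) - sty
    baseline /= np.linalg.norm(baseline)
    profile_distances: dict[float, float] = {}
    for offset in (30.0, 45.0):
        best = None
        for sense in (+1, -1):
            d = rotate_direction(baseline, sense * offset)
            t = np.arange(0.0, 600.0)
            rows = np.round(sty[0] + t * d[0]).astype(int)
            cols = np.round(sty[1] + t * d[1]).astype(int)
            ok = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
            inside = np.zeros(t.size, dtype=bool)
            inside[ok] = radius[rows[ok], cols[ok]]
            if inside[:5].all():
                exit_t = float(np.argmin(inside)) if not inside.all() else float(t[-1])
                # the in-bone sense is the one penetrating deeper into the radius
                if best is None or exit_t > best:
                    best = exit_t
        if best is None:
            raise ValueError("phantom styloid does not anchor a profile in bone")
        profile_distances[offset] = best

    lm_pre = LandmarkSet(
        lunate=tuple(map(float, lunate_lm)),
        styloid=tuple(map(float, styloid)),
        finger=tuple(map(float, finger_centre)),
    )
    pts = transform_points(lm_pre.as_array(), (H, W), p.rotation_deg)
    lm_final = LandmarkSet(
        lunate=tuple(pts[0]), styloid=tuple(pts[1]), finger=tuple(pts[2])
    )

    final = rotate_image(img, p.rotation_deg)
    final = np.maximum(final, 0.0)

    truth = PhantomTruth(
        landmarks=lm_final,
        rotation_deg=p.rotation_deg,
        widths_px=np.asarray(p.width_profile_px, dtype=float),
        finger_ratio=(2 * p.trabecular_px) / (2 * finger_half_w),
        finger_width_px=float(2 * finger_half_w),
        profile_distances=profile_distances,
        radius_mask=radius,
        masks={
            "forearm": forearm,
            "radius": radius,
            "ulna": ulna,
            "lunate": blob,
            "finger": finger_bone,
            "collimator": img == 0,
        },
        landmarks_prerotation=lm_pre,
    )
    radiograph = Radiograph(
        final, s, case_id=f"phantom-{p.seed}", meta={"phantom": True}
    )
    return radiograph, truth


def generate_cohort(
    n_per_group: int, effect_spec: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Synthesise a measurement table directly (no image rendering).

    Each of the 32 measurements gets a family-plausible baseline mean and
    standard deviation; ``effect_spec`` maps measurement name -> {group:
    shift in SD units} to plant group differences. Intended for fast
    statistical-stage testing.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    rng = np.random.default_rng(seed)
    effect_spec = effect_spec or {}

    base: dict[str, tuple[float, float]] = {}
    lbp_base = (0.02, 0.03, 0.05, 0.08, 0.12, 0.15, 0.15, 0.12, 0.20, 0.08)
    for name in MEASUREMENT_NAMES:
        if name.startswith("W") and "/" in name or name.startswith("Min width"):
            base[name] = (1.0, 0.05)
        elif name == "Trabecular Area / Total Area":
            base[name] = (0.65, 0.05)
        elif name == "Width Finger":
            base[name] = (50.0, 3.0)
        elif name.startswith("LBP"):
            base[name] = (lbp_base[int(name.split()[1]) - 1], 0.01)
        elif name.startswith("Slope"):
            base[name] = (0.5, 0.2)
        elif name.startswith("Std"):
            base[name] = (12.0, 3.0)
        else:  # Distance
            base[name] = (100.0, 10.0)

    rows = []
    idx = 0
    for group in GROUP_LABELS:
        for _ in range(n_per_group):
            rec: dict[str, object] = {"case_id": f"case{idx:03d}", "group": group}
            for name in MEASUREMENT_NAMES:
                mean, sd = base[name]
                shift = effect_spec.get(name, {}).get(group, 0.0)
                rec[name] = rng.normal(mean + shift * sd, sd)
            rows.append(rec)
            idx += 1
    return pd.DataFrame(rows, columns=["case_id", "group", *MEASUREMENT_NAMES])


def phantom_cohort_params(
    n_per_group: int, seed: int = 0
) -> list[tuple[str, str, PhantomParams]]:
    """Parameter sets for an image-level cohort: (case_id, group, params)
    with per-case random rotation and width jitter."""
    rng = np.random.default_rng(seed)
    out = []
    idx = 0
    for group in GROUP_LABELS:
        for _ in range(n_per_group):
            widths = 300 + rng.normal(0, 4, size=8).cumsum() * 0 + rng.normal(
                0, 6, size=8
            )
            widths = np.clip(widths, 260, 340)
            p = PhantomParams(
                rotation_deg=float(rng.uniform(-20, 20)),
                width_profile_px=tuple(np.round(widths, 1)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            out.append((f"case{idx:03d}", group, p))
            idx += 1
    return out
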