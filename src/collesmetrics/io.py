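"""Reading radiographs and landmark files; writing measurement tables.

Radiographs arrive either as DICOM (pixel spacing taken from the header) or
as plain PNG/TIFF rasters, in which case the physical pixel spacing must be
supplied by the caller. All coordinates throughout the package are 0-based
(row, col) with row 0 at the top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Table-style measurement names, in canonical output order, with the
#: landmark family each one is anchored on.
MEASUREMENTS: tuple[tuple[str, str], ...] = (
    ("W1 / W4", "Lunate"),
    ("W2 / W4", "Lunate"),
    ("W3 / W4", "Lunate"),
    ("W5 / W4", "Lunate"),
    ("W6 / W4", "Lunate"),
    ("W7 / W4", "Lunate"),
    ("W8 / W4", "Lunate"),
    ("Min width / Max width", "Lunate"),
    ("W1+W8 / W4+W5", "Lunate"),
    ("W1+W2 / W7+W8", "Lunate"),
    ("Trabecular Area / Total Area", "Finger"),
    ("Width Finger", "Finger"),
    ("LBP 1", "L+Rad Sty"),
    ("LBP 2", "L+Rad Sty"),
    ("LBP 3", "L+Rad Sty"),
    ("LBP 4", "L+Rad Sty"),
    ("LBP 5", "L+Rad Sty"),
    ("LBP 6", "L+Rad Sty"),
    ("LBP 7", "L+Rad Sty"),
    ("LBP 8", "L+Rad Sty"),
    ("LBP 9", "L+Rad Sty"),
    ("LBP 10", "L+Rad Sty"),
    ("Slope profile 1 (full line)", "Radial Styloid"),
    ("Slope profile 2 (full line)", "Radial Styloid"),
    ("Slope profile 1 (short segment)", "Radial Styloid"),
    ("Slope profile 2 (short segment)", "Radial Styloid"),
    ("Std profile 1", "Radial Styloid"),
    ("Std profile 2", "Radial Styloid"),
    ("Std profile 1 adjusted", "Radial Styloid"),
    ("Std profile 2 adjusted", "Radial Styloid"),
    ("Distance profile 1", "Radial Styloid"),
    ("Distance profile 2", "Radial Styloid"),
)

MEASUREMENT_NAMES: tuple[str, ...] = tuple(name for name, _ in MEASUREMENTS)
MEASUREMENT_FAMILIES: dict[str, str] = dict(MEASUREMENTS)

GROUP_LABELS = (
    "control",
    "pre-successful",
    "pre-unsuccessful",
    "post-successful",
    "post-unsuccessful",
)

_LANDMARK_COLUMNS = (
    "lunate_row",
    "lunate_col",
    "styloid_row",
    "styloid_col",
    "finger_row",
    "finger_col",
)


@dataclass
class Radiograph:
    """A 2-D radiograph with isotropic physical pixel spacing (mm/pixel)."""

    pixels: np.ndarray
    spacing_mm: float
    case_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("radiograph pixels must be a 2-D array")
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 64:
            raise ValueError("radiograph must be at least 64x64 pixels")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")
        if np.nanmin(self.pixels) < 0:
            raise ValueError("radiograph intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LandmarkSet:
    """The three manually placed landmarks, as (row, col) points."""

    lunate: tuple[float, float]
    styloid: tuple[float, float]
    finger: tuple[float, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.lunate, self.styloid, self.finger], dtype=float)

    def validate_inside(self, shape: tuple[int, int]) -> None:
        for name, (r, c) in zip(("lunate", "styloid", "finger"), self.as_array()):
            if not (0 < r < shape[0] - 1 and 0 < c < shape[1] - 1):
                raise ValueError(
                    f"landmark '{name}' at ({r:.1f}, {c:.1f}) is outside the "
                    f"image bounds {shape}"
                )
        pts = self.as_array()
        for i in range(3):
            for j in range(i + 1, 3):
                if np.allclose(pts[i], pts[j]):
                    raise ValueError("landmarks must be pairwise distinct")


@dataclass(frozen=True)
class CaseRecord:
    """One study case: image path, group label and its landmarks."""

    case_id: str
    group: str
    image_path: str
    landmarks: LandmarkSet

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(
                f"unknown group {self.group!r}; expected one of {GROUP_LABELS}"
            )


def read_radiograph(path, spacing_override: float | None = None) -> Radiograph:
    """Read a DICOM, PNG or TIFF radiograph.

    Pixel spacing comes from the DICOM header (``PixelSpacing`` preferred,
    ``ImagerPixelSpacing`` as fallback); for raster formats it must be given
    through ``spacing_override`` (the CLI exposes it as ``--pixel-spacing``).
    MONOCHROME1 payloads are re-inverted so bone is bright. Integer payloads
    without a rescale transform pass through bit-exact.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".dcm", ".dicom", ""} or _looks_like_dicom(path):
        return _read_dicom(path, spacing_override)
    if suffix in {".png", ".tif", ".tiff"}:
        return _read_raster(path, spacing_override)
    raise ValueError(f"unsupported radiograph format: {path.name}")


def _looks_like_dicom(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def _read_dicom(path: Path, spacing_override: float | None) -> Radiograph:
    import pydicom

    ds = pydicom.dcmread(path)
    pixels = ds.pixel_array
    if pixels.ndim != 2:
        raise ValueError("radiograph must be a single-channel 2-D image")

    spacing = None
    for attr in ("PixelSpacing", "ImagerPixelSpacing"):
        value = getattr(ds, attr, None)
        if value is not None:
            a, b = float(value[0]), float(value[1])
            if abs(a - b) > 0.01 * max(a, b):
                raise ValueError(
                    f"anisotropic pixel spacing ({a}, {b}) differs by more "
                    "than 1%; isotropy is assumed"
                )
            spacing = (a + b) / 2.0
            break
    if spacing is None:
        spacing = spacing_override
    if spacing is None:
        raise ValueError(
            "pixel spacing unavailable in DICOM header; pass --pixel-spacing"
        )

    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    if slope != 1.0 or intercept != 0.0:
        pixels = pixels.astype(float) * slope + intercept
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        pixels = np.max(pixels) - pixels
    if np.min(pixels) < 0:  # negative rescale intercepts: shift, never clip
        pixels = pixels - np.min(pixels)

    meta = {
        "modality": str(getattr(ds, "Modality", "")),
        "photometric": str(getattr(ds, "PhotometricInterpretation", "")),
    }
    return Radiograph(pixels, float(spacing), case_id=path.stem, meta=meta)


def _read_raster(path: Path, spacing_override: float | None) -> Radiograph:
    import imageio.v3 as iio

    pixels = iio.imread(path)
    if pixels.ndim == 3 and pixels.shape[2] == 1:
        pixels = pixels[:, :, 0]
    if pixels.ndim != 2:
        raise ValueError("radiograph must be a single-channel 2-D image")
    if spacing_override is None:
        raise ValueError(
            "pixel spacing unavailable for raster images; pass --pixel-spacing"
        )
    return Radiograph(pixels, float(spacing_override), case_id=path.stem)


def read_landmarks(path) -> dict[str, LandmarkSet]:
    """Read per-case landmarks from CSV (one row per case) or JSON.

    CSV columns: case_id, lunate_row, lunate_col, styloid_row, styloid_col,
    finger_row, finger_col. The JSON dialect maps case_id to an object with
    ``lunate``/``styloid``/``finger`` [row, col] pairs.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        out: dict[str, LandmarkSet] = {}
        for case_id, entry in raw.items():
            out[str(case_id)] = LandmarkSet(
                lunate=tuple(map(float, entry["lunate"])),
                styloid=tuple(map(float, entry["styloid"])),
                finger=tuple(map(float, entry["finger"])),
            )
        return out

    df = pd.read_csv(path)
    missing = {"case_id", *_LANDMARK_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"landmark file missing columns: {sorted(missing)}")
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"duplicate case_id in landmark file: {dupes}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["case_id"])] = LandmarkSet(
            lunate=(float(row["lunate_row"]), float(row["lunate_col"])),
            styloid=(float(row["styloid_row"]), float(row["styloid_col"])),
            finger=(float(row["finger_row"]), float(row["finger_col"])),
        )
    return out


def write_landmarks(landmarks: Mapping[str, LandmarkSet], path) -> None:
    rows = []
    for case_id, lm in landmarks.items():
        rows.append(
            {
                "case_id": case_id,
                "lunate_row": lm.lunate[0],
                "lunate_col": lm.lunate[1],
                "styloid_row": lm.styloid[0],
                "styloid_col": lm.styloid[1],
                "finger_row": lm.finger[0],
                "finger_col": lm.finger[1],
            }
        )
    pd.DataFrame(rows, columns=["case_id", *_LANDMARK_COLUMNS]).to_csv(
        path, index=False
    )


def write_measurements(rows, path) -> None:
    """Write (case_id, group, measurement-mapping) rows to CSV.

    The header is ``case_id, group`` followed by the 32 measurement names in
    canonical order; values round-trip at 12 significant digits.
    """
    records = []
    for case_id, group, vector in rows:
        missing = [n for n in MEASUREMENT_NAMES if n not in vector]
        if missing:
            raise ValueError(f"measurement vector for {case_id!r} missing: {missing}")
        rec = {"case_id": case_id, "group": group}
        rec.update({name: vector[name] for name in MEASUREMENT_NAMES})
        records.append(rec)
    df = pd.DataFrame(records, columns=["case_id", "group", *MEASUREMENT_NAMES])
    df.to_csv(path, index=False, float_format="%.12g")


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement table written by :func:`write_measurements`."""
    df = pd.read_csv(path)
    missing = {"case_id", "group", *MEASUREMENT_NAMES} - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    return df
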