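"""Per-case and whole-study orchestration.

``run_case`` applies the pre-processing and the four measurement families
(forearm widths, finger radiogrammetry, LBP texture, intensity profiles) to
one radiograph and returns the 32-entry named measurement vector. A family
that fails on a given image (anatomy cut off, landmark near a border, …)
degrades to NaN for its measurements with a logged diagnostic rather than
aborting the case. ``run_study`` maps this over a case table and feeds the
result to the group comparison.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .finger import measure_finger
from .forearm import RATIO_NAMES, compute_ratios, measure_widths, trace_forearm_boundaries
from .io import (
    MEASUREMENT_NAMES,
    CaseRecord,
    LandmarkSet,
    Radiograph,
    write_measurements,
)
from .lbp import LBP_NAMES, compute_lbp_histogram, locate_texture_roi
from .preprocess import preprocess
from .profiles import PROFILE_STAT_NAMES, measure_profiles
from .stats import compare_groups

logger = logging.getLogger(__name__)

_FAMILY_NAMES = {
    "forearm": RATIO_NAMES,
    "finger": ("Trabecular Area / Total Area", "Width Finger"),
    "lbp": LBP_NAMES,
    "profiles": PROFILE_STAT_NAMES,
}


def run_case(
    radiograph: Radiograph,
    landmarks: LandmarkSet,
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """Measure one radiograph; returns the 32 named measurements.

    Landmarks are given on the original image and are transformed by the
    fitted rotation internally.
    """
    config = config or PipelineConfig()
    landmarks.validate_inside(radiograph.shape)
    try:
        result = preprocess(radiograph, config)
    except Exception as exc:  # noqa: BLE001 - surfaced with stage name
        raise RuntimeError(f"preprocess failed for {radiograph.case_id!r}: {exc}")

    pts = result.transform_landmarks(landmarks.as_array())
    lunate, styloid, finger = (tuple(p) for p in pts)
    image = result.image.pixels
    spacing = result.image.spacing_mm

    vector: dict[str, float] = {name: np.nan for name in MEASUREMENT_NAMES}

    try:
        boundaries = trace_forearm_boundaries(image, lunate, config.width, config.canny)
        widthset = measure_widths(boundaries, lunate, spacing, config.width)
        vector.update(compute_ratios(widthset))
    except Exception as exc:  # noqa: BLE001
        logger.warning("%s: forearm width family failed: %s", radiograph.case_id, exc)

    try:
        metrics = measure_finger(image, finger, spacing, config.finger)
        vector["Trabecular Area / Total Area"] = metrics.trabecular_total_ratio
        vector["Width Finger"] = metrics.width_finger_px
    except Exception as exc:  # noqa: BLE001
        logger.warning("%s: finger family failed: %s", radiograph.case_id, exc)

    try:
        roi = locate_texture_roi(image, lunate, styloid, spacing, config.lbp)
        vector.update(compute_lbp_histogram(roi).as_dict())
    except Exception as exc:  # noqa: BLE001
        logger.warning("%s: LBP family failed: %s", radiograph.case_id, exc)

    try:
        vector.update(measure_profiles(image, lunate, styloid, config.profile))
    except Exception as exc:  # noqa: BLE001
        logger.warning("%s: profile family failed: %s", radiograph.case_id, exc)

    return vector


def run_study(
    cases: Sequence[tuple[CaseRecord, Radiograph]],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    test_mode: str = "welch",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure every case and compare the groups.

    Returns (study_table, comparison_table); when ``out_dir`` is given both
    are written as CSV together with a config manifest. Individual case
    failures are recorded as all-NaN rows; the study fails only if every
    case does.
    """
    if len(cases) == 0:
        raise ValueError("empty case table")
    config = config or PipelineConfig()
    rows = []
    n_failed = 0
    for record, radiograph in cases:
        try:
            vector = run_case(radiograph, record.landmarks, config)
        except Exception as exc:  # noqa: BLE001
            logger.error("case %s failed: %s", record.case_id, exc)
            vector = {name: np.nan for name in MEASUREMENT_NAMES}
            n_failed += 1
        rows.append({"case_id": record.case_id, "group": record.group, **vector})
    if n_failed == len(cases):
        raise RuntimeError("all cases failed to process")
    study = pd.DataFrame(rows, columns=["case_id", "group", *MEASUREMENT_NAMES])
    comparison = compare_groups(study, mode=test_mode)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_measurements(
            [(r["case_id"], r["group"], r) for r in rows], out_dir / "measurements.csv"
        )
        comparison.to_csv(out_dir / "comparisons.csv", index=False, float_format="%.12g")
        config.to_yaml(out_dir / "config_manifest.yaml")
    return study, comparison
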