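"""Group comparison of the measurement table.

Seven pairwise contrasts are evaluated per measurement across the five
study groups (healthy controls plus pre/post intervention split by
outcome). Pooled groups ("patient", "pre", "successful", …) are unions of
the elementary groups. The default test is Welch's unequal-variance
two-sample t-test: the contrasted groups have unequal sizes and no natural
case pairing, so a paired statistic is not applicable in general; Student
and paired variants remain selectable for matched designs.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GROUP_LABELS, MEASUREMENT_FAMILIES, MEASUREMENT_NAMES

logger = logging.getLogger(__name__)

ALPHA = 0.05

#: contrast name -> (groups on side A, groups on side B)
CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "Control v Patient": (
        ("control",),
        ("pre-successful", "pre-unsuccessful", "post-successful", "post-unsuccessful"),
    ),
    "Pre- v Post-": (
        ("pre-successful", "pre-unsuccessful"),
        ("post-successful", "post-unsuccessful"),
    ),
    "Successful v Unsuccessful": (
        ("pre-successful", "post-successful"),
        ("pre-unsuccessful", "post-unsuccessful"),
    ),
    "Pre-Successful v Pre-Unsuccessful": (
        ("pre-successful",),
        ("pre-unsuccessful",),
    ),
    "Post-Successful v Post-Unsuccessful": (
        ("post-successful",),
        ("post-unsuccessful",),
    ),
    "Pre-Successful v Post-Successful": (
        ("pre-successful",),
        ("post-successful",),
    ),
    "Pre-Unsuccessful v Post-Unsuccessful": (
        ("pre-unsuccessful",),
        ("post-unsuccessful",),
    ),
}


def two_sample_test(a: Iterable[float], b: Iterable[float], mode: str = "welch") -> float:
    """Two-sided p-value for a difference in means between ``a`` and ``b``.

    Modes: ``welch`` (unequal variances, default), ``student`` (pooled
    variance), ``paired`` (requires equal lengths). Degenerate zero-variance
    inputs with equal means give p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if mode == "paired" and a.size != b.size:
        raise ValueError("paired test requires equal-length samples")
    if mode not in {"welch", "student", "paired"}:
        raise ValueError(f"unknown test mode {mode!r}")

    if mode == "paired":
        diff = a - b
        if np.all(diff == diff[0]):
            return 1.0 if diff[0] == 0 else 0.0
        return float(sps.ttest_rel(a, b).pvalue)

    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    res = sps.ttest_ind(a, b, equal_var=(mode == "student"))
    return float(res.pvalue)


def compare_groups(
    table: pd.DataFrame, mode: str = "welch", fdr: bool = False
) -> pd.DataFrame:
    """Build the measurement x contrast p-value table.

    ``table`` holds one row per case with ``case_id``, ``group`` and the 32
    measurement columns. Non-finite values are dropped pairwise (logged);
    contrasts with fewer than 2 finite cases on either side are flagged as
    NaN rather than failing. The result has one row per measurement, its
    landmark family, the 7 p-value columns, and matching boolean
    ``significant (<name>)`` columns marking p < 0.05. With ``fdr=True``,
    Benjamini-Hochberg-adjusted columns are appended.
    """
    unknown = set(table["group"].unique()) - set(GROUP_LABELS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")

    rows = []
    for name in MEASUREMENT_NAMES:
        row: dict[str, object] = {
            "Measurement": name,
            "Landmark": MEASUREMENT_FAMILIES[name],
        }
        for contrast, (groups_a, groups_b) in CONTRASTS.items():
            a = table.loc[table["group"].isin(groups_a), name].to_numpy(dtype=float)
            b = table.loc[table["group"].isin(groups_b), name].to_numpy(dtype=float)
            n_dropped = np.count_nonzero(~np.isfinite(a)) + np.count_nonzero(
                ~np.isfinite(b)
            )
            if n_dropped:
                logger.info(
                    "%s / %s: dropped %d non-finite values", name, contrast, n_dropped
                )
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if a.size < 2 or b.size < 2:
                row[contrast] = np.nan
            else:
                row[contrast] = two_sample_test(a, b, mode)
        rows.append(row)
    out = pd.DataFrame(rows)
    for contrast in CONTRASTS:
        out[f"significant ({contrast})"] = out[contrast] < ALPHA
    if fdr:
        from statsmodels.stats.multitest import multipletests  # lazy; optional path

        for contrast in CONTRASTS:
            p = out[contrast].to_numpy(dtype=float)
            ok = np.isfinite(p)
            adj = np.full_like(p, np.nan)
            if ok.any():
                adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
            out[f"fdr ({contrast})"] = adj
    return out
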