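"""Outlier screening of raw ROI tables with Tukey fences.

Following the ENIGMA protocol, a measurement is flagged when it falls
outside ``[Q1 - k*IQR, Q3 + k*IQR]`` with k = 1.5 by default.  Quartiles
use linear interpolation between order statistics (numpy's default,
"type 7").  Flags are a report for inspection — nothing is removed here;
callers may drop flagged cells explicitly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import QCReport, ROICohort


def flag_outliers(cohort: ROICohort, k: float = 1.5) -> QCReport:
    """Flag every (subject, ROI) measurement outside its ROI's Tukey fences.

    Parameters
    ----------
    cohort : ROICohort
        Raw-scale measurements; missing cells are ignored.
    k : float
        Fence multiplier (> 0); 1.5 is the conventional value.

    Returns
    -------
    QCReport with one row per flagged cell and the per-ROI fences used.
    """
    if k <= 0:
        raise ValueError(f"fence multiplier k must be > 0, got {k}")
    block = cohort.measures
    n_valid = block.notna().sum()
    too_few = n_valid[n_valid < 4]
    if len(too_few):
        raise ValueError(
            f"need >= 4 non-missing values per ROI for fences; too few in: "
            f"{too_few.index.tolist()}"
        )

    q1 = block.quantile(0.25)
    q3 = block.quantile(0.75)
    iqr = q3 - q1
    lower = q1 - k * iqr
    upper = q3 + k * iqr

    zero_iqr = iqr.index[(iqr == 0)]
    for roi in zero_iqr:
        col = block[roi].dropna()
        if (col != col.median()).any():
            warnings.warn(
                f"ROI {roi!r} has zero IQR but off-median values; "
                "fences degenerate to the median",
                stacklevel=2,
            )

    rows = []
    outside = block.lt(lower, axis=1) | block.gt(upper, axis=1)
    for roi in block.columns:
        col = block[roi]
        for subj in block.index[outside[roi] & col.notna()]:
            rows.append((subj, roi, col[subj], lower[roi], upper[roi]))
    flags = pd.DataFrame(
        rows, columns=["subject_id", "roi_name", "value", "lower_fence", "upper_fence"]
    )
    fences = pd.DataFrame({"lower_fence": lower, "upper_fence": upper})
    fences.index.name = "roi_name"
    return QCReport(flags=flags, n_checked=int(block.notna().sum().sum()), fences=fences)


def drop_flagged(cohort: ROICohort, report: QCReport) -> ROICohort:
    """Return a copy of the cohort with flagged cells set to missing."""
    data = cohort.data.copy()
    for _, row in report.flags.iterrows():
        data.loc[row["subject_id"], row["roi_name"]] = np.nan
    return ROICohort(data=data, roi_meta=dict(cohort.roi_meta),
                     unknown_columns=list(cohort.unknown_columns))
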