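"""Domain containers and CSV/JSON readers and writers.

All tabular interchange is comma-separated UTF-8 with a mandatory header
row and ``.`` decimal point.  Floats are written with ``repr`` (shortest
round-tripping) precision, so ``read(write(x)) == x`` at stored precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rois

COVARIATE_COLUMNS = ("age", "sex", "icv")
DEFAULT_SCHEMA = {
    "subject_id": "subject_id",
    "group": "group",
    "age": "age",
    "sex": "sex",
    "icv": "icv",
}


@dataclass
class ROICohort:
    """Wide subject x ROI measurement table with covariates and group labels.

    ``data`` is indexed by subject_id and holds the ``group``, ``age``,
    ``sex``, ``icv`` columns followed by one column per ROI on the raw
    measurement scale (mm^3 / mm / mm^2).  ``roi_meta`` maps each ROI
    column to its metric class.
    """

    data: pd.DataFrame
    roi_meta: dict[str, str]
    unknown_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def roi_names(self) -> list[str]:
        return [c for c in self.data.columns if c in self.roi_meta]

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    @property
    def measures(self) -> pd.DataFrame:
        """Subject x ROI block, raw scale, NaN for missing."""
        return self.data[self.roi_names]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data[list(COVARIATE_COLUMNS)]

    def validate(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dupes = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate subject ids: {dupes}")
        missing_cols = [c for c in ("group", *COVARIATE_COLUMNS) if c not in self.data.columns]
        if missing_cols:
            raise ValueError(f"cohort missing required columns: {missing_cols}")
        for name in self.roi_names:
            if name not in self.roi_meta:
                raise ValueError(f"ROI column {name!r} absent from roi_meta")
        rois_all_nan = [r for r in self.roi_names if self.data[r].isna().all()]
        if rois_all_nan:
            raise ValueError(f"ROI columns entirely missing: {rois_all_nan}")
        block = self.measures
        if (block <= 0).any().any():
            bad = block.columns[(block <= 0).any()].tolist()
            raise ValueError(f"non-positive raw measurements in ROIs: {bad}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ROICohort):
            return NotImplemented
        return self.roi_meta == other.roi_meta and self.data.equals(other.data)


@dataclass
class WeightSet:
    """Signed meta-analytic Cohen's d prior per ROI for one disorder."""

    disorder: str
    weights: pd.Series  # index roi_name, value d
    source: str = ""

    def __post_init__(self) -> None:
        self.weights = self.weights.astype(float)
        if self.weights.index.has_duplicates:
            raise ValueError("duplicate roi_name entries in weight set")
        if (self.weights == 0).all() or self.weights.empty:
            raise ValueError("weight set has no nonzero weights")
        if (self.weights.abs() >= 5).any():
            bad = self.weights[self.weights.abs() >= 5].index.tolist()
            raise ValueError(f"implausible |d| >= 5 for ROIs: {bad}")

    @property
    def roi_names(self) -> list[str]:
        return list(self.weights.index)


@dataclass
class QCReport:
    """Tukey-fence outlier flags: one row per (subject, ROI) outside the fences."""

    flags: pd.DataFrame  # subject_id, roi_name, value, lower_fence, upper_fence
    n_checked: int
    fences: pd.DataFrame | None = None  # per-ROI lower/upper actually used

    def __post_init__(self) -> None:
        if len(self.flags):
            inside = (self.flags["value"] >= self.flags["lower_fence"]) & (
                self.flags["value"] <= self.flags["upper_fence"]
            )
            if inside.any():
                raise ValueError("QCReport contains flags inside their own fences")


def read_cohort(path, schema: dict[str, str] | None = None) -> ROICohort:
    """Read a wide cohort CSV into a validated :class:`ROICohort`.

    ``schema`` maps the standard roles (subject_id/group/age/sex/icv) to
    the file's column names; remaining columns are resolved to canonical
    ROI names.  Unresolvable columns are kept on ``unknown_columns`` and
    reported with a warning, never silently dropped.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype={schema["subject_id"]: str}, float_precision="round_trip")
    missing = [role for role, col in schema.items() if col not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing columns for roles: {missing}")
    rename = {col: role for role, col in schema.items()}
    df = df.rename(columns=rename)
    if df["subject_id"].duplicated().any():
        dupes = sorted(df.loc[df["subject_id"].duplicated(), "subject_id"].unique())
        raise ValueError(f"duplicate subject ids: {dupes}")
    df = df.set_index("subject_id")

    roi_meta: dict[str, str] = {}
    unknown: list[str] = []
    roi_rename: dict[str, str] = {}
    for col in df.columns:
        if col in ("group", *COVARIATE_COLUMNS):
            continue
        canon = rois.canonicalize_roi(col)
        if canon is None:
            unknown.append(col)
            continue
        roi_rename[col] = canon
        roi_meta[canon] = rois.roi_metric(canon)
    df = df.rename(columns=roi_rename)
    if unknown:
        warnings.warn(f"unrecognised columns kept but not scored: {unknown}", stacklevel=2)

    for col in (*roi_meta, *COVARIATE_COLUMNS):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            subj = df.index[bad][0]
            raise ValueError(
                f"non-numeric value {df.loc[subj, col]!r} in column {col!r}, subject {subj!r}"
            )
        df[col] = coerced.astype(float)
    return ROICohort(data=df, roi_meta=roi_meta, unknown_columns=unknown)


def write_cohort(cohort: ROICohort, path) -> None:
    cohort.data.to_csv(path, index_label="subject_id")


def read_weights(path, disorder: str | None = None) -> WeightSet:
    """Read a two-column ``roi_name,d`` weight table.

    Lines starting with ``#`` are treated as metadata; a ``# disorder:``
    or ``# source:`` line populates the corresponding field.
    """
    meta = {"disorder": disorder or "", "source": ""}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, val = stripped.partition(":")
                if key.strip().lower() in meta and not meta[key.strip().lower()]:
                    meta[key.strip().lower()] = val.strip()
        else:
            body.append(line)
    if not body or len(body) <= 1:
        raise ValueError(f"weight file {path} is empty")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), float_precision="round_trip")
    if not {"roi_name", "d"}.issubset(df.columns):
        raise ValueError(f"weight file {path} must have columns roi_name,d")
    if df["roi_name"].duplicated().any():
        dupes = sorted(df.loc[df["roi_name"].duplicated(), "roi_name"].unique())
        raise ValueError(f"duplicate roi_name in weight file: {dupes}")
    weights = pd.Series(df["d"].to_numpy(float), index=df["roi_name"].tolist())
    return WeightSet(
        disorder=meta["disorder"] or "unnamed",
        weights=weights,
        source=meta["source"],
    )


def write_weights(ws: WeightSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# disorder: {ws.disorder}\n")
        if ws.source:
            fh.write(f"# source: {ws.source}\n")
        fh.write("roi_name,d\n")
        for name, d in ws.weights.items():
            fh.write(f"{name},{d!r}\n")


def write_scores(scores: pd.DataFrame, path, contributions: pd.DataFrame | None = None,
                 contributions_path=None) -> None:
    """Write per-subject scores (one row per subject per weight set); the
    per-ROI contribution breakdown optionally goes to a second long CSV."""
    if scores is None or not len(scores):
        raise ValueError("no scores to write")
    scores.to_csv(path, index=False)
    if contributions is not None and contributions_path is not None:
        contributions.to_csv(contributions_path, index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    if "score" not in df.columns:
        raise ValueError(f"score file {path} missing 'score' column")
    return df


def write_qc_report(report: QCReport, path) -> None:
    report.flags.to_csv(path, index=False)


__all__ = [
    "ROICohort",
    "WeightSet",
    "QCReport",
    "read_cohort",
    "write_cohort",
    "read_weights",
    "write_weights",
    "write_scores",
    "read_scores",
    "write_qc_report",
]
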