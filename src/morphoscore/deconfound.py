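"""Covariate residualization and z-standardization of ROI measures.

Each ROI is regressed (OLS) on nuisance covariates — age, sex and
intracranial volume by default — over a *norm* subset of subjects, and
every subject's measurement is then expressed as a standardized residual

    z = (value - predicted) / residual_SD,

where the residual SD is the unbiased estimate on the norm subset
(denominator n - p - 1, p = number of covariates).  With an empty
covariate list this reduces exactly to the classical z-score.  The norm
subset defaults to the pooled sample (cases and controls together), so a
subject's deviation is measured against the whole-sample norm; a
controls-only mode supports conventional normative modelling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ROICohort


@dataclass
class DeconfoundModel:
    """Per-ROI OLS fit: raw-scale intercept/coefficients plus the
    standardized-design representation actually used for prediction."""

    covariates: list[str]
    roi_names: list[str]
    intercept: pd.Series              # raw scale, per ROI
    coef: pd.DataFrame                # ROI x covariate, raw scale
    resid_sd: pd.Series               # per ROI, ddof = n - p - 1
    n_fit: pd.Series                  # norm-subset size used per ROI
    cov_center: pd.Series             # covariate centering (norm subset mean)
    cov_scale: pd.Series              # covariate scaling (norm subset SD)
    coef_std: pd.DataFrame = field(repr=False, default=None)  # standardized design
    intercept_std: pd.Series = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if (self.resid_sd <= 0).any():
            bad = self.resid_sd.index[self.resid_sd <= 0].tolist()
            raise ValueError(f"non-positive residual SD for ROIs: {bad}")

    def predict(self, covariates: pd.DataFrame) -> pd.DataFrame:
        """Predicted ROI values for each subject (rows) given covariates."""
        c = (covariates[self.covariates] - self.cov_center) / self.cov_scale
        pred = c.to_numpy(float) @ self.coef_std.to_numpy(float).T
        pred += self.intercept_std.to_numpy(float)
        return pd.DataFrame(pred, index=covariates.index, columns=self.roi_names)

    def to_json(self, path) -> None:
        payload = {
            "covariates": self.covariates,
            "cov_center": self.cov_center.to_dict(),
            "cov_scale": self.cov_scale.to_dict(),
            "rois": {
                roi: {
                    "intercept": float(self.intercept[roi]),
                    "coef": {c: float(self.coef.loc[roi, c]) for c in self.covariates},
                    "intercept_std": float(self.intercept_std[roi]),
                    "coef_std": {c: float(self.coef_std.loc[roi, c]) for c in self.covariates},
                    "resid_sd": float(self.resid_sd[roi]),
                    "n_fit": int(self.n_fit[roi]),
                }
                for roi in self.roi_names
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DeconfoundModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        covs = payload["covariates"]
        rois = list(payload["rois"])
        rec = payload["rois"]
        return cls(
            covariates=covs,
            roi_names=rois,
            intercept=pd.Series({r: rec[r]["intercept"] for r in rois}),
            coef=pd.DataFrame({c: {r: rec[r]["coef"][c] for r in rois} for c in covs}).loc[rois, covs],
            resid_sd=pd.Series({r: rec[r]["resid_sd"] for r in rois}),
            n_fit=pd.Series({r: rec[r]["n_fit"] for r in rois}),
            cov_center=pd.Series(payload["cov_center"]),
            cov_scale=pd.Series(payload["cov_scale"]),
            coef_std=pd.DataFrame({c: {r: rec[r]["coef_std"][c] for r in rois} for c in covs}).loc[rois, covs],
            intercept_std=pd.Series({r: rec[r]["intercept_std"] for r in rois}),
        )


@dataclass
class DeviationMatrix:
    """Subject x ROI matrix of deconfounded, standardized deviations."""

    z: pd.DataFrame  # index subject_id, columns roi_names
    norm_spec: dict

    @property
    def subject_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def roi_names(self) -> list[str]:
        return list(self.z.columns)


class Deconfounder(BaseEstimator, TransformerMixin):
    """Residualize ROI measures on nuisance covariates and rescale to z.

    Parameters
    ----------
    covariates : sequence of str
        Covariate columns removed from every ROI; default age, sex, ICV
        for all metric classes.  Pass ``()`` for plain z-scoring.
    norm : {"pooled", "controls"} or sequence of subject ids
        Which subjects define the norm: the whole sample (default), the
        control group, or an explicit subject list.
    control_label : str
        Group label identifying controls when ``norm="controls"``.

    Attributes
    ----------
    model_ : DeconfoundModel
        Per-ROI intercept, coefficients and residual SD.
    norm_subjects_ : list of subject ids that defined the norm.
    """

    def __init__(self, covariates=("age", "sex", "icv"), norm="pooled",
                 control_label="control"):
        self.covariates = covariates
        self.norm = norm
        self.control_label = control_label

    def _norm_index(self, cohort: ROICohort) -> pd.Index:
        if isinstance(self.norm, str):
            if self.norm == "pooled":
                return cohort.data.index
            if self.norm == "controls":
                idx = cohort.data.index[cohort.groups == self.control_label]
                if not len(idx):
                    raise ValueError(
                        f"no subjects with group == {self.control_label!r} for controls norm"
                    )
                return idx
            raise ValueError(f"unknown norm {self.norm!r}")
        idx = pd.Index(self.norm)
        missing = idx.difference(cohort.data.index)
        if len(missing):
            raise ValueError(f"norm subjects absent from cohort: {missing.tolist()}")
        return idx

    def fit(self, cohort: ROICohort, y=None) -> "Deconfounder":
        covs = list(self.covariates)
        norm_idx = self._norm_index(cohort)
        sub = cohort.data.loc[norm_idx]
        if covs:
            missing = [c for c in covs if c not in cohort.data.columns]
            if missing:
                raise ValueError(f"covariates absent from cohort: {missing}")
            complete = sub[covs].notna().all(axis=1)
            sub = sub.loc[complete]
        p = len(covs)
        if len(sub) <= p + 1:
            raise ValueError(
                f"norm subset size {len(sub)} must exceed number of covariates + 1 ({p + 1})"
            )

        if covs:
            center = sub[covs].mean()
            scale = sub[covs].std(ddof=1)
            constant = scale.index[(scale == 0) | scale.isna()].tolist()
            if constant:
                raise ValueError(f"constant covariate column(s): {constant}")
            c_std = ((sub[covs] - center) / scale).to_numpy(float)
            corr = np.corrcoef(c_std, rowvar=False)
            dep = [
                (covs[i], covs[j])
                for i in range(p)
                for j in range(i + 1, p)
                if abs(corr[i, j]) > 1 - 1e-10
            ]
            if dep:
                raise ValueError(f"collinear covariates: {dep}")
        else:
            center = pd.Series(dtype=float)
            scale = pd.Series(dtype=float)
            c_std = np.empty((len(sub), 0))

        design = np.column_stack([np.ones(len(sub)), c_std])
        roi_names = cohort.roi_names
        y_block = sub[roi_names].to_numpy(float)

        const = [
            roi for roi, col in zip(roi_names, y_block.T)
            if np.nanmax(col) == np.nanmin(col)
        ]
        if const:
            raise ValueError(f"constant ROI(s) on the norm subset: {const}")

        beta = np.full((p + 1, len(roi_names)), np.nan)
        resid_sd = np.full(len(roi_names), np.nan)
        n_fit = np.zeros(len(roi_names), int)
        complete_rows = ~np.isnan(y_block).any(axis=0)
        if complete_rows.any():
            cols = np.flatnonzero(complete_rows)
            b, *_ = np.linalg.lstsq(design, y_block[:, cols], rcond=None)
            beta[:, cols] = b
            resid = y_block[:, cols] - design @ b
            dof = len(sub) - p - 1
            resid_sd[cols] = np.sqrt((resid**2).sum(axis=0) / dof)
            n_fit[cols] = len(sub)
        for j in np.flatnonzero(~complete_rows):
            yj = y_block[:, j]
            ok = ~np.isnan(yj)
            dof = ok.sum() - p - 1
            if dof < 1:
                raise ValueError(
                    f"ROI {roi_names[j]!r}: only {int(ok.sum())} non-missing norm values"
                )
            b, *_ = np.linalg.lstsq(design[ok], yj[ok], rcond=None)
            beta[:, j] = b
            r = yj[ok] - design[ok] @ b
            resid_sd[j] = np.sqrt((r**2).sum() / dof)
            n_fit[j] = int(ok.sum())

        zero_sd = np.flatnonzero(resid_sd == 0)
        if len(zero_sd):
            raise ValueError(
                f"constant ROI(s) (zero residual SD): {[roi_names[j] for j in zero_sd]}"
            )

        coef_std = pd.DataFrame(beta[1:].T, index=roi_names, columns=covs)
        intercept_std = pd.Series(beta[0], index=roi_names)
        if covs:
            coef_raw = coef_std / scale
            intercept_raw = intercept_std - (coef_std * (center / scale)).sum(axis=1)
        else:
            coef_raw = coef_std
            intercept_raw = intercept_std
        self.model_ = DeconfoundModel(
            covariates=covs,
            roi_names=list(roi_names),
            intercept=intercept_raw,
            coef=coef_raw,
            resid_sd=pd.Series(resid_sd, index=roi_names),
            n_fit=pd.Series(n_fit, index=roi_names),
            cov_center=center,
            cov_scale=scale,
            coef_std=coef_std,
            intercept_std=intercept_std,
        )
        self.norm_subjects_ = list(sub.index)
        self.norm_spec_ = {
            "norm": self.norm if isinstance(self.norm, str) else "explicit",
            "n_norm": len(sub),
            "covariates": covs,
            "sex_coding": "0/1 indicator",
            "residual_sd_denominator": "n - p - 1",
        }
        return self

    def transform(self, cohort: ROICohort) -> DeviationMatrix:
        model = self._fitted_model()
        extra = [r for r in model.roi_names if r not in cohort.data.columns]
        if extra:
            raise ValueError(f"cohort lacks ROIs the model was fit on: {extra}")
        covs = model.covariates
        values = cohort.data[model.roi_names]
        if covs:
            cov_df = cohort.data[covs]
            incomplete = cov_df.isna().any(axis=1)
            if incomplete.any():
                warnings.warn(
                    f"{int(incomplete.sum())} subject(s) missing covariates; "
                    "their z rows are all-missing",
                    stacklevel=2,
                )
            pred = model.predict(cov_df.fillna(0.0))
            z = (values - pred) / model.resid_sd
            z[incomplete] = np.nan
        else:
            z = (values - model.intercept) / model.resid_sd
        return DeviationMatrix(
            z=z,
            norm_spec={**self.norm_spec_, "norm_subjects": list(self.norm_subjects_)},
        )

    def _fitted_model(self) -> DeconfoundModel:
        if not hasattr(self, "model_"):
            raise RuntimeError("Deconfounder is not fitted; call fit() first")
        return self.model_


def fit_deconfound(cohort: ROICohort, norm_subjects=None,
                   covariates=("age", "sex", "icv")) -> DeconfoundModel:
    """OLS fit of every ROI on the covariates over the norm subset."""
    norm = "pooled" if norm_subjects is None else list(norm_subjects)
    return Deconfounder(covariates=covariates, norm=norm).fit(cohort).model_


def standardize(cohort: ROICohort, model: DeconfoundModel | Deconfounder) -> DeviationMatrix:
    """Standardized residual z for every subject under a fitted model."""
    if isinstance(model, Deconfounder):
        return model.transform(cohort)
    dec = Deconfounder(covariates=tuple(model.covariates))
    dec.model_ = model
    dec.norm_subjects_ = []
    dec.norm_spec_ = {"norm": "external-model", "covariates": model.covariates}
    return dec.transform(cohort)
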