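"""Morphometric risk score (MRS) computation.

A subject's MRS is the average, over the M ROIs of a weight set, of the
standardized deviation z_r multiplied by the meta-analytic effect size
d_r for the same ROI:

    MRS_i = (1/M) * sum_r d_r * z_{i,r}          (rule = "all_rois")

Because d_r is signed, deviation in the disorder's characteristic
direction (e.g. a larger putamen, where cases show d = +0.37) contributes
positively and deviation against it negatively.  The alternative
``congruent_only`` rule averages |d_r * z_{i,r}| over only the ROIs whose
deviation is sign-congruent with the prior, as in the schematic reading
where incongruent ROIs drop out.  The negative-control mode
``unweighted_control`` keeps each prior's direction but discards its
magnitude (d_r -> sign(d_r)), isolating the contribution of the
meta-analytic weighting itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .deconfound import DeviationMatrix
from .io import WeightSet

RULES = ("all_rois", "congruent_only")
MODES = ("weighted", "unweighted_control")


@dataclass
class ScoreTable:
    """Per-subject scores plus the per-ROI contribution breakdown.

    ``scores`` has one row per subject per weight set with columns
    subject_id, weight_set, score, n_rois_used, mode, rule, reason;
    ``contributions`` is long format with one row per (subject, ROI).
    """

    scores: pd.DataFrame
    contributions: pd.DataFrame | None = None

    def for_weight_set(self, label: str) -> pd.Series:
        sub = self.scores[self.scores["weight_set"] == label]
        if not len(sub):
            raise KeyError(f"no scores for weight set {label!r}")
        return pd.Series(sub["score"].to_numpy(), index=sub["subject_id"].to_numpy())


class MRSScorer(BaseEstimator, TransformerMixin):
    """Score subjects against one or more meta-analytic weight profiles.

    Parameters
    ----------
    weights : WeightSet or sequence of WeightSet
    rule : {"all_rois", "congruent_only"}
        Signed-product mean over every ROI (default), or mean absolute
        weighted deviation over sign-congruent ROIs only.
    mode : {"weighted", "unweighted_control"}
        Use d_r as weight, or only its sign (negative control).
    min_coverage : float in (0, 1]
        Minimum fraction of the weight set's ROIs with non-missing z a
        subject needs for a score; below it the score is missing with a
        stated reason.
    keep_contributions : bool
        Retain the per-ROI breakdown (z, d, contribution) in the output.
    """

    def __init__(self, weights=None, rule="all_rois", mode="weighted",
                 min_coverage=0.8, keep_contributions=False):
        self.weights = weights
        self.rule = rule
        self.mode = mode
        self.min_coverage = min_coverage
        self.keep_contributions = keep_contributions

    def _weight_sets(self) -> list[WeightSet]:
        ws = self.weights
        if ws is None:
            raise ValueError("MRSScorer requires at least one weight set")
        sets = [ws] if isinstance(ws, WeightSet) else list(ws)
        if not sets:
            raise ValueError("MRSScorer requires at least one weight set")
        labels = [w.disorder for w in sets]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate weight-set labels: {labels}")
        return sets

    def fit(self, dev: DeviationMatrix, y=None) -> "MRSScorer":
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}, got {self.rule!r}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0 < self.min_coverage <= 1:
            raise ValueError(f"min_coverage must be in (0, 1], got {self.min_coverage}")
        for ws in self._weight_sets():
            if not set(ws.roi_names) & set(dev.roi_names):
                raise ValueError(
                    f"weight set {ws.disorder!r} shares no ROI with the deviation matrix"
                )
        return self

    def transform(self, dev: DeviationMatrix) -> ScoreTable:
        self.fit(dev)
        frames, contribs = [], []
        for ws in self._weight_sets():
            res = self._score_one(dev, ws)
            frames.append(res.scores)
            if res.contributions is not None:
                contribs.append(res.contributions)
        return ScoreTable(
            scores=pd.concat(frames, ignore_index=True),
            contributions=pd.concat(contribs, ignore_index=True) if contribs else None,
        )

    def _score_one(self, dev: DeviationMatrix, ws: WeightSet) -> ScoreTable:
        # Canonical (sorted) ROI order makes scores invariant to input
        # column order; weight ROIs absent from dev count as missing z.
        order = sorted(ws.roi_names)
        d = ws.weights.reindex(order).to_numpy(float)
        z = dev.z.reindex(columns=order).to_numpy(float)
        n_subj, m_total = z.shape

        d_use = np.sign(d) if self.mode == "unweighted_control" else d
        contrib = z * d_use
        valid = ~np.isnan(z)
        n_valid = valid.sum(axis=1)
        coverage_ok = n_valid >= self.min_coverage * m_total

        if self.rule == "all_rois":
            used = valid
            values = np.where(used, contrib, 0.0)
        else:  # congruent_only: sign(z) == sign(d), both nonzero
            congruent = valid & (np.sign(z) == np.sign(d)) & (z != 0) & (d != 0)
            used = congruent
            values = np.where(used, np.abs(contrib), 0.0)

        m_used = used.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = values.sum(axis=1) / m_used
        score = np.where(m_used > 0, score, np.nan)

        reason = np.full(n_subj, "", dtype=object)
        reason[m_used == 0] = "no contributing ROIs"
        reason[~coverage_ok] = (
            f"coverage below min_coverage={self.min_coverage}"
        )
        score = np.where(coverage_ok, score, np.nan)

        scores = pd.DataFrame(
            {
                "subject_id": dev.z.index,
                "weight_set": ws.disorder,
                "score": score,
                "n_rois_used": m_used,
                "mode": self.mode,
                "rule": self.rule,
                "reason": reason,
            }
        )
        contributions = None
        if self.keep_contributions:
            long = pd.DataFrame(
                {
                    "subject_id": np.repeat(dev.z.index.to_numpy(), m_total),
                    "weight_set": ws.disorder,
                    "roi_name": np.tile(order, n_subj),
                    "z": z.ravel(),
                    "d": np.tile(d, n_subj),
                    "contribution": np.where(used, values, np.nan).ravel(),
                }
            )
            contributions = long
        return ScoreTable(scores=scores, contributions=contributions)


def compute_mrs(dev: DeviationMatrix, weights: WeightSet, rule: str = "all_rois",
                mode: str = "weighted", min_coverage: float = 0.8,
                keep_contributions: bool = False) -> ScoreTable:
    """Score every subject in ``dev`` against one weight set (see MRSScorer)."""
    scorer = MRSScorer(weights=weights, rule=rule, mode=mode,
                       min_coverage=min_coverage,
                       keep_contributions=keep_contributions)
    return scorer.fit(dev).transform(dev)


def score_multi(dev: DeviationMatrix, weight_sets, rule: str = "all_rois",
                mode: str = "weighted", min_coverage: float = 0.8,
                keep_contributions: bool = False) -> ScoreTable:
    """Score against several weight sets at once (one row per subject per set)."""
    scorer = MRSScorer(weights=list(weight_sets), rule=rule, mode=mode,
                       min_coverage=min_coverage,
                       keep_contributions=keep_contributions)
    return scorer.fit(dev).transform(dev)
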