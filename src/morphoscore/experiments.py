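"""Replicate simulation studies exercising the scoring pipeline.

Each function runs a self-contained study on synthetic cohorts — null
calibration of the group comparison, the weighted-versus-unweighted
control analysis, cross-disorder specificity, and the effect-size
spatial-correlation check — and returns summary numbers.  These back the
validation suite and the reproduction script; they are ordinary library
code and can be reused with other settings.
"""

from __future__ import annotations

import numpy as np

from .deconfound import Deconfounder, DeviationMatrix
from .score import compute_mrs
from .stats import cohens_d_per_roi, group_compare, spatial_correlation
from .synthetic import SimConfig, make_weight_profile, simulate_cohort


def _score_and_compare(cohort, ws, pair, seed, mode="weighted"):
    dev = Deconfounder().fit(cohort).transform(cohort)
    table = compute_mrs(dev, ws, mode=mode)
    return group_compare(table, cohort.groups, pair, n_boot=0, seed=seed)


def single_roi_worked_example() -> float:
    """MRS of one subject with a unit congruent deviation on putamen
    volume, weighted by the bundled meta-analytic putamen effect size:
    with M = 1 and z = +1 the score equals the weight itself."""
    import pandas as pd

    from .io import WeightSet

    ws_full = make_weight_profile("scz_like")
    w = WeightSet("scz", ws_full.weights.loc[["putamen_volume"]])
    dev = DeviationMatrix(
        z=pd.DataFrame({"putamen_volume": [1.0]}, index=["s1"]),
        norm_spec={"norm": "external"},
    )
    table = compute_mrs(dev, w, rule="all_rois", min_coverage=1.0)
    return float(table.scores["score"].iloc[0])


def null_calibration(n_reps: int = 1000, n_per_group: int = 100,
                     alpha: float = 0.05, seed0: int = 1) -> dict:
    """Type-I error of the score group comparison when kappa = 0.

    Cases and controls are drawn from the same distribution; the fraction
    of replicates with parametric p < alpha should sit at alpha.
    """
    ws = make_weight_profile("scz_like")
    rejections = 0
    for rep in range(n_reps):
        cfg = SimConfig(
            n_per_group={"control": n_per_group, "case": n_per_group},
            profiles={"case": (ws, 0.0)},
            seed=seed0 + rep,
        )
        cohort, _ = simulate_cohort(cfg)
        gc = _score_and_compare(cohort, ws, ("control", "case"), seed=seed0 + rep)
        rejections += gc.p < alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps,
            "n_per_group": n_per_group, "alpha": alpha}


def weighted_vs_unweighted(n_reps: int = 200, n_control: int = 125,
                           n_case: int = 50, kappa: float = 0.5,
                           pi: float = 0.8, seed0: int = 1) -> dict:
    """The negative-control analysis: does the meta-analytic weighting
    buy sensitivity?

    Case shifts follow the scz_like profile with per-subject
    heterogeneity; both the weighted MRS and the sign-only unweighted
    control score are compared between groups in each replicate.
    """
    ws = make_weight_profile("scz_like")
    betas_w, betas_u, sig_w, sig_u = [], [], 0, 0
    for rep in range(n_reps):
        cfg = SimConfig(
            n_per_group={"control": n_control, "case": n_case},
            profiles={"case": (ws, kappa)},
            heterogeneity=pi,
            seed=seed0 + rep,
        )
        cohort, _ = simulate_cohort(cfg)
        dev = Deconfounder().fit(cohort).transform(cohort)
        gw = group_compare(compute_mrs(dev, ws), cohort.groups,
                           ("control", "case"), n_boot=0, seed=rep)
        gu = group_compare(compute_mrs(dev, ws, mode="unweighted_control"),
                           cohort.groups, ("control", "case"), n_boot=0, seed=rep)
        betas_w.append(gw.beta)
        betas_u.append(gu.beta)
        sig_w += gw.p < 0.05
        sig_u += gu.p < 0.05
    return {
        "mean_beta_weighted": float(np.mean(betas_w)),
        "mean_beta_unweighted": float(np.mean(betas_u)),
        "power_weighted": sig_w / n_reps,
        "power_unweighted": sig_u / n_reps,
        "n_reps": n_reps,
    }


def cross_disorder_specificity(n_reps: int = 100, n_per_group: int = 100,
                               kappa: float = 0.5, seed0: int = 1,
                               with_spatial: bool = True) -> dict:
    """Three-group specificity study: SCZ-profile and ADHD-profile cases
    against controls, scored with both weight sets.

    Per replicate, the matched beta (SCZ score on SCZ cases, ADHD score
    on ADHD cases) is compared with the mismatched one; optionally the
    in-sample per-ROI Cohen's d profile is correlated with the
    generating weight profile.
    """
    scz = make_weight_profile("scz_like")
    adhd = make_weight_profile("adhd_like")
    matched_wins = 0
    spatial_hits = 0
    for rep in range(n_reps):
        cfg = SimConfig(
            n_per_group={"control": n_per_group, "scz": n_per_group, "adhd": n_per_group},
            profiles={"scz": (scz, kappa), "adhd": (adhd, kappa)},
            seed=seed0 + rep,
        )
        cohort, _ = simulate_cohort(cfg)
        dev = Deconfounder().fit(cohort).transform(cohort)
        betas = {}
        for ws in (scz, adhd):
            table = compute_mrs(dev, ws)
            for grp in ("scz", "adhd"):
                gc = group_compare(table, cohort.groups, ("control", grp),
                                   n_boot=0, seed=rep)
                betas[(ws.disorder, grp)] = gc.beta
        if (betas[("scz_like", "scz")] > betas[("scz_like", "adhd")]
                and betas[("adhd_like", "adhd")] > betas[("adhd_like", "scz")]):
            matched_wins += 1
        if with_spatial:
            esv = cohens_d_per_roi(dev, cohort.groups, ("control", "scz"))
            r, p, _ = spatial_correlation(esv, scz)
            spatial_hits += (r > 0) and (p < 0.05)
    out = {"matched_beats_mismatched": matched_wins / n_reps, "n_reps": n_reps}
    if with_spatial:
        out["spatial_corr_significant"] = spatial_hits / n_reps
    return out
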