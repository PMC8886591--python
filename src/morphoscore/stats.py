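"""Group-level statistics for deviation matrices and risk scores.

Covers the analyses that surround the score itself: per-ROI adjusted
Cohen's d between groups, spatial correlation of an in-sample effect-size
profile against a meta-analytic prior, standardized group comparison of a
score with stratified-bootstrap percentile CIs, the cross-disorder
specificity matrix, an exact one-sided sign test on effect directions,
and score-phenotype regression.  Multiple testing uses Bonferroni
throughout, matching the source analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .deconfound import DeviationMatrix
from .io import WeightSet
from .score import ScoreTable


def bonferroni(p, k: int):
    """Bonferroni adjustment min(1, p*k)."""
    return np.minimum(1.0, np.asarray(p, float) * k)


@dataclass
class EffectSizeVector:
    """Per-ROI covariate-adjusted Cohen's d (group b vs group a) with
    pooled-variance t-test p-values, Bonferroni-adjusted over the ROIs
    actually tested."""

    roi_names: list[str]
    d: pd.Series
    n1: int
    n2: int
    p: pd.Series
    p_adj: pd.Series
    pair: tuple[str, str] = ("a", "b")


@dataclass
class GroupComparison:
    """Standardized group difference in a score with bootstrap 95% CI."""

    score_label: str
    group_a: str
    group_b: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    n_a: int
    n_b: int
    n_boot: int
    seed: int | None


def cohens_d_per_roi(dev: DeviationMatrix, groups: pd.Series,
                     pair: tuple[str, str]) -> EffectSizeVector:
    """Cohen's d per ROI between two groups on deconfounded z-scores.

    d_r = (mean_b - mean_a) / pooled SD; the p-value is the pooled-variance
    two-sample t-test, Bonferroni-corrected over the ROIs tested.  ROIs
    with zero pooled SD get a missing d with a warning.
    """
    a, b = pair
    groups = groups.reindex(dev.z.index)
    za = dev.z.loc[groups == a].to_numpy(float)
    zb = dev.z.loc[groups == b].to_numpy(float)
    n1_col = (~np.isnan(za)).sum(axis=0)
    n2_col = (~np.isnan(zb)).sum(axis=0)
    if (n1_col < 2).any() or (n2_col < 2).any():
        raise ValueError("both groups need >= 2 non-missing subjects per ROI")

    ma, mb = np.nanmean(za, axis=0), np.nanmean(zb, axis=0)
    va, vb = np.nanvar(za, axis=0, ddof=1), np.nanvar(zb, axis=0, ddof=1)
    pooled = np.sqrt(((n1_col - 1) * va + (n2_col - 1) * vb) / (n1_col + n2_col - 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (mb - ma) / pooled
        t = d / np.sqrt(1.0 / n1_col + 1.0 / n2_col)
    zero_sd = pooled == 0
    if zero_sd.any():
        warnings.warn(
            f"zero pooled SD; d missing for ROIs: "
            f"{[r for r, z0 in zip(dev.roi_names, zero_sd) if z0]}",
            stacklevel=2,
        )
        d = np.where(zero_sd, np.nan, d)
        t = np.where(zero_sd, np.nan, t)
    df = n1_col + n2_col - 2
    p = 2 * sps.t.sf(np.abs(t), df)
    k = int((~np.isnan(d)).sum())
    return EffectSizeVector(
        roi_names=list(dev.roi_names),
        d=pd.Series(d, index=dev.roi_names),
        n1=int(za.shape[0]),
        n2=int(zb.shape[0]),
        p=pd.Series(p, index=dev.roi_names),
        p_adj=pd.Series(bonferroni(p, k), index=dev.roi_names),
        pair=(a, b),
    )


def spatial_correlation(v1, v2, method: str = "pearson"):
    """Correlate two ROI effect-size profiles over their shared ROIs.

    ``v1``/``v2`` may be EffectSizeVector, WeightSet, or a Series indexed
    by ROI name.  Returns ``(r, p, n_rois)`` where p comes from the
    standard t transform of r.
    """
    s1, s2 = (_as_series(v) for v in (v1, v2))
    shared = s1.index.intersection(s2.index)
    x = s1.loc[shared].to_numpy(float)
    y = s2.loc[shared].to_numpy(float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 shared ROIs, got {int(ok.sum())}")
    fn = sps.pearsonr if method == "pearson" else sps.spearmanr
    r, p = fn(x[ok], y[ok])
    return float(r), float(p), int(ok.sum())


def _as_series(v) -> pd.Series:
    if isinstance(v, EffectSizeVector):
        return v.d
    if isinstance(v, WeightSet):
        return v.weights
    return pd.Series(v)


def _extract_scores(scores, score_label=None) -> tuple[pd.Series, str]:
    if isinstance(scores, ScoreTable):
        df = scores.scores
        labels = df["weight_set"].unique()
        if score_label is None:
            if len(labels) != 1:
                raise ValueError(
                    f"score table has several weight sets {list(labels)}; pass score_label"
                )
            score_label = labels[0]
        return ScoreTable(df).for_weight_set(score_label), str(score_label)
    s = pd.Series(scores, dtype=float)
    return s, str(score_label or getattr(scores, "name", None) or "score")


def group_compare(scores, groups: pd.Series, pair: tuple[str, str],
                  covariates: pd.DataFrame | None = None, n_boot: int = 5000,
                  seed: int | None = None, score_label: str | None = None) -> GroupComparison:
    """Standardized group difference in a score, with bootstrap 95% CI.

    The score is z-scored across the compared subjects, so beta is in
    score-SD units.  beta is the OLS coefficient of the group-b indicator
    (plus optional covariates); its p-value is parametric.  The CI is a
    percentile bootstrap over within-group (stratified) case resampling,
    reproducible from ``seed``; ``n_boot=0`` skips the bootstrap.
    """
    y, label = _extract_scores(scores, score_label)
    a, b = pair
    groups = groups.reindex(y.index)
    mask_a = (groups == a) & y.notna()
    mask_b = (groups == b) & y.notna()
    if not mask_a.any() or not mask_b.any():
        empty = a if not mask_a.any() else b
        raise ValueError(f"group {empty!r} empty after missing-score removal")
    if n_boot and seed is None:
        raise ValueError("bootstrap requires an explicit seed")

    ya = y[mask_a].to_numpy(float)
    yb = y[mask_b].to_numpy(float)
    cov = None
    if covariates is not None:
        cov = covariates.reindex(y.index)
        cov_a = cov[mask_a].to_numpy(float)
        cov_b = cov[mask_b].to_numpy(float)

    def fit(ya_, yb_, cov_a_=None, cov_b_=None, want_p=False):
        yy = np.concatenate([ya_, yb_])
        sd = yy.std(ddof=1)
        if sd == 0:
            return 0.0, 1.0
        ys = (yy - yy.mean()) / sd
        if cov_a_ is None:
            na = len(ya_)
            beta = ys[na:].mean() - ys[:na].mean()
            if not want_p:
                return beta, None
            _, p = sps.ttest_ind(ys[na:], ys[:na], equal_var=True)
            return beta, float(p)
        ind = np.concatenate([np.zeros(len(ya_)), np.ones(len(yb_))])
        X = sm.add_constant(np.column_stack([ind, np.vstack([cov_a_, cov_b_])]))
        res = sm.OLS(ys, X, missing="drop").fit()
        return float(res.params[1]), float(res.pvalues[1])

    if cov is None:
        beta, p = fit(ya, yb, want_p=True)
    else:
        beta, p = fit(ya, yb, cov_a, cov_b, want_p=True)

    ci_low = ci_high = np.nan
    if n_boot:
        if n_boot < 1000:
            warnings.warn("n_boot < 1000 gives unstable percentile CIs", stacklevel=2)
        rng = np.random.default_rng(seed)
        na, nb = len(ya), len(yb)
        idx_a = rng.integers(0, na, size=(n_boot, na))
        idx_b = rng.integers(0, nb, size=(n_boot, nb))
        if cov is None:
            ra, rb = ya[idx_a], yb[idx_b]
            s1 = ra.sum(axis=1) + rb.sum(axis=1)
            s2 = (ra**2).sum(axis=1) + (rb**2).sum(axis=1)
            n = na + nb
            var = (s2 - s1**2 / n) / (n - 1)
            sd = np.sqrt(np.maximum(var, 0.0))
            diff = rb.mean(axis=1) - ra.mean(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                betas = np.where(sd > 0, diff / sd, 0.0)
        else:
            betas = np.empty(n_boot)
            for i in range(n_boot):
                betas[i], _ = fit(ya[idx_a[i]], yb[idx_b[i]],
                                  cov_a[idx_a[i]], cov_b[idx_b[i]])
        ci_low, ci_high = np.percentile(betas, [2.5, 97.5])
    return GroupComparison(
        score_label=label, group_a=a, group_b=b, beta=float(beta),
        ci_low=float(ci_low), ci_high=float(ci_high), p=float(p),
        n_a=len(ya), n_b=len(yb), n_boot=int(n_boot), seed=seed,
    )


def cross_disorder_matrix(score_table: ScoreTable, groups: pd.Series,
                          reference: str = "control", n_boot: int = 5000,
                          seed: int | None = None,
                          covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Specificity matrix: every weight set compared in every non-reference
    group versus the reference, Bonferroni-corrected over all cells.

    Returns a long DataFrame (weight_set, group_a, group_b, beta, ci_low,
    ci_high, p, p_adj, n_a, n_b).  Per-cell bootstrap seeds are spawned
    deterministically from ``seed``.
    """
    labels = sorted(score_table.scores["weight_set"].unique())
    if len(labels) < 2:
        raise ValueError("cross-disorder matrix needs >= 2 weight sets")
    glabels = [g for g in pd.unique(groups.dropna()) if g != reference]
    if reference not in set(groups.dropna()):
        raise ValueError(f"reference group {reference!r} absent")
    if len(glabels) < 1:
        raise ValueError("need >= 2 groups")
    cells = [(w, g) for w in labels for g in glabels]
    seeds = np.random.SeedSequence(seed).generate_state(len(cells)) % (2**31)
    rows = []
    for (w, g), s in zip(cells, seeds):
        gc = group_compare(score_table, groups, (reference, g), covariates=covariates,
                           n_boot=n_boot, seed=int(s), score_label=w)
        rows.append({
            "weight_set": w, "group_a": reference, "group_b": g,
            "beta": gc.beta, "ci_low": gc.ci_low, "ci_high": gc.ci_high,
            "p": gc.p, "n_a": gc.n_a, "n_b": gc.n_b,
        })
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni(out["p"], len(out))
    return out


def sign_test(directions, hypothesized: str = "+") -> float:
    """Exact one-sided sign test: P(X >= k) under Binomial(n, 1/2).

    ``directions`` holds '+'/'-' (or +1/-1) observed effect directions;
    k counts those matching the hypothesised direction.  Zeros are
    dropped with a warning.
    """
    mapped = []
    for v in directions:
        if v in ("+", 1, +1.0):
            mapped.append(1)
        elif v in ("-", -1, -1.0):
            mapped.append(-1)
        elif v in (0, 0.0, "0"):
            mapped.append(0)
        else:
            raise ValueError(f"direction must be +/-/0, got {v!r}")
    n_zero = mapped.count(0)
    if n_zero:
        warnings.warn(f"dropping {n_zero} zero direction(s)", stacklevel=2)
        mapped = [v for v in mapped if v != 0]
    if not mapped:
        raise ValueError("no nonzero effect directions")
    want = 1 if hypothesized == "+" else -1
    k = sum(v == want for v in mapped)
    return float(sps.binomtest(k, len(mapped), 0.5, alternative="greater").pvalue)


def associate_phenotype(scores, phenotype: pd.Series,
                        covariates: pd.DataFrame | None = None,
                        k_tests: int = 1, score_label: str | None = None):
    """Regress a phenotype on a score (both standardized), with optional
    covariates; returns ``(beta, p, p_adj)`` Bonferroni-adjusted over
    ``k_tests`` phenotypes examined."""
    y, _ = _extract_scores(scores, score_label)
    phen = pd.Series(phenotype, dtype=float).reindex(y.index)
    df = pd.DataFrame({"score": y, "phen": phen})
    if covariates is not None:
        cov = covariates.reindex(y.index)
        df = pd.concat([df, cov], axis=1)
    df = df.dropna()
    if len(df) < 10:
        raise ValueError(f"need >= 10 complete cases, got {len(df)}")
    if df["phen"].std(ddof=1) == 0:
        raise ValueError("constant phenotype")
    ys = (df["phen"] - df["phen"].mean()) / df["phen"].std(ddof=1)
    xs = (df["score"] - df["score"].mean()) / df["score"].std(ddof=1)
    X = pd.DataFrame({"score": xs})
    if covariates is not None:
        X = pd.concat([X, df[covariates.columns]], axis=1)
    res = sm.OLS(ys, sm.add_constant(X)).fit()
    beta = float(res.params["score"])
    p = float(res.pvalues["score"])
    return beta, p, float(bonferroni(p, k_tests))
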