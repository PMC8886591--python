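import itertools

import numpy as np
import pandas as pd
import pytest

from morphoscore import (
    DeviationMatrix,
    WeightSet,
    associate_phenotype,
    cohens_d_per_roi,
    cross_disorder_matrix,
    group_compare,
    sign_test,
    spatial_correlation,
)
from morphoscore.score import ScoreTable
from morphoscore.stats import bonferroni


def make_dev(z, rois, ids=None):
    ids = ids or [f"s{i}" for i in range(len(z))]
    return DeviationMatrix(z=pd.DataFrame(np.asarray(z, float), index=ids,
                                          columns=rois), norm_spec={})


def make_scores(values, ids=None, label="scz"):
    ids = ids or [f"s{i}" for i in range(len(values))]
    return ScoreTable(pd.DataFrame({"subject_id": ids, "weight_set": label,
                                    "score": np.asarray(values, float)}))


# ---------------------------------------------------------------- cohens d

def test_cohens_d_identical_groups_is_zero():
    rng = np.random.default_rng(0)
    z = rng.standard_normal((10, 4))
    dev = make_dev(np.vstack([z, z]), [f"r{i}_volume" for i in range(4)])
    groups = pd.Series(["a"] * 10 + ["b"] * 10, index=dev.z.index)
    esv = cohens_d_per_roi(dev, groups, ("a", "b"))
    assert (esv.d == 0).all()


def test_cohens_d_shift_recovery():
    rng = np.random.default_rng(1)
    rois = [f"r{i}_volume" for i in range(3)]
    za = rng.standard_normal((200, 3))
    zb = rng.standard_normal((200, 3))
    zb[:, 1] += 1.0
    dev = make_dev(np.vstack([za, zb]), rois)
    groups = pd.Series(["a"] * 200 + ["b"] * 200, index=dev.z.index)
    esv = cohens_d_per_roi(dev, groups, ("a", "b"))
    assert 0.8 <= esv.d.iloc[1] <= 1.2
    assert esv.p_adj.iloc[1] < 0.001
    assert (esv.p_adj >= esv.p - 1e-15).all()


def test_cohens_d_null_calibration():
    # same-distribution groups: small effects, ~95% of nominal 95% d CIs
    # cover 0 (averaged over many independent ROI draws)
    rng = np.random.default_rng(1)
    rois = [f"r{i}_volume" for i in range(500)]
    dev = make_dev(rng.standard_normal((400, 500)), rois)
    groups = pd.Series(["a"] * 200 + ["b"] * 200, index=dev.z.index)
    esv = cohens_d_per_roi(dev, groups, ("a", "b"))
    assert esv.d.abs().max() < 0.3
    se = np.sqrt(1 / 200 + 1 / 200)
    covers = (esv.d.abs() < 1.96 * se).mean()
    assert covers >= 0.94 - 1e-12


def test_cohens_d_zero_pooled_sd_warns():
    dev = make_dev([[1.0], [1.0], [1.0], [1.0]], ["r0_volume"])
    groups = pd.Series(["a", "a", "b", "b"], index=dev.z.index)
    with pytest.warns(UserWarning, match="zero pooled SD"):
        esv = cohens_d_per_roi(dev, groups, ("a", "b"))
    assert np.isnan(esv.d.iloc[0])


# ------------------------------------------------------ spatial correlation

def test_spatial_correlation_identity_and_antisymmetry():
    d = pd.Series({"a_volume": 0.3, "b_volume": -0.1, "c_volume": 0.2, "d_volume": 0.05})
    w = WeightSet("x", d)
    r, p, n = spatial_correlation(d, w)
    assert r == pytest.approx(1.0)
    assert n == 4
    r2, _, _ = spatial_correlation(-d, w)
    assert r2 == pytest.approx(-1.0)


def test_spatial_correlation_needs_three_shared():
    a = pd.Series({"a_volume": 0.3, "b_volume": 0.1})
    b = pd.Series({"a_volume": 0.2, "b_volume": 0.4})
    with pytest.raises(ValueError, match=">= 3 shared"):
        spatial_correlation(a, b)


# ------------------------------------------------------------ group compare

def test_group_compare_identical_distributions_beta_zero():
    vals = np.r_[np.linspace(-1, 1, 30), np.linspace(-1, 1, 30)]
    groups = pd.Series(["a"] * 30 + ["b"] * 30,
                       index=[f"s{i}" for i in range(60)])
    gc = group_compare(make_scores(vals), groups, ("a", "b"), n_boot=0, seed=1)
    assert gc.beta == 0.0


def test_group_compare_one_sd_shift_construction():
    rng = np.random.default_rng(3)
    a = rng.standard_normal(100)
    b = a + 1.0
    groups = pd.Series(["a"] * 100 + ["b"] * 100,
                       index=[f"s{i}" for i in range(200)])
    gc = group_compare(make_scores(np.r_[a, b]), groups, ("a", "b"),
                       n_boot=2000, seed=7)
    assert 0.8 <= gc.beta <= 1.2
    assert gc.ci_low > 0
    assert gc.ci_low <= gc.beta <= gc.ci_high


def test_group_compare_bootstrap_deterministic_and_antisymmetric():
    rng = np.random.default_rng(4)
    vals = rng.standard_normal(80)
    groups = pd.Series(["a"] * 40 + ["b"] * 40,
                       index=[f"s{i}" for i in range(80)])
    g1 = group_compare(make_scores(vals), groups, ("a", "b"), n_boot=1500, seed=11)
    g2 = group_compare(make_scores(vals), groups, ("a", "b"), n_boot=1500, seed=11)
    assert (g1.ci_low, g1.ci_high) == (g2.ci_low, g2.ci_high)
    g3 = group_compare(make_scores(vals), groups, ("b", "a"), n_boot=0, seed=11)
    assert g3.beta == pytest.approx(-g1.beta, abs=1e-12)


def test_group_compare_ci_width_shrinks_with_n():
    rng = np.random.default_rng(5)
    widths = []
    for n in (50, 450):
        vals = rng.standard_normal(2 * n)
        groups = pd.Series(["a"] * n + ["b"] * n,
                           index=[f"s{i}" for i in range(2 * n)])
        gc = group_compare(make_scores(vals), groups, ("a", "b"),
                           n_boot=3000, seed=n)
        widths.append(gc.ci_high - gc.ci_low)
    # 9x the sample -> about 3x narrower
    assert widths[1] < widths[0] / 2


def test_group_compare_empty_group_errors():
    vals = np.arange(10, dtype=float)
    groups = pd.Series(["a"] * 10, index=[f"s{i}" for i in range(10)])
    with pytest.raises(ValueError, match="'b' empty"):
        group_compare(make_scores(vals), groups, ("a", "b"), n_boot=0, seed=1)


def test_group_compare_with_covariates():
    rng = np.random.default_rng(6)
    n = 150
    age = rng.normal(35, 10, 2 * n)
    score = 0.05 * age + rng.standard_normal(2 * n)
    score[n:] += 0.5
    ids = [f"s{i}" for i in range(2 * n)]
    groups = pd.Series(["a"] * n + ["b"] * n, index=ids)
    cov = pd.DataFrame({"age": age}, index=ids)
    gc = group_compare(make_scores(score, ids), groups, ("a", "b"),
                       covariates=cov, n_boot=1000, seed=2)
    assert gc.p < 0.01
    assert gc.ci_low <= gc.beta <= gc.ci_high


# --------------------------------------------------------- cross disorder

def test_cross_disorder_matrix_shape_and_bonferroni():
    rng = np.random.default_rng(7)
    n = 20
    ids = [f"s{i}" for i in range(4 * n)]
    groups = pd.Series(["control"] * n + ["g1"] * n + ["g2"] * n + ["g3"] * n,
                       index=ids)
    frames = []
    for label in ("w1", "w2"):
        frames.append(pd.DataFrame({"subject_id": ids, "weight_set": label,
                                    "score": rng.standard_normal(4 * n)}))
    table = ScoreTable(pd.concat(frames, ignore_index=True))
    mat = cross_disorder_matrix(table, groups, reference="control",
                                n_boot=200, seed=1)
    assert len(mat) == 6  # 2 weight sets x 3 non-reference groups
    assert (mat["p_adj"] >= mat["p"] - 1e-15).all()
    assert (mat["p_adj"] <= 1).all()
    mat2 = cross_disorder_matrix(table, groups, reference="control",
                                 n_boot=200, seed=1)
    pd.testing.assert_frame_equal(mat, mat2)


def test_cross_disorder_null_calibrated_under_label_permutation():
    # permuting group labels on a real scored cohort kills every adjusted
    # association in >= 90% of replicates
    from morphoscore import Deconfounder, SimConfig, make_weight_profile, simulate_cohort
    from morphoscore.score import score_multi

    scz = make_weight_profile("scz_like")
    adhd = make_weight_profile("adhd_like")
    cfg = SimConfig(n_per_group={"control": 60, "scz": 60, "adhd": 60},
                    profiles={"scz": (scz, 0.5), "adhd": (adhd, 0.5)}, seed=77)
    cohort, _ = simulate_cohort(cfg)
    dev = Deconfounder().fit(cohort).transform(cohort)
    table = score_multi(dev, [scz, adhd])
    rng = np.random.default_rng(8)
    clean = 0
    reps = 100
    for rep in range(reps):
        permuted = pd.Series(rng.permutation(cohort.groups.to_numpy()),
                             index=cohort.groups.index)
        mat = cross_disorder_matrix(table, permuted, reference="control",
                                    n_boot=0, seed=rep)
        clean += (mat["p_adj"] >= 0.05).all()
    assert clean / reps >= 0.90


# ---------------------------------------------------------------- sign test

def test_sign_test_closed_forms():
    assert sign_test(["+"] * 8) == pytest.approx(0.00390625, abs=1e-15)
    assert sign_test(["+"] * 5 + ["-"] * 5) == pytest.approx(0.623046875, abs=1e-15)


def test_sign_test_matches_brute_force_enumeration():
    for n in range(1, 13):
        for k in range(n + 1):
            directions = ["+"] * k + ["-"] * (n - k)
            expected = sum(
                1 for outcome in itertools.product([1, -1], repeat=n)
                if sum(v == 1 for v in outcome) >= k
            ) / 2**n
            assert sign_test(directions) == pytest.approx(expected, abs=1e-12)


def test_sign_test_zeros_dropped_and_empty_errors():
    with pytest.warns(UserWarning, match="zero"):
        p = sign_test(["+", "+", 0])
    assert p == pytest.approx(0.25)
    with pytest.raises(ValueError, match="no nonzero"):
        with pytest.warns(UserWarning, match="zero"):
            sign_test([0, 0])


# --------------------------------------------------------------- bonferroni

def test_bonferroni_monotone_and_bounded():
    p = np.array([1e-4, 0.01, 0.04, 0.5])
    adj = bonferroni(p, 75)
    assert (np.diff(adj) >= 0).all()
    assert (adj >= p).all() and (adj <= 1).all()


# ------------------------------------------------------ phenotype regression

def test_phenotype_perfect_negative_association():
    rng = np.random.default_rng(9)
    score = rng.standard_normal(50)
    ids = [f"s{i}" for i in range(50)]
    phen = pd.Series(-score, index=ids)
    beta, p, p_adj = associate_phenotype(make_scores(score, ids), phen)
    assert beta == pytest.approx(-1.0, abs=1e-10)
    assert p < 1e-20


def test_phenotype_slope_recovery_and_null():
    rng = np.random.default_rng(10)
    n = 500
    ids = [f"s{i}" for i in range(n)]
    score = rng.standard_normal(n)
    phen = pd.Series(0.5 * score + rng.normal(0, 1, n), index=ids)
    beta, p, p_adj = associate_phenotype(make_scores(score, ids), phen, k_tests=3)
    # standardized slope = 0.5 / sd(phen) = 0.5/sqrt(1.25) ~ 0.447
    assert beta == pytest.approx(0.5 / np.sqrt(1.25), abs=0.1)
    assert p_adj == pytest.approx(min(1, 3 * p), abs=1e-15)
    null_phen = pd.Series(rng.standard_normal(n), index=ids)
    b0, p0, _ = associate_phenotype(make_scores(score, ids), null_phen)
    assert abs(b0) < 3 / np.sqrt(n)


def test_phenotype_degenerate_inputs():
    score = np.arange(20, dtype=float)
    ids = [f"s{i}" for i in range(20)]
    with pytest.raises(ValueError, match="constant phenotype"):
        associate_phenotype(make_scores(score, ids), pd.Series(1.0, index=ids))
    with pytest.raises(ValueError, match=">= 10 complete"):
        associate_phenotype(make_scores(score[:5], ids[:5]),
                            pd.Series(score[:5], index=ids[:5]))
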