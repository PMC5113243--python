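import numpy as np
import pandas as pd
import pytest

from aaastress.stats import (
    FULL_MODEL_TERMS,
    backward_eliminate,
    compare_null_full,
    fit_lme,
    group_compare,
    high_low_stress_split,
    roc_analysis,
)


def toy_table(rng, n_pat=6, n_slice=6, beta=1.0, sd_pat=0.4, sd_resid=0.2):
    rows = []
    for p in range(n_pat):
        bp = rng.normal(0, sd_pat)
        for s in range(n_slice):
            for o in range(1, 9):
                x = rng.uniform(0, 1)
                rows.append(
                    {
                        "patient_id": p,
                        "slice_index": s,
                        "octant_index": o,
                        "norm_stress": x,
                        "ilt_ratio": rng.uniform(0, 1),
                        "calcium_ratio": rng.uniform(0, 0.2),
                        "outer_diameter": 3.5 + 0.2 * p,
                        "lumen_diameter": rng.uniform(1.5, 2.5),
                        "suv_max": 1.0 + beta * x + bp + rng.normal(0, sd_resid),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LME
# ---------------------------------------------------------------------------


def test_lme_balanced_anova_moment_oracle():
    """On balanced one-way data the REML patient variance equals the
    classical ANOVA moment estimator (MS_between - MS_within) / n."""
    rng = np.random.default_rng(7)
    n_pat, n_obs = 12, 40
    b = rng.normal(0, 0.5, n_pat)
    rows = []
    for p in range(n_pat):
        for i in range(n_obs):
            rows.append(
                {
                    "patient_id": p,
                    "slice_index": i % 5,
                    "octant_index": (i % 8) + 1,
                    "norm_stress": 0.5,
                    "suv_max": 2.0 + b[p] + rng.normal(0, 0.3),
                }
            )
    df = pd.DataFrame(rows)
    fit = fit_lme(df, fixed_terms=(), reml=True)
    y = df["suv_max"].to_numpy()
    groups = y.reshape(n_pat, n_obs)
    ms_within = groups.var(axis=1, ddof=1).mean()
    ms_between = n_obs * groups.mean(axis=1).var(ddof=1)
    moment = (ms_between - ms_within) / n_obs
    assert fit.psi["patient"] == pytest.approx(moment, rel=0.05)
    assert fit.residual_variance == pytest.approx(ms_within, rel=0.05)


def test_lme_matches_statsmodels_single_grouping():
    """Cross-check slope and patient variance against statsmodels MixedLM
    on a patient-intercept-only structure."""
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(11)
    df = toy_table(rng)
    fit = fit_lme(df, ("norm_stress",), reml=True)
    sm_fit = smf.mixedlm("suv_max ~ norm_stress", df, groups=df["patient_id"]).fit(reml=True)
    assert fit.coef("norm_stress") == pytest.approx(sm_fit.params["norm_stress"], abs=0.02)
    # our model also carries (near-zero) slice/octant components, so variances
    # agree only approximately
    assert fit.psi["patient"] == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=0.15)


def test_lme_recovers_fixed_effect():
    rng = np.random.default_rng(3)
    df = toy_table(rng, beta=0.8)
    fit = fit_lme(df, ("norm_stress",), reml=True)
    assert fit.coef("norm_stress") == pytest.approx(0.8, abs=0.1)
    assert fit.converged


def test_lme_interaction_term_design():
    rng = np.random.default_rng(4)
    df = toy_table(rng)
    fit = fit_lme(df, ("norm_stress", "ilt_ratio", "norm_stress:ilt_ratio"), reml=True)
    assert "norm_stress:ilt_ratio" in fit.fixed_effects.index


def test_lme_rank_deficiency_raises():
    rng = np.random.default_rng(5)
    df = toy_table(rng)
    df["calcium_ratio"] = 0.0
    with pytest.raises(ValueError, match="rank-deficient"):
        fit_lme(df, ("norm_stress", "calcium_ratio"))


def test_lme_requires_grouping_levels():
    rng = np.random.default_rng(6)
    df = toy_table(rng)
    with pytest.raises(ValueError, match="levels"):
        fit_lme(df[df.patient_id == 0].assign(patient_id=0), ("norm_stress",))


def test_reml_vs_ml_loglik_ordering():
    rng = np.random.default_rng(8)
    df = toy_table(rng)
    ml = fit_lme(df, ("norm_stress",), reml=False)
    assert np.isfinite(ml.aic)
    assert ml.n_params == 2 + 4  # intercept + slope + 3 variances + residual


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


def test_compare_null_full_zero_when_no_stress_terms():
    rng = np.random.default_rng(9)
    df = toy_table(rng)
    out = compare_null_full(df, full_terms=("ilt_ratio",), stress_terms=())
    assert out["delta_aic"] == pytest.approx(0.0, abs=1e-6)


def test_compare_null_full_favours_real_effect():
    rng = np.random.default_rng(10)
    df = toy_table(rng, beta=1.0)
    out = compare_null_full(
        df, full_terms=("norm_stress", "ilt_ratio"), stress_terms=("norm_stress",)
    )
    assert out["delta_aic"] > 10.0


def test_backward_elimination_drops_noise_keeps_signal():
    rng = np.random.default_rng(12)
    df = toy_table(rng, beta=1.0)  # only norm_stress truly matters
    final, trace = backward_eliminate(df, FULL_MODEL_TERMS)
    assert "norm_stress" in final.fixed_effects.index
    assert len(trace) >= 1
    # AIC never increases along the accepted elimination path
    aics = trace["aic"].to_numpy()
    assert all(x >= y - 1e-9 for x, y in zip(aics, aics[1:]))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def test_roc_auc_equals_all_pairs_concordance():
    rng = np.random.default_rng(13)
    for _ in range(100):
        n = 50
        df = pd.DataFrame(
            {
                "norm_stress": rng.random(n),
                "suv_max": rng.random(n) * 4.0,
                "ilt_ratio": rng.random(n),
            }
        )
        label = df["suv_max"].to_numpy() > 2.0
        if label.all() or not label.any():
            continue
        auc = roc_analysis(df, "norm_stress", ilt_strata=(None,))["all"].auc
        pos = df["norm_stress"].to_numpy()[label]
        neg = df["norm_stress"].to_numpy()[~label]
        gt = (pos[:, None] > neg[None, :]).mean()
        ties = (pos[:, None] == neg[None, :]).mean()
        assert auc == pytest.approx(gt + 0.5 * ties, abs=1e-10)


def test_roc_perfect_separation():
    df = pd.DataFrame(
        {
            "norm_stress": np.r_[np.zeros(20), np.ones(20)],
            "suv_max": np.r_[np.ones(20), np.full(20, 3.0)],
            "ilt_ratio": np.zeros(40),
        }
    )
    r = roc_analysis(df, "norm_stress", ilt_strata=(None,))["all"]
    assert r.auc == 1.0
    assert 0.0 < r.youden_threshold <= 1.0


def test_roc_strata_sizes(cohort_table):
    out = roc_analysis(cohort_table, "norm_stress")
    assert out["all"].n == len(cohort_table)
    assert out["ilt>0.33"].n == int((cohort_table["ilt_ratio"] > 0.33).sum())
    assert out["ilt>0.67"].n <= out["ilt>0.33"].n


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def test_group_compare_identical_groups():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    gc = group_compare(a, a, method="mannwhitney")
    assert gc.p == pytest.approx(1.0, abs=0.05)
    assert gc.median_a == gc.median_b


def test_group_compare_exact_u_enumeration():
    """U statistic for tiny samples equals the brute-force count."""
    a = np.array([3.0, 5.0, 9.0])
    b = np.array([1.0, 2.0, 7.0])
    gc = group_compare(a, b, method="mannwhitney")
    u_brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    assert gc.statistic == pytest.approx(u_brute)


def test_group_compare_separated_groups_significant():
    rng = np.random.default_rng(14)
    a = rng.normal(3.0, 0.2, 40)
    b = rng.normal(1.0, 0.2, 40)
    gc = group_compare(a, b)
    assert gc.p < 1e-6
    assert gc.median_a > gc.median_b


def test_group_compare_requires_min_n():
    with pytest.raises(ValueError):
        group_compare([1.0, 2.0], [1.0, 2.0, 3.0])


def test_high_low_stress_split(cohort_table):
    gc = high_low_stress_split(cohort_table, stress_threshold=0.45, ilt_cutoff=0.67)
    assert gc.n_a + gc.n_b == int((cohort_table["ilt_ratio"] > 0.67).sum())


def test_high_low_stress_split_degenerate():
    df = pd.DataFrame(
        {
            "ilt_ratio": np.full(10, 0.9),
            "norm_stress": np.full(10, 0.1),
            "suv_max": np.linspace(1, 2, 10),
        }
    )
    gc = high_low_stress_split(df)
    assert gc.flag == "degenerate-group"
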