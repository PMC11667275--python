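import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import expit, logit

from recoverlab import (REFERENCE_MODELS, ModelSpec, auc, bh_adjust,
                        build_design, classification_metrics, cox_calibration,
                        fit_logistic, lrt_nested_mi, nagelkerke_r2,
                        odds_ratio_2x2)


# ModelSpec / design ----------------------------------------------------------

def test_center_ed_design_columns(complete_merged):
    X = build_design(REFERENCE_MODELS["CENTER-ED"], complete_merged)
    expected = {"age", "sex_male", "prior_mental_health", "pre_injury_asa",
                "iss", "gcs", "concussion_symptom_score"}
    assert expected <= set(X.columns)
    mech = [c for c in X.columns if c.startswith("injury_mechanism_")]
    assert len(mech) == complete_merged["injury_mechanism"].nunique() - 1
    assert "injury_mechanism_road_traffic" not in X.columns  # reference level


def test_upfront_ed_interaction_uses_numeric_scores(complete_merged):
    X = build_design(REFERENCE_MODELS["UPFRONT-ED"], complete_merged)
    assert "age:education_level" in X.columns
    prod = complete_merged["age"] * complete_merged["education_level"]
    assert np.allclose(X["age:education_level"], prod)


def test_dti_addon_adds_exactly_one_column(complete_merged):
    data = complete_merged.assign(dti_lp=np.random.default_rng(0)
                                  .standard_normal(len(complete_merged)))
    base = REFERENCE_MODELS["CENTER-ED"]
    X0 = build_design(base, data)
    X1 = build_design(base.with_addons("dti"), data)
    assert set(X1.columns) - set(X0.columns) == {"dti_lp"}


def test_biomarker_addons_enter_log_scale(complete_merged):
    X = build_design(REFERENCE_MODELS["HeadSMART"].with_addons("s100b"),
                     complete_merged)
    assert np.allclose(X["log_s100b"], np.log(complete_merged["s100b"]))


def test_degenerate_column_pruned_with_warning(complete_merged):
    allmale = complete_merged.assign(sex="male")
    with pytest.warns(UserWarning, match="sex_male"):
        X = build_design(REFERENCE_MODELS["CENTER-ED"], allmale)
    assert "sex_male" not in X.columns


def test_missing_variable_named_in_error(complete_merged):
    with pytest.raises(ValueError, match="ptsd_score"):
        build_design(REFERENCE_MODELS["CENTER-PLUS"],
                     complete_merged.drop(columns=["ptsd_score"]))


def test_addons_must_be_disjoint_from_base():
    with pytest.raises(ValueError):
        ModelSpec("x", ("age",), addons=("age",))


# fit_logistic ----------------------------------------------------------------

def test_intercept_only_fit_equals_logit_of_prevalence():
    y = np.r_[np.ones(38), np.zeros(62)]
    fit = fit_logistic(np.empty((100, 0)), y)
    assert fit.params[0] == pytest.approx(np.log(0.38 / 0.62), abs=1e-8)
    assert fit.converged and not fit.separation


def test_single_binary_predictor_recovers_log_odds_ratio():
    # 2x2 table: exposed 30/70 events, unexposed 20/80
    x = np.r_[np.ones(100), np.zeros(100)]
    y = np.r_[np.ones(30), np.zeros(70), np.ones(20), np.zeros(80)]
    fit = fit_logistic(x[:, None], y)
    or_hand = (30 / 70) / (20 / 80)
    assert fit.params[1] == pytest.approx(np.log(or_hand), abs=1e-8)


def test_duplicating_rows_scales_information():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((80, 2))
    y = (rng.random(80) < expit(X[:, 0])).astype(float)
    f1 = fit_logistic(X, y)
    f4 = fit_logistic(np.tile(X, (4, 1)), np.tile(y, 4))
    assert np.allclose(f1.params, f4.params, atol=1e-7)
    assert np.allclose(f4.se, f1.se / 2.0, atol=1e-6)


def test_separation_flagged_not_raised():
    x = np.r_[np.zeros(10), np.ones(10)]
    y = x.copy()
    with pytest.warns(UserWarning, match="separation"):
        fit = fit_logistic(x[:, None], y)
    assert fit.separation


def test_rank_deficient_design_rejected():
    X = np.ones((20, 2))
    X[:, 1] = 2.0
    y = np.r_[np.ones(10), np.zeros(10)]
    with pytest.raises(ValueError, match="rank deficient"):
        fit_logistic(X, y)


# AUC -------------------------------------------------------------------------

def test_auc_small_enumeration():
    """y=[0,1,0,1], p=[.1,.9,.8,.7]: of the 4 pos-neg pairs, 3 concordant."""
    assert auc([0, 1, 0, 1], [0.1, 0.9, 0.8, 0.7]) == pytest.approx(0.75)
    assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5
    with pytest.raises(ValueError):
        auc([1, 1], [0.2, 0.4])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(2, 40), st.integers(0, 10_000))
def test_auc_invariant_to_monotone_transforms(n, seed):
    rng = np.random.default_rng(seed)
    y = np.zeros(n)
    y[: max(1, n // 3)] = 1
    rng.shuffle(y)
    if y.sum() in (0, len(y)):
        return
    s = rng.standard_normal(n)
    a = auc(y, s)
    assert auc(y, np.exp(s)) == pytest.approx(a, abs=1e-12)
    assert auc(y, 3 * s - 7) == pytest.approx(a, abs=1e-12)
    # oracle: explicit pairwise concordance count with half-credit ties
    pos, neg = s[y == 1], s[y == 0]
    conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    assert a == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)


# Nagelkerke R2 ---------------------------------------------------------------

def test_nagelkerke_zero_when_no_improvement():
    assert nagelkerke_r2(-10.0, -10.0, 50) == 0.0


def test_nagelkerke_saturated_balanced_four_rows():
    """Null LL = 4*log(1/2); a saturated fit has LL=0, so Cox-Snell equals
    its own maximum and the rescaled measure is 100%."""
    ll0 = 4 * np.log(0.5)
    assert nagelkerke_r2(0.0, ll0, 4) == pytest.approx(100.0)


def test_nagelkerke_bounds_and_misuse():
    y = np.r_[np.ones(30), np.zeros(70)]
    rng = np.random.default_rng(1)
    X = rng.standard_normal((100, 3))
    fit = fit_logistic(X, y)
    null = fit_logistic(np.empty((100, 0)), y)
    r2 = nagelkerke_r2(fit.loglik, null.loglik, 100)
    assert 0.0 <= r2 <= 100.0
    with pytest.raises(ValueError):
        nagelkerke_r2(null.loglik - 1.0, null.loglik, 100)


# Calibration -----------------------------------------------------------------

def test_cox_calibration_well_calibrated_limit():
    rng = np.random.default_rng(2)
    n = 10_000
    lp = rng.normal(-0.3, 1.0, n)
    p = expit(lp)
    y = (rng.random(n) < p).astype(float)
    cal = cox_calibration(y, p)
    assert cal["slope"] == pytest.approx(1.0, abs=0.05)
    assert cal["intercept"] == pytest.approx(0.0, abs=0.05)


def test_cox_calibration_overconfident_probabilities():
    rng = np.random.default_rng(3)
    n = 10_000
    lp = rng.normal(0.0, 1.0, n)
    y = (rng.random(n) < expit(lp)).astype(float)
    overconfident = expit(2 * lp)
    cal = cox_calibration(y, overconfident)
    assert cal["slope"] == pytest.approx(0.5, abs=0.05)


def test_cox_calibration_degenerate_and_invalid():
    y = np.r_[np.ones(5), np.zeros(5)]
    cal = cox_calibration(y, np.full(10, 0.5))
    assert cal["degenerate"] and cal["slope"] == 0.0
    with pytest.raises(ValueError):
        cox_calibration(y, np.r_[np.zeros(5), np.full(5, 0.5)])


# Classification metrics ------------------------------------------------------

def test_classification_metrics_closed_forms():
    y = np.r_[np.ones(4), np.zeros(4)]
    perfect = np.r_[np.full(4, 0.9), np.full(4, 0.1)]
    m = classification_metrics(y, perfect, 0.5)
    assert (m["sensitivity"], m["specificity"], m["ppv"], m["npv"]) == \
        (1.0, 1.0, 1.0, 1.0)
    everyone = classification_metrics(y, perfect, 0.0)
    assert everyone["sensitivity"] == 1.0 and everyone["specificity"] == 0.0
    assert "npv" in everyone["undefined"]


def test_classification_metrics_reconstructed_2x2():
    """Hand 2x2 with TP=22, FN=2, TN=13, FP=26 (the GFAP triage table)."""
    y = np.r_[np.ones(24), np.zeros(39)]
    p = np.r_[np.full(22, 0.9), np.full(2, 0.1),
              np.full(26, 0.9), np.full(13, 0.1)]
    m = classification_metrics(y, p, 0.5)
    assert m["sensitivity"] == pytest.approx(0.9167, abs=1e-4)
    assert m["specificity"] == pytest.approx(0.3333, abs=1e-4)
    assert m["ppv"] == pytest.approx(0.4583, abs=1e-4)
    assert m["npv"] == pytest.approx(0.8667, abs=1e-4)


# Likelihood-ratio tests ------------------------------------------------------

def _lrt_data(n, beta_extra, seed, m=1, impute_noise=False):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(m):
        r = np.random.default_rng(seed + 7 * i) if impute_noise else rng
        x1 = r.standard_normal(n) if impute_noise else rng.standard_normal(n)
        x2 = r.standard_normal(n) if impute_noise else rng.standard_normal(n)
        y = (r.random(n) < expit(0.5 * x1 + beta_extra * x2)).astype(float)
        out.append(pd.DataFrame({"x1": x1, "x2": x2, "outcome": y}))
    return out


def test_lrt_single_dataset_matches_classical_chi_square():
    data = _lrt_data(400, 0.0, seed=4)
    full = ModelSpec("full", ("x1", "x2"))
    red = ModelSpec("red", ("x1",))
    res = lrt_nested_mi(full, red, data)
    # oracle: explicit chi-square from the two fitted log-likelihoods
    from recoverlab.models import _fit_pair
    ff, fr, *_ = _fit_pair(full, red, data[0])
    lr = 2 * (ff.loglik - fr.loglik)
    assert res["statistic"] == pytest.approx(lr, abs=1e-8)
    assert res["p"] == pytest.approx(stats.chi2.sf(lr, 1), abs=1e-10)


def test_lrt_identical_specs_p_one():
    data = _lrt_data(100, 0.0, seed=5)
    spec = ModelSpec("m", ("x1",))
    res = lrt_nested_mi(spec, spec, data)
    assert res["p"] == 1.0


def test_lrt_non_nested_rejected():
    data = _lrt_data(100, 0.0, seed=6)
    with pytest.raises(ValueError, match="not nested"):
        lrt_nested_mi(ModelSpec("a", ("x1",)), ModelSpec("b", ("x2",)), data)


def test_lrt_strong_effect_detected_across_imputations():
    data = _lrt_data(500, 1.2, seed=8, m=5, impute_noise=True)
    full = ModelSpec("full", ("x1", "x2"))
    red = ModelSpec("red", ("x1",))
    res = lrt_nested_mi(full, red, data)
    assert res["method"] == "meng-rubin-D3"
    assert res["p"] < 0.001


def test_lrt_null_effect_not_significant():
    data = _lrt_data(500, 0.0, seed=9, m=5, impute_noise=True)
    res = lrt_nested_mi(ModelSpec("f", ("x1", "x2")),
                        ModelSpec("r", ("x1",)), data)
    assert res["p"] > 0.01


# BH and odds ratios ----------------------------------------------------------

def test_bh_hand_step_up():
    adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, 0.04)
    assert bh_adjust([0.2])[0] == pytest.approx(0.2)
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    # classic staggered example
    adj2 = bh_adjust([0.001, 0.02, 0.04, 0.9])
    assert np.allclose(adj2, [0.004, 0.04, 0.05333333, 0.9])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def test_odds_ratio_closed_forms():
    assert odds_ratio_2x2((10, 10, 10, 10))["odds_ratio"] == pytest.approx(1.0)
    res = odds_ratio_2x2((20, 10, 5, 10))
    assert res["odds_ratio"] == pytest.approx(4.0)
    assert res["ci_low"] < 4.0 < res["ci_high"]
    assert not res["zero_cell_corrected"]
    zero = odds_ratio_2x2((5, 0, 3, 7))
    assert zero["zero_cell_corrected"]
    assert np.isfinite(zero["odds_ratio"])
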