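import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from recoverlab import (correlate_log_biomarker, dti_score, fit_dti_lasso,
                        linear_predictor, selection_frequencies,
                        whole_brain_summary)
from recoverlab._lasso import lasso_logistic_path
from recoverlab.atlas import JHU_ICBM_DTI_81
from recoverlab.dti_score import DtiScoreModel

COLS96 = JHU_ICBM_DTI_81.metric_columns()


def _signal_data(n, p, idx, betas, seed, prevalence=0.45):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    lp = X[:, idx] @ np.asarray(betas)
    c = np.log(prevalence / (1 - prevalence))
    y = (rng.random(n) < expit(c + lp)).astype(float)
    return X, y


def _model(features, coef, intercept=0.0):
    p = len(features)
    return DtiScoreModel(
        features=list(features), means=np.zeros(p), sds=np.ones(p),
        intercept=intercept, coef=np.asarray(coef, float), lam=0.1,
        lambda_grid=np.array([0.1]), cv_deviance=np.array([1.0]),
        folds=10, repeats=10, seed=0)


def test_fully_penalized_limit_is_intercept_at_prevalence_logodds():
    """At the top of the penalty path every slope is zero and the intercept
    equals the log-odds of the event rate."""
    X, y = _signal_data(300, 20, [0], [1.0], seed=1)
    Xz = (X - X.mean(0)) / X.std(0)
    lam_max = np.abs(Xz.T @ (y - y.mean())).max() / len(y)
    b0s, betas = lasso_logistic_path(Xz, y, np.array([10 * lam_max, lam_max]))
    assert np.all(betas == 0.0)
    assert b0s[0] == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-8)


def test_informative_predictors_selected_over_noise():
    """2 informative + 94 noise columns, n=400, strong effects: the signal
    columns are always selected, carry the largest coefficients, and noise
    admission at the CV penalty stays modest (median <= 10 columns)."""
    sig_hits, rank_hits, n_noise = 0, 0, []
    for seed in range(10):
        X, y = _signal_data(400, 96, [0, 1], [1.5, -1.5], seed=100 + seed)
        m = fit_dti_lasso(pd.DataFrame(X), y, folds=5, repeats=2,
                          seed=seed, n_lambda=40)
        sel = set(np.nonzero(m.coef)[0])
        sig_hits += {0, 1} <= sel
        top2 = set(np.argsort(np.abs(m.coef))[-2:])
        rank_hits += top2 == {0, 1}
        n_noise.append(len(sel - {0, 1}))
    assert sig_hits >= 9
    assert rank_hits >= 9
    assert np.median(n_noise) <= 10
    assert max(n_noise) <= 25   # lambda_min admits some noise, never floods


def test_duplicated_predictor_mass_is_stable():
    X, y = _signal_data(300, 10, [0], [1.5], seed=7)
    m1 = fit_dti_lasso(pd.DataFrame(X), y, folds=5, repeats=2, seed=3,
                       n_lambda=30)
    Xdup = np.column_stack([X, X[:, 0]])
    m2 = fit_dti_lasso(pd.DataFrame(Xdup), y, folds=5, repeats=2, seed=3,
                       n_lambda=30)
    mass1 = m1.coef[0]
    mass2 = m2.coef[0] + m2.coef[10]
    assert abs(mass2 - mass1) < 1e-3


def test_lambda_positive_and_grid_descending(complete_merged):
    m = fit_dti_lasso(complete_merged[COLS96].head(120),
                      complete_merged["outcome"].head(120).to_numpy(),
                      folds=4, repeats=1, seed=0, n_lambda=25)
    assert m.lam > 0
    assert np.all(np.diff(m.lambda_grid) < 0)


def test_nonzero_count_monotone_on_orthogonal_fixture():
    """On a well-conditioned fixture the active-set size is non-increasing
    in the penalty along the upper path."""
    X, y = _signal_data(500, 12, [0, 1, 2], [1.0, 0.8, -0.9], seed=5)
    Xz = (X - X.mean(0)) / X.std(0)
    lam_max = np.abs(Xz.T @ (y - y.mean())).max() / len(y)
    grid = np.geomspace(lam_max, lam_max * 0.05, 25)
    _, betas = lasso_logistic_path(Xz, y, grid)
    nsel = (betas != 0).sum(axis=1)
    assert np.all(np.diff(nsel) >= 0)   # grows as lambda shrinks


def test_single_class_and_nan_inputs_rejected():
    X = np.random.default_rng(0).standard_normal((30, 5))
    with pytest.raises(ValueError, match="single class"):
        fit_dti_lasso(pd.DataFrame(X), np.zeros(30), folds=3, repeats=1)
    y = np.r_[np.ones(15), np.zeros(15)]
    Xn = X.copy()
    Xn[0, 0] = np.nan
    with pytest.raises(ValueError, match="complete"):
        fit_dti_lasso(pd.DataFrame(Xn), y, folds=3, repeats=1)
    with pytest.raises(ValueError, match="folds"):
        fit_dti_lasso(pd.DataFrame(X[:4]), np.array([0, 1, 0, 1.0]),
                      folds=10, repeats=1)


def test_dti_score_closed_forms():
    m0 = _model(["a", "b"], [0.0, 0.0])
    assert dti_score(m0, np.array([[3.0, -2.0]])) == pytest.approx(1.0)
    m1 = _model(["a"], [1.0])
    assert dti_score(m1, np.array([[1.0]])) == pytest.approx(np.e)
    # probability round trip: odds/(1+odds) == expit(linear predictor)
    m = _model(["a", "b"], [0.4, -0.7], intercept=0.2)
    x = np.array([[1.3, 0.4]])
    odds = dti_score(m, x)
    lp = linear_predictor(m, x)[0]
    assert odds / (1 + odds) == pytest.approx(expit(lp), abs=1e-12)


def test_score_requires_complete_named_columns():
    m = _model(["fa_tapetum_l"], [1.0])
    with pytest.raises(ValueError, match="missing tract columns"):
        linear_predictor(m, pd.DataFrame({"fa_tapetum_r": [0.4]}))
    with pytest.raises(ValueError, match="complete"):
        linear_predictor(m, np.array([[np.nan]]))


def test_standardization_constants_come_from_fitting_sample():
    X, y = _signal_data(200, 6, [0], [1.2], seed=9)
    m = fit_dti_lasso(pd.DataFrame(X), y, folds=4, repeats=1, seed=1,
                      n_lambda=20)
    lp1 = linear_predictor(m, X)
    lp2 = m.intercept + ((X - m.means) / m.sds) @ m.coef
    assert np.allclose(lp1, lp2, atol=1e-12)


# selection frequencies -------------------------------------------------------

def test_selection_frequency_single_run():
    slug = "fa_superior_cerebellar_peduncle_l"
    coef = np.zeros(96)
    coef[COLS96.index(slug)] = 0.8
    run = _model(COLS96, coef)
    tab = selection_frequencies([run])
    top = tab.iloc[0]
    assert top["tract"] == "Superior cerebellar peduncle L"
    assert top["fa_freq"] == 1.0 and top["md_freq"] == 0.0
    assert top["mean_freq"] == 0.5
    assert tab["fa_freq"].sum() + tab["md_freq"].sum() == 1.0


def test_selection_frequency_aggregation_matches_published_layout():
    """Constructed runs with FA selected 94/100 and MD 91/100 times give
    frequencies 0.94 / 0.91 and mean (0.94+0.91)/2."""
    slug_fa = COLS96.index("fa_superior_cerebellar_peduncle_l")
    slug_md = COLS96.index("md_superior_cerebellar_peduncle_l")
    runs = []
    for i in range(100):
        coef = np.zeros(96)
        if i < 94:
            coef[slug_fa] = 0.5
        if i < 91:
            coef[slug_md] = -0.3
        runs.append(_model(COLS96, coef))
    tab = selection_frequencies(runs).set_index("tract")
    row = tab.loc["Superior cerebellar peduncle L"]
    assert row["fa_freq"] == pytest.approx(0.94)
    assert row["md_freq"] == pytest.approx(0.91)
    assert row["mean_freq"] == pytest.approx((0.94 + 0.91) / 2)
    assert tab.index[0] == "Superior cerebellar peduncle L"


def test_selection_frequencies_need_runs():
    with pytest.raises(ValueError):
        selection_frequencies([])


# whole-brain summaries -------------------------------------------------------

def test_whole_brain_mean_of_constant_tracts(small_cohort):
    _, tracts = small_cohort
    t = tracts.copy()
    t[JHU_ICBM_DTI_81.fa_columns()] = 0.47
    wb = whole_brain_summary(t)
    assert np.allclose(wb["wb_fa"], 0.47)


def test_nfl_correlation_sign_detected():
    rng = np.random.default_rng(12)
    n = 150
    fa = rng.normal(0.5, 0.03, n)
    nfl = np.exp(-4 * fa + rng.normal(0, 0.1, n) + 3)
    res = correlate_log_biomarker(fa, nfl)
    assert res["r"] < 0 and res["p"] < 0.01 and not res["degenerate"]
    # age-adjustment removes an age-driven association
    age = rng.uniform(20, 70, n)
    fa_age = 0.6 - 0.002 * age + rng.normal(0, 0.005, n)
    nfl_age = np.exp(0.03 * age + rng.normal(0, 0.1, n))
    raw = correlate_log_biomarker(fa_age, nfl_age)
    adj = correlate_log_biomarker(fa_age, nfl_age, age=age)
    assert raw["r"] < -0.5
    assert abs(adj["r"]) < abs(raw["r"])


def test_degenerate_and_invalid_biomarker_inputs():
    flagged = correlate_log_biomarker(np.ones(20), np.full(20, 3.0))
    assert flagged["degenerate"] and np.isnan(flagged["r"])
    with pytest.raises(ValueError, match="positive"):
        correlate_log_biomarker(np.ones(5), np.array([1.0, -2.0, 1, 1, 1]))
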