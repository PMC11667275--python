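"""Bootstrap optimism correction nested within multiple imputation.

Apparent performance of a prognostic model fitted and evaluated on the same
cohort overstates how the model would do on new patients. Harrell's
bootstrap estimates the inflation: refit the entire modelling pipeline on
each bootstrap resample, score it on the resample (boot-apparent) and on the
original data (test); optimism is the mean gap, and corrected = apparent -
optimism. Here the loop runs inside each multiply-imputed dataset (200
resamples x 10 imputations at study scale) and corrected metrics are pooled
with Rubin's rules.

When the model contains the DTI score, the honest default refits the
cross-validated lasso inside every resample, so the selection step itself is
charged for its optimism; a config flag reproduces the cheaper variant that
fixes the DTI score once (which leaks selection information and looks
better than it should).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dti_score import DtiScoreModel, fit_dti_lasso, linear_predictor
from .impute import PooledEstimate, pool
from .models import (FitResult, ModelSpec, auc, build_design,
                     classification_metrics, cox_calibration, fit_logistic,
                     nagelkerke_r2, _bernoulli_loglik)

__all__ = ["ValidationConfig", "PerformanceEstimate", "bootstrap_optimism",
           "validate", "fit_pipeline", "predict_prob"]

METRICS = ("auc", "r2", "cal_intercept", "cal_slope",
           "sensitivity", "specificity", "ppv", "npv")

# Pooling scales: AUC on logit, calibration slope on log, the rest identity.
_POOL_SCALE = {"auc": "logit", "cal_slope": "log"}


@dataclass
class ValidationConfig:
    """Knobs of the optimism-correction loop.

    ``n_boot``/``m`` default to the study-scale 200 x 10; tests and demos
    scale them down. The lasso refitted inside resamples uses a lighter CV
    (``lasso_folds`` x ``lasso_repeats`` over ``lasso_n_lambda`` penalties)
    than the one-off full fit, since it runs n_boot x m times.
    """

    n_boot: int = 200
    m: int = 10
    seed: int = 0
    refit_dti: bool = True
    stratified: bool = True
    threshold: float | str = "prevalence"
    metrics: tuple[str, ...] = METRICS
    lasso_folds: int = 4
    lasso_repeats: int = 1
    lasso_n_lambda: int = 20
    lasso_lambda_min_ratio: float = 1e-3
    lasso_cv_measure: str = "deviance"
    max_redraws: int = 50

    def __post_init__(self):
        if self.n_boot < 1 or self.m < 1:
            raise ValueError("n_boot and m must be >= 1")


@dataclass
class FittedPipeline:
    spec: ModelSpec
    fit: FitResult
    dti_model: DtiScoreModel | None
    threshold: float
    tract_features: list[str] | None


def _with_dti_lp(data: pd.DataFrame, dti_model: DtiScoreModel | None,
                 tract_features: list[str] | None) -> pd.DataFrame:
    if dti_model is None:
        return data
    out = data.copy()
    out["dti_lp"] = linear_predictor(dti_model, out[tract_features])
    return out


def fit_pipeline(spec: ModelSpec, data: pd.DataFrame,
                 config: ValidationConfig,
                 tract_features: list[str] | None = None,
                 seed: int = 0, refit_dti: bool | None = None,
                 groups: np.ndarray | None = None) -> FittedPipeline:
    """Fit the full modelling pipeline (optional lasso DTI score, then the
    clinical logistic model) on one complete dataset.

    ``groups`` (original-subject labels) keeps bootstrap duplicates of a
    subject inside one CV fold of the lasso penalty search.
    """
    refit = config.refit_dti if refit_dti is None else refit_dti
    dti_model = None
    if "dti" in spec.terms and refit:
        if tract_features is None:
            raise ValueError("tract_features required to refit the DTI score")
        dti_model = fit_dti_lasso(
            data[tract_features], data["outcome"].to_numpy(float),
            folds=config.lasso_folds, repeats=config.lasso_repeats,
            seed=seed, n_lambda=config.lasso_n_lambda,
            lambda_min_ratio=config.lasso_lambda_min_ratio, groups=groups,
            cv_measure=config.lasso_cv_measure)
    work = _with_dti_lp(data, dti_model, tract_features)
    y = work["outcome"].to_numpy(float)
    X = build_design(spec, work)
    fit = fit_logistic(X, y)
    thr = y.mean() if config.threshold == "prevalence" else float(config.threshold)
    return FittedPipeline(spec=spec, fit=fit, dti_model=dti_model,
                          threshold=thr, tract_features=tract_features)


def predict_prob(pipe: FittedPipeline, data: pd.DataFrame) -> np.ndarray:
    """Predicted probabilities on (possibly new) data, aligning design
    columns to the fitted coefficients; unseen category levels contribute 0."""
    work = _with_dti_lp(data, pipe.dti_model, pipe.tract_features)
    X = build_design(pipe.spec, work)
    coef_cols = pipe.fit.columns[1:]
    aligned = np.zeros((len(work), len(coef_cols)))
    for j, c in enumerate(coef_cols):
        if c in X.columns:
            aligned[:, j] = X[c].to_numpy(float)
    lp = pipe.fit.params[0] + aligned @ pipe.fit.params[1:]
    from scipy.special import expit
    return expit(lp)


def _evaluate(pipe: FittedPipeline, data: pd.DataFrame,
              metrics: tuple[str, ...]) -> dict[str, float]:
    y = data["outcome"].to_numpy(float)
    p = np.clip(predict_prob(pipe, data), 1e-12, 1 - 1e-12)
    lp = np.log(p / (1 - p))
    out: dict[str, float] = {}
    if "auc" in metrics:
        out["auc"] = auc(y, p)
    if "r2" in metrics:
        ll = _bernoulli_loglik(y, lp)
        ll0 = fit_logistic(np.empty((len(y), 0)), y).loglik
        out["r2"] = nagelkerke_r2(max(ll, ll0), ll0, len(y))
    if "cal_intercept" in metrics or "cal_slope" in metrics:
        cal = cox_calibration(y, p)
        out["cal_intercept"] = cal["intercept"]
        out["cal_slope"] = cal["slope"] if not cal["degenerate"] else np.nan
    cls_wanted = {"sensitivity", "specificity", "ppv", "npv"} & set(metrics)
    if cls_wanted:
        cm = classification_metrics(y, p, pipe.threshold)
        for k in cls_wanted:
            out[k] = cm[k]
    return {k: out[k] for k in metrics}


def _stratified_resample(rng: np.random.Generator, y: np.ndarray) -> np.ndarray:
    idx = np.arange(len(y))
    pos, neg = idx[y == 1], idx[y == 0]
    return np.concatenate([rng.choice(pos, len(pos), replace=True),
                           rng.choice(neg, len(neg), replace=True)])


def bootstrap_optimism(spec: ModelSpec, dataset: pd.DataFrame,
                       config: ValidationConfig,
                       tract_features: list[str] | None = None,
                       seed: int | None = None,
                       resampler=None) -> dict:
    """Harrell optimism loop on one complete dataset.

    Returns apparent, mean optimism and corrected values per metric, the
    per-resample test values (for intervals), and the count of resamples
    redrawn because they contained a single outcome class.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4242]))
    y = dataset["outcome"].to_numpy(float)

    work = dataset
    if "dti" in spec.terms and not config.refit_dti:
        # leaky variant: DTI score fixed once on the full dataset
        if "dti_lp" not in dataset.columns:
            if tract_features is None:
                raise ValueError("tract_features required for the fixed DTI score")
            dm = fit_dti_lasso(dataset[tract_features], y,
                               folds=config.lasso_folds,
                               repeats=config.lasso_repeats, seed=seed,
                               n_lambda=config.lasso_n_lambda,
                               lambda_min_ratio=config.lasso_lambda_min_ratio,
                               cv_measure=config.lasso_cv_measure)
            work = _with_dti_lp(dataset, dm, tract_features)

    apparent_pipe = fit_pipeline(spec, work, config, tract_features, seed=seed)
    apparent = _evaluate(apparent_pipe, work, config.metrics)

    draw = resampler
    if draw is None:
        draw = _stratified_resample if config.stratified else \
            (lambda r, yy: r.integers(0, len(yy), len(yy)))

    boot_app = {k: [] for k in config.metrics}
    boot_test = {k: [] for k in config.metrics}
    n_redraw = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # separation warnings are routine here
        for b in range(config.n_boot):
            for _ in range(config.max_redraws):
                idx = draw(rng, y)
                if len(np.unique(y[idx])) == 2:
                    break
                n_redraw += 1
            sample = work.iloc[idx].reset_index(drop=True)
            pipe_b = fit_pipeline(spec, sample, config, tract_features,
                                  seed=seed * 100003 + b + 1, groups=idx)
            ev_b = _evaluate(pipe_b, sample, config.metrics)
            ev_t = _evaluate(pipe_b, work, config.metrics)
            for k in config.metrics:
                boot_app[k].append(ev_b[k])
                boot_test[k].append(ev_t[k])

    result = {"apparent": apparent, "optimism": {}, "corrected": {},
              "test_draws": {k: np.asarray(v) for k, v in boot_test.items()},
              "n_redraws": n_redraw, "unstable": []}
    for k in config.metrics:
        ba = np.asarray(boot_app[k], float)
        bt = np.asarray(boot_test[k], float)
        nan_frac = np.mean(np.isnan(ba) | np.isnan(bt))
        if nan_frac > 0.5:
            result["unstable"].append(k)
        opt = np.nanmean(ba - bt) if nan_frac < 1.0 else np.nan
        result["optimism"][k] = float(opt)
        result["corrected"][k] = float(apparent[k] - opt)
    return result


@dataclass
class PerformanceEstimate:
    """Optimism-corrected performance pooled over imputations."""

    spec_name: str
    table: pd.DataFrame                       # rows = metrics
    pooled: dict[str, PooledEstimate] = field(default_factory=dict)
    n_redraws: int = 0
    unstable: list[str] = field(default_factory=list)


def validate(spec: ModelSpec, imputed, config: ValidationConfig,
             tract_features: list[str] | None = None) -> PerformanceEstimate:
    """Optimism-corrected metrics for one model over an imputed set.

    Per imputation, the bootstrap loop yields corrected metrics and the
    bootstrap spread of test performance; corrected values are pooled with
    Rubin's rules (AUC on the logit scale, calibration slope on the log
    scale) and 95% intervals come from the test-performance percentiles
    pooled over imputations.
    """
    datasets = list(imputed)
    per_imp = []
    for i, d in enumerate(datasets):
        per_imp.append(bootstrap_optimism(spec, d, config, tract_features,
                                          seed=config.seed * 1000 + i))
    rows = []
    pooled: dict[str, PooledEstimate] = {}
    unstable = sorted({k for r in per_imp for k in r["unstable"]})
    for k in config.metrics:
        qs = [r["corrected"][k] for r in per_imp]
        us = [np.nanvar(r["test_draws"][k], ddof=1) if len(r["test_draws"][k]) > 1
              else 0.0 for r in per_imp]
        scale = _POOL_SCALE.get(k)
        if scale == "logit":
            qs = [min(max(q, 1e-6), 1 - 1e-6) for q in qs]
        if scale == "log" and any(q <= 0 for q in qs):
            scale = None
        est = pool(list(zip(qs, us)), transformation=scale)
        pooled[k] = est
        draws = np.concatenate([r["test_draws"][k] for r in per_imp])
        draws = draws[~np.isnan(draws)]
        lo, hi = (np.percentile(draws, [2.5, 97.5]) if draws.size
                  else (np.nan, np.nan))
        rows.append({
            "metric": k,
            "apparent": float(np.nanmean([r["apparent"][k] for r in per_imp])),
            "optimism": float(np.nanmean([r["optimism"][k] for r in per_imp])),
            "corrected": est.q_bar,
            "ci_low": float(lo), "ci_high": float(hi),
        })
    table = pd.DataFrame(rows).set_index("metric")
    return PerformanceEstimate(
        spec_name=spec.name, table=table, pooled=pooled,
        n_redraws=sum(r["n_redraws"] for r in per_imp), unstable=unstable)
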