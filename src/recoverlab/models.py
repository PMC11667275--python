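"""Reference clinical prognostic models and their performance metrics.

Five published clinical models predicting incomplete recovery after mild
TBI (UPFRONT-ED, UPFRONT-PLUS, HeadSMART, CENTER-ED, CENTER-PLUS) are
encoded as predictor lists over the cohort schema, refitted by maximum
likelihood to the analysis cohort, optionally extended with log-scale serum
biomarkers or the DTI-score covariate, and scored with AUC, Nagelkerke R^2,
Cox calibration intercept/slope and threshold classification metrics.
Nested models (with vs without an add-on) are compared by likelihood-ratio
tests, pooled over multiply imputed datasets with the Meng-Rubin combining
rule; tables of p-values get Benjamini-Hochberg adjustment.

Variable codings are declared defaults: education is an ordered 1-3 score
(the UPFRONT age x education interaction uses the numeric score), injury
mechanism is a categorical with road-traffic reference, ASA is the 1-3
physical-status score. Neck pain, coping styles and pupils are omitted and
prior mental health substitutes for prior depression, mirroring what is
recordable in the cohort; a positive-head-CT term is constant in a
CT-negative cohort and is auto-pruned as degenerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelSpec", "FitResult", "REFERENCE_MODELS", "build_design",
    "fit_logistic", "auc", "nagelkerke_r2", "cox_calibration",
    "classification_metrics", "lrt_nested_mi", "bh_adjust", "odds_ratio_2x2",
]

_MECH_REFERENCE = "road_traffic"


@dataclass(frozen=True)
class ModelSpec:
    """A clinical model: base predictor terms plus optional add-on covariates.

    Terms are cohort column names; ``a:b`` denotes an interaction of the
    encoded columns; add-ons are biomarkers (entered log-scale) or ``dti``
    (the DTI-score linear predictor, expected as column ``dti_lp``).
    """

    name: str
    predictors: tuple[str, ...]
    addons: tuple[str, ...] = ()

    def __post_init__(self):
        overlap = set(self.predictors) & set(self.addons)
        if overlap:
            raise ValueError(f"add-ons overlap base predictors: {sorted(overlap)}")

    def with_addons(self, *addons: str) -> "ModelSpec":
        label = "+".join(a.upper() for a in addons)
        return replace(self, name=f"{self.name}+{label}",
                       addons=self.addons + tuple(addons))

    @property
    def terms(self) -> tuple[str, ...]:
        return self.predictors + self.addons

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.terms) <= set(other.terms)


REFERENCE_MODELS: dict[str, ModelSpec] = {
    "UPFRONT-ED": ModelSpec("UPFRONT-ED", (
        "age", "sex", "education_level", "prior_mental_health",
        "age:education_level", "alcohol_intoxication", "gcs", "pta_ge_1h",
    )),
    "UPFRONT-PLUS": ModelSpec("UPFRONT-PLUS", (
        "education_level", "prior_mental_health", "alcohol_intoxication",
        "gcs", "pta_ge_1h", "anxiety_score", "depression_score",
        "concussion_symptom_score",
    )),
    "HeadSMART": ModelSpec("HeadSMART", (
        "age", "prior_mental_health", "headache_moderate_severe",
        "difficulty_concentrating", "photophobia",
    )),
    "CENTER-ED": ModelSpec("CENTER-ED", (
        "age", "sex", "prior_mental_health", "pre_injury_asa", "iss", "gcs",
        "injury_mechanism", "concussion_symptom_score",
    )),
    "CENTER-PLUS": ModelSpec("CENTER-PLUS", (
        "age", "prior_mental_health", "iss", "gcs", "injury_mechanism",
        "concussion_symptom_score", "ptsd_score",
    )),
}

_BIOMARKERS = ("gfap", "s100b", "nfl")


def _encode_term(term: str, data: pd.DataFrame) -> dict[str, np.ndarray]:
    if ":" in term:
        a, b = term.split(":")
        ca, cb = _encode_term(a, data), _encode_term(b, data)
        if len(ca) != 1 or len(cb) != 1:
            raise ValueError(f"interaction components must be single-column: {term}")
        (na, va), (nb, vb) = next(iter(ca.items())), next(iter(cb.items()))
        return {f"{na}:{nb}": va * vb}
    if term in _BIOMARKERS:
        if term not in data.columns:
            raise ValueError(f"model variable missing from data: {term!r}")
        v = data[term].to_numpy(float)
        if np.any(v <= 0):
            raise ValueError(f"{term} must be positive to enter on the log scale")
        return {f"log_{term}": np.log(v)}
    if term == "dti":
        if "dti_lp" not in data.columns:
            raise ValueError("model variable missing from data: 'dti_lp' "
                             "(DTI-score linear predictor)")
        return {"dti_lp": data["dti_lp"].to_numpy(float)}
    if term not in data.columns:
        raise ValueError(f"model variable missing from data: {term!r}")
    s = data[term]
    if term == "sex":
        return {"sex_male": (s.astype(str) == "male").to_numpy(float)}
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        levels = sorted(s.astype(str).unique())
        ref = _MECH_REFERENCE if _MECH_REFERENCE in levels else levels[0]
        return {f"{term}_{lv}": (s.astype(str) == lv).to_numpy(float)
                for lv in levels if lv != ref}
    return {term: s.to_numpy(float)}


def build_design(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix for a model spec (no intercept column).

    Categorical terms expand to indicators against a documented reference
    level; degenerate (constant) columns are dropped with a warning.
    """
    cols: dict[str, np.ndarray] = {}
    for term in spec.terms:
        for name, v in _encode_term(term, data).items():
            if np.isnan(v).any():
                raise ValueError(f"design column {name!r} contains missing values")
            cols[name] = v
    X = pd.DataFrame(cols, index=data.index)
    # constant or numerically-constant columns carry no contrast
    constant = [c for c in X.columns
                if X[c].std() < 1e-7 * max(1.0, float(abs(X[c].mean())))]
    if constant:
        warnings.warn(f"dropping degenerate design columns: {constant}")
        X = X.drop(columns=constant)
    return X


@dataclass
class FitResult:
    """Maximum-likelihood logistic fit."""

    columns: list[str]
    params: np.ndarray               # intercept first
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    linear_predictor: np.ndarray
    probabilities: np.ndarray
    converged: bool
    separation: bool = False

    def loglik_at(self, params: np.ndarray, X: np.ndarray, y: np.ndarray,
                  offset: np.ndarray | None = None) -> float:
        lp = X @ params + (offset if offset is not None else 0.0)
        return _bernoulli_loglik(y, lp)


def _bernoulli_loglik(y: np.ndarray, lp: np.ndarray) -> float:
    # stable: log(1+exp(lp)) via logaddexp
    return float((y * lp - np.logaddexp(0.0, lp)).sum())


def fit_logistic(design: pd.DataFrame | np.ndarray, y: np.ndarray,
                 offset: np.ndarray | None = None,
                 add_intercept: bool = True,
                 max_iter: int = 100, tol: float = 1e-10) -> FitResult:
    """Newton-Raphson logistic regression with step halving.

    Converges to gradient max-norm below 1e-8 on regular problems; perfect
    or quasi-perfect separation is flagged (huge coefficients / vanishing
    curvature) and the fit returned with a warning rather than raised, since
    separation arises by chance inside bootstrap resamples.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(float)
    else:
        X = np.atleast_2d(np.asarray(design, float))
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + names
    n, q = X.shape
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("design is rank deficient after pruning")
    off = offset if offset is not None else np.zeros(n)

    beta = np.zeros(q)
    ll = _bernoulli_loglik(y, X @ beta + off)
    converged = False
    for _ in range(max_iter):
        lp = X @ beta + off
        p = expit(lp)
        g = X.T @ (y - p)
        if np.abs(g).max() < 1e-8:
            converged = True
            break
        W = np.maximum(p * (1 - p), 1e-12)
        H = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step halving on the log-likelihood
        t = 1.0
        for _ in range(30):
            ll_new = _bernoulli_loglik(y, X @ (beta + t * step) + off)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        ll = ll_new
    lp = X @ beta + off
    p = expit(lp)
    separation = bool(np.abs(beta).max() > 15.0 or not converged)
    if separation:
        warnings.warn("possible separation: fit flagged, use with care")
    W = np.maximum(p * (1 - p), 1e-12)
    H = X.T @ (X * W[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return FitResult(columns=names, params=beta, se=np.sqrt(np.diag(cov)),
                     cov=cov, loglik=ll, n=n, linear_predictor=lp,
                     probabilities=p, converged=converged, separation=separation)


# Metrics ---------------------------------------------------------------------

def auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney concordance (area under the ROC curve), ties counted 1/2."""
    y = np.asarray(y, float)
    s = np.asarray(scores, float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def nagelkerke_r2(loglik_model: float, loglik_null: float, n: int,
                  as_percent: bool = True) -> float:
    """Nagelkerke's rescaled Cox-Snell R^2 (reported in percent by default)."""
    if loglik_model < loglik_null - 1e-6:
        raise ValueError("model log-likelihood below null: specs not nested "
                         "or fit failed")
    cox_snell = 1.0 - np.exp((2.0 / n) * (loglik_null - loglik_model))
    max_cs = 1.0 - np.exp((2.0 / n) * loglik_null)
    r2 = cox_snell / max_cs if max_cs > 0 else 0.0
    return float(100.0 * r2 if as_percent else r2)


def cox_calibration(y: np.ndarray, p: np.ndarray) -> dict:
    """Cox logistic recalibration: slope of logit(p), and the intercept with
    logit(p) as a fixed offset. Ideal values (0, 1)."""
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    lp = logit(p)
    if np.std(lp) < 1e-10:
        return {"intercept": np.nan, "slope": 0.0, "degenerate": True}
    slope_fit = fit_logistic(lp[:, None], y)
    int_fit = fit_logistic(np.empty((len(y), 0)), y, offset=lp)
    return {"intercept": float(int_fit.params[0]),
            "slope": float(slope_fit.params[1]), "degenerate": False}


def classification_metrics(y: np.ndarray, p: np.ndarray,
                           threshold: float) -> dict:
    """Sensitivity/specificity/PPV/NPV at ``p >= threshold``; metrics with an
    empty margin come back as NaN with a flag instead of raising."""
    y = np.asarray(y, float)
    pos = np.asarray(p, float) >= threshold
    tp = int(np.sum(pos & (y == 1)))
    fp = int(np.sum(pos & (y == 0)))
    fn = int(np.sum(~pos & (y == 1)))
    tn = int(np.sum(~pos & (y == 0)))
    ratio = lambda a, b: a / b if b > 0 else np.nan
    out = {
        "sensitivity": ratio(tp, tp + fn), "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp), "npv": ratio(tn, tn + fn),
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }
    out["undefined"] = [k for k in ("sensitivity", "specificity", "ppv", "npv")
                        if np.isnan(out[k])]
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def odds_ratio_2x2(counts) -> dict:
    """Odds ratio ad/bc with a Woolf log-scale 95% CI; zero cells get the
    Haldane-Anscombe 0.5 correction (flagged)."""
    a, b, c, d = (float(x) for x in np.asarray(counts, float).ravel())
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return {"odds_ratio": float(or_),
            "ci_low": float(np.exp(np.log(or_) - z * se)),
            "ci_high": float(np.exp(np.log(or_) + z * se)),
            "zero_cell_corrected": corrected}


# Likelihood-ratio test pooled over imputations -------------------------------

def _fit_pair(full: ModelSpec, reduced: ModelSpec, data: pd.DataFrame,
              y_col: str = "outcome"):
    y = data[y_col].to_numpy(float)
    Xf = build_design(full, data)
    Xr = build_design(reduced, data)
    return (fit_logistic(Xf, y), fit_logistic(Xr, y),
            np.column_stack([np.ones(len(y)), Xf.to_numpy(float)]),
            np.column_stack([np.ones(len(y)), Xr.to_numpy(float)]), y)


def lrt_nested_mi(full: ModelSpec, reduced: ModelSpec, imputed,
                  y_col: str = "outcome") -> dict:
    """Likelihood-ratio test of nested logistic models across imputations.

    Single dataset: the classical chi-square test. Multiple datasets: the
    Meng-Rubin D3 statistic — mean LR across imputations shrunk by the
    between-imputation variability of the estimates, referred to an F
    distribution.
    """
    if not reduced.is_nested_in(full):
        raise ValueError(f"{reduced.name!r} is not nested in {full.name!r}")
    datasets = list(imputed)
    m = len(datasets)
    fits = [_fit_pair(full, reduced, d, y_col) for d in datasets]
    k = len(fits[0][0].params) - len(fits[0][1].params)
    if k == 0:
        return {"statistic": 0.0, "p": 1.0, "df": 0, "m": m, "method": "identical"}
    lrs = np.array([2.0 * (ff.loglik - fr.loglik) for ff, fr, *_ in fits])
    lrs = np.maximum(lrs, 0.0)
    if m == 1:
        stat = float(lrs[0])
        return {"statistic": stat, "p": float(stats.chi2.sf(stat, k)),
                "df": k, "m": 1, "method": "chi2"}
    # D3: re-evaluate the LR at the pooled coefficient estimates
    beta_full = np.mean([ff.params for ff, *_ in fits], axis=0)
    beta_red = np.mean([fr.params for _, fr, *_ in fits], axis=0)
    d_tilde = np.mean([
        2.0 * (_bernoulli_loglik(y, Xf @ beta_full)
               - _bernoulli_loglik(y, Xr @ beta_red))
        for _, _, Xf, Xr, y in fits
    ])
    d_bar = lrs.mean()
    r = max(((m + 1) / (k * (m - 1))) * (d_bar - d_tilde), 0.0)
    D = max(d_tilde, 0.0) / (k * (1.0 + r))
    t = k * (m - 1)
    if t > 4:
        v = 4 + (t - 4) * (1 + (1 - 2 / t) / max(r, 1e-12)) ** 2
    else:
        v = 0.5 * t * (1 + 1 / k) * (1 + 1 / max(r, 1e-12)) ** 2
    return {"statistic": float(D), "p": float(stats.f.sf(D, k, v)),
            "df": k, "df2": float(v), "m": m, "method": "meng-rubin-D3",
            "r": float(r)}
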