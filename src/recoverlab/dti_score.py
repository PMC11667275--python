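"""Lasso-based DTI score over 96 standardized tract metrics.

The DTI score condenses the 48-tract FA/MD profile (age-corrected, centred,
scaled) into a single predicted odds of incomplete recovery via L1-penalized
logistic regression. The penalty is chosen to minimize cross-validated
binomial deviance on a glmnet-style log-spaced grid (10-fold CV repeated 10
times by default), and the model is refitted on all rows at the chosen
penalty. Tracts are ranked by how often the lasso selects them across
bootstrap-within-imputation runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from ._lasso import lasso_logistic_path
from .atlas import JHU_ICBM_DTI_81, TractAtlas

__all__ = [
    "DtiScoreModel", "fit_dti_lasso", "dti_score", "linear_predictor",
    "selection_frequencies", "whole_brain_summary", "correlate_log_biomarker",
]

_EPS = 1e-10


@dataclass
class DtiScoreModel:
    """Fitted lasso DTI-score model with its standardization constants."""

    features: list[str]
    means: np.ndarray
    sds: np.ndarray
    intercept: float
    coef: np.ndarray
    lam: float
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray
    folds: int
    repeats: int
    seed: int

    @property
    def selected(self) -> list[str]:
        return [f for f, c in zip(self.features, self.coef) if c != 0.0]

    def zscore(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means[None, :]) / self.sds[None, :]


def _deviance(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial deviance contributions summed over rows; p may be (n, L)."""
    p = np.clip(p, _EPS, 1 - _EPS)
    if p.ndim == 1:
        return float(-2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p)).sum())
    return -2.0 * (y[:, None] * np.log(p)
                   + (1 - y[:, None]) * np.log(1 - p)).sum(axis=0)


def fit_dti_lasso(X: pd.DataFrame | np.ndarray, y: np.ndarray,
                  folds: int = 10, repeats: int = 10, seed: int = 0,
                  n_lambda: int = 100, lambda_min_ratio: float = 1e-4,
                  groups: np.ndarray | None = None,
                  cv_measure: str = "deviance") -> DtiScoreModel:
    """Cross-validated lasso logistic regression on tract metrics.

    ``X`` holds the (age-corrected) tract metrics; it is z-scored internally
    with means/SDs from this fitting sample, which are stored on the model.
    The penalty grid runs log-spaced from the smallest penalty that zeroes
    every slope down to ``lambda_min_ratio`` times it; the retained penalty
    minimizes mean held-out binomial deviance over ``repeats`` independent
    ``folds``-fold splits (``cv_measure="auc"`` instead maximizes mean
    held-out concordance; with many uninformative predictors this variant
    overfits far more readily, which makes it the harder stress test for
    optimism correction).

    ``groups`` keeps rows with the same label in the same CV fold. When the
    fit runs inside a bootstrap resample, passing the original subject index
    prevents copies of one subject from appearing on both sides of a CV
    split, which would leak information and bias the penalty downward.
    """
    features = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{i}" for i in range(np.asarray(X).shape[1])]
    Xa = np.asarray(X, float)
    y = np.asarray(y, float)
    if np.isnan(Xa).any() or np.isnan(y).any():
        raise ValueError("lasso input must be complete (run inside an imputed dataset)")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome has a single class; cannot fit")
    n = len(y)
    if n < folds:
        raise ValueError(f"n={n} smaller than number of folds={folds}")

    means = Xa.mean(axis=0)
    sds = Xa.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    Xz = (Xa - means) / sds

    if cv_measure not in ("deviance", "auc"):
        raise ValueError(f"unknown cv_measure: {cv_measure!r}")
    ybar = y.mean()
    lam_max = np.abs(Xz.T @ (y - ybar)).max() / n
    lam_max = max(lam_max, 1e-6)
    grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    dev = np.zeros((repeats, n_lambda))
    for r in range(repeats):
        rs = (seed * 1009 + r) % (2**31 - 1)
        if groups is not None:
            skf = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                       random_state=rs)
            split = skf.split(Xz, y, groups)
        else:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
            split = skf.split(Xz, y)
        for tr, te in split:
            if len(np.unique(y[tr])) < 2:   # pragma: no cover - stratified
                continue
            b0s, betas = lasso_logistic_path(Xz[tr], y[tr], grid)
            p = expit(b0s[None, :] + Xz[te] @ betas.T)     # (n_te, L)
            if cv_measure == "deviance":
                dev[r] += _deviance(y[te], p)
            else:
                yt = y[te]
                if len(np.unique(yt)) < 2:
                    continue
                ranks = stats.rankdata(p, axis=0)
                n1 = int(yt.sum())
                n0 = len(yt) - n1
                u = ranks[yt == 1].sum(axis=0) - n1 * (n1 + 1) / 2.0
                dev[r] -= u / (n1 * n0)    # negated AUC: smaller is better
    mean_dev = dev.mean(axis=0) / n
    j_best = int(np.argmin(mean_dev))
    lam = float(grid[j_best])

    b0s, betas = lasso_logistic_path(Xz, y, grid[:j_best + 1])
    return DtiScoreModel(
        features=features, means=means, sds=sds,
        intercept=float(b0s[-1]), coef=betas[-1].copy(),
        lam=lam, lambda_grid=grid, cv_deviance=mean_dev,
        folds=folds, repeats=repeats, seed=seed,
    )


def linear_predictor(model: DtiScoreModel, X: pd.DataFrame | np.ndarray,
                     ) -> np.ndarray:
    """Log-odds of incomplete recovery from tract metrics alone.

    This is the scale on which the DTI covariate enters downstream models.
    """
    if isinstance(X, pd.DataFrame):
        missing = [f for f in model.features if f not in X.columns]
        if missing:
            raise ValueError(f"missing tract columns: {missing}")
        X = X[model.features].to_numpy(float)
    X = np.atleast_2d(np.asarray(X, float))
    if np.isnan(X).any():
        raise ValueError("tract values must be complete to score")
    return model.intercept + model.zscore(X) @ model.coef


def dti_score(model: DtiScoreModel, x_row) -> np.ndarray | float:
    """Predicted odds of incomplete recovery (exp of the linear predictor)."""
    lp = linear_predictor(model, x_row)
    odds = np.exp(lp)
    return float(odds[0]) if odds.shape == (1,) else odds


def selection_frequencies(runs: list[DtiScoreModel],
                          atlas: TractAtlas = JHU_ICBM_DTI_81) -> pd.DataFrame:
    """Per-tract FA/MD selection frequencies across lasso runs.

    Frequency = fraction of runs in which the tract-metric has a nonzero
    coefficient; ``mean_freq`` averages the FA and MD frequencies. Sorted by
    mean frequency, descending.
    """
    if not runs:
        raise ValueError("need at least one fitted run")
    counts = pd.Series(0.0, index=pd.Index(runs[0].features))
    for m in runs:
        counts[np.asarray(m.features)[m.coef != 0]] += 1
    freq = counts / len(runs)
    rows = []
    for name, slug, side in zip(atlas.names, atlas.slugs, atlas.laterality):
        fa = float(freq.get(f"fa_{slug}", 0.0))
        md = float(freq.get(f"md_{slug}", 0.0))
        rows.append({"tract": name, "laterality": side,
                     "fa_freq": fa, "md_freq": md, "mean_freq": (fa + md) / 2})
    out = pd.DataFrame(rows).sort_values("mean_freq", ascending=False,
                                         kind="mergesort")
    return out.reset_index(drop=True)


def whole_brain_summary(tracts: pd.DataFrame,
                        atlas: TractAtlas = JHU_ICBM_DTI_81) -> pd.DataFrame:
    """Unweighted per-subject mean FA and MD over the 48 tracts."""
    return pd.DataFrame({
        "wb_fa": tracts[atlas.fa_columns()].mean(axis=1),
        "wb_md": tracts[atlas.md_columns()].mean(axis=1),
    }, index=tracts.index)


def correlate_log_biomarker(summary: np.ndarray | pd.Series,
                            concentration: np.ndarray | pd.Series,
                            age: np.ndarray | pd.Series | None = None,
                            ) -> dict:
    """Pearson correlation of a whole-brain DTI summary with log concentration.

    With ``age`` given, returns the partial correlation adjusting for age
    (both variables residualized on age). A constant input is flagged as
    degenerate rather than raising.
    """
    s = np.asarray(summary, float)
    c = np.asarray(concentration, float)
    if np.any(c <= 0):
        raise ValueError("biomarker concentrations must be positive")
    x, y = s, np.log(c)
    if age is not None:
        a = np.column_stack([np.ones(len(s)), np.asarray(age, float)])
        x = x - a @ np.linalg.lstsq(a, x, rcond=None)[0]
        y = y - a @ np.linalg.lstsq(a, y, rcond=None)[0]
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": np.nan, "p": np.nan, "degenerate": True,
                "age_adjusted": age is not None}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "degenerate": False,
            "age_adjusted": age is not None}
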