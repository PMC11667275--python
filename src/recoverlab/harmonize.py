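"""ComBat scanner harmonization for tract-level diffusion metrics.

Parametric empirical-Bayes location/scale batch adjustment: per-feature
standardization against a covariate model (age, age^2, sex, time since
injury, GCS, MR-abnormality flag by default), Gaussian/inverse-gamma priors
on per-batch location and scale estimated by method of moments, and
iterative conditional posterior means for the batch parameters. Covariates
named in the design are protected: their fitted contribution is removed
before batch estimation and restored afterwards.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import JHU_ICBM_DTI_81, TractAtlas

__all__ = ["CombatModel", "fit_combat", "apply_combat", "DEFAULT_COVARIATES"]

DEFAULT_COVARIATES = ["age", "age_sq", "sex", "days_since_injury", "gcs",
                      "mr_abnormality"]


def _covariate_matrix(tracts: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Numeric covariate matrix (no intercept; the batch block spans it)."""
    cols = []
    for c in covariates:
        if c == "age_sq":
            cols.append(tracts["age"].to_numpy(float) ** 2)
        elif c == "sex":
            cols.append((tracts["sex"].astype(str) == "male").to_numpy(float))
        elif c == "mr_abnormality":
            cols.append(tracts["mr_abnormality"].to_numpy(float))
        else:
            if c not in tracts.columns:
                raise ValueError(f"covariate column {c!r} not in tract table")
            v = tracts[c].to_numpy(float)
            if np.isnan(v).any():
                v = np.where(np.isnan(v), np.nanmean(v), v)
            cols.append(v)
    return np.column_stack(cols) if cols else np.empty((len(tracts), 0))


@dataclass
class CombatModel:
    """Fitted ComBat parameters for a set of tract-metric features."""

    features: list[str]
    batches: list[str]
    n_per_batch: np.ndarray          # (B,)
    covariates: list[str]
    grand_mean: np.ndarray           # alpha-hat, (F,)
    beta_cov: np.ndarray             # (q, F) covariate coefficients
    pooled_var: np.ndarray           # sigma-hat^2, (F,)
    gamma_star: np.ndarray           # (B, F) EB batch locations
    delta_sq_star: np.ndarray        # (B, F) EB batch scales
    skipped: list[str] = field(default_factory=list)   # degenerate features

    def to_json(self, path: str | Path) -> None:
        d = {
            "features": self.features,
            "batches": self.batches,
            "n_per_batch": self.n_per_batch.tolist(),
            "covariates": self.covariates,
            "grand_mean": self.grand_mean.tolist(),
            "beta_cov": self.beta_cov.tolist(),
            "pooled_var": self.pooled_var.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_sq_star": self.delta_sq_star.tolist(),
            "skipped": self.skipped,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "CombatModel":
        d = json.loads(Path(path).read_text())
        for k in ("n_per_batch", "grand_mean", "beta_cov", "pooled_var",
                  "gamma_star", "delta_sq_star"):
            d[k] = np.asarray(d[k], float)
        return cls(**d)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(z_batch: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            conv: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Iterated conditional posterior means for one batch (all features)."""
    n = z_batch.shape[0]
    g_new, d_new = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_old, d_old = g_new, d_new
        g_new = (t2 * n * g_hat + d_new * g_bar) / (t2 * n + d_new)
        sum2 = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(np.abs(g_new - g_old).max() / np.abs(g_old).max()
                     if np.abs(g_old).max() > 0 else 0.0,
                     np.abs(d_new - d_old).max() / np.abs(d_old).max())
    return g_new, d_new


def fit_combat(tracts: pd.DataFrame, covariates: list[str] | None = None,
               atlas: TractAtlas = JHU_ICBM_DTI_81,
               features: list[str] | None = None,
               eb: bool = True) -> CombatModel:
    """Fit the ComBat batch-adjustment model on a tract table.

    Parameters
    ----------
    tracts:
        Table with ``scanner_id`` batch labels, covariate columns and the
        96 ``fa_*`` / ``md_*`` features.
    covariates:
        Design columns whose variance is preserved (default
        :data:`DEFAULT_COVARIATES`; ``age_sq`` expands to age squared).
    eb:
        If False, use the raw per-batch location/scale estimates instead of
        their empirical-Bayes shrinkage (the large-sample limit).
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    features = features if features is not None else atlas.metric_columns()
    batch_labels = tracts["scanner_id"].astype(str)
    batches = sorted(batch_labels.unique())
    b_idx = batch_labels.map({b: i for i, b in enumerate(batches)}).to_numpy()
    n, B, F = len(tracts), len(batches), len(features)
    n_per = np.bincount(b_idx, minlength=B)
    singles = [batches[i] for i in range(B) if n_per[i] < 2]
    if singles:
        raise ValueError(f"batches with fewer than 2 subjects: {singles}")

    Y = tracts[features].to_numpy(float)
    # skip features with zero within-batch variance everywhere (scale posterior undefined)
    within_sd = np.zeros(F)
    for i in range(B):
        within_sd += Y[b_idx == i].std(axis=0)
    scale = 1.0 + np.abs(Y.mean(axis=0))
    skipped = [features[j] for j in np.nonzero(within_sd < 1e-10 * scale)[0]]
    if skipped:
        warnings.warn(f"constant features skipped by ComBat: {skipped}")
    keep = np.array([f not in skipped for f in features])

    X = _covariate_matrix(tracts, covariates)
    # constant covariates (e.g. GCS in a healthy-control table) carry no
    # contrast beyond the batch intercepts; drop them rather than erroring
    const = [j for j in range(X.shape[1]) if X[:, j].std() < 1e-12]
    if const:
        dropped = [covariates[j] for j in const]
        warnings.warn(f"dropping constant ComBat covariates: {dropped}")
        keep_cov = [j for j in range(X.shape[1]) if j not in const]
        X = X[:, keep_cov]
        covariates = [covariates[j] for j in keep_cov]
    Bmat = np.zeros((n, B))
    Bmat[np.arange(n), b_idx] = 1.0
    D = np.hstack([Bmat, X])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        # identify offending covariate columns by incremental rank
        bad = []
        r = np.linalg.matrix_rank(Bmat)
        M = Bmat
        for k, c in enumerate(covariates):
            M2 = np.hstack([M, X[:, [k]]])
            r2 = np.linalg.matrix_rank(M2)
            if r2 == r:
                bad.append(c)
            else:
                M, r = M2, r2
        raise ValueError(f"covariate design rank-deficient; collinear columns: {bad}")

    beta_full, *_ = np.linalg.lstsq(D, Y, rcond=None)
    gamma_hat_ols = beta_full[:B]                      # (B, F) batch means
    beta_cov = beta_full[B:]                           # (q, F)
    grand_mean = (n_per / n) @ gamma_hat_ols           # (F,)
    resid = Y - D @ beta_full
    pooled_var = (resid ** 2).mean(axis=0)             # (F,), /n as in ComBat

    stand_mean = grand_mean[None, :] + X @ beta_cov
    sd = np.sqrt(pooled_var)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (Y - stand_mean) / sd_safe[None, :]

    gamma_star = np.zeros((B, F))
    delta_sq_star = np.ones((B, F))
    kj = np.nonzero(keep)[0]
    if B == 1:
        # no batch contrast to estimate: adjustment is the identity
        return CombatModel(
            features=list(features), batches=batches, n_per_batch=n_per,
            covariates=list(covariates), grand_mean=grand_mean,
            beta_cov=beta_cov, pooled_var=pooled_var, gamma_star=gamma_star,
            delta_sq_star=delta_sq_star, skipped=skipped,
        )
    for i in range(B):
        zb = Z[b_idx == i][:, kj]
        g_hat = zb.mean(axis=0)
        d_hat = zb.var(axis=0, ddof=1)
        if eb and len(kj) >= 2 and d_hat.var(ddof=1) > 0:
            g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
            a, b = _aprior(d_hat), _bprior(d_hat)
            g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a, b)
        else:
            g_star, d_star = g_hat, d_hat
        gamma_star[i, kj] = g_star
        delta_sq_star[i, kj] = d_star
    if np.any(delta_sq_star[:, kj] <= 0):
        raise RuntimeError("non-positive posterior batch scale")

    return CombatModel(
        features=list(features), batches=batches, n_per_batch=n_per,
        covariates=list(covariates), grand_mean=grand_mean, beta_cov=beta_cov,
        pooled_var=pooled_var, gamma_star=gamma_star,
        delta_sq_star=delta_sq_star, skipped=skipped,
    )


def apply_combat(model: CombatModel, tracts: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``tracts`` with batch effects removed.

    Adjustment per feature: standardize against the stored covariate fit,
    subtract the batch location ``gamma*``, divide by the batch scale
    ``delta*``, and restore the covariate fit. Unseen batch labels raise.
    """
    labels = tracts["scanner_id"].astype(str)
    unknown = sorted(set(labels) - set(model.batches))
    if unknown:
        raise ValueError(f"batch labels not seen at fit time: {unknown}")
    b_idx = labels.map({b: i for i, b in enumerate(model.batches)}).to_numpy()

    Y = tracts[model.features].to_numpy(float)
    X = _covariate_matrix(tracts, model.covariates)
    stand_mean = model.grand_mean[None, :] + X @ model.beta_cov
    sd = np.sqrt(model.pooled_var)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (Y - stand_mean) / sd_safe[None, :]
    Zadj = (Z - model.gamma_star[b_idx]) / np.sqrt(model.delta_sq_star[b_idx])
    Yadj = Zadj * sd_safe[None, :] + stand_mean

    out = tracts.copy()
    adj_cols = [f for f in model.features if f not in model.skipped]
    j = [model.features.index(f) for f in adj_cols]
    out[adj_cols] = Yadj[:, j]
    if model.skipped:
        warnings.warn(f"features left unadjusted (degenerate variance): {model.skipped}")
    return out
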