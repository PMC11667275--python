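"""Multiple imputation by chained equations and Rubin's-rules pooling.

A compact MICE engine in the style of the R ``mice`` defaults: predictive
mean matching for numeric variables (which keeps integer/positive support),
Bayesian logistic draws for binaries, chained over variables for a fixed
cycle count, producing ``m`` completed datasets whose observed cells are
identical. Downstream estimates computed per completed dataset are pooled
with Rubin's rules (optionally on a transformed scale, e.g. logit for AUC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

__all__ = ["ImputedSet", "PooledEstimate", "impute", "pool", "best_worst_case"]


@dataclass
class ImputedSet:
    """m completed datasets plus bookkeeping of how each variable was filled."""

    m: int
    datasets: list[pd.DataFrame]
    methods: dict[str, str]
    seed: int

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self):
        return self.m


@dataclass
class PooledEstimate:
    """Rubin's-rules pooled estimate.

    Q_bar is reported on the natural scale; pooling may happen on a
    transformed scale (``transformation`` in {None, "logit", "log"}) with the
    interval back-transformed.
    """

    q_bar: float
    within: float
    between: float
    total: float
    df: float
    ci_low: float
    ci_high: float
    m: int
    transformation: str | None = None


# ---------------------------------------------------------------------------

def _predictor_matrix(df: pd.DataFrame, exclude: str,
                      columns: list[str]) -> np.ndarray:
    """Numeric design from all current (filled) variables except `exclude`."""
    parts = [np.ones((len(df), 1))]
    for c in columns:
        if c == exclude:
            continue
        s = df[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s.astype(str), drop_first=True)
            if len(dummies.columns):
                parts.append(dummies.to_numpy(float))
        else:
            v = s.to_numpy(float)
            sd = v.std()
            parts.append(((v - v.mean()) / (sd if sd > 0 else 1.0))[:, None])
    return np.hstack(parts)


def _bayes_ols_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                    ridge: float = 1e-5):
    """Posterior draw (beta, beta_hat) under the normal linear model."""
    n, q = X.shape
    XtX = X.T @ X + ridge * np.eye(q)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ X.T @ y
    resid = y - X @ beta_hat
    df = max(n - q, 1)
    sigma2 = resid @ resid / stats.chi2.rvs(df, random_state=rng)
    L = np.linalg.cholesky(sigma2 * XtX_inv + 1e-12 * np.eye(q))
    beta = beta_hat + L @ rng.standard_normal(q)
    return beta, beta_hat


def _impute_pmm(df, col, miss, columns, rng, k_donors=5):
    X = _predictor_matrix(df, col, columns)
    obs = ~miss
    y_obs = df.loc[obs, col].to_numpy(float)
    beta, beta_hat = _bayes_ols_draw(X[obs], y_obs, rng)
    pred_obs = X[obs] @ beta_hat
    pred_mis = X[miss] @ beta
    # type-1 matching: k nearest observed predictions, draw one donor
    order = np.argsort(pred_obs)
    pred_sorted = pred_obs[order]
    y_sorted = y_obs[order]
    pos = np.searchsorted(pred_sorted, pred_mis)
    filled = np.empty(miss.sum())
    n_obs = len(y_sorted)
    for i, (p, j) in enumerate(zip(pred_mis, pos)):
        lo = max(0, j - k_donors)
        hi = min(n_obs, j + k_donors)
        cand = np.arange(lo, hi)
        d = np.abs(pred_sorted[cand] - p)
        donors = cand[np.argsort(d)[:k_donors]]
        filled[i] = y_sorted[rng.choice(donors)]
    return filled


def _impute_logistic(df, col, miss, columns, rng, ridge: float = 1e-3):
    X = _predictor_matrix(df, col, columns)
    obs = ~miss
    y = df.loc[obs, col].to_numpy(float)
    Xo = X[obs]
    q = Xo.shape[1]
    # ridge-stabilized Newton fit
    beta = np.zeros(q)
    for _ in range(25):
        p = expit(Xo @ beta)
        W = p * (1 - p)
        H = Xo.T @ (Xo * W[:, None]) + ridge * np.eye(q)
        g = Xo.T @ (y - p) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    # asymptotic posterior draw
    cov = np.linalg.inv(H)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(q))
    beta_draw = beta + L @ rng.standard_normal(q)
    p_mis = expit(X[miss] @ beta_draw)
    return (rng.random(miss.sum()) < p_mis).astype(float)


def _infer_method(s: pd.Series) -> str:
    vals = s.dropna().unique()
    if s.dtype != object and set(np.unique(vals)).issubset({0.0, 1.0, 0, 1}):
        return "logreg"
    if s.dtype == object:
        return "sample"           # unordered categorical: draw from observed
    return "pmm"


def impute(cohort: pd.DataFrame, m: int = 10, seed: int = 0,
           n_cycles: int = 10, columns: list[str] | None = None,
           id_columns: tuple[str, ...] = ("subject_id",)) -> ImputedSet:
    """Chained-equations multiple imputation of a cohort table.

    Parameters
    ----------
    columns:
        Variables participating in the imputation model (predictors and
        targets). Defaults to every column except identifiers; the derived
        ``outcome`` flag is always recomputed from imputed ``gose`` rather
        than imputed itself.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    df0 = cohort.copy()
    if columns is None:
        columns = [c for c in df0.columns if c not in id_columns and c != "outcome"]
    fully_missing = [c for c in columns if df0[c].isna().all()]
    if fully_missing:
        raise ValueError(f"variables 100% missing, cannot impute: {fully_missing}")
    targets = [c for c in columns if df0[c].isna().any()]
    if not targets:
        warnings.warn("no missing values; returning m identical copies")
        sets = [df0.copy() for _ in range(m)]
        return ImputedSet(m=m, datasets=sets, methods={}, seed=seed)

    methods = {c: _infer_method(df0[c]) for c in targets}
    # fill least-missing first, as mice does
    targets = sorted(targets, key=lambda c: df0[c].isna().sum())
    masks = {c: df0[c].isna().to_numpy() for c in targets}

    datasets = []
    root = np.random.SeedSequence([seed, 777])
    for imp_seed in root.spawn(m):
        rng = np.random.default_rng(imp_seed)
        df = df0.copy()
        for c in targets:   # initial fill: random draws from observed values
            obs_vals = df0[c].dropna().to_numpy()
            df.loc[masks[c], c] = rng.choice(obs_vals, masks[c].sum(), replace=True)
        for _ in range(n_cycles):
            for c in targets:
                miss = masks[c]
                if methods[c] == "logreg":
                    df.loc[miss, c] = _impute_logistic(df, c, miss, columns, rng)
                elif methods[c] == "sample":
                    obs_vals = df0[c].dropna().to_numpy()
                    df.loc[miss, c] = rng.choice(obs_vals, miss.sum(), replace=True)
                else:
                    df.loc[miss, c] = _impute_pmm(df, c, miss, columns, rng)
        if "gose" in df.columns and "outcome" in df0.columns:
            df["outcome"] = (df["gose"].astype(float) < 8).astype(float)
        datasets.append(df)
    return ImputedSet(m=m, datasets=datasets, methods=methods, seed=seed)


# Rubin's rules ---------------------------------------------------------------

_TRANSFORMS = {
    None: (lambda q: q, lambda q: q, lambda q, v: v),
    "logit": (logit, expit, lambda q, v: v / (q * (1 - q)) ** 2),
    "log": (np.log, np.exp, lambda q, v: v / q ** 2),
}


def pool(estimates: list[tuple[float, float]],
         transformation: str | None = None,
         alpha: float = 0.05, df_com: float | None = None) -> PooledEstimate:
    """Pool per-imputation (estimate, variance) pairs with Rubin's rules.

    Q_bar = mean(Q); W = mean(var); B = sample variance of Q;
    T = W + (1 + 1/m) B; Barnard-Rubin small-sample df when ``df_com`` is
    given, else the classical large-sample df. With a transformation tag the
    pooling happens on that scale (delta-method variances) and the interval
    is mapped back.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one estimate to pool")
    fwd, inv, var_map = _TRANSFORMS[transformation]
    Q = np.array([fwd(q) for q, _ in estimates], float)
    V = np.array([var_map(q, v) for q, v in estimates], float)
    if np.any(V < 0):
        raise ValueError("variances must be non-negative")
    m = len(Q)
    q_bar = Q.mean()
    W = V.mean()
    if m == 1:
        warnings.warn("single imputation: between-imputation variance undefined")
        B, T = 0.0, W
        df = np.inf
    else:
        B = Q.var(ddof=1)
        T = W + (1 + 1 / m) * B
        if B > 0 and W > 0:
            r = (1 + 1 / m) * B / W
            df = (m - 1) * (1 + 1 / r) ** 2
            if df_com is not None:           # Barnard-Rubin adjustment
                lam = (1 + 1 / m) * B / T
                df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
                df = 1 / (1 / df + 1 / df_obs)
        else:
            df = np.inf
    half = stats.t.ppf(1 - alpha / 2, df) * np.sqrt(T) if T > 0 else 0.0
    return PooledEstimate(
        q_bar=float(inv(q_bar)), within=float(W), between=float(B),
        total=float(T), df=float(df),
        ci_low=float(inv(q_bar - half)), ci_high=float(inv(q_bar + half)),
        m=m, transformation=transformation,
    )


def best_worst_case(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outcome sensitivity bounds: missing outcomes set to complete recovery
    (best case) or incomplete recovery (worst case); all else untouched."""
    best, worst = cohort.copy(), cohort.copy()
    miss = cohort["outcome"].isna() if "outcome" in cohort.columns \
        else cohort["gose"].isna()
    best.loc[miss, "gose"] = 8.0
    worst.loc[miss, "gose"] = 7.0
    for df in (best, worst):
        if "outcome" in df.columns:
            df["outcome"] = (df["gose"].astype(float) < 8).astype(float)
    return best, worst
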