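"""Synthetic mTBI cohort generator.

Emulates the statistical structure the downstream analysis assumes for a
CT-negative mild-TBI study cohort: per-tract FA/MD means following quadratic
normal-ageing trajectories, additive/multiplicative scanner batch effects,
serum biomarkers (GFAP, S100B, NFL) drawn log-normally with level depending
on outcome group and sampling window, clinical covariates with realistic
missingness, and a logistic outcome model whose tract effects are
concentrated in a configurable subset of tract-metric pairs.

The generator is the test bed for every downstream stage (harmonization,
detrending, imputation, DTI score, internal validation, triage); the real
study data are access-restricted and are never bundled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .atlas import JHU_ICBM_DTI_81, TractAtlas

__all__ = [
    "SimConfig",
    "simulate_controls",
    "simulate_patients",
    "write_cohort",
    "read_cohort",
    "CLINICAL_COLUMNS",
    "TWO_WEEK_COLUMNS",
    "BIOMARKER_COLUMNS",
]


# Cohort schema ---------------------------------------------------------------

CLINICAL_COLUMNS = [
    "age", "sex", "education_level", "prior_mental_health",
    "pre_injury_asa", "gcs", "pta_ge_1h", "alcohol_intoxication",
    "injury_mechanism", "iss", "concussion_symptom_score",
    "headache_moderate_severe", "difficulty_concentrating", "photophobia",
]
TWO_WEEK_COLUMNS = ["anxiety_score", "depression_score", "ptsd_score"]
BIOMARKER_COLUMNS = ["gfap", "s100b", "nfl"]

MECHANISMS = ["road_traffic", "fall", "violence", "other"]

# log-scale (mu, sigma) per biomarker, sampling window and outcome group.
# Locations are anchored near the triage cutoffs reported for each window
# (GFAP ng/ml, S100B ug/L, NFL pg/ml); NFL rises into the 12-24 h window.
_BIOMARKER_DEFAULTS = {
    "gfap": {
        "lt12": {"complete": (np.log(0.10), 0.80), "incomplete": (np.log(0.20), 0.80)},
        "12to24": {"complete": (np.log(0.07), 0.80), "incomplete": (np.log(0.14), 0.80)},
    },
    "s100b": {
        "lt12": {"complete": (np.log(0.050), 0.60), "incomplete": (np.log(0.080), 0.60)},
        "12to24": {"complete": (np.log(0.035), 0.60), "incomplete": (np.log(0.055), 0.60)},
    },
    "nfl": {
        "lt12": {"complete": (np.log(2.5), 0.70), "incomplete": (np.log(4.2), 0.70)},
        "12to24": {"complete": (np.log(5.0), 0.70), "incomplete": (np.log(9.0), 0.70)},
    },
}

# Default missingness: two-week questionnaires are missing far more often
# than acute variables, mirroring the gap between acute (~0-12%) and
# two-week (~25-27%) completeness in the DTI-eligible cohort.
_MISSING_DEFAULTS = {
    "education_level": 0.05,
    "prior_mental_health": 0.04,
    "pre_injury_asa": 0.03,
    "pta_ge_1h": 0.10,
    "alcohol_intoxication": 0.08,
    "iss": 0.02,
    "concussion_symptom_score": 0.08,
    "headache_moderate_severe": 0.05,
    "difficulty_concentrating": 0.05,
    "photophobia": 0.05,
    "anxiety_score": 0.26,
    "depression_score": 0.26,
    "ptsd_score": 0.27,
    "gfap": 0.05,
    "s100b": 0.05,
    "nfl": 0.05,
    "gose": 0.03,
}


def _default_effect_tracts() -> list[tuple[str, str]]:
    # The three tract-metric pairs carrying outcome effects by default;
    # chosen as the study's top-ranked prognostic tracts.
    return [
        ("Superior cerebellar peduncle L", "FA"),
        ("Uncinate fasciculus R", "MD"),
        ("Posterior thalamic radiation L", "FA"),
    ]


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort generator.

    Defaults reproduce the study conditions: 1025 biomarker-cohort patients
    at 38% incomplete-recovery prevalence, 157 healthy controls, 17 scanners,
    ages 20-70, and outcome effects of one log-odds unit per SD concentrated
    in three tract-metric pairs.
    """

    n_patients: int = 1025
    n_controls: int = 157
    n_scanners: int = 17
    age_range: tuple[float, float] = (20.0, 70.0)
    control_age_range: tuple[float, float] = (21.0, 68.0)
    reference_age: float = 44.0

    # Per-tract quadratic ageing trajectories in centred age a = age - reference_age:
    # value = b0 + b1*a + b2*a^2. Filled per tract at first use from the seed
    # unless given explicitly as {"fa": (48,3) array, "md": (48,3) array}.
    trajectory_coeffs: dict | None = None

    # Scanner batch model per metric: additive shift and multiplicative
    # noise-scale factor per scanner (the location/scale model ComBat assumes).
    batch_shift_sd: dict = field(default_factory=lambda: {"fa": 0.012, "md": 0.020})
    batch_scale_range: tuple[float, float] = (0.75, 1.35)
    batch_shift: np.ndarray | None = None   # (n_scanners, 2) fa/md, optional explicit
    batch_scale: np.ndarray | None = None   # (n_scanners,), optional explicit

    # Residual between-subject SD of tract values around the trajectory.
    noise_sd: dict = field(default_factory=lambda: {"fa": 0.025, "md": 0.040})

    # Outcome model.
    effect_tracts: list[tuple[str, str]] = field(default_factory=_default_effect_tracts)
    effect_sizes: list[float] = field(default_factory=lambda: [-1.0, 1.0, -1.0])
    clinical_effects: bool = True
    prevalence: float = 0.38

    biomarker_params: dict = field(default_factory=lambda: _BIOMARKER_DEFAULTS)
    sample_time_range: tuple[float, float] = (0.5, 24.0)

    missing_rates: dict = field(default_factory=lambda: dict(_MISSING_DEFAULTS))
    mar: bool = True      # missingness depends on observed age/GCS/education
    mnar: bool = False    # stress-test switch: outcome shifts GOSE missingness

    seed: int = 0
    atlas: TractAtlas = field(default_factory=lambda: JHU_ICBM_DTI_81)

    def __post_init__(self):
        if self.n_scanners < 1:
            raise ValueError("n_scanners must be >= 1")
        if not (self.age_range[0] < self.age_range[1]):
            raise ValueError(f"invalid age range {self.age_range}")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        for p in self.missing_rates.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("missing rates must lie in [0, 1]")
        if len(self.effect_tracts) != len(self.effect_sizes):
            raise ValueError("effect_tracts and effect_sizes length mismatch")
        for name, metric in self.effect_tracts:
            if name not in self.atlas or metric.upper() not in ("FA", "MD"):
                raise ValueError(f"effect tract {(name, metric)!r} not in atlas x {{FA, MD}}")
        for m in ("fa", "md"):
            if self.noise_sd[m] < 0:
                raise ValueError("noise SDs must be non-negative")
        if self.batch_scale_range[0] <= 0:
            raise ValueError("batch scale factors must be positive")

    # -- derived, seed-deterministic structure --------------------------------

    def trajectories(self) -> dict[str, np.ndarray]:
        """Per-tract quadratic coefficients (b0, b1, b2) in centred age, per metric.

        Drawn once, deterministically from the seed, unless supplied explicitly.
        FA declines and MD rises with age past the trajectory peak, with
        tract-specific baselines.
        """
        if self.trajectory_coeffs is not None:
            out = {}
            for m in ("fa", "md"):
                arr = np.asarray(self.trajectory_coeffs[m], dtype=float)
                if arr.shape != (len(self.atlas), 3):
                    raise ValueError(f"trajectory_coeffs[{m!r}] must have shape (48, 3)")
                out[m] = arr
            return out
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 101]))
        k = len(self.atlas)
        fa = np.column_stack([
            rng.uniform(0.42, 0.62, k),            # baseline FA at reference age
            rng.normal(-8e-4, 2e-4, k),            # /yr decline
            rng.normal(-8e-6, 3e-6, k),            # curvature
        ])
        md = np.column_stack([
            rng.uniform(0.70, 0.90, k),            # 1e-3 mm^2/s at reference age
            rng.normal(1.2e-3, 3e-4, k),           # /yr increase
            rng.normal(2.0e-5, 6e-6, k),
        ])
        return {"fa": fa, "md": md}

    def batch_effects(self) -> tuple[np.ndarray, np.ndarray]:
        """(shift, scale): shift (n_scanners, 2, n_tracts); scale (n_scanners,).

        Scanner offsets are drawn per tract (each machine biases regions
        differently), which is also the exchangeable-prior structure the
        harmonization model assumes. An explicit (n_scanners, 2) shift is
        broadcast to all tracts.
        """
        k = len(self.atlas)
        if self.batch_shift is not None and self.batch_scale is not None:
            shift = np.asarray(self.batch_shift, float)
            scale = np.asarray(self.batch_scale, float)
            if shift.shape == (self.n_scanners, 2):
                shift = np.repeat(shift[:, :, None], k, axis=2)
            if shift.shape != (self.n_scanners, 2, k) or \
                    scale.shape != (self.n_scanners,):
                raise ValueError("explicit batch effect arrays have wrong shape")
            if np.any(scale <= 0):
                raise ValueError("batch scale factors must be positive")
            return shift, scale
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 202]))
        shift = np.stack([
            rng.normal(0.0, self.batch_shift_sd["fa"], (self.n_scanners, k)),
            rng.normal(0.0, self.batch_shift_sd["md"], (self.n_scanners, k)),
        ], axis=1)
        scale = rng.uniform(*self.batch_scale_range, self.n_scanners)
        return shift, scale

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d.pop("atlas")
        for key in ("batch_shift", "batch_scale"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        if d["trajectory_coeffs"] is not None:
            d["trajectory_coeffs"] = {
                m: np.asarray(v).tolist() for m, v in d["trajectory_coeffs"].items()
            }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        d = json.loads(Path(path).read_text())
        for key in ("age_range", "control_age_range", "batch_scale_range",
                    "sample_time_range"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("effect_tracts"):
            d["effect_tracts"] = [tuple(t) for t in d["effect_tracts"]]
        for key in ("batch_shift", "batch_scale"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], float)
        return cls(**d)


# Tract-table construction ----------------------------------------------------

def _tract_values(config: SimConfig, ages: np.ndarray, scanner: np.ndarray,
                  rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Observed FA/MD table plus the latent biological deviations.

    observed = trajectory(age) + batch_shift + batch_scale * eps, where
    eps ~ N(0, noise_sd^2) is the subject's true (pre-batch, age-detrended)
    deviation. Returns (values df, eps array of shape (n, 96)).
    """
    n = len(ages)
    k = len(config.atlas)
    traj = config.trajectories()
    shift, scale = config.batch_effects()
    a = ages - config.reference_age
    basis = np.column_stack([np.ones(n), a, a * a])      # (n, 3)
    cols, eps_blocks = {}, []
    for j, metric in enumerate(("fa", "md")):
        mean = basis @ traj[metric].T                    # (n, 48)
        eps = rng.normal(0.0, config.noise_sd[metric], size=(n, k))
        obs = mean + shift[scanner, j, :] + scale[scanner][:, None] * eps
        if metric == "fa":
            obs = np.clip(obs, 1e-3, 1 - 1e-3)
        else:
            obs = np.maximum(obs, 1e-3)
        for t, slug in enumerate(config.atlas.slugs):
            cols[f"{metric}_{slug}"] = obs[:, t]
        eps_blocks.append(eps)
    return pd.DataFrame(cols), np.hstack(eps_blocks)


def simulate_controls(config: SimConfig) -> pd.DataFrame:
    """Healthy-control tract table: ageing trajectory + batch effects + noise.

    Controls carry no injury, so ``mr_abnormality`` is False and
    ``days_since_injury`` is NaN throughout.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_controls
    lo, hi = config.control_age_range
    if not lo < hi:
        raise ValueError(f"invalid control age range {(lo, hi)}")
    ages = rng.uniform(lo, hi, n)
    scanner = rng.integers(0, config.n_scanners, n)
    sex = rng.random(n) < 0.57
    values, _ = _tract_values(config, ages, scanner, rng)
    head = pd.DataFrame({
        "subject_id": [f"C{i:04d}" for i in range(n)],
        "scanner_id": [f"scanner_{s:02d}" for s in scanner],
        "age": ages,
        "sex": np.where(sex, "male", "female"),
        "days_since_injury": np.nan,
        "gcs": 15,
        "mr_abnormality": False,
    })
    return pd.concat([head, values], axis=1)


def _clinical_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    lo, hi = config.age_range
    df = pd.DataFrame({
        "subject_id": [f"P{i:04d}" for i in range(n)],
        "age": rng.uniform(lo, hi, n),
        "sex": np.where(rng.random(n) < 0.66, "male", "female"),
        "education_level": rng.choice([1, 2, 3], n, p=[0.3, 0.45, 0.25]),
        "prior_mental_health": (rng.random(n) < 0.15).astype(int),
        "pre_injury_asa": rng.choice([1, 2, 3], n, p=[0.6, 0.3, 0.1]),
        "gcs": rng.choice([13, 14, 15], n, p=[0.06, 0.16, 0.78]),
        "pta_ge_1h": (rng.random(n) < 0.33).astype(int),
        "alcohol_intoxication": (rng.random(n) < 0.20).astype(int),
        "injury_mechanism": rng.choice(MECHANISMS, n, p=[0.4, 0.4, 0.07, 0.13]),
        "iss": np.minimum(rng.poisson(4.0, n) + 1, 25),
        "concussion_symptom_score": np.clip(rng.gamma(2.2, 6.0, n), 0, 66),
        "headache_moderate_severe": (rng.random(n) < 0.40).astype(int),
        "difficulty_concentrating": (rng.random(n) < 0.30).astype(int),
        "photophobia": (rng.random(n) < 0.20).astype(int),
    })
    # Two-week questionnaires correlate with the acute symptom load.
    z = (df["concussion_symptom_score"] - df["concussion_symptom_score"].mean()) \
        / df["concussion_symptom_score"].std()
    df["anxiety_score"] = np.clip(rng.normal(5 + 2.0 * z, 4.0), 0, 21).round(0)
    df["depression_score"] = np.clip(rng.normal(5 + 2.0 * z, 4.5), 0, 27).round(0)
    df["ptsd_score"] = np.clip(rng.normal(12 + 3.0 * z, 8.0), 0, 80).round(0)
    return df


def _clinical_lp(df: pd.DataFrame) -> np.ndarray:
    """Modest clinical contribution to the outcome log-odds (gives the
    reference models their realistic AUC in the 0.6-0.7 range)."""
    z = lambda s: (s - s.mean()) / s.std()
    lp = (
        0.35 * z(df["concussion_symptom_score"])
        + 0.25 * df["pta_ge_1h"]
        + 0.20 * (15 - df["gcs"])
        + 0.30 * df["prior_mental_health"]
        + 0.10 * z(df["iss"])
        + 0.15 * z(df["age"])
        - 0.15 * (df["education_level"] - 2)
        + 0.20 * z(df["ptsd_score"])
        + 0.15 * z(df["anxiety_score"])
    )
    return np.asarray(lp, float)


def _solve_intercept(lp: np.ndarray, prevalence: float) -> float:
    f = lambda c: expit(c + lp).mean() - prevalence
    return brentq(f, -30.0, 30.0)


def _draw_biomarkers(config: SimConfig, outcome: np.ndarray,
                     rng: np.random.Generator) -> pd.DataFrame:
    n = len(outcome)
    t = rng.uniform(*config.sample_time_range, n)
    window = np.where(t < 12.0, "lt12", "12to24")
    out = {"biomarker_sample_time": t}
    group = np.where(outcome == 1, "incomplete", "complete")
    for bm in BIOMARKER_COLUMNS:
        vals = np.empty(n)
        for w in ("lt12", "12to24"):
            for g in ("complete", "incomplete"):
                mask = (window == w) & (group == g)
                mu, sigma = config.biomarker_params[bm][w][g]
                vals[mask] = rng.lognormal(mu, sigma, mask.sum())
        out[bm] = vals
    return pd.DataFrame(out)


def _apply_missingness(config: SimConfig, cohort: pd.DataFrame,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Set cells to NaN per missing_rates; MAR tilts the rate by observed
    age / GCS / education, MNAR (off by default) tilts GOSE by outcome."""
    df = cohort.copy()
    n = len(df)
    if config.mar:
        tilt = (
            0.35 * (df["age"] - df["age"].mean()) / df["age"].std()
            + 0.25 * (15 - df["gcs"])
            - 0.30 * (df["education_level"] - 2)
        ).to_numpy(float)
    else:
        tilt = np.zeros(n)
    for col, rate in config.missing_rates.items():
        if rate == 0 or col not in df.columns:
            continue
        logit_base = np.log(rate / (1 - rate)) if 0 < rate < 1 else np.inf
        p = expit(logit_base + tilt) if rate < 1 else np.ones(n)
        # calibrate the marginal rate back to the configured value
        p *= rate / max(p.mean(), 1e-12)
        p = np.clip(p, 0, 1)
        if config.mnar and col == "gose":
            p = np.clip(p * (1 + 0.8 * df["_outcome_true"].to_numpy()), 0, 1)
        mask = rng.random(n) < p
        df.loc[mask, col] = np.nan
    return df


def simulate_patients(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate (cohort, tract table) for patients.

    The outcome (incomplete recovery, GOSE < 8) is Bernoulli with log-odds
    = intercept + clinical terms + sum over effect tracts of
    effect_size * z-scored latent tract deviation; the intercept is solved
    so the marginal prevalence matches ``config.prevalence``. Biomarkers are
    drawn log-normally given outcome group and sampling window, conditionally
    independent of the tract values.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_patients
    clin = _clinical_frame(config, rng)
    scanner = rng.integers(0, config.n_scanners, n)
    ages = clin["age"].to_numpy()
    values, eps = _tract_values(config, ages, scanner, rng)

    # latent tract contribution to the outcome log-odds
    lp = _clinical_lp(clin) if config.clinical_effects else np.zeros(n)
    cols96 = config.atlas.metric_columns()
    for (name, metric), beta in zip(config.effect_tracts, config.effect_sizes):
        j = cols96.index(config.atlas.column(name, metric))
        sd = config.noise_sd[metric.lower()]
        if sd > 0:   # zero-noise tracts carry no between-subject signal
            lp = lp + beta * eps[:, j] / sd
    intercept = _solve_intercept(lp, config.prevalence)
    p_outcome = expit(intercept + lp)
    outcome = (rng.random(n) < p_outcome).astype(int)

    # GOSE consistent with the dichotomy: complete recovery is GOSE 8,
    # incomplete spreads over 3-7 (CT-negative mild TBI rarely goes lower).
    gose = np.where(outcome == 1,
                    rng.choice([3, 4, 5, 6, 7], n, p=[0.02, 0.06, 0.22, 0.35, 0.35]),
                    8)

    biomarkers = _draw_biomarkers(config, outcome, rng)
    cohort = pd.concat([clin, biomarkers], axis=1)
    cohort["gose"] = gose.astype(float)
    cohort["_outcome_true"] = outcome  # pre-missingness truth, for MNAR tilt
    cohort = _apply_missingness(config, cohort, rng)
    cohort = cohort.drop(columns="_outcome_true")
    cohort["outcome"] = np.where(cohort["gose"].isna(), np.nan,
                                 (cohort["gose"] < 8).astype(float))

    tracts = pd.concat([
        pd.DataFrame({
            "subject_id": clin["subject_id"],
            "scanner_id": [f"scanner_{s:02d}" for s in scanner],
            "age": ages,
            "sex": clin["sex"],
            "days_since_injury": np.clip(rng.gamma(2.0, 6.5, n), 0.0, 31.0),
            "gcs": clin["gcs"],
            "mr_abnormality": rng.random(n) < 0.25,
        }),
        values,
    ], axis=1)
    return cohort, tracts


# CSV round trip --------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, tracts: pd.DataFrame, out_dir: str | Path,
                 ) -> tuple[Path, Path]:
    """Write ``cohort.csv`` and ``tracts.csv``; missing values as empty cells,
    floats at full (round-trippable) precision."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_path, tracts_path = out / "cohort.csv", out / "tracts.csv"
    cohort.to_csv(cohort_path, index=False, float_format="%.17g")
    tracts.to_csv(tracts_path, index=False, float_format="%.17g")
    return cohort_path, tracts_path


def read_cohort(path: str | Path, atlas: TractAtlas = JHU_ICBM_DTI_81,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back a cohort directory written by :func:`write_cohort`.

    Raises ``ValueError`` naming any missing tract column; unknown extra
    columns are kept with a warning.
    """
    d = Path(path)
    cohort = pd.read_csv(d / "cohort.csv")
    tracts = pd.read_csv(d / "tracts.csv")
    required = set(atlas.metric_columns())
    missing = sorted(required - set(tracts.columns))
    if missing:
        raise ValueError(f"tract table is missing columns: {missing}")
    known = required | {"subject_id", "scanner_id", "age", "sex",
                        "days_since_injury", "gcs", "mr_abnormality"}
    extra = [c for c in tracts.columns if c not in known]
    if extra:
        warnings.warn(f"ignoring unknown tract-table columns: {extra}")
    if "mr_abnormality" in tracts.columns:
        tracts["mr_abnormality"] = tracts["mr_abnormality"].astype(bool)
    return cohort, tracts
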