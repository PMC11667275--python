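"""Tract-specific age detrending against healthy-control trajectories.

Normal ageing changes white-matter FA and MD, with a trajectory shape that
differs by tract, so patients of different ages are not directly comparable.
Each tract-metric is fitted on healthy controls with a quadratic age model
on an orthogonalized (centred and normalized) polynomial basis, and every
patient value f is re-expressed at a reference age (default 44, the patient
median) as f + d, where d = prediction(reference age) - prediction(patient
age) is the normal ageing difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import JHU_ICBM_DTI_81, TractAtlas

__all__ = ["DetrendModel", "fit_trajectory", "detrend"]


@dataclass
class DetrendModel:
    """Per-tract-metric quadratic ageing fits on a stored orthogonal basis.

    Basis: u = (age - age_center) / age_scale; regressors [1, u, u^2 - c2]
    with c2 = mean(u^2) on the fitting sample, making the quadratic column
    orthogonal to the intercept. Predictions are identical to a raw
    polynomial fit; the basis only conditions the normal equations, and its
    constants are stored so out-of-sample prediction is well defined.
    """

    features: list[str]
    coeffs: np.ndarray                 # (F, 3) on the stored basis
    age_center: float
    age_scale: float
    c2: float
    reference_age: float = 44.0
    age_range: tuple[float, float] = (0.0, 0.0)
    _pred_ref: np.ndarray = field(init=False, repr=False, default=None)

    def basis_row(self, age: np.ndarray) -> np.ndarray:
        u = (np.asarray(age, float) - self.age_center) / self.age_scale
        return np.column_stack([np.ones_like(u), u, u * u - self.c2])

    def predict(self, age: np.ndarray) -> np.ndarray:
        """Expected control value per feature at the given ages; (n, F)."""
        return self.basis_row(np.atleast_1d(age)) @ self.coeffs.T


def fit_trajectory(controls: pd.DataFrame,
                   atlas: TractAtlas = JHU_ICBM_DTI_81,
                   features: list[str] | None = None,
                   reference_age: float = 44.0) -> DetrendModel:
    """OLS quadratic ageing fit per tract-metric on healthy controls."""
    features = features if features is not None else atlas.metric_columns()
    age = controls["age"].to_numpy(float)
    if len(controls) < 10:
        raise ValueError("need at least 10 controls to fit ageing trajectories")
    if age.std() == 0:
        raise ValueError("degenerate control ages: no age spread")
    model = DetrendModel(
        features=list(features),
        coeffs=np.zeros((len(features), 3)),
        age_center=float(age.mean()),
        age_scale=float(age.std()),
        c2=0.0,
        reference_age=reference_age,
        age_range=(float(age.min()), float(age.max())),
    )
    u = (age - model.age_center) / model.age_scale
    model.c2 = float((u * u).mean())
    X = model.basis_row(age)
    Y = controls[features].to_numpy(float)
    model.coeffs = np.linalg.lstsq(X, Y, rcond=None)[0].T
    return model


def detrend(patients: pd.DataFrame, model: DetrendModel,
            ) -> tuple[pd.DataFrame, list[str]]:
    """Age-correct patient tract values to the model's reference age.

    Returns the corrected table and an audit list of subject ids whose age
    lies outside the control fitting range (still corrected, but
    extrapolated).
    """
    age = patients["age"].to_numpy(float)
    if not np.isfinite(age).all():
        raise ValueError("patient ages must be finite")
    pred_ref = model.predict(np.array([model.reference_age]))[0]   # (F,)
    pred_age = model.predict(age)                                  # (n, F)
    d = pred_ref[None, :] - pred_age
    out = patients.copy()
    out[model.features] = patients[model.features].to_numpy(float) + d
    lo, hi = model.age_range
    extrapolated = patients.loc[(age < lo) | (age > hi), "subject_id"] \
        .astype(str).tolist() if "subject_id" in patients.columns else []
    if "subject_id" not in patients.columns:
        mask = (age < lo) | (age > hi)
        extrapolated = [str(i) for i in np.nonzero(mask)[0]]
    return out, extrapolated
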