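"""End-to-end orchestration: simulate -> harmonize -> detrend -> impute ->
DTI score -> fit/validate -> triage, behind one configuration object.

Each stage reads the previous stage's CSV outputs from the run directory and
writes its own, so stages can be toggled and re-run individually; a manifest
records inputs, outputs, seeds and wall time for exact re-runs. A single
global seed deterministically spawns per-stage substreams.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import JHU_ICBM_DTI_81
from .detrend import detrend, fit_trajectory
from .dti_score import fit_dti_lasso, selection_frequencies
from .harmonize import apply_combat, fit_combat
from .impute import impute
from .models import REFERENCE_MODELS, lrt_nested_mi
from .synthetic import (SimConfig, simulate_controls, simulate_patients,
                        write_cohort)
from .triage import triage_table
from .validate import ValidationConfig, validate

log = logging.getLogger("recoverlab")

STAGES = ("simulate", "harmonize", "detrend", "impute", "dtiscore",
          "validate", "triage")

# Two-week models need the two-week questionnaires, only usable in the DTI
# cohort; the biomarker-cohort analysis uses the acute-variable models.
TWO_WEEK_MODELS = ("UPFRONT-PLUS", "CENTER-PLUS")


@dataclass
class RunConfig:
    """One pipeline run: stage toggles, per-stage parameters, global seed."""

    out_dir: str = "runs/demo"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    sim: SimConfig = None
    validation: ValidationConfig = None
    n_dti: int = 153                      # DTI sub-cohort size
    specs: tuple[str, ...] = ("CENTER-ED",)
    addons: tuple[str, ...] = ("dti",)
    m_imputations: int = 10
    triage_floors: tuple[float, ...] = (0.90, 1.00, 0.95, 0.80)

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        if self.validation is None:
            self.validation = ValidationConfig(seed=self.seed)


def _dti_subset(cohort: pd.DataFrame, n_dti: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 55]))
    ids = cohort["subject_id"].to_numpy()
    take = rng.choice(ids, size=min(n_dti, len(ids)), replace=False)
    return cohort[cohort["subject_id"].isin(take)].reset_index(drop=True)


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = JHU_ICBM_DTI_81
    cols96 = atlas.metric_columns()
    manifest = {"version": __version__, "seed": config.seed, "stages": {}}
    t00 = time.time()

    def record(stage, t0, **outputs):
        manifest["stages"][stage] = {
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": {k: str(v) for k, v in outputs.items()},
        }
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    try:
        if "simulate" in config.stages:
            t0 = time.time()
            cohort, tracts = simulate_patients(config.sim)
            controls = simulate_controls(config.sim)
            write_cohort(cohort, tracts, out)
            controls.to_csv(out / "controls.csv", index=False,
                            float_format="%.17g")
            config.sim.to_json(out / "sim_config.json")
            record("simulate", t0, cohort=out / "cohort.csv",
                   tracts=out / "tracts.csv", controls=out / "controls.csv")

        if "harmonize" in config.stages:
            t0 = time.time()
            tracts = pd.read_csv(out / "tracts.csv")
            controls = pd.read_csv(out / "controls.csv")
            both = pd.concat([tracts, controls], ignore_index=True)
            both["days_since_injury"] = both["days_since_injury"].fillna(0.0)
            model = fit_combat(both, atlas=atlas)
            adj = apply_combat(model, both)
            n_pat = len(tracts)
            adj.iloc[:n_pat].to_csv(out / "harmonized_patients.csv",
                                    index=False, float_format="%.17g")
            adj.iloc[n_pat:].to_csv(out / "harmonized_controls.csv",
                                    index=False, float_format="%.17g")
            model.to_json(out / "combat_model.json")
            record("harmonize", t0, patients=out / "harmonized_patients.csv",
                   controls=out / "harmonized_controls.csv",
                   model=out / "combat_model.json")

        if "detrend" in config.stages:
            t0 = time.time()
            controls = pd.read_csv(out / "harmonized_controls.csv")
            patients = pd.read_csv(out / "harmonized_patients.csv")
            model = fit_trajectory(controls, atlas=atlas,
                                   reference_age=config.sim.reference_age)
            corrected, extrapolated = detrend(patients, model)
            corrected.to_csv(out / "detrended.csv", index=False,
                             float_format="%.17g")
            (out / "detrend_audit.json").write_text(
                json.dumps({"extrapolated_subjects": extrapolated}))
            record("detrend", t0, detrended=out / "detrended.csv")

        if "impute" in config.stages:
            t0 = time.time()
            cohort = pd.read_csv(out / "cohort.csv")
            imp = impute(cohort, m=config.m_imputations, seed=config.seed)
            imp_dir = out / "imputed"
            imp_dir.mkdir(exist_ok=True)
            for i, d in enumerate(imp.datasets, start=1):
                d.to_csv(imp_dir / f"imp_{i:02d}.csv", index=False,
                         float_format="%.17g")
            (imp_dir / "imputation_log.json").write_text(json.dumps(
                {"m": imp.m, "seed": imp.seed, "methods": imp.methods}))
            record("impute", t0, imputed_dir=imp_dir)

        if "dtiscore" in config.stages:
            t0 = time.time()
            detrended = pd.read_csv(out / "detrended.csv")
            imp_dir = out / "imputed"
            runs = []
            for i, f in enumerate(sorted(imp_dir.glob("imp_*.csv")), start=1):
                d = pd.read_csv(f)
                merged = d.merge(detrended[["subject_id"] + cols96],
                                 on="subject_id")
                dti_sub = _dti_subset(merged, config.n_dti, config.seed)
                runs.append(fit_dti_lasso(
                    dti_sub[cols96], dti_sub["outcome"].to_numpy(float),
                    folds=10, repeats=10, seed=config.seed * 100 + i))
            freqs = selection_frequencies(runs, atlas)
            freqs.to_csv(out / "selection_frequencies.csv", index=False)
            best = runs[0]
            (out / "dtiscore_model.json").write_text(json.dumps({
                "lambda": best.lam, "intercept": best.intercept,
                "coef": dict(zip(best.features, best.coef.tolist())),
                "selected": best.selected,
            }))
            record("dtiscore", t0, freqs=out / "selection_frequencies.csv",
                   model=out / "dtiscore_model.json")

        if "validate" in config.stages:
            t0 = time.time()
            detrended = pd.read_csv(out / "detrended.csv")
            imp_dir = out / "imputed"
            imp_sets = []
            for f in sorted(imp_dir.glob("imp_*.csv")):
                d = pd.read_csv(f)
                merged = d.merge(detrended[["subject_id"] + cols96],
                                 on="subject_id")
                imp_sets.append(_dti_subset(merged, config.n_dti, config.seed))
            rows, lrt_rows = [], []
            for name in config.specs:
                base = REFERENCE_MODELS[name]
                variants = [base] + [base.with_addons(a)
                                     for a in config.addons]
                for spec in variants:
                    est = validate(spec, imp_sets, config.validation,
                                   tract_features=cols96)
                    tab = est.table.reset_index()
                    tab.insert(0, "model", spec.name)
                    rows.append(tab)
                    if spec is not base:
                        if "dti" in spec.terms:
                            from .validate import fit_pipeline, _with_dti_lp
                            lrt_sets = []
                            for d in imp_sets:
                                pipe = fit_pipeline(spec, d,
                                                    config.validation,
                                                    cols96, seed=config.seed)
                                lrt_sets.append(
                                    _with_dti_lp(d, pipe.dti_model, cols96))
                        else:
                            lrt_sets = imp_sets
                        lrt = lrt_nested_mi(spec, base, lrt_sets)
                        lrt_rows.append({"model": name,
                                         "addon": spec.name, **lrt})
            perf = pd.concat(rows, ignore_index=True)
            perf.to_csv(out / "validation.csv", index=False)
            if lrt_rows:
                pd.DataFrame(lrt_rows).to_csv(out / "lrt.csv", index=False)
            record("validate", t0, validation=out / "validation.csv")

        if "triage" in config.stages:
            t0 = time.time()
            cohort = pd.read_csv(out / "cohort.csv")
            table = triage_table(cohort,
                                 min_sensitivities=config.triage_floors)
            table.to_csv(out / "triage.csv", index=False)
            record("triage", t0, triage=out / "triage.csv")
    except Exception as e:
        manifest["failed_stage"] = next(
            (s for s in config.stages if s not in manifest["stages"]), "?")
        manifest["error"] = str(e)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["total_wall_time_s"] = round(time.time() - t00, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def report(results_dir: str | Path) -> str:
    """Human-readable summary of a run directory; lists missing inputs and
    renders whatever tables are present."""
    d = Path(results_dir)
    parts = [f"# recoverlab run report: {d}\n"]
    expected = {
        "validation.csv": "Model performance (apparent / optimism-corrected)",
        "lrt.csv": "Nested likelihood-ratio tests",
        "selection_frequencies.csv": "Tract selection frequencies",
        "triage.csv": "Biomarker triage",
    }
    missing = [f for f in expected if not (d / f).exists()]
    found = False
    for fname, title in expected.items():
        if fname in missing:
            continue
        found = True
        df = pd.read_csv(d / fname)
        if fname == "selection_frequencies.csv":
            df = df.head(10)
        parts.append(f"## {title}\n\n{df.to_string(index=False)}\n")
    if not found:
        parts.append("No results present: empty report.\n")
    if missing:
        parts.append(f"Missing inputs (stages not run): {missing}\n")
    text = "\n".join(parts)
    (d / "report.md").write_text(text)
    # calibration-decile plot data, if validation inputs are around
    return text


def plot_calibration(deciles: pd.DataFrame, path: str | Path,
                     title: str = "Calibration") -> Path:
    """Render decile calibration data (observed vs predicted, identity
    line) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 1], [0, 1], color="grey", lw=1, label="ideal")
    ax.errorbar(deciles["mean_predicted"], deciles["observed_rate"],
                fmt="o", color="tab:blue", label="observed")
    ax.set_xlabel("Mean predicted probability")
    ax.set_ylabel("Observed incomplete-recovery rate")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def calibration_deciles(y: np.ndarray, p: np.ndarray,
                        n_bins: int = 10) -> pd.DataFrame:
    """Observed outcome rate per decile of predicted probability (the data
    behind a calibration plot)."""
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    q = pd.qcut(p, q=n_bins, duplicates="drop")
    df = pd.DataFrame({"y": y, "p": p, "bin": q})
    g = df.groupby("bin", observed=True)
    return pd.DataFrame({
        "mean_predicted": g["p"].mean(),
        "observed_rate": g["y"].mean(),
        "n": g["y"].size(),
    }).reset_index(drop=True)
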