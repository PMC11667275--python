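"""Biomarker triage for DTI scanning.

If only patients whose serum biomarker exceeds a cutoff are referred for
DTI, the cutoff trades missed incomplete recoveries (false negatives)
against avoided scans (true negatives). The cutoff is chosen by exhaustive
scan: among candidate thresholds achieving at least a minimum sensitivity
(default 0.90; sensitivity sweep 1.00/0.95/0.90/0.80), pick the one with the
highest specificity. Scan-triage consequences are reported as avoided MRIs
(true negatives), unnecessary MRIs (false positives), missed incomplete
recoveries (false negatives) and number needed to scan.

Apparent (resubstitution) sensitivity/specificity are reported — this is an
exploratory analysis, not an internally validated model. Number needed to
scan is defined here as scans performed per incomplete-recovery patient
scanned, (TP+FP)/TP; this is a declared convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TriageConfig", "TriageResult", "choose_cutoff", "triage_metrics",
           "triage_table"]

WINDOWS = ("<12 h", "12-24 h")


@dataclass(frozen=True)
class TriageConfig:
    """Cutoff-selection settings for one biomarker/window analysis."""

    min_sensitivity: float = 0.90
    biomarker: str = "gfap"
    window: str = "<12 h"
    strict_inequality: bool = False   # positive means >= cutoff by default

    def __post_init__(self):
        # 0 is allowed but pointless (specificity alone); flagged degenerate
        if not (0.0 <= self.min_sensitivity <= 1.0):
            raise ValueError("min_sensitivity must lie in [0, 1]")


@dataclass
class TriageResult:
    """Confusion counts and scan-triage consequences at one cutoff.

    Positive = biomarker at/above cutoff (scan); event = incomplete
    recovery. Display percentages are computed against N with half-up
    rounding; NNS is reported to one decimal.
    """

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    n: int
    sensitivity: float
    specificity: float
    avoided_mris: int
    avoided_pct: int
    unnecessary_mris: int
    unnecessary_pct: int
    missed: int
    missed_pct: int
    number_needed_to_scan: float
    nns_defined: bool = True
    infeasible: bool = False
    degenerate: bool = False


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _confusion(conc: np.ndarray, outcome: np.ndarray, cutoff: float,
               strict: bool) -> tuple[int, int, int, int]:
    pos = conc > cutoff if strict else conc >= cutoff
    tp = int(np.sum(pos & (outcome == 1)))
    fp = int(np.sum(pos & (outcome == 0)))
    fn = int(np.sum(~pos & (outcome == 1)))
    tn = int(np.sum(~pos & (outcome == 0)))
    return tp, fp, tn, fn


def choose_cutoff(concentrations, outcomes,
                  config: TriageConfig) -> tuple[float, dict]:
    """Highest-specificity cutoff subject to the minimum-sensitivity floor.

    Candidates are the midpoints of sorted unique concentrations plus
    extremes just outside the observed range; ties in specificity break
    toward the higher cutoff (fewer scans). If no cutoff meets the floor the
    minimum concentration is returned with ``infeasible`` set.
    """
    conc = np.asarray(concentrations, float)
    y = np.asarray(outcomes, float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes required to choose a cutoff")
    u = np.unique(conc)
    candidates = np.concatenate([[u[0] / 2.0], (u[:-1] + u[1:]) / 2.0,
                                 [u[-1] * 1.01]])
    best, best_spec, best_sens = None, -1.0, None
    for c in candidates:
        tp, fp, tn, fn = _confusion(conc, y, c, config.strict_inequality)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        if sens >= config.min_sensitivity and (
                spec > best_spec or (spec == best_spec and c > best)):
            best, best_spec, best_sens = float(c), spec, sens
    if best is None:
        return float(conc.min()), {"infeasible": True, "sensitivity": None,
                                   "specificity": None, "degenerate": False}
    degenerate = config.min_sensitivity == 0.0 or best_sens == 0.0
    return best, {"infeasible": False, "sensitivity": best_sens,
                  "specificity": best_spec, "degenerate": bool(degenerate)}


def triage_metrics(tp: int, fp: int, tn: int, fn: int, n: int | None = None,
                   cutoff: float = float("nan"),
                   infeasible: bool = False) -> TriageResult:
    """Scan-triage consequences from a confusion matrix.

    Avoided MRIs are the true negatives (below cutoff, complete recovery),
    unnecessary MRIs the false positives, missed incomplete recoveries the
    false negatives; percentages are against N, rounded half-up.
    """
    for v in (tp, fp, tn, fn):
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if n is None:
        n = total
    elif n != total:
        raise ValueError(f"counts sum to {total}, not N={n}")
    sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
    spec = tn / (tn + fp) if tn + fp > 0 else float("nan")
    nns_defined = tp > 0
    nns = round((tp + fp) / tp, 1) if nns_defined else float("nan")
    pct = lambda c: _round_half_up(100.0 * c / n) if n > 0 else 0
    return TriageResult(
        cutoff=cutoff, tp=tp, fp=fp, tn=tn, fn=fn, n=n,
        sensitivity=sens, specificity=spec,
        avoided_mris=tn, avoided_pct=pct(tn),
        unnecessary_mris=fp, unnecessary_pct=pct(fp),
        missed=fn, missed_pct=pct(fn),
        number_needed_to_scan=nns, nns_defined=nns_defined,
        infeasible=infeasible,
    )


def _assign_window(hours: np.ndarray) -> np.ndarray:
    return np.where(hours < 12.0, WINDOWS[0], WINDOWS[1])


def triage_table(cohort: pd.DataFrame,
                 biomarkers: tuple[str, ...] = ("gfap", "s100b", "nfl"),
                 min_sensitivities: tuple[float, ...] = (0.90,),
                 time_column: str = "biomarker_sample_time",
                 outcome_column: str = "outcome",
                 strict_inequality: bool = False) -> pd.DataFrame:
    """One triage row per biomarker x sampling window x sensitivity floor.

    Rows with fewer than 10 subjects in a window are emitted with a
    small-sample flag. Subjects missing the biomarker, sampling time or
    outcome are dropped per row.
    """
    rows = []
    for floor in min_sensitivities:
        for bm in biomarkers:
            for w in WINDOWS:
                sub = cohort.dropna(subset=[bm, time_column, outcome_column])
                sub = sub[_assign_window(sub[time_column].to_numpy(float)) == w]
                small = len(sub) < 10
                if small:
                    warnings.warn(f"{bm} {w}: only {len(sub)} subjects")
                if len(sub) == 0 or sub[outcome_column].nunique() < 2:
                    rows.append({"biomarker": bm, "window": w,
                                 "min_sensitivity": floor, "n": len(sub),
                                 "small_sample": True})
                    continue
                cfg = TriageConfig(min_sensitivity=floor, biomarker=bm,
                                   window=w, strict_inequality=strict_inequality)
                cut, info = choose_cutoff(sub[bm], sub[outcome_column], cfg)
                tpfptnfn = _confusion(sub[bm].to_numpy(float),
                                      sub[outcome_column].to_numpy(float),
                                      cut, strict_inequality)
                res = triage_metrics(*tpfptnfn, cutoff=cut,
                                     infeasible=info["infeasible"])
                rows.append({
                    "biomarker": bm, "window": w, "min_sensitivity": floor,
                    "n": res.n, "cutoff": res.cutoff,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                    "avoided_mris": res.avoided_mris,
                    "avoided_pct": res.avoided_pct,
                    "unnecessary_mris": res.unnecessary_mris,
                    "unnecessary_pct": res.unnecessary_pct,
                    "missed": res.missed, "missed_pct": res.missed_pct,
                    "number_needed_to_scan": res.number_needed_to_scan,
                    "infeasible": res.infeasible, "small_sample": small,
                })
    return pd.DataFrame(rows)
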