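"""Method comparison and deficiency-classification metrics.

Given a cohort table pairing a reference concentration (laboratory
immunoassay) with a strip-predicted concentration per subject, this module
computes the agreement and diagnostic statistics usual for point-of-care
method validation: median relative bias, Pearson correlation, sensitivity
and specificity at clinical deficiency cut-offs (deficient = strictly below
the cut-off), and the ROC curve obtained by sweeping the prediction
threshold.

Predictions clamped at the calibration range carry a flag ("below_range" /
"above_range").  Flagged rows have no usable magnitude, so they are
excluded from bias and correlation but still enter classification through
their flag: below-range reads as deficient, above-range as sufficient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import FLAG_ABOVE_RANGE, FLAG_BELOW_RANGE, FLAG_OK
from .errors import InputError

logger = logging.getLogger(__name__)

#: Clinical deficiency cut-offs (pmol/L) commonly applied to serum B12.
DEFAULT_CUTOFFS = (150.0, 221.0, 258.0, 332.0)

DEFICIENT = "deficient"
NOT_DEFICIENT = "not_deficient"

_REQUIRED_COLUMNS = ("subject_id", "reference_pmol_L", "predicted_pmol_L")


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV (subject_id, reference_pmol_L, predicted_pmol_L[, flag])."""
    df = pd.read_csv(path)
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"cohort table missing columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise InputError("cohort subject_id values must be unique")
    if "flag" not in df.columns:
        df = df.assign(flag=FLAG_OK)
    return df


def _usable(df: pd.DataFrame) -> pd.DataFrame:
    """Rows with a usable predicted magnitude and a positive reference."""
    ok = (df["flag"] == FLAG_OK) & (df["reference_pmol_L"] > 0)
    ok &= np.isfinite(df["predicted_pmol_L"])
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("excluding %d range-flagged or zero-reference rows", dropped)
    return df[ok]


def median_bias(cohort: pd.DataFrame) -> float:
    """Median over subjects of 100*(predicted - reference)/reference, percent."""
    usable = _usable(validate_cohort(cohort))
    if usable.empty:
        raise InputError("no usable rows for bias computation")
    rel = 100.0 * (usable["predicted_pmol_L"] - usable["reference_pmol_L"]) / usable["reference_pmol_L"]
    return float(rel.median())


def correlation(cohort: pd.DataFrame, method: str = "pearson") -> tuple[float, float]:
    """Correlation (r, two-sided p) of predicted vs reference concentration.

    Pearson by default; Spearman available via ``method="spearman"``.
    """
    usable = _usable(validate_cohort(cohort))
    if len(usable) < 3:
        raise InputError("correlation needs at least 3 usable pairs")
    x = usable["reference_pmol_L"].to_numpy(float)
    y = usable["predicted_pmol_L"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("correlation undefined for zero-variance input")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise InputError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


def classify(concentration: float, cutoff: float, flag: str = FLAG_OK) -> str:
    """Deficiency call: deficient iff concentration strictly below the cut-off.

    Range flags override the magnitude: a below-range prediction is
    deficient, an above-range one ("greater than the highest calibrator")
    is not.
    """
    if flag == FLAG_BELOW_RANGE:
        return DEFICIENT
    if flag == FLAG_ABOVE_RANGE:
        return NOT_DEFICIENT
    if concentration < 0 or not math.isfinite(concentration):
        raise InputError(f"cannot classify concentration {concentration} without a flag")
    return DEFICIENT if concentration < cutoff else NOT_DEFICIENT


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float | None
    specificity: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    note: str = ""


def _calls(df: pd.DataFrame, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    ref_pos = df["reference_pmol_L"].to_numpy(float) < cutoff
    pred_pos = np.array(
        [
            classify(c, cutoff, f) == DEFICIENT
            for c, f in zip(df["predicted_pmol_L"], df["flag"])
        ]
    )
    return ref_pos, pred_pos


def sens_spec(cohort: pd.DataFrame, cutoff: float) -> CutoffResult:
    """Sensitivity and specificity of the deficiency call at one cut-off.

    Positive = deficient by the reference assay (reference < cutoff).  If
    the cohort has no positives (or no negatives) the corresponding metric
    is reported as None with a reason.
    """
    df = validate_cohort(cohort)
    ref_pos, pred_pos = _calls(df, cutoff)
    tp = int(np.sum(ref_pos & pred_pos))
    fn = int(np.sum(ref_pos & ~pred_pos))
    tn = int(np.sum(~ref_pos & ~pred_pos))
    fp = int(np.sum(~ref_pos & pred_pos))
    notes = []
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    if sens is None:
        notes.append("no reference-deficient subjects: sensitivity undefined")
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    if spec is None:
        notes.append("no reference-sufficient subjects: specificity undefined")
    return CutoffResult(cutoff=cutoff, sensitivity=sens, specificity=spec,
                        tp=tp, fp=fp, tn=tn, fn=fn, note="; ".join(notes))


def roc(cohort: pd.DataFrame, reference_cutoff: float) -> tuple[pd.DataFrame, float]:
    """ROC of the deficiency call, sweeping the prediction threshold.

    Truth: reference < reference_cutoff.  Decision at threshold t:
    predicted < t (below-range predictions always deficient, above-range
    never).  Thresholds sweep all distinct predicted values plus ±inf, so
    the staircase runs from (0, 0) to (1, 1).  AUC by trapezoid.
    """
    df = validate_cohort(cohort)
    truth = df["reference_pmol_L"].to_numpy(float) < reference_cutoff
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("ROC needs at least one positive and one negative subject")

    # Effective score: flagged predictions pinned to the extremes.
    score = df["predicted_pmol_L"].to_numpy(float).copy()
    score[df["flag"].to_numpy() == FLAG_BELOW_RANGE] = -math.inf
    score[df["flag"].to_numpy() == FLAG_ABOVE_RANGE] = math.inf

    thresholds = np.concatenate(([-math.inf], np.unique(score[np.isfinite(score)]), [math.inf]))
    rows = []
    for t in thresholds:
        pred = score < t
        tpr = float(np.sum(pred & truth)) / n_pos
        fpr = float(np.sum(pred & ~truth)) / n_neg
        rows.append((fpr, tpr, t))
    # Terminal point: every subject called deficient.
    if rows[-1][:2] != (1.0, 1.0):
        rows.append((1.0, 1.0, math.inf))
    points = pd.DataFrame(rows, columns=["fpr", "tpr", "cutoff"]).sort_values(
        ["fpr", "tpr"], kind="stable", ignore_index=True
    )
    auc = float(np.trapezoid(points["tpr"], points["fpr"]))
    return points, auc


@dataclass
class DiagnosticSummary:
    """All headline metrics for one cohort."""

    n_total: int
    n_used: int
    median_bias_pct: float
    pearson_r: float
    pearson_p: float
    cutoffs: list[CutoffResult] = field(default_factory=list)
    roc_auc: float = float("nan")
    roc_reference_cutoff: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_used": self.n_used,
            "median_bias_pct": self.median_bias_pct,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "roc_auc": self.roc_auc,
            "roc_reference_cutoff": self.roc_reference_cutoff,
            "cutoffs": [
                {
                    "cutoff_pmol_L": c.cutoff,
                    "sensitivity": c.sensitivity,
                    "specificity": c.specificity,
                    "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                    "note": c.note,
                }
                for c in self.cutoffs
            ],
        }


def summarize(
    cohort: pd.DataFrame,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    roc_reference_cutoff: float = 332.0,
) -> DiagnosticSummary:
    """Compute bias, correlation, per-cutoff sensitivity/specificity, and ROC."""
    df = validate_cohort(cohort)
    r, p = correlation(df)
    _, auc = roc(df, roc_reference_cutoff)
    return DiagnosticSummary(
        n_total=len(df),
        n_used=len(_usable(df)),
        median_bias_pct=median_bias(df),
        pearson_r=r,
        pearson_p=p,
        cutoffs=[sens_spec(df, c) for c in cutoffs],
        roc_auc=auc,
        roc_reference_cutoff=roc_reference_cutoff,
    )
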