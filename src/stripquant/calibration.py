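"""Four-parameter logistic (4PL) calibration linking T/C ratio to concentration.

In a competitive lateral-flow assay the test-line signal *falls* as analyte
concentration rises, so the calibration is a decreasing sigmoid.  The
standard immunoassay form is the four-parameter logistic

    T/C = d + (a - d) / (1 + (x / c)**b)

with top asymptote ``a`` (T/C at zero concentration), bottom asymptote
``d`` (T/C at saturating concentration), inflection concentration ``c``
(pmol/L), and slope exponent ``b``.  The curve is fitted per strip batch,
stored as JSON, and inverted analytically to predict concentrations from
measured T/C ratios.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr  # noqa: F401  (re-exported convenience)

from .errors import CalibrationError, InputError

#: Reference batch calibration for the silver-enhanced vitamin B12 strip
#: chemistry (T/C at zero analyte 0.99, slope 3, inflection 303.7 pmol/L,
#: bottom asymptote 0.30).  Used as the default curve for simulations.
B12_BATCH_CURVE_PARAMS = {"a": 0.99, "b": 3.0, "c": 303.7, "d": 0.3}

#: Highest calibrator of the reference batch (pmol/L); the top of its
#: reportable range.
B12_BATCH_MAX_CALIBRATOR = 1107.0

# Flags attached to out-of-range predictions.
FLAG_OK = "ok"
FLAG_BELOW_RANGE = "below_range"   # T/C at or above the top asymptote
FLAG_ABOVE_RANGE = "above_range"   # T/C at or below the bottom asymptote


@dataclass
class CalibrationCurve:
    """4PL parameters for one strip batch.

    Invariants: a > d (the curve is decreasing), b > 0, c > 0.
    ``max_concentration`` is the highest calibrator the batch was fitted
    against: predictions beyond it are extrapolation, reported only as
    "greater than the highest calibrator" (above-range), never as a
    magnitude.  Defaults to +inf (no reporting cap).
    """

    a: float
    b: float
    c: float
    d: float
    batch_id: str = ""
    r_squared: float = float("nan")
    max_concentration: float = float("inf")

    def __post_init__(self) -> None:
        if not self.a > self.d:
            raise CalibrationError(f"top asymptote a={self.a} must exceed bottom d={self.d}")
        if not self.b > 0:
            raise CalibrationError(f"slope exponent b={self.b} must be positive")
        if not self.c > 0:
            raise CalibrationError(f"inflection concentration c={self.c} must be positive")

    def __call__(self, concentration):
        return eval_4pl(self, concentration)


def default_b12_curve(batch_id: str = "reference") -> CalibrationCurve:
    """The built-in reference batch calibration for vitamin B12 strips."""
    return CalibrationCurve(batch_id=batch_id,
                            max_concentration=B12_BATCH_MAX_CALIBRATOR,
                            **B12_BATCH_CURVE_PARAMS)


@dataclass
class CalibrationPoint:
    """Replicate T/C measurements at one calibrator concentration."""

    concentration: float
    tc_values: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise InputError("calibrator concentration must be >= 0")
        if len(self.tc_values) < 1:
            raise InputError("a calibration point needs at least one replicate")


def eval_4pl(curve: CalibrationCurve, concentration) -> float | np.ndarray:
    """Evaluate T/C = d + (a-d)/(1+(x/c)**b); returns ``a`` exactly at x=0."""
    x = np.asarray(concentration, dtype=float)
    if np.any(x < 0):
        raise InputError("concentration must be >= 0")
    out = curve.d + (curve.a - curve.d) / (1.0 + np.power(x / curve.c, curve.b))
    return float(out) if np.isscalar(concentration) or out.ndim == 0 else out


def invert_4pl(curve: CalibrationCurve, tc: float) -> float:
    """Analytic inverse of :func:`eval_4pl` on the open range d < tc < a.

    Returns c * ((a-d)/(tc-d) - 1)**(1/b).  Out-of-range T/C raises; use
    :func:`predict_concentration` for the clamp-and-flag policy.
    """
    if not (curve.d < tc < curve.a):
        raise InputError(
            f"T/C {tc} outside the invertible open range ({curve.d}, {curve.a})"
        )
    return curve.c * ((curve.a - curve.d) / (tc - curve.d) - 1.0) ** (1.0 / curve.b)


def predict_concentration(curve: CalibrationCurve, tc: float) -> tuple[float, str]:
    """Predict concentration from a measured T/C, clamping out-of-range values.

    Returns ``(concentration_pmol_L, flag)``.  A T/C at or above the top
    asymptote means no detectable analyte: clamp to 0 with ``below_range``.
    A T/C at or below the bottom asymptote, or one inverting beyond the
    batch's highest calibrator, exceeds the calibrated range: report +inf
    with ``above_range`` (read as "greater than the highest calibrator").
    """
    if tc >= curve.a:
        return 0.0, FLAG_BELOW_RANGE
    if tc <= curve.d:
        return math.inf, FLAG_ABOVE_RANGE
    conc = invert_4pl(curve, tc)
    if conc > curve.max_concentration:
        return math.inf, FLAG_ABOVE_RANGE
    return conc, FLAG_OK


def _4pl_model(x, a, b, c, d):
    return d + (a - d) / (1.0 + np.power(x / c, b))


def fit_4pl(points: list[CalibrationPoint], batch_id: str = "") -> CalibrationCurve:
    """Fit the 4PL to replicate calibrator data by nonlinear least squares.

    All replicates enter the loss unweighted.  Initialisation: a0 = max of
    the per-level mean T/C, d0 = min, c0 = the nonzero calibrator whose mean
    T/C is nearest (a0+d0)/2, b0 = 1.  Bounds: a, d in [0, 2], b in (0, 20],
    c in (0, 1e5].  ``r_squared`` is computed against the per-level replicate
    means (the error-bar summary a 3-replicate design reports).
    """
    concs = np.array([p.concentration for p in points], dtype=float)
    if len(np.unique(concs)) < 4:
        raise InputError("4PL fitting needs at least 4 distinct calibrator concentrations")

    x_all = np.concatenate([[p.concentration] * len(p.tc_values) for p in points])
    y_all = np.concatenate([np.asarray(p.tc_values, dtype=float) for p in points])
    means = np.array([float(np.mean(p.tc_values)) for p in points])

    a0, d0 = float(means.max()), float(means.min())
    mid = (a0 + d0) / 2.0
    nonzero = concs > 0
    c0 = float(concs[nonzero][np.argmin(np.abs(means[nonzero] - mid))])
    p0 = [a0, 1.0, c0, d0]
    lower = [0.0, 1e-9, 1e-9, 0.0]
    upper = [2.0, 20.0, 1e5, 2.0]
    p0 = np.clip(p0, lower, upper)

    try:
        popt, _ = curve_fit(_4pl_model, x_all, y_all, p0=p0,
                            bounds=(lower, upper), maxfev=20000)
    except RuntimeError as err:
        raise CalibrationError(f"4PL fit did not converge: {err}") from err

    a, b, c, d = (float(v) for v in popt)
    residuals = means - _4pl_model(concs, a, b, c, d)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((means - means.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else float("nan"))
    return CalibrationCurve(a=a, b=b, c=c, d=d, batch_id=batch_id, r_squared=r2,
                            max_concentration=float(concs.max()))


def cv_at_level(point: CalibrationPoint) -> float:
    """Coefficient of variation (percent) of replicate T/C at one level:
    100 * sample SD / mean."""
    if len(point.tc_values) < 2:
        raise InputError("CV needs at least 2 replicates")
    vals = np.asarray(point.tc_values, dtype=float)
    mean = float(vals.mean())
    if mean <= 0:
        raise InputError("CV undefined for non-positive mean T/C")
    return 100.0 * float(np.std(vals, ddof=1)) / mean


def save_calibration(curve: CalibrationCurve, path: str | Path) -> None:
    """Write a calibration to JSON with full float precision."""
    payload = asdict(curve)
    payload["fitted_at"] = datetime.now(timezone.utc).isoformat()
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_calibration(path: str | Path) -> CalibrationCurve:
    """Load and validate a JSON calibration file."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise CalibrationError(f"malformed calibration file {path}: {err}") from err
    missing = {"a", "b", "c", "d"} - set(payload)
    if missing:
        raise CalibrationError(f"calibration file {path} missing fields {sorted(missing)}")
    return CalibrationCurve(
        a=payload["a"], b=payload["b"], c=payload["c"], d=payload["d"],
        batch_id=payload.get("batch_id", ""),
        r_squared=payload.get("r_squared", float("nan")),
        max_concentration=payload.get("max_concentration", float("inf")),
    )
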