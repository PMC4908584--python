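"""Synthetic strip images and cohorts with known ground truth.

Real strip photographs show a light nitrocellulose background crossed by
two dark transverse lines about 1 mm wide and 3 mm apart (test line
upstream, control line downstream).  This module renders such images
deterministically from a seed so that every stage of the quantification
pipeline can be exercised against known truth: line cross-sections are
Gaussian dips (dispensed reagent diffuses, so a printed 1 mm line reads as
a smooth dip whose FWHM matches the printed width), pixel noise is additive
Gaussian, and an optional linear illumination ramp along the flow axis
mimics uneven lighting.

Line darkness is driven by a 4PL calibration curve: at concentration x the
test-line depth is ``control_depth * curve(x)``, so the ground-truth T/C
ratio equals the curve value exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, eval_4pl, predict_concentration
from .errors import ConfigurationError
from .quant import StripImage

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

# RGB rendering tints lines reddish-brown: the dip is shallower in the red
# channel than in green/blue, weighted so the luma-converted depth equals
# the nominal grayscale depth exactly.
_RED_TINT = 0.5
_GB_TINT = (1.0 - 0.299 * _RED_TINT) / (0.587 + 0.114)


@dataclass(frozen=True)
class SyntheticStripSpec:
    """Geometry, photometry, and noise parameters of one rendered strip.

    Defaults follow the physical strip: a ~25 mm membrane at 20 px/mm
    (500 rows), 4 mm wide, lines 1 mm wide and 3 mm apart.  Depths are
    grayscale units below the background level.
    """

    height_px: int = 500
    width_px: int = 80
    px_per_mm: float = 20.0
    background_level: float = 200.0
    test_line_depth: float = 40.0
    control_line_depth: float = 80.0
    line_width_mm: float = 1.0
    line_separation_mm: float = 3.0
    test_line_position_mm: float = 12.0
    noise_sd: float = 0.0
    illumination_slope: float = 0.0
    seed: int = 0
    rgb: bool = False

    def __post_init__(self) -> None:
        if self.height_px < 3 or self.width_px < 3:
            raise ConfigurationError("image must be at least 3x3")
        if self.px_per_mm <= 0:
            raise ConfigurationError("px_per_mm must be positive")
        if not (0 < self.background_level <= 255):
            raise ConfigurationError("background_level must be in (0, 255]")
        for name in ("test_line_depth", "control_line_depth"):
            depth = getattr(self, name)
            if depth < 0 or depth >= self.background_level:
                raise ConfigurationError(f"{name}={depth} must be in [0, background_level)")
        if self.line_separation_mm * self.px_per_mm < 2:
            raise ConfigurationError("lines must be at least 2 px apart")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        t, c = self.line_centers_px
        margin = int(round(self.line_width_mm * self.px_per_mm))
        if t - margin < 0 or c + margin >= self.height_px:
            raise ConfigurationError(
                f"lines at rows {t} and {c} (±{margin} px) do not fit in {self.height_px} rows"
            )

    @property
    def line_centers_px(self) -> tuple[int, int]:
        test = int(round(self.test_line_position_mm * self.px_per_mm))
        control = test + int(round(self.line_separation_mm * self.px_per_mm))
        return test, control


@dataclass(frozen=True)
class GroundTruth:
    """True signal parameters of a rendered strip."""

    true_tc_ratio: float
    true_test_depth: float
    true_control_depth: float
    line_centers_px: tuple[int, int]
    true_concentration: float | None = None


def _line_dip(rows: np.ndarray, centre: int, depth: float, sigma: float) -> np.ndarray:
    return depth * np.exp(-((rows - centre) ** 2) / (2.0 * sigma**2))


def render_strip(spec: SyntheticStripSpec) -> tuple[StripImage, GroundTruth]:
    """Render one strip image and its ground truth.

    The noiseless flow-axis profile is
    ``background + slope*row - sum of Gaussian line dips``; at each line
    centre the profile equals background - depth exactly (before the
    illumination ramp and 8-bit rounding).  Identical specs (including
    seed) produce bit-identical images.
    """
    rows = np.arange(spec.height_px, dtype=float)
    sigma = spec.line_width_mm * spec.px_per_mm / _FWHM_TO_SIGMA
    t_centre, c_centre = spec.line_centers_px

    base = spec.background_level + spec.illumination_slope * rows
    dip = _line_dip(rows, t_centre, spec.test_line_depth, sigma) + _line_dip(
        rows, c_centre, spec.control_line_depth, sigma
    )

    rng = np.random.default_rng(spec.seed)
    if spec.rgb:
        tints = np.array([_RED_TINT, _GB_TINT, _GB_TINT])
        field = base[:, None, None] - dip[:, None, None] * tints[None, None, :]
        field = np.broadcast_to(field, (spec.height_px, spec.width_px, 3)).copy()
    else:
        field = np.broadcast_to(
            (base - dip)[:, None], (spec.height_px, spec.width_px)
        ).copy()
    if spec.noise_sd > 0:
        field += rng.normal(0.0, spec.noise_sd, size=field.shape)

    pixels = np.clip(np.rint(field), 0, 255).astype(np.uint8)
    tc = (
        spec.test_line_depth / spec.control_line_depth
        if spec.control_line_depth > 0
        else float("nan")
    )
    truth = GroundTruth(
        true_tc_ratio=tc,
        true_test_depth=spec.test_line_depth,
        true_control_depth=spec.control_line_depth,
        line_centers_px=(t_centre, c_centre),
    )
    return StripImage(pixels, px_per_mm=spec.px_per_mm), truth


def generate_calibration_set(
    curve: CalibrationCurve,
    concentrations: list[float],
    control_depth: float,
    base_spec: SyntheticStripSpec,
    replicates: int = 3,
    seed: int = 0,
) -> list[tuple[float, StripImage, GroundTruth]]:
    """Render a dilution series: replicate strips at each calibrator level.

    At concentration x the test-line depth is ``control_depth * curve(x)``,
    so ground-truth T/C equals the calibration curve exactly.  Each
    replicate gets an independent noise stream derived from ``seed``.
    """
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(concentrations) * replicates
    ) % (2**31)
    out: list[tuple[float, StripImage, GroundTruth]] = []
    k = 0
    for conc in concentrations:
        tc = float(eval_4pl(curve, conc))
        test_depth = control_depth * tc
        if test_depth >= base_spec.background_level or control_depth >= base_spec.background_level:
            raise ConfigurationError(
                f"depths (test {test_depth:.1f}, control {control_depth:.1f}) must stay "
                f"below background {base_spec.background_level}"
            )
        for _ in range(replicates):
            spec = replace(
                base_spec,
                test_line_depth=test_depth,
                control_line_depth=control_depth,
                seed=int(child_seeds[k]),
            )
            k += 1
            image, truth = render_strip(spec)
            truth = replace(truth, true_concentration=conc)
            out.append((conc, image, truth))
    return out


def log_uniform_sampler(low: float = 100.0, high: float = 1100.0):
    """Concentration sampler: log-uniform over the deficient-to-sufficient
    physiological range (default 100-1100 pmol/L)."""
    if not (0 < low < high):
        raise ConfigurationError("need 0 < low < high")

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.uniform(math.log(low), math.log(high), size=n))

    return sample


def generate_cohort(
    curve: CalibrationCurve,
    n: int,
    analytic_cv: float = 0.10,
    seed: int = 0,
    concentration_sampler=None,
) -> pd.DataFrame:
    """Simulate a measurement cohort against a known calibration.

    Per subject: a reference concentration from the sampler, a measured T/C
    equal to the curve value times multiplicative Gaussian noise of the
    given CV, and the concentration predicted by inverting the same curve
    (with out-of-range clamping flags).  CSV-serialisable.
    """
    if n < 1:
        raise ConfigurationError("cohort size must be >= 1")
    if analytic_cv < 0:
        raise ConfigurationError("analytic_cv must be >= 0")
    sampler = concentration_sampler or log_uniform_sampler()
    rng = np.random.default_rng(seed)
    refs = sampler(rng, n)
    tc_true = np.asarray(eval_4pl(curve, refs), dtype=float)
    factors = 1.0 + rng.normal(0.0, analytic_cv, size=n) if analytic_cv > 0 else np.ones(n)
    tc_measured = np.maximum(tc_true * factors, 1e-12)

    predicted = np.empty(n)
    flags = []
    for i in range(n):
        conc, flag = predict_concentration(curve, float(tc_measured[i]))
        predicted[i] = conc
        flags.append(flag)

    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "reference_pmol_L": refs,
            "tc_true": tc_true,
            "tc_measured": tc_measured,
            "predicted_pmol_L": predicted,
            "flag": flags,
        }
    )
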