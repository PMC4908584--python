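"""Strip-image quantification: the line-densitometry pipeline.

A lateral-flow strip photographed with flow along the vertical axis shows a
light membrane background crossed by two dark transverse lines: the test
line (upstream, nearer the sample inlet) and the control line (downstream).
This module turns such an image into a test/control (T/C) signal ratio:

    smooth -> to_gray -> collapse_profile -> find_minima -> assign_lines
           -> tc_ratio

The 2D image is smoothed with a 3x3 Gaussian, converted to grayscale, and
collapsed to a 1D intensity profile by taking the median of each pixel row.
Lines appear as local minima in that profile; a minimum counts as a line
only if it sits at least ``min_depth`` grayscale units (default 10) below
the nearest enclosing turning point on *both* sides — a bilateral-prominence
criterion that rejects noise wiggles.  The T/C ratio is then the ratio of
the baseline-subtracted line depths, which cancels uniform illumination
offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InputError, InvalidTestError

logger = logging.getLogger(__name__)

# 3x3 binomial approximation to the Gaussian: (1-2-1 outer product) / 16.
_KERNEL_1D = np.array([1.0, 2.0, 1.0]) / 4.0
_KERNEL_3X3 = np.outer(_KERNEL_1D, _KERNEL_1D)

#: ITU-R BT.601 luma weights for RGB -> grayscale.
DEFAULT_GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class StripImage:
    """A strip photograph with its physical scale.

    ``pixels`` is a 2D (grayscale) or HxWx3 (RGB) 8-bit-scale array.  Rows
    index the flow axis; row 0 is the sample-inlet end, so the test line
    sits at a smaller row index than the control line.
    """

    pixels: np.ndarray
    px_per_mm: float = 20.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise InputError(f"expected 2D or 3-channel image, got ndim={self.pixels.ndim}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] not in (1, 3):
            raise InputError(f"unsupported channel count {self.pixels.shape[2]}")
        if self.height < 3 or self.width < 3:
            raise InputError("image must be at least 3x3 for 3x3 filtering")
        if self.px_per_mm <= 0:
            raise InputError("px_per_mm must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass
class GrayProfile:
    """1D grayscale intensity along the flow axis, one value per image row."""

    values: np.ndarray
    px_per_mm: float = 20.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError("profile must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class LineDetection:
    """A detected line: a local profile minimum with its enclosing baselines.

    ``depth`` is the prominence of the minimum: min(left, right baseline)
    minus the minimum intensity.
    """

    index: int
    min_value: float
    left_baseline: float
    right_baseline: float

    @property
    def depth(self) -> float:
        return min(self.left_baseline, self.right_baseline) - self.min_value


@dataclass(frozen=True)
class QuantConfig:
    """Tunable parameters of the quantification pipeline.

    min_depth
        Bilateral prominence threshold in grayscale units; a candidate
        minimum must lie at least this far below the nearest enclosing
        turning point on both sides.
    expected_lines
        Number of lines a valid strip carries (test + control = 2).
    grayscale_weights
        (r, g, b) luma weights; must sum to 1.
    tc_mode
        ``depth_ratio`` (default) ratios baseline-subtracted depths;
        ``raw_min_ratio`` ratios the raw minimum intensities (kept for
        ablation only — raw minima do not cancel illumination offsets).
    roi
        Optional (top, bottom) crop as fractions of image height, for
        photographs that include cassette edges.
    """

    min_depth: float = 10.0
    expected_lines: int = 2
    grayscale_weights: tuple[float, float, float] = DEFAULT_GRAY_WEIGHTS
    tc_mode: str = "depth_ratio"
    roi: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.min_depth <= 0:
            raise InputError("min_depth must be positive")
        if abs(sum(self.grayscale_weights) - 1.0) > 1e-9:
            raise InputError("grayscale weights must sum to 1")
        if self.tc_mode not in ("depth_ratio", "raw_min_ratio"):
            raise InputError(f"unknown tc_mode {self.tc_mode!r}")
        lo, hi = self.roi
        if not (0.0 <= lo < hi <= 1.0):
            raise InputError("roi fractions must satisfy 0 <= top < bottom <= 1")


@dataclass
class AnalysisResult:
    """Output of :func:`analyze`: the T/C ratio plus intermediates."""

    tc: float
    test: LineDetection
    control: LineDetection
    detections: list[LineDetection]
    profile: GrayProfile
    log: list[str] = field(default_factory=list)


def smooth(image: StripImage) -> StripImage:
    """Apply the 3x3 Gaussian (binomial 1-2-1 squared / 16) to each channel.

    Borders are handled by edge replication.  Integer inputs are rounded
    back to their dtype so the 0-255 scale is preserved.
    """
    px = image.pixels
    out = np.empty_like(px, dtype=float)
    if px.ndim == 2:
        ndimage.convolve(px.astype(float), _KERNEL_3X3, output=out, mode="nearest")
    else:
        for ch in range(px.shape[2]):
            ndimage.convolve(
                px[:, :, ch].astype(float), _KERNEL_3X3, output=out[:, :, ch], mode="nearest"
            )
    if np.issubdtype(px.dtype, np.integer):
        out = np.rint(out).astype(px.dtype)
    return StripImage(out, px_per_mm=image.px_per_mm)


def to_gray(image: StripImage, config: QuantConfig | None = None) -> StripImage:
    """Convert to single-channel grayscale using the configured luma weights.

    Single-channel input passes through unchanged.
    """
    if image.n_channels == 1:
        px = image.pixels[:, :, 0] if image.pixels.ndim == 3 else image.pixels
        return StripImage(px, px_per_mm=image.px_per_mm)
    weights = (config or QuantConfig()).grayscale_weights
    gray = np.tensordot(image.pixels.astype(float), np.asarray(weights), axes=([2], [0]))
    if np.issubdtype(image.pixels.dtype, np.integer):
        gray = np.rint(gray).astype(image.pixels.dtype)
    return StripImage(gray, px_per_mm=image.px_per_mm)


def collapse_profile(image: StripImage) -> GrayProfile:
    """Collapse a single-channel image to 1D: entry i = median of row i.

    The row median suppresses speckle and dust far better than the mean,
    turning line detection into a 1D signal-processing problem.  Even-width
    rows use the mean-of-middle-two median convention.
    """
    if image.n_channels != 1:
        raise InputError("collapse_profile requires a single-channel image")
    px = image.pixels if image.pixels.ndim == 2 else image.pixels[:, :, 0]
    if px.shape[1] == 0:
        raise InputError("zero-width rows have no median")
    return GrayProfile(np.median(px.astype(float), axis=1), px_per_mm=image.px_per_mm)


def _walk_to_turning_point(v: np.ndarray, start: int, step: int) -> float:
    """Baseline on one side of a minimum: walk outward while the profile is
    non-decreasing and return the value at the last turning point (a local
    maximum, or the array edge)."""
    j = start
    while 0 <= j + step < len(v) and v[j + step] >= v[j]:
        j += step
    return float(v[j])


def find_minima(profile: GrayProfile, config: QuantConfig | None = None) -> list[LineDetection]:
    """Detect line candidates as prominent local minima of the profile.

    Steps through the profile, collapsing runs of equal values to plateaus;
    a plateau strictly below both neighbouring runs is a local minimum and
    reports its centre index.  For each minimum the enclosing baseline on
    each side is the value at the nearest turning point (the point where the
    profile stops rising as one walks away from the minimum; the array edge
    counts).  The minimum is kept only if it lies at least ``min_depth``
    below that baseline on *both* sides.  Boundary extrema are never
    minima, so a strictly monotone profile yields an empty list.
    """
    config = config or QuantConfig()
    v = profile.values
    n = len(v)
    if n < 3:
        raise InputError("profile must have at least 3 samples")

    # Compress into runs of equal values: (value, first index, last index).
    runs: list[tuple[float, int, int]] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or v[i] != v[start]:
            runs.append((float(v[start]), start, i - 1))
            start = i

    detections: list[LineDetection] = []
    for k in range(1, len(runs) - 1):
        val, s, e = runs[k]
        if runs[k - 1][0] > val and runs[k + 1][0] > val:
            centre = (s + e) // 2
            left = _walk_to_turning_point(v, s, -1)
            right = _walk_to_turning_point(v, e, +1)
            if left - val >= config.min_depth and right - val >= config.min_depth:
                detections.append(
                    LineDetection(index=centre, min_value=val, left_baseline=left, right_baseline=right)
                )
    return detections


def assign_lines(
    detections: list[LineDetection], expected_lines: int = 2
) -> tuple[LineDetection, LineDetection]:
    """Pick the test and control lines from the detected minima.

    The two deepest detections are kept (ties broken toward the upstream,
    smaller-index line); of those, the one nearer the sample-inlet end
    (row 0) is the test line, the other the control line.
    """
    if len(detections) < 2:
        raise InvalidTestError(
            f"only {len(detections)} line(s) detected; a valid strip shows both "
            "test and control lines (control line absent => invalid test)",
            stage="assign_lines",
        )
    if len(detections) > expected_lines:
        logger.warning(
            "%d minima detected where %d lines expected; keeping the %d deepest",
            len(detections), expected_lines, expected_lines,
        )
    top_two = sorted(detections, key=lambda det: (-det.depth, det.index))[:2]
    test, control = sorted(top_two, key=lambda det: det.index)
    return test, control


def tc_ratio(
    test: LineDetection, control: LineDetection, config: QuantConfig | None = None
) -> float:
    """T/C ratio of the two line signals.

    In the default ``depth_ratio`` mode this is test.depth / control.depth:
    the baseline-subtracted depths, so a uniform brightness offset cancels.
    ``raw_min_ratio`` divides the raw minimum intensities instead.
    """
    config = config or QuantConfig()
    if config.tc_mode == "depth_ratio":
        if control.depth <= 0:
            raise InvalidTestError("control line depth is zero", stage="tc_ratio")
        return test.depth / control.depth
    if control.min_value <= 0:
        raise InvalidTestError("control minimum intensity is zero", stage="tc_ratio")
    return test.min_value / control.min_value


def analyze(image: StripImage, config: QuantConfig | None = None) -> AnalysisResult:
    """Full pipeline: image in, T/C ratio out, with a log of intermediates."""
    config = config or QuantConfig()
    log: list[str] = []

    if config.roi != (0.0, 1.0):
        lo = int(round(config.roi[0] * image.height))
        hi = int(round(config.roi[1] * image.height))
        image = StripImage(image.pixels[lo:hi], px_per_mm=image.px_per_mm)
        log.append(f"roi: cropped rows to [{lo}, {hi})")

    smoothed = smooth(image)
    log.append(f"smooth: 3x3 Gaussian applied to {image.height}x{image.width} image")
    gray = to_gray(smoothed, config)
    log.append(f"to_gray: {image.n_channels}-channel -> grayscale")
    profile = collapse_profile(gray)
    log.append(f"collapse_profile: {len(profile)} row medians")
    detections = find_minima(profile, config)
    log.append(
        "find_minima: "
        + (", ".join(f"row {d.index} depth {d.depth:.1f}" for d in detections) or "none")
    )
    try:
        test, control = assign_lines(detections, config.expected_lines)
    except InvalidTestError as err:
        err.stage = "assign_lines"
        raise
    tc = tc_ratio(test, control, config)
    log.append(
        f"tc_ratio ({config.tc_mode}): test row {test.index} depth {test.depth:.2f}, "
        f"control row {control.index} depth {control.depth:.2f}, T/C = {tc:.4f}"
    )
    return AnalysisResult(tc=tc, test=test, control=control, detections=detections,
                          profile=profile, log=log)
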