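"""Laser speckle contrast imaging: from raw frames to percent blood flow.

Processing chain (the order is fixed): per-frame spatial contrast in a
5x5 sliding window -> average 25 consecutive contrast frames -> convert
to the 1/K^2 flow index -> Gaussian smooth (sigma = 7 px) -> ROI mean and
standard deviation -> normalise to the individual baseline -> classify
the response against the 20 % physiological-variation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .synthetic import GroundTruthFlowExperiment, SpeckleMovie

__all__ = [
    "ContrastMap",
    "FlowMap",
    "ROISpec",
    "FlowTimeSeries",
    "SafetyLabel",
    "spatial_contrast",
    "frame_contrast",
    "average_contrast",
    "contrast_to_flow",
    "smooth_flow",
    "roi_statistics",
    "normalize_to_baseline",
    "classify_flow_response",
    "relative_change",
    "process_movie",
    "flow_timeseries_from_experiment",
]

PHYSIOLOGICAL = "physiological"
REVERSIBLE = "reversible-drop"
IRREVERSIBLE = "irreversible-drop"


@dataclass
class ContrastMap:
    """Per-pixel speckle contrast K = sigma/mu with a validity mask."""

    values: np.ndarray
    mask: np.ndarray  # True where the value is invalid
    window_px: int
    n_frames_averaged: int = 1


@dataclass
class FlowMap:
    """Per-pixel flow index (1/K^2)."""

    values: np.ndarray
    mask: np.ndarray
    sigma_smooth_px: float | None = None
    n_zero_contrast: int = 0


@dataclass(frozen=True)
class ROISpec:
    """Half-open rectangular region of interest (row0:row0+height, ...)."""

    row0: int = 0
    col0: int = 0
    height: int = 200
    width: int = 200

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0 or self.height < 1 or self.width < 1:
            raise ValueError("ROI must have non-negative origin and positive size")

    def validate_within(self, shape: tuple[int, int]) -> None:
        if self.row0 + self.height > shape[0] or self.col0 + self.width > shape[1]:
            raise ValueError(f"ROI {self} does not fit inside image of shape {shape}")

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )


@dataclass
class FlowTimeSeries:
    """Ordered ROI flow statistics, normalised to an individual baseline."""

    entries: list[tuple[str, float, float]]  # (label, roi_mean, roi_sd)
    baseline_label: str
    percent_of_baseline: dict[str, float] = field(default_factory=dict)

    def labels(self) -> list[str]:
        return [label for label, _, _ in self.entries]


@dataclass(frozen=True)
class SafetyLabel:
    """Three-way perfusion-safety classification of a flow time series."""

    label: str
    threshold_percent: float = 20.0

    def __post_init__(self) -> None:
        if self.label not in (PHYSIOLOGICAL, REVERSIBLE, IRREVERSIBLE):
            raise ValueError(f"unknown label {self.label!r}")
        if not (0.0 < self.threshold_percent < 100.0):
            raise ValueError("threshold must lie in (0, 100)")


def spatial_contrast(frame: np.ndarray, window_px: int = 5) -> ContrastMap:
    """Spatial speckle contrast in a sliding window.

    K is the ratio of the sample (n-1) standard deviation to the mean of
    the intensities inside an odd ``window_px`` x ``window_px`` window,
    evaluated at every pixel with reflective edge padding.  Pixels whose
    window mean falls below a guard threshold (1e-12 of the frame
    maximum) are masked rather than divided.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if window_px % 2 == 0 or window_px < 3:
        raise ValueError(f"window must be odd and >= 3, got {window_px}")
    if min(frame.shape) < window_px:
        raise ValueError("frame smaller than the contrast window")

    # two-pass windowed statistics (mean, then squared deviations): free of
    # the catastrophic cancellation a one-pass E[x^2] - E[x]^2 would suffer
    pad = window_px // 2
    padded = np.pad(frame, pad, mode="symmetric")
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (window_px, window_px)
    )
    mean = windows.mean(axis=(-2, -1))
    sd = windows.std(axis=(-2, -1), ddof=1)

    guard = 1e-12 * float(frame.max()) if frame.max() > 0 else 0.0
    mask = mean <= guard
    if mask.all():
        import warnings

        warnings.warn("all-zero frame: contrast undefined everywhere", stacklevel=2)
    values = np.zeros_like(frame)
    np.divide(sd, mean, out=values, where=~mask)
    return ContrastMap(values, mask, window_px)


def frame_contrast(frame: np.ndarray, roi: ROISpec | None = None) -> float:
    """Single global contrast sigma/mu over a frame (or an ROI of it).

    Used for physics validation against the finite-exposure contrast
    model; unlike the small-window map it carries no correlated-sample
    bias on a frame much larger than the speckle grain.
    """
    frame = np.asarray(frame, dtype=float)
    if roi is not None:
        roi.validate_within(frame.shape)
        frame = frame[roi.slices()]
    mu = float(frame.mean())
    if mu <= 0:
        raise ValueError("frame mean must be positive")
    return float(frame.std(ddof=1)) / mu


def average_contrast(maps: Sequence[ContrastMap], n: int = 25) -> ContrastMap:
    """Element-wise mean of the first ``n`` contrast maps (mask = union)."""
    if len(maps) < n:
        raise ValueError(f"need at least {n} maps, got {len(maps)}")
    first = maps[0]
    shape = first.values.shape
    for m in maps[:n]:
        if m.values.shape != shape:
            raise ValueError("contrast maps must share a common shape")
    values = np.mean([m.values for m in maps[:n]], axis=0)
    mask = np.logical_or.reduce([m.mask for m in maps[:n]])
    return ContrastMap(values, mask, first.window_px, n_frames_averaged=n)


def contrast_to_flow(cmap: ContrastMap) -> FlowMap:
    """Convert contrast to the conventional 1/K^2 flow index.

    Zero-contrast pixels cannot be inverted; they join the mask and their
    count is reported on the result.
    """
    if cmap.mask.all():
        raise ValueError("contrast map has no unmasked pixels")
    zero = (cmap.values == 0) & ~cmap.mask
    mask = cmap.mask | zero
    values = np.zeros_like(cmap.values)
    np.divide(1.0, cmap.values**2, out=values, where=~mask)
    return FlowMap(values, mask, n_zero_contrast=int(zero.sum()))


def smooth_flow(fmap: FlowMap, sigma_px: float = 7.0) -> FlowMap:
    """Gaussian smoothing of the flow map (reflective boundaries).

    Masked pixels are replaced by the mean of the valid pixels before
    convolution so they do not drag the neighbourhood down; the mask
    itself is preserved.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    values = fmap.values
    if fmap.mask.any():
        fill = float(values[~fmap.mask].mean())
        values = np.where(fmap.mask, fill, values)
    smoothed = ndimage.gaussian_filter(values, sigma_px, mode="reflect")
    return FlowMap(
        smoothed,
        fmap.mask.copy(),
        sigma_smooth_px=sigma_px,
        n_zero_contrast=fmap.n_zero_contrast,
    )


def roi_statistics(fmap: FlowMap, roi: ROISpec) -> tuple[float, float]:
    """Mean and sample standard deviation over the unmasked ROI pixels."""
    roi.validate_within(fmap.values.shape)
    sl = roi.slices()
    vals = fmap.values[sl][~fmap.mask[sl]]
    if vals.size < 2:
        raise ValueError("ROI contains fewer than 2 unmasked pixels")
    return float(vals.mean()), float(vals.std(ddof=1))


def normalize_to_baseline(
    entries: Sequence[tuple[str, float, float]] | Mapping[str, tuple[float, float]],
    baseline_label: str = "baseline",
) -> FlowTimeSeries:
    """Express ROI-mean flow at every timepoint as percent of baseline."""
    if isinstance(entries, Mapping):
        entries = [(k, v[0], v[1]) for k, v in entries.items()]
    else:
        entries = [(label, float(m), float(s)) for label, m, s in entries]
    labels = [label for label, _, _ in entries]
    if baseline_label not in labels:
        raise ValueError(f"baseline label {baseline_label!r} not present")
    baseline = dict((label, m) for label, m, _ in entries)[baseline_label]
    if baseline <= 0:
        raise ValueError("baseline flow must be positive")
    percent = {label: 100.0 * m / baseline for label, m, _ in entries}
    percent[baseline_label] = 100.0  # exact, immune to rounding of m / m
    return FlowTimeSeries(list(entries), baseline_label, percent)


def classify_flow_response(
    series: FlowTimeSeries,
    final_label: str,
    threshold_percent: float = 20.0,
) -> SafetyLabel:
    """Three-way safety classification of a baseline-normalised series.

    A change within ``threshold_percent`` of baseline is physiological
    (flow changes of up to 20 % occur without any intervention).  A drop
    below the threshold that has recovered by the final timepoint is a
    reversible drop; a final value still below it is irreversible.  The
    boundary (exactly 100 - threshold) is inclusive: it counts as within
    the normal range.
    """
    if final_label not in series.percent_of_baseline:
        raise ValueError(f"final label {final_label!r} not in series")
    floor = 100.0 - threshold_percent
    final = series.percent_of_baseline[final_label]
    if final < floor:
        label = IRREVERSIBLE
    elif any(p < floor for p in series.percent_of_baseline.values()):
        label = REVERSIBLE
    else:
        label = PHYSIOLOGICAL
    return SafetyLabel(label, threshold_percent)


def relative_change(
    old_value: float, new_value: float, reference: str = "old"
) -> float:
    """Percent change 100 * (new - old) / reference.

    ``reference`` selects which of the two values the change is expressed
    against ('old' or 'new').  E.g. 3.1 -> 4.0 um is +29 % of the old
    diameter; 20e6 -> 10e6 capsules is -50 %.
    """
    if old_value <= 0 or new_value <= 0:
        raise ValueError("both values must be positive")
    if reference == "old":
        ref = old_value
    elif reference == "new":
        ref = new_value
    else:
        raise ValueError("reference must be 'old' or 'new'")
    return 100.0 * (new_value - old_value) / ref


# ---------------------------------------------------------------------------
# whole-movie convenience chain
# ---------------------------------------------------------------------------

def process_movie(
    movie: SpeckleMovie,
    roi: ROISpec,
    window_px: int = 5,
    n_average: int = 25,
    sigma_px: float = 7.0,
) -> tuple[float, float]:
    """Full per-movie chain: contrast -> average -> flow -> smooth -> ROI.

    Returns the ROI mean and sample SD of the smoothed flow index.
    """
    maps = [spatial_contrast(f, window_px) for f in movie.frames]
    avg = average_contrast(maps, n=min(n_average, len(maps)))
    flow = smooth_flow(contrast_to_flow(avg), sigma_px)
    return roi_statistics(flow, roi)


def flow_timeseries_from_experiment(
    experiment: GroundTruthFlowExperiment,
    roi: ROISpec,
    window_px: int = 5,
    n_average: int = 25,
    sigma_px: float = 7.0,
) -> FlowTimeSeries:
    """Run the full chain on every timepoint movie and normalise."""
    entries = []
    for label, movie in experiment.movies.items():
        mean, sd = process_movie(movie, roi, window_px, n_average, sigma_px)
        entries.append((label, mean, sd))
    return normalize_to_baseline(entries, experiment.baseline_label)
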