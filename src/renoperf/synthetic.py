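"""Synthetic generators for every input the perfusion pipeline consumes.

Each generator carries its ground truth alongside the data it emits, so
downstream estimators (speckle-contrast flow, band alteration, %ID
recovery, calibration quantification) can be validated against known
answers.  The statistical structure mirrors what the corresponding
instruments produce:

* fully developed dynamic speckle with a controllable field decorrelation
  time ``tau_c`` and finite-exposure integration,
* ex vivo organ fluorescence tables with additive per-area
  autofluorescence and multiplicative log-normal measurement noise,
* broadband band-limited acoustic noise signals,
* linear-response plate-reader emission spectra peaking at 785 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ORGANS",
    "DEFAULT_ORGAN_AREAS",
    "CapsuleSizeSample",
    "SpeckleSimConfig",
    "SpeckleMovie",
    "GroundTruthFlowExperiment",
    "OrganFluorescenceTable",
    "PASignal",
    "FluorimetryPlate",
    "simulate_capsule_sizes",
    "fit_gaussian_to_sizes",
    "simulate_speckle_movie",
    "simulate_flow_experiment",
    "simulate_organ_tables",
    "simulate_pa_signal",
    "simulate_fluorimetry_plate",
]

#: Dissection panel used in the ex vivo biodistribution workflow.
ORGANS = (
    "left kidney",
    "right kidney",
    "lungs",
    "heart",
    "liver",
    "spleen",
    "stomach",
    "intestines",
    "appendix",
)

#: Plausible relative image areas (arbitrary units) per organ; used when the
#: caller does not supply areas.  Only ratios matter for the correction.
DEFAULT_ORGAN_AREAS: dict[str, float] = {
    "left kidney": 1.2,
    "right kidney": 1.2,
    "lungs": 1.5,
    "heart": 0.8,
    "liver": 3.0,
    "spleen": 0.6,
    "stomach": 1.0,
    "intestines": 4.0,
    "appendix": 0.4,
}


# ---------------------------------------------------------------------------
# capsule size distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CapsuleSizeSample:
    """Diameters (um) drawn from a zero-truncated normal law."""

    diameters: np.ndarray
    nominal_mean: float
    nominal_sd: float
    seed: int

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("diameters must be a non-empty 1-D array")
        if not np.all(d > 0):
            raise ValueError("all diameters must be positive")
        object.__setattr__(self, "diameters", d)


def simulate_capsule_sizes(
    n: int, mean_um: float, sd_um: float, seed: int = 0
) -> CapsuleSizeSample:
    """Draw ``n`` microcapsule diameters from N(mean, sd) truncated at 0.

    ``sd_um = 0`` degenerates to a point mass at ``mean_um``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if mean_um <= 0:
        raise ValueError(f"mean_um must be positive, got {mean_um}")
    if sd_um < 0:
        raise ValueError(f"sd_um must be non-negative, got {sd_um}")
    rng = np.random.default_rng(seed)
    if sd_um == 0:
        d = np.full(n, float(mean_um))
    else:
        a = (0.0 - mean_um) / sd_um  # truncate at zero diameter
        d = stats.truncnorm.rvs(
            a, np.inf, loc=mean_um, scale=sd_um, size=n, random_state=rng
        )
    return CapsuleSizeSample(d, float(mean_um), float(sd_um), seed)


def fit_gaussian_to_sizes(
    sample: CapsuleSizeSample, n_bins: int = 20
) -> tuple[float, float]:
    """Least-squares Gaussian fit to the binned size histogram.

    Returns the fitted ``(mu, sigma)`` in micrometres.  Raises
    ``RuntimeError`` for degenerate (all-equal) samples on which the fit
    cannot converge.
    """
    d = sample.diameters
    if d.size < 10:
        raise ValueError("need at least 10 diameters to fit a histogram")
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    if np.ptp(d) == 0:
        raise RuntimeError("degenerate sample: all diameters equal; fit does not converge")
    counts, edges = np.histogram(d, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, amp, mu, sigma):
        return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    # keep the fit physical: center inside the data range, width at most
    # the data span (spike-like histograms otherwise send sigma to infinity)
    p0 = (counts.max(), d.mean(), max(d.std(ddof=1), 1e-6 * np.ptp(d)))
    bounds = (
        [0.0, d.min(), 1e-9 * np.ptp(d)],
        [np.inf, d.max(), np.ptp(d)],
    )
    try:
        popt, _ = optimize.curve_fit(
            gauss, centers, counts, p0=p0, bounds=bounds, maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - curve_fit failure path
        raise RuntimeError(f"Gaussian fit did not converge: {exc}") from exc
    return float(popt[1]), float(abs(popt[2]))


# ---------------------------------------------------------------------------
# dynamic speckle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeckleSimConfig:
    """Parameters of the dynamic-speckle camera model.

    ``exposure_ms``/``fps`` default to the acquisition settings of the
    imaging system the pipeline targets (10 ms at 30 frames per second).
    ``tau_c_ms`` is the field decorrelation time; ``math.inf`` means a
    static scatterer.  ``n_subframes`` instantaneous speckle fields are
    averaged per exposure; choose at least ``4 * exposure_ms / tau_c_ms``
    for an accurate finite-exposure integral.  ``beta`` is the coherence
    (contrast-reduction) factor and ``speckle_grain_px`` the minimum
    speckle diameter in pixels (>= 2 keeps the pattern Nyquist-sampled).
    """

    frame_height: int = 256
    frame_width: int = 256
    n_frames: int = 25
    exposure_ms: float = 10.0
    fps: float = 30.0
    tau_c_ms: float = 1.0
    n_subframes: int = 8
    beta: float = 1.0
    speckle_grain_px: float = 2.0
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_height < 8 or self.frame_width < 8:
            raise ValueError("frame dimensions must be at least 8 px")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.exposure_ms > 1000.0 / self.fps:
            raise ValueError(
                f"exposure ({self.exposure_ms} ms) exceeds the frame period "
                f"({1000.0 / self.fps:.3f} ms at {self.fps} fps)"
            )
        if self.tau_c_ms <= 0:
            raise ValueError("tau_c_ms must be positive (use math.inf for static)")
        if self.n_subframes < 1:
            raise ValueError("n_subframes must be >= 1")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must lie in (0, 1]")
        if self.speckle_grain_px < 2.0:
            raise ValueError("speckle_grain_px must be >= 2 (Nyquist sampling)")

    @property
    def static(self) -> bool:
        return math.isinf(self.tau_c_ms)


@dataclass
class SpeckleMovie:
    """Stack of speckle frames plus the acquisition metadata."""

    frames: np.ndarray  # (n_frames, H, W), non-negative float
    exposure_ms: float
    fps: float
    provenance: SpeckleSimConfig | str = "measured"

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3:
            raise ValueError("frames must be a (frame, row, col) stack")
        if not np.all(np.isfinite(f)) or f.min() < 0:
            raise ValueError("intensities must be finite and non-negative")
        self.frames = f


def _pupil_mask(h: int, w: int, grain_px: float) -> np.ndarray:
    """Circular pupil in the FFT plane giving the requested speckle grain."""
    n = min(h, w)
    radius = n / (2.0 * grain_px)
    fy = np.fft.fftfreq(h) * h
    fx = np.fft.fftfreq(w) * w
    r2 = fy[:, None] ** 2 + fx[None, :] ** 2
    return r2 <= radius**2


def _speckle_field(rng: np.random.Generator, mask: np.ndarray) -> np.ndarray:
    """One circular-Gaussian speckle field with unit mean intensity."""
    h, w = mask.shape
    a = rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))
    field = np.fft.ifft2(a * mask)
    # ifft2 scales by 1/(h*w); renormalise so E[|field|^2] = 1 exactly.
    n_open = int(mask.sum())
    field *= (h * w) / math.sqrt(2.0 * n_open)
    return field


def simulate_speckle_movie(cfg: SpeckleSimConfig) -> SpeckleMovie:
    """Simulate a camera movie of fully developed dynamic speckle.

    The complex field is a circular-Gaussian process on a Fourier-limited
    grid (random spectrum inside a circular pupil).  Time evolution is a
    first-order autoregression ``E <- rho E + sqrt(1 - rho^2) E_new`` with
    ``rho = exp(-dt / tau_c)``, giving the exponential field correlation
    ``g1(t) = exp(-t / tau_c)``.  Each stored frame is the mean of
    ``n_subframes`` instantaneous intensities spread over the exposure,
    which reproduces the classical finite-exposure contrast curve

        K^2 = beta * (exp(-2x) - 1 + 2x) / (2 x^2),   x = T / tau_c.

    ``beta < 1`` is modelled by an incoherent constant pedestal that
    rescales the contrast by ``sqrt(beta)`` without touching the dynamics.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.frame_height, cfg.frame_width
    mask = _pupil_mask(h, w, cfg.speckle_grain_px)
    frames = np.empty((cfg.n_frames, h, w), dtype=float)

    if cfg.static:
        field = _speckle_field(rng, mask)
        intensity = np.abs(field) ** 2
        frames[:] = intensity  # identical frames: nothing decorrelates
    else:
        dt_sub = cfg.exposure_ms / cfg.n_subframes
        rho_sub = math.exp(-dt_sub / cfg.tau_c_ms)
        gap_ms = 1000.0 / cfg.fps - cfg.exposure_ms
        rho_gap = math.exp(-gap_ms / cfg.tau_c_ms) if gap_ms > 0 else 1.0
        mix_sub = math.sqrt(1.0 - rho_sub**2)
        mix_gap = math.sqrt(1.0 - rho_gap**2)
        field = _speckle_field(rng, mask)
        for k in range(cfg.n_frames):
            acc = np.zeros((h, w), dtype=float)
            for _ in range(cfg.n_subframes):
                acc += np.abs(field) ** 2
                field = rho_sub * field + mix_sub * _speckle_field(rng, mask)
            frames[k] = acc / cfg.n_subframes
            if rho_gap < 1.0:
                field = rho_gap * field + mix_gap * _speckle_field(rng, mask)

    if cfg.beta < 1.0:
        # constant pedestal c so that K -> K / (1 + c) = K * sqrt(beta)
        frames += 1.0 / math.sqrt(cfg.beta) - 1.0
    if cfg.read_noise_sd > 0:
        frames = np.clip(
            frames + rng.normal(0.0, cfg.read_noise_sd, frames.shape), 0.0, None
        )
    return SpeckleMovie(frames, cfg.exposure_ms, cfg.fps, provenance=cfg)


@dataclass
class GroundTruthFlowExperiment:
    """Per-timepoint speckle movies with the true relative flows recorded."""

    movies: dict[str, SpeckleMovie]
    true_relative_flow: dict[str, float]
    baseline_label: str = "baseline"

    def __post_init__(self) -> None:
        if self.baseline_label not in self.movies:
            raise ValueError(f"missing baseline movie {self.baseline_label!r}")
        if self.true_relative_flow.get(self.baseline_label) != 1.0:
            raise ValueError("baseline true relative flow must equal 1.0")


def simulate_flow_experiment(
    baseline_tau_c_ms: float,
    relative_flows: Mapping[str, float],
    cfg: SpeckleSimConfig,
    baseline_label: str = "baseline",
) -> GroundTruthFlowExperiment:
    """Simulate one animal's speckle movies across timepoints.

    Relative flow is mapped onto the decorrelation time through the
    single-scattering assumption ``flow = baseline_tau_c / tau_c``: halving
    the flow doubles ``tau_c``.  Each timepoint gets an independent seed
    derived from ``cfg.seed``.
    """
    if baseline_label not in relative_flows:
        raise ValueError(f"relative_flows must contain {baseline_label!r}")
    if relative_flows[baseline_label] != 1.0:
        raise ValueError("baseline relative flow must be 1.0")
    if any(v <= 0 for v in relative_flows.values()):
        raise ValueError("all relative flows must be positive")
    if baseline_tau_c_ms <= 0:
        raise ValueError("baseline_tau_c_ms must be positive")
    children = np.random.SeedSequence(cfg.seed).spawn(len(relative_flows))
    movies: dict[str, SpeckleMovie] = {}
    for (label, flow), child in zip(relative_flows.items(), children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        sub_cfg = replace(cfg, tau_c_ms=baseline_tau_c_ms / flow, seed=sub_seed)
        movies[label] = simulate_speckle_movie(sub_cfg)
    return GroundTruthFlowExperiment(
        movies, dict(relative_flows), baseline_label=baseline_label
    )


# ---------------------------------------------------------------------------
# organ fluorescence tables
# ---------------------------------------------------------------------------

@dataclass
class OrganFluorescenceTable:
    """Per-organ total radiant efficiency (TRE) and image area.

    ``data`` has columns ``organ``, ``tre`` (photons/s per illumination
    unit), ``area`` (arbitrary area units).  ``truth`` optionally records
    the simulated true %ID per organ.
    """

    data: pd.DataFrame
    group: str  # "experimental" | "control"
    truth: dict[str, float] | None = None

    def __post_init__(self) -> None:
        required = {"organ", "tre", "area"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"table needs columns {sorted(required)}")
        organs = self.data["organ"]
        if organs.duplicated().any():
            raise ValueError("organ names must be unique within a table")
        unknown = set(organs) - set(ORGANS)
        if unknown:
            raise ValueError(f"unknown organs: {sorted(unknown)}")
        if (self.data["tre"] < 0).any():
            raise ValueError("tre must be non-negative")
        if (self.data["area"] <= 0).any():
            raise ValueError("area must be positive")
        if self.group not in ("experimental", "control"):
            raise ValueError("group must be 'experimental' or 'control'")


def simulate_organ_tables(
    true_percent_id: Mapping[str, float],
    autofl_per_area: float = 1.0e6,
    areas: Mapping[str, float] | None = None,
    noise_cv: float = 0.05,
    signal_tre_total: float = 5.0e7,
    seed: int = 0,
) -> tuple[OrganFluorescenceTable, OrganFluorescenceTable]:
    """Simulate matched experimental and control dissection tables.

    Control TRE is pure autofluorescence, ``autofl_per_area * area``;
    experimental TRE adds a dye signal proportional to the organ's true
    %ID (``signal_tre_total`` spread according to ``true_percent_id``).
    Noise is multiplicative log-normal with coefficient of variation
    ``noise_cv`` (fluorescence readouts are positive and right-skewed).
    """
    if areas is None:
        areas = DEFAULT_ORGAN_AREAS
    organs = list(true_percent_id)
    if any(v < 0 for v in true_percent_id.values()):
        raise ValueError("%ID entries must be non-negative")
    total = sum(true_percent_id.values())
    if abs(total - 100.0) > 1e-9:
        raise ValueError(f"true %ID must sum to 100, got {total}")
    if any(areas[o] <= 0 for o in organs):
        raise ValueError("all areas must be positive")

    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        mu = -0.5 * sigma**2  # unit-mean log-normal

        def noise(n: int) -> np.ndarray:
            return rng.lognormal(mu, sigma, n)
    else:

        def noise(n: int) -> np.ndarray:
            return np.ones(n)

    area = np.array([areas[o] for o in organs])
    autofl = autofl_per_area * area
    signal = signal_tre_total * np.array([true_percent_id[o] for o in organs]) / 100.0
    exp_tre = signal * noise(len(organs)) + autofl * noise(len(organs))
    ctrl_tre = autofl * noise(len(organs))
    exp_df = pd.DataFrame({"organ": organs, "tre": exp_tre, "area": area})
    ctrl_df = pd.DataFrame({"organ": organs, "tre": ctrl_tre, "area": area})
    truth = {o: float(true_percent_id[o]) for o in organs}
    return (
        OrganFluorescenceTable(exp_df, "experimental", truth=truth),
        OrganFluorescenceTable(ctrl_df, "control"),
    )


# ---------------------------------------------------------------------------
# broadband acoustic signals
# ---------------------------------------------------------------------------

@dataclass
class PASignal:
    """Broadband acoustic trace with its sampling rate."""

    samples: np.ndarray
    fs: float  # Hz
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.samples = s


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, f_lo: float, f_hi: float, rms: float
) -> np.ndarray:
    """Gaussian noise spectrally confined to (f_lo, f_hi], scaled to ``rms``."""
    if rms == 0:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < f_lo) | (f > f_hi)] = 0.0
    x = np.fft.irfft(spec, n)
    cur = math.sqrt(float(np.mean(x**2)))
    return x * (rms / cur)


def simulate_pa_signal(
    amp_low: float,
    amp_high: float,
    fs: float = 250e6,
    duration: float = 20e-6,
    seed: int = 0,
    timepoint_label: str = "",
    f_split: float = 33e6,
    f_min: float = 11e6,
    f_max: float = 99e6,
) -> PASignal:
    """Two-band synthetic optoacoustic trace.

    The signal is a sum of two independent band-limited Gaussian noise
    processes with RMS amplitudes ``amp_low`` on (``f_min``, ``f_split``]
    and ``amp_high`` on (``f_split``, ``f_max``], mirroring the
    large-vessel (11-33 MHz) / capillary (33-99 MHz) decomposition.
    """
    if fs <= 2 * f_max:
        raise ValueError(f"fs = {fs:g} Hz is below Nyquist for {f_max:g} Hz content")
    if amp_low < 0 or amp_high < 0:
        raise ValueError("band amplitudes must be non-negative")
    n = int(round(fs * duration))
    if n < 64:
        raise ValueError("duration too short: need at least 64 samples")
    rng = np.random.default_rng(seed)
    low = _band_limited_noise(rng, n, fs, f_min, f_split, amp_low)
    high = _band_limited_noise(rng, n, fs, f_split, f_max, amp_high)
    return PASignal(low + high, fs, timepoint_label)


# ---------------------------------------------------------------------------
# plate-reader fluorimetry
# ---------------------------------------------------------------------------

@dataclass
class FluorimetryPlate:
    """Plate-reader emission spectra with known standard and sample masses.

    ``wavelengths`` is the 770-840 nm grid (1 nm step).  ``wells`` maps a
    well id to its emission spectrum; ``standards`` maps calibration wells
    to their known dye-conjugate masses; ``samples`` maps sample wells to
    the simulated true mass (ground truth, absent for measured plates).
    """

    wavelengths: np.ndarray
    wells: dict[str, np.ndarray]
    standards: dict[str, float]
    samples: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if 785.0 not in wl:
            raise ValueError("wavelength grid must contain 785 nm")
        for well, spec in self.wells.items():
            if len(spec) != len(wl):
                raise ValueError(f"well {well!r}: spectrum length mismatch")
        self.wavelengths = wl

    def replicate_wells(self, sample: str) -> list[str]:
        """Well ids of the replicates of logical sample ``sample``."""
        return sorted(w for w in self.wells if w.startswith(f"{sample}_r"))


def simulate_fluorimetry_plate(
    standard_masses: list[float],
    sample_masses: list[float],
    slope: float = 100.0,
    intercept: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 5,
    peak_nm: float = 785.0,
    peak_width_nm: float = 18.0,
) -> FluorimetryPlate:
    """Simulate a 96-well calibration/quantification plate.

    Emission spectra are Gaussian-shaped around 785 nm; the intensity at
    785 nm follows ``intercept + slope * mass`` plus Gaussian noise.  Each
    sample occupies ``n_replicates`` wells (the digest protocol splits one
    homogenate across 5 wells); standards occupy one well each.
    """
    if len(set(standard_masses)) < 3:
        raise ValueError("need at least 3 distinct standard masses")
    if slope <= 0:
        raise ValueError("slope must be positive")
    rng = np.random.default_rng(seed)
    wl = np.arange(770.0, 841.0)
    shape = np.exp(-0.5 * ((wl - peak_nm) / peak_width_nm) ** 2)

    wells: dict[str, np.ndarray] = {}
    standards: dict[str, float] = {}
    samples: dict[str, float] = {}

    def emit(mass: float) -> np.ndarray:
        amp = intercept + slope * mass + rng.normal(0.0, noise_sd)
        return amp * shape

    for i, m in enumerate(standard_masses, start=1):
        well = f"STD{i}"
        wells[well] = emit(m)
        standards[well] = float(m)
    for i, m in enumerate(sample_masses, start=1):
        name = f"S{i}"
        samples[name] = float(m)
        for r in range(1, n_replicates + 1):
            wells[f"{name}_r{r}"] = emit(m)
    return FluorimetryPlate(wl, wells, standards, samples)
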