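"""Biodistribution quantification: organ %ID and calibrated dye mass.

Two complementary routes to the percent of injected dose (%ID):

* imaging route — ex vivo organ fluorescence (total radiant efficiency,
  TRE) corrected for autofluorescence using control-animal organs scaled
  by organ area, then expressed as each organ's share of the corrected
  total;
* digest route — enzymatic kidney digests read on a plate reader, with
  the 785 nm emission intensity mapped to dye-conjugate mass through a
  linear calibration line, and %ID taken against the injected mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import FluorimetryPlate, OrganFluorescenceTable

__all__ = [
    "CalibrationCurve",
    "KidneyQuantResult",
    "correct_autofluorescence",
    "percent_id_from_tre",
    "fit_calibration",
    "calibration_from_plate",
    "mass_from_spectrum",
    "mass_from_plate",
    "percent_id_injected",
    "assemble_timecourse",
    "kidney_ratio",
]

CALIBRATION_WAVELENGTH_NM = 785.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map intensity = intercept + slope * mass at 785 nm."""

    slope: float
    intercept: float
    r_squared: float
    n_standards: int
    wavelength_nm: float = CALIBRATION_WAVELENGTH_NM

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("a valid calibration curve has positive slope")
        if self.n_standards < 3:
            raise ValueError("calibration needs at least 3 standards")


@dataclass(frozen=True)
class KidneyQuantResult:
    """Digest-route quantification of one kidney sample."""

    mass_in_sample: float
    mass_injected: float
    clamped: bool = False

    @property
    def percent_id(self) -> float:
        return percent_id_injected(self.mass_in_sample, self.mass_injected)


# ---------------------------------------------------------------------------
# imaging route
# ---------------------------------------------------------------------------

def correct_autofluorescence(
    experimental: OrganFluorescenceTable, control: OrganFluorescenceTable
) -> pd.DataFrame:
    """Subtract area-scaled control autofluorescence per organ.

    corrected = TRE_exp - (TRE_ctrl / Area_ctrl) * Area_exp: the control
    organ's TRE per unit area, scaled to the experimental organ's area,
    estimates that organ's autofluorescence.  Negative corrections are
    clamped to zero and flagged.  Returns columns ``organ``,
    ``corrected_tre``, ``clamped``.
    """
    exp = experimental.data.set_index("organ")
    ctrl = control.data.set_index("organ")
    missing = set(exp.index) - set(ctrl.index)
    if missing:
        raise ValueError(f"control table lacks organs {sorted(missing)}")
    ctrl = ctrl.loc[exp.index]
    if (ctrl["area"] <= 0).any():
        raise ValueError("control areas must be positive")
    raw = exp["tre"] - (ctrl["tre"] / ctrl["area"]) * exp["area"]
    clamped = raw < 0
    return pd.DataFrame(
        {
            "organ": exp.index,
            "corrected_tre": np.clip(raw.to_numpy(), 0.0, None),
            "clamped": clamped.to_numpy(),
        }
    ).reset_index(drop=True)


def percent_id_from_tre(corrected: pd.DataFrame) -> pd.DataFrame:
    """Each organ's share of the corrected-TRE total, as percent.

    The rows sum to 100 by construction; an all-zero table leaves the
    normalisation undefined and is rejected.
    """
    if "corrected_tre" not in corrected.columns:
        raise ValueError("expected a corrected-TRE table")
    total = float(corrected["corrected_tre"].sum())
    if total <= 0:
        raise ValueError(
            "all corrected TREs are zero: %ID normalisation is undefined"
        )
    return pd.DataFrame(
        {
            "organ": corrected["organ"],
            "percent_id": 100.0 * corrected["corrected_tre"] / total,
        }
    )


# ---------------------------------------------------------------------------
# digest route
# ---------------------------------------------------------------------------

def fit_calibration(
    masses: Sequence[float], intensities: Sequence[float]
) -> CalibrationCurve:
    """Ordinary least-squares calibration line through (mass, I_785) pairs."""
    masses = np.asarray(masses, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if masses.size < 3:
        raise ValueError("need at least 3 standards")
    if np.unique(masses).size < 2:
        raise ValueError("standards must span at least 2 distinct masses")
    fit = stats.linregress(masses, intensities)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_standards=int(masses.size),
    )


def _intensity_at_785(plate: FluorimetryPlate, well: str) -> float:
    idx = int(np.flatnonzero(plate.wavelengths == CALIBRATION_WAVELENGTH_NM)[0])
    return float(plate.wells[well][idx])


def calibration_from_plate(plate: FluorimetryPlate) -> CalibrationCurve:
    """Fit the calibration line from a plate's standard wells."""
    wells = sorted(plate.standards)
    masses = [plate.standards[w] for w in wells]
    intensities = [_intensity_at_785(plate, w) for w in wells]
    return fit_calibration(masses, intensities)


def mass_from_spectrum(
    wavelengths: np.ndarray,
    spectra: Sequence[np.ndarray],
    curve: CalibrationCurve,
) -> tuple[float, bool]:
    """Dye mass from replicate emission spectra via the calibration line.

    The replicate wells' intensities at 785 nm are averaged *before*
    inversion, then mass = (I - intercept) / slope.  A negative mass is
    clamped to zero and flagged.  Returns ``(mass, clamped)``.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    hits = np.flatnonzero(wavelengths == CALIBRATION_WAVELENGTH_NM)
    if hits.size == 0:
        raise ValueError("785 nm missing from the wavelength grid")
    idx = int(hits[0])
    if not spectra:
        raise ValueError("need at least one replicate spectrum")
    intensity = float(np.mean([np.asarray(s, dtype=float)[idx] for s in spectra]))
    mass = (intensity - curve.intercept) / curve.slope
    if mass < 0:
        return 0.0, True
    return mass, False


def mass_from_plate(
    plate: FluorimetryPlate, sample: str, curve: CalibrationCurve
) -> tuple[float, bool]:
    """Quantify one logical sample from its replicate wells on a plate."""
    wells = plate.replicate_wells(sample)
    if not wells:
        raise ValueError(f"plate has no replicate wells for sample {sample!r}")
    spectra = [plate.wells[w] for w in wells]
    return mass_from_spectrum(plate.wavelengths, spectra, curve)


def percent_id_injected(mass_in_sample: float, mass_injected: float) -> float:
    """%ID = mass recovered in the sample / mass injected * 100."""
    if mass_injected <= 0:
        raise ValueError("injected mass must be positive")
    if mass_in_sample < 0:
        raise ValueError("sample mass must be non-negative")
    return 100.0 * mass_in_sample / mass_injected


# ---------------------------------------------------------------------------
# kinetics assembly
# ---------------------------------------------------------------------------

def assemble_timecourse(
    tables: Mapping[str, pd.DataFrame], form: str
) -> pd.DataFrame:
    """Stack per-timepoint %ID tables into one long kinetics table.

    ``tables`` maps a timepoint label (e.g. "1 min" ... "24 h") to a
    %ID table with columns ``organ``, ``percent_id``.  ``form`` records
    whether the dose was encapsulated or free.  Output columns:
    ``timepoint``, ``organ``, ``percent_id``, ``form``.
    """
    if form not in ("encapsulated", "free"):
        raise ValueError("form must be 'encapsulated' or 'free'")
    labels = list(tables)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate timepoint labels")
    frames = []
    for label, df in tables.items():
        if not {"organ", "percent_id"}.issubset(df.columns):
            raise ValueError(f"table {label!r} lacks organ/percent_id columns")
        out = df[["organ", "percent_id"]].copy()
        out.insert(0, "timepoint", label)
        out["form"] = form
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def kidney_ratio(kinetics: pd.DataFrame) -> pd.DataFrame:
    """Target (left) over contralateral (right) kidney %ID per timepoint.

    Quantifies how much more dose the targeted kidney retains than the
    opposite one.
    """
    piv = kinetics.pivot_table(
        index="timepoint", columns="organ", values="percent_id", sort=False
    )
    for organ in ("left kidney", "right kidney"):
        if organ not in piv.columns:
            raise ValueError(f"kinetics table lacks {organ!r}")
    out = piv[["left kidney", "right kidney"]].copy()
    out["left_over_right"] = out["left kidney"] / out["right kidney"]
    return out.reset_index()
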