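"""File formats: TIFF speckle movies, CSV tables, HDF5/CSV acoustic traces.

All on-disk formats are the plain interchange formats of the upstream
instruments: multi-page 16-bit TIFF with a JSON sidecar for speckle
movies, CSV for organ tables and plates, HDF5 (with CSV fallback) for
acoustic traces.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .synthetic import (
    FluorimetryPlate,
    OrganFluorescenceTable,
    PASignal,
    SpeckleMovie,
    SpeckleSimConfig,
)

__all__ = [
    "write_speckle_movie",
    "read_speckle_movie",
    "write_organ_table",
    "read_organ_table",
    "write_pa_signal_h5",
    "read_pa_signal_h5",
    "write_pa_signal_csv",
    "read_pa_signal_csv",
    "write_plate_csv",
    "read_plate_csv",
]


def write_speckle_movie(movie: SpeckleMovie, path: str | Path) -> Path:
    """Write a movie as multi-page uint16 TIFF plus a JSON sidecar.

    Intensities are scaled to the 16-bit range; the scale factor is kept
    in the sidecar so reading restores the original float values.
    """
    path = Path(path)
    peak = float(movie.frames.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    tifffile.imwrite(path, np.round(movie.frames * scale).astype(np.uint16))
    meta = {
        "exposure_ms": movie.exposure_ms,
        "fps": movie.fps,
        "intensity_scale": scale,
    }
    if isinstance(movie.provenance, SpeckleSimConfig):
        cfg = movie.provenance
        meta.update(
            seed=cfg.seed,
            tau_c_ms=None if math.isinf(cfg.tau_c_ms) else cfg.tau_c_ms,
            beta=cfg.beta,
            n_subframes=cfg.n_subframes,
        )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_speckle_movie(path: str | Path) -> SpeckleMovie:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    frames = tifffile.imread(path).astype(float) / meta.get("intensity_scale", 1.0)
    if frames.ndim == 2:
        frames = frames[None]
    return SpeckleMovie(frames, meta["exposure_ms"], meta["fps"], provenance="measured")


def write_organ_table(table: OrganFluorescenceTable, path: str | Path) -> Path:
    path = Path(path)
    df = table.data.copy()
    df["group"] = table.group
    df.to_csv(path, index=False)
    if table.truth is not None:
        truth = pd.DataFrame(
            {"organ": list(table.truth), "percent_id": list(table.truth.values())}
        )
        truth.to_csv(path.with_suffix(".truth.csv"), index=False)
    return path


def read_organ_table(path: str | Path) -> OrganFluorescenceTable:
    path = Path(path)
    df = pd.read_csv(path)
    groups = df["group"].unique()
    if len(groups) != 1:
        raise ValueError(f"{path}: expected a single group, got {list(groups)}")
    truth = None
    truth_path = path.with_suffix(".truth.csv")
    if truth_path.exists():
        tdf = pd.read_csv(truth_path)
        truth = dict(zip(tdf["organ"], tdf["percent_id"]))
    return OrganFluorescenceTable(
        df[["organ", "tre", "area"]], str(groups[0]), truth=truth
    )


def write_pa_signal_h5(signal: PASignal, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("samples", data=signal.samples)
        ds.attrs["fs"] = signal.fs
        ds.attrs["timepoint"] = signal.timepoint_label
    return path


def read_pa_signal_h5(path: str | Path) -> PASignal:
    with h5py.File(path, "r") as f:
        ds = f["samples"]
        return PASignal(ds[:], float(ds.attrs["fs"]), str(ds.attrs["timepoint"]))


def write_pa_signal_csv(signal: PASignal, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(signal.samples.size) / signal.fs
    pd.DataFrame({"t": t, "amplitude": signal.samples}).to_csv(path, index=False)
    return path


def read_pa_signal_csv(path: str | Path, timepoint_label: str = "") -> PASignal:
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return PASignal(df["amplitude"].to_numpy(), fs, timepoint_label)


def write_plate_csv(plate: FluorimetryPlate, path: str | Path) -> Path:
    """Wide CSV (wavelength_nm + one column per well) + standards manifest."""
    path = Path(path)
    wide = pd.DataFrame({"wavelength_nm": plate.wavelengths})
    for well in sorted(plate.wells):
        wide[well] = plate.wells[well]
    wide.to_csv(path, index=False)
    manifest = pd.DataFrame(
        {"well": list(plate.standards), "mass_ng": list(plate.standards.values())}
    )
    manifest.to_csv(path.with_suffix(".standards.csv"), index=False)
    return path


def read_plate_csv(path: str | Path) -> FluorimetryPlate:
    path = Path(path)
    wide = pd.read_csv(path)
    wl = wide.pop("wavelength_nm").to_numpy()
    wells = {c: wide[c].to_numpy() for c in wide.columns}
    manifest = pd.read_csv(path.with_suffix(".standards.csv"))
    standards = dict(zip(manifest["well"], manifest["mass_ng"].astype(float)))
    return FluorimetryPlate(wl, wells, standards)
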