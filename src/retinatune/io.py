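"""CSV / TIFF readers and writers for the pipeline's external interfaces."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ephys import IntensityRun, PolarizationRun, SpectralScan
from .errors import DataError
from .eyeshine import EyeshineStack
from .templates import SpectralSensitivity

__all__ = [
    "read_intensity_runs",
    "read_spectral_scans",
    "read_polarization_runs",
    "write_sensitivities",
    "read_sensitivities",
    "write_eyeshine_stack",
    "read_eyeshine_stack",
]


def _require(df: pd.DataFrame, cols: set, what: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise DataError(f"{what} missing columns {sorted(missing)}")


def read_intensity_runs(path) -> dict[str, IntensityRun]:
    """Read ``intensity_run.csv`` (cell_id, od, response_mv, wavelength_nm)
    into one run per cell."""
    df = pd.read_csv(path)
    _require(df, {"cell_id", "od", "response_mv", "wavelength_nm"}, "intensity_run.csv")
    runs = {}
    for cid, grp in df.groupby("cell_id"):
        runs[str(cid)] = IntensityRun(
            grp["od"].to_numpy(), grp["response_mv"].to_numpy(),
            float(grp["wavelength_nm"].iloc[0]), str(cid),
        )
    return runs


def _parse_adaptation(grp: pd.DataFrame) -> dict | None:
    if "adapt_wavelengths" not in grp.columns:
        return None
    raw = grp["adapt_wavelengths"].iloc[0]
    if pd.isna(raw) or str(raw).strip() in ("", "none"):
        return None
    wavelengths = [float(t) for t in str(raw).split("+")]
    intensity = grp["adapt_intensity"].iloc[0] if "adapt_intensity" in grp.columns else 1.0
    return {"wavelengths": wavelengths, "intensity": float(intensity)}


def read_spectral_scans(path) -> dict[tuple, SpectralScan]:
    """Read ``spectral_scan.csv`` (cell_id, wavelength_nm, response_mv,
    sweep[, adapt_wavelengths, adapt_intensity]); one scan per
    (cell, adaptation) pair, keyed by (cell_id, adaptation-string)."""
    df = pd.read_csv(path)
    _require(df, {"cell_id", "wavelength_nm", "response_mv"}, "spectral_scan.csv")
    if "adapt_wavelengths" in df.columns:
        akey = df["adapt_wavelengths"].fillna("none").astype(str)
    else:
        akey = pd.Series(["none"] * len(df))
    scans = {}
    for (cid, adapt_str), grp in df.groupby([df["cell_id"], akey]):
        scans[(str(cid), adapt_str)] = SpectralScan(
            grp["wavelength_nm"].to_numpy(),
            grp["response_mv"].to_numpy(),
            grp["sweep"].to_numpy() if "sweep" in grp.columns else None,
            _parse_adaptation(grp),
            cell_id=str(cid),
        )
    return scans


def read_polarization_runs(path) -> dict[str, PolarizationRun]:
    """Read ``polarization_run.csv`` (cell_id, angle_deg, response_mv
    [, wavelength_nm])."""
    df = pd.read_csv(path)
    _require(df, {"cell_id", "angle_deg", "response_mv"}, "polarization_run.csv")
    runs = {}
    for cid, grp in df.groupby("cell_id"):
        wl = float(grp["wavelength_nm"].iloc[0]) if "wavelength_nm" in grp.columns else 0.0
        runs[str(cid)] = PolarizationRun(
            grp["angle_deg"].to_numpy(), grp["response_mv"].to_numpy(), wl, str(cid)
        )
    return runs


def write_sensitivities(sensitivities: dict[str, SpectralSensitivity], path) -> None:
    """Write ``sensitivity.csv`` (cell_id, wavelength_nm, sensitivity,
    opponent_flag)."""
    rows = []
    for cid, s in sensitivities.items():
        for wl, v in zip(s.wavelengths, s.values):
            rows.append(
                {"cell_id": cid, "wavelength_nm": wl, "sensitivity": v,
                 "opponent_flag": s.opponent}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sensitivities(path) -> dict[str, SpectralSensitivity]:
    df = pd.read_csv(path)
    _require(df, {"cell_id", "wavelength_nm", "sensitivity"}, "sensitivity.csv")
    out = {}
    for cid, grp in df.groupby("cell_id"):
        grp = grp.sort_values("wavelength_nm")
        opp = bool(grp["opponent_flag"].iloc[0]) if "opponent_flag" in grp.columns else False
        out[str(cid)] = SpectralSensitivity(
            grp["wavelength_nm"].to_numpy(), grp["sensitivity"].to_numpy(),
            {"cell_id": str(cid)}, opponent=opp,
        )
    return out


def write_eyeshine_stack(stack: EyeshineStack, directory, stem: str | None = None) -> Path:
    """Write a stack as multi-page float32 TIFFs plus a sidecar JSON giving
    the wavelength page order, elevation and eye id."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if stem is None:
        stem = f"{stack.eye_id}_e{int(round(stack.elevation)):+04d}"
    wavelengths = sorted(stack.frames, reverse=True)
    pages = np.stack([stack.frames[wl] for wl in wavelengths]).astype(np.float32)
    bg = np.stack([stack.background_frames[wl] for wl in wavelengths]).astype(np.float32)
    tifffile.imwrite(directory / f"{stem}.tif", pages)
    tifffile.imwrite(directory / f"{stem}_bg.tif", bg)
    sidecar = {
        "wavelengths": [int(w) for w in wavelengths],
        "elevation": stack.elevation,
        "eye_id": stack.eye_id,
    }
    with open(directory / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh)
    return directory / f"{stem}.tif"


def read_eyeshine_stack(tif_path) -> EyeshineStack:
    tif_path = Path(tif_path)
    sidecar_path = tif_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise DataError(f"missing sidecar JSON for {tif_path.name}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    pages = tifffile.imread(tif_path)
    bg_path = tif_path.with_name(tif_path.stem + "_bg.tif")
    if not bg_path.exists():
        raise DataError(f"missing background stack for {tif_path.name}")
    bg = tifffile.imread(bg_path)
    wavelengths = sidecar["wavelengths"]
    frames = {wl: pages[i].astype(float) for i, wl in enumerate(wavelengths)}
    backgrounds = {wl: bg[i].astype(float) for i, wl in enumerate(wavelengths)}
    return EyeshineStack(
        float(sidecar["elevation"]), frames, backgrounds, sidecar.get("eye_id", "eye0")
    )
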