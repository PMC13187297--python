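"""TIFF + sidecar persistence for projection series, volumes and masks.

Every array artifact is a multipage TIFF next to a JSON sidecar carrying
the acquisition/geometry metadata and the provenance list, so any stage
can be resumed from disk without re-running its predecessors.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .beam import ProjectionSeries
from .errors import ParameterError
from .recon import CTVolume


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


# ---------------------------------------------------------------------------
# projection series

def save_projections(series: ProjectionSeries, path) -> Path:
    """Write frames as multipage float32 TIFF plus flat/dark and sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, series.frames.astype(np.float32))
    tifffile.imwrite(path.with_name(path.stem + "_flat.tif"),
                     series.flat_frame.astype(np.float32))
    tifffile.imwrite(path.with_name(path.stem + "_dark.tif"),
                     series.dark_frame.astype(np.float32))
    write_json({
        "angles_deg": series.angles_deg,
        "pixel_size_um": series.pixel_size_um,
        "wavelength_A": series.wavelength_A,
        "distance_mm": series.distance_mm,
        "delta_beta": series.delta_beta,
        "incident_intensity": series.incident_intensity,
        "provenance": series.provenance,
    }, _sidecar(path))
    return path


def load_projections(path) -> ProjectionSeries:
    path = Path(path)
    meta = read_json(_sidecar(path))
    frames = tifffile.imread(path)
    flat = tifffile.imread(path.with_name(path.stem + "_flat.tif"))
    dark = tifffile.imread(path.with_name(path.stem + "_dark.tif"))
    return ProjectionSeries(
        frames, np.asarray(meta["angles_deg"], float), meta["pixel_size_um"],
        flat, dark, wavelength_A=meta["wavelength_A"],
        distance_mm=meta["distance_mm"], delta_beta=meta["delta_beta"],
        incident_intensity=meta["incident_intensity"],
        provenance=list(meta["provenance"]))


# ---------------------------------------------------------------------------
# CT volumes and masks

def save_volume(volume: CTVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.opacity_grid)
    write_json({
        "voxel_size_um": volume.voxel_size_um,
        "slope": volume.slope,
        "intercept": volume.intercept,
        "provenance": volume.provenance,
    }, _sidecar(path))
    return path


def load_volume(path) -> CTVolume:
    path = Path(path)
    meta = read_json(_sidecar(path))
    grid = tifffile.imread(path)
    if grid.dtype != np.uint16:
        raise ParameterError(f"{path} is not a 16-bit opacity volume")
    return CTVolume(grid, meta["voxel_size_um"], meta["slope"],
                    meta["intercept"], list(meta["provenance"]))


def save_mask(mask: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(mask, dtype=bool).astype(np.uint8) * 255)
    return path


def load_mask(path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def save_labels(labels: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint8))
    return path


def load_labels(path) -> np.ndarray:
    return tifffile.imread(Path(path))


# ---------------------------------------------------------------------------
# landmarks and reports

def save_landmarks(volume_points_um: np.ndarray, section_points_um: np.ndarray,
                   path) -> Path:
    """Paired landmark rows as delimited text (vz,vy,vx,sz,sy,sx in um)."""
    v = np.atleast_2d(np.asarray(volume_points_um, float))
    s = np.atleast_2d(np.asarray(section_points_um, float))
    if v.shape != s.shape or v.shape[1] != 3:
        raise ParameterError("landmark sets must be matching (n, 3) arrays")
    df = pd.DataFrame(np.hstack([v, s]),
                      columns=["vz_um", "vy_um", "vx_um",
                               "sz_um", "sy_um", "sx_um"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_landmarks(path) -> tuple:
    df = pd.read_csv(Path(path))
    return (df[["vz_um", "vy_um", "vx_um"]].to_numpy(),
            df[["sz_um", "sy_um", "sx_um"]].to_numpy())


def save_report(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


__all__ = [
    "save_projections", "load_projections", "save_volume", "load_volume",
    "save_mask", "load_mask", "save_labels", "load_labels",
    "save_landmarks", "load_landmarks", "save_report",
    "write_json", "read_json",
]
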