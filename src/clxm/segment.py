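"""Glomerular segmentation and volumetry.

The glomerular hierarchy (GB = glomerulus with Bowman's capsule; GM =
glomerulus; PL = parietal layer; BS = Bowman's space) is segmented
manually in practice and ingested here as binary masks; only the
high-density mesangial regions (HDR) are extracted automatically, by a
relative threshold on the GM opacity range (46.9% in the published
analysis) followed by one morphological opening and one closing.
Volumes are voxel counts times the voxel volume, exactly.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def group_z_project(volume: np.ndarray, group_size: int = 15,
                    reducer=np.max) -> np.ndarray:
    """Reduce consecutive non-overlapping groups of slices.

    A group of 15 slices at 0.271 um voxels matches the 4 um thickness of
    a histology section.  The trailing partial group is kept.
    """
    vol = np.asarray(volume)
    if group_size < 1:
        raise ParameterError("group size must be >= 1")
    nz = vol.shape[0]
    bounds = range(0, nz, group_size)
    return np.stack([reducer(vol[i:i + group_size], axis=0) for i in bounds])


def relative_threshold(volume: np.ndarray, gm_mask: np.ndarray,
                       fraction: float) -> float:
    """Absolute threshold at ``fraction`` of the GM opacity range:
    min + fraction * (max - min) over GM-masked opacities."""
    if not (0.0 <= fraction <= 1.0):
        raise ParameterError("fraction must be in [0, 1]")
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if not gm_mask.any():
        raise ParameterError("GM mask is empty")
    vals = np.asarray(volume)[gm_mask]
    lo, hi = float(vals.min()), float(vals.max())
    return lo + fraction * (hi - lo)


def binarize_hdr(volume: np.ndarray, gm_mask: np.ndarray,
                 threshold: float) -> np.ndarray:
    """GM voxels with opacity strictly greater than the threshold."""
    return np.asarray(gm_mask, dtype=bool) & (np.asarray(volume) > threshold)


def smooth_mask(mask: np.ndarray) -> np.ndarray:
    """Morphological opening then closing, 3x3x3 element, once each."""
    m = np.asarray(mask, dtype=bool)
    m = ndimage.binary_opening(m, structure=_STRUCT26)
    return ndimage.binary_closing(m, structure=_STRUCT26)


def threshold_search(volume: np.ndarray, gm_mask: np.ndarray,
                     f_grid: np.ndarray, penalty_weight: float = 0.5
                     ) -> tuple[pd.DataFrame, float]:
    """Scan relative-threshold fractions and score each candidate.

    For each fraction: the HDR volume fraction of GM, the connected
    component count (26-connectivity) and the largest-component fraction
    of the extracted voxels.  The selected fraction maximizes
    largest-component fraction - penalty_weight * volume fraction (a
    continuity-versus-overreach trade-off); the full table is returned
    for manual override.
    """
    gm_mask = np.asarray(gm_mask, dtype=bool)
    f_grid = np.asarray(f_grid, dtype=float)
    if f_grid.min() < 0 or f_grid.max() > 1:
        raise ParameterError("fraction grid must lie in [0, 1]")
    rows = []
    n_gm = gm_mask.sum()
    for f in f_grid:
        thr = relative_threshold(volume, gm_mask, f)
        hdr = binarize_hdr(volume, gm_mask, thr)
        n_hdr = int(hdr.sum())
        if n_hdr == 0:
            rows.append({"fraction": f, "threshold": thr, "volume_fraction": 0.0,
                         "n_components": 0, "largest_component_fraction": 0.0,
                         "score": -penalty_weight * 0.0})
            continue
        labels, n_comp = ndimage.label(hdr, structure=_STRUCT26)
        largest = np.bincount(labels.ravel())[1:].max()
        vol_frac = n_hdr / n_gm
        largest_frac = largest / n_hdr
        rows.append({"fraction": f, "threshold": thr, "volume_fraction": vol_frac,
                     "n_components": int(n_comp),
                     "largest_component_fraction": float(largest_frac),
                     "score": float(largest_frac - penalty_weight * vol_frac)})
    table = pd.DataFrame(rows)
    selected = float(table.loc[table["score"].idxmax(), "fraction"])
    return table, selected


def extract_lesion(hdr_mask: np.ndarray, seed_points: list,
                   bounding_masks: list | None = None) -> list:
    """Connected components (26-connectivity) containing each seed.

    Lesions are sub-parts of a connected mesangial tree, so an optional
    per-seed bounding mask clips the component when it exceeds the lesion
    itself.  Raises :class:`ParameterError` for seeds outside the mask.
    """
    hdr = np.asarray(hdr_mask, dtype=bool)
    labels, _ = ndimage.label(hdr, structure=_STRUCT26)
    out = []
    for i, seed in enumerate(seed_points):
        seed = tuple(int(round(c)) for c in seed)
        if not hdr[seed]:
            raise ParameterError(f"seed {seed} is outside the HDR mask")
        comp = labels == labels[seed]
        if bounding_masks is not None and bounding_masks[i] is not None:
            comp = comp & np.asarray(bounding_masks[i], dtype=bool)
        out.append(comp)
    return out


# Which column each region's second ratio refers to, following the
# published table layout (GM vs GB, HDR vs GM, lesions vs HDR).
_RATIO_PARENT = {"GM": "GB", "PL": "GB", "BS": "GB", "HDR": "GM"}


def volumetry(masks: dict, opacity: np.ndarray | None,
              voxel_size_um: float) -> pd.DataFrame:
    """Per-region volumes, nested ratios and opacity statistics.

    ``masks`` maps region name -> boolean mask (shared shape).  Volume is
    voxel count x voxel_size^3 exactly; the spread statistic is the
    population standard deviation (divisor n).  Empty masks report zero
    volume and NaN opacity statistics.
    """
    v3 = voxel_size_um ** 3
    shapes = {m.shape for m in masks.values()}
    if len(shapes) > 1:
        raise ParameterError("all masks must share one shape")
    if opacity is not None and np.asarray(opacity).shape not in shapes and shapes:
        raise ParameterError("masks must match the volume shape")
    counts = {name: int(np.count_nonzero(m)) for name, m in masks.items()}
    rows = []
    for name, mask in masks.items():
        n = counts[name]
        row = {"region": name, "voxels": n, "volume_um3": n * v3}
        gb = counts.get("GB")
        row["ratio_vs_GB"] = (n / gb) if (gb and name in
                                          ("GB", "GM", "PL", "BS")) else np.nan
        parent = _RATIO_PARENT.get(name, "HDR" if name.startswith("LESION") else None)
        if parent and counts.get(parent):
            row["ratio_vs_parent"] = n / counts[parent]
            row["parent"] = parent
        else:
            row["ratio_vs_parent"] = np.nan
            row["parent"] = None
        if opacity is not None and n > 0:
            vals = np.asarray(opacity)[mask]
            row.update(opacity_mean=float(vals.mean()),
                       opacity_sd=float(vals.std(ddof=0)),  # population SD
                       opacity_min=float(vals.min()),
                       opacity_max=float(vals.max()))
        else:
            row.update(opacity_mean=np.nan, opacity_sd=np.nan,
                       opacity_min=np.nan, opacity_max=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def per_cell_volume(lesion_volumes_um3, cell_counts) -> float:
    """Total lesion volume divided by total cell count (um^3 per cell)."""
    vols = np.asarray(lesion_volumes_um3, dtype=float)
    counts = np.asarray(cell_counts, dtype=float)
    if vols.shape != counts.shape:
        raise ParameterError("volume and count lists must have equal length")
    if np.any(counts < 1):
        raise ParameterError("cell counts must be >= 1")
    total = counts.sum()
    if total == 0:
        raise ParameterError("total cell count is zero")
    return float(vols.sum() / total)
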