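"""Digital kidney-biopsy phantoms with known ground truth.

The phantom emulates an FFPE needle biopsy embedded in paraffin and imaged
by laboratory X-ray microscopy: paraffin acts as a negative contrast medium
around tissue; inside the tissue sits a glomerulus with Bowman's capsule
(GB) split into parietal layer (PL), Bowman's space (BS) and the glomerulus
proper (GM); the mesangium is a branching high-density tree (HDR) carrying
hypercellularity lesions realized as protrusion blobs of prescribed volume;
cell nuclei are dense spheres in the surrounding tissue; a single dense
fiducial microparticle sits in the paraffin off the rotation axis.

All region painting is count-exact: a region requested at volume V is
painted with ``round(V / voxel_size**3)`` voxels, so ground-truth volumes
match the request to within half a voxel-volume by construction.

Coordinates are (z, y, x), 0-based, z along the rotation axis; physical
lengths are micrometres.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Sequence

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError
from .geometry import RigidTransform

# ---------------------------------------------------------------------------
# Region codes (finest labels; every voxel carries exactly one)

AIR = 0
PARAFFIN = 1
TISSUE = 2
PL = 3
BS = 4
GM = 5          # mesangial/glomerular background inside the capsule
HDR = 6         # high-density (mesangial) regions excluding lesions
LESION_BASE = 7  # lesion k -> code LESION_BASE + k - 1
NUCLEUS = 20
MARKER = 21

CODE_NAMES = {
    AIR: "AIR",
    PARAFFIN: "PARAFFIN",
    TISSUE: "TISSUE",
    PL: "PL",
    BS: "BS",
    GM: "GM",
    HDR: "HDR_TRUE",
    NUCLEUS: "NUCLEUS",
    MARKER: "MARKER",
}


def lesion_code(k: int) -> int:
    return LESION_BASE + k - 1


# Relative linear attenuation per finest label (arbitrary scale; only the
# ordering AIR < PARAFFIN < TISSUE < GM < NUCLEUS < MARKER drives the
# downstream metrics).  Multiplied by ``mu_paraffin_per_um`` to get per-um
# coefficients.
DEFAULT_RELATIVE_MU = {
    AIR: 0.0,
    PARAFFIN: 1.0,
    TISSUE: 1.15,
    PL: 1.25,
    BS: 1.05,
    GM: 1.35,
    HDR: 1.50,
    NUCLEUS: 1.60,
    MARKER: 8.0,
}
LESION_RELATIVE_MU = 1.50


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and contrast specification of the synthetic biopsy.

    Volumes follow the published glomerular region ratios (GM/GB 0.574,
    PL/GB 0.267, BS/GB 0.159, HDR/GM 0.293, lesion/GM per lesion) on a
    scaled-down glomerulus that fits the default grid.
    """

    shape: tuple = (192, 128, 128)
    voxel_size_um: float = 0.271
    paraffin_radius_frac: float = 0.47   # of the smaller in-plane extent
    tissue_radius_frac: float = 0.28
    gb_volume_um3: float = 2000.0
    pl_fraction: float = 0.267
    gm_fraction: float = 0.574
    hdr_fraction: float = 0.293
    lesion_volumes_um3: tuple = (4.7, 7.9, 4.8)
    n_nuclei: int = 30
    nucleus_diameter_um: tuple = (2.0, 3.0)
    # axial fraction of the tissue column allowed to carry nuclei; the
    # bands above and below stay cell-free so homogeneous tissue is
    # always available for image-quality windows
    nuclei_z_band: tuple = (0.2, 0.8)
    marker_diameter_vox: float = 3.0
    include_glomerulus: bool = True
    include_nuclei: bool = True
    include_marker: bool = True
    mu_paraffin_per_um: float = 0.005
    paraffin_z_inset: int = 16
    tree_depth: int = 4
    tree_step_frac: float = 0.45         # first-segment length / interior radius

    def with_(self, **kw) -> "PhantomParams":
        return replace(self, **kw)


@dataclass
class Phantom:
    attenuation_grid: np.ndarray     # float32, per-um linear attenuation
    label_grid: np.ndarray           # uint8 finest region codes
    voxel_size_um: float
    marker_center: np.ndarray | None  # (z, y, x) voxels
    nuclei_centers: np.ndarray       # (n, 3) voxels
    truth_volumes: Dict[str, float]  # region name -> um^3 (finest + composite)
    seed: int
    params: PhantomParams

    # composite region definitions on top of the finest labels
    def mask(self, region: str) -> np.ndarray:
        labels = self.label_grid
        lesions = [c for c in np.unique(labels) if c >= LESION_BASE and c < NUCLEUS]
        if region == "GB":
            codes = [PL, BS, GM, HDR] + lesions
        elif region == "GM":
            codes = [GM, HDR] + lesions
        elif region == "HDR":
            codes = [HDR] + lesions
        elif region.startswith("LESION_"):
            codes = [lesion_code(int(region.split("_")[1]))]
        else:
            inv = {v: k for k, v in CODE_NAMES.items()}
            codes = [inv[region]]
        return np.isin(labels, codes)

    @property
    def n_lesions(self) -> int:
        return int(sum(1 for c in np.unique(self.label_grid)
                       if LESION_BASE <= c < NUCLEUS))


# ---------------------------------------------------------------------------
# helpers

def _take_smallest(values: np.ndarray, within: np.ndarray, n: int) -> np.ndarray:
    """Boolean mask of the ``n`` smallest ``values`` among ``within`` voxels.

    Ties are broken by flat index so the result is deterministic.
    """
    idx = np.flatnonzero(within)
    if n > idx.size:
        raise ParameterError(f"requested {n} voxels but only {idx.size} available")
    order = np.argsort(values.ravel()[idx], kind="stable")
    chosen = idx[order[:n]]
    out = np.zeros(values.shape, dtype=bool)
    out.ravel()[chosen] = True
    return out


def _grow_blob(available: np.ndarray, seed_vox: tuple, n: int) -> np.ndarray:
    """Connected blob of exactly ``n`` voxels grown from ``seed_vox``.

    Grows by repeated 26-connected geodesic dilation inside ``available``;
    the final partial shell is trimmed by Euclidean distance to the seed so
    the blob stays compact (a spherical cap when unobstructed).
    """
    if not available[seed_vox]:
        raise ParameterError("lesion seed is not inside the available region")
    struct = np.ones((3, 3, 3), dtype=bool)
    blob = np.zeros(available.shape, dtype=bool)
    blob[seed_vox] = True
    while blob.sum() < n:
        grown = ndimage.binary_dilation(blob, structure=struct, mask=available)
        if grown.sum() == blob.sum():
            raise ParameterError(
                f"lesion of {n} voxels does not fit in the available region"
            )
        if grown.sum() <= n:
            blob = grown
            continue
        shell = grown & ~blob
        need = n - int(blob.sum())
        zz, yy, xx = np.nonzero(shell)
        d2 = (zz - seed_vox[0]) ** 2 + (yy - seed_vox[1]) ** 2 + (xx - seed_vox[2]) ** 2
        keep = np.argsort(d2, kind="stable")[:need]
        blob[zz[keep], yy[keep], xx[keep]] = True
    return blob


def _tree_skeleton(rng: np.random.Generator, center: np.ndarray,
                   interior_radius: float, depth: int, step_frac: float) -> np.ndarray:
    """Points of a random branching skeleton starting at one pole of the
    capsule interior (the vascular/macula-densa pole) and growing inward."""
    points = []
    pole = center + np.array([0.0, interior_radius - 2.0, 0.0])

    def grow(start, direction, level):
        length = interior_radius * step_frac * (0.85 ** level)
        nsteps = max(int(length / 0.5), 2)
        p = start.copy()
        d = direction / np.linalg.norm(direction)
        for _ in range(nsteps):
            p = p + d * 0.5
            # gentle random curvature
            d = d + rng.normal(scale=0.08, size=3)
            # steer back inside if approaching the capsule
            r = p - center
            if np.linalg.norm(r) > interior_radius - 2.0:
                d = d - 0.5 * r / np.linalg.norm(r)
            d = d / np.linalg.norm(d)
            points.append(p.copy())
        if level + 1 < depth:
            for _ in range(2):
                child = d + rng.normal(scale=0.55, size=3)
                grow(p, child, level + 1)
        return p

    grow(pole, np.array([0.0, -1.0, 0.0]), 0)
    return np.array(points)


# ---------------------------------------------------------------------------
# main constructors

def build_kidney_phantom(params: PhantomParams | None = None, seed: int = 0) -> Phantom:
    """Build a voxel phantom honouring the requested region volumes exactly.

    Raises :class:`ParameterError` for infeasible geometry (lesions larger
    than the glomerulus, regions that do not fit the grid).
    """
    p = params or PhantomParams()
    shape = tuple(p.shape)
    if min(shape) < 64:
        raise ParameterError("grid dimensions must be at least 64 in each axis")
    v3 = p.voxel_size_um ** 3
    nz, ny, nx = shape
    center = np.array([(nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0])
    rng = np.random.default_rng(seed)

    zz, yy, xx = np.indices(shape, dtype=np.float32)
    r_xy = np.sqrt((yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    r3 = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)

    r_par = p.paraffin_radius_frac * min(ny, nx)
    r_tis = p.tissue_radius_frac * min(ny, nx)
    if r_par >= min(ny, nx) / 2.0:
        raise ParameterError("paraffin cylinder exceeds the inscribed field of view")

    z_in = p.paraffin_z_inset
    if nz - 2 * z_in < 32:
        raise ParameterError("paraffin z-inset leaves too little block height")
    labels = np.zeros(shape, dtype=np.uint8)
    # the block does not span the full detector height, leaving clean
    # (object-free) air rows for transmission measurements
    labels[(r_xy <= r_par) & (zz >= z_in) & (zz <= nz - 1 - z_in)] = PARAFFIN
    # the biopsy core is a tissue cylinder (as cut by a biopsy needle),
    # inset from the z faces so it is fully embedded in paraffin
    tissue_ball = (r_xy <= r_tis) & (zz >= z_in + 3) & (zz <= nz - 4 - z_in)
    labels[tissue_ball] = TISSUE

    nuclei_centers = np.zeros((0, 3))
    marker_center = None

    if p.include_glomerulus:
        n_gb = int(round(p.gb_volume_um3 / v3))
        gb_radius = (3.0 * n_gb / (4.0 * np.pi)) ** (1.0 / 3.0)
        if gb_radius + 3.0 > min(r_tis, nz / 2.0):
            raise ParameterError("glomerulus does not fit inside the tissue")
        gb = _take_smallest(r3, tissue_ball, n_gb)

        n_pl = int(round(p.pl_fraction * n_gb))
        n_gm = int(round(p.gm_fraction * n_gb))
        pl = _take_smallest(-r3, gb, n_pl)        # outermost shell
        interior = gb & ~pl

        lesion_vox = [int(round(v / v3)) for v in p.lesion_volumes_um3]
        if any(n < 8 for n in lesion_vox):
            raise ParameterError("each lesion must span at least 8 voxels")
        if sum(lesion_vox) >= n_gm:
            raise ParameterError("lesion volumes exceed the glomerulus volume")

        interior_radius = (3.0 * (n_gb - n_pl) / (4.0 * np.pi)) ** (1.0 / 3.0)
        skel_pts = _tree_skeleton(rng, center, interior_radius,
                                  p.tree_depth, p.tree_step_frac)
        skel_mask = np.zeros(shape, dtype=bool)
        iz = np.clip(np.round(skel_pts[:, 0]).astype(int), 0, nz - 1)
        iy = np.clip(np.round(skel_pts[:, 1]).astype(int), 0, ny - 1)
        ix = np.clip(np.round(skel_pts[:, 2]).astype(int), 0, nx - 1)
        skel_mask[iz, iy, ix] = True
        skel_mask &= interior
        if not skel_mask.any():  # degenerate: fall back to the pole voxel
            skel_mask[tuple(np.round(center).astype(int))] = True
        dist_tree = ndimage.distance_transform_edt(~skel_mask)

        # lesions: connected protrusion blobs seeded at well-separated
        # skeleton points
        skel_idx = np.argwhere(skel_mask)
        seeds = [skel_idx[rng.integers(len(skel_idx))]]
        while len(seeds) < len(lesion_vox):
            d = np.min(
                [np.sum((skel_idx - s) ** 2, axis=1) for s in seeds], axis=0
            )
            seeds.append(skel_idx[int(np.argmax(d))])
        lesion_masks = []
        available = interior.copy()
        for n_k, s in zip(lesion_vox, seeds):
            blob = _grow_blob(available, tuple(s), n_k)
            lesion_masks.append(blob)
            available &= ~blob

        taken = np.zeros(shape, dtype=bool)
        for m in lesion_masks:
            taken |= m
        n_fill = n_gm - sum(lesion_vox)
        gm_fill = _take_smallest(dist_tree, interior & ~taken, n_fill)

        n_hdr = max(int(round(p.hdr_fraction * n_gm)), sum(lesion_vox))
        n_hdr_extra = min(n_hdr - sum(lesion_vox), n_fill)
        hdr_extra = _take_smallest(dist_tree, gm_fill, n_hdr_extra)

        labels[interior] = BS
        labels[gm_fill] = GM
        labels[hdr_extra] = HDR
        for k, m in enumerate(lesion_masks, start=1):
            labels[m] = lesion_code(k)
        labels[pl] = PL

    if p.include_nuclei and p.n_nuclei > 0:
        d_lo, d_hi = p.nucleus_diameter_um
        r_lo_vox = d_lo / 2.0 / p.voxel_size_um
        tissue_now = labels == TISSUE
        edt = ndimage.distance_transform_edt(tissue_now)
        cand = np.argwhere(edt > r_lo_vox + 1.0)
        if len(cand):
            tz = np.flatnonzero(tissue_now.any(axis=(1, 2)))
            z0, z1 = tz[0], tz[-1]
            f_lo, f_hi = p.nuclei_z_band
            lo_z = z0 + f_lo * (z1 - z0)
            hi_z = z0 + f_hi * (z1 - z0)
            cand = cand[(cand[:, 0] >= lo_z) & (cand[:, 0] <= hi_z)]
        centers, radii = [], []
        attempts = 0
        # dart-throwing Poisson-disc sampling: reject overlapping spheres
        while len(centers) < p.n_nuclei and attempts < 8000 and len(cand):
            attempts += 1
            c = cand[rng.integers(len(cand))]
            d_um = rng.uniform(d_lo, d_hi)
            r_vox = d_um / 2.0 / p.voxel_size_um
            if edt[tuple(c)] <= r_vox + 1.0:
                continue
            if centers:
                sep = np.sqrt(np.sum((np.array(centers) - c) ** 2, axis=1))
                if np.any(sep < np.array(radii) + r_vox + 1.0):
                    continue
            centers.append(c.astype(float))
            radii.append(r_vox)
        for c, r_vox in zip(centers, radii):
            sphere = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r_vox ** 2
            labels[sphere & tissue_now] = NUCLEUS
        nuclei_centers = np.array(centers) if centers else np.zeros((0, 3))

    if p.include_marker:
        r_m = p.marker_diameter_vox / 2.0
        lo, hi = r_tis + r_m + 2.0, r_par - r_m - 2.0
        if hi <= lo:
            raise ParameterError("no paraffin annulus available for the marker")
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(lo, hi)
        mc = np.array([
            center[0] + rng.uniform(-0.2, 0.2) * nz * 0.1,
            center[1] + rad * np.sin(ang),
            center[2] + rad * np.cos(ang),
        ])
        sphere = (zz - mc[0]) ** 2 + (yy - mc[1]) ** 2 + (xx - mc[2]) ** 2 <= r_m ** 2
        labels[sphere & (labels == PARAFFIN)] = MARKER
        marker_center = mc

    mu = np.zeros(shape, dtype=np.float32)
    for code, rel in DEFAULT_RELATIVE_MU.items():
        mu[labels == code] = rel * p.mu_paraffin_per_um
    for c in np.unique(labels):
        if LESION_BASE <= c < NUCLEUS:
            mu[labels == c] = LESION_RELATIVE_MU * p.mu_paraffin_per_um

    truth = _truth_volumes(labels, p.voxel_size_um)
    return Phantom(mu, labels, p.voxel_size_um, marker_center,
                   nuclei_centers, truth, seed, p)


def _truth_volumes(labels: np.ndarray, voxel_size_um: float) -> Dict[str, float]:
    v3 = voxel_size_um ** 3
    out: Dict[str, float] = {}
    codes, counts = np.unique(labels, return_counts=True)
    lesions = []
    for c, n in zip(codes, counts):
        if c in CODE_NAMES:
            out[CODE_NAMES[c]] = float(n) * v3
        elif LESION_BASE <= c < NUCLEUS:
            k = c - LESION_BASE + 1
            out[f"LESION_{k}"] = float(n) * v3
            lesions.append(f"LESION_{k}")
    # composite regions of the published hierarchy
    hdr = out.get("HDR_TRUE", 0.0) + sum(out[name] for name in lesions)
    gm = out.get("GM", 0.0) + hdr
    gb = gm + out.get("PL", 0.0) + out.get("BS", 0.0)
    out["HDR"] = hdr
    out["GM_total"] = gm
    out["GB"] = gb
    return out


def ground_truth_volumes(phantom: Phantom):
    """Ground-truth volume table with ratio columns versus GB and GM.

    Returns a pandas DataFrame with one row per region (composites GB,
    GM_total, HDR included); volume equals voxel count x voxel_size^3
    exactly.
    """
    import pandas as pd

    t = phantom.truth_volumes
    gb = t.get("GB", np.nan)
    gm = t.get("GM_total", np.nan)
    rows = []
    for name, vol in sorted(t.items()):
        rows.append({
            "region": name,
            "volume_um3": vol,
            "ratio_vs_GB": vol / gb if gb else np.nan,
            "ratio_vs_GM": vol / gm if gm else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pseudo light-microscopy sections

@dataclass
class SectionImage:
    """A rendered pseudo-histology section of the phantom.

    ``pose`` maps phantom coordinates (um) to section coordinates (um);
    the section plane occupies section-z in [0, thickness].
    ``landmarks`` pairs are (2D section pixel coordinate (row, col),
    3D phantom voxel coordinate (z, y, x)) at nuclei inside the slab.
    """

    pixel_grid: np.ndarray
    pixel_size_um: float
    thickness_um: float
    pose: RigidTransform
    landmarks: list
    distortion_amplitude_um: float = 0.0


def extract_section(phantom: Phantom, pose: RigidTransform,
                    thickness_um: float = 4.0,
                    distortion_amplitude_um: float = 0.0,
                    out_shape: tuple | None = None,
                    seed: int = 0) -> SectionImage:
    """Render the maximum-intensity composite of an oblique slab.

    The slab is sampled at the phantom's voxel pitch; intensities are
    mapped to a PAS-like convention (dense structures bright).  Landmarks
    are recorded for every nucleus whose centre falls inside the slab.
    """
    if thickness_um <= 0:
        raise ParameterError("section thickness must be positive")
    vs = phantom.voxel_size_um
    nz, ny, nx = phantom.attenuation_grid.shape
    if out_shape is None:
        out_shape = (ny, nx)
    n_slab = max(int(round(thickness_um / vs)), 1)

    inv = pose.inverse()
    sz = (np.arange(n_slab) + 0.5) * (thickness_um / n_slab)
    sy = np.arange(out_shape[0]) * vs
    sx = np.arange(out_shape[1]) * vs
    gz, gy, gx = np.meshgrid(sz, sy, sx, indexing="ij")
    sec_pts = np.stack([gz.ravel(), gy.ravel(), gx.ravel()], axis=1)
    vol_pts = inv.apply(sec_pts) / vs  # voxel coords

    lo = vol_pts.min(axis=0)
    hi = vol_pts.max(axis=0)
    if (lo < -0.5).any() or (hi > np.array([nz, ny, nx]) - 0.5).any():
        raise GeometryError("section slab extends outside the phantom grid")

    vals = ndimage.map_coordinates(
        phantom.attenuation_grid, vol_pts.T, order=1, mode="nearest"
    ).reshape(n_slab, out_shape[0], out_shape[1])
    composite = vals.max(axis=0)
    # PAS-like rendering: dense structures bright on a pale background
    rng_span = composite.max() - composite.min()
    img = (composite - composite.min()) / (rng_span if rng_span > 0 else 1.0)

    rng = np.random.default_rng(seed)
    if distortion_amplitude_um > 0:
        coarse = rng.normal(size=(2, 8, 8))
        fieldshape = out_shape
        disp = np.stack([
            ndimage.zoom(coarse[i], (fieldshape[0] / 8, fieldshape[1] / 8), order=3)
            for i in range(2)
        ])
        disp = ndimage.gaussian_filter(disp, sigma=(0, 6, 6))
        peak = np.abs(disp).max()
        if peak > 0:
            disp *= distortion_amplitude_um / peak
    else:
        disp = None

    landmarks = []
    for c in phantom.nuclei_centers:
        s = pose.apply(c * vs)
        if not (0.0 <= s[0] <= thickness_um):
            continue
        row, col = s[1] / vs, s[2] / vs
        if not (0 <= row < out_shape[0] and 0 <= col < out_shape[1]):
            continue
        if disp is not None:
            ir, ic = int(round(row)), int(round(col))
            row += disp[0, ir, ic] / vs
            col += disp[1, ir, ic] / vs
        landmarks.append((np.array([row, col]), c.copy()))
    return SectionImage(img.astype(np.float32), vs, thickness_um, pose,
                        landmarks, distortion_amplitude_um)
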