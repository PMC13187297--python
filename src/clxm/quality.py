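"""Quantitative image-quality statistics for reconstructed volumes.

Implements the three quality figures used to report the gain from drift
correction and phase retrieval: transmission (histogram-peak ratio of
tissue to air in the raw projections), contrast-to-noise ratio between
two 15x15-pixel regions with repeated measurements, 95% confidence
intervals and Welch/F/Kolmogorov-Smirnov testing, and the size of
blurring at edges (SBE) from line opacity profiles across a
paraffin-tissue boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, special, stats

from .errors import ParameterError

#: 10%-90% width of a Gaussian-blurred step, in units of sigma
STEP_WIDTH_10_90 = 2.0 * float(special.ndtri(0.9))  # 2.5631...


@dataclass
class QualityReport:
    transmission: float | None = None
    cnr_entries: list = field(default_factory=list)   # (label, mean, ci95, n)
    sbe_entries: list = field(default_factory=list)   # (mean_um, ci95, n)
    test_results: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = [{"statistic": "transmission", "value": self.transmission,
                 "ci95": None, "n": None}]
        for label, mean, ci, n in self.cnr_entries:
            rows.append({"statistic": f"CNR {label}", "value": mean,
                         "ci95": ci, "n": n})
        for mean, ci, n in self.sbe_entries:
            rows.append({"statistic": "SBE (um)", "value": mean,
                         "ci95": ci, "n": n})
        for k, v in self.test_results.items():
            rows.append({"statistic": k, "value": v, "ci95": None, "n": None})
        return pd.DataFrame(rows)


def _hist_peak(values: np.ndarray, bins: int = 256,
               value_range: tuple | None = None) -> float:
    v = np.asarray(values, dtype=float).ravel()
    lo, hi = value_range if value_range is not None else (v.min(), v.max())
    if hi == lo:
        return float(lo)
    counts, edges = np.histogram(v, bins=bins, range=(lo, hi))
    i = int(np.argmax(counts))
    return 0.5 * float(edges[i] + edges[i + 1])


def transmission(raw_frames: np.ndarray, tissue_mask: np.ndarray,
                 air_mask: np.ndarray, bins: int = 256) -> float:
    """Histogram-peak intensity of tissue divided by that of air.

    Masks are 2D and applied to every raw frame; the two 256-bin
    histograms share the joint intensity range.
    """
    frames = np.asarray(raw_frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    air_mask = np.asarray(air_mask, dtype=bool)
    if not tissue_mask.any() or not air_mask.any():
        raise ParameterError("masks must be non-empty")
    if (tissue_mask & air_mask).any():
        raise ParameterError("tissue and air masks must be disjoint")
    tis = frames[:, tissue_mask].ravel()
    air = frames[:, air_mask].ravel()
    rng = (min(tis.min(), air.min()), max(tis.max(), air.max()))
    peak_air = _hist_peak(air, bins, rng)
    if peak_air <= 0:
        raise ParameterError("air histogram peak is non-positive")
    return _hist_peak(tis, bins, rng) / peak_air


def find_windows(mask: np.ndarray, size: int = 15, n: int = 5,
                 rng: np.random.Generator | None = None) -> list:
    """Top-left corners of ``n`` non-overlapping size x size windows that
    lie entirely inside a 2D boolean mask.

    Valid corners are found by erosion with the window footprint; the
    selection greedily maximizes pairwise separation (farthest-point),
    starting from the corner nearest the mask centroid (or a random valid
    corner when ``rng`` is given).  Raises :class:`ParameterError` when
    fewer than ``n`` non-overlapping windows fit.
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ParameterError("mask must be 2D")
    # a corner (r, c) is valid iff mask[r:r+size, c:c+size] is all True
    ok = ndimage.minimum_filter(m.astype(np.uint8), size=size,
                                mode="constant", cval=0,
                                origin=(-(size // 2), -(size // 2))) > 0
    ok[m.shape[0] - size + 1:, :] = False
    ok[:, m.shape[1] - size + 1:] = False
    cand = np.argwhere(ok).astype(float)
    if len(cand) == 0:
        raise ParameterError(f"no {size}x{size} window fits inside the mask")
    if rng is not None:
        first = cand[rng.integers(len(cand))]
    else:
        first = cand[np.argmin(np.sum((cand - cand.mean(axis=0)) ** 2, axis=1))]
    chosen = [first]
    for _ in range(1, n):
        d = np.full(len(cand), np.inf)
        for ch in chosen:
            d = np.minimum(d, np.max(np.abs(cand - ch), axis=1))
        # enforce non-overlap (Chebyshev distance >= size) then pick farthest
        d[d < size] = -1.0
        if d.max() < 0:
            raise ParameterError(
                f"only {len(chosen)} non-overlapping {size}x{size} windows fit")
        chosen.append(cand[int(np.argmax(d))])
    return [(int(r), int(c)) for r, c in chosen]


def axial_exclusion_margin(drift_pp_um: float, pixel_size_um: float,
                           wavelength_A: float, distance_mm: float,
                           n_fringe_orders: float = 3.0) -> int:
    """Number of slices next to a flat specimen cap that carry axial
    artifacts in an *uncompensated* reconstruction.

    The cap smears axially over the full peak-to-peak vertical drift
    excursion (no drift correction is applied to the raw volume), and
    its Fresnel fringe system extends about ``n_fringe_orders`` times
    the first-fringe scale sqrt(lambda * R) into the material.  Windowed
    statistics meant to characterise bulk material must stay this many
    admissible slices away from each cap.
    """
    if pixel_size_um <= 0:
        raise ParameterError("pixel size must be positive")
    fringe_um = np.sqrt(wavelength_A * 1e-4 * distance_mm * 1e3)
    return (int(np.ceil(max(drift_pp_um, 0.0) / pixel_size_um)) +
            int(np.ceil(n_fringe_orders * fringe_um / pixel_size_um)))


def paired_windows(labels: np.ndarray, label_a: int, label_b: int,
                   size: int = 15, n: int = 5, z_margin: int = 0,
                   standoff: int = 4) -> list:
    """Window pairs for a two-material CNR study on a labelled volume.

    Returns ``n`` tuples (z, corner_a, corner_b) from distinct, evenly
    spread slices in which one size x size window fits entirely inside
    each material.  Masks are eroded by ``standoff`` pixels so windows
    stay clear of boundary artifacts (Fresnel fringes extend roughly
    sqrt(lambda R) from an edge), and the first and last ``z_margin``
    admissible slices are dropped to avoid axial edge enhancement at the
    specimen caps (see :func:`axial_exclusion_margin` for how to size
    it from the drift excursion and propagation distance).
    """
    lbl = np.asarray(labels)
    if lbl.ndim != 3:
        raise ParameterError("labels must be a 3D volume")
    st = np.ones((2 * standoff + 1,) * 2, dtype=bool) if standoff else None
    found = []
    for z in range(lbl.shape[0]):
        ma = lbl[z] == label_a
        mb = lbl[z] == label_b
        if st is not None:
            ma = ndimage.binary_erosion(ma, st)
            mb = ndimage.binary_erosion(mb, st)
        try:
            ca = find_windows(ma, size, 1)[0]
            cb = find_windows(mb, size, 1)[0]
        except ParameterError:
            continue
        found.append((z, ca, cb))
    if z_margin:
        found = found[z_margin:len(found) - z_margin]
    if len(found) < n:
        raise ParameterError(
            f"only {len(found)} interior slices admit a window pair "
            f"(need {n})")
    idx = np.linspace(0, len(found) - 1, n).round().astype(int)
    return [found[i] for i in idx]


def cnr(slice_img: np.ndarray, corner_a: tuple, corner_b: tuple,
        size: int = 15, pooled: bool = False) -> float:
    """Contrast-to-noise ratio between two square windows.

    CNR = |mean(A) - mean(B)| / sqrt(var(A) + var(B)) with population
    variances (the pooled-SD alternative divides by sqrt of the average
    variance instead).  Windows must lie inside the slice and must not
    overlap.
    """
    img = np.asarray(slice_img, dtype=float)
    wins = []
    for (r, c) in (corner_a, corner_b):
        if r < 0 or c < 0 or r + size > img.shape[0] or c + size > img.shape[1]:
            raise ParameterError("CNR window extends outside the slice")
        wins.append(img[r:r + size, c:c + size])
    ra, ca = corner_a
    rb, cb = corner_b
    if abs(ra - rb) < size and abs(ca - cb) < size:
        if (ra, ca) != (rb, cb):
            raise ParameterError("CNR windows overlap")
    a, b = wins
    contrast = abs(a.mean() - b.mean())
    if contrast == 0:
        return 0.0
    var_a, var_b = a.var(), b.var()
    if var_a + var_b == 0:
        raise ParameterError("both windows have zero variance")
    denom = np.sqrt((var_a + var_b) / 2.0) if pooled else np.sqrt(var_a + var_b)
    return float(contrast / denom)


def _mean_ci(values: np.ndarray, level: float = 0.95) -> tuple:
    """(mean, half-width of the t-based confidence interval)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ParameterError("confidence interval needs at least 2 measurements")
    half = stats.t.ppf(0.5 + level / 2.0, n - 1) * v.std(ddof=1) / np.sqrt(n)
    return float(v.mean()), float(half)


def cnr_study(slice_a: np.ndarray, slice_b: np.ndarray,
              pairs_a: list, pairs_b: list, size: int = 15,
              alpha: float = 0.05) -> QualityReport:
    """Repeated CNR measurements on two treatment states with testing.

    ``pairs_*`` are lists of (corner_a, corner_b) window pairs (n >= 2).
    Reports per-state mean +/- 95% CI, the F-test for equality of
    variances, per-group Kolmogorov-Smirnov normality checks, and the
    two-tailed Welch t-test P-value for the difference of means.
    """
    if len(pairs_a) < 2 or len(pairs_b) < 2:
        raise ParameterError("each group needs at least 2 region pairs")
    ga = np.array([cnr(slice_a, a, b, size) for (a, b) in pairs_a])
    gb = np.array([cnr(slice_b, a, b, size) for (a, b) in pairs_b])
    rep = QualityReport()
    for label, g in (("group_a", ga), ("group_b", gb)):
        mean, ci = _mean_ci(g)
        rep.cnr_entries.append((label, mean, ci, g.size))

    va, vb = ga.var(ddof=1), gb.var(ddof=1)
    if va > 0 and vb > 0:
        f = va / vb
        p_f = 2.0 * min(stats.f.sf(f, ga.size - 1, gb.size - 1),
                        stats.f.cdf(f, ga.size - 1, gb.size - 1))
        rep.test_results["F_test_P"] = float(min(p_f, 1.0))
        for label, g in (("KS_P_group_a", ga), ("KS_P_group_b", gb)):
            if g.std(ddof=1) > 0:
                p_ks = stats.kstest((g - g.mean()) / g.std(ddof=1), "norm").pvalue
                rep.test_results[label] = float(p_ks)
    t_res = stats.ttest_ind(ga, gb, equal_var=False)
    rep.test_results["welch_t_P"] = float(t_res.pvalue)
    rep.test_results["welch_t"] = float(t_res.statistic)
    return rep


def line_profile(slice_img: np.ndarray, start: tuple, end: tuple,
                 n_samples: int | None = None) -> tuple:
    """Sample a line profile (positions along the line in pixels, values)."""
    img = np.asarray(slice_img, dtype=float)
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    length = float(np.linalg.norm(end - start))
    n = n_samples or max(int(np.ceil(length)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    coords = start[:, None] * (1 - t) + end[:, None] * t
    vals = ndimage.map_coordinates(img, coords, order=1)
    return t * length, vals


def sbe(slice_img: np.ndarray, start: tuple, end: tuple,
        pixel_size_um: float, fraction: float = 0.9) -> float:
    """Size of blurring at edges from a line opacity profile.

    Fits a + b * Phi((x - x0)/sigma) (Phi the standard normal CDF) to the
    profile across a single boundary and returns the distance between the
    10% and 90% points of the fitted step (2.5631 sigma), in micrometres.
    ``fraction`` configures the convention (0.75 gives the 25-75% width).
    """
    pos_px, vals = line_profile(slice_img, start, end)
    x = pos_px * pixel_size_um
    span = vals.max() - vals.min()
    if span == 0:
        raise ParameterError("profile has no edge")

    def model(xx, a, b, x0, sigma):
        return a + b * special.ndtr((xx - x0) / np.abs(sigma))

    rising = vals[-1] >= vals[0]
    p0 = [vals[0], (1 if rising else -1) * span, x.mean(),
          max(x[1] - x[0], 0.1)]
    try:
        popt, _ = optimize.curve_fit(model, x, vals, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise ParameterError(
            f"edge fit failed (profile may be non-monotone): {exc}") from exc
    resid = vals - model(x, *popt)
    if np.sqrt(np.mean(resid ** 2)) > 0.5 * span:
        raise ParameterError("edge fit does not describe the profile")
    width_factor = 2.0 * float(special.ndtri(fraction))
    return float(width_factor * abs(popt[3]))


def sbe_study(slice_img: np.ndarray, profiles: list,
              pixel_size_um: float) -> tuple:
    """Mean +/- 95% CI of SBE over several line profiles."""
    vals = np.array([sbe(slice_img, a, b, pixel_size_um) for (a, b) in profiles])
    mean, ci = _mean_ci(vals)
    return mean, ci, vals.size
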