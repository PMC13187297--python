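import numpy as np
import pytest
from scipy import ndimage, special

from clxm import quality
from clxm.errors import ParameterError
from clxm.phantom import PARAFFIN, TISSUE


# ------------------------------------------------------------------ CNR

def test_cnr_matches_the_closed_form():
    img = np.ones((40, 60))
    # window A: mean 3, population variance 1 (alternating +/-1 pattern)
    pat = np.indices((15, 15)).sum(axis=0) % 2 * 2.0 - 1.0
    img[5:20, 5:20] = 3.0 + pat
    # window B: constant 1, variance 0
    assert pat.mean() == pytest.approx(0.0, abs=0.01)
    a, b = (5, 5), (5, 40)
    expected = abs((3.0 + pat.mean()) - 1.0) / np.sqrt(pat.var())
    assert quality.cnr(img, a, b) == pytest.approx(expected)


def test_cnr_is_symmetric_in_the_two_windows():
    rng = np.random.default_rng(3)
    img = rng.normal(size=(40, 60))
    assert quality.cnr(img, (2, 2), (20, 40)) == pytest.approx(
        quality.cnr(img, (20, 40), (2, 2)))


def test_cnr_rejects_overlap_and_out_of_bounds():
    img = np.zeros((30, 30))
    with pytest.raises(ParameterError):
        quality.cnr(img, (0, 0), (5, 5))            # overlapping windows
    with pytest.raises(ParameterError):
        quality.cnr(img, (0, 0), (20, 20))          # extends outside


def test_cnr_study_detects_a_treatment_difference():
    rng = np.random.default_rng(7)
    base = rng.normal(0.0, 1.0, size=(64, 160))
    lo = base.copy()
    hi = base / 10.0
    for img in (lo, hi):
        img[10:25, 10:25] += 10.0                   # contrast patch A
    pairs = [((10, 10), (10, r)) for r in (40, 60, 80, 100, 120)]
    rep = quality.cnr_study(hi, lo, pairs, pairs)
    (_, mean_hi, _, _), (_, mean_lo, _, _) = rep.cnr_entries
    assert mean_hi > 5 * mean_lo
    assert rep.test_results["welch_t_P"] < 0.01


# ---------------------------------------------------------------- windows

def test_found_windows_fit_and_do_not_overlap():
    mask = np.zeros((80, 80), bool)
    mask[10:70, 10:70] = True
    wins = quality.find_windows(mask, size=15, n=5)
    assert len(wins) == 5
    for (r, c) in wins:
        assert mask[r:r + 15, c:c + 15].all()
    for i in range(5):
        for j in range(i + 1, 5):
            dr = abs(wins[i][0] - wins[j][0])
            dc = abs(wins[i][1] - wins[j][1])
            assert max(dr, dc) >= 15


def test_window_search_fails_when_the_mask_is_too_small():
    mask = np.zeros((30, 30), bool)
    mask[5:21, 5:21] = True                         # room for exactly one
    assert len(quality.find_windows(mask, size=15, n=1)) == 1
    with pytest.raises(ParameterError):
        quality.find_windows(mask, size=15, n=2)


def test_paired_windows_sit_in_their_materials(small_phantom):
    # the reduced phantom's paraffin annulus is too thin for the full
    # 15-px windows, so the geometry contract is checked at 9 px
    lbl = small_phantom.label_grid
    pairs = quality.paired_windows(lbl, PARAFFIN, TISSUE, size=7, n=5,
                                   z_margin=5, standoff=2)
    assert len({z for z, _, _ in pairs}) == 5
    for z, (ra, ca), (rb, cb) in pairs:
        assert (lbl[z, ra:ra + 7, ca:ca + 7] == PARAFFIN).all()
        assert (lbl[z, rb:rb + 7, cb:cb + 7] == TISSUE).all()


def test_axial_margin_combines_drift_and_fringe_terms():
    # full peak-to-peak excursion in pixels plus three fringe orders
    m = quality.axial_exclusion_margin(3.7, 0.271, 1.5406, 5.0)
    drift_px = int(np.ceil(3.7 / 0.271))
    fringe_px = int(np.ceil(3 * np.sqrt(1.5406e-4 * 5000.0) / 0.271))
    assert m == drift_px + fringe_px
    assert quality.axial_exclusion_margin(0.0, 0.271, 1.5406, 5.0) == fringe_px
    with pytest.raises(ParameterError):
        quality.axial_exclusion_margin(1.0, 0.0, 1.5406, 5.0)


# ----------------------------------------------------------- transmission

def test_transmission_is_the_histogram_peak_ratio():
    rng = np.random.default_rng(5)
    frames = np.empty((20, 32, 32))
    frames[:, :16] = rng.normal(1.0, 0.005, size=(20, 16, 32))   # air
    frames[:, 16:] = rng.normal(0.84, 0.005, size=(20, 16, 32))  # tissue
    air = np.zeros((32, 32), bool)
    air[:16] = True
    tis = ~air
    t = quality.transmission(frames, tis, air)
    assert t == pytest.approx(0.84, abs=0.01)


def test_transmission_mask_contracts():
    frames = np.ones((5, 8, 8))
    m = np.ones((8, 8), bool)
    with pytest.raises(ParameterError):
        quality.transmission(frames, m, m)          # overlapping masks
    with pytest.raises(ParameterError):
        quality.transmission(frames, np.zeros((8, 8), bool), m)


# -------------------------------------------------------------------- SBE

def gaussian_edge(sigma_px, n=200, lo=0.2, hi=1.0):
    step = np.full(n, lo)
    step[n // 2:] = hi
    return ndimage.gaussian_filter1d(step, sigma_px)


def test_sbe_recovers_the_blur_width_of_a_known_edge():
    sigma_px, px_um = 3.0, 0.271
    img = np.tile(gaussian_edge(sigma_px), (20, 1))
    w = quality.sbe(img, (10, 40), (10, 160), pixel_size_um=px_um)
    expected = 2 * special.ndtri(0.9) * sigma_px * px_um
    assert w == pytest.approx(expected, rel=0.02)


def test_sbe_quartile_convention_is_narrower():
    img = np.tile(gaussian_edge(3.0), (20, 1))
    w90 = quality.sbe(img, (10, 40), (10, 160), 0.271, fraction=0.9)
    w75 = quality.sbe(img, (10, 40), (10, 160), 0.271, fraction=0.75)
    assert w75 == pytest.approx(
        w90 * special.ndtri(0.75) / special.ndtri(0.9), rel=1e-3)


def test_sbe_rejects_a_flat_profile():
    img = np.ones((20, 100))
    with pytest.raises(ParameterError):
        quality.sbe(img, (10, 10), (10, 90), 0.271)


def test_line_profile_endpoints_and_length():
    img = np.arange(100.0).reshape(10, 10)
    pos, vals = quality.line_profile(img, (2, 1), (2, 7))
    assert pos[0] == 0.0 and pos[-1] == pytest.approx(6.0)
    assert vals[0] == img[2, 1] and vals[-1] == img[2, 7]
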