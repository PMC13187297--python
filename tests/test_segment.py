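import numpy as np
import pandas as pd
import pytest

from clxm import segment
from clxm.errors import ParameterError


# --------------------------------------------------------- thresholding

def test_relative_threshold_arithmetic_on_a_known_range():
    vol = np.linspace(4080.0, 5830.0, 1000).reshape(10, 10, 10)
    gm = np.ones(vol.shape, bool)
    thr = segment.relative_threshold(vol, gm, 0.469)
    assert thr == pytest.approx(4080 + 0.469 * (5830 - 4080))
    assert round(thr, -2) == 4900


def test_threshold_uses_only_masked_opacities():
    vol = np.zeros((4, 4, 4))
    vol[0, 0, 0] = 1e9                      # outside the mask
    gm = np.zeros(vol.shape, bool)
    gm[2:, 2:, 2:] = True
    vol[gm] = np.linspace(10, 20, int(gm.sum()))
    assert segment.relative_threshold(vol, gm, 0.5) == pytest.approx(15.0)


def test_binarization_is_strictly_greater_and_mask_bound():
    vol = np.array([[[1.0, 2.0, 3.0]]])
    gm = np.array([[[True, True, False]]])
    hdr = segment.binarize_hdr(vol, gm, 2.0)
    assert hdr.tolist() == [[[False, False, False]]]
    hdr = segment.binarize_hdr(vol, gm, 1.5)
    assert hdr.tolist() == [[[False, True, False]]]


def test_threshold_fraction_bounds_are_enforced():
    vol = np.ones((2, 2, 2))
    gm = np.ones((2, 2, 2), bool)
    with pytest.raises(ParameterError):
        segment.relative_threshold(vol, gm, 1.5)
    with pytest.raises(ParameterError):
        segment.relative_threshold(vol, np.zeros((2, 2, 2), bool), 0.5)


def test_threshold_search_volume_fraction_is_monotone():
    rng = np.random.default_rng(2)
    vol = rng.normal(size=(20, 20, 20))
    gm = np.ones(vol.shape, bool)
    grid = np.arange(0.3, 0.71, 0.05)
    table, selected = segment.threshold_search(vol, gm, grid)
    vf = table["volume_fraction"].to_numpy()
    assert (np.diff(vf) <= 1e-12).all()
    assert np.abs(grid - selected).min() < 1e-9
    with pytest.raises(ParameterError):
        segment.threshold_search(vol, gm, np.array([0.5, 1.2]))


# ----------------------------------------------------------- morphology

def test_smoothing_removes_isolated_voxels_but_keeps_blobs():
    m = np.zeros((20, 20, 20), bool)
    m[10, 10, 10] = True                    # speckle
    m[2:8, 2:8, 2:8] = True                 # real blob
    out = segment.smooth_mask(m)
    assert not out[10, 10, 10]
    assert out[4, 4, 4]


# ------------------------------------------------------------- grouping

def test_fifteen_slice_grouping_matches_section_thickness():
    vol = np.arange(33 * 4).reshape(33, 2, 2).astype(float)
    out = segment.group_z_project(vol, group_size=15, reducer=np.max)
    assert out.shape[0] == 3                # 15 + 15 + trailing 3
    assert np.array_equal(out[0], vol[:15].max(axis=0))
    assert np.array_equal(out[-1], vol[30:].max(axis=0))
    with pytest.raises(ParameterError):
        segment.group_z_project(vol, group_size=0)


# ------------------------------------------------------ lesion extraction

def test_lesion_extraction_returns_seeded_components():
    hdr = np.zeros((12, 12, 12), bool)
    hdr[1:4, 1:4, 1:4] = True
    hdr[8:11, 8:11, 8:11] = True
    out = segment.extract_lesion(hdr, [(2, 2, 2), (9, 9, 9)])
    assert out[0].sum() == 27 and out[1].sum() == 27
    assert not (out[0] & out[1]).any()
    with pytest.raises(ParameterError):
        segment.extract_lesion(hdr, [(6, 6, 6)])


def test_lesion_bounding_mask_clips_an_overgrown_component():
    hdr = np.zeros((4, 20, 4), bool)
    hdr[1:3, 2:18, 1:3] = True              # one long connected rod
    bound = np.zeros(hdr.shape, bool)
    bound[:, 2:6, :] = True
    (lesion,) = segment.extract_lesion(hdr, [(1, 3, 1)],
                                       bounding_masks=[bound])
    assert lesion.sum() == (hdr & bound).sum() < hdr.sum()


# -------------------------------------------------------------- volumetry

def test_volumetry_volumes_and_ratios_are_exact(small_phantom):
    masks = {k: small_phantom.mask(k) for k in ("GB", "GM", "PL", "BS",
                                                "HDR")}
    v3 = small_phantom.voxel_size_um ** 3
    df = segment.volumetry(masks, None,
                           small_phantom.voxel_size_um).set_index("region")
    for name, m in masks.items():
        assert df.loc[name, "volume_um3"] == pytest.approx(m.sum() * v3)
    assert df.loc["GM", "ratio_vs_GB"] == pytest.approx(
        masks["GM"].sum() / masks["GB"].sum())
    assert df.loc["HDR", "parent"] == "GM"


def test_volumetry_reruns_bit_for_bit(small_phantom):
    masks = {k: small_phantom.mask(k) for k in ("GB", "GM")}
    op = small_phantom.attenuation_grid
    a = segment.volumetry(masks, op, small_phantom.voxel_size_um)
    b = segment.volumetry(masks, op, small_phantom.voxel_size_um)
    pd.testing.assert_frame_equal(a, b, check_exact=True)


def test_volumetry_shape_mismatch_is_rejected():
    with pytest.raises(ParameterError):
        segment.volumetry({"A": np.ones((2, 2, 2), bool),
                           "B": np.ones((3, 3, 3), bool)}, None, 0.271)


def test_per_cell_volume_worked_example():
    assert segment.per_cell_volume([486, 825, 497], [5, 8, 5]) == \
        pytest.approx((486 + 825 + 497) / 18)
    with pytest.raises(ParameterError):
        segment.per_cell_volume([1.0], [1, 2])
    with pytest.raises(ParameterError):
        segment.per_cell_volume([1.0], [0])
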