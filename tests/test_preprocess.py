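import numpy as np
import pytest

from clxm import beam, preprocess
from clxm.errors import ParameterError, TrackingError


@pytest.fixture(scope="module")
def ff_series(small_series):
    return preprocess.flat_field_correct(small_series)


def marker_detector_position(phantom):
    """(v, u) of the marker on the detector at angle 0."""
    return (phantom.marker_center[0], phantom.marker_center[2])


# ---------------------------------------------------------------- rings

def smooth_object_series(n_frames=100, nv=48, nu=96):
    """Flat-field-corrected frames of a smooth object (no sharp edges),
    the regime the column-equalizer is specified for."""
    u = np.linspace(-1, 1, nu)
    v = np.linspace(-1, 1, nv)
    profile = 1.0 - 0.4 * (1 - u ** 2)
    frames = np.broadcast_to(profile[None, None, :] *
                             (1 - 0.1 * v[None, :, None] ** 2),
                             (n_frames, nv, nu)).astype(np.float32).copy()
    return beam.ProjectionSeries(frames, np.arange(n_frames, dtype=float),
                                 0.271, np.ones((nv, nu), np.float32),
                                 np.zeros((nv, nu), np.float32))


def test_sparse_anomalous_columns_are_equalized():
    """Miscalibrated detector columns (the physical ring source) with 5%
    gain error are reduced to below 0.5% residual."""
    clean = smooth_object_series()
    bad = clean.copy()
    cols = [20, 47, 71]
    bad.frames[:, :, cols] *= 1.05
    fixed = preprocess.reduce_ring_artifacts(bad)
    ref = preprocess.reduce_ring_artifacts(clean).frames.mean(axis=0)
    res = fixed.frames.mean(axis=0)
    rel = np.abs(res[:, cols] - ref[:, cols]) / np.abs(ref[:, cols])
    assert rel.max() <= 0.005


def test_ring_reduction_is_identity_on_stripe_free_data():
    """A column-mean equalizer must leave data with a flat across-angle
    column profile (no stripes) untouched."""
    clean = smooth_object_series()
    # remove all column structure: each row carries a constant value
    clean.frames = np.broadcast_to(
        clean.frames.mean(axis=2, keepdims=True),
        clean.frames.shape).astype(np.float32).copy()
    fixed = preprocess.reduce_ring_artifacts(clean)
    assert np.abs(fixed.frames - clean.frames).max() <= 1e-6


def test_ring_correction_preserves_row_mass(ff_series):
    bad = ff_series.copy()
    bad.frames[:, :, 33] *= 1.04
    fixed = preprocess.reduce_ring_artifacts(bad)
    # the zero-mean correction leaves every row's mean frame sum unchanged
    assert np.allclose(fixed.frames.mean(axis=0).sum(axis=1),
                       bad.frames.mean(axis=0).sum(axis=1), rtol=1e-5)


def test_ring_reduction_needs_enough_frames(ff_series):
    short = ff_series.copy()
    short.frames = short.frames[:10]
    short.angles_deg = short.angles_deg[:10]
    with pytest.raises(ParameterError):
        preprocess.reduce_ring_artifacts(short)


# ------------------------------------------------------- frame brightness

def test_brightness_normalization_equalizes_air_peaks(ff_series):
    wobble = ff_series.copy()
    rng = np.random.default_rng(0)
    scale = 1.0 + 0.1 * rng.standard_normal(wobble.frames.shape[0])
    wobble.frames *= scale[:, None, None].astype(np.float32)
    air = (0, 8, 0, wobble.frames.shape[2])   # rows above the block
    out = preprocess.normalize_frame_brightness(wobble, air)
    peaks = np.array([preprocess._hist_peak(f[0:8]) for f in out.frames])
    assert np.ptp(peaks) <= 0.02 * np.median(peaks)


def test_empty_air_region_is_rejected(ff_series):
    with pytest.raises(ParameterError):
        preprocess.normalize_frame_brightness(ff_series, (4, 4, 0, 10))


# ------------------------------------------------------------- median

def test_median_filter_removes_salt_noise(ff_series):
    sick = ff_series.copy()
    sick.frames[:, 30, 40] = 50.0
    out = preprocess.median_filter_frames(sick, radius=1)
    assert np.abs(out.frames[:, 30, 40]).max() < 2.0


# ----------------------------------------------------- tracking and drift

def test_marker_tracking_residuals_are_subpixel(marker_phantom,
                                                marker_series):
    traj = preprocess.track_marker(marker_series,
                                   marker_detector_position(marker_phantom))
    traj = preprocess.fit_trajectory(traj)
    assert np.abs(traj.residual_u).max() < 0.5
    assert np.abs(traj.residual_v).max() < 0.5
    # the fitted sinusoid amplitude equals the marker's radial distance
    c = marker_phantom.marker_center
    ny, nx = marker_phantom.label_grid.shape[1:]
    r = np.hypot(c[1] - (ny - 1) / 2, c[2] - (nx - 1) / 2)
    assert traj.params["amplitude_px"] == pytest.approx(r, abs=0.5)


def test_vertical_drift_is_recovered_and_compensated(marker_phantom,
                                                     marker_series):
    drifted, track = beam.inject_drift(marker_series, 0.0, 2.0, seed=11)
    traj = preprocess.fit_trajectory(
        preprocess.track_marker(drifted,
                                marker_detector_position(marker_phantom)))
    est_v = traj.widths_um[1]
    assert est_v == pytest.approx(2.0, abs=marker_series.pixel_size_um)
    table = preprocess.build_compensation(traj, "vertical_only")
    fixed = preprocess.apply_compensation(drifted, table)
    after = preprocess.fit_trajectory(
        preprocess.track_marker(fixed,
                                marker_detector_position(marker_phantom)))
    # closed loop: compensation removes at least 80% of the drift width
    assert after.widths_um[1] <= 0.2 * est_v


def test_tracking_fails_loudly_without_a_marker(marker_series):
    # a search window entirely in featureless air has no absorbing blob
    with pytest.raises(TrackingError) as err:
        preprocess.track_marker(marker_series, (3, 48), search_radius=3)
    assert err.value.frame == 0


def test_oversized_compensation_is_rejected(marker_series):
    n = marker_series.frames.shape[0]
    table = preprocess.CompensationTable(np.zeros(n),
                                         np.full(n, 50.0), "vertical_only")
    with pytest.raises(ParameterError):
        preprocess.apply_compensation(marker_series, table)


# ------------------------------------------------------------- Paganin

def test_paganin_with_negligible_delta_beta_is_neg_log(ff_series):
    s = ff_series.copy()
    s.delta_beta = 1e-12
    out = preprocess.paganin_retrieve(s)
    ref = preprocess.to_line_integral(ff_series)
    assert np.allclose(out.frames, ref.frames, atol=1e-4)


def test_paganin_suppresses_noise_variance(ff_series):
    noisy = ff_series.copy()
    rng = np.random.default_rng(1)
    noisy.frames = (noisy.frames *
                    (1 + 0.02 * rng.standard_normal(noisy.frames.shape))
                    ).astype(np.float32)
    # propagate the same noise through -log and through Paganin: the
    # retrieval's low-pass must shrink the noise variance by >= 10x
    noise_ref = (preprocess.to_line_integral(noisy).frames -
                 preprocess.to_line_integral(ff_series).frames)
    noise_ret = (preprocess.paganin_retrieve(noisy).frames -
                 preprocess.paganin_retrieve(ff_series).frames)
    assert noise_ref.var() / noise_ret.var() >= 10.0


# -------------------------------------------------------------- presets

def test_disease_preset_applies_published_stage_order(small_phantom,
                                                      small_series):
    noisy = beam.add_detector_effects(small_series, 0.02, poisson=True,
                                      seed=9)
    pos = (small_phantom.marker_center[0], small_phantom.marker_center[2])
    out, artifacts = preprocess.run_preset_pipeline(noisy, "disease",
                                                    marker_position=pos)
    stages = [s.split("(")[0] for s in out.provenance]
    order = ["flat_field", "ring_reduction", "drift_correction",
             "paganin", "median_filter"]
    idx = [stages.index(s) for s in order]
    assert idx == sorted(idx)
    assert artifacts["compensation"].mode == "vertical_only"


def test_unknown_preset_is_rejected(small_series):
    with pytest.raises(ParameterError):
        preprocess.run_preset_pipeline(small_series, "fancy",
                                       marker_position=(1, 1))
    with pytest.raises(ParameterError):
        preprocess.run_preset_pipeline(small_series, "disease")
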