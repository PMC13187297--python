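import numpy as np
import pytest

from clxm import register
from clxm.errors import GeometryError, ParameterError
from clxm.geometry import (RigidTransform, random_rotation,
                           rotation_about_axis, rotation_angle_deg)


def random_pose(rng):
    return RigidTransform(random_rotation(rng), rng.normal(0, 5, 3))


def cloud(rng, n=10, span=40.0):
    return rng.uniform(-span / 2, span / 2, size=(n, 3))


# --------------------------------------------------------------- Kabsch

def test_pose_estimation_is_exact_without_noise():
    rng = np.random.default_rng(0)
    p = cloud(rng)
    ref = random_pose(rng)
    pose = register.estimate_pose(register.LandmarkSet(p, ref.apply(p)))
    assert np.allclose(pose.rotation, ref.rotation, atol=1e-9)
    assert np.allclose(pose.translation, ref.translation, atol=1e-9)
    assert pose.rmsd_um == pytest.approx(0.0, abs=1e-9)


def test_pose_estimation_is_invariant_to_a_common_motion():
    rng = np.random.default_rng(1)
    p = cloud(rng)
    ref = random_pose(rng)
    q = ref.apply(p) + rng.normal(0, 0.5, p.shape)
    pose = register.estimate_pose(register.LandmarkSet(p, q))
    g = random_pose(rng)
    moved = register.estimate_pose(
        register.LandmarkSet(g.apply(p), g.apply(q)))
    # the estimate transforms covariantly: moved = g o pose o g^-1
    expected = g.compose(pose).compose(g.inverse())
    assert register.orientation_residual(moved, expected) < 1e-5
    assert moved.rmsd_um == pytest.approx(pose.rmsd_um, abs=1e-9)


def test_degenerate_landmarks_are_rejected():
    line = np.outer(np.arange(5, dtype=float), [1.0, 2.0, 3.0])
    with pytest.raises(GeometryError):
        register.estimate_pose(register.LandmarkSet(line, line))
    with pytest.raises(ParameterError):
        register.LandmarkSet(np.zeros((2, 3)), np.zeros((2, 3)))


def test_orientation_residual_is_the_axis_angle_gap():
    a = RigidTransform(rotation_about_axis([0, 0, 1], 10.0), np.zeros(3))
    b = RigidTransform(np.eye(3), np.zeros(3))
    assert register.orientation_residual(a, b) == pytest.approx(10.0)
    assert register.orientation_residual(a, a) == pytest.approx(0.0, abs=1e-9)


def test_residual_shrinks_in_expectation_as_landmarks_grow():
    rng = np.random.default_rng(4)
    means = []
    for n in (4, 6, 10, 20):
        res = []
        for _ in range(40):
            p = cloud(rng, n=n)
            ref = random_pose(rng)
            q = ref.apply(p) + rng.normal(0, 0.5, p.shape)
            pose = register.estimate_pose(register.LandmarkSet(p, q))
            res.append(register.orientation_residual(pose, ref))
        means.append(np.mean(res))
    assert all(b < a for a, b in zip(means, means[1:]))


# ---------------------------------------------------------- nuclei blobs

def test_nuclei_detection_localizes_synthetic_particles():
    rng = np.random.default_rng(6)
    vol = np.zeros((48, 48, 48))
    centers = rng.uniform(10, 38, size=(6, 3))
    zz, yy, xx = np.mgrid[:48, :48, :48].astype(float)
    for c in centers:
        r2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        vol += np.exp(-r2 / (2 * 2.0 ** 2))
    det = register.detect_nuclei(vol, voxel_size_um=0.271,
                                 diameter_range_um=(2.0, 3.0))
    assert len(det) >= len(centers)
    for c in centers:
        err = np.linalg.norm(det - c, axis=1).min()
        assert err < 1.0


def test_detection_on_a_constant_volume_is_empty():
    det = register.detect_nuclei(np.zeros((16, 16, 16)), voxel_size_um=0.271)
    assert det.shape == (0, 3)


# ------------------------------------------------------------------ slab

def test_identity_slab_is_the_max_projection(small_phantom):
    arr = small_phantom.attenuation_grid.astype(float)
    vs = small_phantom.voxel_size_um
    n = 8
    pose = RigidTransform(np.eye(3), np.zeros(3))
    slab = register.resample_slab(arr, pose, thickness_um=n * vs,
                                  voxel_size_um=vs)
    assert np.allclose(slab, arr[:n].max(axis=0), atol=1e-9)


def test_slab_outside_the_volume_is_rejected(small_phantom):
    arr = small_phantom.attenuation_grid.astype(float)
    vs = small_phantom.voxel_size_um
    pose = RigidTransform(np.eye(3), np.array([-200.0, 0.0, 0.0]))
    with pytest.raises(GeometryError):
        register.resample_slab(arr, pose, thickness_um=4.0, voxel_size_um=vs)
    with pytest.raises(ParameterError):
        register.resample_slab(arr, pose, thickness_um=-1.0,
                               voxel_size_um=vs)


# ------------------------------------------------------------ round trip

def test_section_registration_wrapper_recovers_the_pose(small_phantom):
    """2D section landmarks paired with 3D nuclei recover the reference
    pose exactly when the nuclei lie on the section midplane (the
    wrapper's stated depth convention)."""
    from clxm.recon import quantize_16bit

    vs = small_phantom.voxel_size_um
    th = 4.0
    vol = quantize_16bit(small_phantom.attenuation_grid.astype(float), vs)
    rng = np.random.default_rng(9)
    vol3d_vox = rng.uniform(10, 80, size=(10, 3))
    ref = RigidTransform(rotation_about_axis([1, 1, 0], 5.0),
                         np.array([0.0, 1.0, -1.0]))
    sec3d = ref.apply(vol3d_vox * vs)
    # place the nuclei exactly on the section midplane
    sec3d[:, 0] = th / 2.0
    vol3d_vox = ref.inverse().apply(sec3d) / vs
    sec2d = sec3d[:, 1:] / vs
    pose = register.register_section(vol, sec2d, vol3d_vox,
                                     section_pixel_um=vs, thickness_um=th,
                                     reference_pose=ref)
    assert pose.orientation_residual_deg == pytest.approx(0.0, abs=1e-6)
    assert pose.rmsd_um == pytest.approx(0.0, abs=1e-6)
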