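"""Forward simulation of quasi-parallel-beam projection acquisition.

The acquisition model mirrors a laboratory X-ray microscope with Cu-Kalpha
radiation and magnification 1: attenuation line integrals through the
rotating phantom, optional single-material Fresnel propagation (the
forward counterpart of Paganin retrieval), per-frame rigid drift, a fixed
per-column detector gain pattern (the source of ring artifacts) and
Poisson counting noise.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError, StageOrderError
from .phantom import Phantom

CU_KALPHA_A = 1.5406  # wavelength, Angstrom


@dataclass
class ProjectionSeries:
    """An angular stack of detector frames with acquisition metadata.

    ``frames`` has shape (n_angles, n_v, n_u); rows v run along the
    rotation axis (z), columns u across it.  Intensities are in counts
    until a preprocessing stage converts them to line integrals.
    """

    frames: np.ndarray
    angles_deg: np.ndarray
    pixel_size_um: float
    flat_frame: np.ndarray
    dark_frame: np.ndarray
    wavelength_A: float = CU_KALPHA_A
    distance_mm: float = 5.0
    delta_beta: float = 100.0
    incident_intensity: float = 1.0e4
    seed: int = 0
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.frames.shape[0] != self.angles_deg.size:
            raise ParameterError("angle count must equal frame count")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ParameterError("angles must be strictly increasing")

    def copy(self) -> "ProjectionSeries":
        new = copy.copy(self)
        new.frames = self.frames.copy()
        new.provenance = list(self.provenance)
        return new

    def log(self, stage: str) -> None:
        self.provenance.append(stage)

    def has_stage(self, stage: str) -> bool:
        return any(s.startswith(stage) for s in self.provenance)


@dataclass
class DriftTrack:
    """Ground-truth per-frame rigid shifts injected into a series."""

    du_px: np.ndarray
    dv_px: np.ndarray
    pixel_size_um: float
    model: dict = field(default_factory=dict)

    @property
    def widths_um(self) -> tuple:
        """Peak-to-peak extent (horizontal, vertical) in micrometres."""
        return (float(np.ptp(self.du_px)) * self.pixel_size_um,
                float(np.ptp(self.dv_px)) * self.pixel_size_um)


# ---------------------------------------------------------------------------

def project_attenuation(phantom: Phantom, angles_deg: np.ndarray,
                        incident_intensity: float = 1.0e4,
                        wavelength_A: float = CU_KALPHA_A,
                        distance_mm: float = 5.0,
                        delta_beta: float = 100.0,
                        seed: int = 0) -> ProjectionSeries:
    """Parallel-ray attenuation projections of the phantom.

    frame(theta) = I0 * exp(-integral mu dl) with rays along +y after
    rotating the phantom by theta about z; sampling is linear
    interpolation.  Raises :class:`GeometryError` if attenuating material
    lies outside the inscribed cylinder (it would leave the field of view
    under rotation).
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    mu = phantom.attenuation_grid
    nz, ny, nx = mu.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    outside = (r > min(ny, nx) / 2.0 - 1.0)
    if np.any(mu.max(axis=0)[outside] > 0):
        raise GeometryError("phantom attenuation extends outside the field of view")

    frames = np.empty((angles_deg.size, nz, nx), dtype=np.float32)
    for i, theta in enumerate(angles_deg):
        if theta % 360.0 == 0.0:
            rot = mu
        else:
            rot = ndimage.rotate(mu, theta, axes=(1, 2), reshape=False,
                                 order=1, prefilter=False)
        b = rot.sum(axis=1) * phantom.voxel_size_um
        frames[i] = incident_intensity * np.exp(-b)

    flat = np.full((nz, nx), incident_intensity, dtype=np.float32)
    dark = np.zeros((nz, nx), dtype=np.float32)
    series = ProjectionSeries(frames, angles_deg, phantom.voxel_size_um,
                              flat, dark, wavelength_A, distance_mm,
                              delta_beta, incident_intensity, seed)
    series.log("project_attenuation")
    return series


def _fresnel_propagator(shape, pixel_um, wavelength_A, distance_mm):
    lam = wavelength_A * 1.0e-4   # um
    dist = distance_mm * 1.0e3    # um
    fv = np.fft.fftfreq(shape[0], d=pixel_um)
    fu = np.fft.fftfreq(shape[1], d=pixel_um)
    f2 = fv[:, None] ** 2 + fu[None, :] ** 2
    return np.exp(-1j * np.pi * lam * dist * f2)


def apply_fresnel(series: ProjectionSeries) -> ProjectionSeries:
    """Single-material Fresnel propagation of each frame.

    The object is treated as homogeneous with the series' delta/beta: the
    exit wave is exp(-B/2 - i (delta/beta) B/2) with B the attenuation
    line integral, propagated by the angular-spectrum operator over the
    stored distance.  At distance 0 the output equals the input.
    """
    if series.has_stage("poisson_noise"):
        raise StageOrderError("Fresnel propagation must precede noise injection")
    out = series.copy()
    if series.distance_mm == 0:
        out.log("apply_fresnel(R=0)")
        return out
    h = _fresnel_propagator(series.frames.shape[1:], series.pixel_size_um,
                            series.wavelength_A, series.distance_mm)
    i0 = series.incident_intensity
    for i, frame in enumerate(series.frames):
        b = -np.log(np.clip(frame / i0, 1e-9, None))
        wave = np.exp(-0.5 * b * (1.0 + 1j * series.delta_beta))
        prop = np.fft.ifft2(np.fft.fft2(wave) * h)
        out.frames[i] = i0 * np.abs(prop).astype(np.float32) ** 2
    out.log("apply_fresnel")
    return out


def make_drift(n_frames: int, width_u_um: float, width_v_um: float,
               pixel_size_um: float, seed: int = 0,
               jitter_frac: float = 0.25) -> DriftTrack:
    """Smooth monotone ramp plus jitter, rescaled to exact peak-to-peak widths.

    The ramp emulates slow thermal relaxation (a smoothstep in frame
    number); the jitter is low-pass-filtered Gaussian noise contributing
    ``jitter_frac`` of the excursion before rescaling.
    """
    if width_u_um < 0 or width_v_um < 0:
        raise ParameterError("drift widths must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_frames)
    ramp = 3 * t ** 2 - 2 * t ** 3

    def one(width_um):
        if width_um == 0:
            return np.zeros(n_frames)
        jit = ndimage.gaussian_filter1d(rng.normal(size=n_frames), 5.0)
        jit = jit / (np.ptp(jit) or 1.0)
        x = ramp + jitter_frac * jit
        x = (x - x.min()) / np.ptp(x)            # exact [0, 1] excursion
        return (x - 0.5) * (width_um / pixel_size_um)

    du = one(width_u_um)
    dv = one(width_v_um)
    return DriftTrack(du, dv, pixel_size_um,
                      model={"ramp": "smoothstep", "jitter_frac": jitter_frac,
                             "seed": seed})


def inject_drift(series: ProjectionSeries, width_u_um: float, width_v_um: float,
                 seed: int = 0) -> tuple:
    """Shift every frame by a drift trajectory; returns (series, DriftTrack)."""
    track = make_drift(series.frames.shape[0], width_u_um, width_v_um,
                       series.pixel_size_um, seed)
    out = apply_shifts(series, track.du_px, track.dv_px)
    out.log(f"inject_drift(u={width_u_um},v={width_v_um})")
    return out, track


def apply_shifts(series: ProjectionSeries, du_px: np.ndarray,
                 dv_px: np.ndarray) -> ProjectionSeries:
    """Subpixel-translate each frame by (du, dv), bilinear, edge-extended."""
    out = series.copy()
    for i in range(out.frames.shape[0]):
        if du_px[i] == 0 and dv_px[i] == 0:
            continue
        out.frames[i] = ndimage.shift(series.frames[i], (dv_px[i], du_px[i]),
                                      order=1, mode="nearest")
    return out


def add_detector_effects(series: ProjectionSeries,
                         gain_stripe_amplitude: float = 0.0,
                         poisson: bool = True, seed: int = 0) -> ProjectionSeries:
    """Fixed-pattern column gain followed by Poisson counting noise.

    The same gain field multiplies the flat frame, so flat-field
    correction can cancel it; Poisson noise is applied to the frames only
    (the flat is treated as a long-exposure average).
    """
    if gain_stripe_amplitude < 0:
        raise ParameterError("gain amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    out = series.copy()
    n_u = out.frames.shape[2]
    if gain_stripe_amplitude > 0:
        g = rng.normal(size=n_u)
        g = (g - g.mean()) / g.std()
        gain = 1.0 + gain_stripe_amplitude * g
        out.frames *= gain[None, None, :].astype(np.float32)
        out.flat_frame = out.flat_frame * gain[None, :].astype(np.float32)
        out.log(f"column_gain({gain_stripe_amplitude})")
    if poisson:
        out.frames = rng.poisson(np.clip(out.frames, 0, None)).astype(np.float32)
        out.log("poisson_noise")
    return out
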