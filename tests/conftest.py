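"""Shared fixtures: small, fast phantoms and projection series.

The package defaults mirror the full study conditions and are exercised
by the acceptance-scale tests; unit tests run on reduced geometries that
keep every physical property intact.
"""
import numpy as np
import pytest

from clxm import beam
from clxm.phantom import PhantomParams, build_kidney_phantom

# A reduced phantom that still contains the full region hierarchy.
SMALL = PhantomParams(shape=(96, 96, 96), tissue_radius_frac=0.35,
                      gb_volume_um3=1500.0,
                      lesion_volumes_um3=(3.5, 5.9, 3.6),
                      n_nuclei=12, paraffin_z_inset=12)

# Marker-only phantom for tracking / drift studies.
MARKER_ONLY = PhantomParams(shape=(64, 96, 96), tissue_radius_frac=0.30,
                            include_glomerulus=False, include_nuclei=False,
                            n_nuclei=0, paraffin_z_inset=10,
                            marker_diameter_vox=4.0)


@pytest.fixture(scope="session")
def small_phantom():
    return build_kidney_phantom(SMALL, seed=1)


@pytest.fixture(scope="session")
def marker_phantom():
    return build_kidney_phantom(MARKER_ONLY, seed=2)


@pytest.fixture(scope="session")
def marker_series(marker_phantom):
    """Noiseless attenuation projections of the marker phantom."""
    angles = np.linspace(0.0, 180.0, 120, endpoint=False)
    return beam.project_attenuation(marker_phantom, angles)


@pytest.fixture(scope="session")
def small_series(small_phantom):
    angles = np.linspace(0.0, 180.0, 120, endpoint=False)
    return beam.project_attenuation(small_phantom, angles)
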