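"""Shared phantom fixtures (generated at test time, module-scoped)."""

import numpy as np
import pytest

import dissectflow as df


@pytest.fixture(scope="session")
def tube():
    """Steady parabolic tube: R=10 mm, v_peak=1 m/s, 2.5 mm grid."""
    spec = df.PhantomSpec(geometry="straight-tube", radius_mm=10.0,
                          peak_velocity_ms=1.0, waveform="steady",
                          n_phases=20, spacing_mm=2.5, length_mm=160.0)
    return df.make_tube_phantom(spec)


@pytest.fixture(scope="session")
def tube_centerline(tube):
    _, mask, _ = tube
    skel = df.extract_skeleton(mask)
    cl = df.order_and_prune(skel, [0.0, 0.0, 0.0], mask.affine)
    return df.resample(cl, 1.0)


@pytest.fixture(scope="session")
def tube_sections(tube, tube_centerline):
    _, mask, _ = tube
    return df.place_cross_sections(tube_centerline, mask)


@pytest.fixture(scope="session")
def helical():
    """Rigid rotation Omega=5 rad/s + uniform axial 0.5 m/s, one phase."""
    spec = df.PhantomSpec(geometry="straight-tube", radius_mm=10.0,
                          peak_velocity_ms=0.5, angular_velocity_rads=5.0,
                          waveform="steady", n_phases=1, length_mm=40.0)
    return df.make_helical_phantom(spec)


@pytest.fixture(scope="session")
def dissection():
    """60/40 TL/FL split, 30% FL retrograde, noise SD 0.05 m/s, pocket."""
    spec = df.PhantomSpec(geometry="straight-tube", radius_mm=12.0,
                          waveform="systolic-pulse", noise_sd_ms=0.05,
                          length_mm=140.0, n_phases=20, seed=3)
    return df.make_dissection_phantom(spec, tl_fraction=0.6,
                                      fl_reverse_fraction=0.3,
                                      total_volume_ml=70.0)


@pytest.fixture(scope="session")
def dissection_centerline(dissection):
    _, mask, gt = dissection
    skel = df.extract_skeleton(mask, close_radius_vox=1)
    cl = df.order_and_prune(skel, gt.meta["landmarks"]["seed"], mask.affine)
    return df.resample(cl, 1.0)


@pytest.fixture(scope="session")
def dissection_sections(dissection, dissection_centerline):
    _, mask, _ = dissection
    return df.place_cross_sections(dissection_centerline, mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
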