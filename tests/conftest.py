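import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("repro", derandomize=True)
hyp_settings.load_profile("repro")

from vfadose import (
    BeamModel,
    PhantomSpec,
    ScanProtocol,
    precompute_acquisition,
)


@pytest.fixture
def protocol():
    return ScanProtocol()


@pytest.fixture(scope="session")
def small_spec():
    """A reduced vial/beam that keeps full-chain tests fast."""
    return PhantomSpec(
        vial_diameter_mm=16.0,
        vial_length_mm=24.0,
        gel_start_mm=2.0,
        kspace_matrix=(32, 24),
        n_slices=24,
        oversample_factor=4,
        beam=BeamModel(
            entrance_dose_gy=300.0,
            peak_depth_mm=14.0,
            peak_width_mm=2.0,
            distal_falloff_mm=0.5,
            penumbra_min_depth_mm=10.0,
            field_side_mm=6.0,
        ),
    )


@pytest.fixture(scope="session")
def small_acq(small_spec):
    return precompute_acquisition(small_spec)


@pytest.fixture(scope="session")
def dose_series():
    """Precomputed (noiseless) acquisitions for the ESD series
    150/300/450/600 Gy at the default phantom; the 600 Gy entry carries
    the shared unirradiated control."""
    series = {}
    for esd in (150.0, 300.0, 450.0, 600.0):
        spec = PhantomSpec(beam=BeamModel(entrance_dose_gy=esd))
        series[esd] = precompute_acquisition(
            spec, include_control=(esd == 600.0)
        )
    return series


def realize_series(series, seed):
    """One noise realization of the full ESD series with a shared control.

    Returns (irradiated volume sets by ESD, control volume set).
    """
    from vfadose.phantom import _rician
    from vfadose import FlipAngleVolumeSet

    acq600 = series[600.0]
    rng = np.random.default_rng(seed)
    spacing = (acq600.spec.voxel_mm,) * 3
    control = FlipAngleVolumeSet(
        [_rician(s, acq600.noise_sigma_control, rng) for s in acq600.control_signals],
        spacing,
        acq600.protocol.flip_angles_deg,
    )
    irradiated = {}
    for esd, acq in series.items():
        irradiated[esd] = FlipAngleVolumeSet(
            [_rician(s, acq.noise_sigma_irradiated, rng) for s in acq.irradiated_signals],
            spacing,
            acq.protocol.flip_angles_deg,
        )
    return irradiated, control
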