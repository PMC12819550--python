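import numpy as np
import pytest

from needlebend.phantom import (
    NeedleCurveSpec,
    PhantomTruth,
    TemplateRegion,
    make_needle_curve,
    rasterize,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_small_phantom(
    seed: int = 0,
    theta_deg: float = 0.0,
    phi_deg: float = 0.0,
    tilt_deg: float = 0.0,
    tilt_az_deg: float = 0.0,
    noise_sigma: float = 20.0,
    nominal_length: float = 90.0,
    artifact_density: float = 0.3,
    with_template_band: bool = True,
):
    """One-needle phantom on a small grid (64 x 128 x 128, default spacing).

    The needle enters the template air-side face at z = 96 mm and runs
    cranially; template band occupies z in [81, 96] mm.  Returns
    (volume, truth, template, spec).
    """
    rng = np.random.default_rng(seed)
    z_entry = 96.0
    tilt = np.radians(tilt_deg)
    az = np.radians(tilt_az_deg)
    direction = np.array(
        [-np.cos(tilt), np.sin(tilt) * np.cos(az), np.sin(tilt) * np.sin(az)]
    )
    spec = NeedleCurveSpec(
        nominal_length=nominal_length,
        insertion_point=np.array([z_entry, 0.0, 0.0]),
        entry_direction=direction,
        straight_extent=45.0,
        arc_angle_deg=theta_deg,
        bend_azimuth_deg=phi_deg,
        air_overhang=20.0,
    )
    curve = make_needle_curve(spec)
    truth = PhantomTruth(
        curves=[curve], specs=[spec], probe_axis=None,
        truncation_mm=np.zeros(1), seed=seed,
    )
    template = TemplateRegion(
        z_body_border=z_entry - 15.0, z_air_border=z_entry,
        artifact_density=artifact_density if with_template_band else 0.0,
    )
    volume = rasterize(
        truth,
        shape=(64, 128, 128),
        spacing=(2.0, 0.3, 0.3),
        origin=(0.0, -19.05, -19.05),
        template=template,
        noise_sigma=noise_sigma,
        rng=rng,
    )
    return volume, truth, template, spec


@pytest.fixture
def small_phantom():
    return make_small_phantom(seed=3)
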