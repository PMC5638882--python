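"""Forward model: dipole intensity law, DIC/parallax rendering, noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paradic import (
    InstrumentModel,
    NanorodPose,
    add_noise,
    dipole_intensities,
    render_fullplane,
    render_parallax,
)


@pytest.mark.parametrize(
    "phi, psi, expected",
    [
        (0.0, 90.0, (1.0, 0.0)),  # rod along bright axis: fully bright image
        (90.0, 90.0, (0.0, 1.0)),  # rod along dark axis: fully dark image
        (45.0, 90.0, (0.25, 0.25)),  # bisector: cos^4(45) = 1/4 each
        (17.0, 0.0, (0.0, 0.0)),  # rod along optical axis: no projection
        (45.0, 45.0, (1 / 16, 1 / 16)),  # (sin45*cos45)^4 = 1/16
    ],
)
def test_dipole_intensity_law(phi, psi, expected):
    i_b, i_d = dipole_intensities(NanorodPose(phi=phi, psi=psi))
    assert i_b == pytest.approx(expected[0], abs=1e-12)
    assert i_d == pytest.approx(expected[1], abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(
    phi=st.floats(-720, 720, allow_nan=False),
    psi=st.floats(-360, 360, allow_nan=False),
)
def test_dipole_intensities_bounded_and_symmetric(phi, psi):
    """Channel intensities stay in [0,1] and swap under phi -> 90 - phi."""
    pose = NanorodPose(phi=phi, psi=psi)
    i_b, i_d = dipole_intensities(pose)
    assert 0.0 <= i_b <= 1.0 and 0.0 <= i_d <= 1.0
    j_b, j_d = dipole_intensities(NanorodPose(phi=90.0 - phi, psi=psi))
    assert j_b == pytest.approx(i_d, abs=1e-9)
    assert j_d == pytest.approx(i_b, abs=1e-9)


@settings(max_examples=50, derandomize=True)
@given(
    phi=st.floats(-720, 720, allow_nan=False),
    psi=st.floats(-360, 360, allow_nan=False),
)
def test_canonicalization_idempotent(phi, psi):
    once = NanorodPose(phi=phi, psi=psi).canonicalized()
    twice = once.canonicalized()
    assert 0.0 <= once.phi < 180.0 and 0.0 <= once.psi <= 90.0
    assert once == twice


def test_fullplane_extrema_match_lobe_amplitudes(inst):
    """Noiseless peak excursions equal b0 +/- A*I when lobes sit on the grid."""
    b0, amp = inst.background, inst.amplitude
    shape = (33, 33)  # odd frame: spot centre on a pixel
    x_on_grid = (1.0 - inst.shear[1] / 2.0) * inst.pixel_size
    bright = render_fullplane(NanorodPose(x=x_on_grid, phi=0, psi=90), inst, shape)
    # single bright lobe: minimum stays at background
    assert bright.max() == pytest.approx(b0 + amp, rel=1e-9)
    assert bright.min() == pytest.approx(b0, abs=1e-6)
    dark = render_fullplane(NanorodPose(x=-x_on_grid, phi=90, psi=90), inst, shape)
    assert dark.min() == pytest.approx(b0 - amp, rel=1e-9)
    assert dark.max() == pytest.approx(b0, abs=1e-6)


def test_axial_rod_renders_flat_background(inst):
    img = render_fullplane(NanorodPose(phi=30, psi=0), inst)
    assert np.allclose(img, inst.background)


def test_out_of_field_pose_rejected(inst):
    with pytest.raises(ValueError, match="out of field"):
        render_fullplane(NanorodPose(x=5e4), inst)
    with pytest.raises(ValueError, match="out of field"):
        render_parallax(NanorodPose(y=1e5), inst)


def test_parallax_pair_mirror_symmetric(inst):
    """The two half-plane spots are exact mirror images about the split axis.

    An odd frame height with even separation puts both spot centres on the
    pixel grid, so the reflection is exact to numerical precision.
    """
    shape = (65, 48)
    pose = NanorodPose(phi=35, psi=75, z=0.0)
    img = render_parallax(pose, inst, shape)
    assert np.allclose(img, img[::-1, :], atol=1e-9)


def test_parallax_separation_linear_in_z(inst):
    """Noiseless pair separation follows d = d0 + g*z exactly."""
    shape = (64, 48)
    rows = np.arange(shape[0])
    for z in (-400.0, -100.0, 0.0, 250.0, 500.0):
        img = render_parallax(NanorodPose(phi=0, psi=90, z=z), inst, shape)
        profile = ((img - inst.background) ** 2).sum(axis=1)
        top, bottom = profile[: shape[0] // 2], profile[shape[0] // 2 :]
        r_u = np.sum(rows[: shape[0] // 2] * top) / top.sum()
        r_l = np.sum(rows[shape[0] // 2 :] * bottom) / bottom.sum()
        expected = inst.d0 + inst.gain_px_per_nm * z
        assert r_l - r_u == pytest.approx(expected, abs=5e-3)


def test_integrated_signal_translation_invariant(inst):
    """sum(image - b0) does not change under in-plane translation."""
    ref = render_fullplane(NanorodPose(phi=20, psi=80), inst)
    shifted = render_fullplane(NanorodPose(x=300.0, y=-200.0, phi=20, psi=80), inst)
    total_ref = (ref - inst.background).sum()
    total_shift = (shifted - inst.background).sum()
    assert total_shift == pytest.approx(total_ref, rel=1e-6)


def test_defocus_conserves_integrated_signal(inst):
    focus = render_fullplane(NanorodPose(phi=0, psi=90, z=0), inst)
    blurred = render_fullplane(NanorodPose(phi=0, psi=90, z=400), inst)
    assert blurred.max() < focus.max()  # broader and dimmer at the peak
    assert (blurred - inst.background).sum() == pytest.approx(
        (focus - inst.background).sum(), rel=1e-3
    )


def test_noise_reproducible_and_optional(inst, quiet_inst):
    img = render_parallax(NanorodPose(phi=30, psi=80), inst)
    assert np.array_equal(add_noise(img, quiet_inst, seed=7), img)
    a = add_noise(img, inst, seed=3)
    b = add_noise(img, inst, seed=3)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, add_noise(img, inst, seed=4))


def test_noise_rejects_negative_counts(inst):
    with pytest.raises(ValueError, match="negative"):
        add_noise(np.full((4, 4), -1.0), inst, seed=0)


def test_lobe_snr_improves_with_amplitude(inst):
    """Doubling the signal amplitude raises the bright-lobe SNR (Monte Carlo)."""
    rng = np.random.default_rng(0)
    snrs = []
    for amp in (700.0, 1400.0):
        instrument = InstrumentModel(amplitude=amp)
        img = render_fullplane(NanorodPose(phi=0, psi=90), instrument)
        peak = np.unravel_index(np.argmax(img), img.shape)
        draws = np.array(
            [add_noise(img, instrument, rng)[peak] for _ in range(1000)]
        )
        snrs.append(amp / draws.std(ddof=1))
    assert snrs[1] > snrs[0]
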