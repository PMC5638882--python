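"""Forward image model: DIC spots of a rod-like dipole, full-plane and parallax.

A rod-shaped plasmonic probe in DIC appears as an anti-symmetric pair of
bright and dark Gaussian lobes on a gray background.  The lobe amplitudes
follow the fourth-power projection of the rod onto the two orthogonal
polarization axes of the microscope:

    I_B = (sin(psi) * cos(phi))**4      (bright channel)
    I_D = (sin(psi) * sin(phi))**4      (dark channel)

In parallax mode the collection aperture is split and two half-plane images
of the same probe are formed, mirror images of each other about the split
axis, whose separation d varies linearly with axial position:
``d = d0 + g * z``.
"""

from __future__ import annotations

import numpy as np

from .instrument import InstrumentModel, NanorodPose

__all__ = [
    "dipole_intensities",
    "render_fullplane",
    "render_parallax",
    "add_noise",
    "DEFAULT_FULLPLANE_SHAPE",
    "DEFAULT_PARALLAX_SHAPE",
]

DEFAULT_FULLPLANE_SHAPE = (32, 32)
DEFAULT_PARALLAX_SHAPE = (64, 48)


def dipole_intensities(pose: NanorodPose) -> tuple[float, float]:
    """Normalized bright/dark channel intensities of a rod at the given pose.

    Returns ``(I_B, I_D)``, both in ``[0, 1]``: the fourth powers of the
    effective projections of the rod's long axis onto the bright and dark
    polarization directions.  Total function; swapping ``phi -> 90 - phi``
    swaps the two channels exactly.
    """
    pose = pose.canonicalized()
    phi = np.deg2rad(pose.phi)
    psi = np.deg2rad(pose.psi)
    s = np.sin(psi)
    i_b = (s * np.cos(phi)) ** 4
    i_d = (s * np.sin(phi)) ** 4
    return float(i_b), float(i_d)


def _lobe_pair(
    rows: np.ndarray,
    cols: np.ndarray,
    center: tuple[float, float],
    amplitudes: tuple[float, float],
    sigma_row: float,
    sigma_col: float,
    shear: tuple[float, float],
    mirror: bool = False,
) -> np.ndarray:
    """Bright-minus-dark Gaussian lobe pair centred at ``center`` (row, col).

    ``mirror=True`` reflects the pattern about the split (row) axis, i.e.
    negates the row component of the shear; this is how the second half-plane
    image of a pair is formed.
    """
    a_b, a_d = amplitudes
    s_r, s_c = shear
    if mirror:
        s_r = -s_r
    r0, c0 = center
    rb, cb = r0 + s_r / 2.0, c0 + s_c / 2.0
    rd, cd = r0 - s_r / 2.0, c0 - s_c / 2.0
    bright = np.exp(
        -((rows - rb) ** 2 / (2 * sigma_row**2) + (cols - cb) ** 2 / (2 * sigma_col**2))
    )
    dark = np.exp(
        -((rows - rd) ** 2 / (2 * sigma_row**2) + (cols - cd) ** 2 / (2 * sigma_col**2))
    )
    return a_b * bright - a_d * dark


def _check_in_field(r: float, c: float, shape: tuple[int, int], margin: float) -> None:
    if not (margin <= r <= shape[0] - 1 - margin and margin <= c <= shape[1] - 1 - margin):
        raise ValueError("out of field")


def render_fullplane(
    pose: NanorodPose,
    instrument: InstrumentModel,
    shape: tuple[int, int] = DEFAULT_FULLPLANE_SHAPE,
) -> np.ndarray:
    """Render a noiseless full-plane DIC frame of a single rod.

    Pixel model: ``b0 + A * I_B * f * G+(r) - A * I_D * f * G-(r)`` where the
    unit-peak Gaussian lobes ``G±`` are offset by ``±shear/2`` from the spot
    centre, ``sigma`` is broadened with defocus and the amplitude factor
    ``f = (sigma0/sigma(z))**2`` conserves the integrated signal.
    """
    pose = pose.canonicalized()
    h, w = shape
    r0 = (h - 1) / 2.0 + pose.y / instrument.pixel_size
    c0 = (w - 1) / 2.0 + pose.x / instrument.pixel_size
    _check_in_field(r0, c0, shape, margin=0.0)
    i_b, i_d = dipole_intensities(pose)
    sigma = instrument.sigma_at(pose.z)
    f = (instrument.psf_sigma / sigma) ** 2
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    img = instrument.background + _lobe_pair(
        rows,
        cols,
        (r0, c0),
        (instrument.amplitude * i_b * f, instrument.amplitude * i_d * f),
        sigma,
        sigma,
        instrument.shear,
    )
    return img


def render_parallax(
    pose: NanorodPose,
    instrument: InstrumentModel,
    shape: tuple[int, int] = DEFAULT_PARALLAX_SHAPE,
) -> np.ndarray:
    """Render a noiseless parallax-DIC frame: a mirror pair of half-plane spots.

    The two spots sit symmetrically about the pair midpoint (which encodes
    the lateral position) along the split (row) axis, separated by
    ``d = d0 + g*z``; the lower spot is the mirror image of the upper about
    the split axis, and both are stretched by ``kappa`` along the split axis.
    Poses with ``|z|`` beyond the calibrated range are still rendered with the
    linear law (the validity flag lives with the localization, not here).
    """
    pose = pose.canonicalized()
    h, w = shape
    r_mid = (h - 1) / 2.0 + pose.y / instrument.pixel_size
    c0 = (w - 1) / 2.0 + pose.x / instrument.pixel_size
    d = instrument.separation_at(pose.z)
    r_u = r_mid - d / 2.0
    r_l = r_mid + d / 2.0
    margin = 2.0 * instrument.kappa * instrument.sigma_at(pose.z)
    _check_in_field(r_u, c0, shape, margin=margin)
    _check_in_field(r_l, c0, shape, margin=margin)
    i_b, i_d = dipole_intensities(pose)
    sigma = instrument.sigma_at(pose.z)
    f = (instrument.psf_sigma / sigma) ** 2 / instrument.kappa
    amps = (instrument.amplitude * i_b * f, instrument.amplitude * i_d * f)
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    img = instrument.background + _lobe_pair(
        rows, cols, (r_u, c0), amps, instrument.kappa * sigma, sigma, instrument.shear
    )
    img += _lobe_pair(
        rows,
        cols,
        (r_l, c0),
        amps,
        instrument.kappa * sigma,
        sigma,
        instrument.shear,
        mirror=True,
    )
    return img


def add_noise(
    image: np.ndarray,
    instrument: InstrumentModel,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Apply shot noise (Poisson on expected counts) and Gaussian read noise.

    Reproducible for a fixed integer seed; a `numpy.random.Generator` may be
    passed directly to share a stream across frames.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.asarray(image, dtype=float)
    if instrument.shot_noise:
        if np.any(img < 0):
            raise ValueError("negative expected counts")
        img = rng.poisson(img).astype(float)
    if instrument.read_noise > 0:
        img = img + rng.normal(0.0, instrument.read_noise, size=img.shape)
    return img
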