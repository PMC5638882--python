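"""Domain types: probe pose, instrument description, frame container.

Conventions
-----------
* Image arrays are indexed ``[row, col]``; the split axis of the parallax
  image pair is the row (vertical) axis.  Physical ``y`` maps to rows and
  ``x`` to columns through ``pixel_size`` (nm per pixel); the frame centre
  corresponds to ``(x, y) = (0, 0)``.
* ``z`` is signed, positive toward the objective.  Moving the probe up
  (``dz > 0``) increases the separation ``d`` of the two half-plane images.
* ``phi`` is the azimuthal angle of the rod's long axis measured from the
  bright polarization axis, canonical range ``[0, 180)`` degrees (a rod is
  invariant under a 180 degree in-plane turn).
* ``psi`` is the elevation angle from the optical axis, canonical range
  ``[0, 90]``; ``psi = 90`` means the rod lies in the focal plane,
  ``psi = 0`` means it points along the optical axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["NanorodPose", "InstrumentModel", "FrameStack"]


def canonical_phi(phi: float) -> float:
    """Fold an azimuth (degrees) into the rod's canonical [0, 180) range."""
    p = float(np.mod(phi, 180.0))
    return 0.0 if p >= 180.0 else p  # np.mod can round up to the period


def canonical_psi(psi: float) -> float:
    """Fold an elevation (degrees) into [0, 90].

    A rod at elevation ``psi`` and one at ``180 - psi`` are the same physical
    dipole, so the elevation is reflected about 90 degrees.
    """
    p = float(np.mod(psi, 180.0))
    return 90.0 - abs(90.0 - p)


@dataclass(frozen=True)
class NanorodPose:
    """Ground-truth or estimated 5D state of a nanorod at one instant.

    Parameters
    ----------
    t : float
        Time in seconds.
    x, y, z : float
        Position in nm.  ``z`` is signed, positive toward the objective.
    phi : float
        Azimuthal angle in degrees, measured from the bright polarization
        axis; canonical range ``[0, 180)``.
    psi : float
        Elevation angle from the optical axis in degrees; canonical range
        ``[0, 90]``.
    """

    t: float = 0.0
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    phi: float = 0.0
    psi: float = 90.0

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "z", "phi", "psi"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"pose field {name!r} must be finite")

    def canonicalized(self) -> "NanorodPose":
        """Return an equivalent pose with angles in canonical ranges.

        Idempotent: canonicalizing twice gives the same pose.
        """
        return replace(self, phi=canonical_phi(self.phi), psi=canonical_psi(self.psi))


@dataclass(frozen=True)
class InstrumentModel:
    """Optical and parallax parameters of the (virtual) microscope.

    All lengths on the camera are in pixels, all sample-space lengths in nm.

    Attributes
    ----------
    pixel_size : float
        Sample-space size of one camera pixel, nm/px.
    background : float
        Gray background level ``b0`` in counts.
    amplitude : float
        Peak signal amplitude ``A`` in counts: a fully bright in-focus rod
        reaches ``b0 + A`` at the bright-lobe peak.
    psf_sigma : float
        In-focus Gaussian lobe width, px.
    defocus_coeff : float
        Fractional PSF broadening per micrometre of defocus:
        ``sigma(z) = psf_sigma * (1 + defocus_coeff * |z| / 1000)``.
        The lobe amplitude is rescaled by ``(psf_sigma / sigma(z))**2`` so the
        integrated signal is conserved.
    shear : tuple of float
        DIC shear vector ``(row, col)`` in px: the bright lobe sits at
        ``center + shear/2`` and the dark lobe at ``center - shear/2``.  The
        default shear is perpendicular to the split axis (purely horizontal),
        which makes each half-plane spot exactly mirror symmetric about the
        split axis.
    parallax_gain : float
        Dimensionless gain ``g = dd/dz`` of the image-pair separation with
        axial position (same length units for d and z).
    d0 : float
        In-focus separation of the two half-plane images, px.
    kappa : float
        Half-plane stretch factor (>= 1): the half-plane PSF is elongated
        along the split axis by ``kappa``.
    z_range : float
        Half-width of the calibrated axial range, nm (validity is
        ``|z| <= z_range``); the linear d(z) law is still applied outside,
        with a flag.
    shot_noise : bool
        Apply Poisson noise to expected counts in :func:`add_noise`.
    read_noise : float
        Gaussian read noise standard deviation in counts.
    """

    pixel_size: float = 160.0
    background: float = 2000.0
    amplitude: float = 1500.0
    psf_sigma: float = 1.2
    defocus_coeff: float = 0.4
    shear: tuple[float, float] = (0.0, 3.2)
    parallax_gain: float = 0.626
    d0: float = 20.0
    kappa: float = 1.6
    z_range: float = 500.0
    shot_noise: bool = True
    read_noise: float = 12.0

    def __post_init__(self) -> None:
        if self.parallax_gain <= 0:
            raise ValueError("parallax gain must be > 0")
        if self.d0 <= 0:
            raise ValueError("d0 must be > 0")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if self.z_range <= 0:
            raise ValueError("z range must be symmetric about 0 and positive")
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be > 0")

    @property
    def gain_px_per_nm(self) -> float:
        """Pair-separation gain in px of d per nm of z."""
        return self.parallax_gain / self.pixel_size

    def sigma_at(self, z_nm: float) -> float:
        """Defocus-broadened lobe sigma (px) at axial offset ``z_nm``."""
        return self.psf_sigma * (1.0 + self.defocus_coeff * abs(z_nm) / 1000.0)

    def separation_at(self, z_nm: float) -> float:
        """Noise-free half-plane pair separation d (px) at axial offset z."""
        return self.d0 + self.gain_px_per_nm * z_nm


@dataclass
class FrameStack:
    """Time-ordered stack of grayscale frames plus acquisition metadata.

    ``mode`` is ``"fullplane"`` (conventional DIC, one spot per probe) or
    ``"parallax"`` (half-plane image pair per probe).
    """

    frames: np.ndarray
    mode: str
    timestamps: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) array")
        if self.mode not in ("fullplane", "parallax"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]
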