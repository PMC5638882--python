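"""Axial calibration and localization-precision evaluation.

The axial readout is calibrated by scanning a stationary probe through the
focal plane in fixed steps (20 nm in the reference protocol), localizing the
half-plane pair in every plane and fitting the linear law ``d = d0 + g*z``
by ordinary least squares.  Planes beyond the calibrated range (|z| > 500 nm
by default) are excluded from the fit.  The calibration also records how the
measured separation spreads when the rod's azimuth is swept through a full
half-turn in each plane (d is orientation independent in the model), and a
Monte-Carlo precision assay measures localization scatter on a stationary
pose under the configured noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instrument import FrameStack, InstrumentModel, NanorodPose
from .localize import LocalizationError, mirror_correlation_localize
from . import optics

__all__ = [
    "CalibrationResult",
    "calibrate_axial",
    "orientation_robustness",
    "precision_assay",
]

logger = logging.getLogger(__name__)


@dataclass
class CalibrationResult:
    """Fitted axial calibration line ``d = d0 + g * z``.

    ``slope_px_per_nm`` is the fit slope in px/nm; ``slope_dimensionless``
    is the same slope expressed as the length ratio d/dz (slope times pixel
    size), the unit the calibration curve is conventionally quoted in.
    """

    slope_px_per_nm: float
    d0: float
    r_squared: float
    z_range: float
    pixel_size: float
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    z_planes: np.ndarray = field(default_factory=lambda: np.array([]))
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("R^2 must lie in [0, 1]")
        if len(self.z_planes) and len(self.residuals) != len(self.z_planes):
            raise ValueError("one residual per fitted plane required")

    @property
    def slope_dimensionless(self) -> float:
        return self.slope_px_per_nm * self.pixel_size

    def to_dict(self) -> dict:
        return {
            "slope_px_per_nm": self.slope_px_per_nm,
            "slope_dimensionless": self.slope_dimensionless,
            "d0": self.d0,
            "r_squared": self.r_squared,
            "z_range": self.z_range,
            "pixel_size": self.pixel_size,
            "n_planes": int(len(self.z_planes)),
            "n_excluded": int(self.n_excluded),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(
            slope_px_per_nm=d["slope_px_per_nm"],
            d0=d["d0"],
            r_squared=d["r_squared"],
            z_range=d["z_range"],
            pixel_size=d["pixel_size"],
        )


def _measure_separations(
    stack: FrameStack, instrument: InstrumentModel, threshold: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Localize every frame; returns (z commanded, d measured, n failed)."""
    z_cmd = np.asarray(stack.meta.get("z_nm"), dtype=float)
    if z_cmd is None or z_cmd.ndim == 0:
        raise ValueError("stack.meta['z_nm'] with one commanded z per frame required")
    if len(z_cmd) != len(stack):
        raise ValueError("one commanded z per frame required")
    d = np.full(len(stack), np.nan)
    for i, frame in enumerate(stack.frames):
        try:
            d[i] = mirror_correlation_localize(frame, instrument, threshold).d
        except LocalizationError:
            pass
    return z_cmd, d, int(np.sum(~np.isfinite(d)))


def calibrate_axial(
    stack: FrameStack,
    instrument: InstrumentModel,
    threshold: float = 0.5,
    z_range: float | None = None,
) -> CalibrationResult:
    """Fit the linear separation-versus-z calibration from a z-scan stack.

    The stack metadata must carry the commanded axial position of every
    frame (``meta['z_nm']``).  Planes with |z| beyond the calibrated range
    are excluded (logged); frames sharing a commanded z are averaged.  One
    round of >5 sigma residual rejection is applied.  Raises on fewer than
    3 usable planes or when more than 20% of in-range planes fail to
    localize.
    """
    z_range = instrument.z_range if z_range is None else z_range
    z_cmd, d, _ = _measure_separations(stack, instrument, threshold)
    in_range = np.abs(z_cmd) <= z_range
    n_excluded = int(np.sum(~in_range))
    if n_excluded:
        logger.info(
            "calibrate_axial: excluding %d plane(s) outside +/-%g nm", n_excluded, z_range
        )
    z_cmd, d = z_cmd[in_range], d[in_range]
    ok = np.isfinite(d)
    if np.mean(~ok) > 0.20:
        raise LocalizationError(
            f"localization failed on {np.sum(~ok)}/{len(ok)} in-range planes (>20%)"
        )
    z_cmd, d = z_cmd[ok], d[ok]
    # average repeated planes (e.g. orientation sweeps per plane)
    planes = np.unique(z_cmd)
    if len(planes) < 3:
        raise ValueError("at least 3 in-range planes required for the fit")
    d_mean = np.array([d[z_cmd == z].mean() for z in planes])
    fit = stats.linregress(planes, d_mean)
    resid = d_mean - (fit.intercept + fit.slope * planes)
    sd = resid.std(ddof=2) if len(planes) > 2 else 0.0
    keep = np.abs(resid) <= 5 * sd if sd > 0 else np.ones_like(resid, bool)
    if not np.all(keep):
        logger.info("calibrate_axial: rejecting %d outlier plane(s) (>5 sigma)",
                    int(np.sum(~keep)))
        if np.sum(keep) < 3:
            raise ValueError("fewer than 3 planes left after outlier rejection")
        fit = stats.linregress(planes[keep], d_mean[keep])
        planes, d_mean = planes[keep], d_mean[keep]
        resid = d_mean - (fit.intercept + fit.slope * planes)
    return CalibrationResult(
        slope_px_per_nm=float(fit.slope),
        d0=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        z_range=z_range,
        pixel_size=instrument.pixel_size,
        residuals=resid,
        z_planes=planes,
        n_excluded=n_excluded,
    )


def orientation_robustness(
    stack: FrameStack,
    instrument: InstrumentModel,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-plane spread of the measured separation over an azimuth sweep.

    The stack metadata must carry ``meta['z_nm']`` and ``meta['phi_deg']``
    per frame; every plane must contain the full 36-orientation sweep
    (0-175 degrees in 5 degree steps), otherwise the missing angles are
    reported in the error.  Returns a data frame with one row per plane:
    ``z_nm``, ``d_mean``, ``d_sd``, ``n``.
    """
    expected = np.arange(0.0, 180.0, 5.0)
    z_cmd = np.asarray(stack.meta.get("z_nm"), dtype=float)
    phi = np.asarray(stack.meta.get("phi_deg"), dtype=float)
    if len(z_cmd) != len(stack) or len(phi) != len(stack):
        raise ValueError("meta['z_nm'] and meta['phi_deg'] per frame required")
    rows = []
    for z in np.unique(z_cmd):
        sel = z_cmd == z
        present = np.unique(np.mod(phi[sel], 180.0))
        if len(present) > 1:
            missing = sorted(set(np.round(expected, 6)) - set(np.round(present, 6)))
            if missing:
                raise ValueError(
                    f"plane z={z:g} nm is missing orientations: {missing}"
                )
        d = []
        for frame in stack.frames[sel]:
            d.append(mirror_correlation_localize(frame, instrument, threshold).d)
        d = np.asarray(d)
        rows.append(
            {"z_nm": z, "d_mean": d.mean(), "d_sd": d.std(ddof=0), "n": len(d)}
        )
    return pd.DataFrame(rows)


def precision_assay(
    pose: NanorodPose,
    instrument: InstrumentModel,
    n_frames: int = 200,
    seed: int | None = 0,
    threshold: float = 0.5,
    noise: bool = True,
) -> dict:
    """Monte-Carlo 3D localization precision on a stationary pose.

    Renders ``n_frames`` parallax frames of the same pose (with the
    configured noise unless ``noise=False``), localizes each one and returns
    the sample standard deviations of x, y and z in nm plus the failure
    count.  ``n_frames`` must be at least 100.
    """
    if n_frames < 100:
        raise ValueError("n_frames must be >= 100")
    rng = np.random.default_rng(seed)
    clean = optics.render_parallax(pose, instrument)
    xs, ys, zs = [], [], []
    n_failed = 0
    g = instrument.gain_px_per_nm
    for _ in range(n_frames):
        frame = optics.add_noise(clean, instrument, rng) if noise else clean
        try:
            loc = mirror_correlation_localize(frame, instrument, threshold)
        except LocalizationError:
            n_failed += 1
            continue
        xs.append(loc.x)
        ys.append(loc.y)
        zs.append((loc.d - instrument.d0) / g)
    xs, ys, zs = map(np.asarray, (xs, ys, zs))
    return {
        "sd_x": float(xs.std(ddof=1)) if len(xs) > 1 else 0.0,
        "sd_y": float(ys.std(ddof=1)) if len(ys) > 1 else 0.0,
        "sd_z": float(zs.std(ddof=1)) if len(zs) > 1 else 0.0,
        "n_used": int(len(xs)),
        "n_failed": n_failed,
    }
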