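"""Simulated closed-loop autofocus on a virtual objective scanner.

The parallax separation measures how far the probe sits from the current
focal plane; a proportional controller moves the focal plane toward the
probe each control step, and the recorded scanner positions (plus the small
residual measured defocus) reconstruct the absolute z trajectory:

    z(t) = command(t) + (d(t) - d0) / g

with ``command`` the focal-plane position in sample coordinates (stage up =
sample up = dz > 0).  Engagement may be continuous or intermittent
(every N seconds), matching the two operating modes of the technique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import CalibrationResult
from .instrument import InstrumentModel, NanorodPose
from .localize import LocalizationError, mirror_correlation_localize
from . import optics

__all__ = ["ScannerState", "control_step", "reconstruct_z", "run_focus_loop"]


@dataclass
class ScannerState:
    """Virtual piezo objective scanner.

    ``position`` is the focal-plane position in sample coordinates (nm);
    commands are clipped to ``+/- travel`` with a saturation flag.  The
    position changes at most once per ``response_frames`` frames.
    """

    position: float = 0.0
    response_frames: int = 1
    travel: float = 5000.0
    gain_k: float = 1.0
    deadband_nm: float = 1.0
    schedule: str = "continuous"
    history: list[float] = field(default_factory=list)
    saturated: bool = False
    _cooldown: int = 0

    def __post_init__(self) -> None:
        if self.response_frames < 1:
            raise ValueError("response time must be >= 1 frame")
        if not 0.0 < self.gain_k <= 1.0:
            raise ValueError("gain_k must lie in (0, 1]")

    def engaged(self, t: float, dt: float) -> bool:
        """Whether the feedback is engaged for the frame at time ``t``."""
        if self.schedule == "continuous":
            return True
        if self.schedule == "off":
            return False
        if self.schedule.startswith("every:"):
            period = float(self.schedule.split(":", 1)[1])
            return np.mod(t, period) < dt * 0.999
        raise ValueError(f"unknown engagement schedule {self.schedule!r}")


def control_step(
    d: float,
    calibration: CalibrationResult,
    scanner: ScannerState,
    engaged: bool = True,
) -> float:
    """One proportional control step; returns the new commanded position.

    The measured separation error maps to a defocus ``(d - d0)/g`` nm; the
    command moves the focal plane by ``gain_k`` times that error toward the
    probe, unless the error is inside the deadband or the scanner is still
    within its response interval.  A failed measurement (``d`` is NaN) holds
    the position.
    """
    if calibration is None:
        raise ValueError("calibration missing")
    scanner.history.append(scanner.position)
    if scanner._cooldown > 0:
        scanner._cooldown -= 1
        return scanner.position
    if not engaged or not np.isfinite(d):
        return scanner.position
    err_nm = (d - calibration.d0) / calibration.slope_px_per_nm
    if abs(err_nm) <= scanner.deadband_nm:
        return scanner.position
    new = scanner.position + scanner.gain_k * err_nm
    clipped = float(np.clip(new, -scanner.travel, scanner.travel))
    scanner.saturated = clipped != new
    scanner.position = clipped
    scanner._cooldown = scanner.response_frames - 1
    return scanner.position


def reconstruct_z(
    commands: np.ndarray,
    d_residual: np.ndarray,
    calibration: CalibrationResult,
) -> np.ndarray:
    """Absolute z trace from scanner history and per-frame residual separation.

    ``z(t) = command(t) + (d(t) - d0)/g``; exact for perfect measurement.
    """
    commands = np.asarray(commands, dtype=float)
    d_residual = np.asarray(d_residual, dtype=float)
    if commands.shape != d_residual.shape:
        raise ValueError("scanner history and separation trace length mismatch")
    return commands + (d_residual - calibration.d0) / calibration.slope_px_per_nm


def run_focus_loop(
    z_true: np.ndarray,
    instrument: InstrumentModel,
    calibration: CalibrationResult,
    scanner: ScannerState | None = None,
    dt: float = 1 / 30,
    measurement: str = "ideal",
    seed: int | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Run the closed loop over a ground-truth z trajectory.

    Each frame the probe sits at ``z_true[i]``; the camera sees the relative
    defocus ``z_true[i] - command`` which sets the measured separation
    (``measurement="ideal"`` uses the exact linear law; ``"render"`` renders
    a frame — with noise when a seed is given — and localizes it).  The
    controller then updates the command.  Returns the loop log with columns
    ``frame, t, engaged, z_true, command, d, z_reconstructed, failed``.
    """
    z_true = np.asarray(z_true, dtype=float)
    scanner = scanner or ScannerState()
    rng = np.random.default_rng(seed) if seed is not None else None
    rows = []
    for i, z in enumerate(z_true):
        t = i * dt
        z_rel = z - scanner.position
        failed = False
        if measurement == "ideal":
            d = instrument.separation_at(z_rel)
        else:
            pose = NanorodPose(t=t, z=z_rel)
            frame = optics.render_parallax(pose, instrument)
            if rng is not None:
                frame = optics.add_noise(frame, instrument, rng)
            try:
                d = mirror_correlation_localize(frame, instrument, threshold).d
            except LocalizationError:
                d, failed = np.nan, True
        engaged = scanner.engaged(t, dt)
        cmd_before = scanner.position
        control_step(d, calibration, scanner, engaged=engaged)
        z_rec = (
            cmd_before + (d - calibration.d0) / calibration.slope_px_per_nm
            if np.isfinite(d)
            else np.nan
        )
        rows.append(
            {
                "frame": i,
                "t": t,
                "engaged": engaged,
                "z_true": z,
                "command": cmd_before,
                "d": d,
                "z_reconstructed": z_rec,
                "failed": failed,
            }
        )
    return pd.DataFrame(rows)
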