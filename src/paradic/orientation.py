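"""Orientation inversion from normalized bright/dark DIC intensities.

Under the fourth-power projection law the normalized channel intensities of
a rod at azimuth phi and elevation psi are

    I_B = (sin psi * cos phi)**4,    I_D = (sin psi * sin phi)**4

which inverts in closed form:

    phi = arctan((I_D / I_B)**(1/4)),      sin^2 psi = sqrt(I_B) + sqrt(I_D).

The inversion is degenerate: within one 180-degree period of the rod axis,
``phi`` and ``180 - phi`` produce identical intensities (four solutions over
the full circle), so canonical angles in [0, 90] are reported together with
the degeneracy class.  ``sqrt(I_B) + sqrt(I_D) > 1`` can only arise from
noise and is projected radially back to the boundary (counted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntensityTrace",
    "OrientationEstimate",
    "normalize_trace",
    "invert_orientation",
]


@dataclass
class IntensityTrace:
    """Per-frame raw and normalized bright/dark lobe intensities."""

    t: np.ndarray
    b_raw: np.ndarray
    d_raw: np.ndarray
    b0: float
    i_b: np.ndarray
    i_d: np.ndarray
    amp_b: float
    amp_d: float
    n_clipped: int = 0

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class OrientationEstimate:
    """Canonical orientation angles with degeneracy bookkeeping.

    ``phi``/``psi`` are canonical (degrees, [0, 90]); ``phi_solutions``
    lists the equivalent azimuths within one 180-degree period; ``valid`` is
    False where both channels vanish (rod axial or signal lost).
    """

    t: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    valid: np.ndarray
    n_projected: int = 0

    def phi_solutions(self, i: int) -> tuple[float, float]:
        return (float(self.phi[i]), float(180.0 - self.phi[i]))

    def __len__(self) -> int:
        return len(self.t)


def normalize_trace(
    b_raw: np.ndarray,
    d_raw: np.ndarray,
    t: np.ndarray | None = None,
    b0: float | None = None,
    quantile: float = 0.99,
) -> IntensityTrace:
    """Normalize raw lobe intensity traces to [0, 1] channel intensities.

    ``I_B = (B_raw - b0)/A_B`` and ``I_D = (b0 - D_raw)/A_D`` with the
    normalization constants ``A_B``/``A_D`` taken as the ``quantile``
    (default 99th percentile) excursion of each trace — robust to isolated
    noise spikes.  The background ``b0`` is estimated from the trace when
    not supplied: the bright trace approaches ``b0`` from above and the dark
    trace from below whenever the corresponding projection vanishes, so the
    midpoint of the opposing 1st/99th percentiles is used.  Values outside
    [0, 1] are clipped and counted.  A flat trace is unnormalizable.
    """
    b_raw = np.asarray(b_raw, dtype=float)
    d_raw = np.asarray(d_raw, dtype=float)
    if b_raw.shape != d_raw.shape:
        raise ValueError("bright and dark traces must have equal length")
    if len(b_raw) < 10:
        raise ValueError("trace too short (need >= 10 frames)")
    if t is None:
        t = np.arange(len(b_raw), dtype=float)
    if b0 is None:
        b0 = 0.5 * (
            np.quantile(b_raw, 1 - quantile) + np.quantile(d_raw, quantile)
        )
    amp_b = float(np.quantile(b_raw - b0, quantile))
    amp_d = float(np.quantile(b0 - d_raw, quantile))
    scale = max(np.ptp(b_raw), np.ptp(d_raw))
    if amp_b <= 0 or amp_d <= 0 or scale <= 1e-12 * max(1.0, abs(b0)):
        raise ValueError("unnormalizable: flat trace (no excursion)")
    i_b = (b_raw - b0) / amp_b
    i_d = (b0 - d_raw) / amp_d
    n_clipped = int(np.sum((i_b < 0) | (i_b > 1) | (i_d < 0) | (i_d > 1)))
    return IntensityTrace(
        t=np.asarray(t, dtype=float),
        b_raw=b_raw,
        d_raw=d_raw,
        b0=float(b0),
        i_b=np.clip(i_b, 0.0, 1.0),
        i_d=np.clip(i_d, 0.0, 1.0),
        amp_b=amp_b,
        amp_d=amp_d,
        n_clipped=n_clipped,
    )


def invert_orientation(
    i_b: np.ndarray | float,
    i_d: np.ndarray | float,
    t: np.ndarray | None = None,
    eps: float = 1e-12,
) -> OrientationEstimate:
    """Closed-form orientation angles from normalized channel intensities.

    Accepts scalars or arrays in [0, 1].  Where ``sqrt(I_B) + sqrt(I_D)``
    exceeds 1 (noise) the intensity pair is projected radially onto the
    boundary and counted; where both intensities vanish the orientation is
    undefined and flagged invalid.
    """
    i_b = np.atleast_1d(np.asarray(i_b, dtype=float)).copy()
    i_d = np.atleast_1d(np.asarray(i_d, dtype=float)).copy()
    if i_b.shape != i_d.shape:
        raise ValueError("intensity arrays must have equal shape")
    if np.any((i_b < -eps) | (i_b > 1 + eps) | (i_d < -eps) | (i_d > 1 + eps)):
        raise ValueError("normalized intensities must lie in [0, 1]")
    i_b = np.clip(i_b, 0.0, 1.0)
    i_d = np.clip(i_d, 0.0, 1.0)
    if t is None:
        t = np.arange(len(i_b), dtype=float)
    s = np.sqrt(i_b) + np.sqrt(i_d)  # = sin^2(psi) in the noise-free model
    over = s > 1.0
    n_projected = int(np.sum(over))
    if n_projected:
        # radial projection: scale both sqrt-intensities so they sum to 1
        f = 1.0 / s[over]
        i_b[over] *= f**2
        i_d[over] *= f**2
        s[over] = 1.0
    valid = (i_b > eps) | (i_d > eps)
    phi = np.zeros_like(i_b)
    np.divide(i_d, i_b, out=phi, where=i_b > eps)
    phi = np.degrees(np.arctan(phi**0.25))
    phi[(i_b <= eps) & (i_d > eps)] = 90.0
    psi = np.degrees(np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0))))
    phi[~valid] = np.nan
    psi[~valid] = np.nan
    return OrientationEstimate(
        t=np.asarray(t, dtype=float),
        phi=phi,
        psi=psi,
        valid=valid,
        n_projected=n_projected,
    )
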