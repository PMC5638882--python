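"""Rotational-dynamics analytics on bright/dark DIC intensity traces.

The two fundamental rotation modes of a rod leave opposite signatures in the
raw bright and dark lobe intensities: in-plane rotation (azimuth changing in
the focal plane) drives the two traces together (Pearson r near +1), while
out-of-plane rotation (elevation changing) drives them apart (r = -1).  The
Pearson statistic is therefore computed on the *raw* lobe intensities —
bright above background, dark below — which fixes the sign convention.

A rolling-variance statistic on the normalized intensities segments a trace
into active and quiet periods (the active -> quiet -> active signature of
cargo enclosure and scission), and an envelope/autocorrelation analysis
quantifies the twister-like z oscillation of transported cargo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RotationSegmentation",
    "window_pearson",
    "classify_mode",
    "segment_activity",
    "particle_correlation_summary",
    "twister_z_oscillation",
]


@dataclass
class RotationSegmentation:
    """Active/quiet segmentation of a rotational intensity trace.

    ``windows`` holds per-window Pearson coefficients and mode calls;
    ``segments`` partition the trace into contiguous active/quiet states.
    """

    windows: pd.DataFrame
    segments: pd.DataFrame
    fps: float
    restoration_events: list[int] = field(default_factory=list)

    @property
    def quiet_durations(self) -> np.ndarray:
        q = self.segments[self.segments["state"] == "quiet"]
        return ((q["end"] - q["start"]) / self.fps).to_numpy()


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def window_pearson(
    b_raw: np.ndarray,
    d_raw: np.ndarray,
    window: int = 16,
    stride: int | None = None,
    r_hi: float = 0.5,
    r_lo: float = -0.5,
) -> pd.DataFrame:
    """Sliding-window Pearson correlation of the raw bright/dark traces.

    Returns one row per window: ``start, end, r, mode``.  Windows where
    either trace has zero variance get ``r = NaN`` and mode ``"static"``.
    The default window of 16 frames is about half a second at the 33 ms
    working exposure; stride defaults to half a window.  r is invariant
    under affine rescaling of either trace.
    """
    b_raw = np.asarray(b_raw, dtype=float)
    d_raw = np.asarray(d_raw, dtype=float)
    if window < 8:
        raise ValueError("window must be >= 8 frames")
    if len(b_raw) < window:
        raise ValueError("trace shorter than one window")
    stride = window // 2 if stride is None else stride
    rows = []
    for start in range(0, len(b_raw) - window + 1, stride):
        end = start + window
        r = _pearson(b_raw[start:end], d_raw[start:end])
        mode = "static" if np.isnan(r) else classify_mode(r, r_hi, r_lo)
        rows.append({"start": start, "end": end, "r": r, "mode": mode})
    return pd.DataFrame(rows)


def classify_mode(r: float, r_hi: float = 0.5, r_lo: float = -0.5) -> str:
    """Rotational-mode call from a Pearson coefficient.

    ``in-plane`` for r >= r_hi (correlated channels), ``out-of-plane`` for
    r <= r_lo (anti-correlated), ``mixed`` in between.
    """
    if np.isnan(r):
        raise ValueError("r undefined (zero-variance window)")
    if r >= r_hi:
        return "in-plane"
    if r <= r_lo:
        return "out-of-plane"
    return "mixed"


def _rolling_var(x: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling variance, same length as x (edges use partial windows)."""
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=max(2, window // 2)).var(ddof=0).to_numpy()


def segment_activity(
    i_b: np.ndarray,
    i_d: np.ndarray,
    fps: float,
    window: int = 16,
    quiet_frac: float = 0.05,
    min_quiet_s: float = 2.0,
    restore_frames: int = 3,
    restore_frac: float = 0.8,
) -> RotationSegmentation:
    """Segment a normalized intensity trace into active and quiet periods.

    A frame is quiet when the summed rolling variance of the two channels
    falls below ``quiet_frac`` of the whole-trace variance; quiet runs
    shorter than ``min_quiet_s`` are absorbed into the surrounding active
    state.  Abrupt restorations — a full-range intensity swing within
    ``restore_frames`` frames, the signature of sudden recovery of free
    rotation — are flagged by frame index.
    """
    i_b = np.asarray(i_b, dtype=float)
    i_d = np.asarray(i_d, dtype=float)
    n = len(i_b)
    if n < 2 * window:
        raise ValueError("trace too short to segment (need >= 2 windows)")
    total_var = i_b.var() + i_d.var()
    if total_var <= 0:
        quiet = np.ones(n, dtype=bool)
    else:
        rv = _rolling_var(i_b, window) + _rolling_var(i_d, window)
        quiet = rv < quiet_frac * total_var
    min_len = int(round(min_quiet_s * fps))
    segments = []
    start = 0
    for i in range(1, n + 1):
        if i == n or quiet[i] != quiet[start]:
            segments.append([start, i, bool(quiet[start])])
            start = i
    # absorb short quiet runs into active neighbours
    merged = []
    for s, e, q in segments:
        if q and (e - s) < min_len:
            q = False
        if merged and merged[-1][2] == q:
            merged[-1][1] = e
        else:
            merged.append([s, e, q])
    seg_df = pd.DataFrame(
        [
            {"start": s, "end": e, "state": "quiet" if q else "active"}
            for s, e, q in merged
        ]
    )
    wins = window_pearson(i_b, i_d, window=window) if n >= window else pd.DataFrame()
    # abrupt full-range swings within <= restore_frames frames
    rng_b, rng_d = np.ptp(i_b), np.ptp(i_d)
    events = []
    k = restore_frames
    for ch, rng in ((i_b, rng_b), (i_d, rng_d)):
        if rng <= 0:
            continue
        swing = np.abs(ch[k:] - ch[:-k])
        events.extend(np.flatnonzero(swing >= restore_frac * rng) + k)
    events = sorted(set(int(e) for e in events))
    # keep only the first event of each run of consecutive frames
    collapsed = [e for i, e in enumerate(events) if i == 0 or e - events[i - 1] > k]
    return RotationSegmentation(
        windows=wins, segments=seg_df, fps=fps, restoration_events=collapsed
    )


def particle_correlation_summary(
    traces_by_stage: dict[str, list[tuple[np.ndarray, np.ndarray]]],
    bins: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """Whole-trace Pearson coefficient per particle, summarized per stage.

    ``traces_by_stage`` maps a stage label to a list of ``(b_raw, d_raw)``
    traces, one per particle.  Returns a per-particle data frame
    (``stage, particle, r``) and a per-stage dict with the histogram over
    [-1, 1] and the distribution centre (median).
    """
    rows = []
    summary: dict[str, dict] = {}
    for stage, traces in traces_by_stage.items():
        if not traces:
            raise ValueError(f"stage {stage!r} has no particles")
        rs = []
        for i, (b, d) in enumerate(traces):
            r = _pearson(np.asarray(b, float), np.asarray(d, float))
            rs.append(r)
            rows.append({"stage": stage, "particle": i, "r": r})
        rs = np.asarray(rs)
        hist, edges = np.histogram(rs[np.isfinite(rs)], bins=bins, range=(-1, 1))
        summary[stage] = {
            "center": float(np.nanmedian(rs)),
            "hist": hist,
            "bin_edges": edges,
            "n": len(rs),
        }
    return pd.DataFrame(rows), summary


def twister_z_oscillation(
    z: np.ndarray,
    xy: np.ndarray,
    fps: float,
    min_autocorr: float = 0.2,
) -> dict:
    """Quantify a twister-like motion: z oscillation over a linear lateral path.

    Returns the peak-to-peak z amplitude (5th-95th percentile envelope of
    the detrended trace, nm), the dominant oscillation period (first
    positive-lag autocorrelation peak, s; ``None`` with an ``"aperiodic"``
    flag when no peak exceeds ``min_autocorr``), and the lateral path
    linearity (fraction of lateral variance along the principal direction).
    Needs at least two oscillation periods to resolve the period.
    """
    z = np.asarray(z, dtype=float)
    xy = np.asarray(xy, dtype=float)
    # detrend z linearly so slow transport does not inflate the envelope
    tt = np.arange(len(z))
    zd = z - np.polyval(np.polyfit(tt, z, 1), tt)
    amplitude = float(np.quantile(zd, 0.95) - np.quantile(zd, 0.05))
    flags = []
    period = None
    if zd.std() > 0:
        ac = np.correlate(zd - zd.mean(), zd - zd.mean(), mode="full")
        ac = ac[len(zd) - 1 :]
        ac /= ac[0]
        # first local maximum after the first zero crossing
        below = np.flatnonzero(ac < 0)
        if len(below):
            # first local maximum after the first zero crossing: the global
            # tail maximum can alias onto a multiple of the period when the
            # true period is a half-integer number of frames
            tail = ac[below[0] :]
            k = None
            for i in range(1, len(tail) - 1):
                if tail[i] >= tail[i - 1] and tail[i] >= tail[i + 1]:
                    k = i
                    break
            if k is not None and tail[k] >= min_autocorr:
                lag = below[0] + k
                # parabolic refinement of the autocorrelation peak
                if 0 < lag < len(ac) - 1:
                    ym, y0, yp = ac[lag - 1], ac[lag], ac[lag + 1]
                    den = ym - 2 * y0 + yp
                    lag = lag + (0.5 * (ym - yp) / den if den != 0 else 0.0)
                period = float(lag / fps)
    if period is None:
        flags.append("aperiodic")
    # lateral linearity: variance fraction along the principal axis
    centred = xy - xy.mean(axis=0)
    cov = np.cov(centred.T)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    linearity = float(evals[0] / evals.sum()) if evals.sum() > 0 else 1.0
    return {
        "amplitude_pp": amplitude,
        "period_s": period,
        "lateral_linearity": linearity,
        "flags": flags,
    }
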