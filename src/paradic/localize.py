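"""Subpixel localization of DIC spots and parallax half-plane image pairs.

Two correlation-mapping strategies are used, both with zero-mean normalized
cross-correlation (ZNCC, scores in [-1, 1]) so that the conventional score
threshold of 0.4-0.6 is meaningful:

* **Mirror-template correlation** for the parallax pair.  One half-plane
  image is cropped and used as the model for the other.  Matching the
  *mirrored* crop measures the sum of the two spot coordinates along the
  split axis (the pair midpoint); matching the *unmirrored* crop measures
  their difference (the separation ``d``).  With the default geometry (shear
  perpendicular to the split axis) each half-plane spot is its own mirror
  image, so both correlations are exact matched-template correlations and
  the two split-axis coordinates are recovered model-free.  The coordinate
  perpendicular to the split axis is recovered by model-based correlation
  against rendered templates (below).

* **Model-based correlation** for full-plane DIC spots, and for the
  coordinate of the parallax pair perpendicular to the split axis: the
  anti-symmetric DIC PSF cannot be fitted with a simple peak function, so
  the frame is correlated against a bank of rendered model PSFs spanning
  the azimuth (for the parallax pair, a rendered model of the *whole* pair
  at the measured separation), and the match is refined iteratively with a
  template whose lobe amplitudes and subpixel position are re-estimated by
  least squares — a template matching ratio and subpixel offset makes the
  correlation map even about the true shift, hence unbiased.

Subpixel peaks of all correlation maps are score-weighted centroids over the
pixels exceeding the threshold, with weights ``(score - threshold)**2``,
evaluated on a spline-upsampled copy of the peak region to remove pixel-grid
discretization bias; a 3x3 parabolic fit is the fallback when fewer than 4
pixels pass.  A mild Gaussian pre-smoothing is applied identically to search
regions and templates (matched correlations stay matched, so no bias) to
stabilize scores at low signal-to-noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, label, zoom
from skimage.feature import match_template

from .instrument import InstrumentModel
from . import optics

__all__ = [
    "Localization5D",
    "LocalizationError",
    "PairLocalization",
    "mirror_correlation_localize",
    "fullplane_localize",
    "measure_lobe_intensities",
    "z_from_distance",
]


class LocalizationError(RuntimeError):
    """Raised when a frame cannot be localized."""


@dataclass
class Localization5D:
    """Per-frame localization record.

    ``x``/``y`` are in nm relative to the frame centre, ``d`` is the pair
    separation in px (parallax mode only), ``z`` in nm is finite only when a
    separation was measured or a scanner position supplied.  ``score`` is the
    correlation peak score in [-1, 1].
    """

    t: float = 0.0
    x: float = np.nan
    y: float = np.nan
    d: float = np.nan
    z: float = np.nan
    score: float = np.nan
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.score) and not -1.0 - 1e-9 <= self.score <= 1.0 + 1e-9:
            raise ValueError("correlation score must lie in [-1, 1]")

    @property
    def ok(self) -> bool:
        return "failed" not in self.flags


@dataclass
class PairLocalization:
    """Result of mirror-template localization of a half-plane image pair."""

    center_upper: tuple[float, float]
    center_lower: tuple[float, float]
    d: float
    score: float
    x: float
    y: float
    flags: list[str] = field(default_factory=list)


def _weighted_peak(
    corr: np.ndarray,
    threshold: float,
    prev: tuple[float, float] | None = None,
    upsample: int = 8,
) -> tuple[float, float, float, list[str]]:
    """Subpixel peak of a correlation map.

    Score-weighted centroid with weights ``(score - threshold)**2`` over the
    above-threshold pixels, evaluated on a cubic-spline upsampled copy of
    the peak region so the centroid is free of pixel-grid discretization
    bias.  With several disjoint above-threshold blobs the one with the
    largest integrated excess score is used (nearest ``prev`` on ties) and
    an ambiguity flag is raised.  Raising the threshold can only shrink the
    set of contributing pixels.  Fewer than 4 passing pixels fall back to a
    3x3 parabolic fit around the integer peak.
    """
    flags: list[str] = []
    mask = corr >= threshold
    if not np.any(mask):
        raise LocalizationError("no correlation above threshold")
    labels, n_blobs = label(mask)
    if n_blobs > 1:
        flags.append("ambiguous")
        masses = np.array(
            [np.sum(corr[labels == i] - threshold) for i in range(1, n_blobs + 1)]
        )
        best = np.flatnonzero(masses >= masses.max() * (1 - 1e-12)) + 1
        if len(best) > 1 and prev is not None:
            centers = [np.mean(np.argwhere(labels == i), axis=0) for i in best]
            dist = [np.hypot(c[0] - prev[0], c[1] - prev[1]) for c in centers]
            chosen = best[int(np.argmin(dist))]
        else:
            chosen = best[0]
        mask = labels == chosen
    score = float(corr[mask].max())
    idx = np.argwhere(mask)
    if len(idx) < 4:
        # parabolic 3x3 fallback around the integer peak
        pr, pc = np.unravel_index(np.argmax(np.where(mask, corr, -np.inf)), corr.shape)
        dr = _parabolic_offset(corr, pr, pc, axis=0)
        dc = _parabolic_offset(corr, pr, pc, axis=1)
        return pr + dr, pc + dc, score, flags
    # bounding box of the chosen blob (+3 px margin so spline edge effects
    # stay clear of the centroid support), upsampled
    r_lo, c_lo = idx.min(axis=0)
    r_hi, c_hi = idx.max(axis=0)
    r_lo, c_lo = max(0, r_lo - 3), max(0, c_lo - 3)
    r_hi = min(corr.shape[0], r_hi + 4)
    c_hi = min(corr.shape[1], c_hi + 4)
    sub = corr[r_lo:r_hi, c_lo:c_hi]
    order = min(3, min(sub.shape) - 1)
    up = zoom(sub, upsample, order=order, grid_mode=False)
    scale_r = (sub.shape[0] - 1) / (up.shape[0] - 1) if up.shape[0] > 1 else 1.0
    scale_c = (sub.shape[1] - 1) / (up.shape[1] - 1) if up.shape[1] > 1 else 1.0
    m = up >= threshold
    if not np.any(m):  # spline undershoot on a marginal blob
        m = up >= up.max() - 1e-12
    w = (up[m] - threshold) ** 2
    if w.sum() <= 0:
        w = np.ones_like(w)
    uidx = np.argwhere(m)
    r = r_lo + float(np.sum(w * uidx[:, 0]) / np.sum(w)) * scale_r
    c = c_lo + float(np.sum(w * uidx[:, 1]) / np.sum(w)) * scale_c
    return r, c, score, flags


def _parabolic_offset(corr: np.ndarray, pr: int, pc: int, axis: int) -> float:
    h, w = corr.shape
    if axis == 0:
        if pr == 0 or pr == h - 1:
            return 0.0
        ym, y0, yp = corr[pr - 1, pc], corr[pr, pc], corr[pr + 1, pc]
    else:
        if pc == 0 or pc == w - 1:
            return 0.0
        ym, y0, yp = corr[pr, pc - 1], corr[pr, pc], corr[pr, pc + 1]
    denom = ym - 2 * y0 + yp
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (ym - yp) / denom, -1.0, 1.0))


def _coarse_pair(frame: np.ndarray, instrument: InstrumentModel) -> tuple[int, int, int]:
    """Integer-pixel detection of the two half-plane spots and their column."""
    b0 = np.median(frame)
    dev = gaussian_filter((frame - b0) ** 2, 1.5)
    row_profile = dev.sum(axis=1)
    col_profile = dev.sum(axis=0)
    r1 = int(np.argmax(row_profile))
    gap = max(3, int(round(2 * instrument.kappa * instrument.psf_sigma)))
    masked = row_profile.copy()
    lo, hi = max(0, r1 - gap), min(len(masked), r1 + gap + 1)
    masked[lo:hi] = -np.inf
    r2 = int(np.argmax(masked))
    c = int(np.argmax(col_profile))
    return min(r1, r2), max(r1, r2), c


def _patch_half(instrument: InstrumentModel) -> int:
    sig = instrument.sigma_at(instrument.z_range)
    ext = 3.0 * instrument.kappa * sig + abs(instrument.shear[0]) / 2.0
    ext = max(ext, 3.0 * sig + abs(instrument.shear[1]) / 2.0)
    return int(np.ceil(ext)) + 1


def _clip_window(lo: int, hi: int, n: int) -> tuple[int, int]:
    return max(0, lo), min(n, hi)


def _render_half_template(
    instrument: InstrumentModel,
    i_b: float,
    i_d: float,
    z_nm: float,
    half: int,
    mirror: bool = False,
    offset: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Rendered half-plane spot model, spot at the patch centre + ``offset``."""
    w = 2 * half + 1
    rows, cols = np.mgrid[0:w, 0:w].astype(float)
    sigma = instrument.sigma_at(z_nm)
    return optics._lobe_pair(
        rows,
        cols,
        (half + offset[0], half + offset[1]),
        (i_b, i_d),
        instrument.kappa * sigma,
        sigma,
        instrument.shear,
        mirror=mirror,
    )


def _render_pair_template(
    instrument: InstrumentModel,
    i_b: float,
    i_d: float,
    z_nm: float,
    d: float,
    half_c: int,
    offset: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Rendered half-plane image *pair* at known separation ``d``.

    The pair midpoint sits at the patch centre + ``offset``; the lower spot
    is the mirror image of the upper, exactly as the forward model forms it.
    """
    sigma = instrument.sigma_at(z_nm)
    half_r = int(np.ceil(d / 2.0 + 3.0 * instrument.kappa * sigma
                         + abs(instrument.shear[0]) / 2.0)) + 1
    h, w = 2 * half_r + 1, 2 * half_c + 1
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    r_mid, c_mid = half_r + offset[0], half_c + offset[1]
    img = optics._lobe_pair(
        rows, cols, (r_mid - d / 2.0, c_mid), (i_b, i_d),
        instrument.kappa * sigma, sigma, instrument.shear,
    )
    img += optics._lobe_pair(
        rows, cols, (r_mid + d / 2.0, c_mid), (i_b, i_d),
        instrument.kappa * sigma, sigma, instrument.shear, mirror=True,
    )
    return img


def _render_full_template(
    instrument: InstrumentModel,
    i_b: float,
    i_d: float,
    z_nm: float,
    half: int,
    offset: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    w = 2 * half + 1
    rows, cols = np.mgrid[0:w, 0:w].astype(float)
    sigma = instrument.sigma_at(z_nm)
    return optics._lobe_pair(
        rows,
        cols,
        (half + offset[0], half + offset[1]),
        (i_b, i_d),
        sigma,
        sigma,
        instrument.shear,
    )


def _bank_correlate(
    search: np.ndarray,
    render,
    threshold: float,
    phi_step: float = 5.0,
    refine: bool = True,
) -> tuple[float, float, float, list[str]]:
    """Correlate ``search`` against a template bank spanning the azimuth.

    ``render(i_b, i_d, offset)`` must return a template patch with the spot
    at its centre plus the subpixel ``offset``.  The best-scoring bank
    template fixes the integer peak and a first subpixel estimate; the
    match is then refined iteratively: the bright/dark lobe amplitudes are
    re-estimated by linear least squares on the two lobe basis patterns
    rendered at the current subpixel offset, and the correlation repeated
    with the matched template rendered at that offset.  A template matching
    both the amplitude ratio and the subpixel position makes the ZNCC map
    an exact sampled autocorrelation - even about the true shift - so the
    score-weighted centroid converges to an unbiased subpixel position.
    Returns the spot position within ``search`` plus the final peak score.
    """
    best = None
    phis = np.arange(0.0, 90.0 + phi_step / 2, phi_step)
    for phi in phis:
        i_b = np.cos(np.deg2rad(phi)) ** 4
        i_d = np.sin(np.deg2rad(phi)) ** 4
        tmpl = render(i_b, i_d, (0.0, 0.0))
        corr = match_template(search, tmpl)
        peak = float(corr.max())
        if best is None or peak > best[0]:
            best = (peak, corr)
    peak, corr = best
    half_r = (search.shape[0] - corr.shape[0]) // 2  # template half height
    half_c = (search.shape[1] - corr.shape[1]) // 2  # template half width
    h, w = 2 * half_r + 1, 2 * half_c + 1
    pr, pc, score, flags = _weighted_peak(corr, min(threshold, peak - 1e-6))
    if refine:
        for _ in range(3):
            ip, jp = int(round(pr)), int(round(pc))
            ip = int(np.clip(ip, 0, search.shape[0] - h))
            jp = int(np.clip(jp, 0, search.shape[1] - w))
            off = (pr - ip, pc - jp)
            win = search[ip : ip + h, jp : jp + w]
            basis_b = render(1.0, 0.0, off)  # +bright lobe
            basis_d = render(0.0, 1.0, off)  # -dark lobe
            design = np.stack(
                [basis_b.ravel(), basis_d.ravel(), np.ones(basis_b.size)], axis=1
            )
            coef, *_ = np.linalg.lstsq(design, win.ravel(), rcond=None)
            a_b, a_d = max(float(coef[0]), 0.0), max(float(coef[1]), 0.0)
            if a_b + a_d <= 0:
                break
            c2 = match_template(search, render(a_b, a_d, off))
            if not np.all(np.isfinite(c2)):
                break
            peak = float(c2.max())
            pr2, pc2, score, flags = _weighted_peak(c2, min(threshold, peak - 1e-6))
            pr, pc = pr2 + off[0], pc2 + off[1]
    return pr + half_r, pc + half_c, score, flags


def mirror_correlation_localize(
    frame: np.ndarray,
    instrument: InstrumentModel,
    threshold: float = 0.5,
    prev: tuple[float, float] | None = None,
    template_source: str = "same",
    reference_frame: np.ndarray | None = None,
    smooth_sigma: float = 0.7,
) -> PairLocalization:
    """Localize a parallax half-plane image pair by mirror-template correlation.

    One half-plane image is cropped and used as the model to map the other.
    The mirrored-template match yields the pair midpoint along the split
    axis, the direct match yields the separation ``d``; the column (x)
    coordinate comes from a model-template correlation of the upper spot.
    ``(x, y)`` is the pair midpoint in nm relative to the frame centre.

    Parameters
    ----------
    threshold : float
        ZNCC score threshold in (0, 1); map pixels above it enter the
        weighted centroid.
    template_source : {"same", "reference"}
        Take the half-plane model from the same frame (default) or from
        ``reference_frame``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    # mild smoothing, applied identically to the search regions and to every
    # template (frame crops and rendered models): matched correlations stay
    # exactly matched, so no bias is introduced, while the score loss from
    # per-pixel noise is strongly reduced
    smoothed = gaussian_filter(frame, smooth_sigma) if smooth_sigma > 0 else frame
    half = _patch_half(instrument)
    r_u0, r_l0, c0i = _coarse_pair(frame, instrument)
    r_u0 = int(np.clip(r_u0, half, h - half - 1))
    r_l0 = int(np.clip(r_l0, half, h - half - 1))
    c0i = int(np.clip(c0i, half, w - half - 1))
    if r_l0 - r_u0 < 3:
        raise LocalizationError("half-plane pair not resolved")
    src = (
        smoothed
        if template_source == "same"
        else gaussian_filter(np.asarray(reference_frame, float), smooth_sigma)
        if smooth_sigma > 0
        else np.asarray(reference_frame, float)
    )
    p_lo, p_hi = _clip_window(r_l0 - half, r_l0 + half + 1, src.shape[0])
    q_lo, q_hi = _clip_window(c0i - half, c0i + half + 1, src.shape[1])
    patch = src[p_lo:p_hi, q_lo:q_hi]
    flags: list[str] = []
    if patch.shape != (2 * half + 1, 2 * half + 1):
        flags.append("edge-clipped")
    # search window around the upper spot, wide enough for the full z range
    m = half + int(np.ceil(instrument.gain_px_per_nm * instrument.z_range)) + 3
    s_rlo, s_rhi = _clip_window(r_u0 - m, r_u0 + m + 1, h)
    s_clo, s_chi = _clip_window(c0i - m, c0i + m + 1, w)
    if s_rhi - s_rlo <= patch.shape[0] or s_chi - s_clo <= patch.shape[1]:
        raise LocalizationError("search window too small (target at frame edge)")
    search = smoothed[s_rlo:s_rhi, s_clo:s_chi]

    corr_mirror = match_template(search, patch[::-1, :])
    corr_direct = match_template(search, patch)
    pr_m, pc_m, score_m, f_m = _weighted_peak(corr_mirror, threshold, prev)
    pr_d, pc_d, score_d, f_d = _weighted_peak(corr_direct, threshold, prev)
    flags += f_m + f_d

    ph = patch.shape[0]  # patch rows (may be clipped)
    # mirrored template: spot row within template = (ph - 1) - (r_l - p_lo),
    # so a match at top-left (s_rlo + pr_m) ties r_u to known integers plus
    # r_l; solve the two linear relations for r_u and r_l:
    #   mirror match:  r_u + r_l = s_rlo + pr_m + (ph - 1) + p_lo
    #   direct match:  r_u - r_l = s_rlo + pr_d - p_lo
    sum_rows = s_rlo + pr_m + (ph - 1) + p_lo
    diff_rows = s_rlo + pr_d - p_lo
    r_u = (sum_rows + diff_rows) / 2.0
    r_l = (sum_rows - diff_rows) / 2.0
    d = r_l - r_u
    # column difference from the direct match; absolute column of the upper
    # spot from model-template correlation
    dc = s_clo + pc_d - q_lo  # c_u - c_l
    slack = 1.5 * instrument.gain_px_per_nm * instrument.z_range
    if not instrument.d0 - slack <= d <= instrument.d0 + slack:
        raise LocalizationError("implausible pair separation (low signal)")
    z_est = (d - instrument.d0) / instrument.gain_px_per_nm
    b_lo, b_hi = _clip_window(r_u0 - half - 6, r_l0 + half + 7, h)
    bc_lo, bc_hi = _clip_window(c0i - half - 9, c0i + half + 10, w)
    pair_roi = smoothed[b_lo:b_hi, bc_lo:bc_hi] - np.median(frame)
    thalf_c = min(half + 3, (pair_roi.shape[1] - 5) // 2)
    probe = _render_pair_template(instrument, 1.0, 1.0, z_est, d, thalf_c)
    if probe.shape[0] >= pair_roi.shape[0] or probe.shape[1] >= pair_roi.shape[1]:
        raise LocalizationError("pair model does not fit the search window")

    pad = 4  # render wide, smooth, crop: avoids boundary mismatch with the
    # pre-smoothed frame

    def _pair_tmpl(ib, id_, off=(0.0, 0.0)):
        tmpl = _render_pair_template(
            instrument, ib, id_, z_est, d, thalf_c + pad, offset=off
        )
        if smooth_sigma > 0:
            tmpl = gaussian_filter(tmpl, smooth_sigma)
        return tmpl[pad:-pad, pad:-pad]

    br, bc, score_bank, f_b = _bank_correlate(pair_roi, _pair_tmpl, threshold)
    flags += f_b
    c_mid = bc_lo + bc
    c_u = c_mid + dc / 2.0
    c_l = c_mid - dc / 2.0
    y_mid = (r_u + r_l) / 2.0
    x_mid = (c_u + c_l) / 2.0
    x = (x_mid - (w - 1) / 2.0) * instrument.pixel_size
    y = (y_mid - (h - 1) / 2.0) * instrument.pixel_size
    return PairLocalization(
        center_upper=(r_u, c_u),
        center_lower=(r_l, c_l),
        d=float(d),
        score=float(score_m),
        x=float(x),
        y=float(y),
        flags=sorted(set(flags)),
    )


def fullplane_localize(
    frame: np.ndarray,
    instrument: InstrumentModel,
    threshold: float = 0.5,
    phi_step: float = 5.0,
    smooth_sigma: float = 0.7,
) -> tuple[float, float, float, list[str]]:
    """Model-based correlation localization of a full-plane DIC spot.

    Correlates the frame against a bank of rendered model PSFs spanning the
    azimuth (``phi_step`` degrees apart), keeps the best-scoring template and
    takes the score-weighted centroid of its ZNCC map.  Returns
    ``(x_nm, y_nm, score, flags)`` with ``x, y`` relative to the frame
    centre; a best score below ``threshold`` (or a signal-free frame) yields
    a ``"failed"`` flag.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    b0 = np.median(frame)
    dev = gaussian_filter((frame - b0) ** 2, 1.5)
    if dev.max() < 1e-12 * max(1.0, b0**2) + 1e-9:
        return np.nan, np.nan, np.nan, ["failed", "no-signal"]
    smoothed = gaussian_filter(frame, smooth_sigma) if smooth_sigma > 0 else frame
    r0, c0 = np.unravel_index(int(np.argmax(dev)), dev.shape)
    half = _patch_half(instrument)
    lo_r, hi_r = _clip_window(r0 - 2 * half, r0 + 2 * half + 1, h)
    lo_c, hi_c = _clip_window(c0 - 2 * half, c0 + 2 * half + 1, w)
    roi = smoothed[lo_r:hi_r, lo_c:hi_c] - b0
    thalf = min(half + 3, (min(roi.shape) - 5) // 2)

    pad = 4

    def _tmpl(ib, id_, off=(0.0, 0.0)):
        t = _render_full_template(
            instrument, ib, id_, 0.0, thalf + pad, offset=off
        )
        if smooth_sigma > 0:
            t = gaussian_filter(t, smooth_sigma)
        return t[pad:-pad, pad:-pad]

    try:
        pr, pc, score, flags = _bank_correlate(
            roi, _tmpl, threshold, phi_step=phi_step
        )
    except LocalizationError:
        return np.nan, np.nan, np.nan, ["failed", "no correlation above threshold"]
    if score < threshold:
        return np.nan, np.nan, np.nan, ["failed", "below-threshold"]
    r = lo_r + pr
    c = lo_c + pc
    x = (c - (w - 1) / 2.0) * instrument.pixel_size
    y = (r - (h - 1) / 2.0) * instrument.pixel_size
    return float(x), float(y), float(score), flags


def measure_lobe_intensities(
    frame: np.ndarray,
    center: tuple[float, float],
    instrument: InstrumentModel,
    halfplane: bool = False,
) -> tuple[float, float, list[str]]:
    """Raw bright/dark lobe intensities around a localized spot centre.

    The bright (dark) window is a box centred at ``center + shear/2``
    (``- shear/2``); ``B_raw`` is the mean of the k largest pixels of the
    bright window and ``D_raw`` the mean of the k smallest of the dark
    window, with k the number of pixels within one sigma of the lobe centre.
    Windows clipped by the frame edge raise an ``"edge-clipped"`` flag.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    s_r, s_c = instrument.shear
    sigma = instrument.psf_sigma
    hw = int(np.ceil(2 * sigma * (instrument.kappa if halfplane else 1.0)))
    flags: list[str] = []

    def window_mean(r_lobe: float, c_lobe: float, top: bool) -> float:
        nonlocal flags
        ri, ci = int(round(r_lobe)), int(round(c_lobe))
        lo_r, hi_r = _clip_window(ri - hw, ri + hw + 1, h)
        lo_c, hi_c = _clip_window(ci - hw, ci + hw + 1, w)
        if hi_r - lo_r < 2 * hw + 1 or hi_c - lo_c < 2 * hw + 1:
            flags.append("edge-clipped")
        win = frame[lo_r:hi_r, lo_c:hi_c]
        rows, cols = np.mgrid[lo_r:hi_r, lo_c:hi_c].astype(float)
        sr = sigma * (instrument.kappa if halfplane else 1.0)
        inside = ((rows - r_lobe) / sr) ** 2 + ((cols - c_lobe) / sigma) ** 2 <= 1.0
        k = max(1, int(np.sum(inside)))
        vals = np.sort(win.ravel())
        return float(np.mean(vals[-k:] if top else vals[:k]))

    b_raw = window_mean(center[0] + s_r / 2.0, center[1] + s_c / 2.0, top=True)
    d_raw = window_mean(center[0] - s_r / 2.0, center[1] - s_c / 2.0, top=False)
    return b_raw, d_raw, sorted(set(flags))


def z_from_distance(d: float, calibration) -> tuple[float, list[str]]:
    """Convert a measured pair separation (px) to axial position (nm).

    ``z = (d - d0) / g`` with the fitted slope ``g`` in px/nm; positions
    beyond the calibrated range are returned with an ``"out-of-range"``
    flag.  Raises if no calibration is supplied.
    """
    if calibration is None:
        raise ValueError("calibration missing")
    z = (d - calibration.d0) / calibration.slope_px_per_nm
    flags = [] if abs(z) <= calibration.z_range else ["out-of-range"]
    return float(z), flags
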