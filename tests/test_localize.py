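"""Mirror-template and model-based correlation localization."""

import numpy as np
import pytest

from paradic import (
    CalibrationResult,
    InstrumentModel,
    LocalizationError,
    NanorodPose,
    add_noise,
    fullplane_localize,
    measure_lobe_intensities,
    mirror_correlation_localize,
    render_fullplane,
    render_parallax,
    z_from_distance,
)
from paradic.localize import _weighted_peak


def _zncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / den) if den > 0 else 0.0


def _parabolic(y_m: float, y_0: float, y_p: float) -> float:
    den = y_m - 2 * y_0 + y_p
    return 0.5 * (y_m - y_p) / den if den != 0 else 0.0


def _oracle_pair(frame: np.ndarray, d_guess: float):
    """Independent exhaustive-shift NCC oracle for the half-plane pair.

    Separation: the upper-spot band of the frame is correlated against the
    band shifted down by every candidate integer separation (the two spots
    have identical shape in the default geometry); the peak, refined with a
    parabola, sits at d.  Midpoint row: same procedure against the frame's
    reflection about the split axis, whose peak sits at
    ``r_u + r_l - (H - 1)``.
    """
    h = frame.shape[0]
    profile = ((frame - np.median(frame)) ** 2).sum(axis=1)
    r_u = int(np.argmax(profile[: h // 2]))
    band = slice(max(0, r_u - 7), r_u + 8)
    shifts = np.arange(int(round(d_guess)) - 4, int(round(d_guess)) + 5)
    scores = np.array(
        [_zncc(frame[band, :], frame[band.start + s : band.stop + s, :]) for s in shifts]
    )
    k = int(np.clip(np.argmax(scores), 1, len(scores) - 2))
    d = shifts[k] + _parabolic(scores[k - 1], scores[k], scores[k + 1])
    flipped = frame[::-1, :]
    r_l = int(np.argmax(profile[h // 2 :])) + h // 2
    s0 = r_u + r_l - (h - 1)  # mirror-match shift sits at the centre sum
    mshifts = np.arange(s0 - 6, s0 + 7)
    mscores = np.array(
        [
            _zncc(frame[band, :], flipped[band.start - s : band.stop - s, :])
            if 0 <= band.start - s and band.stop - s <= h
            else -2.0
            for s in mshifts
        ]
    )
    k = int(np.clip(np.argmax(mscores), 1, len(mscores) - 2))
    ssum = mshifts[k] + _parabolic(mscores[k - 1], mscores[k], mscores[k + 1])
    r_mid = (ssum + h - 1) / 2.0
    return float(d), float(r_mid)


def test_roundtrip_recovers_pose_within_2nm(inst):
    """render -> mirror localize -> z conversion recovers x, y, z to <= 2 nm."""
    rng = np.random.default_rng(7)
    for _ in range(8):
        x, y = rng.uniform(-60, 60, size=2)
        z = rng.uniform(-450, 450)
        pose = NanorodPose(
            x=x, y=y, z=z, phi=rng.uniform(0, 180), psi=rng.uniform(25, 90)
        )
        loc = mirror_correlation_localize(render_parallax(pose, inst), inst)
        z_est = (loc.d - inst.d0) / inst.gain_px_per_nm
        assert abs(loc.x - x) <= 2.0
        assert abs(loc.y - y) <= 2.0
        assert abs(z_est - z) <= 2.0


def test_agrees_with_exhaustive_shift_oracle(inst):
    """Subpixel separations/centres match the exhaustive-NCC oracle (50 poses)."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        pose = NanorodPose(
            x=rng.uniform(-40, 40),
            y=rng.uniform(-40, 40),
            z=rng.uniform(-450, 450),
            phi=rng.uniform(0, 180),
            psi=rng.uniform(25, 90),
        )
        frame = render_parallax(pose, inst)
        loc = mirror_correlation_localize(frame, inst)
        d_oracle, r_mid_oracle = _oracle_pair(frame, inst.separation_at(pose.z))
        assert loc.d == pytest.approx(d_oracle, abs=0.05)
        r_mid = (loc.center_upper[0] + loc.center_lower[0]) / 2.0
        assert r_mid == pytest.approx(r_mid_oracle, abs=0.05)


def test_mirror_image_frame_has_zero_relative_shift(inst):
    """A frame equal to its own reflection correlates at zero relative offset."""
    shape = (65, 48)
    frame = render_parallax(NanorodPose(phi=30, psi=80), inst, shape)
    assert np.allclose(frame, frame[::-1, :], atol=1e-9)
    loc = mirror_correlation_localize(frame, inst)
    r_mid = (loc.center_upper[0] + loc.center_lower[0]) / 2.0
    assert r_mid == pytest.approx((shape[0] - 1) / 2.0, abs=0.01)


def test_high_threshold_on_noisy_frame_fails(inst):
    weak = InstrumentModel(amplitude=120.0)
    frame = add_noise(render_parallax(NanorodPose(phi=0, psi=90), weak), weak, seed=0)
    with pytest.raises(LocalizationError):
        mirror_correlation_localize(frame, weak, threshold=0.99)


def test_threshold_raising_shrinks_centroid_set():
    """Raising the score threshold never adds pixels to the weighted centroid."""
    yy, xx = np.mgrid[0:21, 0:21].astype(float)
    corr = np.exp(-((yy - 10.3) ** 2 + (xx - 9.6) ** 2) / 8.0)
    sizes = [np.sum(corr >= tau) for tau in (0.3, 0.5, 0.7, 0.9)]
    assert sizes == sorted(sizes, reverse=True)
    r1, c1, *_ = _weighted_peak(corr, 0.5)
    r2, c2, *_ = _weighted_peak(corr, 0.7)
    assert r1 == pytest.approx(10.3, abs=0.02) and c1 == pytest.approx(9.6, abs=0.02)
    assert r2 == pytest.approx(10.3, abs=0.05) and c2 == pytest.approx(9.6, abs=0.05)


def test_precision_degrades_as_amplitude_drops(inst):
    """Shot-noise localization scatter grows monotonically as A/b0 shrinks."""
    pose = NanorodPose(x=10, y=-5, z=50, phi=30, psi=80)
    spreads = []
    for amp in (2000.0, 1000.0):
        instrument = InstrumentModel(amplitude=amp)
        clean = render_parallax(pose, instrument)
        rng = np.random.default_rng(11)
        pts = []
        for _ in range(40):
            loc = mirror_correlation_localize(
                add_noise(clean, instrument, rng), instrument
            )
            pts.append((loc.x, loc.y))
        spreads.append(np.std(np.asarray(pts), axis=0).sum())
    assert spreads[1] > spreads[0]


def test_z_from_distance_inverts_linear_law(inst):
    cal = CalibrationResult(
        slope_px_per_nm=inst.gain_px_per_nm,
        d0=inst.d0,
        r_squared=1.0,
        z_range=inst.z_range,
        pixel_size=inst.pixel_size,
    )
    z0, flags = z_from_distance(inst.d0, cal)
    assert z0 == 0.0 and flags == []
    z300, flags = z_from_distance(inst.d0 + inst.gain_px_per_nm * 300.0, cal)
    assert z300 == pytest.approx(300.0)
    # monotonic: larger separation means higher position
    z_a, _ = z_from_distance(inst.d0 + 0.8, cal)
    z_b, _ = z_from_distance(inst.d0 + 0.4, cal)
    assert z_a > z_b
    _, flags = z_from_distance(inst.d0 + inst.gain_px_per_nm * 700.0, cal)
    assert "out-of-range" in flags
    with pytest.raises(ValueError, match="calibration"):
        z_from_distance(20.0, None)


def test_fullplane_matches_bruteforce_bank_oracle(inst):
    """Model-bank localization lands within 0.1 px of an exhaustive oracle."""
    from paradic.localize import _render_full_template

    rng = np.random.default_rng(3)
    for _ in range(10):
        x, y = rng.uniform(-50, 50, size=2)
        pose = NanorodPose(x=x, y=y, phi=rng.uniform(0, 180), psi=rng.uniform(30, 90))
        frame = render_fullplane(pose, inst)
        fx, fy, score, flags = fullplane_localize(frame, inst)
        assert "failed" not in flags
        # oracle: exhaustive integer placement of the best bank template
        roi = frame - np.median(frame)
        best = (-2.0, None)
        for phi_t in np.arange(0.0, 90.1, 5.0):
            tm = _render_full_template(
                inst,
                np.cos(np.deg2rad(phi_t)) ** 4,
                np.sin(np.deg2rad(phi_t)) ** 4,
                0.0,
                7,
            )
            for r in range(roi.shape[0] - 15):
                for c in range(roi.shape[1] - 15):
                    s = _zncc(roi[r : r + 15, c : c + 15], tm)
                    if s > best[0]:
                        best = (s, (r + 7, c + 7))
        o_r, o_c = best[1]
        assert fy / inst.pixel_size + 15.5 == pytest.approx(o_r, abs=1.1)
        assert fx / inst.pixel_size + 15.5 == pytest.approx(o_c, abs=1.1)
        assert abs(fx - x) <= 0.1 * inst.pixel_size
        assert abs(fy - y) <= 0.1 * inst.pixel_size


def test_fullplane_signal_free_frame_flags_failure(inst):
    frame = render_fullplane(NanorodPose(phi=30, psi=0), inst)
    x, y, score, flags = fullplane_localize(frame, inst)
    assert "failed" in flags and np.isnan(x)


def test_fullplane_translation_equivariance(inst):
    frame = render_fullplane(NanorodPose(phi=25, psi=80), inst, (40, 40))
    x0, y0, *_ = fullplane_localize(frame, inst)
    rolled = np.roll(np.roll(frame, 3, axis=0), -2, axis=1)
    x1, y1, *_ = fullplane_localize(rolled, inst)
    assert y1 - y0 == pytest.approx(3 * inst.pixel_size, abs=0.5)
    assert x1 - x0 == pytest.approx(-2 * inst.pixel_size, abs=0.5)


class TestLobeIntensities:
    def _center(self, shape):
        return ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)

    def test_fully_bright_rod(self, inst):
        frame = render_fullplane(NanorodPose(phi=0, psi=90), inst)
        b, d, flags = measure_lobe_intensities(frame, self._center(frame.shape), inst)
        assert flags == []
        # top-k window mean sits between the lobe mean and the peak
        assert inst.background + 0.5 * inst.amplitude < b <= inst.background + inst.amplitude
        assert d == pytest.approx(inst.background, abs=5.0)

    def test_bisector_symmetric_excursions(self, inst):
        frame = render_fullplane(NanorodPose(phi=45, psi=90), inst)
        b, d, _ = measure_lobe_intensities(frame, self._center(frame.shape), inst)
        b0 = inst.background
        assert (b - b0) == pytest.approx(b0 - d, rel=0.01)
        bright = render_fullplane(NanorodPose(phi=0, psi=90), inst)
        b_full, _, _ = measure_lobe_intensities(bright, self._center(frame.shape), inst)
        # quarter of the full excursion, up to the small lobe cross-talk
        assert (b - b0) / (b_full - b0) == pytest.approx(0.25, abs=0.02)

    def test_axial_rod_reads_background(self, inst):
        frame = render_fullplane(NanorodPose(phi=10, psi=0), inst)
        b, d, _ = measure_lobe_intensities(frame, self._center(frame.shape), inst)
        assert b == pytest.approx(inst.background, abs=1e-9)
        assert d == pytest.approx(inst.background, abs=1e-9)

    def test_edge_window_flagged(self, inst):
        frame = render_fullplane(NanorodPose(phi=0, psi=90), inst)
        _, _, flags = measure_lobe_intensities(frame, (1.0, 1.0), inst)
        assert "edge-clipped" in flags
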