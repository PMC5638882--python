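"""Rotational-mode analytics: Pearson signatures, segmentation, twister motion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paradic import (
    NanorodPose,
    classify_mode,
    particle_correlation_summary,
    segment_activity,
    twister_z_oscillation,
    window_pearson,
)
from paradic.scenarios import (
    generate_trajectory,
    intensity_trace_from_poses,
    make_preset,
)


def _outofplane_traces(inst, n=240):
    t = np.arange(n) / 30.0
    psi = 55.0 + 35.0 * np.sin(2 * np.pi * t / 4.0)
    poses = [NanorodPose(t=tt, phi=45.0, psi=p) for tt, p in zip(t, psi)]
    return intensity_trace_from_poses(poses, inst, readout="windowed")


def _inplane_sweep_traces(inst, n=720):
    phi = np.linspace(0.0, 180.0, n, endpoint=False)
    poses = [NanorodPose(t=i / 30, phi=p, psi=90.0) for i, p in enumerate(phi)]
    return intensity_trace_from_poses(poses, inst, readout="ideal")


def test_outofplane_swing_perfectly_anticorrelated(inst):
    """An elevation swing at azimuth 45 deg gives r = -1 in every window."""
    b, d = _outofplane_traces(inst)
    wins = window_pearson(b, d, window=16)
    live = wins[wins["mode"] != "static"]
    assert len(live) > 10
    assert np.allclose(live["r"], -1.0, atol=1e-9)
    assert (live["mode"] == "out-of-plane").all()


def test_uniform_inplane_sweep_matches_moment_oracle(inst):
    """Whole-sweep r equals corr(cos^4, -sin^4) = +15/17 over uniform azimuth."""
    b, d = _inplane_sweep_traces(inst)
    r = window_pearson(b, d, window=len(b), stride=1)["r"].iloc[0]
    # independent dense-grid moment oracle
    phi = np.linspace(0, np.pi, 200_001, endpoint=False)
    x, y = np.cos(phi) ** 4, np.sin(phi) ** 4
    oracle = float(np.corrcoef(x, -y)[0, 1])
    assert oracle == pytest.approx(15 / 17, abs=1e-6)
    assert r == pytest.approx(oracle, abs=1e-3)


def test_frozen_orientation_is_static(inst):
    b = np.full(64, 2400.0)
    d = np.full(64, 1700.0)
    wins = window_pearson(b, d, window=16)
    assert (wins["mode"] == "static").all()
    assert wins["r"].isna().all()


@pytest.mark.parametrize(
    "r, expected",
    [(-1.0, "out-of-plane"), (0.9, "in-plane"), (0.1, "mixed"), (-0.5, "out-of-plane")],
)
def test_mode_thresholds(r, expected):
    assert classify_mode(r) == expected


@settings(max_examples=50, derandomize=True)
@given(
    scale=st.floats(0.01, 100.0),
    offset=st.floats(-1e4, 1e4),
)
def test_pearson_invariant_under_affine_rescaling(scale, offset):
    rng = np.random.default_rng(0)
    b = rng.normal(size=64)
    d = 0.3 * b + rng.normal(size=64)
    r0 = window_pearson(b, d, window=64)["r"].iloc[0]
    r1 = window_pearson(scale * b + offset, d, window=64)["r"].iloc[0]
    assert r1 == pytest.approx(r0, abs=1e-9)


class TestSegmentation:
    def test_quiet_period_recovered_across_seeds(self, inst):
        """active/quiet/active traces yield one quiet segment of 20 +/- 1 s."""
        from paradic.orientation import normalize_trace

        spec = make_preset("endocytosis")
        for seed in range(5):
            poses, labels = generate_trajectory(spec, seed=seed)
            b, d = intensity_trace_from_poses(poses, inst)
            trace = normalize_trace(b, d)
            seg = segment_activity(trace.i_b, trace.i_d, fps=spec.fps)
            quiet = seg.quiet_durations
            assert len(quiet) == 1
            assert quiet[0] == pytest.approx(20.0, abs=1.0)

    def test_all_active_trace_has_no_quiet(self, inst):
        rng = np.random.default_rng(1)
        b = 2000 + 800 * rng.random(600)
        d = 2000 - 800 * rng.random(600)
        seg = segment_activity(b, d, fps=30.0)
        assert len(seg.quiet_durations) == 0

    def test_all_static_trace_is_one_quiet_segment(self):
        b = np.full(300, 0.4)
        d = np.full(300, 0.2)
        seg = segment_activity(b, d, fps=30.0)
        assert len(seg.segments) == 1
        assert seg.segments["state"].iloc[0] == "quiet"
        assert seg.quiet_durations[0] == pytest.approx(10.0)

    def test_abrupt_restoration_flagged(self):
        rng = np.random.default_rng(3)
        quiet = np.full(300, 0.05)
        active = 0.5 + 0.4 * rng.standard_normal(300).clip(-1, 1)
        b = np.concatenate([quiet, active])  # dark-to-bright jump in <= 3 frames
        d = 1.0 - b
        seg = segment_activity(b, d, fps=30.0)
        assert any(295 <= e <= 310 for e in seg.restoration_events)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="short"):
            segment_activity(np.ones(10), np.ones(10), fps=30.0)


class TestParticleSummary:
    def test_identical_traces_identical_r(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=200)
        d = 0.5 * b + rng.normal(size=200)
        df, summary = particle_correlation_summary({"stage": [(b, d), (b, d)]})
        assert df["r"].iloc[0] == df["r"].iloc[1]
        assert summary["stage"]["n"] == 2

    def test_single_particle_histogram(self):
        b = np.sin(np.linspace(0, 10, 100))
        df, summary = particle_correlation_summary({"s": [(b, b)]})
        assert summary["s"]["hist"].sum() == 1
        assert summary["s"]["center"] == pytest.approx(1.0)

    def test_empty_stage_rejected(self):
        with pytest.raises(ValueError, match="no particles"):
            particle_correlation_summary({"s": []})


class TestTwister:
    def test_pure_sine_recovered(self):
        fps = 30.0
        t = np.arange(300) / fps
        z = 65.0 * np.sin(2 * np.pi * t / 0.35)
        xy = np.stack([2600 * t, np.zeros_like(t)], axis=1)
        res = twister_z_oscillation(z, xy, fps)
        assert res["flags"] == []
        assert res["period_s"] == pytest.approx(0.35, rel=0.02)
        # 5th-95th percentile envelope of a sine: ~1.975 * amplitude
        assert res["amplitude_pp"] == pytest.approx(2 * 65.0, rel=0.06)
        assert res["lateral_linearity"] > 0.99

    def test_transport_preset_twister_amplitude_in_range(self, inst):
        poses, labels = generate_trajectory(make_preset("transport"), seed=0)
        sel = [i for i, lab in enumerate(labels) if lab == "transport"]
        z = np.array([poses[i].z for i in sel])
        xy = np.array([(poses[i].x, poses[i].y) for i in sel])
        res = twister_z_oscillation(z, xy, 30.0)
        assert 100.0 <= res["amplitude_pp"] <= 160.0
        assert res["period_s"] == pytest.approx(0.35, rel=0.1)
        assert res["lateral_linearity"] > 0.95

    def test_planar_transport_is_aperiodic(self):
        t = np.arange(200) / 30.0
        z = np.zeros_like(t)
        xy = np.stack([1000 * t, 500 * t], axis=1)
        res = twister_z_oscillation(z, xy, 30.0)
        assert "aperiodic" in res["flags"]
        assert res["amplitude_pp"] == pytest.approx(0.0, abs=1e-9)
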