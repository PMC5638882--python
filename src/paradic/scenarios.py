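"""Ground-truthed motion scenarios: membrane binding, endocytosis, transport.

Each scenario is a list of phases; a phase combines a translational model
(confined diffusion in a square corral, full stop, directed run, or helical
transport) with a rotational model (isotropic rotational diffusion by
composed small random rotations, in-plane- or out-of-plane-biased
diffusion, a deterministic elevation swing, frozen orientation, or slow
directed orientation drift).  Every generated frame carries exactly one
phase label, and identical spec + seed reproduce the trajectory bit for
bit.

The presets emulate, at desk scale, the characteristic motion sequences of
endocytic cargo: active rotation -> progressive confinement -> a quiet
period of tens of seconds inside the coated pit -> restored active rotation
(``endocytosis``); and intracellular transport with a vertical run along a
perpendicular track, a turn, and fast lateral transport with a twister-like
z oscillation (``transport``).  ``calibration`` and ``sweep`` reproduce the
axial-calibration protocols (20 nm z steps with a 36-orientation azimuth
sweep per plane; a slow 100 nm/s vertical ramp at 200 ms exposure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .instrument import FrameStack, InstrumentModel, NanorodPose
from .localize import measure_lobe_intensities
from . import optics

__all__ = [
    "Phase",
    "ScenarioSpec",
    "generate_trajectory",
    "rotational_diffusion_step",
    "render_movie",
    "intensity_trace_from_poses",
    "PRESETS",
    "make_preset",
]


@dataclass(frozen=True)
class Phase:
    """One contiguous motion phase.

    ``translation`` and ``rotation`` are model dicts with a ``"model"`` key
    and model parameters; ``label`` tags every frame generated in the phase.
    """

    duration_s: float
    translation: dict
    rotation: dict
    label: str

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("phase duration must be > 0")


@dataclass(frozen=True)
class ScenarioSpec:
    phases: tuple[Phase, ...]
    fps: float = 30.0
    x0: float = 0.0
    y0: float = 0.0
    z0: float = 0.0
    phi0: float = 30.0
    psi0: float = 70.0
    name: str = "custom"


TRANSLATION_MODELS = {"confined", "stop", "directed", "helical"}
ROTATION_MODELS = {
    "isotropic",
    "inplane",
    "outofplane",
    "mixed",
    "psi_swing",
    "frozen",
    "slow_directed",
}


def _angles_to_vec(phi_deg: float, psi_deg: float) -> np.ndarray:
    phi, psi = np.deg2rad(phi_deg), np.deg2rad(psi_deg)
    return np.array(
        [np.sin(psi) * np.cos(phi), np.sin(psi) * np.sin(phi), np.cos(psi)]
    )


def _vec_to_angles(u: np.ndarray) -> tuple[float, float]:
    psi = np.degrees(np.arccos(np.clip(abs(u[2]), 0.0, 1.0)))
    phi = np.degrees(np.arctan2(u[1], u[0])) % 180.0
    return float(phi), float(psi)


def rotational_diffusion_step(
    u: np.ndarray, d_rot: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """One isotropic rotational-diffusion step of a unit axis vector.

    Applies a small random rotation (Rodrigues formula) with rotation-vector
    components drawn from N(0, 2*D_rot*dt); for small steps the mean squared
    angular displacement of the axis is 4*D_rot*dt.  ``d_rot = 0`` leaves
    the axis unchanged.
    """
    if d_rot < 0 or dt <= 0:
        raise ValueError("need d_rot >= 0 and dt > 0")
    if d_rot == 0:
        return u
    omega = rng.normal(0.0, np.sqrt(2.0 * d_rot * dt), size=3)
    theta = np.linalg.norm(omega)
    if theta == 0:
        return u
    k = omega / theta
    return (
        u * np.cos(theta)
        + np.cross(k, u) * np.sin(theta)
        + k * np.dot(k, u) * (1 - np.cos(theta))
    )


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    return float(lo + (y if y <= span else 2 * span - y))


def generate_trajectory(
    spec: ScenarioSpec, seed: int = 0
) -> tuple[list[NanorodPose], list[str]]:
    """Generate one pose per frame, with a phase label per frame.

    Reproducible: identical spec and seed give identical poses.  Raises on
    unknown model names.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / spec.fps
    pos = np.array([spec.x0, spec.y0, spec.z0], dtype=float)
    phi, psi = spec.phi0, spec.psi0
    u = _angles_to_vec(phi, psi)
    poses: list[NanorodPose] = []
    labels: list[str] = []
    frame = 0
    for phase in spec.phases:
        tmodel = phase.translation.get("model")
        rmodel = phase.rotation.get("model")
        if tmodel not in TRANSLATION_MODELS:
            raise ValueError(f"unknown translational model {tmodel!r}")
        if rmodel not in ROTATION_MODELS:
            raise ValueError(f"unknown rotational model {rmodel!r}")
        n = max(1, int(round(phase.duration_s * spec.fps)))
        corral = pos[:2].copy()
        t_phase0 = frame * dt
        psi_ref = psi
        for i in range(n):
            t = frame * dt
            # --- translation ---
            if tmodel == "confined":
                D = phase.translation["D"]
                L = phase.translation["L"]
                step = rng.normal(0.0, np.sqrt(2 * D * dt), size=2)
                for ax in range(2):
                    pos[ax] = _reflect(
                        pos[ax] + step[ax], corral[ax] - L, corral[ax] + L
                    )
            elif tmodel == "directed":
                v = np.asarray(phase.translation["v"], dtype=float)
                pos += v * dt
            elif tmodel == "helical":
                direction = np.asarray(
                    phase.translation.get("direction", (1.0, 0.0)), dtype=float
                )
                direction = direction / np.linalg.norm(direction)
                speed = phase.translation["speed"]
                radius = phase.translation["radius"]
                period = phase.translation["period"]
                tau = t - t_phase0
                omega = 2 * np.pi / period
                perp = np.array([-direction[1], direction[0]])
                lateral = corral + direction * speed * tau
                lateral = lateral + perp * radius * np.cos(omega * tau)
                pos[0], pos[1] = lateral
                pos[2] = spec.z0 + radius * np.sin(omega * tau)
            # "stop": no translation
            # --- rotation ---
            if rmodel == "isotropic":
                u = rotational_diffusion_step(u, phase.rotation["D_rot"], dt, rng)
                phi, psi = _vec_to_angles(u)
            elif rmodel == "inplane":
                D_phi = phase.rotation["D_phi"]
                jitter = phase.rotation.get("psi_jitter", 0.0)
                phi = (phi + np.degrees(rng.normal(0, np.sqrt(2 * D_phi * dt)))) % 180
                psi = _reflect(90.0 - abs(rng.normal(0, jitter)), 0.0, 90.0)
                u = _angles_to_vec(phi, psi)
            elif rmodel == "outofplane":
                D_psi = phase.rotation["D_psi"]
                lo = phase.rotation.get("psi_min", 20.0)
                psi = _reflect(
                    psi + np.degrees(rng.normal(0, np.sqrt(2 * D_psi * dt))), lo, 90.0
                )
                phi = phase.rotation.get("phi0", phi)
                u = _angles_to_vec(phi, psi)
            elif rmodel == "mixed":
                D_phi = phase.rotation["D_phi"]
                D_psi = phase.rotation["D_psi"]
                lo = phase.rotation.get("psi_min", 20.0)
                phi = (phi + np.degrees(rng.normal(0, np.sqrt(2 * D_phi * dt)))) % 180
                psi = _reflect(
                    psi + np.degrees(rng.normal(0, np.sqrt(2 * D_psi * dt))), lo, 90.0
                )
                u = _angles_to_vec(phi, psi)
            elif rmodel == "psi_swing":
                mid = phase.rotation.get("psi_mid", 55.0)
                amp = phase.rotation.get("psi_amp", 35.0)
                period = phase.rotation["period"]
                phi = phase.rotation.get("phi0", 45.0)
                psi = mid + amp * np.sin(2 * np.pi * (t - t_phase0) / period)
                u = _angles_to_vec(phi, psi)
            elif rmodel == "slow_directed":
                rate = phase.rotation.get("rate_deg_s", 1.0)
                phi = phase.rotation.get("phi0", phi)
                if i == 0:
                    psi_ref = phase.rotation.get("psi0", psi)
                psi = _reflect(psi_ref + rate * (t - t_phase0), 0.0, 90.0)
                u = _angles_to_vec(phi, psi)
            # "frozen": orientation unchanged
            poses.append(
                NanorodPose(t=t, x=pos[0], y=pos[1], z=pos[2], phi=phi, psi=psi)
            )
            labels.append(phase.label)
            frame += 1
    return poses, labels


def render_movie(
    poses: list[NanorodPose],
    instrument: InstrumentModel,
    mode: str = "parallax",
    shape: tuple[int, int] | None = None,
    noise: bool = True,
    seed: int = 0,
    labels: list[str] | None = None,
    extra_meta: dict | None = None,
    follow: bool = False,
) -> FrameStack:
    """Render a pose sequence into a frame stack with ground-truth metadata.

    The sidecar metadata records the seed, the instrument parameters and the
    ground-truth pose (and optional phase label) of every frame.  With
    ``follow=True`` the region of interest recentres on the probe at integer
    pixels each frame (single-target ROI tracking, as a stage-tracking
    acquisition would); the per-frame ROI offset in nm is stored in the
    metadata under ``roi_offset_nm`` so absolute coordinates can be
    reassembled.
    """
    if not poses:
        raise ValueError("empty pose list")
    if shape is None:
        shape = (
            optics.DEFAULT_PARALLAX_SHAPE
            if mode == "parallax"
            else optics.DEFAULT_FULLPLANE_SHAPE
        )
    render = optics.render_parallax if mode == "parallax" else optics.render_fullplane
    rng = np.random.default_rng(seed)
    frames = np.empty((len(poses), *shape))
    offsets = []
    for i, pose in enumerate(poses):
        if follow:
            px = instrument.pixel_size
            off_x = round(pose.x / px) * px
            off_y = round(pose.y / px) * px
            offsets.append((off_x, off_y))
            pose = NanorodPose(
                t=pose.t, x=pose.x - off_x, y=pose.y - off_y, z=pose.z,
                phi=pose.phi, psi=pose.psi,
            )
        img = render(pose, instrument, shape)
        frames[i] = optics.add_noise(img, instrument, rng) if noise else img
    t = np.array([p.t for p in poses])
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        t = np.arange(len(poses), dtype=float)
    meta = {
        "seed": seed,
        "mode": mode,
        "noise": noise,
        "instrument": vars(instrument).copy(),
        "poses": [
            {"t": p.t, "x": p.x, "y": p.y, "z": p.z, "phi": p.phi, "psi": p.psi}
            for p in poses
        ],
    }
    if follow:
        meta["roi_offset_nm"] = offsets
    if labels is not None:
        meta["labels"] = list(labels)
    if extra_meta:
        meta.update(extra_meta)
    return FrameStack(
        frames=frames,
        mode=mode,
        timestamps=t,
        pixel_size=instrument.pixel_size,
        meta=meta,
    )


def _readout_coefficients(instrument: InstrumentModel) -> np.ndarray:
    """Linear response of the windowed lobe readout to the two unit lobes.

    Returns a 2x2 matrix ``M`` such that, at fixed centred in-focus pose,
    ``(B_raw - b0, D_raw - b0) ~= A * M @ (I_B, I_D)``.  The off-diagonal
    terms capture the cross-talk of overlapping lobes.
    """
    b0 = instrument.background
    shape = optics.DEFAULT_FULLPLANE_SHAPE
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    m = np.zeros((2, 2))
    for j, (phi, psi) in enumerate(((0.0, 90.0), (90.0, 90.0))):  # (I_B, I_D) bases
        img = optics.render_fullplane(NanorodPose(phi=phi, psi=psi), instrument, shape)
        b, d, _ = measure_lobe_intensities(img, center, instrument)
        m[0, j] = (b - b0) / instrument.amplitude
        m[1, j] = (d - b0) / instrument.amplitude
    return m


def intensity_trace_from_poses(
    poses: list[NanorodPose],
    instrument: InstrumentModel,
    readout: str = "windowed",
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw bright/dark lobe intensity traces for a pose sequence.

    A fast closed-form equivalent of render + localize + lobe readout for a
    laterally stationary, in-focus probe.  ``readout="ideal"`` uses the pure
    dipole law (``B = b0 + A*I_B``, ``D = b0 - A*I_D``); ``"windowed"``
    additionally applies the linear cross-talk of overlapping lobes measured
    from the renderer's unit-lobe responses.  Optional Gaussian noise of
    standard deviation ``noise_sd`` counts is added to both traces.
    """
    i_b = np.empty(len(poses))
    i_d = np.empty(len(poses))
    for i, p in enumerate(poses):
        i_b[i], i_d[i] = optics.dipole_intensities(p)
    b0, amp = instrument.background, instrument.amplitude
    if readout == "ideal":
        b = b0 + amp * i_b
        d = b0 - amp * i_d
    elif readout == "windowed":
        m = _readout_coefficients(instrument)
        excess = amp * (m @ np.vstack([i_b, i_d]))
        b = b0 + excess[0]
        d = b0 + excess[1]
    else:
        raise ValueError(f"unknown readout {readout!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        b = b + rng.normal(0, noise_sd, size=b.shape)
        d = d + rng.normal(0, noise_sd, size=d.shape)
    return b, d


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _endocytosis_spec() -> ScenarioSpec:
    return ScenarioSpec(
        phases=(
            Phase(
                15.0,
                {"model": "confined", "D": 2.0e4, "L": 600.0},
                {"model": "isotropic", "D_rot": 5.0},
                "active",
            ),
            Phase(
                10.0,
                {"model": "confined", "D": 2.0e3, "L": 150.0},
                {"model": "inplane", "D_phi": 2.0, "psi_jitter": 5.0},
                "restrained",
            ),
            Phase(
                20.0,
                {"model": "stop"},
                {"model": "slow_directed", "phi0": 5.0, "psi0": 80.0, "rate_deg_s": 1.0},
                "quiet",
            ),
            Phase(
                15.0,
                {"model": "confined", "D": 2.0e4, "L": 600.0},
                {"model": "isotropic", "D_rot": 5.0},
                "active",
            ),
        ),
        fps=30.0,
        name="endocytosis",
    )


def _transport_spec() -> ScenarioSpec:
    return ScenarioSpec(
        phases=(
            Phase(
                1.0,
                {"model": "confined", "D": 5.0e3, "L": 100.0},
                {"model": "isotropic", "D_rot": 1.0},
                "search",
            ),
            Phase(
                0.55,
                {"model": "directed", "v": (0.0, 0.0, 545.0)},
                {"model": "frozen"},
                "vertical",
            ),
            Phase(
                0.55,
                {"model": "directed", "v": (0.0, 0.0, -545.0)},
                {"model": "frozen"},
                "vertical",
            ),
            Phase(
                0.8,
                {"model": "stop"},
                {"model": "slow_directed", "rate_deg_s": 20.0},
                "turn",
            ),
            Phase(
                2.0,
                {
                    "model": "helical",
                    "direction": (1.0, 0.0),
                    "speed": 2600.0,
                    "radius": 65.0,
                    "period": 0.35,
                },
                {"model": "slow_directed", "rate_deg_s": 30.0},
                "transport",
            ),
        ),
        fps=30.0,
        name="transport",
    )


def _calibration_scan(
    sweep: bool = True,
    z_min: float = -500.0,
    z_max: float = 500.0,
    z_step: float = 20.0,
    fps: float = 30.0,
) -> tuple[list[NanorodPose], dict]:
    """Axial calibration fixture: a z scan in fixed steps.

    With ``sweep=True`` every plane carries the full 36-orientation azimuth
    sweep (0-175 degrees in 5 degree steps, elevation 90); otherwise a
    single stationary orientation per plane.
    """
    z_planes = np.arange(z_min, z_max + z_step / 2, z_step)
    phis = np.arange(0.0, 180.0, 5.0) if sweep else np.array([30.0])
    poses, z_meta, phi_meta = [], [], []
    i = 0
    for z in z_planes:
        for phi in phis:
            poses.append(NanorodPose(t=i / fps, z=float(z), phi=float(phi), psi=90.0))
            z_meta.append(float(z))
            phi_meta.append(float(phi))
            i += 1
    return poses, {"z_nm": z_meta, "phi_deg": phi_meta}


def _sweep_spec() -> ScenarioSpec:
    # slow vertical ramp: -400 to +400 nm at 100 nm/s, 200 ms exposure
    return ScenarioSpec(
        phases=(
            Phase(
                8.0,
                {"model": "directed", "v": (0.0, 0.0, 100.0)},
                {"model": "frozen"},
                "sweep",
            ),
        ),
        fps=5.0,
        z0=-400.0,
        name="sweep",
    )


PRESETS = {
    "endocytosis": _endocytosis_spec,
    "transport": _transport_spec,
    "calibration": _calibration_scan,
    "sweep": _sweep_spec,
}


def make_preset(name: str, **kwargs):
    """Instantiate a named preset.

    ``endocytosis``, ``transport`` and ``sweep`` return a
    :class:`ScenarioSpec`; ``calibration`` returns ``(poses, meta)`` for
    direct rendering with :func:`render_movie`.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name](**kwargs)
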