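"""Synthetic marker-cluster trials for the stepping-down task.

One trial covers the analysed gait cycle: the heel strike preceding the
step-down (trailing foot, upper level), the landing of the leading foot on
the lower level, and the next heel strike (trailing foot, lower level).
Foot trajectories are authored with quintic-smoothstep swings so that foot
contacts are exact local minima of vertical position with zero forward
velocity; the pelvis translates at exactly the imposed speed.  Segment
orientations of the leading (right) leg are composed from latent sagittal
joint-angle splines through :func:`stepdown.kinematics.joint_rotation`, so
the analysis-side Euler decomposition recovers the latent angles exactly at
zero noise.  Rigid four-marker clusters are attached to all seven segments
(feet, calves, thighs, pelvis), sampled at 100 per second.

The latent truth (event samples, angle curves, orientations, speed, step
length) is retained on the trial object and serves as the oracle for the
kinematic pipeline tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .cohort import Participant
from .kinematics import GaitCycleEvents, joint_rotation

__all__ = ["MarkerTrial", "LatentTruth", "synthesize_markers",
            "CLUSTER_GEOMETRY", "angle_templates"]

FS = 100.0  # samples per second
_LEVER_ARM = 0.05  # m, nominal cluster radius converting angular noise to
# marker-position noise: sd_m = radians(sd_deg) * lever arm

SEGMENTS = ("pelvis", "thigh_r", "thigh_l", "calf_r", "calf_l",
            "foot_r", "foot_l")

# cluster-local marker layouts (m): four non-coplanar markers per segment
_BASE_CLUSTER = np.array(
    [
        [0.060, 0.020, 0.010],
        [-0.040, 0.050, 0.025],
        [-0.025, -0.050, 0.030],
        [0.030, 0.005, 0.070],
    ]
)
CLUSTER_GEOMETRY: dict[str, np.ndarray] = {
    seg: _BASE_CLUSTER * scale
    for seg, scale in [
        ("pelvis", 1.4), ("thigh_r", 1.2), ("thigh_l", 1.2),
        ("calf_r", 1.0), ("calf_l", 1.0), ("foot_r", 0.8), ("foot_l", 0.8),
    ]
}


@dataclass(frozen=True)
class LatentTruth:
    """Generator-side ground truth retained for oracle tests."""

    events: GaitCycleEvents
    angles_deg: dict  # 'ankle', 'knee' -> (T,) leading-leg sagittal angles
    velocities_degps: dict
    orientations: dict  # segment -> Rotation stack (T,)
    origins: dict  # segment -> (T, 3)
    speed_mps: float
    step_length_m: float


@dataclass(frozen=True)
class MarkerTrial:
    """Marker positions of one synthetic stepping-down trial."""

    fs: float
    time_s: np.ndarray  # (T,)
    markers: dict  # segment -> (T, 4, 3) world positions
    geometry: dict  # segment -> (4, 3) cluster-local layout
    latent: LatentTruth
    participant_id: str = "p000"
    condition: str = "low"
    step_height_m: float = 0.050
    strategy: str = "heel"
    noise_sd_deg: float = 0.0
    meta: dict = field(default_factory=dict, compare=False)


def _smoothstep(tau: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: zero first and second derivatives at both ends."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def _swing(t, t_start, t_end, p_start, p_end, z_level_start, z_level_end,
           clearance=0.03):
    """Foot trajectory for one swing phase (positions (T, 3))."""
    tau = (t - t_start) / (t_end - t_start)
    s = _smoothstep(tau)
    x = p_start + (p_end - p_start) * s
    z = z_level_start + (z_level_end - z_level_start) * s
    in_swing = (tau > 0) & (tau < 1)
    z = z + np.where(in_swing, clearance * np.sin(np.pi * np.clip(tau, 0, 1)) ** 2, 0.0)
    return x, z


def angle_templates(
    strategy: str,
    t: np.ndarray,
    t_hs_pre: float,
    t_land: float,
    t_hs_next: float,
    rng: np.random.Generator | None = None,
    shape_sd_deg: float = 0.0,
):
    """Latent sagittal ankle/knee angle splines for the leading leg.

    Landing shape depends on the strategy: a heel landing arrives
    dorsiflexed (positive ankle angle), a toe landing plantar-flexed
    (negative).  Negative knee values indicate flexion.  Optional
    ``shape_sd_deg`` jitters the keypoint values (participant-level curve
    variability) using ``rng``; the curves remain smooth splines.
    """
    if strategy not in ("heel", "toe"):
        raise ValueError(f"unknown strategy {strategy!r}")
    step = t_land - t_hs_pre
    toe_off = t_hs_pre + 0.3 * step
    mid_swing = t_hs_pre + 0.65 * step
    land_ankle = 10.0 if strategy == "heel" else -20.0
    land_knee = -5.0 if strategy == "heel" else -25.0
    t0, t_end = t[0], t[-1]
    knots = np.array([t0, t_hs_pre, toe_off, mid_swing, t_land,
                      t_land + 0.4 * step, t_hs_next, t_end])
    ankle_vals = np.array([-5.0, -3.0, -15.0, 5.0, land_ankle, -8.0, -5.0, -5.0])
    knee_vals = np.array([-8.0, -10.0, -20.0, -50.0, land_knee, -15.0, -10.0, -8.0])
    if shape_sd_deg > 0.0:
        if rng is None:
            raise ValueError("shape jitter requested without an rng")
        ankle_vals = ankle_vals + rng.normal(0.0, shape_sd_deg, ankle_vals.size)
        knee_vals = knee_vals + rng.normal(0.0, shape_sd_deg, knee_vals.size)
    ankle = CubicSpline(knots, ankle_vals, bc_type="clamped")
    knee = CubicSpline(knots, knee_vals, bc_type="clamped")
    return ankle, knee


def _trailing_leg_curves(t, t_hs_pre, t_land, t_hs_next):
    step = t_land - t_hs_pre
    knots = np.array([t[0], t_hs_pre, t_land, t_land + 0.3 * step,
                      t_hs_next - 0.2 * step, t_hs_next, t[-1]])
    hip = CubicSpline(knots, [15.0, 18.0, -12.0, -15.0, 5.0, 18.0, 15.0],
                      bc_type="clamped")
    knee = CubicSpline(knots, [-30.0, -8.0, -10.0, -25.0, -45.0, -8.0, -8.0],
                       bc_type="clamped")
    ankle = CubicSpline(knots, [0.0, -3.0, -10.0, -12.0, 5.0, -3.0, -3.0],
                        bc_type="clamped")
    return hip, knee, ankle


def synthesize_markers(
    participant: Participant,
    condition: str,
    step_height: float,
    strategy: str,
    rng: np.random.Generator,
    noise_sd_deg: float | None = None,
    step_length: float | None = None,
    shape_sd_deg: float = 0.0,
    fs: float = FS,
) -> MarkerTrial:
    """Build one marker-cluster trial for a decided landing strategy.

    Parameters
    ----------
    noise_sd_deg : isotropic cluster jitter in degrees; converted to
        marker-position noise through a 0.05 m lever arm.  Defaults to 0
        when not given (the cohort generator passes its
        ``trajectory_noise_sd``).
    step_length : forward distance between the feet at the step-down
        double support; defaults to a strategy-dependent value (0.58 m
        heel, 0.52 m toe) plus participant-independent jitter from ``rng``.
    shape_sd_deg : keypoint jitter of the latent angle templates
        (trial/participant-level curve variability); 0 reproduces the
        strategy's canonical curve exactly.
    """
    if noise_sd_deg is None:
        noise_sd_deg = 0.0
    if noise_sd_deg < 0:
        raise ValueError("noise SD must be non-negative")
    speed = participant.speed_low if condition == "low" else participant.speed_high
    if step_length is None:
        base = 0.58 if strategy == "heel" else 0.52
        step_length = base + rng.normal(0.0, 0.03)
    dt = 1.0 / fs
    step_time = step_length / speed
    t_hs_pre = 0.45
    t_land = t_hs_pre + step_time
    t_hs_next = t_land + step_time
    # snap events to the sample grid
    t_hs_pre = round(t_hs_pre / dt) * dt
    t_land = round(t_land / dt) * dt
    t_hs_next = round(t_hs_next / dt) * dt
    T = int(round((t_hs_next + 0.25) / dt)) + 1
    t = np.arange(T) * dt

    zoff = 0.07  # foot-cluster origin height above the support surface
    h = step_height
    swing_time = 0.7 * step_time

    # contact abscissae: L1 (upper, t_hs_pre), R1 (lower, t_land), L2 (lower)
    x_l1 = 0.0
    x_r1 = x_l1 + step_length
    x_l2 = x_r1 + step_length

    # --- leading (right) foot: stance upper -> swing down -> stance lower
    toe_off_r = t_hs_pre + 0.1 * step_time
    x_r = np.full(T, x_r1 - 2.0 * step_length)
    z_r = np.full(T, h + zoff)
    sw = (t > toe_off_r) & (t < t_land)
    xs, zs = _swing(t, toe_off_r, t_land, x_r1 - 2.0 * step_length, x_r1,
                    h + zoff, zoff)
    x_r[sw], z_r[sw] = xs[sw], zs[sw]
    x_r[t >= t_land] = x_r1
    z_r[t >= t_land] = zoff

    # --- trailing (left) foot: swing to upper-level strike, stance, swing
    # to the lower level
    t_toeoff_l0 = t_hs_pre - swing_time
    t_toeoff_l1 = t_hs_next - swing_time  # after t_land: double support holds
    x_l = np.full(T, x_l1 - 2.0 * step_length)
    z_l = np.full(T, h + zoff)
    sw0 = (t > t_toeoff_l0) & (t < t_hs_pre)
    xs0, zs0 = _swing(t, t_toeoff_l0, t_hs_pre, x_l1 - 2.0 * step_length, x_l1,
                      h + zoff, h + zoff)
    x_l[sw0], z_l[sw0] = xs0[sw0], zs0[sw0]
    mid = (t >= t_hs_pre) & (t <= t_toeoff_l1)
    x_l[mid], z_l[mid] = x_l1, h + zoff
    sw1 = (t > t_toeoff_l1) & (t < t_hs_next)
    xs1, zs1 = _swing(t, t_toeoff_l1, t_hs_next, x_l1, x_l2, h + zoff, zoff)
    x_l[sw1], z_l[sw1] = xs1[sw1], zs1[sw1]
    x_l[t >= t_hs_next] = x_l2
    z_l[t >= t_hs_next] = zoff

    # --- pelvis: exact constant forward speed; height steps down smoothly
    x_p = (x_l1 - 0.5 * step_length) + speed * t
    z_p = zoff + 0.92 + h * (1.0 - _smoothstep((t - (t_land - 0.15)) / 0.3))
    y = np.zeros(T)

    # --- latent joint-angle curves and orientations
    ankle_spl, knee_spl = angle_templates(
        strategy, t, t_hs_pre, t_land, t_hs_next,
        rng=rng, shape_sd_deg=shape_sd_deg,
    )
    hip_knots = np.array([t[0], t_hs_pre, t_hs_pre + 0.5 * step_time, t_land,
                          t_hs_next, t[-1]])
    hip_spl = CubicSpline(hip_knots, [-5.0, -18.0, 5.0, 20.0, -15.0, -5.0],
                          bc_type="clamped")
    ankle_deg = ankle_spl(t)
    knee_deg = knee_spl(t)
    hip_deg = hip_spl(t)

    r_pelvis = Rotation.identity(T)
    r_thigh_r = joint_rotation(hip_deg)
    r_calf_r = r_thigh_r * joint_rotation(knee_deg)
    r_foot_r = r_calf_r * joint_rotation(ankle_deg)

    hip_l, knee_l, ankle_l = _trailing_leg_curves(t, t_hs_pre, t_land, t_hs_next)
    r_thigh_l = joint_rotation(hip_l(t))
    r_calf_l = r_thigh_l * joint_rotation(knee_l(t))
    r_foot_l = r_calf_l * joint_rotation(ankle_l(t))

    foot_r_pos = np.column_stack([x_r, y, z_r])
    foot_l_pos = np.column_stack([x_l, y - 0.09, z_l])
    pelvis_pos = np.column_stack([x_p, y, z_p])
    calf_r_pos = foot_r_pos + [0.0, 0.04, 0.30]
    calf_l_pos = foot_l_pos + [0.0, -0.04, 0.30]
    thigh_r_pos = 0.5 * (calf_r_pos + pelvis_pos) + [0.0, 0.09, 0.0]
    thigh_l_pos = 0.5 * (calf_l_pos + pelvis_pos) + [0.0, -0.09, 0.0]

    orientations = {
        "pelvis": r_pelvis, "thigh_r": r_thigh_r, "thigh_l": r_thigh_l,
        "calf_r": r_calf_r, "calf_l": r_calf_l,
        "foot_r": r_foot_r, "foot_l": r_foot_l,
    }
    origins = {
        "pelvis": pelvis_pos, "thigh_r": thigh_r_pos, "thigh_l": thigh_l_pos,
        "calf_r": calf_r_pos, "calf_l": calf_l_pos,
        "foot_r": foot_r_pos, "foot_l": foot_l_pos,
    }

    noise_sd_m = np.radians(noise_sd_deg) * _LEVER_ARM
    markers = {}
    for seg in SEGMENTS:
        local = CLUSTER_GEOMETRY[seg]
        rotmats = orientations[seg].as_matrix()  # (T, 3, 3)
        world = np.einsum("tij,mj->tmi", rotmats, local) + origins[seg][:, None, :]
        if noise_sd_m > 0:
            world = world + rng.normal(0.0, noise_sd_m, world.shape)
        markers[seg] = world

    events = GaitCycleEvents(
        int(round(t_hs_pre * fs)), int(round(t_land * fs)),
        int(round(t_hs_next * fs)),
    )
    latent = LatentTruth(
        events=events,
        angles_deg={"ankle": ankle_deg, "knee": knee_deg},
        velocities_degps={"ankle": ankle_spl.derivative()(t),
                          "knee": knee_spl.derivative()(t)},
        orientations=orientations,
        origins=origins,
        speed_mps=float(speed),
        step_length_m=float(step_length),
    )
    return MarkerTrial(
        fs=fs, time_s=t, markers=markers, geometry=dict(CLUSTER_GEOMETRY),
        latent=latent, participant_id=participant.id, condition=condition,
        step_height_m=float(step_height), strategy=strategy,
        noise_sd_deg=float(noise_sd_deg),
    )
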