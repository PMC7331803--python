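"""Marker-cluster kinematics: rigid poses, gap filling, joint angles, events.

Coordinate convention: right-handed, ``x`` = travel direction, ``z`` = up,
``y`` = mediolateral; positions in metres, sampling at ``fs`` per second.

Joint angles use a flexion-first Euler decomposition of the relative
rotation between parent and child segment (intrinsic Y-X-Z, with Y the
mediolateral flexion axis).  The sagittal component is reported with the
convention that negative values indicate plantar flexion at the ankle and
flexion at the knee; :func:`joint_rotation` builds the rotation realizing a
given reported sagittal angle, so synthesis and analysis share one
convention by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation, Slerp

__all__ = [
    "SegmentPose",
    "JointAngleTrajectory",
    "GaitCycleEvents",
    "TrialKinematics",
    "joint_rotation",
    "estimate_pose",
    "fill_orientation_gaps",
    "fill_marker_gaps",
    "joint_angles",
    "detect_events",
    "time_normalize",
    "spatiotemporal",
    "analyze_trial",
]

N_NODES = 101  # gait-cycle normalization resolution; landing pinned at node 50
GIMBAL_DEG = 80.0


@dataclass
class SegmentPose:
    """Per-frame rigid pose of one segment (scalar-last unit quaternions)."""

    name: str
    quat: np.ndarray  # (T, 4), NaN rows where invalid
    origin: np.ndarray  # (T, 3)
    valid: np.ndarray  # (T,) bool
    residual_rms: np.ndarray | None = None  # (T,) marker fit residual, m

    def __len__(self) -> int:
        return self.quat.shape[0]

    def rotations(self) -> Rotation:
        """Rotations of the valid frames (raises if any frame is invalid)."""
        if not self.valid.all():
            raise ValueError(f"{self.name}: pose has unfilled invalid frames")
        return Rotation.from_quat(self.quat)


@dataclass(frozen=True)
class JointAngleTrajectory:
    """Sagittal joint angle/velocity series (negative = flexion)."""

    joint: str  # 'ankle' | 'knee'
    angle_deg: np.ndarray
    velocity_degps: np.ndarray
    gimbal_flag: np.ndarray  # True where the decomposition nears gimbal lock


@dataclass(frozen=True)
class GaitCycleEvents:
    """Sample indices of the analysed step-down cycle."""

    hs_pre: int  # heel strike preceding the step-down
    landing: int  # first contact at the lower level
    hs_next: int  # heel strike of the following step

    def __post_init__(self):
        if not self.hs_pre < self.landing < self.hs_next:
            raise ValueError(
                f"events must be ordered hs_pre < landing < hs_next, got "
                f"{self.hs_pre}, {self.landing}, {self.hs_next}"
            )


@dataclass(frozen=True)
class TrialKinematics:
    """Outcome bundle of one analysed stepping-down trial."""

    events: GaitCycleEvents
    curves: dict  # keys ankle_deg, ankle_degps, knee_deg, knee_degps -> (101,)
    step_length_m: float
    walking_speed_mps: float


def joint_rotation(sagittal_deg: float | np.ndarray) -> Rotation:
    """Rotation of a child segment realizing a reported sagittal angle.

    Inverse of the decomposition in :func:`joint_angles`:
    ``joint_angles(parent, parent * joint_rotation(a))`` returns ``a``.
    """
    angles = -np.atleast_1d(np.asarray(sagittal_deg, dtype=float))
    return Rotation.from_euler("y", angles[:, None], degrees=True)


def _continuous_hemisphere(quat: np.ndarray, valid: np.ndarray) -> np.ndarray:
    prev = None
    out = quat.copy()
    for i in np.flatnonzero(valid):
        if prev is not None and np.dot(out[i], prev) < 0:
            out[i] = -out[i]
        prev = out[i]
    return out


def estimate_pose(
    markers: np.ndarray, reference: np.ndarray, name: str = "segment"
) -> SegmentPose:
    """Least-squares rigid pose of a marker cluster per frame.

    Parameters
    ----------
    markers : (T, M, 3) world marker positions; NaN marks missing markers.
    reference : (M, 3) cluster-local marker geometry.

    Solves the orthogonal Procrustes problem per frame for a proper
    rotation (det = +1); a mirrored marker set (improper optimum) raises.
    Frames with fewer than 3 visible markers are marked invalid for
    subsequent gap filling.
    """
    markers = np.asarray(markers, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if markers.ndim != 3 or markers.shape[1:] != reference.shape:
        raise ValueError("markers must be (T, M, 3) matching reference (M, 3)")
    ref_c = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-10) < 2:
        raise ValueError("collinear reference cluster: pose unobservable")
    T = markers.shape[0]
    quat = np.full((T, 4), np.nan)
    origin = np.full((T, 3), np.nan)
    valid = np.zeros(T, dtype=bool)
    resid = np.full(T, np.nan)

    vis = ~np.isnan(markers).any(axis=2)  # (T, M)
    full = vis.all(axis=1)

    def _solve(w: np.ndarray, r: np.ndarray):
        wc = w - w.mean(axis=0)
        rc = r - r.mean(axis=0)
        C = wc.T @ rc
        U, s, Vt = np.linalg.svd(C)
        d = np.sign(np.linalg.det(U @ Vt))
        if d < 0 and s[-1] > 1e-9 * s[0]:
            # a genuinely 3-D cluster that only an improper rotation fits
            raise ValueError(
                f"{name}: mirrored marker set (improper rotation required)"
            )
        # planar/3-marker clusters: flip the null direction to stay proper
        R = U @ np.diag([1.0, 1.0, d]) @ Vt
        t = w.mean(axis=0) - R @ r.mean(axis=0)
        res = np.sqrt(np.mean(np.sum((w - (r @ R.T + t)) ** 2, axis=1)))
        return R, t, res

    if full.all():
        # vectorized Kabsch over all frames
        wc = markers - markers.mean(axis=1, keepdims=True)
        C = np.einsum("tmi,mj->tij", wc, ref_c)
        U, s, Vt = np.linalg.svd(C)
        dets = np.sign(np.linalg.det(np.einsum("tij,tjk->tik", U, Vt)))
        if np.any((dets < 0) & (s[:, -1] > 1e-9 * s[:, 0])):
            raise ValueError(
                f"{name}: mirrored marker set (improper rotation required)"
            )
        U = U.copy()
        U[:, :, 2] *= dets[:, None]
        R = np.einsum("tij,tjk->tik", U, Vt)
        t = markers.mean(axis=1) - np.einsum("tij,j->ti", R, reference.mean(axis=0))
        fitted = np.einsum("tij,mj->tmi", R, reference) + t[:, None, :]
        resid = np.sqrt(np.mean(np.sum((markers - fitted) ** 2, axis=2), axis=1))
        quat = Rotation.from_matrix(R).as_quat()
        origin = t
        valid[:] = True
    else:
        for i in range(T):
            m = vis[i]
            if m.sum() < 3:
                continue
            sub_ref = ref_c[m] + reference.mean(axis=0)
            if np.linalg.matrix_rank(sub_ref - sub_ref.mean(axis=0), tol=1e-10) < 2:
                continue
            R, t, res = _solve(markers[i, m], reference[m])
            quat[i] = Rotation.from_matrix(R).as_quat()
            origin[i] = t
            resid[i] = res
            valid[i] = True

    quat = _continuous_hemisphere(quat, valid)
    return SegmentPose(name, quat, origin, valid, resid)


def fill_orientation_gaps(pose: SegmentPose, max_gap: int = 20) -> SegmentPose:
    """Fill invalid frames by slerp of orientation, linear origin.

    Gaps must be bounded by valid frames and no longer than ``max_gap``
    samples (default 20, i.e. 0.2 s at 100/s); a boundary gap or a longer
    gap invalidates the trial and raises.
    """
    valid = pose.valid.copy()
    if valid.all():
        return pose
    quat = pose.quat.copy()
    origin = pose.origin.copy()
    idx = np.flatnonzero(~valid)
    # split into contiguous runs
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        a, b = run[0] - 1, run[-1] + 1
        if a < 0 or b >= len(pose):
            raise ValueError(f"{pose.name}: gap at series boundary cannot be filled")
        if run.size > max_gap:
            raise ValueError(
                f"{pose.name}: gap of {run.size} samples exceeds max_gap={max_gap}"
            )
        rots = Rotation.from_quat(quat[[a, b]])
        quat[run] = Slerp([a, b], rots)(run).as_quat()
        frac = (run - a) / (b - a)
        origin[run] = origin[a] + frac[:, None] * (origin[b] - origin[a])
        valid[run] = True
    quat = _continuous_hemisphere(quat, valid)
    return replace(pose, quat=quat, origin=origin, valid=valid)


def fill_marker_gaps(
    markers: np.ndarray, pose: SegmentPose, reference: np.ndarray
) -> np.ndarray:
    """Reconstruct a missing marker through the cluster's rigid pose.

    While the cluster pose remains solvable from the visible markers, a
    missing marker's cluster-local coordinates are interpolated with a
    cubic spline over time and mapped back through the rigid transform.
    """
    markers = np.asarray(markers, dtype=float).copy()
    T, M, _ = markers.shape
    rots = Rotation.from_quat(pose.quat)
    for m in range(M):
        missing = np.isnan(markers[:, m]).any(axis=1)
        if not missing.any():
            continue
        if np.any(missing & ~pose.valid):
            raise ValueError(
                "cluster pose unsolved during marker gap; cannot reconstruct"
            )
        ok = ~missing
        local = rots[ok].inv().apply(markers[ok, m] - pose.origin[ok])
        t_ok = np.flatnonzero(ok)
        spline = CubicSpline(t_ok, local, axis=0)
        t_gap = np.flatnonzero(missing)
        markers[t_gap, m] = rots[t_gap].apply(spline(t_gap)) + pose.origin[t_gap]
    return markers


def joint_angles(
    parent: SegmentPose, child: SegmentPose, fs: float, joint: str = "knee"
) -> JointAngleTrajectory:
    """Sagittal joint angle and angular velocity from two segment poses.

    The relative rotation (child in the parent frame) is decomposed with
    the mediolateral flexion axis first (intrinsic Y-X-Z); the sagittal
    angle is sign-flipped so that negative values indicate flexion.  The
    angular velocity is the mediolateral component of the relative
    angular-velocity vector (central differences of the relative rotation),
    under the same sign convention.  Frames where the second Euler angle
    exceeds 80 degrees are flagged as gimbal-proximal.
    """
    if len(parent) != len(child):
        raise ValueError("parent and child poses must be synchronized")
    rel = parent.rotations().inv() * child.rotations()
    eul = rel.as_euler("YXZ", degrees=True)
    angle = -eul[:, 0]
    gimbal = np.abs(eul[:, 1]) > GIMBAL_DEG

    T = len(parent)
    dt = 1.0 / fs
    omega_y = np.empty(T)
    if T >= 3:
        d = (rel[2:] * rel[:-2].inv()).as_rotvec()[:, 1] / (2.0 * dt)
        omega_y[1:-1] = d
        omega_y[0] = (rel[1] * rel[0].inv()).as_rotvec()[1] / dt
        omega_y[-1] = (rel[-1] * rel[-2].inv()).as_rotvec()[1] / dt
    else:
        omega_y[:] = 0.0
    velocity = -np.degrees(omega_y)
    return JointAngleTrajectory(joint, angle, velocity, gimbal)


def _foot_contacts(
    pos: np.ndarray, fs: float, speed_threshold: float, window_s: float
) -> list[int]:
    """Contact onsets: forward-velocity downcrossings refined to the local
    vertical-position minimum within the surrounding window."""
    x = pos[:, 0]
    z = pos[:, 2]
    v = np.gradient(x, 1.0 / fs)
    cross = np.flatnonzero((v[1:] < speed_threshold) & (v[:-1] >= speed_threshold)) + 1
    w = max(1, int(round(window_s * fs)))
    out = []
    for c in cross:
        lo, hi = max(0, c - w), min(len(z), c + w + 1)
        seg = z[lo:hi]
        zmin = seg.min()
        refined = lo + int(np.flatnonzero(seg <= zmin + 1e-9)[0])
        out.append(refined)
    return out


def detect_events(
    foot_left: np.ndarray,
    foot_right: np.ndarray,
    fs: float,
    speed_threshold: float = 0.2,
    window_s: float = 0.1,
    level_tol: float = 0.01,
) -> GaitCycleEvents:
    """Detect the step-down gait cycle from the two foot trajectories.

    Foot contacts are forward-velocity threshold downcrossings refined to
    the local minimum of the vertical heel-cluster position.  The landing
    is the first contact at the lower level (inferred as the minimum
    contact height); ``hs_pre``/``hs_next`` are the contacts immediately
    before and after it (either foot).
    """
    contacts = []
    for pos in (foot_left, foot_right):
        pos = np.asarray(pos, dtype=float)
        for c in _foot_contacts(pos, fs, speed_threshold, window_s):
            contacts.append((c, pos[c, 2]))
    if len(contacts) < 3:
        raise ValueError(f"found only {len(contacts)} contacts; need 3 events")
    contacts.sort()
    z_low = min(z for _, z in contacts)
    lower = [c for c, z in contacts if z <= z_low + level_tol]
    landing = lower[0]
    before = [c for c, _ in contacts if c < landing]
    after = [c for c, _ in contacts if c > landing]
    if not before or not after:
        raise ValueError("could not bracket the landing with heel strikes")
    return GaitCycleEvents(before[-1], landing, after[0])


def time_normalize(signal: np.ndarray, events: GaitCycleEvents) -> np.ndarray:
    """Resample a trial signal to 101 nodes with the landing at node 50.

    Piecewise-linear time warp: [hs_pre, landing] maps to nodes 0-50 and
    [landing, hs_next] to nodes 50-100.
    """
    signal = np.asarray(signal, dtype=float)
    if events.hs_next >= signal.size:
        raise ValueError("events extend beyond the signal")
    first = np.linspace(events.hs_pre, events.landing, 51)
    second = np.linspace(events.landing, events.hs_next, 51)
    nodes = np.concatenate([first, second[1:]])
    return np.interp(nodes, np.arange(signal.size), signal)


def spatiotemporal(
    foot_left: np.ndarray,
    foot_right: np.ndarray,
    pelvis: np.ndarray,
    events: GaitCycleEvents,
    fs: float,
) -> tuple[float, float]:
    """Step length (m) and walking speed (m/s) of the analysed cycle.

    Step length is the forward distance between the two feet at the
    double-support instant of the step-down (the landing sample); walking
    speed is the mean first derivative of the pelvis position along the
    travel path over [hs_pre, hs_next].
    """
    pelvis = np.asarray(pelvis, dtype=float)
    if pelvis.ndim != 2 or np.isnan(pelvis).any():
        raise ValueError("missing pelvis data")
    step_length = float(
        abs(foot_right[events.landing, 0] - foot_left[events.landing, 0])
    )
    vx = np.gradient(pelvis[:, 0], 1.0 / fs)
    speed = float(np.mean(vx[events.hs_pre : events.hs_next + 1]))
    return step_length, speed


def analyze_trial(
    markers: Mapping[str, np.ndarray],
    geometry: Mapping[str, np.ndarray],
    fs: float,
    max_gap: int = 20,
) -> TrialKinematics:
    """Full kinematic analysis of one stepping-down trial.

    ``markers`` maps segment names (``pelvis``, ``thigh_r``, ``calf_r``,
    ``foot_r``, and left-side counterparts) to (T, M, 3) world marker
    arrays; ``geometry`` holds the matching cluster-local layouts.  The
    leading (right) leg provides the ankle and knee angle curves.
    """
    poses = {}
    for seg, arr in markers.items():
        pose = estimate_pose(arr, np.asarray(geometry[seg]), name=seg)
        if not pose.valid.all():
            pose = fill_orientation_gaps(pose, max_gap=max_gap)
        poses[seg] = pose

    events = detect_events(poses["foot_l"].origin, poses["foot_r"].origin, fs)
    ankle = joint_angles(poses["calf_r"], poses["foot_r"], fs, joint="ankle")
    knee = joint_angles(poses["thigh_r"], poses["calf_r"], fs, joint="knee")
    curves = {
        "ankle_deg": time_normalize(ankle.angle_deg, events),
        "ankle_degps": time_normalize(ankle.velocity_degps, events),
        "knee_deg": time_normalize(knee.angle_deg, events),
        "knee_degps": time_normalize(knee.velocity_degps, events),
    }
    step_length, speed = spatiotemporal(
        poses["foot_l"].origin, poses["foot_r"].origin, poses["pelvis"].origin,
        events, fs,
    )
    return TrialKinematics(events, curves, step_length, speed)
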