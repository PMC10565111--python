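"""3D rotational dynamics of an airborne rigid body with posture change.

Integrates the Euler rigid-body equations with an aerodynamic drag torque
and a time-varying inertia tensor (leg extension interpolated between the
legs-tucked and legs-extended posture models), propagating spatial attitude
as a unit quaternion.  Also provides the analytic posture-change relations:
per-axis angular momentum conservation for a symmetric inertia change, and
the angular-momentum "twist" (appendage throw) two-segment model.

State formulation: the integrator advances the body-frame angular momentum
L rather than omega,

    dL/dt = L x omega - (ln 2 / t_char) L,      omega = I(t)^-1 L,

which is algebraically identical to the Euler equations for constant
inertia, and makes angular momentum exactly continuous through inertia
changes, so an instantaneous posture switch reproduces the per-axis
conservation relation omega_after = (I_before/I_after) omega_before.

Units: ms, mg*mm^2 internally (angular velocity rad/ms inside the
integrator); all public angular velocities are in rev/s, the convention
1 Hz = 2*pi rad/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .mesh_mechanics import RigidBodyProperties

__all__ = [
    "DragModel",
    "InertiaSchedule",
    "RotationSimResult",
    "TaitBryan",
    "euler_rhs",
    "simulate_rotation",
    "interpolate_inertia",
    "posture_change_omega",
    "momentum_twist",
    "attitude_to_tait_bryan",
    "rev_s_to_rad_ms",
    "rad_ms_to_rev_s",
    "schedule_from_moments",
    "DEFAULT_DT_MS",
]

LN2 = np.log(2.0)

#: default integration step, ms (2.6e-6 s)
DEFAULT_DT_MS = 2.6e-3


def rev_s_to_rad_ms(omega):
    """rev/s -> rad/ms (1 Hz = 2*pi rad/s)."""
    return np.asarray(omega, dtype=float) * (2.0 * np.pi / 1000.0)


def rad_ms_to_rev_s(omega):
    """rad/ms -> rev/s."""
    return np.asarray(omega, dtype=float) * (1000.0 / (2.0 * np.pi))


@dataclass(frozen=True)
class DragModel:
    """Drag torque with one characteristic time per posture.

    ``t_char`` is the time for the angular speed about a principal axis to
    halve.  The default ``law="exponential"`` uses
    omega(t) = omega_0 * 2**(-t/t_char), equivalent to the torque
    tau_i = -(ln 2 / t_char) * I_i * omega_i.  ``law="quadratic"`` makes the
    torque proportional to omega^2 (tau = -(|omega|/(omega_ref t_char)) I
    omega with omega_ref the initial spin magnitude), which also halves a
    pure principal-axis spin at t_char but decays slower afterwards.
    ``None`` for both times disables drag.
    """

    t_char_tucked: float | None
    t_char_extended: float | None
    law: str = "exponential"

    def __post_init__(self):
        for v in (self.t_char_tucked, self.t_char_extended):
            if v is not None and v <= 0:
                raise ValueError("t_char must be positive (or None for no drag)")
        if self.law not in ("exponential", "quadratic"):
            raise ValueError("law must be 'exponential' or 'quadratic'")

    def t_char_at(self, fraction: float) -> float | None:
        """Characteristic time at extension fraction in [0, 1] (0 = tucked);
        blends linearly across the window, mirroring the inertia schedule."""
        a, b = self.t_char_tucked, self.t_char_extended
        if a is None and b is None:
            return None
        if a is None:
            a = b
        if b is None:
            b = a
        return (1.0 - fraction) * a + fraction * b

    def decay_rate(self, fraction: float) -> float:
        """Exponential-law rate ln2/t_char at the given extension fraction."""
        t_char = self.t_char_at(fraction)
        return 0.0 if t_char is None else LN2 / t_char


NO_DRAG = DragModel(None, None)


def _props_moments_axes(props) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(props, RigidBodyProperties):
        return props.principal_moments, props.principal_axes
    moments, axes = props
    return np.asarray(moments, dtype=float), np.asarray(axes, dtype=float)


@dataclass(frozen=True)
class InertiaSchedule:
    """Inertia tensor schedule across the leg-extension window.

    ``props_tucked``/``props_extended`` are :class:`RigidBodyProperties` or
    bare ``(principal_moments, principal_axes)`` pairs, with moments already
    matched by anatomical role (roll, pitch, yaw).  Between ``t_ext_start``
    and ``t_ext`` (ms after take-off) the principal moments interpolate
    linearly per axis and the axis triads blend along the geodesic
    (quaternion slerp); outside the window the posture properties are
    returned exactly.
    """

    props_tucked: object
    props_extended: object
    t_ext: float
    t_ext_start: float = 0.0

    def __post_init__(self):
        if not (self.t_ext > self.t_ext_start >= 0.0):
            raise ValueError("need t_ext > t_ext_start >= 0")

    def fraction(self, t: float) -> float:
        if t <= self.t_ext_start:
            return 0.0
        if t >= self.t_ext:
            return 1.0
        return (t - self.t_ext_start) / (self.t_ext - self.t_ext_start)


def schedule_from_moments(moments_tucked, moments_extended, t_ext,
                          t_ext_start=0.0, axes_tucked=None,
                          axes_extended=None) -> InertiaSchedule:
    """Convenience constructor from bare principal moments (axes default to
    the anatomical identity triad)."""
    eye = np.eye(3)
    return InertiaSchedule(
        props_tucked=(np.asarray(moments_tucked, float),
                      eye if axes_tucked is None else np.asarray(axes_tucked, float)),
        props_extended=(np.asarray(moments_extended, float),
                        eye if axes_extended is None else np.asarray(axes_extended, float)),
        t_ext=t_ext, t_ext_start=t_ext_start,
    )


def interpolate_inertia(schedule: InertiaSchedule, t: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Principal moments and axes at time t (ms after take-off)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    m0, a0 = _props_moments_axes(schedule.props_tucked)
    f = schedule.fraction(t)
    if f == 0.0:
        return m0.copy(), a0.copy()
    m1, a1 = _props_moments_axes(schedule.props_extended)
    if f == 1.0:
        return m1.copy(), a1.copy()
    moments = (1.0 - f) * m0 + f * m1
    if np.allclose(a0, a1, atol=1e-12):
        return moments, a0.copy()
    return moments, _geodesic_blend(a0, a1, f)


def _geodesic_blend(a0: np.ndarray, a1: np.ndarray, f: float) -> np.ndarray:
    """Shortest-arc rotation blend: a0 @ exp(f * log(a0^T a1))."""
    rel = Rotation.from_matrix(a0.T @ a1).as_rotvec()
    return a0 @ _rodrigues(f * rel)


def _rodrigues(rotvec: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(rotvec)
    if theta < 1e-15:
        return np.eye(3)
    kx, ky, kz = rotvec / theta
    k_cross = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return (np.eye(3) + np.sin(theta) * k_cross
            + (1.0 - np.cos(theta)) * (k_cross @ k_cross))


# ---------------------------------------------------------------------------
# Euler equations
# ---------------------------------------------------------------------------


def euler_rhs(omega_body, principal_moments, drag_rate_per_axis=None) -> np.ndarray:
    """Euler-equation angular acceleration in the principal frame.

    d omega_i / dt = [ (I_j - I_k) omega_j omega_k + tau_i ] / I_i with
    (i, j, k) cyclic and drag torque tau_i = -drag_rate_i * I_i * omega_i
    (drag_rate = ln2 / t_char).  Pure function; any consistent units.
    """
    w = np.asarray(omega_body, dtype=float)
    im = np.asarray(principal_moments, dtype=float)
    if np.any(im <= 0):
        raise ValueError("principal moments must be positive")
    i1, i2, i3 = im
    dw = np.array([
        (i2 - i3) * w[1] * w[2],
        (i3 - i1) * w[2] * w[0],
        (i1 - i2) * w[0] * w[1],
    ]) / im
    if drag_rate_per_axis is not None:
        dw = dw - np.asarray(drag_rate_per_axis, dtype=float) * w
    return dw


@dataclass(frozen=True)
class RotationSimResult:
    """Time series from an Euler-equation integration.

    ``omega_body`` is the angular velocity in the body frame, rev/s;
    ``attitude`` holds scalar-last unit quaternions mapping body to spatial
    coordinates; ``angular_momentum_spatial`` is in mg*mm^2/ms.
    """

    times: np.ndarray
    omega_body: np.ndarray
    attitude_quat: np.ndarray
    angular_momentum_spatial: np.ndarray

    @property
    def attitudes(self) -> Rotation:
        return Rotation.from_quat(self.attitude_quat)

    def cranial_caudal_axis(self) -> np.ndarray:
        """Spatial unit vectors of the body +x (cranial) axis per step."""
        return self.attitudes.apply(np.array([1.0, 0.0, 0.0]))

    def momentum_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.angular_momentum_spatial, axis=1)

    def tait_bryan_deg(self) -> np.ndarray:
        """Per-step (roll, pitch, yaw) in degrees, ZYX convention."""
        ypr = self.attitudes.as_euler("ZYX", degrees=True)
        return ypr[:, ::-1]


def _quat_mult_omega(q, w):
    """0.5 * q (x) (w, 0) for scalar-last quaternion q, body-frame rates w."""
    qx, qy, qz, qw = q
    wx, wy, wz = w
    return 0.5 * np.array([
        qw * wx + qy * wz - qz * wy,
        qw * wy + qz * wx - qx * wz,
        qw * wz + qx * wy - qy * wx,
        -qx * wx - qy * wy - qz * wz,
    ])


def simulate_rotation(initial_omega, schedule: InertiaSchedule,
                      drag: DragModel = NO_DRAG, duration: float = 100.0,
                      dt: float = DEFAULT_DT_MS,
                      sample_every: int | None = None) -> RotationSimResult:
    """Integrate the Euler equations with drag and a posture-change schedule.

    Parameters
    ----------
    initial_omega : array (3,)
        Take-off angular velocity in rev/s, given in the spatial frame; the
        initial attitude is the identity (body axes aligned with the
        measured take-off orientation), so spatial and body components
        coincide at t=0.
    schedule : InertiaSchedule
    drag : DragModel
    duration, dt : float
        Simulated span and fixed RK4 step, ms.
    sample_every : int, optional
        Store every k-th step (default: every step).

    Returns
    -------
    RotationSimResult
    """
    if duration <= 0 or dt <= 0 or dt > duration:
        raise ValueError("need 0 < dt <= duration")
    n_steps = int(round(duration / dt))
    stride = 1 if sample_every is None else max(int(sample_every), 1)

    w0 = rev_s_to_rad_ms(initial_omega)
    m0, a0 = interpolate_inertia(schedule, 0.0)
    # L in the body frame: I = A diag(m) A^T
    L = a0 @ (m0 * (a0.T @ w0))
    q = np.array([0.0, 0.0, 0.0, 1.0])

    t0, t1 = schedule.t_ext_start, schedule.t_ext
    m1, a1 = interpolate_inertia(schedule, t1)
    diag0 = np.allclose(a0, np.eye(3), atol=1e-12)
    diag1 = np.allclose(a1, np.eye(3), atol=1e-12)
    same_axes = np.allclose(a0, a1, atol=1e-12)
    rel_rotvec = (None if same_axes
                  else Rotation.from_matrix(a0.T @ a1).as_rotvec())

    def omega_of(L_vec, t):
        if t <= t0:
            if diag0:
                return L_vec / m0
            m, a = m0, a0
        elif t >= t1:
            if diag1:
                return L_vec / m1
            m, a = m1, a1
        else:
            f = (t - t0) / (t1 - t0)
            m = (1.0 - f) * m0 + f * m1
            a = a0 if same_axes else a0 @ _rodrigues(f * rel_rotvec)
        return a @ ((a.T @ L_vec) / m)

    has_drag = (drag.t_char_tucked is not None
                or drag.t_char_extended is not None)
    quadratic = has_drag and drag.law == "quadratic"
    omega_ref = max(float(np.linalg.norm(w0)), 1e-300)

    def rhs(t, q_vec, L_vec):
        w = omega_of(L_vec, t)
        dL = np.cross(L_vec, w)
        if quadratic:
            t_char = drag.t_char_at(schedule.fraction(t))
            dL = dL - (np.linalg.norm(w) / (omega_ref * t_char)) * L_vec
        elif has_drag:
            dL = dL - drag.decay_rate(schedule.fraction(t)) * L_vec
        return _quat_mult_omega(q_vec, w), dL

    n_out = n_steps // stride + 1
    times = np.empty(n_out)
    omega_out = np.empty((n_out, 3))
    quat_out = np.empty((n_out, 4))
    L_spatial = np.empty((n_out, 3))

    def record(k, t):
        w = omega_of(L, t)
        times[k] = t
        omega_out[k] = rad_ms_to_rev_s(w)
        quat_out[k] = q
        L_spatial[k] = Rotation.from_quat(q).apply(L)

    record(0, 0.0)
    k_out = 1
    t = 0.0
    for step in range(1, n_steps + 1):
        dq1, dL1 = rhs(t, q, L)
        dq2, dL2 = rhs(t + 0.5 * dt, q + 0.5 * dt * dq1, L + 0.5 * dt * dL1)
        dq3, dL3 = rhs(t + 0.5 * dt, q + 0.5 * dt * dq2, L + 0.5 * dt * dL2)
        dq4, dL4 = rhs(t + dt, q + dt * dq3, L + dt * dL3)
        q = q + (dt / 6.0) * (dq1 + 2.0 * dq2 + 2.0 * dq3 + dq4)
        L = L + (dt / 6.0) * (dL1 + 2.0 * dL2 + 2.0 * dL3 + dL4)
        q = q / np.linalg.norm(q)
        t = step * dt
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(L))):
            raise FloatingPointError(f"non-finite state at step {step} (t={t} ms)")
        if step % stride == 0:
            record(k_out, t)
            k_out += 1
    return RotationSimResult(
        times=times[:k_out], omega_body=omega_out[:k_out],
        attitude_quat=quat_out[:k_out],
        angular_momentum_spatial=L_spatial[:k_out],
    )


def rotational_energy(result: RotationSimResult,
                      schedule: InertiaSchedule) -> np.ndarray:
    """Rotational kinetic energy series, mg*mm^2/ms^2 (0.5 omega.I.omega)."""
    e = np.empty(len(result.times))
    for k, t in enumerate(result.times):
        m, a = interpolate_inertia(schedule, t)
        w = rev_s_to_rad_ms(result.omega_body[k])
        wp = a.T @ w
        e[k] = 0.5 * np.sum(m * wp ** 2)
    return e


# ---------------------------------------------------------------------------
# analytic posture-change relations
# ---------------------------------------------------------------------------


def posture_change_omega(i_before, i_after, omega_before) -> np.ndarray:
    """Angular velocity after a posture change with unchanged principal axes.

    Per-axis angular momentum conservation (zero external torque):
    omega_after_i = (I_before_i / I_after_i) * omega_before_i.
    """
    ib = np.asarray(i_before, dtype=float)
    ia = np.asarray(i_after, dtype=float)
    if np.any(ia == 0):
        raise ValueError("post-change moments must be nonzero")
    return ib / ia * np.asarray(omega_before, dtype=float)


def momentum_twist(i_appendage: float, i_body: float,
                   delta_theta_appendage: float) -> float:
    """Body counter-rotation from an appendage "throw" (two-segment model).

    Rotating an appendage of moment I_A by an angle about a shared principal
    axis forces the body (I_B) to counter-rotate so total angular momentum
    is unchanged:  delta_theta_B = -I_A * delta_theta_A / (I_A + I_B).
    Angles in any unit (degrees in, degrees out).
    """
    if i_appendage < 0 or i_body <= 0:
        raise ValueError("inertias must be positive")
    return -i_appendage * delta_theta_appendage / (i_appendage + i_body)


# ---------------------------------------------------------------------------
# attitude angles
# ---------------------------------------------------------------------------


class TaitBryan(NamedTuple):
    roll: float
    pitch: float
    yaw: float
    gimbal_lock: bool


def attitude_to_tait_bryan(attitude, atol: float = 1e-8) -> TaitBryan:
    """ZYX (yaw-pitch-roll) intrinsic Tait-Bryan angles, degrees.

    ``attitude`` is a rotation matrix, a scalar-last quaternion, or a scipy
    Rotation.  Pitch is in [-90, 90]; at gimbal lock (|pitch| = 90) roll is
    set to 0 and the flag raised.
    """
    if isinstance(attitude, Rotation):
        rot = attitude
    else:
        arr = np.asarray(attitude, dtype=float)
        if arr.shape == (4,):
            rot = Rotation.from_quat(arr)
        elif arr.shape == (3, 3):
            if not np.allclose(arr @ arr.T, np.eye(3), atol=1e-6):
                raise ValueError("attitude matrix is not orthogonal")
            if np.linalg.det(arr) < 0:
                raise ValueError("attitude matrix is a reflection")
            rot = Rotation.from_matrix(arr)
        else:
            raise ValueError("attitude must be 3x3 matrix or quaternion")
    m = rot.as_matrix()
    sp = -m[2, 0]
    sp = np.clip(sp, -1.0, 1.0)
    if abs(abs(sp) - 1.0) < atol:
        pitch = np.degrees(np.arcsin(sp))
        yaw = np.degrees(np.arctan2(-m[0, 1], m[1, 1]))
        return TaitBryan(0.0, float(pitch), float(yaw), True)
    pitch = np.degrees(np.arcsin(sp))
    roll = np.degrees(np.arctan2(m[2, 1], m[2, 2]))
    yaw = np.degrees(np.arctan2(m[1, 0], m[0, 0]))
    return TaitBryan(float(roll), float(pitch), float(yaw), False)
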