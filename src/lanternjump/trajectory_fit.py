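"""Ballistic and planar fitting of tracked center-of-mass trajectories.

The zero-drag ballistic model is a parabola in the vertical launch plane;
here it is parameterized in full 3D with an explicit azimuth,

    x(t) = x0 + v cos(theta) cos(phi) t
    y(t) = y0 + v cos(theta) sin(phi) t
    z(t) = z0 + v sin(theta) t - g t^2 / 2,

with g fixed at 9.81 m/s^2 and every other parameter free, so planarity is
a testable special case rather than an assumption.  Also: total-least-squares
plane fits (steering test), sliding-window quadratic heading estimation, and
take-off performance metrics (a_TO, maximum range, time of flight, Reynolds
number).

Units: positions mm, times ms; speeds in mm/ms, numerically equal to m/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ComTrack",
    "BallisticFit",
    "PlanarFit",
    "PerformanceMetrics",
    "fit_ballistic",
    "fit_plane",
    "heading_series",
    "performance_metrics",
    "residual_window_compare",
    "G_MM_MS2",
    "AIR_DENSITY",
    "AIR_VISCOSITY",
]

#: gravity, mm/ms^2 (= 9.81 m/s^2)
G_MM_MS2 = 9.81e-3
#: air density, kg/m^3
AIR_DENSITY = 1.2
#: dynamic viscosity of air, Pa s
AIR_VISCOSITY = 18.3e-6


@dataclass
class ComTrack:
    """A tracked center-of-mass trajectory with event times.

    ``times`` in ms (1 ms spacing at the default 1000 frames/s),
    ``positions`` (n, 3) in mm in the spatial frame (origin at take-off,
    z up).  Event times: take_off <= leg_extension <= impact.
    """

    times: np.ndarray
    positions: np.ndarray
    take_off: float | None = None
    leg_extension: float | None = None
    impact: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.times), 3):
            raise ValueError("positions must be (n, 3) matching times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        events = [e for e in (self.take_off, self.leg_extension, self.impact)
                  if e is not None]
        if events != sorted(events):
            raise ValueError("need take_off <= leg_extension <= impact")


@dataclass
class BallisticFit:
    """Zero-drag parabola fit results.

    ``v_to`` m/s, ``theta``/``azimuth`` deg, ``launch_offset`` mm,
    residual RMSEs mm.  ``window_rmse`` holds the take-off / mid-air /
    impact event-window residual RMSEs when event times were available.
    """

    v_to: float
    theta: float
    azimuth: float
    launch_offset: np.ndarray
    r_squared: float
    rmse: float
    residuals: np.ndarray
    window_rmse: dict[str, float] = field(default_factory=dict)
    azimuth_degenerate: bool = False

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        v = self.v_to
        th = np.deg2rad(self.theta)
        ph = np.deg2rad(self.azimuth)
        out = np.empty((len(t), 3))
        out[:, 0] = self.launch_offset[0] + v * np.cos(th) * np.cos(ph) * t
        out[:, 1] = self.launch_offset[1] + v * np.cos(th) * np.sin(ph) * t
        out[:, 2] = self.launch_offset[2] + v * np.sin(th) * t - 0.5 * G_MM_MS2 * t ** 2
        return out


def _ballistic_residuals(p, t, pos):
    x0, y0, z0, v, th, ph = p
    model = np.empty_like(pos)
    model[:, 0] = x0 + v * np.cos(th) * np.cos(ph) * t
    model[:, 1] = y0 + v * np.cos(th) * np.sin(ph) * t
    model[:, 2] = z0 + v * np.sin(th) * t - 0.5 * G_MM_MS2 * t ** 2
    return (model - pos).ravel()


def fit_ballistic(track: ComTrack, window: tuple[float, float] | None = None
                  ) -> BallisticFit:
    """Nonlinear least-squares fit of the zero-drag ballistic model.

    All parameters except g vary freely.  ``window`` optionally restricts
    the fit to a [t_lo, t_hi] span (e.g. the first 25 ms after take-off for
    take-off performance fits).
    """
    t = track.times
    pos = track.positions
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, pos = t[mask], pos[mask]
    if len(t) < 6:
        raise ValueError("need at least 6 samples (6 free parameters)")
    t = t - t[0]

    # initial guess from finite-difference launch velocity
    k = min(5, len(t) - 1)
    v0_vec = (pos[k] - pos[0]) / (t[k] - t[0]) + np.array(
        [0.0, 0.0, 0.5 * G_MM_MS2 * (t[k] + t[0])])
    v0 = max(np.linalg.norm(v0_vec), 1e-6)
    th0 = np.arcsin(np.clip(v0_vec[2] / v0, -1.0, 1.0))
    ph0 = np.arctan2(v0_vec[1], v0_vec[0]) if np.hypot(*v0_vec[:2]) > 1e-12 else 0.0
    p0 = np.array([*pos[0], v0, th0, ph0])

    sol = least_squares(_ballistic_residuals, p0, args=(t, pos), method="lm",
                        max_nfev=2000)
    if not sol.success:
        raise RuntimeError(f"ballistic fit did not converge: {sol.message}; "
                           f"last iterate {sol.x}")
    x0, y0, z0, v, th, ph = sol.x
    if v < 0:  # canonicalize sign ambiguity
        v, th, ph = -v, np.pi - th, ph + np.pi
    th = np.arctan2(np.sin(th), np.cos(th))
    degenerate = False
    if abs(np.cos(th)) * v < 1e-9 * max(v, 1.0):
        ph, degenerate = 0.0, True
    ph = np.arctan2(np.sin(ph), np.cos(ph))

    resid = _ballistic_residuals(sol.x, t, pos).reshape(-1, 3)
    ss_res = float(np.sum(resid ** 2))
    centered = pos - pos.mean(axis=0)
    ss_tot = float(np.sum(centered ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    # scalar-residual convention: comparable to the per-axis tracking error
    rmse = float(np.sqrt(ss_res / resid.size))

    fit = BallisticFit(
        v_to=float(v), theta=float(np.degrees(th)),
        azimuth=float(np.degrees(ph)),
        launch_offset=np.array([x0, y0, z0]), r_squared=r2, rmse=rmse,
        residuals=resid, azimuth_degenerate=degenerate,
    )
    events = (track.take_off, track.leg_extension, track.impact)
    if window is None and any(e is not None for e in events):
        per_point = np.linalg.norm(resid, axis=1) / np.sqrt(3.0)
        comp = residual_window_compare(per_point, track.times, track,
                                       n_permutations=0)
        fit.window_rmse = comp["rmse"]
    return fit


@dataclass
class PlanarFit:
    """Total-least-squares plane fit (steering test)."""

    normal: np.ndarray
    offset: float  # plane: normal . x = offset
    rmse: float


def fit_plane(track: ComTrack) -> PlanarFit:
    """Fit the track to a plane by total least squares.

    The normal is the smallest principal component of the centered
    coordinates; RMSE is the root-mean-square orthogonal distance.
    """
    pos = track.positions
    if len(pos) < 3:
        raise ValueError("need at least 3 points")
    center = pos.mean(axis=0)
    centered = pos - center
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("points are collinear; plane is underdetermined")
    normal = vt[2]
    dists = centered @ normal
    return PlanarFit(normal=normal, offset=float(normal @ center),
                     rmse=float(np.sqrt(np.mean(dists ** 2))))


def heading_series(track: ComTrack, window_ms: float = 25.0) -> dict:
    """Velocity direction (heading) by sliding quadratic regression.

    Per coordinate, a quadratic polynomial is fitted in a centered window of
    ``window_ms``; its derivative at the window center gives the velocity.
    Returns dict with ``times``, ``velocity`` (mm/ms), ``elevation`` and
    ``azimuth`` (deg).
    """
    t, pos = track.times, track.positions
    if window_ms > t[-1] - t[0]:
        raise ValueError("window longer than track")
    half = window_ms / 2.0
    centers, vels = [], []
    for tc in t:
        mask = (t >= tc - half) & (t <= tc + half)
        if mask.sum() < 4:
            continue
        # require the window to be (roughly) two-sided around the center
        if t[mask].max() - tc < half * 0.5 or tc - t[mask].min() < half * 0.5:
            continue
        tw = t[mask] - tc
        v = np.empty(3)
        for d in range(3):
            coef = np.polyfit(tw, pos[mask, d], 2)
            v[d] = coef[1]  # derivative at window center
        centers.append(tc)
        vels.append(v)
    if not centers:
        raise ValueError("no window had enough samples")
    vels = np.asarray(vels)
    horiz = np.hypot(vels[:, 0], vels[:, 1])
    elevation = np.degrees(np.arctan2(vels[:, 2], horiz))
    azimuth = np.degrees(np.arctan2(vels[:, 1], vels[:, 0]))
    return {"times": np.asarray(centers), "velocity": vels,
            "elevation": elevation, "azimuth": azimuth}


@dataclass(frozen=True)
class PerformanceMetrics:
    """Take-off performance summary.

    a_to in m/s^2; r_max (theoretical maximum range at theta=45 deg) in cm;
    t_tof (time of flight at 45 deg) in s; Reynolds number dimensionless.
    """

    a_to: float
    t_accel: float
    r_max: float
    t_tof: float
    reynolds: float
    rho: float = AIR_DENSITY
    mu: float = AIR_VISCOSITY
    g: float = 9.81


def performance_metrics(fit: BallisticFit, t_accel: float, l_b: float
                        ) -> PerformanceMetrics:
    """Take-off metrics from a ballistic fit.

    ``t_accel`` in ms (measured from video events: first leg motion to loss
    of contact), ``l_b`` body length in mm.  Maximum range and time of
    flight are evaluated at the optimal launch angle theta = 45 deg using
    the standard projectile forms R = v^2 sin(2 theta)/g and
    t_TOF = 2 v sin(theta)/g.
    """
    if t_accel <= 0 or l_b <= 0:
        raise ValueError("t_accel and l_b must be positive")
    v = fit.v_to  # m/s
    g = 9.81
    a_to = v / (t_accel * 1e-3)
    theta = np.deg2rad(45.0)
    r_max = v ** 2 * np.sin(2 * theta) / g * 100.0  # cm
    t_tof = 2 * v * np.sin(theta) / g  # s
    reynolds = AIR_DENSITY * v * (l_b * 1e-3) / AIR_VISCOSITY
    return PerformanceMetrics(a_to=float(a_to), t_accel=float(t_accel),
                              r_max=float(r_max), t_tof=float(t_tof),
                              reynolds=float(reynolds))


def residual_window_compare(residuals, times, track: ComTrack,
                            n_permutations: int = 10_000,
                            seed: int | None = 0) -> dict:
    """Residual RMSE in the take-off / mid-air / impact event windows.

    Windows: [take_off, take_off + 25 ms], [t_ext - 25, t_ext + 25 ms],
    [impact - 5 ms, impact].  Pairwise RMSE differences get a permutation
    p-value (window labels shuffled over the pooled residuals); empty
    windows are flagged and excluded.
    """
    residuals = np.abs(np.asarray(residuals, dtype=float))
    times = np.asarray(times, dtype=float)
    windows = {}
    if track.take_off is not None:
        windows["take_off"] = (track.take_off, track.take_off + 25.0)
    if track.leg_extension is not None:
        windows["mid_air"] = (track.leg_extension - 25.0, track.leg_extension + 25.0)
    if track.impact is not None:
        windows["impact"] = (track.impact - 5.0, track.impact)
    rmse, members, skipped = {}, {}, []
    for name, (lo, hi) in windows.items():
        mask = (times >= lo) & (times <= hi)
        if mask.sum() == 0:
            skipped.append(name)
            continue
        rmse[name] = float(np.sqrt(np.mean(residuals[mask] ** 2)))
        members[name] = residuals[mask]
    out = {"rmse": rmse, "skipped": skipped, "differences": {},
           "p_values": {}}
    names = list(rmse)
    rng = np.random.default_rng(seed)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            na, nb = names[a], names[b]
            key = f"{na}-{nb}"
            diff = rmse[na] - rmse[nb]
            out["differences"][key] = diff
            if n_permutations <= 0:
                continue
            xa, xb = members[na], members[nb]
            pooled = np.concatenate([xa, xb])
            n_a = len(xa)
            count = 0
            observed = abs(diff)
            for _ in range(n_permutations):
                perm = rng.permutation(pooled)
                d = np.sqrt(np.mean(perm[:n_a] ** 2)) - np.sqrt(np.mean(perm[n_a:] ** 2))
                if abs(d) >= observed - 1e-15:
                    count += 1
            out["p_values"][key] = (count + 1) / (n_permutations + 1)
    return out
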