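"""Rotational kinematics from tracked head/caudal points.

The only body axis observable from two tracked points is the cranial-caudal
unit vector u_cc; its angular speed omega_cc(t) is the frame-to-frame
rotation angle of u_cc divided by the frame interval (roll about u_cc is
unobservable).  This module extracts omega_cc series, take-off angular
velocity from attitudes 5 ms apart, fits the exponential drag-decay
envelope omega(t) = omega_0 * 2**(-t/t_char), measures the precession
oscillation period from inter-peak intervals, and compares tracked against
simulated series with Wilcoxon tests (implemented in-repo with exact
small-sample distributions).

Angular speeds are in rev/s (1 Hz = 2*pi rad/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation
from scipy.stats import norm

__all__ = [
    "OrientationTrack",
    "OmegaCcSeries",
    "DragDecayFit",
    "omega_cc_series",
    "initial_angular_velocity",
    "fit_drag_decay",
    "oscillation_period",
    "compare_tracked_vs_simulated",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "box_average",
]


@dataclass
class OrientationTrack:
    """Cranial-caudal axis orientation vs time.

    ``u_cc``: (n, 3) unit vectors (caudal -> head); frames with zero-length
    head-caudal separation should be passed as NaN rows and are interpolated.
    ``attitude_t0`` / ``attitude_t5`` optionally hold the full take-off
    attitude and the attitude 5 ms later (when resolvable on video).
    """

    times: np.ndarray
    u_cc: np.ndarray
    attitude_t0: Rotation | None = None
    attitude_t5: Rotation | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        u = np.asarray(self.u_cc, dtype=float)
        if u.shape != (len(self.times), 3):
            raise ValueError("u_cc must be (n, 3)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        # flag zero-length rows, interpolate them from neighbours
        norms = np.linalg.norm(u, axis=1)
        bad = ~np.isfinite(norms) | (norms < 1e-12)
        self.flagged_frames = np.nonzero(bad)[0]
        if bad.all():
            raise ValueError("no valid orientation frames")
        if bad.any():
            good = ~bad
            for d in range(3):
                u[bad, d] = np.interp(self.times[bad], self.times[good], u[good, d])
            norms = np.linalg.norm(u, axis=1)
        self.u_cc = u / norms[:, None]

    @classmethod
    def from_points(cls, times, head, caudal, **kw) -> "OrientationTrack":
        """Build from tracked head and caudal 3D points (mm)."""
        vec = np.asarray(head, dtype=float) - np.asarray(caudal, dtype=float)
        return cls(times=times, u_cc=vec, **kw)


@dataclass
class OmegaCcSeries:
    """Angular speed of the cranial-caudal axis.

    ``omega_cc`` in rev/s at the midpoints of consecutive frame pairs.
    Scalar summaries are attached by the extraction/analysis functions.
    """

    times: np.ndarray
    omega_cc: np.ndarray
    omega_to: float | None = None  # angular speed at take-off
    omega_ext: float | None = None  # angular speed at full leg extension
    t_osc: float | None = None

    @property
    def ratio_ext_to(self) -> float | None:
        if self.omega_to and self.omega_ext is not None:
            return self.omega_ext / self.omega_to
        return None


def omega_cc_series(track: OrientationTrack, t_ext: float | None = None
                    ) -> OmegaCcSeries:
    """Angular speed series from consecutive cranial-caudal directions.

    The per-step rotation angle uses atan2(|u_i x u_{i+1}|, u_i . u_{i+1}),
    numerically stable near 0 and pi, divided by the frame interval.
    ``omega_to`` is the first sample; ``omega_ext`` the sample nearest
    ``t_ext`` when given.
    """
    u = track.u_cc
    t = track.times
    if len(t) < 2:
        raise ValueError("need at least 2 frames")
    cross = np.cross(u[:-1], u[1:])
    dot = np.einsum("ij,ij->i", u[:-1], u[1:])
    ang = np.arctan2(np.linalg.norm(cross, axis=1), dot)  # rad per step
    dt = np.diff(t)  # ms
    omega = ang / dt * 1000.0 / (2.0 * np.pi)  # rev/s
    mid = 0.5 * (t[:-1] + t[1:])
    series = OmegaCcSeries(times=mid, omega_cc=omega)
    series.omega_to = float(omega[0])
    if t_ext is not None:
        series.omega_ext = float(omega[np.argmin(np.abs(mid - t_ext))])
    return series


def initial_angular_velocity(attitude_t0: Rotation, attitude_t5: Rotation,
                             interval_ms: float = 5.0) -> np.ndarray:
    """Take-off angular velocity from two attitudes a short interval apart.

    The relative rotation's axis-angle divided by the interval, reported in
    the spatial frame, rev/s.  A relative angle >= 180 deg aliases and is
    rejected.
    """
    rel = attitude_t5 * attitude_t0.inv()  # spatial-frame relative rotation
    rotvec = rel.as_rotvec()
    angle = np.linalg.norm(rotvec)
    # a relative angle at/near 180 deg is direction-ambiguous (any larger
    # true rotation aliases back below 180)
    if angle >= np.pi - 1e-6:
        raise ValueError(
            "relative rotation is ~180 deg over the interval; angular "
            "velocity is aliased - use a smaller interval")
    return rotvec / interval_ms * 1000.0 / (2.0 * np.pi)


@dataclass
class DragDecayFit:
    """Exponential half-life decay fit of an angular-speed series."""

    t_char: float  # ms; inf when the series does not decay
    omega_0: float  # rev/s
    rmse: float
    t_char_ci: tuple[float, float] | None = None
    no_decay: bool = False


def _decay_model(t, omega0, t_char):
    return omega0 * np.power(2.0, -t / t_char)


def fit_drag_decay(series: OmegaCcSeries,
                   windows: dict[str, tuple[float, float]] | None = None,
                   n_bootstrap: int = 200, seed: int | None = 0,
                   ) -> dict[str, DragDecayFit] | DragDecayFit:
    """Least-squares fit of omega(t) = omega_0 * 2**(-t/t_char).

    ``windows`` maps posture names (e.g. "tucked", "extended") to [t_lo,
    t_hi] spans fitted separately; omitted, the whole series is fitted and a
    single fit returned.  CI on t_char by seeded residual bootstrap.  A
    non-decaying window is reported with t_char = inf and flagged.
    """
    if windows is None:
        return _fit_decay_window(series.times, series.omega_cc, n_bootstrap, seed)
    out = {}
    for name, (lo, hi) in windows.items():
        mask = (series.times >= lo) & (series.times <= hi)
        if mask.sum() < 5:
            raise ValueError(f"window {name!r} has fewer than 5 samples")
        out[name] = _fit_decay_window(series.times[mask], series.omega_cc[mask],
                                      n_bootstrap, seed)
    return out


def _fit_decay_window(t, w, n_bootstrap, seed) -> DragDecayFit:
    t = np.asarray(t, float)
    w = np.asarray(w, float)
    t0 = t[0]
    tt = t - t0
    # non-decaying guard: slope of log2(omega) vs t
    with np.errstate(divide="ignore"):
        logs = np.log2(np.maximum(w, 1e-300))
    slope = np.polyfit(tt, logs, 1)[0]
    if slope >= -1e-12:
        return DragDecayFit(t_char=np.inf, omega_0=float(w.mean()),
                            rmse=float(np.std(w)), no_decay=True)
    p0 = (w[0], -1.0 / slope)
    try:
        popt, _ = curve_fit(_decay_model, tt, w, p0=p0, maxfev=5000)
    except RuntimeError as err:
        raise RuntimeError(f"drag-decay fit did not converge: {err}") from err
    omega0, t_char = popt
    resid = w - _decay_model(tt, *popt)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        draws = []
        fitted = _decay_model(tt, *popt)
        for _ in range(n_bootstrap):
            wb = fitted + rng.choice(resid, size=len(resid), replace=True)
            try:
                pb, _ = curve_fit(_decay_model, tt, wb, p0=popt, maxfev=2000)
                if pb[1] > 0:
                    draws.append(pb[1])
            except RuntimeError:
                continue
        if len(draws) >= 20:
            ci = (float(np.percentile(draws, 2.5)),
                  float(np.percentile(draws, 97.5)))
    return DragDecayFit(t_char=float(t_char), omega_0=float(omega0),
                        rmse=rmse, t_char_ci=ci)


def oscillation_period(series: OmegaCcSeries,
                       min_prominence_frac: float = 0.05,
                       min_separation_ms: float = 10.0,
                       detrend: bool = True) -> float | None:
    """Mean inter-peak interval of the (detrended) angular-speed series, ms.

    The decay envelope (fitted half-life model) is divided out first by
    default; peaks need prominence >= 5% of the series maximum and
    >= 10 ms separation.  Returns None (flagged undefined) with < 2 peaks.
    """
    t, w = series.times, series.omega_cc
    x = w.astype(float)
    if detrend:
        fit = fit_drag_decay(series, n_bootstrap=0)
        if not fit.no_decay and np.isfinite(fit.t_char):
            env = _decay_model(t - t[0], fit.omega_0, fit.t_char)
            x = w / np.maximum(env, 1e-12)
    if np.ptp(x) < 1e-12:
        series.t_osc = None
        return None
    dt = np.median(np.diff(t))
    distance = max(int(round(min_separation_ms / dt)), 1)
    prominence = min_prominence_frac * np.max(x)
    peaks, _ = find_peaks(x, prominence=prominence, distance=distance)
    if len(peaks) < 2:
        series.t_osc = None
        return None
    t_osc = float(np.mean(np.diff(t[peaks])))
    series.t_osc = t_osc
    return t_osc


# ---------------------------------------------------------------------------
# Wilcoxon tests (in-repo, exact small-sample null distributions)
# ---------------------------------------------------------------------------


def _rankdata_mid(x: np.ndarray) -> np.ndarray:
    """Mid-ranks with ties."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _signed_rank_exact_p(doubled_ranks: list[int], w2: float) -> float:
    """Two-sided exact p for W+ (ranks doubled to integers).

    Dynamic program over the distribution of the sum of an arbitrary subset
    of the ranks (each sign pattern equally likely under H0).
    """
    total = sum(doubled_ranks)
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        counts[r:] += counts[:total + 1 - r].copy()
    counts /= counts.sum()
    w2i = int(round(w2))
    p_le = counts[: w2i + 1].sum()
    p_ge = counts[w2i:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 25) -> dict:
    """Wilcoxon signed-rank test for paired samples (or one sample vs 0).

    Zero differences are dropped; ties get mid-ranks.  Exact null
    distribution for n <= ``exact_max_n`` (enumerated by dynamic
    programming), normal approximation with tie correction otherwise.
    Returns dict with ``w`` (sum of positive-difference ranks), ``n``
    (nonzero pairs), ``p`` (two-sided), ``exact``, ``degenerate``.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return {"w": 0.0, "n": 0, "p": 1.0, "exact": True, "degenerate": True}
    ranks = _rankdata_mid(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        doubled = [int(round(2 * r)) for r in ranks]
        p = _signed_rank_exact_p(doubled, 2 * w_plus)
        return {"w": w_plus, "n": n, "p": p, "exact": True, "degenerate": False}
    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts ** 3 - tie_counts) / 48.0
    z = (w_plus - mean) / math.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return {"w": w_plus, "n": n, "p": float(min(p, 1.0)), "exact": False,
            "degenerate": False}


def _rank_sum_exact_p(doubled_ranks: list[int], n1: int, w2: float) -> float:
    """Two-sided exact p for the rank-sum W of sample 1 (size n1)."""
    total = sum(doubled_ranks)
    # dp[k][s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in doubled_ranks:
        for k in range(n1, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    dist = dp[n1]
    dist /= dist.sum()
    w2i = int(round(w2))
    p_le = dist[: w2i + 1].sum()
    p_ge = dist[w2i:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_rank_sum(x, y, exact_max_n: int = 25) -> dict:
    """Wilcoxon rank-sum (Mann-Whitney) test for two independent samples.

    ``w`` is the rank sum of the first sample.  Exact enumeration when both
    samples have <= ``exact_max_n`` observations, else normal approximation
    with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _rankdata_mid(pooled)
    w = float(ranks[:n1].sum())
    if n1 <= exact_max_n and n2 <= exact_max_n:
        doubled = [int(round(2 * r)) for r in ranks]
        p = _rank_sum_exact_p(doubled, n1, 2 * w)
        return {"w": w, "n1": n1, "n2": n2, "p": p, "exact": True}
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (w - mean) / math.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return {"w": w, "n1": n1, "n2": n2, "p": float(min(p, 1.0)), "exact": False}


# ---------------------------------------------------------------------------
# tracked vs simulated comparison
# ---------------------------------------------------------------------------


def box_average(times, values, window_ms: float = 25.0,
                t_start: float | None = None, t_stop: float | None = None):
    """Non-overlapping boxcar averages of a series over fixed windows."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    lo = times[0] if t_start is None else t_start
    hi = times[-1] if t_stop is None else t_stop
    centers, means = [], []
    edge = lo
    while edge + window_ms <= hi + 1e-9:
        mask = (times >= edge) & (times < edge + window_ms)
        if mask.any():
            centers.append(edge + window_ms / 2.0)
            means.append(values[mask].mean())
        edge += window_ms
    return np.asarray(centers), np.asarray(means)


def compare_tracked_vs_simulated(tracked: OmegaCcSeries,
                                 simulated: OmegaCcSeries,
                                 window_ms: float = 25.0) -> dict:
    """Paired comparison of tracked and simulated omega_cc series.

    Both series are boxcar-averaged over ``window_ms`` windows spanning the
    overlapping time range and paired by window; the paired Wilcoxon
    signed-rank test (exact for small n) is reported.  With all paired
    differences zero the test is degenerate and reported as such.
    """
    lo = max(tracked.times[0], simulated.times[0])
    hi = min(tracked.times[-1], simulated.times[-1])
    if hi <= lo:
        raise ValueError("series do not overlap in time")
    _, a = box_average(tracked.times, tracked.omega_cc, window_ms, lo, hi)
    centers, b = box_average(simulated.times, simulated.omega_cc, window_ms, lo, hi)
    n = min(len(a), len(b))
    if n < 3:
        raise ValueError("fewer than 3 paired windows")
    a, b = a[:n], b[:n]
    test = wilcoxon_signed_rank(a, b)
    return {
        "window_centers": centers[:n],
        "tracked_means": a,
        "simulated_means": b,
        "differences": a - b,
        "signed_rank": test,
        "degenerate": test["degenerate"],
    }
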