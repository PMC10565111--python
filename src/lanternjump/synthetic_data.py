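"""Synthetic jump-trial generator.

Emulates the statistical structure of tracked jumping trials: zero-drag
parabolic center-of-mass motion sampled at 1000 frames/s with isotropic
Gaussian tracking noise (sigma = 0.54 mm, the 3D reconstruction error
bound), body orientation evolving under the Euler-equation rotational
dynamics model (drag torque, leg-extension posture switch), head/caudal
tracking points placed at +-L_b/2 along the attitude's cranial-caudal axis,
and categorical landing outcomes over the six impact orientations.

Every generated quantity's ground truth is stored on the trial, enabling
parameter-recovery tests; trials are bit-reproducible from their seed.
Defaults emulate a third-instar cohort: take-off speeds around 3.0 m/s
(printed range 2.7-3.4), launch angles near 45 deg, initial spin ~19 rev/s
(within the 5-45 Hz range), t_ext = 40 ms, t_char = 155/76 ms for the
tucked/extended postures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics_sim, mesh_mechanics
from .dynamics_sim import DragModel, InertiaSchedule, simulate_rotation
from .landing_stats import ORIENTATIONS, LandingOutcomeTable
from .trajectory_fit import ComTrack, G_MM_MS2
from .rotation_analysis import OrientationTrack

__all__ = [
    "OutcomeModel",
    "TrialConfig",
    "JumpTrial",
    "PopulationModel",
    "default_inertia_schedule",
    "generate_trial",
    "generate_cohort",
    "write_trial",
    "read_trial",
    "TRACK_COLUMNS",
]

TRACK_COLUMNS = ["t_ms", "com_x", "com_y", "com_z",
                 "head_x", "head_y", "head_z",
                 "caudal_x", "caudal_y", "caudal_z"]


# ---------------------------------------------------------------------------
# landing-outcome model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeModel:
    """6 x 2 probability table: orientation marginal and success|orientation.

    The default emulates the observed pattern: ventral impacts most frequent
    and most successful, dorsal impacts most failure-prone, overall success
    probability ~0.59 (122/207).
    """

    p_orientation: tuple = (0.35, 0.15, 0.12, 0.12, 0.13, 0.13)
    p_success_given: tuple = (0.79, 0.31, 0.54, 0.54, 0.54, 0.54)

    def __post_init__(self):
        p = np.asarray(self.p_orientation, float)
        s = np.asarray(self.p_success_given, float)
        if len(p) != 6 or len(s) != 6:
            raise ValueError("need 6 orientation categories")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("orientation probabilities must sum to 1")
        if np.any((s < 0) | (s > 1)) or np.any(p < 0):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def overall_success_probability(self) -> float:
        return float(np.dot(self.p_orientation, self.p_success_given))

    def sample(self, rng: np.random.Generator) -> tuple[str, str]:
        i = rng.choice(6, p=self.p_orientation)
        success = rng.random() < self.p_success_given[i]
        return ORIENTATIONS[i], "success" if success else "failure"

    @classmethod
    def uniform(cls, p_success: float = 122 / 207) -> "OutcomeModel":
        return cls(p_orientation=(1 / 6,) * 6,
                   p_success_given=(p_success,) * 6)


# ---------------------------------------------------------------------------
# trial configuration
# ---------------------------------------------------------------------------


@dataclass
class TrialConfig:
    """Ground-truth parameters of one synthetic jump trial.

    Speeds m/s, angles deg, times ms, angular velocity rev/s, noise mm.
    """

    v_to: float = 3.0
    theta: float = 45.0
    azimuth: float = 0.0
    duration: float = 120.0
    frame_rate: float = 1000.0
    sigma: float = 0.54
    omega0: tuple = (2.0, 18.0, 5.0)
    t_char_tucked: float | None = 155.0
    t_char_extended: float | None = 76.0
    t_ext: float = 40.0
    t_ext_start: float = 0.0
    body_length: float = 8.9
    mass: float = 28.4
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    steering_curvature: float = 0.0  # deg azimuth drift per ms (positive control)
    pre_impact_kick: float = 0.0  # rev/s added to omega over final 10 ms
    simulate_orientation: bool = True
    sim_dt: float = dynamics_sim.DEFAULT_DT_MS
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("invalid config")


@dataclass
class JumpTrial:
    """One synthetic trial: tracks, events, outcome, and ground truth."""

    com_track: ComTrack
    orientation_track: OrientationTrack | None
    impact_orientation: str
    outcome: str
    ground_truth: dict
    specimen_id: str = "S000"
    trial_id: str = "T000"
    head: np.ndarray | None = None
    caudal: np.ndarray | None = None


@lru_cache(maxsize=4)
def default_inertia_schedule(body_length: float = 8.9, mass: float = 28.4,
                             t_ext: float = 40.0, t_ext_start: float = 0.0
                             ) -> InertiaSchedule:
    """Inertia schedule from the default posture meshes (built once, cached)."""
    geo = mesh_mechanics.PostureGeometry(body_length=body_length)
    props = {}
    for label in ("legs_tucked", "legs_extended"):
        mesh = mesh_mechanics.build_nymph_mesh(geo, label)
        props[label] = mesh_mechanics.compute_rigid_body_properties(mesh, mass)
    return InertiaSchedule(props_tucked=props["legs_tucked"],
                           props_extended=props["legs_extended"],
                           t_ext=t_ext, t_ext_start=t_ext_start)


def _parabola(times_ms: np.ndarray, v: float, theta_deg: float,
              azimuth_deg: float, curvature_deg_per_ms: float = 0.0
              ) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    t = np.asarray(times_ms, float)
    out = np.empty((len(t), 3))
    if curvature_deg_per_ms == 0.0:
        ph = np.deg2rad(azimuth_deg)
        out[:, 0] = v * np.cos(th) * np.cos(ph) * t
        out[:, 1] = v * np.cos(th) * np.sin(ph) * t
    else:
        # steering positive control: azimuth drifts linearly -> curved track
        ph = np.deg2rad(azimuth_deg + curvature_deg_per_ms * t)
        vh = v * np.cos(th)
        dt = np.diff(t, prepend=t[0])
        out[:, 0] = np.cumsum(vh * np.cos(ph) * dt)
        out[:, 1] = np.cumsum(vh * np.sin(ph) * dt)
        out[:, 0] -= out[0, 0]
        out[:, 1] -= out[0, 1]
    out[:, 2] = v * np.sin(th) * t - 0.5 * G_MM_MS2 * t ** 2
    return out


def generate_trial(config: TrialConfig, schedule: InertiaSchedule | None = None
                   ) -> JumpTrial:
    """Generate one synthetic jump trial (bit-reproducible from its seed)."""
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration * config.frame_rate / 1000.0)) + 1
    times = np.arange(n_frames) * (1000.0 / config.frame_rate)

    com_true = _parabola(times, config.v_to, config.theta, config.azimuth,
                         config.steering_curvature)
    com = com_true + rng.normal(0.0, config.sigma, com_true.shape)

    head = caudal = None
    orientation_track = None
    sim = None
    if config.simulate_orientation:
        schedule = schedule or default_inertia_schedule(
            config.body_length, config.mass, config.t_ext, config.t_ext_start)
        drag = DragModel(config.t_char_tucked, config.t_char_extended)
        stride = max(int(round((1000.0 / config.frame_rate) / config.sim_dt)), 1)
        sim = simulate_rotation(np.asarray(config.omega0, float), schedule,
                                drag, duration=config.duration,
                                dt=config.sim_dt, sample_every=stride)
        u_cc = sim.cranial_caudal_axis()[: n_frames]
        if config.pre_impact_kick > 0.0:
            # abrupt angular-speed rise in the final 10 ms: spin u_cc faster
            # about a fixed axis (phenomenological, not mechanistic)
            t_kick = times[-1] - 10.0
            extra = np.zeros(n_frames)
            late = times >= t_kick
            extra[late] = np.cumsum(
                np.full(late.sum(), config.pre_impact_kick *
                        (2 * np.pi / 1000.0) * (1000.0 / config.frame_rate)))
            axis = np.array([0.0, 0.0, 1.0])
            for i in np.nonzero(late)[0]:
                c, s = np.cos(extra[i]), np.sin(extra[i])
                u = u_cc[i]
                u_cc[i] = (u * c + np.cross(axis, u) * s
                           + axis * (axis @ u) * (1 - c))
        half = config.body_length / 2.0
        head = com + half * u_cc + rng.normal(0.0, config.sigma, (n_frames, 3))
        caudal = com - half * u_cc + rng.normal(0.0, config.sigma, (n_frames, 3))
        orientation_track = OrientationTrack.from_points(times, head, caudal)

    impact_orientation, outcome = config.outcome_model.sample(rng)
    com_track = ComTrack(times=times, positions=com, take_off=0.0,
                         leg_extension=config.t_ext, impact=float(times[-1]))
    truth = dataclasses.asdict(config)
    truth["outcome_model"] = {
        "p_orientation": list(config.outcome_model.p_orientation),
        "p_success_given": list(config.outcome_model.p_success_given),
    }
    return JumpTrial(com_track=com_track, orientation_track=orientation_track,
                     impact_orientation=impact_orientation, outcome=outcome,
                     ground_truth=truth, head=head, caudal=caudal)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class PopulationModel:
    """Between-specimen parameter distributions (Gaussian, truncated > 0).

    Defaults span the printed ranges: take-off speed 2.7-3.4 m/s, spin
    5-45 rev/s.
    """

    v_to_mean: float = 3.0
    v_to_sd: float = 0.2
    theta_mean: float = 45.0
    theta_sd: float = 8.0
    omega_mag_mean: float = 19.0
    omega_mag_sd: float = 8.0

    def draw_specimen(self, rng: np.random.Generator) -> dict:
        def trunc_pos(mean, sd, lo=1e-3):
            for _ in range(100):
                x = rng.normal(mean, sd)
                if x > lo:
                    return float(x)
            return float(mean)

        v = trunc_pos(self.v_to_mean, self.v_to_sd)
        theta = float(np.clip(rng.normal(self.theta_mean, self.theta_sd),
                              10.0, 80.0))
        mag = trunc_pos(self.omega_mag_mean, self.omega_mag_sd, lo=1.0)
        base = np.array([2.0, 18.0, 5.0])
        omega0 = tuple(base / np.linalg.norm(base) * mag)
        return {"v_to": v, "theta": theta, "omega0": omega0}


def generate_cohort(n_specimens: int = 48,
                    trials_per_specimen: tuple[int, int] = (1, 5),
                    population: PopulationModel | None = None,
                    seed: int = 0,
                    base_config: TrialConfig | None = None,
                    simulate_orientation: bool = False,
                    ) -> tuple[list[JumpTrial], LandingOutcomeTable]:
    """Generate a cohort of trials with between-specimen variation.

    Specimen-level parameters are drawn once per specimen; trial-level noise
    is independent per trial.  Orientation simulation is off by default
    (cohort-level analyses need only COM tracks and outcomes; enable it for
    full-pipeline runs).
    """
    if n_specimens < 1:
        raise ValueError("need at least one specimen")
    lo, hi = trials_per_specimen
    if not 1 <= lo <= hi:
        raise ValueError("invalid trials_per_specimen range")
    population = population or PopulationModel()
    base = base_config or TrialConfig()
    rng = np.random.default_rng(seed)
    trials: list[JumpTrial] = []
    records = []
    for s in range(n_specimens):
        spec_id = f"S{s:03d}"
        draws = population.draw_specimen(rng)
        n_trials = int(rng.integers(lo, hi + 1))
        for k in range(n_trials):
            cfg = dataclasses.replace(
                base, seed=int(rng.integers(0, 2 ** 31 - 1)),
                simulate_orientation=simulate_orientation, **draws)
            trial = generate_trial(cfg)
            trial.specimen_id = spec_id
            trial.trial_id = f"T{len(trials):04d}"
            trials.append(trial)
            records.append({"specimen_id": spec_id,
                            "trial_id": trial.trial_id,
                            "impact_orientation": trial.impact_orientation,
                            "outcome": trial.outcome})
    table = LandingOutcomeTable(records=pd.DataFrame(records))
    return trials, table


# ---------------------------------------------------------------------------
# trial I/O (CSV track + JSON sidecar)
# ---------------------------------------------------------------------------


def write_trial(trial: JumpTrial, directory) -> tuple[Path, Path]:
    """Write a trial as <trial_id>.csv (track) + <trial_id>.json (events,
    outcome, ground truth)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = len(trial.com_track.times)
    data = {"t_ms": trial.com_track.times}
    for i, ax in enumerate("xyz"):
        data[f"com_{ax}"] = trial.com_track.positions[:, i]
    for name, arr in (("head", trial.head), ("caudal", trial.caudal)):
        for i, ax in enumerate("xyz"):
            data[f"{name}_{ax}"] = (arr[:, i] if arr is not None
                                    else np.full(n, np.nan))
    csv_path = directory / f"{trial.trial_id}.csv"
    pd.DataFrame(data)[TRACK_COLUMNS].to_csv(csv_path, index=False,
                                             float_format="%.9g")
    sidecar = {
        "specimen_id": trial.specimen_id,
        "trial_id": trial.trial_id,
        "events": {
            "take_off": trial.com_track.take_off,
            "leg_extension": trial.com_track.leg_extension,
            "impact": trial.com_track.impact,
        },
        "impact_orientation": trial.impact_orientation,
        "outcome": trial.outcome,
        "ground_truth": trial.ground_truth,
    }
    json_path = directory / f"{trial.trial_id}.json"
    json_path.write_text(json.dumps(sidecar, indent=1, default=float))
    return csv_path, json_path


def read_trial(csv_path) -> JumpTrial:
    """Read a trial written by :func:`write_trial`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    events = meta["events"]
    com = df[["com_x", "com_y", "com_z"]].to_numpy()
    track = ComTrack(times=df["t_ms"].to_numpy(), positions=com,
                     take_off=events.get("take_off"),
                     leg_extension=events.get("leg_extension"),
                     impact=events.get("impact"))
    head = df[["head_x", "head_y", "head_z"]].to_numpy()
    caudal = df[["caudal_x", "caudal_y", "caudal_z"]].to_numpy()
    orientation = None
    if np.isfinite(head).all() and np.isfinite(caudal).all():
        orientation = OrientationTrack.from_points(df["t_ms"].to_numpy(),
                                                   head, caudal)
    else:
        head = caudal = None
    return JumpTrial(com_track=track, orientation_track=orientation,
                     impact_orientation=meta["impact_orientation"],
                     outcome=meta["outcome"],
                     ground_truth=meta.get("ground_truth", {}),
                     specimen_id=meta.get("specimen_id", "S000"),
                     trial_id=meta.get("trial_id", csv_path.stem),
                     head=head, caudal=caudal)
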