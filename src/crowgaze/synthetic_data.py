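"""Ground-truthed synthetic sessions and perimetry.

No recordings ship with the package; instead this module emulates the five
experimental inputs so every pipeline stage is testable against known truth:

* object trajectories for the three presentation scenarios (wiggle 5 s,
  ballistic throw, still on the ground/wall; or ceiling wiggle only);
* head-pose time series composed of fixations with configurable per-movement
  region preferences, connected by minimum-jerk head saccades, with smooth
  pursuit during the throw when the policy selects the binocular field;
* rigid marker clouds rendered from the true poses with Gaussian noise and
  dropout, in the motion-capture table dialect;
* trial event logs (M1/M2/M3 onsets);
* perimetry sampled at 1-deg azimuth / 10-deg (or 30-deg) elevation steps
  from a parametric ground-truth field, with replicate scatter emulating eye
  movement.

Everything is driven by a :class:`numpy.random.Generator`; identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation, Slerp

from .gaze_analysis import TrialEvent
from .geometry import minimal_rotation, vectors_from_directions
from .head_pose import MarkerTemplate
from .kinematics import MarkerTrajectories, PoseSeries, SaccadeEvent
from .visual_field import VisualFieldModel, classify_directions

__all__ = [
    "ScenarioConfig",
    "GazePolicy",
    "GroundTruth",
    "SyntheticSession",
    "simulate_object_path",
    "simulate_session_objects",
    "simulate_head_gaze",
    "render_marker_data",
    "simulate_perimetry",
    "simulate_session",
    "default_marker_template",
]

GRAVITY = 9.81  # m/s^2
NATIVE_RATE = 120.0  # Hz

SCENARIOS = ("ground_throw", "wall_throw", "ceiling_wiggle")


@dataclass(frozen=True)
class ScenarioConfig:
    """Geometry and timing of one presentation experiment.

    Defaults mirror the motion-capture room (4 x 4 x 4.6 m) with a central
    perch at 2 m height and an experimenter by the near wall; positions in
    metres, world frame: x right, y away from the experimenter wall, z up.
    """

    scenario: str = "ground_throw"
    n_trials: int = 10
    wiggle_duration_s: float = 5.0
    wiggle_frequency_hz: float = 2.0
    wiggle_amplitude_m: float = 0.08
    still_duration_s: float = 3.0
    pre_trial_s: float = 1.0
    inter_trial_s: float = 2.0
    throw_flight_s: float = 0.9
    gravity: float = GRAVITY
    room_size_m: tuple[float, float, float] = (4.0, 4.0, 4.6)
    perch_head_m: tuple[float, float, float] = (2.0, 2.2, 2.3)
    hold_point_m: tuple[float, float, float] = (2.0, 0.7, 1.9)
    landing_ground_m: tuple[float, float, float] = (2.0, 1.9, 0.0)
    landing_wall_m: tuple[float, float, float] = (2.0, 4.0, 2.3)
    ceiling_point_m: tuple[float, float, float] = (2.0, 2.2, 3.0)
    landing_scatter_m: float = 0.25
    rate_hz: float = NATIVE_RATE

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")


def _default_preferences() -> dict[str, dict[str, float]]:
    # region preferences per object movement: wiggling and thrown targets are
    # tracked mostly binocularly, still targets mostly laterally with a
    # slight right-eye preference
    return {
        "M1": {"binocular": 0.60, "right": 0.22, "left": 0.18},
        "M2": {"binocular": 0.85, "right": 0.08, "left": 0.07},
        "M3": {"binocular": 0.15, "right": 0.50, "left": 0.35},
        "idle": {"binocular": 0.25, "right": 0.40, "left": 0.35},
    }


@dataclass(frozen=True)
class GazePolicy:
    """How the simulated bird allocates its visual field per movement."""

    preferences: dict[str, dict[str, float]] = field(
        default_factory=_default_preferences
    )
    fixation_mean_s: float = 1.0
    fixation_min_s: float = 0.2
    eye_jitter_deg: float = 15.0  # bounded stand-in for untracked eye movement
    saccade_peak_speed_deg_s: float = 1000.0
    saccade_min_duration_s: float = 2.0 / NATIVE_RATE  # small saccades are abrupt
    saccade_max_duration_s: float = 0.35
    pursuit_during_throw: bool = True
    # smooth pursuit saturates well below the saccade threshold; the head
    # lags the target when it moves faster than this
    pursuit_max_speed_deg_s: float = 150.0

    def __post_init__(self) -> None:
        for mov, prefs in self.preferences.items():
            total = sum(prefs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"preferences for {mov!r} sum to {total}, not 1")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    poses: PoseSeries  # true poses at the native rate, no saccade flags
    saccades: list[SaccadeEvent]  # every inserted transition
    region_labels: np.ndarray  # per-frame label from true pose + model ('' in saccades)
    dwell_fractions: dict[str, float]  # over non-saccade frames
    saccade_mask: np.ndarray
    noise_mm: float = 0.0
    dropout_p: float = 0.0

    def retained_saccades(
        self, min_duration_s: float = 0.05, min_amplitude_deg: float = 5.0
    ) -> list[SaccadeEvent]:
        """Inserted saccades that the small-saccade rule would keep."""
        return [
            ev
            for ev in self.saccades
            if not (ev.duration_s < min_duration_s and ev.amplitude_deg < min_amplitude_deg)
        ]


@dataclass
class SyntheticSession:
    """A complete simulated recording (positions in mm, world frame)."""

    subject: str
    session: str
    config: ScenarioConfig
    policy: GazePolicy
    time: np.ndarray
    target_positions: np.ndarray  # (n, 3) mm, aligned with `time`
    events: list[TrialEvent]
    truth: GroundTruth
    markers: MarkerTrajectories | None = None
    template: MarkerTemplate | None = None


# ---------------------------------------------------------------------------
# object motion


def simulate_object_path(
    cfg: ScenarioConfig,
    trial: int,
    rng: np.random.Generator,
    start_from: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """One trial's object track: ``(time, positions, onsets)``.

    M1 = sinusoidal wiggle about the hold point; M2 = ballistic arc under
    gravity to the landing plane; M3 = at rest.  The ceiling scenario emits
    M1 only.  Onsets are exact grid times relative to the trial start.
    ``start_from`` (the previous trial's landing point) makes the
    experimenter carry the object back to the hold point during the
    pre-trial second instead of it jumping there.
    """
    dt = 1.0 / cfg.rate_hz
    hold = np.asarray(
        cfg.ceiling_point_m if cfg.scenario == "ceiling_wiggle" else cfg.hold_point_m
    )
    n_pre = int(round(cfg.pre_trial_s * cfg.rate_hz))
    n_wig = int(round(cfg.wiggle_duration_s * cfg.rate_hz))
    if start_from is None:
        segs = [np.tile(hold, (n_pre, 1))]
    else:
        tau = np.arange(n_pre) / max(n_pre - 1, 1)
        ease = _min_jerk(tau)[:, None]
        segs = [np.asarray(start_from) + ease * (hold - np.asarray(start_from))]
    onsets = {"M1": n_pre * dt}

    t_w = np.arange(n_wig) * dt
    phase = rng.uniform(0, 2 * np.pi)
    wig = np.tile(hold, (n_wig, 1))
    wig[:, 0] += cfg.wiggle_amplitude_m * np.sin(
        2 * np.pi * cfg.wiggle_frequency_hz * t_w + phase
    )
    wig[:, 2] += cfg.wiggle_amplitude_m * 0.6 * np.sin(
        2 * np.pi * cfg.wiggle_frequency_hz * 1.5 * t_w
    )
    segs.append(wig)

    if cfg.scenario != "ceiling_wiggle":
        onsets["M2"] = onsets["M1"] + cfg.wiggle_duration_s
        land_nominal = np.asarray(
            cfg.landing_ground_m
            if cfg.scenario == "ground_throw"
            else cfg.landing_wall_m
        )
        land = land_nominal.copy()
        scatter = rng.uniform(-cfg.landing_scatter_m, cfg.landing_scatter_m, size=2)
        if cfg.scenario == "ground_throw":
            land[:2] += scatter  # scatter on the floor
        else:
            land[0] += scatter[0]  # scatter on the wall
            land[2] += scatter[1]
        T = cfg.throw_flight_s
        n_fly = int(round(T * cfg.rate_hz))
        start = segs[-1][-1]
        v0 = (land - start) / T + 0.5 * cfg.gravity * T * np.array([0.0, 0.0, 1.0])
        t_f = (np.arange(n_fly) + 1) * dt
        arc = (
            start
            + v0 * t_f[:, None]
            - 0.5 * cfg.gravity * np.outer(t_f**2, [0.0, 0.0, 1.0])
        )
        apex = arc[:, 2].max()
        if apex > cfg.room_size_m[2] or np.any(arc < -1e-9) or np.any(
            arc[:, :2] > np.asarray(cfg.room_size_m[:2]) + 1e-9
        ):
            raise ValueError("throw arc leaves the room; adjust the scenario config")
        segs.append(arc)
        onsets["M3"] = onsets["M2"] + n_fly * dt
        n_still = int(round(cfg.still_duration_s * cfg.rate_hz))
        segs.append(np.tile(land, (n_still, 1)))
    else:
        n_still = int(round(cfg.still_duration_s * cfg.rate_hz))
        segs.append(np.tile(hold, (n_still, 1)))

    n_gap = int(round(cfg.inter_trial_s * cfg.rate_hz))
    segs.append(np.tile(segs[-1][-1], (n_gap, 1)))

    pos = np.vstack(segs)
    time = np.arange(len(pos)) * dt
    return time, pos, onsets


def simulate_session_objects(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[TrialEvent]]:
    """Concatenated trials: ``(time, positions, events)`` with absolute onsets."""
    all_pos = []
    events: list[TrialEvent] = []
    offset = 0.0
    prev_end: np.ndarray | None = None
    for trial in range(1, cfg.n_trials + 1):
        t, pos, onsets = simulate_object_path(cfg, trial, rng, start_from=prev_end)
        prev_end = pos[-1]
        for kind, onset in onsets.items():
            events.append(TrialEvent(trial, kind, offset + onset))
        all_pos.append(pos)
        offset += len(pos) / cfg.rate_hz
    pos = np.vstack(all_pos)
    time = np.arange(len(pos)) / cfg.rate_hz
    return time, pos, events


# ---------------------------------------------------------------------------
# head gaze


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _phase_of_frames(
    time: np.ndarray, events: Sequence[TrialEvent], cfg: ScenarioConfig
) -> np.ndarray:
    phase = np.full(time.size, "idle", dtype=object)
    marks = sorted(events, key=lambda e: e.onset_s)
    spans = {
        "M1": cfg.wiggle_duration_s,
        "M2": cfg.throw_flight_s,
        "M3": cfg.still_duration_s,
    }
    for ev in marks:
        i0 = int(np.searchsorted(time, ev.onset_s - 1e-9))
        i1 = int(np.searchsorted(time, ev.onset_s + spans[ev.kind] - 1e-9))
        phase[i0:i1] = ev.kind
    return phase


def _sample_gaze_direction(
    region: str,
    model: VisualFieldModel,
    policy: GazePolicy,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> np.ndarray:
    """Unit head-frame vector at which the target is held for one fixation.

    The reference is the beak projection for the binocular field and the
    optical axis for each lateral field; a bounded random offset stands in
    for the untracked eye movement, rejection-sampled until the direction
    classifies into the requested region.
    """
    ref = {
        "binocular": model.beak_projection,
        "right": model.optical_axis_right,
        "left": model.optical_axis_left,
    }[region]
    v_ref = vectors_from_directions(np.array(ref.azimuth), np.array(ref.elevation))
    want = {
        "binocular": ("binocular",),
        "right": ("right_monocular_anterior",),
        "left": ("left_monocular_anterior",),
    }[region]
    for _ in range(max_tries):
        angle = np.radians(policy.eye_jitter_deg) * np.sqrt(rng.uniform())
        psi = rng.uniform(0, 2 * np.pi)
        # rotate the reference by `angle` about a perpendicular axis
        a = np.array([1.0, 0.0, 0.0])
        if abs(v_ref @ a) > 0.9:
            a = np.array([0.0, 0.0, 1.0])
        e1 = np.cross(v_ref, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(v_ref, e1)
        v = (
            np.cos(angle) * v_ref
            + np.sin(angle) * (np.cos(psi) * e1 + np.sin(psi) * e2)
        )
        az = np.degrees(np.arctan2(v[0], v[1]))
        el = np.degrees(np.arcsin(np.clip(v[2], -1, 1)))
        if classify_directions(model, np.array([az]), np.array([el]))[0] in want:
            return v
    raise RuntimeError(f"could not sample a direction inside region {region!r}")


def _orient(target_world: np.ndarray, origin: np.ndarray, v_head: np.ndarray) -> np.ndarray:
    w = target_world - origin
    w = w / np.linalg.norm(w)
    return minimal_rotation(v_head, w)


def simulate_head_gaze(
    time: np.ndarray,
    target_positions: np.ndarray,
    events: Sequence[TrialEvent],
    model: VisualFieldModel,
    policy: GazePolicy,
    rng: np.random.Generator,
    cfg: ScenarioConfig,
) -> GroundTruth:
    """Ground-truth head-pose series realizing the gaze policy.

    Fixations hold the target at a sampled within-region offset (the head is
    still; during the throw a binocular fixation becomes smooth pursuit);
    transitions are minimum-jerk saccades whose duration follows the
    configured peak speed.  Region labels are then *re-derived* from the
    generated poses and the model, so the stored truth is self-consistent by
    construction.
    """
    n = time.size
    rate = cfg.rate_hz
    origin = np.asarray(cfg.perch_head_m) * 1000.0  # head origin, mm
    targets_mm = np.asarray(target_positions) * 1000.0
    phase = _phase_of_frames(time, events, cfg)

    quats = np.empty((n, 4))
    saccade_mask = np.zeros(n, dtype=bool)
    events_out: list[SaccadeEvent] = []

    region0 = _choose_region(policy, str(phase[0]), rng)
    v0 = _sample_gaze_direction(region0, model, policy, rng)
    current = Rotation.from_matrix(_orient(targets_mm[0], origin, v0))

    i = 0
    while i < n:
        mov = str(phase[i])
        region = _choose_region(policy, mov, rng)
        v_head = _sample_gaze_direction(region, model, policy, rng)
        target_R = Rotation.from_matrix(_orient(targets_mm[i], origin, v_head))
        if i == 0:
            current = target_R

        # --- saccade toward the new fixation, aimed at where the target
        # will be when the saccade lands (two-pass prediction)
        amp = float(np.degrees((target_R * current.inv()).magnitude()))
        if amp > 0.2 and i > 0:
            n_sac = 2
            for _ in range(2):
                dur = np.clip(
                    1.875 * amp / policy.saccade_peak_speed_deg_s,
                    policy.saccade_min_duration_s,
                    policy.saccade_max_duration_s,
                )
                n_sac = max(2, int(round(dur * rate)))
                n_sac = min(n_sac, n - i)
                j = min(i + n_sac - 1, n - 1)
                target_R = Rotation.from_matrix(_orient(targets_mm[j], origin, v_head))
                amp = float(np.degrees((target_R * current.inv()).magnitude()))
            if n_sac >= 2:
                key = Slerp(
                    [0.0, 1.0], Rotation.concatenate([current, target_R])
                )
                tau = _min_jerk(np.arange(n_sac) / (n_sac - 1))
                quats[i : i + n_sac] = key(tau).as_quat()
                saccade_mask[i : i + n_sac] = True
                peak = float(np.max(np.diff(tau)) * amp * rate)  # discrete peak
                events_out.append(
                    SaccadeEvent(
                        start_s=float(time[i]),
                        end_s=float(time[i + n_sac - 1]),
                        amplitude_deg=amp,
                        peak_speed_deg_s=peak,
                    )
                )
                i += n_sac
                current = target_R
        if i >= n:
            break

        # --- fixation (interrupted by object-movement onsets: the bird
        # re-fixates when the stimulus changes)
        dur = max(policy.fixation_min_s, rng.exponential(policy.fixation_mean_s))
        n_fix = max(1, int(round(dur * rate)))
        n_fix = min(n_fix, n - i)
        ahead = phase[i : i + n_fix]
        change = np.flatnonzero(ahead != mov)
        if change.size:
            n_fix = max(1, int(change[0]))
        pursuit = (
            policy.pursuit_during_throw and region == "binocular" and mov == "M2"
        )
        if pursuit:
            max_step = np.radians(policy.pursuit_max_speed_deg_s) / rate
            catch_up = np.radians(max(5.0, policy.eye_jitter_deg / 3.0))
            end_fix = i + n_fix
            while i < end_fix:
                desired = Rotation.from_matrix(_orient(targets_mm[i], origin, v_head))
                step = desired * current.inv()
                ang = float(step.magnitude())
                if ang > max_step:  # pursuit gain saturates; lag the target
                    step = Rotation.from_rotvec(step.as_rotvec() * (max_step / ang))
                current = step * current
                quats[i] = current.as_quat()
                i += 1
                if ang - max_step > catch_up:
                    break  # too far behind: end the fixation, saccade to catch up
        else:
            # held fixation: the head is still, but if the target drifts away
            # from the fixated offset the bird re-fixates (stimulus-driven)
            drift_thresh = np.cos(np.radians(max(5.0, policy.eye_jitter_deg)))
            desired_world = current.apply(v_head)
            end_fix = i + n_fix
            while i < end_fix:
                quats[i] = current.as_quat()
                w = targets_mm[i] - origin
                w = w / np.linalg.norm(w)
                i += 1
                if float(w @ desired_world) < drift_thresh:
                    break
        if i >= n:
            break

    rotations = Rotation.from_quat(quats)
    poses = PoseSeries(
        time=time,
        rate=rate,
        rotations=rotations,
        translations=np.tile(origin, (n, 1)),
        valid=np.ones(n, dtype=bool),
        saccade=np.zeros(n, dtype=bool),
        native_rate=rate,
    )

    # re-derive labels from the generated poses (self-consistency)
    rel = rotations.inv().apply(targets_mm - origin)
    az = np.degrees(np.arctan2(rel[:, 0], rel[:, 1]))
    el = np.degrees(np.arcsin(np.clip(rel[:, 2] / np.linalg.norm(rel, axis=1), -1, 1)))
    labels = classify_directions(model, az, el)
    labels = np.where(saccade_mask, "", labels)

    keep = ~saccade_mask
    total = max(int(keep.sum()), 1)
    dwell = {
        lab: float(np.sum(labels[keep] == lab)) / total
        for lab in np.unique(labels[keep])
    }
    return GroundTruth(
        poses=poses,
        saccades=events_out,
        region_labels=labels,
        dwell_fractions=dwell,
        saccade_mask=saccade_mask,
    )


def _choose_region(policy: GazePolicy, movement: str, rng: np.random.Generator) -> str:
    prefs = policy.preferences.get(movement, policy.preferences["idle"])
    regions = sorted(prefs)
    p = np.array([prefs[r] for r in regions])
    return str(rng.choice(regions, p=p / p.sum()))


# ---------------------------------------------------------------------------
# marker rendering


def default_marker_template() -> MarkerTemplate:
    """A plausible 5-marker crow head template (mm, calibrated head frame)."""
    return MarkerTemplate(
        labels=("m1", "m2", "m3", "m4", "m5"),
        positions=np.array(
            [
                [0.0, 18.0, 14.0],
                [12.0, 2.0, 20.0],
                [-12.0, 2.0, 20.0],
                [8.0, -14.0, 16.0],
                [-8.0, -14.0, 12.0],
            ]
        ),
        meta={"synthetic": True},
    )


def render_marker_data(
    poses: PoseSeries,
    template: MarkerTemplate,
    noise_mm: float,
    dropout_p: float,
    rng: np.random.Generator,
) -> MarkerTrajectories:
    """World-frame marker table from true poses (mm, native rate).

    Each marker sample gets isotropic Gaussian noise and is independently
    missing with probability ``dropout_p``.
    """
    n = poses.n_frames
    k = len(template.labels)
    world = np.empty((n, k, 3))
    Rm = poses.rotations.as_matrix()
    world = np.einsum("nij,kj->nki", Rm, template.positions) + poses.translations[:, None, :]
    if noise_mm > 0:
        world = world + rng.normal(0.0, noise_mm, size=world.shape)
    if dropout_p > 0:
        drop = rng.uniform(size=(n, k)) < dropout_p
        world[drop] = np.nan
    world[~poses.valid] = np.nan
    markers = {lab: world[:, j, :] for j, lab in enumerate(template.labels)}
    return MarkerTrajectories(time=poses.time.copy(), rate=poses.rate, markers=markers)


# ---------------------------------------------------------------------------
# perimetry


def simulate_perimetry(
    model: VisualFieldModel,
    rng: np.random.Generator,
    subject: str = "sim",
    condition: str = "rest",
    elevation_step_deg: float = 10.0,
    azimuth_step_deg: float = 1.0,
    eye_movement_span_deg: float = 0.0,
    noise_deg: float = 0.0,
    n_replicates: int = 3,
    eye_offset_deg: float = 0.0,
    n_axis_replicates: int = 9,
    axis_noise_deg: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Perimetry and optical-axis tables sampled from a ground-truth field.

    The true boundary at each grid elevation is the model's (maximal-extent)
    representative; each replicate observes it retracted by a uniform
    eye-movement draw on ``[0, span]`` plus Gaussian reading noise, then
    quantized to the ``azimuth_step_deg`` graduation (0 disables
    quantization).  ``eye_offset_deg`` rotates both eyes in their orbits:
    positive = converged (larger frontal overlap), negative = diverged, which
    retracts the anterior boundaries (a frontal blind wedge appears, as under
    the 'away' induction) while extending the posterior ones.  Optical-axis
    replicates scatter around the true axes.
    """
    grid_step = float(np.round(np.diff(model.phi_deg).mean(), 9))
    stride = max(1, int(round(elevation_step_deg / grid_step)))
    rows = []
    for idx in range(0, model.phi_deg.size, stride):
        phi = float(model.phi_deg[idx])
        kind = "anterior" if -90.0 <= phi <= 90.0 else "posterior"
        for eye, true_b in (
            ("right", float(model.right_boundary_deg[idx])),
            ("left", float(model.left_boundary_deg[idx])),
        ):
            center = true_b + (eye_offset_deg if kind == "anterior" else -eye_offset_deg)
            for _ in range(n_replicates):
                obs = center - rng.uniform(0.0, eye_movement_span_deg)
                if noise_deg > 0:
                    obs += rng.normal(0.0, noise_deg)
                if azimuth_step_deg > 0:
                    obs = round(obs / azimuth_step_deg) * azimuth_step_deg
                obs = float(np.clip(obs, -90.0, 90.0))
                rows.append(
                    {
                        "subject": subject,
                        "eye": eye,
                        "condition": condition,
                        "landmark": "retina_edge",
                        "arm_elevation_deg": phi,
                        "boundary_azimuth_deg": obs,
                        "boundary_kind": kind,
                    }
                )
    perimetry = pd.DataFrame(rows)

    axis_rows = []
    for eye, axis in (
        ("right", model.optical_axis_right),
        ("left", model.optical_axis_left),
    ):
        for rep in range(1, n_axis_replicates + 1):
            axis_rows.append(
                {
                    "subject": subject,
                    "eye": eye,
                    "azimuth_deg": axis.azimuth
                    + (rng.normal(0.0, axis_noise_deg) if axis_noise_deg > 0 else 0.0),
                    "elevation_deg": axis.elevation
                    + (rng.normal(0.0, axis_noise_deg) if axis_noise_deg > 0 else 0.0),
                    "replicate": rep,
                }
            )
    axes = pd.DataFrame(axis_rows)
    return perimetry, axes


# ---------------------------------------------------------------------------
# one-call session


def simulate_session(
    model: VisualFieldModel,
    seed: int,
    cfg: ScenarioConfig = ScenarioConfig(),
    policy: GazePolicy = GazePolicy(),
    subject: str = "sim_bird",
    session: str = "s01",
    noise_mm: float = 0.3,
    dropout_p: float = 0.02,
    template: MarkerTemplate | None = None,
    render_markers: bool = True,
) -> SyntheticSession:
    """Simulate a full recording session (objects, gaze, markers)."""
    rng = np.random.default_rng(seed)
    time, target_m, events = simulate_session_objects(cfg, rng)
    truth = simulate_head_gaze(time, target_m, events, model, policy, rng, cfg)
    target_pos = target_m * 1000.0  # the tracking pipeline works in mm
    truth.noise_mm = noise_mm
    truth.dropout_p = dropout_p
    tmpl = template or default_marker_template()
    markers = None
    if render_markers:
        markers = render_marker_data(truth.poses, tmpl, noise_mm, dropout_p, rng)
    return SyntheticSession(
        subject=subject,
        session=session,
        config=cfg,
        policy=policy,
        time=time,
        target_positions=target_pos,
        events=events,
        truth=truth,
        markers=markers,
        template=tmpl,
    )
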