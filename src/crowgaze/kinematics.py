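"""Marker-trajectory cleaning, pose time series and head-saccade detection.

Raw marker tables arrive on a regular 120 Hz grid with per-marker dropouts.
Preprocessing invalidates physically impossible spikes, fills short gaps by
cubic interpolation, low-pass filters with a zero-phase Butterworth filter
and resamples onto the 36 Hz working grid.  Head saccades are detected where
the axial angle speed (the geodesic rotation angle between consecutive
orientations times the frame rate) exceeds 200 deg/s; brief, small
supra-threshold events (shorter than 50 ms AND smaller than 5 deg) are
demoted back into the inter-saccadic intervals because they are not
distinguishable from tracking noise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .geometry import RigidPose
from .head_pose import MarkerTemplate, estimate_head_pose

__all__ = [
    "MarkerTrajectories",
    "PoseSeries",
    "SaccadeEvent",
    "PreprocessConfig",
    "SaccadeConfig",
    "read_marker_table",
    "write_marker_table",
    "preprocess",
    "track_poses",
    "angular_speed_series",
    "detect_saccades",
    "resample_track",
    "saccade_table",
]


@dataclass
class MarkerTrajectories:
    """Labeled marker positions on a regular time grid; NaN rows = missing."""

    time: np.ndarray  # (n,) seconds
    rate: float  # Hz
    markers: dict[str, np.ndarray]  # label -> (n, 3)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(np.abs(dt - 1.0 / self.rate) > 1e-6 / self.rate):
                raise ValueError("marker timestamps are not a regular grid at the stated rate")
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}

    @property
    def n_frames(self) -> int:
        return self.time.size

    def stacked(self, labels: Sequence[str]) -> np.ndarray:
        return np.stack([self.markers[l] for l in labels], axis=1)  # (n, k, 3)


@dataclass
class PoseSeries:
    """Time-stamped rigid head poses with validity and saccade flags."""

    time: np.ndarray
    rate: float
    rotations: Rotation  # length n (invalid frames hold identity)
    translations: np.ndarray  # (n, 3)
    valid: np.ndarray  # (n,) bool
    saccade: np.ndarray  # (n,) bool
    rms_mm: np.ndarray | None = None
    native_rate: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.saccade = np.asarray(self.saccade, dtype=bool)
        n = self.time.size
        if len(self.rotations) != n or self.translations.shape != (n, 3):
            raise ValueError("pose arrays must share one length")
        if np.any(self.saccade & ~self.valid):
            raise ValueError("saccade flags may only be set on valid frames")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or np.ptp(dt) > 1e-9 + 1e-6 / self.rate:
                raise ValueError("timestamps must be strictly increasing and uniform")

    @property
    def n_frames(self) -> int:
        return self.time.size

    def pose(self, i: int) -> RigidPose | None:
        if not self.valid[i]:
            return None
        return RigidPose(self.rotations[int(i)].as_matrix(), self.translations[i])

    def with_saccade_mask(self, mask: np.ndarray) -> "PoseSeries":
        return replace(self, saccade=np.asarray(mask, dtype=bool) & self.valid)


@dataclass(frozen=True)
class SaccadeEvent:
    """A detected head saccade (times in seconds, amplitude in degrees)."""

    start_s: float
    end_s: float
    amplitude_deg: float
    peak_speed_deg_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PreprocessConfig:
    """Trajectory-cleaning parameters (per-subject in the original workflow)."""

    max_gap_s: float = 0.1
    smooth_cutoff_hz: float = 10.0
    # linear bound on marker displacement; ~2000 deg/s of head rotation at
    # head-marker radius plus locomotion stays well under 5 m/s
    spike_speed_mm_s: float = 5000.0
    working_rate_hz: float = 36.0
    filter_order: int = 4


@dataclass(frozen=True)
class SaccadeConfig:
    threshold_deg_s: float = 200.0
    min_duration_s: float = 0.05
    min_amplitude_deg: float = 5.0
    merge_gap_frames: int = 1


# ---------------------------------------------------------------------------
# marker-table dialect


def read_marker_table(path) -> MarkerTrajectories:
    """Read the delimited marker-trajectory dialect.

    Comma-separated with a header row ``frame,time,<label>_x,<label>_y,
    <label>_z,...``; blank cells are missing samples; lines starting with
    ``#`` are metadata and skipped.
    """
    df = pd.read_csv(path, comment="#")
    if "time" not in df.columns:
        raise ValueError("marker table needs a 'time' column")
    labels = []
    for c in df.columns:
        if c.endswith("_x"):
            base = c[:-2]
            if f"{base}_y" in df.columns and f"{base}_z" in df.columns:
                labels.append(base)
    time = df["time"].to_numpy(dtype=float)
    if time.size < 2:
        raise ValueError("marker table needs >= 2 frames")
    dt = np.diff(time)
    if np.ptp(dt) > 1e-6 * dt.mean():
        raise ValueError("irregular timestamps; resample the export first")
    rate = 1.0 / dt.mean()
    markers = {
        l: df[[f"{l}_x", f"{l}_y", f"{l}_z"]].to_numpy(dtype=float) for l in labels
    }
    return MarkerTrajectories(time=time, rate=float(round(rate, 6)), markers=markers)


def write_marker_table(traj: MarkerTrajectories, path) -> None:
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(traj.n_frames),
        "time": traj.time,
    }
    for label, xyz in traj.markers.items():
        for j, ax in enumerate("xyz"):
            cols[f"{label}_{ax}"] = xyz[:, j]
    df = pd.DataFrame(cols)
    buf = io.StringIO()
    buf.write("# crowgaze marker trajectory export\n")
    buf.write(f"# rate_hz,{traj.rate}\n")
    df.to_csv(buf, index=False)
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# preprocessing


def _fill_gaps(xyz: np.ndarray, max_gap: int) -> np.ndarray:
    """Cubic interpolation of interior NaN runs no longer than ``max_gap``."""
    out = xyz.copy()
    ok = np.all(np.isfinite(xyz), axis=1)
    if ok.sum() < 2:
        return out
    idx = np.arange(len(xyz))
    missing = ~ok
    if not missing.any():
        return out
    # locate runs of missing frames
    edges = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    valid_idx = idx[ok]
    if ok.sum() >= 4:
        spline = CubicSpline(valid_idx, xyz[ok], axis=0)
        interp = spline
    else:  # too few samples for a cubic; fall back to linear
        interp = lambda q: np.column_stack(  # noqa: E731
            [np.interp(q, valid_idx, xyz[ok][:, j]) for j in range(3)]
        )
    for a, b in zip(starts, ends):
        if b - a > max_gap:
            continue
        if a == 0 or b == len(xyz):  # leading/trailing gaps stay missing
            continue
        out[a:b] = interp(idx[a:b])
    return out


def _despike(xyz: np.ndarray, rate: float, speed_bound: float) -> np.ndarray:
    """Invalidate frames whose displacement implies impossible speed."""
    out = xyz.copy()
    ok = np.all(np.isfinite(out), axis=1)
    prev = None
    for i in np.flatnonzero(ok):
        if prev is not None:
            speed = np.linalg.norm(out[i] - out[prev]) / ((i - prev) / rate)
            if speed > speed_bound:
                out[i] = np.nan
                continue
        prev = i
    return out


def _lowpass_runs(xyz: np.ndarray, rate: float, cutoff: float, order: int) -> np.ndarray:
    out = xyz.copy()
    if cutoff <= 0 or cutoff >= rate / 2:
        return out
    b, a = butter(order, cutoff / (rate / 2.0))
    padlen = 3 * (max(len(a), len(b)) - 1)
    ok = np.all(np.isfinite(xyz), axis=1)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s > padlen:
            out[s:e] = filtfilt(b, a, xyz[s:e], axis=0)
    return out


def preprocess(
    traj: MarkerTrajectories, config: PreprocessConfig = PreprocessConfig()
) -> MarkerTrajectories:
    """Clean and resample marker trajectories to the working rate.

    Spike frames are invalidated, interior gaps up to ``max_gap_s`` are
    filled by cubic interpolation, a zero-phase Butterworth low-pass at
    ``smooth_cutoff_hz`` is applied per contiguous valid run, and the result
    is resampled onto a uniform ``working_rate_hz`` grid
    (``floor(n * working / native)`` frames).  Longer gaps remain missing.
    """
    max_gap = int(round(config.max_gap_s * traj.rate))
    cleaned = {}
    for label, xyz in traj.markers.items():
        x = _despike(xyz, traj.rate, config.spike_speed_mm_s)
        x = _fill_gaps(x, max_gap)
        x = _lowpass_runs(x, traj.rate, config.smooth_cutoff_hz, config.filter_order)
        cleaned[label] = x

    n_out = int(np.floor(traj.n_frames * config.working_rate_hz / traj.rate))
    t_new = traj.time[0] + np.arange(n_out) / config.working_rate_hz
    resampled = {}
    for label, xyz in cleaned.items():
        out = np.full((n_out, 3), np.nan)
        ok = np.all(np.isfinite(xyz), axis=1)
        # a resampled frame is valid only if its bracketing native frames are
        pos = np.clip(np.searchsorted(traj.time, t_new, side="right") - 1, 0, traj.n_frames - 1)
        nxt = np.minimum(pos + 1, traj.n_frames - 1)
        good = ok[pos] & ok[nxt]
        for j in range(3):
            col = np.interp(t_new, traj.time[ok], xyz[ok, j]) if ok.any() else np.nan
            out[:, j] = col
        out[~good] = np.nan
        resampled[label] = out
    return MarkerTrajectories(time=t_new, rate=config.working_rate_hz, markers=resampled)


# ---------------------------------------------------------------------------
# pose tracking


def track_poses(
    traj: MarkerTrajectories,
    template: MarkerTemplate,
    native_rate: float | None = None,
) -> PoseSeries:
    """Per-frame rigid head pose from cleaned marker trajectories."""
    labels = [l for l in template.labels if l in traj.markers]
    if len(labels) < 3:
        raise ValueError("fewer than 3 template markers present in the trajectories")
    order = [template.labels.index(l) for l in labels]
    sub = MarkerTemplate(
        tuple(labels), template.positions[order], meta=dict(template.meta)
    )
    stack = traj.stacked(labels)  # (n, k, 3)
    n = traj.n_frames
    quats = np.tile([0.0, 0.0, 0.0, 1.0], (n, 1))
    trans = np.zeros((n, 3))
    valid = np.zeros(n, dtype=bool)
    rms = np.full(n, np.nan)
    for i in range(n):
        pose, r = estimate_head_pose(sub, stack[i])
        if pose is not None:
            quats[i] = Rotation.from_matrix(pose.rotation).as_quat()
            trans[i] = pose.translation
            valid[i] = True
            rms[i] = r
    return PoseSeries(
        time=traj.time,
        rate=traj.rate,
        rotations=Rotation.from_quat(quats),
        translations=trans,
        valid=valid,
        saccade=np.zeros(n, dtype=bool),
        rms_mm=rms,
        native_rate=native_rate,
    )


# ---------------------------------------------------------------------------
# saccades


def angular_speed_series(ps: PoseSeries) -> np.ndarray:
    """Axial angle speed (deg/s) of the frame-to-frame head rotation.

    ``speed[i]`` describes the transition from frame ``i`` to ``i+1``; the
    last entry and transitions touching invalid frames are NaN.
    """
    n = ps.n_frames
    speed = np.full(n, np.nan)
    if n < 2:
        return speed
    rel = ps.rotations[1:] * ps.rotations[:-1].inv()
    ang = np.degrees(rel.magnitude())
    ok = ps.valid[:-1] & ps.valid[1:]
    speed[:-1] = np.where(ok, ang * ps.rate, np.nan)
    return speed


def detect_saccades(
    ps: PoseSeries,
    config: SaccadeConfig = SaccadeConfig(),
    speed: np.ndarray | None = None,
) -> tuple[list[SaccadeEvent], np.ndarray]:
    """Detect head saccades from the axial-angle speed series.

    Contiguous supra-threshold transition runs (runs separated by at most
    ``merge_gap_frames`` sub-threshold transitions are merged) become
    candidate events, then each event is extended outward to the surrounding
    local speed minima so that its bounds sit at movement onset and offset
    rather than at the threshold crossings.  Event amplitude is the axial
    angle between the poses bounding the extended run; events that are BOTH
    shorter than ``min_duration_s`` and smaller than ``min_amplitude_deg``
    are demoted to the inter-saccadic interval.  Returns the retained events
    and the per-frame saccade mask.
    """
    if speed is None:
        speed = angular_speed_series(ps)
    sp = np.nan_to_num(speed, nan=0.0)
    supra = np.zeros(ps.n_frames, dtype=bool)
    supra[: len(speed)] = sp > config.threshold_deg_s

    edges = np.flatnonzero(np.diff(np.concatenate(([0], supra.view(np.int8), [0]))))
    starts, ends = list(edges[::2]), list(edges[1::2])

    # anti-chatter: merge runs separated by short valid sub-threshold gaps
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if (
            merged
            and s - merged[-1][1] <= config.merge_gap_frames
            and ps.valid[merged[-1][1] : s + 1].all()
        ):
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # onset/offset refinement: walk each bound to the local speed minimum
    prev_end = 0
    for k, (s, e) in enumerate(merged):
        while s > prev_end and np.isfinite(speed[s - 1]) and sp[s - 1] < sp[s]:
            s -= 1
        nxt = merged[k + 1][0] if k + 1 < len(merged) else len(sp)
        while e < min(nxt, len(sp) - 1) and np.isfinite(speed[e]) and sp[e] < sp[e - 1]:
            e += 1
        merged[k] = [s, e]
        prev_end = e

    events: list[SaccadeEvent] = []
    mask = np.zeros(ps.n_frames, dtype=bool)
    for s, e in merged:
        last = min(e, ps.n_frames - 1)  # pose frame bounding the run
        start_t = float(ps.time[s])
        end_t = float(ps.time[last])
        duration = end_t - start_t
        rel = ps.rotations[int(last)] * ps.rotations[int(s)].inv()
        amplitude = float(np.degrees(rel.magnitude()))
        peak = float(np.nanmax(speed[s:e]))
        if duration < config.min_duration_s and amplitude < config.min_amplitude_deg:
            continue  # small-saccade rule: kept in the inter-saccadic interval
        events.append(SaccadeEvent(start_t, end_t, amplitude, peak))
        mask[s : last + 1] = True
    mask &= ps.valid
    return events, mask


def resample_track(
    time_src: np.ndarray, positions: np.ndarray, time_dst: np.ndarray
) -> np.ndarray:
    """Linear resampling of a world track onto another time grid."""
    time_src = np.asarray(time_src, dtype=float)
    positions = np.asarray(positions, dtype=float)
    return np.column_stack(
        [np.interp(time_dst, time_src, positions[:, j]) for j in range(positions.shape[1])]
    )


def saccade_table(events: Sequence[SaccadeEvent]) -> pd.DataFrame:
    """Events as the delimited output dialect."""
    return pd.DataFrame(
        [
            {
                "start_s": ev.start_s,
                "end_s": ev.end_s,
                "amplitude_deg": ev.amplitude_deg,
                "peak_speed_deg_s": ev.peak_speed_deg_s,
            }
            for ev in events
        ],
        columns=["start_s", "end_s", "amplitude_deg", "peak_speed_deg_s"],
    )
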