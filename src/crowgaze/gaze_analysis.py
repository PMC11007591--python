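"""Target projection, event windows, region dwell, heatmaps and scores.

A visual target at world position ``p`` seen from head pose ``(R, o)``
projects to the head-centric direction of ``R.T (p - o)``.  Around each
object-movement onset (M1 wiggle, M2 throw, M3 still) a 1 s window is
extracted; valid non-saccade frames are classified into visual-field regions
and accumulated as dwell time, pooled per (subject, session, movement).

Differential looking scores:

* binocular use score ``(B - N) / (B + N)`` -- binocular vs non-binocular
  anterior looking time;
* laterality score ``(nR - nL) / (nR + nL)`` -- right vs left non-binocular
  anterior looking time.

Chance levels under random viewing come from the field model's region areas
(:func:`crowgaze.visual_field.chance_levels`); the score table carries
chance-adjusted columns ready for a standard mixed-model routine (the
fitting itself is outside this package).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kinematics import PoseSeries
from .geometry import directions_from_vectors
from .visual_field import (
    VisualFieldModel,
    chance_levels,
    classify_directions,
)

__all__ = [
    "TrialEvent",
    "RegionDwell",
    "SessionData",
    "target_directions",
    "extract_windows",
    "dwell_by_region",
    "make_heatmap",
    "heatmap_marginals",
    "binocular_use_score",
    "laterality_score",
    "score_table",
    "read_events",
    "DWELL_REGIONS",
]

DWELL_REGIONS = (
    "binocular",
    "right_monocular_anterior",
    "left_monocular_anterior",
    "right_monocular_posterior",
    "left_monocular_posterior",
    "blind",
)

MOVEMENTS = ("M1", "M2", "M3")


@dataclass(frozen=True)
class TrialEvent:
    trial_id: int
    kind: str  # M1 | M2 | M3
    onset_s: float

    def __post_init__(self) -> None:
        if self.kind not in MOVEMENTS:
            raise ValueError(f"event kind must be one of {MOVEMENTS}, got {self.kind!r}")


@dataclass
class RegionDwell:
    """Seconds of valid, non-saccade looking time per visual-field region."""

    seconds: dict[str, float]
    total_s: float

    def __post_init__(self) -> None:
        for r in DWELL_REGIONS:
            self.seconds.setdefault(r, 0.0)

    def __add__(self, other: "RegionDwell") -> "RegionDwell":
        return RegionDwell(
            {r: self.seconds[r] + other.seconds[r] for r in DWELL_REGIONS},
            self.total_s + other.total_s,
        )


@dataclass
class SessionData:
    """One recording session: poses, target track and trial events."""

    subject: str
    session: str
    poses: PoseSeries
    target_positions: np.ndarray  # (n, 3) world, aligned with poses.time
    events: list[TrialEvent]
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# projection and windows


def target_directions(
    ps: PoseSeries, target_positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Head-centric (azimuth, elevation) of the target, NaN where undefined."""
    p = np.asarray(target_positions, dtype=float)
    if p.shape != (ps.n_frames, 3):
        raise ValueError("target positions must be time-aligned with the pose series")
    rel_world = p - ps.translations
    rel_head = ps.rotations.inv().apply(rel_world)
    dist = np.linalg.norm(rel_head, axis=1)
    bad = ~ps.valid | ~np.isfinite(dist) | (dist == 0.0)
    rel_head = np.where(bad[:, None], np.nan, rel_head)
    with np.errstate(invalid="ignore"):
        az, el = directions_from_vectors(np.where(bad[:, None], 1.0, rel_head))
    az = np.where(bad, np.nan, az)
    el = np.where(bad, np.nan, el)
    return az, el


def extract_windows(
    ps: PoseSeries,
    events: Iterable[TrialEvent],
    window_s: float = 1.0,
) -> dict[str, np.ndarray]:
    """Frame-index sets of the analysis windows, pooled per movement kind.

    Each window is ``[onset, onset + window_s)`` on the working grid; windows
    running past the end of the recording are truncated with a warning.
    """
    pooled: dict[str, list[np.ndarray]] = {}
    t0 = ps.time[0]
    for ev in events:
        if ev.onset_s < t0 - 1e-9 or ev.onset_s > ps.time[-1] + 1e-9:
            raise ValueError(f"event onset {ev.onset_s} s outside the recording")
        start = int(np.ceil((ev.onset_s - t0) * ps.rate - 1e-9))
        stop = start + int(round(window_s * ps.rate))
        if stop > ps.n_frames:
            warnings.warn(
                f"window for trial {ev.trial_id} {ev.kind} truncated at recording end",
                stacklevel=2,
            )
            stop = ps.n_frames
        pooled.setdefault(ev.kind, []).append(np.arange(start, stop))
    return {k: np.concatenate(v) for k, v in pooled.items()}


# ---------------------------------------------------------------------------
# dwell and heatmaps


def dwell_by_region(
    az: np.ndarray,
    el: np.ndarray,
    saccade_mask: np.ndarray,
    model: VisualFieldModel,
    rate: float,
    frames: np.ndarray | None = None,
) -> RegionDwell:
    """Valid non-saccade looking time per region (seconds).

    Saccade frames and frames with undefined target direction are excluded;
    region seconds sum to the retained time exactly.
    """
    az = np.asarray(az, dtype=float)
    el = np.asarray(el, dtype=float)
    saccade_mask = np.asarray(saccade_mask, dtype=bool)
    if frames is not None:
        az, el, saccade_mask = az[frames], el[frames], saccade_mask[frames]
    keep = np.isfinite(az) & np.isfinite(el) & ~saccade_mask
    labels = classify_directions(model, az[keep], el[keep])
    seconds = {r: float(np.sum(labels == r)) / rate for r in DWELL_REGIONS}
    return RegionDwell(seconds, total_s=float(keep.sum()) / rate)


def make_heatmap(
    az: np.ndarray, el: np.ndarray, bin_deg: float = 5.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Proportion-of-time grid over azimuth x elevation.

    Returns ``(grid, az_edges, el_edges)`` where ``grid[i, j]`` is the
    proportion of (finite) samples with azimuth in bin ``i`` and elevation in
    bin ``j``; the grid sums to 1 (all-zero and flagged via a plain sum check
    when there are no samples).
    """
    if 360.0 % bin_deg or 180.0 % bin_deg:
        raise ValueError("bin size must divide 360 and 180 degrees")
    az = np.asarray(az, dtype=float).ravel()
    el = np.asarray(el, dtype=float).ravel()
    ok = np.isfinite(az) & np.isfinite(el)
    az_edges = np.arange(-180.0, 180.0 + bin_deg / 2, bin_deg)
    el_edges = np.arange(-90.0, 90.0 + bin_deg / 2, bin_deg)
    grid, _, _ = np.histogram2d(az[ok], el[ok], bins=[az_edges, el_edges])
    if ok.sum() > 0:
        grid = grid / ok.sum()
    return grid, az_edges, el_edges


def heatmap_marginals(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Azimuth and elevation marginal histograms of a heatmap grid."""
    return grid.sum(axis=1), grid.sum(axis=0)


# ---------------------------------------------------------------------------
# differential looking scores


def binocular_use_score(d: RegionDwell) -> float:
    """(B - N)/(B + N); NaN when neither field was used (flagged undefined)."""
    B = d.seconds["binocular"]
    N = d.seconds["right_monocular_anterior"] + d.seconds["left_monocular_anterior"]
    if B + N == 0:
        return float("nan")
    return (B - N) / (B + N)


def laterality_score(d: RegionDwell) -> float:
    """(nR - nL)/(nR + nL); NaN when the anterior monocular dwell is zero."""
    nR = d.seconds["right_monocular_anterior"]
    nL = d.seconds["left_monocular_anterior"]
    if nR + nL == 0:
        return float("nan")
    return (nR - nL) / (nR + nL)


def score_table(
    sessions: Sequence[SessionData],
    model: VisualFieldModel,
    window_s: float = 1.0,
    weighting: str = "solid_angle",
) -> pd.DataFrame:
    """Per subject x session x movement scores with chance-adjusted columns.

    The chance levels are recomputed from the supplied field model (not
    hard-coded), and subtracted to give ``*_adj`` columns centred on zero
    under random viewing.  Undefined scores (zero denominators) are NaN and
    should be excluded, not treated as zero, by downstream models.
    """
    if not sessions:
        raise ValueError("need at least one session")
    chance = chance_levels(model, weighting=weighting)
    rows = []
    for sd in sessions:
        az, el = target_directions(sd.poses, sd.target_positions)
        windows = extract_windows(sd.poses, sd.events, window_s=window_s)
        for movement in MOVEMENTS:
            if movement not in windows:
                continue
            dwell = dwell_by_region(
                az, el, sd.poses.saccade, model, sd.poses.rate, frames=windows[movement]
            )
            b = binocular_use_score(dwell)
            lat = laterality_score(dwell)
            rows.append(
                {
                    "subject": sd.subject,
                    "session": sd.session,
                    "movement": movement,
                    "binocular_use_score": b,
                    "laterality_score": lat,
                    "binocular_use_score_adj": b - chance["binocular_use_chance"],
                    "laterality_score_adj": lat - chance["laterality_chance"],
                    "dwell_s": dwell.total_s,
                    "binocular_s": dwell.seconds["binocular"],
                    "right_anterior_s": dwell.seconds["right_monocular_anterior"],
                    "left_anterior_s": dwell.seconds["left_monocular_anterior"],
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["binocular_use_chance"] = chance["binocular_use_chance"]
    df.attrs["laterality_chance"] = chance["laterality_chance"]
    return df


def read_events(path) -> list[TrialEvent]:
    """Read a trial event log (CSV: trial_id, kind, onset_s)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("trial_id", "kind", "onset_s") if c not in df.columns]
    if missing:
        raise ValueError(f"event log missing columns {missing}")
    return [
        TrialEvent(int(r.trial_id), str(r.kind), float(r.onset_s))
        for r in df.itertuples()
    ]
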