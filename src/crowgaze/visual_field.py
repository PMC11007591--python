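"""Species visual-field model from ophthalmoscopic perimetry.

The model represents each eye's monocular field as a boundary curve in arm
coordinates: at every arm elevation ``phi`` (full sagittal circle) the eye
sees the arc of the arm from its boundary to its own lateral pole.  The
boundary azimuth ``b_e(phi)`` is *signed toward midline crossing*, so at a
given elevation

* binocular width  = ``max(0, b_left + b_right)``
* blind-area width = ``max(0, -(b_left + b_right))``

In the signed arm coordinate ``s`` (positive toward the right pole) the
right eye covers ``s >= -b_right`` and the left eye covers ``s <= b_left``.
Because ``(phi, s)`` is a spherical coordinate system about the ``+x`` pole,
region solid angles reduce to one-dimensional integrals in ``phi`` with
``sin`` terms in the boundaries, and the head-calibration pitch (aligning
the eye--beak-tip line to azimuth 0, elevation -10) is a pure shift of
``phi``.

Directions with ``|azimuth| <= 90`` are *anterior*; the non-binocular
anterior field is the anterior part seen by exactly one eye.  Differential
looking scores are compared against chance levels set by the relative region
areas (cos-weighted solid angle by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    Direction,
    InvalidInputError,
    arm_coordinates,
    vectors_from_directions,
)

__all__ = [
    "PerimetryRecord",
    "OpticalAxisRecord",
    "VisualFieldModel",
    "BoundarySummary",
    "correct_viewpoint",
    "summarize_boundaries",
    "estimate_optical_axis",
    "build_field_model",
    "classify_direction",
    "classify_directions",
    "field_metrics",
    "chance_levels",
    "region_areas",
    "mirror_symmetrize",
    "read_perimetry",
    "read_optical_axes",
    "field_model_from_perimetry",
    "REGION_LABELS",
]

REGION_LABELS = (
    "binocular",
    "right_monocular_anterior",
    "left_monocular_anterior",
    "right_monocular_posterior",
    "left_monocular_posterior",
    "blind",
    "pecten",
)

PERIMETRY_COLUMNS = [
    "subject",
    "eye",
    "condition",
    "landmark",
    "arm_elevation_deg",
    "boundary_azimuth_deg",
    "boundary_kind",
]

AXIS_COLUMNS = ["subject", "eye", "azimuth_deg", "elevation_deg", "replicate"]


class MissingDataError(ValueError):
    """Raised when a summary or estimate is requested from no records."""


class InsufficientDataError(ValueError):
    """Raised when too few elevations are available to build a field model."""


class UndefinedScoreError(ValueError):
    """Raised when a differential-looking chance level has a zero denominator."""


@dataclass(frozen=True)
class PerimetryRecord:
    """One observed field boundary on the perimeter arm.

    ``boundary_azimuth`` is signed toward midline crossing (positive = the
    eye sees past the median plane at this elevation).
    """

    subject: str
    eye: str
    condition: str
    landmark: str
    arm_elevation: float
    boundary_azimuth: float
    boundary_kind: str


@dataclass(frozen=True)
class OpticalAxisRecord:
    subject: str
    eye: str
    azimuth: float
    elevation: float
    replicate: int


@dataclass(frozen=True)
class BoundarySummary:
    """Representative boundary plus replicate spread at one elevation."""

    representative: float
    span: float
    n: int


# ---------------------------------------------------------------------------
# elementary operations


def correct_viewpoint(
    measured_azimuth: float,
    internodal_distance: float,
    perimeter_radius: float,
    eye: str = "right",
) -> float:
    """Eye-centred boundary azimuth from a perimeter-centred measurement.

    The perimeter arm is graduated about the head centre, but each eye's
    nodal point sits ``d/2`` lateral of it (toward the eye's own pole).  For
    a boundary recorded at arm azimuth ``a`` (degrees, signed toward midline
    crossing) the limiting ray through the nodal point makes the angle

        ``a' = atan2(R sin a + d/2, R cos a)``

    with the median plane, which exceeds ``a``: referenced to the eye, the
    field reaches slightly further across the midline.  The shift vanishes as
    ``d -> 0`` or ``R -> inf``.  The returned azimuth keeps the
    midline-crossing sign convention, which makes the correction independent
    of ``eye`` (the argument is kept for interface symmetry and validation).
    """
    if eye not in ("left", "right"):
        raise InvalidInputError(f"eye must be 'left' or 'right', got {eye!r}")
    d = float(internodal_distance)
    R = float(perimeter_radius)
    if d < 0:
        raise InvalidInputError("internodal distance must be non-negative")
    if R <= d / 2.0:
        raise InvalidInputError("eye nodal point lies outside the perimeter arm")
    a = np.radians(float(measured_azimuth))
    corrected = np.arctan2(R * np.sin(a) + d / 2.0, R * np.cos(a))
    return float(np.degrees(corrected))


def summarize_boundaries(
    boundary_azimuths: Sequence[float] | np.ndarray,
    strategy: str = "max_extent",
) -> BoundarySummary:
    """Representative boundary from repeated observations at one elevation.

    Repeated passes of the ophthalmoscope see the field edge at several
    azimuths because the (untracked) eye moves; the representative score is
    the extremum that maximizes the field extent, i.e. the largest
    midline-crossing value in the signed convention.  The replicate span
    (max - min) estimates the eye-movement amplitude at that elevation.
    """
    a = np.asarray(list(boundary_azimuths), dtype=float)
    if a.size == 0:
        raise MissingDataError("no boundary observations at this elevation")
    if strategy == "max_extent":
        rep = float(a.max())
    elif strategy == "min_extent":
        rep = float(a.min())
    elif strategy == "median":
        rep = float(np.median(a))
    else:
        raise InvalidInputError(f"unknown strategy {strategy!r}")
    return BoundarySummary(rep, float(a.max() - a.min()), int(a.size))


def estimate_optical_axis(
    records: Iterable[OpticalAxisRecord] | pd.DataFrame,
    min_replicates: int = 9,
) -> Direction:
    """Component-wise median of repeated optical-axis sightings."""
    if isinstance(records, pd.DataFrame):
        az = records["azimuth_deg"].to_numpy(dtype=float)
        el = records["elevation_deg"].to_numpy(dtype=float)
    else:
        records = list(records)
        az = np.array([r.azimuth for r in records], dtype=float)
        el = np.array([r.elevation for r in records], dtype=float)
    if az.size == 0:
        raise MissingDataError("no optical-axis replicates")
    if az.size < min_replicates:
        warnings.warn(
            f"only {az.size} optical-axis replicates (< {min_replicates}); "
            "estimate may be unstable",
            stacklevel=2,
        )
    return Direction(float(np.median(az)), float(np.median(el)))


# ---------------------------------------------------------------------------
# field model


@dataclass
class VisualFieldModel:
    """Per-eye field boundaries and derived regions on the sphere.

    ``phi_deg`` is the (calibrated) arm-elevation grid over the full sagittal
    circle, strictly increasing within ``(-90, 270]``.  ``right_boundary_deg``
    and ``left_boundary_deg`` are the midline-crossing-signed boundary
    azimuths of each eye at those elevations; curves are piecewise-linear and
    periodic in ``phi``.  Pecten wedges are stored per eye as rows of
    ``(phi, u_min, u_max)`` in the eye's own arm azimuth ``u`` (positive
    toward that eye's pole).
    """

    phi_deg: np.ndarray
    right_boundary_deg: np.ndarray
    left_boundary_deg: np.ndarray
    right_fill: np.ndarray
    left_fill: np.ndarray
    optical_axis_right: Direction
    optical_axis_left: Direction
    beak_projection: Direction = field(default_factory=lambda: Direction(0.0, -10.0))
    pecten_right: np.ndarray | None = None
    pecten_left: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi_deg = np.asarray(self.phi_deg, dtype=float)
        self.right_boundary_deg = np.asarray(self.right_boundary_deg, dtype=float)
        self.left_boundary_deg = np.asarray(self.left_boundary_deg, dtype=float)
        self.right_fill = np.asarray(self.right_fill, dtype=bool)
        self.left_fill = np.asarray(self.left_fill, dtype=bool)
        n = self.phi_deg.size
        if n < 2:
            raise InsufficientDataError("need boundaries at >= 2 elevations")
        if np.any(np.diff(self.phi_deg) <= 0):
            raise InvalidInputError("phi grid must be strictly increasing")
        for arr in (
            self.right_boundary_deg,
            self.left_boundary_deg,
            self.right_fill,
            self.left_fill,
        ):
            if arr.shape != (n,):
                raise InvalidInputError("boundary arrays must match the phi grid")
        if np.any(np.abs(self.right_boundary_deg) > 90) or np.any(
            np.abs(self.left_boundary_deg) > 90
        ):
            raise InvalidInputError("boundary azimuths must lie in [-90, 90]")

    # -- boundary interpolation (periodic, piecewise linear) ----------------

    def boundaries_at(self, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        phi = np.asarray(phi, dtype=float)
        phi_wrapped = np.mod(phi + 90.0, 360.0) - 90.0
        grid = self.phi_deg
        period = 360.0
        xp = np.concatenate(([grid[-1] - period], grid, [grid[0] + period]))
        bR = self.right_boundary_deg
        bL = self.left_boundary_deg
        fpR = np.concatenate(([bR[-1]], bR, [bR[0]]))
        fpL = np.concatenate(([bL[-1]], bL, [bL[0]]))
        return np.interp(phi_wrapped, xp, fpR), np.interp(phi_wrapped, xp, fpL)

    # -- convenience ---------------------------------------------------------

    def binocular_width(self, phi: np.ndarray) -> np.ndarray:
        bR, bL = self.boundaries_at(phi)
        return np.clip(bR + bL, 0.0, None)

    def copy(self) -> "VisualFieldModel":
        return replace(
            self,
            phi_deg=self.phi_deg.copy(),
            right_boundary_deg=self.right_boundary_deg.copy(),
            left_boundary_deg=self.left_boundary_deg.copy(),
            right_fill=self.right_fill.copy(),
            left_fill=self.left_fill.copy(),
            pecten_right=None if self.pecten_right is None else self.pecten_right.copy(),
            pecten_left=None if self.pecten_left is None else self.pecten_left.copy(),
            meta=dict(self.meta),
        )

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        payload = {
            "format": "crowgaze-visual-field-model",
            "version": 1,
            "phi_deg": arr(self.phi_deg),
            "right_boundary_deg": arr(self.right_boundary_deg),
            "left_boundary_deg": arr(self.left_boundary_deg),
            "right_fill": arr(self.right_fill.astype(int)),
            "left_fill": arr(self.left_fill.astype(int)),
            "optical_axis_right": [
                self.optical_axis_right.azimuth,
                self.optical_axis_right.elevation,
            ],
            "optical_axis_left": [
                self.optical_axis_left.azimuth,
                self.optical_axis_left.elevation,
            ],
            "beak_projection": [
                self.beak_projection.azimuth,
                self.beak_projection.elevation,
            ],
            "pecten_right": arr(self.pecten_right),
            "pecten_left": arr(self.pecten_left),
            "meta": self.meta,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "VisualFieldModel":
        p = json.loads(text)
        if p.get("format") != "crowgaze-visual-field-model":
            raise InvalidInputError("not a crowgaze visual-field model file")
        return cls(
            phi_deg=np.array(p["phi_deg"], dtype=float),
            right_boundary_deg=np.array(p["right_boundary_deg"], dtype=float),
            left_boundary_deg=np.array(p["left_boundary_deg"], dtype=float),
            right_fill=np.array(p["right_fill"], dtype=bool),
            left_fill=np.array(p["left_fill"], dtype=bool),
            optical_axis_right=Direction(*p["optical_axis_right"]),
            optical_axis_left=Direction(*p["optical_axis_left"]),
            beak_projection=Direction(*p["beak_projection"]),
            pecten_right=(
                None if p["pecten_right"] is None else np.array(p["pecten_right"], float)
            ),
            pecten_left=(
                None if p["pecten_left"] is None else np.array(p["pecten_left"], float)
            ),
            meta=p.get("meta", {}),
        )


def build_field_model(
    boundaries: pd.DataFrame,
    optical_axes: dict[str, Direction],
    pecten_boundaries: dict[str, np.ndarray] | None = None,
    beak_elevation_measured: float = -10.0,
    beak_elevation_target: float = -10.0,
    meta: dict | None = None,
) -> VisualFieldModel:
    """Assemble a :class:`VisualFieldModel` from representative boundaries.

    Parameters
    ----------
    boundaries
        DataFrame with columns ``eye`` ('left'/'right'), ``arm_elevation_deg``
        and ``boundary_azimuth_deg`` (representative, midline-crossing
        signed, viewpoint correction already applied if desired).  One row
        per eye and elevation; elevations missing for one eye are filled by
        periodic linear interpolation and flagged.
    optical_axes
        ``{'left': Direction, 'right': Direction}``.
    pecten_boundaries
        Optional per-eye arrays of ``(phi, u_min, u_max)`` rows.
    beak_elevation_measured
        Arm elevation at which the eye--beak-tip line pointed during the
        measurements.  The whole grid is pitched so that the beak projects to
        ``beak_elevation_target`` (the natural-posture calibration); a pitch
        about the inter-eye axis is an exact shift of ``phi``.
    """
    required = {"eye", "arm_elevation_deg", "boundary_azimuth_deg"}
    if not required.issubset(boundaries.columns):
        raise InvalidInputError(f"boundaries table needs columns {sorted(required)}")

    shift = float(beak_elevation_target) - float(beak_elevation_measured)
    grid = np.unique(boundaries["arm_elevation_deg"].to_numpy(dtype=float))
    per_eye: dict[str, np.ndarray] = {}
    fills: dict[str, np.ndarray] = {}
    for eye in ("right", "left"):
        sub = boundaries[boundaries["eye"] == eye]
        if sub["arm_elevation_deg"].nunique() < 2:
            raise InsufficientDataError(f"need >= 2 elevations for the {eye} eye")
        if sub["arm_elevation_deg"].duplicated().any():
            raise InvalidInputError(
                f"contradictory duplicate boundaries for the {eye} eye; "
                "summarize replicates first"
            )
        have = sub["arm_elevation_deg"].to_numpy(dtype=float)
        vals = sub["boundary_azimuth_deg"].to_numpy(dtype=float)
        order = np.argsort(have)
        have, vals = have[order], vals[order]
        # periodic linear interpolation onto the union grid; mark fills
        xp = np.concatenate(([have[-1] - 360.0], have, [have[0] + 360.0]))
        fp = np.concatenate(([vals[-1]], vals, [vals[0]]))
        per_eye[eye] = np.interp(grid, xp, fp)
        fills[eye] = ~np.isin(grid, have)

    model = VisualFieldModel(
        phi_deg=grid + shift,
        right_boundary_deg=per_eye["right"],
        left_boundary_deg=per_eye["left"],
        right_fill=fills["right"],
        left_fill=fills["left"],
        optical_axis_right=optical_axes["right"],
        optical_axis_left=optical_axes["left"],
        beak_projection=Direction(0.0, float(beak_elevation_target)),
        pecten_right=None
        if pecten_boundaries is None
        else _shift_pecten(pecten_boundaries.get("right"), shift),
        pecten_left=None
        if pecten_boundaries is None
        else _shift_pecten(pecten_boundaries.get("left"), shift),
        meta=dict(meta or {}),
    )
    model.meta.setdefault("calibration_shift_deg", shift)
    return model


def _shift_pecten(p: np.ndarray | None, shift: float) -> np.ndarray | None:
    if p is None:
        return None
    p = np.asarray(p, dtype=float).copy()
    p[:, 0] += shift
    return p


# ---------------------------------------------------------------------------
# classification


def _pecten_mask(
    pecten: np.ndarray | None, phi: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """True where (phi, u) lies inside the pecten wedge band."""
    if pecten is None or len(pecten) == 0:
        return np.zeros(phi.shape, dtype=bool)
    lo = np.interp(phi, pecten[:, 0], pecten[:, 1], left=np.inf, right=np.inf)
    hi = np.interp(phi, pecten[:, 0], pecten[:, 2], left=-np.inf, right=-np.inf)
    return (u >= lo) & (u <= hi)


def classify_directions(
    model: VisualFieldModel,
    azimuth_deg: np.ndarray,
    elevation_deg: np.ndarray,
    include_pecten: bool = False,
) -> np.ndarray:
    """Region label for each direction (vectorized).

    Every direction maps to exactly one label; ties on a boundary classify
    binocular.  NaN input yields the empty label ''.
    """
    az = np.asarray(azimuth_deg, dtype=float)
    el = np.asarray(elevation_deg, dtype=float)
    v = vectors_from_directions(az, el)
    phi, s = arm_coordinates(v)
    valid = np.isfinite(phi) & np.isfinite(s)
    bR, bL = model.boundaries_at(np.where(valid, phi, 0.0))

    out = np.full(az.shape, "", dtype=object)
    anterior = np.abs(az) <= 90.0

    seen_right = s >= -bR
    seen_left = s <= bL
    bino = seen_right & seen_left
    right_only = seen_right & ~seen_left
    left_only = seen_left & ~seen_right
    blind = ~seen_right & ~seen_left

    out[valid & bino] = "binocular"
    out[valid & right_only & anterior] = "right_monocular_anterior"
    out[valid & right_only & ~anterior] = "right_monocular_posterior"
    out[valid & left_only & anterior] = "left_monocular_anterior"
    out[valid & left_only & ~anterior] = "left_monocular_posterior"
    out[valid & blind] = "blind"

    if include_pecten:
        pr = _pecten_mask(model.pecten_right, phi, s)
        pl = _pecten_mask(model.pecten_left, phi, -s)
        out[valid & (pr | pl)] = "pecten"
    return out


def classify_direction(
    model: VisualFieldModel, d: Direction, include_pecten: bool = False
) -> str:
    """Region label of a single direction."""
    lab = classify_directions(
        model, np.asarray([d.azimuth]), np.asarray([d.elevation]), include_pecten
    )
    return str(lab[0])


# ---------------------------------------------------------------------------
# areas, metrics, chance levels


def region_areas(
    model: VisualFieldModel,
    weighting: str = "solid_angle",
    phi_step_deg: float = 0.02,
) -> dict[str, float]:
    """Region areas (steradians, or square degrees in 'map' mode).

    In arm coordinates the area of an arc ``s in [lo, hi]`` at elevation
    ``phi`` is ``(sin hi - sin lo) dphi`` on the sphere, or ``(hi - lo)
    dphi`` on the unweighted equirectangular map; regions therefore reduce
    to 1-D integrals over ``phi`` of the piecewise-linear boundaries,
    evaluated here on a fine grid.
    """
    if weighting not in ("solid_angle", "map"):
        raise InvalidInputError("weighting must be 'solid_angle' or 'map'")
    phi = np.arange(-90.0, 270.0, phi_step_deg) + phi_step_deg / 2.0
    bR, bL = model.boundaries_at(phi)

    if weighting == "solid_angle":
        g = lambda x: np.sin(np.radians(x))  # noqa: E731
        dphi = np.radians(phi_step_deg)
    else:
        g = lambda x: np.asarray(x, dtype=float)  # noqa: E731
        dphi = phi_step_deg

    anterior = np.abs(phi) <= 90.0
    top, bottom = g(90.0), g(-90.0)

    bino = np.clip(g(bL) - g(-bR), 0.0, None) * dphi
    right_only = (top - g(np.maximum(bL, -bR))) * dphi
    left_only = (g(np.minimum(bL, -bR)) - bottom) * dphi
    blind = np.clip(g(-bR) - g(bL), 0.0, None) * dphi

    areas = {
        "binocular": float(bino.sum()),
        "right_monocular_anterior": float(right_only[anterior].sum()),
        "right_monocular_posterior": float(right_only[~anterior].sum()),
        "left_monocular_anterior": float(left_only[anterior].sum()),
        "left_monocular_posterior": float(left_only[~anterior].sum()),
        "blind": float(blind.sum()),
    }
    return areas


def field_metrics(model: VisualFieldModel) -> dict[str, float]:
    """Maximum binocular and blind widths over the elevation grid."""
    width = model.right_boundary_deg + model.left_boundary_deg
    bino = np.clip(width, 0.0, None)
    blind = np.clip(-width, 0.0, None)
    i_b = int(np.argmax(bino))
    i_d = int(np.argmax(blind))
    out = {
        "max_binocular_width_deg": float(bino[i_b]),
        "max_binocular_width_elevation_deg": float(model.phi_deg[i_b]),
        "max_blind_width_deg": float(blind[i_d]),
        "max_blind_width_elevation_deg": float(model.phi_deg[i_d]),
    }
    for key in ("right_boundary_span_deg", "left_boundary_span_deg"):
        if key in model.meta:
            out[key] = float(model.meta[key])
    return out


def chance_levels(
    model: VisualFieldModel, weighting: str = "solid_angle"
) -> dict[str, float]:
    """Differential-looking-score chance levels under random viewing.

    ``binocular_use_chance = (A_b - A_n)/(A_b + A_n)`` with ``A_b`` the
    binocular area and ``A_n`` the non-binocular anterior area;
    ``laterality_chance`` is the analogous right/left contrast within the
    non-binocular anterior field.
    """
    a = region_areas(model, weighting=weighting)
    A_b = a["binocular"]
    A_nR = a["right_monocular_anterior"]
    A_nL = a["left_monocular_anterior"]
    A_n = A_nR + A_nL
    if A_b + A_n == 0:
        raise UndefinedScoreError("binocular and anterior monocular areas are all zero")
    if A_nR + A_nL == 0:
        raise UndefinedScoreError("non-binocular anterior area is zero")
    return {
        "binocular_use_chance": (A_b - A_n) / (A_b + A_n),
        "laterality_chance": (A_nR - A_nL) / (A_nR + A_nL),
    }


def mirror_symmetrize(model: VisualFieldModel) -> VisualFieldModel:
    """Left-right mirror-symmetric version (mean of the two eyes)."""
    mean_b = (model.right_boundary_deg + model.left_boundary_deg) / 2.0
    az = (model.optical_axis_right.azimuth - model.optical_axis_left.azimuth) / 2.0
    el = (model.optical_axis_right.elevation + model.optical_axis_left.elevation) / 2.0
    pect = None
    if model.pecten_right is not None and model.pecten_left is not None:
        pect = (model.pecten_right + model.pecten_left) / 2.0
    m = model.copy()
    m.right_boundary_deg = mean_b.copy()
    m.left_boundary_deg = mean_b.copy()
    m.right_fill = model.right_fill | model.left_fill
    m.left_fill = m.right_fill.copy()
    m.optical_axis_right = Direction(az, el)
    m.optical_axis_left = Direction(-az, el)
    m.pecten_right = pect
    m.pecten_left = None if pect is None else pect.copy()
    m.meta["symmetrized"] = True
    return m


# ---------------------------------------------------------------------------
# tabular input and the full perimetry -> model pipeline


def read_perimetry(path) -> pd.DataFrame:
    """Read a perimetry table (CSV with a header row)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PERIMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"perimetry table missing columns {missing}")
    return df


def read_optical_axes(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in AXIS_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"optical-axis table missing columns {missing}")
    return df


def field_model_from_perimetry(
    perimetry: pd.DataFrame,
    optical_axes: pd.DataFrame,
    condition: str = "rest",
    strategy: str = "max_extent",
    viewpoint: dict | None = None,
    beak_elevation_measured: float = -10.0,
    subject: str | None = None,
) -> VisualFieldModel:
    """Raw perimetry records -> representative boundaries -> field model.

    ``viewpoint``, if given, is ``{'internodal_distance_mm': d,
    'perimeter_radius_mm': R}`` and applies the nodal-point correction to
    every representative boundary.
    """
    df = perimetry[perimetry["condition"] == condition]
    if subject is not None:
        df = df[df["subject"] == subject]
    df = df[df["landmark"] == "retina_edge"]
    if df.empty:
        raise MissingDataError("no retina-edge records for the requested condition")

    rows = []
    spans: dict[str, list[float]] = {"left": [], "right": []}
    for (eye, elev), grp in df.groupby(["eye", "arm_elevation_deg"]):
        summ = summarize_boundaries(grp["boundary_azimuth_deg"], strategy=strategy)
        rep = summ.representative
        if viewpoint is not None:
            rep = correct_viewpoint(
                rep,
                viewpoint["internodal_distance_mm"],
                viewpoint["perimeter_radius_mm"],
                eye=eye,
            )
        rows.append(
            {"eye": eye, "arm_elevation_deg": float(elev), "boundary_azimuth_deg": rep}
        )
        if summ.n > 1:
            spans[eye].append(summ.span)
    boundaries = pd.DataFrame(rows)

    axes = {}
    for eye in ("left", "right"):
        sub = optical_axes[optical_axes["eye"] == eye]
        if subject is not None:
            sub = sub[sub["subject"] == subject]
        axes[eye] = estimate_optical_axis(sub)

    pecten = _pecten_from_records(perimetry, condition, subject)
    meta = {}
    for eye in ("left", "right"):
        if spans[eye]:
            meta[f"{eye}_boundary_span_deg"] = float(np.max(spans[eye]))
    return build_field_model(
        boundaries,
        axes,
        pecten_boundaries=pecten,
        beak_elevation_measured=beak_elevation_measured,
        meta=meta,
    )


def _pecten_from_records(
    perimetry: pd.DataFrame, condition: str, subject: str | None
) -> dict[str, np.ndarray] | None:
    df = perimetry[
        (perimetry["condition"] == condition) & (perimetry["landmark"] == "pecten_edge")
    ]
    if subject is not None:
        df = df[df["subject"] == subject]
    if df.empty:
        return None
    out: dict[str, np.ndarray] = {}
    for eye, grp in df.groupby("eye"):
        rows = []
        for elev, g in grp.groupby("arm_elevation_deg"):
            ant = g[g["boundary_kind"] == "anterior"]["boundary_azimuth_deg"]
            post = g[g["boundary_kind"] == "posterior"]["boundary_azimuth_deg"]
            if ant.empty or post.empty:
                continue
            # pecten bands stored in the eye's own (pole-ward) azimuth; the
            # records carry crossing-signed azimuths, so negate
            u1, u2 = -float(ant.iloc[0]), -float(post.iloc[0])
            rows.append([float(elev), min(u1, u2), max(u1, u2)])
        if rows:
            arr = np.array(sorted(rows), dtype=float)
            out[eye] = arr
    return out or None
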