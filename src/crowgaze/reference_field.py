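"""Synthetic digitization of the published mean crow visual field.

The mean visual-field figure of the source study is available only as an
image, so this module packages a *synthetic* reconstruction of its boundary
curves: a piecewise-linear boundary profile on the 10-degree perimetry grid
(pitched by -3.6 degrees by the head calibration, so the printed peak
elevations 16.4 and 176.4 lie on grid points), constrained by every printed
anchor value:

* maximum binocular width 48.4 deg at elevation 16.4 deg,
* maximum blind-area width 17.1 deg at elevation 176.4 deg (the nearest
  calibrated grid point to the reported 176.3),
* optical axes at (62.7, -32.9) right and (-59.4, -33.8) left,
* beak projection at (0, -10) after head calibration,
* area-derived binocular-use chance level -0.42 (solid angle).

The profile between those anchors is under-determined by the printed text;
it was drawn once with a plausible corvid field shape and its lower anterior
shoulder solved analytically so that the solid-angle areas reproduce the
printed chance level.  The small fixed left/right asymmetry (+-0.3 deg)
keeps the per-elevation widths unchanged while making the model realistically
non-mirror-symmetric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import Direction
from .visual_field import (
    VisualFieldModel,
    build_field_model,
    field_model_from_perimetry,
)

__all__ = [
    "REFERENCE_PHI_DEG",
    "REFERENCE_HALF_WIDTH_DEG",
    "reference_boundaries",
    "reference_field_model",
    "reference_perimetry_tables",
]

# Calibrated arm-elevation grid (deg): the 10-deg measurement grid after the
# -3.6 deg head-calibration pitch.
REFERENCE_PHI_DEG = np.round(np.arange(-83.6, 266.5, 10.0), 6)

# Mean per-eye boundary azimuth (deg, signed toward midline crossing) at each
# grid elevation.  Positive values: the eyes' fields overlap (binocular width
# = twice the value); negative values: a blind wedge (width = twice the
# magnitude).  SHOULDER entries were solved so the solid-angle chance level
# of the binocular use score equals -0.42 (see module docstring).
_SHOULDER = 10.048215000779997  # solved lower-anterior shoulder value (deg)
REFERENCE_HALF_WIDTH_DEG = np.array(
    [
        -1.0,  # -83.6  (narrow blind sliver below the bill)
        -0.5,  # -73.6
        0.0,  # -63.6
        _SHOULDER,  # -53.6
        _SHOULDER + 5.0,  # -43.6
        _SHOULDER + 8.0,  # -33.6
        21.0,  # -23.6
        22.0,  # -13.6
        23.2,  # -3.6
        24.0,  # 6.4
        24.2,  # 16.4   <- peak: binocular width 48.4
        23.8,  # 26.4
        23.0,  # 36.4
        22.0,  # 46.4
        20.5,  # 56.4
        18.5,  # 66.4
        16.0,  # 76.4
        14.0,  # 86.4
        9.0,  # 96.4
        5.0,  # 106.4
        1.0,  # 116.4
        -2.5,  # 126.4
        -4.5,  # 136.4
        -6.0,  # 146.4
        -7.0,  # 156.4
        -8.0,  # 166.4
        -8.55,  # 176.4  <- peak: blind width 17.1
        -8.0,  # 186.4
        -7.0,  # 196.4
        -6.0,  # 206.4
        -4.5,  # 216.4
        -2.5,  # 226.4
        -1.0,  # 236.4
        -0.5,  # 246.4
        -0.8,  # 256.4
        -1.0,  # 266.4
    ]
)

# Fixed small left/right asymmetry (deg): per-elevation widths are preserved.
_ASYMMETRY = 0.3

OPTICAL_AXIS_RIGHT = Direction(62.7, -32.9)
OPTICAL_AXIS_LEFT = Direction(-59.4, -33.8)

# Illustrative pecten wedges, (phi, u_min, u_max) in each eye's own arm
# azimuth; excluded from scoring analyses by default.
_PECTEN = np.array(
    [
        [96.4, 50.0, 56.0],
        [106.4, 46.0, 60.0],
        [116.4, 45.0, 61.0],
        [126.4, 47.0, 59.0],
        [136.4, 51.0, 55.0],
    ]
)


def reference_boundaries() -> pd.DataFrame:
    """Representative per-eye boundaries on the calibrated grid."""
    rows = []
    for eye, sign in (("right", -1.0), ("left", +1.0)):
        b = REFERENCE_HALF_WIDTH_DEG + sign * _ASYMMETRY
        for phi, val in zip(REFERENCE_PHI_DEG, b):
            rows.append(
                {
                    "eye": eye,
                    "arm_elevation_deg": float(phi),
                    "boundary_azimuth_deg": float(val),
                }
            )
    return pd.DataFrame(rows)


def reference_field_model() -> VisualFieldModel:
    """The packaged mean visual-field model (already head-calibrated)."""
    model = build_field_model(
        reference_boundaries(),
        {"right": OPTICAL_AXIS_RIGHT, "left": OPTICAL_AXIS_LEFT},
        pecten_boundaries={"right": _PECTEN.copy(), "left": _PECTEN.copy()},
        beak_elevation_measured=-10.0,
    )
    model.meta["source"] = "synthetic digitization of the published mean crow field"
    return model


def reference_perimetry_tables(
    subject: str = "mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The fixture as external-dialect perimetry and optical-axis tables.

    Boundary rows carry the representative (already summarized and
    viewpoint-referenced) values; feeding them through
    :func:`crowgaze.visual_field.field_model_from_perimetry` with the default
    max-extent strategy reproduces :func:`reference_field_model` exactly.
    """
    rows = []
    bdf = reference_boundaries()
    for _, r in bdf.iterrows():
        kind = "anterior" if -90.0 <= r["arm_elevation_deg"] <= 90.0 else "posterior"
        rows.append(
            {
                "subject": subject,
                "eye": r["eye"],
                "condition": "rest",
                "landmark": "retina_edge",
                "arm_elevation_deg": r["arm_elevation_deg"],
                "boundary_azimuth_deg": r["boundary_azimuth_deg"],
                "boundary_kind": kind,
            }
        )
    for eye, sign in (("right", -1.0), ("left", +1.0)):
        for phi, umin, umax in _PECTEN:
            for kind, u in (("anterior", umin), ("posterior", umax)):
                rows.append(
                    {
                        "subject": subject,
                        "eye": eye,
                        "condition": "rest",
                        "landmark": "pecten_edge",
                        "arm_elevation_deg": float(phi),
                        "boundary_azimuth_deg": -float(u),
                        "boundary_kind": kind,
                    }
                )
    perimetry = pd.DataFrame(rows)

    axis_rows = []
    for eye, axis in (("right", OPTICAL_AXIS_RIGHT), ("left", OPTICAL_AXIS_LEFT)):
        for k in range(9):
            axis_rows.append(
                {
                    "subject": subject,
                    "eye": eye,
                    "azimuth_deg": axis.azimuth,
                    "elevation_deg": axis.elevation,
                    "replicate": k + 1,
                }
            )
    axes = pd.DataFrame(axis_rows)
    return perimetry, axes


def reference_model_from_tables(subject: str = "mean") -> VisualFieldModel:
    """Round-trip convenience: fixture tables -> pipeline -> model."""
    perimetry, axes = reference_perimetry_tables(subject)
    return field_model_from_perimetry(perimetry, axes, condition="rest", subject=subject)
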