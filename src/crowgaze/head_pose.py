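"""Head calibration and rigid head-pose estimation.

Workflow: 2-D annotations of morphological key points (eye centres, beak
tip, the corners of a 30 mm triangular scale, and the reflective markers) in
two or more calibrated views are reconstructed to 3-D by classical two-view
relative orientation (eight-point essential matrix), incremental camera
resection and multi-view triangulation, refined by reprojection least
squares, and scaled with the triangle.  The head-centric frame is defined
from the eyes and beak tip (x toward the right eye, y toward the beak tip,
z up), pitched so the eye--beak-tip line projects to elevation -10 deg (the
natural perching posture).  Marker positions expressed in that frame form
the rigid-body template; per-frame head pose is the proper-rotation
orthogonal superposition (Kabsch) of the observed markers onto the template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import RigidPose, direction_from_vector, rot_x

__all__ = [
    "CameraView",
    "KeyPoints3D",
    "HeadFrame",
    "MarkerTemplate",
    "ReconstructionError",
    "reconstruct_keypoints",
    "define_head_frame",
    "estimate_head_pose",
    "kabsch",
]

KEYPOINT_LABELS = ("left_eye", "right_eye", "beak_tip")
SCALE_LABELS = ("scale_1", "scale_2", "scale_3")


class ReconstructionError(RuntimeError):
    """Raised when the multi-view geometry is degenerate or inconsistent."""


@dataclass
class CameraView:
    """One annotated view: intrinsics plus 2-D pixel annotations."""

    intrinsics: np.ndarray  # 3x3 camera matrix
    annotations: Mapping[str, tuple[float, float]]
    distortion: Sequence[float] = ()  # radial k1, k2

    def __post_init__(self) -> None:
        self.intrinsics = np.asarray(self.intrinsics, dtype=float)
        if self.intrinsics.shape != (3, 3):
            raise ValueError("intrinsics must be a 3x3 camera matrix")
        self.annotations = dict(self.annotations)

    def normalized(self, labels: Sequence[str]) -> np.ndarray:
        """Undistorted normalized image coordinates (n, 2) for ``labels``."""
        K = self.intrinsics
        pts = np.array([self.annotations[l] for l in labels], dtype=float)
        x = (pts[:, 0] - K[0, 2]) / K[0, 0]
        y = (pts[:, 1] - K[1, 2]) / K[1, 1]
        xy = np.stack([x, y], axis=1)
        if any(k != 0 for k in self.distortion):
            xy = _undistort(xy, self.distortion)
        return xy


def _undistort(xy: np.ndarray, dist: Sequence[float], iters: int = 20) -> np.ndarray:
    k1 = dist[0] if len(dist) > 0 else 0.0
    k2 = dist[1] if len(dist) > 1 else 0.0
    und = xy.copy()
    for _ in range(iters):
        r2 = np.sum(und**2, axis=1, keepdims=True)
        factor = 1.0 + k1 * r2 + k2 * r2**2
        und = xy / factor
    return und


@dataclass
class KeyPoints3D:
    """Reconstructed metric key points (mm) plus reconstruction diagnostics."""

    left_eye: np.ndarray
    right_eye: np.ndarray
    beak_tip: np.ndarray
    markers: dict[str, np.ndarray]
    scale_residual_mm: float
    reprojection_rms_px: float

    @property
    def inter_eye_distance(self) -> float:
        return float(np.linalg.norm(self.right_eye - self.left_eye))


@dataclass
class HeadFrame:
    """Calibrated head-centric frame: origin + rotation (frame -> world)."""

    origin: np.ndarray
    rotation: np.ndarray  # columns are the x, y, z axes in world coordinates


@dataclass
class MarkerTemplate:
    """Marker positions expressed in the calibrated head frame (mm)."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (k, 3)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.labels = tuple(self.labels)
        k = len(self.labels)
        if self.positions.shape != (k, 3):
            raise ValueError("positions must be (n_markers, 3)")
        if k < 3:
            raise ValueError("a rigid-body template needs at least 3 markers")
        if _collinear(self.positions):
            raise ValueError("template markers are collinear")

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "positions": self.positions.tolist(),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerTemplate":
        return cls(tuple(d["labels"]), np.array(d["positions"], float), d.get("meta", {}))


def _collinear(p: np.ndarray, tol: float = 1e-9) -> bool:
    c = p - p.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


# ---------------------------------------------------------------------------
# multi-view reconstruction


def _triangulate(points_nx2: list[np.ndarray], poses: list[np.ndarray]) -> np.ndarray:
    """DLT triangulation of one point from >= 2 views (normalized coords)."""
    rows = []
    for (x, y), P in zip(points_nx2, poses):
        rows.append(x * P[2] - P[0])
        rows.append(y * P[2] - P[1])
    A = np.asarray(rows)
    _, _, vt = np.linalg.svd(A)
    X = vt[-1]
    if abs(X[3]) < 1e-12:
        raise ReconstructionError("triangulated point at infinity")
    return X[:3] / X[3]


def _essential_eight_point(x0: np.ndarray, x1: np.ndarray) -> np.ndarray:
    """Essential matrix from >= 8 normalized correspondences (x1' E x0 = 0)."""
    n = len(x0)
    h0 = np.column_stack([x0, np.ones(n)])
    h1 = np.column_stack([x1, np.ones(n)])
    A = np.einsum("ni,nj->nij", h1, h0).reshape(n, 9)
    _, _, vt = np.linalg.svd(A)
    E = vt[-1].reshape(3, 3)
    U, s, Vt = np.linalg.svd(E)
    sig = (s[0] + s[1]) / 2.0
    return U @ np.diag([sig, sig, 0.0]) @ Vt


def _decompose_essential(
    E: np.ndarray, x0: np.ndarray, x1: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the (R, t) decomposition with maximal cheirality support."""
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    t = U[:, 2]
    best, best_count = None, -1
    P0 = np.hstack([np.eye(3), np.zeros((3, 1))])
    for R in (U @ W @ Vt, U @ W.T @ Vt):
        for tt in (t, -t):
            P1 = np.hstack([R, tt.reshape(3, 1)])
            count = 0
            for a, b in zip(x0, x1):
                try:
                    X = _triangulate([a, b], [P0, P1])
                except ReconstructionError:
                    continue
                z0 = X[2]
                z1 = (R @ X + tt)[2]
                if z0 > 0 and z1 > 0:
                    count += 1
            if count > best_count:
                best, best_count = (R, tt), count
    if best is None or best_count == 0:
        raise ReconstructionError("no essential-matrix decomposition passes cheirality")
    return best


def _register_view(
    x0: np.ndarray, xk: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pose of an extra view from two-view geometry against the first view.

    The essential matrix fixes the view's rotation and translation direction;
    the translation magnitude is recovered by matching the pairwise
    triangulation to the existing reconstruction ``X`` (both share the
    first camera's frame, so they differ by a pure scale).
    """
    E = _essential_eight_point(x0, xk)
    R, t_dir = _decompose_essential(E, x0, xk)
    P0 = np.hstack([np.eye(3), np.zeros((3, 1))])
    Pk = np.hstack([R, t_dir.reshape(3, 1)])
    Xk = np.array([_triangulate([a, b], [P0, Pk]) for a, b in zip(x0, xk)])
    norms_k = np.linalg.norm(Xk, axis=1)
    norms = np.linalg.norm(X, axis=1)
    good = norms_k > 1e-9
    if not good.any():
        raise ReconstructionError("degenerate registration (points at the origin)")
    scale = float(np.median(norms[good] / norms_k[good]))
    return _refine_pose_pnp(xk, X, R, t_dir * scale)


def _refine_pose_pnp(
    x: np.ndarray, X: np.ndarray, R0: np.ndarray, t0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nonlinear single-view pose polish (points held fixed)."""

    def residuals(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        proj = X @ R.T + p[3:]
        return (proj[:, :2] / proj[:, 2:3] - x).ravel()

    p0 = np.concatenate([Rotation.from_matrix(R0).as_rotvec(), t0])
    sol = least_squares(
        residuals, p0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=120
    )
    return Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:]


def _refine(
    poses: list[np.ndarray],
    X: np.ndarray,
    obs: list[np.ndarray],
    alt_iter: int = 5,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Two-stage refinement; view 0 fixed to pin the gauge.

    A few rounds of resection--intersection (single-view pose polish plus
    linear multi-view retriangulation) pull the initialization close, then a
    joint reprojection least squares over all free cameras and points
    finishes the job.  The Jacobian sparsity (each residual touches one
    camera and one point) keeps the numeric differentiation cheap.
    """
    from scipy.sparse import lil_matrix

    poses = [p.copy() for p in poses]
    for _ in range(alt_iter):
        X = np.array(
            [_triangulate([o[i] for o in obs], poses) for i in range(len(X))]
        )
        for v in range(1, len(poses)):
            R, t = _refine_pose_pnp(obs[v], X, poses[v][:, :3], poses[v][:, 3])
            poses[v] = np.hstack([R, t.reshape(3, 1)])

    n_views = len(poses)
    n_pts = len(X)
    n_cam_par = 6 * (n_views - 1)
    x0 = np.concatenate(
        [Rotation.from_matrix(P[:, :3]).as_rotvec() for P in poses[1:]]
        + [P[:, 3] for P in poses[1:]]
        + [X.ravel()]
    )

    def unpack(p):
        rv = p[: 3 * (n_views - 1)].reshape(-1, 3)
        tv = p[3 * (n_views - 1) : n_cam_par].reshape(-1, 3)
        cams = [np.hstack([np.eye(3), np.zeros((3, 1))])]
        for r, t in zip(rv, tv):
            cams.append(np.hstack([Rotation.from_rotvec(r).as_matrix(), t.reshape(3, 1)]))
        return cams, p[n_cam_par:].reshape(n_pts, 3)

    def residuals(p):
        cams, pts = unpack(p)
        return np.concatenate(
            [
                ((pts @ c[:, :3].T + c[:, 3])[:, :2]
                 / (pts @ c[:, :3].T + c[:, 3])[:, 2:3] - xy).ravel()
                for c, xy in zip(cams, obs)
            ]
        )

    sparsity = lil_matrix((2 * n_pts * n_views, n_cam_par + 3 * n_pts), dtype=int)
    for v in range(n_views):
        for i in range(n_pts):
            rows = slice(2 * (v * n_pts + i), 2 * (v * n_pts + i) + 2)
            if v > 0:
                sparsity[rows, 3 * (v - 1) : 3 * v] = 1
                sparsity[rows, 3 * (n_views - 1) + 3 * (v - 1) : 3 * (n_views - 1) + 3 * v] = 1
            sparsity[rows, n_cam_par + 3 * i : n_cam_par + 3 * i + 3] = 1

    sol = least_squares(
        residuals, x0, method="trf", jac_sparsity=sparsity,
        xtol=1e-14, ftol=1e-14, max_nfev=60,
    )
    cams, pts = unpack(sol.x)
    return cams, pts


def _initialize_and_refine(
    obs: list[np.ndarray], seed_view: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Initial pair (0, seed_view) -> registration of the rest -> joint LM."""
    E = _essential_eight_point(obs[0], obs[seed_view])
    Rs, ts = _decompose_essential(E, obs[0], obs[seed_view])
    pair = [
        np.hstack([np.eye(3), np.zeros((3, 1))]),
        np.hstack([Rs, ts.reshape(3, 1)]),
    ]
    X = np.array(
        [_triangulate([a, b], pair) for a, b in zip(obs[0], obs[seed_view])]
    )
    poses = [pair[0]]
    for v_idx in range(1, len(obs)):
        if v_idx == seed_view:
            poses.append(pair[1])
            continue
        R, t = _register_view(obs[0], obs[v_idx], X)
        poses.append(np.hstack([R, t.reshape(3, 1)]))
    poses, X = _refine(poses, X, obs)
    for cam in poses:
        depth = X @ cam[2, :3] + cam[2, 3]
        if np.any(depth <= 0):
            raise ReconstructionError("points behind a camera after refinement")
    return poses, X


def _reprojection_rms(
    poses: list[np.ndarray], X: np.ndarray, obs: list[np.ndarray]
) -> float:
    sq = []
    for cam, xy in zip(poses, obs):
        proj = X @ cam[:, :3].T + cam[:, 3]
        sq.append(((proj[:, :2] / proj[:, 2:3] - xy) ** 2).ravel())
    return float(np.sqrt(np.mean(np.concatenate(sq))))


def reconstruct_keypoints(
    views: Sequence[CameraView], scale_edge_mm: float = 30.0
) -> KeyPoints3D:
    """Metric 3-D key points from annotated calibrated views.

    Requires >= 2 views sharing >= 8 annotated points (including the three
    scale-triangle corners).  The reconstruction is expressed in the first
    camera's frame (gauge choice); the triangle fixes the global scale and
    its worst edge-length error after scaling is reported as
    ``scale_residual_mm``.
    """
    if len(views) < 2:
        raise ReconstructionError("need at least two views")
    labels = [l for l in views[0].annotations if all(l in v.annotations for v in views)]
    if len(labels) < 8:
        raise ReconstructionError(
            f"only {len(labels)} shared annotations; the eight-point algorithm "
            "needs at least 8"
        )
    for lab in KEYPOINT_LABELS + SCALE_LABELS:
        if lab not in labels:
            raise ReconstructionError(f"required key point {lab!r} not shared by all views")

    obs_all = [v.normalized(labels) for v in views]

    # Near-planar scenes make two-view initialization fragile (the classic
    # planar twofold ambiguity), so every ordered view pair is tried as the
    # initial pair and the refined solution with the smallest reprojection
    # error (and positive depths) wins; the spurious basin has a clearly
    # larger residual.
    best: tuple[float, list[np.ndarray], np.ndarray, list[int]] | None = None
    errors: list[str] = []
    n_views = len(views)
    for ref in range(n_views):
        order = [ref] + [k for k in range(n_views) if k != ref]
        obs = [obs_all[k] for k in order]
        for seed_view in range(1, n_views):
            try:
                poses, X = _initialize_and_refine(obs, seed_view)
            except (ReconstructionError, np.linalg.LinAlgError) as exc:
                errors.append(f"pair ({ref},{order[seed_view]}): {exc}")
                continue
            rms = _reprojection_rms(poses, X, obs)
            if best is None or rms < best[0]:
                best = (rms, poses, X, order)
    if best is None:
        raise ReconstructionError("no valid initialization; " + "; ".join(errors))
    _, poses_ordered, X, order = best
    # express the result in the first annotated view's camera frame and
    # restore the pose list to input order
    back = {v: i for i, v in enumerate(order)}
    cam0 = poses_ordered[back[0]]
    X = X @ cam0[:, :3].T + cam0[:, 3]
    inv0_R = cam0[:, :3].T
    poses = []
    for v_idx in range(n_views):
        cam = poses_ordered[back[v_idx]]
        R_new = cam[:, :3] @ inv0_R
        t_new = cam[:, 3] - R_new @ cam0[:, 3]
        poses.append(np.hstack([R_new, t_new.reshape(3, 1)]))
    obs = obs_all

    idx = {l: i for i, l in enumerate(labels)}
    tri = X[[idx[l] for l in SCALE_LABELS]]
    edges = np.array(
        [
            np.linalg.norm(tri[0] - tri[1]),
            np.linalg.norm(tri[1] - tri[2]),
            np.linalg.norm(tri[2] - tri[0]),
        ]
    )
    if edges.mean() <= 0:
        raise ReconstructionError("degenerate scale triangle")
    factor = scale_edge_mm / edges.mean()
    X = X * factor
    scale_residual = float(np.max(np.abs(edges * factor - scale_edge_mm)))

    # reprojection rms in pixels (using each view's focal lengths)
    sq = []
    for view, cam, xy in zip(views, poses, obs):
        proj = (X / factor) @ cam[:, :3].T + cam[:, 3]
        err = proj[:, :2] / proj[:, 2:3] - xy
        f = np.array([view.intrinsics[0, 0], view.intrinsics[1, 1]])
        sq.append((err * f) ** 2)
    rms = float(np.sqrt(np.mean(np.concatenate(sq))))

    markers = {
        l: X[idx[l]] for l in labels if l not in KEYPOINT_LABELS + SCALE_LABELS
    }
    return KeyPoints3D(
        left_eye=X[idx["left_eye"]],
        right_eye=X[idx["right_eye"]],
        beak_tip=X[idx["beak_tip"]],
        markers=markers,
        scale_residual_mm=scale_residual,
        reprojection_rms_px=rms,
    )


# ---------------------------------------------------------------------------
# head frame and template


def define_head_frame(
    kp: KeyPoints3D, pitch_offset_deg: float = -10.0
) -> tuple[HeadFrame, MarkerTemplate]:
    """Calibrated head frame and marker template from the key points.

    The raw frame has x toward the right eye, y toward the beak tip and
    z = x cross y; it is then pitched about x so the beak tip projects to
    elevation ``pitch_offset_deg`` (azimuth stays 0): the y axis of the
    calibrated frame points at the horizon in natural posture.
    """
    origin = (kp.left_eye + kp.right_eye) / 2.0
    x = kp.right_eye - origin
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError("eyes are coincident")
    x = x / nx
    yraw = kp.beak_tip - origin
    y = yraw - np.dot(yraw, x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise ValueError("beak tip lies on the inter-eye line (degenerate frame)")
    y = y / ny
    z = np.cross(x, y)
    R0 = np.column_stack([x, y, z])
    # pitch the frame about x so the beak tip projects to elevation
    # pitch_offset exactly; the beak may sit slightly off the median plane
    # (asymmetric eyes), hence the solve instead of a fixed -10 deg rotation
    r = np.linalg.norm(yraw)
    sin_alpha = -r * np.sin(np.radians(float(pitch_offset_deg))) / ny
    if abs(sin_alpha) > 1.0:
        raise ValueError("beak tip too close to the inter-eye line for the pitch offset")
    alpha = float(np.degrees(np.arcsin(sin_alpha)))
    R = R0 @ rot_x(alpha)

    labels = tuple(sorted(kp.markers))
    positions = np.array([(kp.markers[l] - origin) @ R for l in labels])
    template = MarkerTemplate(
        labels,
        positions,
        meta={
            "inter_eye_distance_mm": kp.inter_eye_distance,
            "pitch_offset_deg": float(pitch_offset_deg),
        },
    )
    frame = HeadFrame(origin=origin, rotation=R)
    # contract check: beak tip projects to (0, pitch_offset)
    beak_dir = direction_from_vector((kp.beak_tip - origin) @ R)
    assert abs(beak_dir.elevation - pitch_offset_deg) < 1e-6
    return frame, template


# ---------------------------------------------------------------------------
# per-frame pose


def kabsch(template: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Proper-rotation orthogonal superposition (least squares).

    Returns ``(R, t, rms)`` minimizing ``sum |observed - (R template + t)|^2``
    with det(R) = +1 (reflections are excluded).
    """
    tc = template.mean(axis=0)
    oc = observed.mean(axis=0)
    H = (template - tc).T @ (observed - oc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = oc - R @ tc
    resid = observed - (template @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return R, t, rms


def estimate_head_pose(
    template: MarkerTemplate,
    observed: Mapping[str, np.ndarray] | np.ndarray,
) -> tuple[RigidPose | None, float]:
    """Rigid head pose from labeled marker observations.

    ``observed`` is either a ``{label: xyz}`` mapping (labels matched to the
    template; missing markers simply absent) or an array aligned with
    ``template.labels`` where missing markers are NaN rows.  Frames with
    fewer than 3 visible non-collinear markers are untrackable and return
    ``(None, nan)`` rather than raising.
    """
    if isinstance(observed, Mapping):
        pairs = [
            (i, np.asarray(observed[l], dtype=float))
            for i, l in enumerate(template.labels)
            if l in observed
        ]
        if not pairs:
            return None, float("nan")
        idx = [i for i, _ in pairs]
        obs = np.array([p for _, p in pairs])
    else:
        obs = np.asarray(observed, dtype=float).reshape(-1, 3)
        ok = np.all(np.isfinite(obs), axis=1)
        idx = np.flatnonzero(ok)
        obs = obs[ok]
    ok = np.all(np.isfinite(obs), axis=1)
    idx = np.asarray(idx)[ok]
    obs = obs[ok]
    if len(idx) < 3:
        return None, float("nan")
    tmpl = template.positions[idx]
    if _collinear(tmpl, tol=1e-8):
        return None, float("nan")
    R, t, rms = kabsch(tmpl, obs)
    return RigidPose(R, t), rms
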