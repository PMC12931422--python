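"""Skeletal point extraction and rigid point-set registration.

The patient skeleton is isolated from CT by Hounsfield-unit thresholding
(default floor 200 HU, a conventional lower bound for bone attenuation);
the phantom skeleton is the set of all labeled bone voxels. The two point
sets are aligned with the iterative closest point (ICP) algorithm in its
canonical point-to-point form: nearest-neighbour correspondences (k-d
tree) alternate with a closed-form least-squares rigid update (Kabsch
SVD; Umeyama similarity when isotropic scaling is enabled). The phantom
skeleton is the moving set, so after registration every phantom bone
voxel has a position in the patient's DICOM coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .grids import CTVolume
from .phantom import Phantom

__all__ = [
    "SkeletonPointSet",
    "RigidTransform",
    "ICPConfig",
    "ICPResult",
    "extract_skeleton",
    "phantom_skeleton_points",
    "initial_align",
    "icp_register",
    "apply_transform",
    "fit_rigid",
]

DEFAULT_HU_THRESHOLD = 200.0


@dataclass
class SkeletonPointSet:
    """An ``(N, 3)`` mm point cloud in a named coordinate frame."""

    points: np.ndarray
    frame: str  # "patient" or "phantom"
    source_voxel_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        if len(self.points) < 1:
            raise ValueError("point set must be non-empty")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class RigidTransform:
    """p' = scale * R @ p + translation, mapping one frame into another.

    ``rotation`` is proper orthonormal (det +1); ``scale`` is 1.0 for a
    pure rigid transform and only differs when similarity registration
    was explicitly requested.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.scale = float(self.scale)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det +1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def about_point(
        cls, rotation: np.ndarray, translation: np.ndarray, point: np.ndarray, scale: float = 1.0
    ) -> "RigidTransform":
        """Rotation (and scaling) anchored at ``point``, then translated.

        Equivalent to ``p' = scale * R (p - point) + point + translation``.
        """
        rotation = np.asarray(rotation, dtype=float)
        point = np.asarray(point, dtype=float)
        trans = point + np.asarray(translation, dtype=float) - scale * rotation @ point
        return cls(rotation=rotation, translation=trans, scale=scale)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation + self.translation,
            scale=self.scale * other.scale,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(
            rotation=rot_inv,
            translation=-rot_inv @ self.translation / self.scale,
            scale=1.0 / self.scale,
        )

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (row-major)."""
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class ICPConfig:
    max_iterations: int = 100
    convergence_tol: float = 0.01  # mm change in mean correspondence distance
    subsample: int = 20000  # max points per side
    allow_scale: bool = False
    # also try principal-axis rotational initializations (recommended for
    # voxel-derived clouds, whose solid interiors give plain ICP almost no
    # rotational gradient) and keep the start with the lowest final mean
    # correspondence distance
    multi_start: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class ICPResult:
    transform: RigidTransform
    history: list[float]
    converged: bool
    seed: int

    def to_report(self) -> dict:
        return {
            "transform": self.transform.matrix().ravel().tolist(),
            "history_mean_distance_mm": self.history,
            "converged": self.converged,
            "seed": self.seed,
        }


def extract_skeleton(ct: CTVolume, hu_threshold: float = DEFAULT_HU_THRESHOLD) -> SkeletonPointSet:
    """Patient skeletal point set: centers of all voxels with HU >= threshold."""
    mask = ct.hu >= hu_threshold
    if not np.any(mask):
        raise ValueError(f"no voxel reaches the HU threshold {hu_threshold}")
    idx = np.argwhere(mask)
    return SkeletonPointSet(
        points=ct.voxel_centers(idx), frame="patient", source_voxel_index=idx
    )


def phantom_skeleton_points(phantom: Phantom) -> SkeletonPointSet:
    """All bone voxels of the phantom (every tissue subtype), in the phantom frame."""
    idx = np.argwhere(phantom.label_volume > 0)
    if len(idx) == 0:
        raise ValueError("phantom contains no bone voxels")
    return SkeletonPointSet(
        points=phantom.voxel_centers(idx), frame="phantom", source_voxel_index=idx
    )


def initial_align(source: SkeletonPointSet, target: SkeletonPointSet) -> RigidTransform:
    """Centroid-to-centroid translation; rotation is left to ICP."""
    shift = target.points.mean(axis=0) - source.points.mean(axis=0)
    return RigidTransform(translation=shift)


def fit_rigid(source_pts: np.ndarray, target_pts: np.ndarray, allow_scale: bool = False) -> RigidTransform:
    """Closed-form least-squares rigid (or similarity) fit of paired points.

    Kabsch SVD solution; the Umeyama scale estimate is used when
    ``allow_scale``. Raises on rank-deficient (collinear) geometry.
    """
    p = np.asarray(source_pts, dtype=float)
    q = np.asarray(target_pts, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("paired point arrays must both be (N, 3)")
    n = len(p)
    mu_p = p.mean(axis=0)
    mu_q = q.mean(axis=0)
    x = p - mu_p
    y = q - mu_q
    cov = x.T @ y / n
    if np.linalg.matrix_rank(cov, tol=1e-12) < 2:
        raise ValueError("degenerate geometry: cross-covariance is rank deficient")
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(diag) @ u.T
    if allow_scale:
        var_p = (x**2).sum() / n
        scale = float((s * diag).sum() / var_p)
    else:
        scale = 1.0
    trans = mu_q - scale * rot @ mu_p
    return RigidTransform(rotation=rot, translation=trans, scale=scale)


def _subsample(points: np.ndarray, limit: int, rng: np.random.Generator) -> np.ndarray:
    if len(points) <= limit:
        return points
    keep = rng.choice(len(points), size=limit, replace=False)
    return points[np.sort(keep)]


def _icp_loop(
    src: np.ndarray,
    tgt: np.ndarray,
    tree: cKDTree,
    start: RigidTransform,
    cfg: ICPConfig,
) -> tuple[RigidTransform, list[float], bool]:
    """The canonical ICP loop from one starting transform.

    Alternates nearest-neighbour correspondence with a full closed-form
    re-fit of the original source onto the corresponded targets. The
    history records the mean correspondence distance per accepted
    iteration and is non-increasing; an update that would worsen it is
    discarded and iteration stops.
    """
    transform = start
    prev_transform = start
    history: list[float] = []
    converged = False
    prev_mean = np.inf
    for _ in range(cfg.max_iterations):
        moved = transform.apply(src)
        dist, nn = tree.query(moved, workers=-1)
        mean_d = float(dist.mean())
        if mean_d > prev_mean:  # squared-loss step worsened the mean: keep previous
            transform = prev_transform
            converged = True
            break
        history.append(mean_d)
        if prev_mean - mean_d < cfg.convergence_tol:
            converged = True
            break
        prev_mean = mean_d
        prev_transform = transform
        transform = fit_rigid(src, tgt[nn], allow_scale=cfg.allow_scale)
    return transform, history, converged


def _principal_axes(points: np.ndarray) -> np.ndarray:
    """Right-handed principal-axis frame (columns, descending variance)."""
    centered = points - points.mean(axis=0)
    evals, evecs = np.linalg.eigh(centered.T @ centered)
    frame = evecs[:, ::-1]  # descending
    if np.linalg.det(frame) < 0:
        frame[:, 2] = -frame[:, 2]
    return frame


def _candidate_starts(
    src: np.ndarray, tgt: np.ndarray, multi_start: bool, allow_scale: bool
) -> list[RigidTransform]:
    """Centroid-only start plus, optionally, principal-axis alignments.

    Solid voxel clouds are self-similar under small lattice shifts, so
    plain ICP from an identity rotation easily locks into a nearby local
    minimum; aligning principal axes (all four proper sign choices)
    supplies rotational starts that bracket the true orientation. In
    similarity mode the RMS-radius ratio seeds the scale.
    """
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    scale = 1.0
    if allow_scale:
        r_s = np.sqrt(((src - mu_s) ** 2).sum(axis=1).mean())
        r_t = np.sqrt(((tgt - mu_t) ** 2).sum(axis=1).mean())
        if r_s > 0 and r_t > 0:
            scale = float(r_t / r_s)
    starts = [RigidTransform(translation=mu_t - scale * mu_s, scale=scale)]
    if multi_start:
        f_s = _principal_axes(src)
        f_t = _principal_axes(tgt)
        for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            rot = f_t @ np.diag([s1, s2, s1 * s2]) @ f_s.T
            starts.append(
                RigidTransform(rotation=rot, translation=mu_t - scale * rot @ mu_s,
                               scale=scale)
            )
    return starts


def icp_register(
    source: SkeletonPointSet, target: SkeletonPointSet, cfg: ICPConfig | None = None
) -> ICPResult:
    """Align ``source`` onto ``target`` with point-to-point ICP.

    The canonical loop (k-d-tree nearest-neighbour correspondence
    alternating with a Kabsch/Umeyama closed-form update) is run from a
    centroid-translation start and, when ``cfg.multi_start`` is on, from
    the four principal-axis rotational alignments as well; the start
    reaching the lowest final mean correspondence distance wins (ties go
    to the earlier start, so identical clouds return the identity).
    ``converged`` is True when the winning run's mean distance improved
    by less than ``convergence_tol`` before ``max_iterations``.
    """
    cfg = cfg or ICPConfig()
    if len(source) < 3 or len(target) < 3:
        raise ValueError("ICP needs at least 3 points per side")
    rng = np.random.default_rng(cfg.seed)
    src = _subsample(source.points, cfg.subsample, rng)
    tgt = _subsample(target.points, cfg.subsample, rng)
    tree = cKDTree(tgt)

    best: tuple[RigidTransform, list[float], bool] | None = None
    for start in _candidate_starts(src, tgt, cfg.multi_start, cfg.allow_scale):
        transform, history, converged = _icp_loop(src, tgt, tree, start, cfg)
        if best is None or history[-1] < best[1][-1]:
            best = (transform, history, converged)
    transform, history, converged = best
    return ICPResult(transform=transform, history=history, converged=converged, seed=cfg.seed)


def apply_transform(transform: RigidTransform, points: np.ndarray) -> np.ndarray:
    """Apply ``p' = scale * R p + t`` elementwise."""
    return transform.apply(points)
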