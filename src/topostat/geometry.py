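"""Canonical surfaces, sensor-layout projection, and rigid coregistration.

Head coordinate convention: origin midway between the preauricular
points, x toward the right preauricular point, y toward the nasion,
z up.  Lengths are meters internally; interfaces accepting mm convert
explicitly.

The canonical (non-cortical) surfaces are icospheres: a regular
icosahedron recursively subdivided, each triangle splitting into four
with deduplicated midpoints re-projected onto the sphere.  Level 4 gives
the 2562-vertex meshes used for the inner-skull, outer-skull and scalp
surfaces.

Coregistration is a rigid landmark (fiducial) fit by orthogonal
Procrustes with a reflection guard, optionally refined by the
three-phase iterative-closest-point loop: find nearest-neighbour
correspondences, fit the rigid map of sources onto their
correspondences, apply it, repeat until the RMS stops improving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface: ``vertices`` (V, 3) in meters, ``faces`` (F, 3)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=float))
        object.__setattr__(self, "faces", np.asarray(self.faces, dtype=int))

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as sorted index pairs."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces


@dataclass
class FiducialSet:
    """Named 3D anatomical landmarks (nasion, lpa, rpa, or user-defined)."""

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        if len(self.points) < 3:
            raise ValueError("a fiducial set needs at least 3 points")

    @property
    def names(self) -> list[str]:
        return list(self.points)

    def array(self, names: list[str] | None = None) -> np.ndarray:
        names = names or self.names
        return np.stack([self.points[n] for n in names])


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (proper, det=+1) plus translation, meters."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-10:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-10:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


# ---------------------------------------------------------------------------
# Icosphere
# ---------------------------------------------------------------------------

def icosphere(subdivision_level: int, radius: float = 1.0) -> SurfaceMesh:
    """Recursively subdivided icosahedron projected onto a sphere.

    Vertex count is ``10 * 4**level + 2`` (12, 42, 162, 642, 2562, ...);
    level 4 yields the canonical 2562-vertex head surfaces.
    """
    if not isinstance(subdivision_level, (int, np.integer)) or subdivision_level < 0:
        raise ValueError("subdivision level must be a non-negative integer")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    verts = list(map(tuple, verts))
    for _ in range(int(subdivision_level)):
        midpoint: dict[tuple[int, int], int] = {}

        def mid(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in midpoint:
                p = np.array(verts[a]) + np.array(verts[b])
                p /= np.linalg.norm(p)
                verts.append(tuple(p))
                midpoint[key] = len(verts) - 1
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = np.array(new_faces, dtype=int)
    v = np.array(verts) * radius
    return SurfaceMesh(v, faces)


# ---------------------------------------------------------------------------
# Layout projection
# ---------------------------------------------------------------------------

def project_to_layout(
    positions3d: np.ndarray, head_center: np.ndarray | None = None
):
    """Azimuthal-equidistant flattening of 3D sensor positions.

    The planar radius is proportional to the polar angle from the apex
    (straight up from the head center) and the azimuth is preserved; the
    result is scaled into the unit disc.  A sensor at the apex maps to
    the origin.
    """
    from topostat.core_data import ChannelLayout2D

    pts = np.asarray(positions3d, dtype=float)
    center = np.zeros(3) if head_center is None else np.asarray(head_center, float)
    rel = pts - center
    r = np.linalg.norm(rel, axis=1)
    if np.any(r < 1e-12):
        raise ValueError("sensor coincident with head center")
    polar = np.arccos(np.clip(rel[:, 2] / r, -1.0, 1.0))
    azim = np.arctan2(rel[:, 1], rel[:, 0])
    rho = polar / max(polar.max(), 1e-12)  # scale into the unit disc
    xy = np.stack([rho * np.cos(azim), rho * np.sin(azim)], axis=1)
    return ChannelLayout2D(xy)


# ---------------------------------------------------------------------------
# Rigid fits
# ---------------------------------------------------------------------------

def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid map of src onto dst (SVD, reflection guarded)."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cd - R @ cs
    return RigidTransform(R, t)


def _collinear(pts: np.ndarray, tol: float = 1e-12) -> bool:
    pts = np.asarray(pts, float)
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s.size < 2 or s[1] <= tol * max(s[0], 1.0)


def landmark_fit(
    src: FiducialSet | np.ndarray, dst: FiducialSet | np.ndarray
) -> tuple[RigidTransform, float]:
    """Rigid fiducial fit: map each source landmark onto its namesake.

    Returns the transform and the residual RMS (same units as input).
    Point arrays are matched row-by-row; fiducial sets are matched by
    name and must share all names.
    """
    if isinstance(src, FiducialSet) and isinstance(dst, FiducialSet):
        if set(src.names) != set(dst.names):
            raise ValueError("fiducial name mismatch between source and target")
        names = src.names
        a, b = src.array(names), dst.array(names)
    else:
        a = src.array() if isinstance(src, FiducialSet) else np.asarray(src, float)
        b = dst.array() if isinstance(dst, FiducialSet) else np.asarray(dst, float)
        if a.shape != b.shape:
            raise ValueError("source and target point counts differ")
    if a.shape[0] < 3:
        raise ValueError("at least 3 landmark pairs required")
    if _collinear(a) or _collinear(b):
        raise ValueError("landmarks are collinear; rigid fit is degenerate")
    tf = _kabsch(a, b)
    rms = float(np.sqrt(np.mean(np.sum((tf.apply(a) - b) ** 2, axis=1))))
    return tf, rms


@dataclass
class ICPResult:
    transform: RigidTransform
    rms: float
    n_iter: int
    converged: bool
    rms_history: list[float] = field(default_factory=list)


def icp_align(
    points: np.ndarray,
    target: SurfaceMesh | np.ndarray,
    init: RigidTransform | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> ICPResult:
    """Iterative closest point: align a point cloud to a surface or cloud.

    Each iteration (i) pairs every source point with its nearest target
    vertex, (ii) fits the rigid transform mapping sources onto their
    pairs, (iii) applies it; iteration stops when the RMS improves by
    less than ``tol`` (meters) or after ``max_iter`` rounds.  The RMS is
    non-increasing by construction of the least-squares fit.

    A good initial estimate (typically the fiducial landmark fit) is
    expected; ICP refines, it does not search globally.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty point set")
    tgt = target.vertices if isinstance(target, SurfaceMesh) else np.asarray(target, float)
    tree = cKDTree(tgt)
    tf = RigidTransform.identity() if init is None else init
    moved = tf.apply(pts)
    prev_rms = float(np.sqrt(np.mean(tree.query(moved)[0] ** 2)))
    history = [prev_rms]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d, idx = tree.query(moved)
        step = _kabsch(moved, tgt[idx])
        tf = step.compose(tf)
        moved = tf.apply(pts)
        rms = float(np.sqrt(np.mean(tree.query(moved)[0] ** 2)))
        history.append(rms)
        if abs(prev_rms - rms) < tol:
            converged = True
            prev_rms = rms
            break
        prev_rms = rms
    return ICPResult(tf, prev_rms, n_iter, converged, history)
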