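"""Frame and proximity mathematics.

Euler-angle to rotation-matrix conversion for subtomogram particle
orientations, rigid frame offsets (peptide exit tunnel, mRNA ports),
nearest-surface-triangle queries against membrane meshes, relative
particle-to-membrane angles, and area-weighted surface sampling.

Conventions: intrinsic ZYZ Euler angles in degrees,
``R = Rz(rot) @ Ry(tilt) @ Rz(psi)`` mapping reference-frame vectors into
the tomogram frame (the common subtomogram-averaging convention for the
``rlnAngleRot/Tilt/Psi`` columns). All lengths Angstrom.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .containers import FrameOffset, ParticleTable, TriangleMesh

__all__ = [
    "euler_to_matrix",
    "euler_to_matrices",
    "matrix_to_euler",
    "particle_axes",
    "apply_frame_offset",
    "nearest_triangle",
    "closest_point_on_mesh",
    "relative_angles",
    "sample_surface_points",
]


def _rz(deg: np.ndarray) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    out = np.zeros(np.shape(deg) + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out


def _ry(deg: np.ndarray) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    out = np.zeros(np.shape(deg) + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 1, 1] = 1.0
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def euler_to_matrix(rot: float, tilt: float, psi: float, convention: str = "zyz") -> np.ndarray:
    """Convert an Euler triplet (degrees) to a 3x3 rotation matrix.

    The default (and only built-in) convention is intrinsic ZYZ:
    ``R = Rz(rot) @ Ry(tilt) @ Rz(psi)``. Angles wrap; no input is
    rejected. The result is orthonormal with determinant +1.
    """
    if convention.lower() != "zyz":
        raise ValueError(f"unsupported Euler convention {convention!r}")
    return _rz(rot) @ _ry(tilt) @ _rz(psi)


def euler_to_matrices(eulers: np.ndarray, convention: str = "zyz") -> np.ndarray:
    """Vectorised :func:`euler_to_matrix` for an (n, 3) array of triplets."""
    if convention.lower() != "zyz":
        raise ValueError(f"unsupported Euler convention {convention!r}")
    eulers = np.atleast_2d(np.asarray(eulers, dtype=float))
    return _rz(eulers[:, 0]) @ _ry(eulers[:, 1]) @ _rz(eulers[:, 2])


def matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix` (intrinsic ZYZ, degrees).

    Gimbal-locked matrices (tilt = 0 or 180) return psi = 0 with the full
    in-plane rotation folded into rot.
    """
    R = np.asarray(R, dtype=float)
    tilt = np.rad2deg(np.arccos(np.clip(R[2, 2], -1.0, 1.0)))
    if abs(R[2, 2]) > 1 - 1e-12:
        # degenerate: rot and psi share an axis
        rot = np.rad2deg(np.arctan2(R[1, 0], R[0, 0]))
        if R[2, 2] < 0:
            rot = -rot
        return float(rot), float(tilt), 0.0
    rot = np.rad2deg(np.arctan2(R[1, 2], R[0, 2]))
    psi = np.rad2deg(np.arctan2(R[2, 1], -R[2, 0]))
    return float(rot), float(tilt), float(psi)


def particle_axes(R: np.ndarray) -> np.ndarray:
    """Images of the reference axes x, y, z in the tomogram frame.

    Returns a (3, 3) array whose rows are the rotated axes (i.e. the
    columns of R) — the three-colour arrows a 3D viewer draws on a
    particle.
    """
    R = np.asarray(R, dtype=float)
    return R.T.copy()


def apply_frame_offset(
    table: ParticleTable, offset: FrameOffset, convention: str = "zyz"
) -> np.ndarray:
    """Map a particle-frame offset to tomogram coordinates per particle.

    point_i = position_i + R_i @ offset.vector — a rigid-body shift, so
    every displacement norm equals ``|offset.vector|``.
    """
    R = euler_to_matrices(table.eulers, convention)
    return table.positions + R @ offset.array


def _point_triangle_closest(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each paired triangle to each point.

    points: (n, 3); tri: (n, 3, 3). Standard barycentric region test.
    """
    b, e0, e1 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    d = b - points
    a = np.einsum("ij,ij->i", e0, e0)
    bb = np.einsum("ij,ij->i", e0, e1)
    c = np.einsum("ij,ij->i", e1, e1)
    dd = np.einsum("ij,ij->i", e0, d)
    e = np.einsum("ij,ij->i", e1, d)
    det = a * c - bb * bb
    s = bb * e - c * dd
    t = bb * dd - a * e

    s_out = np.empty_like(a)
    t_out = np.empty_like(a)

    # region logic vectorised per Eberly's classification
    cond_inside = (s + t <= det) & (s >= 0) & (t >= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_det = np.where(det > 0, 1.0 / np.maximum(det, 1e-300), 0.0)
    s_out[cond_inside] = (s * inv_det)[cond_inside]
    t_out[cond_inside] = (t * inv_det)[cond_inside]

    def clamp01(x):
        return np.clip(x, 0.0, 1.0)

    # edge/vertex regions
    rem = ~cond_inside
    # region where s < 0 branch of outside set
    r4 = rem & (s + t <= det) & (s < 0) & (t < 0)
    r3 = rem & (s + t <= det) & (s < 0) & (t >= 0)
    r5 = rem & (s + t <= det) & (s >= 0) & (t < 0)
    r2 = rem & (s + t > det) & (s < 0)
    r6 = rem & (s + t > det) & (t < 0) & ~r2
    r1 = rem & (s + t > det) & ~r2 & ~r6

    with np.errstate(divide="ignore", invalid="ignore"):
        # region 4: closest to vertex b or along an edge
        m = r4
        s_out[m] = np.where(dd[m] < 0, clamp01(-dd[m] / np.maximum(a[m], 1e-300)), 0.0)
        t_out[m] = np.where(dd[m] < 0, 0.0, clamp01(-e[m] / np.maximum(c[m], 1e-300)))
        # region 3: edge e1
        m = r3
        s_out[m] = 0.0
        t_out[m] = clamp01(-e[m] / np.maximum(c[m], 1e-300))
        # region 5: edge e0
        m = r5
        s_out[m] = clamp01(-dd[m] / np.maximum(a[m], 1e-300))
        t_out[m] = 0.0
        # region 2
        m = r2
        tmp0 = bb[m] + dd[m]
        tmp1 = c[m] + e[m]
        num = tmp1 - tmp0
        den = a[m] - 2 * bb[m] + c[m]
        sm = np.where(tmp1 > tmp0, clamp01(num / np.maximum(den, 1e-300)), 0.0)
        s_out[m] = sm
        t_out[m] = 1.0 - sm
        # region 6
        m = r6
        tmp0 = bb[m] + e[m]
        tmp1 = a[m] + dd[m]
        num = tmp1 - tmp0
        den = a[m] - 2 * bb[m] + c[m]
        tm = np.where(tmp1 > tmp0, clamp01(num / np.maximum(den, 1e-300)), 0.0)
        t_out[m] = tm
        s_out[m] = 1.0 - tm
        # region 1: diagonal edge
        m = r1
        num = (c[m] + e[m]) - (bb[m] + dd[m])
        den = a[m] - 2 * bb[m] + c[m]
        sm = clamp01(num / np.maximum(den, 1e-300))
        s_out[m] = sm
        t_out[m] = 1.0 - sm

    return b + s_out[:, None] * e0 + t_out[:, None] * e1


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    closest = _point_triangle_closest(points, tri)
    return np.linalg.norm(closest - points, axis=1)


def nearest_triangle(
    points: np.ndarray,
    mesh: TriangleMesh,
    mode: str = "centroid",
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest mesh triangle and distance for each query point.

    mode ``"centroid"`` (default) measures point-to-centroid distance via
    a k-d tree over triangle centroids; mode ``"exact_surface"`` measures
    the true point-to-triangle-surface minimum (centroid k-d tree used
    only to prune candidates, with a bound that guarantees exactness).

    Returns ``(ids, distances)`` with distances in Angstrom.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tree = cKDTree(mesh.centroids)
    d_cen, idx = tree.query(points, k=1)
    if mode == "centroid":
        return idx.astype(np.int64), d_cen
    if mode != "exact_surface":
        raise ValueError(f"unknown mode {mode!r}")
    _, ids, dists = closest_point_on_mesh(points, mesh)
    return ids, dists


def closest_point_on_mesh(
    points: np.ndarray, mesh: TriangleMesh
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact closest surface point, owning face id and distance per point.

    Candidates are pruned with a centroid k-d tree using the bound that a
    triangle nearer than the current best must have its centroid within
    ``best + r_max`` (r_max = largest centroid-to-vertex distance), so
    the result equals a full scan.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tree = cKDTree(mesh.centroids)
    _, idx = tree.query(points, k=1)
    tri = mesh.triangles
    r_max = float(np.linalg.norm(tri - mesh.centroids[:, None, :], axis=2).max())

    ids = np.empty(len(points), dtype=np.int64)
    dists = np.empty(len(points))
    surface = np.empty((len(points), 3))
    for i, p in enumerate(points):
        best = _point_triangle_distance(p[None], tri[idx[i]][None])[0]
        cand = np.asarray(
            tree.query_ball_point(p, best + r_max + 1e-9), dtype=np.int64
        )
        closest = _point_triangle_closest(
            np.broadcast_to(p, (len(cand), 3)), tri[cand]
        )
        dc = np.linalg.norm(closest - p, axis=1)
        j = int(np.argmin(dc))
        ids[i] = cand[j]
        dists[i] = dc[j]
        surface[i] = closest[j]
    return surface, ids, dists


def relative_angles(R: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Angles between the particle axes and a surface normal, degrees.

    theta_i = arccos(|v_i . n|) for the three rotated reference axes v_i;
    the modulus folds obtuse angles so each theta is in [0, 90] and the
    result is invariant to flipping the normal's sign.
    """
    normal = np.asarray(normal, dtype=float)
    if abs(np.linalg.norm(normal) - 1.0) > 1e-6:
        raise ValueError("normal must be a unit vector")
    axes = particle_axes(np.asarray(R, dtype=float))
    cosines = np.abs(axes @ normal)
    return np.rad2deg(np.arccos(np.clip(cosines, 0.0, 1.0)))


def sample_surface_points(
    mesh: TriangleMesh, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n points uniformly by area on a mesh surface.

    Faces are chosen with probability proportional to area, then a point
    is placed uniformly in each chosen face via barycentric coordinates.
    Returns ``(points, face_ids)``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    areas = mesh.areas
    probs = areas / areas.sum()
    face_ids = rng.choice(mesh.n_triangles, size=n, p=probs)
    tri = mesh.triangles[face_ids]
    u = rng.random(n)
    v = rng.random(n)
    flip = u + v > 1
    u[flip] = 1 - u[flip]
    v[flip] = 1 - v[flip]
    pts = tri[:, 0] + u[:, None] * (tri[:, 1] - tri[:, 0]) + v[:, None] * (tri[:, 2] - tri[:, 0])
    return pts, face_ids.astype(np.int64)
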