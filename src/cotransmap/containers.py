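"""Core in-memory containers shared across the pipeline.

All positions and distances are Angstrom in the tomogram frame; all angles
are degrees. Voxel units never leave the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TriangleMesh",
    "ParticleTable",
    "FrameOffset",
    "PixelScale",
    "Patch",
    "PatchSet",
    "KCurve",
    "PARTICLE_COLUMNS",
    "ANNOTATION_COLUMNS",
]

# canonical ParticleTable column order
PARTICLE_COLUMNS = ["tomogram_id", "x", "y", "z", "rot", "tilt", "psi"]
ANNOTATION_COLUMNS = [
    "nearest_omm_triangle",
    "d_center",
    "d_exit",
    "theta_1",
    "theta_2",
    "theta_3",
    "class_label",
]


@dataclass
class TriangleMesh:
    """A triangle surface mesh with derived per-triangle quantities.

    Parameters
    ----------
    vertices : (n_v, 3) float array, Angstrom.
    faces : (n_f, 3) int array of vertex indices.
    compartment : membrane identity tag, e.g. ``"OMM"``, ``"IMM"``, ``"ER"``.
    labels : named boolean vectors over triangles (e.g.
        ``"crista_associated_OMM"``).

    Degenerate (zero-area) faces are dropped at construction; the dropped
    count is kept in :attr:`n_degenerate_dropped`.
    """

    vertices: np.ndarray
    faces: np.ndarray
    compartment: str = ""
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    n_degenerate_dropped: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if len(self.faces) == 0:
            raise ValueError("empty mesh")
        self._drop_degenerate()
        self._centroids: np.ndarray | None = None
        self._areas: np.ndarray | None = None
        self._normals: np.ndarray | None = None
        for name, vec in self.labels.items():
            vec = np.asarray(vec, dtype=bool)
            if vec.shape != (len(self.faces),):
                raise ValueError(
                    f"label {name!r} has length {vec.shape}, "
                    f"expected ({len(self.faces)},)"
                )
            self.labels[name] = vec

    def _drop_degenerate(self) -> None:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area2 = np.linalg.norm(cross, axis=1)
        keep = area2 > 1e-12
        self.n_degenerate_dropped = int((~keep).sum())
        if self.n_degenerate_dropped:
            self.faces = self.faces[keep]
            self.labels = {k: np.asarray(v)[keep] for k, v in self.labels.items()}
            if len(self.faces) == 0:
                raise ValueError("mesh has no non-degenerate faces")

    # ---- derived, lazily cached ------------------------------------
    @property
    def n_triangles(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(n_f, 3, 3) vertex coordinates per face."""
        return self.vertices[self.faces]

    @property
    def centroids(self) -> np.ndarray:
        if self._centroids is None:
            self._centroids = self.triangles.mean(axis=1)
        return self._centroids

    @property
    def areas(self) -> np.ndarray:
        if self._areas is None:
            tri = self.triangles
            cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            self._areas = 0.5 * np.linalg.norm(cross, axis=1)
        return self._areas

    @property
    def normals(self) -> np.ndarray:
        """Unit face normals (right-hand rule over the face winding)."""
        if self._normals is None:
            tri = self.triangles
            cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            self._normals = cross / np.linalg.norm(cross, axis=1, keepdims=True)
        return self._normals

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def get_label(self, name: str) -> np.ndarray:
        if name not in self.labels:
            raise KeyError(f"mesh has no label {name!r}")
        return self.labels[name]

    def set_label(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=bool)
        if values.shape != (self.n_triangles,):
            raise ValueError("label length must equal triangle count")
        self.labels[name] = values

    # ---- trimesh bridge --------------------------------------------
    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, mesh, compartment: str = "", labels=None) -> "TriangleMesh":
        return cls(
            vertices=np.asarray(mesh.vertices),
            faces=np.asarray(mesh.faces),
            compartment=compartment,
            labels=dict(labels or {}),
        )

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def signed_volume(self) -> float:
        """Signed enclosed volume; positive when normals point outward."""
        tri = self.triangles
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


@dataclass(frozen=True)
class FrameOffset:
    """A fixed vector in the particle reference frame marking a site.

    role is one of ``exit_tunnel``, ``mrna_entry_3p``, ``mrna_exit_5p``.
    vector is Angstrom in the particle's own frame.
    """

    role: str
    vector: tuple[float, float, float]

    VALID_ROLES = ("exit_tunnel", "mrna_entry_3p", "mrna_exit_5p")

    def __post_init__(self) -> None:
        if self.role not in self.VALID_ROLES:
            raise ValueError(f"unknown offset role {self.role!r}")
        v = np.asarray(self.vector, dtype=float)
        if v.shape != (3,) or not np.all(np.isfinite(v)):
            raise ValueError("offset vector must be a finite 3-vector")
        object.__setattr__(self, "vector", tuple(float(x) for x in v))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.vector, dtype=float)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.array))


@dataclass(frozen=True)
class PixelScale:
    """Voxel size in Angstrom per voxel (e.g. 9.98)."""

    voxel_size: float

    def __post_init__(self) -> None:
        if not (self.voxel_size > 0):
            raise ValueError("voxel_size must be > 0")


class ParticleTable:
    """Per-tomogram particle positions, Euler angles and annotations.

    Thin wrapper over a pandas DataFrame with the canonical columns
    ``tomogram_id, x, y, z`` (Angstrom) and ``rot, tilt, psi`` (degrees),
    plus annotation columns filled downstream.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in PARTICLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing particle columns: {missing}")
        pos = df[["x", "y", "z"]].to_numpy(dtype=float)
        if pos.size and not np.all(np.isfinite(pos)):
            raise ValueError("particle positions must be finite")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParticleTable):
            return NotImplemented
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            av, bv = a[c].to_numpy(), b[c].to_numpy()
            if av.dtype.kind in "fc":
                ok = np.allclose(av, bv.astype(float), rtol=0, atol=1e-9, equal_nan=True)
            else:
                ok = (av == bv).all() if len(av) else True
            if not ok:
                return False
        return True

    @property
    def positions(self) -> np.ndarray:
        return self.df[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def eulers(self) -> np.ndarray:
        return self.df[["rot", "tilt", "psi"]].to_numpy(dtype=float)

    @property
    def tomogram_ids(self) -> pd.Series:
        return self.df["tomogram_id"]

    def is_annotated(self) -> bool:
        return all(
            c in self.df.columns and not self.df[c].isna().all()
            for c in ("nearest_omm_triangle", "d_center", "d_exit")
        ) or len(self.df) == 0 and "d_exit" in self.df.columns

    def copy(self) -> "ParticleTable":
        return ParticleTable(self.df.copy())

    @classmethod
    def from_arrays(
        cls,
        positions: np.ndarray,
        eulers: np.ndarray,
        tomogram_id: str = "tomo_1",
    ) -> "ParticleTable":
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        eulers = np.atleast_2d(np.asarray(eulers, dtype=float))
        if len(positions) != len(eulers):
            raise ValueError("positions and eulers must have equal length")
        df = pd.DataFrame(
            {
                "tomogram_id": tomogram_id,
                "x": positions[:, 0],
                "y": positions[:, 1],
                "z": positions[:, 2],
                "rot": eulers[:, 0],
                "tilt": eulers[:, 1],
                "psi": eulers[:, 2],
            }
        )
        return cls(df)


@dataclass
class Patch:
    """Triangles within ``radius`` of a seed triangle's centroid."""

    seed_triangle: int
    members: np.ndarray  # sorted triangle ids
    radius: float
    label: str = ""

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.int64)
        if self.seed_triangle not in self.members:
            raise ValueError("seed must be a member of its own patch")


@dataclass
class PatchSet:
    """A collection of patches over one mesh, with their union label."""

    patches: list[Patch]
    mesh: TriangleMesh
    label: str = ""

    def __len__(self) -> int:
        return len(self.patches)

    def member_mask(self) -> np.ndarray:
        """Boolean OR of all patch memberships over the mesh triangles."""
        mask = np.zeros(self.mesh.n_triangles, dtype=bool)
        for p in self.patches:
            mask[p.members] = True
        return mask

    @property
    def seed_ids(self) -> np.ndarray:
        return np.asarray([p.seed_triangle for p in self.patches], dtype=np.int64)


@dataclass
class KCurve:
    """Ripley's-K ratio curve against a CSR null on the same domain.

    radii are nm; K_obs / K_csr are mean pair counts within r (per point);
    ratio is NaN wherever the null mean is zero.
    """

    radii: np.ndarray
    k_obs: np.ndarray
    k_csr: np.ndarray
    n_points: int
    n_null_reps: int
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        self.k_csr = np.asarray(self.k_csr, dtype=float)
        if not np.all(np.diff(self.radii) > 0):
            raise ValueError("radii must be strictly increasing")
        for arr in (self.k_obs, self.k_csr):
            if arr.shape != self.radii.shape:
                raise ValueError("K arrays must match the radius grid")
            if np.any(arr < -1e-12):
                raise ValueError("K values must be non-negative")

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.k_obs / self.k_csr
        r[self.k_csr <= 0] = np.nan
        return r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius_nm": self.radii,
                "k_obs": self.k_obs,
                "k_csr": self.k_csr,
                "ratio": self.ratio,
            }
        )
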