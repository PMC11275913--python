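"""Parametric double-membrane scenes with ground-truth particle placements.

The generator emulates the geometry the downstream morphometrics expect
from a mitochondrion: a closed ellipsoidal outer membrane (OMM) mesh, an
inner membrane (IMM) offset a fixed boundary gap (135 A by default)
inside it, cristae invaginations whose necks put IMM triangles into the
18-30 nm distance band used to detect cristae junctions, and optional
local OMM-IMM constrictions at chosen surface sites. Particles hover a
fixed height above the OMM with a controllable fraction oriented for
protein import (peptide exit tunnel facing the membrane), optional
Thomas-process surface clustering, and optional polysome chains with
aligned mRNA ports. Every random choice flows from one seed, so scenes
are bit-reproducible; every particle carries its ground-truth class,
cluster parent and chain membership for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh as _trimesh

from .containers import FrameOffset, ParticleTable, TriangleMesh
from .geometry import closest_point_on_mesh, matrix_to_euler, sample_surface_points

__all__ = [
    "SceneConfig",
    "PlacementConfig",
    "ThomasParams",
    "ChainSpec",
    "SceneGroundTruth",
    "generate_scene",
    "place_particles",
    "default_offsets",
    "connected_components",
]

# documented synthetic frame offsets (Angstrom, particle frame): the exit
# tunnel points down the particle -z axis; the mRNA ports sit either side
# of the small subunit along +-x, 210 A apart.
DEFAULT_EXIT_TUNNEL = FrameOffset("exit_tunnel", (0.0, 0.0, -120.0))
DEFAULT_ENTRY_3P = FrameOffset("mrna_entry_3p", (-105.0, 0.0, -40.0))
DEFAULT_EXIT_5P = FrameOffset("mrna_exit_5p", (105.0, 0.0, -40.0))


def default_offsets() -> dict[str, FrameOffset]:
    return {
        "exit_tunnel": DEFAULT_EXIT_TUNNEL,
        "mrna_entry_3p": DEFAULT_ENTRY_3P,
        "mrna_exit_5p": DEFAULT_EXIT_5P,
    }


@dataclass(frozen=True)
class SceneConfig:
    """Geometry of one synthetic double-membrane scene (Angstrom).

    constriction_sites entries are ``(site_point, amplitude, radius)``:
    the IMM is displaced toward the OMM by ``amplitude`` at the site,
    decaying as a Gaussian of scale ``radius`` along the surface.
    """

    omm_semi_axes: tuple[float, float, float] = (2000.0, 2000.0, 2000.0)
    mesh_edge_target: float = 50.0
    ibm_gap: float = 135.0
    n_cristae: int = 0
    crista_neck_radius: float = 300.0
    crista_depth: float = 500.0
    constriction_sites: tuple = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.ibm_gap <= 0:
            raise ValueError("ibm_gap must be > 0")
        if min(self.omm_semi_axes) <= 10 * self.mesh_edge_target:
            raise ValueError("semi-axes must exceed 10 x mesh_edge_target")
        if self.n_cristae and self.crista_depth + self.ibm_gap >= min(self.omm_semi_axes):
            raise ValueError(
                "infeasible geometry: crista_depth + ibm_gap exceeds the "
                "smallest semi-axis"
            )
        if self.n_cristae and not self.crista_depth > self.cj_band_margin:
            raise ValueError(
                "infeasible geometry: crista_depth too shallow to reach the "
                "cristae-junction distance band"
            )
        for site in self.constriction_sites:
            _, amplitude, radius = site
            if amplitude >= self.ibm_gap:
                raise ValueError(
                    "infeasible geometry: constriction amplitude "
                    f"{amplitude} >= ibm_gap {self.ibm_gap}"
                )
            if radius <= 0:
                raise ValueError("constriction radius must be > 0")

    @property
    def cj_band_margin(self) -> float:
        # extra IMM->OMM distance needed to reach the 180-300 A band
        return 300.0 - self.ibm_gap


@dataclass(frozen=True)
class ThomasParams:
    """Thomas cluster process on the membrane surface.

    n_parents parent centres uniform by area; n_offspring points per
    parent displaced by an isotropic tangent-plane Gaussian of scale
    spread_nm and re-projected onto the surface.
    """

    n_parents: int = 10
    n_offspring: int = 10
    spread_nm: float = 15.0

    def __post_init__(self) -> None:
        if self.n_parents < 1 or self.n_offspring < 1 or self.spread_nm <= 0:
            raise ValueError("invalid Thomas parameters")


@dataclass(frozen=True)
class ChainSpec:
    """A polysome chain to synthesise: member count and center spacing."""

    length: int
    spacing: float = 250.0

    def __post_init__(self) -> None:
        if self.length < 2 or self.spacing <= 0:
            raise ValueError("chains need length >= 2 and spacing > 0")


@dataclass(frozen=True)
class PlacementConfig:
    """Particle placement on a scene's OMM.

    n_particles counts the non-chain particles; when ``cluster`` is set
    the non-chain particles are exactly ``n_parents * n_offspring``
    Thomas points instead. hover_height is the particle-center height
    above the OMM along the local normal; frac_import_oriented of the
    non-chain particles get their exit tunnel facing the membrane (chain
    members are always import-oriented). min_separation, when positive,
    is enforced between all particle centers by rejection.
    """

    n_particles: int = 100
    hover_height: float = 150.0
    frac_import_oriented: float = 1.0
    cluster: ThomasParams | None = None
    polysome_chains: tuple[ChainSpec, ...] = ()
    orientation_noise: float = 0.0
    min_separation: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.hover_height < 0:
            raise ValueError("hover_height must be >= 0")
        if not 0.0 <= self.frac_import_oriented <= 1.0:
            raise ValueError("frac_import_oriented must be in [0, 1]")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")


@dataclass
class SceneGroundTruth:
    """Per-particle truth plus scene-level site lists.

    ``table`` columns: particle_id, true_class, parent_id (-1 when not a
    cluster offspring), chain_id (-1 when unchained), chain_order
    (1-based within a chain, 0 otherwise), anchor_x/y/z (the OMM surface
    point under the particle).
    """

    table: pd.DataFrame
    constriction_sites: list[np.ndarray] = field(default_factory=list)
    crista_sites: list[np.ndarray] = field(default_factory=list)

    def class_counts(self) -> pd.Series:
        return self.table["true_class"].value_counts()


# ---------------------------------------------------------------------------
# scene geometry
# ---------------------------------------------------------------------------

def _icosphere_subdivisions(cfg: SceneConfig) -> int:
    # unit icosphere edge length ~0.0755 at 4 subdivisions, halving per level
    mean_axis = float(np.mean(cfg.omm_semi_axes))
    edge4 = 0.0755 * mean_axis
    s = 4
    while edge4 / 2 ** (s - 4) > cfg.mesh_edge_target and s < 7:
        s += 1
    return s


def _ellipsoid_normals(points: np.ndarray, semi_axes) -> np.ndarray:
    grad = points / np.square(np.asarray(semi_axes, dtype=float))
    return grad / np.linalg.norm(grad, axis=1, keepdims=True)


def generate_scene(
    config: SceneConfig,
) -> tuple[TriangleMesh, TriangleMesh, SceneGroundTruth]:
    """Build the OMM and IMM meshes for one synthetic tomogram.

    The OMM is a subdivided icosphere scaled to the configured semi-axes;
    the IMM starts as the inward normal offset of the OMM by ``ibm_gap``
    and is then deformed: cristae push IMM vertices further inward
    (Gaussian bumps of depth ``crista_depth`` and scale
    ``crista_neck_radius`` at well-separated random sites) and
    constrictions pull them back toward the OMM at the given sites.
    Both meshes are closed, outward-oriented, and the IMM lies strictly
    inside the OMM.
    """
    rng = np.random.default_rng(config.rng_seed)
    sub = _icosphere_subdivisions(config)
    unit = _trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
    semi = np.asarray(config.omm_semi_axes, dtype=float)
    omm_vertices = np.asarray(unit.vertices) * semi
    faces = np.asarray(unit.faces)

    omm = TriangleMesh(vertices=omm_vertices, faces=faces, compartment="OMM")

    normals_v = _ellipsoid_normals(omm_vertices, semi)
    imm_vertices = omm_vertices - config.ibm_gap * normals_v

    # cristae: separated random unit directions; displacement measured
    # from the site point on the base IMM surface
    crista_sites: list[np.ndarray] = []
    if config.n_cristae:
        min_arc = 6.0 * config.crista_neck_radius
        mean_axis = float(semi.mean())
        directions: list[np.ndarray] = []
        attempts = 0
        while len(directions) < config.n_cristae:
            if attempts > 5000:
                raise ValueError(
                    "infeasible geometry: cannot separate "
                    f"{config.n_cristae} cristae by {min_arc:.0f} A on this surface"
                )
            attempts += 1
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            if directions and min(
                mean_axis * np.arccos(np.clip(d @ e, -1, 1)) for e in directions
            ) < min_arc:
                continue
            directions.append(d)
        for d in directions:
            # d * semi lies on the ellipsoid; offset inward to the base IMM
            site = d * semi - config.ibm_gap * _ellipsoid_normals((d * semi)[None], semi)[0]
            crista_sites.append(site)
            s = np.linalg.norm(imm_vertices - site, axis=1)
            falloff = np.exp(-0.5 * (s / config.crista_neck_radius) ** 2)
            imm_vertices = imm_vertices - (config.crista_depth * falloff)[:, None] * normals_v

    # constrictions: pull the IMM toward the OMM around projected sites
    constriction_sites: list[np.ndarray] = []
    if config.constriction_sites:
        base_imm = TriangleMesh(
            vertices=omm_vertices - config.ibm_gap * normals_v,
            faces=faces,
            compartment="IMM",
        )
        for site, amplitude, radius in config.constriction_sites:
            site = np.asarray(site, dtype=float)
            projected, _, _ = closest_point_on_mesh(site[None], base_imm)
            projected = projected[0]
            constriction_sites.append(projected)
            s = np.linalg.norm(imm_vertices - projected, axis=1)
            falloff = np.exp(-0.5 * (s / radius) ** 2)
            imm_vertices = imm_vertices + (amplitude * falloff)[:, None] * normals_v

    imm = TriangleMesh(vertices=imm_vertices, faces=faces, compartment="IMM")
    truth = SceneGroundTruth(
        table=pd.DataFrame(
            columns=[
                "particle_id", "true_class", "parent_id", "chain_id",
                "chain_order", "anchor_x", "anchor_y", "anchor_z",
            ]
        ),
        constriction_sites=constriction_sites,
        crista_sites=crista_sites,
    )
    return omm, imm, truth


# ---------------------------------------------------------------------------
# particle placement
# ---------------------------------------------------------------------------

def _surface_frame(
    anchors: np.ndarray, mesh: TriangleMesh
) -> tuple[np.ndarray, np.ndarray]:
    """Surface point and outward face normal under each anchor."""
    surface, face_ids, _ = closest_point_on_mesh(anchors, mesh)
    return surface, mesh.normals[face_ids]


def _random_tangent(n: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v -= (v @ n) * n
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        return _random_tangent(n, rng)
    return v / nv


def _orientation_matrix(t: np.ndarray, n: np.ndarray, import_oriented: bool) -> np.ndarray:
    """Rotation mapping the particle frame onto the membrane frame.

    Import-oriented: particle z -> outward normal (exit tunnel, at -z,
    faces the membrane), particle x -> the tangent t. Otherwise the
    particle is flipped so the exit tunnel points away.
    """
    t = t / np.linalg.norm(t)
    n = n / np.linalg.norm(n)
    if import_oriented:
        return np.column_stack([t, np.cross(n, t), n])
    return np.column_stack([t, -np.cross(n, t), -n])


def _perturb(R: np.ndarray, noise_deg: float, rng: np.random.Generator) -> np.ndarray:
    if noise_deg <= 0:
        return R
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(scale=noise_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return rot @ R


def _project_to_surface(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    surface, _, _ = closest_point_on_mesh(points, mesh)
    return surface


def place_particles(
    omm: TriangleMesh,
    pconfig: PlacementConfig,
    offsets: dict[str, FrameOffset] | None = None,
    tomogram_id: str = "tomo_1",
) -> tuple[ParticleTable, SceneGroundTruth]:
    """Place particles above the OMM with known classes and structure.

    Chain members are laid out along approximate surface geodesics with
    the configured spacing and are always import-oriented with their
    particle x axes aligned to the walking direction, which lines up the
    5' exit port of each member with the 3' entry port of the next.
    Non-chain particles are CSR (area-uniform) or Thomas-process points;
    the first floor(frac * n) of them are import-oriented before a
    seeded shuffle. Import-oriented particles have their exit tunnel
    anti-parallel to the local membrane normal, then perturbed by
    ``orientation_noise``.
    """
    if offsets is None:
        offsets = default_offsets()
    if "exit_tunnel" not in offsets:
        raise ValueError("offsets must include an exit_tunnel FrameOffset")
    rng = np.random.default_rng(pconfig.rng_seed)

    anchors: list[np.ndarray] = []
    tangents: list[np.ndarray] = []
    import_flags: list[bool] = []
    parent_ids: list[int] = []
    chain_ids: list[int] = []
    chain_orders: list[int] = []

    def _too_close(p: np.ndarray) -> bool:
        if pconfig.min_separation <= 0 or not anchors:
            return False
        return bool(
            np.min(np.linalg.norm(np.asarray(anchors) - p, axis=1))
            < pconfig.min_separation
        )

    # 1. polysome chains
    for cid, spec in enumerate(pconfig.polysome_chains):
        placed = False
        for _attempt in range(200):
            start, _ = sample_surface_points(omm, 1, rng)
            p = start[0]
            _, n = _surface_frame(p[None], omm)
            n = n[0]
            t = _random_tangent(n, rng)
            pts = [p]
            ts = [t]
            ok = True
            for _k in range(spec.length - 1):
                q = _project_to_surface((pts[-1] + spec.spacing * ts[-1])[None], omm)[0]
                step = q - pts[-1]
                _, nq = _surface_frame(q[None], omm)
                nq = nq[0]
                tq = step - (step @ nq) * nq
                tq /= np.linalg.norm(tq)
                pts.append(q)
                ts.append(tq)
            if pconfig.min_separation > 0:
                flat = np.asarray(pts)
                if anchors and np.min(
                    np.linalg.norm(
                        flat[:, None, :] - np.asarray(anchors)[None, :, :], axis=2
                    )
                ) < pconfig.min_separation:
                    ok = False
            if ok:
                for order, (p_i, t_i) in enumerate(zip(pts, ts), start=1):
                    anchors.append(p_i)
                    tangents.append(t_i)
                    import_flags.append(True)
                    parent_ids.append(-1)
                    chain_ids.append(cid)
                    chain_orders.append(order)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place chain {cid} (length {spec.length}) with the "
                "requested separation; scene too crowded"
            )

    # 2. non-chain particles: CSR or Thomas
    if pconfig.cluster is None:
        n_free = pconfig.n_particles
        free_pts = []
        free_parents = []
        fail_streak = 0
        while len(free_pts) < n_free:
            if fail_streak >= 2000:
                raise RuntimeError(
                    f"placed {len(free_pts)}/{n_free} particles before the "
                    "attempt budget ran out; reduce n_particles or min_separation"
                )
            p, _ = sample_surface_points(omm, 1, rng)
            p = p[0]
            if _too_close(p) or (
                free_pts
                and pconfig.min_separation > 0
                and np.min(np.linalg.norm(np.asarray(free_pts) - p, axis=1))
                < pconfig.min_separation
            ):
                fail_streak += 1
                continue
            fail_streak = 0
            free_pts.append(p)
            free_parents.append(-1)
    else:
        tp = pconfig.cluster
        parents, _ = sample_surface_points(omm, tp.n_parents, rng)
        free_pts = []
        free_parents = []
        spread = tp.spread_nm * 10.0
        for pid, parent in enumerate(parents):
            disp = rng.normal(scale=spread, size=(tp.n_offspring, 3))
            kids = _project_to_surface(parent[None] + disp, omm)
            for kid in kids:
                free_pts.append(kid)
                free_parents.append(pid)
        n_free = len(free_pts)

    # deterministic class assignment, then seeded shuffle
    n_import = int(np.floor(pconfig.frac_import_oriented * n_free))
    flags = np.zeros(n_free, dtype=bool)
    flags[:n_import] = True
    perm = rng.permutation(n_free)
    flags = flags[perm]

    for p, parent, flag in zip(free_pts, free_parents, flags):
        anchors.append(np.asarray(p))
        tangents.append(None)  # filled below (needs the local normal)
        import_flags.append(bool(flag))
        parent_ids.append(parent)
        chain_ids.append(-1)
        chain_orders.append(0)

    if not anchors:
        table = ParticleTable.from_arrays(
            np.empty((0, 3)), np.empty((0, 3)), tomogram_id
        )
        truth = SceneGroundTruth(table=pd.DataFrame(
            columns=["particle_id", "true_class", "parent_id", "chain_id",
                     "chain_order", "anchor_x", "anchor_y", "anchor_z"]))
        return table, truth

    anchor_arr = np.asarray(anchors)
    surface, normals = _surface_frame(anchor_arr, omm)

    positions = np.empty((len(anchors), 3))
    eulers = np.empty((len(anchors), 3))
    classes = []
    near_label = "near_unoriented" if pconfig.hover_height <= 250.0 else "other"
    for i in range(len(anchors)):
        n = normals[i]
        t = tangents[i] if tangents[i] is not None else _random_tangent(n, rng)
        t = t - (t @ n) * n
        t /= np.linalg.norm(t)
        R = _orientation_matrix(t, n, import_flags[i])
        R = _perturb(R, pconfig.orientation_noise, rng)
        positions[i] = surface[i] + pconfig.hover_height * n
        eulers[i] = matrix_to_euler(R)
        classes.append("import_oriented" if import_flags[i] else near_label)

    table = ParticleTable.from_arrays(positions, eulers, tomogram_id)
    truth_df = pd.DataFrame(
        {
            "particle_id": np.arange(len(anchors)),
            "true_class": classes,
            "parent_id": parent_ids,
            "chain_id": chain_ids,
            "chain_order": chain_orders,
            "anchor_x": surface[:, 0],
            "anchor_y": surface[:, 1],
            "anchor_z": surface[:, 2],
        }
    )
    return table, SceneGroundTruth(table=truth_df)


def add_constrictions_at(
    config: SceneConfig,
    sites: np.ndarray,
    amplitude: float = 35.0,
    radius: float = 400.0,
) -> SceneConfig:
    """A copy of ``config`` with constrictions at the given 3D sites."""
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    new_sites = tuple(
        (tuple(site), float(amplitude), float(radius)) for site in sites
    )
    return replace(config, constriction_sites=config.constriction_sites + new_sites)


def connected_components(mesh: TriangleMesh, mask: np.ndarray) -> int:
    """Number of edge-connected components among the masked triangles."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components as _cc

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0
    adj = mesh.to_trimesh().face_adjacency
    keep = mask[adj[:, 0]] & mask[adj[:, 1]]
    adj = adj[keep]
    idx = np.flatnonzero(mask)
    remap = -np.ones(mesh.n_triangles, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    m = len(idx)
    if len(adj) == 0:
        return m
    graph = coo_matrix(
        (np.ones(len(adj)), (remap[adj[:, 0]], remap[adj[:, 1]])), shape=(m, m)
    )
    n_comp, _ = _cc(graph, directed=False)
    return int(n_comp)
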