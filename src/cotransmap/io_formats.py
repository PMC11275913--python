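"""Read/write the standard formats the pipeline touches.

STAR-dialect particle tables (the ``rln*`` loop_ columns of subtomogram
averaging), STL/PLY triangle meshes with optional per-triangle boolean
labels, and per-tomogram CSV result files.

Unit handling is total here: every position leaving this module is
Angstrom. STAR coordinates may be stored in voxels; the voxel size (e.g.
9.98 A/voxel) must then be supplied explicitly — it is never guessed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh as _trimesh

from .containers import (
    ANNOTATION_COLUMNS,
    PARTICLE_COLUMNS,
    ParticleTable,
    PixelScale,
    TriangleMesh,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_particle_star",
    "write_particle_star",
    "read_mesh",
    "write_mesh",
    "read_labeled_ply",
    "write_labeled_ply",
    "read_label_sidecar",
    "write_label_sidecar",
    "write_annotations_csv",
    "read_annotations_csv",
]

# STAR column names for the canonical particle fields
_STAR_REQUIRED = {
    "rlnCoordinateX": "x",
    "rlnCoordinateY": "y",
    "rlnCoordinateZ": "z",
    "rlnAngleRot": "rot",
    "rlnAngleTilt": "tilt",
    "rlnAnglePsi": "psi",
}
_TOMO_COLUMNS = ("rlnMicrographName", "rlnTomoName")
# annotation columns written with custom (non-rln) names
_STAR_ANNOTATIONS = {
    "nearest_omm_triangle": "ctmNearestOmmTriangle",
    "d_center": "ctmDistCenterOmm",
    "d_exit": "ctmDistExitOmm",
    "theta_1": "ctmRelAngle1",
    "theta_2": "ctmRelAngle2",
    "theta_3": "ctmRelAngle3",
    "class_label": "ctmClassLabel",
}


# ---------------------------------------------------------------------------
# STAR parsing (simple single-loop dialect)
# ---------------------------------------------------------------------------

def _parse_star_loop(path: Path) -> pd.DataFrame:
    """Parse the first loop_ block of a STAR file into a DataFrame.

    Handles the plain whitespace-delimited dialect produced by
    subtomogram-averaging packages: optional ``data_`` header, one
    ``loop_`` with ``_name #i`` column declarations followed by rows.
    """
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    reading_rows = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                if reading_rows and not line:
                    break  # blank line ends the loop body
                continue
            if line.startswith("data_"):
                continue
            if line == "loop_":
                if reading_rows:
                    break  # a second loop; only the first is read
                in_loop = True
                continue
            if in_loop and line.startswith("_"):
                columns.append(line.split()[0].lstrip("_"))
                continue
            if in_loop and columns:
                reading_rows = True
                fields = line.split()
                if len(fields) != len(columns):
                    raise ValueError(
                        f"{path}: row at line {lineno} has {len(fields)} "
                        f"fields, expected {len(columns)}"
                    )
                rows.append(fields)
    if not columns:
        raise ValueError(f"{path}: no loop_ block with column declarations found")
    return pd.DataFrame(rows, columns=columns)


def read_particle_star(
    path,
    scale: PixelScale | None = None,
    units_mode: str = "voxels",
) -> ParticleTable:
    """Read a particle STAR file into a :class:`ParticleTable`.

    Parameters
    ----------
    path : STAR file with one loop_ carrying the six required columns
        (rlnCoordinateX/Y/Z, rlnAngleRot/Tilt/Psi) and a tomogram-name
        column (rlnMicrographName, with rlnTomoName accepted as
        fallback).
    scale : voxel size; required when ``units_mode="voxels"``.
    units_mode : ``"voxels"`` multiplies coordinates by the voxel size;
        ``"angstrom"`` passes them through.

    Positions are returned in Angstrom; angles pass through in degrees;
    row order is preserved.
    """
    path = Path(path)
    if units_mode not in ("voxels", "angstrom"):
        raise ValueError(f"unknown units_mode {units_mode!r}")
    if units_mode == "voxels" and scale is None:
        raise ValueError("units_mode='voxels' requires a PixelScale")
    raw = _parse_star_loop(path)

    missing = [c for c in _STAR_REQUIRED if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required STAR columns: {missing}")

    out = pd.DataFrame()
    tomo_col = next((c for c in _TOMO_COLUMNS if c in raw.columns), None)
    out["tomogram_id"] = raw[tomo_col] if tomo_col is not None else "tomo_1"
    for star_name, name in _STAR_REQUIRED.items():
        try:
            out[name] = raw[star_name].astype(float)
        except ValueError as exc:
            bad = raw.index[pd.to_numeric(raw[star_name], errors="coerce").isna()]
            raise ValueError(
                f"{path}: non-numeric value in column {star_name} "
                f"at row(s) {list(bad[:5])}"
            ) from exc
    if units_mode == "voxels":
        out[["x", "y", "z"]] *= scale.voxel_size
    # restore annotation columns when present
    for name, star_name in _STAR_ANNOTATIONS.items():
        if star_name in raw.columns:
            if name == "class_label":
                out[name] = raw[star_name].astype(str)
            elif name == "nearest_omm_triangle":
                out[name] = raw[star_name].astype(float).astype(np.int64)
            else:
                out[name] = raw[star_name].astype(float)
    if len(out) == 0:
        out = pd.DataFrame(columns=list(out.columns))
        for c in PARTICLE_COLUMNS:
            if c not in out.columns:
                out[c] = []
        out = out[PARTICLE_COLUMNS]
    return ParticleTable(out)


def write_particle_star(
    table: ParticleTable, path, scale: PixelScale | None = None
) -> None:
    """Write a :class:`ParticleTable` as a STAR loop_ table.

    Positions are written in voxels when a ``scale`` is given (the
    inverse of :func:`read_particle_star`'s voxel mode), otherwise in
    Angstrom. Annotation columns, when present, are written under the
    documented ``ctm*`` names.
    """
    path = Path(path)
    df = table.df
    cols: list[tuple[str, str]] = [("rlnMicrographName", "tomogram_id")]
    cols += [(star, name) for star, name in _STAR_REQUIRED.items()]
    ann = [
        (star, name)
        for name, star in _STAR_ANNOTATIONS.items()
        if name in df.columns
    ]
    cols += ann

    lines = ["data_particles", "", "loop_"]
    lines += [f"_{star} #{i + 1}" for i, (star, _) in enumerate(cols)]
    div = scale.voxel_size if scale is not None else 1.0
    for _, row in df.iterrows():
        fields = []
        for star, name in cols:
            val = row[name]
            if name in ("x", "y", "z"):
                fields.append(f"{val / div:.6f}")
            elif name in ("rot", "tilt", "psi") or name.startswith(("d_", "theta")):
                fields.append(f"{float(val):.6f}")
            elif name == "nearest_omm_triangle":
                fields.append(str(int(val)))
            else:
                fields.append(str(val))
        lines.append(" ".join(fields))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Mesh I/O
# ---------------------------------------------------------------------------

def read_mesh(path, compartment: str = "") -> TriangleMesh:
    """Load an STL or PLY mesh; derive centroids/areas/normals.

    Degenerate (zero-area) faces are dropped with a logged count. ASCII
    PLY files carrying extra per-face properties have those restored as
    boolean labels. A sidecar label CSV (``<stem>.labels.csv``) next to
    the file, if present, is merged in.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply" and _ply_has_face_properties(path):
        mesh = read_labeled_ply(path, compartment)
    elif suffix in (".stl", ".ply"):
        tm = _trimesh.load_mesh(str(path), process=False)
        if tm.is_empty or len(tm.faces) == 0:
            raise ValueError(f"{path}: empty mesh")
        mesh = TriangleMesh.from_trimesh(tm, compartment=compartment)
    else:
        raise ValueError(f"{path}: unsupported mesh format {suffix!r}")
    if mesh.n_degenerate_dropped:
        log.info("%s: dropped %d degenerate faces", path, mesh.n_degenerate_dropped)
    sidecar = path.with_suffix(path.suffix + ".labels.csv")
    if sidecar.exists():
        for name, vec in read_label_sidecar(sidecar, mesh.n_triangles).items():
            mesh.set_label(name, vec)
    return mesh


def write_mesh(path, mesh: TriangleMesh) -> None:
    """Write STL (labels to a sidecar CSV) or PLY (labels as face props)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        write_labeled_ply(path, mesh)
    elif suffix == ".stl":
        mesh.to_trimesh().export(str(path))
        if mesh.labels:
            write_label_sidecar(path.with_suffix(path.suffix + ".labels.csv"), mesh.labels)
    else:
        raise ValueError(f"{path}: unsupported mesh format {suffix!r}")


def _ply_has_face_properties(path: Path) -> bool:
    """True when an ASCII PLY declares face properties beyond the index list."""
    try:
        with open(path, "rb") as fh:
            header = fh.read(4096).decode("ascii", errors="ignore")
    except OSError:
        return False
    if "format ascii" not in header:
        return False
    in_face = False
    for line in header.splitlines():
        if line.startswith("element face"):
            in_face = True
            continue
        if line.startswith("element"):
            in_face = False
        if in_face and line.startswith("property") and "list" not in line:
            return True
    return False


def write_labeled_ply(path, mesh: TriangleMesh) -> None:
    """Write an ASCII PLY with boolean labels as uchar face properties."""
    path = Path(path)
    names = sorted(mesh.labels)
    lines = [
        "ply",
        "format ascii 1.0",
        "comment cotransmap labeled mesh",
        f"comment compartment {mesh.compartment or 'none'}",
        f"element vertex {len(mesh.vertices)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_triangles}",
        "property list uchar int vertex_indices",
    ]
    lines += [f"property uchar {n}" for n in names]
    lines.append("end_header")
    for v in mesh.vertices:
        lines.append(f"{v[0]:.8g} {v[1]:.8g} {v[2]:.8g}")
    for i, f in enumerate(mesh.faces):
        extra = " ".join(str(int(mesh.labels[n][i])) for n in names)
        lines.append(f"3 {f[0]} {f[1]} {f[2]}" + (" " + extra if extra else ""))
    path.write_text("\n".join(lines) + "\n")


def read_labeled_ply(path, compartment: str = "") -> TriangleMesh:
    """Read an ASCII PLY, restoring scalar face properties as labels."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError(f"{path}: not a PLY file")
    n_vert = n_face = 0
    face_props: list[str] = []
    stored_compartment = ""
    element = None
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if line == "end_header":
            break
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "comment":
            if len(parts) >= 3 and parts[1] == "compartment" and parts[2] != "none":
                stored_compartment = parts[2]
            continue
        if parts[0] == "element":
            element = parts[1]
            if element == "vertex":
                n_vert = int(parts[2])
            elif element == "face":
                n_face = int(parts[2])
        elif parts[0] == "property" and element == "face" and parts[1] != "list":
            face_props.append(parts[-1])
    if n_vert == 0 or n_face == 0:
        raise ValueError(f"{path}: empty mesh")
    verts = np.array(
        [[float(x) for x in lines[i + k].split()[:3]] for k in range(n_vert)]
    )
    i += n_vert
    faces = np.empty((n_face, 3), dtype=np.int64)
    labels = {n: np.empty(n_face, dtype=bool) for n in face_props}
    for k in range(n_face):
        parts = lines[i + k].split()
        if int(parts[0]) != 3:
            raise ValueError(f"{path}: non-triangular face at index {k}")
        faces[k] = [int(parts[1]), int(parts[2]), int(parts[3])]
        for j, n in enumerate(face_props):
            labels[n][k] = bool(int(parts[4 + j]))
    return TriangleMesh(
        vertices=verts,
        faces=faces,
        compartment=compartment or stored_compartment,
        labels=labels,
    )


def write_label_sidecar(path, labels: dict[str, np.ndarray]) -> None:
    """Write per-triangle labels keyed by face index as CSV."""
    df = pd.DataFrame({n: np.asarray(v).astype(int) for n, v in labels.items()})
    df.insert(0, "face_index", np.arange(len(df)))
    df.to_csv(path, index=False)


def read_label_sidecar(path, n_triangles: int) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    if "face_index" not in df.columns:
        raise ValueError(f"{path}: label sidecar must carry a face_index column")
    if len(df) != n_triangles or not (df["face_index"].to_numpy() == np.arange(n_triangles)).all():
        raise ValueError(f"{path}: label sidecar does not cover every face exactly once")
    return {
        c: df[c].to_numpy().astype(bool)
        for c in df.columns
        if c != "face_index"
    }


# ---------------------------------------------------------------------------
# CSV results
# ---------------------------------------------------------------------------

def write_annotations_csv(table: ParticleTable, path, allow_empty: bool = True) -> None:
    """Write a particle table (with annotations) as one CSV.

    Stable documented column order: the canonical particle columns first,
    then any annotation columns present.
    """
    if len(table) == 0 and not allow_empty:
        raise ValueError("refusing to write empty annotations (allow_empty=False)")
    cols = [c for c in PARTICLE_COLUMNS + ANNOTATION_COLUMNS if c in table.df.columns]
    extra = [c for c in table.df.columns if c not in cols]
    table.df[cols + extra].to_csv(path, index=False)


def read_annotations_csv(path) -> ParticleTable:
    return ParticleTable(pd.read_csv(path))
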