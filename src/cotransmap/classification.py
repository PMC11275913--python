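"""Annotate particles against the OMM and split them into analysis classes.

A ribosome is *import-oriented* when its peptide exit tunnel sits within
95 A of the outer mitochondrial membrane — close enough for the nascent
chain to reach the import machinery. Ribosomes whose center is within
250 A of the OMM but whose exit tunnel is not membrane-proximal form the
*near-unoriented* comparison class. Both cutoffs are inclusive and
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import FrameOffset, ParticleTable, TriangleMesh
from .geometry import (
    apply_frame_offset,
    euler_to_matrices,
    nearest_triangle,
    relative_angles,
)

__all__ = ["ClassifierConfig", "annotate_particles", "classify_import_oriented",
           "classify_near_unoriented", "classify"]

LABEL_IMPORT = "import_oriented"
LABEL_NEAR = "near_unoriented"
LABEL_OTHER = "other"


@dataclass(frozen=True)
class ClassifierConfig:
    """Distance cutoffs, Angstrom. Both boundaries are inclusive."""

    d_exit_max: float = 95.0
    d_near_max: float = 250.0

    def __post_init__(self) -> None:
        if not (self.d_exit_max > 0 and self.d_near_max > 0):
            raise ValueError("cutoffs must be > 0")


def annotate_particles(
    table: ParticleTable,
    omm: TriangleMesh,
    exit_offset: FrameOffset,
    mode: str = "centroid",
) -> ParticleTable:
    """Fill per-particle OMM annotations; idempotent.

    Records, for every particle: the id of and distance to the nearest
    OMM surface triangle (``nearest_omm_triangle``, ``d_center``), the
    distance from the peptide-exit point to the OMM (``d_exit``), and the
    three relative angles between the particle axes and the nearest
    triangle's normal (``theta_1..3``).
    """
    if exit_offset.role != "exit_tunnel":
        raise ValueError("annotate_particles needs the exit_tunnel offset")
    if omm.compartment and omm.compartment != "OMM":
        raise ValueError(f"expected an OMM mesh, got {omm.compartment!r}")
    out = table.copy()
    if len(out) == 0:
        for c in ("nearest_omm_triangle", "d_center", "d_exit",
                  "theta_1", "theta_2", "theta_3"):
            out.df[c] = []
        return out
    ids, d_center = nearest_triangle(out.positions, omm, mode=mode)
    exit_points = apply_frame_offset(out, exit_offset)
    _, d_exit = nearest_triangle(exit_points, omm, mode=mode)
    mats = euler_to_matrices(out.eulers)
    normals = omm.normals[ids]
    thetas = np.array(
        [relative_angles(R, n) for R, n in zip(mats, normals)]
    )
    out.df["nearest_omm_triangle"] = ids
    out.df["d_center"] = d_center
    out.df["d_exit"] = d_exit
    out.df["theta_1"] = thetas[:, 0]
    out.df["theta_2"] = thetas[:, 1]
    out.df["theta_3"] = thetas[:, 2]
    return out


def _require_annotations(table: ParticleTable) -> None:
    for c in ("d_center", "d_exit"):
        if c not in table.df.columns:
            raise ValueError("table is unannotated; run annotate_particles first")


def classify_import_oriented(
    table: ParticleTable, cfg: ClassifierConfig = ClassifierConfig()
) -> np.ndarray:
    """Boolean vector: exit-tunnel distance <= d_exit_max (inclusive)."""
    _require_annotations(table)
    return table.df["d_exit"].to_numpy(dtype=float) <= cfg.d_exit_max


def classify_near_unoriented(
    table: ParticleTable, cfg: ClassifierConfig = ClassifierConfig()
) -> np.ndarray:
    """Boolean vector: center within d_near_max AND not import-oriented.

    Disjoint from the import-oriented class by construction.
    """
    _require_annotations(table)
    imp = classify_import_oriented(table, cfg)
    near = table.df["d_center"].to_numpy(dtype=float) <= cfg.d_near_max
    return near & ~imp


def classify(
    table: ParticleTable, cfg: ClassifierConfig = ClassifierConfig()
) -> ParticleTable:
    """Attach a ``class_label`` column with the three-way partition."""
    out = table.copy()
    imp = classify_import_oriented(out, cfg)
    near = classify_near_unoriented(out, cfg)
    labels = np.full(len(out), LABEL_OTHER, dtype=object)
    labels[near] = LABEL_NEAR
    labels[imp] = LABEL_IMPORT
    out.df["class_label"] = labels
    return out
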