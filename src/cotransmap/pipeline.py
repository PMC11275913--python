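"""End-to-end orchestration: annotate -> classify -> patches -> stats -> polysomes.

A run processes one or more tomograms — either real inputs (a STAR
particle table plus OMM/IMM meshes per tomogram) or synthetic scenes —
and writes per-tomogram CSVs, a group-level Mann-Whitney summary, and a
JSON manifest recording seeds, versions and a config hash. Per-tomogram
statistics are kept independent (group tests compare per-tomogram
summaries, never pooled triangles or particles), and a fixed seed
reproduces every stochastic output bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import ClassifierConfig, annotate_particles, classify
from .containers import FrameOffset, ParticleTable, PixelScale, TriangleMesh
from .io_formats import read_mesh, read_particle_star, write_annotations_csv
from .membrane_patches import (
    PatchConfig,
    build_patches,
    classify_crista_associated_omm,
    overlap_fraction,
    patch_imm_distances,
    randomize_patches,
)
from .polysomes import PolysomeConfig, chains_to_frame, link_chains
from .spatial_stats import (
    KConfig,
    histogram_peak,
    k_ratio_curve,
    mann_whitney,
    max_ratio_by_interval,
)
from .synthetic_scene import (
    PlacementConfig,
    SceneConfig,
    default_offsets,
    generate_scene,
    place_particles,
)

log = logging.getLogger(__name__)

__all__ = ["TomogramInput", "RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class TomogramInput:
    """Paths for one real tomogram (positions read in voxels unless
    ``units_mode='angstrom'``)."""

    tomogram_id: str
    star_path: str
    omm_path: str
    imm_path: str
    voxel_size: float = 1.0
    units_mode: str = "angstrom"


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``tomograms`` (real inputs) or ``n_synthetic``
    (synthetic scenes derived from ``scene`` / ``placement``) drives the
    run. Module configs carry their own documented defaults; the global
    ``rng_seed`` derives every per-tomogram seed.
    """

    output_dir: str = "cotransmap_out"
    rng_seed: int = 0
    tomograms: list[TomogramInput] = field(default_factory=list)
    n_synthetic: int = 0
    scene: SceneConfig = field(default_factory=SceneConfig)
    placement: PlacementConfig = field(default_factory=PlacementConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    patches: PatchConfig = field(default_factory=PatchConfig)
    k: KConfig = field(default_factory=KConfig)
    polysome: PolysomeConfig = field(default_factory=PolysomeConfig)
    exit_tunnel: FrameOffset = field(
        default_factory=lambda: default_offsets()["exit_tunnel"]
    )

    def validate(self) -> None:
        if bool(self.tomograms) == bool(self.n_synthetic):
            raise ValueError(
                "configure exactly one of 'tomograms' or 'n_synthetic'"
            )
        for t in self.tomograms:
            for p in (t.star_path, t.omm_path, t.imm_path):
                if not Path(p).exists():
                    raise FileNotFoundError(f"input path does not exist: {p}")


def _config_hash(cfg: RunConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            # output_dir is not part of the scientific configuration
            return {
                f.name: encode(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
                if f.name != "output_dir"
            }
        if isinstance(obj, (list, tuple)):
            return [encode(x) for x in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    payload = json.dumps(encode(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_tomogram(t: TomogramInput):
    table = read_particle_star(
        t.star_path, PixelScale(t.voxel_size), units_mode=t.units_mode
    )
    omm = read_mesh(t.omm_path, compartment="OMM")
    imm = read_mesh(t.imm_path, compartment="IMM")
    return table, omm, imm


def _analyse_tomogram(
    tomo_id: str,
    table: ParticleTable,
    omm: TriangleMesh,
    imm: TriangleMesh,
    cfg: RunConfig,
    seed: int,
    outdir: Path,
) -> dict:
    """All per-tomogram analyses; returns the summary row."""
    files: dict[str, str] = {}

    ann = annotate_particles(table, omm, cfg.exit_tunnel)
    ann = classify(ann, cfg.classifier)
    f = outdir / f"{tomo_id}_annotations.csv"
    write_annotations_csv(ann, f)
    files["annotations"] = f.name

    imp_mask = ann.df["class_label"] == "import_oriented"
    near_mask = ann.df["class_label"] == "near_unoriented"
    summary: dict = {
        "tomogram_id": tomo_id,
        "n_particles": len(ann),
        "n_import_oriented": int(imp_mask.sum()),
        "n_near_unoriented": int(near_mask.sum()),
    }

    # clustering per class
    for name, mask in (("import", imp_mask), ("near", near_mask)):
        pts = ann.positions[mask.to_numpy()]
        if len(pts) >= 2:
            kcfg = dataclasses.replace(cfg.k, rng_seed=seed + 1)
            curve = k_ratio_curve(pts, omm, kcfg)
            cf = outdir / f"{tomo_id}_kcurve_{name}.csv"
            curve.to_frame().to_csv(cf, index=False)
            files[f"kcurve_{name}"] = cf.name
            maxima = max_ratio_by_interval(curve, cfg.k.interval_width)
            mf = outdir / f"{tomo_id}_interval_maxima_{name}.csv"
            pd.DataFrame(
                [
                    {"interval_start_nm": a, "interval_end_nm": b, "max_ratio": v}
                    for (a, b), v in maxima.items()
                ]
            ).to_csv(mf, index=False)
            files[f"interval_maxima_{name}"] = mf.name
            key_30_40 = next(
                (v for (a, b), v in maxima.items() if a <= 30 < b), np.nan
            )
            summary[f"k_max_30_40_{name}"] = key_30_40
        else:
            summary[f"k_max_30_40_{name}"] = np.nan

    # crista-associated OMM + overlap fractions
    crista = classify_crista_associated_omm(imm, omm, cfg.patches)
    seeds_imp = np.unique(
        ann.df.loc[imp_mask, "nearest_omm_triangle"].to_numpy(dtype=np.int64)
    )
    seeds_near = np.unique(
        ann.df.loc[near_mask, "nearest_omm_triangle"].to_numpy(dtype=np.int64)
    )
    for name, seeds in (("import", seeds_imp), ("near", seeds_near)):
        if len(seeds):
            ps = build_patches(omm, seeds, cfg.patches.patch_radius)
            omm.set_label(f"ribosome_associated_{name}", ps.member_mask())
            summary[f"overlap_{name}"] = overlap_fraction(
                omm, f"ribosome_associated_{name}", "crista_associated_OMM"
            )
        else:
            summary[f"overlap_{name}"] = np.nan
    if len(seeds_imp):
        rnd = randomize_patches(
            omm,
            n=len(seeds_imp),
            radius=cfg.patches.patch_radius,
            min_center_sep=cfg.patches.random_min_center_sep,
            rng_seed=seed + 2,
        )
        omm.set_label("ribosome_associated_random", rnd.member_mask())
        summary["overlap_random"] = overlap_fraction(
            omm, "ribosome_associated_random", "crista_associated_OMM"
        )
    else:
        summary["overlap_random"] = np.nan

    # OMM-IMM distances at co-translation patches
    if len(seeds_imp):
        in_d, out_d = patch_imm_distances(omm, imm, "ribosome_associated_import")
        summary["peak_in_patch"] = histogram_peak(in_d) if in_d.size else np.nan
        summary["peak_out_patch"] = histogram_peak(out_d) if out_d.size else np.nan
        summary["peak_all"] = histogram_peak(np.concatenate([in_d, out_d]))
        if "ribosome_associated_random" in omm.labels:
            rin, _rout = patch_imm_distances(omm, imm, "ribosome_associated_random")
            summary["peak_random"] = histogram_peak(rin) if rin.size else np.nan
        df = pd.DataFrame(
            {
                "distance": np.concatenate([in_d, out_d]),
                "in_patch": np.concatenate(
                    [np.ones(len(in_d), bool), np.zeros(len(out_d), bool)]
                ),
            }
        )
        pf = outdir / f"{tomo_id}_patch_imm_distances.csv"
        df.to_csv(pf, index=False)
        files["patch_imm_distances"] = pf.name
    else:
        summary["peak_in_patch"] = np.nan
        summary["peak_out_patch"] = np.nan
        summary["peak_all"] = histogram_peak(
            patch_imm_distances(omm, imm, np.zeros(omm.n_triangles, bool))[1]
        )
        summary["peak_random"] = np.nan

    # polysomes among import-oriented particles
    imp_table = ParticleTable(ann.df[imp_mask].reset_index(drop=True))
    chains = link_chains(imp_table, cfg.polysome)
    cdf = chains_to_frame(chains)
    cf = outdir / f"{tomo_id}_polysomes.csv"
    cdf.to_csv(cf, index=False)
    files["polysomes"] = cf.name
    summary["n_chains"] = len(chains)
    summary["files"] = files
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage for every tomogram; return the manifest.

    Per-tomogram failures are isolated and reported in the manifest;
    the call raises only if every tomogram fails.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    jobs: list[tuple[str, object]] = []
    if config.tomograms:
        jobs = [(t.tomogram_id, t) for t in config.tomograms]
    else:
        jobs = [(f"synthetic_{i}", i) for i in range(config.n_synthetic)]

    summaries: list[dict] = []
    failures: dict[str, str] = {}
    for j, (tomo_id, payload) in enumerate(jobs):
        seed = int(config.rng_seed) * 10_000 + 10 * j
        try:
            if config.tomograms:
                table, omm, imm = _load_tomogram(payload)
            else:
                scene_cfg = dataclasses.replace(config.scene, rng_seed=seed)
                pl_cfg = dataclasses.replace(config.placement, rng_seed=seed + 5)
                omm, imm, _truth = generate_scene(scene_cfg)
                table, _gt = place_particles(
                    omm, pl_cfg, tomogram_id=tomo_id
                )
            summaries.append(
                _analyse_tomogram(tomo_id, table, omm, imm, config, seed, outdir)
            )
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            log.exception("tomogram %s failed", tomo_id)
            failures[tomo_id] = f"{type(exc).__name__}: {exc}"
    if jobs and not summaries:
        raise RuntimeError(f"all tomograms failed: {failures}")

    summary_df = pd.DataFrame([
        {k: v for k, v in s.items() if k != "files"} for s in summaries
    ])
    summary_path = outdir / "per_tomogram_summary.csv"
    summary_df.to_csv(summary_path, index=False)

    # group-level Mann-Whitney comparisons over per-tomogram summaries
    tests = {}
    pairs = [
        ("k_max_30_40_import", "k_max_30_40_near", "clustering_import_vs_near"),
        ("overlap_import", "overlap_near", "overlap_import_vs_near"),
        ("overlap_import", "overlap_random", "overlap_import_vs_random"),
        ("peak_in_patch", "peak_out_patch", "imm_distance_in_vs_out"),
        ("peak_random", "peak_out_patch", "imm_distance_random_vs_out"),
    ]
    for col_a, col_b, name in pairs:
        if col_a not in summary_df or col_b not in summary_df:
            continue
        a = summary_df[col_a].dropna().to_numpy()
        b = summary_df[col_b].dropna().to_numpy()
        if len(a) and len(b):
            u, p = mann_whitney(a, b)
            tests[name] = {"U": u, "p_two_sided": p, "n_a": len(a), "n_b": len(b)}
    tests_path = outdir / "group_tests.json"
    tests_path.write_text(json.dumps(tests, indent=2))

    manifest = {
        "version": __version__,
        "rng_seed": config.rng_seed,
        "config_hash": _config_hash(config),
        "n_tomograms": len(jobs),
        "n_failed": len(failures),
        "failures": failures,
        "outputs": {
            "per_tomogram_summary": summary_path.name,
            "group_tests": tests_path.name,
            "per_tomogram": {s["tomogram_id"]: s["files"] for s in summaries},
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
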