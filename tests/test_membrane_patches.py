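"""Patch construction, cristae detection, overlap and distance statistics."""

import numpy as np
import pytest

from cotransmap import (
    PatchConfig,
    SceneConfig,
    TriangleMesh,
    build_patches,
    classify_crista_associated_omm,
    connected_components,
    generate_scene,
    intermesh_distances,
    overlap_fraction,
    patch_imm_distances,
    proximity_region,
    randomize_patches,
)
from conftest import flat_grid_mesh


class TestBuildPatches:
    def test_radius_zero_is_singleton(self, coarse_sphere_scene):
        omm = coarse_sphere_scene[0]
        ps = build_patches(omm, [5, 17], radius=0.0)
        for p in ps.patches:
            assert list(p.members) == [p.seed_triangle]

    def test_flat_grid_matches_brute_force_disc(self):
        mesh = flat_grid_mesh(n=20, spacing=50.0)
        seed = mesh.n_triangles // 2
        ps = build_patches(mesh, [seed], radius=150.0)
        dists = np.linalg.norm(mesh.centroids - mesh.centroids[seed], axis=1)
        expected = np.sort(np.flatnonzero(dists <= 150.0))
        assert np.array_equal(ps.patches[0].members, expected)

    def test_nearby_seeds_differ_only_in_ring(self):
        mesh = flat_grid_mesh(n=20, spacing=50.0)
        dists = np.linalg.norm(mesh.centroids - mesh.centroids[0], axis=1)
        # two adjacent triangles ~ tens of A apart
        a, b = 420, 421
        sep = np.linalg.norm(mesh.centroids[a] - mesh.centroids[b])
        ps = build_patches(mesh, [a, b], radius=150.0)
        sym = set(ps.patches[0].members) ^ set(ps.patches[1].members)
        for t in sym:
            da = np.linalg.norm(mesh.centroids[t] - mesh.centroids[a])
            db = np.linalg.norm(mesh.centroids[t] - mesh.centroids[b])
            # symmetric difference lives within `sep` of the 150 A boundary
            assert min(abs(da - 150.0), abs(db - 150.0)) <= sep + 1e-9

    def test_invalid_seed_rejected(self, coarse_sphere_scene):
        with pytest.raises(ValueError, match="seed"):
            build_patches(coarse_sphere_scene[0], [10 ** 9], radius=10.0)


class TestCristaClassification:
    def test_concentric_spheres_have_no_cristae(self, sphere_scene):
        omm, imm, _ = sphere_scene
        labels = classify_crista_associated_omm(imm, omm)
        assert labels["cj_IMM"].sum() == 0
        assert labels["crista_associated_OMM"].sum() == 0

    def test_single_crista_gives_one_component(self):
        cfg = SceneConfig(mesh_edge_target=100.0, n_cristae=1, rng_seed=31)
        omm, imm, truth = generate_scene(cfg)
        labels = classify_crista_associated_omm(imm, omm)
        assert labels["cj_IMM"].sum() > 0
        assert connected_components(omm, labels["crista_associated_OMM"]) == 1
        # the label sits over the crista site
        site = truth.crista_sites[0]
        labelled = omm.centroids[labels["crista_associated_OMM"]]
        assert np.linalg.norm(labelled - site, axis=1).min() < 1000.0

    def test_projected_subset_of_associated(self):
        cfg = SceneConfig(mesh_edge_target=100.0, n_cristae=2, rng_seed=32)
        omm, imm, _ = generate_scene(cfg)
        labels = classify_crista_associated_omm(imm, omm)
        assert not np.any(labels["cj_projected_OMM"] & ~labels["crista_associated_OMM"])

    def test_exclusion_mask_empties_all_labels(self):
        cfg = SceneConfig(mesh_edge_target=100.0, n_cristae=1, rng_seed=33)
        omm, imm, _ = generate_scene(cfg)
        mask = np.ones(imm.n_triangles, dtype=bool)
        labels = classify_crista_associated_omm(imm, omm, exclusion_mask=mask)
        assert labels["cj_IMM"].sum() == 0
        assert labels["cj_projected_OMM"].sum() == 0
        assert labels["crista_associated_OMM"].sum() == 0


class TestOverlapFraction:
    def test_identical_labels_give_one(self, coarse_sphere_scene):
        omm = coarse_sphere_scene[0]
        a = np.zeros(omm.n_triangles, bool)
        a[:50] = True
        assert overlap_fraction(omm, a, a) == 1.0

    def test_disjoint_labels_give_zero(self, coarse_sphere_scene):
        omm = coarse_sphere_scene[0]
        a = np.zeros(omm.n_triangles, bool)
        b = np.zeros(omm.n_triangles, bool)
        a[:50] = True
        b[50:100] = True
        assert overlap_fraction(omm, a, b) == 0.0

    def test_constructed_half_area_overlap(self):
        """b covers triangles holding exactly half of a's area."""
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 0, 0], [2, 1, 0]],
            dtype=float,
        )
        faces = np.array([[0, 1, 2], [1, 3, 2], [1, 4, 3], [4, 5, 3]])
        mesh = TriangleMesh(vertices=verts, faces=faces)
        assert np.allclose(mesh.areas, 0.5)
        a = np.array([True, True, True, True])
        b = np.array([True, True, False, False])
        assert np.isclose(overlap_fraction(mesh, a, b), 0.5)

    def test_empty_label_a_is_missing_not_zero(self, coarse_sphere_scene):
        omm = coarse_sphere_scene[0]
        empty = np.zeros(omm.n_triangles, bool)
        full = np.ones(omm.n_triangles, bool)
        assert overlap_fraction(omm, empty, full) is None

    def test_monotone_in_label_b(self, coarse_sphere_scene, rng):
        omm = coarse_sphere_scene[0]
        a = rng.random(omm.n_triangles) < 0.2
        b1 = rng.random(omm.n_triangles) < 0.3
        b2 = b1 | (rng.random(omm.n_triangles) < 0.3)
        assert overlap_fraction(omm, a, b2) >= overlap_fraction(omm, a, b1)


class TestRandomizePatches:
    def test_zero_patches(self, coarse_sphere_scene):
        ps = randomize_patches(coarse_sphere_scene[0], 0, radius=150.0)
        assert len(ps) == 0

    def test_pairwise_separation_holds(self, coarse_sphere_scene):
        omm = coarse_sphere_scene[0]
        ps = randomize_patches(omm, 20, radius=150.0, min_center_sep=150.0, rng_seed=5)
        centers = omm.centroids[ps.seed_ids]
        d = np.linalg.norm(centers[:, None] - centers[None], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 150.0

    def test_deterministic_under_seed(self, coarse_sphere_scene):
        omm = coarse_sphere_scene[0]
        a = randomize_patches(omm, 10, radius=100.0, rng_seed=9)
        b = randomize_patches(omm, 10, radius=100.0, rng_seed=9)
        assert np.array_equal(a.seed_ids, b.seed_ids)

    def test_impossible_separation_reports_achieved_count(self):
        mesh = flat_grid_mesh(n=4, spacing=50.0)  # 200 A square
        with pytest.raises(RuntimeError, match=r"placed \d+/50"):
            randomize_patches(mesh, 50, radius=10.0, min_center_sep=150.0,
                              rng_seed=1, max_attempts=500)

    def test_mean_overlap_approaches_area_fraction(self, coarse_sphere_scene):
        """Law of large numbers: random matched-n patches overlap a fixed
        label in proportion to its area share, on a homogeneous mesh."""
        omm, imm, _ = coarse_sphere_scene
        rng = np.random.default_rng(2)
        target = rng.random(omm.n_triangles) < 0.3
        area_frac = omm.areas[target].sum() / omm.total_area
        fracs = [
            overlap_fraction(
                omm,
                randomize_patches(omm, 10, radius=150.0, rng_seed=s).member_mask(),
                target,
            )
            for s in range(40)
        ]
        assert abs(np.mean(fracs) - area_frac) < 0.05


class TestProximityRegion:
    def test_concentric_threshold_above_gap_labels_all(self, sphere_scene):
        omm, imm, _ = sphere_scene
        label = proximity_region(omm, imm, threshold=250.0)
        assert label.all()

    def test_threshold_below_gap_labels_none(self, sphere_scene):
        omm, imm, _ = sphere_scene
        label = proximity_region(omm, imm, threshold=100.0)
        assert not label.any()

    def test_matches_brute_force(self, coarse_sphere_scene):
        omm, imm, _ = coarse_sphere_scene
        label = proximity_region(omm, imm, threshold=140.0)
        d = np.linalg.norm(
            omm.centroids[:, None] - imm.centroids[None], axis=2
        ).min(axis=1)
        assert np.array_equal(label, d <= 140.0)

    def test_missing_mesh_warns_and_returns_empty(self, sphere_scene):
        omm = sphere_scene[0]
        label = proximity_region(omm, None, threshold=250.0)
        assert label.shape == (omm.n_triangles,) and not label.any()


class TestPatchImmDistances:
    def test_concentric_spheres_concentrate_at_gap(self, sphere_scene):
        omm, imm, _ = sphere_scene
        mask = np.zeros(omm.n_triangles, bool)
        mask[:500] = True
        in_d, out_d = patch_imm_distances(omm, imm, mask)
        assert abs(np.median(in_d) - 135.0) < 10
        assert abs(np.median(out_d) - 135.0) < 10

    def test_all_true_patch_empties_outside(self, sphere_scene):
        omm, imm, _ = sphere_scene
        in_d, out_d = patch_imm_distances(omm, imm, np.ones(omm.n_triangles, bool))
        assert out_d.size == 0 and in_d.size == omm.n_triangles

    def test_area_partition_is_exact(self, sphere_scene, rng):
        omm, imm, _ = sphere_scene
        mask = rng.random(omm.n_triangles) < 0.3
        in_d, out_d = patch_imm_distances(omm, imm, mask)
        assert in_d.size + out_d.size == omm.n_triangles
        assert np.isclose(
            omm.areas[mask].sum() + omm.areas[~mask].sum(), omm.total_area
        )

    def test_constriction_under_patch_lowers_in_patch_minimum(self):
        base = SceneConfig(mesh_edge_target=100.0, rng_seed=41)
        omm0, _, _ = generate_scene(base)
        site = omm0.centroids[123]
        cfg = SceneConfig(
            mesh_edge_target=100.0, rng_seed=41,
            constriction_sites=((tuple(site), 35.0, 300.0),),
        )
        omm, imm, _ = generate_scene(cfg)
        mask = np.linalg.norm(omm.centroids - site, axis=1) <= 150.0
        in_d, out_d = patch_imm_distances(omm, imm, mask)
        assert in_d.min() < out_d.min()
        assert abs(in_d.min() - 100.0) < 8.0
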