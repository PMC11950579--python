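"""Voxel fields, marching-cubes surfaces, refinement, and the three samplers."""
import numpy as np
import pytest
import trimesh

from ivdpipe.phantom import DISC_CLASS_CODES
from ivdpipe.reconstruction import (
    DiscPointCloud,
    EmptyStructureError,
    ScalarField,
    SurfaceMesh,
    extract_surface,
    masks_to_field,
    points_inside_mesh,
    refine_mesh,
    sample_ellipsoid,
    sample_rejection,
    sample_voxel,
)


def sphere_field(radius_vox=10, pad=2, spacing=(1.0, 1.0, 1.0)):
    n = 2 * (radius_vox + pad)
    c = (n - 1) / 2.0
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    occ = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= radius_vox ** 2
    return ScalarField(occ.astype(float), spacing)


def mesh_from_trimesh(tm, provenance=("P", "L")):
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), provenance)


class TestMasksToField:
    def test_single_voxel_anchor_maps_to_index_times_spacing(self, one_patient):
        stack, labels, _ = one_patient
        lab = np.zeros_like(labels.labels)
        lab[3, 10, 20] = 7
        labels2 = type(labels)(lab)
        occ, inten = masks_to_field(labels2, stack, 7)
        assert occ.values.sum() == 1
        np.testing.assert_allclose(
            occ.voxel_centers_mm()[0], np.array([3, 10, 20]) * np.array(stack.spacing_mm)
        )

    def test_spacing_metadata_propagates_to_bounding_box(self, one_patient):
        stack, labels, _ = one_patient
        occ, _ = masks_to_field(labels, stack, 8)
        pts = occ.voxel_centers_mm()
        ext = pts.max(axis=0) - pts.min(axis=0)
        idx = np.argwhere(occ.values > 0)
        ext_vox = idx.max(axis=0) - idx.min(axis=0)
        np.testing.assert_allclose(ext, ext_vox * np.array(stack.spacing_mm))

    def test_occupancy_sum_equals_constructed_voxel_count(self, one_patient):
        stack, labels, _ = one_patient
        for code in DISC_CLASS_CODES:
            occ, inten = masks_to_field(labels, stack, code)
            assert occ.values.sum() == (labels.labels == code).sum()
            assert (inten.values[occ.values == 0] == 0).all()

    def test_absent_class_raises_named_error(self, one_patient):
        stack, labels, _ = one_patient
        lab = np.where(labels.labels == 11, 0, labels.labels)
        with pytest.raises(EmptyStructureError, match=stack.patient_id):
            masks_to_field(type(labels)(lab), stack, 11)


class TestExtractSurface:
    def test_digitized_sphere_volume_within_five_percent(self):
        mesh = extract_surface(sphere_field(10))
        assert mesh.is_watertight
        analytic = 4 / 3 * np.pi * 10 ** 3
        assert abs(mesh.volume_mm3 - analytic) / analytic < 0.05

    def test_cube_volume_within_five_percent(self):
        occ = np.zeros((14, 14, 14))
        occ[2:12, 2:12, 2:12] = 1.0
        mesh = extract_surface(ScalarField(occ, (1, 1, 1)))
        assert abs(mesh.volume_mm3 - 1000.0) / 1000.0 < 0.05

    def test_single_voxel_yields_small_closed_mesh(self):
        occ = np.zeros((3, 3, 3))
        occ[1, 1, 1] = 1.0
        mesh = extract_surface(ScalarField(occ, (1.0, 1.0, 3.0)))
        # marching cubes turns one voxel into its dual octahedron: closed,
        # positive volume, no larger than the voxel itself
        assert mesh.is_watertight
        assert 0 < mesh.volume_mm3 <= 3.0

    def test_anisotropic_spacing_scales_volume(self):
        iso = extract_surface(sphere_field(6, spacing=(1, 1, 1))).volume_mm3
        stretched = extract_surface(sphere_field(6, spacing=(2, 1, 1))).volume_mm3
        assert stretched == pytest.approx(2 * iso, rel=1e-9)

    def test_empty_and_full_fields_rejected(self):
        with pytest.raises(ValueError):
            extract_surface(ScalarField(np.zeros((4, 4, 4)), (1, 1, 1)))
        with pytest.raises(ValueError):
            extract_surface(ScalarField(np.ones((4, 4, 4)), (1, 1, 1)))


class TestRefineMesh:
    def test_identity_configuration_returns_input_geometry(self):
        mesh = extract_surface(sphere_field(6))
        out = refine_mesh(mesh, smoothing_iterations=0, max_edge_length=np.inf)
        np.testing.assert_allclose(out.vertices, mesh.vertices)
        np.testing.assert_array_equal(out.faces, mesh.faces)

    def test_smoothing_reduces_deviation_from_analytic_sphere(self):
        mesh = extract_surface(sphere_field(10))
        center = mesh.vertices.mean(axis=0)

        def rms(m):
            r = np.linalg.norm(m.vertices - center, axis=1)
            return np.sqrt(np.mean((r - 10.0) ** 2))

        refined = refine_mesh(mesh, smoothing_iterations=10, max_edge_length=np.inf)
        assert rms(refined) < rms(mesh)

    def test_volume_change_bounded_on_phantom_discs(self, one_patient):
        stack, labels, _ = one_patient
        for code in DISC_CLASS_CODES[:3]:
            occ, _ = masks_to_field(labels, stack, code)
            mesh = extract_surface(occ)
            refined = refine_mesh(mesh, smoothing_iterations=10, max_edge_length=3.0)
            assert abs(refined.volume_mm3 - mesh.volume_mm3) / mesh.volume_mm3 <= 0.05
            edges = refined.vertices[refined.as_trimesh().edges_unique]
            assert np.linalg.norm(edges[:, 0] - edges[:, 1], axis=1).max() <= 3.0 + 1e-9


class TestSampleVoxel:
    def test_full_fraction_returns_every_voxel_centre_once(self, one_patient):
        stack, labels, _ = one_patient
        occ, inten = masks_to_field(labels, stack, 9)
        cloud = sample_voxel(occ, inten, fraction=1.0, seed=0)
        ref = occ.voxel_centers_mm()
        assert len(cloud.points) == len(ref)
        assert len(np.unique(cloud.points, axis=0)) == len(ref)

    def test_eighty_percent_of_1000_voxels_is_800_points(self):
        occ = np.zeros((10, 10, 10))
        occ.ravel()[:1000] = 1.0
        cloud = sample_voxel(ScalarField(occ, (1, 1, 1)), fraction=0.8, seed=1)
        assert len(cloud.points) == 800

    def test_same_seed_reproduces_point_set(self, one_patient):
        stack, labels, _ = one_patient
        occ, inten = masks_to_field(labels, stack, 8)
        c1 = sample_voxel(occ, inten, 0.5, seed=7)
        c2 = sample_voxel(occ, inten, 0.5, seed=7)
        np.testing.assert_array_equal(c1.points, c2.points)
        np.testing.assert_array_equal(c1.intensity, c2.intensity)


class TestSampleRejection:
    def test_unit_cube_points_stay_inside(self):
        tm = trimesh.creation.box(extents=(1, 1, 1))
        cloud = sample_rejection(mesh_from_trimesh(tm), 1000, seed=0)
        assert (np.abs(cloud.points) < 0.5).all()

    def test_uniformity_mean_near_cube_centre(self):
        tm = trimesh.creation.box(extents=(1, 1, 1))
        cloud = sample_rejection(mesh_from_trimesh(tm), 8000, seed=1)
        se = (1 / np.sqrt(12)) / np.sqrt(8000)
        assert np.abs(cloud.points.mean(axis=0)).max() < 3 * se

    def test_sphere_inner_half_radius_holds_one_eighth_of_points(self):
        tm = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        cloud = sample_rejection(mesh_from_trimesh(tm), 6000, seed=2)
        frac = np.mean(np.linalg.norm(cloud.points, axis=1) < 0.5)
        se = np.sqrt(0.125 * 0.875 / 6000)
        assert abs(frac - 0.125) < 3 * se

    def test_deterministic_given_seed(self):
        tm = trimesh.creation.icosphere(subdivisions=1, radius=2.0)
        c1 = sample_rejection(mesh_from_trimesh(tm), 100, seed=3)
        c2 = sample_rejection(mesh_from_trimesh(tm), 100, seed=3)
        np.testing.assert_array_equal(c1.points, c2.points)


class TestSampleEllipsoid:
    def test_sphere_mesh_fits_equal_semi_axes(self):
        tm = trimesh.creation.icosphere(subdivisions=2, radius=3.0)
        cloud = sample_ellipsoid(mesh_from_trimesh(tm), 500, seed=0)
        ext = cloud.points.max(axis=0) - cloud.points.min(axis=0)
        assert ext.max() / ext.min() < 1.15

    def test_all_points_satisfy_ellipsoid_inequality(self, one_patient):
        stack, labels, _ = one_patient
        occ, _ = masks_to_field(labels, stack, 10)
        mesh = extract_surface(occ)
        cloud = sample_ellipsoid(mesh, 600, seed=1)
        lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
        c, a = (lo + hi) / 2, (hi - lo) / 2
        q = (((cloud.points - c) / a) ** 2).sum(axis=1)
        assert q.max() <= 1.0 + 1e-9

    def test_oblate_disc_fits_short_vertical_axis(self, one_patient):
        stack, labels, _ = one_patient
        occ, _ = masks_to_field(labels, stack, 9)
        mesh = extract_surface(occ)
        lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
        semi = (hi - lo) / 2  # axes: (slice, row, col); row is cranio-caudal
        assert semi[1] < semi[0]
        assert semi[1] < semi[2]

    def test_deterministic_given_seed(self):
        tm = trimesh.creation.icosphere(subdivisions=1, radius=1.0)
        c1 = sample_ellipsoid(mesh_from_trimesh(tm), 200, seed=5)
        c2 = sample_ellipsoid(mesh_from_trimesh(tm), 200, seed=5)
        np.testing.assert_array_equal(c1.points, c2.points)


def test_pipeline_closure_on_phantom_discs(one_patient):
    """Every disc survives fields -> surface -> refinement -> all samplers."""
    stack, labels, _ = one_patient
    for code in (7, 10):
        occ, inten = masks_to_field(labels, stack, code)
        mesh = refine_mesh(extract_surface(occ), smoothing_iterations=5,
                           max_edge_length=3.0)
        for cloud in (
            sample_voxel(occ, inten, 0.8, seed=0),
            sample_rejection(mesh, 256, seed=0, intensity_field=inten),
            sample_ellipsoid(mesh, 256, seed=0, intensity_field=inten),
        ):
            assert len(cloud.points) >= 4
            assert np.isfinite(cloud.points).all()
    inside = points_inside_mesh(mesh, sample_rejection(mesh, 128, seed=1).points)
    assert inside.all()


def test_point_cloud_validation():
    with pytest.raises(ValueError):
        DiscPointCloud(np.zeros((3, 3)), "voxel")
    with pytest.raises(ValueError):
        DiscPointCloud(np.zeros((10, 3)), "bogus")


class TestExport:
    def test_cloud_ply_roundtrip_preserves_points_and_intensity(self, one_patient, tmp_path):
        stack, labels, _ = one_patient
        occ, inten = masks_to_field(labels, stack, 8)
        cloud = sample_voxel(occ, inten, 0.5, seed=1)
        path = sample_path = tmp_path / "disc.ply"
        from ivdpipe.reconstruction import load_cloud_ply, save_cloud_ply
        save_cloud_ply(cloud, path)
        back = load_cloud_ply(sample_path)
        np.testing.assert_allclose(back.points, cloud.points, atol=1e-5)
        np.testing.assert_allclose(back.intensity, cloud.intensity, atol=1e-5)

    def test_mesh_export_formats(self, tmp_path):
        from ivdpipe.reconstruction import save_mesh
        mesh = extract_surface(sphere_field(5))
        for name in ("m.ply", "m.obj"):
            p = save_mesh(mesh, tmp_path / name)
            assert p.exists() and p.stat().st_size > 0
        with pytest.raises(ValueError):
            save_mesh(mesh, tmp_path / "m.stl")
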