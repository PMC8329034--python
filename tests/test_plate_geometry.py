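"""Feature grid, skeleton, loft, solid extrusion, holes, fit deviation,
mesh export."""

import numpy as np
import pytest
import trimesh

from osteoplate.bone import PlanarSurface, generate_bone_surface
from osteoplate.feature_model import eagle_template_matrix, validate_topology
from osteoplate.plate_geometry import (
    UndersurfacePatch, build_feature_points, build_skeleton, export_mesh,
    extrude_solid, fit_deviation, hole_count, loft_undersurface, place_holes,
    sample_contact_points, station_layout,
)


def _rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------------------
# stations & feature points

def test_station_layout_strictly_increasing(plate_a_params):
    z = station_layout(plate_a_params.l1, plate_a_params.l2)
    assert len(z) == 11
    assert np.all(np.diff(z) > 0)
    assert z[0] == 0 and z[-1] == pytest.approx(plate_a_params.L)


def test_flat_bone_zero_heights_coplanar(plate_a_params, flat_bone):
    grid = build_feature_points(plate_a_params, flat_bone)
    assert np.allclose(grid.points[:, :, 0], 0.0, atol=1e-12)
    assert np.allclose(grid.heights, 0.0, atol=1e-9)


def test_doubling_w5_doubles_station_chord(plate_a_params, flat_bone):
    grid = build_feature_points(plate_a_params, flat_bone)
    w = list(plate_a_params.w)
    w[5] *= 2
    import dataclasses
    p2 = dataclasses.replace(plate_a_params, w=tuple(w), W=max(w))
    grid2 = build_feature_points(p2, flat_bone)
    # station 6 carries w5
    def chord(g, i):
        return np.linalg.norm(g.profiles[i][-1] - g.profiles[i][0])
    assert chord(grid2, 6) == pytest.approx(2 * chord(grid, 6), abs=1e-6)


def test_plate_a_grid_on_mean_femur(plate_a_params, mean_bone):
    grid = build_feature_points(plate_a_params, mean_bone)
    assert grid.n_stations == 11
    extent = grid.points[-1, 0, 2] - grid.points[0, 0, 2]
    assert extent == pytest.approx(plate_a_params.l1 + plate_a_params.l2, abs=1e-6)
    # every grid point sits on the contact surface
    z0 = grid.z_offset
    for i, z in enumerate(grid.stations):
        on_surface = mean_bone.surface_point(z0 + z, grid.s_values)
        assert np.abs(grid.points[i] - on_surface).max() < 1e-3


def test_footprint_overflow_errors(plate_a_params):
    small = PlanarSurface(extent=100.0, halfwidth=40.0)
    with pytest.raises(ValueError, match="axially by 168"):
        build_feature_points(plate_a_params, small)
    narrow = PlanarSurface(extent=320.0, halfwidth=10.0)
    with pytest.raises(ValueError, match="laterally"):
        build_feature_points(plate_a_params, narrow)


# ---------------------------------------------------------------------------
# skeleton

def test_skeleton_topology_on_mean_femur(mean_build):
    assert validate_topology(mean_build.skeleton.topology(),
                             eagle_template_matrix()) == []


def test_ridges_share_exactly_the_neck_junction(mean_build):
    c1, c2 = mean_build.skeleton["C1"], mean_build.skeleton["C2"]
    assert np.allclose(c1.points[-1], c2.points[0], atol=1e-12)
    from osteoplate.feature_model import intersection_profile
    hits = intersection_profile(c1, c2)
    assert len(hits) == 1 and hits[0][1] == "endpoint-endpoint"


def test_skeleton_rigid_equivariance(plate_a_params, flat_bone, rng):
    grid = build_feature_points(plate_a_params, flat_bone, n_profile=9)
    skel = build_skeleton(grid)
    t = np.array([5.0, -3.0, 11.0])
    skel_t = build_skeleton(grid.transformed(translation=t))
    for c, ct in zip(skel.curves, skel_t.curves):
        assert np.abs(ct.points - (c.points + t)).max() < 1e-9


def test_skeleton_requires_full_grid(plate_a_params, flat_bone):
    grid = build_feature_points(plate_a_params, flat_bone, n_profile=9)
    grid.stations = grid.stations[:8]
    with pytest.raises(ValueError, match="11-station"):
        build_skeleton(grid)


# ---------------------------------------------------------------------------
# loft

def test_planar_skeleton_gives_planar_patch(plate_a_params, flat_bone):
    patch = loft_undersurface(build_skeleton(build_feature_points(plate_a_params, flat_bone)))
    _, _, pts = patch.dense_samples(100, 21)
    assert np.abs(pts[:, 0]).max() < 1e-9


def test_cylinder_skeleton_reproduces_radius(mean_femur):
    femur = mean_femur.replace(A_fs=180.0, H_t1=1e-12)
    bone = generate_bone_surface(femur)
    from osteoplate.feature_model import derive_semantic_parameters
    params = derive_semantic_parameters(femur, constraints=[])
    patch = loft_undersurface(build_skeleton(build_feature_points(params, bone)))
    uu = np.linspace(*patch.u_domain, 37)
    vv = np.linspace(-10.0, 10.0, 9)
    U, V = np.meshgrid(uu, vv, indexing="ij")
    pts = patch.evaluate(U.ravel(), V.ravel())
    r = np.hypot(pts[:, 0], pts[:, 1])
    assert np.abs(r - femur["D_fs"] / 2).max() < 1e-3


def test_loft_interpolates_skeleton_samples(mean_build):
    pts = np.vstack(mean_build.grid.profiles)
    rep = fit_deviation(mean_build.patch, pts)
    assert rep.max < 1e-6


# ---------------------------------------------------------------------------
# solid & holes

def test_planar_extrusion_gives_uniform_slab(plate_a_params, flat_bone):
    patch = loft_undersurface(build_skeleton(build_feature_points(plate_a_params, flat_bone)))
    spec = extrude_solid(patch, plate_a_params)
    x = spec.mesh.vertices[:, 0]
    assert set(np.round(np.unique(x), 6).tolist()) == {0.0, 3.0}
    assert spec.mesh.is_watertight


def test_shell_thickness_on_mean_femur(mean_build):
    spec = mean_build.solid
    n_half = len(spec.mesh.vertices) // 2
    inner = spec.mesh.vertices[:n_half]
    outer = spec.mesh.vertices[n_half:]
    d = np.linalg.norm(outer - inner, axis=1)
    assert np.abs(d - 3.0).max() < 1e-9     # offset construction, t1 = t2 = 3
    # measured shortest distance from outer samples back to the undersurface
    rep = fit_deviation(mean_build.patch, outer[:: max(1, len(outer) // 200)])
    assert np.abs(rep.distances - 3.0).max() < 1e-3
    assert spec.mesh.is_watertight


def test_hole_count_closed_form(rng):
    for _ in range(50):
        l1 = rng.uniform(100, 300)
        d1 = rng.uniform(3, 9)
        s1 = rng.uniform(2, 20)
        # brute-force placement: centers at d1/2 + i*(s1+d1) within l1 - d1/2
        n = 0
        a = d1 / 2
        while a <= l1 - d1 / 2 + 1e-12:
            n += 1
            a += s1 + d1
        assert hole_count(l1, d1, s1) == n


def test_tail_hole_spacing_and_axes(plate_a_params, flat_bone):
    skel = build_skeleton(build_feature_points(plate_a_params, flat_bone))
    patch = loft_undersurface(skel)
    spec = place_holes(extrude_solid(patch, plate_a_params), skel)
    tail = [h for h in spec.holes if h.label.startswith("tail")]
    assert len(tail) == hole_count(229.0, 7.0, 6.0)
    centers = np.array([h.center for h in tail])
    gaps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    assert np.abs(gaps - 13.0).max() < 1e-6          # s1 + d1
    for h in spec.holes:
        assert np.abs(np.abs(h.axis[0]) - 1.0) < 1e-6    # planar normal is +/-x
    head = [h for h in spec.holes if h.label.startswith("head")]
    assert [h.diameter for h in head] == [5.0, 5.0]


def test_single_hole_when_spacing_huge(plate_a_params, flat_bone):
    import dataclasses
    p = dataclasses.replace(plate_a_params, s1=1e6)
    skel = build_skeleton(build_feature_points(p, flat_bone))
    spec = place_holes(extrude_solid(loft_undersurface(skel), p), skel)
    assert len([h for h in spec.holes if h.label.startswith("tail")]) == 1


def test_oversized_hole_rejected(plate_a_params, flat_bone):
    import dataclasses
    p = dataclasses.replace(plate_a_params, d1=12.5)
    skel = build_skeleton(build_feature_points(p, flat_bone))
    with pytest.raises(ValueError, match="tail width"):
        place_holes(extrude_solid(loft_undersurface(skel), p), skel)


# ---------------------------------------------------------------------------
# fit deviation

def test_fit_of_translated_plane(plate_a_params, flat_bone, rng):
    patch = loft_undersurface(build_skeleton(build_feature_points(plate_a_params, flat_bone)))
    z0 = flat_bone.z_max - plate_a_params.L      # bone z of the plate tail
    z = z0 + rng.uniform(40, 220, 100)
    y = rng.uniform(-4, 4, 100)
    pts = np.column_stack([np.ones(100), y, z])   # plane lifted by 1 mm
    rep = fit_deviation(patch, pts)
    assert rep.max == pytest.approx(1.0, abs=1e-6)
    assert rep.mean == pytest.approx(1.0, abs=1e-6)
    assert rep.max >= rep.mean >= 0


def test_fit_report_rigid_invariance(mean_build, rng):
    pts = sample_contact_points(mean_build.bone, mean_build.params, n=120, seed=5)
    base = fit_deviation(mean_build.patch, pts)
    R = _rotation(rng)
    t = np.array([-20.0, 7.0, 3.0])
    patch_t = UndersurfacePatch(mean_build.grid.transformed(R, t))
    moved = fit_deviation(patch_t, pts @ R.T + t)
    assert np.abs(moved.distances - base.distances).max() < 1e-9


def test_fit_requires_points(mean_build):
    with pytest.raises(ValueError):
        fit_deviation(mean_build.patch, np.empty((0, 3)))


def test_profile_resolution_sensitivity_is_monotone(plate_a_params, mean_bone):
    """Halving the profile sampling can at most double the deviation."""
    fine = loft_undersurface(build_skeleton(
        build_feature_points(plate_a_params, mean_bone, n_profile=49)))
    coarse = loft_undersurface(build_skeleton(
        build_feature_points(plate_a_params, mean_bone, n_profile=25)))
    pts = sample_contact_points(mean_bone, plate_a_params, n=300, seed=2)
    d_fine = fit_deviation(fine, pts).max
    d_coarse = fit_deviation(coarse, pts).max
    assert d_coarse <= 2 * d_fine + 1e-6


# ---------------------------------------------------------------------------
# export

def test_mesh_export_round_trips(tmp_path, mean_build):
    mesh = mean_build.solid.mesh
    p = export_mesh(mesh, tmp_path / "plate.stl")
    back = trimesh.load(p)
    assert back.is_watertight
    tree_err = np.abs(np.asarray(back.bounds) - np.asarray(mesh.bounds)).max()
    assert tree_err < 1e-4          # float32 STL round trip
    for fmt in ("obj", "ply"):
        q = export_mesh(mesh, tmp_path / f"plate.{fmt}")
        again = trimesh.load(q)
        assert len(again.vertices) > 0
        assert np.abs(np.asarray(again.bounds) - np.asarray(mesh.bounds)).max() < 1e-4
    with pytest.raises(ValueError, match="unknown"):
        export_mesh(mesh, tmp_path / "plate.xyz")
    with pytest.raises(ValueError, match="empty"):
        export_mesh(trimesh.Trimesh(), tmp_path / "e.stl")
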