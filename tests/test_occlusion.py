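"""Geometric occlusion simulator: primitives, ray casting, sweeps, optics."""

import math

import numpy as np
import pytest

from mobivls.occlusion import (
    STRUCTURE_LEVELS,
    CameraPose,
    FlightPlan,
    GeometryQuery,
    GeometryRangeError,
    KoalaModel,
    TreeScene,
    attenuation_profile,
    build_scene,
    camera_poses,
    detection_probability,
    foliage_path_length,
    koala_pixel_size,
    koala_visibility,
    segment_blocked,
    slant_range,
)


def single_sphere_scene(centre, radius):
    return TreeScene(spacing=3.0, structure_level="light_foliage", grid=1,
                     cyl_base=np.zeros((0, 3)), cyl_axis=np.zeros((0, 3)),
                     cyl_len=np.zeros(0), cyl_rad=np.zeros(0),
                     sph_centre=np.array([centre], dtype=float),
                     sph_rad=np.array([radius], dtype=float))


def single_cylinder_scene(base, axis, length, radius):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return TreeScene(spacing=3.0, structure_level="stems", grid=1,
                     cyl_base=np.array([base], dtype=float),
                     cyl_axis=np.array([axis]),
                     cyl_len=np.array([length], dtype=float),
                     cyl_rad=np.array([radius], dtype=float),
                     sph_centre=np.zeros((0, 3)), sph_rad=np.zeros(0))


# ---------------------------------------------------------------------------
# scene construction


def test_stems_scene_counts():
    scene = build_scene(3.0, "stems")
    assert scene.cyl_base.shape == (81, 3)
    assert scene.sph_centre.shape == (0, 3)
    assert (scene.cyl_rad == 0.15).all() and (scene.cyl_len == 30.0).all()


def test_heavy_foliage_scene_has_81_unit_radius_spheres_at_stem_tops():
    scene = build_scene(3.0, "heavy_foliage")
    assert scene.sph_centre.shape == (81, 3)
    assert (scene.sph_rad == 1.0).all()
    assert (scene.sph_centre[:, 2] == 30.0).all()
    assert build_scene(3.0, "light_foliage").sph_rad[0] == 0.5


def test_branch_cylinders_added_above_stems_level():
    scene = build_scene(3.0, "stems_branches")
    assert scene.cyl_base.shape == (81 * 5, 3)  # stem + 4 branches per tree
    branches = scene.cyl_rad == 0.075
    assert branches.sum() == 324
    assert np.allclose(scene.cyl_axis[branches][:, 2], math.sin(math.radians(45)))


def test_one_metre_spacing_lattice_extent():
    scene = build_scene(1.0, "stems")
    xy = scene.cyl_base[:, :2]
    assert xy.min() == -4.0 and xy.max() == 4.0  # 8 m x 8 m footprint


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError, match="structure level"):
        build_scene(3.0, "jungle")
    with pytest.raises(ValueError, match="spacing"):
        build_scene(0.2, "stems")


# ---------------------------------------------------------------------------
# flight plans


def test_serpentine_pose_grid_counts():
    plan = FlightPlan(altitude=40.0, bounds=(-8, 8, -8, 8))
    poses = camera_poses(plan, 90.0)
    assert len(poses) == 81  # 9 transects x 9 stations
    first, last = poses[0], poses[8]
    assert first.position[1] < last.position[1]
    second = poses[9:18]
    assert second[0].position[1] > second[-1].position[1]  # reversed track
    assert first.heading_deg != second[0].heading_deg


def test_transect_angular_discrimination_at_40m():
    # 2 m spacing seen from 40 m altitude
    assert math.degrees(math.atan2(2.0, 40.0)) == pytest.approx(2.9, abs=0.05)


# ---------------------------------------------------------------------------
# ray casting against a marching oracle


def _marching_hit(o, t, scene, steps=20000):
    taus = np.linspace(1e-6, 1 - 1e-6, steps)
    pts = o[None, :] + taus[:, None] * (t - o)[None, :]
    for c, r in zip(scene.sph_centre, scene.sph_rad):
        if (np.linalg.norm(pts - c, axis=1) <= r).any():
            return True
    for b, a, ln, r in zip(scene.cyl_base, scene.cyl_axis,
                           scene.cyl_len, scene.cyl_rad):
        rel = pts - b
        m = rel @ a
        radial = np.linalg.norm(rel - m[:, None] * a[None, :], axis=1)
        if ((radial <= r) & (m >= 0) & (m <= ln)).any():
            return True
    return False


def _tolerant_oracle_check(scene_for, params, o, t):
    """Analytic result must agree with marching on radius -/+ 1 mm."""
    inner = scene_for(*params[:-1], params[-1] - 1e-3)
    outer = scene_for(*params[:-1], params[-1] + 1e-3)
    analytic = bool(segment_blocked(o[None, :], t[None, :], scene_for(*params))[0])
    if _marching_hit(o, t, inner):
        assert analytic
    if not _marching_hit(o, t, outer):
        assert not analytic


def test_segment_sphere_agrees_with_marching_oracle(rng):
    for _ in range(150):
        centre = rng.uniform(-2, 2, 3)
        radius = rng.uniform(0.3, 1.5)
        o = rng.uniform(-5, 5, 3)
        t = rng.uniform(-5, 5, 3)
        _tolerant_oracle_check(lambda c0, c1, c2, r: single_sphere_scene([c0, c1, c2], r),
                               (*centre, radius), o, t)


def test_segment_cylinder_agrees_with_marching_oracle(rng):
    for _ in range(150):
        base = rng.uniform(-2, 2, 3)
        axis = rng.normal(size=3)
        length = rng.uniform(0.5, 4.0)
        radius = rng.uniform(0.1, 0.8)
        o = rng.uniform(-5, 5, 3)
        t = rng.uniform(-5, 5, 3)

        def make(b0, b1, b2, a0, a1, a2, ln, r):
            return single_cylinder_scene([b0, b1, b2], [a0, a1, a2], ln, r)

        _tolerant_oracle_check(make, (*base, *axis, length, radius), o, t)


def test_segment_inside_sphere_is_blocked():
    scene = single_sphere_scene([0, 0, 0], 5.0)
    assert segment_blocked(np.array([[0.0, 0, 1]]), np.array([[0.0, 0, -1]]), scene)[0]


# ---------------------------------------------------------------------------
# visibility


def test_no_occluders_gives_full_visibility():
    scene = build_scene(3.0, "stems", grid=0)
    pose = CameraPose(position=np.array([0.4, 0.0, 40.0]), depression_deg=90.0)
    res = koala_visibility(scene, KoalaModel(altitude=25.0), pose)
    assert res.in_fov and res.detected
    assert res.visible_fraction == 1.0


def test_blocking_stem_hides_koala():
    koala = KoalaModel(altitude=25.0)
    scene = single_cylinder_scene(koala.centre + [0, 0, 5], [0, 0, 1], 2.0, 2.0)
    pose = CameraPose(position=koala.centre + [0, 0, 15.0], depression_deg=90.0)
    res = koala_visibility(scene, koala, pose)
    assert res.visible_fraction == 0.0 and not res.detected


def test_out_of_fov_flagged():
    pose = CameraPose(position=np.array([0.0, 500.0, 40.0]), depression_deg=90.0)
    res = koala_visibility(build_scene(3.0, "stems", grid=0),
                           KoalaModel(altitude=25.0), pose)
    assert not res.in_fov and not res.detected


def test_rendered_size_matches_pinhole_relation():
    """Unoccluded visible-pixel estimate agrees with the slant-range and
    pixel-size relations within 1 px per side at nadir."""
    koala = KoalaModel(altitude=25.0)
    pose = CameraPose(position=koala.centre + [0, 0, 15.0], depression_deg=90.0)
    res = koala_visibility(build_scene(3.0, "stems", grid=0), koala, pose)
    q = GeometryQuery(fh=float(pose.position[2]), ka=25.0, da=90.0)
    assert math.sqrt(res.visible_pixels) == pytest.approx(koala_pixel_size(q), abs=1.0)


# ---------------------------------------------------------------------------
# slant range and pixel size


@pytest.mark.parametrize("fh,ka,da,expected", [
    (40.0, 25.0, 90.0, 15.0),
    (70.0, 0.0, 90.0, 70.0),
    (40.0, 25.0, 60.0, 15.0 / math.cos(math.radians(30))),
])
def test_slant_range_cases(fh, ka, da, expected):
    assert slant_range(GeometryQuery(fh=fh, ka=ka, da=da)) == pytest.approx(expected)


def test_slant_range_undefined_when_cosine_nonpositive():
    with pytest.raises(GeometryRangeError):
        slant_range(GeometryQuery(fh=40.0, ka=25.0, da=0.0))


def test_pixel_size_at_15m_slant_range():
    q = GeometryQuery(fh=40.0, ka=25.0, da=90.0)
    assert koala_pixel_size(q) == pytest.approx(
        320.0 / (30.0 * math.tan(math.radians(25.0))), rel=1e-12)


def test_pixel_size_inverse_proportional_to_range():
    near = koala_pixel_size(GeometryQuery(fh=40.0, ka=25.0, da=90.0))
    far = koala_pixel_size(GeometryQuery(fh=55.0, ka=25.0, da=90.0))  # dca doubles
    assert near == pytest.approx(2 * far)


# ---------------------------------------------------------------------------
# foliage path length


def test_chord_through_sphere_centre_is_diameter():
    scene = single_sphere_scene([0, 0, 30], 1.0)
    path = foliage_path_length(scene, np.array([0, 0, 40.0]), np.array([0, 0, 20.0]))
    assert path == pytest.approx(2.0)


def test_chord_at_half_radius_offset():
    scene = single_sphere_scene([0, 0, 30], 1.0)
    path = foliage_path_length(scene, np.array([0.5, 0, 40.0]),
                               np.array([0.5, 0, 20.0]))
    assert path == pytest.approx(math.sqrt(3.0))


def test_clear_line_of_sight_has_zero_path():
    scene = single_sphere_scene([0, 0, 30], 1.0)
    path = foliage_path_length(scene, np.array([10.0, 0, 40.0]),
                               np.array([10.0, 0, 20.0]))
    assert path == 0.0


def test_attenuation_profile_shape_and_bounds():
    scene = build_scene(3.0, "heavy_foliage")
    prof = attenuation_profile(scene, n_samples=25, max_offset_pct=400.0)
    assert list(prof.columns) == ["offset_pct_R", "path_pct_R"]
    assert (prof.path_pct_R >= 0).all()


# ---------------------------------------------------------------------------
# detection-probability sweeps (reduced resolution)


def test_no_tree_control_has_unit_detection_probability():
    table = detection_probability(spacings=[3.0], structure_levels=["stems"],
                                  koala_altitudes=[25.0],
                                  depression_angles=[30.0, 60.0, 90.0],
                                  flight_heights=[40.0], grid=0)
    assert (table.n_images > 0).all()
    assert (table["pd"] == 1.0).all()


def test_nested_structure_levels_monotonically_occlude():
    table = detection_probability(spacings=[3.0],
                                  structure_levels=list(STRUCTURE_LEVELS),
                                  koala_altitudes=[25.0],
                                  depression_angles=[60.0, 90.0],
                                  flight_heights=[40.0])
    for (_, _, _), cell in table.groupby(["ka", "da", "fh"]):
        by_level = cell.set_index("structure_level")["pd"]
        seq = [by_level[lvl] for lvl in STRUCTURE_LEVELS]
        assert all(a >= b - 1e-12 for a, b in zip(seq, seq[1:]))


def test_detection_probability_is_deterministic():
    kwargs = dict(spacings=[1.0], structure_levels=["heavy_foliage"],
                  koala_altitudes=[25.0], depression_angles=[90.0],
                  flight_heights=[40.0])
    t1 = detection_probability(**kwargs)
    t2 = detection_probability(**kwargs)
    assert t1.equals(t2)
    assert t1.loc[0, "pd"] == 0.0  # closed canopy at nadir
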