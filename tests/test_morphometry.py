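import numpy as np
import pytest

from footmetry.errors import (
    EmptyTraceError,
    GeometryError,
    MeasurementError,
    OpenSectionError,
)
from footmetry.mesh_io import MEASUREMENT_NAMES, LandmarkSet, TriangleMesh
from footmetry.morphometry import (
    SectionPlane,
    ankle_angle,
    arch_metrics,
    cross_section_perimeter,
    foot_length,
    girths,
    landmark_distances,
    measure_foot,
    plantar_trace,
    truncated_lengths,
    widths,
)
from footmetry.primitives import box_mesh, cylinder_mesh
from footmetry.registration import register
from footmetry.synthetic_foot import FootParams, generate_foot, random_rigid_transform


def ramanujan_perimeter(a, b):
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


def merge_meshes(*meshes):
    verts, faces, off = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        off += m.n_vertices
    return TriangleMesh(np.vstack(verts), np.vstack(faces), "merged")


class TestPlantarTrace:
    def test_box_silhouette(self):
        box = box_mesh((250, 90, 40), center=(0, 0, 20))
        trace = plantar_trace(box, 50.0)
        assert trace.area == pytest.approx(250 * 90, abs=1e-6)
        minx, miny, maxx, maxy = trace.polygon.bounds
        assert (maxx - minx, maxy - miny) == pytest.approx((250, 90), abs=1e-9)

    def test_concave_union_area(self):
        # two overlapping prisms forming an L; union area by inclusion-exclusion
        a = box_mesh((100, 40, 20), center=(0, 0, 10))
        b = box_mesh((40, 100, 20), center=(-30, 30, 10))
        trace = plantar_trace(merge_meshes(a, b), 30.0)
        expected = 100 * 40 + 40 * 100 - 40 * 40
        assert trace.area == pytest.approx(expected, abs=1e-6)

    def test_mesh_above_cutoff_errors(self):
        box = box_mesh((10, 10, 10), center=(0, 0, 100))
        with pytest.raises(EmptyTraceError):
            plantar_trace(box, 50.0)

    def test_largest_component_selected(self):
        a = box_mesh((100, 40, 20), center=(0, 0, 10))
        b = box_mesh((10, 10, 20), center=(200, 0, 10))  # small distant island
        trace = plantar_trace(merge_meshes(a, b), 30.0)
        assert trace.area == pytest.approx(100 * 40, abs=1e-6)


class TestCrossSection:
    def test_cylinder_circumference(self):
        cyl = cylinder_mesh(30.0, height=100.0, sections=128, axis="y")
        per = cross_section_perimeter(
            cyl, SectionPlane(point=(0, 0, 0), normal=(0, 1, 0), anchor=(0, 0, 0))
        )
        assert per == pytest.approx(2 * np.pi * 30, rel=5e-3)

    def test_cube_midplane_exact(self):
        cube = box_mesh((10, 10, 10))
        per = cross_section_perimeter(
            cube, SectionPlane(point=(0, 0, 0.37), normal=(0, 0, 1), anchor=(0, 0, 0))
        )
        assert per == pytest.approx(40.0, abs=1e-9)

    def test_oblique_cylinder_vs_ramanujan(self):
        cyl = cylinder_mesh(30.0, height=200.0, sections=256, axis="z")
        ang = np.radians(30.0)
        per = cross_section_perimeter(
            cyl,
            SectionPlane(
                point=(0, 0, 0.123),
                normal=(0, -np.sin(ang), np.cos(ang)),
                anchor=(0, 0, 0),
            ),
        )
        expected = ramanujan_perimeter(30.0 / np.cos(ang), 30.0)
        assert per == pytest.approx(expected, rel=5e-3)

    def test_plane_missing_mesh_errors(self):
        cube = box_mesh((10, 10, 10))
        with pytest.raises(OpenSectionError):
            cross_section_perimeter(
                cube, SectionPlane(point=(0, 0, 50), normal=(0, 0, 1), anchor=(0, 0, 0))
            )

    def test_open_surface_errors(self):
        from footmetry.primitives import grid_mesh

        grid = grid_mesh(4, 4, 10, 10)
        with pytest.raises(OpenSectionError):
            cross_section_perimeter(
                grid, SectionPlane(point=(0, 0, 0), normal=(1, 0, 0), anchor=(0, 0, 0))
            )


class TestLengths:
    @staticmethod
    def _leg_scene():
        foot = box_mesh((90, 250, 40), center=(0, 125, 20))
        leg = box_mesh((60, 60, 60), center=(0, 40, 70))
        mesh = merge_meshes(foot, leg)
        lm = LandmarkSet(
            {
                "HEEL": [0.0, 5.0, 0.0],
                "MT1": [-40.0, 180.0, 0.0],
                "MT5": [40.0, 180.0, 0.0],
                "ARCH": [-30.0, 105.0, 15.0],
                "MED_MAL": [-30.0, 40.0, 50.0],
                "LAT_MAL": [30.0, 40.0, 50.0],
            }
        )
        return mesh, lm

    def test_leg_block_trimmed(self):
        mesh, lm = self._leg_scene()
        length, untrimmed = foot_length(mesh, lm)
        assert not untrimmed
        assert length == pytest.approx(250.0, abs=1e-9)

    def test_untrimmed_fallback(self):
        mesh, lm = self._leg_scene()
        partial = LandmarkSet({k: lm[k] for k in ("HEEL", "MT1", "MT5", "ARCH")})
        length, untrimmed = foot_length(mesh, partial)
        assert untrimmed
        assert length == pytest.approx(250.0, abs=1e-9)  # leg block is not longer

    def test_truncated_lengths(self):
        mesh, lm = self._leg_scene()
        l1, l5 = truncated_lengths(mesh, lm)
        assert l1 == pytest.approx(180.0, abs=1e-9)
        assert l5 == pytest.approx(180.0, abs=1e-9)

    def test_mt_behind_heel_errors(self):
        mesh, lm = self._leg_scene()
        lm.points["MT1"] = np.array([-40.0, -10.0, 0.0])
        with pytest.raises(GeometryError):
            truncated_lengths(mesh, lm)


class TestLandmarkDistances:
    def test_worked_example(self):
        lm = LandmarkSet(
            {
                "HEEL": [0.0, 0.0, 0.0],
                "MT1": [-40.0, 180.0, 0.0],
                "MT5": [40.0, 180.0, 0.0],
                "ARCH": [-25.0, 100.0, 15.0],
            }
        )
        d1h, d15, d5h = landmark_distances(lm)
        assert d1h == pytest.approx(np.sqrt(40**2 + 180**2))
        assert d15 == pytest.approx(80.0)
        assert d5h == pytest.approx(np.sqrt(40**2 + 180**2))

    def test_triangle_inequality(self, foot_scene):
        _, lm = foot_scene
        d1h, d15, d5h = landmark_distances(lm)
        assert d1h < d15 + d5h
        assert d15 < d1h + d5h
        assert d5h < d1h + d15


class TestWidths:
    def test_rectangle_chords(self):
        box = box_mesh((90, 250, 40), center=(0, 125, 20))
        trace = plantar_trace(box, 50.0)
        lm = LandmarkSet(
            {
                "HEEL": [0.0, 20.0, 0.0],
                "MT1": [-40.0, 180.0, 5.0],
                "MT5": [42.0, 175.0, 6.0],
                "ARCH": [-20.0, 100.0, 15.0],
            }
        )
        wf, wm, wh = widths(trace, lm)
        assert wf == pytest.approx(np.hypot(82.0, 5.0))  # projected MT distance
        assert wm == pytest.approx(90.0, abs=1e-9)
        assert wh == pytest.approx(90.0, abs=1e-9)

    def test_chord_missing_errors(self):
        box = box_mesh((90, 250, 40), center=(0, 125, 20))
        trace = plantar_trace(box, 50.0)
        lm = LandmarkSet(
            {
                "HEEL": [0.0, -500.0, 0.0],  # far behind the trace
                "MT1": [-40.0, 180.0, 0.0],
                "MT5": [40.0, 180.0, 0.0],
                "ARCH": [-20.0, 100.0, 15.0],
            }
        )
        with pytest.raises(GeometryError):
            widths(trace, lm)


class TestGirths:
    def test_elliptical_cylinder_oracle(self):
        # axis-Y elliptical cylinder: cross-section semi-axes (x=25, z=40)
        cyl = cylinder_mesh(40.0, height=300.0, sections=256, radius_y=25.0,
                            axis="y", center=(0, 150, 0))
        lm = LandmarkSet(
            {
                "HEEL": [0.0, 20.0, 0.0],
                "MT1": [-15.0, 260.0, 0.0],
                "MT5": [15.0, 260.0, 0.0],
                "ARCH": [-20.0, 120.0, 10.0],
            }
        )
        gf, gm, gh = girths(cyl, lm)
        expected = ramanujan_perimeter(40.0, 25.0)
        assert gm == pytest.approx(expected, rel=5e-3)  # Y-normal plane
        assert gf == pytest.approx(expected, rel=5e-3)  # vertical plane through MTs
        assert gh is None  # no malleoli

    def test_girth_scales_with_scene(self, foot_scene):
        mesh, lm = foot_scene
        g1 = girths(mesh, lm)
        scaled = TriangleMesh(mesh.vertices * 2.0, mesh.faces)
        lm2 = LandmarkSet({lid: lm[lid] * 2.0 for lid in lm.ids})
        g2 = girths(scaled, lm2)
        for a, b in zip(g1, g2):
            assert b == pytest.approx(2.0 * a, rel=1e-9)

    def test_forefoot_girth_exceeds_twice_width(self, foot_report):
        assert foot_report.forefoot_girth > 2 * foot_report.forefoot_width


class TestArchAndAnkle:
    def test_arch_arithmetic(self):
        lm = LandmarkSet({"HEEL": [0, 0, 0], "MT1": [-40, 180, 0],
                          "MT5": [40, 180, 0], "ARCH": [-25, 100, 15]})
        ah, ahi = arch_metrics(lm, 180.0)
        assert ah == pytest.approx(15.0)
        assert ahi == pytest.approx(15.0 / 180.0)

    def test_arch_on_plane_is_zero(self):
        lm = LandmarkSet({"HEEL": [0, 0, 0], "MT1": [-40, 180, 0],
                          "MT5": [40, 180, 0], "ARCH": [-25, 100, 0]})
        ah, ahi = arch_metrics(lm, 180.0)
        assert ah == 0.0
        assert ahi == 0.0

    def test_arch_below_plane_errors(self):
        lm = LandmarkSet({"HEEL": [0, 0, 0], "MT1": [-40, 180, 0],
                          "MT5": [40, 180, 0], "ARCH": [-25, 100, -5]})
        with pytest.raises(GeometryError):
            arch_metrics(lm, 180.0)

    def test_ankle_vertical_is_zero(self):
        lm = LandmarkSet({"HEEL": [0, 0, 0], "MT1": [-40, 180, 0],
                          "MT5": [40, 180, 0], "ARCH": [-25, 100, 15],
                          "MED_MAL": [-20, 0, 60], "LAT_MAL": [20, 0, 60]})
        assert ankle_angle(lm) == pytest.approx(0.0, abs=1e-12)

    def test_ankle_45_degrees(self):
        lm = LandmarkSet({"HEEL": [0, 0, 0], "MT1": [-40, 180, 0],
                          "MT5": [40, 180, 0], "ARCH": [-25, 100, 15],
                          "MED_MAL": [-20, 60, 60], "LAT_MAL": [20, 60, 60]})
        assert ankle_angle(lm) == pytest.approx(45.0, abs=1e-9)

    def test_coincident_points_error(self):
        lm = LandmarkSet({"HEEL": [0, 0, 0], "MT1": [-40, 180, 0],
                          "MT5": [40, 180, 0], "ARCH": [-25, 100, 15],
                          "MED_MAL": [0, 0, 0], "LAT_MAL": [0, 0, 0]})
        with pytest.raises(GeometryError):
            ankle_angle(lm)


class TestMeasureFoot:
    def test_full_report_has_15_values(self, foot_report):
        assert len(foot_report.values) == 15
        assert set(foot_report.values) == set(MEASUREMENT_NAMES)
        assert all(v is not None for v in foot_report.values.values())
        foot_report.validate()

    def test_missing_malleoli_flagged(self, foot_scene):
        mesh, lm = foot_scene
        partial = LandmarkSet({k: lm[k] for k in ("HEEL", "MT1", "MT5", "ARCH")})
        rep = measure_foot(mesh, partial)
        assert rep.values["hindfoot_girth"] is None
        assert rep.values["ankle_angle"] is None
        assert "hindfoot_girth:missing_malleoli" in rep.flags
        assert "ankle_angle:missing_malleoli" in rep.flags
        assert "foot_length:untrimmed" in rep.flags
        assert rep.values["foot_length"] is not None

    def test_similarity_equivariance(self, foot_scene, foot_report):
        mesh, lm = foot_scene
        s = 2.0
        scaled = TriangleMesh(mesh.vertices * s, mesh.faces)
        lm2 = LandmarkSet({lid: lm[lid] * s for lid in lm.ids})
        rep = measure_foot(scaled, lm2)
        for name in MEASUREMENT_NAMES:
            if name in ("arch_height_index", "ankle_angle"):
                assert rep.values[name] == pytest.approx(
                    foot_report.values[name], rel=1e-6
                )
            else:
                assert rep.values[name] == pytest.approx(
                    s * foot_report.values[name], rel=1e-6
                )

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_invariance(self, foot_scene, foot_report, seed):
        mesh, lm = foot_scene
        t = random_rigid_transform(seed, max_translation=120.0)
        mesh_t, lm_t = register(mesh, lm, t)
        rep = measure_foot(mesh_t, lm_t)
        for name in MEASUREMENT_NAMES:
            assert rep.values[name] == pytest.approx(
                foot_report.values[name], rel=1e-6
            ), name

    def test_errors_carry_measurement_name(self, foot_scene):
        mesh, lm = foot_scene
        bad = lm.copy()
        bad.points["ARCH"][2] = -30.0  # below the plantar plane after registration
        with pytest.raises(MeasurementError) as err:
            measure_foot(mesh, bad)
        assert err.value.measurement in MEASUREMENT_NAMES

    def test_arch_parameter_monotonicity(self):
        values = []
        for ah in (10.0, 16.0, 22.0):
            mesh, lm = generate_foot(
                FootParams(arch_height=ah), resolution=24, seed=0
            )
            rep = measure_foot(mesh, lm)
            values.append((rep.values["arch_height"], rep.values["arch_height_index"]))
        heights = [v[0] for v in values]
        indices = [v[1] for v in values]
        assert heights == sorted(heights) and len(set(heights)) == 3
        assert indices == sorted(indices) and len(set(indices)) == 3
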