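import collections

import numpy as np
import pytest

from footmetry.errors import InvalidDesignError
from footmetry.mesh_io import MEASUREMENT_NAMES
from footmetry.morphometry import measure_foot
from footmetry.reliability_stats import reliability_table
from footmetry.synthetic_foot import (
    FootParams,
    RaterModel,
    StudyDesign,
    apply_weight_bearing,
    default_raters,
    generate_foot,
    generate_study_scans,
    perturb_landmarks,
    random_rigid_transform,
    simulate_reliability_study,
)


def edge_face_counts(mesh):
    counts = collections.Counter()
    for a, b, c in mesh.faces:
        for e in ((a, b), (b, c), (c, a)):
            counts[tuple(sorted(e))] += 1
    return counts


class TestGenerator:
    def test_determinism(self, default_params):
        m1, l1 = generate_foot(default_params, resolution=24, seed=5)
        m2, l2 = generate_foot(default_params, resolution=24, seed=5)
        np.testing.assert_array_equal(m1.vertices, m2.vertices)
        np.testing.assert_array_equal(m1.faces, m2.faces)
        for lid in l1.ids:
            np.testing.assert_array_equal(l1[lid], l2[lid])

    @pytest.mark.parametrize("resolution", [16, 32, 48])
    def test_closed_manifold(self, default_params, resolution):
        mesh, _ = generate_foot(default_params, resolution=resolution)
        counts = edge_face_counts(mesh)
        assert set(counts.values()) == {2}

    def test_landmarks_inside_expanded_bbox(self, foot_scene):
        mesh, lm = foot_scene
        lo, hi = mesh.bounds()
        for lid in lm.ids:
            assert np.all(lm[lid] >= lo - 10.0) and np.all(lm[lid] <= hi + 10.0)

    def test_parameter_recovery(self):
        params = FootParams(
            length=250.0, forefoot_width=95.0, heel_width=62.0, arch_height=22.0
        )
        mesh, lm = generate_foot(params, resolution=48, seed=0)
        rep = measure_foot(mesh, lm)
        assert rep.values["foot_length"] == pytest.approx(250.0, abs=2.0)
        assert rep.values["forefoot_width"] == pytest.approx(95.0, abs=2.0)
        assert rep.values["heel_width"] == pytest.approx(62.0, abs=2.0)
        assert rep.values["arch_height"] == pytest.approx(22.0, abs=0.5)

    def test_mesh_convergence(self, default_params):
        m1, l1 = generate_foot(default_params, resolution=32)
        m2, l2 = generate_foot(default_params, resolution=64)
        r1 = measure_foot(m1, l1)
        r2 = measure_foot(m2, l2)
        for name in MEASUREMENT_NAMES:
            assert r2.values[name] == pytest.approx(r1.values[name], rel=5e-3), name

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidDesignError):
            generate_foot(FootParams(arch_height=80.0, instep_height=60.0))
        with pytest.raises(InvalidDesignError):
            generate_foot(FootParams(), resolution=8)


class TestWeightBearing:
    def test_zero_load_identity(self, foot_scene, default_params):
        mesh, lm = foot_scene
        m0, l0 = apply_weight_bearing(mesh, lm, default_params, 0.0)
        np.testing.assert_array_equal(m0.vertices, mesh.vertices)
        for lid in lm.ids:
            np.testing.assert_array_equal(l0[lid], lm[lid])

    def test_full_load_halves_arch(self, foot_scene, default_params):
        mesh, lm = foot_scene
        base = measure_foot(mesh, lm).values["arch_height"]
        m1, l1 = apply_weight_bearing(mesh, lm, default_params, 1.0)
        loaded = measure_foot(m1, l1).values["arch_height"]
        assert loaded == pytest.approx(0.5 * base, abs=0.5)

    def test_widths_increase_with_load(self, foot_scene, default_params):
        mesh, lm = foot_scene
        widths = []
        for load in (0.0, 0.5, 1.0):
            m, l = apply_weight_bearing(mesh, lm, default_params, load)
            rep = measure_foot(m, l)
            widths.append((rep.values["forefoot_width"], rep.values["heel_width"]))
        assert widths[0][0] < widths[1][0] < widths[2][0]
        assert widths[0][1] < widths[1][1] < widths[2][1]

    def test_bad_load_rejected(self, foot_scene, default_params):
        mesh, lm = foot_scene
        with pytest.raises(InvalidDesignError):
            apply_weight_bearing(mesh, lm, default_params, 1.5)


class TestRaterNoise:
    def test_zero_noise_is_identity(self, foot_scene):
        _, lm = foot_scene
        model = RaterModel.guided(sigma=0.0)
        out = perturb_landmarks(lm, model, seed=3)
        for lid in lm.ids:
            np.testing.assert_array_equal(out[lid], lm[lid])

    def test_seed_determinism(self, foot_scene):
        _, lm = foot_scene
        model = RaterModel.guided(sigma=2.0)
        a = perturb_landmarks(lm, model, seed=7)
        b = perturb_landmarks(lm, model, seed=7)
        c = perturb_landmarks(lm, model, seed=8)
        for lid in lm.ids:
            np.testing.assert_array_equal(a[lid], b[lid])
        assert any(not np.array_equal(a[lid], c[lid]) for lid in lm.ids)

    def test_sample_sd_matches_sigma(self, foot_scene):
        _, lm = foot_scene
        sigma = 2.0
        model = RaterModel(mode="guided", sigma=sigma)  # isotropic jitter
        draws = np.array(
            [perturb_landmarks(lm, model, seed=i)["HEEL"] for i in range(10_000)]
        )
        sd = draws.std(axis=0, ddof=1)
        np.testing.assert_allclose(sd, sigma, rtol=0.05)

    def test_tangential_jitter_stays_in_plane(self, foot_scene):
        _, lm = foot_scene
        model = RaterModel(
            mode="guided", sigma=3.0, tangential_only=True
        )
        out = perturb_landmarks(lm, model, seed=11)
        for lid in ("HEEL", "MT1", "MT5"):  # plantar normal is +Z
            assert out[lid][2] == pytest.approx(lm[lid][2], abs=1e-12)

    def test_source_field_set(self, foot_scene):
        _, lm = foot_scene
        model = RaterModel.scan_derived(seed=1)
        assert perturb_landmarks(lm, model, seed=0).source == "scan_derived"

    def test_guided_default_sigma_below_scan_derived(self):
        guided = RaterModel.guided()
        scan = RaterModel.scan_derived(seed=0)
        assert max(guided.sigma.values()) <= min(scan.sigma.values())


class TestStudySimulation:
    @staticmethod
    def _small_design(**kw):
        defaults = dict(
            n_subjects=3,
            feet_per_subject=1,
            conditions=("NWB",),
            raters=tuple(default_raters("guided", n=3, sigma=0.0)),
            repetitions=1,
            seed=4,
            resolution=24,
        )
        defaults.update(kw)
        return StudyDesign(**defaults)

    def test_scan_count_per_condition(self):
        design = self._small_design(n_subjects=2, feet_per_subject=2,
                                    conditions=("NWB", "HWB"))
        scans = generate_study_scans(design)
        by_cond = collections.Counter(s["condition"] for s in scans)
        assert by_cond == {"NWB": 4, "HWB": 4}

    def test_zero_noise_gives_unit_icc(self):
        panel, prov = simulate_reliability_study(self._small_design())
        assert prov["n_scans"] == 3
        out = reliability_table(panel, mode="inter")
        assert len(out) == 15
        assert (out["icc"] == 1.0).all()

    def test_panel_shape(self):
        design = self._small_design(repetitions=2)
        panel, _ = simulate_reliability_study(design)
        # 3 scans x 3 raters x 2 reps x 15 measurements
        assert len(panel) == 3 * 3 * 2 * 15
        assert set(panel.columns) == {
            "subject", "rater", "repetition", "condition", "measurement", "value",
        }

    def test_panel_determinism(self):
        p1, _ = simulate_reliability_study(self._small_design())
        p2, _ = simulate_reliability_study(self._small_design())
        assert p1.equals(p2)

    def test_noise_reduces_icc(self):
        quiet, _ = simulate_reliability_study(self._small_design(n_subjects=4))
        noisy, _ = simulate_reliability_study(
            self._small_design(
                n_subjects=4,
                raters=tuple(default_raters("scan_derived", n=3, seed=1, sigma=4.0)),
            )
        )
        icc_q = reliability_table(quiet, mode="inter")["icc"].mean()
        icc_n = reliability_table(noisy, mode="inter")["icc"].mean()
        assert icc_n < icc_q


class TestRandomRigidTransform:
    def test_proper_rotation(self):
        for seed in range(10):
            t = random_rigid_transform(seed)
            assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(
                t.rotation @ t.rotation.T, np.eye(3), atol=1e-12
            )

    def test_seed_determinism(self):
        t1 = random_rigid_transform(9)
        t2 = random_rigid_transform(9)
        np.testing.assert_array_equal(t1.rotation, t2.rotation)
        np.testing.assert_array_equal(t1.translation, t2.translation)

    def test_translation_bounded(self):
        t = random_rigid_transform(3, max_translation=10.0)
        assert np.all(np.abs(t.translation) <= 10.0)
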