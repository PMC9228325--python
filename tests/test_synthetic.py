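"""Generator: growth curve, parametric solids, sampling, herd simulation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bovimetry import synthetic as syn
from bovimetry.morphometrics import mesh_surface_area, mesh_volume


@pytest.fixture(scope="module")
def growth():
    return syn.default_growth_params()


class TestGrowthCurve:
    def test_birth_weight_at_age_zero(self, growth):
        assert syn.growth_state_at_age(growth, 0.0).bw == pytest.approx(
            growth.birth_bw, rel=1e-12
        )

    def test_asymptote_at_large_age(self, growth):
        assert syn.growth_state_at_age(growth, 1e7).bw == pytest.approx(
            growth.asymptote_bw, rel=1e-6
        )

    def test_one_year_weight_matches_reference_envelope(self, growth):
        # reference herd weighed 366.8 (±47.2) kg at 369.2 d
        assert 320.0 <= syn.growth_state_at_age(growth, 369.0).bw <= 414.0

    def test_strictly_increasing_in_age(self, growth):
        ages = np.linspace(0, 900, 120)
        states = [syn.growth_state_at_age(growth, a) for a in ages]
        for trait in ("bw", "hg", "wh", "cd", "hw", "kw", "bsa", "volume"):
            vals = np.array([getattr(s, trait) for s in states])
            assert np.all(np.diff(vals) > 0), trait

    def test_negative_age_rejected(self, growth):
        with pytest.raises(ValueError):
            syn.growth_state_at_age(growth, -1.0)


class TestShapeGroundTruth:
    def test_scaling_law_exact(self):
        shape = syn.shape_preset("month12")
        t1 = syn.ground_truth(shape)
        t2 = syn.ground_truth(shape.scaled(2.0))
        assert t2.volume == pytest.approx(8.0 * t1.volume, rel=1e-9)
        assert t2.bsa == pytest.approx(4.0 * t1.bsa, rel=1e-9)
        for trait in ("hg", "wh", "cd", "hw", "kw"):
            assert getattr(t2, trait) == pytest.approx(
                2.0 * getattr(t1, trait), rel=1e-9
            )

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(s=st.floats(min_value=0.5, max_value=3.0))
    def test_scaling_law_any_factor(self, s):
        shape = syn.shape_preset("month06")
        t1, t2 = syn.ground_truth(shape), syn.ground_truth(shape.scaled(s))
        assert t2.volume == pytest.approx(s**3 * t1.volume, rel=1e-9)
        assert t2.bsa == pytest.approx(s**2 * t1.bsa, rel=1e-9)

    def test_girth_encloses_chest_depth(self):
        for stage in syn.PRESET_STAGES:
            t = syn.ground_truth(syn.shape_preset(stage))
            assert t.hg > 2 * t.cd

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            syn.AnimalShapeParams(
                torso_length=1.0, torso_height_radius=0.3, torso_width_radius=0.2,
                cap_front=0.6, cap_rear=0.6,  # caps longer than the torso
                leg_length=0.5, leg_radius=0.05, neck_length=0.2, neck_radius=0.08,
                head_length=0.3, head_radius=0.12, leg_stance_fore=0.3,
                leg_stance_hind=0.8, leg_stance_y=0.12,
            )


def _sphere_params(r):
    return syn.AnimalShapeParams(
        torso_length=2 * r, torso_height_radius=r, torso_width_radius=r,
        cap_front=r, cap_rear=r, leg_length=0.0, leg_radius=0.0,
        neck_length=0.0, neck_radius=0.0, head_length=0.0, head_radius=0.0,
        leg_stance_fore=0.0, leg_stance_hind=0.0, leg_stance_y=0.0,
        include_legs=False, include_neck=False, include_head=False,
    )


class TestMeshBuild:
    @pytest.mark.parametrize("resolution,tol", [(64, 0.01), (256, 0.001)])
    def test_degenerate_sphere_closed_form(self, resolution, tol):
        r = 0.4
        mesh, truth = syn.build_heifer_mesh(_sphere_params(r), resolution=resolution)
        v_true, a_true = 4 / 3 * np.pi * r**3, 4 * np.pi * r**2
        assert truth.volume == pytest.approx(v_true, rel=1e-6)
        assert truth.bsa == pytest.approx(a_true, rel=1e-6)
        assert mesh_volume(mesh) == pytest.approx(v_true, rel=tol)
        assert mesh_surface_area(mesh) == pytest.approx(a_true, rel=tol)

    def test_watertight_and_single_component(self, month12):
        mesh, _ = month12
        assert mesh.is_watertight
        assert len(mesh.split()) == 1
        assert mesh.volume > 0  # outward orientation

    def test_month12_volume_brackets_reference(self, month12):
        _, truth = month12
        assert 0.33 <= truth.volume <= 0.53  # 0.43 ± 2*0.05

    def test_resolution_floor(self):
        with pytest.raises(ValueError):
            syn.build_heifer_mesh(syn.shape_preset("month02"), resolution=4)


class TestPointSampling:
    def test_noiseless_points_on_surface(self):
        import trimesh

        box = trimesh.creation.box(extents=[1.0, 1.0, 1.0])
        cloud = syn.sample_point_cloud(box, 2000, 0.0, seed=5)
        # every noiseless sample of the unit cube lies on a face plane
        assert np.max(np.abs(np.abs(cloud.points).max(axis=1) - 0.5)) < 1e-12

    def test_same_seed_bitwise_identical(self, month12_coarse):
        mesh, _ = month12_coarse
        a = syn.sample_point_cloud(mesh, 1000, 0.001, seed=9)
        b = syn.sample_point_cloud(mesh, 1000, 0.001, seed=9)
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.normals, b.normals)
        c = syn.sample_point_cloud(mesh, 1000, 0.001, seed=10)
        assert not np.array_equal(a.points, c.points)

    def test_noisy_sphere_mean_radius(self, unit_sphere):
        # displacement along the radial normal keeps E[r] = 1
        sd, n = 0.01, 10000
        cloud = syn.sample_point_cloud(unit_sphere, n, sd, seed=3)
        r = np.linalg.norm(cloud.points, axis=1)
        assert abs(r.mean() - 1.0) < 3 * sd / np.sqrt(n) + 5e-4  # + facet sagitta

    def test_minimum_points_enforced(self, unit_sphere):
        with pytest.raises(ValueError):
            syn.sample_point_cloud(unit_sphere, 50, 0.0, seed=1)


class TestSkirt:
    def test_zero_severity_is_identity(self, month12_coarse):
        mesh, _ = month12_coarse
        out = syn.inject_skirt(mesh, 0.0, seed=1)
        assert out.volume == pytest.approx(mesh.volume, abs=1e-9)

    def test_positive_severity_strictly_inflates(self, month12_coarse):
        mesh, _ = month12_coarse
        prev = mesh.volume
        for sev in (0.25, 0.5, 1.0):
            out = syn.inject_skirt(mesh, sev, seed=2)
            assert out.is_watertight
            assert out.volume > prev
            assert out.area > mesh.area

    def test_no_legs_errors(self, month12_coarse):
        mesh, _ = month12_coarse
        headless_legless = syn.remove_region(mesh, "legs")
        with pytest.raises(ValueError):
            syn.inject_skirt(mesh, -0.1, seed=1)
        with pytest.raises(ValueError):
            # legless body has no leg pairs to web (also not watertight)
            syn.inject_skirt(headless_legless, 0.5, seed=1)


class TestHerdSimulation:
    def test_zero_noise_matches_growth_curve(self, growth):
        quiet = dataclasses.replace(growth, noise_sd={}, animal_cv=0.0, bw_scale_sd=0.0)
        traits, weights = syn.simulate_herd(quiet, 1, [62.0, 369.0], seed=0)
        for rec in traits:
            state = syn.growth_state_at_age(quiet, rec.age)
            for t in ("hg", "wh", "cd", "hw", "kw", "bsa", "volume"):
                assert rec.get(t) == pytest.approx(getattr(state, t), rel=1e-12)
        for w in weights:
            assert w.bw == pytest.approx(syn.growth_state_at_age(quiet, w.age).bw)

    def test_monthly_visits_give_at_least_20_weighings(self, growth):
        ages = list(np.arange(35.0, 620.0, 30.0))
        traits, weights = syn.simulate_herd(growth, 5, ages, seed=1)
        per_animal = {}
        for w in weights:
            per_animal[w.animal_id] = per_animal.get(w.animal_id, 0) + 1
        assert len(per_animal) == 5
        assert all(c >= 20 for c in per_animal.values())

    def test_between_animal_sd_calibrated(self, growth):
        """Sample SD of BW at 369 d vs the configured between-animal spread."""
        _, weights = syn.simulate_herd(growth, 100, [369.0], seed=7)
        sample_sd = np.std([w.bw for w in weights], ddof=1)
        a, b0, k = growth.asymptote_bw, growth.birth_bw, growth.rate
        t = 369.0
        sd_asym = growth.animal_cv * a * (1 - np.exp(-k * t))
        sd_rate = 0.5 * growth.animal_cv * k * (a - b0) * t * np.exp(-k * t)
        implied = np.sqrt(sd_asym**2 + sd_rate**2 + growth.bw_scale_sd**2)
        assert abs(sample_sd - implied) / implied < 0.30

    def test_determinism(self, growth):
        t1, w1 = syn.simulate_herd(growth, 3, [100.0, 200.0], seed=11)
        t2, w2 = syn.simulate_herd(growth, 3, [100.0, 200.0], seed=11)
        assert [r.as_dict() for r in t1] == [r.as_dict() for r in t2]
        assert [(w.animal_id, w.age, w.bw) for w in w1] == [
            (w.animal_id, w.age, w.bw) for w in w2
        ]
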