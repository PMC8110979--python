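"""Synthetic cohort generator: determinism, calibration, geometry, meshes."""
import math

import numpy as np
import pytest

from airwaymorph.errors import ConfigError
from airwaymorph.geometry import AFH_LANDMARKS, Plane
from airwaymorph.measure import region_volume
from airwaymorph.normative import fit_growth
from airwaymorph.simulate import (
    GrowthConfig,
    _POLY_C,
    _profile_volume,
    draw_measurements,
    expected_value,
    generate_airway_mesh,
    generate_cohort,
    generate_subject,
    template_skull,
    tube_mesh,
    verify_latent_consistency,
)


class TestTemplate:
    def test_mirror_symmetry(self, template):
        for name in template.names():
            pos = template[name]
            if name.endswith("_L"):
                twin = template[name[:-2] + "_R"]
                assert pos[0] == pytest.approx(-twin[0], abs=1e-9)
                assert np.abs(pos[1:] - twin[1:]).max() < 1e-9
            elif not name.endswith("_R"):
                assert abs(pos[0]) < 1e-9      # midline landmarks on x=0

    def test_frankfort_landmarks_coplanar(self, template):
        zs = [template[n][2] for n in AFH_LANDMARKS]
        assert np.ptp(zs) < 1e-9

    def test_template_reproduces_control_reference_values(self, default_config):
        """Every directly constrained measurement of the noise-free template
        at the reference age lands within 20% of the control targets."""
        cfg = default_config.noiseless()
        s = generate_subject(cfg, "control", cfg.reference_age, "F", 0,
                             label_intercept=0.0)
        for name, params in cfg.measurements.items():
            assert s.true_measurements[name] == pytest.approx(
                params.value60, rel=0.20), name

    def test_all_thirty_landmarks(self, template):
        assert len(template) == 30


class TestDrawAndBuild:
    def test_noiseless_control_at_reference_age_is_template(self,
                                                            default_config):
        cfg = default_config.noiseless()
        s = generate_subject(cfg, "control", cfg.reference_age, "M", 1,
                             label_intercept=0.0)
        tpl = template_skull(default_config)
        for name in tpl.names():
            assert np.abs(s.landmarks_true[name] - tpl[name]).max() < 1e-9

    def test_hypoplasia_angle_offset(self, default_config):
        """Control baseline 69.0 plus the 9.6-degree deficit gives 78.6."""
        cfg = default_config.noiseless()
        s = generate_subject(cfg, "hypoplasia", cfg.reference_age, "M", 1,
                             label_intercept=0.0)
        assert s.true_measurements["inferior_pogonial_angle"] == pytest.approx(
            78.6, abs=1e-9)

    def test_determinism_same_seed_identical(self, default_config):
        a = generate_subject(default_config, "hypoplasia", 30.0, "F", 99,
                             label_intercept=-10.0)
        b = generate_subject(default_config, "hypoplasia", 30.0, "F", 99,
                             label_intercept=-10.0)
        assert a.true_measurements == b.true_measurements
        assert a.difficult_airway == b.difficult_airway
        for name in a.landmarks_true.names():
            assert np.array_equal(a.landmarks_true[name],
                                  b.landmarks_true[name])
            assert np.array_equal(a.observations["O2"][name],
                                  b.observations["O2"][name])

    def test_bilateral_symmetry_without_noise(self, default_config):
        cfg = default_config.noiseless()
        s = generate_subject(cfg, "hypoplasia", 45.0, "M", 3,
                             label_intercept=0.0)
        lm = s.landmarks_true
        for name in ("Go", "S_Co", "Pia", "Aia", "Body"):
            left, right = lm[f"{name}_L"], lm[f"{name}_R"]
            assert left[0] == pytest.approx(-right[0], abs=1e-9)
            assert np.abs(left[1:] - right[1:]).max() < 1e-9

    def test_latent_values_realized_by_geometry(self, cohort42,
                                                default_config):
        for subject in cohort42.subjects[:3]:
            table = verify_latent_consistency(subject, default_config)
            assert table["error"].max() < 1e-6

    def test_effect_directions_follow_group_contrasts(self, default_config):
        """Hypoplasia shortens hyoid/body measures and widens the angles."""
        cfg = default_config.noiseless()
        age = 30.0
        h = generate_subject(cfg, "hypoplasia", age, "M", 0,
                             label_intercept=0.0).true_measurements
        c = generate_subject(cfg, "control", age, "M", 0,
                             label_intercept=0.0).true_measurements
        for shorter in ("hyoid_anterior_distance", "hyoid_posterior_distance",
                        "body_total_length", "ramus_width",
                        "tongue_position_palate"):
            assert h[shorter] < c[shorter]
        for wider in ("inferior_pogonial_angle", "gonial_angle",
                      "tongue_position_ans"):
            assert h[wider] > c[wider]


class TestCohort:
    def test_group_contrast_converges(self):
        """Law of large numbers: the empirical angle contrast at large n and
        zero noise matches the configured offset."""
        cfg = GrowthConfig().noiseless()
        rng = np.random.default_rng(60)
        diffs = []
        for _ in range(2000):
            age = float(np.exp(rng.uniform(np.log(4), np.log(200))))
            h = draw_measurements(cfg, "hypoplasia", age, rng)
            c = draw_measurements(cfg, "control", age, rng)
            diffs.append(h["inferior_pogonial_angle"]
                         - c["inferior_pogonial_angle"])
        assert abs(np.mean(diffs) - 9.6) < 0.5

    def test_smoke_cohort_runs_end_to_end(self, cohort42):
        assert len(cohort42.subjects) == 84
        demo = cohort42.demographics()
        assert set(demo["group"]) == {"hypoplasia", "control"}
        assert demo["difficult_airway"].isin([0, 1]).all()
        truth = cohort42.truth()
        assert truth.groupby("subject_id").size().min() >= 20

    def test_prevalence_calibration(self):
        cfg = GrowthConfig()
        cohort = generate_cohort(cfg, n_per_group=2500, seed=61)
        frac = cohort.demographics()["difficult_airway"].mean()
        assert frac == pytest.approx(0.12, abs=0.02)

    def test_cohort_determinism(self, default_config):
        a = generate_cohort(GrowthConfig(), n_per_group=5, seed=62)
        b = generate_cohort(GrowthConfig(), n_per_group=5, seed=62)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.subject_id == sb.subject_id
            assert sa.age_months == sb.age_months
            assert sa.true_measurements == sb.true_measurements
        c = generate_cohort(GrowthConfig(), n_per_group=5, seed=63)
        assert any(sa.age_months != sc.age_months
                   for sa, sc in zip(a.subjects, c.subjects))

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigError):
            GrowthConfig(prevalence=1.5)
        with pytest.raises(ConfigError):
            GrowthConfig(landmark_noise_sd=-1.0)
        with pytest.raises(ConfigError):
            generate_cohort(GrowthConfig(), n_per_group=0)

    def test_growth_parameter_recovery(self):
        """Fitting the normative model on a large control arm recovers the
        configured power-law exponent within Monte-Carlo error."""
        cfg = GrowthConfig()
        rng = np.random.default_rng(64)
        ages, values = [], []
        for _ in range(2000):
            age = float(np.exp(rng.uniform(np.log(4), np.log(200))))
            ages.append(age)
            values.append(draw_measurements(cfg, "control", age, rng)
                          ["ramus_height"])
        fit = fit_growth(ages, values)
        p = cfg.measurements["ramus_height"]
        assert fit.slope == pytest.approx(p.exponent, abs=0.02)
        assert math.exp(fit.intercept) * 60.0 ** fit.slope == pytest.approx(
            p.value60, rel=0.02)


class TestMeshes:
    def test_straight_tube_matches_cylinder_volumes(self):
        r, knots = 5.0, [(30.0, 5.0), (0.0, 5.0)]
        mesh = tube_mesh(knots)
        assert mesh.is_watertight
        lo = Plane((0, 0, 10.0), (0, 0, 1))
        hi = Plane((0, 0, 25.0), (0, 0, 1))
        v = region_volume(mesh, lo, hi) * 1000.0
        exact_circle = math.pi * r * r * 15.0
        assert abs(v - exact_circle) / exact_circle < 0.005
        # exact against the polygonal closed form
        assert v == pytest.approx(_POLY_C * r * r * 15.0, abs=1e-9)

    def test_zero_height_compartment_volume(self):
        knots = [(10.0, 3.0), (0.0, 3.0)]
        assert _profile_volume(knots, 5.0, 5.0) == 0.0

    def test_mesh_volumes_match_generator_analytics(self, cohort42,
                                                    default_config):
        subject = cohort42.subjects[5]
        meshes, analytic = generate_airway_mesh(subject, default_config)
        for m in meshes.values():
            assert m.is_watertight
        total = sum(analytic[f"airway_volume_{c}"] for c in
                    ("nasopharynx", "oropharynx", "hypopharynx"))
        assert abs(meshes["airway_total"].volume / 1000.0 - total) < 1e-6

    def test_growth_expectation_monotone_in_age(self, default_config):
        p = default_config.measurements["hyoid_anterior_distance"]
        v1 = expected_value(p, "control", 12.0)
        v2 = expected_value(p, "control", 120.0)
        assert v2 > v1
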