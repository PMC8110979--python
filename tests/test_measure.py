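"""Distances, angles, projections and plane-bounded mesh regions."""
import math
import warnings

import numpy as np
import pytest
import trimesh

from airwaymorph.errors import (
    DegenerateAngleError,
    EmptyRegionWarning,
    MissingLandmarkError,
    OpenMeshError,
)
from airwaymorph.geometry import LandmarkSet, Plane
from airwaymorph.measure import (
    angle,
    distance,
    evaluate_specs,
    path_length,
    projected_distance,
    region_area,
    region_volume,
)
from airwaymorph.specs import DEFAULT_MEASUREMENT_NAMES, DEFAULT_SPECS
from airwaymorph.simulate import generate_airway_mesh

from conftest import random_rigid


def lmset(**points) -> LandmarkSet:
    return LandmarkSet("s", "o", points)


class TestPointMeasures:
    def test_three_four_five(self):
        lm = lmset(A=(0, 0, 0), B=(3, 4, 0))
        assert distance(lm, "A", "B") == pytest.approx(5.0, abs=1e-12)
        assert distance(lm, "B", "A") == pytest.approx(5.0, abs=1e-12)

    def test_distance_identity_and_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a, b = rng.uniform(-50, 50, (2, 3))
            lm = lmset(A=a, B=b)
            oracle = math.sqrt(sum((a[i] - b[i]) ** 2 for i in range(3)))
            assert distance(lm, "A", "B") == pytest.approx(oracle, abs=1e-12)
        lm = lmset(A=(1, 2, 3), B=(1, 2, 3))
        assert distance(lm, "A", "B") == 0.0

    def test_missing_landmark_raises(self):
        with pytest.raises(MissingLandmarkError):
            distance(lmset(A=(0, 0, 0)), "A", "B")

    def test_right_angle_and_collinear(self):
        lm = lmset(Go_L=(-1, 0, 0), Pog=(0, 1, 0), Go_R=(1, 0, 0))
        assert angle(lm, "Go_L", "Pog", "Go_R") == pytest.approx(90.0, abs=1e-9)
        lm = lmset(A=(-2, 0, 0), M=(0, 0, 0), B=(5, 0, 0))
        assert angle(lm, "A", "M", "B") == pytest.approx(180.0, abs=1e-9)

    def test_angle_against_law_of_cosines_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a, apex, b = rng.uniform(-20, 20, (3, 3))
            lm = lmset(A=a, M=apex, B=b)
            ra = np.linalg.norm(a - apex)
            rb = np.linalg.norm(b - apex)
            c = np.linalg.norm(a - b)
            oracle = math.degrees(math.acos(
                np.clip((ra * ra + rb * rb - c * c) / (2 * ra * rb), -1, 1)))
            assert angle(lm, "A", "M", "B") == pytest.approx(oracle, abs=1e-9)

    def test_degenerate_ray_raises(self):
        lm = lmset(A=(0, 0, 0), M=(0, 0, 0), B=(1, 0, 0))
        with pytest.raises(DegenerateAngleError):
            angle(lm, "A", "M", "B")

    def test_projected_distance_examples_and_oracle(self):
        plane = Plane((0, 0, 0), (0, 0, 1))
        assert projected_distance(lmset(P=(0, 0, 5)), "P", plane) == pytest.approx(5.0)
        assert projected_distance(lmset(P=(3, -2, 0)), "P", plane) == 0.0
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(-10, 10, 3)
            anchor = rng.uniform(-10, 10, 3)
            n = rng.normal(size=3)
            pl = Plane(anchor, n)
            d = projected_distance(lmset(P=p), "P", pl)
            foot = p - d * pl.normal          # orthogonal projection
            assert abs(pl.signed_distance(foot)) < 1e-9
            assert abs(abs(d) - np.linalg.norm(p - foot)) < 1e-9

    def test_rigid_invariance_of_distances_and_angles(self):
        rng = np.random.default_rng(3)
        pts = {k: rng.uniform(-30, 30, 3) for k in "ABCD"}
        lm = lmset(**pts)
        T = random_rigid(rng)
        lm2 = lm.transformed(T)
        assert distance(lm, "A", "B") == pytest.approx(
            distance(lm2, "A", "B"), abs=1e-9)
        assert angle(lm, "A", "C", "D") == pytest.approx(
            angle(lm2, "A", "C", "D"), abs=1e-9)
        assert path_length(lm, "ABCD") == pytest.approx(
            path_length(lm2, "ABCD"), abs=1e-9)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-10, 10, (3, 3))
        lm = lmset(A=pts[0], B=pts[1], C=pts[2])
        ab, bc, ac = (distance(lm, "A", "B"), distance(lm, "B", "C"),
                      distance(lm, "A", "C"))
        assert ac <= ab + bc + 1e-12


def zplane(z: float) -> Plane:
    return Plane((0.0, 0.0, z), (0.0, 0.0, 1.0))


class TestRegions:
    def test_cube_slab_volume_exact(self):
        cube = trimesh.creation.box(extents=[10, 10, 10])   # 1000 mm^3
        v = region_volume(cube, zplane(-2.5), zplane(2.5))
        assert v == pytest.approx(0.5, abs=1e-12)           # half, in cm^3

    def test_whole_mesh_volume(self):
        cube = trimesh.creation.box(extents=[10, 10, 10])
        v = region_volume(cube, zplane(-50), zplane(50))
        assert v == pytest.approx(abs(cube.volume) / 1000.0, abs=1e-12)

    def test_sphere_cap_closed_form(self):
        sph = trimesh.creation.icosphere(subdivisions=5, radius=10.0)
        assert len(sph.faces) >= 10000
        r, h = 10.0, 3.0
        v = region_volume(sph, zplane(h), zplane(r + 5))
        exact = math.pi * (r - h) ** 2 * (2 * r + h) / 3.0 / 1000.0
        assert abs(v - exact) / exact < 0.005

    def test_compartment_additivity(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        whole = region_volume(sph, zplane(-4), zplane(6))
        lowr = region_volume(sph, zplane(-4), zplane(1.234))
        uppr = region_volume(sph, zplane(1.234), zplane(6))
        assert abs(whole - (lowr + uppr)) < 1e-6

    def test_empty_region_warns_and_returns_zero(self):
        cube = trimesh.creation.box(extents=[10, 10, 10])
        with pytest.warns(EmptyRegionWarning):
            v = region_volume(cube, zplane(20), zplane(30))
        assert v == 0.0
        with pytest.warns(EmptyRegionWarning):
            a = region_area(cube, zplane(20), zplane(30),
                            Plane((0, 0, 0), (1, 0, 0)))
        assert a == 0.0

    def test_open_mesh_rejected(self):
        cube = trimesh.creation.box(extents=[10, 10, 10])
        open_mesh = trimesh.Trimesh(cube.vertices, cube.faces[:-2],
                                    process=False)
        with pytest.raises(OpenMeshError):
            region_volume(open_mesh, zplane(-1), zplane(1))

    def test_cube_section_area(self):
        cube = trimesh.creation.box(extents=[10, 10, 10])
        a = region_area(cube, zplane(-50), zplane(50),
                        Plane((0, 0, 0), (1, 0, 0)))
        assert a == pytest.approx(1.0, abs=1e-9)            # 100 mm^2 face
        half = region_area(cube, zplane(0), zplane(50),
                           Plane((0, 0, 0), (1, 0, 0)))
        assert half == pytest.approx(0.5, abs=1e-9)

    def test_sphere_segment_area_closed_form(self):
        sph = trimesh.creation.icosphere(subdivisions=5, radius=10.0)
        r, h = 10.0, 4.0
        a = region_area(sph, zplane(-h), zplane(h), Plane((0, 0, 0), (1, 0, 0)))
        exact = 2 * (h * math.sqrt(r * r - h * h)
                     + r * r * math.asin(h / r)) / 100.0
        assert abs(a - exact) / exact < 0.005


class TestEvaluateSpecs:
    def test_every_default_measurement_present(self, cohort42, default_config):
        subject = cohort42.subjects[0]
        meshes, _ = generate_airway_mesh(subject, default_config)
        table = evaluate_specs(subject.landmarks_true, meshes, DEFAULT_SPECS)
        produced = set(table["measurement"])
        for name in DEFAULT_MEASUREMENT_NAMES:
            assert name in produced
        avail = table[table["measurement"].isin(DEFAULT_MEASUREMENT_NAMES)]
        assert avail["available"].all()

    def test_unilateral_degradation(self, template):
        partial = template.drop("S_Co_R")
        table = evaluate_specs(partial, None, DEFAULT_SPECS)
        row = table[table["measurement"] == "ramus_height"].iloc[0]
        assert row["available"]
        assert row["note"] == "unilateral"
        left = table[table["measurement"] == "ramus_height__L"].iloc[0]
        assert row["value"] == pytest.approx(left["value"])

    def test_missing_landmark_flags_unavailable(self, template):
        partial = template.drop("Hyoid")
        table = evaluate_specs(partial, None, DEFAULT_SPECS)
        row = table[table["measurement"] == "hyoid_anterior_distance"].iloc[0]
        assert not row["available"]
        assert "MissingLandmarkError" in row["note"]

    def test_bigonial_distance_plausibility_fixture(self):
        lm = lmset(Go_L=(-34.7, 0, 0), Go_R=(34.7, 0, 0))
        assert distance(lm, "Go_L", "Go_R") == pytest.approx(69.4, abs=1e-12)

    def test_rigid_invariance_of_landmark_specs(self, template):
        rng = np.random.default_rng(12)
        specs = [s for s in DEFAULT_SPECS
                 if s.kind in ("distance", "angle", "path_length")]
        base = evaluate_specs(template, None, specs)
        moved = evaluate_specs(template.transformed(random_rigid(rng)),
                               None, specs)
        merged = base.merge(moved, on="measurement", suffixes=("_a", "_b"))
        assert np.allclose(merged["value_a"], merged["value_b"], atol=1e-9)
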