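"""Synthetic study-cohort generator.

Generates complete pipeline inputs — two-observer landmark sets, airway
meshes, demographics and difficult-airway labels — for two demographically
matched cohorts (mandibular hypoplasia vs healthy controls) with the
statistical structure the analysis assumes:

* each measurement follows power-law growth ``a * age^b`` in months,
  anchored so the control expectation at the 60-month reference age equals
  the control cohort's published central value;
* hypoplasia acts in measurement space (multiplicative deficits for
  dimensions, additive offsets for angles) and is back-propagated to
  landmark positions along fixed displacement directions, so the latent
  measurement values are realized by the geometry exactly;
* between-subject variation combines a shared log-normal size factor
  (weighted by the dimensionality of each measure) with independent
  per-measurement noise; angles get additive group-specific noise;
* difficult-airway labels are Bernoulli draws from a logistic model on the
  true (noise-free) inferior pogonial angle and hyoid anterior distance,
  with the intercept calibrated to the target prevalence;
* each observer sees the true landmarks plus isotropic Gaussian noise.

The generated geometry lives directly in the canonical frame (Frankfort
plane at z=0, midsagittal at x=0, coronal-vomer at y=0), so the reference
frame of a noise-free subject is the identity transform.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy import optimize
from scipy.special import expit

from .errors import ConfigError
from .geometry import LandmarkSet
from .measure import evaluate_specs
from .specs import DEFAULT_SPECS

REFERENCE_AGE = 60.0      # months
TUBE_SEGMENTS = 64        # polygon resolution of the airway tube
TRANSITION = 0.5          # mm, height of inter-compartment radius blends
#: polygonal cross-section area factor: area = _POLY_C * r^2
_POLY_C = 0.5 * TUBE_SEGMENTS * math.sin(2.0 * math.pi / TUBE_SEGMENTS)

#: cranial-base landmark coordinates (mm) at the reference age, canonical
#: frame; the Frankfort landmarks are exactly coplanar at z=0 and the set
#: is exactly mirror-symmetric across x=0.
CRANIAL_BASE = {
    "Orbitale_L": (-28.0, 60.0, 0.0), "Orbitale_R": (28.0, 60.0, 0.0),
    "Porion_L": (-55.0, 0.0, 0.0), "Porion_R": (55.0, 0.0, 0.0),
    "Nasion": (0.0, 72.0, 18.0), "Opisthion": (0.0, -68.0, -20.0),
    "Pa_V": (0.0, 0.0, -18.0), "ANS": (0.0, 52.0, -22.0),
    "Palate_Mid": (0.0, 30.0, -26.0),
}


@dataclass(frozen=True)
class MeasurementParams:
    """Growth-law and group-effect parameters for one measurement.

    ``dim`` is the length-dimensionality (1 length, 2 area, 3 volume, 0
    angle) and weights the shared log-normal size factor.  Angles use the
    additive ``hypo_offset`` and per-group additive SDs; everything else
    uses the multiplicative ``hypo_ratio``.
    """

    value60: float
    exponent: float
    dim: int = 1
    hypo_ratio: float = 1.0
    hypo_offset: float = 0.0
    sd_control: float = 0.0
    sd_hypo: float = 0.0

    def __post_init__(self):
        if self.value60 <= 0:
            raise ConfigError("value60 must be positive")


def _default_measurements() -> dict[str, MeasurementParams]:
    P = MeasurementParams
    return {
        # lengths / offsets (mm): control value at 60 months, growth
        # exponent, hypoplasia ratio
        "tongue_length": P(67.3, 0.12, 1, 74.1 / 67.3),
        "tongue_height": P(38.2, 0.12, 1, 39.1 / 38.2),
        "tongue_position_ans": P(8.3, 0.10, 1, 10.8 / 8.3),
        "tongue_position_palate": P(5.2, 0.10, 1, 3.1 / 5.2),
        "hyoid_anterior_distance": P(37.4, 0.137, 1, 31.6 / 37.4),
        "hyoid_posterior_distance": P(24.2, 0.077, 1, 21.8 / 24.2),
        "hyoid_craniocaudal_length": P(32.8, 0.15, 1, 33.5 / 32.8),
        "mandibular_plane_distance": P(5.3, 0.10, 1, 5.6 / 5.3),
        "ramus_height": P(36.2, 0.21, 1, 32.7 / 36.2),
        "ramus_width": P(27.8, 0.152, 1, 23.9 / 27.8),
        "body_total_length": P(86.6, 0.16, 1, 78.2 / 86.6),
        "body_width": P(63.3, 0.152, 1, 53.6 / 63.3),
        "bigonial_distance": P(73.6, 0.142, 1, 69.4 / 73.6),
        # angles (degrees): flat growth, additive offsets, per-group SDs
        "gonial_angle": P(129.1, 0.0, 0, hypo_offset=7.1,
                          sd_control=5.4, sd_hypo=6.4),
        "inferior_pogonial_angle": P(69.0, 0.0, 0, hypo_offset=9.6,
                                     sd_control=4.8, sd_hypo=9.6),
        # areas (cm^2) and volumes (cm^3)
        "tongue_area": P(10.30, 0.30, 2, 11.68 / 10.30),
        "airway_area_oral_cavity": P(20.23, 0.30, 2, 20.01 / 20.23),
        "airway_volume_nasopharynx": P(0.25, 0.55, 3, 0.32 / 0.25),
        "airway_volume_oropharynx": P(2.59, 0.57, 3, 1.74 / 2.59),
        "airway_volume_hypopharynx": P(1.37, 0.55, 3, 1.31 / 1.37),
        "airway_volume_oral_cavity": P(2.94, 0.40, 3, 2.35 / 2.94),
    }


@dataclass
class GrowthConfig:
    """All tunable parameters of the synthetic cohort."""

    measurements: dict[str, MeasurementParams] = field(
        default_factory=_default_measurements)
    landmark_noise_sd: float = 0.9       # mm per axis per observer
    shared_log_sd: float = 0.12          # shared size factor (log scale)
    meas_log_sd: float = 0.08            # independent residual (log scale)
    beta_ipa: float = math.log(1.11)     # label model, per degree
    beta_had: float = math.log(0.83)     # label model, per mm
    label_intercept: float | None = None  # None -> calibrated to prevalence
    prevalence: float = 10.0 / 84.0
    age_range: tuple[float, float] = (4.0, 200.0)   # months, log-uniform
    cranial_exponent: float = 0.08
    mandible_depth_exponent: float = 0.15
    reference_age: float = REFERENCE_AGE

    def __post_init__(self):
        if self.landmark_noise_sd < 0 or self.shared_log_sd < 0 \
                or self.meas_log_sd < 0:
            raise ConfigError("noise SDs must be non-negative")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError("prevalence must be in (0, 1)")
        if self.age_range[0] <= 0 or self.age_range[1] <= self.age_range[0]:
            raise ConfigError("invalid age range")

    def noiseless(self) -> "GrowthConfig":
        """Copy with all random variation switched off."""
        meas = {k: replace(v, sd_control=0.0, sd_hypo=0.0)
                for k, v in self.measurements.items()}
        return replace(self, measurements=meas, landmark_noise_sd=0.0,
                       shared_log_sd=0.0, meas_log_sd=0.0,
                       label_intercept=self.label_intercept)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str                       # "hypoplasia" | "control"
    age_months: float
    sex: str                         # "M" | "F"
    height_cm: float
    weight_kg: float
    difficult_airway: bool
    label_probability: float
    true_measurements: dict[str, float]
    landmarks_true: LandmarkSet
    observations: dict[str, LandmarkSet]


@dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    config: GrowthConfig
    seed: int

    def demographics(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "subject_id": s.subject_id, "group": s.group,
            "age_months": s.age_months, "sex": s.sex,
            "height_cm": s.height_cm, "weight_kg": s.weight_kg,
            "difficult_airway": int(s.difficult_airway)}
            for s in self.subjects])

    def landmark_sets(self, observer: str = "O1") -> list[LandmarkSet]:
        return [s.observations[observer] for s in self.subjects]

    def truth(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for m, v in s.true_measurements.items():
                rows.append({"subject_id": s.subject_id, "measurement": m,
                             "value": v})
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path, meshes: bool = False) -> None:
        from .io import write_demographics_csv, write_landmarks_csv
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sets = [ls for s in self.subjects for ls in s.observations.values()]
        write_landmarks_csv(sets, out / "landmarks.csv")
        write_demographics_csv(self.demographics(), out / "demographics.csv")
        truth = {s.subject_id: {"group": s.group,
                                "label_probability": s.label_probability,
                                "measurements": s.true_measurements}
                 for s in self.subjects}
        (out / "truth.json").write_text(json.dumps(truth, indent=2,
                                                   sort_keys=True))
        if meshes:
            mesh_dir = out / "meshes"
            mesh_dir.mkdir(exist_ok=True)
            for s in self.subjects:
                for label, mesh in generate_airway_mesh(s)[0].items():
                    mesh.export(mesh_dir / f"{s.subject_id}_{label}.off")


# ---------------------------------------------------------------------------
# measurement-space draws
# ---------------------------------------------------------------------------

def expected_value(params: MeasurementParams, group: str, age: float,
                   reference_age: float = REFERENCE_AGE) -> float:
    """Noise-free expected measurement for a group at an age."""
    v = params.value60 * (age / reference_age) ** params.exponent
    if group == "hypoplasia":
        v = v * params.hypo_ratio + params.hypo_offset
    return v


def draw_measurements(config: GrowthConfig, group: str, age: float,
                      rng: np.random.Generator) -> dict[str, float]:
    """One subject's latent measurement values (pre-geometry clamps)."""
    if group not in ("hypoplasia", "control"):
        raise ConfigError(f"unknown group {group!r}")
    shared = rng.normal(0.0, config.shared_log_sd) if config.shared_log_sd else 0.0
    out = {}
    for name in sorted(config.measurements):
        p = config.measurements[name]
        mu = expected_value(p, group, age, config.reference_age)
        if p.dim == 0:
            sd = p.sd_hypo if group == "hypoplasia" else p.sd_control
            out[name] = mu + (rng.normal(0.0, sd) if sd else 0.0)
        else:
            eps = rng.normal(0.0, config.meas_log_sd) if config.meas_log_sd else 0.0
            out[name] = mu * math.exp(p.dim * (shared + eps))
    return out


# ---------------------------------------------------------------------------
# landmark back-propagation
# ---------------------------------------------------------------------------

def build_landmarks(meas: dict[str, float], age: float,
                    config: GrowthConfig,
                    subject_id: str = "template") -> tuple[LandmarkSet, dict]:
    """Construct the 30-landmark geometry realizing the latent measurements.

    Works constraint-by-constraint so every directly constrained
    measurement is reproduced exactly; geometrically infeasible noise draws
    are clamped to the feasible boundary and the clamped value replaces the
    latent one (returned in the second element).
    """
    m = dict(meas)
    s = (age / config.reference_age) ** config.cranial_exponent
    sm = (age / config.reference_age) ** config.mandible_depth_exponent
    lm = LandmarkSet(subject_id, "truth")
    for name, pos in CRANIAL_BASE.items():
        lm.add(name, np.asarray(pos) * s)

    # feasibility clamps (see docs/methods.md)
    m["inferior_pogonial_angle"] = float(np.clip(m["inferior_pogonial_angle"],
                                                 20.0, 170.0))
    m["gonial_angle"] = float(np.clip(m["gonial_angle"], 95.0, 175.0))
    m["hyoid_craniocaudal_length"] = max(
        m["hyoid_craniocaudal_length"],
        18.0 * sm + m["mandibular_plane_distance"] + 1.0)
    m["hyoid_anterior_distance"] = max(
        m["hyoid_anterior_distance"],
        abs(m["hyoid_craniocaudal_length"] - 26.0 * sm) + 2.0)

    y_go, z_go, z_pog = -2.0 * sm, -18.0 * sm, -26.0 * sm

    # mandibular arch: bigonial distance and inferior pogonial angle
    bg = m["bigonial_distance"]
    ipa = math.radians(m["inferior_pogonial_angle"])
    a = (bg / 2.0) / math.tan(ipa / 2.0)        # apex-to-gonion line offset
    dz = z_go - z_pog
    y_pog = y_go + math.sqrt(max(a * a - dz * dz, 1.0))
    go_l = np.array([-bg / 2.0, y_go, z_go])
    go_r = np.array([bg / 2.0, y_go, z_go])
    pog = np.array([0.0, y_pog, z_pog])
    lm.add("Go_L", go_l)
    lm.add("Go_R", go_r)
    lm.add("Pog", pog)

    # ramus: condylion via gonial angle + ramus height; inner aspects via width
    ga = math.radians(m["gonial_angle"])
    rh, rw = m["ramus_height"], m["ramus_width"]
    z_hat = np.array([0.0, 0.0, 1.0])
    for side, go in (("L", go_l), ("R", go_r)):
        u = (pog - go) / np.linalg.norm(pog - go)
        w = z_hat - (z_hat @ u) * u
        w /= np.linalg.norm(w)
        sco = go + rh * (math.cos(ga) * u + math.sin(ga) * w)
        lm.add(f"S_Co_{side}", sco)
        r_hat = (sco - go) / rh
        d = np.cross([1.0, 0.0, 0.0], r_hat)
        d /= np.linalg.norm(d)
        if d[1] < 0:
            d = -d                              # orient anteriorly
        mid = go + 0.45 * rh * r_hat
        lm.add(f"Pia_{side}", mid - 0.5 * rw * d)
        lm.add(f"Aia_{side}", mid + 0.5 * rw * d)

    # mandibular body: lateral body points fix body width exactly and the
    # Go -> Body -> Pog path length via a vertical bow solved by brentq
    bw = m["body_width"]
    for side, go, sign in (("L", go_l, -1.0), ("R", go_r, 1.0)):
        mid = (go + pog) / 2.0
        base = np.array([sign * bw / 2.0, mid[1], mid[2]])

        def path(v):
            b = base - np.array([0.0, 0.0, v])
            return np.linalg.norm(go - b) + np.linalg.norm(b - pog)

        min_path = path(0.0)
        if m["body_total_length"] < min_path + 1.0:
            m["body_total_length"] = min_path + 1.0
        v = optimize.brentq(lambda t: path(t) - m["body_total_length"],
                            0.0, 400.0, xtol=1e-12)
        lm.add(f"Body_{side}", base - np.array([0.0, 0.0, v]))

    # hyoid: midline, depth below Frankfort = craniocaudal length,
    # anterior distance to pogonion exact
    z_h = -m["hyoid_craniocaudal_length"]
    had = m["hyoid_anterior_distance"]
    y_h = y_pog - math.sqrt(had * had - (z_h - z_pog) ** 2)
    hyoid = np.array([0.0, y_h, z_h])
    lm.add("Hyoid", hyoid)

    # menton depth solved so the hyoid's perpendicular offset from the
    # gonion-menton plane equals the mandibular plane distance
    y_me = y_pog - 4.0 * s
    mpd = m["mandibular_plane_distance"]

    def mpd_signed(z_me):
        me = np.array([0.0, y_me, z_me])
        n = np.cross(go_r - go_l, me - go_l)
        n /= np.linalg.norm(n)
        if n[2] < 0:
            n = -n
        return float(n @ (hyoid - go_l))

    zs = np.linspace(z_go - 1e-9, z_go - 120.0 * sm, 241)
    fs = np.array([mpd_signed(z) + mpd for z in zs])
    if np.all(fs < 0):
        # hyoid farther from every achievable plane than the target:
        # take the closest plane and clamp the latent distance to it
        k = int(np.argmax(fs))
        z_me = float(zs[k])
        m["mandibular_plane_distance"] = float(mpd - fs[k])
    else:
        k = int(np.argmax(fs >= 0))
        if k == 0:
            z_me = float(zs[0])
        else:
            z_me = optimize.brentq(lambda z: mpd_signed(z) + mpd,
                                   zs[k], zs[k - 1], xtol=1e-12)
    lm.add("Menton", np.array([0.0, y_me, z_me]))

    # cervical column: C3 posterior of the hyoid at the exact posterior
    # distance; neighbours placed relative to C3
    hpd = m["hyoid_posterior_distance"]
    c3 = hyoid + np.array([0.0, -hpd, 0.0])
    lm.add("Aa_C3", c3)
    lm.add("Aa_C2", c3 + np.array([0.0, 2.0 * s, 12.0 * s]))
    z_b1 = -20.0 * s                             # naso/oro boundary plane
    z_aia_c2 = min(c3[2] + 7.0 * s, z_b1 - 3.0 * s)
    lm.add("AIa_C2", np.array([0.0, c3[1] + 1.0 * s, z_aia_c2]))
    lm.add("AIa_C4", np.array([0.0, c3[1] - 2.0 * s, c3[2] - 16.0 * s]))

    # tongue: posterior offset from ANS and inferior offset from palate
    ans = lm["ANS"]
    pal = lm["Palate_Mid"]
    tip = np.array([0.0, ans[1] - m["tongue_position_ans"], ans[2] - 4.0 * s])
    dorsum = np.array([0.0, pal[1], pal[2] - m["tongue_position_palate"]])
    phi = math.radians(25.0)                     # tongue inclination
    base_pt = tip + m["tongue_length"] * np.array([0.0, -math.cos(phi),
                                                   -math.sin(phi)])
    lm.add("Tongue_Tip", tip)
    lm.add("Tongue_Dorsum", dorsum)
    lm.add("Tongue_Base", base_pt)
    lm.add("Tongue_Inf", dorsum + np.array([0.0, 0.0, -m["tongue_height"]]))
    return lm, m


def template_skull(config: GrowthConfig | None = None) -> LandmarkSet:
    """The canonical noise-free control template at the reference age."""
    config = (config or GrowthConfig()).noiseless()
    meas = {name: expected_value(p, "control", config.reference_age,
                                 config.reference_age)
            for name, p in config.measurements.items()}
    lm, _ = build_landmarks(meas, config.reference_age, config)
    return lm


# ---------------------------------------------------------------------------
# airway / oral-cavity meshes with analytic region values
# ---------------------------------------------------------------------------

def _profile_volume(knots: list[tuple[float, float]], z0: float,
                    z1: float) -> float:
    """Volume (mm^3) of the revolved polygonal profile between z0 < z1."""
    total = 0.0
    for (za, ra), (zb, rb) in zip(knots[1:], knots[:-1]):
        lo, hi = max(za, z0), min(zb, z1)
        if hi <= lo:
            continue
        r_lo = ra + (rb - ra) * (lo - za) / (zb - za)
        r_hi = ra + (rb - ra) * (hi - za) / (zb - za)
        total += _POLY_C * (hi - lo) * (r_lo ** 2 + r_lo * r_hi
                                        + r_hi ** 2) / 3.0
    return total


def _profile_section_area(knots, z0: float, z1: float) -> float:
    """Axis-plane section area (mm^2) of the profile between z0 < z1."""
    total = 0.0
    for (za, ra), (zb, rb) in zip(knots[1:], knots[:-1]):
        lo, hi = max(za, z0), min(zb, z1)
        if hi <= lo:
            continue
        r_lo = ra + (rb - ra) * (lo - za) / (zb - za)
        r_hi = ra + (rb - ra) * (hi - za) / (zb - za)
        total += (hi - lo) * (r_lo + r_hi)       # width 2r, trapezoid rule
    return total


def _make_knots(z_top, z_b1, z_b2, z_b3, radii) -> list[tuple[float, float]]:
    r1, r2, r3 = radii
    eps = TRANSITION / 2.0
    return [(z_top, r1), (z_b1 + eps, r1), (z_b1 - eps, r2),
            (z_b2 + eps, r2), (z_b2 - eps, r3), (z_b3, r3)]


def airway_profile(meas: dict[str, float], age: float,
                   config: GrowthConfig) -> dict:
    """Pharyngeal tube profile whose compartment volumes equal the latent
    targets exactly; returns knots, boundaries and analytic values."""
    s = (age / config.reference_age) ** config.cranial_exponent
    # boundary planes follow the same placement rules as the landmarks
    z_b1 = -20.0 * s
    z_h = -meas["hyoid_craniocaudal_length"]
    c3_z = z_h
    z_b2 = min(c3_z + 7.0 * s, z_b1 - 3.0 * s)
    z_b3 = c3_z - 16.0 * s
    z_top = z_b1 + 14.0 * s
    targets = np.array([meas["airway_volume_nasopharynx"],
                        meas["airway_volume_oropharynx"],
                        meas["airway_volume_hypopharynx"]]) * 1000.0
    heights = np.array([z_top - z_b1, z_b1 - z_b2, z_b2 - z_b3])
    r0 = np.sqrt(targets / (_POLY_C * heights))  # cylinder first guess

    bounds = [(z_b1, z_top), (z_b2, z_b1), (z_b3, z_b2)]

    def residual(log_r):
        knots = _make_knots(z_top, z_b1, z_b2, z_b3, np.exp(log_r))
        return [_profile_volume(knots, lo, hi) - t
                for (lo, hi), t in zip(bounds, targets)]

    sol = optimize.root(residual, np.log(r0), method="hybr", tol=1e-12)
    radii = np.exp(sol.x)
    knots = _make_knots(z_top, z_b1, z_b2, z_b3, radii)
    resid = np.abs(residual(np.log(radii)))
    if not sol.success or np.max(resid / targets) > 1e-8:
        raise ConfigError("airway profile radii failed to converge")
    areas = {name: _profile_section_area(knots, lo, hi) / 100.0
             for name, (lo, hi) in zip(
                 ("airway_area_nasopharynx", "airway_area_oropharynx",
                  "airway_area_hypopharynx"), bounds)}
    return {"knots": knots, "boundaries": (z_top, z_b1, z_b2, z_b3),
            "radii": radii, "areas": areas,
            "axis_y": -meas["hyoid_posterior_distance"] / 2.0}


def tube_mesh(knots: list[tuple[float, float]], n_seg: int = TUBE_SEGMENTS,
              center: tuple[float, float] = (0.0, 0.0)) -> trimesh.Trimesh:
    """Closed surface of revolution (polygonal) for a piecewise-linear
    radius profile; knots ordered top to bottom."""
    cx, cy = center
    theta = 2.0 * math.pi * np.arange(n_seg) / n_seg
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    verts, faces = [], []
    for z, r in knots:
        ring0 = len(verts)
        verts.extend(np.column_stack([cx + r * cos_t, cy + r * sin_t,
                                      np.full(n_seg, z)]))
        if ring0 >= n_seg:
            prev = ring0 - n_seg
            for k in range(n_seg):
                k2 = (k + 1) % n_seg
                faces.append([prev + k, ring0 + k, prev + k2])
                faces.append([prev + k2, ring0 + k, ring0 + k2])
    top_c = len(verts)
    verts.append([cx, cy, knots[0][0]])
    bot_c = len(verts)
    verts.append([cx, cy, knots[-1][0]])
    last = (len(knots) - 1) * n_seg
    for k in range(n_seg):
        k2 = (k + 1) % n_seg
        faces.append([top_c, k, k2])
        faces.append([bot_c, last + k2, last + k])
    mesh = trimesh.Trimesh(vertices=np.asarray(verts, dtype=float),
                           faces=np.asarray(faces, dtype=int), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _box(extents, center) -> trimesh.Trimesh:
    box = trimesh.creation.box(extents=extents)
    box.apply_translation(center)
    return box


def generate_airway_mesh(subject: SubjectRecord,
                         config: GrowthConfig | None = None
                         ) -> tuple[dict[str, trimesh.Trimesh], dict]:
    """Closed meshes (pharyngeal tube, oral-cavity box, tongue box) plus the
    analytic per-compartment volumes/areas they realize."""
    config = config or GrowthConfig()
    meas = subject.true_measurements
    age = subject.age_months
    s = (age / config.reference_age) ** config.cranial_exponent
    prof = airway_profile(meas, age, config)
    meshes = {"airway_total": tube_mesh(prof["knots"],
                                        center=(0.0, prof["axis_y"]))}

    # calibration solids: box dimensions chosen so midsagittal section area
    # and volume both equal the latent targets exactly
    v_oral = meas["airway_volume_oral_cavity"] * 1000.0
    a_oral = meas["airway_area_oral_cavity"] * 100.0
    h_oral = math.sqrt(a_oral / 2.0)
    meshes["oral_cavity"] = _box([v_oral / a_oral, 2.0 * h_oral, h_oral],
                                 [0.0, 35.0 * s, -30.0 * s])
    a_tongue = meas["tongue_area"] * 100.0
    d_tongue = 0.75 * meas["tongue_length"]
    meshes["tongue"] = _box([0.5 * d_tongue, d_tongue, a_tongue / d_tongue],
                            [0.0, 20.0 * s, -32.0 * s])
    analytic = dict(prof["areas"])
    analytic.update({
        "airway_volume_nasopharynx": meas["airway_volume_nasopharynx"],
        "airway_volume_oropharynx": meas["airway_volume_oropharynx"],
        "airway_volume_hypopharynx": meas["airway_volume_hypopharynx"],
        "airway_volume_oral_cavity": meas["airway_volume_oral_cavity"],
        "airway_area_oral_cavity": meas["airway_area_oral_cavity"],
        "tongue_area": meas["tongue_area"],
    })
    return meshes, analytic


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

_CALIBRATION_SEED = 932801        # internal, fixed: intercept calibration
_CALIBRATION_N = 20000


def calibrate_label_intercept(config: GrowthConfig,
                              target: float | None = None) -> float:
    """Intercept of the difficult-airway label model giving the target
    prevalence over the mixed two-group cohort (deterministic: fixed
    internal sample)."""
    target = config.prevalence if target is None else target
    rng = np.random.default_rng(_CALIBRATION_SEED)
    lo, hi = config.age_range
    ages = np.exp(rng.uniform(math.log(lo), math.log(hi), _CALIBRATION_N))
    groups = np.where(np.arange(_CALIBRATION_N) % 2 == 0,
                      "hypoplasia", "control")
    ipa = np.empty(_CALIBRATION_N)
    had = np.empty(_CALIBRATION_N)
    for i in range(_CALIBRATION_N):
        m = draw_measurements(config, groups[i], ages[i], rng)
        ipa[i] = m["inferior_pogonial_angle"]
        had[i] = m["hyoid_anterior_distance"]
    eta0 = config.beta_ipa * ipa + config.beta_had * had

    def mean_prev(b0):
        return float(np.mean(expit(b0 + eta0))) - target

    return float(optimize.brentq(mean_prev, -80.0, 80.0, xtol=1e-10))


def generate_subject(config: GrowthConfig, group: str, age: float, sex: str,
                     seed, subject_id: str = "S000",
                     label_intercept: float | None = None) -> SubjectRecord:
    """One synthetic subject; fully determined by (config, args, seed)."""
    rng = np.random.default_rng(seed)
    meas = draw_measurements(config, group, age, rng)
    landmarks, meas = build_landmarks(meas, age, config, subject_id)
    _, analytic = generate_airway_mesh_values(meas, age, config)
    meas.update(analytic)

    if label_intercept is None:
        if config.label_intercept is None:
            config.label_intercept = calibrate_label_intercept(config)
        label_intercept = config.label_intercept
    p = float(expit(label_intercept
                    + config.beta_ipa * meas["inferior_pogonial_angle"]
                    + config.beta_had * meas["hyoid_anterior_distance"]))
    label = bool(rng.random() < p)

    height = 65.0 * (age / 12.0) ** 0.28 * math.exp(rng.normal(0, 0.04))
    weight = 9.5 * (age / 12.0) ** 0.45 * math.exp(rng.normal(0, 0.10))

    observations = {}
    for obs in ("O1", "O2"):
        noisy = LandmarkSet(subject_id, obs)
        for name, pos in landmarks.items():
            noise = (rng.normal(0.0, config.landmark_noise_sd, 3)
                     if config.landmark_noise_sd else np.zeros(3))
            noisy.add(name, pos + noise)
        observations[obs] = noisy
    return SubjectRecord(subject_id=subject_id, group=group,
                         age_months=float(age), sex=sex,
                         height_cm=float(height), weight_kg=float(weight),
                         difficult_airway=label, label_probability=p,
                         true_measurements=meas, landmarks_true=landmarks,
                         observations=observations)


def generate_airway_mesh_values(meas: dict[str, float], age: float,
                                config: GrowthConfig) -> tuple[None, dict]:
    """Analytic mesh-derived values without building the meshes."""
    prof = airway_profile(meas, age, config)
    return None, dict(prof["areas"])


def generate_cohort(config: GrowthConfig | None = None, n_per_group: int = 42,
                    seed: int = 0) -> SyntheticCohort:
    """Two matched cohorts of independent subjects, bit-reproducible from
    (config, seed)."""
    config = config or GrowthConfig()
    if n_per_group < 1:
        raise ConfigError("n_per_group must be >= 1")
    if config.label_intercept is None:
        config.label_intercept = calibrate_label_intercept(config)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_group + 1)
    master = np.random.default_rng(children[0])
    lo, hi = config.age_range
    subjects = []
    for i in range(2 * n_per_group):
        group = "hypoplasia" if i < n_per_group else "control"
        prefix = "H" if group == "hypoplasia" else "C"
        sid = f"{prefix}{(i % n_per_group) + 1:03d}"
        age = float(np.exp(master.uniform(math.log(lo), math.log(hi))))
        sex = "M" if master.random() < 0.5 else "F"
        subjects.append(generate_subject(config, group, age, sex,
                                         children[i + 1], sid,
                                         config.label_intercept))
    return SyntheticCohort(subjects=subjects, config=config, seed=seed)


def verify_latent_consistency(subject: SubjectRecord,
                              config: GrowthConfig | None = None,
                              specs=DEFAULT_SPECS) -> pd.DataFrame:
    """Evaluate the spec bundle on the noise-free landmarks/meshes and
    report latent vs measured values (the generator's self-check)."""
    config = config or GrowthConfig()
    meshes, _ = generate_airway_mesh(subject, config)
    table = evaluate_specs(subject.landmarks_true, meshes, specs)
    table = table[table["measurement"].isin(subject.true_measurements)]
    table = table.assign(latent=[subject.true_measurements[m]
                                 for m in table["measurement"]])
    table = table.assign(error=(table["value"] - table["latent"]).abs())
    return table
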