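"""Declarative landmark/mesh measurements (distances, angles, offsets,
plane-bounded airway compartment volumes and sagittal areas).

All evaluation assumes landmark sets already reoriented into the canonical
frame (+x right, +y anterior, +z superior), so the reference planes are the
coordinate planes.  Lengths are mm; volumes are reported in cm^3 and areas
in cm^2, matching the usual cephalometric convention.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh

from .errors import (
    CollinearPointsError,
    ConfigError,
    DegenerateAngleError,
    EmptyRegionWarning,
    InvalidRegionError,
    MissingLandmarkError,
    OpenMeshError,
)

_SOFT_ERRORS = (MissingLandmarkError, DegenerateAngleError, OpenMeshError,
                CollinearPointsError, InvalidRegionError)
from .geometry import LandmarkSet, Plane, plane_from_points

VALID_KINDS = ("distance", "angle", "projected_distance", "path_length",
               "region_volume", "region_area")
VALID_LATERALITY = ("average_lr", "left_only", "right_only", "midline")

#: canonical-frame reference planes
CANONICAL_PLANES = {
    "afh": Plane(np.zeros(3), (0.0, 0.0, 1.0)),
    "midsagittal": Plane(np.zeros(3), (1.0, 0.0, 0.0)),
    "coronal": Plane(np.zeros(3), (0.0, 1.0, 0.0)),
}

_AXIS_NORMALS = {"axial": (0.0, 0.0, 1.0), "coronal": (0.0, 1.0, 0.0),
                 "sagittal": (1.0, 0.0, 0.0)}


@dataclass(frozen=True)
class MeasurementSpec:
    """Declarative definition of one measurement.

    ``operands`` are landmark names, plane references or a mesh label,
    depending on ``kind``:

    - distance: (a, b) landmark names
    - angle: (ray1_end, apex, ray2_end)
    - projected_distance: (landmark, plane_ref)
    - path_length: (n1, n2, ..., nk), k >= 2
    - region_volume: (mesh_label, lower_plane_ref, upper_plane_ref)
    - region_area: (mesh_label, lower_plane_ref, upper_plane_ref, section_ref)

    Plane references: ``afh`` / ``midsagittal`` / ``coronal`` (canonical
    planes), ``axial@NAME`` or ``coronal@NAME`` (axis-aligned plane through
    a landmark; ``NAME1+NAME2`` anchors at the midpoint), ``axial@-inf`` /
    ``axial@+inf`` (beyond the mesh bounds), and ``plane3:A,B,C`` (plane
    through three landmarks).  Bilateral specs write ``{side}`` in operand
    names; ``laterality`` controls how sides are combined.
    """

    name: str
    kind: str
    operands: tuple[str, ...]
    laterality: str = "midline"
    units: str = "mm"
    sign: float = 1.0
    absolute: bool = False
    provisional: bool = False
    description: str = ""

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ConfigError(f"unknown measurement kind {self.kind!r}")
        if self.laterality not in VALID_LATERALITY:
            raise ConfigError(f"unknown laterality {self.laterality!r}")
        n = len(self.operands)
        expected = {"distance": (2,), "angle": (3,), "projected_distance": (2,),
                    "region_volume": (3,), "region_area": (4,)}
        if self.kind == "path_length":
            if n < 2:
                raise ConfigError("path_length needs at least two landmarks")
        elif n not in expected[self.kind]:
            raise ConfigError(
                f"{self.kind} expects {expected[self.kind][0]} operands, got {n}")
        object.__setattr__(self, "operands", tuple(self.operands))


def distance(lm: LandmarkSet, a: str, b: str) -> float:
    """Euclidean distance between two landmarks (mm)."""
    return float(np.linalg.norm(lm[a] - lm[b]))


def angle(lm: LandmarkSet, ray1_end: str, apex: str, ray2_end: str) -> float:
    """Angle at ``apex`` between the rays to the two end landmarks (degrees)."""
    v1 = lm[ray1_end] - lm[apex]
    v2 = lm[ray2_end] - lm[apex]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 <= 1e-9 or n2 <= 1e-9:
        raise DegenerateAngleError(f"zero-length ray at apex {apex!r}")
    c = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def projected_distance(lm: LandmarkSet, a: str, plane: Plane) -> float:
    """Signed perpendicular distance from a landmark to a plane (mm)."""
    return float(plane.signed_distance(lm[a]))


def path_length(lm: LandmarkSet, names: Sequence[str]) -> float:
    """Sum of consecutive Euclidean distances along a landmark chain (mm)."""
    pts = lm.positions(names)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _validate_slab(mesh: trimesh.Trimesh, lower: Plane, upper: Plane):
    if mesh is None:
        raise ConfigError("mesh required for region measurements")
    if not mesh.is_watertight:
        raise OpenMeshError("mesh is not closed; region quantities undefined")
    n = lower.normal
    if np.linalg.norm(np.cross(n, upper.normal)) > 1e-6:
        raise InvalidRegionError("bounding planes must be parallel")
    lo = float(n @ lower.anchor)
    hi = float(n @ upper.anchor)
    if hi <= lo:
        raise InvalidRegionError(
            "lower plane must lie strictly below upper plane")
    return n, lo, hi


def _clip_polygon_halfspace(poly: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Sutherland-Hodgman clip of a planar 3D polygon against d >= 0,
    where ``d`` holds the per-vertex signed distances."""
    out = []
    k = len(poly)
    for i in range(k):
        j = (i + 1) % k
        pi, pj, di, dj = poly[i], poly[j], d[i], d[j]
        if di >= 0:
            out.append(pi)
        if (di > 0) != (dj > 0) and di != dj:
            t = di / (di - dj)
            out.append(pi + t * (pj - pi))
    return np.asarray(out) if out else np.empty((0, 3))


def _poly_flux(poly: np.ndarray, e: np.ndarray) -> float:
    """∫ (e·p)(e·n) dA over a convex planar polygon (fan decomposition):
    the divergence-theorem volume contribution for F = e (e·p)."""
    total = 0.0
    for i in range(1, len(poly) - 1):
        v0, v1, v2 = poly[0], poly[i], poly[i + 1]
        half_cross = 0.5 * np.cross(v1 - v0, v2 - v0)
        centroid = (v0 + v1 + v2) / 3.0
        total += float((e @ centroid) * (e @ half_cross))
    return total


def region_volume(mesh: trimesh.Trimesh, lower: Plane, upper: Plane) -> float:
    """Volume (cm^3) of the mesh region between two parallel planes.

    Computed by the divergence theorem with the flux field chosen parallel
    to the planes, so the flat cut faces contribute nothing and only the
    mesh triangles clipped to the slab need integrating — exact for
    polyhedra, no re-meshing involved.
    """
    n, lo, hi = _validate_slab(mesh, lower, upper)
    verts = mesh.vertices.view(np.ndarray)
    d = verts @ n
    if d.min() >= hi or d.max() <= lo:
        warnings.warn("bounding planes miss the mesh; volume 0",
                      EmptyRegionWarning, stacklevel=2)
        return 0.0
    # flux direction orthogonal to the slab normal
    seed = np.array([1.0, 0.0, 0.0])
    if abs(n @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e = np.cross(n, seed)
    e /= np.linalg.norm(e)

    faces = mesh.faces.view(np.ndarray)
    fd = d[faces]                                   # (F, 3) signed offsets
    inside = (fd >= lo).all(axis=1) & (fd <= hi).all(axis=1)
    outside = (fd <= lo).all(axis=1) | (fd >= hi).all(axis=1)
    total = 0.0
    if inside.any():
        tri = verts[faces[inside]]                  # (K, 3, 3)
        half_cross = 0.5 * np.cross(tri[:, 1] - tri[:, 0],
                                    tri[:, 2] - tri[:, 0])
        centroid = tri.mean(axis=1)
        total += float(np.sum((centroid @ e) * (half_cross @ e)))
    for fi in np.nonzero(~inside & ~outside)[0]:
        poly = verts[faces[fi]]
        poly = _clip_polygon_halfspace(poly, poly @ n - lo)
        if len(poly) >= 3:
            poly = _clip_polygon_halfspace(poly, hi - poly @ n)
        if len(poly) >= 3:
            total += _poly_flux(poly, e)
    return abs(total) / 1000.0


def _halfplane_patch(a: float, b: float, c: float, bound: float):
    """Shapely polygon covering {a x + b y >= c} within a radius ``bound``."""
    from shapely.geometry import Polygon as ShPolygon
    g = np.array([a, b])
    u = g / np.linalg.norm(g)
    v = np.array([-u[1], u[0]])
    d0 = c / np.linalg.norm(g)
    corners = [d0 * u + bound * v, d0 * u - bound * v,
               (d0 + 2 * bound) * u - bound * v,
               (d0 + 2 * bound) * u + bound * v]
    return ShPolygon(corners)


def region_area(mesh: trimesh.Trimesh, lower: Plane, upper: Plane,
                section: Plane) -> float:
    """Cross-sectional area (cm^2) of the between-planes region cut by the
    section plane (by default the midsagittal plane).

    The closed mesh is sectioned into planar polygons; the bounding-plane
    slab becomes a band of half-plane constraints in section coordinates
    and the polygons are clipped against it.
    """
    n, lo, hi = _validate_slab(mesh, lower, upper)
    d = mesh.vertices.view(np.ndarray) @ n
    if d.min() >= hi or d.max() <= lo:
        warnings.warn("bounding planes miss the mesh; area 0",
                      EmptyRegionWarning, stacklevel=2)
        return 0.0
    path = mesh.section(plane_origin=section.anchor,
                        plane_normal=section.normal)
    if path is None:
        return 0.0
    planar, T = path.to_2D()
    # slab constraint in 2D coords: n·(T [x, y, 0, 1]) = a x + b y + c
    a = float(n @ T[:3, 0])
    b = float(n @ T[:3, 1])
    c = float(n @ T[:3, 3])
    polys = planar.polygons_full
    if abs(a) < 1e-12 and abs(b) < 1e-12:
        if lo <= c <= hi:
            return float(sum(p.area for p in polys)) / 100.0
        return 0.0
    bounds = np.array([p.bounds for p in polys])
    g = math.hypot(a, b)
    radius = (float(np.abs(bounds).max())
              + max(abs(lo - c), abs(hi - c)) / g + 10.0)
    band = (_halfplane_patch(a, b, lo - c, radius)
            .intersection(_halfplane_patch(-a, -b, -(hi - c), radius)))
    area = sum(p.intersection(band).area for p in polys)
    return float(area) / 100.0


def resolve_plane(ref: str, lm: LandmarkSet | None = None,
                  mesh: trimesh.Trimesh | None = None) -> Plane:
    """Resolve a plane-reference string to a concrete canonical-frame plane."""
    if ref in CANONICAL_PLANES:
        return CANONICAL_PLANES[ref]
    if ref.startswith("plane3:"):
        names = [s.strip() for s in ref[len("plane3:"):].split(",")]
        if len(names) != 3 or lm is None:
            raise ConfigError(f"bad plane reference {ref!r}")
        return plane_from_points(*(lm[n] for n in names))
    if "@" in ref:
        axis, anchor_ref = ref.split("@", 1)
        if axis not in _AXIS_NORMALS:
            raise ConfigError(f"unknown plane axis {axis!r}")
        normal = np.asarray(_AXIS_NORMALS[axis])
        if anchor_ref in ("-inf", "+inf"):
            if mesh is None:
                raise ConfigError(f"{ref!r} requires a mesh to bound")
            lo, hi = (mesh.vertices @ normal).min(), (mesh.vertices @ normal).max()
            offset = lo - 1.0 if anchor_ref == "-inf" else hi + 1.0
            return Plane(offset * normal, normal)
        if lm is None:
            raise ConfigError(f"{ref!r} requires landmarks")
        names = [s.strip() for s in anchor_ref.split("+")]
        anchor = np.mean([lm[n] for n in names], axis=0)
        return Plane(anchor, normal)
    raise ConfigError(f"unknown plane reference {ref!r}")


def _eval_one(lm: LandmarkSet, meshes, spec: MeasurementSpec,
              operands: tuple[str, ...]) -> float:
    if spec.kind == "distance":
        value = distance(lm, *operands)
    elif spec.kind == "angle":
        value = angle(lm, *operands)
    elif spec.kind == "projected_distance":
        plane = resolve_plane(operands[1], lm)
        value = projected_distance(lm, operands[0], plane)
    elif spec.kind == "path_length":
        value = path_length(lm, operands)
    else:
        label = operands[0]
        if not meshes or label not in meshes:
            raise MissingLandmarkError(f"mesh:{label}")
        mesh = meshes[label]
        lower = resolve_plane(operands[1], lm, mesh)
        upper = resolve_plane(operands[2], lm, mesh)
        if spec.kind == "region_volume":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EmptyRegionWarning)
                value = region_volume(mesh, lower, upper)
        else:
            section = resolve_plane(operands[3], lm, mesh)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EmptyRegionWarning)
                value = region_area(mesh, lower, upper, section)
    value = spec.sign * value
    return abs(value) if spec.absolute else value


def evaluate_specs(lm: LandmarkSet,
                   meshes: Mapping[str, trimesh.Trimesh] | None,
                   specs: Sequence[MeasurementSpec]) -> pd.DataFrame:
    """Evaluate a spec bundle on one canonical landmark set.

    Never raises on a missing landmark or degenerate operand: the row is
    flagged unavailable with the failure recorded in ``note``.  Bilateral
    specs with ``laterality='average_lr'`` return the left/right mean; if
    only one side is measurable the value is computed from that side and
    flagged ``unilateral``.  Per-side values are retained as extra rows
    suffixed ``__L``/``__R``.
    """
    rows = []

    def emit(name, value, units, available, note=""):
        rows.append({"subject_id": lm.subject_id, "observer_id": lm.observer_id,
                     "measurement": name, "value": value, "units": units,
                     "available": available, "note": note})

    for spec in specs:
        bilateral = any("{side}" in op for op in spec.operands)
        if not bilateral:
            try:
                value = _eval_one(lm, meshes, spec, spec.operands)
                emit(spec.name, value, spec.units, True)
            except _SOFT_ERRORS as exc:
                emit(spec.name, np.nan, spec.units, False, type(exc).__name__)
            continue
        side_values: dict[str, float] = {}
        notes = []
        sides = {"average_lr": ("L", "R"), "left_only": ("L",),
                 "right_only": ("R",), "midline": ("L", "R")}[spec.laterality]
        for side in sides:
            ops = tuple(op.replace("{side}", side) for op in spec.operands)
            try:
                side_values[side] = _eval_one(lm, meshes, spec, ops)
            except _SOFT_ERRORS as exc:
                notes.append(f"{side}:{type(exc).__name__}")
        for side, v in side_values.items():
            emit(f"{spec.name}__{side}", v, spec.units, True)
        if not side_values:
            emit(spec.name, np.nan, spec.units, False, "; ".join(notes))
        elif spec.laterality == "average_lr" and len(side_values) == 1:
            emit(spec.name, next(iter(side_values.values())), spec.units,
                 True, "unilateral")
        else:
            emit(spec.name, float(np.mean(list(side_values.values()))),
                 spec.units, True)
    return pd.DataFrame(rows)


def table_from_rows(frames: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-subject measurement rows into one long table."""
    if not frames:
        return pd.DataFrame(columns=["subject_id", "observer_id", "measurement",
                                     "value", "units", "available", "note"])
    return pd.concat(frames, ignore_index=True)
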