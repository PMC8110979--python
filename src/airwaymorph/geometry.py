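"""Landmark containers, plane algebra and the averaged Frankfort reference frame.

All coordinates are millimetres in a right-handed Cartesian frame.  The
canonical anatomical frame used downstream is +x right, +y anterior,
+z superior, with the origin at the intersection of the three reference
planes (averaged Frankfort horizontal, midsagittal, coronal-vomer).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import (
    CollinearPointsError,
    DegenerateAverageError,
    DegenerateFrameError,
    MissingLandmarkError,
)

# tolerances separating genuine degeneracy from float noise at mm scale
COLLINEAR_AREA_TOL = 1e-9      # mm^2
ORTHOGONALITY_TOL = 1e-6
FRAME_AXIS_TOL = 1e-6

#: Controlled vocabulary: the 30 landmarks of the digitization scheme.
LANDMARK_NAMES: tuple[str, ...] = (
    "Orbitale_L", "Orbitale_R", "Porion_L", "Porion_R",
    "Nasion", "Opisthion", "Pa_V", "ANS", "Palate_Mid",
    "Go_L", "Go_R", "Pog", "Menton",
    "S_Co_L", "S_Co_R", "Pia_L", "Pia_R", "Aia_L", "Aia_R",
    "Body_L", "Body_R",
    "Hyoid", "Aa_C2", "Aa_C3", "AIa_C2", "AIa_C4",
    "Tongue_Tip", "Tongue_Dorsum", "Tongue_Base", "Tongue_Inf",
)

#: The four landmarks defining the averaged Frankfort horizontal plane.
AFH_LANDMARKS = ("Orbitale_L", "Orbitale_R", "Porion_L", "Porion_R")


def as_point(p) -> np.ndarray:
    """Coerce to a finite (3,) float array."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("point coordinates must be finite")
    return arr


def side_of(name: str) -> str:
    if name.endswith("_L"):
        return "left"
    if name.endswith("_R"):
        return "right"
    return "midline"


@dataclass(frozen=True)
class Landmark:
    """A named anatomical point; ``side`` is derived from the name suffix."""

    name: str
    position: np.ndarray
    side: str = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "position", as_point(self.position))
        object.__setattr__(self, "side", side_of(self.name))


class LandmarkSet:
    """Named 3D points for one subject/observer.  May be partial."""

    def __init__(self, subject_id: str, observer_id: str = "O1",
                 landmarks: Mapping[str, Iterable[float]] | None = None):
        self.subject_id = str(subject_id)
        self.observer_id = str(observer_id)
        self._points: dict[str, np.ndarray] = {}
        if landmarks:
            for name, pos in landmarks.items():
                self.add(name, pos)

    def add(self, name: str, position) -> None:
        if name in self._points:
            raise ValueError(f"duplicate landmark {name!r}")
        self._points[name] = as_point(position)

    def __contains__(self, name: str) -> bool:
        return name in self._points

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self._points[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def __len__(self) -> int:
        return len(self._points)

    def __iter__(self) -> Iterator[str]:
        return iter(self._points)

    def names(self) -> list[str]:
        return list(self._points)

    def items(self):
        return self._points.items()

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self._points]
        if missing:
            raise MissingLandmarkError(missing)

    def positions(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self[n] for n in names])

    def transformed(self, transform: "RigidTransform") -> "LandmarkSet":
        out = LandmarkSet(self.subject_id, self.observer_id)
        for name, pos in self._points.items():
            out.add(name, transform.apply(pos))
        return out

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(self.subject_id, self.observer_id, dict(self._points))

    def drop(self, name: str) -> "LandmarkSet":
        out = self.copy()
        out._points.pop(name, None)
        return out


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by an anchor point and a unit normal."""

    anchor: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "anchor", as_point(self.anchor))
        n = as_point(self.normal)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points) -> np.ndarray | float:
        pts = np.asarray(points, dtype=float)
        return (pts - self.anchor) @ self.normal

    def contains(self, point, tol: float = 1e-9) -> bool:
        return abs(float(self.signed_distance(point))) <= tol

    def transformed(self, transform: "RigidTransform") -> "Plane":
        return Plane(transform.apply(self.anchor),
                     transform.rotation @ self.normal)


@dataclass(frozen=True)
class RigidTransform:
    """p' = R p + t, with R a rotation matrix."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = as_point(self.translation)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class ReferenceFrame:
    """The (Frankfort, midsagittal, coronal-vomer) orthogonal plane triple
    together with the rigid transform into the canonical frame."""

    afh: Plane
    midsagittal: Plane
    coronal_vomer: Plane
    to_canonical: RigidTransform

    def __post_init__(self):
        for a, b in ((self.afh, self.midsagittal),
                     (self.afh, self.coronal_vomer),
                     (self.midsagittal, self.coronal_vomer)):
            if abs(float(a.normal @ b.normal)) > ORTHOGONALITY_TOL:
                raise DegenerateFrameError("reference plane normals not orthogonal")


def plane_from_points(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points; anchor at their centroid."""
    p1, p2, p3 = as_point(p1), as_point(p2), as_point(p3)
    cross = np.cross(p2 - p1, p3 - p1)
    area = 0.5 * np.linalg.norm(cross)
    if area <= COLLINEAR_AREA_TOL:
        raise CollinearPointsError(f"triangle area {area:.3e} mm^2 below tolerance")
    return Plane((p1 + p2 + p3) / 3.0, cross)


def average_plane(points, reference_normal) -> Plane:
    """Leave-one-out averaged plane through four points.

    Each of the four three-point planes has its normal sign-aligned with
    ``reference_normal``; the result has the normalized mean normal and is
    anchored at the centroid of the four points.  For exactly coplanar
    points this reduces to their common plane.
    """
    pts = np.asarray([as_point(p) for p in points], dtype=float)
    if pts.shape != (4, 3):
        raise ValueError("average_plane expects exactly four points")
    ref = np.asarray(reference_normal, dtype=float)
    normals = []
    for i in range(4):
        tri = np.delete(pts, i, axis=0)
        n = plane_from_points(*tri).normal
        if float(n @ ref) < 0:
            n = -n
        normals.append(n)
    mean = np.mean(normals, axis=0)
    if np.linalg.norm(mean) < 1e-9:
        raise DegenerateAverageError("sign-aligned normals average to zero")
    return Plane(pts.mean(axis=0), mean)


def build_reference_frame(lm: LandmarkSet, superior_hint=None) -> ReferenceFrame:
    """Construct the canonical reference frame from cranial landmarks.

    The Frankfort plane is the leave-one-out average over the two orbitale
    and two porion landmarks; the midsagittal plane contains nasion and
    opisthion and is perpendicular to the Frankfort plane; the coronal
    plane passes through the posterior vomer point perpendicular to both.

    ``superior_hint`` disambiguates the Frankfort normal sign; when omitted
    it is taken as the direction from the porion midpoint toward nasion
    (nasion lies above the Frankfort plane).
    """
    lm.require("Orbitale_L", "Orbitale_R", "Porion_L", "Porion_R",
               "Nasion", "Opisthion", "Pa_V")
    pts4 = [lm[n] for n in AFH_LANDMARKS]
    nasion, opisthion, vomer = lm["Nasion"], lm["Opisthion"], lm["Pa_V"]
    if superior_hint is None:
        superior_hint = nasion - 0.5 * (lm["Porion_L"] + lm["Porion_R"])
    afh = average_plane(pts4, superior_hint)

    z_hat = afh.normal
    v = nasion - opisthion                      # posterior -> anterior axis
    v_plane = v - (v @ z_hat) * z_hat           # project onto Frankfort plane
    norm_v = np.linalg.norm(v_plane)
    if norm_v < FRAME_AXIS_TOL * max(np.linalg.norm(v), 1.0):
        raise DegenerateFrameError(
            "Nasion-Opisthion axis parallel to the Frankfort normal")
    y_hat = v_plane / norm_v
    x_hat = np.cross(y_hat, z_hat)              # right-handed: x = y × z

    midsagittal = Plane(nasion, x_hat)
    coronal = Plane(vomer, y_hat)

    # triple-plane intersection: R p = b with orthonormal rows
    R = np.vstack([x_hat, y_hat, z_hat])
    b = np.array([x_hat @ nasion, y_hat @ vomer, z_hat @ afh.anchor])
    origin = R.T @ b
    to_canonical = RigidTransform(R, -R @ origin)
    return ReferenceFrame(afh, midsagittal, coronal, to_canonical)


def reorient(lm: LandmarkSet, frame: ReferenceFrame) -> LandmarkSet:
    """Map all landmark positions into the canonical frame (isometric)."""
    return lm.transformed(frame.to_canonical)
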