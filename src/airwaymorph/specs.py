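"""The default measurement spec bundle.

Encodes the main-text/figure definitions of the upper-airway measurement
scheme: hyoid distances, mandibular dimensions and angles, tongue offsets,
and plane-bounded pharyngeal compartments.  Measurements whose exact
operand chains are not published (body length/width, craniocaudal hyoid
position) are marked ``provisional``; any operand mapping can be overridden
from a TOML file, because the measurement definitions are data, not code.
"""
from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Sequence

from .measure import MeasurementSpec

#: pharyngeal compartment boundary plane references (axial planes through
#: the vomer/ANS midpoint, the anterior-inferior C2 point and the
#: anterior-inferior C4 point)
NASO_ORO_BOUNDARY = "axial@Pa_V+ANS"
ORO_HYPO_BOUNDARY = "axial@AIa_C2"
HYPO_FLOOR = "axial@AIa_C4"

DEFAULT_SPECS: tuple[MeasurementSpec, ...] = (
    # --- airway compartments (closed airway mesh, axial bounding planes) ---
    MeasurementSpec("airway_volume_nasopharynx", "region_volume",
                    ("airway_total", NASO_ORO_BOUNDARY, "axial@+inf"),
                    units="cm3"),
    MeasurementSpec("airway_volume_oropharynx", "region_volume",
                    ("airway_total", ORO_HYPO_BOUNDARY, NASO_ORO_BOUNDARY),
                    units="cm3"),
    MeasurementSpec("airway_volume_hypopharynx", "region_volume",
                    ("airway_total", HYPO_FLOOR, ORO_HYPO_BOUNDARY),
                    units="cm3"),
    MeasurementSpec("airway_volume_oral_cavity", "region_volume",
                    ("oral_cavity", "axial@-inf", "axial@+inf"), units="cm3"),
    MeasurementSpec("airway_area_nasopharynx", "region_area",
                    ("airway_total", NASO_ORO_BOUNDARY, "axial@+inf",
                     "midsagittal"), units="cm2"),
    MeasurementSpec("airway_area_oropharynx", "region_area",
                    ("airway_total", ORO_HYPO_BOUNDARY, NASO_ORO_BOUNDARY,
                     "midsagittal"), units="cm2"),
    MeasurementSpec("airway_area_hypopharynx", "region_area",
                    ("airway_total", HYPO_FLOOR, ORO_HYPO_BOUNDARY,
                     "midsagittal"), units="cm2"),
    MeasurementSpec("airway_area_oral_cavity", "region_area",
                    ("oral_cavity", "axial@-inf", "axial@+inf",
                     "midsagittal"), units="cm2"),
    # --- tongue ---
    MeasurementSpec("tongue_length", "distance", ("Tongue_Tip", "Tongue_Base")),
    MeasurementSpec("tongue_height", "distance", ("Tongue_Dorsum", "Tongue_Inf")),
    MeasurementSpec("tongue_area", "region_area",
                    ("tongue", "axial@-inf", "axial@+inf", "midsagittal"),
                    units="cm2"),
    # posterior offset of the tongue tip from the anterior nasal spine
    MeasurementSpec("tongue_position_ans", "projected_distance",
                    ("Tongue_Tip", "coronal@ANS"), sign=-1.0),
    # inferior offset of the tongue dorsum from the palate
    MeasurementSpec("tongue_position_palate", "projected_distance",
                    ("Tongue_Dorsum", "axial@Palate_Mid"), sign=-1.0),
    # --- hyoid ---
    MeasurementSpec("hyoid_anterior_distance", "distance", ("Hyoid", "Pog")),
    MeasurementSpec("hyoid_posterior_distance", "distance", ("Hyoid", "Aa_C3")),
    MeasurementSpec("hyoid_craniocaudal_length", "projected_distance",
                    ("Hyoid", "afh"), sign=-1.0, provisional=True,
                    description="depth of the hyoid below the Frankfort plane"),
    MeasurementSpec("mandibular_plane_distance", "projected_distance",
                    ("Hyoid", "plane3:Go_L,Go_R,Menton"), absolute=True,
                    description="perpendicular hyoid offset from the "
                                "gonion-menton mandibular plane"),
    # --- mandible ---
    MeasurementSpec("ramus_height", "distance", ("S_Co_{side}", "Go_{side}"),
                    laterality="average_lr"),
    MeasurementSpec("ramus_width", "distance", ("Pia_{side}", "Aia_{side}"),
                    laterality="average_lr"),
    MeasurementSpec("body_total_length", "path_length",
                    ("Go_{side}", "Body_{side}", "Pog"),
                    laterality="average_lr", provisional=True),
    MeasurementSpec("body_width", "distance", ("Body_L", "Body_R"),
                    provisional=True),
    MeasurementSpec("gonial_angle", "angle",
                    ("S_Co_{side}", "Go_{side}", "Pog"),
                    laterality="average_lr", units="degree"),
    MeasurementSpec("inferior_pogonial_angle", "angle", ("Go_L", "Pog", "Go_R"),
                    units="degree"),
    MeasurementSpec("bigonial_distance", "distance", ("Go_L", "Go_R")),
)

#: names of every measurement in the default bundle, in bundle order
DEFAULT_MEASUREMENT_NAMES = tuple(s.name for s in DEFAULT_SPECS)


def load_specs(path: str | Path) -> tuple[MeasurementSpec, ...]:
    """Load a spec bundle from TOML: one table per measurement name with
    keys kind, operands, and optionally laterality/units/sign/absolute."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    specs = []
    for name, entry in data.items():
        if not isinstance(entry, dict):
            raise ValueError(f"spec entry {name!r} must be a table")
        specs.append(MeasurementSpec(
            name=name,
            kind=entry["kind"],
            operands=tuple(entry["operands"]),
            laterality=entry.get("laterality", "midline"),
            units=entry.get("units", "mm"),
            sign=float(entry.get("sign", 1.0)),
            absolute=bool(entry.get("absolute", False)),
        ))
    return tuple(specs)


def specs_with_overrides(overrides: Sequence[MeasurementSpec]) -> tuple[MeasurementSpec, ...]:
    """Default bundle with named specs replaced by the given overrides."""
    by_name = {s.name: s for s in DEFAULT_SPECS}
    for s in overrides:
        by_name[s.name] = s
    return tuple(by_name.values())
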