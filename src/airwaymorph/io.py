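"""CSV/JSON interchange for landmark sets, demographics, measurements and
growth fits.  Landmark CSVs use the columns subject_id, observer_id, name,
x_mm, y_mm, z_mm (one row per landmark, UTF-8, header required)."""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .geometry import LandmarkSet
from .normative import GrowthFit

LANDMARK_COLUMNS = ("subject_id", "observer_id", "name", "x_mm", "y_mm", "z_mm")


def write_landmarks_csv(sets: list[LandmarkSet], path: str | Path) -> None:
    rows = []
    for lm in sets:
        for name, pos in lm.items():
            rows.append({"subject_id": lm.subject_id,
                         "observer_id": lm.observer_id, "name": name,
                         "x_mm": pos[0], "y_mm": pos[1], "z_mm": pos[2]})
    pd.DataFrame(rows, columns=list(LANDMARK_COLUMNS)).to_csv(path, index=False)


def read_landmarks_csv(path: str | Path) -> list[LandmarkSet]:
    df = pd.read_csv(path)
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing columns {sorted(missing)}")
    sets = []
    for (sid, oid), grp in df.groupby(["subject_id", "observer_id"],
                                      sort=True):
        lm = LandmarkSet(str(sid), str(oid))
        for rec in grp.itertuples(index=False):
            lm.add(rec.name, (rec.x_mm, rec.y_mm, rec.z_mm))
        sets.append(lm)
    return sets


def write_demographics_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_demographics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "age_months", "sex", "difficult_airway"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"demographics CSV missing columns {sorted(missing)}")
    return df


def write_fits_json(fits: dict[str, GrowthFit], path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {name: fit.to_dict() for name, fit in sorted(fits.items())},
        indent=2, sort_keys=True))


def read_fits_json(path: str | Path) -> dict[str, GrowthFit]:
    data = json.loads(Path(path).read_text())
    return {name: GrowthFit.from_dict(d) for name, d in data.items()}
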