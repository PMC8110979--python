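#!/usr/bin/env python
"""Fit the normative log-log growth curves per measurement and group, write
the control-curve fits and every subject's Δ deviation scores.

Δ = (control-curve prediction at the subject's age) − (observed value), so
hypoplasia subjects score positive on shortened dimensions and negative on
widened angles."""
from pathlib import Path

import pandas as pd

from airwaymorph.errors import AirwayMorphError
from airwaymorph.io import read_demographics_csv, write_fits_json
from airwaymorph.normative import delta_scores, fit_growth
from airwaymorph.pipeline import DELTA_MEASUREMENTS

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    meas = pd.read_csv(ROOT / "measurements.csv")
    demo = read_demographics_csv(ROOT / "cohort" / "demographics.csv")
    long = meas[meas["available"]].merge(demo, on="subject_id")
    control_fits = {}
    print(f"{'measurement':32s} {'slope ctrl':>10s} {'slope hypo':>10s}")
    for name in DELTA_MEASUREMENTS:
        row = {}
        for group in ("control", "hypoplasia"):
            sub = long[(long["measurement"] == name)
                       & (long["group"] == group)]
            try:
                fit = fit_growth(sub["age_months"], sub["value"], name, group)
            except AirwayMorphError:
                continue
            row[group] = fit
        if "control" in row:
            control_fits[name] = row["control"]
        print(f"{name:32s} "
              f"{row['control'].slope if 'control' in row else float('nan'):10.3f} "
              f"{row['hypoplasia'].slope if 'hypoplasia' in row else float('nan'):10.3f}")
    write_fits_json(control_fits, ROOT / "control_fits.json")
    deltas = delta_scores(control_fits,
                          long[long["measurement"].isin(control_fits)])
    deltas.to_csv(ROOT / "delta_scores.csv", index=False)
    print(f"wrote {len(control_fits)} control fits and "
          f"{len(deltas)} delta scores")


if __name__ == "__main__":
    main()
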