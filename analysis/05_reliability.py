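#!/usr/bin/env python
"""Inter-rater reliability: Bland-Altman on landmark-to-origin distances
between the two observers (18 landmarks, 40 scans) plus the 3D landmark
placement error per cohort.  Writes results/reliability.json and a
Bland-Altman plot."""
import json
from pathlib import Path

import numpy as np

from airwaymorph.io import read_demographics_csv, read_landmarks_csv
from airwaymorph.pipeline import RELIABILITY_LANDMARKS, _jsonify
from airwaymorph.reliability import (afh_origin, bland_altman, landmark_error,
                                     pair_observers, plot_bland_altman)

ROOT = Path(__file__).resolve().parents[1] / "results"
N_SCANS = 40


def main() -> None:
    sets = read_landmarks_csv(ROOT / "cohort" / "landmarks.csv")
    demo = read_demographics_csv(ROOT / "cohort" / "demographics.csv")
    group = demo.set_index("subject_id")["group"]
    by_obs = {}
    for lm in sets:
        by_obs.setdefault(lm.observer_id, {})[lm.subject_id] = lm
    # alternate the two cohorts across the scan budget
    hypo = sorted(s for s in by_obs["O1"] if group.get(s) == "hypoplasia")
    ctrl = sorted(s for s in by_obs["O1"] if group.get(s) == "control")
    scans = [s for pair in zip(hypo, ctrl) for s in pair][:N_SCANS]
    pairs = pair_observers([by_obs["O1"][s] for s in scans],
                           [by_obs["O2"][s] for s in scans],
                           list(RELIABILITY_LANDMARKS))
    origins = {s: (afh_origin(by_obs["O1"][s]) + afh_origin(by_obs["O2"][s]))
               / 2.0 for s in scans}
    origin_arr = np.vstack([origins[s] for s in pairs["subject_id"]])
    ba = bland_altman(pairs, origin_arr)
    err = landmark_error(pairs, group.reindex(pairs["subject_id"]).to_numpy())
    out = {"n_scans": len(scans), "n_landmarks": len(RELIABILITY_LANDMARKS),
           "bias": ba.bias, "sd": ba.sd, "loa": [ba.loa_low, ba.loa_high],
           "n_pairs": ba.n, "origin_rule": ba.origin_rule,
           "landmark_error": err}
    (ROOT / "reliability.json").write_text(
        json.dumps(_jsonify(out), indent=2, sort_keys=True))
    plot_bland_altman(ba, ROOT / "bland_altman.svg",
                      title="Inter-rater agreement, landmark-origin distances")
    print(f"{ba.n} pairs from {len(scans)} scans: bias {ba.bias:.3f} mm, "
          f"LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}] mm")
    for g, st in err.items():
        print(f"  landmark error [{g}]: {st['mean']:.2f} ± {st['sd']:.2f} mm "
              f"(n={st['n']})")
    print(f"wrote {ROOT / 'reliability.json'} and bland_altman.svg")


if __name__ == "__main__":
    main()
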