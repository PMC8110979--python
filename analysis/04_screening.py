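#!/usr/bin/env python
"""Difficult-airway screening: group comparisons, crude and age/sex-adjusted
logistic regressions per measurement, ROC of the Δ scores, and the combined
ΔIPA+ΔHAD logistic score.  Writes results/screening.json."""
import json
from pathlib import Path

import pandas as pd

from airwaymorph.errors import AirwayMorphError
from airwaymorph.io import read_demographics_csv
from airwaymorph.pipeline import DELTA_MEASUREMENTS, _jsonify
from airwaymorph.screening import (combine_scores, compare_groups,
                                   fit_logistic, roc_analysis)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    meas = pd.read_csv(ROOT / "measurements.csv")
    demo = read_demographics_csv(ROOT / "cohort" / "demographics.csv")
    deltas = pd.read_csv(ROOT / "delta_scores.csv")
    long = meas[meas["available"]].merge(demo, on="subject_id")
    labels = demo.set_index("subject_id")["difficult_airway"]

    comparisons, logistic, rocs = {}, {}, {}
    obs = long.pivot_table(index="subject_id", columns="measurement",
                           values="value")
    adjust = pd.DataFrame({
        "age_months": demo.set_index("subject_id")["age_months"],
        "sex_male": (demo.set_index("subject_id")["sex"] == "M").astype(float)})
    for name in DELTA_MEASUREMENTS:
        sub = long[long["measurement"] == name]
        cmp_ = compare_groups(
            sub.loc[sub["group"] == "hypoplasia", "value"],
            sub.loc[sub["group"] == "control", "value"],
            measurement=name, groups=("hypoplasia", "control"))
        comparisons[name] = {"test": cmp_.test, "p": cmp_.p_value}
        x = obs[name].dropna()
        y = labels.loc[x.index].to_numpy(dtype=int)
        entry = {}
        for mode, adj in (("crude", None), ("adjusted", adjust.loc[x.index])):
            try:
                fit = fit_logistic(y, pd.DataFrame({name: x.to_numpy()}), adj)
                entry[mode] = {"or": fit.odds_ratio[name],
                               "ci": [fit.ci_low[name], fit.ci_high[name]],
                               "p": fit.p_value[name]}
            except AirwayMorphError as exc:
                entry[mode] = {"error": type(exc).__name__}
        logistic[name] = entry

    wide = deltas.pivot(index="subject_id", columns="measurement",
                        values="delta")
    for name in wide.columns:
        d = wide[name].dropna()
        roc = roc_analysis(d.to_numpy(),
                           labels.loc[d.index].to_numpy(dtype=int),
                           score_name=f"delta_{name}")
        rocs[f"delta_{name}"] = {
            "auc": roc.auc, "ci": [roc.ci_low, roc.ci_high],
            "cutoff": roc.cutoff, "direction": roc.direction,
            "sens": roc.sensitivity, "spec": roc.specificity}
    combo = wide[["inferior_pogonial_angle", "hyoid_anterior_distance"]].dropna()
    roc = combine_scores(combo, labels.loc[combo.index].to_numpy(dtype=int),
                         score_name="delta_ipa_plus_delta_had")
    rocs["delta_ipa_plus_delta_had"] = {
        "auc": roc.auc, "ci": [roc.ci_low, roc.ci_high],
        "sens": roc.sensitivity, "spec": roc.specificity}

    out = {"group_comparisons": comparisons, "logistic": logistic,
           "roc": rocs}
    (ROOT / "screening.json").write_text(
        json.dumps(_jsonify(out), indent=2, sort_keys=True))
    ipa = rocs["delta_inferior_pogonial_angle"]
    print(f"delta-IPA: AUC {ipa['auc']:.3f} "
          f"(95% CI {ipa['ci'][0]:.3f}-{ipa['ci'][1]:.3f}), "
          f"cutoff {ipa['cutoff']:.1f} deg ({ipa['direction']}), "
          f"sens {ipa['sens']:.2f} spec {ipa['spec']:.2f}")
    print(f"combined delta-IPA + delta-HAD: AUC "
          f"{rocs['delta_ipa_plus_delta_had']['auc']:.3f}")
    print(f"wrote {ROOT / 'screening.json'}")


if __name__ == "__main__":
    main()
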