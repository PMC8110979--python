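"""End-to-end study pipeline and report assembly.

Orchestrates simulate/load → reference frames → measurements → group
comparisons (overall and stratified by stage of dentition) → normative
growth fits and Δ scores → crude and age/sex-adjusted logistic screening →
ROC of Δ parameters → inter-rater reliability, and assembles everything
into one JSON-serializable study report.  Deterministic for a fixed
config/seed; subjects failing frame construction are dropped with a logged
reason, never silently.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .errors import (
    AirwayMorphError,
    InsufficientDataError,
    NonConvergenceError,
    NoVarianceError,
    SeparationError,
    SingleClassError,
)
from .geometry import LandmarkSet, build_reference_frame, reorient
from .measure import evaluate_specs, table_from_rows
from .normative import delta_scores, fit_growth
from .reliability import afh_origin, bland_altman, landmark_error, pair_observers
from .screening import combine_scores, compare_groups, fit_logistic, roc_analysis
from .simulate import GrowthConfig, SyntheticCohort, generate_airway_mesh, generate_cohort
from .specs import DEFAULT_SPECS

log = logging.getLogger("airwaymorph")

#: measurements carried into growth curves, Δ scores and screening models
DELTA_MEASUREMENTS = (
    "ramus_height", "ramus_width", "body_total_length", "body_width",
    "hyoid_anterior_distance", "hyoid_posterior_distance",
    "inferior_pogonial_angle", "bigonial_distance",
)

#: the 18-landmark subset used for the inter-rater reliability analysis
RELIABILITY_LANDMARKS = (
    "Orbitale_L", "Orbitale_R", "Porion_L", "Porion_R", "Nasion",
    "Opisthion", "Pa_V", "ANS", "Palate_Mid", "Go_L", "Go_R", "Pog",
    "Menton", "S_Co_L", "S_Co_R", "Hyoid", "Aa_C3", "Tongue_Tip",
)


@dataclass
class RunConfig:
    """Pipeline options; serialized verbatim into every report."""

    seed: int = 7
    n_per_group: int = 42
    simulate: bool = True
    cohort_dir: str | None = None
    growth_model: str = "log_log"        # log_log | log_age_only
    area_mode: str = "midsagittal_section"
    auc_ci: str = "delong"               # delong | bootstrap
    bootstrap_reps: int = 2000
    dentition_cutoff_months: float = 60.0
    reliability_scans: int = 40
    delta_measurements: tuple[str, ...] = DELTA_MEASUREMENTS
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        if "delta_measurements" in data:
            data = {**data,
                    "delta_measurements": tuple(data["delta_measurements"])}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["delta_measurements"] = list(self.delta_measurements)
        d["version"] = __version__
        return d


def _jsonify(obj):
    """Recursively convert numpy scalars/arrays for JSON output."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def report_to_json(report: dict) -> str:
    return json.dumps(_jsonify(report), indent=2, sort_keys=True)


def _load_cohort(config: RunConfig):
    from .io import read_demographics_csv, read_landmarks_csv
    cohort_dir = Path(config.cohort_dir)
    sets = read_landmarks_csv(cohort_dir / "landmarks.csv")
    demo = read_demographics_csv(cohort_dir / "demographics.csv")
    return sets, demo, None


def _measure_subjects(subjects, demo: pd.DataFrame, cohort, config: RunConfig):
    """Frames, reorientation and measurement evaluation with exclusion
    accounting.  ``subjects`` maps subject_id -> {observer -> LandmarkSet}."""
    exclusions = []
    frames_rows = []
    by_record = {s.subject_id: s for s in cohort.subjects} if cohort else {}
    for sid in sorted(subjects):
        lm = subjects[sid].get("O1") or next(iter(subjects[sid].values()))
        try:
            frame = build_reference_frame(lm)
        except AirwayMorphError as exc:
            exclusions.append({"subject_id": sid, "stage": "reference_frame",
                               "reason": str(exc)})
            log.warning("excluded %s at frame stage: %s", sid, exc)
            continue
        canonical = reorient(lm, frame)
        meshes = None
        if sid in by_record:
            meshes, _ = generate_airway_mesh(by_record[sid], cohort.config)
        frames_rows.append(evaluate_specs(canonical, meshes, DEFAULT_SPECS))
    measurements = table_from_rows(frames_rows)
    return measurements, exclusions


def _table_block(measurements: pd.DataFrame, demo: pd.DataFrame) -> dict:
    """Per-measurement two-group comparison block (Table-1 style)."""
    block = {}
    merged = measurements.merge(demo[["subject_id", "group"]], on="subject_id")
    names = [m for m in merged["measurement"].unique() if "__" not in m]
    for name in names:
        sub = merged[(merged["measurement"] == name) & merged["available"]]
        x = sub.loc[sub["group"] == "hypoplasia", "value"].to_numpy()
        y = sub.loc[sub["group"] == "control", "value"].to_numpy()
        try:
            cmp_ = compare_groups(x, y, measurement=name,
                                  groups=("hypoplasia", "control"))
            block[name] = {"summaries": cmp_.summaries, "test": cmp_.test,
                           "p_value": cmp_.p_value}
        except InsufficientDataError:
            block[name] = {"error": "insufficient data"}
    # demographics rows
    age_h = demo.loc[demo["group"] == "hypoplasia", "age_months"].to_numpy()
    age_c = demo.loc[demo["group"] == "control", "age_months"].to_numpy()
    try:
        cmp_age = compare_groups(age_h, age_c, "age_months",
                                 ("hypoplasia", "control"))
        block["age_months"] = {"summaries": cmp_age.summaries,
                               "test": cmp_age.test,
                               "p_value": cmp_age.p_value}
    except InsufficientDataError:
        block["age_months"] = {"error": "insufficient data"}
    sex_tab = pd.crosstab(demo["group"], demo["sex"])
    if sex_tab.shape == (2, 2):
        _, p_sex = stats.fisher_exact(sex_tab.to_numpy())
    else:
        p_sex = 1.0
    block["sex_male"] = {
        "counts": {g: int((demo.loc[demo["group"] == g, "sex"] == "M").sum())
                   for g in ("hypoplasia", "control")},
        "test": "fisher", "p_value": float(p_sex)}
    return block


def run_pipeline(config: RunConfig, cohort: SyntheticCohort | None = None) -> dict:
    """Execute every stage and return the study report dictionary."""
    stage_counts = {}
    if cohort is None and config.simulate:
        cohort = generate_cohort(GrowthConfig(), config.n_per_group,
                                 config.seed)
    if cohort is not None:
        demo = cohort.demographics()
        subjects = {s.subject_id: dict(s.observations)
                    for s in cohort.subjects}
    else:
        sets, demo, _ = _load_cohort(config)
        subjects = {}
        for lm in sets:
            subjects.setdefault(lm.subject_id, {})[lm.observer_id] = lm
    stage_counts["input_subjects"] = len(subjects)

    measurements, exclusions = _measure_subjects(subjects, demo, cohort, config)
    included = measurements["subject_id"].unique()
    stage_counts["measured_subjects"] = int(len(included))
    demo_in = demo[demo["subject_id"].isin(included)].reset_index(drop=True)

    # Table-1 style block and dentition-stratified Table-2 style block
    table1 = _table_block(measurements, demo_in)
    cutoff = config.dentition_cutoff_months
    young_ids = demo_in.loc[demo_in["age_months"] <= cutoff, "subject_id"]
    old_ids = demo_in.loc[demo_in["age_months"] > cutoff, "subject_id"]
    table2 = {}
    for label, ids in (("age_le_60m", young_ids), ("age_gt_60m", old_ids)):
        sub_meas = measurements[measurements["subject_id"].isin(ids)]
        sub_demo = demo_in[demo_in["subject_id"].isin(ids)]
        if sub_demo["group"].nunique() == 2:
            table2[label] = _table_block(sub_meas, sub_demo)
        else:
            table2[label] = {"error": "one group empty in stratum"}
    stage_counts["stratum_le_60m"] = int(len(young_ids))
    stage_counts["stratum_gt_60m"] = int(len(old_ids))

    # growth curves per group and Δ scores against the control curves
    long = measurements[measurements["available"]].merge(
        demo_in[["subject_id", "group", "age_months", "sex",
                 "difficult_airway"]], on="subject_id")
    fig2 = {}
    control_fits = {}
    for name in config.delta_measurements:
        fig2[name] = {}
        for group in ("control", "hypoplasia"):
            sub = long[(long["measurement"] == name) & (long["group"] == group)]
            try:
                fit = fit_growth(sub["age_months"], sub["value"], name, group,
                                 model=config.growth_model)
            except AirwayMorphError as exc:
                fig2[name][group] = {"error": str(exc)}
                continue
            fig2[name][group] = fit.to_dict()
            if group == "control":
                control_fits[name] = fit
    delta_long = long[long["measurement"].isin(control_fits)]
    deltas = delta_scores(control_fits, delta_long)
    delta_wide = deltas.pivot(index="subject_id", columns="measurement",
                              values="delta")

    # Table-3 style crude and age/sex-adjusted logistic regressions
    labels = demo_in.set_index("subject_id")["difficult_airway"]
    adjust = pd.DataFrame({
        "age_months": demo_in.set_index("subject_id")["age_months"],
        "sex_male": (demo_in.set_index("subject_id")["sex"] == "M").astype(float),
    })
    obs_wide = long[long["measurement"].isin(config.delta_measurements)].pivot(
        index="subject_id", columns="measurement", values="value")
    table3 = {}
    for name in config.delta_measurements:
        if name not in obs_wide.columns:
            continue
        x = obs_wide[name].dropna()
        y = labels.loc[x.index].to_numpy(dtype=int)
        entry = {}
        for mode, adj in (("crude", None), ("adjusted", adjust.loc[x.index])):
            try:
                fit = fit_logistic(y, pd.DataFrame({name: x.to_numpy()}),
                                   adjust=adj)
                entry[mode] = {"odds_ratio": fit.odds_ratio[name],
                               "ci": [fit.ci_low[name], fit.ci_high[name]],
                               "p_value": fit.p_value[name], "n": fit.n}
            except (SeparationError, NoVarianceError, NonConvergenceError,
                    InsufficientDataError) as exc:
                entry[mode] = {"error": type(exc).__name__}
        table3[name] = entry

    # Fig-3 style ROC of Δ parameters and the combined two-score model
    fig3 = {}
    y_all = labels.loc[delta_wide.index].to_numpy(dtype=int)
    for name in delta_wide.columns:
        scores = delta_wide[name]
        ok = scores.notna()
        try:
            roc = roc_analysis(scores[ok].to_numpy(),
                               labels.loc[scores[ok].index].to_numpy(dtype=int),
                               score_name=f"delta_{name}",
                               ci_method=config.auc_ci,
                               n_boot=config.bootstrap_reps, seed=config.seed)
            fig3[f"delta_{name}"] = {
                "auc": roc.auc, "ci": [roc.ci_low, roc.ci_high],
                "cutoff": roc.cutoff, "direction": roc.direction,
                "sensitivity": roc.sensitivity, "specificity": roc.specificity}
        except (SingleClassError, AirwayMorphError) as exc:
            fig3[f"delta_{name}"] = {"error": type(exc).__name__}
    combo_cols = ["inferior_pogonial_angle", "hyoid_anterior_distance"]
    if all(c in delta_wide.columns for c in combo_cols):
        D = delta_wide[combo_cols].dropna()
        try:
            roc = combine_scores(D, labels.loc[D.index].to_numpy(dtype=int),
                                 score_name="delta_ipa_plus_delta_had",
                                 ci_method=config.auc_ci,
                                 n_boot=config.bootstrap_reps,
                                 seed=config.seed)
            fig3["delta_ipa_plus_delta_had"] = {
                "auc": roc.auc, "ci": [roc.ci_low, roc.ci_high],
                "cutoff": roc.cutoff, "direction": roc.direction,
                "sensitivity": roc.sensitivity, "specificity": roc.specificity}
        except (SingleClassError, AirwayMorphError) as exc:
            fig3["delta_ipa_plus_delta_had"] = {"error": type(exc).__name__}

    # Fig-4 style inter-rater reliability on a fixed landmark subset
    fig4 = {"error": "needs two observers"}
    two_obs = [sid for sid in sorted(subjects) if len(subjects[sid]) >= 2]
    if two_obs:
        # alternate between groups so both cohorts contribute scans
        grp = demo_in.set_index("subject_id")["group"]
        by_grp: dict[str, list] = {}
        for sid in two_obs:
            by_grp.setdefault(str(grp.get(sid, "?")), []).append(sid)
        queues = [by_grp[g] for g in sorted(by_grp)]
        scans = []
        while len(scans) < min(config.reliability_scans, len(two_obs)):
            for q in queues:
                if q and len(scans) < config.reliability_scans:
                    scans.append(q.pop(0))
        sets1 = [subjects[sid]["O1"] for sid in scans]
        sets2 = [subjects[sid]["O2"] for sid in scans]
        pairs = pair_observers(sets1, sets2, list(RELIABILITY_LANDMARKS))
        origins = {}
        for sid in scans:
            lm1, lm2 = subjects[sid]["O1"], subjects[sid]["O2"]
            try:
                origins[sid] = (afh_origin(lm1) + afh_origin(lm2)) / 2.0
            except AirwayMorphError:
                continue
        pairs = pairs[pairs["subject_id"].isin(origins)].reset_index(drop=True)
        if len(pairs) >= 2:
            origin_arr = np.vstack([origins[sid]
                                    for sid in pairs["subject_id"]])
            ba = bland_altman(pairs, origin_arr)
            groups = demo_in.set_index("subject_id")["group"].reindex(
                pairs["subject_id"]).to_numpy()
            err = landmark_error(pairs, groups)
            fig4 = {"bias": ba.bias, "sd": ba.sd,
                    "loa": [ba.loa_low, ba.loa_high], "n_pairs": ba.n,
                    "n_scans": len(scans), "origin_rule": ba.origin_rule,
                    "landmark_error": err}

    report = {
        "config": config.to_dict(),
        "counts": stage_counts,
        "exclusions": exclusions,
        "group_sizes": demo_in["group"].value_counts().to_dict(),
        "table1": table1,
        "table2": table2,
        "table3": table3,
        "growth_curves": fig2,
        "roc": fig3,
        "reliability": fig4,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report_to_json(report))
        measurements.to_csv(out / "measurements.csv", index=False)
        deltas.to_csv(out / "delta_scores.csv", index=False)
    return report
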