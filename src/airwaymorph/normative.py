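"""Normative log-growth modelling and Δ deviation scores.

Craniofacial dimensional growth is modelled as a power law in age,
``value = exp(α) * age^β``, fitted by ordinary least squares of ln(value)
on ln(age) within a group.  A subject's Δ score for a measurement is the
control-curve prediction at the subject's age minus the observed value;
positive Δ means the subject falls short of the age-expected normal, and
for angles a negative Δ means the angle is wider than expected.  A
``log_age_only`` variant (value linear in ln(age)) is kept as a config
switch.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    InsufficientDataError,
    MissingFitError,
    NonPositiveAgeError,
    NonPositiveDataError,
)

GROWTH_MODELS = ("log_log", "log_age_only")


@dataclass(frozen=True)
class GrowthFit:
    """Per-measurement growth regression on one group."""

    measurement: str
    group: str
    intercept: float
    slope: float
    resid_sd: float
    n: int
    r2: float
    model: str = "log_log"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthFit":
        return cls(**d)


def fit_growth(ages, values, measurement: str = "", group: str = "",
               model: str = "log_log") -> GrowthFit:
    """OLS fit of the growth law; deterministic and order-invariant.

    ``log_log`` regresses ln(value) on ln(age); ``log_age_only`` regresses
    value on ln(age).
    """
    if model not in GROWTH_MODELS:
        raise ValueError(f"unknown growth model {model!r}")
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(ages) & np.isfinite(values)
    ages, values = ages[mask], values[mask]
    n = len(ages)
    if n < 3:
        raise InsufficientDataError(f"growth fit needs n >= 3, got {n}")
    if np.any(ages <= 0):
        raise NonPositiveDataError("ages must be strictly positive")
    y = values
    if model == "log_log":
        if np.any(values <= 0):
            raise NonPositiveDataError("values must be strictly positive "
                                       "for the log-log model")
        y = np.log(values)
    x = np.log(ages)
    # sort for bitwise order invariance of the linear algebra
    order = np.lexsort((y, x))
    x, y = x[order], y[order]
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    resid = y - res.predict(X)
    resid_sd = float(np.sqrt(resid @ resid / (n - 2))) if n > 2 else 0.0
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if tss < 1e-300 else float(res.rsquared)
    return GrowthFit(measurement=measurement, group=group,
                     intercept=float(res.params[0]), slope=float(res.params[1]),
                     resid_sd=resid_sd, n=n, r2=r2, model=model)


def predict(fit: GrowthFit, age) -> float | np.ndarray:
    """Expected measurement value at an age (months) under the fit."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise NonPositiveAgeError("age must be strictly positive")
    eta = fit.intercept + fit.slope * np.log(age)
    out = np.exp(eta) if fit.model == "log_log" else eta
    return float(out) if out.ndim == 0 else out


def delta_scores(control_fits: dict[str, GrowthFit],
                 cohort: pd.DataFrame) -> pd.DataFrame:
    """Δ = control-curve prediction at the subject's age − observed value.

    ``cohort`` is long-format with columns subject_id, age_months,
    measurement, value (plus any extra columns, carried through).  Every
    subject with an available measurement gets a Δ row; a missing control
    fit for a requested measurement raises :class:`MissingFitError`.
    """
    required = {"subject_id", "age_months", "measurement", "value"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    wanted = cohort["measurement"].unique()
    missing = [m for m in wanted if m not in control_fits]
    if missing:
        raise MissingFitError(missing)
    rows = []
    for rec in cohort.itertuples(index=False):
        if not np.isfinite(rec.value):
            continue
        fit = control_fits[rec.measurement]
        pred = predict(fit, rec.age_months)
        rows.append({"subject_id": rec.subject_id,
                     "measurement": rec.measurement,
                     "predicted": pred, "observed": float(rec.value),
                     "delta": pred - float(rec.value)})
    return pd.DataFrame(rows)
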