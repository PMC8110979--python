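"""Group comparisons, difficult-airway logistic models and ROC screening.

Implements the screening statistics of the analysis: normality-gated
two-group tests, crude and age/sex-adjusted logistic regression with Wald
odds-ratio intervals, ROC analysis of Δ deviation scores with Youden-index
cutoffs and DeLong confidence intervals, and the logistic combination of
several Δ scores into one screening score.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit

from .errors import (
    InsufficientDataError,
    NonConvergenceError,
    NoVarianceError,
    SeparationError,
    SingleClassError,
)

SHAPIRO_ALPHA = 0.05
WALD_Z = 1.959963984540054  # two-sided 95%


@dataclass(frozen=True)
class GroupComparison:
    measurement: str
    groups: tuple[str, str]
    summaries: dict
    test: str           # "t" | "mann_whitney"
    statistic: float
    p_value: float
    normality_p: tuple[float, float]


@dataclass(frozen=True)
class LogisticFitResult:
    outcome: str
    predictors: tuple[str, ...]
    coef: dict[str, float]
    se: dict[str, float]
    odds_ratio: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_value: dict[str, float]
    converged: bool
    adjusted_for: tuple[str, ...]
    n: int
    log_likelihood: float
    linear_predictor: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class RocResult:
    score_name: str
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    direction: str          # "greater": score >= cutoff predicts positive
    sensitivity: float
    specificity: float
    flipped: bool
    thresholds: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)
    fpr: np.ndarray = field(repr=False, default=None)
    ci_method: str = "delong"


def _summary(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"n": int(len(x)), "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
            "median": float(med), "q1": float(q1), "q3": float(q3)}


def _normal(x: np.ndarray) -> float:
    """Shapiro-Wilk p value; constant samples are treated as non-normal."""
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def compare_groups(x, y, measurement: str = "",
                   groups: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Two-group comparison with a normality-based test switch.

    Shapiro-Wilk at alpha 0.05 per group; Welch's t when both groups pass,
    otherwise a two-sided Mann-Whitney U (exact where SciPy allows, normal
    approximation with tie correction otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 3 or len(y) < 3:
        raise InsufficientDataError("each group needs n >= 3")
    px, py = _normal(x), _normal(y)
    if px > SHAPIRO_ALPHA and py > SHAPIRO_ALPHA:
        res = stats.ttest_ind(x, y, equal_var=False)
        test = "t"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        test = "mann_whitney"
    return GroupComparison(measurement=measurement, groups=groups,
                           summaries={groups[0]: _summary(x),
                                      groups[1]: _summary(y)},
                           test=test, statistic=float(res.statistic),
                           p_value=float(res.pvalue), normality_p=(px, py))


def fit_logistic(outcome, predictors, adjust=None,
                 outcome_name: str = "difficult_airway") -> LogisticFitResult:
    """Maximum-likelihood logistic regression with Wald 95% OR intervals.

    ``predictors`` is a DataFrame (or array) of the exposures of interest;
    ``adjust`` optionally adds covariates (e.g. age and sex) whose ORs are
    also reported.  Perfect separation and non-convergence raise.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise NoVarianceError("outcome has a single class")
    X = pd.DataFrame(predictors).reset_index(drop=True)
    X.columns = [str(c) for c in X.columns]
    adjusted_for: tuple[str, ...] = ()
    if adjust is not None:
        A = pd.DataFrame(adjust).reset_index(drop=True)
        A.columns = [str(c) for c in A.columns]
        adjusted_for = tuple(A.columns)
        X = pd.concat([X, A], axis=1)
    for col in X.columns:
        if np.ptp(X[col].to_numpy(dtype=float)) == 0:
            raise NoVarianceError(f"constant predictor {col!r}")
    if len(y) <= X.shape[1] + 2:
        raise InsufficientDataError("n must exceed #predictors + 2")
    design = sm.add_constant(X.to_numpy(dtype=float))
    names = ("const",) + tuple(X.columns)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=100, tol=1e-8,
                                          method="newton")
    except np.linalg.LinAlgError as exc:
        # singular information matrix: separated or collinear data
        raise SeparationError(str(exc)) from exc
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        if "separation" in type(exc).__name__.lower() or "Separation" in str(exc):
            raise SeparationError(str(exc)) from exc
        raise
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(bse)) or np.max(np.abs(params)) > 50:
        raise SeparationError("diverging coefficients: data are separated")
    if not res.mle_retvals.get("converged", False):
        raise NonConvergenceError("logistic fit did not converge")
    pvals = np.asarray(res.pvalues, dtype=float)
    coef = dict(zip(names, params))
    se = dict(zip(names, bse))
    return LogisticFitResult(
        outcome=outcome_name, predictors=tuple(X.columns),
        coef={k: float(v) for k, v in coef.items()},
        se={k: float(v) for k, v in se.items()},
        odds_ratio={k: float(np.exp(v)) for k, v in coef.items() if k != "const"},
        ci_low={k: float(np.exp(coef[k] - WALD_Z * se[k]))
                for k in names if k != "const"},
        ci_high={k: float(np.exp(coef[k] + WALD_Z * se[k]))
                 for k in names if k != "const"},
        p_value={k: float(p) for k, p in zip(names, pvals) if k != "const"},
        converged=True, adjusted_for=adjusted_for, n=len(y),
        log_likelihood=float(res.llf),
        linear_predictor=design @ params)


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney probability P(score+ > score-), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise SingleClassError("both classes required")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - m * (m + 1) / 2) / (m * n))


def _delong_ci(scores, labels) -> tuple[float, float, float]:
    """DeLong variance-based 95% CI for the AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    x = scores[labels == 1]   # positives
    y = scores[labels == 0]
    m, n = len(x), len(y)
    allr = stats.rankdata(np.concatenate([x, y]))
    xr, yr = stats.rankdata(x), stats.rankdata(y)
    auc = (allr[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (allr[:m] - xr) / n                 # placement of each positive
    v01 = 1.0 - (allr[m:] - yr) / m           # placement of each negative
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = WALD_Z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def _bootstrap_ci(scores, labels, n_boot: int, seed: int) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    aucs = []
    idx = np.arange(len(labels))
    for _ in range(n_boot):
        b = rng.choice(idx, size=len(idx), replace=True)
        if labels[b].min() == labels[b].max():
            continue
        aucs.append(auc_mann_whitney(scores[b], labels[b]))
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def roc_analysis(scores, labels, score_name: str = "",
                 ci_method: str = "delong", n_boot: int = 2000,
                 seed: int = 0) -> RocResult:
    """ROC curve, AUC with 95% CI, and the Youden-optimal cutoff.

    Higher score is taken to indicate the positive class; if the raw AUC is
    below 0.5 the score orientation is flipped and reported as
    ``direction='less'`` with the cutoff on the original scale.  Candidate
    cutoffs are midpoints of adjacent sorted unique scores, ties in the
    Youden index broken toward the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("both classes required for ROC analysis")
    flipped = False
    work = scores
    if auc_mann_whitney(scores, labels) < 0.5:
        flipped = True
        work = -scores

    uniq = np.unique(work)
    thr = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else uniq.copy()
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    # confusion counts at each threshold: positive call when score >= thr
    tpr = np.array([(work[pos] >= t).mean() for t in thr])
    fpr = np.array([(work[~pos] >= t).mean() for t in thr])
    youden = tpr - fpr
    best = int(np.argmax(youden))              # first index wins ties
    cutoff_internal = float(thr[best])
    sens, spec = float(tpr[best]), float(1.0 - fpr[best])
    # consistency assertion: re-derive from raw confusion counts
    tp = int(np.sum(work[pos] >= cutoff_internal))
    tn = int(np.sum(work[~pos] < cutoff_internal))
    assert abs(sens - tp / m) < 1e-12 and abs(spec - tn / n) < 1e-12

    auc = auc_mann_whitney(work, labels)
    if ci_method == "delong":
        _, lo, hi = _delong_ci(work, labels)
    elif ci_method == "bootstrap":
        lo, hi = _bootstrap_ci(work, labels, n_boot, seed)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    if flipped:
        cutoff, direction = -cutoff_internal, "less"
        thr_out = -thr[::-1]
        tpr_out, fpr_out = tpr[::-1], fpr[::-1]
    else:
        cutoff, direction = cutoff_internal, "greater"
        thr_out, tpr_out, fpr_out = thr, tpr, fpr
    return RocResult(score_name=score_name, auc=auc, ci_low=lo, ci_high=hi,
                     cutoff=cutoff, direction=direction, sensitivity=sens,
                     specificity=spec, flipped=flipped, thresholds=thr_out,
                     tpr=tpr_out, fpr=fpr_out, ci_method=ci_method)


def combine_scores(deltas: pd.DataFrame | dict, labels,
                   score_name: str = "combined", **roc_kwargs) -> RocResult:
    """ROC of the logistic combination of two or more Δ score sets.

    The combined score is the linear predictor of a logistic fit of the
    label on all Δ scores jointly — the standard construction for 'adding'
    a second screening parameter.
    """
    D = pd.DataFrame(deltas)
    if D.shape[1] < 2:
        raise ValueError("combine_scores needs at least two score sets")
    fit = fit_logistic(labels, D, outcome_name=score_name)
    return roc_analysis(fit.linear_predictor, labels, score_name=score_name,
                        **roc_kwargs)


# ---------------------------------------------------------------------------
# simulate-then-refit round trip for the crude odds-ratio models
# ---------------------------------------------------------------------------

def calibrate_intercept(mu_case: float, sd_case: float, mu_ctrl: float,
                        sd_ctrl: float, beta: float,
                        prevalence: float) -> float:
    """Intercept b0 such that the mixture-average event probability equals
    ``prevalence`` under P(y=1|x) = expit(b0 + beta*x), with x drawn from
    an equal mixture of two normals (Gauss-Hermite quadrature, exact to
    quadrature precision and fully deterministic)."""
    nodes, weights = np.polynomial.hermite.hermgauss(96)
    weights = weights / np.sqrt(np.pi)

    def mean_prob(b0: float) -> float:
        p = 0.0
        for mu, sd in ((mu_case, sd_case), (mu_ctrl, sd_ctrl)):
            x = mu + np.sqrt(2.0) * sd * nodes
            p += 0.5 * float(weights @ expit(b0 + beta * x))
        return p

    return float(optimize.brentq(lambda b: mean_prob(b) - prevalence,
                                 -80.0, 80.0, xtol=1e-12))


def crude_or_roundtrip(mu_case: float, sd_case: float, mu_ctrl: float,
                       sd_ctrl: float, true_or: float, n: int = 840,
                       prevalence: float = 10 / 84, n_seeds: int = 50,
                       seed: int = 0) -> dict:
    """Simulate-then-refit recovery of a crude logistic odds ratio.

    Draws ``n`` subjects (half from each group's normal distribution of the
    predictor), assigns labels from the Bernoulli logistic model with slope
    ln(true_or) and an intercept calibrated to the target prevalence, then
    refits the univariable logistic regression.  Returns the per-seed and
    mean refitted odds ratios.
    """
    beta = float(np.log(true_or))
    b0 = calibrate_intercept(mu_case, sd_case, mu_ctrl, sd_ctrl, beta,
                             prevalence)
    ss = np.random.SeedSequence(seed)
    ors = []
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        half = n // 2
        x = np.concatenate([rng.normal(mu_case, sd_case, half),
                            rng.normal(mu_ctrl, sd_ctrl, n - half)])
        ylab = (rng.random(n) < expit(b0 + beta * x)).astype(int)
        fit = fit_logistic(ylab, pd.DataFrame({"x": x}))
        ors.append(fit.odds_ratio["x"])
    ors = np.asarray(ors)
    return {"true_or": true_or, "intercept": b0, "n": n,
            "n_seeds": n_seeds, "per_seed": ors,
            "mean_or": float(ors.mean()), "sd_or": float(ors.std(ddof=1))}
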