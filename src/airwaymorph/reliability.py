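"""Inter-rater reliability: Bland-Altman agreement on landmark-to-origin
distances and the 3D landmark placement error between two observers.

The Bland-Altman statistic follows the scalar convention of comparing each
observer's Euclidean distance from the landmark to a common per-scan
origin; because that scalar can hide tangential disagreement, the full 3D
placement error (mean ± SD of the inter-observer distance) is always
reported alongside.  SDs use the n-1 denominator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .geometry import AFH_LANDMARKS, LandmarkSet

LOA_Z = 1.96  # conventional Bland-Altman limits multiplier


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)
    origin_rule: str = "afh_centroid"


def pair_observers(sets_1: list[LandmarkSet], sets_2: list[LandmarkSet],
                   landmarks: list[str] | None = None) -> pd.DataFrame:
    """Match two observers' placements on (subject, landmark name).

    Only landmarks digitized by both observers are included.  Returns a
    long table with both positions per matched pair.
    """
    by_subject_2 = {s.subject_id: s for s in sets_2}
    rows = []
    for s1 in sets_1:
        s2 = by_subject_2.get(s1.subject_id)
        if s2 is None:
            continue
        for name in s1.names():
            if name not in s2:
                continue
            if landmarks is not None and name not in landmarks:
                continue
            p1, p2 = s1[name], s2[name]
            rows.append({"subject_id": s1.subject_id, "name": name,
                         "x1": p1[0], "y1": p1[1], "z1": p1[2],
                         "x2": p2[0], "y2": p2[1], "z2": p2[2]})
    return pd.DataFrame(rows)


def _positions(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    p1 = pairs[["x1", "y1", "z1"]].to_numpy(dtype=float)
    p2 = pairs[["x2", "y2", "z2"]].to_numpy(dtype=float)
    return p1, p2


def afh_origin(lm: LandmarkSet) -> np.ndarray:
    """Per-scan origin: centroid of the four Frankfort landmarks."""
    lm.require(*AFH_LANDMARKS)
    return np.mean([lm[n] for n in AFH_LANDMARKS], axis=0)


def bland_altman(pairs: pd.DataFrame, origin) -> BlandAltmanResult:
    """Bland-Altman analysis on landmark-to-origin distances.

    ``origin`` is a single 3-vector or an (n, 3) array of per-pair origins.
    Differences are observer1 − observer2.
    """
    if len(pairs) < 2:
        raise InsufficientDataError("Bland-Altman needs at least two pairs")
    p1, p2 = _positions(pairs)
    origin = np.asarray(origin, dtype=float)
    d1 = np.linalg.norm(p1 - origin, axis=1)
    d2 = np.linalg.norm(p2 - origin, axis=1)
    diffs = d1 - d2
    means = (d1 + d2) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd=sd, loa_low=bias - LOA_Z * sd,
                             loa_high=bias + LOA_Z * sd, n=len(diffs),
                             means=means, diffs=diffs)


def landmark_error(pairs: pd.DataFrame,
                   groups: pd.Series | None = None) -> dict:
    """Mean ± SD of the 3D inter-observer placement distance.

    With ``groups`` (aligned to pairs rows) the statistic is also reported
    per group, mirroring the per-cohort error summaries.
    """
    if len(pairs) < 1:
        raise InsufficientDataError("no matched pairs")
    p1, p2 = _positions(pairs)
    err = np.linalg.norm(p1 - p2, axis=1)

    def stat(e):
        return {"mean": float(np.mean(e)),
                "sd": float(np.std(e, ddof=1)) if len(e) > 1 else 0.0,
                "n": int(len(e))}

    out = {"overall": stat(err)}
    if groups is not None:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            out[str(g)] = stat(err[groups == g])
    return out


def plot_bland_altman(result: BlandAltmanResult, path, title: str = ""):
    """Mean-vs-difference scatter with bias and limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.means, result.diffs, s=12, alpha=0.6, edgecolors="none")
    for yv, style, label in ((result.bias, "-", "bias"),
                             (result.loa_low, "--", "-1.96 SD"),
                             (result.loa_high, "--", "+1.96 SD")):
        ax.axhline(yv, linestyle=style, color="firebrick", linewidth=1)
        ax.annotate(f"{label}: {yv:.2f}", xy=(1.0, yv),
                    xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8)
    ax.set_xlabel("mean of observer distances to origin (mm)")
    ax.set_ylabel("difference observer1 - observer2 (mm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
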