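"""Group statistics for tissue discrimination: Welch tests, ROC/AUC, summaries.

Per-specimen metrics (attenuation coefficient, trendline descending
angle, grid band count) are compared between tissue groups with Welch's
unequal-variance t-test (group SDs differ several-fold, so the pooled
test is inappropriate; no multiple-comparison correction is applied).
Discrimination performance is summarized by the ROC curve and its AUC,
computed with the Mann-Whitney pairwise identity (ties count one half),
together with the Youden-optimal operating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

__all__ = ["WelchResult", "ROCResult", "welch_t", "roc_auc", "summarize_groups"]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch's two-sided unequal-variance t-test with Satterthwaite df."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


@dataclass
class ROCResult:
    """ROC analysis of a scalar classifier separating tumor from nontumor."""

    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden_threshold: float
    youden_j: float
    direction: str                # "lower" (lower value => tumor) or "higher"


def _resolve_direction(tumor: np.ndarray, nontumor: np.ndarray,
                       direction: str) -> str:
    if direction in ("lower", "higher"):
        return direction
    if direction != "auto":
        raise ValueError("direction must be 'lower', 'higher' or 'auto'")
    return "lower" if tumor.mean() < nontumor.mean() else "higher"


def roc_auc(tumor_values: Sequence[float], nontumor_values: Sequence[float],
            direction: str = "auto") -> ROCResult:
    """ROC curve and AUC for a scalar metric, tumor as the positive class.

    The AUC equals the Mann-Whitney probability that a random tumor
    specimen scores on the tumor side of a random nontumor specimen,
    ties counted one half. ``direction="lower"`` means smaller metric
    values indicate tumor (the attenuation convention: gliomas attenuate
    less than peritumoral brain).
    """
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(nontumor_values, dtype=float)
    if t.size == 0 or n.size == 0:
        raise ValueError("both groups must be nonempty")
    direction = _resolve_direction(t, n, direction)
    sign = -1.0 if direction == "lower" else 1.0
    scores = sign * np.concatenate([t, n])
    labels = np.concatenate([np.ones(t.size), np.zeros(n.size)])
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))
    # map the score threshold back to the metric scale (drop the sign and
    # the synthetic +inf sentinel of the first point)
    raw_thr = sign * thr
    youden = float(raw_thr[best]) if np.isfinite(raw_thr[best]) else float("nan")
    return ROCResult(auc=auc, thresholds=raw_thr, sensitivity=tpr,
                     specificity=1.0 - fpr, youden_threshold=youden,
                     youden_j=float(j[best]), direction=direction)


def summarize_groups(samples: dict[str, Sequence[float]],
                     reference: Optional[str] = None) -> pd.DataFrame:
    """Per-group n / mean / SD summary with Welch p against a reference.

    ``reference`` defaults to the last group (e.g. the peritumoral
    nontumoral tissue row); single-specimen groups report no SD and no p
    (rendered as NaN, formatted "-" downstream). SD uses the n-1
    denominator.
    """
    if not samples:
        raise ValueError("need at least one group")
    names = list(samples)
    ref = reference if reference is not None else names[-1]
    if ref not in samples:
        raise ValueError(f"unknown reference group {ref!r}")
    ref_vals = np.asarray(samples[ref], dtype=float)
    rows = []
    for name in names:
        vals = np.asarray(samples[name], dtype=float)
        if vals.size < 1:
            raise ValueError(f"group {name!r} is empty")
        sd = float(vals.std(ddof=1)) if vals.size > 1 else math.nan
        p = math.nan
        if name != ref and vals.size >= 2 and ref_vals.size >= 2:
            p = welch_t(vals, ref_vals).p
        rows.append({"group": name, "n": int(vals.size),
                     "mean": float(vals.mean()), "sd": sd, "p_vs_ref": p})
    return pd.DataFrame(rows)
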