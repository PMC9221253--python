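"""Statistical validation of image-derived scores against movement counts.

Given a subject × task table of paired scores (the administrator's
movement count and the image-derived mean speed), this module provides:

* Pearson agreement between the two scores,
* the below-population-mean "low motility" labelling rule,
* ROC analysis of the image-derived score as a classifier of low motility
  (low motility is the positive class; *lower* image-derived scores
  indicate it, so the decision rule is score ≤ threshold),
* specificity at a fixed sensitivity level (the operating point reported
  for the five tasks),
* stratified-bootstrap confidence bands for the ROC curve and AUC,
* descriptive summary rows (mean, SD, index of dispersion, quartiles,
  extremes) for score distributions.

The dispersion statistic is SD²/mean (index of dispersion), reported next
to the conventional coefficient of variation SD/mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn import metrics as _skm

__all__ = [
    "ROCResult",
    "RocBand",
    "SpecificityAtSensitivity",
    "pearson",
    "low_motility_labels",
    "roc_curve",
    "specificity_at_sensitivity",
    "bootstrap_roc_band",
    "summarize_scores",
    "dispersion_from_moments",
    "validate_paired_scores",
    "PAIRED_SCORE_COLUMNS",
]

PAIRED_SCORE_COLUMNS = ("subject_id", "task_id", "conventional", "image_derived")


@dataclass
class ROCResult:
    """ROC curve of the image-derived score for the low-motility class.

    ``thresholds`` are in original score units; with orientation
    ``lower_is_positive`` a subject is predicted positive when its score is
    ≤ the threshold.  Points are ordered from the most conservative
    threshold (nobody positive) to the most liberal (everybody positive).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    orientation: str = "lower_is_positive"

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


class SpecificityAtSensitivity(NamedTuple):
    specificity: float
    threshold: float
    sensitivity: float


@dataclass
class RocBand:
    """Pointwise bootstrap band over a fixed FPR grid, plus an AUC CI."""

    fpr_grid: np.ndarray
    tpr_point: np.ndarray
    tpr_low: np.ndarray
    tpr_high: np.ndarray
    auc_ci: tuple[float, float]
    level: float
    n_boot: int


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p-value (t transform, n−2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("sequences must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the sequences")
    r, p = _stats.pearsonr(x, y)
    return float(r), float(p)


def low_motility_labels(scores) -> np.ndarray:
    """Label a subject low-motility iff its score is strictly below the mean.

    Ties at the mean (e.g. an all-equal sample) are labelled False.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) < 2:
        raise ValueError("need at least 2 scores to define a population mean")
    return scores < scores.mean()


def roc_curve(labels, scores, orientation: str = "lower_is_positive") -> ROCResult:
    """ROC of a continuous score against binary low-motility labels.

    Thresholds sweep the unique scores; AUC by the trapezoidal rule.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if orientation not in ("lower_is_positive", "higher_is_positive"):
        raise ValueError("unknown orientation")
    sign = -1.0 if orientation == "lower_is_positive" else 1.0
    fpr, tpr, thr = _skm.roc_curve(labels, sign * scores, drop_intermediate=False)
    # map decision thresholds back into original score units; the leading
    # sentinel (predict nobody positive) becomes +/-inf accordingly
    thresholds = sign * thr
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        orientation=orientation,
    )


def specificity_at_sensitivity(
    roc: ROCResult, target_sensitivity: float = 0.70
) -> SpecificityAtSensitivity:
    """Best specificity among thresholds achieving the target sensitivity.

    Ties on specificity are broken toward the lower threshold (the more
    conservative decision rule) so the result is deterministic.  If no
    threshold reaches the target a warning is issued and specificity 0 is
    returned at the most liberal threshold.
    """
    if not 0.0 < target_sensitivity <= 1.0:
        raise ValueError("target sensitivity must be in (0, 1]")
    ok = roc.sensitivity >= target_sensitivity - 1e-12
    if not ok.any():
        warnings.warn(
            f"no threshold reaches sensitivity {target_sensitivity}; reporting specificity 0"
        )
        i = len(roc.thresholds) - 1
        return SpecificityAtSensitivity(0.0, float(roc.thresholds[i]), float(roc.sensitivity[i]))
    spec = np.where(ok, roc.specificity, -np.inf)
    best = spec.max()
    candidates = np.nonzero(spec == best)[0]
    i = candidates[np.argmin(roc.thresholds[candidates])]
    return SpecificityAtSensitivity(
        float(roc.specificity[i]), float(roc.thresholds[i]), float(roc.sensitivity[i])
    )


def _interp_tpr(fpr: np.ndarray, tpr: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Interpolate a (possibly stepwise, duplicated-FPR) ROC onto a grid."""
    # collapse duplicate FPR values to their maximal TPR (vertical steps)
    order = np.argsort(fpr, kind="stable")
    fpr, tpr = fpr[order], tpr[order]
    uniq, idx = np.unique(fpr[::-1], return_index=True)
    tpr_max = tpr[::-1][idx]  # last occurrence in sorted order = max tpr
    return np.interp(grid, uniq, tpr_max)


def bootstrap_roc_band(
    labels,
    scores,
    n_boot: int = 2000,
    seed: int | None = None,
    level: float = 0.95,
    orientation: str = "lower_is_positive",
    n_grid: int = 101,
) -> RocBand:
    """Stratified percentile bootstrap band for the ROC curve and AUC.

    Resamples within each class independently; deterministic given
    ``seed``.  TPR is interpolated on a fixed FPR grid before taking
    pointwise percentiles.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    pos = np.nonzero(labels)[0]
    neg = np.nonzero(~labels)[0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 members to bootstrap")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, n_grid)

    point = roc_curve(labels, scores, orientation)
    tpr_point = _interp_tpr(1.0 - point.specificity, point.sensitivity, grid)

    tprs = np.empty((n_boot, n_grid))
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        roc_b = roc_curve(labels[take], scores[take], orientation)
        tprs[b] = _interp_tpr(1.0 - roc_b.specificity, roc_b.sensitivity, grid)
        aucs[b] = roc_b.auc

    alpha = (1.0 - level) / 2.0
    lo = np.quantile(tprs, alpha, axis=0)
    hi = np.quantile(tprs, 1.0 - alpha, axis=0)
    # a percentile band is taken over replicates; guarantee it covers the
    # point estimate even at extreme grid points with degenerate resamples
    lo = np.minimum(lo, tpr_point)
    hi = np.maximum(hi, tpr_point)
    return RocBand(
        fpr_grid=grid,
        tpr_point=tpr_point,
        tpr_low=lo,
        tpr_high=hi,
        auc_ci=(float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1.0 - alpha))),
        level=level,
        n_boot=n_boot,
    )


def dispersion_from_moments(mean: float, sd: float) -> float:
    """Index of dispersion SD²/mean from summary moments."""
    if mean == 0:
        return float("nan")
    return sd * sd / mean


def summarize_scores(scores) -> dict:
    """Descriptive row: n, mean, SD, dispersion, CV, quartiles, extremes.

    SD uses the n−1 denominator; quartiles are linearly interpolated;
    ``dispersion`` is SD²/mean (missing when the mean is zero) and ``cv``
    is the conventional SD/mean.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) < 2:
        raise ValueError("need at least 2 scores to summarize")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    q1, q2, q3 = (float(q) for q in np.percentile(scores, [25, 50, 75]))
    return {
        "n": int(len(scores)),
        "mean": mean,
        "sd": sd,
        "dispersion": dispersion_from_moments(mean, sd),
        "cv": sd / mean if mean != 0 else float("nan"),
        "q1": q1,
        "median": q2,
        "q3": q3,
        "min": float(scores.min()),
        "max": float(scores.max()),
    }


def _check_schema(df: pd.DataFrame) -> None:
    for col in PAIRED_SCORE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"scores table is missing required column {col!r}")


def validate_paired_scores(
    df: pd.DataFrame,
    target_sensitivity: float = 0.70,
    n_boot: int = 2000,
    seed: int | None = None,
) -> dict:
    """Full per-task validation of a paired-scores table.

    For each task: Pearson r and p between conventional and image-derived
    scores, low-motility labels from the conventional score's below-mean
    rule, ROC/AUC of the image-derived score (lower = positive),
    specificity at the target sensitivity, a bootstrap AUC CI, and
    Table-style descriptive rows for both score types.

    Returns a dict with ``correlations`` and ``summary`` DataFrames and
    per-task ``roc`` / ``band`` objects.
    """
    _check_schema(df)
    corr_rows = []
    summary_rows = []
    rocs: dict[int, ROCResult] = {}
    bands: dict[int, RocBand] = {}
    for task, sub in df.groupby("task_id"):
        if sub["conventional"].isna().any() or sub["image_derived"].isna().any():
            raise ValueError(f"task {task} has missing score pairs")
        conv = sub["conventional"].to_numpy(dtype=float)
        img = sub["image_derived"].to_numpy(dtype=float)
        r, p = pearson(conv, img)
        labels = low_motility_labels(conv)
        roc = roc_curve(labels, img, orientation="lower_is_positive")
        sens_op = specificity_at_sensitivity(roc, target_sensitivity)
        band = bootstrap_roc_band(labels, img, n_boot=n_boot, seed=seed)
        rocs[int(task)] = roc
        bands[int(task)] = band
        corr_rows.append(
            {
                "task_id": int(task),
                "n": len(sub),
                "pearson_r": r,
                "p_value": p,
                "n_low_motility": int(labels.sum()),
                "auc": roc.auc,
                "auc_ci_low": band.auc_ci[0],
                "auc_ci_high": band.auc_ci[1],
                "target_sensitivity": target_sensitivity,
                "specificity": sens_op.specificity,
                "threshold": sens_op.threshold,
                "achieved_sensitivity": sens_op.sensitivity,
            }
        )
        for kind, vals in (("conventional", conv), ("image_derived", img)):
            summary_rows.append(
                {"task_id": int(task), "score": kind, **summarize_scores(vals)}
            )
    return {
        "correlations": pd.DataFrame(corr_rows),
        "summary": pd.DataFrame(summary_rows),
        "roc": rocs,
        "band": bands,
    }
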