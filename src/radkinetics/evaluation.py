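"""ROC scoring of prediction sets: AUC, confidence intervals, Youden cutoff.

Probabilities are of the Control class; ORN is the detection-positive class
and is predicted when ``prob_control`` falls *below* the threshold (a VOI
with probability exactly at the cutoff is called Control, following the
'cutoff above which a region is predicted Control' convention).  The AUC
therefore measures how reliably ORN VOIs receive lower Control probabilities
than Control VOIs, and equals the tie-corrected two-sample U-statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCReport",
    "roc_and_auc",
    "auc_ci",
    "delong_ci",
    "bootstrap_ci",
    "youden_optimal",
    "classify_at_threshold",
    "evaluate_predictions",
    "comparison_table",
]

POSITIVE = "ORN"
NEGATIVE = "Control"


@dataclass
class ROCReport:
    thresholds: np.ndarray   # candidate cutoffs on prob_control
    sensitivity: np.ndarray  # P(prob_control < tau | ORN)
    specificity: np.ndarray  # P(prob_control >= tau | Control)
    auc: float
    ci: tuple[float, float] | None = None
    ci_method: str = ""
    youden: np.ndarray = field(default_factory=lambda: np.array([]))

    def as_points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "youden_j": self.youden,
            }
        )


def _split_groups(prob_control, labels):
    prob_control = np.asarray(prob_control, dtype=float)
    labels = np.asarray(labels)
    pos = prob_control[labels == POSITIVE]
    neg = prob_control[labels == NEGATIVE]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_and_auc(prob_control, labels) -> ROCReport:
    """ROC over all distinct cutoffs and the trapezoidal AUC.

    Thresholds are the midpoints between sorted distinct probabilities plus
    sentinels below and above the observed range, so the curve includes the
    (0,0) and (1,1) operating points.
    """
    pos, neg = _split_groups(prob_control, labels)
    uniq = np.unique(np.concatenate([pos, neg]))
    mids = (uniq[:-1] + uniq[1:]) / 2
    thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    sens = np.array([np.mean(pos < t) for t in thresholds])
    spec = np.array([np.mean(neg >= t) for t in thresholds])
    fpr = 1 - spec
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return ROCReport(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden=sens + spec - 1,
    )


def delong_ci(prob_control, labels, alpha: float = 0.05) -> tuple[float, float]:
    """DeLong variance-based 95% (by default) interval for the AUC.

    Uses midrank placements of the ORN scores (``-prob_control``) among the
    Control scores; the interval is truncated to [0, 1].
    """
    pos, neg = _split_groups(prob_control, labels)
    x = -pos  # higher score = more ORN-like
    y = -neg
    m, n = len(x), len(y)
    allv = np.concatenate([x, y])
    tz = stats.rankdata(allv)
    tx = stats.rankdata(x)
    ty = stats.rankdata(y)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (tz[:m] - tx) / n          # placements of each positive among negatives
    v10 = 1.0 - (tz[m:] - ty) / m    # placements of each negative among positives
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    var = s01 / m + s10 / n
    if var <= 0:
        raise ValueError("degenerate DeLong variance")
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def bootstrap_ci(
    prob_control, labels, alpha: float = 0.05, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Stratified percentile-bootstrap interval for the AUC (seeded)."""
    pos, neg = _split_groups(prob_control, labels)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(len(pos), size=len(pos))]
        bn = neg[rng.integers(len(neg), size=len(neg))]
        # AUC as the tie-corrected U statistic: ORN lower => concordant
        greater = np.sum(bn[None, :] > bp[:, None])
        ties = np.sum(bn[None, :] == bp[:, None])
        aucs[b] = (greater + 0.5 * ties) / (len(bp) * len(bn))
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return (float(max(0.0, lo)), float(min(1.0, hi)))


def auc_ci(
    prob_control, labels, method: str = "delong", alpha: float = 0.05, seed: int = 0
) -> tuple[tuple[float, float], str]:
    """AUC confidence interval; DeLong by default, bootstrap as alternative
    and as fallback when the DeLong variance degenerates."""
    if method == "bootstrap":
        return bootstrap_ci(prob_control, labels, alpha=alpha, seed=seed), "bootstrap"
    if method != "delong":
        raise ValueError(f"unknown CI method {method!r}")
    try:
        return delong_ci(prob_control, labels, alpha=alpha), "delong"
    except ValueError:
        warnings.warn("DeLong variance degenerate; falling back to bootstrap")
        return bootstrap_ci(prob_control, labels, alpha=alpha, seed=seed), "bootstrap"


def youden_optimal(report: ROCReport) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity − 1.

    Ties are broken toward higher sensitivity, then toward the lower
    threshold, making the choice deterministic.
    """
    J = report.youden
    best = np.flatnonzero(J == J.max())
    sens = report.sensitivity[best]
    best = best[sens == sens.max()]
    idx = best[np.argmin(report.thresholds[best])]
    return (
        float(report.thresholds[idx]),
        float(report.sensitivity[idx]),
        float(report.specificity[idx]),
    )


def classify_at_threshold(prob_control, labels, tau: float) -> dict:
    """Hard classification at a cutoff with the per-class confusion summary.

    ``prob_control < tau`` ⇒ ORN, ``prob_control >= tau`` ⇒ Control.
    Returns predicted classes, the 2×2 counts and the percent of each class
    correctly classified.
    """
    prob_control = np.asarray(prob_control, dtype=float)
    labels = np.asarray(labels)
    pred = np.where(prob_control < tau, POSITIVE, NEGATIVE)
    counts = {
        (t, p): int(np.sum((labels == t) & (pred == p)))
        for t in (POSITIVE, NEGATIVE)
        for p in (POSITIVE, NEGATIVE)
    }
    n_pos = int(np.sum(labels == POSITIVE))
    n_neg = int(np.sum(labels == NEGATIVE))
    return {
        "threshold": float(tau),
        "predicted": pred,
        "confusion": {
            "orn_correct": counts[(POSITIVE, POSITIVE)],
            "orn_missed": counts[(POSITIVE, NEGATIVE)],
            "control_correct": counts[(NEGATIVE, NEGATIVE)],
            "control_missed": counts[(NEGATIVE, POSITIVE)],
        },
        "percent_orn_correct": (
            100.0 * counts[(POSITIVE, POSITIVE)] / n_pos if n_pos else float("nan")
        ),
        "percent_control_correct": (
            100.0 * counts[(NEGATIVE, NEGATIVE)] / n_neg if n_neg else float("nan")
        ),
    }


def evaluate_predictions(
    prob_control, labels, ci_method: str = "delong", seed: int = 0
) -> dict:
    """Full report for one prediction set: AUC + CI, Youden point, confusion
    matrix at the Youden-optimal cutoff."""
    report = roc_and_auc(prob_control, labels)
    ci, method = auc_ci(prob_control, labels, method=ci_method, seed=seed)
    report.ci, report.ci_method = ci, method
    tau, sens, spec = youden_optimal(report)
    cls = classify_at_threshold(prob_control, labels, tau)
    return {
        "auc": report.auc,
        "ci_low": ci[0],
        "ci_high": ci[1],
        "ci_method": method,
        "youden_threshold": tau,
        "sensitivity": sens,
        "specificity": spec,
        "confusion": cls["confusion"],
        "percent_orn_correct": cls["percent_orn_correct"],
        "percent_control_correct": cls["percent_control_correct"],
        "roc": report,
    }


def comparison_table(reports: dict[str, dict]) -> pd.DataFrame:
    """Across-representation summary in the study's comparison layout."""
    rows = []
    for rep, r in reports.items():
        rows.append(
            {
                "representation": rep,
                "auc": round(r["auc"], 3),
                "ci": f"({r['ci_low']:.2f}-{r['ci_high']:.2f})",
                "youden_threshold": round(r["youden_threshold"], 3),
                "sensitivity": round(r["sensitivity"], 3),
                "specificity": round(r["specificity"], 3),
            }
        )
    return pd.DataFrame(rows).sort_values("auc", ascending=False).reset_index(drop=True)
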