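"""Feature pre-selection: correlation filtering and Mann-Whitney screening.

Multicollinearity reduction uses the mean-absolute-Spearman filter applied
at the pre-treatment time point (month 0): features whose average absolute
correlation with the currently retained set exceeds the threshold (default
0.5) are removed greedily, worst first, with recomputation after each
removal.  Screening then tests each retained feature for an ORN-vs-Control
location difference with a two-sided Mann-Whitney U test and reports the
direction of the difference of group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationFilterConfig",
    "spearman_matrix",
    "mean_correlation_filter",
    "mann_whitney_screen",
    "screen_table",
]


@dataclass(frozen=True)
class CorrelationFilterConfig:
    threshold: float = 0.5
    timepoint_month: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


def feature_columns(table: pd.DataFrame) -> list[str]:
    meta = {"voi_id", "patient_id", "label", "timepoint_month"}
    return [c for c in table.columns if c not in meta]


def spearman_matrix(data: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Spearman rho matrix (average ranks for ties); rows are observations.

    Constant columns must be excluded beforehand — their rank correlation is
    undefined.
    """
    X = np.asarray(data, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant column passed to spearman_matrix")
    rho = stats.spearmanr(X).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # two-column input returns a scalar
        r = float(rho.item())
        rho = np.array([[1.0, r], [r, 1.0]])
    return rho


def mean_correlation_filter(
    corr: np.ndarray,
    config: CorrelationFilterConfig = CorrelationFilterConfig(),
    names: Sequence[str] | None = None,
) -> list:
    """Greedy mean-absolute-correlation filter.

    While any feature's mean |rho| with the other retained features exceeds
    the threshold, drop the feature with the largest such mean (ties broken
    by earliest column order) and recompute.  Returns the retained features
    (names if given, else column indices) in original order.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if corr.shape != (p, p) or not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    keep = list(range(p))
    while len(keep) > 1:
        sub = np.abs(corr[np.ix_(keep, keep)])
        np.fill_diagonal(sub, 0.0)
        means = sub.sum(axis=1) / (len(keep) - 1)
        worst = int(np.argmax(means))  # argmax takes the first max: earliest column wins ties
        if means[worst] <= config.threshold:
            break
        keep.pop(worst)
    if not keep:
        raise ValueError("all features removed; raise the threshold")
    if names is not None:
        return [names[i] for i in keep]
    return keep


def mann_whitney_screen(
    table: pd.DataFrame,
    alpha: float = 0.05,
    features: Sequence[str] | None = None,
    bh: bool = False,
    label_col: str = "label",
    positive: str = "ORN",
) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney screen of ORN vs Control rows.

    Uses the exact null distribution when both groups have <= 10
    observations and the pooled sample is tie-free, otherwise the normal
    approximation with tie and continuity corrections.  ``direction`` is the
    sign of mean(ORN) − mean(Control) ('Positive'/'Negative'; empty when the
    means coincide).  Raw p-values are reported; ``bh=True`` appends a
    Benjamini–Hochberg column.
    """
    if features is None:
        features = feature_columns(table)
    is_pos = table[label_col] == positive
    if is_pos.sum() == 0 or (~is_pos).sum() == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for f in features:
        x = table.loc[is_pos, f].to_numpy(dtype=float)
        y = table.loc[~is_pos, f].to_numpy(dtype=float)
        pooled = np.concatenate([x, y])
        exact = (
            len(x) <= 10
            and len(y) <= 10
            and np.unique(pooled).size == pooled.size
        )
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        diff = x.mean() - y.mean()
        rows.append(
            {
                "feature": f,
                "U": float(res.statistic),
                "p": float(res.pvalue),
                "direction": "Positive" if diff > 0 else ("Negative" if diff < 0 else ""),
                "significant": bool(res.pvalue < alpha),
                "method": "exact" if exact else "asymptotic",
            }
        )
    out = pd.DataFrame(rows)
    if bh:
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
        out["significant_bh"] = out["p_bh"] < alpha
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def screen_table(
    table: pd.DataFrame,
    filter_config: CorrelationFilterConfig = CorrelationFilterConfig(),
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Full pre-selection on a trajectory table.

    Drops features that are undefined (NaN) or constant anywhere, applies
    the mean-correlation filter on month-``filter_config.timepoint_month``
    values, then Mann-Whitney-screens the retained features at that month.
    Returns ``(retained feature names, screening DataFrame)``.
    """
    feats = feature_columns(table)
    usable = [
        f
        for f in feats
        if table[f].notna().all() and table.groupby("timepoint_month")[f].std().min() > 0
    ]
    month0 = table[table["timepoint_month"] == filter_config.timepoint_month]
    if month0.empty:
        raise ValueError(f"no rows at month {filter_config.timepoint_month}")
    corr = spearman_matrix(month0[usable])
    retained = mean_correlation_filter(corr, filter_config, names=usable)
    screening = mann_whitney_screen(month0, alpha=alpha, features=retained)
    return retained, screening
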