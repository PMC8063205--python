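"""Competing ORN classifiers over repeated random-subsampling random forests.

Five representations of the longitudinal feature data are compared:

* ``baseline``   — month-0 feature values;
* ``delta2``     — relative change month 0 → 2;
* ``delta6``     — relative change month 0 → 6;
* ``trajectory`` — MFPCA trajectory scores;
* ``ensemble``   — per-VOI average of the baseline and trajectory
  out-of-sample probabilities.

Each representation is scored by Monte-Carlo cross-validation: repeated
random patient-grouped train/test splits, a random forest per split, and the
per-VOI mean held-out probability of the Control class.  All representations
share one split schedule so the comparison is paired.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import kinetics, screening

__all__ = [
    "ModelSpec",
    "PredictionSet",
    "REPRESENTATIONS",
    "build_representation",
    "make_split_schedule",
    "mc_cv_random_forest",
    "ensemble_average",
    "run_model_suite",
]

REPRESENTATIONS = ("baseline", "delta2", "delta6", "trajectory", "ensemble")


@dataclass(frozen=True)
class ModelSpec:
    """Random-forest Monte-Carlo cross-validation settings.

    ``split_candidates=None`` means the conventional floor(sqrt(p)) rule;
    an integer forces that many candidate features per split (the literal
    reading of 'p features' is ``split_candidates=p``).  ``grouped=True``
    keeps all VOIs of one patient on the same side of every split.
    """

    representation: str = "trajectory"
    n_trees: int = 500
    split_candidates: int | None = None
    n_repeats: int = 200
    test_fraction: float = 1 / 3
    grouped: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"unknown representation {self.representation!r}")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_trees < 1 or self.n_repeats < 1:
            raise ValueError("n_trees and n_repeats must be positive")


@dataclass
class PredictionSet:
    """Per-VOI mean out-of-sample probability of the Control class."""

    table: pd.DataFrame  # voi_id, patient_id, label, prob_control, n_heldout
    representation: str = ""
    split_log: pd.DataFrame | None = None

    @property
    def prob_control(self) -> np.ndarray:
        return self.table["prob_control"].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()


def _month_matrix(table: pd.DataFrame, month: float, features: Sequence[str]) -> pd.DataFrame:
    sub = table[table["timepoint_month"] == month]
    if sub.empty:
        raise ValueError(f"no rows at month {month}")
    return sub.set_index("voi_id").sort_index()


def build_representation(
    table: pd.DataFrame,
    representation: str,
    features: Sequence[str] | None = None,
    scores: pd.DataFrame | None = None,
    months: Sequence[float] = (0, 2, 6),
) -> pd.DataFrame:
    """VOI × feature design matrix for one representation.

    ``baseline``: month-0 values.  ``delta2``/``delta6``: relative change
    (x_t − x_0) / max(|x_0|, eps) with eps = 1e-8 × the feature's month-0
    scale, guarding near-zero baselines.  ``trajectory``: the MFPCA score
    table (``scores`` argument).  ``ensemble`` has no design matrix — it
    averages probabilities downstream.
    """
    if representation == "ensemble":
        raise ValueError("ensemble is formed from prediction sets, not a design matrix")
    if representation == "trajectory":
        if scores is None:
            raise ValueError("trajectory representation needs the MFPCA score table")
        out = scores.set_index("voi_id").sort_index()
        return out[[c for c in out.columns if c.startswith("rho_")]]
    if features is None:
        features = screening.feature_columns(table)
    base = _month_matrix(table, months[0], features)
    meta_drop = [c for c in ("patient_id", "label", "timepoint_month") if c in base.columns]
    x0 = base.drop(columns=meta_drop)[list(features)]
    if representation == "baseline":
        return x0
    month = {"delta2": months[1], "delta6": months[2]}[representation]
    xt = _month_matrix(table, month, features)[list(features)]
    xt = xt.loc[x0.index]
    scale = x0.abs().to_numpy()
    floor = 1e-8 * np.maximum(np.abs(x0).to_numpy().mean(axis=0, keepdims=True), 1e-300)
    denom = np.maximum(scale, floor)
    return pd.DataFrame((xt.to_numpy() - x0.to_numpy()) / denom, index=x0.index, columns=features)


def _voi_meta(table: pd.DataFrame) -> pd.DataFrame:
    meta = (
        table[["voi_id", "patient_id", "label"]]
        .drop_duplicates("voi_id")
        .set_index("voi_id")
        .sort_index()
    )
    return meta


def make_split_schedule(
    patient_ids: np.ndarray,
    labels: np.ndarray,
    spec: ModelSpec,
    max_retries: int = 50,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated random train/test partitions of the VOI index.

    With ``grouped=True``, test membership is drawn at the patient level so
    paired ORN/Control VOIs never straddle a partition; any draw leaving a
    single-class training set is redrawn (bounded retries).
    """
    rng = np.random.default_rng(spec.seed)
    n = len(patient_ids)
    splits = []
    for _ in range(spec.n_repeats):
        for attempt in range(max_retries):
            if spec.grouped:
                uniq = np.unique(patient_ids)
                n_test = max(1, int(round(len(uniq) * spec.test_fraction)))
                test_pat = set(rng.choice(uniq, size=n_test, replace=False))
                test = np.array([p in test_pat for p in patient_ids])
            else:
                n_test = max(1, int(round(n * spec.test_fraction)))
                idx = rng.choice(n, size=n_test, replace=False)
                test = np.zeros(n, dtype=bool)
                test[idx] = True
            train = ~test
            if len(np.unique(labels[train])) == 2 and test.any():
                splits.append((np.where(train)[0], np.where(test)[0]))
                break
        else:
            raise RuntimeError("could not draw a two-class training set")
    # guarantee every VOI is held out at least once: append corrective splits
    # that force still-uncovered patients into the test set
    covered = np.zeros(n, dtype=bool)
    for _, test_idx in splits:
        covered[test_idx] = True
    while not covered.all():
        uncovered_pat = np.unique(patient_ids[~covered])
        uniq = np.unique(patient_ids)
        n_test = max(len(uncovered_pat), max(1, int(round(len(uniq) * spec.test_fraction))))
        n_test = min(n_test, len(uniq) - 1)
        pool = np.setdiff1d(uniq, uncovered_pat)
        extra = rng.choice(pool, size=max(0, n_test - len(uncovered_pat)), replace=False)
        test_pat = set(uncovered_pat) | set(extra)
        test = np.array([p in test_pat for p in patient_ids])
        train = ~test
        if len(np.unique(labels[train])) < 2:
            raise RuntimeError("could not draw a two-class training set")
        splits.append((np.where(train)[0], np.where(test)[0]))
        covered[test] = True
    return splits


def mc_cv_random_forest(
    X: pd.DataFrame,
    meta: pd.DataFrame,
    spec: ModelSpec,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> PredictionSet:
    """Monte-Carlo cross-validated random-forest Control probabilities.

    ``X`` is a VOI-indexed design matrix; ``meta`` provides ``patient_id``
    and ``label`` for the same index.  Per repeat a forest (``n_trees``
    trees, bootstrap rows, sqrt-p split candidates by default) is fitted on
    the training VOIs and the held-out VOIs receive Control-class
    probabilities; the final probability is the mean over the repeats in
    which a VOI was held out.  Deterministic given ``spec.seed``.
    """
    meta = meta.loc[X.index]
    labels = meta["label"].to_numpy()
    patients = meta["patient_id"].to_numpy()
    if splits is None:
        splits = make_split_schedule(patients, labels, spec)
    Xa = X.to_numpy(dtype=float)
    p = Xa.shape[1]
    max_features = spec.split_candidates or max(1, int(np.sqrt(p)))
    max_features = min(max_features, p)

    prob_sum = np.zeros(len(X))
    heldout = np.zeros(len(X), dtype=int)
    rng = np.random.default_rng(spec.seed + 1)
    log_rows = []
    for rep, (train, test) in enumerate(splits):
        rf = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features=max_features,
            bootstrap=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(Xa[train], labels[train])
        col = list(rf.classes_).index("Control")
        probs = rf.predict_proba(Xa[test])[:, col]
        prob_sum[test] += probs
        heldout[test] += 1
        log_rows.extend(
            {"repeat": rep, "voi_id": X.index[i], "partition": "test"} for i in test
        )
    if np.any(heldout == 0):
        missing = list(X.index[heldout == 0])
        raise RuntimeError(
            f"VOIs never held out (increase n_repeats): {missing[:5]}"
        )
    out = meta.copy()
    out["prob_control"] = prob_sum / heldout
    out["n_heldout"] = heldout
    return PredictionSet(
        table=out.reset_index().rename(columns={"index": "voi_id"}),
        representation=spec.representation,
        split_log=pd.DataFrame(log_rows),
    )


def ensemble_average(a: PredictionSet, b: PredictionSet) -> PredictionSet:
    """Unweighted per-VOI mean of two prediction sets' Control probabilities."""
    ta = a.table.set_index("voi_id").sort_index()
    tb = b.table.set_index("voi_id").sort_index()
    if not ta.index.equals(tb.index):
        raise ValueError("prediction sets cover different VOI sets")
    out = ta.copy()
    out["prob_control"] = (ta["prob_control"] + tb["prob_control"]) / 2
    out["n_heldout"] = np.minimum(ta["n_heldout"], tb["n_heldout"])
    return PredictionSet(table=out.reset_index(), representation="ensemble")


@dataclass(frozen=True)
class SuiteConfig:
    """End-to-end settings for the five-model comparison."""

    model: ModelSpec = ModelSpec()
    correlation_threshold: float = 0.5
    uni_pve: float = 0.99
    multi_pve: float = 0.9
    months: tuple[float, ...] = (0, 2, 6)


def run_model_suite(
    table: pd.DataFrame, config: SuiteConfig = SuiteConfig()
) -> dict[str, PredictionSet]:
    """Screen, encode and score all five representations with paired splits.

    Returns a dict representation → PredictionSet.  The same split schedule
    is used for every representation so AUC differences are paired, and the
    ensemble averages the baseline and trajectory probabilities.
    """
    retained, _ = screening.screen_table(
        table,
        screening.CorrelationFilterConfig(
            threshold=config.correlation_threshold, timepoint_month=config.months[0]
        ),
    )
    scores, _, _ = kinetics.fit_trajectory_scores(
        table,
        retained,
        months=config.months,
        uni_pve=config.uni_pve,
        multi_pve=config.multi_pve,
    )
    meta = _voi_meta(table)
    splits = make_split_schedule(
        meta["patient_id"].to_numpy(), meta["label"].to_numpy(), config.model
    )
    preds: dict[str, PredictionSet] = {}
    for rep in ("baseline", "delta2", "delta6", "trajectory"):
        X = build_representation(
            table, rep, features=retained, scores=scores, months=config.months
        )
        X = X.loc[meta.index]
        preds[rep] = mc_cv_random_forest(
            X, meta, replace(config.model, representation=rep), splits=splits
        )
    preds["ensemble"] = ensemble_average(preds["baseline"], preds["trajectory"])
    return preds
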