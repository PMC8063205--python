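"""Trajectory encoding by functional principal component analysis.

Three observed feature values per VOI (months 0, 2, 6) are completed to a
dense monthly curve by a natural cubic spline, each feature's curve set is
decomposed by univariate FPCA under trapezoid quadrature, and the per-VOI
univariate scores of all features are stacked and eigendecomposed to obtain
multivariate FPCA (MFPCA) trajectory scores — a compact representation of
each VOI's temporal kinetics that sees the *shape* of the path, not only its
endpoints.

The stacked-score construction: with univariate expansions
x_ij(t) ≈ μ_j(t) + Σ_a ξ_ija φ_ja(t), collect Ξ_i = (ξ_ij a)_{j,a} and
eigendecompose (1/(n−1)) ΞᵀΞ into (ν_m, c_m).  The multivariate scores are
ρ_im = Ξ_i · c_m and the m-th multivariate eigenfunction has per-feature
components ψ_m^(j)(t) = Σ_a [c_m]_{(j,a)} φ_ja(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .screening import feature_columns
from .synthetic import trapezoid_weights

__all__ = [
    "DenseCurveSet",
    "UFPCAResult",
    "MFPCAResult",
    "spline_complete",
    "ufpca",
    "mfpca",
    "reconstruct",
    "fit_trajectory_scores",
]

DEFAULT_GRID = np.arange(0.0, 7.0)  # integer months 0..6


@dataclass
class DenseCurveSet:
    """Curves on a common monthly grid: ``values`` is (n_vois, n_features, T)."""

    grid: np.ndarray
    values: np.ndarray
    voi_ids: list[str]
    feature_names: list[str]
    labels: list[str] = field(default_factory=list)
    patient_ids: list[str] = field(default_factory=list)

    @property
    def weights(self) -> np.ndarray:
        return trapezoid_weights(self.grid)


@dataclass
class UFPCAResult:
    grid: np.ndarray
    weights: np.ndarray
    mean: np.ndarray            # (T,)
    eigenfunctions: np.ndarray  # (M, T), orthonormal under quadrature
    eigenvalues: np.ndarray     # (M,), non-increasing
    scores: np.ndarray          # (n, M)
    pve: np.ndarray             # (M,) proportion of variance per component


@dataclass
class MFPCAResult:
    univariate: list[UFPCAResult]
    feature_names: list[str]
    eigenvectors: np.ndarray       # (M, sum_j M_j) stacked-score directions c_m
    eigenvalues: np.ndarray        # (M,) multivariate nu_m
    scores: np.ndarray             # (n, M) multivariate rho_im
    eigenfunctions: np.ndarray     # (M, n_features, T) per-feature components psi_m^(j)
    pve: np.ndarray
    score_blocks: list[slice]      # columns of the stacked matrix per feature
    feature_scales: np.ndarray | None = None


def spline_complete(
    table: pd.DataFrame,
    grid: np.ndarray = DEFAULT_GRID,
    months: Sequence[float] = (0, 2, 6),
    features: Sequence[str] | None = None,
) -> DenseCurveSet:
    """Natural-cubic-spline completion of each VOI × feature trajectory.

    The spline passes exactly through the observed (month, value) points and
    is evaluated on ``grid`` (default integer months 0..6); the grid must
    stay inside the observed range, so this is interpolation only.
    """
    grid = np.asarray(grid, dtype=float)
    months = np.asarray(months, dtype=float)
    if grid.min() < months.min() or grid.max() > months.max():
        raise ValueError("grid extends beyond the observed months (no extrapolation)")
    if features is None:
        features = feature_columns(table)

    voi_ids, labels, patients = [], [], []
    curves = []
    for voi_id, sub in table.groupby("voi_id", sort=True):
        sub = sub.sort_values("timepoint_month")
        got = sub["timepoint_month"].to_numpy(dtype=float)
        if not np.array_equal(got, months):
            raise ValueError(f"VOI {voi_id}: observed months {got} != required {months}")
        voi_ids.append(voi_id)
        labels.append(sub["label"].iloc[0])
        patients.append(sub["patient_id"].iloc[0])
        y = sub[list(features)].to_numpy(dtype=float)  # (n_months, p)
        cs = CubicSpline(months, y, bc_type="natural", axis=0)
        curves.append(cs(grid).T)  # (p, T)
    return DenseCurveSet(
        grid=grid,
        values=np.stack(curves),
        voi_ids=voi_ids,
        feature_names=list(features),
        labels=labels,
        patient_ids=patients,
    )


def _fix_signs(phi: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: positive quadrature integral, falling
    back to a positive first grid value when the integral is near zero."""
    out = phi.copy()
    for m in range(out.shape[0]):
        integral = float(np.sum(out[m] * weights))
        ref = integral if abs(integral) > 1e-10 else out[m, 0]
        if ref < 0:
            out[m] = -out[m]
    return out


def ufpca(
    curves: np.ndarray,
    grid: np.ndarray = DEFAULT_GRID,
    pve_threshold: float = 0.99,
    max_components: int | None = None,
    weights: np.ndarray | None = None,
) -> UFPCAResult:
    """Univariate FPCA of a curve set under trapezoid quadrature.

    Centers by the pointwise mean, forms the empirical covariance C, and
    solves the quadrature-weighted eigenproblem via the symmetrization
    W^{1/2} C W^{1/2}; eigenvectors are back-transformed by W^{-1/2} so the
    eigenfunctions are orthonormal under the quadrature inner product.
    Scores are quadrature integrals of centered curves against the
    eigenfunctions.  Retains the smallest M with cumulative PVE >=
    ``pve_threshold``.
    """
    Y = np.asarray(curves, dtype=float)
    n, T = Y.shape
    if n < 3:
        raise ValueError("need at least 3 curves")
    grid = np.asarray(grid, dtype=float)
    w = trapezoid_weights(grid) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != grid.shape or np.any(w <= 0):
        raise ValueError("weights must be positive and match the grid")
    mean = Y.mean(axis=0)
    Yc = Y - mean
    C = (Yc.T @ Yc) / (n - 1)
    sw = np.sqrt(w)
    B = sw[:, None] * C * sw[None, :]
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.clip(min=0).sum()
    if total <= 0:
        raise ValueError("zero total variance")
    if np.any(evals < -1e-10 * total):
        raise ValueError("covariance eigenproblem produced a large negative eigenvalue")
    evals = evals.clip(min=0.0)
    cum = np.cumsum(evals) / total
    M = int(np.searchsorted(cum, pve_threshold) + 1)
    M = min(M, T, n - 1 if n > 1 else 1)
    if max_components is not None:
        M = min(M, max_components)
    phi = (evecs[:, :M] / sw[:, None]).T  # (M, T)
    phi = _fix_signs(phi, w)
    scores = Yc @ (w[None, :] * phi).T  # quadrature integration
    return UFPCAResult(
        grid=grid,
        weights=w,
        mean=mean,
        eigenfunctions=phi,
        eigenvalues=evals[:M],
        scores=scores,
        pve=evals[:M] / total,
    )


def mfpca(
    uni_results: Sequence[UFPCAResult],
    pve_threshold: float = 0.9,
    M: int | None = None,
    feature_names: Sequence[str] | None = None,
) -> MFPCAResult:
    """Multivariate FPCA from per-feature univariate decompositions.

    Stacks the univariate scores into Ξ (n × Σ_j M_j), eigendecomposes
    (1/(n−1)) ΞᵀΞ, and retains components by cumulative PVE >= 0.9 (or a
    fixed ``M``).  The eigenvector blocks double as loadings of each feature
    on each multivariate component.
    """
    if not uni_results:
        raise ValueError("no univariate results supplied")
    n = uni_results[0].scores.shape[0]
    blocks, cols = [], 0
    for r in uni_results:
        if r.scores.shape[0] != n:
            raise ValueError("all features must share the VOI set")
        blocks.append(slice(cols, cols + r.scores.shape[1]))
        cols += r.scores.shape[1]
    if cols == 0:
        raise ValueError("no univariate components to stack")
    Xi = np.hstack([r.scores for r in uni_results])
    Z = (Xi.T @ Xi) / (n - 1)
    evals, evecs = np.linalg.eigh(Z)
    order = np.argsort(evals)[::-1]
    evals = evals[order].clip(min=0.0)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise ValueError("stacked scores carry no variance")
    cum = np.cumsum(evals) / total
    if M is None:
        M = int(np.searchsorted(cum, pve_threshold) + 1)
    M = min(M, cols)

    c = evecs[:, :M].T  # (M, cols)
    # sign convention on the stacked eigenvectors: first nonzero-ish entry positive
    for m in range(M):
        s = c[m][np.argmax(np.abs(c[m]))]
        if s < 0:
            c[m] = -c[m]
    rho = Xi @ c.T
    T = uni_results[0].grid.shape[0]
    p = len(uni_results)
    psi = np.zeros((M, p, T))
    for m in range(M):
        for j, r in enumerate(uni_results):
            psi[m, j] = c[m, blocks[j]] @ r.eigenfunctions
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p)]
    return MFPCAResult(
        univariate=list(uni_results),
        feature_names=names,
        eigenvectors=c,
        eigenvalues=evals[:M],
        scores=rho,
        eigenfunctions=psi,
        pve=evals[:M] / total,
        score_blocks=blocks,
    )


def reconstruct(result: MFPCAResult, M: int | None = None) -> np.ndarray:
    """Curves rebuilt from the first M multivariate components.

    Returns an (n, p, T) array: per feature, mean curve plus
    Σ_{m<=M} ρ_im ψ_m^(j).  M = 0 gives the mean curves.
    """
    if M is None:
        M = result.scores.shape[1]
    if M > result.scores.shape[1]:
        raise ValueError("M exceeds the number of retained components")
    n = result.scores.shape[0]
    p = len(result.univariate)
    T = result.univariate[0].grid.shape[0]
    out = np.empty((n, p, T))
    for j, r in enumerate(result.univariate):
        out[:, j, :] = r.mean
    if M:
        out += np.einsum("im,mjt->ijt", result.scores[:, :M], result.eigenfunctions[:M])
    return out


def fit_trajectory_scores(
    table: pd.DataFrame,
    features: Sequence[str],
    grid: np.ndarray = DEFAULT_GRID,
    months: Sequence[float] = (0, 2, 6),
    uni_pve: float = 0.99,
    multi_pve: float = 0.9,
    standardize: bool = True,
) -> tuple[pd.DataFrame, MFPCAResult, DenseCurveSet]:
    """Trajectory table → MFPCA score table (the 'temporal trajectory' design).

    Features are standardized to unit variance of the stacked observations
    before completion (scales differ by orders of magnitude and would
    otherwise dominate the covariance); the applied scales are stored on the
    result so curves can be mapped back.
    """
    table = table.copy()
    scales = np.ones(len(features))
    if standardize:
        for j, f in enumerate(features):
            sd = table[f].std(ddof=1)
            if sd > 0:
                scales[j] = sd
                table[f] = table[f] / sd
    dense = spline_complete(table, grid=grid, months=months, features=features)
    uni = [
        ufpca(dense.values[:, j, :], grid=grid, pve_threshold=uni_pve)
        for j in range(len(features))
    ]
    result = mfpca(uni, pve_threshold=multi_pve, feature_names=list(features))
    result.feature_scales = scales
    score_df = pd.DataFrame(
        result.scores, columns=[f"rho_{m + 1}" for m in range(result.scores.shape[1])]
    )
    score_df.insert(0, "voi_id", dense.voi_ids)
    score_df.insert(1, "patient_id", dense.patient_ids)
    score_df.insert(2, "label", dense.labels)
    return score_df, result, dense
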