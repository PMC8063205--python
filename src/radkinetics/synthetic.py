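"""Synthetic cohorts with known ground truth.

The clinical cohort this analysis was designed around (CT follow-up of the
irradiated mandible, with one osteoradionecrosis (ORN) lesion subvolume and a
same-dose Control subvolume per patient, imaged at months 0, 2 and 6) is not
publicly available.  This module generates stand-ins at two levels:

* feature-trajectory cohorts — long-format tables of multivariate radiomic
  feature values per VOI per month, with configurable inter-feature
  correlation blocks and a discriminative signal placed either at baseline,
  in the net change, or purely in the trajectory *shape* (a month-2 detour
  that baseline and delta representations cannot see);
* textured phantom volumes — small 3D grids with two spherical VOIs carrying
  analytically known sinusoidal textures, used to exercise the feature
  extractor end to end.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "PhantomSpec",
    "generate_trajectory_cohort",
    "generate_curves_from_basis",
    "generate_textured_phantom",
    "write_cohort",
]

SIGNAL_MODES = ("none", "baseline", "delta", "shape")


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic two-arm longitudinal cohort.

    Defaults mirror the study design: 21 patients contributing 22 ORN and
    21 Control VOIs (one patient has two ORN lesions), 16 features observed
    at months 0, 2 and 6.  ``effect_size`` is the standardized mean group
    separation injected according to ``signal_mode``; ``noise_sd`` is the
    per-timepoint observation noise on the standardized feature scale.
    ``within_patient_rho`` is the share of latent variance common to all
    VOIs of one patient (the study never reports it, so it is a parameter).
    """

    n_patients: int = 21
    n_orn_vois: int = 22
    n_control_vois: int = 21
    n_features: int = 16
    correlation_blocks: tuple[tuple[int, float], ...] = ((4, 0.8), (4, 0.6))
    signal_mode: str = "none"
    effect_size: float = 1.5
    noise_sd: float = 0.2
    obs_months: tuple[int, ...] = (0, 2, 6)
    within_patient_rho: float = 0.3
    trend_per_month: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_mode not in SIGNAL_MODES:
            raise ValueError(
                f"unknown signal_mode {self.signal_mode!r}; expected one of {SIGNAL_MODES}"
            )
        if self.n_orn_vois < self.n_patients:
            raise ValueError("every patient must contribute at least one ORN VOI")
        if self.n_control_vois > self.n_patients:
            raise ValueError("Control VOIs are paired one-per-patient")
        months = tuple(self.obs_months)
        if months[0] != 0 or any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("obs_months must be strictly increasing and start at 0")
        if not 0 <= self.within_patient_rho < 1:
            raise ValueError("within_patient_rho must be in [0, 1)")
        used = sum(size for size, _ in self.correlation_blocks)
        if used > self.n_features:
            raise ValueError("correlation blocks exceed n_features")
        for size, rho in self.correlation_blocks:
            if not 0 <= rho < 1:
                raise ValueError("within-block correlation must be in [0, 1)")
            if size < 1:
                raise ValueError("block size must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Two-VOI textured phantom: a scalar volume plus two spherical masks.

    Each texture is ``(base_level, contrast_amplitude, period_voxels)`` of a
    separable sinusoidal field; white observation noise is added on top.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 16)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    texture_a: tuple[float, float, float] = (100.0, 40.0, 4.0)
    texture_b: tuple[float, float, float] = (100.0, 40.0, 9.0)
    mask_radius_mm: float = 9.0
    noise_sd: float = 2.0
    seed: int = 0


def _correlation_matrix(spec: CohortSpec) -> np.ndarray:
    """Block-diagonal exchangeable correlation; leftover features independent."""
    sigma = np.eye(spec.n_features)
    start = 0
    for size, rho in spec.correlation_blocks:
        block = np.full((size, size), rho)
        np.fill_diagonal(block, 1.0)
        sigma[start : start + size, start : start + size] = block
        start += size
    # exchangeable blocks with rho in [0,1) are positive definite; guard anyway
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - unreachable by construction
        raise ValueError("implied correlation matrix is not positive definite") from exc
    return sigma


def _signal_offset(spec: CohortSpec, month: float, is_orn: bool) -> float:
    """Group-mean offset injected at ``month`` for one arm.

    baseline: constant shift of the ORN arm at every month (so the net change
    carries no information); delta: shift accruing linearly to ``effect_size``
    at the final month (identical baselines); shape: a detour of the ORN arm
    at the middle month only — baselines and net changes match in
    distribution, only the path differs.
    """
    if not is_orn or spec.signal_mode == "none":
        return 0.0
    last = spec.obs_months[-1]
    if spec.signal_mode == "baseline":
        return spec.effect_size
    if spec.signal_mode == "delta":
        return spec.effect_size * month / last
    # shape: bump at the middle observed month
    mid = spec.obs_months[len(spec.obs_months) // 2]
    return spec.effect_size if month == mid else 0.0


def generate_trajectory_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a long-format feature-trajectory table plus its ground truth.

    Per VOI, feature values at month t are

        x_t = z + trend·t + signal(mode, arm, t) + eps_t

    with z the VOI's latent feature vector (patient random effect share
    ``within_patient_rho``) and eps_t the per-month observation noise.  Both
    z and eps_t are multivariate Gaussian with the block correlation
    structure, so the inter-feature correlation of the emitted values equals
    the specified rho exactly at every month.

    Returns ``(table, truth)`` where ``table`` has one row per (VOI, month)
    — columns ``voi_id, patient_id, label, timepoint_month, f001..`` — and
    ``truth`` records labels and the injected signal.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = _correlation_matrix(spec)
    chol = np.linalg.cholesky(sigma)
    p = spec.n_features

    patients = [f"P{i + 1:03d}" for i in range(spec.n_patients)]
    # one ORN lesion per patient; extras assigned to randomly chosen patients
    orn_patients = list(range(spec.n_patients))
    extra = spec.n_orn_vois - spec.n_patients
    if extra:
        orn_patients += list(rng.choice(spec.n_patients, size=extra, replace=False))
    control_patients = list(range(spec.n_control_vois))

    vois: list[tuple[str, int, str]] = []  # (voi_id, patient index, label)
    for k, pi in enumerate(orn_patients):
        vois.append((f"ORN{k + 1:03d}", pi, "ORN"))
    for k, pi in enumerate(control_patients):
        vois.append((f"CTL{k + 1:03d}", pi, "Control"))

    w = spec.within_patient_rho
    patient_latent = rng.standard_normal((spec.n_patients, p)) @ chol.T
    voi_latent = rng.standard_normal((len(vois), p)) @ chol.T
    latent = np.sqrt(w) * patient_latent[[pi for _, pi, _ in vois]] + np.sqrt(1 - w) * voi_latent

    rows = []
    for v, (voi_id, pi, label) in enumerate(vois):
        for month in spec.obs_months:
            eps = spec.noise_sd * (rng.standard_normal(p) @ chol.T)
            x = (
                latent[v]
                + spec.trend_per_month * month
                + _signal_offset(spec, month, label == "ORN")
                + eps
            )
            rows.append(
                {
                    "voi_id": voi_id,
                    "patient_id": patients[pi],
                    "label": label,
                    "timepoint_month": month,
                    **{f"f{j + 1:03d}": x[j] for j in range(p)},
                }
            )
    table = pd.DataFrame(rows)

    truth = {
        "spec": asdict(spec),
        "labels": {voi_id: label for voi_id, _, label in vois},
        "patients": {voi_id: patients[pi] for voi_id, pi, _ in vois},
        "signal_mode": spec.signal_mode,
        "effect_size": spec.effect_size,
        "group_mean_offset": {
            str(m): {
                "ORN": _signal_offset(spec, m, True),
                "Control": _signal_offset(spec, m, False),
            }
            for m in spec.obs_months
        },
    }
    return table, truth


def generate_curves_from_basis(
    grid: np.ndarray,
    eigenfunctions: np.ndarray,
    eigenvalues: Sequence[float],
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    mean: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw dense curves from a known Karhunen–Loève expansion.

    ``eigenfunctions`` is (M, T) and must be orthonormal under the trapezoid
    quadrature implied by ``grid`` (checked to 1e-6).  Curve i is
    ``mean + sum_m score_im * psi_m + iid noise`` with
    ``score_im ~ N(0, eigenvalue_m)``.  Returns ``(curves (n,T), scores (n,M))``.
    """
    grid = np.asarray(grid, dtype=float)
    phi = np.atleast_2d(np.asarray(eigenfunctions, dtype=float))
    lam = np.asarray(eigenvalues, dtype=float)
    if phi.shape[0] != lam.shape[0]:
        raise ValueError("one eigenvalue per eigenfunction required")
    weights = trapezoid_weights(grid)
    gram = (phi * weights) @ phi.T
    if not np.allclose(gram, np.eye(phi.shape[0]), atol=1e-6):
        raise ValueError("eigenfunctions are not orthonormal under the grid quadrature")
    rng = np.random.default_rng(seed)
    scores = rng.standard_normal((n, lam.shape[0])) * np.sqrt(lam)
    curves = scores @ phi
    if mean is not None:
        curves = curves + np.asarray(mean, dtype=float)
    if noise_sd > 0:
        curves = curves + noise_sd * rng.standard_normal(curves.shape)
    return curves, scores


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoid-rule quadrature weights for a strictly increasing grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def _sinusoidal_field(shape, base, amplitude, period, rng, noise_sd):
    idx = np.indices(shape, dtype=float)
    field = base + amplitude * np.prod(np.sin(2 * np.pi * idx / period), axis=0)
    return field + noise_sd * rng.standard_normal(shape)


def generate_textured_phantom(spec: PhantomSpec):
    """Build a two-VOI textured phantom volume.

    Returns ``(volume, mask_a, mask_b)``: a float array of ``grid_shape``
    and two disjoint boolean sphere masks on the same grid, region A and B
    carrying their own sinusoidal texture over a shared base level.
    """
    from .textures import VoxelVolume  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.voxel_spacing_mm, dtype=float)

    # voxel-centre physical coordinates
    coords = np.stack(
        [(np.indices(shape)[a] + 0.5) * spacing[a] for a in range(3)], axis=0
    )
    extent = np.array(shape) * spacing
    centre_a = extent * np.array([0.25, 0.5, 0.5])
    centre_b = extent * np.array([0.75, 0.5, 0.5])
    r = spec.mask_radius_mm
    mask_a = np.sum((coords - centre_a[:, None, None, None]) ** 2, axis=0) <= r**2
    mask_b = np.sum((coords - centre_b[:, None, None, None]) ** 2, axis=0) <= r**2

    for centre in (centre_a, centre_b):
        if np.any(centre - r < 0) or np.any(centre + r > extent):
            raise ValueError("VOI sphere extends outside the grid")
    if np.any(mask_a & mask_b):
        raise ValueError("VOI masks collide; increase grid size or shrink radius")

    base = spec.texture_a[0]
    volume = base + spec.noise_sd * rng.standard_normal(shape)
    field_a = _sinusoidal_field(shape, *spec.texture_a, rng=rng, noise_sd=spec.noise_sd)
    field_b = _sinusoidal_field(shape, *spec.texture_b, rng=rng, noise_sd=spec.noise_sd)
    volume[mask_a] = field_a[mask_a]
    volume[mask_b] = field_b[mask_b]

    vol = VoxelVolume(values=volume, spacing_mm=tuple(spacing))
    return vol, mask_a, mask_b


def write_cohort(table: pd.DataFrame, truth: dict, csv_path: str | Path) -> Path:
    """Write the trajectory table as CSV with its ground truth JSON alongside."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(csv_path, index=False)
    truth_path = csv_path.with_suffix(".truth.json")
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth_path
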