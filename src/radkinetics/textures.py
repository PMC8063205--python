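"""Radiomic texture features over a volume of interest.

Implements the feature families used in the mandibular CT analysis: first
order intensity statistics, gray-level co-occurrence (GLCM), gray-level run
length (GLRL) and the neighborhood gray-tone difference family (NGTDM, often
written NID), each in full-3D and slice-wise 2.5D modes, after trilinear
voxel-size standardisation and equal-width gray-level discretisation.

Conventions (recorded in every FeatureVector's provenance):

* arrays are indexed ``(x, y, z)``; 2.5D slices are ``values[:, :, k]``;
* GLCM/GLRL offsets: the 13 unique distance-1 directions of the
  26-neighborhood in 3D, the 4 unique in-plane directions of the
  8-neighborhood per slice in 2.5D; per-direction (and per-slice) matrices
  are summed before normalisation and feature computation;
* discretisation: equal-width bins between the in-mask min and max,
  default 32 levels;
* features whose definition degenerates (zero variance, empty entropy) are
  flagged undefined rather than silently NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelVolume",
    "FeatureVector",
    "ExtractionConfig",
    "resample_trilinear",
    "discretize_levels",
    "compute_glcm",
    "glcm_features",
    "compute_glrl",
    "glrl_features",
    "ngtdm_features",
    "first_order_features",
    "extract_features",
    "extract_feature_table",
    "load_nifti_volume",
    "save_nifti_volume",
    "OFFSETS_3D",
    "OFFSETS_2D",
]

# 13 unique direction-1 offsets covering the 26-neighborhood up to sign
OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
# 4 unique in-plane offsets of the 8-neighborhood
OFFSETS_2D: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1), (1, -1))


@dataclass
class VoxelVolume:
    """A 3D scalar grid with anisotropic voxel spacing in mm."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class FeatureVector:
    """Named feature values plus the settings that produced them.

    ``undefined`` lists features whose definition degenerated on this input
    (their value is NaN); downstream screening drops such columns.
    """

    values: dict[str, float]
    undefined: set[str] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def flag(self, name: str) -> None:
        self.values[name] = float("nan")
        self.undefined.add(name)


@dataclass(frozen=True)
class ExtractionConfig:
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    n_levels: int = 32
    modes: tuple[str, ...] = ("3D", "2.5D")
    nid_neighborhoods: tuple[int, ...] = (3, 5, 7)


# --------------------------------------------------------------------------
# resampling and discretisation


def resample_trilinear(
    volume: VoxelVolume, target_spacing_mm: Sequence[float]
) -> VoxelVolume:
    """Resample to a new voxel spacing by trilinear interpolation.

    The output grid covers the same physical extent (voxel-centre
    convention); identical target spacing returns a copy of the input.
    """
    target = np.asarray(target_spacing_mm, dtype=float)
    if np.any(target <= 0):
        raise ValueError("target spacing must be positive")
    spacing = np.asarray(volume.spacing_mm, dtype=float)
    if np.allclose(target, spacing):
        return VoxelVolume(volume.values.copy(), tuple(spacing))
    shape = np.array(volume.values.shape)
    if np.any((shape < 2) & ~np.isclose(target, spacing)):
        raise ValueError("cannot resample a single-voxel axis")
    extent = shape * spacing
    new_shape = np.maximum(1, np.round(extent / target).astype(int))
    # fractional source index of each target voxel centre
    axes = [
        ((np.arange(new_shape[a]) + 0.5) * target[a]) / spacing[a] - 0.5
        for a in range(3)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        volume.values, np.stack(coords), order=1, mode="nearest"
    )
    return VoxelVolume(out, tuple(target))


def resample_mask(mask: np.ndarray, spacing_mm, target_spacing_mm) -> np.ndarray:
    """Nearest-neighbour companion resampling for a binary VOI mask."""
    vol = VoxelVolume(mask.astype(float), tuple(spacing_mm))
    res = resample_trilinear(vol, target_spacing_mm)
    return res.values >= 0.5


def discretize_levels(values: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width discretisation of in-mask intensities to 1..n_levels.

    Returns an int array, 0 outside the mask.  A constant region maps
    entirely to level 1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    inside = np.asarray(values, dtype=float)[mask]
    lo, hi = inside.min(), inside.max()
    labels = np.zeros(mask.shape, dtype=np.int32)
    if hi == lo:
        labels[mask] = 1
        return labels
    lv = np.floor((inside - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
    labels[mask] = np.minimum(lv, n_levels)
    return labels


# --------------------------------------------------------------------------
# GLCM


def _accumulate_pairs(counts, labels, mask, offset3):
    """Add symmetric co-occurrence counts for one 3-D offset."""
    dx, dy, dz = offset3
    nx, ny, nz = labels.shape
    sl_a = tuple(
        slice(max(0, -d), min(n, n - d)) for d, n in zip((dx, dy, dz), (nx, ny, nz))
    )
    sl_b = tuple(
        slice(max(0, d), min(n, n + d)) for d, n in zip((dx, dy, dz), (nx, ny, nz))
    )
    a, b = labels[sl_a], labels[sl_b]
    valid = mask[sl_a] & mask[sl_b]
    if not valid.any():
        return
    np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    np.add.at(counts, (b[valid] - 1, a[valid] - 1), 1)


def compute_glcm(
    labels: np.ndarray,
    mask: np.ndarray,
    mode: str = "3D",
    n_levels: int | None = None,
    offsets: Sequence[tuple[int, ...]] | None = None,
) -> np.ndarray:
    """Normalized symmetric gray-level co-occurrence matrix.

    3D mode accumulates over the 13 unique distance-1 offsets; 2.5D mode
    accumulates the 4 in-plane offsets slice by slice and sums the per-slice
    matrices.  Pairs count only when both voxels are in-mask.  The returned
    matrix sums to 1 and equals its transpose.
    """
    mask = np.asarray(mask, dtype=bool)
    if n_levels is None:
        n_levels = int(labels.max())
    counts = np.zeros((n_levels, n_levels), dtype=float)
    if mode == "3D":
        offs = offsets if offsets is not None else OFFSETS_3D
        for off in offs:
            _accumulate_pairs(counts, labels, mask, off)
    elif mode == "2.5D":
        offs2 = offsets if offsets is not None else OFFSETS_2D
        for off in offs2:
            _accumulate_pairs(counts, labels, mask, (off[0], off[1], 0))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-mask voxel pairs for GLCM")
    return counts / total


def glcm_features(P: np.ndarray) -> FeatureVector:
    """Haralick-family features of a normalized symmetric GLCM.

    contrast, dissimilarity, correlation, cluster shade, inverse difference
    moment normalized (IDMN), and information measure of correlation 1
    (IMC1; base-2 entropies, 0·log0 := 0).
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    i, j = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    lv = np.arange(1, n + 1)
    mu_i = float(np.sum(lv * px))
    mu_j = float(np.sum(lv * py))
    var_i = float(np.sum((lv - mu_i) ** 2 * px))
    var_j = float(np.sum((lv - mu_j) ** 2 * py))

    fv = FeatureVector(values={}, provenance={"n_levels": n})
    fv.values["contrast"] = float(np.sum(P * (i - j) ** 2))
    fv.values["dissimilarity"] = float(np.sum(P * np.abs(i - j)))
    fv.values["cluster_shade"] = float(np.sum(P * (i + j - mu_i - mu_j) ** 3))
    fv.values["inverse_difference_moment_normalized"] = float(
        np.sum(P / (1.0 + (i - j) ** 2 / n**2))
    )
    if var_i > 0 and var_j > 0:
        fv.values["correlation"] = float(
            np.sum(P * (i - mu_i) * (j - mu_j)) / math.sqrt(var_i * var_j)
        )
    else:
        fv.flag("correlation")

    def _h(p):
        p = p[p > 0]
        return float(-np.sum(p * np.log2(p)))

    hx, hy = _h(px), _h(py)
    hxy = _h(P.ravel())
    outer = np.outer(px, py)
    nz = (P > 0) & (outer > 0)
    hxy1 = float(-np.sum(P[nz] * np.log2(outer[nz])))
    if max(hx, hy) > 0:
        fv.values["information_measure_correlation_1"] = (hxy - hxy1) / max(hx, hy)
    else:
        fv.flag("information_measure_correlation_1")
    return fv


# --------------------------------------------------------------------------
# GLRL


def _runs_along(labels, mask, offset3):
    """Yield (level, length) for maximal equal-level in-mask runs along one direction."""
    nx, ny, nz = labels.shape
    d = np.array(offset3)
    runs = []
    it = np.argwhere(mask)
    inside = lambda p: 0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz
    for p0 in it:
        lv = labels[tuple(p0)]
        prev = p0 - d
        if inside(prev) and mask[tuple(prev)] and labels[tuple(prev)] == lv:
            continue  # not a run start
        length = 1
        nxt = p0 + d
        while inside(nxt) and mask[tuple(nxt)] and labels[tuple(nxt)] == lv:
            length += 1
            nxt = nxt + d
        runs.append((int(lv), length))
    return runs


def compute_glrl(
    labels: np.ndarray,
    mask: np.ndarray,
    mode: str = "3D",
    n_levels: int | None = None,
    offsets: Sequence[tuple[int, ...]] | None = None,
) -> np.ndarray:
    """Gray-level run-length matrix summed over the direction set.

    Entry (g, l) counts runs of level g+1 and length l+1; runs truncate at
    the mask boundary.  Σ entries = number of runs.
    """
    mask = np.asarray(mask, dtype=bool)
    if n_levels is None:
        n_levels = int(labels.max())
    if mode == "3D":
        offs = list(offsets) if offsets is not None else list(OFFSETS_3D)
    elif mode == "2.5D":
        offs2 = offsets if offsets is not None else OFFSETS_2D
        offs = [(o[0], o[1], 0) for o in offs2]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    max_len = max(labels.shape) * 2  # generous bound incl. diagonals
    R = np.zeros((n_levels, max_len), dtype=float)
    n_runs = 0
    for off in offs:
        for lv, length in _runs_along(labels, mask, off):
            R[lv - 1, length - 1] += 1
            n_runs += 1
    if n_runs == 0:
        raise ValueError("empty run set")
    longest = int(np.max(np.nonzero(R.sum(axis=0))[0])) + 1
    return R[:, :longest]


def glrl_features(
    labels: np.ndarray,
    mask: np.ndarray,
    mode: str = "3D",
    n_levels: int | None = None,
    offsets=None,
) -> FeatureVector:
    """Galloway run-length features over the direction-merged GLRL matrix."""
    mask = np.asarray(mask, dtype=bool)
    R = compute_glrl(labels, mask, mode=mode, n_levels=n_levels, offsets=offsets)
    n_dirs = len(offsets) if offsets is not None else (
        len(OFFSETS_3D) if mode == "3D" else len(OFFSETS_2D)
    )
    nr = R.sum()
    lengths = np.arange(1, R.shape[1] + 1, dtype=float)
    per_level = R.sum(axis=1)
    per_length = R.sum(axis=0)
    n_vox = int(mask.sum())
    fv = FeatureVector(values={}, provenance={"mode": mode, "n_directions": n_dirs})
    fv.values["short_run_emphasis"] = float(np.sum(per_length / lengths**2) / nr)
    fv.values["long_run_emphasis"] = float(np.sum(per_length * lengths**2) / nr)
    fv.values["gray_level_nonuniformity"] = float(np.sum(per_level**2) / nr)
    fv.values["run_length_nonuniformity"] = float(np.sum(per_length**2) / nr)
    fv.values["run_percentage"] = float(nr / (n_vox * n_dirs))
    return fv


# --------------------------------------------------------------------------
# NGTDM (neighborhood gray-tone / intensity difference)


def _ngtdm_table(labels, mask, k, mode):
    """Per-level occurrence counts n_i and summed deviations s_i.

    A voxel contributes only when its full k-window (k×k×k in 3D, k×k
    in-plane in 2.5D, centre excluded) lies inside both the volume and the
    mask.
    """
    if k % 2 != 1 or k < 3:
        raise ValueError("neighborhood size must be odd and >= 3")
    r = k // 2
    mask = np.asarray(mask, dtype=bool)
    nx, ny, nz = labels.shape
    n_levels = int(labels.max())
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    if mode == "3D":
        zr = range(-r, r + 1)
    elif mode == "2.5D":
        zr = range(0, 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    count = 0
    for x, y, z in np.argwhere(mask):
        if not (r <= x < nx - r and r <= y < ny - r):
            continue
        if mode == "3D" and not (r <= z < nz - r):
            continue
        if mode == "3D":
            window = mask[x - r : x + r + 1, y - r : y + r + 1, z - r : z + r + 1]
            wl = labels[x - r : x + r + 1, y - r : y + r + 1, z - r : z + r + 1]
        else:
            window = mask[x - r : x + r + 1, y - r : y + r + 1, z : z + 1]
            wl = labels[x - r : x + r + 1, y - r : y + r + 1, z : z + 1]
        if not window.all():
            continue
        total = wl.sum() - labels[x, y, z]
        nn = window.size - 1
        mean_nb = total / nn
        lv = int(labels[x, y, z])
        n[lv - 1] += 1
        s[lv - 1] += abs(lv - mean_nb)
        count += 1
    if count == 0:
        raise ValueError("no voxel has a complete in-mask window")
    return n, s


def ngtdm_features(
    labels: np.ndarray, mask: np.ndarray, neighborhood: int = 3, mode: str = "3D"
) -> FeatureVector:
    """Amadasun–King neighborhood gray-tone difference features.

    coarseness, contrast, busyness, complexity and texture strength over the
    occurrence probabilities p_i = n_i / N and deviations s_i.  Degenerate
    cases: a constant region has all s_i = 0, giving contrast = busyness =
    complexity = texture_strength = 0 and a coarseness capped at 1e12.
    """
    n, s = _ngtdm_table(labels, mask, neighborhood, mode)
    N = n.sum()
    p = n / N
    present = np.nonzero(p)[0]
    ng = present.size
    lv = np.arange(1, len(p) + 1, dtype=float)

    fv = FeatureVector(
        values={}, provenance={"neighborhood": neighborhood, "mode": mode}
    )
    ps = float(np.sum(p * s))
    fv.values["coarseness"] = float(min(1.0 / ps, 1e12)) if ps > 0 else 1e12

    if ng > 1:
        pi = p[present]
        li = lv[present]
        diff2 = (li[:, None] - li[None, :]) ** 2
        fv.values["contrast"] = float(
            np.sum(pi[:, None] * pi[None, :] * diff2) / (ng * (ng - 1)) * (s.sum() / N)
        )
        denom = np.sum(np.abs(li[:, None] * pi[:, None] - li[None, :] * pi[None, :]))
        fv.values["busyness"] = float(ps / denom) if denom > 0 else 0.0
        si = s[present]
        fv.values["complexity"] = float(
            np.sum(
                np.abs(li[:, None] - li[None, :])
                * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
                / (pi[:, None] + pi[None, :])
            )
            / N
        )
        ssum = s.sum()
        if ssum > 0:
            fv.values["texture_strength"] = float(
                np.sum((pi[:, None] + pi[None, :]) * diff2) / ssum
            )
        else:
            fv.values["texture_strength"] = 0.0
    else:
        fv.values["contrast"] = 0.0
        fv.values["busyness"] = 0.0
        fv.values["complexity"] = 0.0
        fv.values["texture_strength"] = 0.0
    return fv


# --------------------------------------------------------------------------
# first order


def _window_entropy(labels, mask, x, y, z):
    """Base-2 entropy of the in-mask discretized levels in a 3×3×1 window."""
    nx, ny, _ = labels.shape
    xs = slice(max(0, x - 1), min(nx, x + 2))
    ys = slice(max(0, y - 1), min(ny, y + 2))
    w = labels[xs, ys, z : z + 1]
    wm = mask[xs, ys, z : z + 1]
    vals = w[wm]
    if vals.size == 0:
        return 0.0
    _, counts = np.unique(vals, return_counts=True)
    pr = counts / counts.sum()
    return float(-np.sum(pr * np.log2(pr)))


def first_order_features(
    volume: VoxelVolume,
    mask: np.ndarray,
    n_levels: int = 32,
    labels: np.ndarray | None = None,
) -> FeatureVector:
    """Intensity statistics over the in-mask voxels.

    mean, sd (sample), skewness, kurtosis (Fisher), base-2 histogram entropy
    of the discretized levels, the median of per-voxel 3×3×1 local entropies,
    and VOI physical volume in mm³.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = volume.values[mask]
    if labels is None:
        labels = discretize_levels(volume.values, mask, n_levels)
    fv = FeatureVector(values={}, provenance={"n_levels": n_levels})
    fv.values["mean"] = float(vals.mean())
    fv.values["sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if vals.size > 2 and vals.std() > 0:
        fv.values["skewness"] = float(stats.skew(vals))
        fv.values["kurtosis"] = float(stats.kurtosis(vals))
    else:
        fv.values["skewness"] = 0.0
        fv.values["kurtosis"] = 0.0
    _, counts = np.unique(labels[mask], return_counts=True)
    pr = counts / counts.sum()
    fv.values["entropy"] = float(-np.sum(pr * np.log2(pr)))
    ents = [_window_entropy(labels, mask, x, y, z) for x, y, z in np.argwhere(mask)]
    fv.values["local_entropy_median"] = float(np.median(ents))
    fv.values["voxel_volume"] = float(mask.sum()) * volume.voxel_volume_mm3
    return fv


# --------------------------------------------------------------------------
# full extraction

# readable names for the six features highlighted in the source study's
# screening table, mapped to this package's naming scheme
PUBLISHED_FEATURE_MAP = {
    "GLCM 2.5D InformationMeasureCorr1": "glcm_25d_information_measure_correlation_1",
    "GLCM 3D Cluster Shade": "glcm_3d_cluster_shade",
    "GLCM 3D Dissimilarity": "glcm_3d_dissimilarity",
    "GLCM 3D InverseDiffMomentNorm": "glcm_3d_inverse_difference_moment_normalized",
    "Intensity Mean": "fo_mean",
    "Intensity Local entropy median": "fo_local_entropy_median",
}


def extract_features(
    volume: VoxelVolume, mask: np.ndarray, config: ExtractionConfig = ExtractionConfig()
) -> FeatureVector:
    """All configured families for one VOI at one time point.

    Resamples to ``target_spacing_mm``, discretizes, then computes first
    order plus GLCM/GLRL in each configured mode and NGTDM at each
    configured neighborhood.  Column names encode family, mode and
    parameters (e.g. ``ngtdm_25d_k5_busyness``); order is deterministic.
    """
    res = resample_trilinear(volume, config.target_spacing_mm)
    rmask = resample_mask(mask, volume.spacing_mm, config.target_spacing_mm)
    if rmask.sum() < 27:
        raise ValueError("VOI too small after resampling (< 27 voxels)")
    labels = discretize_levels(res.values, rmask, config.n_levels)

    out = FeatureVector(
        values={},
        provenance={
            "target_spacing_mm": tuple(config.target_spacing_mm),
            "n_levels": config.n_levels,
            "modes": tuple(config.modes),
            "nid_neighborhoods": tuple(config.nid_neighborhoods),
        },
    )

    def _merge(prefix: str, fv: FeatureVector) -> None:
        for name, value in fv.values.items():
            key = f"{prefix}_{name}"
            out.values[key] = value
            if name in fv.undefined:
                out.undefined.add(key)

    _merge("fo", first_order_features(res, rmask, config.n_levels, labels=labels))
    for mode in config.modes:
        tag = "3d" if mode == "3D" else "25d"
        P = compute_glcm(labels, rmask, mode=mode, n_levels=config.n_levels)
        _merge(f"glcm_{tag}", glcm_features(P))
        _merge(f"glrl_{tag}", glrl_features(labels, rmask, mode=mode, n_levels=config.n_levels))
        for k in config.nid_neighborhoods:
            try:
                fv = ngtdm_features(labels, rmask, neighborhood=k, mode=mode)
            except ValueError:
                fv = FeatureVector(values={})
                for name in ("coarseness", "contrast", "busyness", "complexity", "texture_strength"):
                    fv.flag(name)
            _merge(f"ngtdm_{tag}_k{k}", fv)
    return out


def extract_feature_table(
    vois: Iterable[Mapping],
    config: ExtractionConfig = ExtractionConfig(),
    required_months: Sequence[float] = (0, 2, 6),
) -> pd.DataFrame:
    """Long-format trajectory table from per-(VOI, month) volumes + masks.

    ``vois`` yields mappings with keys ``voi_id, patient_id, label,
    timepoint_month, volume (VoxelVolume), mask (bool array)``.  A VOI
    missing any required month is dropped with a logged warning, mirroring
    the exclusion of subjects without a 6-month scan.
    """
    records = list(vois)
    by_voi: dict[str, list[Mapping]] = {}
    for rec in records:
        by_voi.setdefault(rec["voi_id"], []).append(rec)

    rows = []
    for voi_id, recs in by_voi.items():
        months = {r["timepoint_month"] for r in recs}
        missing = set(required_months) - months
        if missing:
            logger.warning(
                "VOI %s missing month(s) %s; excluded from the feature table",
                voi_id,
                sorted(missing),
            )
            continue
        for rec in sorted(recs, key=lambda r: r["timepoint_month"]):
            fv = extract_features(rec["volume"], rec["mask"], config)
            rows.append(
                {
                    "voi_id": voi_id,
                    "patient_id": rec["patient_id"],
                    "label": rec["label"],
                    "timepoint_month": rec["timepoint_month"],
                    **fv.values,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# NIfTI IO


def load_nifti_volume(path: str | Path) -> VoxelVolume:
    import nibabel as nib

    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelVolume(np.asarray(img.get_fdata(), dtype=float), spacing)


def save_nifti_volume(volume: VoxelVolume | np.ndarray, spacing_or_path, path=None) -> Path:
    """Save a volume (or a mask array + spacing) as NIfTI."""
    import nibabel as nib

    if path is None:
        vol, out = volume, Path(spacing_or_path)
        data, spacing = vol.values, vol.spacing_mm
    else:
        data, spacing, out = np.asarray(volume, dtype=float), spacing_or_path, Path(path)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(out))
    return out
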