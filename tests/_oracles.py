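"""Independent brute-force oracles for the test suite.

Everything here is written as plain per-voxel / per-pair loops, kept
deliberately separate from the package implementations so agreement is a
real cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


# --------------------------------------------------------------------------
# GLCM


def glcm_matrix(labels, mask, offsets, n_levels):
    """Symmetric co-occurrence counts by explicit voxel loops."""
    counts = np.zeros((n_levels, n_levels))
    shape = labels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in offsets:
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]):
                        continue
                    if not mask[nx, ny, nz]:
                        continue
                    a, b = labels[x, y, z] - 1, labels[nx, ny, nz] - 1
                    counts[a, b] += 1
                    counts[b, a] += 1
    return counts / counts.sum()


def glcm_features(P):
    """Double-loop Haralick features of a normalized GLCM."""
    n = P.shape[0]
    px = [sum(P[i, j] for j in range(n)) for i in range(n)]
    py = [sum(P[i, j] for i in range(n)) for j in range(n)]
    mu_i = sum((i + 1) * px[i] for i in range(n))
    mu_j = sum((j + 1) * py[j] for j in range(n))
    var_i = sum((i + 1 - mu_i) ** 2 * px[i] for i in range(n))
    var_j = sum((j + 1 - mu_j) ** 2 * py[j] for j in range(n))
    out = {"contrast": 0.0, "dissimilarity": 0.0, "cluster_shade": 0.0,
           "inverse_difference_moment_normalized": 0.0}
    corr_num = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            out["contrast"] += p * (i - j) ** 2
            out["dissimilarity"] += p * abs(i - j)
            out["cluster_shade"] += p * ((i + 1) + (j + 1) - mu_i - mu_j) ** 3
            out["inverse_difference_moment_normalized"] += p / (1 + (i - j) ** 2 / n**2)
            corr_num += p * ((i + 1) - mu_i) * ((j + 1) - mu_j)
    if var_i > 0 and var_j > 0:
        out["correlation"] = corr_num / math.sqrt(var_i * var_j)
    hx = -sum(p * math.log2(p) for p in px if p > 0)
    hy = -sum(p * math.log2(p) for p in py if p > 0)
    hxy = -sum(P[i, j] * math.log2(P[i, j]) for i in range(n) for j in range(n) if P[i, j] > 0)
    hxy1 = -sum(
        P[i, j] * math.log2(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if P[i, j] > 0 and px[i] * py[j] > 0
    )
    if max(hx, hy) > 0:
        out["information_measure_correlation_1"] = (hxy - hxy1) / max(hx, hy)
    return out


# --------------------------------------------------------------------------
# GLRL: enumerate maximal lines through the grid, split at mask/level breaks


def glrl_runs(labels, mask, offset):
    """All (level, length) runs along one direction via full line sweeps."""
    shape = labels.shape
    d = np.array(offset)
    starts = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                prev = np.array([x, y, z]) - d
                if not (
                    0 <= prev[0] < shape[0]
                    and 0 <= prev[1] < shape[1]
                    and 0 <= prev[2] < shape[2]
                ):
                    starts.append((x, y, z))
    runs = []
    for s in starts:
        pos = np.array(s)
        current_level, current_len = None, 0
        while 0 <= pos[0] < shape[0] and 0 <= pos[1] < shape[1] and 0 <= pos[2] < shape[2]:
            t = tuple(pos)
            if mask[t]:
                lv = labels[t]
                if lv == current_level:
                    current_len += 1
                else:
                    if current_level is not None:
                        runs.append((current_level, current_len))
                    current_level, current_len = lv, 1
            else:
                if current_level is not None:
                    runs.append((current_level, current_len))
                current_level, current_len = None, 0
            pos = pos + d
        if current_level is not None:
            runs.append((current_level, current_len))
    return runs


def glrl_features(labels, mask, offsets):
    runs = []
    for off in offsets:
        runs.extend(glrl_runs(labels, mask, off))
    nr = len(runs)
    levels = sorted({lv for lv, _ in runs})
    lengths = sorted({ln for _, ln in runs})
    out = {
        "short_run_emphasis": sum(1 / ln**2 for _, ln in runs) / nr,
        "long_run_emphasis": sum(ln**2 for _, ln in runs) / nr,
        "gray_level_nonuniformity": sum(
            sum(1 for lv, _ in runs if lv == g) ** 2 for g in levels
        )
        / nr,
        "run_length_nonuniformity": sum(
            sum(1 for _, ln in runs if ln == l) ** 2 for l in lengths
        )
        / nr,
        "run_percentage": nr / (int(mask.sum()) * len(offsets)),
    }
    return out


# --------------------------------------------------------------------------
# NGTDM


def ngtdm_features(labels, mask, k, mode):
    """Per-voxel window loops, then the Amadasun-King formulas."""
    r = k // 2
    shape = labels.shape
    n_levels = int(labels.max())
    n = [0.0] * n_levels
    s = [0.0] * n_levels
    zrange = range(-r, r + 1) if mode == "3D" else [0]
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                vals = []
                ok = True
                for dx in range(-r, r + 1):
                    for dy in range(-r, r + 1):
                        for dz in zrange:
                            if dx == dy == dz == 0:
                                continue
                            xx, yy, zz = x + dx, y + dy, z + dz
                            if not (
                                0 <= xx < shape[0]
                                and 0 <= yy < shape[1]
                                and 0 <= zz < shape[2]
                            ) or not mask[xx, yy, zz]:
                                ok = False
                                break
                            vals.append(labels[xx, yy, zz])
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    continue
                lv = int(labels[x, y, z])
                n[lv - 1] += 1
                s[lv - 1] += abs(lv - sum(vals) / len(vals))
    N = sum(n)
    if N == 0:
        raise ValueError("no complete windows")
    p = [ni / N for ni in n]
    present = [i for i in range(n_levels) if p[i] > 0]
    ng = len(present)
    out = {}
    ps = sum(p[i] * s[i] for i in range(n_levels))
    out["coarseness"] = min(1.0 / ps, 1e12) if ps > 0 else 1e12
    if ng > 1:
        out["contrast"] = (
            sum(
                p[i] * p[j] * (i - j) ** 2
                for i in present
                for j in present
            )
            / (ng * (ng - 1))
            * (sum(s) / N)
        )
        denom = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
        )
        out["busyness"] = ps / denom if denom > 0 else 0.0
        out["complexity"] = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in present
                for j in present
            )
            / N
        )
        ssum = sum(s)
        out["texture_strength"] = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / ssum
            if ssum > 0
            else 0.0
        )
    else:
        out.update(contrast=0.0, busyness=0.0, complexity=0.0, texture_strength=0.0)
    return out


# --------------------------------------------------------------------------
# first order


def local_entropy_median(labels, mask):
    shape = labels.shape
    ents = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                counts = {}
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        xx, yy = x + dx, y + dy
                        if 0 <= xx < shape[0] and 0 <= yy < shape[1] and mask[xx, yy, z]:
                            lv = labels[xx, yy, z]
                            counts[lv] = counts.get(lv, 0) + 1
                total = sum(counts.values())
                ent = -sum(
                    (c / total) * math.log2(c / total) for c in counts.values()
                )
                ents.append(ent)
    return float(np.median(ents))


# --------------------------------------------------------------------------
# interpolation and splines


def trilinear_probe(values, spacing, target_spacing, index):
    """Nearest-8-corner weighted average at one target voxel (interior only)."""
    coord = [
        (index[a] + 0.5) * target_spacing[a] / spacing[a] - 0.5 for a in range(3)
    ]
    lo = [math.floor(c) for c in coord]
    frac = [c - l for c, l in zip(coord, lo)]
    acc = 0.0
    for cx in (0, 1):
        for cy in (0, 1):
            for cz in (0, 1):
                w = (
                    (frac[0] if cx else 1 - frac[0])
                    * (frac[1] if cy else 1 - frac[1])
                    * (frac[2] if cz else 1 - frac[2])
                )
                acc += w * values[lo[0] + cx, lo[1] + cy, lo[2] + cz]
    return acc


def natural_spline_3pt(t, y, x):
    """Natural cubic spline through 3 points via the tridiagonal equation."""
    t0, t1, t2 = t
    y0, y1, y2 = y
    h0, h1 = t1 - t0, t2 - t1
    # second derivatives: M0 = M2 = 0; interior equation solved directly
    m1 = 6 * ((y2 - y1) / h1 - (y1 - y0) / h0) / (2 * (h0 + h1))
    if x <= t1:
        a, b, h, mA, mB, yA, yB = t0, t1, h0, 0.0, m1, y0, y1
    else:
        a, b, h, mA, mB, yA, yB = t1, t2, h1, m1, 0.0, y1, y2
    return (
        mA * (b - x) ** 3 / (6 * h)
        + mB * (x - a) ** 3 / (6 * h)
        + (yA / h - mA * h / 6) * (b - x)
        + (yB / h - mB * h / 6) * (x - a)
    )


def auc_by_enumeration(prob_control, labels):
    """Tie-corrected two-sample U statistic: ORN scored by lower prob."""
    pos = [p for p, l in zip(prob_control, labels) if l == "ORN"]
    neg = [p for p, l in zip(prob_control, labels) if l == "Control"]
    acc = 0.0
    for a in pos:
        for b in neg:
            if a < b:
                acc += 1.0
            elif a == b:
                acc += 0.5
    return acc / (len(pos) * len(neg))
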