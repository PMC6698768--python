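"""Independent brute-force oracles used to validate the texture matrices.

Everything here is written as plain position-by-position enumeration,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_glcm(grid: np.ndarray, offset: tuple[int, ...], n_bins: int) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix by exhaustive pair
    enumeration; level 0 marks out-of-mask cells."""
    counts = np.zeros((n_bins, n_bins))
    for pos in itertools.product(*[range(s) for s in grid.shape]):
        nb = tuple(p + d for p, d in zip(pos, offset))
        if any(not 0 <= c < s for c, s in zip(nb, grid.shape)):
            continue
        a, b = int(grid[pos]), int(grid[nb])
        if a > 0 and b > 0:
            counts[a - 1, b - 1] += 1
            counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def brute_gldm(grid: np.ndarray, offset: tuple[int, ...], n_bins: int) -> np.ndarray:
    """Absolute-difference probabilities by exhaustive pair enumeration."""
    counts = np.zeros(n_bins)
    for pos in itertools.product(*[range(s) for s in grid.shape]):
        nb = tuple(p + d for p, d in zip(pos, offset))
        if any(not 0 <= c < s for c, s in zip(nb, grid.shape)):
            continue
        a, b = int(grid[pos]), int(grid[nb])
        if a > 0 and b > 0:
            counts[abs(a - b)] += 1
    total = counts.sum()
    return counts / total if total else counts


def brute_glrlm(grid: np.ndarray, offset: tuple[int, ...], n_bins: int) -> np.ndarray:
    """Run-length counts by explicit line walking in both directions.

    A run is a maximal sequence of equal nonzero levels along the offset
    direction; each run is counted once.
    """
    l_max = max(grid.shape)
    counts = np.zeros((n_bins, l_max))
    seen: set[tuple] = set()
    for pos in itertools.product(*[range(s) for s in grid.shape]):
        v = int(grid[pos])
        if v == 0:
            continue
        prev = tuple(p - d for p, d in zip(pos, offset))
        prev_inside = all(0 <= c < s for c, s in zip(prev, grid.shape))
        if prev_inside and int(grid[prev]) == v:
            continue  # not the start of a run
        length = 0
        cur = pos
        while all(0 <= c < s for c, s in zip(cur, grid.shape)) and int(grid[cur]) == v:
            length += 1
            cur = tuple(c + d for c, d in zip(cur, offset))
        key = (pos, v)
        if key not in seen:
            seen.add(key)
            counts[v - 1, length - 1] += 1
    return counts


def naive_glcm_stats(p: np.ndarray) -> dict[str, float]:
    """The 15 co-occurrence statistics via explicit double loops."""
    n = p.shape[0]
    log2 = lambda v: math.log2(v) if v > 0 else 0.0

    px = [sum(p[i][j] for j in range(n)) for i in range(n)]
    mu = sum((i + 1) * px[i] for i in range(n))
    var_x = sum((i + 1 - mu) ** 2 * px[i] for i in range(n))

    p_sum = [0.0] * (2 * n + 1)
    p_diff = [0.0] * n
    for i in range(n):
        for j in range(n):
            p_sum[(i + 1) + (j + 1)] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    energy = sum(p[i][j] ** 2 for i in range(n) for j in range(n))
    contrast = sum((i - j) ** 2 * p[i][j] for i in range(n) for j in range(n))
    if var_x > 0:
        correlation = sum(
            (i + 1 - mu) * (j + 1 - mu) * p[i][j] for i in range(n) for j in range(n)
        ) / var_x
    else:
        correlation = 0.0
    variance = sum((i + 1 - mu) ** 2 * p[i][j] for i in range(n) for j in range(n))
    idm = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    sum_average = sum(k * p_sum[k] for k in range(2 * n + 1))
    sum_variance = sum((k - sum_average) ** 2 * p_sum[k] for k in range(2 * n + 1))
    sum_entropy = -sum(v * log2(v) for v in p_sum if v > 0)
    entropy = -sum(
        p[i][j] * log2(p[i][j]) for i in range(n) for j in range(n) if p[i][j] > 0
    )
    mu_d = sum(k * p_diff[k] for k in range(n))
    difference_variance = sum((k - mu_d) ** 2 * p_diff[k] for k in range(n))
    difference_entropy = -sum(v * log2(v) for v in p_diff if v > 0)

    hx = -sum(v * log2(v) for v in px if v > 0)
    hxy1 = -sum(
        p[i][j] * log2(px[i] * px[j])
        for i in range(n) for j in range(n)
        if p[i][j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * log2(px[i] * px[j])
        for i in range(n) for j in range(n)
        if px[i] * px[j] > 0
    )
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))
    autocorrelation = sum(
        (i + 1) * (j + 1) * p[i][j] for i in range(n) for j in range(n)
    )
    return {
        "energy": energy, "contrast": contrast, "correlation": correlation,
        "variance": variance, "idm": idm, "sum_average": sum_average,
        "sum_variance": sum_variance, "sum_entropy": sum_entropy,
        "entropy": entropy, "difference_variance": difference_variance,
        "difference_entropy": difference_entropy, "imc1": imc1, "imc2": imc2,
        "autocorrelation": autocorrelation, "max_probability": float(np.max(p)),
    }


def naive_gldm_stats(prob: np.ndarray) -> dict[str, float]:
    log2 = lambda v: math.log2(v) if v > 0 else 0.0
    return {
        "contrast": sum(k * k * pk for k, pk in enumerate(prob)),
        "asm": sum(pk * pk for pk in prob),
        "entropy": -sum(pk * log2(pk) for pk in prob if pk > 0),
        "mean": sum(k * pk for k, pk in enumerate(prob)),
        "idm": sum(pk / (1 + k * k) for k, pk in enumerate(prob)),
    }


def naive_glrlm_stats(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    n_runs = counts.sum()
    vals = {k: 0.0 for k in
            ("sre", "lre", "gln", "rln", "rp", "lgre", "hgre",
             "srlge", "srhge", "lrlge", "lrhge")}
    if n_runs == 0:
        return vals
    ni, nj = counts.shape
    for i in range(ni):
        for j in range(nj):
            r = counts[i, j]
            if r == 0:
                continue
            gi, gj = i + 1.0, j + 1.0
            vals["sre"] += r / gj**2
            vals["lre"] += r * gj**2
            vals["lgre"] += r / gi**2
            vals["hgre"] += r * gi**2
            vals["srlge"] += r / (gi**2 * gj**2)
            vals["srhge"] += r * gi**2 / gj**2
            vals["lrlge"] += r * gj**2 / gi**2
            vals["lrhge"] += r * gi**2 * gj**2
    vals["gln"] = sum(counts[i, :].sum() ** 2 for i in range(ni))
    vals["rln"] = sum(counts[:, j].sum() ** 2 for j in range(nj))
    for k in vals:
        vals[k] /= n_runs
    vals["rp"] = n_runs / n_voxels
    return vals


def brute_best_plane(mask: np.ndarray, spacing: tuple[float, float, float]):
    """Exhaustive largest-diameter plane search over all orientations and
    slices; returns (plane name, slice index)."""
    names = ("axial", "coronal", "sagittal")
    best = None
    for axis in range(3):
        others = [a for a in range(3) if a != axis]
        for s in range(mask.shape[axis]):
            sl = [slice(None)] * 3
            sl[axis] = s
            plane = mask[tuple(sl)]
            pts = np.argwhere(plane).astype(float)
            if len(pts) == 0:
                continue
            pts *= [spacing[a] for a in others]
            diam = 0.0
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    diam = max(diam, float(np.linalg.norm(pts[i] - pts[j])))
            key = (-diam, axis, s)
            if best is None or key < best:
                best = key
    return names[best[1]], best[2]
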