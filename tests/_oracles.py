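"""Independent brute-force oracles for texture features and ROC.

Deliberately written as plain Python loops over voxels, pairs, runs and
matrix entries so they share no code path with the vectorized package
implementation.
"""

from __future__ import annotations

import math

import numpy as np


def brute_glcm(level_grid: np.ndarray, offsets, distance: int = 1):
    """Symmetric pooled co-occurrence counts by looping over every voxel and
    every ± offset; returns (probability matrix, n_pairs)."""
    shape = level_grid.shape
    ng = int(level_grid.max())
    counts = {}
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                a = level_grid[i, j, k]
                if a == 0:
                    continue
                for off in offsets:
                    for sign in (1, -1):
                        ii = i + sign * off[0] * distance
                        jj = j + sign * off[1] * distance
                        kk = k + sign * off[2] * distance
                        if not (0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]):
                            continue
                        b = level_grid[ii, jj, kk]
                        if b == 0:
                            continue
                        counts[(a, b)] = counts.get((a, b), 0) + 1
    n_pairs = sum(counts.values())
    p = np.zeros((ng, ng))
    for (a, b), c in counts.items():
        p[a - 1, b - 1] = c / n_pairs
    return p, n_pairs


def brute_glcm_features(p: np.ndarray) -> dict[str, float]:
    """The sixteen GLCM features evaluated entry by entry."""
    ng = p.shape[0]
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng))

    psum = {}
    pdiff = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i][j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i][j]

    def ent(values):
        return -sum(v * math.log2(v) for v in values if v > 0)

    sum_average = sum(k * v for k, v in psum.items())
    mu_d = sum(k * v for k, v in pdiff.items())
    out = {
        "glcm_autocorrelation": sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)),
        "glcm_cluster_prominence": sum(
            (i + j + 2 - mu_x - mu_y) ** 4 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "glcm_cluster_shade": sum(
            (i + j + 2 - mu_x - mu_y) ** 3 * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "glcm_contrast": sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)),
        "glcm_correlation": (
            (sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)) - mu_x * mu_y)
            / math.sqrt(var_x * var_y)
            if var_x * var_y > 0
            else 0.0
        ),
        "glcm_difference_entropy": ent(pdiff.values()),
        "glcm_difference_variance": sum((k - mu_d) ** 2 * v for k, v in pdiff.items()),
        "glcm_dissimilarity": sum(abs(i - j) * p[i][j] for i in range(ng) for j in range(ng)),
        "glcm_energy": sum(p[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "glcm_entropy": ent(p.ravel()),
        "glcm_homogeneity_idm": sum(
            p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
        ),
        "glcm_maximum_probability": max(p[i][j] for i in range(ng) for j in range(ng)),
        "glcm_sum_average": sum_average,
        "glcm_sum_entropy": ent(psum.values()),
        "glcm_sum_variance": sum((k - sum_average) ** 2 * v for k, v in psum.items()),
        "glcm_variance": sum((i + 1 - mu_x) ** 2 * p[i][j] for i in range(ng) for j in range(ng)),
    }
    return {k: float(v) for k, v in out.items()}


def brute_rlm(level_grid: np.ndarray, offsets):
    """Run counts by walking every grid line voxel by voxel.

    Returns (run-count dict {(level, length): n}, n_runs, n_voxels_traversed).
    """
    shape = level_grid.shape
    runs = {}
    n_voxels = 0
    for off in offsets:
        # line starts: voxels with no in-grid predecessor along the offset
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    pi, pj, pk = i - off[0], j - off[1], k - off[2]
                    if 0 <= pi < shape[0] and 0 <= pj < shape[1] and 0 <= pk < shape[2]:
                        continue
                    # walk the line and split into maximal equal-level runs
                    seq = []
                    ci, cj, ck = i, j, k
                    while 0 <= ci < shape[0] and 0 <= cj < shape[1] and 0 <= ck < shape[2]:
                        seq.append(int(level_grid[ci, cj, ck]))
                        ci, cj, ck = ci + off[0], cj + off[1], ck + off[2]
                    run_level, run_len = 0, 0
                    for lev in seq + [0]:
                        if lev != 0:
                            n_voxels += 1
                        if lev == run_level:
                            run_len += 1
                        else:
                            if run_level != 0:
                                runs[(run_level, run_len)] = runs.get((run_level, run_len), 0) + 1
                            run_level, run_len = lev, 1
    n_runs = sum(runs.values())
    return runs, n_runs, n_voxels


def brute_rlm_features(runs: dict, n_runs: int, n_voxels: int) -> dict[str, float]:
    def agg(weight):
        return sum(weight(i, j) * c for (i, j), c in runs.items()) / n_runs

    gl_totals = {}
    len_totals = {}
    for (i, j), c in runs.items():
        gl_totals[i] = gl_totals.get(i, 0) + c
        len_totals[j] = len_totals.get(j, 0) + c
    return {
        "rlm_sre": agg(lambda i, j: 1 / j**2),
        "rlm_lre": agg(lambda i, j: j**2),
        "rlm_gln": sum(v**2 for v in gl_totals.values()) / n_runs,
        "rlm_rln": sum(v**2 for v in len_totals.values()) / n_runs,
        "rlm_rp": n_runs / n_voxels,
        "rlm_lgre": agg(lambda i, j: 1 / i**2),
        "rlm_hgre": agg(lambda i, j: i**2),
        "rlm_srlge": agg(lambda i, j: 1 / (i**2 * j**2)),
        "rlm_srhge": agg(lambda i, j: i**2 / j**2),
        "rlm_lrlge": agg(lambda i, j: j**2 / i**2),
        "rlm_lrhge": agg(lambda i, j: i**2 * j**2),
    }


def brute_auc(scores, labels) -> float:
    """Mann–Whitney probability by explicit pairwise comparison (½ for ties),
    oriented so the area is at least 0.5."""
    scores = list(map(float, scores))
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    auc = total / (len(pos) * len(neg))
    return max(auc, 1.0 - auc)
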