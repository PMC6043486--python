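"""Independent brute-force oracles used to verify the vectorized builders.

Everything here is written as plain nested Python loops (or recursion-free
flood fill) directly from the defining descriptions, deliberately sharing no
code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
DIRECTIONS_13 = [o for o in OFFSETS_26 if o > (0, 0, 0)]


def _inside(shape, x, y, z):
    return 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]


def trilinear_point(values, fx, fy, fz):
    """Direct 8-neighbor weighted sum at fractional index coordinates,
    clamped to the edge."""
    nx, ny, nz = values.shape
    fx = min(max(fx, 0.0), nx - 1.0)
    fy = min(max(fy, 0.0), ny - 1.0)
    fz = min(max(fz, 0.0), nz - 1.0)
    x0, y0, z0 = int(math.floor(fx)), int(math.floor(fy)), int(math.floor(fz))
    x1, y1, z1 = min(x0 + 1, nx - 1), min(y0 + 1, ny - 1), min(z0 + 1, nz - 1)
    tx, ty, tz = fx - x0, fy - y0, fz - z0
    acc = 0.0
    for cx, wx in ((x0, 1 - tx), (x1, tx)):
        for cy, wy in ((y0, 1 - ty), (y1, ty)):
            for cz, wz in ((z0, 1 - tz), (z1, tz)):
                acc += wx * wy * wz * values[cx, cy, cz]
    return acc


def glcm_oracle(grid, directions=None):
    """Triple-loop pair enumeration; returns the direction-averaged
    symmetric probability matrix."""
    dirs = directions if directions is not None else DIRECTIONS_13
    d = int(grid.max())
    shape = grid.shape
    acc = np.zeros((d, d))
    used = 0
    for off in dirs:
        m = np.zeros((d, d))
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if grid[x, y, z] == 0:
                        continue
                    xx, yy, zz = x + off[0], y + off[1], z + off[2]
                    if _inside(shape, xx, yy, zz) and grid[xx, yy, zz] > 0:
                        i, j = grid[x, y, z] - 1, grid[xx, yy, zz] - 1
                        m[i, j] += 1
                        m[j, i] += 1
        if m.sum() > 0:
            acc += m / m.sum()
            used += 1
    if used == 0:
        raise ValueError("no valid pair")
    return acc / used


def glrlm_oracle(grid, directions=None):
    """Walk every lattice line in each direction and record maximal runs.

    Returns dict (level, length) -> count summed over directions.
    """
    dirs = directions if directions is not None else DIRECTIONS_13
    shape = grid.shape
    runs: dict[tuple[int, int], int] = {}
    for off in dirs:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    g = grid[x, y, z]
                    if g == 0:
                        continue
                    # run start: predecessor not a same-level in-mask voxel
                    px, py, pz = x - off[0], y - off[1], z - off[2]
                    if _inside(shape, px, py, pz) and grid[px, py, pz] == g:
                        continue
                    length = 1
                    cx, cy, cz = x + off[0], y + off[1], z + off[2]
                    while _inside(shape, cx, cy, cz) and grid[cx, cy, cz] == g:
                        length += 1
                        cx, cy, cz = cx + off[0], cy + off[1], cz + off[2]
                    runs[(g, length)] = runs.get((g, length), 0) + 1
    return runs


def glszm_oracle(grid):
    """Iterative flood fill over 26-connected equal-level zones.

    Returns dict (level, size) -> count.
    """
    shape = grid.shape
    seen = np.zeros(shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = grid[x, y, z]
                if g == 0 or seen[x, y, z]:
                    continue
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for off in OFFSETS_26:
                        nx_, ny_, nz_ = cx + off[0], cy + off[1], cz + off[2]
                        if (_inside(shape, nx_, ny_, nz_) and not seen[nx_, ny_, nz_]
                                and grid[nx_, ny_, nz_] == g):
                            seen[nx_, ny_, nz_] = True
                            stack.append((nx_, ny_, nz_))
                zones[(g, size)] = zones.get((g, size), 0) + 1
    return zones


def ngtdm_oracle(grid, d):
    """Per-voxel neighborhood scan; returns (n_i, s_i, n_valid) arrays."""
    shape = grid.shape
    n = np.zeros(d)
    s = np.zeros(d)
    n_valid = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = grid[x, y, z]
                if g == 0:
                    continue
                nbrs = []
                for off in OFFSETS_26:
                    nx_, ny_, nz_ = x + off[0], y + off[1], z + off[2]
                    if _inside(shape, nx_, ny_, nz_) and grid[nx_, ny_, nz_] > 0:
                        nbrs.append(grid[nx_, ny_, nz_])
                if not nbrs:
                    continue
                n_valid += 1
                n[g - 1] += 1
                s[g - 1] += abs(g - sum(nbrs) / len(nbrs))
    return n, s, n_valid


# --- feature-formula oracles (direct summation over the matrices) -----------

def glcm_features_oracle(p):
    d = p.shape[0]
    ent = sum_avg = dis = mean = con = inv = 0.0
    psum = {k: 0.0 for k in range(2, 2 * d + 1)}
    pdiff = {k: 0.0 for k in range(0, d)}
    for i in range(1, d + 1):
        for j in range(1, d + 1):
            v = p[i - 1, j - 1]
            psum[i + j] += v
            pdiff[abs(i - j)] += v
            if v > 0:
                ent -= v * math.log2(v)
            dis += abs(i - j) * v
            mean += i * v
            con += (i - j) ** 2 * v
            if i != j:
                inv += v / (i - j) ** 2
    sum_ent = -sum(v * math.log2(v) for v in psum.values() if v > 0)
    diff_ent = -sum(v * math.log2(v) for v in pdiff.values() if v > 0)
    sum_avg = sum(k * v for k, v in psum.items())
    diff_avg = sum(k * v for k, v in pdiff.items())
    sum_var = sum((k - sum_avg) ** 2 * v for k, v in psum.items())
    diff_var = sum((k - diff_avg) ** 2 * v for k, v in pdiff.items())
    return {
        "GLCM-Entropy": ent,
        "GLCM-Sum Entropy": sum_ent,
        "GLCM-Difference Entropy": diff_ent,
        "GLCM-Sum Average": sum_avg,
        "GLCM-Difference Average": diff_avg,
        "GLCM-Dissimilarity": dis,
        "GLCM-Sum Variance": sum_var,
        "GLCM-Difference Variance": diff_var,
        "GLCM-Mean": mean,
        "GLCM-Contrast": con,
        "GLCM-Inverse Variance": inv,
    }


def glrlm_features_oracle(runs):
    """From a dict (level, length) -> count."""
    n_runs = sum(runs.values())
    by_level: dict[int, float] = {}
    by_length: dict[int, float] = {}
    hgre = srhge = 0.0
    for (g, l), c in runs.items():
        by_level[g] = by_level.get(g, 0) + c
        by_length[l] = by_length.get(l, 0) + c
        hgre += c * g ** 2
        srhge += c * g ** 2 / l ** 2
    return {
        "GLRLM-GLNU": sum(v ** 2 for v in by_level.values()) / n_runs,
        "GLRLM-RLNU": sum(v ** 2 for v in by_length.values()) / n_runs,
        "GLRLM-HGRE": hgre / n_runs,
        "GLRLM-SRHGE": srhge / n_runs,
    }


def glszm_features_oracle(zones):
    n_zones = sum(zones.values())
    hie = sum(c * g ** 2 for (g, _), c in zones.items())
    return {"GLSZM-HIE": hie / n_zones}


def ngtdm_features_oracle(n, s, n_valid, eps=1e-6):
    d = len(n)
    p = [ni / n_valid for ni in n]
    occ = [i for i in range(d) if n[i] > 0]
    coarse = 1.0 / (eps + sum(p[i] * s[i] for i in range(d)))
    ngp = len(occ)
    if ngp > 1:
        con = (
            sum(p[i] * p[j] * ((i - j) ** 2) for i in occ for j in occ)
            / (ngp * (ngp - 1))
        ) * (sum(s) / n_valid)
    else:
        con = 0.0
    comp = sum(
        abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
        for i in occ for j in occ
    ) / n_valid
    strength = sum((p[i] + p[j]) * (i - j) ** 2 for i in occ for j in occ) / (eps + sum(s))
    return {
        "NGTDM-Contrast": con,
        "NGTDM-Complexity": comp,
        "NGTDM-Coarseness": coarse,
        "NGTDM-Texture Strength": strength,
    }


def intensity_features_oracle(grid):
    """Direct-loop intensity features on a level-valued grid (0 = outside)."""
    shape = grid.shape
    vals = [float(grid[x, y, z]) for x in range(shape[0]) for y in range(shape[1])
            for z in range(shape[2]) if grid[x, y, z] > 0]
    n = len(vals)
    energy = sum(v * v for v in vals)
    lo, hi = min(vals), max(vals)
    if hi == lo:
        entropy = 0.0
    else:
        counts = [0] * 64
        for v in vals:
            b = int(64 * (v - lo) / (hi - lo))
            counts[min(b, 63)] += 1
        entropy = -sum(
            (c / n) * math.log2(c / n) for c in counts if c > 0
        )
    tgv = 0.0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if grid[x, y, z] == 0:
                    continue
                for off in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                            (0, 0, 1), (0, 0, -1)):
                    xx, yy, zz = x + off[0], y + off[1], z + off[2]
                    if _inside(shape, xx, yy, zz) and grid[xx, yy, zz] > 0:
                        tgv += abs(float(grid[x, y, z]) - float(grid[xx, yy, zz]))
    return {
        "Intensity-TGV": tgv,
        "Intensity-Energy": energy,
        "Intensity-Entropy": entropy,
        "Intensity-Contrast": hi - lo,
    }


def icc_oracle(table, model="oneway"):
    """From-scratch sum-of-squares arithmetic for (BMS-RMS)/(BMS+(d-1)RMS)."""
    table = [list(map(float, row)) for row in table]
    n = len(table)
    d = len(table[0])
    total = sum(sum(row) for row in table)
    grand = total / (n * d)
    row_means = [sum(row) / d for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(d)]
    ss_tot = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(d))
    ss_rows = d * sum((m - grand) ** 2 for m in row_means)
    bms = ss_rows / (n - 1)
    if model == "oneway":
        ss_within = sum(
            (table[i][j] - row_means[i]) ** 2 for i in range(n) for j in range(d)
        )
        rms = ss_within / (n * (d - 1))
    else:
        ss_cols = n * sum((m - grand) ** 2 for m in col_means)
        ss_res = ss_tot - ss_rows - ss_cols
        rms = max(ss_res, 0.0) / ((n - 1) * (d - 1))
    if rms == 0.0:
        return 1.0
    return (bms - rms) / (bms + (d - 1) * rms)


def random_level_grid(rng, shape=(5, 5, 3), d=4, mask_p=1.0):
    """Random discretized grid: levels 1..d inside a random mask, 0 outside."""
    grid = rng.integers(1, d + 1, size=shape).astype(np.int32)
    if mask_p < 1.0:
        mask = rng.random(shape) < mask_p
        if not mask.any():
            mask.flat[rng.integers(0, mask.size)] = True
        grid[~mask] = 0
    return grid
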