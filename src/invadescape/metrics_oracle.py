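"""Brute-force reference implementations of every landscape-metric family.

Each function here recomputes a metric directly from its definition with
naive loops (flood-fill labeling, per-cell adjacency tallies, explicit
pair/triple enumeration for the smallest enclosing circle), deliberately
sharing no code with :mod:`invadescape.metrics`. They are slow and only
meant for small rasters; the test suite and the acceptance checks compare
the fast implementations against these on random rasters.

Degenerate-input conventions (single-class contagion/IJI, two-class IJI,
ENN imputation, PAFRAC imputation) intentionally match the documented
conventions of the fast path so the comparison is meaningful everywhere.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import ConvexHull

from . import habitat
from .landscapes import LandscapeRaster
from .metrics import METRIC_NAMES

__all__ = ["oracle_metric_vector"]


def _flood_fill_patches(grid: np.ndarray, connectivity: int) -> list[dict]:
    """Label patches by explicit BFS; returns per-patch dicts of cells."""
    nr, nc = grid.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1),
                (-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros(grid.shape, dtype=bool)
    patches = []
    for r0 in range(nr):
        for c0 in range(nc):
            if seen[r0, c0]:
                continue
            code = grid[r0, c0]
            stack = [(r0, c0)]
            seen[r0, c0] = True
            cells = []
            while stack:
                r, c = stack.pop()
                cells.append((r, c))
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < nr and 0 <= cc < nc and not seen[rr, cc]
                            and grid[rr, cc] == code):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            patches.append({"class": int(code), "cells": cells})
    return patches


def _perimeter_edges(grid: np.ndarray, cells: list[tuple[int, int]]) -> int:
    """Count cell edges facing a different patch... by definition: edges of
    the patch's cells not shared with another cell of the same patch."""
    nr, nc = grid.shape
    cellset = set(cells)
    edges = 0
    for r, c in cells:
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            if (r + dr, c + dc) not in cellset:
                edges += 1
    return edges


def _min_perim(n: int) -> int:
    m = int(math.isqrt(n))
    if m * m == n:
        return 4 * m
    if n <= m * (m + 1):
        return 4 * m + 2
    return 4 * m + 4


def _circumcircle(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
          + (cx * cx + cy * cy) * (ay - by)) / d
    uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
          + (cx * cx + cy * cy) * (bx - ax)) / d
    r = math.hypot(ax - ux, ay - uy)
    return (ux, uy, r)


def _smallest_circle_radius(points: np.ndarray) -> float:
    """Exact smallest enclosing circle by enumerating hull pairs/triples."""
    pts = np.unique(points, axis=0).astype(float)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 3:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # collinear points
            pass
    n = len(pts)
    best = None
    eps = 1e-9

    def contains_all(cx, cy, r):
        for px, py in pts:
            if math.hypot(px - cx, py - cy) > r + eps:
                return False
        return True

    for i in range(n):
        for j in range(i + 1, n):
            cx, cy = (pts[i] + pts[j]) / 2.0
            r = math.hypot(*(pts[i] - pts[j])) / 2.0
            if contains_all(cx, cy, r) and (best is None or r < best):
                best = r
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                circ = _circumcircle(pts[i], pts[j], pts[k])
                if circ is None:
                    continue
                cx, cy, r = circ
                if (best is None or r < best) and contains_all(cx, cy, r):
                    best = r
    return best if best is not None else 0.0


def _weighted_mean_median_sd(values, weights):
    values = [v for v in values]
    am = sum(v * w for v, w in zip(values, weights)) / sum(weights)
    s = sorted(values)
    n = len(s)
    md = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2.0
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / n)
    return am, md, sd


def oracle_metric_vector(raster: LandscapeRaster,
                         connectivity: int = 8) -> np.ndarray:
    """Recompute the full 50-metric vector from first principles."""
    grid = np.asarray(raster.grid)
    cell = raster.cell_size_m
    nr, nc = grid.shape
    n_cells = nr * nc
    total_ha = n_cells * cell * cell / 1e4
    out: dict[str, float] = {}

    # composition
    for code, name in enumerate(METRIC_NAMES[:11]):
        out[name] = sum(
            1 for r in range(nr) for c in range(nc) if grid[r, c] == code
        ) / n_cells

    patches = _flood_fill_patches(grid, connectivity)
    for p in patches:
        p["n"] = len(p["cells"])
        p["perim_edges"] = _perimeter_edges(grid, p["cells"])
        p["area_ha"] = p["n"] * cell * cell / 1e4

    out["np"] = float(len(patches))
    out["pd"] = len(patches) / total_ha * 100.0
    out["lpi"] = 100.0 * max(p["area_ha"] for p in patches) / total_ha

    te = 0
    for r in range(nr):
        for c in range(nc):
            if c + 1 < nc and grid[r, c] != grid[r, c + 1]:
                te += 1
            if r + 1 < nr and grid[r, c] != grid[r + 1, c]:
                te += 1
    out["te"] = te * cell
    out["ed"] = te * cell / total_ha

    weights = [float(p["n"]) for p in patches]

    def fill(prefix, values):
        am, md, sd = _weighted_mean_median_sd(values, weights)
        out[prefix + "_am"], out[prefix + "_md"], out[prefix + "_sd"] = am, md, sd

    fill("area", [p["area_ha"] for p in patches])

    gyr = []
    for p in patches:
        cy = sum(r for r, _ in p["cells"]) / p["n"]
        cx = sum(c for _, c in p["cells"]) / p["n"]
        gyr.append(
            sum(math.hypot(r - cy, c - cx) for r, c in p["cells"]) / p["n"] * cell
        )
    fill("gyrate", gyr)

    fill("shape", [p["perim_edges"] / _min_perim(p["n"]) for p in patches])

    frac = []
    for p in patches:
        pm = p["perim_edges"] * cell
        am = p["n"] * cell * cell
        frac.append(1.0 if am == 1.0 else 2.0 * math.log(0.25 * pm) / math.log(am))
    fill("frac", frac)

    fill("para", [p["perim_edges"] * cell / (p["n"] * cell * cell)
                  for p in patches])

    circ = []
    for p in patches:
        corners = []
        for r, c in p["cells"]:
            corners.extend([(r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)])
        radius = _smallest_circle_radius(np.array(corners, dtype=float))
        circ.append(1.0 - p["n"] / (math.pi * radius * radius))
    fill("circle", circ)

    contig = []
    for p in patches:
        cellset = set(p["cells"])
        tot = 0.0
        for r, c in p["cells"]:
            v = 1.0
            for dr, dc, w in ((-1, 0, 2), (1, 0, 2), (0, -1, 2), (0, 1, 2),
                              (-1, -1, 1), (-1, 1, 1), (1, -1, 1), (1, 1, 1)):
                if (r + dr, c + dc) in cellset:
                    v += w
            tot += v
        contig.append((tot / p["n"] - 1.0) / 12.0)
    fill("contig", contig)

    # PAFRAC: 2 x OLS slope of ln(perimeter) on ln(area)
    if len(patches) < 2:
        out["pafrac"] = 1.0
    else:
        xs = [math.log(p["n"] * cell * cell) for p in patches]
        ys = [math.log(p["perim_edges"] * cell) for p in patches]
        mx = sum(xs) / len(xs)
        my = sum(ys) / len(ys)
        sxx = sum((x - mx) ** 2 for x in xs)
        if sxx == 0:
            out["pafrac"] = 1.0
        else:
            sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
            out["pafrac"] = 2.0 * sxy / sxx

    # ENN: min center-to-center distance to another patch of the same class
    enn_vals, enn_w = [], []
    for i, p in enumerate(patches):
        best = None
        for j, q in enumerate(patches):
            if i == j or q["class"] != p["class"]:
                continue
            for r1, c1 in p["cells"]:
                for r2, c2 in q["cells"]:
                    d = math.hypot(r1 - r2, c1 - c2)
                    if best is None or d < best:
                        best = d
        if best is not None:
            enn_vals.append(best * cell)
            enn_w.append(float(p["n"]))
    if enn_vals:
        am, md, sd = _weighted_mean_median_sd(enn_vals, enn_w)
    else:
        diag = math.hypot(nr, nc) * cell
        am, md, sd = diag, diag, 0.0
    out["enn_am"], out["enn_md"], out["enn_sd"] = am, md, sd

    # adjacency tallies (double count) by explicit cell loops
    mcl = habitat.N_CLASSES
    g = [[0.0] * mcl for _ in range(mcl)]
    for r in range(nr):
        for c in range(nc):
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < nr and cc < nc:
                    a, b = int(grid[r, c]), int(grid[rr, cc])
                    g[a][b] += 1
                    g[b][a] += 1

    counts = [0] * mcl
    for r in range(nr):
        for c in range(nc):
            counts[int(grid[r, c])] += 1
    present = [i for i in range(mcl) if counts[i] > 0]
    m = len(present)

    total_adj = sum(sum(row) for row in g)
    like = sum(g[i][i] for i in range(mcl))
    out["pladj"] = 100.0 * like / total_adj if total_adj else 100.0

    if m < 2:
        out["contag"] = 100.0
    else:
        acc = 0.0
        for i in present:
            pi = counts[i] / n_cells
            row = sum(g[i][k] for k in present)
            for k in present:
                if g[i][k] > 0:
                    q = pi * g[i][k] / row
                    acc += q * math.log(q)
        out["contag"] = 100.0 * (1.0 + acc / (2.0 * math.log(m)))

    if m < 2:
        out["iji"] = 0.0
    elif m == 2:
        out["iji"] = 100.0
    else:
        e, etot = {}, 0.0
        for ii, i in enumerate(present):
            for k in present[ii + 1:]:
                e[(i, k)] = g[i][k] / 2.0
                etot += g[i][k] / 2.0
        h = sum((v / etot) * math.log(v / etot) for v in e.values() if v > 0)
        out["iji"] = 100.0 * (-h) / math.log(0.5 * m * (m - 1))

    out["pr"] = float(m)
    props = [counts[i] / n_cells for i in present]
    out["shdi"] = -sum(p * math.log(p) for p in props)
    out["sidi"] = 1.0 - sum(p * p for p in props)
    out["shei"] = out["shdi"] / math.log(m) if m > 1 else 0.0
    out["siei"] = out["sidi"] / (1.0 - 1.0 / m) if m > 1 else 0.0

    ai = 0.0
    for i in present:
        n = counts[i]
        mm = int(math.isqrt(n))
        rem = n - mm * mm
        if rem == 0:
            gmax = 2 * mm * (mm - 1)
        elif rem <= mm:
            gmax = 2 * mm * (mm - 1) + 2 * rem - 1
        else:
            gmax = 2 * mm * (mm - 1) + 2 * rem - 2
        if gmax > 0:
            ai += (n / n_cells) * (g[i][i] / 2.0) / gmax
    out["ai"] = 100.0 * ai

    return np.array([out[name] for name in METRIC_NAMES])
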