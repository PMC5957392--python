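"""FRAGSTATS-style landscape pattern metrics.

Computes the 50-entry metric vector characterizing one categorical raster:
11 composition proportions followed by 39 landscape-level spatial structure
metrics (patch counts and size distributions, shape, connectivity,
aggregation and diversity families). Definitions follow the standard
FRAGSTATS v4 conventions: 8-neighbor patch delineation, 4-neighbor
adjacency tallies with the double-count method, areas in hectares, edge
density in m/ha, percent metrics in [0, 100]. The landscape boundary is not
counted as edge (patch perimeters, however, do include raster-edge
segments). Core-area and contrast families are deliberately out of scope.

Degenerate inputs are imputed rather than dropped so every raster yields a
complete 50-vector for the downstream regression; each imputation raises a
named flag (ENN with no same-class patch pair -> raster diagonal; contagion
with one class -> 100; IJI with fewer than three classes -> 0 or 100; SD of
a single patch -> 0; PAFRAC with degenerate regression -> 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, cKDTree

from . import habitat
from .errors import ConfigurationError, DimensionError
from .landscapes import LandscapeRaster

__all__ = [
    "PatchMap",
    "MetricVector",
    "METRIC_NAMES",
    "COMPOSITION_NAMES",
    "DISTRIBUTION_QUANTITIES",
    "label_patches",
    "composition_proportions",
    "patch_distribution_stats",
    "aggregation_metrics",
    "diversity_metrics",
    "compute_metric_vector",
]

COMPOSITION_NAMES: tuple[str, ...] = tuple(
    "prop_" + name.replace(" ", "_") for name in habitat.CLASS_NAMES
)

METRIC_NAMES: tuple[str, ...] = COMPOSITION_NAMES + (
    "np", "pd", "lpi", "te", "ed",
    "area_am", "area_md", "area_sd",
    "gyrate_am", "gyrate_md", "gyrate_sd",
    "shape_am", "shape_md", "shape_sd",
    "frac_am", "frac_md", "frac_sd",
    "para_am", "para_md", "para_sd",
    "circle_am", "circle_md", "circle_sd",
    "contig_am", "contig_md", "contig_sd",
    "pafrac",
    "enn_am", "enn_md", "enn_sd",
    "contag", "pladj", "iji",
    "pr", "shdi", "sidi", "shei", "siei",
    "ai",
)

assert len(METRIC_NAMES) == 50

DISTRIBUTION_QUANTITIES = (
    "area", "radius_of_gyration", "shape_index", "fractal_index",
    "perim_area_ratio", "circumscribing_circle", "contiguity", "euclidean_nn",
)

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass
class PatchMap:
    """Patch delineation of one raster: per-cell labels plus a patch table.

    ``labels`` holds 1-based patch ids in row-major first-occurrence order;
    ``patch_class``, ``cell_count`` and ``perimeter_edges`` are aligned
    per-patch arrays (perimeter in cell-edge counts, raster boundary
    included, as FRAGSTATS defines patch perimeter).
    """

    labels: np.ndarray
    patch_class: np.ndarray
    cell_count: np.ndarray
    perimeter_edges: np.ndarray
    connectivity: int
    cell_size_m: float

    @property
    def n_patches(self) -> int:
        return len(self.patch_class)

    @property
    def n_cells(self) -> int:
        return int(self.labels.size)


def label_patches(raster: LandscapeRaster, connectivity: int = 8) -> PatchMap:
    """Delineate patches: maximal connected same-class regions.

    Labels are assigned in row-major order of each patch's first cell, so
    the labeling is deterministic for a given raster and neighborhood rule.
    """
    if connectivity == 4:
        structure = _STRUCTURE_4
    elif connectivity == 8:
        structure = _STRUCTURE_8
    else:
        raise ConfigurationError("connectivity must be 4 or 8")
    grid = raster.grid
    if grid.size == 0:
        raise DimensionError("raster is empty")

    combined = np.zeros(grid.shape, dtype=np.int64)
    offset = 0
    for code in np.unique(grid):
        lab, n = ndimage.label(grid == code, structure=structure)
        combined[lab > 0] = lab[lab > 0] + offset
        offset += n

    # relabel by row-major first occurrence
    flat = combined.ravel()
    _, first_idx = np.unique(flat, return_index=True)
    order = np.argsort(first_idx)
    old_ids = flat[np.sort(first_idx)][order]  # unique ids ordered by first cell
    remap = np.zeros(offset + 1, dtype=np.int64)
    remap[old_ids] = np.arange(1, offset + 1)
    labels = remap[combined]

    counts = np.bincount(labels.ravel(), minlength=offset + 1)[1:]
    patch_class = np.zeros(offset, dtype=np.int64)
    patch_class[labels.ravel() - 1] = grid.ravel()

    # perimeter = 4*n - 2*(internal same-patch 4-adjacencies)
    same_h = labels[:, :-1] == labels[:, 1:]
    same_v = labels[:-1, :] == labels[1:, :]
    internal = (
        np.bincount(labels[:, :-1][same_h].ravel(), minlength=offset + 1)
        + np.bincount(labels[:-1, :][same_v].ravel(), minlength=offset + 1)
    )[1:]
    perimeter = 4 * counts - 2 * internal

    return PatchMap(labels, patch_class, counts, perimeter,
                    connectivity, raster.cell_size_m)


def composition_proportions(raster: LandscapeRaster) -> np.ndarray:
    """The 11 class proportions in registry order; sums to exactly 1."""
    return raster.class_proportions()


# ---------------------------------------------------------------------------
# per-patch quantities
# ---------------------------------------------------------------------------

def _patch_cells(pm: PatchMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rr, cc = np.nonzero(pm.labels > 0)
    return pm.labels[rr, cc] - 1, rr, cc


def patch_area_ha(pm: PatchMap) -> np.ndarray:
    return pm.cell_count * pm.cell_size_m**2 / 1e4


def patch_gyration_m(pm: PatchMap) -> np.ndarray:
    """Mean distance (m) of each patch's cell centers from its centroid."""
    lab, rr, cc = _patch_cells(pm)
    n = pm.n_patches
    cy = np.bincount(lab, weights=rr, minlength=n) / pm.cell_count
    cx = np.bincount(lab, weights=cc, minlength=n) / pm.cell_count
    d = np.hypot(rr - cy[lab], cc - cx[lab])
    return np.bincount(lab, weights=d, minlength=n) / pm.cell_count * pm.cell_size_m


def _min_perimeter_edges(n: np.ndarray) -> np.ndarray:
    """Smallest cell-edge perimeter achievable by an n-cell raster patch."""
    m = np.floor(np.sqrt(n)).astype(np.int64)
    out = np.where(
        m * m == n, 4 * m,
        np.where(n <= m * (m + 1), 4 * m + 2, 4 * m + 4),
    )
    return out


def patch_shape_index(pm: PatchMap) -> np.ndarray:
    return pm.perimeter_edges / _min_perimeter_edges(pm.cell_count)


def patch_fractal_index(pm: PatchMap) -> np.ndarray:
    p = pm.perimeter_edges * pm.cell_size_m
    a = pm.cell_count * pm.cell_size_m**2
    ln_a = np.log(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 2.0 * np.log(0.25 * p) / ln_a
    return np.where(ln_a == 0, 1.0, frac)


def patch_para(pm: PatchMap) -> np.ndarray:
    """Perimeter (m) to area (m^2) ratio per patch."""
    return (pm.perimeter_edges * pm.cell_size_m) / (
        pm.cell_count * pm.cell_size_m**2
    )


def _welzl(points: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Smallest enclosing circle of 2-D points (Welzl, move-to-front)."""

    def circle_two(a, b):
        c = (a + b) / 2.0
        return c, float(np.hypot(*(a - c)))

    def circle_three(a, b, c):
        ax, ay = a
        bx, by = b
        cx, cy = c
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            return None
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
        ctr = np.array([ux, uy])
        return ctr, float(np.hypot(*(a - ctr)))

    def contains(circle, p, eps=1e-9):
        ctr, r = circle
        return np.hypot(*(p - ctr)) <= r + eps

    pts = points[rng.permutation(len(points))]
    circ = (pts[0].astype(float), 0.0)
    for i in range(1, len(pts)):
        if contains(circ, pts[i]):
            continue
        circ = (pts[i].astype(float), 0.0)
        for j in range(i):
            if contains(circ, pts[j]):
                continue
            circ = circle_two(pts[i], pts[j])
            for k in range(j):
                if contains(circ, pts[k]):
                    continue
                c3 = circle_three(pts[i], pts[j], pts[k])
                if c3 is not None:
                    circ = c3
    return circ


def patch_circle(pm: PatchMap) -> np.ndarray:
    """Related circumscribing circle: 1 - area / smallest enclosing circle.

    The circle is fitted to the patch's cell corners; larger values mean
    more elongated patches.
    """
    lab, rr, cc = _patch_cells(pm)
    out = np.zeros(pm.n_patches)
    rng = np.random.default_rng(12345)  # interior algorithmic shuffle only
    for p in range(pm.n_patches):
        sel = lab == p
        r, c = rr[sel], cc[sel]
        corners = np.unique(np.stack([
            np.concatenate([r, r, r + 1, r + 1]),
            np.concatenate([c, c + 1, c, c + 1]),
        ], axis=1), axis=0).astype(float)
        if len(corners) > 16:
            hull = ConvexHull(corners)
            corners = corners[hull.vertices]
        _, radius = _welzl(corners, rng)
        a_circle = math.pi * radius**2
        out[p] = 1.0 - pm.cell_count[p] / a_circle
    return out


_CONTIG_OFFSETS = (
    (-1, 0, 2.0), (1, 0, 2.0), (0, -1, 2.0), (0, 1, 2.0),
    (-1, -1, 1.0), (-1, 1, 1.0), (1, -1, 1.0), (1, 1, 1.0),
)


def patch_contiguity(pm: PatchMap) -> np.ndarray:
    """Contiguity index per patch (3x3 template: center 1, rook 2, diag 1).

    A one-cell patch scores 0; a large solid block approaches 1.
    """
    lab = pm.labels
    value = np.ones(lab.shape)  # center weight
    for dr, dc, w in _CONTIG_OFFSETS:
        shifted = np.full(lab.shape, -1, dtype=np.int64)
        rs = slice(max(dr, 0), lab.shape[0] + min(dr, 0))
        rd = slice(max(-dr, 0), lab.shape[0] + min(-dr, 0))
        cs = slice(max(dc, 0), lab.shape[1] + min(dc, 0))
        cd = slice(max(-dc, 0), lab.shape[1] + min(-dc, 0))
        shifted[rd, cd] = lab[rs, cs]
        value += w * (shifted == lab)
    lab_flat = lab.ravel() - 1
    sums = np.bincount(lab_flat, weights=value.ravel(), minlength=pm.n_patches)
    template_sum = 1.0 + sum(w for _, _, w in _CONTIG_OFFSETS)  # = 13
    return (sums / pm.cell_count - 1.0) / (template_sum - 1.0)


def _boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Cells on a patch boundary (some 4-neighbor differs or raster edge)."""
    b = np.zeros(labels.shape, dtype=bool)
    b[0, :] = b[-1, :] = b[:, 0] = b[:, -1] = True
    b[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    b[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    b[1:, :] |= labels[1:, :] != labels[:-1, :]
    b[:-1, :] |= labels[:-1, :] != labels[1:, :]
    return b


def patch_enn_m(pm: PatchMap) -> np.ndarray:
    """Euclidean nearest-neighbor distance (m, cell centers) per patch.

    NaN for patches whose class has no second patch.
    """
    out = np.full(pm.n_patches, np.nan)
    boundary = _boundary_mask(pm.labels)
    for code in np.unique(pm.patch_class):
        ids = np.nonzero(pm.patch_class == code)[0]
        if len(ids) < 2:
            continue
        cells = []
        for p in ids:
            mask = (pm.labels == p + 1) & boundary
            cells.append(np.argwhere(mask))
        for i, p in enumerate(ids):
            others = np.concatenate([c for j, c in enumerate(cells) if j != i])
            tree = cKDTree(others)
            d, _ = tree.query(cells[i])
            out[p] = float(np.min(d)) * pm.cell_size_m
    return out


_QUANTITY_FUNCS = {
    "area": patch_area_ha,
    "radius_of_gyration": patch_gyration_m,
    "shape_index": patch_shape_index,
    "fractal_index": patch_fractal_index,
    "perim_area_ratio": patch_para,
    "circumscribing_circle": patch_circle,
    "contiguity": patch_contiguity,
    "euclidean_nn": patch_enn_m,
}


def patch_distribution_stats(pm: PatchMap, quantity: str
                             ) -> tuple[float, float, float]:
    """(area-weighted mean, median, population SD) of a per-patch quantity.

    For ``euclidean_nn``, patches without a same-class neighbor are excluded
    from the distribution; when no patch has one, all three summaries are
    NaN (imputed by :func:`compute_metric_vector`).
    """
    if quantity not in _QUANTITY_FUNCS:
        raise ConfigurationError(f"unknown patch quantity {quantity!r}")
    if pm.n_patches == 0:
        raise DimensionError("patch map has no patches")
    values = _QUANTITY_FUNCS[quantity](pm)
    weights = pm.cell_count.astype(float)
    defined = ~np.isnan(values)
    if not defined.any():
        return (math.nan, math.nan, math.nan)
    v, w = values[defined], weights[defined]
    am = float((v * w).sum() / w.sum())
    md = float(np.median(v))
    sd = float(np.std(v))
    return am, md, sd


# ---------------------------------------------------------------------------
# adjacency-based aggregation metrics
# ---------------------------------------------------------------------------

def _adjacency_matrix(grid: np.ndarray) -> np.ndarray:
    """Double-count 4-neighbor class adjacency tallies g[i, k]."""
    m = habitat.N_CLASSES
    g = np.zeros((m, m))
    a = grid[:, :-1].ravel()
    b = grid[:, 1:].ravel()
    np.add.at(g, (a, b), 1)
    np.add.at(g, (b, a), 1)
    a = grid[:-1, :].ravel()
    b = grid[1:, :].ravel()
    np.add.at(g, (a, b), 1)
    np.add.at(g, (b, a), 1)
    return g


def _max_like_adjacencies(n: int) -> int:
    """Largest single-count like-adjacency tally an n-cell class can reach."""
    m = int(math.isqrt(n))
    rem = n - m * m
    if rem == 0:
        return 2 * m * (m - 1)
    if rem <= m:
        return 2 * m * (m - 1) + 2 * rem - 1
    return 2 * m * (m - 1) + 2 * rem - 2


def aggregation_metrics(raster: LandscapeRaster,
                        patch_map: PatchMap | None = None) -> dict[str, float]:
    """Contagion, PLADJ, IJI and AI, all in percent.

    Conventions for degenerate rasters: one class present -> contagion 100,
    IJI 0; exactly two classes -> IJI 100 (the single class pair is
    trivially evenly interspersed). Single-cell classes contribute zero to
    AI with their area weight retained.
    """
    grid = raster.grid
    g = _adjacency_matrix(grid)
    counts = np.bincount(grid.ravel(), minlength=habitat.N_CLASSES)
    present = np.nonzero(counts)[0]
    m = len(present)
    total_adj = g.sum()

    pladj = 100.0 * np.trace(g) / total_adj if total_adj else 100.0

    if m < 2:
        contag = 100.0
    else:
        p = counts[present] / counts.sum()
        rows = g[np.ix_(present, present)]
        row_sums = rows.sum(axis=1, keepdims=True)
        q = p[:, None] * rows / row_sums
        nz = q > 0
        entropy = float((q[nz] * np.log(q[nz])).sum())
        contag = 100.0 * (1.0 + entropy / (2.0 * math.log(m)))

    if m < 2:
        iji = 0.0
    elif m == 2:
        iji = 100.0
    else:
        e = np.triu(g[np.ix_(present, present)], k=1) / 2.0  # single count
        etot = e.sum()
        nz = e > 0
        h = float((e[nz] / etot * np.log(e[nz] / etot)).sum())
        iji = 100.0 * (-h) / math.log(0.5 * m * (m - 1))

    ai_sum = 0.0
    area_total = counts.sum()
    for code in present:
        gmax = _max_like_adjacencies(int(counts[code]))
        if gmax > 0:
            ai_sum += (counts[code] / area_total) * (g[code, code] / 2.0) / gmax
    ai = 100.0 * ai_sum

    return {
        "contagion": float(contag),
        "percentage_like_adjacencies": float(pladj),
        "interspersion_juxtaposition": float(iji),
        "aggregation_index": float(ai),
    }


def diversity_metrics(raster: LandscapeRaster) -> dict[str, float]:
    """Richness, Shannon/Simpson diversity and their evenness forms."""
    props = raster.class_proportions()
    p = props[props > 0]
    pr = len(p)
    shdi = float(-(p * np.log(p)).sum())
    sidi = float(1.0 - (p**2).sum())
    shei = shdi / math.log(pr) if pr > 1 else 0.0
    siei = sidi / (1.0 - 1.0 / pr) if pr > 1 else 0.0
    return {
        "patch_richness": float(pr),
        "shannon_diversity": shdi,
        "simpson_diversity": sidi,
        "shannon_evenness": float(shei),
        "simpson_evenness": float(siei),
    }


@dataclass
class MetricVector:
    """The ordered 50-metric characterization of one raster.

    ``flags`` records which entries were imputed under a degenerate-input
    convention (and the PAFRAC low-confidence flag), keyed by metric name.
    """

    values: np.ndarray
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (50,):
            raise DimensionError("metric vector must have exactly 50 entries")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(METRIC_NAMES))

    def __getitem__(self, name: str) -> float:
        return float(self.values[METRIC_NAMES.index(name)])


def _pafrac(pm: PatchMap) -> tuple[float, str | None]:
    """2 x OLS slope of ln(perimeter) on ln(area) over all patches."""
    if pm.n_patches < 2:
        return 1.0, "imputed_single_patch"
    ln_a = np.log(pm.cell_count * pm.cell_size_m**2)
    ln_p = np.log(pm.perimeter_edges * pm.cell_size_m)
    var = np.var(ln_a)
    if var == 0:
        return 1.0, "imputed_degenerate_regression"
    slope = float(np.cov(ln_a, ln_p, bias=True)[0, 1] / var)
    flag = "low_confidence_lt10_patches" if pm.n_patches < 10 else None
    return 2.0 * slope, flag


def compute_metric_vector(raster: LandscapeRaster,
                          connectivity: int = 8) -> MetricVector:
    """Compute all 50 metrics in registry order for one raster."""
    pm = label_patches(raster, connectivity)
    flags: dict[str, str] = {}
    vals: list[float] = list(composition_proportions(raster))

    total_ha = raster.n_cells * raster.cell_size_m**2 / 1e4
    areas = patch_area_ha(pm)

    vals.append(float(pm.n_patches))                       # np
    vals.append(pm.n_patches / total_ha * 100.0)           # pd per 100 ha
    vals.append(100.0 * float(areas.max()) / total_ha)     # lpi

    # total edge: single-count different-class 4-adjacencies, no boundary
    grid = raster.grid
    diff_h = int((grid[:, :-1] != grid[:, 1:]).sum())
    diff_v = int((grid[:-1, :] != grid[1:, :]).sum())
    te = (diff_h + diff_v) * raster.cell_size_m
    vals.append(te)                                        # te (m)
    vals.append(te / total_ha)                             # ed (m/ha)

    for quantity in ("area", "radius_of_gyration", "shape_index",
                     "fractal_index", "perim_area_ratio",
                     "circumscribing_circle", "contiguity"):
        vals.extend(patch_distribution_stats(pm, quantity))

    pafrac, pafrac_flag = _pafrac(pm)
    if pafrac_flag:
        flags["pafrac"] = pafrac_flag
    vals.append(pafrac)

    enn = patch_distribution_stats(pm, "euclidean_nn")
    if math.isnan(enn[0]):
        diag = math.hypot(*grid.shape) * raster.cell_size_m
        enn = (diag, diag, 0.0)
        for name in ("enn_am", "enn_md", "enn_sd"):
            flags[name] = "imputed_no_neighbor"
    vals.extend(enn)

    agg = aggregation_metrics(raster, pm)
    present = int((raster.class_proportions() > 0).sum())
    if present < 2:
        flags["contag"] = "imputed_single_class"
        flags["iji"] = "imputed_single_class"
    elif present == 2:
        flags["iji"] = "imputed_two_classes"
    vals.append(agg["contagion"])
    vals.append(agg["percentage_like_adjacencies"])
    vals.append(agg["interspersion_juxtaposition"])

    div = diversity_metrics(raster)
    vals.extend([div["patch_richness"], div["shannon_diversity"],
                 div["simpson_diversity"], div["shannon_evenness"],
                 div["simpson_evenness"]])
    vals.append(agg["aggregation_index"])

    return MetricVector(np.array(vals), flags)
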