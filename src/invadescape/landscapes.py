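"""Synthetic categorical habitat landscapes.

Generates square rasters of habitat-class codes that emulate reclassified
land-cover tiles: controllable class composition, a fragmentation gradient
(modified-random-clusters generation), linear road corridors spanning the
tile, and water bodies acting as dispersal barriers. Also reads and writes
the ESRI ASCII grid dialect so rasters round-trip through plain text.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from . import habitat
from .errors import ConfigurationError, DimensionError, FormatError

__all__ = [
    "LandscapeRaster",
    "LandscapeConfig",
    "generate_landscape",
    "add_roads",
    "add_water_bodies",
    "read_ascii_grid",
    "write_ascii_grid",
]

_NODATA = -9999

# 4-neighbor structuring element used to grow the percolation clusters.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class LandscapeRaster:
    """A square grid of habitat-class codes plus the physical cell size."""

    grid: np.ndarray
    cell_size_m: float = 30.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int16)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise DimensionError("raster grid must be a non-empty 2-D array")
        if self.cell_size_m <= 0:
            raise ConfigurationError("cell_size_m must be positive")
        bad = (self.grid < 0) | (self.grid >= habitat.N_CLASSES)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid habitat code {self.grid[r, c]} at cell ({r}, {c})"
            )

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    @property
    def n_cells(self) -> int:
        return int(self.grid.size)

    def class_proportions(self) -> np.ndarray:
        """Proportion of cells in each of the 11 classes (sums to 1)."""
        counts = np.bincount(self.grid.ravel(), minlength=habitat.N_CLASSES)
        return counts / self.grid.size

    def copy(self) -> "LandscapeRaster":
        return LandscapeRaster(self.grid.copy(), self.cell_size_m)


@dataclass
class LandscapeConfig:
    """Recipe for one synthetic landscape.

    ``target_proportions`` maps class names (or integer codes) to fractions
    summing to 1. ``fragmentation`` in (0, 1] controls clump size: values
    near 0 give few large patches, values near 1 give salt-and-pepper
    texture. Roads and water bodies are stamped after class assignment and
    displace whatever they cover.
    """

    target_proportions: dict
    fragmentation: float = 0.5
    n_rows: int = 216
    n_cols: int = 216
    cell_size_m: float = 30.0
    n_roads: int = 0
    road_width_cells: int = 1
    n_water_bodies: int = 0
    seed: int = 0

    def resolved_proportions(self) -> np.ndarray:
        """Return the 11-vector of target proportions, validated."""
        vec = np.zeros(habitat.N_CLASSES)
        for key, frac in self.target_proportions.items():
            code = habitat.CODE_BY_NAME[key] if isinstance(key, str) else int(key)
            if not 0 <= code < habitat.N_CLASSES:
                raise ConfigurationError(f"unknown habitat class {key!r}")
            if frac < 0:
                raise ConfigurationError(f"negative proportion for {key!r}")
            vec[code] += frac
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"target proportions sum to {vec.sum():.12g}, expected 1"
            )
        return vec

    def validate(self) -> None:
        self.resolved_proportions()
        if not 0 < self.fragmentation <= 1:
            raise ConfigurationError("fragmentation must lie in (0, 1]")
        if self.n_rows < 9 or self.n_cols < 9:
            raise DimensionError("raster must be at least 9 x 9 cells")
        if self.road_width_cells < 1:
            raise ConfigurationError("road width must be >= 1 cell")
        if self.n_roads < 0 or self.n_water_bodies < 0:
            raise ConfigurationError("feature counts must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "LandscapeConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dict(self.__dict__)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _assign_clusters(labels: np.ndarray, n_clusters: int, targets: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Assign each percolation cluster a class, tracking per-class deficits.

    Clusters are visited in a seeded random order; each takes the class
    drawn with probability proportional to the remaining (unfilled) target
    cell count, which keeps realized proportions within tolerance as long as
    clusters stay small relative to the grid.
    """
    sizes = np.bincount(labels.ravel(), minlength=n_clusters + 1)
    remaining = targets.astype(float).copy()
    class_of = np.zeros(n_clusters + 1, dtype=np.int16)
    order = rng.permutation(np.arange(1, n_clusters + 1))
    codes = np.arange(habitat.N_CLASSES)
    for lab in order:
        avail = np.clip(remaining, 0.0, None)
        tot = avail.sum()
        if tot > 0:
            code = rng.choice(codes, p=avail / tot)
        else:  # every class overshot: take the least-overshot one
            code = int(np.argmax(remaining))
        class_of[lab] = code
        remaining[code] -= sizes[lab]
    return class_of[labels]


def generate_landscape(config: LandscapeConfig) -> LandscapeRaster:
    """Generate one synthetic habitat raster from a config.

    Modified-random-clusters generation: a sub-critical percolation mask is
    labeled into clumps (4-neighbor rule), every off-mask cell forms a
    singleton, and clumps are assigned classes to match the target
    composition. Water bodies and roads are stamped afterwards and may
    displace other classes. Identical config (including seed) always yields
    an identical raster.
    """
    config.validate()
    targets = config.resolved_proportions()
    shape = (config.n_rows, config.n_cols)
    n_cells = shape[0] * shape[1]

    for attempt in range(20):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed) % (2**63), attempt])
        )
        # Sub-critical site percolation; cap below the 4-neighbor threshold
        # (~0.593) so no giant cluster defeats the composition tolerance.
        p_occ = 0.45 * (1.0 - config.fragmentation)
        mask = rng.random(shape) < p_occ
        labels, n_clumps = ndimage.label(mask, structure=_CROSS)
        singles = ~mask
        n_single = int(singles.sum())
        labels[singles] = n_clumps + 1 + np.arange(n_single)
        n_clusters = n_clumps + n_single

        grid = _assign_clusters(labels, n_clusters, targets * n_cells, rng)
        raster = LandscapeRaster(grid.astype(np.int16), config.cell_size_m)
        if config.n_water_bodies:
            raster = add_water_bodies(
                raster, config.n_water_bodies, seed=rng.integers(2**31)
            )
        if config.n_roads:
            raster = add_roads(
                raster, config.n_roads, config.road_width_cells,
                seed=rng.integers(2**31),
            )
        water_frac = raster.class_proportions()[habitat.WATER]
        if water_frac < 0.5:  # emitted tiles must be mostly terrestrial
            return raster
    raise ConfigurationError(
        "could not generate a landscape with <50% water in 20 attempts; "
        "lower the water target or body count"
    )


def _line_cells(r0: int, c0: int, r1: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """8-connected raster line from (r0, c0) to (r1, c1), inclusive."""
    n = max(abs(r1 - r0), abs(c1 - c0)) + 1
    rr = np.rint(np.linspace(r0, r1, n)).astype(int)
    cc = np.rint(np.linspace(c0, c1, n)).astype(int)
    return rr, cc


def add_roads(raster: LandscapeRaster, n_roads: int, width: int = 1,
              seed: int = 0) -> LandscapeRaster:
    """Stamp ``n_roads`` linear road corridors onto a copy of the raster.

    Each road is a straight (axis-aligned or oblique) polyline connecting
    two opposite raster edges, thickened to ``width`` cells perpendicular to
    its main axis, so its cells form one 8-connected patch spanning a full
    raster dimension. Road cells overwrite whatever class they cover.
    """
    if width < 1:
        raise ConfigurationError("road width must be >= 1 cell")
    if n_roads < 0:
        raise ConfigurationError("n_roads must be non-negative")
    if n_roads == 0:
        return raster.copy()
    rng = np.random.default_rng(seed)
    grid = raster.grid.copy()
    nr, nc = grid.shape
    for _ in range(n_roads):
        horizontal = bool(rng.integers(2))
        if horizontal:  # left edge -> right edge
            r0 = int(rng.integers(nr))
            r1 = int(np.clip(r0 + rng.integers(-nr // 2, nr // 2 + 1), 0, nr - 1))
            rr, cc = _line_cells(r0, 0, r1, nc - 1)
            for off in range(width):
                ro = np.clip(rr + off, 0, nr - 1)
                grid[ro, cc] = habitat.ROAD
        else:  # top edge -> bottom edge
            c0 = int(rng.integers(nc))
            c1 = int(np.clip(c0 + rng.integers(-nc // 2, nc // 2 + 1), 0, nc - 1))
            rr, cc = _line_cells(0, c0, nr - 1, c1)
            for off in range(width):
                co = np.clip(cc + off, 0, nc - 1)
                grid[rr, co] = habitat.ROAD
    return LandscapeRaster(grid, raster.cell_size_m)


def add_water_bodies(raster: LandscapeRaster, n_bodies: int,
                     seed: int = 0) -> LandscapeRaster:
    """Stamp roughly circular water bodies onto a copy of the raster."""
    if n_bodies < 0:
        raise ConfigurationError("n_bodies must be non-negative")
    if n_bodies == 0:
        return raster.copy()
    rng = np.random.default_rng(seed)
    grid = raster.grid.copy()
    nr, nc = grid.shape
    rows, cols = np.ogrid[:nr, :nc]
    max_radius = max(2.0, min(nr, nc) / 12.0)
    for _ in range(n_bodies):
        cy, cx = rng.integers(nr), rng.integers(nc)
        radius = rng.uniform(1.5, max_radius)
        disk = (rows - cy) ** 2 + (cols - cx) ** 2 <= radius**2
        grid[disk] = habitat.WATER
    return LandscapeRaster(grid, raster.cell_size_m)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def write_ascii_grid(raster: LandscapeRaster, path) -> None:
    """Write a raster as an ESRI ASCII grid (row 0 = northernmost row)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols         {raster.n_cols}\n")
        fh.write(f"nrows         {raster.n_rows}\n")
        fh.write("xllcorner     0.0\n")
        fh.write("yllcorner     0.0\n")
        fh.write(f"cellsize      {raster.cell_size_m:g}\n")
        fh.write(f"NODATA_value  {_NODATA}\n")
        for row in raster.grid:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_ascii_grid(path) -> LandscapeRaster:
    """Read an ESRI ASCII grid of habitat codes.

    Raises :class:`FormatError` naming the offending line (1-based) for a
    malformed header, non-integer cell values, codes outside 0-10, NODATA
    cells, or a body inconsistent with the declared shape.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()

    header: dict[str, float] = {}
    idx = 0
    while idx < len(lines) and len(header) < 6:
        parts = lines[idx].split()
        if len(parts) == 2 and not _is_number(parts[0]):
            key = parts[0].lower()
            try:
                header[key] = float(parts[1])
            except ValueError:
                raise FormatError(
                    f"{path.name} line {idx + 1}: bad header value {parts[1]!r}"
                ) from None
            idx += 1
            if key not in _HEADER_KEYS and key != "nodata_value":
                raise FormatError(
                    f"{path.name} line {idx}: unknown header key {key!r}"
                )
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise FormatError(
            f"{path.name}: missing header keys {missing} before line {idx + 1}"
        )
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", _NODATA)

    body = lines[idx:]
    values: list[list[int]] = []
    for li, line in enumerate(body, start=idx + 1):
        if not line.strip():
            continue
        row = []
        for ci, tok in enumerate(line.split()):
            try:
                fval = float(tok)
                ival = int(fval)
                if ival != fval:
                    raise ValueError
            except ValueError:
                raise FormatError(
                    f"{path.name} line {li}: non-integer cell value {tok!r}"
                ) from None
            if ival == nodata:
                raise FormatError(
                    f"{path.name} line {li}: NODATA cell at column {ci + 1}; "
                    "pipeline rasters must be fully classified"
                )
            if not 0 <= ival < habitat.N_CLASSES:
                raise FormatError(
                    f"{path.name} line {li}: habitat code {ival} at column "
                    f"{ci + 1} outside 0-{habitat.N_CLASSES - 1}"
                )
            row.append(ival)
        values.append(row)
    if len(values) != nrows or any(len(r) != ncols for r in values):
        raise FormatError(
            f"{path.name}: body shape {len(values)} rows does not match "
            f"header nrows={nrows} / ncols={ncols}"
        )
    grid = np.asarray(values, dtype=np.int16)
    return LandscapeRaster(grid, float(header["cellsize"]))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
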