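"""Stochastic annual-time-step invasion simulator.

A founding population of a perennial invader starts in the center of a
categorical habitat raster and spreads through local logistic growth,
log-normal seed dispersal, optional transport along road corridors, and
habitat-scaled establishment. Plants live in two stages: juveniles
(first-year) mature into adults, adults are perennial. Habitat quality
enters three ways: the local expansion rate r_i, the carrying capacity K_i,
and the establishment probability of a dispersing seed, which is scaled by
r_i relative to grassland (the best habitat).

The per-seed establishment trial factorizes as
``establishment_freq * (r_i / r_grassland)`` with a destination-independent
first factor, so seed dispersal is binomially thinned by
``establishment_freq`` at the source; only the thinned candidates are given
explicit displacement draws. This is an exact reformulation, not an
approximation, and it is what makes whole-landscape simulation cheap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from . import habitat
from .errors import ConfigurationError, DimensionError, StateError
from .landscapes import LandscapeRaster

__all__ = [
    "TraitSet",
    "HabitatParams",
    "DispersalKernel",
    "InvasionState",
    "Trajectory",
    "InvasionSummary",
    "RoadNetwork",
    "initialize_invasion",
    "step_year",
    "run_simulation",
    "summarize_trajectory",
    "build_trait_grid",
    "TRAIT_LEVELS",
]

# Factorial levels of the four invasiveness traits used in the full design.
TRAIT_LEVELS: dict[str, tuple[float, ...]] = {
    "dispersal_mult": (0.33, 0.5, 1.0, 1.5, 2.0),
    "growth_mult": (0.33, 0.5, 1.0, 1.5, 2.0),
    "establishment_freq": (0.005, 0.01, 0.025, 0.05),
    "corridor_usage": (0.0, 0.25, 0.5, 0.75, 1.0),
}


@dataclass(frozen=True)
class TraitSet:
    """Invasiveness trait levels for one simulated invader."""

    dispersal_mult: float = 1.0
    growth_mult: float = 1.0
    establishment_freq: float = 0.03
    corridor_usage: float = 0.5

    def __post_init__(self) -> None:
        if self.dispersal_mult < 0 or self.growth_mult < 0:
            raise ConfigurationError("trait multipliers must be non-negative")
        if not 0 <= self.establishment_freq <= 1:
            raise ConfigurationError("establishment_freq must lie in [0, 1]")
        if not 0 <= self.corridor_usage <= 1:
            raise ConfigurationError("corridor_usage must lie in [0, 1]")


def build_trait_grid() -> list[TraitSet]:
    """Full factorial grid over the four trait level sets (5*5*4*5 = 500).

    Ordering is lexicographic over (dispersal, growth, establishment,
    corridor) in the level orders of :data:`TRAIT_LEVELS`.
    """
    return [
        TraitSet(d, g, e, c)
        for d, g, e, c in itertools.product(
            TRAIT_LEVELS["dispersal_mult"],
            TRAIT_LEVELS["growth_mult"],
            TRAIT_LEVELS["establishment_freq"],
            TRAIT_LEVELS["corridor_usage"],
        )
    ]


# Relative expansion rates by habitat class (fraction of grassland's rate).
# Grassland is the best habitat; crop is nearly hostile; roads, water and
# unsuitable land support no growth or establishment at all.
_RELATIVE_R: dict[int, float] = {
    habitat.UNSUITABLE: 0.0,
    habitat.GRASSLAND: 1.0,
    habitat.DECIDUOUS: 0.6,
    habitat.CONIFEROUS: 0.4,
    habitat.MIXED_FOREST: 0.5,
    habitat.PASTURE: 0.7,
    habitat.CROP: 0.1,
    habitat.ROAD: 0.0,
    habitat.WETLAND: 0.3,
    habitat.WATER: 0.0,
    habitat.SHRUBLAND: 0.5,
}


@dataclass
class HabitatParams:
    """Habitat-specific demography: per-class expansion rate and carrying
    capacity (indexed by class code), plus fecundity.

    Defaults: r_grassland = 0.5 / yr with other suitable classes scaled down,
    K = 100 adults/cell in grassland scaled by the same ratios, and 200
    seeds per adult per year. ``founders_on_unsuitable_die`` removes founder
    adults sitting on zero-growth classes after ``founder_lifespan_yr``.
    """

    r: np.ndarray = field(default_factory=lambda: 0.5 * np.array(
        [_RELATIVE_R[c] for c in range(habitat.N_CLASSES)]))
    K: np.ndarray = field(default_factory=lambda: np.round(100.0 * np.array(
        [_RELATIVE_R[c] for c in range(habitat.N_CLASSES)])).astype(np.int64))
    fecundity: float = 200.0
    founders_on_unsuitable_die: bool = True
    founder_lifespan_yr: int = 5

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.K = np.asarray(self.K, dtype=np.int64)
        if self.r.shape != (habitat.N_CLASSES,) or self.K.shape != (habitat.N_CLASSES,):
            raise ConfigurationError("r and K must have one entry per habitat class")
        if (self.r < 0).any() or (self.K < 0).any() or self.fecundity < 0:
            raise ConfigurationError("rates, capacities and fecundity must be >= 0")
        if self.r[habitat.GRASSLAND] <= 0:
            raise ConfigurationError("grassland expansion rate must be positive")
        for code in habitat.BARRIER_CODES:
            if self.r[code] != 0 or self.K[code] != 0:
                raise ConfigurationError(
                    f"class {habitat.CLASS_NAMES[code]!r} must have r = K = 0"
                )

    def relative_r(self) -> np.ndarray:
        """Establishment scaling r_i / r_grassland, in [0, 1] per class."""
        return self.r / self.r[habitat.GRASSLAND]

    @classmethod
    def from_yaml(cls, path) -> "HabitatParams":
        """Load demography from YAML (class-name keyed r/K maps plus
        fecundity and the founder flags)."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        kwargs = {}
        for key in ("r", "K"):
            if key in data:
                vec = np.zeros(habitat.N_CLASSES)
                for name, value in data[key].items():
                    vec[habitat.CODE_BY_NAME[name]] = value
                kwargs[key] = vec
        for key in ("fecundity", "founders_on_unsuitable_die",
                    "founder_lifespan_yr"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        import yaml

        data = {
            "r": {n: float(v) for n, v in zip(habitat.CLASS_NAMES, self.r)},
            "K": {n: int(v) for n, v in zip(habitat.CLASS_NAMES, self.K)},
            "fecundity": float(self.fecundity),
            "founders_on_unsuitable_die": self.founders_on_unsuitable_die,
            "founder_lifespan_yr": self.founder_lifespan_yr,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class DispersalKernel:
    """Log-normal distance kernel with uniform direction.

    ``log_mean`` is the mean of log-distance (meters); the default gives a
    median displacement of 60 m (two 30 m cells). A trait's dispersal
    multiplier scales every drawn distance multiplicatively.
    """

    log_mean: float = math.log(60.0)
    log_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ConfigurationError("log_sd must be positive")

    def draw_distances(self, n: int, rng: np.random.Generator,
                       mult: float = 1.0) -> np.ndarray:
        """Draw ``n`` displacement distances in meters."""
        return mult * rng.lognormal(self.log_mean, self.log_sd, size=n)


@dataclass
class InvasionState:
    """Per-cell juvenile and adult counts at one point in time."""

    juveniles: np.ndarray
    adults: np.ndarray
    year: int = 0

    def __post_init__(self) -> None:
        self.juveniles = np.asarray(self.juveniles, dtype=np.int64)
        self.adults = np.asarray(self.adults, dtype=np.int64)
        if self.juveniles.shape != self.adults.shape:
            raise StateError("juvenile and adult grids must share a shape")
        if (self.juveniles < 0).any() or (self.adults < 0).any():
            raise StateError("negative plant counts")

    def copy(self) -> "InvasionState":
        return InvasionState(self.juveniles.copy(), self.adults.copy(), self.year)


def initialize_invasion(raster: LandscapeRaster) -> InvasionState:
    """Found the invasion: 50 adults in each cell of the central 3x3 block.

    For even-sided rasters the block's top-left corner is anchored at
    ``((n_rows - 3) // 2, (n_cols - 3) // 2)``, i.e. the block sits just
    above/left of the exact midpoint.
    """
    nr, nc = raster.grid.shape
    if nr < 3 or nc < 3:
        raise DimensionError("raster must be at least 3 x 3 to seat the founders")
    adults = np.zeros((nr, nc), dtype=np.int64)
    r0, c0 = (nr - 3) // 2, (nc - 3) // 2
    adults[r0:r0 + 3, c0:c0 + 3] = 50
    return InvasionState(np.zeros_like(adults), adults, year=0)


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Round non-negative reals to integers without systematic bias."""
    lo = np.floor(x)
    return (lo + (rng.random(x.shape) < (x - lo))).astype(np.int64)


class RoadNetwork:
    """Connectivity structure of the road cells of one raster.

    Supports corridor transport: given an entry road cell and a distance in
    cells, walk that graph distance along the 8-connected road network and
    deposit at the nearest non-road cell to the exit (Euclidean ties broken
    N, E, S, W, then clockwise diagonals).
    """

    def __init__(self, raster: LandscapeRaster) -> None:
        grid = raster.grid
        self.shape = grid.shape
        self.mask = grid == habitat.ROAD
        self.cells = np.argwhere(self.mask)  # (m, 2) road cell coords
        m = len(self.cells)
        self.index = -np.ones(self.shape, dtype=np.int64)
        if m:
            self.index[self.mask] = np.arange(m)
            self.graph = self._build_graph()
        self._dist_cache: dict[int, np.ndarray] = {}
        self._deposit_cache: dict[int, tuple[int, int] | None] = {}

    def _build_graph(self) -> sparse.csr_matrix:
        rows, cols, nr, nc = [], [], *self.shape
        rr, cc = self.cells[:, 0], self.cells[:, 1]
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                r2, c2 = rr + dr, cc + dc
                ok = (r2 >= 0) & (r2 < nr) & (c2 >= 0) & (c2 < nc)
                ok[ok] &= self.mask[r2[ok], c2[ok]]
                rows.append(np.nonzero(ok)[0])
                cols.append(self.index[r2[ok], c2[ok]])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        m = len(self.cells)
        return sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(m, m)
        )

    def _distances_from(self, entry: int) -> np.ndarray:
        if entry not in self._dist_cache:
            self._dist_cache[entry] = csgraph.dijkstra(
                self.graph, unweighted=True, indices=entry
            )
        return self._dist_cache[entry]

    def _nearest_nonroad(self, cell_idx: int) -> tuple[int, int] | None:
        """Nearest non-road cell to a road cell; None if the raster is all road."""
        if cell_idx in self._deposit_cache:
            return self._deposit_cache[cell_idx]
        r0, c0 = self.cells[cell_idx]
        nr, nc = self.shape
        best = None
        for ring in range(1, max(nr, nc)):
            cands = []
            for dr in range(-ring, ring + 1):
                for dc in range(-ring, ring + 1):
                    if max(abs(dr), abs(dc)) != ring:
                        continue
                    r, c = r0 + dr, c0 + dc
                    if 0 <= r < nr and 0 <= c < nc and not self.mask[r, c]:
                        # tie-break: distance, then clockwise angle from North
                        ang = math.atan2(dc, -dr) % (2 * math.pi)
                        cands.append((dr * dr + dc * dc, ang, r, c))
            if cands:
                cands.sort()
                best = (cands[0][2], cands[0][3])
                break
            if ring > max(nr, nc):  # pragma: no cover - defensive
                break
        self._deposit_cache[cell_idx] = best
        return best

    def transport(self, entry_r: np.ndarray, entry_c: np.ndarray,
                  dist_cells: np.ndarray, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Move seeds along the road network.

        Returns (dest_r, dest_c, ok): deposit coordinates for each seed and
        a mask of seeds that found a non-road deposit cell.
        """
        n = len(entry_r)
        dest_r = np.zeros(n, dtype=np.int64)
        dest_c = np.zeros(n, dtype=np.int64)
        ok = np.zeros(n, dtype=bool)
        entries = self.index[entry_r, entry_c]
        for entry in np.unique(entries):
            sel = np.nonzero(entries == entry)[0]
            dists = self._distances_from(int(entry))
            finite = np.isfinite(dists)
            dmax = dists[finite].max()
            for i in sel:
                d_star = min(float(dist_cells[i]), dmax)
                at = np.nonzero(finite & (dists == d_star))[0]
                exit_idx = int(at[rng.integers(len(at))]) if len(at) > 1 else int(at[0])
                dep = self._nearest_nonroad(exit_idx)
                if dep is not None:
                    dest_r[i], dest_c[i] = dep
                    ok[i] = True
        return dest_r, dest_c, ok


def step_year(state: InvasionState, raster: LandscapeRaster,
              params: HabitatParams, traits: TraitSet,
              kernel: DispersalKernel, rng: np.random.Generator,
              road_network: RoadNetwork | None = None) -> InvasionState:
    """Advance the invasion by one year.

    Order of operations: (1) juveniles mature to adults; (2) stochastic
    logistic local growth at rate r_i * growth_mult; (3) seed production
    (fecundity per adult) with establishment-thinned log-normal dispersal;
    (4) corridor transport of seeds landing on roads; (5) establishment of
    candidate seeds in unoccupied suitable cells at probability
    r_i / r_grassland (the establishment_freq factor was applied at the
    source); (6) carrying-capacity truncation of adults.
    """
    grid = raster.grid
    if state.adults.shape != grid.shape:
        raise StateError("state shape does not match raster shape")
    if (state.adults < 0).any() or (state.juveniles < 0).any():
        raise StateError("negative plant counts")

    # (1) maturation
    adults = state.adults + state.juveniles
    juveniles = np.zeros_like(adults)

    # (2) local growth, stochastically rounded
    K = params.K[grid]
    r_eff = params.r[grid] * traits.growth_mult
    grow = (adults > 0) & (K > 0) & (r_eff > 0)
    if grow.any():
        n = adults[grow].astype(float)
        expected = np.clip(r_eff[grow] * n * (1.0 - n / K[grow]), 0.0, None)
        adults[grow] += _stochastic_round(expected, rng)

    # (3) seed production and dispersal (thinned by establishment_freq)
    src = np.nonzero(adults > 0)
    n_seeds = np.round(params.fecundity * adults[src]).astype(np.int64)
    cand = rng.binomial(n_seeds, traits.establishment_freq)
    total = int(cand.sum())
    if total:
        src_r = np.repeat(src[0], cand).astype(float)
        src_c = np.repeat(src[1], cand).astype(float)
        dist = kernel.draw_distances(total, rng, traits.dispersal_mult)
        theta = rng.uniform(0.0, 2.0 * math.pi, total)
        cells = dist / raster.cell_size_m
        dest_r = np.floor(src_r + 0.5 + cells * np.cos(theta)).astype(np.int64)
        dest_c = np.floor(src_c + 0.5 + cells * np.sin(theta)).astype(np.int64)
        nr, nc = grid.shape
        inside = (dest_r >= 0) & (dest_r < nr) & (dest_c >= 0) & (dest_c < nc)
        dest_r, dest_c = dest_r[inside], dest_c[inside]
        dist = dist[inside]

        # (4) corridor transport for seeds landing on road cells
        on_road = grid[dest_r, dest_c] == habitat.ROAD
        if on_road.any() and traits.corridor_usage > 0:
            riders = on_road & (rng.random(len(dest_r)) < traits.corridor_usage)
            if riders.any():
                if road_network is None:
                    road_network = RoadNetwork(raster)
                hop = kernel.draw_distances(
                    int(riders.sum()), rng, traits.dispersal_mult)
                hop_cells = np.round(hop / raster.cell_size_m)
                new_r, new_c, ok = road_network.transport(
                    dest_r[riders], dest_c[riders], hop_cells, rng)
                idx = np.nonzero(riders)[0][ok]
                dest_r[idx] = new_r[ok]
                dest_c[idx] = new_c[ok]
        # seeds still on road cells (non-riders or failed transport) die in (5)

        # (5) establishment in unoccupied suitable cells
        rel = params.relative_r()[grid[dest_r, dest_c]]
        empty = (adults[dest_r, dest_c] == 0) & (juveniles[dest_r, dest_c] == 0)
        found = empty & (rng.random(len(dest_r)) < rel)
        if found.any():
            np.add.at(juveniles, (dest_r[found], dest_c[found]), 1)

    # (6) carrying-capacity truncation (zero-K cells keep founder adults;
    # their fate is governed by the founder-lifespan rule upstream)
    cap = K > 0
    adults[cap] = np.minimum(adults[cap], K[cap])

    return InvasionState(juveniles, adults, state.year + 1)


@dataclass
class Trajectory:
    """Per-year landscape totals of one simulation run."""

    years: np.ndarray
    adults_total: np.ndarray
    juveniles_total: np.ndarray
    occupied_cells: np.ndarray  # cells with >= 1 adult
    n_cells: int

    def __len__(self) -> int:
        return len(self.years)


@dataclass
class InvasionSummary:
    """The four invasion response metrics plus bookkeeping.

    ``expansion_rate``: mean yearly increment of occupied-cell proportion
    over the first 30 years. ``growth_rate``: mean of yearly population
    ratios N_{t+1}/N_t over the same window, skipping undefined years
    (N_t = 0). ``final_extent``: proportion of cells with >= 1 adult at the
    final year. ``final_population``: mean adults per cell at the final year.
    """

    expansion_rate: float
    growth_rate: float
    final_extent: float
    final_population: float
    skipped_years: int = 0
    transient_years_used: int = 30

    def as_dict(self) -> dict[str, float]:
        return {
            "expansion_rate": self.expansion_rate,
            "growth_rate": self.growth_rate,
            "final_extent": self.final_extent,
            "final_population": self.final_population,
        }


RESPONSE_NAMES = ("expansion_rate", "growth_rate", "final_extent",
                  "final_population")


def summarize_trajectory(trajectory: Trajectory,
                         transient_years: int = 30) -> InvasionSummary:
    """Compute the four response metrics from a per-year trajectory."""
    if len(trajectory) < 2:
        raise DimensionError("trajectory must cover at least two years")
    n_cells = trajectory.n_cells
    horizon = min(transient_years, len(trajectory) - 1)
    occ = trajectory.occupied_cells.astype(float)
    pop = trajectory.adults_total.astype(float)

    d_occ = (occ[1:horizon + 1] - occ[:horizon]) / n_cells
    expansion = float(d_occ.mean())

    prev = pop[:horizon]
    nxt = pop[1:horizon + 1]
    defined = prev > 0
    skipped = int((~defined).sum())
    growth = float((nxt[defined] / prev[defined]).mean()) if defined.any() else 0.0

    return InvasionSummary(
        expansion_rate=expansion,
        growth_rate=growth,
        final_extent=float(occ[-1]) / n_cells,
        final_population=float(pop[-1]) / n_cells,
        skipped_years=skipped,
        transient_years_used=horizon,
    )


def run_simulation(raster: LandscapeRaster, params: HabitatParams,
                   traits: TraitSet, years: int = 100, seed: int = 0,
                   kernel: DispersalKernel | None = None,
                   road_network: RoadNetwork | None = None
                   ) -> tuple[Trajectory, InvasionSummary]:
    """Run one seeded invasion for ``years`` annual steps.

    Returns the per-year trajectory (length ``years + 1``, including year 0)
    and its four-metric summary. Runs shorter than 31 years compute the
    transient metrics over the available window, recorded in
    ``transient_years_used``.
    """
    if years < 1:
        raise ConfigurationError("years must be >= 1")
    kernel = kernel or DispersalKernel()
    rng = np.random.default_rng(seed)
    if road_network is None and (raster.grid == habitat.ROAD).any():
        road_network = RoadNetwork(raster)

    state = initialize_invasion(raster)
    founder_barrier = (state.adults > 0) & (params.K[raster.grid] == 0)

    adults_t = np.zeros(years + 1, dtype=np.int64)
    juv_t = np.zeros(years + 1, dtype=np.int64)
    occ_t = np.zeros(years + 1, dtype=np.int64)

    def record(s: InvasionState) -> None:
        adults_t[s.year] = s.adults.sum()
        juv_t[s.year] = s.juveniles.sum()
        occ_t[s.year] = int((s.adults > 0).sum())

    record(state)
    for _ in range(years):
        state = step_year(state, raster, params, traits, kernel, rng,
                          road_network)
        if (params.founders_on_unsuitable_die
                and state.year == params.founder_lifespan_yr
                and founder_barrier.any()):
            state.adults[founder_barrier] = 0
        record(state)

    traj = Trajectory(np.arange(years + 1), adults_t, juv_t, occ_t,
                      raster.n_cells)
    return traj, summarize_trajectory(traj)
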