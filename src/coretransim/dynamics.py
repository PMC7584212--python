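"""The demographic engine: death, birth, dispersal, establishment.

Each grid cell is a local community with a hard carrying capacity of K
individuals. A time step applies, in order:

1. *Death* — every individual dies independently with probability ``d``
   (habitat-independent). Individuals dying this step do not reproduce this
   step.
2. *Birth* — every surviving adult in its preferred habitat produces ``f``
   propagules; adults in non-preferred habitat do not reproduce.
3. *Dispersal* — new propagules move from their natal cell in a uniformly
   random direction by a distance drawn from a half-normal kernel. Adults
   sitting in non-preferred habitat leave their cell and disperse the same
   way, joining the propagule pool. Dispersal off the grid edge is absorbing:
   the model has an explicit outside world (GSAD immigration), so propagules
   leaving the grid are simply lost.
4. *Establishment* — each empty slot in each cell is filled, independently,
   by a GSAD immigrant with probability ``m``, otherwise by a uniform draw
   without replacement from the propagules that arrived at that cell (the
   slot stays empty if the arrival pool is exhausted). Propagules that fail
   to establish are destroyed at the end of the step.

The community state is stored as a per-cell x per-species count matrix;
individuals carry no state beyond species identity and location, so the count
representation is exact. Propagules are materialised as per-individual arrays
only within a step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from math import sqrt, pi

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import HabitatGrid, generate_landscape, focal_cell, local_similarity
from .species import SpeciesPool, GSAD, build_species_pool, draw_gsad

__all__ = [
    "SimulationConfig",
    "DispersalKernel",
    "kernel_from_q99",
    "CommunityState",
    "PropaguleBatch",
    "SimulationRecord",
    "initialize_communities",
    "apply_mortality",
    "produce_propagules",
    "collect_adult_dispersers",
    "disperse",
    "establish",
    "step",
    "run_simulation",
]

#: z-quantile at 0.995; the 99th percentile of |N(0, sigma)| is sigma * Z995.
Z995 = float(stats.norm.ppf(0.995))

DEFAULT_DETECTION_PROBS = tuple(round(0.1 * i, 1) for i in range(1, 11))


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one simulation run.

    Defaults are the study conditions: a 32x32 landscape, 40 habitat
    specialists (half per habitat), K=100 individuals per cell, mortality 0.5,
    two offspring per matched adult per step, per-slot immigration probability
    0.001, a half-normal dispersal kernel with 99th percentile 4 grid cells,
    200 steps with temporal occupancy read from the last 15.
    """

    width: int = 32
    height: int = 32
    h_a: float = 0.5
    n_species: int = 40
    carrying_capacity: int = 100
    mortality: float = 0.5
    fecundity: int = 2
    immigration_rate: float = 0.001
    dispersal_q99: float = 4.0
    immigration_granularity: str = "slot"  # "slot" or "cell"
    n_steps: int = 200
    occupancy_window: int = 15
    similarity_window: int = 7
    detection_probs: tuple[float, ...] = DEFAULT_DETECTION_PROBS
    gsad_meanlog: float = 0.0
    gsad_sdlog: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("h_a", "mortality", "immigration_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("carrying_capacity", "n_steps", "occupancy_window", "fecundity"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.occupancy_window > self.n_steps:
            raise ValueError("occupancy_window cannot exceed n_steps")
        if self.dispersal_q99 <= 0:
            raise ValueError("dispersal_q99 must be positive")
        if any(not (0.0 <= p <= 1.0) for p in self.detection_probs):
            raise ValueError("detection probabilities must lie in [0, 1]")
        if self.similarity_window % 2 != 1 or self.similarity_window < 1:
            raise ValueError("similarity_window must be a positive odd integer")
        if self.immigration_granularity not in ("slot", "cell"):
            raise ValueError("immigration_granularity must be 'slot' or 'cell'")

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DispersalKernel:
    """Half-normal dispersal-distance kernel, parameterized by its scale.

    ``mean = sigma * sqrt(2/pi)`` and ``q99 = sigma * Z995`` with
    Z995 = Phi^-1(0.995) ~ 2.5758; both are exact closed forms of the
    half-normal, so the kernel is fully recoverable from any one of the three.
    """

    sigma: float

    @property
    def mean(self) -> float:
        return self.sigma * sqrt(2.0 / pi)

    @property
    def q99(self) -> float:
        return self.sigma * Z995

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw dispersal distances |N(0, sigma)|."""
        return np.abs(rng.normal(0.0, self.sigma, size=size))


def kernel_from_q99(q99: float) -> DispersalKernel:
    """Kernel whose 99th-percentile dispersal distance is ``q99`` grid cells.

    q99=4 gives mean distance ~1.24 cells (the study's main kernel); q99=2 and
    q99=8 are the narrow and broad variants.
    """
    if q99 <= 0:
        raise ValueError(f"q99 must be positive, got {q99}")
    return DispersalKernel(sigma=q99 / Z995)


@dataclass
class CommunityState:
    """Established individuals on the landscape.

    ``counts[cell, species]`` with cells flattened row-major; every cell total
    is capped at the carrying capacity.
    """

    counts: np.ndarray  # (n_cells, n_species) int64
    height: int
    width: int

    @property
    def n_cells(self) -> int:
        return self.height * self.width

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    def cell_occupancy(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def landscape_abundance(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def assert_capacity(self, k: int) -> None:
        occ = self.cell_occupancy()
        if occ.max(initial=0) > k:
            raise RuntimeError(
                f"internal consistency failure: cell occupancy {occ.max()} exceeds K={k}"
            )

    def copy(self) -> "CommunityState":
        return CommunityState(self.counts.copy(), self.height, self.width)


@dataclass
class PropaguleBatch:
    """Per-individual arrays for propagules in flight within one time step."""

    row: np.ndarray
    col: np.ndarray
    species: np.ndarray
    is_adult: np.ndarray  # True for displaced adults, False for offspring

    @property
    def size(self) -> int:
        return self.species.size

    @classmethod
    def empty(cls) -> "PropaguleBatch":
        z = np.empty(0, dtype=np.int64)
        return cls(z, z.copy(), z.copy(), np.empty(0, dtype=bool))

    @classmethod
    def from_counts(cls, counts: np.ndarray, width: int, is_adult: bool) -> "PropaguleBatch":
        """Expand a (n_cells, n_species) count matrix to individuals."""
        cell_idx, sp_idx = np.nonzero(counts)
        reps = counts[cell_idx, sp_idx]
        cells = np.repeat(cell_idx, reps).astype(np.int64)
        species = np.repeat(sp_idx, reps).astype(np.int64)
        return cls(
            row=cells // width,
            col=cells % width,
            species=species,
            is_adult=np.full(species.size, is_adult),
        )

    @classmethod
    def concatenate(cls, batches: list["PropaguleBatch"]) -> "PropaguleBatch":
        if not batches:
            return cls.empty()
        return cls(
            row=np.concatenate([b.row for b in batches]),
            col=np.concatenate([b.col for b in batches]),
            species=np.concatenate([b.species for b in batches]),
            is_adult=np.concatenate([b.is_adult for b in batches]),
        )


def _match_matrix(grid: HabitatGrid, pool: SpeciesPool) -> np.ndarray:
    """(n_cells, n_species) bool: does the cell's habitat match the species'?"""
    cell_is_a = grid.is_a.ravel()
    return cell_is_a[:, None] == pool.prefers_a[None, :]


def initialize_communities(
    grid: HabitatGrid, gsad: GSAD, k: int, rng: np.random.Generator
) -> CommunityState:
    """Fill every cell to carrying capacity with iid GSAD draws.

    Habitat match is ignored at initialization; mismatched individuals sort
    themselves out through the dynamics.
    """
    counts = rng.multinomial(k, gsad.weights, size=grid.n_cells).astype(np.int64)
    return CommunityState(counts, grid.height, grid.width)


def apply_mortality(
    state: CommunityState, d: float, rng: np.random.Generator
) -> CommunityState:
    """Kill each individual independently with probability ``d``."""
    if not (0.0 <= d <= 1.0):
        raise ValueError(f"mortality must lie in [0, 1], got {d}")
    survivors = rng.binomial(state.counts, 1.0 - d).astype(np.int64)
    return CommunityState(survivors, state.height, state.width)


def produce_propagules(
    state: CommunityState, pool: SpeciesPool, grid: HabitatGrid, f: int
) -> PropaguleBatch:
    """``f`` offspring per adult in matched habitat; none elsewhere.

    Offspring start at the parent's cell and do not establish until the
    establishment phase.
    """
    if f < 0:
        raise ValueError(f"fecundity must be nonnegative, got {f}")
    match = _match_matrix(grid, pool)
    offspring_counts = state.counts * match * f
    return PropaguleBatch.from_counts(offspring_counts, state.width, is_adult=False)


def collect_adult_dispersers(
    state: CommunityState, pool: SpeciesPool, grid: HabitatGrid
) -> tuple[CommunityState, PropaguleBatch]:
    """Remove every adult sitting in non-preferred habitat into the dispersal pool.

    Displaced adults are treated exactly like propagules from here on: they
    compete for slots at their destination and are destroyed if unplaced.
    """
    match = _match_matrix(grid, pool)
    mismatched = state.counts * ~match
    remaining = CommunityState(state.counts * match, state.height, state.width)
    return remaining, PropaguleBatch.from_counts(mismatched, state.width, is_adult=True)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (per axis)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def disperse(
    batch: PropaguleBatch,
    kernel: DispersalKernel,
    grid: HabitatGrid,
    rng: np.random.Generator,
) -> PropaguleBatch:
    """Move each propagule by a half-normal distance in a uniform direction.

    The continuous displacement from the natal cell's center is rounded to the
    nearest cell per axis (halves away from zero). Destinations outside the
    grid are discarded (absorbing boundary).
    """
    n = batch.size
    if n == 0:
        return batch
    theta = rng.uniform(0.0, 2.0 * pi, size=n)
    dist = kernel.sample(n, rng)
    dr = _round_half_away(dist * np.sin(theta)).astype(np.int64)
    dc = _round_half_away(dist * np.cos(theta)).astype(np.int64)
    row = batch.row + dr
    col = batch.col + dc
    inside = (row >= 0) & (row < grid.height) & (col >= 0) & (col < grid.width)
    return PropaguleBatch(
        row=row[inside],
        col=col[inside],
        species=batch.species[inside],
        is_adult=batch.is_adult[inside],
    )


def establish(
    state: CommunityState,
    arrivals: PropaguleBatch,
    gsad: GSAD,
    m: float,
    k: int,
    rng: np.random.Generator,
    granularity: str = "slot",
) -> CommunityState:
    """Fill empty slots from immigrants and the per-cell arrival pools.

    Each of a cell's ``K - occupancy`` empty slots is processed independently:
    with probability ``m`` it takes a GSAD immigrant; otherwise it takes a
    uniform without-replacement draw from the cell's arrival pool, staying
    empty if the pool is exhausted. Unused arrivals are destroyed.

    Distributionally this is: immigrant slots ~ Binomial(empty, m) per cell;
    the remaining slots take a multivariate-hypergeometric subset of the
    cell's arrival pool (sampled by its exact sequential species-by-species
    hypergeometric decomposition, vectorized across cells).
    """
    if not (0.0 <= m <= 1.0):
        raise ValueError(f"immigration rate must lie in [0, 1], got {m}")
    state.assert_capacity(k)
    counts = state.counts.copy()
    n_cells, n_species = counts.shape

    occ = counts.sum(axis=1)
    empty = (k - occ).astype(np.int64)

    # Immigrant slots, then identities (iid from the GSAD), assigned per cell.
    if granularity == "cell":
        # at most one immigration event per community per step
        imm = ((rng.random(n_cells) < m) & (empty > 0)).astype(np.int64)
    else:
        imm = rng.binomial(empty, m)
    total_imm = int(imm.sum())
    if total_imm > 0:
        imm_species = rng.choice(n_species, size=total_imm, p=gsad.weights)
        imm_cells = np.repeat(np.arange(n_cells), imm)
        np.add.at(counts, (imm_cells, imm_species), 1)

    # Non-immigrant slots draw uniformly without replacement from the cell's
    # arrival pool: per cell the established species counts are multivariate
    # hypergeometric, sampled by conditioning one species at a time
    # (X_s ~ Hypergeom(pool_s, pool_rest, slots_remaining)), all cells at once.
    slots = empty - imm
    if arrivals.size > 0:
        dest_cell = arrivals.row * state.width + arrivals.col
        pool_counts = np.bincount(
            dest_cell * n_species + arrivals.species, minlength=n_cells * n_species
        ).reshape(n_cells, n_species)
        remaining = pool_counts.sum(axis=1)
        take = np.minimum(slots, remaining)
        for s in range(n_species):
            good = pool_counts[:, s]
            bad = remaining - good
            active = take > 0
            if not active.any():
                break
            x = np.zeros(n_cells, dtype=np.int64)
            x[active] = rng.hypergeometric(good[active], bad[active], take[active])
            counts[:, s] += x
            take -= x
            remaining = bad

    new_state = CommunityState(counts, state.height, state.width)
    new_state.assert_capacity(k)
    return new_state


def step(
    state: CommunityState,
    grid: HabitatGrid,
    pool: SpeciesPool,
    gsad: GSAD,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CommunityState:
    """One full time step: death -> birth -> dispersal -> establishment."""
    kernel = kernel_from_q99(config.dispersal_q99)
    state = apply_mortality(state, config.mortality, rng)
    offspring = produce_propagules(state, pool, grid, config.fecundity)
    state, adult_dispersers = collect_adult_dispersers(state, pool, grid)
    in_flight = PropaguleBatch.concatenate([offspring, adult_dispersers])
    arrivals = disperse(in_flight, kernel, grid, rng)
    return establish(
        state, arrivals, gsad, config.immigration_rate, config.carrying_capacity, rng,
        granularity=config.immigration_granularity,
    )


@dataclass
class SimulationRecord:
    """Everything downstream analysis needs from one finished run."""

    config: SimulationConfig
    seed: int | None
    grid: HabitatGrid
    pool: SpeciesPool
    gsad: GSAD
    focal: tuple[int, int]
    similarity: float
    #: (occupancy_window, n_species) true focal-cell abundance, oldest year first
    focal_abundance: np.ndarray
    #: (n_species,) landscape-wide abundance at the final step
    landscape_abundance: np.ndarray

    @property
    def focal_habitat(self) -> str:
        return self.grid.habitat_at(self.focal)

    def focal_occupancy_frame(self) -> pd.DataFrame:
        """Tidy focal time series: year, species_id, true_abundance."""
        w, s = self.focal_abundance.shape
        years, species = np.meshgrid(np.arange(w), np.arange(s), indexing="ij")
        return pd.DataFrame(
            {
                "year": years.ravel(),
                "species_id": species.ravel(),
                "true_abundance": self.focal_abundance.ravel(),
            }
        )

    def save(self, prefix) -> None:
        """Serialize as focal CSV + landscape CSV + metadata JSON."""
        from .landscape import HABITAT_A, HABITAT_B

        prefix = str(prefix)
        self.focal_occupancy_frame().to_csv(prefix + "_focal.csv", index=False)
        pd.DataFrame(
            {
                "species_id": np.arange(self.pool.n_species),
                "preferred_habitat": np.where(self.pool.prefers_a, HABITAT_A, HABITAT_B),
                "landscape_abundance": self.landscape_abundance,
            }
        ).to_csv(prefix + "_landscape.csv", index=False)
        meta = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "focal": list(self.focal),
            "focal_habitat": self.focal_habitat,
            "similarity": self.similarity,
            "coordinate_convention": "0-based (row, col), row-major",
        }
        with open(prefix + "_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)


def run_simulation(
    config: SimulationConfig,
    rng: np.random.Generator | int | np.random.SeedSequence | None = None,
    grid: HabitatGrid | None = None,
    pool: SpeciesPool | None = None,
    gsad: GSAD | None = None,
) -> SimulationRecord:
    """Run one full simulation and record the focal window.

    Generates the landscape, species pool and GSAD (unless supplied, e.g. for
    fixture scenarios with prescribed habitat maps), fills the landscape to
    capacity, advances ``n_steps`` steps, and records the focal cell's true
    per-species abundance over the final ``occupancy_window`` steps plus
    landscape-wide abundance at the last step. Fully reproducible from the
    seed (``rng=None`` uses ``config.seed``).
    """
    seed = None
    if rng is None or isinstance(rng, (int, np.integer, np.random.SeedSequence)):
        seed_src = config.seed if rng is None else rng
        seed = int(seed_src) if isinstance(seed_src, (int, np.integer)) else None
        rng = np.random.default_rng(seed_src)

    if grid is None:
        grid = generate_landscape(config.width, config.height, config.h_a, rng)
    if pool is None:
        pool = build_species_pool(config.n_species)
    if gsad is None:
        gsad = draw_gsad(
            config.n_species, rng, meanlog=config.gsad_meanlog, sdlog=config.gsad_sdlog
        )
    focal = focal_cell(grid, config.similarity_window)
    similarity = local_similarity(grid, focal, config.similarity_window)
    focal_idx = focal[0] * grid.width + focal[1]

    state = initialize_communities(grid, gsad, config.carrying_capacity, rng)
    window_start = config.n_steps - config.occupancy_window
    focal_abund = np.zeros((config.occupancy_window, config.n_species), dtype=np.int64)
    for t in range(config.n_steps):
        state = step(state, grid, pool, gsad, config, rng)
        if t >= window_start:
            focal_abund[t - window_start] = state.counts[focal_idx]

    return SimulationRecord(
        config=config,
        seed=seed,
        grid=grid,
        pool=pool,
        gsad=gsad,
        focal=focal,
        similarity=similarity,
        focal_abundance=focal_abund,
        landscape_abundance=state.landscape_abundance(),
    )
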