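"""Deterministic small-scale scenarios for fast, hand-checkable testing.

Every fixture is regenerated from ``(name, seed)`` in code — nothing is
checked in — so each stage of the pipeline can be exercised in milliseconds
without running the full model. Available scenarios:

``tiny``
    4x4 grid, K=5, 4 species, narrow kernel (q99=1.5), short run — small
    enough to compare against a literal per-individual reference engine.
``homogeneous``
    8x8 all-habitat-A grid: similarity is exactly 1, no transient source pool.
``checkerboard``
    8x8 alternating habitats: the focal similarity is countable by hand
    (25/49 same-parity cells in the 7x7 window).
``two_block``
    8x8 grid split into a left A half and right B half: the classic
    source-sink geometry, focal cell on the A side of the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import SimulationConfig, SimulationRecord, run_simulation
from .landscape import HabitatGrid
from .species import SpeciesPool, GSAD, build_species_pool, draw_gsad

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("tiny", "homogeneous", "checkerboard", "two_block")


@dataclass
class Fixture:
    """One named deterministic scenario; regeneration is bit-identical."""

    name: str
    seed: int
    config: SimulationConfig
    grid: HabitatGrid
    pool: SpeciesPool
    gsad: GSAD

    def run(self) -> SimulationRecord:
        """Run the scenario's simulation on its prescribed landscape."""
        return run_simulation(
            self.config,
            np.random.default_rng(self.seed),
            grid=self.grid,
            pool=self.pool,
            gsad=self.gsad,
        )


def make_fixture(name: str, seed: int = 0) -> Fixture:
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")
    rng = np.random.default_rng(seed)

    if name == "tiny":
        config = SimulationConfig(
            width=4, height=4, h_a=0.5, n_species=4, carrying_capacity=5,
            dispersal_q99=1.5, n_steps=30, occupancy_window=5,
            similarity_window=3, seed=seed,
        )
        is_a = rng.random((4, 4)) < config.h_a
    elif name == "homogeneous":
        config = SimulationConfig(
            width=8, height=8, h_a=1.0, n_species=8, carrying_capacity=20,
            n_steps=50, occupancy_window=10, seed=seed,
        )
        is_a = np.ones((8, 8), dtype=bool)
    elif name == "checkerboard":
        config = SimulationConfig(
            width=8, height=8, h_a=0.5, n_species=8, carrying_capacity=20,
            n_steps=50, occupancy_window=10, seed=seed,
        )
        r, c = np.indices((8, 8))
        is_a = (r + c) % 2 == 0
    else:  # two_block
        config = SimulationConfig(
            width=8, height=8, h_a=0.5, n_species=8, carrying_capacity=20,
            n_steps=50, occupancy_window=10, seed=seed,
        )
        is_a = np.zeros((8, 8), dtype=bool)
        is_a[:, :4] = True

    grid = HabitatGrid(is_a)
    pool = build_species_pool(config.n_species)
    gsad = draw_gsad(config.n_species, rng, config.gsad_meanlog, config.gsad_sdlog)
    return Fixture(name=name, seed=seed, config=config, grid=grid, pool=pool, gsad=gsad)
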