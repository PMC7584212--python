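"""Literal one-individual-at-a-time engine used as an independent oracle.

Implements the same death -> birth -> dispersal -> establishment step as the
vectorized engine, but with plain Python loops over individuals and slots,
following the process rules as directly as possible. Deliberately slow and
simple; used only on tiny grids to check the vectorized engine
distributionally.
"""

from __future__ import annotations

from math import cos, sin, floor, pi, copysign

import numpy as np


def _round_half_away(x: float) -> int:
    return int(copysign(floor(abs(x) + 0.5), x))


def reference_step(counts, grid, pool, gsad, config, rng):
    """One time step on a per-individual representation; returns a counts matrix."""
    height, width = grid.is_a.shape
    n_species = pool.n_species
    k = config.carrying_capacity

    # individuals as (row, col, species) tuples
    individuals = []
    for cell in range(height * width):
        r, c = divmod(cell, width)
        for s in range(n_species):
            individuals.extend([(r, c, s)] * int(counts[cell, s]))

    # death
    survivors = [ind for ind in individuals if rng.random() >= config.mortality]

    # birth: f propagules per matched adult, at the natal cell
    propagules = []
    for r, c, s in survivors:
        if grid.is_a[r, c] == pool.prefers_a[s]:
            propagules.extend([(r, c, s)] * config.fecundity)

    # adult dispersers: mismatched adults leave their cell, join the pool
    staying = []
    for r, c, s in survivors:
        if grid.is_a[r, c] == pool.prefers_a[s]:
            staying.append((r, c, s))
        else:
            propagules.append((r, c, s))

    # dispersal: uniform direction, half-normal distance, absorbing edges
    sigma = config.dispersal_q99 / 2.5758293035489004
    arrivals: dict[tuple[int, int], list[int]] = {}
    for r, c, s in propagules:
        theta = rng.uniform(0.0, 2.0 * pi)
        dist = abs(rng.normal(0.0, sigma))
        nr = r + _round_half_away(dist * sin(theta))
        nc = c + _round_half_away(dist * cos(theta))
        if 0 <= nr < height and 0 <= nc < width:
            arrivals.setdefault((nr, nc), []).append(s)

    # establishment: per empty slot, immigrant w.p. m else pop from the
    # shuffled arrival pool
    new_counts = np.zeros_like(counts)
    for r, c, s in staying:
        new_counts[r * width + c, s] += 1
    for cell in range(height * width):
        r, c = divmod(cell, width)
        pool_here = arrivals.get((r, c), [])
        rng.shuffle(pool_here)
        n_empty = k - int(new_counts[cell].sum())
        for _ in range(n_empty):
            if rng.random() < config.immigration_rate:
                s = rng.choice(n_species, p=gsad.weights)
                new_counts[cell, s] += 1
            elif pool_here:
                new_counts[cell, pool_here.pop()] += 1
    return new_counts
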