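"""Species pool and the global species abundance distribution (GSAD).

The regional pool holds ``n_species`` habitat specialists: the first half can
only reproduce in habitat A, the second half only in habitat B. The GSAD is a
vector of relative abundances drawn once per simulation from a lognormal
distribution; it governs both the initial filling of the landscape and the
identity of immigrants arriving from outside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import HABITAT_A, HABITAT_B

__all__ = ["SpeciesPool", "GSAD", "build_species_pool", "draw_gsad", "sample_species"]


@dataclass(frozen=True)
class SpeciesPool:
    """Habitat preferences for the regional species pool.

    ``prefers_a[s]`` is True for species that reproduce only in habitat A.
    Assignment is deterministic by index (first half A, second half B):
    preference labels are exchangeable, so nothing is lost, and runs stay
    reproducible.
    """

    prefers_a: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "prefers_a", np.asarray(self.prefers_a, dtype=bool))

    @property
    def n_species(self) -> int:
        return self.prefers_a.size

    def preferred_habitat(self, species_id: int) -> str:
        if not (0 <= species_id < self.n_species):
            raise KeyError(f"unknown species id {species_id}")
        return HABITAT_A if self.prefers_a[species_id] else HABITAT_B


@dataclass(frozen=True)
class GSAD:
    """Relative regional abundances, normalized to sum to 1."""

    weights: np.ndarray = field(repr=False)
    meanlog: float = 0.0
    sdlog: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("GSAD weights must all be positive")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("GSAD weights must sum to 1 within 1e-12")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n_species(self) -> int:
        return self.weights.size


def build_species_pool(n_species: int = 40, rng: np.random.Generator | None = None) -> SpeciesPool:
    """Build an even pool: species ``0..n/2-1`` prefer A, the rest prefer B.

    ``rng`` is accepted for interface symmetry but unused — the assignment is
    deterministic.
    """
    if n_species < 2 or n_species % 2 != 0:
        raise ValueError(f"n_species must be an even integer >= 2, got {n_species}")
    prefers_a = np.zeros(n_species, dtype=bool)
    prefers_a[: n_species // 2] = True
    return SpeciesPool(prefers_a)


def draw_gsad(
    n_species: int,
    rng: np.random.Generator,
    meanlog: float = 0.0,
    sdlog: float = 1.0,
) -> GSAD:
    """Draw a lognormal GSAD: n iid Lognormal(meanlog, sdlog), normalized."""
    if sdlog <= 0:
        raise ValueError(f"sdlog must be positive, got {sdlog}")
    raw = rng.lognormal(mean=meanlog, sigma=sdlog, size=n_species)
    return GSAD(raw / raw.sum(), meanlog=meanlog, sdlog=sdlog)


def sample_species(gsad: GSAD, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``k`` iid species identities with probabilities = GSAD weights."""
    if k < 0:
        raise ValueError(f"k must be nonnegative, got {k}")
    if k == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(gsad.n_species, size=k, p=gsad.weights).astype(np.int64)


def species_table(pool: SpeciesPool, gsad: GSAD) -> pd.DataFrame:
    """Tidy species table: species_id, preferred_habitat, gsad_weight."""
    return pd.DataFrame(
        {
            "species_id": np.arange(pool.n_species),
            "preferred_habitat": np.where(pool.prefers_a, HABITAT_A, HABITAT_B),
            "gsad_weight": gsad.weights,
        }
    )
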