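"""Binary two-habitat landscapes and the local landscape-similarity metric.

The landscape is a rectangular grid of cells, each labelled with one of two
habitat types, ``A`` or ``B``. All demographic dynamics play out on this grid;
the analysis focuses on a single central cell and on how similar its
surroundings (a 7x7 window by default) are to its own habitat type.

Habitat is assigned iid Bernoulli(h_A) per cell. How habitat was arranged
spatially in the original study system is genuinely open — iid assignment is a
documented default chosen because the downstream analyses treat landscape
similarity as a continuous predictor that varies across replicates at fixed
h_A, which iid generation produces naturally. ``generate_landscape`` accepts an
alternative cell-assignment hook for spatially structured generators.

Coordinate convention: 0-based ``(row, col)``, row-major, everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

HABITAT_A = "A"
HABITAT_B = "B"

__all__ = [
    "HabitatGrid",
    "generate_landscape",
    "focal_cell",
    "local_similarity",
]


@dataclass(frozen=True)
class HabitatGrid:
    """A binary habitat raster.

    Parameters
    ----------
    is_a
        Boolean array of shape ``(height, width)``; ``True`` marks habitat A.
    """

    is_a: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.is_a, dtype=bool)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(
                f"habitat raster must be 2-D with positive dimensions, got shape {arr.shape}"
            )
        object.__setattr__(self, "is_a", arr)

    @property
    def height(self) -> int:
        return self.is_a.shape[0]

    @property
    def width(self) -> int:
        return self.is_a.shape[1]

    @property
    def n_cells(self) -> int:
        return self.is_a.size

    @property
    def fraction_a(self) -> float:
        """Realized proportion of habitat A."""
        return float(self.is_a.mean())

    def habitat_at(self, cell: tuple[int, int]) -> str:
        return HABITAT_A if self.is_a[cell] else HABITAT_B

    def to_csv(self, path) -> None:
        """Write the grid as plain CSV of 0/1 labels (1 = habitat A)."""
        np.savetxt(path, self.is_a.astype(int), fmt="%d", delimiter=",")

    @classmethod
    def from_csv(cls, path) -> "HabitatGrid":
        return cls(np.loadtxt(path, delimiter=",", ndmin=2).astype(bool))


def generate_landscape(
    width: int,
    height: int,
    h_a: float,
    rng: np.random.Generator,
    cell_sampler: Callable[[int, int, float, np.random.Generator], np.ndarray] | None = None,
) -> HabitatGrid:
    """Generate a two-habitat landscape with expected A-fraction ``h_a``.

    Each cell is labelled habitat A independently with probability ``h_a``
    (iid Bernoulli). Pass ``cell_sampler(width, height, h_a, rng) ->
    bool array`` to substitute a spatially structured generator without
    changing any downstream code.
    """
    if not (0.0 <= h_a <= 1.0):
        raise ValueError(f"h_a must lie in [0, 1], got {h_a}")
    if width < 1 or height < 1:
        raise ValueError(f"grid dimensions must be positive, got {width}x{height}")
    if cell_sampler is None:
        is_a = rng.random((height, width)) < h_a
    else:
        is_a = np.asarray(cell_sampler(width, height, h_a, rng), dtype=bool)
        if is_a.shape != (height, width):
            raise ValueError("cell_sampler returned wrong shape")
    return HabitatGrid(is_a)


def focal_cell(grid: HabitatGrid, window: int = 7) -> tuple[int, int]:
    """Central focal cell, ``floor((n - 1) / 2)`` per axis.

    For even dimensions there is no exact center; the upper-left of the four
    central cells is chosen (32x32 -> (15, 15)) — under iid habitat generation
    any central cell is statistically equivalent. Rejects grids too small to
    hold the ``window`` x ``window`` similarity block around the center.
    """
    if grid.height < window or grid.width < window:
        raise ValueError(
            f"grid {grid.height}x{grid.width} cannot hold a {window}x{window} "
            "window around a central focal cell"
        )
    return ((grid.height - 1) // 2, (grid.width - 1) // 2)


def local_similarity(
    grid: HabitatGrid, focus: tuple[int, int], window: int = 7
) -> float:
    """Proportion of the window x window block sharing the focal habitat.

    The block is centered on ``focus`` and includes the focal cell itself, so
    the minimum attainable value is ``1 / window**2`` and a homogeneous
    neighbourhood scores exactly 1.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    r, c = focus
    half = window // 2
    if r - half < 0 or c - half < 0 or r + half >= grid.height or c + half >= grid.width:
        raise ValueError(
            f"{window}x{window} window around focus {focus} extends past the "
            f"edge of the {grid.height}x{grid.width} grid"
        )
    block = grid.is_a[r - half : r + half + 1, c - half : c + half + 1]
    same = block if grid.is_a[r, c] else ~block
    return float(same.sum()) / float(window * window)
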