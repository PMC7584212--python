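"""Imperfect detection overlaid on true focal-cell abundances.

Surveys never see everything. Here each individual present is detected
independently with probability ``p`` in each year, so the observed count is a
binomial thinning of the true count, and a species with ``n`` individuals is
detected at all with probability ``1 - (1 - p)**n``. Temporal occupancy is the
fraction of the survey window's years with at least one detection.

Detection is an overlay: several detection levels reuse the same finished
simulation, each with its own independent stream of detection draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import SimulationRecord

__all__ = [
    "OccupancyRecord",
    "observe_abundance",
    "species_detection_prob",
    "occupancy_from_record",
    "occupancy_frame",
]

CORE = "core"
TRANSIENT = "transient"


@dataclass(frozen=True)
class OccupancyRecord:
    """One observed species' detection history at the focal cell."""

    species_id: int
    detected_years: int
    window: int
    true_status: str  # core | transient, by habitat match at the focal cell
    landscape_abundance: int
    #: percent of the most abundant species' landscape-wide abundance
    relative_abundance: float

    @property
    def occupancy(self) -> float:
        return self.detected_years / self.window


def observe_abundance(n: int, p: float, rng: np.random.Generator) -> int:
    """Observed count ~ Binomial(n, p): each individual detected independently."""
    if np.any(np.asarray(n) < 0):
        raise ValueError("true abundance must be nonnegative")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"detection probability must lie in [0, 1], got {p}")
    return rng.binomial(n, p)


def species_detection_prob(n: int, p: float) -> float:
    """Probability a species with ``n`` individuals is detected: 1 - (1-p)^n."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    return 1.0 - (1.0 - p) ** n

def occupancy_from_record(
    record: SimulationRecord, p: float, rng: np.random.Generator
) -> list[OccupancyRecord]:
    """Detection histories for every species observed at least once.

    A species counts as detected in a year iff its binomially thinned count
    is >= 1 that year. Species never detected across the window produce no
    record — an observer has no datum for them, just as in a real survey.
    True status is core iff the species' preferred habitat matches the focal
    cell's; relative abundance is percent of the landscape-wide maximum.
    """
    abund = record.focal_abundance  # (W, S)
    window = abund.shape[0]
    observed = observe_abundance(abund, p, rng)
    detected_years = (observed >= 1).sum(axis=0)

    landscape = record.landscape_abundance
    max_abund = landscape.max()
    focal_is_a = record.grid.is_a[record.focal]
    is_core = record.pool.prefers_a == focal_is_a

    out = []
    for s in np.flatnonzero(detected_years):
        rel = 100.0 * landscape[s] / max_abund if max_abund > 0 else np.nan
        out.append(
            OccupancyRecord(
                species_id=int(s),
                detected_years=int(detected_years[s]),
                window=window,
                true_status=CORE if is_core[s] else TRANSIENT,
                landscape_abundance=int(landscape[s]),
                relative_abundance=float(rel),
            )
        )
    return out


def occupancy_frame(records: list[OccupancyRecord], **extra) -> pd.DataFrame:
    """Tidy frame of occupancy records; ``extra`` adds constant id columns."""
    df = pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "true_status": [r.true_status for r in records],
            "detected_years": [r.detected_years for r in records],
            "occupancy": [r.occupancy for r in records],
            "landscape_abundance": [r.landscape_abundance for r in records],
            "relative_abundance": [r.relative_abundance for r in records],
        }
    )
    for k, v in extra.items():
        df.insert(0, k, v)
    return df
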