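"""Core/transient status inference and the confusion-table bookkeeping.

A species' *inferred* status comes from temporal occupancy alone: observed in
at most a third of the window's years -> transient; in more than two thirds ->
core; in between -> intermediate, excluded from the error analysis. Its *true*
(biological) status is whether its preferred habitat matches the focal cell's,
i.e. whether it can maintain a self-sustaining population there.

Crossing the two gives four categories:

=====================  =================  ==============
                        inferred transient  inferred core
true core               A (error)           C
true transient          B                   D (error)
=====================  =================  ==============

with core misclassification rate ``A / (A + C)`` and transient
misclassification rate ``D / (B + D)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor, nan

from .observation import OccupancyRecord, CORE, TRANSIENT
from .species import SpeciesPool

__all__ = [
    "INTERMEDIATE",
    "ConfusionTable",
    "infer_status",
    "true_status",
    "tabulate",
]

INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class ConfusionTable:
    """Counts of the four classification categories for one (run, p) pair."""

    a: int  # true core, inferred transient  (core error)
    b: int  # true transient, inferred transient
    c: int  # true core, inferred core
    d: int  # true transient, inferred core  (transient error)
    n_intermediate_excluded: int = 0

    @property
    def n_true_core(self) -> int:
        return self.a + self.c

    @property
    def n_true_transient(self) -> int:
        return self.b + self.d

    @property
    def core_error(self) -> float:
        """A / (A + C); NaN (not zero) when no true core species observed."""
        return self.a / self.n_true_core if self.n_true_core else nan

    @property
    def transient_error(self) -> float:
        """D / (B + D); NaN (not zero) when no true transient species observed."""
        return self.d / self.n_true_transient if self.n_true_transient else nan


def infer_status(
    detected_years: int,
    window: int,
    low_frac: float = 1.0 / 3.0,
    high_frac: float = 2.0 / 3.0,
) -> str:
    """Occupancy-threshold classification.

    Transient iff detected in at most ``floor(low_frac * window)`` years, core
    iff detected in more than ``floor(high_frac * window)`` years, otherwise
    intermediate. For a 15-year window: transient <= 5, core >= 11,
    intermediate 6-10. The boundaries follow the year-count rule (<=5, >10 of
    15); the fractions are its generalization to other window lengths.
    """
    if not (0 <= detected_years <= window):
        raise ValueError(
            f"detected_years must lie in [0, {window}], got {detected_years}"
        )
    if not (0 <= low_frac < high_frac <= 1):
        raise ValueError("need 0 <= low_frac < high_frac <= 1")
    if detected_years <= floor(low_frac * window):
        return TRANSIENT
    if detected_years > floor(high_frac * window):
        return CORE
    return INTERMEDIATE


def true_status(species_id: int, pool: SpeciesPool, focal_habitat: str) -> str:
    """Biological status: core iff the species' preferred habitat matches."""
    return CORE if pool.preferred_habitat(species_id) == focal_habitat else TRANSIENT


def tabulate(
    records: list[OccupancyRecord],
    low_frac: float = 1.0 / 3.0,
    high_frac: float = 2.0 / 3.0,
) -> ConfusionTable:
    """Cross true against inferred status for one (run, detection) pair.

    Intermediate-occupancy species are counted only in
    ``n_intermediate_excluded``; every other observed species lands in exactly
    one of the four cells.
    """
    a = b = c = d = n_mid = 0
    for r in records:
        inferred = infer_status(r.detected_years, r.window, low_frac, high_frac)
        if inferred == INTERMEDIATE:
            n_mid += 1
        elif r.true_status == CORE:
            if inferred == TRANSIENT:
                a += 1
            else:
                c += 1
        else:
            if inferred == TRANSIENT:
                b += 1
            else:
                d += 1
    return ConfusionTable(a=a, b=b, c=c, d=d, n_intermediate_excluded=n_mid)
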