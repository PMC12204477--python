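"""Stationary counterparts and the binary population pair.

The stationary counterpart of an observed population is the hypothetical
population that shares its period life table, has zero growth, and an age
structure fixed by that table alone.  Pairing the two — observed and
stationary — turns the stationary case into a scientific control against
which structural deviations (age structure, momentum, longevity gains) are
measured.

Discrete weighting.  On a one-year grid two stationary age structures are in
use: survivorship ``l_x`` (counts at exact age) and person-years ``L_x``
(mid-interval exposure).  This package defaults to survivorship because it
makes the stationary identities exact on the integer grid: the remaining-years
distribution of the counterpart (via the cohort death matrix) telescopes to
``l_x`` itself, so life lived equals life left age-for-age, not just
approximately.  Person-years weighting is available via ``weighting="person-years"``
and differs by O(q_x) per age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError, ValidationError
from .lifetable import LifeTable, PopulationSnapshot

__all__ = ["AgeDistribution", "BinaryPair", "age_distribution", "build_stationary_population", "make_pair"]

_WEIGHTINGS = ("survivorship", "person-years")


@dataclass
class AgeDistribution:
    """Non-negative mass per single year of age (or of remaining years).

    Used both for chronological age structures (mass ``n_x``) and for
    thanatological structures (mass ``d_x``, persons with x years left).
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            x = int(np.flatnonzero(self.weights < 0)[0])
            raise ValidationError(f"negative mass at index {x}: {self.weights[x]}")

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    @property
    def fractions(self) -> np.ndarray:
        t = self.total
        if t <= 0:
            raise ComputationError("cannot normalize a zero-total distribution")
        return self.weights / t

    def normalized(self) -> "AgeDistribution":
        return AgeDistribution(self.fractions)

    def mean(self) -> float:
        """Mass-weighted mean index (mean age / mean years remaining)."""
        return float(np.arange(len(self.weights)) @ self.fractions)


def age_distribution(pop: PopulationSnapshot) -> AgeDistribution:
    """The chronological age distribution of a snapshot (mass = counts)."""
    return AgeDistribution(pop.n)


def build_stationary_population(
    lifetable: LifeTable,
    total: float = 1.0,
    time: int = 0,
    *,
    weighting: str = "survivorship",
    label: str = "stationary",
) -> PopulationSnapshot:
    """Build the stationary population implied by a period life table.

    Counts are proportional to ``l_x`` (default) or ``L_x`` and scaled to
    ``total``.  The result satisfies the stationary population identity:
    its age distribution equals its remaining-years distribution, and mean
    age equals mean years remaining (exactly under survivorship weighting,
    to O(q) under person-years).
    """
    if weighting not in _WEIGHTINGS:
        raise ValidationError(f"weighting must be one of {_WEIGHTINGS}, got {weighting!r}")
    if not total > 0:
        raise ValidationError(f"total must be positive, got {total}")
    w = lifetable.l if weighting == "survivorship" else lifetable.L
    s = w.sum()
    if s <= 0:
        raise ComputationError("degenerate life table: no person-years to distribute")
    return PopulationSnapshot(time=time, n=total * w / s, lifetable=lifetable, label=label)


@dataclass
class BinaryPair:
    """An observed population and its stationary counterpart, sharing one life table."""

    observed: PopulationSnapshot
    stationary: PopulationSnapshot

    def __post_init__(self) -> None:
        if self.observed.omega != self.stationary.omega:
            raise ValidationError("pair members disagree on omega")
        if self.observed.time != self.stationary.time:
            raise ValidationError("pair members disagree on time")

    @property
    def lifetable(self) -> LifeTable:
        return self.observed.lifetable


def make_pair(observed: PopulationSnapshot, *, weighting: str = "survivorship") -> BinaryPair:
    """Pair an observed snapshot with its stationary counterpart.

    The counterpart is scaled to the observed total so absolute exports
    (cohort bars, death matrices) are directly comparable; every ratio
    metric is scale-free regardless.
    """
    stationary = build_stationary_population(
        observed.lifetable,
        total=observed.total,
        time=observed.time,
        weighting=weighting,
        label=f"{observed.label} (stationary)".strip(),
    )
    return BinaryPair(observed=observed, stationary=stationary)
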