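"""The cohort death matrix and thanatological (remaining-years) structure.

``m[a, y]`` is the expected number of deaths occurring y completed years
after the reference time among persons aged a at that time, projected by
holding the period life table fixed:

    m[a, y] = n_a * (l_{a+y} - l_{a+y+1}) / l_a        (a + y <= omega)

The matrix is upper-triangular in the (age, horizon) sense — every cohort is
extinct by age omega.  Row a is the death band of the age-a cohort (its total
returns n_a); column y collects the persons with y completed years remaining,
so the column sums are the thanatological age distribution d(x) whose total D
equals the population size N.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .lifetable import PopulationSnapshot
from .pair import AgeDistribution

__all__ = [
    "DeathMatrix",
    "ThanatologicalBar",
    "build_death_matrix",
    "remaining_years_distribution",
    "cohort_death_band",
    "thanatological_bar",
    "matrix_checksums",
]


@dataclass
class DeathMatrix:
    """Upper-triangular matrix of projected deaths by (current age, years ahead)."""

    m: np.ndarray
    source: PopulationSnapshot

    @property
    def omega(self) -> int:
        return self.m.shape[0] - 1

    def row_sums(self) -> np.ndarray:
        return self.m.sum(axis=1)

    def column_sums(self) -> np.ndarray:
        return self.m.sum(axis=0)

    def anti_diagonals(self) -> list[np.ndarray]:
        """Entries with constant a + y (single birth-cohort-by-death-year bands)."""
        flipped = np.fliplr(self.m)
        k = self.omega
        return [np.diagonal(flipped, offset=k - s) for s in range(self.omega + 1)]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form (age, years_ahead, deaths) table of the non-structural-zero cells."""
        a, y = np.meshgrid(np.arange(self.omega + 1), np.arange(self.omega + 1), indexing="ij")
        keep = (a + y) <= self.omega
        return pd.DataFrame(
            {"age": a[keep].ravel(), "years_ahead": y[keep].ravel(), "deaths": self.m[keep].ravel()}
        )

    def to_csv(self, square_path: str | Path, long_path: str | Path | None = None) -> None:
        pd.DataFrame(
            self.m,
            index=pd.Index(range(self.omega + 1), name="age"),
            columns=[str(y) for y in range(self.omega + 1)],
        ).to_csv(square_path)
        if long_path is not None:
            self.to_long_frame().to_csv(long_path, index=False)


def build_death_matrix(pop: PopulationSnapshot) -> DeathMatrix:
    """Project each living cohort to extinction under its period life table.

    Raises if a cohort exists at an age the life table declares extinct
    (n_a > 0 with l_a = 0): its conditional death distribution is undefined.
    """
    lt = pop.lifetable
    omega = lt.omega
    bad = np.flatnonzero((pop.n > 0) & (lt.l <= 0))
    if bad.size:
        a = int(bad[0])
        raise ValidationError(f"cohort of size {pop.n[a]} at age {a} but survivorship l_{a} = 0")
    m = np.zeros((omega + 1, omega + 1))
    for a in range(omega + 1):
        if pop.n[a] == 0:
            continue
        m[a, : omega + 1 - a] = pop.n[a] * lt.d[a:] / lt.l[a]
    return DeathMatrix(m=m, source=pop)


def remaining_years_distribution(dm: DeathMatrix) -> AgeDistribution:
    """Column sums d(x): persons with x completed years remaining; total D = N."""
    return AgeDistribution(dm.column_sums())


def cohort_death_band(dm: DeathMatrix, age: int) -> list[tuple[int, float]]:
    """Row ``age`` of the matrix as (years-ahead, deaths) pairs; totals to n_age.

    This is the diagonal band of the birth-death cohort graph: the projected
    death schedule of the cohort currently aged ``age``, out to extinction.
    """
    if not 0 <= age <= dm.omega:
        raise ValidationError(f"age {age} outside 0..{dm.omega}")
    horizon = dm.omega + 1 - age
    return [(y, float(dm.m[age, y])) for y in range(horizon)]


class ThanatologicalBar(NamedTuple):
    """One stacked bar of the remaining-years panel.

    ``composition`` decomposes the persons with exactly ``years_left``
    remaining by their current age; ``column_total`` is its sum; ``tail``
    counts persons with **at least** ``years_left`` remaining.
    """

    years_left: int
    composition: dict[int, float]
    column_total: float
    tail: float


def thanatological_bar(dm: DeathMatrix, years_left: int) -> ThanatologicalBar:
    """Column ``years_left`` decomposed by contributing age, plus the at-least tail."""
    if not 0 <= years_left <= dm.omega:
        raise ValidationError(f"years_left {years_left} outside 0..{dm.omega}")
    col = dm.m[:, years_left]
    composition = {int(a): float(v) for a, v in enumerate(col) if v != 0.0}
    tail = float(dm.m[:, years_left:].sum())
    return ThanatologicalBar(years_left, composition, float(col.sum()), tail)


def matrix_checksums(dm: DeathMatrix, *, rel_tol: float = 1e-9) -> dict:
    """Conservation and stationarity diagnostics for one matrix.

    Reports the worst relative row-sum error against the cohort counts, the
    largest row-vs-column sum discrepancy per age, and the largest spread
    along any anti-diagonal.  For a stationary (survivorship-weighted)
    snapshot the latter two vanish; for an observed population they do not,
    and that asymmetry is the point of the comparison.
    """
    n = dm.source.n
    rows = dm.row_sums()
    cols = dm.column_sums()
    scale = max(n.max(), 1e-300)
    row_err = float(np.max(np.abs(rows - n) / np.maximum(n, scale * 1e-15)))
    row_col_gap = float(np.max(np.abs(rows - cols)) / scale)
    anti_spread = max((float(band.max() - band.min()) for band in dm.anti_diagonals()), default=0.0) / scale
    return {
        "row_sum_rel_error": row_err,
        "row_sums_match_counts": bool(row_err <= rel_tol),
        "max_row_col_gap": row_col_gap,
        "rows_equal_columns": bool(row_col_gap <= rel_tol),
        "max_anti_diagonal_spread": float(anti_spread),
        "anti_diagonals_constant": bool(anti_spread <= rel_tol),
        "total_deaths": float(dm.m.sum()),
        "population_total": float(n.sum()),
    }
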