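"""Synthetic life tables and populations with known structure.

Every pipeline stage is testable without external data: Gompertz-Makeham
mortality generates realistic period life tables (hazard mu(x) = lambda +
alpha * exp(beta * x), covering e(0) roughly 40-90 for sensible parameters),
and Lotka stable age structures n_x proportional to exp(-r x) * l_x generate
populations of known youthfulness, reducing to the stationary counterpart at
r = 0.  Writers emit the same CSV dialects the readers consume, so reader
round-trips are part of the test surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .lifetable import LifeTable, PopulationSnapshot, complete_life_table
from .pair import build_stationary_population

__all__ = [
    "GompertzMakeham",
    "StableStructure",
    "make_life_table",
    "make_stable_population",
    "make_time_pair",
    "perturb_counts",
    "write_life_table_csv",
    "write_population_csv",
    "write_fixture_grid",
]


@dataclass(frozen=True)
class GompertzMakeham:
    """Gompertz-Makeham mortality: constant background plus senescent hazard.

    ``makeham`` is the age-independent hazard (accidents, infections),
    ``gompertz_a`` the baseline senescent hazard at age 0 and ``gompertz_b``
    the exponential rate of aging (per year); typical human-like values are
    a ~ 1e-5..1e-4 and b ~ 0.08..0.12.
    """

    makeham: float = 0.0
    gompertz_a: float = 1e-5
    gompertz_b: float = 0.1
    omega: int = 100

    def __post_init__(self) -> None:
        if self.makeham < 0 or self.gompertz_a < 0 or self.gompertz_b < 0:
            raise ValidationError("hazard parameters must be non-negative")
        if self.makeham + self.gompertz_a <= 0:
            raise ValidationError("hazard must be positive somewhere: makeham + gompertz_a > 0 required")
        if self.omega < 1:
            raise ValidationError(f"omega must be at least 1, got {self.omega}")
        if not np.isfinite(self.hazard(float(self.omega))):
            raise ValidationError("hazard overflows at omega; reduce gompertz_b or omega")

    def hazard(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.makeham + self.gompertz_a * np.exp(self.gompertz_b * np.asarray(x, dtype=float))

    def interval_hazard(self, x: np.ndarray) -> np.ndarray:
        """Integral of the hazard over [x, x+1], in closed form."""
        x = np.asarray(x, dtype=float)
        if self.gompertz_b == 0:
            return np.full_like(x, self.makeham + self.gompertz_a)
        b = self.gompertz_b
        return self.makeham + self.gompertz_a / b * (np.exp(b * (x + 1)) - np.exp(b * x))


def make_life_table(model: GompertzMakeham, radix: float = 1.0, *, a_omega: float = 0.5) -> LifeTable:
    """Life table under the model: q_x = 1 - exp(-integral of the hazard), q_omega = 1."""
    x = np.arange(model.omega + 1)
    H = model.interval_hazard(x)
    if not np.all(np.isfinite(H)):
        raise ValidationError("cumulative hazard overflows before omega")
    q = 1.0 - np.exp(-H)
    q[-1] = 1.0
    return complete_life_table(q=q, radix=radix, a_omega=a_omega)


@dataclass(frozen=True)
class StableStructure:
    """A Lotka stable population: fixed life table, constant growth rate r per year."""

    r: float
    lifetable: LifeTable


def make_stable_population(
    structure: StableStructure,
    total: float = 1.0,
    time: int = 0,
    *,
    weighting: str = "survivorship",
    label: str | None = None,
) -> PopulationSnapshot:
    """Stable age structure n_x proportional to exp(-r x) times the stationary weights.

    At r = 0 this is identical to :func:`demopair.pair.build_stationary_population`
    with the same weighting.  Positive r skews young (LPR > 1), negative r
    skews old (LPR < 1).
    """
    lt = structure.lifetable
    stationary = build_stationary_population(lt, total=1.0, time=time, weighting=weighting)
    ages = np.arange(lt.omega + 1)
    w = np.exp(-structure.r * ages) * stationary.n
    s = w.sum()
    if not np.isfinite(s) or s <= 0:
        raise ValidationError(f"degenerate stable structure for r={structure.r}")
    if label is None:
        label = f"stable(r={structure.r:+.3f})"
    return PopulationSnapshot(time=time, n=total * w / s, lifetable=lt, label=label)


def make_time_pair(
    model_then: GompertzMakeham,
    model_now: GompertzMakeham,
    r_then: float,
    r_now: float,
    gap: int = 50,
    *,
    total: float = 1.0,
    time_now: int = 2020,
    weighting: str = "survivorship",
) -> tuple[PopulationSnapshot, PopulationSnapshot]:
    """Two stable snapshots ``gap`` years apart with independent mortality and growth.

    The standard fixture for survival-offset / net-structural-aging tests:
    mortality improvement alone raises SO, a fertility-driven drop in r alone
    raises NSA.
    """
    if gap <= 0:
        raise ValidationError(f"gap must be positive, got {gap}")
    then = make_stable_population(
        StableStructure(r_then, make_life_table(model_then)), total=total, time=time_now - gap, weighting=weighting
    )
    now = make_stable_population(
        StableStructure(r_now, make_life_table(model_now)), total=total, time=time_now, weighting=weighting
    )
    return then, now


def perturb_counts(pop: PopulationSnapshot, sigma: float, seed: int | np.random.Generator) -> PopulationSnapshot:
    """Multiplicative log-normal noise per age; preserves non-negativity, reproducible by seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.lognormal(mean=0.0, sigma=sigma, size=len(pop.n))
    return PopulationSnapshot(time=pop.time, n=pop.n * noise, lifetable=pop.lifetable, label=pop.label)


# --- CSV fixture writers (mirror the reader dialect) -----------------------


def write_life_table_csv(lt: LifeTable, path: str | Path, *, location: str = "Synthetica", year: int = 2020) -> None:
    pd.DataFrame(
        {
            "Location": location,
            "Time": year,
            "AgeGrpStart": np.arange(lt.omega + 1),
            "lx": lt.l,
            "qx": lt.q,
            "ex": lt.e,
        }
    ).to_csv(path, index=False)


def write_population_csv(
    pop: PopulationSnapshot, path: str | Path, *, location: str | None = None, year: int | None = None
) -> None:
    pd.DataFrame(
        {
            "Location": location if location is not None else (pop.label or "Synthetica"),
            "Time": year if year is not None else pop.time,
            "AgeGrpStart": np.arange(pop.omega + 1),
            "PopTotal": pop.n,
        }
    ).to_csv(path, index=False)


def write_fixture_grid(
    out_dir: str | Path,
    *,
    seed: int = 0,
    models: list[GompertzMakeham] | None = None,
    rates: tuple[float, ...] = (-0.02, 0.0, 0.02),
    year: int = 2020,
    total: float = 1e6,
    noise_sigma: float = 0.0,
) -> list[Path]:
    """Write a deterministic grid of life-table and population fixtures.

    One life-table CSV per model and one population CSV per (model, r) cell;
    file contents depend only on the arguments and the seed.  Returns the
    written paths in a fixed order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if models is None:
        models = [
            GompertzMakeham(makeham=0.0, gompertz_a=1e-5, gompertz_b=0.1),
            GompertzMakeham(makeham=2e-3, gompertz_a=5e-5, gompertz_b=0.09),
        ]
    rng = np.random.default_rng(seed)
    written: list[Path] = []
    for i, model in enumerate(models):
        lt = make_life_table(model)
        lt_path = out_dir / f"lifetable_m{i}.csv"
        write_life_table_csv(lt, lt_path, location=f"Synthetica-{i}", year=year)
        written.append(lt_path)
        for r in rates:
            pop = make_stable_population(
                StableStructure(r, lt), total=total, time=year, label=f"Synthetica-{i}"
            )
            if noise_sigma > 0:
                pop = perturb_counts(pop, noise_sigma, rng)
            pop_path = out_dir / f"population_m{i}_r{r:+.3f}.csv"
            write_population_csv(pop, pop_path, location=f"Synthetica-{i}", year=year)
            written.append(pop_path)
    return written
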