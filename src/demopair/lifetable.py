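"""Period life tables and single-age population counts.

A period life table summarises the mortality regime of one calendar year as
if a synthetic cohort lived through it: ``l_x`` survivors to exact age x,
``q_x`` probability of dying in [x, x+1), ``d_x`` life-table deaths in that
interval, ``L_x`` person-years lived in it, and ``e_x`` remaining life
expectancy at age x.  Ages are integers on 0..omega with half-open one-year
intervals; the top age omega is absorbing (``q_omega = 1``).

The readers consume single-age CSV exports in the layout of the UN World
Population Prospects files (Location / Time / AgeGrpStart / lx / qx / ex and
Location / Time / AgeGrpStart / PopTotal), with configurable column names and
auto-detected delimiters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputNotFoundError, ValidationError

__all__ = [
    "LifeTable",
    "PopulationSnapshot",
    "complete_life_table",
    "read_life_table",
    "read_population",
    "LIFETABLE_COLUMNS",
    "POPULATION_COLUMNS",
]

#: canonical-name -> default CSV column header (UN WPP single-age dialect)
LIFETABLE_COLUMNS = {
    "location": "Location",
    "year": "Time",
    "age": "AgeGrpStart",
    "l": "lx",
    "q": "qx",
    "e": "ex",
}

POPULATION_COLUMNS = {
    "location": "Location",
    "year": "Time",
    "age": "AgeGrpStart",
    "count": "PopTotal",
}

#: default disagreement (years) between a provided and a derived e_x column
#: before a warning is recorded
E_CONFLICT_TOLERANCE = 0.5


@dataclass
class LifeTable:
    """A completed single-age period life table on ages 0..omega.

    All arrays have length ``omega + 1``.  ``radix`` is the l_0 scale
    (1.0 or 100000 are both common); every derived metric in the package is
    invariant to it.  ``a_omega`` is the mean fraction of the final year
    lived by those reaching omega, so ``L_omega = a_omega * l_omega``.
    """

    l: np.ndarray
    q: np.ndarray
    e: np.ndarray
    d: np.ndarray
    L: np.ndarray
    radix: float = 1.0
    a_omega: float = 0.5
    year: int | None = None
    location: str | None = None

    @property
    def omega(self) -> int:
        return len(self.l) - 1

    def validate(self) -> "LifeTable":
        """Check the structural invariants, naming the first offending age."""
        n = len(self.l)
        for name in ("q", "e", "d", "L"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"column {name!r} has length {len(getattr(self, name))}, expected {n}")
        if not (self.radix > 0):
            raise ValidationError(f"radix must be positive, got {self.radix}")
        if abs(self.l[0] - self.radix) > 1e-9 * self.radix:
            raise ValidationError(f"l_0 = {self.l[0]} does not equal the radix {self.radix}")
        bad = np.flatnonzero(np.diff(self.l) > 1e-12 * self.radix)
        if bad.size:
            x = int(bad[0])
            raise ValidationError(f"survivorship l increases between ages {x} and {x + 1} ({self.l[x]} -> {self.l[x + 1]})")
        bad = np.flatnonzero((self.q < 0) | (self.q > 1))
        if bad.size:
            x = int(bad[0])
            raise ValidationError(f"q out of [0, 1] at age {x}: {self.q[x]}")
        if self.q[-1] != 1.0:
            raise ValidationError(f"terminal q_omega must be 1, got {self.q[-1]}")
        if np.any(self.e < 0):
            x = int(np.flatnonzero(self.e < 0)[0])
            raise ValidationError(f"negative life expectancy at age {x}: {self.e[x]}")
        return self

    def with_expectancy_shift(self, years: float) -> "LifeTable":
        """Return a copy with every e_x shifted by a constant (testing aid)."""
        return replace(self, e=self.e + years)


def _l_from_q(q: np.ndarray, radix: float) -> np.ndarray:
    l = np.empty(len(q))
    l[0] = radix
    l[1:] = radix * np.cumprod(1.0 - q[:-1])
    return l


def _q_from_l(l: np.ndarray) -> np.ndarray:
    q = np.ones(len(l))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(l[:-1] > 0, l[1:] / l[:-1], 0.0)
    q[:-1] = 1.0 - frac
    q[-1] = 1.0  # omega is absorbing
    return np.clip(q, 0.0, 1.0)


def complete_life_table(
    l: np.ndarray | None = None,
    q: np.ndarray | None = None,
    e: np.ndarray | None = None,
    *,
    radix: float | None = None,
    a_omega: float = 0.5,
    year: int | None = None,
    location: str | None = None,
    e_tolerance: float = E_CONFLICT_TOLERANCE,
) -> LifeTable:
    """Close a partial life table into a fully populated :class:`LifeTable`.

    At least one of ``l`` or ``q`` must be given.  Derivations:

    * ``q_x = 1 - l_{x+1}/l_x`` with ``q_omega = 1``;
    * ``l`` from ``q`` by cumulative product of survival;
    * ``d_x = l_x - l_{x+1}`` (``d_omega = l_omega``);
    * ``L_x = (l_x + l_{x+1})/2`` for x < omega, ``L_omega = a_omega * l_omega``
      (midpoint rule, a_x = 0.5, the standard single-year convention);
    * ``e_x = (sum_{y >= x} L_y) / l_x``.

    A provided column always wins over a derived one; if a provided ``e``
    disagrees with the ``e`` derived from ``l`` by more than ``e_tolerance``
    years anywhere, a ``UserWarning`` is recorded and the provided values are
    kept (published expectancies reflect finer age detail than the midpoint
    rule can recover).
    """
    if l is None and q is None:
        raise ValidationError("cannot complete a life table: both l and q are absent")
    if l is not None:
        l = np.asarray(l, dtype=float)
        if radix is None:
            radix = float(l[0])
        if q is None:
            q = _q_from_l(l)
        else:
            q = np.asarray(q, dtype=float)
    else:
        q = np.asarray(q, dtype=float)
        bad = np.flatnonzero((q < 0) | (q > 1))
        if bad.size:
            x = int(bad[0])
            raise ValidationError(f"q out of [0, 1] at age {x}: {q[x]}")
        q = q.copy()
        q[-1] = 1.0
        if radix is None:
            radix = 1.0
        l = _l_from_q(q, radix)
    q = q.copy()
    q[-1] = 1.0

    l_next = np.append(l[1:], 0.0)
    d = l - l_next
    L = (l + l_next) / 2.0
    L[-1] = a_omega * l[-1]
    T = np.cumsum(L[::-1])[::-1]  # person-years above exact age x
    with np.errstate(divide="ignore", invalid="ignore"):
        e_derived = np.where(l > 0, T / np.where(l > 0, l, 1.0), 0.0)

    if e is not None:
        e = np.asarray(e, dtype=float)
        gap = np.max(np.abs(np.where(l > 0, e - e_derived, 0.0)))
        if gap > e_tolerance:
            warnings.warn(
                f"provided e_x disagrees with the value derived from l by up to {gap:.3f} years; "
                "keeping the provided column",
                UserWarning,
                stacklevel=2,
            )
    else:
        e = e_derived

    table = LifeTable(l=l, q=q, e=e, d=d, L=L, radix=float(radix), a_omega=a_omega, year=year, location=location)
    return table.validate()


@dataclass
class PopulationSnapshot:
    """Observed single-age population counts at one point in time.

    ``n[x]`` counts persons with completed age x; the top interval is
    open-ended and top-coded into omega by the reader.  The attached
    :class:`LifeTable` is the period table in force at ``time``.
    """

    time: int
    n: np.ndarray
    lifetable: LifeTable
    label: str = ""

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if len(self.n) != self.lifetable.omega + 1:
            raise ValidationError(
                f"population has {len(self.n)} ages but the life table spans 0..{self.lifetable.omega}"
            )
        neg = np.flatnonzero(self.n < 0)
        if neg.size:
            x = int(neg[0])
            raise ValidationError(f"negative count at age {x}: {self.n[x]}")
        if self.n.sum() <= 0:
            raise ValidationError("population total must be positive")

    @property
    def total(self) -> float:
        return float(self.n.sum())

    @property
    def omega(self) -> int:
        return self.lifetable.omega

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.omega + 1)


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputNotFoundError(f"input file not found: {path}")
    # sep=None sniffs among comma/semicolon/tab
    return pd.read_csv(path, sep=None, engine="python")


def _select_rows(
    frame: pd.DataFrame,
    colmap: dict[str, str],
    year: int | None,
    location: str | None,
    path: str | Path,
) -> pd.DataFrame:
    out = frame
    if year is not None and colmap["year"] in out.columns:
        out = out[out[colmap["year"]] == year]
    if location is not None and colmap["location"] in out.columns:
        out = out[out[colmap["location"]] == location]
    if out.empty:
        raise InputNotFoundError(f"no rows for year={year!r} location={location!r} in {path}")
    age_col = colmap["age"]
    if age_col not in out.columns:
        raise ValidationError(f"age column {age_col!r} missing from {path}")
    if out[age_col].duplicated().any():
        dup = sorted(out.loc[out[age_col].duplicated(), age_col].unique())
        raise ValidationError(f"duplicate ages {dup[:5]} for year={year!r} location={location!r} in {path}")
    return out.sort_values(age_col)


def read_life_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    year: int | None = None,
    location: str | None = None,
    *,
    omega: int = 100,
    a_omega: float = 0.5,
) -> LifeTable:
    """Read a single-age life table from a UN-WPP-like CSV.

    ``column_map`` overrides entries of :data:`LIFETABLE_COLUMNS` for other
    dialects.  The file must carry at least the age column and one of l / q;
    whatever is missing is derived via :func:`complete_life_table`.  Ages must
    cover 0..omega with no gaps; rows above omega are dropped (the terminal
    interval absorbs them through ``q_omega = 1``).
    """
    colmap = {**LIFETABLE_COLUMNS, **(column_map or {})}
    rows = _select_rows(_read_csv(path), colmap, year, location, path)
    ages = rows[colmap["age"]].to_numpy(dtype=int)
    rows = rows[ages <= omega]
    ages = ages[ages <= omega]
    expected = np.arange(omega + 1)
    if len(ages) != omega + 1 or not np.array_equal(ages, expected):
        missing = sorted(set(expected) - set(ages.tolist()))
        raise ValidationError(f"life table ages are not dense on 0..{omega}; missing {missing[:5]} in {path}")

    def _col(key: str) -> np.ndarray | None:
        name = colmap[key]
        if name in rows.columns:
            return rows[name].to_numpy(dtype=float)
        return None

    l, q, e = _col("l"), _col("q"), _col("e")
    if l is None and q is None:
        raise ValidationError(f"need at least one of columns {colmap['l']!r}, {colmap['q']!r} in {path}")
    return complete_life_table(l=l, q=q, e=e, a_omega=a_omega, year=year, location=location)


def read_population(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    year: int | None = None,
    location: str | None = None,
    *,
    lifetable: LifeTable,
    scale: float = 1.0,
) -> PopulationSnapshot:
    """Read single-age population counts and attach the period life table.

    Counts for ages above the table's omega are folded into age omega
    (the open-ended top interval); ages absent from the file get zero.
    ``scale`` converts the file's units (UN files are in thousands).
    """
    colmap = {**POPULATION_COLUMNS, **(column_map or {})}
    rows = _select_rows(_read_csv(path), colmap, year, location, path)
    ages = rows[colmap["age"]].to_numpy(dtype=int)
    count_col = colmap["count"]
    if count_col not in rows.columns:
        raise ValidationError(f"count column {count_col!r} missing from {path}")
    counts = rows[count_col].to_numpy(dtype=float)
    neg = np.flatnonzero(counts < 0)
    if neg.size:
        i = int(neg[0])
        raise ValidationError(f"negative count at age {ages[i]}: {counts[i]}")
    omega = lifetable.omega
    n = np.zeros(omega + 1)
    np.add.at(n, np.minimum(ages, omega), counts)
    n *= scale
    if year is None and colmap["year"] in rows.columns:
        year = int(rows[colmap["year"]].iloc[0])
    return PopulationSnapshot(time=int(year) if year is not None else 0, n=n, lifetable=lifetable, label=location or "")
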