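"""Conventional and structural population-aging metrics.

Conventional reference metrics: percent aged 65+ and the old-age dependency
ratio (population 65+ over population 15-64).  Structural metrics derived
from the binary population pair:

* mean age (life lived) and mean years remaining (life left);
* Lifespan Parity Ratio, LPR = mean years remaining / mean age — the
  keystone ratio, 1.0 at stationarity, above 1 for youthful populations;
* Stationarity Gap, SG — the dissimilarity index (half the summed absolute
  difference) between two normalized age-axis distributions, here between
  the chronological and thanatological structures;
* Terminal Dependency Ratio, TDR — expected deaths within five years
  relative to the population aged 20-64;
* Survival Offset, SO — the change in mean years remaining across a time
  interval; and Net Structural Aging, NSA = change in mean age minus SO,
  the portion of chronological aging not offset by survival gains.

Time conventions.  Mean age uses completed (integer) ages by default.  Mean
years remaining has three estimators: ``"expectancy"`` (counts weighted by
e_x, the published-table route), ``"matrix"`` (mean of the remaining-years
distribution from the cohort death matrix, in completed years), and
``"survivorship"`` (e_x weighted by l_x, which reproduces the stationary
value regardless of the observed structure).  Under the midpoint person-years
rule the matrix estimator equals the expectancy estimator minus exactly half
a year — the completed-years vs exact-age offset.  The LPR therefore uses the
matrix estimator by default so that numerator and denominator share the
completed-years convention and stationarity lands exactly on 1.0.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .deathmatrix import build_death_matrix, remaining_years_distribution
from .errors import ComputationError, ValidationError
from .lifetable import PopulationSnapshot
from .pair import AgeDistribution, BinaryPair, age_distribution

__all__ = [
    "MetricsRecord",
    "pct_over_65",
    "oadr",
    "mean_age",
    "mean_years_remaining",
    "lifespan_parity_ratio",
    "stationarity_gap",
    "remaining_years_gap",
    "structural_gap",
    "terminal_dependency_ratio",
    "five_year_deaths",
    "survival_offset",
    "net_structural_aging",
    "compute_all",
    "table1_frame",
]


def pct_over_65(pop: PopulationSnapshot) -> float:
    """Percent of the population aged 65 and older."""
    total = pop.total
    if total <= 0:
        raise ComputationError("empty population")
    return 100.0 * float(pop.n[65:].sum()) / total


def oadr(pop: PopulationSnapshot, *, percent: bool = False) -> float:
    """Old-age dependency ratio: population 65+ over population 15-64.

    Returned as a raw ratio; ``percent=True`` applies the x100 reporting
    convention used in published tables.
    """
    denom = float(pop.n[15:65].sum())
    if denom <= 0:
        raise ComputationError("no working-age (15-64) population")
    ratio = float(pop.n[65:].sum()) / denom
    return 100.0 * ratio if percent else ratio


def mean_age(pop: PopulationSnapshot, *, midpoint: bool = False) -> float:
    """Count-weighted mean age, in completed years (``midpoint=True`` adds 0.5)."""
    total = pop.total
    if total <= 0:
        raise ComputationError("empty population")
    a = float(pop.ages @ pop.n) / total
    return a + 0.5 if midpoint else a


def mean_years_remaining(pop: PopulationSnapshot, *, method: str = "expectancy") -> float:
    """Mean years of life remaining for the average individual.

    ``"expectancy"``: sum n_x e_x / N.  ``"matrix"``: mean of the
    remaining-years distribution (completed years; equals expectancy - 0.5
    under the midpoint rule).  ``"survivorship"``: sum l_x e_x / sum l_x,
    the stationary population's own value.
    """
    if pop.total <= 0:
        raise ComputationError("empty population")
    lt = pop.lifetable
    if method == "expectancy":
        return float(pop.n @ lt.e) / pop.total
    if method == "matrix":
        return remaining_years_distribution(build_death_matrix(pop)).mean()
    if method == "survivorship":
        return float(lt.l @ lt.e) / float(lt.l.sum())
    raise ValidationError(f"unknown method {method!r}")


def lifespan_parity_ratio(pop: PopulationSnapshot, *, method: str = "matrix") -> float:
    """Life left over life lived: mean years remaining / mean age.

    Above 1 the population is youthful (more future than past person-years),
    exactly 1 at stationarity, below 1 aged.  Defaults to the matrix
    estimator of the numerator so both sides count completed years.
    """
    a = mean_age(pop)
    if a <= 0:
        raise ComputationError("mean age is zero; LPR undefined")
    return mean_years_remaining(pop, method=method) / a


def stationarity_gap(p: AgeDistribution | np.ndarray, q: AgeDistribution | np.ndarray) -> float:
    """Dissimilarity index between two distributions on the same age axis.

    SG = 0.5 * sum_x |p_x/P - q_x/Q|, in [0, 1]: 0 for identical shapes,
    1 for disjoint supports.  Symmetric in its arguments.
    """
    pw = p if isinstance(p, AgeDistribution) else AgeDistribution(p)
    qw = q if isinstance(q, AgeDistribution) else AgeDistribution(q)
    if len(pw.weights) != len(qw.weights):
        raise ValidationError(f"distributions have different supports ({len(pw.weights)} vs {len(qw.weights)} ages)")
    return 0.5 * float(np.abs(pw.fractions - qw.fractions).sum())


def remaining_years_gap(pop: PopulationSnapshot) -> float:
    """SG between a population's age distribution and its remaining-years distribution.

    Zero iff the population is structurally stationary; the default Stationarity
    Gap reading (chronological vs thanatological structure of one population).
    """
    return stationarity_gap(age_distribution(pop), remaining_years_distribution(build_death_matrix(pop)))


def structural_gap(pair: BinaryPair) -> float:
    """SG between the observed and the stationary member's age distributions.

    The alternative reading: dissimilarity between the actual age structure
    and the stationary age structure of the same life table.  Both readings
    vanish exactly at stationarity but measure different departures away
    from it (the thanatological reading folds every cohort's projected death
    schedule in; this one compares standing structures only).
    """
    return stationarity_gap(age_distribution(pair.observed), age_distribution(pair.stationary))


def five_year_deaths(pop: PopulationSnapshot) -> np.ndarray:
    """Expected deaths per current age over the next five years.

    d5_x = n_x * (1 - prod_{i=0..4} (1 - q_{x+i})), with q = 1 beyond omega
    (the top age is absorbing) and annual mortality treated as independent.
    """
    lt = pop.lifetable
    q_ext = np.concatenate([lt.q, np.ones(5)])
    surv5 = np.array([np.prod(1.0 - q_ext[x : x + 5]) for x in range(lt.omega + 1)])
    return pop.n * (1.0 - surv5)


def terminal_dependency_ratio(pop: PopulationSnapshot) -> float:
    """Imminent-mortality burden: expected five-year deaths over population 20-64."""
    denom = float(pop.n[20:65].sum())
    if denom <= 0:
        raise ComputationError("no population aged 20-64; TDR undefined")
    return float(five_year_deaths(pop).sum()) / denom


def _check_interval(pop_then: PopulationSnapshot, pop_now: PopulationSnapshot) -> None:
    if pop_then.time >= pop_now.time:
        raise ValidationError(
            f"baseline time {pop_then.time} must precede comparison time {pop_now.time}"
        )


def survival_offset(
    pop_then: PopulationSnapshot, pop_now: PopulationSnapshot, *, method: str = "expectancy"
) -> float:
    """Change in mean years remaining across the interval (positive: farther from death)."""
    _check_interval(pop_then, pop_now)
    return mean_years_remaining(pop_now, method=method) - mean_years_remaining(pop_then, method=method)


def net_structural_aging(
    pop_then: PopulationSnapshot, pop_now: PopulationSnapshot, *, method: str = "expectancy"
) -> float:
    """Change in mean age minus the survival offset: unmitigated structural aging.

    Satisfies SO + NSA = (change in mean age) identically.
    """
    _check_interval(pop_then, pop_now)
    delta_a = mean_age(pop_now) - mean_age(pop_then)
    return delta_a - survival_offset(pop_then, pop_now, method=method)


@dataclass
class MetricsRecord:
    """The full metric suite for one population at one time."""

    label: str
    time: int
    e0: float
    mean_age: float
    mean_years_remaining: float
    lpr: float
    sg: float
    tdr: float
    oadr: float
    pct65: float
    so: float | None = None
    nsa: float | None = None
    stage: int | None = None
    stage_name: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def _record(pop: PopulationSnapshot, so: float | None, nsa: float | None) -> MetricsRecord:
    from .typology import classify_stage  # late import: typology is metric-free

    lpr = lifespan_parity_ratio(pop)
    stage = classify_stage(lpr)
    return MetricsRecord(
        label=pop.label,
        time=pop.time,
        e0=float(pop.lifetable.e[0]),
        mean_age=mean_age(pop),
        mean_years_remaining=mean_years_remaining(pop),
        lpr=lpr,
        sg=remaining_years_gap(pop),
        tdr=terminal_dependency_ratio(pop),
        oadr=oadr(pop),
        pct65=pct_over_65(pop),
        so=so,
        nsa=nsa,
        stage=int(stage),
        stage_name=stage.label,
    )


def compute_all(
    pair: BinaryPair, pair_then: BinaryPair | None = None
) -> tuple[MetricsRecord, MetricsRecord]:
    """Evaluate the whole metric suite for both members of a binary pair.

    Returns (observed record, stationary record).  When a baseline pair is
    supplied, SO and NSA are filled for each member against the matching
    member of the baseline; otherwise they are left absent.
    """
    if pair_then is not None and pair_then.observed.omega != pair.observed.omega:
        raise ValidationError("baseline pair has a different omega")

    def _so_nsa(then: PopulationSnapshot | None, now: PopulationSnapshot) -> tuple[float | None, float | None]:
        if then is None:
            return None, None
        return survival_offset(then, now), net_structural_aging(then, now)

    so_o, nsa_o = _so_nsa(pair_then.observed if pair_then else None, pair.observed)
    so_s, nsa_s = _so_nsa(pair_then.stationary if pair_then else None, pair.stationary)
    return _record(pair.observed, so_o, nsa_o), _record(pair.stationary, so_s, nsa_s)


_TABLE_ROWS = [
    ("Expectation of life at birth, e(0)", "e0", "{:.1f}"),
    ("Old Age Dependency Ratio (OADR)", "oadr", None),  # printed x100, handled below
    ("Percent 65 and older (%P65)", "pct65", "{:.1f}"),
    ("Mean Age", "mean_age", "{:.1f}"),
    ("Mean Years Remaining", "mean_years_remaining", "{:.1f}"),
    ("Lifespan Parity Ratio (LPR)", "lpr", "{:.2f}"),
    ("Terminal Dependency Ratio (TDR)", "tdr", "{:.4f}"),
    ("Stationarity Gap (SG)", "sg", "{:.4f}"),
    ("Survival Offset (SO)", "so", "{:.1f}"),
    ("Net Structural Aging (NSA)", "nsa", "{:.1f}"),
]


def table1_frame(
    observed: MetricsRecord, stationary: MetricsRecord, *, oadr_percent: bool = True
) -> pd.DataFrame:
    """Two-column (observed, stationary) table in the conventional report layout."""

    def _fmt(rec: MetricsRecord, attr: str, fmt: str | None) -> str:
        v = getattr(rec, attr)
        if v is None:
            return ""
        if attr == "oadr":
            return f"{100.0 * v:.1f}" if oadr_percent else f"{v:.3f}"
        return fmt.format(v)

    rows = [
        {"Metric": name, "Observed": _fmt(observed, attr, fmt), "Stationary": _fmt(stationary, attr, fmt)}
        for name, attr, fmt in _TABLE_ROWS
    ]
    return pd.DataFrame(rows)
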