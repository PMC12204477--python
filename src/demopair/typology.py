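"""The five-stage demographic succession typology.

Populations age through an ordered succession, from youth-heavy structures
through a youth-age crossover to age dominance.  Classification rests on a
single keystone metric, the Lifespan Parity Ratio (life left over life
lived), partitioned by fixed thresholds:

    Stage 1  Youth Dominance       LPR > 1.75
    Stage 2  Youth Descent         1.10 < LPR <= 1.75
    Stage 3  Youth-Age Crossover   0.90 < LPR <= 1.10
    Stage 4  Age Ascent            0.85 < LPR <= 0.90
    Stage 5  Age Dominance         LPR <= 0.85

The thresholds partition (0, inf) with no gaps or overlaps; boundaries are
upper-inclusive exactly as stated, with no epsilon snapping.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "Stage",
    "StageSummary",
    "CrossoverResult",
    "classify_stage",
    "find_crossover_year",
    "quadrant_label",
    "stage_summary",
    "stage_census_frame",
    "is_demographic_vortex",
]


class Stage(enum.IntEnum):
    """Succession stage, ordered from youngest structure to oldest."""

    YOUTH_DOMINANCE = 1
    YOUTH_DESCENT = 2
    YOUTH_AGE_CROSSOVER = 3
    AGE_ASCENT = 4
    AGE_DOMINANCE = 5

    @property
    def label(self) -> str:
        return _STAGE_LABELS[self]


_STAGE_LABELS = {
    Stage.YOUTH_DOMINANCE: "Youth Dominance",
    Stage.YOUTH_DESCENT: "Youth Descent",
    Stage.YOUTH_AGE_CROSSOVER: "Youth-Age Crossover",
    Stage.AGE_ASCENT: "Age Ascent",
    Stage.AGE_DOMINANCE: "Age Dominance",
}


def classify_stage(lpr: float) -> Stage:
    """Map a positive, finite Lifespan Parity Ratio to its succession stage."""
    if not math.isfinite(lpr) or lpr <= 0:
        raise ValidationError(f"LPR must be positive and finite, got {lpr}")
    if lpr > 1.75:
        return Stage.YOUTH_DOMINANCE
    if lpr > 1.10:
        return Stage.YOUTH_DESCENT
    if lpr > 0.90:
        return Stage.YOUTH_AGE_CROSSOVER
    if lpr > 0.85:
        return Stage.AGE_ASCENT
    return Stage.AGE_DOMINANCE


@dataclass(frozen=True)
class CrossoverResult:
    """A detected youth-age crossover in a (year, mean age, mean remaining) series."""

    year: int
    interpolated: float
    degenerate: bool = False  # mean age equalled mean remaining exactly at a grid year


def find_crossover_year(
    series: Sequence[tuple[float, float, float]] | pd.DataFrame,
) -> CrossoverResult | None:
    """Locate the first year where mean age reaches mean years remaining.

    ``series`` is an ordered sequence of (year, mean_age, mean_remaining)
    triples (or a DataFrame with those three columns, in order).  Returns the
    first grid year t with A_t >= R_t while A_{t-1} < R_{t-1}, alongside the
    linearly interpolated root of A - R between the bracketing years; None if
    the difference never reaches zero.  Exact equality at a grid year is a
    (degenerate) crossover at that year.
    """
    if isinstance(series, pd.DataFrame):
        arr = series.iloc[:, :3].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(series), dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 3 or arr.shape[0] < 2:
        raise ValidationError("series must hold at least two (year, mean_age, mean_remaining) points")
    years, diff = arr[:, 0], arr[:, 1] - arr[:, 2]
    if np.any(np.diff(years) <= 0):
        raise ValidationError("series must be strictly sorted by year")
    if diff[0] == 0.0:
        return CrossoverResult(year=int(years[0]), interpolated=float(years[0]), degenerate=True)
    for i in range(1, len(diff)):
        if diff[i] == 0.0:
            return CrossoverResult(year=int(years[i]), interpolated=float(years[i]), degenerate=True)
        if diff[i] > 0.0 and diff[i - 1] < 0.0:
            t0, t1 = years[i - 1], years[i]
            root = t0 + (t1 - t0) * (-diff[i - 1]) / (diff[i] - diff[i - 1])
            return CrossoverResult(year=int(years[i]), interpolated=float(root), degenerate=False)
    return None


def quadrant_label(so: float, nsa: float) -> str:
    """Label a (Survival Offset, Net Structural Aging) point by its quadrant.

    Negative SO with positive NSA is aging unmitigated by survival gains;
    both positive is partial mitigation; positive SO with negative NSA means
    survival gains outpaced the rise in mean age (structural rejuvenation).
    Exact zeros sit on a boundary and get the dedicated label
    ``"stationary-change"`` rather than an arbitrary quadrant.
    """
    if not (math.isfinite(so) and math.isfinite(nsa)):
        raise ValidationError(f"SO and NSA must be finite, got ({so}, {nsa})")
    if so == 0.0 or nsa == 0.0:
        return "stationary-change"
    if so < 0 and nsa > 0:
        return "unmitigated structural aging"
    if so > 0 and nsa > 0:
        return "partially mitigated aging"
    if so > 0 and nsa < 0:
        return "structural rejuvenation"
    return "other (lower-left)"


_SUMMARY_METRICS = ("lpr", "tdr", "sg", "so", "nsa")


@dataclass
class StageSummary:
    """Median and interquartile range of each metric within one stage."""

    stage: Stage
    count: int
    stats: dict[str, tuple[float, float, float]]  # metric -> (median, q25, q75)
    labels: list[str]


def stage_summary(records: Iterable, metrics: Sequence[str] = _SUMMARY_METRICS) -> list[StageSummary]:
    """Group metric records by succession stage and summarise each group.

    ``records`` are objects exposing ``lpr`` (classified on the fly) plus the
    requested metric attributes; ``None`` values are dropped per metric.
    Percentiles use linear interpolation.  Empty stages are reported with
    count 0 so the census always covers all five stages.
    """
    groups: dict[Stage, list] = {s: [] for s in Stage}
    for rec in records:
        groups[classify_stage(rec.lpr)].append(rec)
    out = []
    for stage in Stage:
        members = groups[stage]
        stats: dict[str, tuple[float, float, float]] = {}
        for m in metrics:
            vals = [getattr(r, m, None) for r in members]
            vals = np.array([v for v in vals if v is not None], dtype=float)
            if vals.size:
                med, q25, q75 = (float(np.percentile(vals, p)) for p in (50, 25, 75))
                stats[m] = (med, q25, q75)
        out.append(
            StageSummary(
                stage=stage,
                count=len(members),
                stats=stats,
                labels=[getattr(r, "label", "") for r in members],
            )
        )
    return out


def stage_census_frame(summaries: list[StageSummary], *, max_examples: int = 5) -> pd.DataFrame:
    """Stage census table: one row per stage with count and example members."""
    return pd.DataFrame(
        {
            "stage": [int(s.stage) for s in summaries],
            "stage_name": [s.stage.label for s in summaries],
            "count": [s.count for s in summaries],
            "examples": ["; ".join(s.labels[:max_examples]) for s in summaries],
        }
    )


def is_demographic_vortex(stages: Sequence[Stage | int]) -> bool:
    """Flag a series locked in Age Dominance at every supplied time point.

    A descriptive extrapolation of the post-successional condition (chronic
    Stage 5 with no recovery in the series); it is a flag on supplied
    history, not a projection, and reports are free to ignore it.
    """
    stages = list(stages)
    return bool(stages) and all(int(s) == int(Stage.AGE_DOMINANCE) for s in stages)
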