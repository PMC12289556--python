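"""Longitudinal trend and disruption analysis of pair co-occurrence counts.

A utilization shock (such as the 2022 pandemic-peak dip in chronic-care
claims) shows up as a year-over-year *relative* drop in pair co-occurrence
counts, followed by a rebound.  Relative change is used deliberately: pair
series span orders of magnitude, and a fixed relative threshold treats them
uniformly.  Partial calendar years (e.g. a final year covering only
January-June) are either excluded from change statistics or linearly scaled
up to a full-year estimate.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

__all__ = ["TrendSeries", "DisruptionReport", "annualize_partial", "detect_disruption"]


@dataclasses.dataclass(frozen=True)
class TrendSeries:
    """Yearly co-occurrence counts for one code pair.

    ``coverage`` maps each year to the observed fraction of that year in
    (0, 1] (1.0 = full year); ``estimated`` marks years whose count was
    scaled up from partial coverage.  Years must be contiguous.
    """

    pair: tuple[str, str]
    counts: dict[int, int]
    coverage: dict[int, float] = dataclasses.field(default_factory=dict)
    estimated: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", tuple(sorted(self.pair)))
        years = sorted(self.counts)
        if not years:
            raise ValueError("trend series needs at least one year")
        if years != list(range(years[0], years[-1] + 1)):
            raise ValueError(f"years must be contiguous, got {years}")
        for y, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count in {y}")
        cov = {y: float(self.coverage.get(y, 1.0)) for y in years}
        for y, f in cov.items():
            if not 0 < f <= 1:
                raise ValueError(f"coverage for {y} must be in (0, 1]: {f}")
        object.__setattr__(self, "coverage", cov)

    @property
    def years(self) -> list[int]:
        return sorted(self.counts)

    @property
    def partial_years(self) -> list[int]:
        return [y for y in self.years if self.coverage[y] < 1.0]


@dataclasses.dataclass(frozen=True)
class DisruptionReport:
    """Dip/rebound classification of one trend series.

    ``relative_changes[t]`` is (c_t - c_{t-1}) / c_{t-1}, defined only where
    both years are usable and the previous count is positive.  A dip year
    drops by at least the drop threshold; a rebound year rises by at least
    the rise threshold *after* some dip year.
    """

    pair: tuple[str, str]
    dip_years: tuple[int, ...]
    rebound_years: tuple[int, ...]
    relative_changes: dict[int, float]


def annualize_partial(series: TrendSeries, mode: str = "flag") -> TrendSeries:
    """Handle partially observed years.

    ``"flag"`` (default) leaves counts untouched; partial years are already
    identifiable from coverage and are excluded from change statistics
    downstream.  ``"scale"`` divides each partial year's count by its
    coverage, rounds to the nearest integer, marks the year as estimated, and
    sets coverage to 1.  With full coverage everywhere both modes return the
    series unchanged.
    """
    if mode not in ("flag", "scale"):
        raise ValueError(f"unknown mode: {mode!r}")
    if mode == "flag" or not series.partial_years:
        return series
    counts = dict(series.counts)
    estimated = set(series.estimated)
    for y in series.partial_years:
        counts[y] = int(round(counts[y] / series.coverage[y]))
        estimated.add(y)
    return TrendSeries(
        pair=series.pair,
        counts=counts,
        coverage={y: 1.0 for y in series.years},
        estimated=frozenset(estimated),
    )


def detect_disruption(
    series: TrendSeries,
    drop_threshold: float = 0.2,
    rise_threshold: float = 0.2,
) -> DisruptionReport:
    """Flag dip and rebound years from year-over-year relative changes.

    Partial-coverage years are excluded; scaled estimates (coverage restored
    to 1) participate.  Years following a zero count are skipped rather than
    producing infinite changes.

    Raises
    ------
    ValueError
        With fewer than 3 usable (full-coverage) years, or non-positive
        thresholds.
    """
    if drop_threshold <= 0 or rise_threshold <= 0:
        raise ValueError("thresholds must be positive")
    usable = [y for y in series.years if series.coverage[y] >= 1.0]
    if len(usable) < 3:
        raise ValueError(
            f"need at least 3 full-coverage years, have {len(usable)}"
        )
    changes: dict[int, float] = {}
    for y in usable:
        prev = y - 1
        if prev not in usable:
            continue
        c_prev = series.counts[prev]
        if c_prev == 0:
            continue
        changes[y] = (series.counts[y] - c_prev) / c_prev

    dips = tuple(y for y in sorted(changes) if changes[y] <= -drop_threshold)
    rebounds = tuple(
        y
        for y in sorted(changes)
        if changes[y] >= rise_threshold and any(d < y for d in dips)
    )
    return DisruptionReport(
        pair=series.pair,
        dip_years=dips,
        rebound_years=rebounds,
        relative_changes=changes,
    )
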