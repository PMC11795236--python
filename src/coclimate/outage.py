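"""Long power-outage episode detection and county-day flagging.

A county contributes power-outage (PO) analysis only if its outage feed
is *reliable*: providers reported >= 50% of expected intervals and the
reported customer base covered >= 50% of county customers (both
boundary inclusive). Within a reliable county, a qualifying episode is
a maximal run of consecutive readings with customers-out strictly above
0.5% of county customers, lasting >= 8 hours. Readings are interval
censored, so a run's duration is right-extended by one reporting
interval (8 consecutive hourly exceedances = 8 h). Missing intervals
are treated as service restored (conservative; a gap-tolerance knob
exists for sensitivity analysis). A county-day is flagged when its
[00:00, 24:00) window intersects an episode's [start, end) span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "OutageSeries",
    "ReliabilityError",
    "assess_reliability",
    "detect_episodes",
    "episodes_to_county_days",
]

EPISODE_COLUMNS = ["county", "start", "end", "duration_h", "peak_fraction"]


def empty_episodes() -> pd.DataFrame:
    """Typed empty episode frame (safe to concatenate)."""
    return pd.DataFrame(
        {
            "county": pd.Series(dtype=str),
            "start": pd.Series(dtype="datetime64[ns]"),
            "end": pd.Series(dtype="datetime64[ns]"),
            "duration_h": pd.Series(dtype=float),
            "peak_fraction": pd.Series(dtype=float),
        }
    )


class ReliabilityError(ValueError):
    """Raised when episode detection is attempted on an excluded county."""


@dataclass
class OutageSeries:
    """Timestamped customers-without-power counts for one county.

    ``records`` has columns ``timestamp`` (strictly increasing) and
    ``customers_out``; ``reporting_fraction`` is the share of expected
    reporting intervals actually present, and ``coverage_fraction`` the
    maximum reported customers divided by the county customer total.
    """

    county: str
    records: pd.DataFrame
    customers_total: int
    reporting_fraction: float = 1.0
    coverage_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.customers_total <= 0:
            raise ValueError(f"county {self.county}: customers_total must be > 0")
        for name in ("reporting_fraction", "coverage_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"county {self.county}: {name}={v} outside [0, 1]")
        rec = self.records
        if list(rec.columns[:2]) != ["timestamp", "customers_out"] and not {
            "timestamp",
            "customers_out",
        }.issubset(rec.columns):
            raise ValueError(
                f"county {self.county}: records need timestamp/customers_out columns"
            )
        ts = pd.to_datetime(rec["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError(
                f"county {self.county}: timestamps must be strictly increasing"
            )
        out = rec["customers_out"].to_numpy()
        if (out < 0).any() or (out > self.customers_total).any():
            raise ValueError(
                f"county {self.county}: customers_out outside [0, customers_total]"
            )
        self.records = pd.DataFrame(
            {"timestamp": ts, "customers_out": out.astype(np.int64)}
        )


def assess_reliability(
    series: Iterable[OutageSeries],
    min_reporting: float = 0.5,
    min_coverage: float = 0.5,
) -> tuple[set[str], dict[str, str]]:
    """Split counties into the reliable set and an exclusion-reason map.

    A county is reliable iff ``reporting_fraction >= min_reporting`` AND
    ``coverage_fraction >= min_coverage`` (both inclusive, matching the
    >= 50% inclusion rules). Excluded counties map to a reason code
    ``"low_reporting"`` or ``"low_coverage"`` (reporting checked first).
    """
    reliable: set[str] = set()
    excluded: dict[str, str] = {}
    for s in series:
        if s.reporting_fraction < min_reporting:
            excluded[s.county] = "low_reporting"
        elif s.coverage_fraction < min_coverage:
            excluded[s.county] = "low_coverage"
        else:
            reliable.add(s.county)
    return reliable, excluded


def _infer_interval(ts: pd.Series) -> pd.Timedelta:
    diffs = ts.diff().dropna()
    if diffs.empty:
        return pd.Timedelta(hours=1)
    return diffs.median()


def detect_episodes(
    series: OutageSeries,
    pct_threshold: float = 0.005,
    min_hours: float = 8.0,
    interval: pd.Timedelta | None = None,
    gap_tolerance: int = 0,
    reliable_counties: set[str] | None = None,
) -> pd.DataFrame:
    """Detect qualifying long-outage episodes in one county's series.

    An exceedance reading has ``customers_out > pct_threshold *
    customers_total`` (strict). Maximal runs of consecutive exceedance
    readings — broken by any non-exceeding reading, or by a timestamp
    gap of more than ``(1 + gap_tolerance)`` reporting intervals
    (missing readings count as restored) — are emitted when their
    duration, ``last exceedance - first exceedance + one interval``,
    is >= ``min_hours``.

    ``reliable_counties``, when given, guards the inclusion rule: a
    county outside the set raises :class:`ReliabilityError`.
    Returns a frame ``county, start, end, duration_h, peak_fraction``
    with ``end`` exclusive (start + duration).
    """
    if reliable_counties is not None and series.county not in reliable_counties:
        raise ReliabilityError(
            f"county {series.county} lacks reliable outage data; episode "
            "detection is undefined for it"
        )
    rec = series.records
    if rec.empty:
        return empty_episodes()
    ts = rec["timestamp"]
    if interval is None:
        interval = _infer_interval(ts)
    exceed = rec["customers_out"].to_numpy() > pct_threshold * series.customers_total
    idx = np.flatnonzero(exceed)
    if idx.size == 0:
        return empty_episodes()

    tvals = ts.to_numpy()
    max_gap = interval * (1 + gap_tolerance)
    # split exceedance indices into runs: break on an intervening
    # non-exceeding reading or a reporting gap larger than max_gap
    breaks = np.flatnonzero(
        (np.diff(idx) > 1) | (np.diff(tvals[idx]) > max_gap.to_timedelta64())
    )
    runs = np.split(idx, breaks + 1)

    frac = rec["customers_out"].to_numpy() / series.customers_total
    rows = []
    for run in runs:
        start = ts.iloc[run[0]]
        end = ts.iloc[run[-1]] + interval
        duration_h = (end - start) / pd.Timedelta(hours=1)
        if duration_h >= min_hours:
            rows.append(
                (series.county, start, end, float(duration_h), float(frac[run].max()))
            )
    return pd.DataFrame(rows, columns=EPISODE_COLUMNS)


def episodes_to_county_days(episodes: pd.DataFrame) -> pd.DataFrame:
    """Flag every calendar date whose day window intersects an episode.

    A date d is flagged for a county when [d 00:00, d+1 00:00)
    intersects the episode's [start, end) span; a multi-day episode
    flags every intersected date. Returns a distinct ``county, date``
    frame.
    """
    if episodes.empty:
        return pd.DataFrame(columns=["county", "date"])
    rows = []
    for county, start, end in episodes[["county", "start", "end"]].itertuples(
        index=False
    ):
        start = pd.Timestamp(start)
        # end is exclusive: an episode ending exactly at midnight does
        # not touch the following day
        last_day = (pd.Timestamp(end) - pd.Timedelta(nanoseconds=1)).normalize()
        for d in pd.date_range(start.normalize(), last_day, freq="D"):
            rows.append((county, d))
    flags = pd.DataFrame(rows, columns=["county", "date"]).drop_duplicates()
    return flags.sort_values(["county", "date"]).reset_index(drop=True)
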